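table_name,glandularity_pct,thickness_mm,hvl_mm_al,anode,filter,age_group,role,value
g,,20,0.3,,,,,0.390
g,,20,0.5,,,,,0.541
g,,20,0.8,,,,,0.683
g,,30,0.3,,,,,0.273
g,,30,0.5,,,,,0.405
g,,30,0.8,,,,,0.555
g,,40,0.3,,,,,0.207
g,,40,0.5,,,,,0.319
g,,40,0.8,,,,,0.460
g,,50,0.3,,,,,0.165
g,,50,0.5,,,,,0.259
g,,50,0.8,,,,,0.388
g,,60,0.3,,,,,0.136
g,,60,0.5,,,,,0.215
g,,60,0.8,,,,,0.333
g,,70,0.3,,,,,0.115
g,,70,0.5,,,,,0.182
g,,70,0.8,,,,,0.289
g,,80,0.3,,,,,0.099
g,,80,0.5,,,,,0.157
g,,80,0.8,,,,,0.254
g,,90,0.3,,,,,0.0868
g,,90,0.5,,,,,0.138
g,,90,0.8,,,,,0.226
g,,100,0.3,,,,,0.0774
g,,100,0.5,,,,,0.123
g,,100,0.8,,,,,0.204
g,,110,0.3,,,,,0.0699
g,,110,0.5,,,,,0.112
g,,110,0.8,,,,,0.186
c,100,20,0.3,,,,,0.863
c,100,20,0.5,,,,,0.885
c,100,20,0.8,,,,,0.917
c,72,30,0.3,,,,,0.923
c,72,30,0.5,,,,,0.935
c,72,30,0.8,,,,,0.952
c,50,40,0.3,,,,,0.998
c,50,40,0.5,,,,,1.00
c,50,40,0.8,,,,,1.00
c,33,50,0.3,,,,,1.08
c,33,50,0.5,,,,,1.07
c,33,50,0.8,,,,,1.06
c,21,60,0.3,,,,,1.15
c,21,60,0.5,,,,,1.13
c,21,60,0.8,,,,,1.11
c,12,70,0.3,,,,,1.21
c,12,70,0.5,,,,,1.19
c,12,70,0.8,,,,,1.15
c,7,80,0.3,,,,,1.26
c,7,80,0.5,,,,,1.23
c,7,80,0.8,,,,,1.18
c,4,90,0.3,,,,,1.29
c,4,90,0.5,,,,,1.26
c,4,90,0.8,,,,,1.21
c,3,100,0.3,,,,,1.31
c,3,100,0.5,,,,,1.28
c,3,100,0.8,,,,,1.22
c,3,110,0.3,,,,,1.32
c,3,110,0.5,,,,,1.29
c,3,110,0.8,,,,,1.23
c,94.4,23,0.380,,,<50,dance,0.882
c,46.2,23,0.380,,,<50,volpara,1.012
c,77.4,32.5,0.380,,,<50,dance,0.909
c,37,32.5,0.380,,,<50,volpara,1.047
c,58.3,44.5,0.397,,,<50,dance,0.967
c,30.2,44.5,0.397,,,<50,volpara,1.083
c,44.8,53.5,0.414,,,<50,dance,1.021
c,23.1,53.5,0.414,,,<50,volpara,1.121
c,32.9,62,0.430,,,<50,dance,1.077
c,17.9,62,0.430,,,<50,volpara,1.153
c,18.6,75,0.459,,,<50,dance,1.157
c,12.6,75,0.459,,,<50,volpara,1.193
c,6.2,90,0.459,,,<50,dance,1.249
c,9.8,90,0.459,,,<50,volpara,1.223
c,91.1,23,0.380,,,>=50,dance,0.890
c,47.4,23,0.380,,,>=50,volpara,1.009
c,66.4,32.5,0.380,,,>=50,dance,0.944
c,28.5,32.5,0.380,,,>=50,volpara,1.080
c,42.9,44.5,0.397,,,>=50,dance,1.028
c,16.9,44.5,0.397,,,>=50,volpara,1.145
c,29.1,53.5,0.414,,,>=50,dance,1.092
c,12.4,53.5,0.414,,,>=50,volpara,1.177
c,19.0,62,0.430,,,>=50,dance,1.147
c,10.9,62,0.430,,,>=50,volpara,1.192
c,9.2,75,0.459,,,>=50,dance,1.214
c,9.6,75,0.459,,,>=50,volpara,1.212
c,3.5,90,0.459,,,>=50,dance,1.270
c,9.4,90,0.459,,,>=50,volpara,1.226
s,,,,Mo,Mo,,,1.000
s,,,,Mo,Rh,,,1.017
s,,,,Rh,Rh,,,1.061
s,,,,Rh,Al,,,1.044
s,,,,W,Rh,,,1.042
s,,,,W,Ag,,,1.042
glandularity,100,20,,,,50-64,,100
glandularity,72,30,,,,50-64,,72
glandularity,50,40,,,,50-64,,50
glandularity,33,50,,,,50-64,,33
glandularity,21,60,,,,50-64,,21
glandularity,12,70,,,,50-64,,12
glandularity,7,80,,,,50-64,,7
glandularity,4,90,,,,50-64,,4
glandularity,3,100,,,,50-64,,3
glandularity,3,110,,,,50-64,,3
glandularity,94.4,23,,,,40-49,,94.4
glandularity,77.4,32.5,,,,40-49,,77.4
glandularity,58.3,44.5,,,,40-49,,58.3
glandularity,44.8,53.5,,,,40-49,,44.8
glandularity,32.9,62,,,,40-49,,32.9
glandularity,18.6,75,,,,40-49,,18.6
glandularity,6.2,90,,,,40-49,,6.2
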