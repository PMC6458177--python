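"""Factor-table loading, node fidelity, interpolation and range handling."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammodose.factor_tables import (
    AgeGroupPolicy,
    FactorRangeError,
    FactorTableError,
    FactorTables,
    SpectrumLookupError,
    load_factor_tables,
)

# Printed g-factor grid: {thickness: (g@0.3, g@0.5, g@0.8 mm Al)}.
G_TABLE = {
    20: (0.390, 0.541, 0.683),
    30: (0.273, 0.405, 0.555),
    40: (0.207, 0.319, 0.460),
    50: (0.165, 0.259, 0.388),
    60: (0.136, 0.215, 0.333),
    70: (0.115, 0.182, 0.289),
    80: (0.099, 0.157, 0.254),
    90: (0.0868, 0.138, 0.226),
    100: (0.0774, 0.123, 0.204),
    110: (0.0699, 0.112, 0.186),
}

# Printed c-factor grid and the 50-64 age-group glandularity per thickness.
C_TABLE = {
    20: (100, 0.863, 0.885, 0.917),
    30: (72, 0.923, 0.935, 0.952),
    40: (50, 0.998, 1.00, 1.00),
    50: (33, 1.08, 1.07, 1.06),
    60: (21, 1.15, 1.13, 1.11),
    70: (12, 1.21, 1.19, 1.15),
    80: (7, 1.26, 1.23, 1.18),
    90: (4, 1.29, 1.26, 1.21),
    100: (3, 1.31, 1.28, 1.22),
    110: (3, 1.32, 1.29, 1.23),
}

HVLS = (0.3, 0.5, 0.8)


@pytest.mark.parametrize("thickness", sorted(G_TABLE))
def test_g_factor_exact_at_grid_nodes(tables, thickness):
    for hvl, expected in zip(HVLS, G_TABLE[thickness]):
        assert tables.g(thickness, hvl) == expected


@pytest.mark.parametrize("thickness", sorted(C_TABLE))
def test_c_factor_exact_at_grid_nodes(tables, thickness):
    gland = C_TABLE[thickness][0]
    for hvl, expected in zip(HVLS, C_TABLE[thickness][1:]):
        assert tables.c(gland, thickness, hvl) == expected


@pytest.mark.parametrize("thickness", sorted(C_TABLE))
def test_glandularity_exact_at_thickness_nodes(tables, thickness):
    assert tables.dance_glandularity(55.0, thickness) == C_TABLE[thickness][0]


def test_g_bilinear_between_nodes_matches_hand_oracle(tables):
    # midway in thickness at an HVL node: plain average of the two rows
    assert tables.g(45, 0.5) == pytest.approx((0.259 + 0.319) / 2, abs=1e-12)
    # bilinear in both axes: average the four surrounding nodes appropriately
    t_lo, t_hi = G_TABLE[40], G_TABLE[50]
    wh = (0.4 - 0.3) / (0.5 - 0.3)
    expected = 0.5 * ((1 - wh) * t_lo[0] + wh * t_lo[1]) + 0.5 * (
        (1 - wh) * t_hi[0] + wh * t_hi[1]
    )
    assert tables.g(45, 0.4) == pytest.approx(expected, abs=1e-12)


def test_g_monotone_over_grid(tables):
    ts = sorted(G_TABLE)
    for hvl in HVLS:
        vals = [tables.g(t, hvl) for t in ts]
        assert all(a > b for a, b in zip(vals, vals[1:])), "g must fall with thickness"
    for t in ts:
        vals = [tables.g(t, h) for h in HVLS]
        assert all(a < b for a, b in zip(vals, vals[1:])), "g must rise with HVL"


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    t=st.floats(20, 110),
    hvl=st.floats(0.3, 0.8),
)
def test_g_interpolation_bounded_by_bracketing_nodes(tables, t, hvl):
    ts = np.array(sorted(G_TABLE))
    hs = np.array(HVLS)
    i = np.clip(np.searchsorted(ts, t) - 1, 0, len(ts) - 2)
    j = np.clip(np.searchsorted(hs, hvl) - 1, 0, len(hs) - 2)
    corners = [
        G_TABLE[ts[i + a]][j + b] for a in (0, 1) for b in (0, 1)
    ]
    val = tables.g(float(t), float(hvl))
    assert min(corners) - 1e-12 <= val <= max(corners) + 1e-12


def test_c_paired_points_exact(tables):
    # isolated printed c points (population vs personalized glandularity pairs)
    assert tables.c(46.2, 23, 0.380) == 1.012
    assert tables.c(94.4, 23, 0.380) == 0.882
    assert tables.c(94.4, 23, 0.380) < tables.c(46.2, 23, 0.380)
    assert tables.c(47.4, 23, 0.380) == 1.009
    assert tables.c(9.4, 90, 0.459) == 1.226


def test_c_near_unity_at_50pct_node(tables):
    for hvl in HVLS:
        assert tables.c(50, 40, hvl) == pytest.approx(1.0, abs=0.002 + 1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    t=st.floats(20, 110),
    hvl=st.floats(0.3, 0.8),
    g_lo=st.floats(1, 99),
    delta=st.floats(0.5, 40),
)
def test_c_decreasing_in_glandularity(tables, t, hvl, g_lo, delta):
    g_hi = min(g_lo + delta, 100.0)
    c_lo = tables.c(float(g_lo), float(t), float(hvl))
    c_hi = tables.c(float(g_hi), float(t), float(hvl))
    assert c_hi <= c_lo + 1e-12


def test_c_clamps_beyond_outermost_anchors(tables):
    # below every tabulated glandularity at this thickness: end-anchor value
    before = tables.clamp_warnings
    v0 = tables.c(0.0, 100, 0.5)
    v1 = tables.c(1.0, 100, 0.5)
    assert tables.clamp_warnings > before
    assert v0 == v1  # constant on the clamped stretch


def test_range_errors_identify_axis(tables):
    with pytest.raises(FactorRangeError, match="thickness_mm"):
        tables.g(15, 0.5)
    with pytest.raises(FactorRangeError, match="hvl_mm_al"):
        tables.g(50, 0.9)
    with pytest.raises(FactorRangeError, match="thickness_mm"):
        tables.c(50, 130, 0.5)
    with pytest.raises(FactorRangeError):
        tables.c(120, 50, 0.5)
    with pytest.raises(FactorRangeError, match="thickness_mm"):
        tables.dance_glandularity(50, 10)


def test_s_factor_lookup(tables):
    assert tables.s("Mo", "Mo") == 1.0
    assert tables.s("Rh", "Rh") > 1.0
    assert tables.s("MOLYBDENUM", "RHODIUM") == tables.s("Mo", "Rh")
    with pytest.raises(SpectrumLookupError, match="Mo"):
        tables.s("W", "unobtainium")


def test_dance_glandularity_age_groups_and_interpolation(tables):
    assert tables.dance_glandularity(55, 30) == 72
    # neighbour substitution: >= 65 uses the 50-64 profile
    assert tables.dance_glandularity(70, 30) == 72
    # hand-computed linear interpolation between the 20 and 30 mm rows
    assert tables.dance_glandularity(55, 25) == pytest.approx(86.0)
    # younger group has its own (flatter-topped) profile
    assert tables.dance_glandularity(35, 44.5) == pytest.approx(58.3)
    assert tables.dance_glandularity(45, 44.5) == tables.dance_glandularity(35, 44.5)


def test_age_policy_validation():
    policy = AgeGroupPolicy(bounds=(45.0, 130.0), labels=("40-49", "50-64"))
    assert policy.group_for(44) == "40-49"
    assert policy.group_for(45) == "50-64"
    with pytest.raises(FactorTableError):
        policy.group_for(-1)
    with pytest.raises(FactorTableError):
        AgeGroupPolicy(bounds=(50.0,), labels=("a", "b"))


def _default_frame():
    import importlib.resources

    ref = importlib.resources.files("mammodose.data") / "dance_factors.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def test_load_rejects_nonpositive_factor():
    frame = _default_frame()
    frame.loc[frame.table_name == "g", "value"] = -0.1
    with pytest.raises(FactorTableError, match="non-positive"):
        FactorTables(frame)


def test_load_rejects_missing_axis():
    frame = _default_frame()
    frame.loc[frame.table_name == "g", "hvl_mm_al"] = np.nan
    with pytest.raises(FactorTableError, match="hvl_mm_al"):
        FactorTables(frame)


def test_load_rejects_missing_table_and_bad_path():
    frame = _default_frame()
    with pytest.raises(FactorTableError, match="'s'"):
        FactorTables(frame[frame.table_name != "s"])
    with pytest.raises(FactorTableError, match="not found"):
        load_factor_tables("/nonexistent/factors.csv")


def test_user_override_roundtrip(tmp_path):
    frame = _default_frame()
    path = tmp_path / "factors.csv"
    frame.to_csv(path, index=False)
    t = load_factor_tables(str(path))
    assert t.g(40, 0.5) == 0.319


def test_constant_dgn_table(tables):
    t = tables.with_dgn(0.15)
    assert t.dgn(50, 50, 0.4, "Mo", "Mo") == 0.15
    with pytest.raises(FactorTableError, match="DgN"):
        tables.dgn(50, 50, 0.4, "Mo", "Mo")
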