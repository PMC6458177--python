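"""Cohort-level comparison of the three AGD estimates.

Reproduces the analysis stage of a dosimetric model comparison: pairwise
AGD-ratio summaries stratified by breast-thickness class, density-category
distributions for the population vs the personalized glandularity estimate,
an OLS regression of measured glandularity on age and thickness, and Pearson
correlations of the ratios with covariates.

The stage is exposed both as plain functions and as a model object:

>>> model = AGDComparison.from_dataframe(frame, tables=tables)
>>> results = model.fit()
>>> print(results.summary())
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import cohort_to_frame, read_cohort
from .dosimetry import DosimetryConfig, compute_agd_table
from .factor_tables import FactorTables, load_factor_tables

logger = logging.getLogger(__name__)

__all__ = [
    "THICKNESS_CLASSES",
    "RegressionResult",
    "AGDComparison",
    "AGDComparisonResults",
    "thickness_class",
    "summarize_ratios",
    "density_categories",
    "fit_glandularity_regression",
    "ratio_covariate_correlation",
]

#: Thickness class labels (mm, integer binning as printed on report tables).
THICKNESS_CLASSES = ("20-40", "41-60", "61-80", ">80")

RATIO_COLUMNS = ("dance_over_volpara", "wu_over_volpara", "dance_over_wu")


def thickness_class(thickness_mm: float) -> str:
    """Assign a thickness to its class; fractional mm are rounded first.

    Values below 20 mm fall outside the tabulated classes and are assigned
    to 20-40 with a warning.
    """
    t = int(round(thickness_mm))
    if t < 20:
        logger.warning("thickness %.1f mm below the 20 mm class floor; "
                       "assigned to 20-40", thickness_mm)
        return "20-40"
    if t <= 40:
        return "20-40"
    if t <= 60:
        return "41-60"
    if t <= 80:
        return "61-80"
    return ">80"


def summarize_ratios(triples: pd.DataFrame) -> pd.DataFrame:
    """Stratified N/min/max/mean/SD of each AGD ratio by thickness class.

    ``triples`` needs the three ratio columns plus ``thickness_mm``.  The SD
    uses the sample (n-1) denominator; single-record classes report SD 0.
    Class order and ratio order follow the report-table layout.
    """
    if len(triples) == 0:
        raise ValueError("cannot summarize an empty ratio table")
    if "thickness_mm" not in triples:
        raise ValueError("ratio table lacks a thickness_mm column")
    frame = triples.copy()
    frame["thickness_class"] = [thickness_class(t) for t in frame.thickness_mm]
    rows = []
    for cls in THICKNESS_CLASSES:
        sub = frame[frame.thickness_class == cls]
        for ratio in RATIO_COLUMNS:
            if len(sub) == 0:
                continue
            vals = sub[ratio].to_numpy(float)
            rows.append({
                "thickness_class": cls,
                "ratio": ratio,
                "n": len(vals),
                "min": vals.min(),
                "max": vals.max(),
                "mean": vals.mean(),
                "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
            })
    return pd.DataFrame(rows)


#: Vendor-style volumetric-density-grade cutpoints (% VBD), selectable with
#: ``bins="vendor"``; the default categorization is by glandularity quartiles.
VENDOR_DENSITY_BINS = (0.0, 4.5, 7.5, 15.5, 100.0)


def density_categories(
    glandularities, bins=(0.0, 25.0, 50.0, 75.0, 100.0)
) -> np.ndarray:
    """Counts per density category defined by glandularity quartile bins.

    Category k covers (bins[k-1], bins[k]]; boundary values go to the lower
    bin, except exact 0 which goes to category 1.  ``bins="vendor"`` selects
    the vendor-style volumetric-grade cutpoints instead of quartiles.
    """
    if isinstance(bins, str):
        if bins != "vendor":
            raise ValueError(f"unknown bin preset {bins!r}")
        bins = VENDOR_DENSITY_BINS
    values = np.asarray(list(glandularities), dtype=float)
    if values.size and (values.min() < bins[0] or values.max() > bins[-1]):
        raise ValueError("glandularity values outside the bin range")
    # right-closed bins; 0 included in the first
    counts, _ = np.histogram(values, bins=np.asarray(bins))
    # np.histogram is left-closed: move boundary values down one bin
    for k, edge in enumerate(bins[1:-1], start=1):
        on_edge = int(np.count_nonzero(values == edge))
        counts[k] -= on_edge
        counts[k - 1] += on_edge
    return counts


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of glandularity on age and thickness."""

    intercept: float
    age_coef: float
    thickness_coef: float
    intercept_se: float
    age_se: float
    thickness_se: float
    r_squared: float
    anova_p: float
    n: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def fit_glandularity_regression(frame: pd.DataFrame) -> RegressionResult:
    """OLS of ``Glandularity = c + a*age + b*thickness`` with SEs, R², ANOVA p.

    ``frame`` needs columns ``age``, ``thickness_mm`` and ``volpara_gpw``.
    """
    required = {"age", "thickness_mm", "volpara_gpw"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"regression input lacks column(s): {sorted(missing)}")
    sub = frame[list(required)].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete records for the regression")
    X = sm.add_constant(sub[["age", "thickness_mm"]].to_numpy(float), has_constant="add")
    y = sub["volpara_gpw"].to_numpy(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design (constant covariates?)")
    fit = sm.OLS(y, X).fit()
    degenerate = float(np.sum((y - y.mean()) ** 2)) == 0.0
    return RegressionResult(
        intercept=float(fit.params[0]),
        age_coef=float(fit.params[1]),
        thickness_coef=float(fit.params[2]),
        intercept_se=float(fit.bse[0]),
        age_se=float(fit.bse[1]),
        thickness_se=float(fit.bse[2]),
        r_squared=0.0 if degenerate else float(fit.rsquared),
        anova_p=1.0 if degenerate else float(fit.f_pvalue),
        n=int(fit.nobs),
    )


def ratio_covariate_correlation(
    triples: pd.DataFrame, ratio: str, covariate: str
) -> tuple[float, float]:
    """Pearson r (with two-sided p) between an AGD ratio and a covariate."""
    if ratio not in triples.columns or covariate not in triples.columns:
        raise ValueError(f"columns {ratio!r}/{covariate!r} not in the ratio table")
    sub = triples[[ratio, covariate]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    x = sub[covariate].to_numpy(float)
    y = sub[ratio].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance on one side")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# --------------------------------------------------------------------------
# Model / Results objects


class AGDComparison:
    """Dose-comparison model over a cohort of exposure records.

    Built from a cohort DataFrame (or a cohort CSV); ``fit`` runs the
    per-exposure dosimetry and the cohort-level analysis and returns an
    :class:`AGDComparisonResults`.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        tables: FactorTables | None = None,
        config: DosimetryConfig | None = None,
    ):
        if len(frame) == 0:
            raise ValueError("empty cohort")
        self.frame = frame.reset_index(drop=True)
        self.tables = tables or load_factor_tables("default")
        self.config = config or DosimetryConfig(wu_mode="compute")
        if self.config.wu_mode == "compute" and self.tables.dgn_table is None:
            from .dosimetry import dance_equivalent_dgn

            self.tables = self.tables.with_dgn(dance_equivalent_dgn(self.tables))

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "AGDComparison":
        return cls(frame, **kwargs)

    @classmethod
    def from_records(cls, records, **kwargs) -> "AGDComparison":
        return cls(cohort_to_frame(records), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "AGDComparison":
        return cls.from_records(read_cohort(path), **kwargs)

    def fit(self) -> "AGDComparisonResults":
        records = _records_from_frame(self.frame)
        agd_table, skipped = compute_agd_table(records, self.tables, self.config)
        if len(agd_table) == 0:
            raise ValueError("no record produced a complete AGD triple")
        summary = summarize_ratios(agd_table)

        regression = None
        if "volpara_gpw" in self.frame and self.frame.volpara_gpw.notna().any():
            try:
                regression = fit_glandularity_regression(self.frame)
            except ValueError as exc:
                logger.info("glandularity regression skipped: %s", exc)

        dance_gland = [
            self.tables.dance_glandularity(r.age, r.thickness_mm,
                                           policy=self.config.age_policy)
            for r in records
            if r.age is not None and r.thickness_mm is not None
        ]
        volpara_gland = (
            self.frame.volpara_gpw.dropna().tolist()
            if "volpara_gpw" in self.frame else []
        )
        categories = pd.DataFrame(
            {
                "category": [1, 2, 3, 4],
                "dance": density_categories(dance_gland),
                "volpara": density_categories(volpara_gland),
            }
        )

        correlations = {}
        for ratio in RATIO_COLUMNS:
            for covariate in ("thickness_mm", "age"):
                try:
                    correlations[(ratio, covariate)] = ratio_covariate_correlation(
                        agd_table, ratio, covariate
                    )
                except ValueError:
                    pass

        return AGDComparisonResults(
            model=self,
            agd_table=agd_table,
            skipped=skipped,
            ratio_summary=summary,
            regression=regression,
            density_category_counts=categories,
            correlations=correlations,
        )


def _records_from_frame(frame: pd.DataFrame):
    from .dosimetry import ExamRecord

    defaults = {"anode": "Mo", "filter": "Mo", "view": "CC"}
    records = []
    for i, row in frame.iterrows():
        data = row.to_dict()
        kwargs = {
            "exam_id": str(data.get("exam_id", f"row-{i}")),
            "view": str(data.get("view", defaults["view"])),
            "anode": str(data.get("anode", defaults["anode"])),
            "filter": str(data.get("filter", defaults["filter"])),
        }
        for name in ("age", "thickness_mm", "hvl_mm_al", "iak_mgy",
                     "entrance_exposure", "vendor_agd_mgy",
                     "volpara_gpw", "volpara_vbd"):
            value = data.get(name)
            kwargs[name] = None if value is None or pd.isna(value) else float(value)
        records.append(ExamRecord(**kwargs))
    return records


@dataclass
class AGDComparisonResults:
    """Fitted comparison: per-exposure AGDs plus every cohort-level table."""

    model: AGDComparison
    agd_table: pd.DataFrame
    skipped: list
    ratio_summary: pd.DataFrame
    regression: RegressionResult | None
    density_category_counts: pd.DataFrame
    correlations: dict

    def summary(self) -> str:
        """Human-readable report of ratios, regression and correlations."""
        lines = ["AGD comparison summary", "======================", ""]
        lines.append(f"exposures analysed: {len(self.agd_table)}"
                     f" (skipped: {len(self.skipped)})")
        lines.append("")
        lines.append("AGD ratios by thickness class (mean [min, max] +/- SD):")
        for _, row in self.ratio_summary.iterrows():
            lines.append(
                f"  {row.thickness_class:>6} mm  {row.ratio:<18}"
                f" n={row.n:<5d} {row['mean']:.3f}"
                f" [{row['min']:.3f}, {row['max']:.3f}] +/- {row.sd:.3f}"
            )
        if self.regression is not None:
            r = self.regression
            lines.append("")
            lines.append("Glandularity ~ age + thickness (OLS):")
            lines.append(
                f"  intercept {r.intercept:8.3f} (SE {r.intercept_se:.3f})"
            )
            lines.append(f"  age       {r.age_coef:8.3f} (SE {r.age_se:.3f})")
            lines.append(
                f"  thickness {r.thickness_coef:8.3f} (SE {r.thickness_se:.3f})"
            )
            lines.append(
                f"  R^2 = {r.r_squared:.3f}, ANOVA p = {r.anova_p:.3g}, n = {r.n}"
            )
        lines.append("")
        lines.append("Density categories (glandularity quartile bins), counts:")
        for _, row in self.density_category_counts.iterrows():
            lines.append(
                f"  category {row.category}: population model {row.dance:>5d},"
                f" personalized {row.volpara:>5d}"
            )
        if self.correlations:
            lines.append("")
            lines.append("Pearson correlations of ratios with covariates:")
            for (ratio, cov), (r, p) in sorted(self.correlations.items()):
                lines.append(f"  {ratio:<18} vs {cov:<12} r = {r:+.3f} (p = {p:.3g})")
        return "\n".join(lines)

    def plot_ratio_vs(self, covariate: str = "thickness_mm", ax=None):
        """Scatter of each AGD ratio against a covariate (one panel each)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=True)
        else:
            axes = np.atleast_1d(ax)
        for a, ratio in zip(np.ravel(axes), RATIO_COLUMNS):
            a.plot(self.agd_table[covariate], self.agd_table[ratio], ".", ms=2, alpha=0.5)
            a.axhline(1.0, color="grey", lw=0.8)
            a.set_xlabel(covariate)
            a.set_title(ratio.replace("_", " "))
        np.ravel(axes)[0].set_ylabel("AGD ratio")
        return axes
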