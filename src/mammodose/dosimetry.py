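"""Per-exposure average glandular dose (AGD) under three formalisms.

For every exposure three AGD estimates are computed and compared:

* **Dance AGD** — ``IAK * g * c * s`` with the population glandularity from
  the age/thickness model.
* **Wu (vendor) AGD** — ``X_ese * DgN``: entrance exposure times the
  normalized glandular dose, the formalism implemented by the acquisition
  system.  In clinical data the vendor-computed value is read from the image
  header (pass-through mode); for synthetic cohorts a pluggable DgN table is
  evaluated at the densest-region glandularity (compute mode).
* **Personalized (Volpara) AGD** — the Dance formula again, but with the
  individually measured percent-by-weight glandularity instead of the
  population model.

The three pairwise ratios satisfy the closure identity
``(dance/wu) * (wu/volpara) = dance/volpara`` record by record.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, asdict

import pandas as pd

from .factor_tables import AgeGroupPolicy, FactorTables

logger = logging.getLogger(__name__)

__all__ = [
    "ExamRecord",
    "AGDTriple",
    "DosimetryConfig",
    "MissingDataError",
    "dance_agd",
    "wu_agd",
    "densest_region_glandularity",
    "dance_equivalent_dgn",
    "compute_agd_triple",
    "compute_agd_table",
]


class MissingDataError(ValueError):
    """A required exposure field is absent for the requested computation."""


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


@dataclass
class ExamRecord:
    """One mammographic exposure, as read from a header or a cohort file.

    Units: thickness in mm, HVL in mm Al, IAK (incident air kerma, without
    backscatter) and vendor AGD in mGy, glandularity fields in percent.
    ``entrance_exposure`` carries whatever entrance metric the configured DgN
    table is normalized to (the packaged default is air-kerma-normalized, so
    it equals IAK in mGy).
    """

    exam_id: str
    age: float | None = None
    thickness_mm: float | None = None
    hvl_mm_al: float | None = None
    anode: str = "Mo"
    filter: str = "Mo"
    iak_mgy: float | None = None
    view: str = "CC"
    entrance_exposure: float | None = None
    vendor_agd_mgy: float | None = None
    volpara_gpw: float | None = None
    volpara_vbd: float | None = None

    def __post_init__(self) -> None:
        if not _is_missing(self.thickness_mm) and self.thickness_mm <= 0:
            raise ValueError(f"{self.exam_id}: thickness must be > 0 mm")
        if not _is_missing(self.hvl_mm_al) and self.hvl_mm_al <= 0:
            raise ValueError(f"{self.exam_id}: HVL must be > 0 mm Al")
        if not _is_missing(self.iak_mgy) and self.iak_mgy < 0:
            raise ValueError(f"{self.exam_id}: IAK must be >= 0 mGy")
        for name in ("volpara_gpw", "volpara_vbd"):
            v = getattr(self, name)
            if not _is_missing(v) and not 0.0 <= v <= 100.0:
                raise ValueError(f"{self.exam_id}: {name} must be in [0, 100]")

    def require(self, *names: str) -> None:
        missing = [n for n in names if _is_missing(getattr(self, n))]
        if missing:
            raise MissingDataError(f"{self.exam_id}: missing field(s) {missing}")


@dataclass(frozen=True)
class AGDTriple:
    """The three AGD estimates (mGy) and their pairwise ratios for one exposure."""

    exam_id: str
    dance_agd: float
    wu_agd: float
    volpara_agd: float
    dance_over_volpara: float
    wu_over_volpara: float
    dance_over_wu: float
    thickness_mm: float | None = None
    age: float | None = None

    @classmethod
    def from_agds(cls, exam_id, dance, wu, volpara, **extra) -> "AGDTriple":
        return cls(
            exam_id=exam_id,
            dance_agd=dance,
            wu_agd=wu,
            volpara_agd=volpara,
            dance_over_volpara=dance / volpara,
            wu_over_volpara=wu / volpara,
            dance_over_wu=dance / wu,
            **extra,
        )


@dataclass(frozen=True)
class DosimetryConfig:
    """Method switches for the AGD triple.

    glandularity_source
        ``"dance_model"`` (age/thickness table) or ``"volpara"`` (the record's
        measured percent-by-weight glandularity) for the Dance pathway.
    wu_mode
        ``"passthrough"`` reads the vendor AGD from the record; ``"compute"``
        evaluates ``entrance_exposure * DgN``.
    densest_region_mode / densest_region_cap
        How the whole-breast glandularity is mapped to the densest-region
        value used by the vendor exposure control in compute mode.
    on_error
        ``"skip"`` logs and drops failing records in table computations;
        ``"raise"`` fails fast.
    """

    glandularity_source: str = "dance_model"
    wu_mode: str = "passthrough"
    densest_region_mode: str = "double_capped"
    densest_region_cap: float = 100.0
    on_error: str = "skip"
    age_policy: AgeGroupPolicy = field(default_factory=AgeGroupPolicy)


def densest_region_glandularity(
    whole_breast_gpw: float,
    mode: str = "double_capped",
    cap: float = 100.0,
) -> float:
    """Approximate glandularity of the densest breast region.

    The automatic exposure control estimates density in the densest area of
    the breast; that value approaches the whole-breast glandularity for very
    dense and extremely fatty breasts but is roughly twice as large
    otherwise.  ``double_capped`` returns ``min(2 * gpw, cap)``; ``identity``
    returns the input unchanged.
    """
    if not 0.0 <= whole_breast_gpw <= 100.0:
        raise ValueError(f"whole-breast glandularity {whole_breast_gpw} not in [0, 100]")
    if not 0.0 < cap <= 100.0:
        raise ValueError(f"densest-region cap {cap} must be in (0, 100]")
    if mode == "identity":
        return whole_breast_gpw
    if mode == "double_capped":
        return min(2.0 * whole_breast_gpw, cap)
    raise ValueError(f"unknown densest-region mode {mode!r}")


def dance_equivalent_dgn(tables: FactorTables):
    """Approximate DgN table built from the g·c·s factor surfaces.

    Returns a callable ``dgn(glandularity, thickness, hvl, anode, filter)``
    normalized to incident air kerma in mGy (so the matching entrance metric
    is IAK).  The glandularity argument is the value the caller deems
    representative (for the vendor pathway, the densest-region estimate).
    This is a documented stand-in: it carries the glandularity dependence of
    the Dance surfaces, not the skin-layer and spectrum differences of the
    true Wu/Boone tables.
    """

    def _dgn(gland, thickness, hvl, anode, filt):
        return (
            tables.g(thickness, hvl)
            * tables.c(gland, thickness, hvl)
            * tables.s(anode, filt)
        )

    return _dgn


def dance_agd(
    record: ExamRecord,
    tables: FactorTables,
    glandularity_source: str = "dance_model",
    age_policy: AgeGroupPolicy | None = None,
) -> float:
    """AGD (mGy) via ``IAK * g * c * s``.

    The c-factor glandularity comes from the age/thickness population model
    (``"dance_model"``) or from the record's measured percent-by-weight value
    (``"volpara"``) — the two pathways differ *only* through that estimate.
    """
    record.require("iak_mgy", "thickness_mm", "hvl_mm_al")
    if glandularity_source == "dance_model":
        record.require("age")
        gland = tables.dance_glandularity(
            record.age, record.thickness_mm, policy=age_policy
        )
    elif glandularity_source == "volpara":
        record.require("volpara_gpw")
        gland = record.volpara_gpw
    else:
        raise ValueError(f"unknown glandularity source {glandularity_source!r}")
    return (
        record.iak_mgy
        * tables.g(record.thickness_mm, record.hvl_mm_al)
        * tables.c(gland, record.thickness_mm, record.hvl_mm_al)
        * tables.s(record.anode, record.filter)
    )


def wu_agd(
    record: ExamRecord,
    tables: FactorTables,
    mode: str = "passthrough",
    densest_mode: str = "double_capped",
    cap: float = 100.0,
) -> float:
    """AGD (mGy) via the Wu formalism ``X_ese * DgN``.

    ``passthrough`` returns the vendor-computed header value unchanged (the
    vendor system already evaluated the formalism); ``compute`` evaluates the
    configured DgN table at the densest-region glandularity derived from the
    record's whole-breast value (see :func:`densest_region_glandularity`).
    """
    if mode == "passthrough":
        record.require("vendor_agd_mgy")
        return record.vendor_agd_mgy
    if mode == "compute":
        record.require("entrance_exposure", "thickness_mm", "hvl_mm_al", "volpara_gpw")
        densest = densest_region_glandularity(
            record.volpara_gpw, mode=densest_mode, cap=cap
        )
        dgn = tables.dgn(
            densest,
            record.thickness_mm,
            record.hvl_mm_al,
            record.anode,
            record.filter,
        )
        return record.entrance_exposure * dgn
    raise ValueError(f"unknown Wu mode {mode!r}")


def compute_agd_triple(
    record: ExamRecord,
    tables: FactorTables,
    config: DosimetryConfig | None = None,
) -> AGDTriple:
    """All three AGD estimates and their pairwise ratios for one exposure."""
    config = config or DosimetryConfig()
    dance = dance_agd(
        record, tables,
        glandularity_source=config.glandularity_source,
        age_policy=config.age_policy,
    )
    volpara = dance_agd(record, tables, glandularity_source="volpara")
    wu = wu_agd(
        record, tables, mode=config.wu_mode,
        densest_mode=config.densest_region_mode, cap=config.densest_region_cap,
    )
    return AGDTriple.from_agds(
        record.exam_id, dance, wu, volpara,
        thickness_mm=record.thickness_mm, age=record.age,
    )


def compute_agd_table(
    records,
    tables: FactorTables,
    config: DosimetryConfig | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """AGD triples for a cohort, as a DataFrame keyed by exam id.

    Returns ``(table, skipped)`` where ``skipped`` lists ``(exam_id, reason)``
    for records dropped under the ``on_error="skip"`` policy.
    """
    config = config or DosimetryConfig()
    rows, skipped = [], []
    for record in records:
        try:
            rows.append(asdict(compute_agd_triple(record, tables, config)))
        except (MissingDataError, ValueError) as exc:
            if config.on_error == "raise":
                raise
            skipped.append((record.exam_id, str(exc)))
            logger.warning("skipping %s: %s", record.exam_id, exc)
    frame = pd.DataFrame(rows, columns=[f.name for f in fields(AGDTriple)])
    return frame, skipped
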