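"""Pipeline orchestration: read or simulate exposures, run the dosimetry and
comparison stages, and write a reproducible report bundle.

Every run writes the resolved configuration and a manifest (package and
library versions, seed, config hash) alongside the outputs; identical
configuration and seed reproduce the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortParams, generate_cohort, read_cohort, write_cohort
from .comparison import AGDComparison
from .dicom_io import DEFAULT_TAG_MAP, DicomTagMap, read_dicom_headers
from .dosimetry import DosimetryConfig
from .factor_tables import load_factor_tables

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Configuration or stage failure; carries the stage name."""


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run.

    ``mode`` is ``"csv"`` (read a cohort CSV), ``"dicom"`` (read headers from
    a directory) or ``"simulate"`` (generate a synthetic cohort).
    """

    mode: str = "simulate"
    input_path: str | None = None
    tables: str = "default"
    output_dir: str = "mammodose-out"
    seed: int = 0
    glandularity_source: str = "dance_model"
    wu_mode: str = "compute"
    densest_region_mode: str = "double_capped"
    densest_region_cap: float = 100.0
    on_error: str = "skip"
    cohort: CohortParams = field(default_factory=CohortParams)
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("csv", "dicom", "simulate"):
            raise PipelineError(f"config: unknown mode {self.mode!r}")
        if self.mode in ("csv", "dicom"):
            if not self.input_path:
                raise PipelineError(f"config: mode {self.mode!r} needs input_path")
            if not Path(self.input_path).exists():
                raise PipelineError(f"config: input path {self.input_path} not found")
        if self.tables not in ("default", "paper-default") and not Path(self.tables).exists():
            raise PipelineError(f"config: factor table {self.tables} not found")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig, tag_map: DicomTagMap = DEFAULT_TAG_MAP) -> dict:
    """Execute read/simulate -> dosimetry -> comparison; write the report bundle.

    Returns a dict of output paths keyed by artifact name.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    resolved = yaml.safe_dump(config.as_dict(), sort_keys=True)
    (out / "config.yaml").write_text(resolved)

    try:
        tables = load_factor_tables(config.tables)
    except Exception as exc:
        raise PipelineError(f"stage factor_tables: {exc}") from exc

    sidecar = None
    if config.mode == "simulate":
        params = dataclasses.replace(config.cohort, seed=config.seed)
        records, sidecar = generate_cohort(params, tables=tables)
        write_cohort(records, out / "cohort.csv")
        with open(out / "cohort_sidecar.yaml", "w") as fh:
            yaml.safe_dump(sidecar, fh, sort_keys=True)
    elif config.mode == "csv":
        records = read_cohort(config.input_path)
    else:  # dicom
        paths = sorted(Path(config.input_path).glob("*"))
        records = read_dicom_headers(paths, tag_map=tag_map)

    dconfig = DosimetryConfig(
        glandularity_source=config.glandularity_source,
        wu_mode=config.wu_mode,
        densest_region_mode=config.densest_region_mode,
        densest_region_cap=config.densest_region_cap,
        on_error=config.on_error,
    )
    try:
        results = AGDComparison.from_records(records, tables=tables, config=dconfig).fit()
    except Exception as exc:
        raise PipelineError(f"stage dosimetry/comparison: {exc}") from exc

    paths = {"config": out / "config.yaml"}
    results.agd_table.to_csv(out / "agd_table.csv", index=False)
    paths["agd_table"] = out / "agd_table.csv"
    results.ratio_summary.to_csv(out / "ratio_summary.csv", index=False)
    paths["ratio_summary"] = out / "ratio_summary.csv"
    results.density_category_counts.to_csv(out / "density_categories.csv", index=False)
    paths["density_categories"] = out / "density_categories.csv"
    if results.regression is not None:
        (out / "regression.json").write_text(
            json.dumps(results.regression.as_dict(), indent=2, sort_keys=True)
        )
        paths["regression"] = out / "regression.json"
    correlations = {
        f"{ratio}~{cov}": {"r": r, "p": p}
        for (ratio, cov), (r, p) in results.correlations.items()
    }
    (out / "correlations.json").write_text(
        json.dumps(correlations, indent=2, sort_keys=True)
    )
    paths["correlations"] = out / "correlations.json"
    (out / "summary.txt").write_text(results.summary() + "\n")
    paths["summary"] = out / "summary.txt"
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        for covariate in ("thickness_mm", "age"):
            results.plot_ratio_vs(covariate)
            fig_path = out / f"ratios_vs_{covariate}.png"
            plt.gcf().savefig(fig_path, dpi=120)
            plt.close("all")
            paths[f"figure_{covariate}"] = fig_path
    except Exception as exc:  # plotting is best-effort reporting
        logger.warning("figure generation failed: %s", exc)
    if results.skipped:
        pd.DataFrame(results.skipped, columns=["exam_id", "reason"]).to_csv(
            out / "skipped.csv", index=False
        )
        paths["skipped"] = out / "skipped.csv"

    import numpy, scipy, statsmodels  # versions for the manifest

    manifest = {
        "mammodose": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(resolved.encode()).hexdigest(),
        "n_records": len(records),
        "n_analysed": int(len(results.agd_table)),
        "n_skipped": len(results.skipped),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = out / "manifest.json"
    return {k: str(v) for k, v in paths.items()}
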