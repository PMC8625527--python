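"""End-to-end orchestration: read inputs, run a full analysis, write
every intermediate and final table plus a run manifest.

The manifest (JSON) echoes the configuration, records package and
dependency versions, SHA-256 checksums of every input file and the
warnings emitted during the run, which is enough to re-run the
deterministic stages bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from .methylation import SimpoMethylation
from .mr import MRModel, TwoStepMR

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_methylation_pipeline", "run_mr_pipeline"]


@dataclass
class RunConfig:
    """Paths, thresholds and flags for one pipeline run."""

    out_dir: str
    beta_path: str | None = None
    annotation_path: str | None = None
    groups_path: str | None = None
    exposure_path: str | None = None
    mediator_path: str | None = None
    outcome_path: str | None = None
    alpha: float = 0.05
    q_threshold: float = 0.001
    instrument_pvalue: float = 5e-8
    methods: tuple[str, ...] = ("ivw", "weighted_median", "egger")
    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    seed: int | None = None

    def __post_init__(self):
        for name in ("alpha", "q_threshold", "instrument_pvalue"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.seed is None and ("weighted_median" in self.methods):
            raise ValueError("seed is required when the weighted-median bootstrap runs")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "methods" in raw and isinstance(raw["methods"], list):
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)


@dataclass
class ReportBundle:
    """Outputs of one pipeline run: tables by name, plus the manifest."""

    tables: dict[str, pd.DataFrame]
    manifest: dict
    out_dir: Path
    result: object = None

    def write(self) -> None:
        self.out_dir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            io.write_table(table, self.out_dir / f"{name}.tsv", index=name == "simpo_scores")
        with open(self.out_dir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _WarningCounter(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(record.getMessage())


def _manifest(cfg: RunConfig, inputs: dict[str, str], warnings: list[str]) -> dict:
    import numpy
    import pandas
    import scipy

    return {
        "config": {k: v for k, v in vars(cfg).items()},
        "versions": {
            "simpomr": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        "input_checksums": {name: _checksum(p) for name, p in inputs.items() if p},
        "warnings": warnings,
    }


def run_methylation_pipeline(cfg: RunConfig) -> ReportBundle:
    """Score genes, run both differential screens, intersect, write."""
    counter = _WarningCounter()
    logging.getLogger("simpomr").addHandler(counter)
    try:
        model = SimpoMethylation.from_files(cfg.beta_path, cfg.annotation_path, cfg.groups_path)
        missing = set(model.beta.columns) ^ set(model.groups.index)
        if missing:
            raise ValueError(
                f"sample sets differ between beta matrix and group file: {sorted(missing)[:5]}"
            )
        res = model.fit(alpha=cfg.alpha, q_threshold=cfg.q_threshold)
    finally:
        logging.getLogger("simpomr").removeHandler(counter)

    tables = {
        "simpo_scores": res.scores,
        "simpo_diff": res.gene_tests,
        "dmp": res.dmp_tests,
        "intersection": pd.DataFrame({"gene": res.intersection}),
    }
    inputs = {
        "beta": cfg.beta_path,
        "annotation": cfg.annotation_path,
        "groups": cfg.groups_path,
    }
    bundle = ReportBundle(
        tables=tables,
        manifest=_manifest(cfg, inputs, counter.messages),
        out_dir=Path(cfg.out_dir),
        result=res,
    )
    bundle.write()
    if not res.intersection:
        logger.warning("the two-method intersection is empty")
    return bundle


def run_mr_pipeline(cfg: RunConfig) -> ReportBundle:
    """Run a two-sample MR (or, with a mediator table, two-step MR)."""
    counter = _WarningCounter()
    logging.getLogger("simpomr").addHandler(counter)
    try:
        exposure = io.read_gwas(cfg.exposure_path)
        outcome = io.read_gwas(cfg.outcome_path)
        if cfg.mediator_path:
            mediator = io.read_gwas(cfg.mediator_path)
            model = TwoStepMR(
                exposure, mediator, outcome, instrument_pvalue=cfg.instrument_pvalue
            )
            res = model.fit(ivw_model=cfg.ivw_model, n_boot=cfg.n_boot, seed=cfg.seed)
            tables = {
                "step1_estimates": res.step1.estimates_frame(),
                "step2_estimates": res.step2.estimates_frame(),
                "mediation": pd.DataFrame(
                    [
                        {
                            "mediated_effect": res.mediated_effect,
                            "mediated_se": res.mediated_se,
                            "pleiotropy_flags": "; ".join(res.flags),
                        }
                    ]
                ),
            }
            for label, step in (("step1", res.step1), ("step2", res.step2)):
                tables[f"{label}_diagnostics"] = _diagnostics_frame(step)
                if step.loo is not None:
                    tables[f"{label}_leave_one_out"] = step.loo
        else:
            model = MRModel.from_summary_stats(
                exposure, outcome, instrument_pvalue=cfg.instrument_pvalue
            )
            res = model.fit(
                methods=cfg.methods, ivw_model=cfg.ivw_model, n_boot=cfg.n_boot, seed=cfg.seed
            )
            tables = {
                "estimates": res.estimates_frame(),
                "diagnostics": _diagnostics_frame(res),
                "scatter": res.pairs,
            }
            if res.loo is not None:
                tables["leave_one_out"] = res.loo
    finally:
        logging.getLogger("simpomr").removeHandler(counter)

    inputs = {
        "exposure": cfg.exposure_path,
        "mediator": cfg.mediator_path,
        "outcome": cfg.outcome_path,
    }
    bundle = ReportBundle(
        tables=tables,
        manifest=_manifest(cfg, inputs, counter.messages),
        out_dir=Path(cfg.out_dir),
        result=res,
    )
    bundle.write()
    return bundle


def _diagnostics_frame(res) -> pd.DataFrame:
    row = {}
    if res.heterogeneity is not None:
        row.update(
            q_stat=res.heterogeneity.q_stat,
            q_df=res.heterogeneity.df,
            q_p_value=res.heterogeneity.p_value,
        )
    if res.pleiotropy is not None:
        row.update(
            egger_intercept=res.pleiotropy.intercept,
            egger_intercept_se=res.pleiotropy.se,
            egger_intercept_p=res.pleiotropy.p_value,
        )
    return pd.DataFrame([row])
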