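"""Gene-level methylation scoring and differential-methylation screens.

The central quantity is the SIMPO score: a per-gene, per-sample t-form
statistic contrasting the mean methylation (beta value) of the gene's
body probes against its promoter probes,

    score = (x_bar - y_bar) / (Sw * sqrt(1/m + 1/n)),
    Sw    = sqrt( [(m-1)*S1^2 + (n-1)*S2^2] / (m + n - 2) ),

where x_bar, S1^2 are the mean and variance of the sample's m body-probe
betas and y_bar, S2^2 those of its n promoter probes.  Under a
no-difference null with normal probe noise the score follows t(m+n-2).
Collapsing probes to one number per gene this way makes the gene, not
the probe, the unit of the downstream two-group comparison.

Two differential screens are provided:

* :func:`diff_methylation_simpo` — per-gene two-sample t-test of SIMPO
  scores between groups (Welch by default), screened at ``p < alpha``.
* :func:`dmp_scan` — the classical per-probe scan: a linear model on the
  group indicator (for two groups, an F-test equal to the squared pooled
  t), with Benjamini-Hochberg q-values screened at ``q < 0.001``.

The two resulting gene lists are combined with
:func:`intersect_gene_lists`.

A statsmodels-style front end is provided by :class:`SimpoMethylation`
(model) and :class:`SimpoMethylationResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

REGION_PROMOTER = "promoter"
REGION_BODY = "body"
VALID_REGIONS = (REGION_PROMOTER, REGION_BODY)

__all__ = [
    "SimpoMethylation",
    "SimpoMethylationResults",
    "compute_simpo_scores",
    "diff_methylation_simpo",
    "dmp_scan",
    "adjust_qvalues",
    "annotate_and_collapse",
    "intersect_gene_lists",
    "eligible_genes",
]


def _validate_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    required = {"probe_id", "gene", "region"}
    missing = required - set(annot.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if annot["probe_id"].duplicated().any():
        dup = annot.loc[annot["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id in annotation: {dup!r}")
    bad = ~annot["region"].isin(VALID_REGIONS)
    if bad.any():
        raise ValueError(
            f"invalid region values: {sorted(annot.loc[bad, 'region'].unique())}; "
            f"expected one of {VALID_REGIONS}"
        )
    return annot


def eligible_genes(annot: pd.DataFrame) -> list[str]:
    """Genes with >= 2 promoter probes and >= 2 body probes.

    Both variance terms in the pooled SD need at least two observations,
    so genes below this floor cannot be scored.
    """
    _validate_annotation(annot)
    counts = annot.pivot_table(
        index="gene", columns="region", values="probe_id", aggfunc="count", fill_value=0
    )
    for region in VALID_REGIONS:
        if region not in counts:
            counts[region] = 0
    ok = (counts[REGION_PROMOTER] >= 2) & (counts[REGION_BODY] >= 2)
    return sorted(counts.index[ok])


def compute_simpo_scores(
    beta: pd.DataFrame,
    annot: pd.DataFrame,
    *,
    sw_denominator: str = "df",
) -> tuple[pd.DataFrame, pd.Series]:
    """Compute gene x sample SIMPO scores from a probe x sample beta matrix.

    Parameters
    ----------
    beta
        Probe x sample DataFrame of methylation beta values in [0, 1];
        NaN marks a missing value.
    annot
        DataFrame with columns ``probe_id``, ``gene``, ``region``
        (``promoter`` / ``body``); each probe maps to exactly one
        (gene, region).
    sw_denominator
        ``"df"`` (default) uses the standard pooled-variance denominator
        ``m + n - 2``, consistent with the declared t(m+n-2) reference.
        ``"printed"`` uses ``m + n + 1`` — a historical variant kept for
        comparison only.

    Returns
    -------
    (scores, df)
        ``scores``: gene x sample DataFrame of SIMPO scores (NaN where a
        sample lacks two valid probes in either region, or where the
        pooled SD is zero with unequal means).  ``df``: per-gene integer
        degrees of freedom ``m + n - 2`` from the full annotation.

    Notes
    -----
    Missing betas are dropped per sample; the effective m and n for that
    sample enter both the pooled variance and the 1/m + 1/n factor.  A
    gene whose effective count drops below 2 in either region is left
    unscored (NaN) for that sample.
    """
    if sw_denominator not in ("df", "printed"):
        raise ValueError("sw_denominator must be 'df' or 'printed'")
    _validate_annotation(annot)

    unknown = ~np.asarray(beta.index.isin(annot["probe_id"]))
    if unknown.any():
        logger.warning(
            "%d probes in the beta matrix are absent from the annotation; ignored",
            int(unknown.sum()),
        )

    genes = eligible_genes(annot)
    if not genes:
        logger.warning("no SIMPO-eligible genes (need >=2 probes per region)")
        return (
            pd.DataFrame(index=pd.Index([], name="gene"), columns=beta.columns, dtype=float),
            pd.Series(dtype=int, name="df"),
        )

    annot_idx = annot.set_index("probe_id")
    samples = beta.columns
    values = beta.to_numpy(dtype=float)
    probe_pos = {p: i for i, p in enumerate(beta.index)}

    scores = np.full((len(genes), len(samples)), np.nan)
    dof = np.zeros(len(genes), dtype=int)
    n_sw_zero = 0

    by_gene = annot_idx.groupby("gene")
    for gi, gene in enumerate(genes):
        sub = by_gene.get_group(gene)
        body_probes = [p for p in sub.index[sub["region"] == REGION_BODY] if p in probe_pos]
        prom_probes = [p for p in sub.index[sub["region"] == REGION_PROMOTER] if p in probe_pos]
        dof[gi] = len(body_probes) + len(prom_probes) - 2
        if len(body_probes) < 2 or len(prom_probes) < 2:
            # probes present in annotation but absent from the matrix
            continue
        body = values[[probe_pos[p] for p in body_probes], :]
        prom = values[[probe_pos[p] for p in prom_probes], :]

        m = np.sum(~np.isnan(body), axis=0).astype(float)
        n = np.sum(~np.isnan(prom), axis=0).astype(float)
        valid = (m >= 2) & (n >= 2)
        if not valid.any():
            continue
        with np.errstate(invalid="ignore"):
            x_bar = np.nanmean(body, axis=0)
            y_bar = np.nanmean(prom, axis=0)
            s1 = np.nanvar(body, axis=0, ddof=1)
            s2 = np.nanvar(prom, axis=0, ddof=1)
        denom = (m + n + 1.0) if sw_denominator == "printed" else (m + n - 2.0)
        sw = np.sqrt(((m - 1.0) * s1 + (n - 1.0) * s2) / denom)
        scale = sw * np.sqrt(1.0 / m + 1.0 / n)

        row = np.full(len(samples), np.nan)
        diff = x_bar - y_bar
        nonzero = valid & (scale > 0)
        row[nonzero] = diff[nonzero] / scale[nonzero]
        degenerate_zero = valid & (scale == 0) & (diff == 0)
        row[degenerate_zero] = 0.0
        degenerate_bad = valid & (scale == 0) & (diff != 0)
        n_sw_zero += int(degenerate_bad.sum())
        scores[gi] = row

    if n_sw_zero:
        logger.warning(
            "%d gene/sample cells had zero pooled SD with unequal means; set to NaN",
            n_sw_zero,
        )
    return (
        pd.DataFrame(scores, index=pd.Index(genes, name="gene"), columns=samples),
        pd.Series(dof, index=pd.Index(genes, name="gene"), name="df"),
    )


def _split_groups(columns: pd.Index, groups: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    groups = groups.reindex(columns)
    if groups.isna().any():
        missing = list(columns[groups.isna()])[:5]
        raise ValueError(f"samples without group assignment: {missing}")
    bad = ~groups.isin(["control", "treated"])
    if bad.any():
        raise ValueError(
            f"invalid group labels: {sorted(groups[bad].unique())}; expected control/treated"
        )
    ctrl = np.asarray(groups == "control")
    trt = np.asarray(groups == "treated")
    if ctrl.sum() < 2 or trt.sum() < 2:
        raise ValueError("need >= 2 samples per group for a differential analysis")
    return ctrl, trt


def diff_methylation_simpo(
    scores: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    *,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sample t-test of SIMPO scores between groups.

    Welch's t by default (``equal_var=False``); set ``equal_var=True``
    for the pooled-variance test.  ``direction`` is ``up`` when the
    treated mean score exceeds the control mean.  A gene with zero
    variance in both groups and equal means gets t=0, p=1.
    """
    ctrl, trt = _split_groups(scores.columns, groups)
    vals = scores.to_numpy(dtype=float)
    a = vals[:, trt]
    b = vals[:, ctrl]
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p_val = stats.ttest_ind(
            a, b, axis=1, equal_var=equal_var, nan_policy="omit"
        )
    t_stat = np.asarray(t_stat, dtype=float)
    p_val = np.asarray(p_val, dtype=float)

    mean_trt = np.nanmean(a, axis=1)
    mean_ctrl = np.nanmean(b, axis=1)
    degenerate = np.isnan(p_val) & np.isclose(mean_trt, mean_ctrl)
    if degenerate.any():
        logger.warning(
            "%d genes with zero variance in both groups and equal means; p set to 1",
            int(degenerate.sum()),
        )
    t_stat[degenerate] = 0.0
    p_val[degenerate] = 1.0

    out = pd.DataFrame(
        {
            "gene": scores.index,
            "t_stat": t_stat,
            "p_value": p_val,
            "direction": np.where(mean_trt > mean_ctrl, "up", "down"),
        }
    )
    out["significant"] = out["p_value"] < alpha
    return out


def dmp_scan(
    beta: pd.DataFrame,
    groups: pd.Series,
    q_threshold: float = 0.001,
    annot: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-probe two-group scan: linear model on the group indicator.

    For a two-level factor the OLS F-statistic equals the squared pooled
    two-sample t, which is how the scan is computed (vectorised across
    probes).  Missing values are dropped per probe.  p-values are
    adjusted to Benjamini-Hochberg q-values and screened at
    ``q < q_threshold``.  If ``annot`` is given, each probe carries its
    gene symbol (empty string when unannotated).
    """
    ctrl, trt = _split_groups(beta.columns, groups)
    vals = beta.to_numpy(dtype=float)
    a = vals[:, trt]
    b = vals[:, ctrl]

    n1 = np.sum(~np.isnan(a), axis=1).astype(float)
    n2 = np.sum(~np.isnan(b), axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.nanmean(a, axis=1)
        m2 = np.nanmean(b, axis=1)
        v1 = np.nanvar(a, axis=1, ddof=1)
        v2 = np.nanvar(b, axis=1, ddof=1)
        pooled = ((n1 - 1.0) * v1 + (n2 - 1.0) * v2) / (n1 + n2 - 2.0)
        f_stat = (m1 - m2) ** 2 / (pooled * (1.0 / n1 + 1.0 / n2))
    df2 = n1 + n2 - 2.0
    p_val = stats.f.sf(f_stat, 1.0, df2)

    constant = np.isclose(pooled, 0.0) | np.isnan(pooled)
    equal_means = constant & np.isclose(m1, m2)
    f_stat = np.where(equal_means, 0.0, f_stat)
    p_val = np.where(equal_means, 1.0, p_val)
    # constant within groups but different between: infinite F, p -> 0
    sep = constant & ~np.isclose(m1, m2)
    p_val = np.where(sep, 0.0, p_val)
    f_stat = np.where(sep, np.inf, f_stat)

    out = pd.DataFrame(
        {
            "probe_id": beta.index,
            "stat": f_stat,
            "p_value": p_val,
        }
    )
    out["q_value"] = adjust_qvalues(out["p_value"].to_numpy())
    if annot is not None:
        gene_map = annot.set_index("probe_id")["gene"]
        out["gene"] = out["probe_id"].map(gene_map).fillna("")
    else:
        out["gene"] = ""
    out["significant"] = out["q_value"] < q_threshold
    return out


def adjust_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def annotate_and_collapse(dmps: pd.DataFrame, annot: pd.DataFrame | None = None) -> list[str]:
    """Collapse significant probes to a sorted, deduplicated gene list.

    ``dmps`` should already be filtered to significant probes (rows with
    a ``significant`` column are filtered here for convenience).  Probes
    without a gene annotation are dropped, with the count logged.
    """
    sub = dmps
    if "significant" in sub.columns:
        sub = sub[sub["significant"]]
    if annot is not None:
        gene_map = annot.set_index("probe_id")["gene"]
        genes = sub["probe_id"].map(gene_map)
    else:
        genes = sub["gene"] if "gene" in sub.columns else pd.Series(dtype=object)
    n_unannotated = int((genes.isna() | (genes == "")).sum())
    if n_unannotated:
        logger.warning("%d significant probes lacked a gene annotation; dropped", n_unannotated)
    genes = genes[genes.notna() & (genes != "")]
    return sorted(set(genes))


def intersect_gene_lists(a, b) -> list[str]:
    """Sorted set intersection of two gene-symbol lists (case-sensitive)."""
    return sorted(set(a) & set(b))


@dataclass
class SimpoMethylationResults:
    """Fitted results of the two-route differential-methylation screen.

    Attributes
    ----------
    scores : DataFrame
        Gene x sample SIMPO score matrix.
    df : Series
        Per-gene degrees of freedom (m + n - 2).
    gene_tests : DataFrame
        Per-gene t-test of scores between groups.
    dmp_tests : DataFrame
        Per-probe scan with q-values.
    simpo_genes, dmp_genes : list of str
        Significant genes from each route.
    intersection : list of str
        Genes significant under both routes.
    """

    scores: pd.DataFrame
    df: pd.Series
    gene_tests: pd.DataFrame
    dmp_tests: pd.DataFrame
    alpha: float
    q_threshold: float
    simpo_genes: list[str] = field(default_factory=list)
    dmp_genes: list[str] = field(default_factory=list)
    intersection: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "SIMPO differential methylation",
            "==============================",
            f"genes scored:              {len(self.scores)}",
            f"samples:                   {self.scores.shape[1]}",
            f"score-screen genes (p<{self.alpha:g}): {len(self.simpo_genes)}",
            f"probes scanned:            {len(self.dmp_tests)}",
            f"DMP-route genes (q<{self.q_threshold:g}): {len(self.dmp_genes)}",
            f"intersection:              {len(self.intersection)}",
        ]
        if self.intersection:
            lines.append("  " + ", ".join(self.intersection[:20]))
        return "\n".join(lines)


class SimpoMethylation:
    """Two-route differential-methylation model for a two-group cohort.

    Parameters
    ----------
    beta
        Probe x sample beta-value matrix (values in [0, 1], NaN missing).
    annotation
        probe_id / gene / region table.
    groups
        Series mapping sample id -> ``"control"`` / ``"treated"``.
    """

    def __init__(self, beta: pd.DataFrame, annotation: pd.DataFrame, groups: pd.Series):
        bad = beta.stack(future_stack=True).dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError("beta values must lie in [0, 1]")
        self.beta = beta
        self.annotation = _validate_annotation(annotation)
        self.groups = groups

    @classmethod
    def from_files(cls, beta_path, annotation_path, groups_path) -> "SimpoMethylation":
        from . import io as _io

        return cls(
            _io.read_beta_matrix(beta_path),
            _io.read_probe_annotation(annotation_path),
            _io.read_groups(groups_path),
        )

    def fit(
        self,
        alpha: float = 0.05,
        q_threshold: float = 0.001,
        *,
        equal_var: bool = False,
        sw_denominator: str = "df",
    ) -> SimpoMethylationResults:
        scores, dof = compute_simpo_scores(
            self.beta, self.annotation, sw_denominator=sw_denominator
        )
        gene_tests = diff_methylation_simpo(
            scores, self.groups, alpha=alpha, equal_var=equal_var
        )
        dmp_tests = dmp_scan(
            self.beta, self.groups, q_threshold=q_threshold, annot=self.annotation
        )
        simpo_genes = sorted(gene_tests.loc[gene_tests["significant"], "gene"])
        dmp_genes = annotate_and_collapse(dmp_tests, self.annotation)
        return SimpoMethylationResults(
            scores=scores,
            df=dof,
            gene_tests=gene_tests,
            dmp_tests=dmp_tests,
            alpha=alpha,
            q_threshold=q_threshold,
            simpo_genes=simpo_genes,
            dmp_genes=dmp_genes,
            intersection=intersect_gene_lists(simpo_genes, dmp_genes),
        )
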