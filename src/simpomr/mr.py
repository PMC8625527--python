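"""Model/Results front end for two-sample and two-step MR.

:class:`MRModel` is built from harmonized instrument pairs (or directly
from exposure/outcome GWAS tables via :meth:`MRModel.from_summary_stats`,
which performs instrument selection and allele harmonization).  Its
:meth:`~MRModel.fit` runs the requested estimators and diagnostics and
returns an :class:`MRResults` carrying per-method estimates, the
Cochran's Q heterogeneity test, the Egger pleiotropy-intercept test and
leave-one-out sensitivity results, with ``summary()`` and a scatter
``plot()``.

:class:`TwoStepMR` chains two such models through a mediator —
exposure -> mediator (step 1) and mediator -> outcome (step 2) — and
reports the mediated effect as the product of the two IVW slopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimators as est
from .estimators import HeterogeneityTest, MrEstimate, PleiotropyTest
from .harmonize import harmonize, select_instruments

logger = logging.getLogger(__name__)

__all__ = ["MRModel", "MRResults", "TwoStepMR", "TwoStepResults"]

_METHODS = ("ivw", "weighted_median", "egger")


@dataclass
class MRResults:
    """Fitted two-sample MR results.

    ``estimates`` maps method name -> :class:`MrEstimate`;
    ``heterogeneity`` is Cochran's Q about the IVW estimate;
    ``pleiotropy`` the Egger intercept test (None unless Egger was run);
    ``loo`` the leave-one-out table (None unless requested).
    """

    pairs: pd.DataFrame
    estimates: dict[str, MrEstimate]
    heterogeneity: HeterogeneityTest | None = None
    pleiotropy: PleiotropyTest | None = None
    loo: pd.DataFrame | None = None
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"

    @property
    def n_snps(self) -> int:
        return len(self.pairs)

    def estimates_frame(self) -> pd.DataFrame:
        """Per-method table in the conventional reporting layout."""
        rows = [
            {
                "method": e.method,
                "n_snps": e.n_snps,
                "beta": e.beta,
                "se": e.se,
                "p_value": e.p_value,
                "odds_ratio": e.odds_ratio,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
            }
            for e in self.estimates.values()
        ]
        return pd.DataFrame(rows)

    def pleiotropy_absent(self, alpha: float = 0.05) -> bool | None:
        """Egger-intercept rule: no evidence of directional pleiotropy
        when the intercept p-value exceeds ``alpha``."""
        if self.pleiotropy is None:
            return None
        return self.pleiotropy.p_value > alpha

    def summary(self) -> str:
        lines = [
            f"Two-sample MR: {self.exposure_name} -> {self.outcome_name}",
            "=" * 60,
            f"instruments: {self.n_snps}",
            "",
            f"{'method':<16}{'beta':>9}{'se':>9}{'p':>11}{'OR':>8}{'95% CI':>18}",
        ]
        for e in self.estimates.values():
            lines.append(
                f"{e.method:<16}{e.beta:>9.4f}{e.se:>9.4f}{e.p_value:>11.3g}"
                f"{e.odds_ratio:>8.3f}  [{e.ci_low:.3f}, {e.ci_high:.3f}]"
            )
        if self.heterogeneity is not None:
            h = self.heterogeneity
            lines.append(
                f"\nheterogeneity: Q = {h.q_stat:.3f}, df = {h.df}, p = {h.p_value:.3g}"
            )
        if self.pleiotropy is not None:
            pl = self.pleiotropy
            verdict = "no evidence of pleiotropy" if pl.p_value > 0.05 else "pleiotropy suspected"
            lines.append(
                f"Egger intercept: {pl.intercept:.4f} (se {pl.se:.4f}, p = {pl.p_value:.3g})"
                f" — {verdict}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of outcome vs exposure effects with fitted lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        bx = self.pairs["beta_exp"].to_numpy()
        by = self.pairs["beta_out"].to_numpy()
        ax.errorbar(
            bx,
            by,
            xerr=self.pairs["se_exp"],
            yerr=self.pairs["se_out"],
            fmt="o",
            ms=3,
            alpha=0.6,
            lw=0.8,
        )
        grid = np.linspace(min(0.0, bx.min()), bx.max(), 50)
        for name, e in self.estimates.items():
            if name == "egger" and self.pleiotropy is not None:
                ax.plot(grid, self.pleiotropy.intercept + e.beta * grid, label="MR-Egger")
            else:
                ax.plot(grid, e.beta * grid, label=name.replace("_", " "))
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_xlabel(f"SNP effect on {self.exposure_name}")
        ax.set_ylabel(f"SNP effect on {self.outcome_name}")
        ax.legend(fontsize=8)
        return ax


class MRModel:
    """Two-sample MR model over harmonized instrument pairs.

    Parameters
    ----------
    pairs
        DataFrame with columns ``snp``, ``beta_exp``, ``se_exp``,
        ``beta_out``, ``se_out`` (the output of
        :func:`simpomr.harmonize.harmonize`).
    """

    def __init__(
        self,
        pairs: pd.DataFrame,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ):
        needed = {"snp", "beta_exp", "se_exp", "beta_out", "se_out"}
        missing = needed - set(pairs.columns)
        if missing:
            raise ValueError(f"pairs missing columns: {sorted(missing)}")
        self.pairs = pairs.reset_index(drop=True)
        self.exposure_name = exposure_name
        self.outcome_name = outcome_name
        self.exclusions: pd.DataFrame | None = None

    @classmethod
    def from_summary_stats(
        cls,
        exposure: pd.DataFrame,
        outcome: pd.DataFrame,
        instrument_pvalue: float = 5e-8,
        palindromic_eaf_window: float = 0.08,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ) -> "MRModel":
        """Select instruments from the exposure GWAS and harmonize them
        against the outcome GWAS."""
        instruments = select_instruments(exposure, threshold=instrument_pvalue)
        if instruments.empty:
            raise ValueError(
                f"no instruments pass p < {instrument_pvalue:g} in the exposure GWAS"
            )
        pairs, exclusions = harmonize(
            instruments, outcome, palindromic_eaf_window=palindromic_eaf_window
        )
        model = cls(pairs, exposure_name=exposure_name, outcome_name=outcome_name)
        model.exclusions = exclusions
        return model

    def fit(
        self,
        methods: tuple[str, ...] = _METHODS,
        *,
        ivw_model: str = "multiplicative_random",
        n_boot: int = 1000,
        seed: int | None = None,
        leave_one_out: bool = True,
    ) -> MRResults:
        unknown = set(methods) - set(_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}; choose from {_METHODS}")
        pairs = self.pairs
        estimates: dict[str, MrEstimate] = {}
        pleiotropy = None
        if "ivw" in methods:
            estimates["ivw"] = est.ivw_estimate(pairs, model=ivw_model)
        if "weighted_median" in methods:
            estimates["weighted_median"] = est.weighted_median_estimate(
                pairs, n_boot=n_boot, seed=seed
            )
        if "egger" in methods:
            egger, pleiotropy = est.egger_estimate(pairs)
            estimates["egger"] = egger

        heterogeneity = None
        if "ivw" in estimates and len(pairs) >= 2:
            heterogeneity = est.cochran_q(pairs, estimates["ivw"].beta)

        loo = None
        if leave_one_out and len(pairs) >= 3:
            loo = est.leave_one_out(pairs, model=ivw_model)

        return MRResults(
            pairs=pairs,
            estimates=estimates,
            heterogeneity=heterogeneity,
            pleiotropy=pleiotropy,
            loo=loo,
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
        )


@dataclass
class TwoStepResults:
    """Results of a two-step (mediation) MR.

    ``mediated_effect`` is the product of the two IVW slopes; its
    optional delta-method SE treats the steps as independent (two
    non-overlapping GWAS pairs).  ``flags`` lists steps whose Egger
    intercept test suggests directional pleiotropy (p <= 0.05).
    """

    step1: MRResults
    step2: MRResults
    mediated_effect: float
    mediated_se: float | None = None
    flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        parts = [
            self.step1.summary(),
            "",
            self.step2.summary(),
            "",
            f"mediated effect (IVW step1 x IVW step2): {self.mediated_effect:.4f}",
        ]
        if self.mediated_se is not None:
            parts[-1] += f" (se {self.mediated_se:.4f})"
        if self.flags:
            parts.append("pleiotropy flags: " + "; ".join(self.flags))
        return "\n".join(parts)


class TwoStepMR:
    """Two-step MR through a mediator.

    Step 1 estimates exposure -> mediator; step 2 mediator -> outcome.
    Each step is a full :class:`MRModel` analysis (instrument selection
    at the genome-wide threshold, harmonization, all estimators,
    heterogeneity, pleiotropy, leave-one-out).
    """

    def __init__(
        self,
        exposure: pd.DataFrame,
        mediator: pd.DataFrame,
        outcome: pd.DataFrame,
        instrument_pvalue: float = 5e-8,
        palindromic_eaf_window: float = 0.08,
        names: tuple[str, str, str] = ("exposure", "mediator", "outcome"),
    ):
        self.exposure = exposure
        self.mediator = mediator
        self.outcome = outcome
        self.instrument_pvalue = instrument_pvalue
        self.palindromic_eaf_window = palindromic_eaf_window
        self.names = names

    def _step(self, exp, out, exp_name, out_name, which) -> MRModel:
        try:
            model = MRModel.from_summary_stats(
                exp,
                out,
                instrument_pvalue=self.instrument_pvalue,
                palindromic_eaf_window=self.palindromic_eaf_window,
                exposure_name=exp_name,
                outcome_name=out_name,
            )
        except ValueError as exc:
            raise ValueError(f"{which}: {exc}") from exc
        if len(model.pairs) < 2:
            raise ValueError(
                f"{which}: fewer than 2 instruments survive harmonization"
            )
        return model

    def fit(
        self,
        *,
        ivw_model: str = "multiplicative_random",
        n_boot: int = 1000,
        seed: int | None = None,
        mediated_se: bool = True,
    ) -> TwoStepResults:
        e_name, m_name, o_name = self.names
        ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
        seed1, seed2 = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

        model1 = self._step(self.exposure, self.mediator, e_name, m_name, "step 1")
        res1 = model1.fit(ivw_model=ivw_model, n_boot=n_boot, seed=seed1)
        model2 = self._step(self.mediator, self.outcome, m_name, o_name, "step 2")
        res2 = model2.fit(ivw_model=ivw_model, n_boot=n_boot, seed=seed2)

        b1, b2 = res1.estimates["ivw"].beta, res2.estimates["ivw"].beta
        s1, s2 = res1.estimates["ivw"].se, res2.estimates["ivw"].se
        se = float(np.sqrt(b1**2 * s2**2 + b2**2 * s1**2)) if mediated_se else None

        flags = []
        for label, res in (("step 1", res1), ("step 2", res2)):
            if res.pleiotropy is not None and res.pleiotropy.p_value <= 0.05:
                flags.append(
                    f"{label}: Egger intercept p = {res.pleiotropy.p_value:.3g} <= 0.05"
                )
        return TwoStepResults(
            step1=res1,
            step2=res2,
            mediated_effect=float(b1 * b2),
            mediated_se=se,
            flags=flags,
        )
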