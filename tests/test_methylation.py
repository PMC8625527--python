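"""Unit tests for gene-level scoring and the differential screens."""

import statistics

import numpy as np
import pandas as pd
import pytest

from simpomr.methylation import (
    SimpoMethylation,
    adjust_qvalues,
    annotate_and_collapse,
    compute_simpo_scores,
    diff_methylation_simpo,
    dmp_scan,
    eligible_genes,
    intersect_gene_lists,
)


def simpo_oracle(body, promoter, denominator="df"):
    """Direct evaluation of the score from first principles (stdlib only)."""
    m, n = len(body), len(promoter)
    x_bar, y_bar = statistics.mean(body), statistics.mean(promoter)
    s1, s2 = statistics.variance(body), statistics.variance(promoter)
    denom = (m + n + 1) if denominator == "printed" else (m + n - 2)
    sw = ((m - 1) * s1 + (n - 1) * s2) / denom
    return (x_bar - y_bar) / (sw**0.5 * (1 / m + 1 / n) ** 0.5)


def build_cohort(rng, n_genes, n_samples, probe_range=(2, 6)):
    """Random beta matrix + annotation with per-gene probe counts."""
    rows, annot = [], []
    for g in range(n_genes):
        gene = f"G{g}"
        for region, tag in (("body", "b"), ("promoter", "p")):
            for k in range(rng.integers(*probe_range, endpoint=True)):
                annot.append((f"{gene}_{tag}{k}", gene, region))
                rows.append(rng.uniform(0.01, 0.99, n_samples))
    annot = pd.DataFrame(annot, columns=["probe_id", "gene", "region"])
    beta = pd.DataFrame(
        np.array(rows), index=pd.Index(annot["probe_id"], name="probe_id"),
        columns=[f"s{i}" for i in range(n_samples)],
    )
    return beta, annot


class TestSimpoScore:
    def test_worked_example(self, worked_example):
        beta, annot = worked_example
        scores, df = compute_simpo_scores(beta, annot)
        assert scores.loc["G", "s1"] == pytest.approx(2.8284, abs=1e-4)
        assert scores.loc["G", "s1"] == pytest.approx(simpo_oracle([0.6, 0.8], [0.2, 0.4]))
        assert df.loc["G"] == 2

    def test_matches_oracle_on_random_genes(self):
        rng = np.random.default_rng(42)
        beta, annot = build_cohort(rng, n_genes=200, n_samples=3)
        scores, _ = compute_simpo_scores(beta, annot)
        by_gene = annot.groupby("gene")
        for gene in scores.index:
            sub = by_gene.get_group(gene)
            body = sub.loc[sub["region"] == "body", "probe_id"]
            prom = sub.loc[sub["region"] == "promoter", "probe_id"]
            for s in beta.columns:
                expected = simpo_oracle(list(beta.loc[body, s]), list(beta.loc[prom, s]))
                assert scores.loc[gene, s] == pytest.approx(expected, rel=1e-10)

    def test_printed_denominator_variant_matches_oracle(self, worked_example):
        beta, annot = worked_example
        scores, _ = compute_simpo_scores(beta, annot, sw_denominator="printed")
        assert scores.loc["G", "s1"] == pytest.approx(
            simpo_oracle([0.6, 0.8], [0.2, 0.4], denominator="printed"), rel=1e-10
        )

    def test_zero_numerator_gives_zero(self):
        beta = pd.DataFrame(
            {"s1": [0.4, 0.6, 0.45, 0.55]},
            index=pd.Index(["b1", "b2", "p1", "p2"], name="probe_id"),
        )
        annot = pd.DataFrame(
            {
                "probe_id": ["b1", "b2", "p1", "p2"],
                "gene": ["G"] * 4,
                "region": ["body", "body", "promoter", "promoter"],
            }
        )
        scores, _ = compute_simpo_scores(beta, annot)
        assert scores.loc["G", "s1"] == pytest.approx(0.0, abs=1e-15)

    def test_region_swap_negates_score(self):
        rng = np.random.default_rng(7)
        beta, annot = build_cohort(rng, n_genes=20, n_samples=4)
        swapped = annot.assign(
            region=annot["region"].map({"body": "promoter", "promoter": "body"})
        )
        s1, _ = compute_simpo_scores(beta, annot)
        s2, _ = compute_simpo_scores(beta, swapped)
        pd.testing.assert_frame_equal(s2, -s1)

    def test_probe_permutation_invariance(self):
        rng = np.random.default_rng(8)
        beta, annot = build_cohort(rng, n_genes=10, n_samples=3)
        perm = rng.permutation(len(beta))
        s1, _ = compute_simpo_scores(beta, annot)
        s2, _ = compute_simpo_scores(beta.iloc[perm], annot.iloc[perm].reset_index(drop=True))
        pd.testing.assert_frame_equal(s1, s2)

    def test_balanced_equal_variance_closed_form(self):
        # with m = n and S1^2 = S2^2 the score reduces to (x-y)/(S1*sqrt(2/m))
        body, prom = [0.5, 0.6, 0.7], [0.2, 0.3, 0.4]
        beta = pd.DataFrame(
            {"s1": body + prom},
            index=pd.Index([f"b{i}" for i in range(3)] + [f"p{i}" for i in range(3)], name="probe_id"),
        )
        annot = pd.DataFrame(
            {
                "probe_id": beta.index,
                "gene": "G",
                "region": ["body"] * 3 + ["promoter"] * 3,
            }
        )
        scores, _ = compute_simpo_scores(beta, annot)
        s1 = statistics.stdev(body)
        expected = (statistics.mean(body) - statistics.mean(prom)) / (s1 * (2 / 3) ** 0.5)
        assert scores.loc["G", "s1"] == pytest.approx(expected, rel=1e-12)

    def test_ineligible_genes_excluded(self):
        annot = pd.DataFrame(
            {
                "probe_id": ["a1", "a2", "a3", "b1", "b2", "b3", "b4"],
                "gene": ["A"] * 3 + ["B"] * 4,
                "region": ["body", "body", "promoter"] + ["body", "body", "promoter", "promoter"],
            }
        )
        assert eligible_genes(annot) == ["B"]
        beta = pd.DataFrame(
            np.full((7, 2), 0.5), index=pd.Index(annot["probe_id"], name="probe_id"),
            columns=["s1", "s2"],
        )
        scores, _ = compute_simpo_scores(beta, annot)
        assert list(scores.index) == ["B"]

    def test_missing_values_dropped_per_sample(self):
        # sample s2 loses one body probe; effective m drops from 3 to 2
        beta = pd.DataFrame(
            {
                "s1": [0.6, 0.7, 0.8, 0.2, 0.3],
                "s2": [0.6, np.nan, 0.8, 0.2, 0.3],
            },
            index=pd.Index(["b1", "b2", "b3", "p1", "p2"], name="probe_id"),
        )
        annot = pd.DataFrame(
            {
                "probe_id": beta.index,
                "gene": "G",
                "region": ["body"] * 3 + ["promoter"] * 2,
            }
        )
        scores, _ = compute_simpo_scores(beta, annot)
        assert scores.loc["G", "s1"] == pytest.approx(simpo_oracle([0.6, 0.7, 0.8], [0.2, 0.3]))
        assert scores.loc["G", "s2"] == pytest.approx(simpo_oracle([0.6, 0.8], [0.2, 0.3]))

    def test_sample_unscored_when_region_drops_below_two(self):
        beta = pd.DataFrame(
            {"s1": [0.6, np.nan, 0.2, 0.3]},
            index=pd.Index(["b1", "b2", "p1", "p2"], name="probe_id"),
        )
        annot = pd.DataFrame(
            {
                "probe_id": beta.index,
                "gene": "G",
                "region": ["body", "body", "promoter", "promoter"],
            }
        )
        scores, _ = compute_simpo_scores(beta, annot)
        assert np.isnan(scores.loc["G", "s1"])

    def test_no_eligible_genes_returns_empty(self):
        annot = pd.DataFrame(
            {"probe_id": ["a1", "a2"], "gene": ["A", "A"], "region": ["body", "promoter"]}
        )
        beta = pd.DataFrame(
            {"s1": [0.5, 0.5]}, index=pd.Index(["a1", "a2"], name="probe_id")
        )
        scores, df = compute_simpo_scores(beta, annot)
        assert scores.empty and df.empty


class TestDifferentialScreen:
    def test_identical_groups_not_significant(self):
        scores = pd.DataFrame(
            [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]],
            index=pd.Index(["G"], name="gene"),
            columns=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series(
            ["control"] * 3 + ["treated"] * 3, index=scores.columns
        )
        res = diff_methylation_simpo(scores, groups)
        assert res.loc[0, "t_stat"] == pytest.approx(0.0)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)
        assert not res.loc[0, "significant"]

    def test_threshold_is_strict_on_alpha(self):
        rng = np.random.default_rng(3)
        # two genes: one with a strong planted shift, one null
        base = rng.normal(0, 1, (2, 40))
        base[0, 20:] += 5.0
        scores = pd.DataFrame(
            base, index=pd.Index(["shifted", "null"], name="gene"),
            columns=[f"s{i}" for i in range(40)],
        )
        groups = pd.Series(["control"] * 20 + ["treated"] * 20, index=scores.columns)
        res = diff_methylation_simpo(scores, groups, alpha=0.05).set_index("gene")
        assert bool(res.loc["shifted", "significant"])
        assert res.loc["shifted", "direction"] == "up"
        assert not bool(res.loc["null", "significant"])
        assert int(res["significant"].sum()) == 1

    def test_zero_variance_equal_means_p_one(self):
        scores = pd.DataFrame(
            [[1.0] * 8], index=pd.Index(["G"], name="gene"), columns=[f"s{i}" for i in range(8)]
        )
        groups = pd.Series(["control"] * 4 + ["treated"] * 4, index=scores.columns)
        res = diff_methylation_simpo(scores, groups)
        assert res.loc[0, "p_value"] == 1.0

    def test_welch_matches_scipy_per_gene(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        scores = pd.DataFrame(
            rng.normal(0, 1, (20, 30)),
            index=pd.Index([f"G{i}" for i in range(20)], name="gene"),
            columns=[f"s{i}" for i in range(30)],
        )
        groups = pd.Series(["control"] * 14 + ["treated"] * 16, index=scores.columns)
        res = diff_methylation_simpo(scores, groups).set_index("gene")
        for gene in scores.index:
            t, p = stats.ttest_ind(
                scores.loc[gene][groups == "treated"],
                scores.loc[gene][groups == "control"],
                equal_var=False,
            )
            assert res.loc[gene, "t_stat"] == pytest.approx(t, rel=1e-12)
            assert res.loc[gene, "p_value"] == pytest.approx(p, rel=1e-12)


class TestDmpScan:
    @staticmethod
    def _toy(rng, n_probes=12, n1=7, n2=9):
        beta = pd.DataFrame(
            rng.uniform(0.1, 0.9, (n_probes, n1 + n2)),
            index=pd.Index([f"cg{i}" for i in range(n_probes)], name="probe_id"),
            columns=[f"s{i}" for i in range(n1 + n2)],
        )
        groups = pd.Series(["control"] * n1 + ["treated"] * n2, index=beta.columns)
        return beta, groups

    def test_constant_probe(self):
        beta, groups = self._toy(np.random.default_rng(0))
        beta.iloc[0] = 0.5
        res = dmp_scan(beta, groups).set_index("probe_id")
        assert res.loc["cg0", "stat"] == 0.0
        assert res.loc["cg0", "p_value"] == 1.0

    def test_matches_ols_oracle(self):
        """The vectorised scan must equal per-probe OLS on a group indicator."""
        import statsmodels.api as sm

        beta, groups = self._toy(np.random.default_rng(1))
        res = dmp_scan(beta, groups).set_index("probe_id")
        x = sm.add_constant((groups == "treated").astype(float).to_numpy())
        for probe in beta.index:
            fit = sm.OLS(beta.loc[probe].to_numpy(), x).fit()
            assert res.loc[probe, "stat"] == pytest.approx(fit.fvalue, rel=1e-10)
            assert res.loc[probe, "p_value"] == pytest.approx(fit.f_pvalue, rel=1e-10)

    def test_q_threshold_screen(self):
        rng = np.random.default_rng(2)
        beta, groups = self._toy(rng, n_probes=30, n1=15, n2=15)
        beta.iloc[0, 15:] = np.clip(beta.iloc[0, 15:] + 0.6, 0, 1)  # planted probe
        res = dmp_scan(beta, groups)
        assert res["significant"].equals(res["q_value"] < 0.001)

    def test_gene_annotation_attached(self):
        beta, groups = self._toy(np.random.default_rng(3), n_probes=4)
        annot = pd.DataFrame(
            {
                "probe_id": ["cg0", "cg1", "cg2", "cg3"],
                "gene": ["A", "A", "B", ""],
                "region": ["body", "promoter", "body", "promoter"],
            }
        )
        res = dmp_scan(beta, groups, annot=annot)
        assert list(res["gene"]) == ["A", "A", "B", ""]


class TestQvalues:
    @staticmethod
    def bh_oracle(p):
        """Brute-force step-up: q_(i) = min_{j >= i} m * p_(j) / j, capped at 1."""
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        q = [0.0] * m
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            q[i] = running
        return q

    def test_single_p_unchanged(self):
        assert adjust_qvalues([0.05]) == pytest.approx([0.05])

    def test_matches_oracle(self):
        p = [0.01, 0.04, 0.03, 0.005]
        assert adjust_qvalues(p) == pytest.approx(self.bh_oracle(p), rel=1e-12)

    def test_spec_example(self):
        assert adjust_qvalues([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_ties_all_equal(self):
        assert adjust_qvalues([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_empty(self):
        assert adjust_qvalues([]).size == 0

    def test_all_permutations_of_random_pvalues(self):
        from itertools import permutations

        rng = np.random.default_rng(11)
        base = rng.uniform(0, 1, 6)
        for perm in permutations(base):
            assert adjust_qvalues(list(perm)) == pytest.approx(
                self.bh_oracle(list(perm)), rel=1e-12
            )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_qvalues([0.5, 1.2])


class TestCollapseAndIntersect:
    def test_dedup(self):
        dmps = pd.DataFrame(
            {"probe_id": ["c1", "c2", "c3"], "gene": ["G1", "G1", "G2"], "significant": True}
        )
        assert annotate_and_collapse(dmps) == ["G1", "G2"]

    def test_empty(self):
        dmps = pd.DataFrame({"probe_id": [], "gene": [], "significant": []})
        assert annotate_and_collapse(dmps) == []

    def test_unannotated_probes_dropped(self):
        dmps = pd.DataFrame(
            {"probe_id": ["c1", "c2"], "gene": ["G1", ""], "significant": True}
        )
        assert annotate_and_collapse(dmps) == ["G1"]

    def test_many_to_few_cardinality(self):
        # 165 significant probes spread over exactly 140 genes
        rng = np.random.default_rng(9)
        genes = [f"GENE{i:03d}" for i in range(140)]
        assignment = genes + list(rng.choice(genes, 25))
        dmps = pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(165)],
                "gene": assignment,
                "significant": True,
            }
        )
        assert len(annotate_and_collapse(dmps)) == 140

    def test_intersection_sorted(self):
        assert intersect_gene_lists(
            ["UNC13A", "OTOF", "A"], ["UNC13A", "OTOF", "B"]
        ) == ["OTOF", "UNC13A"]

    def test_disjoint(self):
        assert intersect_gene_lists(["A"], ["B"]) == []

    def test_idempotent(self):
        a = ["Z", "A", "A", "M"]
        assert intersect_gene_lists(a, a) == ["A", "M", "Z"]


class TestModelFrontEnd:
    def test_fit_produces_consistent_results(self):
        from simpomr import MethylSimConfig, simulate_methylation_cohort

        beta, annot, groups, truth = simulate_methylation_cohort(
            MethylSimConfig(n_genes=30, effect_genes=3, n_control=25, n_treated=25, seed=21)
        )
        res = SimpoMethylation(beta, annot, groups).fit()
        assert set(res.intersection) == set(res.simpo_genes) & set(res.dmp_genes)
        assert res.scores.shape == (30, 50)
        assert "intersection" in res.summary()

    def test_rejects_out_of_range_beta(self):
        beta = pd.DataFrame({"s1": [1.5, 0.2]}, index=pd.Index(["a", "b"], name="probe_id"))
        annot = pd.DataFrame(
            {"probe_id": ["a", "b"], "gene": "G", "region": ["body", "promoter"]}
        )
        groups = pd.Series(["control"], index=["s1"])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            SimpoMethylation(beta, annot, groups)
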