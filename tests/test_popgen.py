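"""Diversity, exact HWE, F-statistics, outlier scan, admixture, K choice."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txsnp import popgen
from txsnp import simulate as sim
from txsnp.io_formats import GenotypeMatrix


def matrix_from_counts(n_aa, n_ab, n_bb, a="A", b="G", pop="P"):
    col = [a + a] * n_aa + ["".join(sorted(a + b))] * n_ab + [b + b] * n_bb
    ids = [f"i{k}" for k in range(len(col))]
    return GenotypeMatrix(
        calls=pd.DataFrame({"L1": col}, index=ids),
        populations=pd.Series([pop] * len(col), index=ids),
    )


class TestLocusStats:
    def test_textbook_heterozygosity(self):
        # AA=25, AB=50, BB=25: Ho=0.5, unbiased He=(200/199)*0.5
        stats = popgen.locus_stats(matrix_from_counts(25, 50, 25))
        row = stats.loc["L1"]
        assert row["ho"] == pytest.approx(0.5)
        assert row["he"] == pytest.approx((200 / 199) * 0.5)
        assert row["maf"] == pytest.approx(0.5)

    def test_monomorphic_locus(self):
        stats = popgen.locus_stats(matrix_from_counts(30, 0, 0))
        row = stats.loc["L1"]
        assert (row["ho"], row["he"], row["hwe_p"]) == (0.0, 0.0, 1.0)

    def test_allele_label_swap_invariance(self):
        a = popgen.locus_stats(matrix_from_counts(10, 14, 6)).loc["L1"]
        b = popgen.locus_stats(matrix_from_counts(6, 14, 10)).loc["L1"]
        for field in ("maf", "ho", "he", "hwe_p"):
            assert a[field] == pytest.approx(b[field])


class TestExactHwe:
    def test_two_heterozygotes_enumeration(self):
        # alleles (2,2), outcomes: het=0 w.p. 1/3, het=2 w.p. 2/3;
        # observed het=2 -> p = 1 (the other outcome is less likely... no:
        # P(0)=1/3 <= P(2)=2/3, so both included)
        assert popgen.hwe_exact_pvalue(0, 2, 0) == pytest.approx(1.0)
        dist = popgen.hwe_enumeration(2, 2)
        assert dist[0] == pytest.approx(1 / 3)
        assert dist[2] == pytest.approx(2 / 3)

    def test_extreme_het_deficit_is_significant(self):
        p = popgen.hwe_exact_pvalue(50, 0, 50)
        assert p < 1e-6

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(n_a=st.integers(0, 60), n_b=st.integers(0, 60))
    def test_enumeration_sums_to_one(self, n_a, n_b):
        if (n_a + n_b) % 2:
            n_b += 1
        dist = popgen.hwe_enumeration(n_a, n_b)
        assert abs(sum(dist.values()) - 1.0) < 1e-9

    def test_matches_small_case_brute_force(self):
        # n=3 diploids, alleles (3,3): enumerate genotype assignments
        # directly: P(h) proportional to n!/(n_AA! h! n_BB!) * 2^h
        import math
        weights = {}
        for h in (1, 3):
            n_aa = (3 - h) // 2
            n_bb = (3 - h) // 2
            weights[h] = (math.factorial(3)
                          / (math.factorial(n_aa) * math.factorial(h)
                             * math.factorial(n_bb))) * 2 ** h
        total = sum(weights.values())
        dist = popgen.hwe_enumeration(3, 3)
        for h, w in weights.items():
            assert dist[h] == pytest.approx(w / total)


class TestWeirCockerham:
    def test_identical_groups_give_null_theta(self):
        col = ["AA"] * 10 + ["AG"] * 10 + ["GG"] * 10
        ids = [f"i{k}" for k in range(60)]
        m = GenotypeMatrix(
            calls=pd.DataFrame({"L1": col * 2, "L2": col * 2}, index=ids),
            populations=pd.Series(["X"] * 30 + ["Y"] * 30, index=ids),
        )
        res = popgen.weir_cockerham(m, n_permutations=100, seed=0)
        assert res.overall_fst <= 0.005
        assert res.overall_p > 0.5

    def test_fixed_differences_give_theta_one(self):
        ids = [f"i{k}" for k in range(40)]
        m = GenotypeMatrix(
            calls=pd.DataFrame({"L1": ["AA"] * 20 + ["GG"] * 20,
                                "L2": ["CC"] * 20 + ["TT"] * 20}, index=ids),
            populations=pd.Series(["X"] * 20 + ["Y"] * 20, index=ids),
        )
        res = popgen.weir_cockerham(m, n_permutations=100, seed=0)
        assert res.overall_fst == pytest.approx(1.0)
        assert res.overall_p < 0.05

    def test_recovery_at_target_fst(self, panel):
        matrix, _ = panel
        res = popgen.weir_cockerham(matrix, n_permutations=200, seed=3)
        assert abs(res.overall_fst - 0.05) < 0.02
        assert res.overall_p < 0.05

    def test_group_relabeling_invariance(self, panel):
        matrix, _ = panel
        dosage = matrix.dosage()
        labels = matrix.populations.to_numpy()
        swapped = np.where(labels == "Hungarian", "Tabor", "Hungarian")
        assert popgen.theta_multilocus(dosage, labels) == pytest.approx(
            popgen.theta_multilocus(dosage, swapped))

    def test_tiny_group_rejected(self):
        m = matrix_from_counts(2, 0, 0)
        m.populations.iloc[0] = "Q"
        with pytest.raises(ValueError, match="fewer than 2"):
            popgen.weir_cockerham(m, n_permutations=10)

    def test_ordered_recovery_across_fst_levels(self):
        """Estimates at F = 0, 0.05, 0.2 are ordered and close."""
        estimates = []
        for f in (0.0, 0.05, 0.2):
            cfg = sim.SimulationConfig(seed=41, target_fst=f)
            matrix, _ = sim.simulate_genotypes(cfg)
            estimates.append(popgen.theta_multilocus(
                matrix.dosage(), matrix.populations.to_numpy()))
        assert estimates == sorted(estimates)
        assert abs(estimates[0]) < 0.02
        assert abs(estimates[1] - 0.05) < 0.02
        assert abs(estimates[2] - 0.2) < 0.05


class TestHolm:
    def test_holm_rejects_subset_of_uncorrected(self):
        from statsmodels.stats.multitest import multipletests
        pvals = [0.001, 0.012, 0.02, 0.04, 0.3]
        holm, _, _, _ = multipletests(pvals, alpha=0.05, method="holm")
        raw = np.array(pvals) < 0.05
        assert set(np.where(holm)[0]) <= set(np.where(raw)[0])


class TestOutlierScan:
    def test_null_simulation_yields_no_outliers(self):
        cfg = sim.SimulationConfig(seed=11, target_fst=0.0)
        matrix, _ = sim.simulate_genotypes(cfg)
        rep = popgen.outlier_scan(matrix, n_permutations=300, seed=3)
        assert len(rep.outlier_loci) <= 1   # <= 1 tolerated per ~100 loci

    def test_planted_fixed_loci_flagged(self):
        cfg = sim.SimulationConfig(seed=9, target_fst=0.02, n_loci=95)
        matrix, _ = sim.simulate_genotypes(cfg)
        calls = matrix.calls.copy()
        planted = [f"X{j}" for j in range(5)]
        for loc in planted:
            calls[loc] = ["AA"] * 70 + ["GG"] * 70
        m2 = GenotypeMatrix(calls=calls, populations=matrix.populations,
                            gh_genotypes=matrix.gh_genotypes)
        rep = popgen.outlier_scan(m2, n_permutations=300, seed=2)
        assert set(rep.outlier_loci) == set(planted)

    def test_partition_is_exhaustive_and_reusable(self):
        cfg = sim.SimulationConfig(seed=12, target_fst=0.05)
        matrix, _ = sim.simulate_genotypes(cfg)
        rep = popgen.outlier_scan(matrix, n_permutations=150, seed=4)
        assert (set(rep.outlier_loci) | set(rep.neutral_loci)
                == set(matrix.loci))
        neutral = matrix.subset(loci=rep.neutral_loci)
        assert len(neutral.loci) == len(matrix.loci) - len(rep.outlier_loci)

    def test_few_permutations_warn(self):
        cfg = sim.SimulationConfig(seed=13, n_individuals=10, n_loci=5)
        matrix, _ = sim.simulate_genotypes(cfg)
        with pytest.warns(UserWarning, match="permutations"):
            popgen.outlier_scan(matrix, n_permutations=50, seed=1)


class TestAdmixture:
    def test_k1_closed_form(self, panel):
        matrix, _ = panel
        fit = popgen.admixture_em(matrix, K=1)
        assert np.allclose(fit.Q, 1.0)
        # loglik equals the binomial log-probability at pooled frequencies
        dosage = matrix.dosage().astype(float)
        called = dosage >= 0
        d = np.where(called, dosage, 0.0)
        p = d.sum(0) / np.maximum((2.0 * called).sum(0), 1)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        ll = (d * np.log(p) + (2 * called - d) * np.log(1 - p)).sum()
        assert fit.loglik == pytest.approx(ll, rel=1e-9)

    def test_separable_mixture_recovers_assignments(self):
        rng = np.random.default_rng(0)
        n, L = 30, 60
        ids = [f"i{k}" for k in range(2 * n)]
        rows = []
        for k in range(2 * n):
            p = 1.0 if k < n else 0.0   # fully diverged populations
            dos = rng.binomial(2, p, size=L)
            rows.append(["AA" if d == 2 else ("AG" if d == 1 else "GG")
                         for d in dos])
        m = GenotypeMatrix(
            calls=pd.DataFrame(rows, index=ids,
                               columns=[f"L{j}" for j in range(L)]),
            populations=pd.Series(["X"] * n + ["Y"] * n, index=ids),
        )
        fit = popgen.admixture_em(m, K=2, seed=1)
        # align cluster order to population X
        q1 = fit.Q[:n].mean(axis=0)
        k_x = int(np.argmax(q1))
        err = np.concatenate([1 - fit.Q[:n, k_x], fit.Q[n:, k_x]])
        assert err.max() <= 0.05

    def test_loglik_monotone_nondecreasing(self, admixture_fits):
        for fits in admixture_fits.values():
            for fit in fits:
                diffs = np.diff(fit.loglik_trace)
                assert (diffs >= -1e-6).all()

    def test_k_above_individuals_rejected(self, panel):
        matrix, _ = panel
        with pytest.raises(ValueError):
            popgen.admixture_em(matrix, K=matrix.n_individuals + 1)


class TestChooseK:
    @staticmethod
    def runs_from_means(means, d=10 / np.sqrt(2)):
        """Two runs per K at mean +- d: sd (ddof=1) = d*sqrt(2)."""
        return {k + 1: [_FakeFit(m + d), _FakeFit(m - d)]
                for k, m in enumerate(means)}

    def test_hand_computed_delta_k(self):
        fits = self.runs_from_means([-2000.0, -1500.0, -1450.0, -1445.0])
        out = popgen.choose_k(fits)
        table = out["delta_k_table"]
        assert table.loc[2, "delta_k"] == pytest.approx(45.0)
        assert table.loc[3, "delta_k"] == pytest.approx(4.5)
        assert out["k_evanno"] == 2

    def test_linear_loglik_is_flat(self):
        fits = self.runs_from_means([-300.0, -200.0, -100.0])
        with pytest.warns(UserWarning, match="flat"):
            out = popgen.choose_k(fits)
        assert np.isclose(out["delta_k_table"]["delta_k"].dropna(), 0).all()

    def test_two_population_panel_selects_k2(self, admixture_fits):
        out = popgen.choose_k(admixture_fits)
        assert out["k_evanno"] == 2

    def test_requires_consecutive_ks_and_replicates(self):
        with pytest.raises(ValueError, match="consecutive"):
            popgen.choose_k({1: [_FakeFit(-10)] * 2, 3: [_FakeFit(-9)] * 2})


class _FakeFit:
    def __init__(self, loglik):
        self.loglik = loglik
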