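"""Mendelian expectation engine, test statistics and corrections."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chipforge import mendel
from chipforge import synthdata as sd
from chipforge.containers import AA, AB, BB, CrossCohort


class TestExpectedOffspringDist:
    def test_all_nine_combinations_sum_and_symmetry(self):
        for gm, gf in itertools.product((AA, AB, BB), repeat=2):
            d = mendel.expected_offspring_dist(gm, gf)
            assert d.sum() == pytest.approx(1.0)
            assert np.allclose(d, mendel.expected_offspring_dist(gf, gm))

    @pytest.mark.parametrize(
        "gm,gf,expected",
        [
            (AB, AA, [0.5, 0.5, 0.0]),
            (AB, AB, [0.25, 0.5, 0.25]),
            (AA, BB, [0.0, 1.0, 0.0]),
            (AA, AA, [1.0, 0.0, 0.0]),
            (AB, BB, [0.0, 0.5, 0.5]),
        ],
    )
    def test_punnett_values(self, gm, gf, expected):
        assert np.allclose(mendel.expected_offspring_dist(gm, gf), expected)

    def test_invalid_genotype_rejected(self):
        with pytest.raises(ValueError):
            mendel.expected_offspring_dist(5, AA)


class TestInformativeLoci:
    def test_criterion(self):
        maternal = np.array([AB, AB, AA, AA, -1])
        paternal = np.array([AA, AB, BB, AB, AB])
        mask = mendel.informative_loci(maternal, paternal)
        assert mask.tolist() == [True, False, False, True, False]


class TestSelectCrosses:
    def test_k1_picks_largest(self):
        crosses = {"a": {1, 2}, "b": {1, 2, 3}, "c": {4}}
        assert mendel.select_crosses(crosses, 1) == ["b"]

    def test_disjoint_sets_all_chosen(self):
        crosses = {"a": {1}, "b": {2}, "c": {3}}
        assert sorted(mendel.select_crosses(crosses, 3)) == ["a", "b", "c"]

    def test_matches_exhaustive_optimum_small_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(3, 8))
            crosses = {
                f"x{i}": set(rng.choice(30, size=rng.integers(1, 12), replace=False).tolist())
                for i in range(n)
            }
            k = int(rng.integers(1, n + 1))
            chosen = mendel.select_crosses(crosses, k)
            best = max(
                len(set().union(*(crosses[c] for c in combo)))
                for combo in itertools.combinations(crosses, k)
            )
            assert len(set().union(*(crosses[c] for c in chosen))) == best

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mendel.select_crosses({}, 1)


class TestChi2Gof:
    def test_perfect_fit(self):
        stat, df, p = mendel.chi2_gof([16, 16], [0.5, 0.5])
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_statistic(self):
        # (10-16)^2/16 + (22-16)^2/16 = 4.5 on 1 df
        stat, df, p = mendel.chi2_gof([10, 22], [0.5, 0.5])
        assert stat == pytest.approx(4.5)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(4.5, 1))

    def test_expected_zero_category_hit_is_incompatible(self):
        out = mendel.chi2_gof([31, 0, 1], [0.5, 0.5, 0.0])
        assert out == "incompatible"

    def test_all_nocall_rejected(self):
        with pytest.raises(ValueError):
            mendel.chi2_gof([0, 0], [0.5, 0.5])

    def test_matches_from_scratch_oracle_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            probs = rng.dirichlet(np.ones(3))
            obs = rng.multinomial(50, probs)
            stat, df, p = mendel.chi2_gof(obs, probs)
            expected = probs * obs.sum()
            oracle = float(((obs - expected) ** 2 / expected).sum())
            assert stat == pytest.approx(oracle)


class TestFisherCombine:
    def test_identity_cases(self):
        assert mendel.fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)
        assert mendel.fisher_combine([0.05]) == 0.05

    def test_three_tenths_example(self):
        # X = -2 * 3 * ln(0.1) = 13.8155, chi2_6 upper tail
        assert mendel.fisher_combine([0.1, 0.1, 0.1]) == pytest.approx(0.0319, abs=5e-4)

    def test_zero_propagates_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert mendel.fisher_combine([0.0, 0.5]) == 0.0

    def test_k2_closed_form_grid(self):
        # for two p values the combined p has closed form q(1 - ln q), q = p1*p2
        for p1 in (0.01, 0.1, 0.4, 0.9):
            for p2 in (0.05, 0.3, 0.7):
                q = p1 * p2
                assert mendel.fisher_combine([p1, p2]) == pytest.approx(
                    q * (1 - math.log(q)), rel=1e-10
                )

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            p = rng.uniform(0.001, 1.0, size=rng.integers(2, 6))
            expected = stats.combine_pvalues(p, method="fisher").pvalue
            assert mendel.fisher_combine(p) == pytest.approx(expected, rel=1e-9)


class TestHolm:
    def test_stepdown_example(self):
        adjusted, reject = mendel.holm_correct([0.01, 0.03, 0.04], alpha=0.05)
        assert np.allclose(adjusted, [0.03, 0.06, 0.06])
        assert reject.tolist() == [True, False, False]

    def test_single_p_unchanged(self):
        adjusted, _ = mendel.holm_correct([0.2])
        assert adjusted[0] == pytest.approx(0.2)

    def test_all_ones_never_rejected(self):
        _, reject = mendel.holm_correct([1.0] * 10)
        assert not reject.any()

    def test_empty_input(self):
        adjusted, reject = mendel.holm_correct([])
        assert adjusted.size == 0 and reject.size == 0

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, size=40)
        adjusted, reject = mendel.holm_correct(p, alpha=0.05)
        sm_reject, sm_adjusted, _, _ = multipletests(p, alpha=0.05, method="holm")
        assert np.allclose(adjusted, sm_adjusted)
        assert np.array_equal(reject, sm_reject)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_holm_rejects_superset_of_bonferroni(self, pvals):
        _, holm = mendel.holm_correct(pvals, alpha=0.05)
        _, bonf = mendel.bonferroni_correct(pvals, alpha=0.05)
        assert np.all(holm | ~bonf)  # bonferroni => holm


def _fair_cohorts(n_loci, seed, sizes=(32, 31, 32), distortion=0.5):
    rng = np.random.default_rng(seed)
    cohorts = []
    for ci, size in enumerate(sizes):
        spec = sd.CrossSpec(
            maternal=rng.choice([AA, AB, BB], n_loci, p=[0.3, 0.4, 0.3]),
            paternal=rng.choice([AA, AB, BB], n_loci, p=[0.3, 0.4, 0.3]),
            n_offspring=size,
            distortion=distortion,
        )
        cohorts.append(sd.simulate_cross(spec, seed=seed * 7 + ci, cross_id=f"c{ci}"))
    return cohorts


class TestMendelScreen:
    def test_null_combined_p_near_uniform(self):
        # discrete chi-square p values at n~32: the empirical CDF may exceed
        # the uniform CDF slightly; bound the excess
        cohorts = _fair_cohorts(10_000, seed=5)
        result, _ = mendel.mendel_screen(cohorts)
        p = result.table.combined_p.dropna().to_numpy()
        grid = np.linspace(0.001, 1.0, 200)
        ecdf = np.searchsorted(np.sort(p), grid, side="right") / p.size
        assert np.max(ecdf - grid) < 0.08

    def test_agrees_with_scalar_engine(self):
        # vectorized screen vs per-locus chi2_gof + fisher on a small cohort set
        cohorts = _fair_cohorts(50, seed=6)
        result, _ = mendel.mendel_screen(cohorts)
        for li, locus in enumerate(cohorts[0].locus_ids):
            ps = []
            for cohort in cohorts:
                if not mendel.informative_loci(
                    cohort.maternal[li : li + 1], cohort.paternal[li : li + 1]
                )[0]:
                    continue
                exp = mendel.expected_offspring_dist(
                    int(cohort.maternal[li]), int(cohort.paternal[li])
                )
                out = mendel.chi2_gof(cohort.counts[li], exp)
                assert out != "incompatible"
                ps.append(out[2])
            row = result.table.loc[locus]
            if not ps:
                assert row.verdict == "untestable"
            else:
                assert row.combined_p == pytest.approx(mendel.fisher_combine(ps), rel=1e-9)

    def test_incompatible_flagged_and_excluded(self):
        cohort = CrossCohort(
            cross_id="c",
            locus_ids=["good", "bad"],
            maternal=np.array([AB, AB], dtype=np.int8),
            paternal=np.array([AA, AA], dtype=np.int8),
            counts=np.array([[16, 16, 0], [15, 16, 1]]),
            nocalls=np.array([0, 0]),
            n_offspring=32,
        )
        result, summary = mendel.mendel_screen([cohort])
        assert result.table.loc["bad", "verdict"] == "incompatible"
        assert summary.incompatible == 1
        assert "bad" not in summary.retained_loci

    def test_retained_ledger_arithmetic(self):
        cohorts = _fair_cohorts(500, seed=7, distortion=0.9)
        retained = cohorts[0].locus_ids[:400]
        result, summary = mendel.mendel_screen(cohorts, retained)
        n_final = len([l for l in summary.retained_loci])
        assert n_final == 400 - summary.deviant - summary.incompatible

    def test_mismatched_locus_ids_rejected(self):
        cohorts = _fair_cohorts(10, seed=8)
        with pytest.raises(ValueError):
            mendel.mendel_screen(cohorts, retained_loci=["nope"])
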