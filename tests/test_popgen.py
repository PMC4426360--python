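"""LD, Hardy-Weinberg, relatedness and PCA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chipforge import popgen
from chipforge import synthdata as sd
from chipforge.containers import DosageMatrix


def make_dosage(dosages, contigs=None, positions=None):
    d = np.asarray(dosages)
    m = d.shape[0]
    return DosageMatrix(
        dosages=d,
        marker_ids=[f"m{i}" for i in range(m)],
        sample_ids=[f"s{j}" for j in range(d.shape[1])],
        contigs=np.array(contigs if contigs is not None else ["c"] * m, dtype=object),
        positions=np.array(positions if positions is not None else np.arange(1, m + 1) * 100),
    )


class TestR2Dosage:
    def test_identity_and_orthogonal(self):
        assert popgen.r2_dosage([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)
        assert popgen.r2_dosage([0, 2, 0, 2], [0, 0, 2, 2]) == pytest.approx(0.0)

    def test_matches_pearson_oracle(self):
        x = np.array([0, 1, 2, 2])
        y = np.array([0, 0, 1, 2])
        expected = stats.pearsonr(x, y).statistic ** 2
        assert popgen.r2_dosage(x, y) == pytest.approx(expected)

    def test_monomorphic_not_computable(self):
        assert math.isnan(popgen.r2_dosage([1, 1, 1, 1], [0, 1, 2, 0]))

    def test_pairwise_complete_samples(self):
        x = np.array([0, 1, 2, -1, 2])
        y = np.array([0, 1, 2, 2, -1])
        expected = stats.pearsonr([0, 1, 2], [0, 1, 2]).statistic ** 2
        assert popgen.r2_dosage(x, y) == pytest.approx(expected)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_relabel_invariance_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, size=20)
        y = rng.integers(0, 3, size=20)
        r2 = popgen.r2_dosage(x, y)
        if math.isnan(r2):
            assert math.isnan(popgen.r2_dosage(2 - x, y))
            return
        assert 0.0 <= r2 <= 1.0
        assert popgen.r2_dosage(2 - x, y) == pytest.approx(r2)
        assert popgen.r2_dosage(y, x) == pytest.approx(r2)

    def test_approaches_haplotype_r2_when_phase_unambiguous(self):
        # with no double heterozygotes the diplotype pairs are phase-known;
        # composite r2 is the phase-free estimator of the gamete r2 and the
        # two agree closely at large n
        rng = np.random.default_rng(7)
        n = 500
        g1, h1 = rng.integers(0, 2, n), rng.integers(0, 2, n)
        g2, h2 = rng.integers(0, 2, n), rng.integers(0, 2, n)
        for i in range(n):
            while g1[i] + g2[i] == 1 and h1[i] + h2[i] == 1:
                g2[i], h2[i] = rng.integers(0, 2), rng.integers(0, 2)
        r2c = popgen.r2_dosage(g1 + g2, h1 + h2)
        gam = np.corrcoef(np.r_[g1, g2], np.r_[h1, h2])[0, 1] ** 2
        assert r2c == pytest.approx(gam, abs=0.02)


class TestLdScan:
    def test_perfect_pool_all_one(self):
        hap = np.array([[0, 1, 0, 1], [1, 0, 1, 0]])
        pool = sd.HaplotypePool({"c1": (np.array([100, 300, 600, 900]), hap)}, rho=0.0)
        m = sd.simulate_linked_genotypes(pool, 40, seed=1)
        scan = popgen.ld_scan(m)
        assert np.allclose(scan.pairs.r2, 1.0)
        # median perfect-LD distance = median of the pairwise gaps
        gaps = sorted(
            abs(a - b)
            for i, a in enumerate([100, 300, 600, 900])
            for b in [100, 300, 600, 900][i + 1 :]
        )
        assert scan.median_perfect_ld_distance == pytest.approx(np.median(gaps))

    def test_half_open_distance_bins(self):
        d = np.array([[0, 0, 1, 1, 2, 2], [0, 0, 1, 1, 2, 2], [0, 1, 0, 2, 1, 2]])
        dm = make_dosage(d, positions=[1, 200, 201])
        scan = popgen.ld_scan(dm, distance_bin=200)
        # pair (m0, m1): distance 199 -> bin [0, 200); (m0, m2): 200 -> [200, 400)
        h = scan.hist2d
        assert h.loc[0].sum() >= 1 and h.loc[200].sum() >= 1
        row_199 = scan.pairs.set_index(["marker_a", "marker_b"]).loc[("m0", "m1")]
        assert row_199.distance == 199

    def test_same_vs_cross_contig_summaries(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(6, 30))
        dm = make_dosage(d, contigs=["a", "a", "a", "b", "b", "b"],
                         positions=[100, 300, 900, 100, 500, 800])
        scan = popgen.ld_scan(dm)
        same = scan.pairs[scan.pairs.same_contig]
        cross = scan.pairs[~scan.pairs.same_contig]
        assert len(same) == 6 and len(cross) == 9
        assert scan.same_contig_mean == pytest.approx(same.r2.mean())
        assert scan.cross_contig_mean == pytest.approx(cross.r2.mean())
        assert scan.mean_r2 == pytest.approx(scan.pairs.r2.mean())

    def test_cross_contig_mean_near_inverse_n(self):
        means = []
        for seed in range(20):
            pool = sd.random_haplotype_pool(4, 25, 100_000, 8, 1e-4, seed=seed)
            m = sd.simulate_linked_genotypes(pool, 40, seed=1000 + seed)
            means.append(popgen.ld_scan(m).cross_contig_mean)
        assert np.mean(means) == pytest.approx(1 / 40, abs=0.01)


def _hwe_exact_oracle(n_aa, n_ab, n_bb):
    """Full-enumeration conditional HWE test with exact rational arithmetic."""
    from fractions import Fraction

    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    f = math.factorial

    def prob(h):
        aa = (n_a - h) // 2
        bb = (n_b - h) // 2
        return Fraction(f(n) * 2**h * f(n_a) * f(n_b), f(aa) * f(h) * f(bb) * f(2 * n))

    hets = [h for h in range(0, min(n_a, n_b) + 1) if (h % 2) == (n_a % 2)]
    probs = {h: prob(h) for h in hets}
    obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHWE:
    def test_matches_enumeration_oracle_small_n(self):
        for n in (5, 12, 25, 50):
            for n_ab in range(0, n + 1):
                for n_aa in range(0, n - n_ab + 1):
                    n_bb = n - n_ab - n_aa
                    got = popgen.hwe_test(n_aa, n_ab, n_bb)
                    want = _hwe_exact_oracle(n_aa, n_ab, n_bb)
                    assert got == pytest.approx(want, abs=1e-9), (n_aa, n_ab, n_bb)

    def test_equilibrium_table_large_p(self):
        assert popgen.hwe_test(25, 50, 25) > 0.5

    def test_extreme_departure_small_p(self):
        assert popgen.hwe_test(0, 100, 0) < 1e-10

    def test_monomorphic_p_one(self):
        assert popgen.hwe_test(40, 0, 0) == 1.0

    def test_chisq_mode_matches_scipy(self):
        p_hat = (2 * 20 + 40) / (2 * 100.0)
        expected = 100 * np.array([p_hat**2, 2 * p_hat * (1 - p_hat), (1 - p_hat) ** 2])
        stat = ((np.array([20, 40, 40]) - expected) ** 2 / expected).sum()
        want = stats.chi2.sf(stat, 1)
        assert popgen.hwe_test(20, 40, 40, mode="chisq") == pytest.approx(want)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            popgen.hwe_test(-1, 0, 2)
        with pytest.raises(ValueError):
            popgen.hwe_test(0, 0, 0)
        with pytest.raises(ValueError):
            popgen.hwe_test(1, 1, 1, mode="bogus")


class TestAjk:
    def test_single_locus_formula(self):
        # p = 0.5 from dosages [2, 2, 0, 0]; for the two B-homozygotes:
        # (2-1)(2-1) / (2 * 0.5 * 0.5) = 2
        dm = make_dosage([[2, 2, 0, 0]])
        kin = popgen.ajk_relatedness(dm)
        assert kin.values[0, 1] == pytest.approx(2.0)

    def test_symmetric_and_marker_order_invariant(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(100, 20))
        dm = make_dosage(d)
        kin = popgen.ajk_relatedness(dm)
        assert np.allclose(kin.values, kin.values.T)
        perm = rng.permutation(100)
        kin2 = popgen.ajk_relatedness(make_dosage(d[perm]))
        assert np.allclose(kin.values, kin2.values)

    def test_fixed_markers_excluded(self):
        d = np.array([[2, 2, 2, 2], [0, 1, 2, 1]])
        kin = popgen.ajk_relatedness(make_dosage(d))
        assert kin.n_markers_excluded == 1
        assert kin.n_markers_used == 1

    def test_unrelated_mean_near_zero_at_reference_freqs(self):
        # unrelated pairs standardized by the generating frequencies have
        # expectation 0 (sample frequencies would shift them to -1/(n-1))
        offs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            freqs = rng.uniform(0.1, 0.9, 5000)
            model = sd.PopulationModel(ancestral_freqs=freqs)
            m = sd.simulate_population(model, 50, seed=seed)
            kin = popgen.ajk_relatedness(m, allele_freqs=freqs)
            off = kin.values[np.triu_indices(50, k=1)]
            offs.append(np.abs(off).mean())
        assert np.mean(offs) < 0.02

    def test_sample_freq_offdiagonal_bias_is_minus_one_over_n_minus_one(self):
        rng = np.random.default_rng(0)
        model = sd.PopulationModel(ancestral_freqs=rng.uniform(0.1, 0.9, 5000))
        m = sd.simulate_population(model, 50, seed=0)
        kin = popgen.ajk_relatedness(m)
        off = kin.values[np.triu_indices(50, k=1)]
        assert off.mean() == pytest.approx(-1 / 49, abs=0.01)

    def test_parent_offspring_near_half(self):
        rng = np.random.default_rng(2)
        n_loci, n_fam = 4000, 30
        p = rng.uniform(0.2, 0.8, n_loci)
        pa = rng.binomial(2, p[:, None], size=(n_loci, n_fam))
        pb = rng.binomial(2, p[:, None], size=(n_loci, n_fam))
        ta = np.where(pa == 1, rng.integers(0, 2, pa.shape), pa // 2)
        tb = np.where(pb == 1, rng.integers(0, 2, pb.shape), pb // 2)
        child = ta + tb
        d = np.concatenate([pa, pb, child], axis=1)
        dm = make_dosage(d)
        kin = popgen.ajk_relatedness(dm)
        po = [kin.values[j, 2 * n_fam + j] for j in range(n_fam)]
        assert np.mean(po) == pytest.approx(0.5, abs=0.05)


class TestPCA:
    def test_two_fixed_populations_rank_one(self):
        d = np.concatenate(
            [np.zeros((50, 10), dtype=int), np.full((50, 10), 2, dtype=int)], axis=1
        )
        dm = make_dosage(d)
        res = popgen.pca_genotypes(dm)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)
        pc1 = res.scores.PC1.to_numpy()
        assert (pc1[:10] * pc1[10:] < 0).all()

    def test_identical_samples_rejected(self):
        d = np.ones((20, 10), dtype=int)
        with pytest.raises(ValueError):
            popgen.pca_genotypes(make_dosage(d))

    def test_structured_populations_separate_on_pc1(self):
        gaps = []
        for seed in range(5):
            model = sd.PopulationModel(
                ancestral_freqs=np.full(1000, 0.5), fst=0.2, n_populations=2
            )
            m = sd.simulate_population(model, 12, seed=seed)
            res = popgen.pca_genotypes(m)
            pc1 = res.scores.PC1.to_numpy()
            pops = res.populations
            mean_gap = abs(pc1[pops == "pop0"].mean() - pc1[pops == "pop1"].mean())
            within = max(pc1[pops == "pop0"].std(), pc1[pops == "pop1"].std())
            gaps.append(mean_gap / within)
        assert np.mean(gaps) > 5

    def test_marker_order_and_duplication_invariance(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(200, 15))
        dm = make_dosage(d)
        base = popgen.pca_genotypes(dm).scores.PC1.to_numpy()
        perm = rng.permutation(200)
        shuffled = popgen.pca_genotypes(make_dosage(d[perm])).scores.PC1.to_numpy()
        assert np.allclose(np.abs(base), np.abs(shuffled), atol=1e-8)
        doubled = popgen.pca_genotypes(
            make_dosage(np.concatenate([d, d], axis=0))
        ).scores.PC1.to_numpy()
        corr = abs(np.corrcoef(base, doubled)[0, 1])
        assert corr == pytest.approx(1.0, abs=1e-8)

    def test_subsample_plan(self):
        model = sd.PopulationModel(
            ancestral_freqs=np.linspace(0.2, 0.8, 300), fst=0.1, n_populations=2
        )
        m = sd.simulate_population(model, [40, 12], seed=4)
        res = popgen.pca_genotypes(m, subsample_plan={"pop0": 12}, seed=1)
        assert len(res.scores) == 24
        with pytest.raises(ValueError):
            popgen.pca_genotypes(m, subsample_plan={"pop1": 40}, seed=1)


class TestMultipleTestCorrect:
    def test_all_ones(self):
        _, reject = popgen.multiple_test_correct(np.ones(100), "holm")
        assert not reject.any()

    def test_strong_signal_survives_both_methods(self):
        p = np.full(100, 0.5)
        p[17] = 1e-6
        for method in ("holm", "bonferroni"):
            _, reject = popgen.multiple_test_correct(p, method)
            assert reject[17] and reject.sum() == 1

    def test_empty_and_unknown(self):
        adjusted, reject = popgen.multiple_test_correct([], "holm")
        assert adjusted.size == 0
        with pytest.raises(ValueError):
            popgen.multiple_test_correct([0.5], "bh")
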