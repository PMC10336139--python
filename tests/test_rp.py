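"""Regulatory-potential model: arithmetic, likelihood, fitting, deletion."""
import numpy as np
import pytest
from scipy.stats import kstest, nbinom

from codal.rp import (RPGeneModel, TechnicalContext, assign_peaks, fit_rp,
                      in_silico_deletion, motif_enrichment,
                      regulatory_potential, rp_log_likelihood)


def simple_model(**kw):
    defaults = dict(gene="g", peak_sets={"U": [0], "D": [1], "P": [2]},
                    distances={"U": np.array([10.0]), "D": np.array([5.0]),
                               "P": np.array([0.5])})
    defaults.update(kw)
    return RPGeneModel(**defaults)


class TestRPGeneModel:
    def test_positive_effects_enforced(self):
        with pytest.raises(ValueError):
            simple_model(a=np.array([1.0, -0.5, 1.0]))

    def test_decay_above_one_enforced(self):
        with pytest.raises(ValueError):
            simple_model(decay=np.array([0.5, 10.0]))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            simple_model(distances={"U": np.array([-1.0]),
                                    "D": np.array([5.0]),
                                    "P": np.array([0.5])})


class TestAssignPeaks:
    def test_compartments_and_distances(self):
        # TSS at 100_000, + strand; midpoints at -10kb, +5kb, +0.5kb
        starts = np.array([89_500, 104_500, 100_400])
        ends = np.array([90_500, 105_500, 100_600])
        sets, dists = assign_peaks(starts, ends, tss=100_000, strand="+")
        assert list(sets["U"]) == [0]
        assert list(sets["D"]) == [1]
        assert list(sets["P"]) == [2]
        assert np.isclose(dists["U"][0], 10.0)
        assert np.isclose(dists["D"][0], 5.0)
        assert np.isclose(dists["P"][0], 0.5)

    def test_strand_flip_swaps_up_down(self):
        starts = np.array([89_500, 104_500])
        ends = np.array([90_500, 105_500])
        sets, _ = assign_peaks(starts, ends, tss=100_000, strand="-")
        assert list(sets["D"]) == [0]
        assert list(sets["U"]) == [1]

    def test_window_excludes_distal(self):
        sets, _ = assign_peaks(np.array([0]), np.array([1000]),
                               tss=700_000_0, strand="+")
        assert all(len(sets[c]) == 0 for c in ("U", "D", "P"))


class TestRegulatoryPotential:
    def test_delta_equals_decay_halves(self):
        # single upstream peak at delta = Delta -> contribution a*A*0.5
        m = RPGeneModel("g", {"U": [0], "D": [], "P": []},
                        {"U": np.array([10.0]), "D": np.array([]),
                         "P": np.array([])},
                        a=np.array([2.0, 1.0, 1.0]),
                        decay=np.array([10.0, 10.0]))
        c = regulatory_potential(np.array([[0.3]]), m)
        assert np.isclose(c[0], 2.0 * 0.3 * 0.5)

    def test_spec_arithmetic_example(self):
        # a_U = 2, A = 0.01, delta = 10, Delta = 5 -> c = 0.005
        m = RPGeneModel("g", {"U": [0], "D": [], "P": []},
                        {"U": np.array([10.0]), "D": np.array([]),
                         "P": np.array([])},
                        a=np.array([2.0, 1.0, 1.0]),
                        decay=np.array([5.0, 10.0]))
        c = regulatory_potential(np.array([[0.01]]), m)
        assert np.isclose(c[0], 0.005)

    def test_promoter_ignores_distance(self):
        m = RPGeneModel("g", {"U": [], "D": [], "P": [0]},
                        {"U": np.array([]), "D": np.array([]),
                         "P": np.array([1.4])},
                        a=np.array([1.0, 1.0, 3.0]))
        c = regulatory_potential(np.array([[0.2]]), m)
        assert np.isclose(c[0], 3.0 * 0.2)

    def test_linear_in_accessibility(self):
        rng = np.random.default_rng(0)
        m = simple_model()
        A = rng.uniform(0, 1, size=(5, 3))
        assert np.allclose(regulatory_potential(2 * A, m),
                           2 * regulatory_potential(A, m))

    def test_monotone_in_A(self):
        m = simple_model()
        A = np.full((1, 3), 0.2)
        c0 = regulatory_potential(A, m)[0]
        A2 = A.copy()
        A2[0, 1] += 0.1
        assert regulatory_potential(A2, m)[0] > c0


def toy_ctx(n_cells=3, n_genes=2, n_peaks=3, t=None, seed=0):
    rng = np.random.default_rng(seed)
    return TechnicalContext(
        t=np.zeros((n_cells, n_genes)) if t is None else t,
        kappa=np.full(n_cells, 2.0),
        size_factors=np.full(n_cells, 100.0),
        accessibility=rng.uniform(0, 1, size=(n_cells, n_peaks)))


class TestLogLikelihood:
    def test_matches_scalar_nb_oracle(self):
        m = simple_model(gamma=0.8, bias=-1.2, dispersion=3.0,
                         c_mean=0.0, c_sd=1.0)
        ctx = toy_ctx()
        X = np.array([4.0, 0.0, 7.0])
        c = np.array([0.5, -0.2, 1.1])
        ll = rp_log_likelihood(X, c, ctx, m, gene_index=0)
        lam = m.gamma * c + m.bias
        mu = ctx.size_factors * np.exp(lam) / ctx.kappa
        th = m.dispersion
        p = th / (th + mu)
        oracle = nbinom.logpmf(X.astype(int), th, p).sum()
        assert np.isclose(ll, oracle, rtol=1e-10)

    def test_t_zero_reduces_to_unaugmented(self):
        rng = np.random.default_rng(1)
        m = simple_model(gamma=0.5, bias=0.0, dispersion=2.0)
        t = rng.normal(size=(3, 2))
        X = np.array([3.0, 1.0, 5.0])
        c = np.array([0.1, 0.6, -0.3])
        ll_aug = rp_log_likelihood(X, c, toy_ctx(t=t), m, gene_index=0)
        ll_un = rp_log_likelihood(X, c, toy_ctx(), m, gene_index=0)
        assert not np.isclose(ll_aug, ll_un)
        # augmented with t == 0 is exactly the unaugmented value
        assert np.isclose(
            rp_log_likelihood(X, c, toy_ctx(t=np.zeros((3, 2))), m, 0), ll_un)

    def test_constant_t_shift_absorbed_by_kappa(self):
        m = simple_model(gamma=0.5, bias=0.0, dispersion=2.0)
        X = np.array([3.0, 1.0, 5.0])
        c = np.array([0.1, 0.6, -0.3])
        shift = 0.7
        ctx_a = toy_ctx(t=np.full((3, 2), shift))
        ctx_b = toy_ctx()
        ctx_b.kappa = ctx_b.kappa / np.exp(shift)
        assert np.isclose(rp_log_likelihood(X, c, ctx_a, m, 0),
                          rp_log_likelihood(X, c, ctx_b, m, 0), rtol=1e-10)

    def test_kappa_positive_enforced(self):
        with pytest.raises(ValueError):
            TechnicalContext(t=np.zeros((2, 1)), kappa=np.array([1.0, 0.0]),
                             size_factors=np.ones(2),
                             accessibility=np.ones((2, 1)))


def simulate_rp(n_cells=2000, decay_u=10.0, seed=0, t_shift=None):
    """Data from the RP generative law with known parameters."""
    rng = np.random.default_rng(seed)
    n_peaks = 8
    dist_u = np.array([2.0, 5.0, 10.0, 20.0])
    dist_d = np.array([3.0, 12.0])
    dist_p = np.array([0.5, 1.0])
    peak_sets = {"U": np.arange(4), "D": np.arange(4, 6),
                 "P": np.arange(6, 8)}
    distances = {"U": dist_u, "D": dist_d, "P": dist_p}
    true = RPGeneModel("g", peak_sets, distances,
                       a=np.array([1.5, 1.0, 2.0]),
                       decay=np.array([decay_u, 8.0]),
                       gamma=1.2, bias=-0.5, dispersion=5.0)
    A = rng.uniform(0, 1, size=(n_cells, n_peaks))
    c = regulatory_potential(A, true)
    true.c_mean, true.c_sd = float(c.mean()), float(c.std())
    zc = (c - true.c_mean) / true.c_sd
    lam = true.gamma * zc + true.bias
    t = np.zeros((n_cells, 1))
    if t_shift is not None:
        t[:] = t_shift[:, None]
    kappa = np.full(n_cells, 2.0)
    n_i = np.full(n_cells, 500.0)
    mu = n_i * np.exp(lam + t[:, 0]) / kappa
    th = true.dispersion
    X = rng.negative_binomial(th, th / (th + mu))
    ctx = TechnicalContext(t=t, kappa=kappa, size_factors=n_i,
                           accessibility=A)
    return X.astype(float), ctx, true, peak_sets, distances, lam


class TestFitRP:
    @pytest.fixture(scope="class")
    def recovery(self):
        X, ctx, true, peak_sets, distances, lam_true = simulate_rp(seed=3)
        fitted = fit_rp("g", X, ctx, peak_sets, distances, seed=0)
        return fitted, true, ctx, lam_true

    def test_decay_recovered_within_twofold(self, recovery):
        fitted, true, _, _ = recovery
        ratio = fitted.decay[0] / true.decay[0]
        assert 0.5 <= ratio <= 2.0

    def test_lambda_correlation(self, recovery):
        fitted, true, ctx, lam_true = recovery
        c = regulatory_potential(ctx.accessibility, fitted)
        lam_fit = (fitted.gamma * (c - fitted.c_mean) / fitted.c_sd
                   + fitted.bias)
        r = np.corrcoef(lam_fit, lam_true)[0, 1]
        assert r >= 0.8

    def test_deterministic_given_seed(self):
        X, ctx, _, peak_sets, distances, _ = simulate_rp(n_cells=300, seed=5)
        a = fit_rp("g", X, ctx, peak_sets, distances, seed=2)
        b = fit_rp("g", X, ctx, peak_sets, distances, seed=2)
        assert np.allclose(a.a, b.a) and np.allclose(a.decay, b.decay)

    def test_no_proximal_peaks_skipped(self):
        X, ctx, _, _, _, _ = simulate_rp(n_cells=50, seed=1)
        empty = {"U": np.array([], dtype=int), "D": np.array([], dtype=int),
                 "P": np.array([], dtype=int)}
        dists = {"U": np.array([]), "D": np.array([]), "P": np.array([])}
        assert fit_rp("g", X, ctx, empty, dists) is None


class TestInSilicoDeletion:
    def test_empty_hit_set_zero(self):
        X, ctx, true, _, _, _ = simulate_rp(n_cells=100, seed=2)
        assert in_silico_deletion(true, [], X, ctx) == 0.0

    def test_zero_accessibility_peaks_no_effect(self):
        X, ctx, true, _, _, _ = simulate_rp(n_cells=100, seed=2)
        ctx.accessibility[:, 3] = 0.0
        assert np.isclose(in_silico_deletion(true, [3], X, ctx), 0.0)

    def test_dominant_arm_beats_random_masks(self):
        X, ctx, true, _, _, _ = simulate_rp(n_cells=800, seed=4)
        # promoter peaks (6, 7) have the largest effect a_P = 2
        assoc = in_silico_deletion(true, [6, 7], X, ctx)
        rng = np.random.default_rng(0)
        null = []
        others = [i for i in range(8) if i not in (6, 7)]
        for _ in range(40):
            pick = rng.choice(others, size=2, replace=False)
            null.append(in_silico_deletion(true, list(pick), X, ctx))
        assert assoc > np.percentile(null, 95)


class TestMotifEnrichment:
    def test_shifted_set_detected(self):
        rng = np.random.default_rng(0)
        assoc = {f"g{i}": float(rng.normal(0, 1)) for i in range(60)}
        gene_set = [f"g{i}" for i in range(12)]
        for g in gene_set:
            assoc[g] += 2.5
        p, p_adj = motif_enrichment(assoc, gene_set)
        assert p < 0.05
        assert p_adj == min(1.0, p)

    def test_bonferroni(self):
        rng = np.random.default_rng(0)
        assoc = {f"g{i}": float(rng.normal()) for i in range(30)}
        p, p_adj = motif_enrichment(assoc, ["g0", "g1"], n_motifs=20)
        assert np.isclose(p_adj, min(1.0, 20 * p))

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(200):
            assoc = {f"g{i}": float(rng.normal()) for i in range(40)}
            gene_set = [f"g{i}" for i in rng.choice(40, 8, replace=False)]
            ps.append(motif_enrichment(assoc, gene_set)[0])
        stat, p = kstest(ps, "uniform")
        assert p > 0.01

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            motif_enrichment({"g0": 1.0}, [])
        with pytest.raises(ValueError):
            motif_enrichment({"g0": 1.0}, ["g0"])

    def test_single_elements_match_enumeration(self):
        # one fg vs two bg values: P(fg ranks top) = 1/3 under the null;
        # with fg largest the one-sided mid-rank p equals 1/3
        p, _ = motif_enrichment({"a": 3.0, "b": 1.0, "c": 2.0}, ["a"])
        assert np.isclose(p, 1.0 / 3.0, atol=0.02)
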