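"""Frankencell simulator: plans, paths, mixing, read synthesis, datasets."""
import numpy as np
import pytest
import sympy
from scipy.special import expit
from scipy.stats import chisquare, kstest

from codal.frankencell import (CELL_TYPES, TERMINALS, build_plan,
                               check_weights_symbolic, generate_dataset,
                               interpolate_weights, locate_on_path,
                               node_weight_expressions, sample_cell_path,
                               synthesize_cell, synthetic_base_populations)


class TestPlan:
    def test_weights_sum_to_one_symbolically(self):
        assert check_weights_symbolic()

    def test_node2_row_is_paper_row(self):
        k = sympy.Symbol("k", nonnegative=True)
        row = node_weight_expressions()["2"]
        expected = {"HSC": sympy.Rational(1, 5) + k,
                    "CD16+Mono": sympy.Rational(2, 5) - k / 2,
                    "pDC": sympy.Rational(1, 5) - k / 4,
                    "cDC2": sympy.Rational(1, 5) - k / 4}
        for ct, expr in expected.items():
            assert sympy.simplify(row[ct] - expr) == 0

    def test_node4_pure_at_k_zero(self):
        plan = build_plan(0.0, 0.5)
        w = plan.weights["4"]
        assert w[CELL_TYPES.index("CD16+Mono")] == 1.0
        assert w.sum() == 1.0

    def test_numeric_rows_sum_to_one(self):
        for k in (0.0, 0.05, 0.1, 0.25):
            plan = build_plan(k, 0.3)
            for w in plan.weights.values():
                assert np.isclose(w.sum(), 1.0)
                assert (w >= -1e-12).all()

    def test_out_of_range_k_rejected(self):
        with pytest.raises(ValueError):
            build_plan(0.3, 0.5)
        with pytest.raises(ValueError):
            build_plan(-0.01, 0.5)
        with pytest.raises(ValueError):
            build_plan(0.05, 1.5)

    def test_transitions_sum_to_one(self):
        plan = build_plan(0.05, 0.37)
        for node, out in plan.transitions.items():
            assert np.isclose(sum(p for _, p in out), 1.0)


class TestPathSampling:
    def test_terminal_frequencies_match_enumeration(self):
        # P(Mono)=0.2, P(Dendritic)=0.2, P(B)=0.6(1-P), P(T)=0.6P
        plan = build_plan(0.05, 0.7)
        rng = np.random.default_rng(0)
        n = 10_000
        counts = dict.fromkeys(TERMINALS, 0)
        for _ in range(n):
            path, _ = sample_cell_path(plan, rng)
            counts[path[-1]] += 1
        expected = np.array([0.2, 0.2, 0.6 * 0.3, 0.6 * 0.7]) * n
        observed = np.array([counts[t] for t in TERMINALS])
        _, p = chisquare(observed, expected)
        assert p > 0.01

    def test_batch_exclusive_terminal(self):
        plan = build_plan(0.05, 1.0)
        rng = np.random.default_rng(0)
        terms = {sample_cell_path(plan, rng)[0][-1] for _ in range(2000)}
        assert "6" not in terms     # no B-cell fate at P_Tcell = 1
        assert "7" in terms

    def test_progress_is_beta_half_one(self):
        plan = build_plan(0.05, 0.5)
        rng = np.random.default_rng(1)
        ps = np.array([sample_cell_path(plan, rng)[1]
                       for _ in range(10_000)])
        stat, p = kstest(ps, "beta", args=(0.5, 1.0))
        assert p > 0.01

    def test_path_starts_at_root_ends_terminal(self):
        plan = build_plan(0.0, 0.5)
        rng = np.random.default_rng(2)
        for _ in range(50):
            path, p = sample_cell_path(plan, rng)
            assert path[0] == "root"
            assert path[-1] in TERMINALS
            assert 0 <= p <= 1


class TestInterpolation:
    def test_edge_midpoint_is_even_mixture(self):
        plan = build_plan(0.05, 0.5)
        path = ["root", "1", "2", "4"]
        # p = 0.5 on a 3-edge path -> edge 1 at within-edge fraction 0.5
        w = interpolate_weights(plan, path, 0.5)
        expected = 0.5 * plan.weights["1"] + 0.5 * plan.weights["2"]
        assert np.allclose(w, expected / expected.sum())

    def test_edge_start_logistic_value(self):
        # p_edge = 0 -> delta = sigma(-1) = 0.26894...
        plan = build_plan(0.05, 0.5)
        path = ["root", "1", "2", "4"]
        w = interpolate_weights(plan, path, 0.0)
        delta = expit(-1.0)
        expected = (1 - delta) * plan.weights["root"] + delta * plan.weights["1"]
        assert np.allclose(w, expected / expected.sum())
        assert np.isclose(delta, 0.2689414, atol=1e-6)

    def test_rows_sum_to_one_for_any_p(self):
        plan = build_plan(0.1, 0.5)
        path = ["root", "1", "3", "7"]
        for p in np.linspace(0, 1, 23):
            assert np.isclose(interpolate_weights(plan, path, p).sum(), 1.0)

    def test_locate_on_path(self):
        path = ["root", "1", "2", "4"]
        node, frac = locate_on_path(path, 0.5)
        assert node == "2" and np.isclose(frac, 0.5)
        assert locate_on_path(path, 0.0)[0] == "1"
        assert locate_on_path(path, 1.0)[0] == "4"

    def test_pseudotime_monotone_distance_from_root(self):
        # expected distance of pi_cell from the root composition grows in p
        plan = build_plan(0.05, 0.5)
        path = ["root", "1", "2", "4"]
        root = plan.weights["root"]
        dists = [np.abs(interpolate_weights(plan, path, p) - root).sum()
                 for p in np.linspace(0.01, 0.99, 25)]
        assert all(b >= a - 1e-12 for a, b in zip(dists, dists[1:]))


@pytest.fixture(scope="module")
def base():
    return synthetic_base_populations(n_genes=60, cells_per_pool=15, seed=0)


class TestSynthesizeCell:
    def test_read_conservation(self, base):
        plan = build_plan(0.05, 0.5)
        rng = np.random.default_rng(3)
        for _ in range(20):
            path, p = sample_cell_path(plan, rng)
            pi = interpolate_weights(plan, path, p)
            seed = int(rng.integers(2**31))
            n_total = max(int(round(np.random.default_rng(seed)
                                    .lognormal(np.log(500), 0.3))), 1)
            counts = synthesize_cell(pi, base, "batch1",
                                     np.random.default_rng(seed),
                                     depth_logmean=np.log(500))
            assert counts.sum() == n_total  # exact conservation

    def test_single_population_hypergeometric_marginals(self, base):
        # all reads from one donor: gene marginal = quota * g/total, +-3 SE
        pi = np.zeros(len(CELL_TYPES))
        pi[0] = 1.0
        pool = base.pools[("batch1", "HSC")]
        donor_rng = np.random.default_rng(0)
        # pin the donor by a single-cell pool
        from codal.frankencell import BasePopulations
        single = BasePopulations({("batch1", ct): pool[:1]
                                  for ct in CELL_TYPES}, base.n_genes)
        donor = pool[0].astype(float)
        total = donor.sum()
        reps, quota_log = 400, np.log(200)
        sums = np.zeros(base.n_genes)
        quotas = 0
        for _ in range(reps):
            c = synthesize_cell(pi, single, "batch1", donor_rng,
                                depth_logmean=quota_log, depth_logsd=0.0)
            sums += c
            quotas += c.sum()
        expect = quotas * donor / total
        # hypergeometric variance per draw, scaled by reps
        q = quotas / reps
        var = reps * (q * (donor / total) * (1 - donor / total)
                      * (total - q) / (total - 1))
        se = np.sqrt(np.maximum(var, 1e-12))
        z = np.abs(sums - expect) / np.maximum(se, 1e-9)
        assert (z[donor > 0] <= 3.5).mean() > 0.97

    def test_seeded_determinism(self, base):
        pi = np.full(len(CELL_TYPES), 1 / len(CELL_TYPES))
        a = synthesize_cell(pi, base, "batch2", np.random.default_rng(7))
        b = synthesize_cell(pi, base, "batch2", np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_shallow_donor_fallback(self):
        from codal.frankencell import BasePopulations
        shallow = np.zeros((1, 4), dtype=int)
        shallow[0] = [1, 1, 0, 0]  # only 2 reads available
        pools = {("batch1", ct): shallow for ct in CELL_TYPES}
        base_s = BasePopulations(pools, 4)
        pi = np.zeros(len(CELL_TYPES))
        pi[0] = 1.0
        c = synthesize_cell(pi, base_s, "batch1", np.random.default_rng(0),
                            depth_logmean=np.log(50), depth_logsd=0.0)
        assert c.sum() == 50  # multinomial fallback still conserves


class TestBasePopulations:
    def test_marker_blocks_upregulated(self, base):
        # marker genes express higher in their own type than in other types
        # (same-gene comparison cancels the shared lognormal baseline)
        markers = max(60 // (2 * len(CELL_TYPES)), 3)
        rates = {}
        for ct in CELL_TYPES:
            pool = base.pools[("batch1", ct)].astype(float)
            rates[ct] = pool.sum(0) / pool.sum()
        for i, ct in enumerate(CELL_TYPES):
            block = slice(i * markers, (i + 1) * markers)
            own = rates[ct][block]
            other = np.mean([rates[o][block] for o in CELL_TYPES if o != ct],
                            axis=0)
            assert (own > 2 * other).all()

    def test_pools_present_and_nonempty(self, base):
        for batch in ("batch1", "batch2"):
            for ct in CELL_TYPES:
                assert len(base.pools[(batch, ct)]) == 15

    def test_seeded_determinism(self):
        a = synthetic_base_populations(n_genes=30, cells_per_pool=5, seed=4)
        b = synthetic_base_populations(n_genes=30, cells_per_pool=5, seed=4)
        for key in a.pools:
            assert np.array_equal(a.pools[key], b.pools[key])


class TestGenerateDataset:
    def test_completely_confounded_fates(self, base):
        p1, p2 = build_plan(0.05, 1.0), build_plan(0.05, 0.0)
        X, C, truth = generate_dataset(p1, p2, base, n_per_batch=150, seed=0)
        b1 = truth[truth.batch == "batch1"]
        b2 = truth[truth.batch == "batch2"]
        assert (b1.fate == "B-cell").sum() == 0
        assert (b2.fate == "T-cell").sum() == 0
        assert (b1.fate == "T-cell").sum() > 0
        assert (b2.fate == "B-cell").sum() > 0

    def test_sizes_and_covariates(self, base):
        p1, p2 = build_plan(0.0, 0.5), build_plan(0.0, 0.5)
        X, C, truth = generate_dataset(p1, p2, base, n_per_batch=60, seed=1)
        assert X.shape[0] == len(truth) <= 120
        assert C.matrix.shape[0] == X.shape[0]
        assert set(truth.batch) == {"batch1", "batch2"}

    def test_branch_consistent_with_path(self, base):
        p1, p2 = build_plan(0.05, 0.5), build_plan(0.05, 0.5)
        _, _, truth = generate_dataset(p1, p2, base, n_per_batch=80, seed=2)
        for _, row in truth.iterrows():
            path = row["path"].split("->")
            node, _ = locate_on_path(path, row["progress"])
            assert row["branch"] in {"progenitor", "myeloid", "lymphoid",
                                     "Mono", "Dendritic", "B-cell", "T-cell"}
            # fate is the terminal label of the sampled path
            assert row["fate"] in {"Mono", "Dendritic", "B-cell", "T-cell"}

    def test_pi_columns_sum_to_one(self, base):
        p1, p2 = build_plan(0.05, 0.5), build_plan(0.05, 0.5)
        _, _, truth = generate_dataset(p1, p2, base, n_per_batch=40, seed=3)
        pis = truth[[f"pi_{ct}" for ct in CELL_TYPES]].to_numpy()
        assert np.allclose(pis.sum(axis=1), 1.0)

    def test_mismatched_k_rejected(self, base):
        with pytest.raises(ValueError):
            generate_dataset(build_plan(0.0, 0.5), build_plan(0.05, 0.5),
                             base, n_per_batch=10)
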