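import itertools

import numpy as np
import pytest

import mrrake as m
from ipf_oracle import brute_force_ipf


def _marginset_2x2(rows, cols):
    return m.MarginSet(
        "A",
        [m.Margin(("row",), np.asarray(rows, float)), m.Margin(("col",), np.asarray(cols, float))],
    )


class TestRakeSingleArea:
    def test_uniform_seed_gives_independence_table(self, scheme_2x2):
        res = m.rake(scheme_2x2, _marginset_2x2([3, 1], [2, 2]))
        np.testing.assert_allclose(
            res.grid("A"), [[1.5, 1.5], [0.5, 0.5]], atol=1e-10
        )
        assert res.info["A"].converged

    def test_seed_satisfying_margins_is_fixed_point(self, scheme_2x2):
        seed = np.array([[1.5, 1.5], [0.5, 0.5]])
        res = m.rake(scheme_2x2, _marginset_2x2([3, 1], [2, 2]), seed=seed)
        np.testing.assert_allclose(res.grid("A"), seed, atol=1e-12)

    def test_nonuniform_seed_matches_brute_force_oracle(self, scheme_2x2):
        seed = np.array([[2.0, 1.0], [1.0, 2.0]])
        res = m.rake(scheme_2x2, _marginset_2x2([4, 2], [3, 3]), seed=seed)
        oracle = brute_force_ipf(seed, [((0,), np.array([4.0, 2.0])), ((1,), np.array([3.0, 3.0]))])
        np.testing.assert_allclose(res.grid("A"), oracle, atol=1e-8)

    def test_structural_zero_cells_are_exactly_zero(self, scheme_2x2):
        res = m.rake(scheme_2x2, _marginset_2x2([4, 0], [2, 2]))
        grid = res.grid("A")
        assert grid[1, 0] == 0.0 and grid[1, 1] == 0.0
        np.testing.assert_allclose(grid[0], [2, 2], atol=1e-10)

    def test_negative_margin_is_input_error(self, scheme_2x2):
        with pytest.raises(m.InputError, match="negative"):
            m.rake(scheme_2x2, _marginset_2x2([4, -1], [2, 1]))

    def test_infeasible_margins_flagged_not_raised(self):
        # a zero row margin together with positive column demand everywhere
        scheme = m.StratificationScheme([("row", ["a", "b"]), ("col", ["x", "y"])])
        ms = m.MarginSet(
            "A",
            [
                m.Margin(("row",), np.array([4.0, 0.0])),
                m.Margin(("col",), np.array([2.0, 2.0])),
            ],
        )
        # make it infeasible by a seed zero blocking the only feasible mass
        seed = np.array([[0.0, 3.0], [1.0, 1.0]])
        with pytest.warns(RuntimeWarning, match="infeasible|stopped"):
            res = m.rake(scheme, ms, seed=seed, max_iter=50)
        assert not res.info["A"].converged

    def test_multiway_margin_subsets(self):
        # joint two-way margin plus a one-way margin on the third factor
        scheme = m.StratificationScheme(
            [("a", ["a0", "a1", "a2"]), ("b", ["b0", "b1"]), ("c", ["c0", "c1"])]
        )
        rng = np.random.default_rng(3)
        joint = rng.uniform(1, 5, scheme.shape)
        ms = m.MarginSet(
            "A",
            [
                m.Margin(("a", "b"), joint.sum(axis=2)),
                m.Margin(("c",), joint.sum(axis=(0, 1))),
            ],
        )
        res = m.rake(scheme, ms, tol=1e-12)
        fitted = res.grid("A")
        np.testing.assert_allclose(fitted.sum(axis=2), joint.sum(axis=2), rtol=1e-9)
        np.testing.assert_allclose(fitted.sum(axis=(0, 1)), joint.sum(axis=(0, 1)), rtol=1e-9)


SUBSET_CHOICES = {
    2: [[("f0",), ("f1",)]],
    3: [
        [("f0",), ("f1",), ("f2",)],
        [("f0", "f1"), ("f2",)],
        [("f0", "f1"), ("f1", "f2")],
    ],
}


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_random_fixtures_match_brute_force(self, seed):
        """Raked tables match an independent loop-based IPF to 1e-8."""
        rng = np.random.default_rng(seed)
        n_factors = 2 + seed % 2
        shape = tuple(rng.integers(2, 4) for _ in range(n_factors))
        scheme = m.StratificationScheme(
            [(f"f{i}", [f"l{j}" for j in range(k)]) for i, k in enumerate(shape)]
        )
        subsets = SUBSET_CHOICES[n_factors][seed % len(SUBSET_CHOICES[n_factors])]
        joint = rng.uniform(0.5, 5.0, shape)
        margins = []
        oracle_margins = []
        for sub in subsets:
            keep = tuple(sorted(scheme.factor_axis(f) for f in sub))
            axes = tuple(ax for ax in range(n_factors) if ax not in keep)
            target = joint.sum(axis=axes)
            margins.append(m.Margin(tuple(sub), target))
            oracle_margins.append((keep, target))
        seed_table = rng.uniform(0.5, 2.0, shape)
        res = m.rake(scheme, m.MarginSet("A", margins), seed=seed_table, tol=1e-12)
        oracle = brute_force_ipf(seed_table, oracle_margins)
        np.testing.assert_allclose(res.grid("A"), oracle, atol=1e-8)


class TestInvariantsAndProperties:
    @pytest.mark.parametrize("seed", range(6))
    def test_total_preserved_and_counts_nonnegative(self, seed):
        rng = np.random.default_rng(100 + seed)
        scheme = m.StratificationScheme(
            [("a", ["a0", "a1", "a2"]), ("b", ["b0", "b1"]), ("c", ["c0", "c1", "c2"])]
        )
        joint = rng.uniform(0.2, 4.0, scheme.shape)
        ms = m.MarginSet(
            "A",
            [
                m.Margin(("a", "b"), joint.sum(axis=2)),
                m.Margin(("c",), joint.sum(axis=(0, 1))),
            ],
        )
        res = m.rake(scheme, ms)
        N = ms.total
        assert abs(res.total("A") - N) < 1e-9 * N
        assert (res.counts["A"] >= 0).all()

    def test_order_invariance_at_convergence(self):
        rng = np.random.default_rng(7)
        scheme = m.StratificationScheme(
            [("a", ["a0", "a1"]), ("b", ["b0", "b1", "b2"]), ("c", ["c0", "c1"])]
        )
        joint = rng.uniform(0.5, 3.0, scheme.shape)
        margins = [
            m.Margin(("a",), joint.sum(axis=(1, 2))),
            m.Margin(("b",), joint.sum(axis=(0, 2))),
            m.Margin(("c",), joint.sum(axis=(0, 1))),
        ]
        tol = 1e-10
        res_fwd = m.rake(scheme, m.MarginSet("A", margins), tol=tol)
        res_rev = m.rake(scheme, m.MarginSet("A", margins[::-1]), tol=tol)
        N = joint.sum()
        assert np.abs(res_fwd.counts["A"] - res_rev.counts["A"]).max() < 10 * tol * N

    @pytest.mark.parametrize("seed", range(5))
    def test_margin_deviation_monotone_over_cycles(self, seed, scheme_2x2):
        rng = np.random.default_rng(200 + seed)
        joint = rng.uniform(0.3, 4.0, (2, 2))
        ms = _marginset_2x2(joint.sum(axis=1), joint.sum(axis=0))
        res = m.rake(scheme_2x2, ms, seed=rng.uniform(0.5, 2.0, (2, 2)))
        dev = np.array(res.info["A"].deviations)
        assert (np.diff(dev) <= 1e-12).all()


class TestRakeAllAreas:
    def test_full_joint_margin_degenerates_to_copy(self, tiny_bundle):
        _, pop, _, _ = tiny_bundle
        scheme = pop.scheme
        full = m.derive_margins(pop.joints, scheme, [scheme.factor_names])
        raked = m.rake_all_areas(scheme, full)
        for a in pop.area_ids:
            np.testing.assert_allclose(raked.counts[a], pop.joints[a], atol=1e-10)

    def test_every_margin_reproduced_within_tolerance(self, tiny_bundle, tiny_raked):
        _, pop, margins, _ = tiny_bundle
        tol = 1e-8
        for a, mset in margins.items():
            grid = tiny_raked.grid(a)
            N = mset.total
            for mg in mset.margins:
                keep = {pop.scheme.factor_axis(f) for f in mg.factors}
                axes = tuple(ax for ax in range(len(pop.scheme.factors)) if ax not in keep)
                assert np.abs(grid.sum(axis=axes) - mg.table).max() < tol * N

    def test_sample_counts_plus_epsilon_seed(self, tiny_bundle):
        _, pop, margins, survey = tiny_bundle
        raked = m.rake_all_areas(
            pop.scheme, margins, seed_policy="sample_counts_plus_epsilon", survey=survey
        )
        for a in pop.area_ids:
            assert raked.info[a].converged
            assert abs(raked.total(a) - margins[a].total) < 1e-8 * margins[a].total

    def test_sample_seed_policy_requires_survey(self, tiny_bundle):
        _, pop, margins, _ = tiny_bundle
        with pytest.raises(m.InputError, match="requires a survey"):
            m.rake_all_areas(pop.scheme, margins, seed_policy="sample_counts_plus_epsilon")

    def test_unknown_seed_policy(self, tiny_bundle):
        _, pop, margins, _ = tiny_bundle
        with pytest.raises(m.InputError, match="seed policy"):
            m.rake_all_areas(pop.scheme, margins, seed_policy="bogus")

    def test_default_scale_performance(self):
        """58 areas x 240 cells rake in well under the 5 s budget."""
        import time

        cfg = m.default_config(seed=99)
        pop, margins, _ = m.generate_dataset(cfg)
        t0 = time.time()
        raked = m.rake_all_areas(pop.scheme, margins, tol=1e-8)
        assert time.time() - t0 < 5.0
        assert all(raked.info[a].converged for a in raked.area_ids)
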