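"""Mapped-power bootstrap: enumeration oracles and surface properties."""

import numpy as np
import pandas as pd
import pytest

import mixpower as mp
from mixpower.mcmp import DeltaOFVPool, PoolConsistencyError


def make_pool(values, covs=None, arm="A_dense"):
    values = np.asarray(values, float)
    if covs is None:
        covs = [-1] * len(values)
    df = pd.DataFrame({"ID": np.arange(1, len(values) + 1),
                       "ARM": arm, "COV": covs, "DOFV": values})
    return DeltaOFVPool(df, arm)


class TestPowerAt:
    def test_all_large_entries_give_certain_detection(self):
        pool = make_pool([10.0, 10.0, 10.0])
        s = mp.LRTSettings(n_draws=2000)
        assert mp.power_at(pool, None, 2, 0, s, balance=False, seed=1) == 100.0

    def test_enumeration_oracle_small_pool(self):
        # pool {5, 0, 0}, two draws with replacement: 9 equally likely
        # pairs, sum > 3.84 iff at least one 5 is drawn: 1 - (2/3)^2
        pool = make_pool([5.0, 0.0, 0.0])
        exact = 100 * (1 - (2 / 3) ** 2)
        s = mp.LRTSettings(n_draws=10_000)
        est = mp.power_at(pool, None, 2, 0, s, balance=False, seed=7)
        se = 100 * np.sqrt(exact / 100 * (1 - exact / 100) / 10_000)
        assert abs(est - exact) < 3 * se

    def test_enumeration_oracle_converges_with_draws(self):
        pool = make_pool([5.0, 0.0, 0.0])
        exact = 100 * (1 - (2 / 3) ** 2)
        s = mp.LRTSettings(n_draws=1_000_000)
        est = mp.power_at(pool, None, 2, 0, s, balance=False, seed=11)
        assert abs(est - exact) < 0.5

    def test_three_draw_enumeration_with_mixed_pools(self):
        # dense pool {4,0}, sparse pool {1,-1}: one dense + two sparse
        # draws; exact P(sum > 3.84) enumerated over 2·4 = 8 outcomes
        poolA = make_pool([4.0, 0.0])
        poolB = make_pool([1.0, -1.0], arm="B_sparse")
        outcomes = []
        for a in (4.0, 0.0):
            for b1 in (1.0, -1.0):
                for b2 in (1.0, -1.0):
                    outcomes.append(a + b1 + b2 > 3.84)
        exact = 100 * np.mean(outcomes)
        s = mp.LRTSettings(n_draws=10_000)
        est = mp.power_at(poolA, poolB, 1, 2, s, balance=False, seed=3)
        se = 100 * np.sqrt(exact / 100 * (1 - exact / 100) / 10_000)
        assert abs(est - exact) < 3 * se

    def test_balanced_draws_require_even_counts_and_strata(self):
        pool = make_pool([1.0, 2.0, 3.0, 4.0], covs=[1, 1, 0, 0])
        s = mp.LRTSettings(n_draws=100)
        with pytest.raises(ValueError):
            mp.power_at(pool, None, 3, 0, s, balance=True, seed=1)
        assert mp.power_at(pool, None, 2, 0, s, balance=True, seed=1) >= 0

    def test_deterministic_given_seed(self):
        pool = make_pool(np.linspace(-1, 2, 50))
        s = mp.LRTSettings()
        a = mp.power_at(pool, None, 10, 0, s, balance=False, seed=42)
        b = mp.power_at(pool, None, 10, 0, s, balance=False, seed=42)
        assert a == b

    def test_empty_design_rejected(self):
        pool = make_pool([1.0])
        with pytest.raises(ValueError):
            mp.power_at(pool, None, 0, 0, mp.LRTSettings(), seed=0)

    def test_without_replacement_mode(self):
        pool = make_pool([5.0, 0.0, 0.0])
        s = mp.LRTSettings(n_draws=4000)
        # drawing all 3 entries without replacement always includes the 5
        assert mp.power_at(pool, None, 3, 0, s, balance=False, seed=1,
                           with_replacement=False) == 100.0


class TestPools:
    def _fits(self, dofv_full, dofv_red):
        import mixpower.nlme as nlme
        subjects = pd.DataFrame({"ID": list(dofv_full), "ARM": "dense",
                                 "COV": [1] * len(dofv_full)})
        spec = object.__new__(nlme.ModelSpec)
        mk = lambda io: nlme.FitResult(
            estimates={}, ofv_total=sum(io.values()), iofv=io, converged=True,
            n_subjects=len(io), n_obs=0, spec=None, subjects=subjects)
        return mk(dofv_full), mk(dofv_red)

    def test_identical_fits_give_zero_pool(self):
        f, _ = self._fits({1: 3.0, 2: -1.0}, {1: 3.0, 2: -1.0})
        pools = mp.build_pools(f, f)
        assert np.all(pools["A_dense"].values == 0)

    def test_pool_sum_matches_total_ofv_difference(self):
        f, r = self._fits({1: 3.0, 2: -1.0, 3: 0.5}, {1: 4.0, 2: 0.0, 3: 2.5})
        pools = mp.build_pools(f, r)
        assert pools["A_dense"].total == pytest.approx(
            r.ofv_total - f.ofv_total, abs=1e-9)

    def test_subject_mismatch_raises(self):
        f, _ = self._fits({1: 1.0, 2: 2.0}, {1: 1.0, 2: 2.0})
        _, r = self._fits({1: 1.0, 3: 2.0}, {1: 1.0, 3: 2.0})
        with pytest.raises(PoolConsistencyError):
            mp.build_pools(f, r)


class TestSurfaceAndMinN:
    def test_surface_composition_matches_direct_calls(self):
        poolA = make_pool([2.0, 1.0], arm="A_dense")
        poolB = make_pool([0.5, 3.0], arm="B_sparse")
        s = mp.LRTSettings(n_draws=500)
        surf = mp.power_surface({"A_dense": poolA, "B_sparse": poolB},
                                ((0, 2), (0, 2)), s, seed=9, balance=False, step=1)
        assert len(surf.table) == 8  # 3x3 grid minus the empty (0,0) cell
        surf2 = mp.power_surface({"A_dense": poolA, "B_sparse": poolB},
                                 ((0, 2), (0, 2)), s, seed=9, balance=False, step=1)
        pd.testing.assert_frame_equal(surf.table, surf2.table)

    def test_power_monotone_in_n_for_positive_pools(self):
        rng = np.random.default_rng(5)
        pool = make_pool(rng.normal(0.4, 0.5, size=400))
        s = mp.LRTSettings(n_draws=10_000)
        powers = [mp.power_at(pool, None, n, 0, s, balance=False, seed=100 + n)
                  for n in (5, 10, 20, 40, 80)]
        se = 3 * 100 * np.sqrt(0.25 / 10_000)
        for lo, hi in zip(powers, powers[1:]):
            assert hi >= lo - 3 * se

    def test_min_n_on_saturated_surface(self):
        pool = make_pool([10.0, 10.0], arm="A_dense")
        s = mp.LRTSettings(n_draws=200)
        surf = mp.power_surface({"A_dense": pool}, ((0, 6), (0, 0)), s,
                                seed=1, balance=False, step=1)
        res = mp.min_n(surf, "dense_only")
        assert res["achieved"] and res["total"] == 1

    def test_min_n_unreachable_reported(self):
        pool = make_pool([0.0, 0.0], arm="A_dense")
        s = mp.LRTSettings(n_draws=200)
        surf = mp.power_surface({"A_dense": pool}, ((0, 4), (0, 0)), s,
                                seed=1, balance=False, step=1)
        res = mp.min_n(surf, "dense_only")
        assert not res["achieved"] and res["total"] is None

    def test_min_n_search_agrees_with_surface(self):
        rng = np.random.default_rng(17)
        pool = make_pool(rng.normal(0.6, 0.4, size=300))
        s = mp.LRTSettings(n_draws=10_000)
        res = mp.min_n_search({"A_dense": pool}, "dense_only", s, seed=3,
                              balance=False, n_max=100)
        assert res["achieved"]
        # the crossing should be where the (noisy) power curve first
        # exceeds 80: check power just below is lower than just above
        below = mp.power_at(pool, None, max(res["total"] - 3, 1), 0, s,
                            balance=False, seed=55)
        assert below <= res["power"] + 5
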