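"""MITOMIX exhaustive admixture search: grid enumeration, recovery, pruning."""

import itertools

import numpy as np
import pytest

from mtadmix.mix import (MixSearchConfig, ancient_only_filter, evaluate_mix,
                         search, summarize_source_ranges, weight_grid)
from mtadmix.shd import shd
from mtadmix.synth import HaplogroupProfile, admix_profiles


def disjoint_profiles(labels):
    return [HaplogroupProfile(l, {f"hg_{l}": 1.0}) for l in labels]


def brute_force_search(test, pool, k_min, k_max, grid_step):
    """Independent enumerator: nested loops, no vectorisation, no pruning."""
    m = round(1 / grid_step)
    best = (2.0, None, None)
    for K in range(k_min, k_max + 1):
        for subset in itertools.combinations(range(len(pool)), K):
            for cuts in itertools.combinations(range(1, m), K - 1):
                bounds = (0,) + cuts + (m,)
                w = [(bounds[i + 1] - bounds[i]) * grid_step for i in range(K)]
                mixed = admix_profiles([pool[i] for i in subset], w)
                d = shd(test, mixed)
                if d < best[0] - 1e-12:
                    best = (d, subset, tuple(w))
    return best


class TestEvaluateMix:
    def test_self_mixture_zero(self):
        p = HaplogroupProfile("a", {"H": 0.5, "U": 0.5})
        assert evaluate_mix(p, [p], [1.0]) == 0.0

    def test_exact_mixture_recovered_at_true_weights(self):
        a, b = disjoint_profiles(["A", "B"])
        t = admix_profiles([a, b], [0.6, 0.4], "t")
        assert evaluate_mix(t, [a, b], [0.6, 0.4]) == pytest.approx(0.0)

    def test_off_weights_give_l1_gap(self):
        a, b = disjoint_profiles(["A", "B"])
        t = admix_profiles([a, b], [0.6, 0.4], "t")
        # overlap min(0.6,0.5) + min(0.4,0.5) = 0.9
        assert evaluate_mix(t, [a, b], [0.5, 0.5]) == pytest.approx(0.1)

    def test_simplex_violation_rejected(self):
        a, b = disjoint_profiles(["A", "B"])
        with pytest.raises(ValueError):
            evaluate_mix(a, [a, b], [0.6, 0.6])


class TestWeightGrid:
    def test_stars_and_bars_count(self):
        # compositions of 10 into 3 positive parts = C(9,2) = 36
        assert len(weight_grid(3, 0.1)) == 36

    def test_rows_sum_to_one_and_positive(self):
        W = weight_grid(4, 0.05)
        assert np.allclose(W.sum(axis=1), 1.0)
        assert (W > 0).all()


class TestSearch:
    def test_pool_member_recovered_at_full_proportion(self):
        pool = disjoint_profiles(["A", "B", "C"])
        test = HaplogroupProfile("T", dict(pool[1].freqs))
        sols = search(test, pool, MixSearchConfig(k_min=1, k_max=2, grid_step=0.1))
        assert sols[0].achieved_shd == pytest.approx(0.0)
        assert sols[0].sources == [("B", 1.0)]
        assert sols[0].K == 1

    def test_three_source_mixture_recovered_within_grid_step(self):
        pool = disjoint_profiles(["A", "B", "C", "D"])
        truth = {"A": 0.5, "B": 0.3, "C": 0.2}
        test = admix_profiles(pool[:3], [0.5, 0.3, 0.2], "T")
        sols = search(test, pool, MixSearchConfig(k_min=1, k_max=3, grid_step=0.01))
        best = sols[0]
        assert best.achieved_shd <= 0.01
        got = dict(best.sources)
        assert set(got) == set(truth)
        for l, w in truth.items():
            assert abs(got[l] - w) <= 0.01 + 1e-9

    def test_agrees_with_independent_enumerator(self):
        rng = np.random.default_rng(17)
        hgs = [f"h{i}" for i in range(5)]
        pool = []
        for k in range(4):
            f = rng.dirichlet(np.ones(5))
            pool.append(HaplogroupProfile(f"P{k}", dict(zip(hgs, f))))
        f = rng.dirichlet(np.ones(5))
        test = HaplogroupProfile("T", dict(zip(hgs, f)))
        best_val, subset, weights = brute_force_search(test, pool, 1, 3, 0.1)
        sols = search(test, pool, MixSearchConfig(k_min=1, k_max=3, grid_step=0.1))
        assert sols[0].achieved_shd == pytest.approx(best_val, abs=1e-12)

    def test_pruning_never_changes_results(self):
        rng = np.random.default_rng(23)
        hgs = [f"h{i}" for i in range(6)]
        pool = [HaplogroupProfile(f"P{k}", dict(zip(hgs, rng.dirichlet(np.ones(6)))))
                for k in range(5)]
        test = HaplogroupProfile("T", dict(zip(hgs, rng.dirichlet(np.ones(6)))))
        cfg_on = MixSearchConfig(k_min=1, k_max=3, grid_step=0.1, prune=True, top_n=10)
        cfg_off = MixSearchConfig(k_min=1, k_max=3, grid_step=0.1, prune=False, top_n=10)
        s_on = search(test, pool, cfg_on)
        s_off = search(test, pool, cfg_off)
        assert [(s.sources, round(s.achieved_shd, 12)) for s in s_on] == \
            [(s.sources, round(s.achieved_shd, 12)) for s in s_off]

    def test_best_shd_non_increasing_in_k_max(self):
        rng = np.random.default_rng(31)
        hgs = [f"h{i}" for i in range(6)]
        pool = [HaplogroupProfile(f"P{k}", dict(zip(hgs, rng.dirichlet(np.ones(6)))))
                for k in range(5)]
        test = HaplogroupProfile("T", dict(zip(hgs, rng.dirichlet(np.ones(6)))))
        prev = 2.0
        for k_max in (1, 2, 3):
            best = search(test, pool, MixSearchConfig(k_min=1, k_max=k_max,
                                                      grid_step=0.1))[0]
            assert best.achieved_shd <= prev + 1e-12
            prev = best.achieved_shd

    def test_k1_result_is_nearest_pool_member(self):
        rng = np.random.default_rng(37)
        hgs = [f"h{i}" for i in range(6)]
        pool = [HaplogroupProfile(f"P{k}", dict(zip(hgs, rng.dirichlet(np.ones(6)))))
                for k in range(5)]
        test = HaplogroupProfile("T", dict(zip(hgs, rng.dirichlet(np.ones(6)))))
        best = search(test, pool, MixSearchConfig(k_min=1, k_max=1, grid_step=0.1))[0]
        dists = {p.population: shd(test, p) for p in pool}
        assert best.sources[0][0] == min(dists, key=dists.get)

    def test_exclude_self(self):
        pool = disjoint_profiles(["A", "B"])
        test = HaplogroupProfile("A", dict(pool[0].freqs))
        sols = search(test, pool, MixSearchConfig(k_min=1, k_max=1, grid_step=0.5))
        assert all(l != "A" for s in sols for l, _ in s.sources)

    def test_infeasible_k_max_rejected(self):
        pool = disjoint_profiles(["A", "B"])
        test = HaplogroupProfile("T", {"x": 1.0})
        with pytest.raises(ValueError):
            search(test, pool, MixSearchConfig(k_min=1, k_max=5))

    def test_parameter_recovery_across_seeded_runs(self):
        """2- and 3-source disjoint mixtures recovered within one grid step
        in at least 19 of 20 seeded runs."""
        successes = 0
        for run in range(20):
            rng = np.random.default_rng(1000 + run)
            k_true = 2 + run % 2
            pool = disjoint_profiles([f"S{i}" for i in range(5)])
            idx = rng.choice(5, size=k_true, replace=False)
            w = rng.dirichlet(np.ones(k_true))
            w = np.round(w / w.sum(), 2)
            w[-1] = 1.0 - w[:-1].sum()  # keep on the 0.01 grid exactly
            if (w <= 0).any():
                w = np.full(k_true, 1.0 / k_true)
                w = np.round(w, 2)
                w[-1] = 1.0 - w[:-1].sum()
            test = admix_profiles([pool[i] for i in idx], w.tolist(), "T")
            sols = search(test, pool,
                          MixSearchConfig(k_min=1, k_max=3, grid_step=0.01))
            got = dict(sols[0].sources)
            truth = {pool[i].population: w[k] for k, i in enumerate(idx)}
            ok = (set(got) == set(truth)
                  and all(abs(got[l] - truth[l]) <= 0.01 + 1e-9 for l in truth))
            successes += ok
        assert successes >= 19

    def test_deterministic_tie_breaking(self):
        pool = disjoint_profiles(["A", "B", "C"])
        test = HaplogroupProfile("T", {"z": 1.0})  # all solutions tie at 1.0
        s1 = search(test, pool, MixSearchConfig(k_min=1, k_max=2, grid_step=0.5))
        s2 = search(test, pool, MixSearchConfig(k_min=1, k_max=2, grid_step=0.5))
        assert [(s.sources, s.K) for s in s1] == [(s.sources, s.K) for s in s2]
        assert s1[0].K == 1 and s1[0].sources[0][0] == "A"  # smaller K, then labels


class TestAncientOnlyFilter:
    POOL = disjoint_profiles(["old", "same", "new"])
    EPOCHS = {"old": -500.0, "same": 900.0, "new": 1900.0}

    def test_later_populations_removed(self):
        out = ancient_only_filter(self.POOL, self.EPOCHS, test_epoch=900.0)
        assert [p.population for p in out] == ["old", "same"]

    def test_contemporary_boundary_kept(self):
        out = ancient_only_filter(self.POOL, self.EPOCHS, test_epoch=-500.0)
        assert [p.population for p in out] == ["old"]

    def test_all_later_gives_empty_pool(self):
        out = ancient_only_filter(self.POOL, self.EPOCHS, test_epoch=-10000.0)
        assert out == []

    def test_missing_epoch_rejected_with_label(self):
        with pytest.raises(ValueError, match="same"):
            ancient_only_filter(self.POOL, {"old": 0.0, "new": 1.0}, 0.0)


def test_source_range_summary():
    pool = disjoint_profiles(["A", "B", "C"])
    t = admix_profiles(pool[:2], [0.7, 0.3], "T")
    sols = search(t, pool, MixSearchConfig(k_min=2, k_max=2, grid_step=0.1, top_n=3))
    ranges = summarize_source_ranges(sols)
    lo, hi = ranges["A"]
    assert lo <= 0.7 <= hi
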