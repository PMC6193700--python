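"""MITOMIX: exhaustive admixture-combination search under SHD.

Because raw SHD is proportional to admixing ratios (SHD between a target and
a w/(1-w) mixture of it with an unrelated source is exactly 1-w), the best
explanation of a test population as a mixture of candidate sources can be
found by brute force: for each subset of K candidate populations and each
weight vector on a proportion grid, form the convex combination of the
source profiles and measure its SHD to the test profile; report the
combinations with the smallest distance.  In practice 3-6 sources suffice —
larger K stops improving the fit.

The search is exhaustive over the grid but vectorised (all weight vectors of
a subset are evaluated in one matrix product), and an optional
branch-and-bound prune skips subsets whose best conceivable overlap —
sum_h min(test_h, max_source_h) — already cannot beat the current top list.
Pruning never changes the returned optimum; it only avoids work.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .shd import shd_corrected
from .synth import HaplogroupProfile, HaplogroupTree, admix_profiles

__all__ = [
    "AdmixtureSolution",
    "MixSearchConfig",
    "evaluate_mix",
    "search",
    "ancient_only_filter",
    "summarize_source_ranges",
    "weight_grid",
    "write_solutions",
]


@dataclass
class AdmixtureSolution:
    test_population: str
    sources: list[tuple[str, float]]  # sorted by descending proportion
    achieved_shd: float
    K: int


@dataclass
class MixSearchConfig:
    k_min: int = 1
    k_max: int = 6
    grid_step: float = 0.01
    exclude_self: bool = True
    top_n: int = 20
    corrected: bool = False
    correction_weight: float = 0.5
    prune: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.grid_step <= 0.5:
            raise ValueError("grid_step must be in (0, 0.5]")
        m = 1.0 / self.grid_step
        if abs(m - round(m)) > 1e-9:
            raise ValueError("grid_step must divide 1 evenly")
        if self.k_min < 1 or self.k_min > self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")


def weight_grid(K: int, grid_step: float) -> np.ndarray:
    """All weight vectors with strictly positive entries on the grid.

    Compositions of m = 1/grid_step into K positive parts — there are
    C(m-1, K-1) of them — scaled back to the simplex.
    """
    m = round(1.0 / grid_step)
    if K > m:
        raise ValueError("grid too coarse for that many sources")
    comps = []
    for cuts in itertools.combinations(range(1, m), K - 1):
        bounds = (0,) + cuts + (m,)
        comps.append([bounds[i + 1] - bounds[i] for i in range(K)])
    return np.array(comps, dtype=float) * grid_step


def evaluate_mix(test: HaplogroupProfile, sources: list[HaplogroupProfile],
                 weights: list[float], corrected: bool = False,
                 tree: HaplogroupTree | None = None,
                 correction_weight: float = 0.5) -> float:
    """SHD between the test profile and one specific source mixture."""
    mixed = admix_profiles(sources, list(weights), name="mix")
    if corrected:
        return shd_corrected(test, mixed, tree, correction_weight)
    from .shd import shd as raw_shd
    return raw_shd(test, mixed)


def _vectorize(test: HaplogroupProfile, pool: list[HaplogroupProfile]):
    support = sorted(set(test.freqs) | {h for p in pool for h in p.freqs})
    hidx = {h: i for i, h in enumerate(support)}
    t = np.zeros(len(support))
    for h, f in test.freqs.items():
        t[hidx[h]] = f
    P = np.zeros((len(pool), len(support)))
    for r, p in enumerate(pool):
        for h, f in p.freqs.items():
            P[r, hidx[h]] = f
    return t, P, support


def search(test: HaplogroupProfile, pool: list[HaplogroupProfile],
           config: MixSearchConfig = MixSearchConfig(),
           tree: HaplogroupTree | None = None) -> list[AdmixtureSolution]:
    """Exhaustive search for the best-fitting admixtures of the test profile.

    For each K in [k_min, k_max], every K-subset of the candidate pool and
    every positive grid weight vector is evaluated; the global ``top_n``
    solutions are returned by ascending SHD, ties broken by smaller K then
    lexicographic source labels.  Deterministic: no randomness anywhere.
    """
    pool = [p for p in pool
            if not (config.exclude_self and p.population == test.population)]
    if not pool:
        raise ValueError("candidate pool is empty")
    if config.k_max > len(pool):
        raise ValueError(f"k_max={config.k_max} exceeds pool size {len(pool)}")
    names = [p.population for p in pool]
    if len(set(names)) != len(names):
        raise ValueError("duplicate population labels in pool")

    t, P, _ = _vectorize(test, pool)
    entries: list[tuple] = []  # (shd, K, label-tuple, weight-tuple)

    def worst_kept() -> float:
        if len(entries) < config.top_n:
            return np.inf
        return sorted(e[0] for e in entries)[config.top_n - 1]

    for K in range(config.k_min, config.k_max + 1):
        W = weight_grid(K, config.grid_step)
        for subset in itertools.combinations(range(len(pool)), K):
            sub = np.array(subset)
            if config.prune and not config.corrected:
                best_overlap = np.minimum(t, P[sub].max(axis=0)).sum()
                if 1.0 - best_overlap > worst_kept() + 1e-12:
                    continue
            labels = tuple(names[i] for i in subset)
            if config.corrected:
                vals = np.array([
                    evaluate_mix(test, [pool[i] for i in subset], w.tolist(),
                                 corrected=True, tree=tree,
                                 correction_weight=config.correction_weight)
                    for w in W])
            else:
                mixes = W @ P[sub]
                vals = 1.0 - np.minimum(mixes, t).sum(axis=1)
            keep = min(config.top_n, len(vals))
            top = np.argpartition(vals, keep - 1)[:keep]
            for r in top:
                entries.append((float(vals[r]), K, labels, tuple(W[r])))
            entries.sort(key=_rank_key)
            del entries[config.top_n * 4:]  # keep memory bounded

    entries.sort(key=_rank_key)
    out = []
    for val, K, labels, weights in entries[: config.top_n]:
        sources = sorted(zip(labels, weights), key=lambda sw: (-sw[1], sw[0]))
        out.append(AdmixtureSolution(test_population=test.population,
                                     sources=[(l, float(w)) for l, w in sources],
                                     achieved_shd=max(val, 0.0), K=K))
    return out


def _rank_key(entry):
    val, K, labels, weights = entry
    return (round(val, 12), K, labels, tuple(-w for w in weights))


def ancient_only_filter(pool: list[HaplogroupProfile],
                        epochs: dict[str, float],
                        test_epoch: float) -> list[HaplogroupProfile]:
    """Keep only candidate populations contemporary with or older than the
    test population.  Epochs are numeric on a 'later is larger' axis (e.g.
    median calendar year); a population at exactly the test epoch is kept.
    """
    out = []
    for p in pool:
        if p.population not in epochs:
            raise ValueError(f"population {p.population!r} has no epoch tag")
        if epochs[p.population] <= test_epoch:
            out.append(p)
    return out


def summarize_source_ranges(solutions: list[AdmixtureSolution],
                            ) -> dict[str, tuple[float, float]]:
    """Per-source min-max proportion across a ranked solution list — the
    '26-38%' style summary of near-optimal admixture components."""
    ranges: dict[str, tuple[float, float]] = {}
    for sol in solutions:
        for label, w in sol.sources:
            lo, hi = ranges.get(label, (w, w))
            ranges[label] = (min(lo, w), max(hi, w))
    return ranges


def write_solutions(solutions: list[AdmixtureSolution], path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tshd\tK\tsources\n")
        for r, sol in enumerate(solutions, 1):
            src = ";".join(f"{l}:{w:.2f}" for l, w in sol.sources)
            fh.write(f"{r}\t{sol.achieved_shd:.6f}\t{sol.K}\t{src}\n")
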