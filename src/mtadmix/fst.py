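"""Sequence-based population differentiation for mitogenome haplotypes.

Distances between haplotypes use the Tamura–Nei (1993) substitution model,
which separates the two transition classes (A<->G within purines, C<->T
within pyrimidines) from transversions and allows unequal base frequencies —
appropriate for mtDNA, where transitions dominate and composition is skewed.
Rate heterogeneity across sites is modelled with a gamma distribution
(shape 0.325 by default, a typical mtDNA value).

Population differentiation is the distance-matrix AMOVA form of Fst (often
written Phi_st): the among-population share of molecular variance, with the
haplotype distances playing the role of squared Euclidean distances, as in
Arlequin.  Significance comes from permuting individuals between the two
populations (10,000 permutations by default).  Negative point estimates are
legitimate (sampling noise around zero) and reported as computed; they are
clamped to zero only where a transform requires a true distance (Slatkin
linearization, MDS).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .recode import VariantTable

__all__ = [
    "TN93Params",
    "FstResult",
    "MDSCoordinates",
    "tn93_distance",
    "tn93_matrix",
    "amova_phist",
    "pairwise_fst",
    "slatkin_linearize",
    "classical_mds",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class TN93Params:
    """gamma_alpha: gamma shape for across-site rate variation (inf = equal
    rates); base frequencies are always estimated from the pooled pair."""

    gamma_alpha: float = 0.325

    def __post_init__(self) -> None:
        if not self.gamma_alpha > 0:
            raise ValueError("gamma_alpha must be positive")


@dataclass
class FstResult:
    populations: list[str]
    fst: np.ndarray
    pvalues: np.ndarray
    n_permutations: int = 10000


@dataclass
class MDSCoordinates:
    populations: list[str]
    coords: np.ndarray  # (n, k)
    eigenvalues: np.ndarray


def _encode(seq) -> np.ndarray:
    return np.array([_CODE.get(c, -1) for c in seq], dtype=np.int8)


def _pair_counts(a: np.ndarray, b: np.ndarray):
    """Comparable-site count, transition/transversion fractions and pooled
    base frequencies for one sequence pair under pairwise deletion."""
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable (unambiguous) sites between the pair")
    x, y = a[ok], b[ok]
    diff = x != y
    purine = np.isin(x, (0, 2)) & np.isin(y, (0, 2))
    pyrim = np.isin(x, (1, 3)) & np.isin(y, (1, 3))
    P1 = float((diff & purine).sum()) / n
    P2 = float((diff & pyrim).sum()) / n
    Q = float((diff & ~purine & ~pyrim).sum()) / n
    counts = np.bincount(np.concatenate([x, y]), minlength=4).astype(float)
    pi = counts / counts.sum()
    return n, P1, P2, Q, pi


def tn93_distance(seq_a, seq_b, params: TN93Params = TN93Params()) -> float:
    """TN93 distance with gamma rate heterogeneity between two sequences.

    Sequences are strings or recoded letter rows of equal length; sites where
    either letter is not an unambiguous A/C/G/T are excluded pairwise.  With
    shape ``alpha`` the correction uses the standard closed form
    ``alpha * k * (w**(-1/alpha) - 1)`` per substitution class, which tends to
    ``-k * ln(w)`` as alpha -> inf.  Saturated pairs (non-positive argument)
    return ``inf``.
    """
    a, b = _encode(seq_a), _encode(seq_b)
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return tn93_distance_encoded(a, b, params)


def tn93_matrix(table: VariantTable, params: TN93Params = TN93Params(),
                deletion: str = "pairwise") -> np.ndarray:
    """All-pairs TN93 distance matrix over the recoded haplotype rows.

    ``deletion='pairwise'`` drops incomparable sites per pair; ``'complete'``
    drops every site that is ambiguous in any sample before any comparison.
    """
    rows = [_encode(row) for row in ("".join(r) for r in table.matrix)]
    if deletion == "complete":
        ok = np.ones(len(table.loci), dtype=bool)
        for r in rows:
            ok &= r >= 0
        rows = [r[ok] for r in rows]
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    n = len(rows)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        same = np.array_equal(rows[i], rows[j])
        D[i, j] = D[j, i] = 0.0 if same else tn93_distance_encoded(rows[i], rows[j], params)
    return D


def tn93_distance_encoded(a: np.ndarray, b: np.ndarray,
                          params: TN93Params) -> float:
    n, P1, P2, Q, pi = _pair_counts(a, b)
    if P1 == 0 and P2 == 0 and Q == 0:
        return 0.0
    return _tn93_from_counts(P1, P2, Q, pi, params)


def _tn93_from_counts(P1, P2, Q, pi, params: TN93Params) -> float:
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    k1 = 2 * piA * piG / piR if piR > 0 else 0.0
    k2 = 2 * piC * piT / piY if piY > 0 else 0.0
    k3 = 2 * (piR * piY
              - (piA * piG * piY / piR if piR > 0 else 0.0)
              - (piC * piT * piR / piY if piY > 0 else 0.0))
    terms = []
    for k, w in (
        (k1, 1 - (P1 / k1 if k1 > 0 else 0.0) - (Q / (2 * piR) if piR > 0 else 0.0)),
        (k2, 1 - (P2 / k2 if k2 > 0 else 0.0) - (Q / (2 * piY) if piY > 0 else 0.0)),
        (k3, 1 - (Q / (2 * piR * piY) if piR * piY > 0 else 0.0)),
    ):
        if k <= 0:
            continue
        if w <= 0:
            return float("inf")
        terms.append((k, w))
    alpha = params.gamma_alpha
    if np.isinf(alpha):
        d = -sum(k * np.log(w) for k, w in terms)
    else:
        d = alpha * sum(k * (w ** (-1.0 / alpha) - 1.0) for k, w in terms)
    return max(float(d), 0.0)


def amova_phist(d2: np.ndarray, labels: np.ndarray) -> float:
    """Phi_st from a squared-distance matrix and integer group labels.

    One-level AMOVA variance decomposition: SS(total) is the mean pairwise
    squared distance over all individuals, SS(within) the per-group mean;
    variance components follow the standard expected-mean-square algebra
    with the unequal-sample-size coefficient n_c.
    """
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two populations")
    N = len(labels)
    iu = np.triu_indices(N, 1)
    ss_total = d2[iu].sum() / N
    ss_within = 0.0
    sizes = []
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            raise ValueError(f"population {g} has fewer than 2 samples")
        sub = d2[np.ix_(idx, idx)]
        ss_within += np.triu(sub, 1).sum() / len(idx)
        sizes.append(len(idx))
    sizes = np.array(sizes, dtype=float)
    P = len(sizes)
    ss_among = ss_total - ss_within
    sigma_w = ss_within / (N - P)
    n_c = (N - (sizes ** 2).sum() / N) / (P - 1)
    sigma_a = (ss_among / (P - 1) - sigma_w) / n_c
    denom = sigma_a + sigma_w
    if denom == 0:
        return 0.0
    return float(sigma_a / denom)


def pairwise_fst(table: VariantTable, groups: dict[str, str],
                 params: TN93Params = TN93Params(),
                 n_permutations: int = 10000, seed: int = 0,
                 deletion: str = "pairwise") -> FstResult:
    """Pairwise Phi_st between all populations with permutation p-values.

    The TN93 distances enter the AMOVA as squared distances.  The p-value for
    a pair is the fraction of label permutations whose Phi_st is at least the
    observed value; permutations reuse the fixed distance matrix, so the test
    is exact-in-distribution and deterministic for a given seed.
    """
    pops = sorted(set(groups[s] for s in table.sample_ids))
    counts = {p: sum(1 for s in table.sample_ids if groups[s] == p) for p in pops}
    for p, c in counts.items():
        if c < 2:
            raise ValueError(f"population {p!r} has fewer than 2 samples")
    D = tn93_matrix(table, params, deletion=deletion)
    # saturated pairs (distance inf) would poison the variance decomposition;
    # cap them at twice the largest finite distance so they stay maximal but
    # finite — fixed-difference designs still yield Phi_st = 1 exactly
    if np.isinf(D).any():
        finite = D[np.isfinite(D)]
        cap = 2.0 * finite.max() if finite.max() > 0 else 1.0
        D = np.where(np.isinf(D), cap, D)
    label_arr = np.array([pops.index(groups[s]) for s in table.sample_ids])
    n = len(pops)
    fst = np.zeros((n, n))
    pvals = np.zeros((n, n))
    rng = np.random.default_rng(seed)
    for i, j in itertools.combinations(range(n), 2):
        idx = np.flatnonzero((label_arr == i) | (label_arr == j))
        sub = D[np.ix_(idx, idx)]
        lab = (label_arr[idx] == j).astype(int)
        obs = amova_phist(sub, lab)
        fst[i, j] = fst[j, i] = obs
        if n_permutations > 0:
            perm_vals = _permuted_phist(sub, int(lab.sum()), n_permutations, rng)
            p = float(np.mean(perm_vals >= obs - 1e-12))
        else:
            p = float("nan")
        pvals[i, j] = pvals[j, i] = p
    return FstResult(populations=pops, fst=fst, pvalues=pvals,
                     n_permutations=n_permutations)


def _permuted_phist(d2: np.ndarray, n_second: int, n_perm: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Phi_st for ``n_perm`` random relabelings of a two-group design.

    Group sizes are preserved (a label permutation cannot change them), so
    the two-group AMOVA reduces to the two within-group sums, evaluated for
    all permutations at once with one quadratic form each.
    """
    N = d2.shape[0]
    n1 = N - n_second
    total = d2.sum() / 2.0
    # membership matrices: first n1 of each random order form group 1
    order = np.argsort(rng.random((n_perm, N)), axis=1)
    M1 = np.zeros((n_perm, N))
    np.put_along_axis(M1, order[:, :n1], 1.0, axis=1)
    M2 = 1.0 - M1
    w1 = np.einsum("bi,ij,bj->b", M1, d2, M1) / 2.0
    w2 = np.einsum("bi,ij,bj->b", M2, d2, M2) / 2.0
    ss_within = w1 / n1 + w2 / n_second
    ss_among = total / N - ss_within
    sigma_w = ss_within / (N - 2)
    n_c = N - (n1 ** 2 + n_second ** 2) / N
    sigma_a = (ss_among - sigma_w) / n_c
    denom = sigma_a + sigma_w
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom == 0, 0.0, sigma_a / denom)
    return out


def slatkin_linearize(fst: np.ndarray) -> np.ndarray:
    """Slatkin's linearized Fst, elementwise Fst/(1-Fst).

    Negative estimates are clamped to 0 first (they are noise around zero and
    would otherwise produce negative "distances"); an entry equal to 1 has no
    finite linearization and is rejected.
    """
    f = np.asarray(fst, dtype=float)
    if np.any(f >= 1.0):
        raise ValueError("Fst of 1 cannot be linearized (infinite)")
    f = np.clip(f, 0.0, None)
    return f / (1.0 - f)


def classical_mds(dist: np.ndarray, k: int = 2,
                  populations: list[str] | None = None) -> MDSCoordinates:
    """Classical (Torgerson) metric MDS of a distance matrix.

    Double-centers the squared distances, eigendecomposes the Gram matrix and
    scales the top-k eigenvectors by the square roots of their (non-negative)
    eigenvalues.  Axis signs are fixed so each axis' largest-magnitude
    loading is positive, making the output deterministic.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam = np.clip(evals[:k], 0.0, None)
    coords = evecs[:, :k] * np.sqrt(lam)
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    if populations is None:
        populations = [f"pop{i}" for i in range(n)]
    return MDSCoordinates(populations=list(populations), coords=coords,
                          eigenvalues=evals)
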