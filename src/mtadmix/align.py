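"""IUPAC-ambiguity-aware global alignment of mitogenomes to a reference.

Ancient-DNA consensus sequences routinely carry IUPAC ambiguity codes and
'N' runs where coverage was thin.  A standard aligner treats those as
mismatches and distorts the alignment around them; here a column pairing two
compatible codes is rewarded by the ambiguity class of the *more ambiguous*
symbol, so an uncertain call is tolerated rather than punished.

Scoring (defaults): exact A/C/G/T identity 6; intersecting pair whose more
ambiguous symbol is a 2-fold code (R Y M W S K) 3; 3-fold code (B D H V) 2;
4-fold (N) 1; disjoint base sets -12.  Gaps are affine: a run of length L
costs gap_open + (L-1)*gap_extend with defaults -24 / -6.  Terminal gaps are
charged like internal ones (true global alignment) — inputs are complete
mitogenomes of near-equal length, so end-free alignment is not wanted.

Alignment is O(n*m) Gotoh dynamic programming, vectorised row-by-row with
numpy; the horizontal gap state is resolved with a running-maximum
transformation so no inner Python loop is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import Mitogenome, Variant

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "M": frozenset("AC"),
    "W": frozenset("AT"), "S": frozenset("CG"), "K": frozenset("GT"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
IUPAC_ALPHABET = "".join(IUPAC_SETS)

__all__ = [
    "AlignmentWeights",
    "PairwiseAlignment",
    "score_column",
    "align_global",
    "call_variants",
    "write_vcf",
    "IUPAC_SETS",
    "IUPAC_ALPHABET",
]


@dataclass(frozen=True)
class AlignmentWeights:
    match: float = 6.0
    iupac2_match: float = 3.0
    iupac3_match: float = 2.0
    iupac4_match: float = 1.0
    mismatch: float = -12.0
    gap_open: float = -24.0
    gap_extend: float = -6.0

    def __post_init__(self) -> None:
        if not (self.match > self.iupac2_match > self.iupac3_match
                > self.iupac4_match > 0 > self.mismatch > self.gap_open):
            raise ValueError("weights must satisfy match > iupac2 > iupac3 > iupac4 "
                             "> 0 > mismatch > gap_open")


@dataclass
class PairwiseAlignment:
    aligned_ref: str
    aligned_query: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_query):
            raise ValueError("gapped rows must have equal length")
        if any(a == "-" and b == "-" for a, b in zip(self.aligned_ref, self.aligned_query)):
            raise ValueError("column with gap in both rows")


def score_column(ref_base: str, query_base: str,
                 weights: AlignmentWeights = AlignmentWeights()) -> float:
    """Score one aligned column of IUPAC symbols.

    Compatible symbols (intersecting base sets) score by the ambiguity class
    of the more ambiguous of the two; disjoint sets score as a mismatch.
    """
    try:
        sa, sb = IUPAC_SETS[ref_base.upper()], IUPAC_SETS[query_base.upper()]
    except KeyError as exc:
        raise ValueError(f"symbol {exc.args[0]!r} outside the IUPAC nucleotide alphabet")
    if not sa & sb:
        return weights.mismatch
    fold = max(len(sa), len(sb))
    return {1: weights.match, 2: weights.iupac2_match,
            3: weights.iupac3_match, 4: weights.iupac4_match}[fold]


def _substitution_matrix(weights: AlignmentWeights) -> tuple[np.ndarray, dict[str, int]]:
    idx = {c: i for i, c in enumerate(IUPAC_ALPHABET)}
    n = len(IUPAC_ALPHABET)
    S = np.empty((n, n))
    for a, i in idx.items():
        for b, j in idx.items():
            S[i, j] = score_column(a, b, weights)
    return S, idx


def _encode(seq: str, idx: dict[str, int]) -> np.ndarray:
    try:
        return np.array([idx[c] for c in seq.upper()], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"symbol {exc.args[0]!r} outside the IUPAC nucleotide alphabet")


# traceback pointer codes: which state the optimal path came from
_M, _X, _Y = 0, 1, 2  # X: gap in query (consumes reference); Y: gap in reference

NEG = -1e18


def align_global(reference: str, query: str,
                 weights: AlignmentWeights = AlignmentWeights()) -> PairwiseAlignment:
    """Optimal global alignment under affine gap costs (Gotoh three-state DP).

    A gap run of length L costs ``gap_open + (L-1) * gap_extend``.  Among
    co-optimal alignments the traceback prefers substitution over gap, then
    gap-in-query over gap-in-reference, making the output deterministic.
    """
    if not reference or not query:
        raise ValueError("sequences must be non-empty")
    S, idx = _substitution_matrix(weights)
    a = _encode(reference, idx)
    b = _encode(query, idx)
    n, m = len(a), len(b)
    go, ge = weights.gap_open, weights.gap_extend

    # current/previous row score vectors for the three states
    M_prev = np.full(m + 1, NEG)
    X_prev = np.full(m + 1, NEG)
    Y_prev = np.full(m + 1, NEG)
    M_prev[0] = 0.0
    Y_prev[1:] = go + ge * np.arange(m)

    tbM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tbX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tbY = np.zeros((n + 1, m + 1), dtype=np.uint8)
    tbY[0, 1:] = _Y
    tbY[0, 1] = _M

    j_idx = np.arange(1, m + 1)
    for i in range(1, n + 1):
        srow = S[a[i - 1], b]  # substitution scores vs every query base

        M_cur = np.full(m + 1, NEG)
        diag = np.stack((M_prev[:-1], X_prev[:-1], Y_prev[:-1]))
        choice = np.argmax(diag, axis=0)  # ties -> first: M, then X, then Y
        M_cur[1:] = diag[choice, np.arange(m)] + srow
        tbM[i, 1:] = choice

        # vertical gap (gap in query): extends X or opens from M/Y of row above
        up = np.stack((M_prev + go, X_prev + ge, Y_prev + go))
        # preference: substitution state first on ties, then continuing X
        cx = np.argmax(up, axis=0)
        X_cur = up[cx, np.arange(m + 1)]
        tbX[i] = cx

        # horizontal gap (gap in reference): Y[j] = max over k<j of
        # best(M,X)[k] + go + (j-1-k)*ge, resolved via a running maximum
        base = np.maximum(M_cur, X_cur)
        open_from_M = M_cur >= X_cur  # records which state the gap opened from
        # contribution of opening after column k: base[k] + go + (j-1-k)*ge
        #   = (base[k] + go - (k+1)*ge) + j*ge, so a cumulative max suffices
        shifted = base[:-1] + go - ge * j_idx
        run = np.maximum.accumulate(shifted)
        Y_cur = np.full(m + 1, NEG)
        Y_cur[1:] = run + ge * j_idx
        # traceback for Y: whether this column extends the previous Y run
        ext = np.full(m + 1, False)
        ext[2:] = shifted[1:] < run[:-1] - 1e-12  # strictly worse to open here -> extend
        tbY[i, 1:] = np.where(ext[1:], _Y,
                              np.where(open_from_M[:-1], _M, _X))

        M_prev, X_prev, Y_prev = M_cur, X_cur, Y_cur

    finals = (M_prev[m], X_prev[m], Y_prev[m])
    state = int(np.argmax(finals))  # ties prefer M, then X, then Y
    score = float(finals[state])

    # traceback
    i, j = n, m
    ar: list[str] = []
    aq: list[str] = []
    while i > 0 or j > 0:
        if state == _M:
            prev = tbM[i, j]
            ar.append(reference[i - 1])
            aq.append(query[j - 1])
            i -= 1
            j -= 1
            state = int(prev)
        elif state == _X:
            prev = tbX[i, j]
            ar.append(reference[i - 1])
            aq.append("-")
            i -= 1
            state = int(prev)
        else:
            prev = tbY[i, j]
            ar.append("-")
            aq.append(query[j - 1])
            j -= 1
            state = int(prev)
    return PairwiseAlignment("".join(reversed(ar)), "".join(reversed(aq)), score)


def alignment_score(aln: PairwiseAlignment,
                    weights: AlignmentWeights = AlignmentWeights()) -> float:
    """Re-score an alignment independently of the DP (sum of columns + gaps)."""
    total = 0.0
    prev_gap = None  # 'ref' / 'query' / None
    for ra, qa in zip(aln.aligned_ref, aln.aligned_query):
        if ra == "-":
            total += weights.gap_extend if prev_gap == "ref" else weights.gap_open
            prev_gap = "ref"
        elif qa == "-":
            total += weights.gap_extend if prev_gap == "query" else weights.gap_open
            prev_gap = "query"
        else:
            total += score_column(ra, qa, weights)
            prev_gap = None
    return total


def call_variants(aln: PairwiseAlignment) -> list[Variant]:
    """Read variants off an alignment, 1-based in reference coordinates.

    Substitution columns where the letters differ give SNP records (ambiguity
    letters are reported verbatim as the alternate).  Runs of gap-in-reference
    give a single insertion record anchored at the preceding reference
    position; runs of gap-in-query give one single-position deletion record
    per deleted base (per-event granularity, matching downstream recoding).
    """
    variants: list[Variant] = []
    pos = 0  # last consumed reference position
    ins_anchor = None
    ins_bases: list[str] = []

    def flush_insertion():
        nonlocal ins_anchor, ins_bases
        if ins_bases:
            variants.append(Variant("ins", ins_anchor, "", "".join(ins_bases)))
            ins_bases = []
        ins_anchor = None

    for ra, qa in zip(aln.aligned_ref, aln.aligned_query):
        if ra == "-":
            if ins_anchor is None:
                ins_anchor = max(pos, 1)
            ins_bases.append(qa)
            continue
        flush_insertion()
        pos += 1
        if qa == "-":
            variants.append(Variant("del", pos, ra, ""))
        elif qa != ra:
            variants.append(Variant("snp", pos, ra, qa))
    flush_insertion()
    return variants


def align_and_call(reference: str, genome: Mitogenome,
                   weights: AlignmentWeights = AlignmentWeights()) -> list[Variant]:
    """Convenience: align one mitogenome to the reference and call variants."""
    return call_variants(align_global(reference, genome.sequence, weights))


def write_vcf(calls: dict[str, list[Variant]], reference: str, path,
              contig: str = "chrM") -> None:
    """Minimal multi-sample VCF (8 fixed columns + GT) of all called variants.

    Indels are written left-anchored per VCF convention: an insertion after
    position p is REF=base(p), ALT=base(p)+inserted; a deletion of position p
    is REF=base(p-1)+base(p), ALT=base(p-1), POS=p-1.
    """
    samples = list(calls)
    keyed: dict[tuple, dict[str, bool]] = {}
    for s, variants in calls.items():
        for v in variants:
            keyed.setdefault((v.position, v.kind, v.ref, v.alt), {})[s] = True
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={len(reference)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for (pos, kind, ref, alt), carriers in sorted(keyed.items()):
            if kind == "snp":
                vpos, vref, valt = pos, ref, alt
            elif kind == "ins":
                vpos = pos
                vref = reference[pos - 1]
                valt = vref + alt
            else:  # deletion, anchor on the base before
                vpos = max(pos - 1, 1)
                anchor = reference[vpos - 1]
                if vpos == pos:  # deletion at position 1
                    vref, valt = reference[0] + reference[1], reference[1]
                else:
                    vref, valt = anchor + ref, anchor
            gts = "\t".join("1" if s in carriers else "0" for s in samples)
            fh.write(f"{contig}\t{vpos}\t.\t{vref}\t{valt}\t.\t.\t.\tGT\t{gts}\n")
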