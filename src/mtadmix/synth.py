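"""Synthetic mitogenome populations with known haplogroup structure.

Human mtDNA is maternally inherited and non-recombining, so a population's
maternal history is summarised by the frequencies of the sub-haplogroups its
members carry.  This module builds the objects the rest of the pipeline
analyses, with a fully known ground truth:

* a haplogroup hierarchy whose labels follow mtDNA nomenclature (a child's
  label extends its parent's label, e.g. ``R1a`` under ``R1``);
* per-haplogroup defining variants layered cumulatively down the tree, so a
  genome of a child haplogroup carries all of its parent's variants;
* populations described by a frequency vector over sub-haplogroups, possibly
  formed as convex combinations (admixtures) of other populations' vectors;
* individual mitogenome sequences derived from a reference by the defining
  variants of a drawn haplogroup, plus Poisson private mutations and
  Bernoulli missing-data ('N') masking.

All randomness flows through explicit seeds; no global state is touched.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

NUCLEOTIDES = "ACGT"

__all__ = [
    "Mitogenome",
    "HaplogroupTree",
    "HaplogroupProfile",
    "SyntheticPopulationSpec",
    "Variant",
    "HaplotypeModel",
    "generate_tree",
    "admix_profiles",
    "make_reference",
    "build_haplotype_model",
    "sample_population",
    "write_fasta",
    "write_table",
]


@dataclass(frozen=True)
class Mitogenome:
    """One sample's complete mtDNA sequence (IUPAC letters allowed)."""

    sample_id: str
    sequence: str

    def missing_or_uncertain(self) -> int:
        """Count of letters that are not unambiguous A/C/G/T (gaps excluded)."""
        return sum(1 for c in self.sequence if c not in NUCLEOTIDES and c != "-")


@dataclass
class HaplogroupTree:
    """Haplogroup hierarchy; a node's label extends its parent's label."""

    nodes: list[str]
    parent: dict[str, str | None]

    def __post_init__(self) -> None:
        roots = [n for n in self.nodes if self.parent.get(n) is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        self.root = roots[0]
        for n in self.nodes:
            p = self.parent[n]
            if p is not None and not n.startswith(p):
                raise ValueError(f"label {n!r} does not extend its parent {p!r}")
        # acyclicity: walking up from every node must reach the root
        for n in self.nodes:
            seen = set()
            while n is not None:
                if n in seen:
                    raise ValueError("cycle detected in haplogroup tree")
                seen.add(n)
                n = self.parent[n]

    def children(self, node: str) -> list[str]:
        return [n for n in self.nodes if self.parent.get(n) == node]

    def ancestors(self, node: str) -> list[str]:
        """Path from node's parent up to the root."""
        out = []
        p = self.parent[node]
        while p is not None:
            out.append(p)
            p = self.parent[p]
        return out

    def leaves(self) -> list[str]:
        has_child = set(self.parent.values()) - {None}
        return [n for n in self.nodes if n not in has_child]


@dataclass
class HaplogroupProfile:
    """A population's relative frequencies over sub-haplogroups (sums to 1)."""

    population: str
    freqs: dict[str, float]
    n_samples: int = 0

    def __post_init__(self) -> None:
        if any(not h for h in self.freqs):
            raise ValueError("empty haplogroup label in profile")
        if any(f < 0 for f in self.freqs.values()):
            raise ValueError("negative frequency in profile")
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile frequencies sum to {total}, expected 1")

    def support(self) -> set[str]:
        return {h for h, f in self.freqs.items() if f > 0}


@dataclass
class SyntheticPopulationSpec:
    name: str
    profile: HaplogroupProfile
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class Variant:
    """A defining variant in 1-based reference coordinates.

    kind 'snp': ref base -> alt base at ``position``.
    kind 'ins': single base ``alt`` inserted after ``position``.
    kind 'del': the single base at ``position`` deleted.
    """

    kind: str
    position: int
    ref: str = ""
    alt: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("snp", "ins", "del"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("positions are 1-based")


@dataclass
class HaplotypeModel:
    """Reference sequence plus cumulative defining variants per haplogroup."""

    reference: str
    defining_variants: dict[str, list[Variant]]
    private_mutation_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if len(self.reference) < 100:
            raise ValueError("reference must be at least 100 nt")
        for hg, variants in self.defining_variants.items():
            for v in variants:
                if v.position > len(self.reference):
                    raise ValueError(f"{hg}: variant at {v.position} beyond reference")


def make_reference(length: int = 16569, seed: int = 0) -> str:
    """Random A/C/G/T reference of the given length (rCRS length by default)."""
    if length < 100:
        raise ValueError("reference length must be >= 100")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


def generate_tree(n_major: int, depth: int, branching: int, seed: int = 0) -> HaplogroupTree:
    """Build a haplogroup hierarchy with ``n_major`` clades under one root.

    Each major clade is expanded for ``depth`` levels with ``branching``
    children per node, so each major clade subtends ``branching ** depth``
    leaves.  Labels mimic mtDNA nomenclature: digits and letters are appended
    alternately (root ``R`` -> ``R1`` -> ``R1a`` -> ``R1a1`` ...), which keeps
    every label a prefix-extension of its parent.  Output is deterministic
    for a fixed seed (the seed is kept for interface symmetry; topology and
    labels are fully determined by the size arguments).
    """
    if n_major < 1 or depth < 1 or branching < 1:
        raise ValueError("n_major, depth and branching must all be >= 1")
    root = "R"
    nodes = [root]
    parent: dict[str, str | None] = {root: None}
    for m in range(1, n_major + 1):
        major = f"{root}{m}"
        nodes.append(major)
        parent[major] = root
        _expand_below(major, 1, depth, branching, nodes, parent)
    return HaplogroupTree(nodes=nodes, parent=parent)


def _expand_below(node, level, depth, branching, nodes, parent):
    if level > depth:
        return
    if node[-1].isdigit():
        suffixes = list(string.ascii_lowercase)
    else:
        suffixes = [str(i) for i in range(1, 100)]
    for k in range(branching):
        child = node + str(suffixes[k])
        nodes.append(child)
        parent[child] = node
        _expand_below(child, level + 1, depth, branching, nodes, parent)


def admix_profiles(
    sources: list[HaplogroupProfile],
    weights: list[float],
    name: str = "admixed",
) -> HaplogroupProfile:
    """Convex combination of source profiles: the admixed population's profile."""
    if len(sources) != len(weights):
        raise ValueError("need one weight per source profile")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {sum(weights)}, expected 1")
    freqs: dict[str, float] = {}
    for prof, w in zip(sources, weights):
        for hg, f in prof.freqs.items():
            freqs[hg] = freqs.get(hg, 0.0) + w * f
    # drop numerically-zero entries so supports stay meaningful
    freqs = {h: f for h, f in freqs.items() if f > 0}
    total = sum(freqs.values())
    freqs = {h: f / total for h, f in freqs.items()}
    return HaplogroupProfile(population=name, freqs=freqs)


def build_haplotype_model(
    tree: HaplogroupTree,
    reference: str,
    snps_per_branch: int = 3,
    indel_prob: float = 0.0,
    private_mutation_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> HaplotypeModel:
    """Assign defining variants to every branch of the tree, cumulatively.

    Each non-root node receives ``snps_per_branch`` new variants at positions
    not used by any other branch; with probability ``indel_prob`` a variant is
    a single-base insertion or deletion instead of a SNP.  A node's defining
    set is its parent's set plus its own new variants, matching the nested
    structure of real haplogroup-defining mutations.
    """
    rng = np.random.default_rng(seed)
    L = len(reference)
    n_branches = len(tree.nodes) - 1
    needed = n_branches * snps_per_branch
    # keep positions away from the sequence ends so indels stay representable
    candidates = rng.permutation(np.arange(10, L - 10)) + 1
    if needed > len(candidates):
        raise ValueError("reference too short for the requested variant density")
    pos_iter = iter(candidates[:needed].tolist())

    own: dict[str, list[Variant]] = {tree.root: []}
    for node in tree.nodes:
        if node == tree.root:
            continue
        variants = []
        for _ in range(snps_per_branch):
            p = next(pos_iter)
            refbase = reference[p - 1]
            roll = rng.random()
            if roll < indel_prob / 2:
                ins_base = NUCLEOTIDES[rng.integers(4)]
                variants.append(Variant("ins", p, "", ins_base))
            elif roll < indel_prob:
                variants.append(Variant("del", p, refbase, ""))
            else:
                alt = rng.choice([b for b in NUCLEOTIDES if b != refbase])
                variants.append(Variant("snp", p, refbase, str(alt)))
        own[node] = variants

    defining: dict[str, list[Variant]] = {}
    for node in tree.nodes:
        acc: list[Variant] = []
        for anc in reversed(tree.ancestors(node)):
            acc.extend(own[anc])
        acc.extend(own[node])
        defining[node] = acc
    return HaplotypeModel(
        reference=reference,
        defining_variants=defining,
        private_mutation_rate=private_mutation_rate,
        missing_rate=missing_rate,
    )


def _apply_variants(reference: str, variants: list[Variant]) -> str:
    """Apply SNPs in place, then indels right-to-left so coordinates hold."""
    seq = list(reference)
    for v in variants:
        if v.kind == "snp":
            seq[v.position - 1] = v.alt
    for v in sorted((v for v in variants if v.kind != "snp"),
                    key=lambda v: v.position, reverse=True):
        if v.kind == "ins":
            seq.insert(v.position, v.alt)
        else:
            del seq[v.position - 1]
    return "".join(seq)


def sample_population(
    spec: SyntheticPopulationSpec,
    model: HaplotypeModel,
) -> list[tuple[Mitogenome, str]]:
    """Draw ``spec.n_samples`` mitogenomes from the population's profile.

    Each sample's haplogroup is drawn from ``spec.profile``; its genome is the
    reference with that haplogroup's defining variants applied, plus a
    Poisson(``private_mutation_rate``) number of private SNPs at positions not
    used by any defining variant, plus independent per-site 'N' masking at
    ``missing_rate``.  Deterministic for a fixed ``spec.seed``.
    """
    for hg in spec.profile.support():
        if hg not in model.defining_variants:
            raise ValueError(f"haplogroup {hg!r} not present in haplotype model")
    rng = np.random.default_rng(spec.seed)
    hgs = sorted(spec.profile.support())
    probs = np.array([spec.profile.freqs[h] for h in hgs])
    probs = probs / probs.sum()
    L = len(model.reference)
    reserved = {v.position for vs in model.defining_variants.values() for v in vs}
    free_positions = np.array(sorted(set(range(1, L + 1)) - reserved))

    out = []
    draws = rng.choice(len(hgs), size=spec.n_samples, p=probs)
    for i, hi in enumerate(draws):
        hg = hgs[hi]
        variants = list(model.defining_variants[hg])
        if model.private_mutation_rate > 0 and len(free_positions):
            k = rng.poisson(model.private_mutation_rate)
            k = min(k, len(free_positions))
            for p in rng.choice(free_positions, size=k, replace=False):
                refbase = model.reference[p - 1]
                alt = str(rng.choice([b for b in NUCLEOTIDES if b != refbase]))
                variants.append(Variant("snp", int(p), refbase, alt))
        seq = _apply_variants(model.reference, variants)
        if model.missing_rate > 0:
            mask = rng.random(len(seq)) < model.missing_rate
            seq = "".join("N" if m else c for c, m in zip(seq, mask))
        out.append((Mitogenome(f"{spec.name}_{i:04d}", seq), hg))
    return out


def write_fasta(genomes: list[Mitogenome], path) -> None:
    """Write one FASTA record per sample, sample ID in the header."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(g.sequence), id=g.sample_id, description="") for g in genomes]
    SeqIO.write(records, str(path), "fasta")


def write_table(mapping: dict[str, str], path, columns=("sample", "value")) -> None:
    """Two-column tab-separated table (sample -> population or haplogroup)."""
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for k, v in mapping.items():
            fh.write(f"{k}\t{v}\n")
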