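"""Recode called variants into the SNP-ized matrix used for Fst.

Insertions and deletions make a multiple alignment of whole mitogenomes
awkward, so only variable positions are tabulated and indel events are
recoded as pseudo-SNP columns:

* insertion event: carriers get **T**, samples with the reference sequence
  get **C**;
* deletion event: carriers get **C**, samples with the reference sequence
  get **T**;
* SNP columns carry the literal alternate allele for carriers and the
  reference letter otherwise.

Common indel hotspots (the rCRS positions around 309/315/523, 3106, and the
16182/16183/16193/16519 region) are mutational noise rather than lineage
signal and are excluded by default.  Sequences riddled with missing or
uncertain calls (more than 500 non-ACGT letters by default) are dropped by
the QC filter before tabulation; the filter is meant for modern database
sequences — ancient genomes are tabulated as-is, with per-locus 'N'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .synth import Mitogenome, Variant

__all__ = [
    "Locus",
    "VariantTable",
    "HotspotList",
    "DEFAULT_HOTSPOTS",
    "qc_filter",
    "build_variant_table",
    "recode_indels",
    "apply_hotspot_exclusion",
    "find_identical_sequences",
    "write_variant_matrix",
    "write_arp",
]


@dataclass(frozen=True)
class Locus:
    """Descriptor of one matrix column: reference position + event kind.

    ``detail`` disambiguates distinct events at the same position: the
    alternate allele for SNP loci, the inserted bases for insertions, empty
    for single-position deletions.
    """

    position: int
    kind: str  # 'snp' | 'ins' | 'del'
    detail: str = ""

    def __str__(self) -> str:
        if self.kind == "snp":
            return f"{self.position}{self.detail}"
        if self.kind == "ins":
            return f"{self.position}.{self.detail}ins"
        return f"{self.position}del"


@dataclass
class VariantTable:
    """Samples x variable-loci matrix of recoded single letters."""

    sample_ids: list[str]
    loci: list[Locus]
    matrix: list[list[str]]  # rows follow sample_ids, columns follow loci

    def __post_init__(self) -> None:
        if any(len(row) != len(self.loci) for row in self.matrix):
            raise ValueError("matrix is not rectangular")
        if len(self.matrix) != len(self.sample_ids):
            raise ValueError("one row per sample required")

    def column(self, j: int) -> list[str]:
        return [row[j] for row in self.matrix]

    def row(self, sample_id: str) -> list[str]:
        return self.matrix[self.sample_ids.index(sample_id)]

    def drop_columns(self, drop: set[int]) -> "VariantTable":
        keep = [j for j in range(len(self.loci)) if j not in drop]
        return VariantTable(
            sample_ids=list(self.sample_ids),
            loci=[self.loci[j] for j in keep],
            matrix=[[row[j] for j in keep] for row in self.matrix],
        )


def _default_hotspots() -> list[tuple]:
    # (kind, positions, inserted-base constraint)
    return [
        ("ins", (309,), "C"),     # 309.1C and 309.1CC
        ("ins", (315,), "C"),     # 315.1C
        ("del", (522, 523, 524), None),  # 523-524del, alternatively 522-523del
        ("del", (3106,), None),
        ("snp", (16182,), None),
        ("snp", (16183,), None),
        ("ins", (16193,), "C"),   # 16193.1C and 16193.1CC
        ("snp", (16519,), None),
    ]


@dataclass
class HotspotList:
    """Indel/SNP hotspot loci excluded from the recoded matrix.

    The default list covers the rCRS poly-C stretches (309.1C(C), 315.1C,
    16193.1C(C)), the 522-524 AC-repeat deletions under both coordinate
    conventions, the 3106 reference artefact deletion, and the hypervariable
    16182C/16183C/16519C positions.
    """

    entries: list[tuple] = field(default_factory=_default_hotspots)

    def matches(self, locus: Locus) -> bool:
        for kind, positions, base in self.entries:
            if locus.kind != kind or locus.position not in positions:
                continue
            if kind == "ins" and base is not None:
                if set(locus.detail) != {base}:
                    continue
            return True
        return False


DEFAULT_HOTSPOTS = HotspotList()


def qc_filter(genomes: list[Mitogenome], max_missing: int = 500,
              ) -> tuple[list[Mitogenome], list[Mitogenome]]:
    """Split genomes into (kept, excluded) by missing/uncertain-letter count.

    A genome is excluded iff it has strictly more than ``max_missing``
    letters outside A/C/G/T (N and partial-ambiguity codes both count;
    alignment gaps do not — length variation is genuine variation).
    """
    kept, excluded = [], []
    for g in genomes:
        (excluded if g.missing_or_uncertain() > max_missing else kept).append(g)
    return kept, excluded


def build_variant_table(calls: dict[str, list[Variant]], reference: str) -> VariantTable:
    """Tabulate per-sample variant calls into the recoded matrix.

    ``calls`` maps sample id -> variants in reference coordinates (one entry
    per sample; an empty list means the sample equals the reference).  SNP
    loci are keyed by position only — all samples share one column per
    variable position, carriers showing their own alternate letter.  Each
    distinct indel event (position + inserted bases) becomes its own
    pseudo-SNP column via :func:`recode_indels`.
    """
    samples = list(calls)
    snp_letters: dict[int, dict[str, str]] = {}
    snp_conflict: dict[tuple[str, int], str] = {}
    indel_records: list[tuple[str, Variant]] = []
    for s, variants in calls.items():
        for v in variants:
            if v.kind == "snp":
                prev = snp_conflict.get((s, v.position))
                if prev is not None and prev != v.alt:
                    raise ValueError(f"conflicting SNP records for {s} at {v.position}")
                snp_conflict[(s, v.position)] = v.alt
                snp_letters.setdefault(v.position, {})[s] = v.alt
            else:
                indel_records.append((s, v))

    loci: list[Locus] = []
    columns: list[dict[str, str]] = []
    for pos in sorted(snp_letters):
        refbase = reference[pos - 1]
        letters = {s: snp_letters[pos].get(s, refbase) for s in samples}
        if len(set(letters.values())) < 2:
            continue  # not variable after all (every sample carries the alt)
        loci.append(Locus(pos, "snp", detail=_major_alt(snp_letters[pos])))
        columns.append(letters)

    indel_loci, indel_columns = recode_indels(indel_records, samples)

    # keep loci in reference-position order, SNPs before indels at a tie
    order = sorted(range(len(loci) + len(indel_loci)),
                   key=lambda k: ((loci + indel_loci)[k].position,
                                  (loci + indel_loci)[k].kind != "snp",
                                  str((loci + indel_loci)[k])))
    all_loci = loci + indel_loci
    all_cols = columns + indel_columns
    matrix = [[all_cols[k][s] for k in order] for s in samples]
    return VariantTable(sample_ids=samples,
                        loci=[all_loci[k] for k in order],
                        matrix=matrix)


def _major_alt(carriers: dict[str, str]) -> str:
    counts: dict[str, int] = {}
    for alt in carriers.values():
        counts[alt] = counts.get(alt, 0) + 1
    return max(sorted(counts), key=counts.get)


def recode_indels(records: list[tuple[str, Variant]], samples: list[str],
                  ) -> tuple[list[Locus], list[dict[str, str]]]:
    """Turn indel events into pseudo-SNP columns.

    One column per distinct insertion event (anchor position + inserted
    bases): carriers T, reference samples C.  One column per distinct
    deletion position: carriers C, reference samples T.
    """
    events: dict[Locus, set[str]] = {}
    for s, v in records:
        if v.kind == "ins":
            locus = Locus(v.position, "ins", detail=v.alt)
        elif v.kind == "del":
            locus = Locus(v.position, "del")
        else:
            raise ValueError("recode_indels expects only indel records")
        events.setdefault(locus, set()).add(s)
    loci, columns = [], []
    for locus in sorted(events, key=lambda l: (l.position, l.kind, l.detail)):
        carriers = events[locus]
        if locus.kind == "ins":
            col = {s: ("T" if s in carriers else "C") for s in samples}
        else:
            col = {s: ("C" if s in carriers else "T") for s in samples}
        loci.append(locus)
        columns.append(col)
    return loci, columns


def apply_hotspot_exclusion(table: VariantTable,
                            hotspots: HotspotList = DEFAULT_HOTSPOTS) -> VariantTable:
    """Drop matrix columns matching a hotspot descriptor; order preserved."""
    drop = {j for j, locus in enumerate(table.loci) if hotspots.matches(locus)}
    if not drop:
        return table
    return table.drop_columns(drop)


def find_identical_sequences(table: VariantTable,
                             groups: dict[str, str] | None = None,
                             ) -> list[dict]:
    """Clusters of samples with bit-identical recoded variant rows.

    Identical whole-mtDNA sequences within a burial community flag potential
    direct maternal relatives.  Matching is strict letter equality ('N' is
    not treated as a wildcard), so only fully concordant rows cluster.
    Returns clusters of size >= 2 with member ids and their populations.
    """
    by_row: dict[tuple, list[str]] = {}
    for sid, row in zip(table.sample_ids, table.matrix):
        by_row.setdefault(tuple(row), []).append(sid)
    clusters = []
    for members in by_row.values():
        if len(members) >= 2:
            clusters.append({
                "samples": sorted(members),
                "populations": sorted({groups[s] for s in members}) if groups else [],
            })
    clusters.sort(key=lambda c: c["samples"])
    return clusters


def write_variant_matrix(table: VariantTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(str(l) for l in table.loci) + "\n")
        for sid, row in zip(table.sample_ids, table.matrix):
            fh.write(sid + "\t" + "\t".join(row) + "\n")


def write_arp(table: VariantTable, groups: dict[str, str], path,
              title: str = "mtadmix recoded haplotypes") -> None:
    """Arlequin-style profile (.arp dialect) of the recoded haplotypes.

    Plain-text [Profile]/[Data]/[[Samples]] sections with one SampleData
    block per population; validated structurally, not against the Arlequin
    binary.
    """
    pops: dict[str, list[str]] = {}
    for sid in table.sample_ids:
        pops.setdefault(groups[sid], []).append(sid)
    with open(path, "w") as fh:
        fh.write("[Profile]\n")
        fh.write(f'  Title="{title}"\n')
        fh.write(f"  NbSamples={len(pops)}\n")
        fh.write("  DataType=DNA\n")
        fh.write("  GenotypicData=0\n")
        fh.write("  LocusSeparator=NONE\n")
        fh.write("[Data]\n")
        fh.write("  [[Samples]]\n")
        for pop, members in pops.items():
            fh.write(f'    SampleName="{pop}"\n')
            fh.write(f"    SampleSize={len(members)}\n")
            fh.write("    SampleData= {\n")
            for sid in members:
                hap = "".join(table.row(sid))
                fh.write(f"      {sid} 1 {hap}\n")
            fh.write("    }\n")
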