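"""QC-filter the genomes and build the recoded variant matrix.

Sequences with more than 500 missing/uncertain letters are dropped (none
should be, at the simulated 0.1% missingness); indels become C/T pseudo-SNP
columns; hotspot loci are excluded; identical recoded haplotypes (potential
maternal relatives) are reported.
"""

import json
import sys

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from paths import DATA, RESULTS

from mtadmix.align import align_and_call
from mtadmix.pipeline import read_fasta, read_table
from mtadmix.recode import (apply_hotspot_exclusion, build_variant_table,
                            find_identical_sequences, qc_filter, write_arp,
                            write_variant_matrix)


def main() -> None:
    reference = read_fasta(DATA / "reference.fasta")[0].sequence
    genomes = read_fasta(DATA / "samples.fasta")
    groups = read_table(DATA / "populations.tsv")

    kept, excluded = qc_filter(genomes, max_missing=500)
    print(f"QC: kept {len(kept)}/{len(genomes)} genomes "
          f"({len(excluded)} with >500 missing/uncertain nt)")

    calls = {g.sample_id: align_and_call(reference, g) for g in kept}
    table = build_variant_table(calls, reference)
    n_before = len(table.loci)
    table = apply_hotspot_exclusion(table)
    print(f"variable loci: {n_before} called, {len(table.loci)} after hotspot "
          f"exclusion ({n_before - len(table.loci)} hotspot columns removed)")

    write_variant_matrix(table, RESULTS / "variant_matrix.tsv")
    write_arp(table, groups, RESULTS / "haplotypes.arp")
    clusters = find_identical_sequences(table, groups)
    (RESULTS / "identical_clusters.json").write_text(json.dumps(clusters, indent=1))
    if clusters:
        print(f"{len(clusters)} clusters of identical haplotypes "
              "(candidate maternal relatives):")
        for c in clusters:
            print("  ", ", ".join(c["samples"]), "in", "/".join(c["populations"]))
    else:
        print("no identical recoded haplotypes (no candidate maternal relatives)")
    print(f"matrix and .arp written under {RESULTS}")


if __name__ == "__main__":
    main()
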