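"""Build the synthetic study world.

Five 'panel' populations with distinct sub-haplogroup profiles (two drawn
from eastern major clades, three from western ones) plus one 'focal'
population constructed as a 30/70 east/west admixture — the shape of the
motivating dataset, where roughly a third of the focal maternal lineages
were east-Eurasian.  Every downstream script works only from the files
written here; the true admixture proportions are recorded for comparison.
"""

import json
import sys

import numpy as np

sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
from paths import DATA, SEED

from mtadmix import synth

N_PER_POP = 12
REF_LEN = 2000
TRUE_MIX = {"east1": 0.3, "west1": 0.7}


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    reference = synth.make_reference(REF_LEN, seed=SEED)
    tree = synth.generate_tree(n_major=4, depth=2, branching=2, seed=SEED)
    model = synth.build_haplotype_model(
        tree, reference, snps_per_branch=3, indel_prob=0.1,
        private_mutation_rate=1.0, missing_rate=0.001, seed=SEED + 1)

    leaves = tree.leaves()  # 4 majors x 4 leaves
    by_major = {m: [l for l in leaves if l.startswith(m)]
                for m in tree.children(tree.root)}
    majors = sorted(by_major)
    rng = np.random.default_rng(SEED + 2)

    def profile(name, major_ids):
        pool = [l for m in major_ids for l in by_major[majors[m]]]
        chosen = rng.choice(pool, size=3, replace=False)
        w = rng.dirichlet(np.ones(3) * 5)
        return synth.HaplogroupProfile(name, {h: float(x) for h, x in zip(chosen, w)})

    profiles = {
        "east1": profile("east1", [0]),
        "east2": profile("east2", [1]),
        "west1": profile("west1", [2]),
        "west2": profile("west2", [3]),
        "west3": profile("west3", [2, 3]),
    }
    profiles["focal"] = synth.admix_profiles(
        [profiles["east1"], profiles["west1"]],
        [TRUE_MIX["east1"], TRUE_MIX["west1"]], "focal")

    genomes, groups, hgs = [], {}, {}
    for i, (name, prof) in enumerate(sorted(profiles.items())):
        spec = synth.SyntheticPopulationSpec(name, prof, N_PER_POP,
                                             seed=SEED + 100 + i)
        for g, h in synth.sample_population(spec, model):
            genomes.append(g)
            groups[g.sample_id] = name
            hgs[g.sample_id] = h

    synth.write_fasta(genomes, DATA / "samples.fasta")
    synth.write_fasta([synth.Mitogenome("reference", reference)],
                      DATA / "reference.fasta")
    synth.write_table(groups, DATA / "populations.tsv", ("sample", "population"))
    synth.write_table(hgs, DATA / "haplogroups.tsv", ("sample", "haplogroup"))
    (DATA / "ground_truth.json").write_text(json.dumps({
        "true_mix": TRUE_MIX,
        "profiles": {n: p.freqs for n, p in profiles.items()},
        "n_per_population": N_PER_POP,
        "reference_length": REF_LEN,
        "seed": SEED,
    }, indent=1))

    print(f"simulated {len(genomes)} mitogenomes "
          f"({len(profiles)} populations x {N_PER_POP} samples, "
          f"reference {REF_LEN} nt)")
    print(f"focal population is a true {TRUE_MIX['east1']:.0%}/"
          f"{TRUE_MIX['west1']:.0%} east1/west1 admixture")
    print(f"data written under {DATA}")


if __name__ == "__main__":
    main()
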