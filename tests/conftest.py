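import numpy as np
import pytest

from mtadmix import synth


@pytest.fixture(scope="session")
def toy_reference():
    return synth.make_reference(600, seed=11)


@pytest.fixture(scope="session")
def toy_tree():
    return synth.generate_tree(n_major=3, depth=2, branching=2, seed=0)


@pytest.fixture(scope="session")
def toy_model(toy_tree, toy_reference):
    return synth.build_haplotype_model(toy_tree, toy_reference,
                                       snps_per_branch=4, seed=3)


def make_dataset(tmp_path, n_pops=3, n_samples=8, ref_len=600, seed=11,
                 missing_rate=0.0, private_rate=0.0, indel_prob=0.15):
    """Full synthetic dataset on disk: FASTA + reference + both tables."""
    ref = synth.make_reference(ref_len, seed=seed)
    tree = synth.generate_tree(3, 2, 2, seed=0)
    model = synth.build_haplotype_model(
        tree, ref, snps_per_branch=4, indel_prob=indel_prob,
        private_mutation_rate=private_rate, missing_rate=missing_rate,
        seed=seed + 1)
    leaves = tree.leaves()
    genomes, groups, hgs = [], {}, {}
    for p in range(n_pops):
        chosen = leaves[p * 4:(p + 1) * 4][:3]
        prof = synth.HaplogroupProfile(f"pop{p}", dict(zip(chosen, [0.5, 0.3, 0.2])))
        spec = synth.SyntheticPopulationSpec(f"pop{p}", prof, n_samples,
                                             seed=seed * 100 + p)
        for g, h in synth.sample_population(spec, model):
            genomes.append(g)
            groups[g.sample_id] = f"pop{p}"
            hgs[g.sample_id] = h
    synth.write_fasta(genomes, tmp_path / "samples.fasta")
    synth.write_fasta([synth.Mitogenome("ref", ref)], tmp_path / "reference.fasta")
    synth.write_table(groups, tmp_path / "populations.tsv", ("sample", "population"))
    synth.write_table(hgs, tmp_path / "haplogroups.tsv", ("sample", "haplogroup"))
    return dict(ref=ref, tree=tree, model=model, genomes=genomes,
                groups=groups, hgs=hgs, dir=tmp_path)
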