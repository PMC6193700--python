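"""End-to-end orchestration: align -> recode -> QC -> (Fst + MDS) and
(profiles -> SHD -> admixture search), with a machine-readable run manifest.

The two analysis branches are deliberately independent: the Fst branch works
from whole-mitogenome sequence variation, the SHD/MITOMIX branch only from
sub-haplogroup assignments.  Agreement between them is the study design's
internal consistency check, so nothing is shared past the input tables.

All randomness derives from the single config seed through named per-stage
substreams; reruns with an identical config produce bit-identical outputs
(the manifest records a digest of every artifact so this is checkable).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import align as _align
from . import fst as _fst
from . import mix as _mix
from . import recode as _recode
from .import_shims import shd_module as _shd
from .synth import Mitogenome

log = logging.getLogger("mtadmix")

__all__ = ["PipelineConfig", "SubpopulationScheme", "run_pipeline",
           "subpopulation_reanalysis", "read_fasta", "read_table"]

_STAGE_SEEDS = {"fst": 1, "reanalysis": 2}


@dataclass
class PipelineConfig:
    fasta: str
    reference: str
    population_table: str
    haplogroup_table: str
    outdir: str
    seed: int = 0
    # alignment
    weights: _align.AlignmentWeights = field(default_factory=_align.AlignmentWeights)
    # QC / recoding
    max_missing: int = 500
    ancient_populations: tuple[str, ...] = ()  # exempt from the QC filter
    exclude_hotspots: bool = True
    # Fst
    gamma_alpha: float = 0.325
    n_permutations: int = 10000
    deletion: str = "pairwise"
    # SHD / MITOMIX
    corrected: bool = False
    correction_weight: float = 0.5
    k_min: int = 1
    k_max: int = 3
    grid_step: float = 0.05
    top_n: int = 20
    mitomix_test: str | None = None  # default: first population alphabetically
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Plain-text key=value configuration; '#' starts a comment."""
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        kwargs: dict = {}
        for f_ in cls.__dataclass_fields__.values():
            if f_.name in kv:
                raw = kv[f_.name]
                if f_.name == "ancient_populations":
                    kwargs[f_.name] = tuple(x for x in raw.split(",") if x)
                elif f_.type in ("int", "int | None"):
                    kwargs[f_.name] = int(raw)
                elif f_.type == "float":
                    kwargs[f_.name] = float(raw)
                elif f_.type == "bool":
                    kwargs[f_.name] = raw.lower() in ("1", "true", "yes")
                else:
                    kwargs[f_.name] = raw
        kwargs.update(overrides)
        return cls(**kwargs)

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([int(self.seed), _STAGE_SEEDS[stage]])
        return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class SubpopulationScheme:
    """Named partition of a focal population into disjoint sample subsets."""

    name: str
    subsets: dict[str, set[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, members in self.subsets.items():
            if seen & members:
                raise ValueError(f"subset {label!r} overlaps another subset")
            seen |= members


def read_fasta(path) -> list[Mitogenome]:
    from Bio import SeqIO

    return [Mitogenome(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def read_table(path) -> dict[str, str]:
    """Two-column tab-separated table with a header row."""
    out: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        sample, value = line.split("\t")[:2]
        out[sample] = value
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the run manifest."""
    logging.basicConfig(level=config.log_level)
    t0 = time.time()
    for p in (config.fasta, config.reference, config.population_table,
              config.haplogroup_table):
        if not Path(p).exists():
            raise FileNotFoundError(f"input path does not exist: {p}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    reference = read_fasta(config.reference)[0].sequence
    genomes = read_fasta(config.fasta)
    groups = read_table(config.population_table)
    assignments = read_table(config.haplogroup_table)
    stages: dict[str, dict] = {}
    outputs: list[Path] = []

    # --- QC (modern sequences only; ancient populations are exempt) -------
    modern = [g for g in genomes if groups.get(g.sample_id) not in config.ancient_populations]
    ancient = [g for g in genomes if g not in modern]
    kept, excluded = _recode.qc_filter(modern, config.max_missing)
    usable = kept + ancient
    usable_ids = {g.sample_id for g in usable}
    stages["qc"] = {"input": len(genomes), "kept": len(usable),
                    "excluded": [g.sample_id for g in excluded]}
    log.info("QC: %d/%d genomes kept", len(usable), len(genomes))

    # --- alignment and variant calling ------------------------------------
    calls = {g.sample_id: _align.align_and_call(reference, g, config.weights)
             for g in usable}
    vcf_path = outdir / "variants.vcf"
    _align.write_vcf(calls, reference, vcf_path)
    outputs.append(vcf_path)
    stages["align"] = {"samples": len(calls),
                       "records": sum(len(v) for v in calls.values())}

    # --- recoding ----------------------------------------------------------
    table = _recode.build_variant_table(calls, reference)
    if config.exclude_hotspots:
        table = _recode.apply_hotspot_exclusion(table)
    matrix_path = outdir / "variant_matrix.tsv"
    _recode.write_variant_matrix(table, matrix_path)
    arp_path = outdir / "haplotypes.arp"
    _recode.write_arp(table, groups, arp_path)
    outputs += [matrix_path, arp_path]
    clusters = _recode.find_identical_sequences(table, groups)
    clusters_path = outdir / "identical_clusters.json"
    clusters_path.write_text(json.dumps(clusters, indent=1))
    outputs.append(clusters_path)
    stages["recode"] = {"loci": len(table.loci),
                        "identical_clusters": len(clusters)}

    # --- Fst branch ---------------------------------------------------------
    params = _fst.TN93Params(gamma_alpha=config.gamma_alpha)
    result = _fst.pairwise_fst(table, groups, params,
                               n_permutations=config.n_permutations,
                               seed=config.stage_seed("fst"),
                               deletion=config.deletion)
    _write_matrix(outdir / "fst.tsv", result.populations, result.fst)
    _write_matrix(outdir / "fst_pvalues.tsv", result.populations, result.pvalues)
    lin = _fst.slatkin_linearize(result.fst)
    np.fill_diagonal(lin, 0.0)
    _write_matrix(outdir / "fst_slatkin.tsv", result.populations, lin)
    mds = _fst.classical_mds(lin, k=min(2, len(result.populations) - 1),
                             populations=result.populations)
    mds_path = outdir / "mds.tsv"
    with open(mds_path, "w") as fh:
        fh.write("population\t" + "\t".join(f"dim{i+1}" for i in range(mds.coords.shape[1])) + "\n")
        for name, row in zip(mds.populations, mds.coords):
            fh.write(name + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    outputs += [outdir / "fst.tsv", outdir / "fst_pvalues.tsv",
                outdir / "fst_slatkin.tsv", mds_path]
    stages["fst"] = {"populations": result.populations,
                     "n_permutations": result.n_permutations}

    # --- SHD / MITOMIX branch ----------------------------------------------
    sub_groups = {s: p for s, p in groups.items() if s in usable_ids}
    sub_assign = {s: h for s, h in assignments.items() if s in usable_ids}
    profiles = _shd.profile_from_assignments(sub_assign, sub_groups)
    shd_m = _shd.shd_matrix(profiles, corrected=config.corrected,
                            correction_weight=config.correction_weight)
    shd_path = outdir / "shd.tsv"
    _shd.write_shd_matrix(shd_m, shd_path)
    outputs.append(shd_path)
    stages["shd"] = {"populations": shd_m.populations,
                     "corrected": shd_m.corrected}

    test_label = config.mitomix_test or shd_m.populations[0]
    test_profile = next(p for p in profiles if p.population == test_label)
    mix_cfg = _mix.MixSearchConfig(k_min=config.k_min,
                                   k_max=min(config.k_max, len(profiles) - 1),
                                   grid_step=config.grid_step,
                                   top_n=config.top_n,
                                   corrected=config.corrected,
                                   correction_weight=config.correction_weight)
    solutions = _mix.search(test_profile, profiles, mix_cfg)
    sol_path = outdir / "mitomix.tsv"
    _mix.write_solutions(solutions, sol_path)
    outputs.append(sol_path)
    stages["mitomix"] = {"test": test_label, "solutions": len(solutions),
                         "best_shd": solutions[0].achieved_shd if solutions else None}

    manifest = {
        "inputs": {"fasta": config.fasta, "reference": config.reference,
                   "population_table": config.population_table,
                   "haplogroup_table": config.haplogroup_table},
        "parameters": {k: v for k, v in asdict(config).items()
                       if k not in ("fasta", "reference", "population_table",
                                    "haplogroup_table", "outdir")},
        "seed": config.seed,
        "stages": stages,
        "outputs": {str(p.name): _sha256(p) for p in outputs},
        "elapsed_s": round(time.time() - t0, 3),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _write_matrix(path, labels, M) -> None:
    with open(path, "w") as fh:
        fh.write("population\t" + "\t".join(labels) + "\n")
        for name, row in zip(labels, np.asarray(M)):
            fh.write(name + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def subpopulation_reanalysis(config: PipelineConfig, scheme: SubpopulationScheme,
                             ) -> dict:
    """Re-run the distance analyses with each scheme subset treated as a
    standalone population against the full comparison panel.

    Mirrors the study pattern of splitting a focal population into lineage
    classes (e.g. east vs west Eurasian) and asking which panel populations
    each class resembles.  Subsets too small for Fst (< 2 samples) are
    skipped with a warning; SHD is still computed for one-sample subsets.
    """
    reference = read_fasta(config.reference)[0].sequence
    genomes = read_fasta(config.fasta)
    groups = dict(read_table(config.population_table))
    assignments = read_table(config.haplogroup_table)
    results: dict[str, dict] = {}
    for label, members in scheme.subsets.items():
        if not members:
            log.warning("subset %r is empty; skipped", label)
            results[label] = {"skipped": "empty subset"}
            continue
        sub_label = f"{scheme.name}:{label}"
        new_groups = {s: (sub_label if s in members else p)
                      for s, p in groups.items()}
        # drop focal-population samples outside this subset so the subset is
        # compared against the untouched panel only
        focal_pops = {groups[s] for s in members}
        keep = {s for s, p in groups.items()
                if s in members or p not in focal_pops}
        sub_genomes = [g for g in genomes if g.sample_id in keep]
        sub_group_map = {s: new_groups[s] for s in keep}

        entry: dict = {}
        profiles = _shd.profile_from_assignments(
            {s: assignments[s] for s in keep}, sub_group_map)
        shd_m = _shd.shd_matrix(profiles, corrected=config.corrected,
                                correction_weight=config.correction_weight)
        entry["shd"] = {"populations": shd_m.populations,
                        "values": shd_m.values.tolist()}
        if len(members) >= 2:
            calls = {g.sample_id: _align.align_and_call(reference, g, config.weights)
                     for g in sub_genomes}
            table = _recode.build_variant_table(calls, reference)
            if config.exclude_hotspots:
                table = _recode.apply_hotspot_exclusion(table)
            res = _fst.pairwise_fst(table, sub_group_map,
                                    _fst.TN93Params(config.gamma_alpha),
                                    n_permutations=config.n_permutations,
                                    seed=config.stage_seed("reanalysis"),
                                    deletion=config.deletion)
            entry["fst"] = {"populations": res.populations,
                            "values": res.fst.tolist(),
                            "pvalues": res.pvalues.tolist()}
        else:
            log.warning("subset %r has < 2 samples; Fst skipped", label)
            entry["fst"] = {"skipped": "fewer than 2 samples"}
        results[label] = entry
    return results
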