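# Methods

## Scope and model

`mtadmix` compares populations of complete human mitochondrial genomes.
Because mtDNA is maternally inherited and does not recombine, each genome is
a single haplotype on one tree, and a population is summarised two ways:
by its set of sequences (for sequence-divergence statistics) and by its
frequency vector over named sub-haplogroups (for overlap statistics).
Both are computed here, deliberately kept independent of one another:
agreement between the Fst branch and the SHD branch is the analysis design's
internal consistency check.

## Alignment and variant calling

Each sample is aligned globally to the reference with a three-state Gotoh
dynamic program. Column scores depend on the IUPAC ambiguity class of the
*more ambiguous* of the two symbols when their base sets intersect:
exact A/C/G/T identity 6; 2-fold codes (R Y M W S K) 3; 3-fold (B D H V) 2;
4-fold (N) 1; disjoint sets −12. Gaps are affine with open −24 and extend
−6; a run of length L costs open + (L−1)·extend. Choices that the weight
constants do not determine, and that we fixed:

* **One-sided ambiguity counts as an ambiguity match.** A vs R scores 3, not
  mismatch. The scheme's purpose is tolerating uncertain ancient-DNA calls,
  and the class names refer to the code's fold, so the more ambiguous symbol
  sets the class. This is a design choice, not forced by the constants.
* **Terminal gaps cost like internal gaps** (true global alignment): inputs
  are complete mitogenomes of near-equal length, so free end gaps would
  reward truncation artifacts.
* **Tie-breaking** among co-optimal alignments prefers substitution over
  gap, then gap-in-query over gap-in-reference, during traceback. This
  makes outputs bit-reproducible.
* The circular molecule is treated as linear in reference coordinates.

Variants are read off the alignment in 1-based reference coordinates:
substitution columns give SNP records (ambiguity letters kept verbatim as
alternates), a run of gap-in-reference gives one insertion record anchored
at the preceding reference position, and each deleted base gives one
single-position deletion record (per-event granularity, matching the
recoding below). The DP is vectorised row-by-row (the horizontal affine
state is a running maximum), so a 16.6 kb genome aligns in seconds; the
aligner is verified against exhaustive enumeration of all global alignments
on short sequences.

## QC and recoding

Sequences with **more than 500** letters outside A/C/G/T are excluded
("missing or uncertain": N and all partial-ambiguity codes count, alignment
gaps do not — length variation is genuine variation, not uncertainty). The
filter is intended for modern database sequences; ancient genomes can be
exempted and carry per-locus N instead.

Only variable positions are tabulated. Indels become pseudo-SNP columns:
insertion carriers **T** / reference samples **C**; deletion carriers **C**
/ reference samples **T**; SNP columns carry the literal alternate for
carriers and the reference letter otherwise. Distinct insertion events at
one anchor (different inserted bases) stay distinct columns, which keeps the
recoding invertible.

Common indel/length hotspots are excluded by default: C-insertions at 309,
315 and 16193 (single or double), the 522–524 AC-repeat deletions under both
published coordinate conventions, the 3106 reference artifact, and the
hypervariable 16182/16183/16519 positions. Hotspot exclusion is a switch:
whether hypervariable *SNP* positions should also leave the Fst input is a
judgment call, so the step can be disabled.

Samples with bit-identical recoded rows are reported as candidate direct
maternal relatives; matching is strict (N is not a wildcard), so only fully
concordant haplotypes cluster.

## TN93 distances and Fst

Haplotype distances use the Tamura–Nei (1993) closed form, separating the
two transition classes from transversions, with gamma rate heterogeneity
of shape α = 0.325 (default) applied through the standard
α·k·(w^(−1/α) − 1) correction per class; α = ∞ gives the log form. Base
frequencies are estimated from the pooled pair being compared; sites where
either letter is ambiguous are deleted pairwise (complete deletion is
available). The implementation reproduces `ape::dist.dna(model="TN93",
gamma=0.325)` to printed precision.

Numerical edges: a pair with no comparable sites is an error; a saturated
pair (non-positive logarithm argument) returns infinity, and before the
AMOVA such entries are capped at twice the largest finite distance in the
matrix so that maximal divergence stays maximal without destroying the
variance decomposition. Recoded mtDNA tables never approach saturation;
the cap exists so that degenerate toy inputs (e.g. two populations fixed
for different haplotypes) still give the exact expected Φst of 1.

Population differentiation is the distance-matrix AMOVA form (Φst): the
TN93 distances enter as squared Euclidean distances, the one-level variance
decomposition uses the standard expected-mean-square algebra with the
unequal-size coefficient n_c, and Φst = σ²_among/(σ²_among + σ²_within).
Negative estimates are sampling noise around zero and are reported as
computed. Significance: the fraction of label permutations (default
10,000) whose Φst is at least the observed value, with no +1 correction,
mirroring the proportion a permutation test reports directly; permutations
are evaluated for all replicates at once as quadratic forms over membership
matrices, and the generator seed is an explicit parameter.

Slatkin linearization Fst/(1−Fst) clamps negative inputs to 0 first (a
negative "distance" would break the subsequent scaling) and rejects entries
of 1. Ordination is classical Torgerson scaling: square the distances,
double-center, eigendecompose, scale the top-k eigenvectors by the square
roots of their non-negative eigenvalues; axis signs are fixed so each
axis's largest-magnitude loading is positive. Verified against
scikit-bio's PCoA and by round-trip on planar point sets.

## Shared Haplogroup Distance

Raw SHD is 1 − Σ_h min(f_a(h), f_b(h)). This is the unique symmetric
overlap complement that is 0 exactly for identical profiles, 1 exactly for
disjoint supports, and exactly 1 − w against a w/(1−w) admixture with a
disjoint source — the proportionality that makes the admixture search
meaningful. It equals half the L1 distance between the frequency vectors,
hence is a true metric.

The corrected variant models one step of lineage turnover: after exact
matching, unmatched mass in haplogroup h may match unmatched mass in h's
*direct* parent or child (one nomenclature step), each unit counting as
`correction_weight` (default 0.5) units of overlap; weight 0 recovers the
raw distance, and credit can only reduce a distance. The exact published
turnover weighting is not reproducible from the method description alone,
so the credit scheme is parameterised and the uncontested raw metric is the
default. Parent resolution uses an explicit haplogroup tree when given and
otherwise falls back to nomenclature (strip the trailing digit or letter
run: N1a1a1a1a → N1a1a1a1, H16 → H), which encodes mtDNA ancestry by
construction. Matching order is deterministic (sorted labels), and since
all one-step credits are equal, order cannot change the total credit.

SHD is frequency-only: sample sizes are kept as metadata but do not weight
the distance.

## MITOMIX search

For each K from k_min to k_max (defaults 1 and 6; in practice 3–6 sources
suffice and larger K stops improving the fit), every K-subset of the
candidate pool is combined with every strictly positive weight vector on a
1 % grid (compositions of 100 into K parts; the grid matches the integer
percentages such searches report). Each subset's full weight grid is
evaluated as one matrix product. Solutions are ranked by ascending SHD with
ties broken by smaller K, then lexicographic source labels, then weight
vectors — fully deterministic. The per-source minimum–maximum across the
top-n (default 20) solutions is reported as the "26–38 %"-style range
summary. An optional branch-and-bound prune skips a subset when
1 − Σ_h min(test_h, max_source_h) — a lower bound on any mixture's SHD,
since a convex combination never exceeds the elementwise maximum — cannot
beat the current top list; pruning is tested to never change the result.
An epoch filter restricts the pool to populations contemporary with or
older than the test population for ancient-only searches.

## Synthetic data generator

The generator emulates exactly the statistical structure the analysis
assumes: a haplogroup hierarchy whose labels extend their parent's label;
per-branch defining variants accumulated down the tree (so a child's genome
carries all parent variants); populations as frequency vectors over
sub-haplogroups; admixed populations as convex combinations of source
vectors; and genomes derived from a reference by defining SNPs, single-base
insertions/deletions, Poisson private SNPs and Bernoulli N-masking.

Deliberate simplifications, hence what passing tests do *not* show about
real data: no coalescent genealogy within a haplogroup (private mutations
are i.i.d., not tree-structured), no mutation-rate variation along the
molecule, no heteroplasmy, no sequencing-error model beyond N-masking, no
reference-bias or damage artifacts, and indels only as single-base events.
Private mutations never hit defining-variant positions, so the simulated
haplogroup assignment is unambiguous ground truth. Defaults: reference
length 16,569 nt (any length ≥ 100 is accepted so tests run on toy
references), missing rate 0.001 (the order of a good ancient consensus),
one private mutation per sample. All randomness flows through explicit
seeds; there is no global random state.

## Problem sizes used in the bundled analysis

The `analysis/` chain runs 6 populations × 12 samples on a 2,000 nt
reference with 3 defining SNPs per tree branch, 10 % indel branches,
1 private mutation and 0.1 % missingness per genome — enough samples for
stable 3-population Fst and visibly proportional SHD, while the whole chain
completes in about two minutes. The focal population is a 30/70 east/west
admixture, matching the motivating case of a population whose maternal
lineages split roughly one-third/two-thirds between eastern and western
Eurasian clades. Permutation counts are 10,000 in the Fst script (the
analysis default) and reduced in unit tests.

## Known limitations

* Φst permutation p-values are proportions over a finite permutation set;
  at 10,000 permutations the resolution is 10⁻⁴.
* The corrected SHD is a one-step credit scheme, not a calibrated
  mutation/fixation-rate model; conclusions that depend on the correction
  should be checked against the raw metric (the package default).
* The exhaustive search is exponential in K; the prune helps but the
  intended regime is pools of tens of populations with K ≤ 6, coarser grids
  for larger K.
* The `.arp` export is a structural dialect writer for interoperability; it
  is validated by section structure, not against the Arlequin binary.
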