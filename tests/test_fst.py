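"""TN93 distances, AMOVA Phi_st with permutations, Slatkin transform, MDS."""

import itertools
import shutil
import subprocess

import numpy as np
import pytest
import scipy.stats

from mtadmix.fst import (TN93Params, amova_phist, classical_mds, pairwise_fst,
                         slatkin_linearize, tn93_distance, tn93_matrix)
from mtadmix.recode import Locus, VariantTable


def table_from_rows(rows: list[str]) -> VariantTable:
    loci = [Locus(i + 1, "snp", "G") for i in range(len(rows[0]))]
    ids = [f"s{i}" for i in range(len(rows))]
    return VariantTable(ids, loci, [list(r) for r in rows])


def low_divergence_rows(rng, n, L=40, flips=3, base=None):
    """Haplotype rows with balanced base composition and few differences,
    mimicking recoded mtDNA tables (which never approach saturation)."""
    if base is None:
        base = list("ACGT" * (L // 4))
    rows = []
    for _ in range(n):
        hap = list(base)
        for j in rng.choice(L, size=flips, replace=False):
            hap[j] = rng.choice([c for c in "ACGT" if c != hap[j]])
        rows.append("".join(hap))
    return rows


class TestTN93:
    def test_identical_sequences_zero(self):
        assert tn93_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_transversions_only_equal_frequencies_reduces_to_closed_form(self):
        # equal pooled base frequencies and P1 = P2 = 0: the TN93 distance
        # collapses to d = -1/2 ln(1-Q) - 1/4 ln(1-2Q) (alpha -> inf limit)
        core = "ACGT" * 10
        # transversion pairs arranged to keep pooled frequencies equal
        a = core + "ACGT"
        b = core + "CATG"  # A<->C, C<->A, G<->T, T<->G : 4 transversions
        Q = 4 / 44
        expected = -0.5 * np.log(1 - Q) - 0.25 * np.log(1 - 2 * Q)
        got = tn93_distance(a, b, TN93Params(float("inf")))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_gamma_closed_form_oracle(self):
        """Independent re-implementation of the TN93-Gamma formula on a toy
        pair with 2 transitions + 1 transversion over 100 sites."""
        a = list("ACGT" * 25)
        b = list(a)
        b[0] = "G"   # A->G transition
        b[1] = "T"   # C->T transition
        b[2] = "T"   # G->T transversion
        a, b = "".join(a), "".join(b)
        alpha = 0.325
        # oracle: written straight from the published closed form
        n = 100
        P1, P2, Q = 1 / n, 1 / n, 1 / n
        counts = {c: (a + b).count(c) for c in "ACGT"}
        tot = sum(counts.values())
        gA, gC, gG, gT = (counts[c] / tot for c in "ACGT")
        gR, gY = gA + gG, gC + gT
        k1 = 2 * gA * gG / gR
        k2 = 2 * gC * gT / gY
        k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
        w1 = 1 - P1 / k1 - Q / (2 * gR)
        w2 = 1 - P2 / k2 - Q / (2 * gY)
        w3 = 1 - Q / (2 * gR * gY)
        expected = alpha * (k1 * (w1 ** (-1 / alpha) - 1)
                            + k2 * (w2 ** (-1 / alpha) - 1)
                            + k3 * (w3 ** (-1 / alpha) - 1))
        assert tn93_distance(a, b, TN93Params(alpha)) == pytest.approx(expected, rel=1e-12)

    def test_ambiguous_sites_deleted_pairwise(self):
        a = "ACGTACGT" + "NN"
        b = "ACGTACGA" + "CC"
        # the N/C columns are excluded; one A<->T ... actually T->A transversion over 8 sites
        assert tn93_distance(a, b) == tn93_distance("ACGTACGT", "ACGTACGA")

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(ValueError):
            tn93_distance("NNNN", "ACGT")

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="R not available for the cross-check")
    def test_against_ape_dist_dna(self, tmp_path):
        """Cross-check against ape::dist.dna on a random diverged pair."""
        rng = np.random.default_rng(7)
        L = 300
        a = "".join(rng.choice(list("ACGT"), size=L))
        b = list(a)
        tr = {"A": "G", "G": "A", "C": "T", "T": "C"}
        tv = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for k, i in enumerate(rng.choice(L, size=30, replace=False)):
            b[i] = tr[b[i]] if k % 3 else tv[b[i]]
        b = "".join(b)
        fasta = tmp_path / "pair.fasta"
        fasta.write_text(f">a\n{a}\n>b\n{b}\n")
        out = subprocess.run(
            ["Rscript", "-e",
             f'library(ape); s <- read.dna("{fasta}", format="fasta");'
             'cat(dist.dna(s, model="TN93", gamma=0.325)[1])'],
            capture_output=True, text=True, check=True)
        ape_value = float(out.stdout.strip().split()[-1])
        assert tn93_distance(a, b, TN93Params(0.325)) == pytest.approx(ape_value, abs=1e-6)


def brute_force_phist(d2: np.ndarray, labels: np.ndarray) -> float:
    """Oracle: AMOVA by explicit sum-of-squares partition, spelled out."""
    N = len(labels)
    groups = sorted(set(labels.tolist()))
    ss_total = sum(d2[i, j] for i in range(N) for j in range(i + 1, N)) / N
    ss_within = 0.0
    sizes = []
    for g in groups:
        idx = [i for i in range(N) if labels[i] == g]
        sizes.append(len(idx))
        ss_within += sum(d2[i, j] for i, j in itertools.combinations(idx, 2)) / len(idx)
    ss_among = ss_total - ss_within
    P = len(groups)
    sigma_w = ss_within / (N - P)
    n_c = (N - sum(s * s for s in sizes) / N) / (P - 1)
    sigma_a = (ss_among / (P - 1) - sigma_w) / n_c
    return sigma_a / (sigma_a + sigma_w)


class TestPairwiseFst:
    def test_matches_brute_force_amova_on_4_plus_4(self):
        rng = np.random.default_rng(3)
        rows = low_divergence_rows(rng, 8, L=40, flips=4)
        table = table_from_rows(rows)
        groups = {f"s{i}": ("P1" if i < 4 else "P2") for i in range(8)}
        res = pairwise_fst(table, groups, n_permutations=0)
        d2 = tn93_matrix(table)
        labels = np.array([0] * 4 + [1] * 4)
        assert res.fst[0, 1] == pytest.approx(brute_force_phist(d2, labels), abs=1e-9)

    def test_fixed_difference_gives_one(self):
        table = table_from_rows(["AAAA"] * 4 + ["GGGG"] * 4)
        groups = {f"s{i}": ("P1" if i < 4 else "P2") for i in range(8)}
        res = pairwise_fst(table, groups, n_permutations=100, seed=0)
        assert res.fst[0, 1] == pytest.approx(1.0)

    def test_null_populations_near_zero(self):
        # two populations drawn from one haplotype pool
        rng = np.random.default_rng(42)
        pool = low_divergence_rows(rng, 10, L=40, flips=3)
        rows = [pool[rng.integers(10)] for _ in range(40)]
        table = table_from_rows(rows)
        groups = {f"s{i}": ("P1" if i < 20 else "P2") for i in range(40)}
        res = pairwise_fst(table, groups, n_permutations=1000, seed=1)
        assert abs(res.fst[0, 1]) < 0.05
        assert res.pvalues[0, 1] > 0.05

    def test_invariant_under_relabeling_and_column_permutation(self):
        rng = np.random.default_rng(8)
        rows = low_divergence_rows(rng, 10, L=40, flips=4)
        table = table_from_rows(rows)
        groups = {f"s{i}": ("P1" if i < 5 else "P2") for i in range(10)}
        base = pairwise_fst(table, groups, n_permutations=0).fst[0, 1]
        # permute sample order within populations
        order = [3, 1, 4, 0, 2, 8, 5, 9, 7, 6]
        table2 = VariantTable([table.sample_ids[i] for i in order],
                              table.loci,
                              [table.matrix[i] for i in order])
        assert pairwise_fst(table2, groups, n_permutations=0).fst[0, 1] == \
            pytest.approx(base)
        # permute locus columns
        cperm = rng.permutation(len(table.loci))
        table3 = VariantTable(table.sample_ids,
                              [table.loci[j] for j in cperm],
                              [[row[j] for j in cperm] for row in table.matrix])
        assert pairwise_fst(table3, groups, n_permutations=0).fst[0, 1] == \
            pytest.approx(base)

    def test_small_population_rejected_with_label(self):
        table = table_from_rows(["AAAA", "GGGG", "GGGG"])
        groups = {"s0": "tiny", "s1": "P2", "s2": "P2"}
        with pytest.raises(ValueError, match="tiny"):
            pairwise_fst(table, groups, n_permutations=0)

    def test_monotone_in_divergence(self):
        """Mean Fst never decreases along a 3-level divergence ladder."""
        rng = np.random.default_rng(5)
        means = []
        for k_fixed in (1, 3, 6):
            vals = []
            for rep in range(10):
                base = list("ACGT" * 10)
                rows = []
                for i in range(16):
                    hap = list(base)
                    if i >= 8:  # population 2 carries k fixed differences
                        for j in range(k_fixed):
                            hap[j] = "G" if base[j] != "G" else "A"
                    # private polymorphism at the tail positions
                    for j in range(30, 40):
                        if rng.random() < 0.3:
                            hap[j] = rng.choice([c for c in "ACGT" if c != hap[j]])
                    rows.append("".join(hap))
                table = table_from_rows(rows)
                groups = {f"s{i}": ("P1" if i < 8 else "P2") for i in range(16)}
                vals.append(pairwise_fst(table, groups, n_permutations=0).fst[0, 1])
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]

    def test_permutation_pvalues_uniform_under_null(self):
        """Across 50 null simulations the p-values stay inside the KS 0.05
        band around the uniform distribution."""
        rng = np.random.default_rng(12)
        pvals = []
        for sim in range(50):
            pool = low_divergence_rows(rng, 8, L=40, flips=3)
            rows = [pool[rng.integers(8)] for _ in range(20)]
            table = table_from_rows(rows)
            groups = {f"s{i}": ("P1" if i < 10 else "P2") for i in range(20)}
            res = pairwise_fst(table, groups, n_permutations=500,
                               seed=int(rng.integers(2 ** 31)))
            pvals.append(res.pvalues[0, 1])
        stat = scipy.stats.kstest(pvals, "uniform").statistic
        assert stat < 1.358 / np.sqrt(len(pvals))  # 0.05-level KS band

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(9)
        rows = low_divergence_rows(rng, 12, L=40, flips=3)
        table = table_from_rows(rows)
        groups = {f"s{i}": ("P1" if i < 6 else "P2") for i in range(12)}
        r1 = pairwise_fst(table, groups, n_permutations=200, seed=7)
        r2 = pairwise_fst(table, groups, n_permutations=200, seed=7)
        assert np.array_equal(r1.pvalues, r2.pvalues)


class TestSlatkin:
    def test_values(self):
        m = np.array([[0.0, 0.5], [0.5, 0.0]])
        out = slatkin_linearize(m)
        assert out[0, 1] == pytest.approx(1.0)
        assert out[0, 0] == 0.0

    def test_negative_clamped_to_zero(self):
        assert slatkin_linearize(np.array([[-0.02]]))[0, 0] == 0.0

    def test_unit_fst_rejected(self):
        with pytest.raises(ValueError):
            slatkin_linearize(np.array([[1.0]]))


class TestClassicalMDS:
    def test_equilateral_triangle(self):
        d = 2.5
        D = np.full((3, 3), d)
        np.fill_diagonal(D, 0.0)
        mds = classical_mds(D, 2)
        got = np.sqrt(((mds.coords[:, None] - mds.coords[None]) ** 2).sum(-1))
        assert np.allclose(got, D, atol=1e-9)

    def test_round_trip_planar_points(self):
        pts = np.random.default_rng(0).normal(size=(7, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        mds = classical_mds(D, 2)
        got = np.sqrt(((mds.coords[:, None] - mds.coords[None]) ** 2).sum(-1))
        assert np.abs(got - D).max() < 1e-6

    def test_two_points_at_plus_minus_half_distance(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        mds = classical_mds(D, 1)
        assert sorted(mds.coords[:, 0]) == pytest.approx([-1.5, 1.5])

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            classical_mds(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_agrees_with_skbio_pcoa(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa

        pts = np.random.default_rng(4).normal(size=(6, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        mine = classical_mds(D, 2)
        ref = pcoa(skbio.DistanceMatrix(D)).samples.values[:, :2]
        # same embedding up to per-axis sign
        for axis in range(2):
            col, rcol = mine.coords[:, axis], ref[:, axis]
            assert (np.allclose(col, rcol, atol=1e-6)
                    or np.allclose(col, -rcol, atol=1e-6))
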