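"""Star alignment, TN93/p distances, neighbor joining, bootstrap."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from cenbarcode.phylo import (
    PhyloParams,
    SaturationError,
    bootstrap_support,
    distance_matrix,
    nj_tree,
    p_distance,
    star_align,
    tn93_distance,
    tree_bipartitions,
)
from cenbarcode.synthetic_data import SimulationConfig, build_hor_array
from conftest import mutate

# Deterministic 6-row, 60-column gap-free alignment (4..14 substitutions
# from a fixed consensus) with reference TN93 distances computed by an
# independent implementation of the estimator (pairwise deletion,
# base frequencies pooled per pair).
TN93_ROWS = [
    "TTCAGAACGACAACGGTAATCGTCGCCCCGAGGTTCCAGTGCTTTTCCACCTACATAGGA",
    "GTCGGAACGACAACGGAAATCGTCGGACCGAGGTCCCAGGGCTTATCAACCTCCATAGGA",
    "GTCGGAACAACAAGGGTAATCATCGGCCCGAGGTCGCAGGACTCTTCCACCTAGATAGGA",
    "ATCGCAAAGTCAACAGTAATCGTCACCCCGGGGTCCGAGGACTTTTCCACCTCCATAGGA",
    "GTCTGAACGATACCGGTACTCGTCGCACCGGGGTCTCAGAGCCTTTCCGCCTCCATAGGG",
    "GTCAGAACGACAATGGTTATCGGCGTGCTGAAATCCCAGGGTTTTTCCGCCTACTACGGA",
]
TN93_REFERENCE = {
    (0, 1): 0.189310045783,
    (0, 2): 0.235943723898,
    (0, 3): 0.269659469729,
    (0, 4): 0.282535856484,
    (0, 5): 0.335092626428,
    (1, 2): 0.233589487821,
    (1, 3): 0.292278512034,
    (1, 4): 0.283322248942,
    (1, 5): 0.386960110131,
    (2, 3): 0.345836381479,
    (2, 4): 0.436534201383,
    (2, 5): 0.458401683316,
    (3, 4): 0.418985707723,
    (3, 5): 0.654775086575,
    (4, 5): 0.530157938018,
}


class TestStarAlign:
    def test_identical_monomers_gap_free(self, cons4):
        aln = star_align([cons4, cons4], cons4)
        assert aln.rows == [cons4, cons4]

    def test_single_deletion_creates_one_gap(self, cons4):
        deleted = cons4[:100] + cons4[101:]
        aln = star_align([deleted, cons4], cons4)
        assert aln.rows[0].count("-") == 1
        assert aln.rows[1] == cons4

    def test_rows_match_consensus_length(self, cons4):
        rng = np.random.default_rng(1)
        monomers = [mutate(cons4, 0.05, rng) for _ in range(5)]
        aln = star_align(monomers, cons4)
        assert len(aln.rows) == 5
        assert all(len(r) == len(cons4) for r in aln.rows)

    def test_empty_monomer_rejected(self, cons4):
        with pytest.raises(ValueError):
            star_align(["", cons4], cons4)


class TestPDistance:
    def test_identical(self):
        assert p_distance("ACGT", "ACGT") == 0.0

    def test_half_different(self):
        assert p_distance("AAAA", "AATT") == 0.5

    def test_gap_columns_excluded(self):
        assert p_distance("A-CG", "AACG") == 0.0

    def test_all_gap_rejected(self):
        with pytest.raises(ValueError):
            p_distance("--", "AA")


class TestTn93:
    def test_identical_rows_zero(self):
        assert tn93_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_matches_independent_reference(self):
        for (i, j), expected in TN93_REFERENCE.items():
            assert tn93_distance(TN93_ROWS[i], TN93_ROWS[j]) == pytest.approx(
                expected, abs=1e-9
            )

    def test_transversion_only_equals_k2p_limit(self):
        # equal base frequencies preserved by swapping A<->C at two sites
        a = "ACGT" * 20
        b = "CA" + a[2:]
        q = 2 / 80
        k2p = -0.5 * math.log(1 - q) - 0.25 * math.log(1 - 2 * q)
        assert tn93_distance(a, b) == pytest.approx(k2p, abs=1e-9)

    def test_saturation_raises(self):
        # every site differs: one third A<->G, one third C<->T, one third
        # transversions
        a = "AAACCCTTT"
        b = "GGGTTTAAA"
        with pytest.raises(SaturationError):
            tn93_distance(a, b)

    def test_tn93_dominates_p_distance(self, cons4):
        rng = np.random.default_rng(3)
        rows = [mutate(cons4, r, rng) for r in (0.02, 0.08, 0.15, 0.25)]
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                assert tn93_distance(rows[i], rows[j]) >= p_distance(
                    rows[i], rows[j]
                )


def random_additive_matrix(ntax: int, rng: np.random.Generator):
    """Leaf distance matrix of a random binary tree with branch lengths in
    [0.1, 2]; the generating bipartitions come back alongside."""
    active = list(range(ntax))
    contrib = {i: {i: 0.0} for i in range(ntax)}
    dist = np.zeros((ntax, ntax))
    clades = []
    next_id = ntax
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        la, lb = rng.uniform(0.1, 2, 2)
        for x, dx in contrib[a].items():
            for y, dy in contrib[b].items():
                dist[x, y] = dist[y, x] = dx + la + dy + lb
        merged = {x: dx + la for x, dx in contrib[a].items()}
        merged.update({y: dy + lb for y, dy in contrib[b].items()})
        contrib[next_id] = merged
        clades.append(frozenset(merged))
        del contrib[a], contrib[b]
        active = [n for n in active if n not in (a, b)] + [next_id]
        next_id += 1
    return dist, clades


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float), ids=list("abc")
        )
        tree = nj_tree(dm)
        lengths = {n.name: n.length for n in tree.children}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_additive_four_taxon_exact(self):
        # tree ((a:1,b:2):1,(c:3,d:4))
        ids = list("abcd")
        m = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(DistanceMatrix(m, ids=ids))
        assert tree_bipartitions(tree) == {frozenset({"c", "d"})}
        lengths = {leaf.name: leaf.length for leaf in tree.tips()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}

    def test_all_zero_matrix_zero_total_length(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        tree = nj_tree(dm)
        total = sum(n.length or 0 for n in tree.traverse() if n.length is not None)
        assert total == 0.0

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"]))

    @pytest.mark.parametrize("trial", range(20))
    def test_random_additive_recovery(self, trial):
        """NJ recovers the generating topology of random additive 4-6
        taxon matrices (checked against the true tree's bipartitions and
        against an independent NJ implementation)."""
        rng = np.random.default_rng(trial)
        ntax = int(rng.integers(4, 7))
        dist, clades = random_additive_matrix(ntax, rng)
        ids = [f"t{k}" for k in range(ntax)]
        dm = DistanceMatrix(dist, ids=ids)
        mine = tree_bipartitions(nj_tree(dm))
        # truth: internal bipartitions of the generating tree
        full = frozenset(range(ntax))
        truth = set()
        for clade in clades:
            side = clade if 0 not in clade else full - clade
            if 1 < len(side) < ntax - 1:
                truth.add(frozenset(f"t{k}" for k in side))
        assert mine == truth
        assert mine == tree_bipartitions(skbio_nj(dm))


@pytest.fixture(scope="module")
def clade_alignment(cons4):
    rng = np.random.default_rng(9)
    clade_a = mutate(cons4, 0.10, rng)
    clade_b = mutate(cons4, 0.10, rng)
    monomers = [(f"A{i}", mutate(clade_a, 0.01, rng)) for i in range(5)]
    monomers += [(f"B{i}", mutate(clade_b, 0.01, rng)) for i in range(5)]
    return star_align(monomers, cons4)


class TestBootstrap:
    def test_well_separated_clades_high_support(self, clade_alignment):
        tree, dropped = bootstrap_support(
            clade_alignment, "tn93", PhyloParams(bootstrap_replicates=200, seed=3)
        )
        names_a = frozenset(f"A{i}" for i in range(5))
        full = frozenset(leaf.name for leaf in tree.tips())
        supports = [
            node.support
            for node in tree.non_tips()
            if frozenset(l.name for l in node.tips()) in (names_a, full - names_a)
        ]
        assert supports and supports[0] >= 0.95

    def test_single_replicate_supports_binary(self, clade_alignment):
        tree, _ = bootstrap_support(
            clade_alignment, "tn93", PhyloParams(bootstrap_replicates=1, seed=1)
        )
        values = {
            node.support for node in tree.non_tips() if hasattr(node, "support")
        }
        assert values <= {0.0, 1.0}

    def test_same_seed_identical_supports(self, clade_alignment):
        params = PhyloParams(bootstrap_replicates=50, seed=4)
        t1, _ = bootstrap_support(clade_alignment, "tn93", params)
        t2, _ = bootstrap_support(clade_alignment, "tn93", params)
        assert str(t1) == str(t2)

    def test_default_replicates_is_one_thousand(self):
        assert PhyloParams().bootstrap_replicates == 1000


class TestChromosomeHomogenization:
    def test_leaves_cluster_by_chromosome(self, cons4):
        """With intra-chromosome divergence below inter-chromosome
        divergence, at least 90% of monomer leaves sit in monophyletic
        chromosome clades (the homogenization readout)."""
        rng = np.random.default_rng(5)
        leaves = []
        n_chrom, per_chrom = 5, 8
        for c in range(n_chrom):
            chrom_consensus = mutate(cons4, 0.08, rng)
            config = SimulationConfig(
                n_copies=per_chrom, sub_rate=0.02, variant_divergence=0, seed=100 + c
            )
            seq, truth = build_hor_array(config, consensus=chrom_consensus)
            leaves += [
                (f"chr{c}.{i}", seq[r.start : r.end])
                for i, r in enumerate(truth.records)
            ]
        aln = star_align(leaves, cons4)
        tree = nj_tree(distance_matrix(aln, "tn93"))
        full = frozenset(leaf.name for leaf in tree.tips())
        clades = {frozenset(l.name for l in node.tips()) for node in tree.non_tips()}
        mono_leaves = 0
        for c in range(n_chrom):
            want = frozenset(n for n in full if n.startswith(f"chr{c}."))
            if want in clades or (full - want) in clades:
                mono_leaves += per_chrom
        assert mono_leaves >= 0.9 * n_chrom * per_chrom
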