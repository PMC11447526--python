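"""Distance-based phylogenetics for satellite monomers.

Implements the textbook chain used for centromeric-repeat trees: a star
multiple alignment of monomers against a family consensus, p or
Tamura-Nei (TN93) pairwise distances with pairwise gap deletion,
Saitou-Nei neighbor-joining, and non-parametric column bootstrap with
bipartition supports. Trees are scikit-bio TreeNode objects and serialize
to Newick with support values as internal node labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .align import global_aligner
from .repeatio import SeqRecord

GAP = "-"


class SaturationError(ValueError):
    """A TN93 logarithm argument was <= 0 (substitution saturation)."""


@dataclass
class StarAlignment:
    """Monomers projected onto consensus columns (insertions relative to
    the consensus are dropped); every row has consensus length."""

    consensus: str
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        L = len(self.consensus)
        for rid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise ValueError(f"row {rid!r} length {len(row)} != consensus {L}")


@dataclass
class PhyloParams:
    bootstrap_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")


def _normalize(monomers: Sequence) -> list[tuple[str, str]]:
    pairs = []
    for i, m in enumerate(monomers):
        if isinstance(m, SeqRecord):
            pairs.append((m.id, m.sequence))
        elif isinstance(m, tuple):
            pairs.append((m[0], m[1]))
        else:
            pairs.append((f"m{i + 1}", str(m)))
    return pairs


def star_align(monomers: Sequence, consensus: str) -> StarAlignment:
    """Align every monomer globally to the consensus and project onto
    consensus columns."""
    pairs = _normalize(monomers)
    if len(pairs) < 2:
        raise ValueError("need at least 2 monomers")
    aligner = global_aligner()
    ids, rows = [], []
    for rid, seq in pairs:
        if not seq:
            raise ValueError(f"monomer {rid!r} is empty")
        aln = aligner.align(consensus, seq)[0]
        t_blocks, q_blocks = aln.aligned
        row = [GAP] * len(consensus)
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
            for offset in range(te - ts):
                row[ts + offset] = seq[qs + offset]
        ids.append(rid)
        rows.append("".join(row))
    return StarAlignment(consensus=consensus, ids=ids, rows=rows)


def p_distance(row_a: str, row_b: str) -> float:
    """Mismatch proportion over sites where both rows are non-gap."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    comparable = mismatches = 0
    for a, b in zip(row_a, row_b):
        if a == GAP or b == GAP:
            continue
        comparable += 1
        if a != b:
            mismatches += 1
    if comparable == 0:
        raise ValueError("no comparable (gap-free) sites")
    return mismatches / comparable


_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def tn93_distance(row_a: str, row_b: str) -> float:
    """Tamura-Nei (1993) distance from the two transition classes and the
    transversion proportion, with empirical base frequencies pooled over
    both rows. Gap-containing columns are excluded pairwise; saturation
    (a log argument <= 0) raises SaturationError.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    n = 0
    p1 = p2 = q = 0  # A<->G, C<->T transitions; transversions
    counts = {b: 0 for b in "ACGT"}
    for a, b in zip(row_a, row_b):
        if a == GAP or b == GAP or a == "N" or b == "N":
            continue
        n += 1
        counts[a] += 1
        counts[b] += 1
        if a == b:
            continue
        pair = {a, b}
        if pair == {"A", "G"}:
            p1 += 1
        elif pair == {"C", "T"}:
            p2 += 1
        else:
            q += 1
    if n == 0:
        raise ValueError("no comparable (gap-free) sites")
    P1, P2, Q = p1 / n, p2 / n, q / n
    if P1 == P2 == Q == 0:
        return 0.0
    total = 2 * n
    pi = {b: counts[b] / total for b in "ACGT"}
    piR = pi["A"] + pi["G"]
    piY = pi["C"] + pi["T"]

    d = 0.0
    # purine-transition term
    gR = pi["A"] * pi["G"]
    if gR > 0:
        w1 = 1 - piR / (2 * gR) * P1 - Q / (2 * piR)
        if w1 <= 0:
            raise SaturationError("purine transition term saturated")
        d += -(2 * gR / piR) * math.log(w1)
    elif P1 > 0:
        raise SaturationError("A<->G transitions with zero purine frequency product")
    # pyrimidine-transition term
    gY = pi["C"] * pi["T"]
    if gY > 0:
        w2 = 1 - piY / (2 * gY) * P2 - Q / (2 * piY)
        if w2 <= 0:
            raise SaturationError("pyrimidine transition term saturated")
        d += -(2 * gY / piY) * math.log(w2)
    elif P2 > 0:
        raise SaturationError("C<->T transitions with zero pyrimidine frequency product")
    # transversion term
    if piR > 0 and piY > 0:
        w3 = 1 - Q / (2 * piR * piY)
        if w3 <= 0:
            raise SaturationError("transversion term saturated")
        coeff = 2 * (piR * piY - gR * piY / piR - gY * piR / piY)
        d += -coeff * math.log(w3)
    elif Q > 0:
        raise SaturationError("transversions with a missing base class")
    return d


def distance_matrix(alignment: StarAlignment, model: str = "tn93") -> DistanceMatrix:
    """Pairwise distances under the chosen model ('p' or 'tn93')."""
    fn = {"p": p_distance, "tn93": tn93_distance}.get(model)
    if fn is None:
        raise ValueError(f"unknown model {model!r}")
    n = len(alignment.ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = fn(alignment.rows[i], alignment.rows[j])
    return DistanceMatrix(mat, ids=alignment.ids)


def nj_tree(dm: DistanceMatrix, params: PhyloParams | None = None) -> TreeNode:
    """Canonical Saitou-Nei neighbor joining.

    Joins the pair minimizing Q(i,j) = (n-2) d(i,j) - sum_k d(i,k)
    - sum_k d(j,k); ties broken by lowest index pair; limb lengths by the
    standard split formula, negative lengths clamped to zero with the
    excess moved to the sibling branch. Returns an unrooted tree
    (trifurcating root).
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin scans row-major, so equal minima resolve to the lowest
        # (i, j) index pair
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode()
        nodes[i].length = float(li)
        nodes[j].length = float(max(lj, 0.0))
        parent.extend([nodes[i], nodes[j]])

        du = (d[i, :] + d[j, :] - dij) / 2
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.zeros((m - 1, m - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = du[keep]
        d = new_d
        nodes = [nodes[k] for k in keep] + [parent]

    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    lengths = [
        (d01 + d02 - d12) / 2,
        (d01 + d12 - d02) / 2,
        (d02 + d12 - d01) / 2,
    ]
    root = TreeNode()
    for node, length in zip(nodes, lengths):
        node.length = float(max(length, 0.0))
        root.append(node)
    return root


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each encoded as the
    leaf-name side not containing the alphabetically first taxon."""
    taxa = sorted(leaf.name for leaf in tree.tips())
    full = frozenset(taxa)
    ref = taxa[0]
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        below = frozenset(leaf.name for leaf in node.tips())
        if ref in below:
            below = full - below
        if 1 < len(below) < len(full) - 1:
            splits.add(below)
    return splits


def bootstrap_support(
    alignment: StarAlignment,
    model: str = "tn93",
    params: PhyloParams | None = None,
) -> tuple[TreeNode, int]:
    """NJ tree from the full alignment with column-bootstrap supports.

    Each replicate resamples alignment columns with replacement, rebuilds
    distances and the NJ tree, and votes for the bipartitions it contains;
    replicates hitting substitution saturation are dropped (their count is
    returned). Support is the fraction of successful replicates containing
    the bipartition and is written to each internal node's name.
    """
    if params is None:
        params = PhyloParams()
    if len(alignment.ids) < 4:
        raise ValueError("need at least 4 taxa for bootstrap supports")
    main_tree = nj_tree(distance_matrix(alignment, model))
    L = len(alignment.consensus)
    rows = np.array([list(r) for r in alignment.rows])
    rng = np.random.default_rng(params.seed)
    counts: dict[frozenset[str], int] = {}
    dropped = 0
    successful = 0
    for _ in range(params.bootstrap_replicates):
        cols = rng.integers(0, L, size=L)
        resampled = StarAlignment(
            consensus="".join(alignment.consensus[c] for c in cols),
            ids=alignment.ids,
            rows=["".join(row[cols]) for row in rows],
        )
        try:
            rep_tree = nj_tree(distance_matrix(resampled, model))
        except (SaturationError, ValueError):
            dropped += 1
            continue
        successful += 1
        for split in tree_bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1

    full = frozenset(leaf.name for leaf in main_tree.tips())
    taxa = sorted(full)
    ref = taxa[0]
    for node in main_tree.non_tips(include_self=False):
        below = frozenset(leaf.name for leaf in node.tips())
        if ref in below:
            below = full - below
        if not 1 < len(below) < len(full) - 1:
            continue
        support = counts.get(below, 0) / successful if successful else 0.0
        node.support = support
        node.name = f"{support:.3f}"
    return main_tree, dropped
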