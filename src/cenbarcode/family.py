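"""Repeat-family registry, monomer-variant clustering, and similarity
statistics.

The registry fixes the two soybean centromeric satellite superfamilies:
the CentGm-1 superfamily (monomers 88-93 bp, split into the 92-bp
CentGm-1 and 91-bp CentGm-2 subfamilies by conserved monomer-length
change) and the CentGm-4 superfamily (395-437 bp, mean 413 bp). The
registry consensus sequences shipped here are synthetic stand-ins with
the correct lengths, generated from fixed seeds.
"""

from __future__ import annotations

import itertools
import string
from collections import Counter
from dataclasses import dataclass, field
from statistics import fmean

import numpy as np

from .align import global_identity
from .monomer import MonomerHit
from .synthetic_data import default_family_consensus


@dataclass
class Subfamily:
    name: str
    length: int
    consensus: str = ""


@dataclass
class RepeatFamilyDef:
    """A satellite superfamily: a monomer length range plus exact-length
    subfamilies. `fallback_name` is returned when a consensus falls in the
    length range but matches no subfamily length exactly."""

    name: str
    length_range: tuple[int, int]
    subfamilies: list[Subfamily] = field(default_factory=list)
    fallback_name: str | None = None


def default_registry() -> list[RepeatFamilyDef]:
    consensus = default_family_consensus()
    return [
        RepeatFamilyDef(
            name="CentGm-1 superfamily",
            length_range=(88, 93),
            subfamilies=[
                Subfamily("CentGm-1", 92, consensus["CentGm-1"]),
                Subfamily("CentGm-2", 91, consensus["CentGm-2"]),
            ],
        ),
        RepeatFamilyDef(
            name="CentGm-4 superfamily",
            length_range=(395, 437),
            subfamilies=[Subfamily("CentGm-4", 413, consensus["CentGm-4"])],
            fallback_name="CentGm-4",
        ),
    ]


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity over the optimal global alignment (gap columns,
    including end gaps, count against identity); symmetric."""
    return global_identity(a, b)


def mean_pairwise_similarity(monomers: list[str]) -> float:
    """Mean pairwise identity over all unordered pairs."""
    if len(monomers) < 2:
        raise ValueError("need at least 2 monomers")
    return fmean(
        pairwise_identity(a, b) for a, b in itertools.combinations(monomers, 2)
    )


# cluster symbols: A = largest cluster, then B, ..., then lowercase, digits
_SYMBOLS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _cluster_symbol(rank: int) -> str:
    if rank < len(_SYMBOLS):
        return _SYMBOLS[rank]
    return chr(0x100 + rank)  # arbitrary distinct symbols beyond 62 clusters


@dataclass
class VariantLabeling:
    labels: list[str]
    centroids: dict[str, str]
    identity_threshold: float


def cluster_variants(monomers: list[str], identity_threshold: float = 95.0) -> VariantLabeling:
    """Greedy centroid clustering in input order.

    Each monomer joins the first existing centroid it matches at
    >= identity_threshold, else opens a new cluster whose centroid is that
    monomer. Clusters are then relabeled by decreasing size (A = largest;
    ties by order of first appearance), so labels are deterministic for a
    given input order.
    """
    if not 50 < identity_threshold <= 100:
        raise ValueError("identity_threshold must be in (50, 100]")
    centroids: list[str] = []
    assignments: list[int] = []
    for monomer in monomers:
        for idx, centroid in enumerate(centroids):
            if pairwise_identity(monomer, centroid) >= identity_threshold:
                assignments.append(idx)
                break
        else:
            centroids.append(monomer)
            assignments.append(len(centroids) - 1)
    sizes = [(assignments.count(i), -i) for i in range(len(centroids))]
    order = sorted(range(len(centroids)), key=lambda i: sizes[i], reverse=True)
    symbol_of = {cluster: _cluster_symbol(rank) for rank, cluster in enumerate(order)}
    return VariantLabeling(
        labels=[symbol_of[a] for a in assignments],
        centroids={symbol_of[i]: c for i, c in enumerate(centroids)},
        identity_threshold=identity_threshold,
    )


def _column_majority(seqs: list[str]) -> str:
    """Per-column majority over equal-length sequences (ties toward the
    lexicographically smallest base)."""
    arr = np.array([list(s) for s in seqs])
    out = []
    for col in arr.T:
        values, counts = np.unique(col, return_counts=True)
        out.append(values[np.lexsort((values, -counts))[0]])
    return "".join(out)


def refine_variant_clusters(
    monomers: list[str],
    labeling: VariantLabeling,
    min_cluster_frac: float = 0.05,
) -> VariantLabeling:
    """Consensus-based refinement of a greedy clustering.

    Single noisy copies acting as centroids make greedy clustering spill
    low-identity members into spurious singleton clusters. This pass keeps
    only clusters holding >= max(2, min_cluster_frac * N) members, builds a
    per-cluster majority consensus from its modal-length members, and
    reassigns every monomer to the nearest consensus -- the consensus is
    far closer to each true variant than any single mutated copy, so the
    reassignment is near noise-free.
    """
    if not monomers:
        return labeling
    n = len(monomers)
    min_size = max(2, round(min_cluster_frac * n))
    sizes = Counter(labeling.labels)
    candidates = [lab for lab, size in sizes.items() if size >= min_size]
    if not candidates:
        candidates = [sizes.most_common(1)[0][0]]
    consensi = []
    for lab in candidates:
        members = [m for m, l in zip(monomers, labeling.labels) if l == lab]
        mode_len = Counter(len(m) for m in members).most_common(1)[0][0]
        modal = [m for m in members if len(m) == mode_len]
        consensi.append(_column_majority(modal) if modal else members[0])
    assignments = []
    for m in monomers:
        scores = [pairwise_identity(m, c) for c in consensi]
        assignments.append(int(np.argmax(scores)))
    order = sorted(
        range(len(candidates)),
        key=lambda i: (assignments.count(i), -i),
        reverse=True,
    )
    symbol_of = {cluster: _cluster_symbol(rank) for rank, cluster in enumerate(order)}
    return VariantLabeling(
        labels=[symbol_of[a] for a in assignments],
        centroids={symbol_of[i]: c for i, c in enumerate(consensi)},
        identity_threshold=labeling.identity_threshold,
    )


def classify_subfamily(consensus: str, registry: list[RepeatFamilyDef] | None = None) -> str:
    """Assign a consensus monomer to a subfamily by length.

    Exact subfamily length wins (92 bp -> CentGm-1, 91 bp -> CentGm-2);
    a length inside the CentGm-4 superfamily range returns "CentGm-4";
    anything else is "unassigned".
    """
    if registry is None:
        registry = default_registry()
    length = len(consensus)
    for fam in registry:
        lo, hi = fam.length_range
        if lo <= length <= hi:
            for sub in fam.subfamilies:
                if sub.length == length:
                    return sub.name
            if fam.fallback_name:
                return fam.fallback_name
    return "unassigned"


@dataclass
class SamplingParams:
    n_per_chromosome: int = 50
    strategy: str = "evenly_spaced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_chromosome < 2:
            raise ValueError("n_per_chromosome must be >= 2")
        if self.strategy not in {"evenly_spaced", "random"}:
            raise ValueError("strategy must be 'evenly_spaced' or 'random'")


def sample_monomers(hits: list[MonomerHit], params: SamplingParams) -> list[MonomerHit]:
    """Select n monomers per chromosome from the non-partial hits, either
    evenly spaced along the array or at random (seeded)."""
    full = [h for h in hits if not h.partial]
    n = params.n_per_chromosome
    if len(full) < n:
        raise ValueError(
            f"requested {n} monomers but only {len(full)} non-partial hits available"
        )
    if params.strategy == "evenly_spaced":
        idx = sorted({round(i * (len(full) - 1) / (n - 1)) for i in range(n)})
    else:
        rng = np.random.default_rng(params.seed)
        idx = sorted(rng.choice(len(full), size=n, replace=False).tolist())
    return [full[i] for i in idx]
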