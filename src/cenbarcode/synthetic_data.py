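"""Synthetic centromeric satellite arrays, karyotypes, and ChIP/input reads.

Everything downstream of this module (monomer decomposition, variant
clustering, HOR calling, phylogenies, enrichment statistics) is exercised
against arrays generated here with known ground truth:

* tandem arrays built from a consensus monomer with per-base substitution
  and indel divergence;
* higher-order-repeat (HOR) patterns of unit size 1-5 over monomer variants,
  where each variant carries a fixed marker-substitution set;
* truncated ("partial") monomer copies at fixed fractions of the unit length;
* a 40-chromosome (20 chromosome sets) karyotype with per-chromosome HOR
  configurations;
* MiSeq-like 2x300 bp paired-end ChIP/input libraries with a configurable
  centromeric enrichment factor rho.

Coordinates are 0-based half-open throughout; BED6 is the ground-truth
interval format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .repeatio import FastqRead, IntervalRecord, SeqRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")

#: Seeds from which the synthetic family consensus monomers are drawn.
#: These stand in for the real deposited CentGm-1/2/4 consensus sequences
#: (which are not shipped); only their lengths carry the biology.
DEFAULT_CONSENSUS_SEEDS: dict[str, tuple[int, int]] = {
    "CentGm-1": (92, 9201),
    "CentGm-2": (91, 9102),
    "CentGm-4": (413, 41304),
}

#: The three partial-unit lengths observed in CentGm-4 HOR arrays, as
#: fractions of the 413-bp monomer.
PARTIAL_FRACTIONS: tuple[float, ...] = (209 / 413, 252 / 413, 317 / 413)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def draw_consensus(length: int, seed: int) -> str:
    """Draw a uniform-random consensus monomer of the given length."""
    if length < 10:
        raise ValueError(f"consensus length must be >= 10, got {length}")
    rng = np.random.default_rng(seed)
    return rng.choice(BASES, size=length).tobytes().decode()


def default_family_consensus() -> dict[str, str]:
    """Synthetic consensus monomer per repeat family (fixed seeds)."""
    return {
        name: draw_consensus(length, seed)
        for name, (length, seed) in DEFAULT_CONSENSUS_SEEDS.items()
    }


@dataclass
class SimulationConfig:
    """Parameters of one tandem HOR array.

    hor_pattern is the ordered unit of variant labels (length 1-5, the
    monomer-to-pentamer range); variant_divergence is the per-base
    probability of a fixed marker substitution distinguishing each variant
    from the base consensus.
    """

    monomer_length: int = 413
    n_copies: int = 60
    sub_rate: float = 0.05
    indel_rate: float = 0.0
    hor_pattern: tuple[str, ...] = ("A",)
    variant_divergence: float = 0.08
    truncation_fractions: tuple[float, ...] = ()
    truncation_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.monomer_length < 10:
            raise ValueError("monomer_length must be >= 10")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        for name in ("sub_rate", "indel_rate", "variant_divergence"):
            value = getattr(self, name)
            if not 0 <= value < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5), got {value}")
        self.hor_pattern = tuple(self.hor_pattern)
        if not 1 <= len(self.hor_pattern) <= 5:
            raise ValueError("hor_pattern length must be in 1..5")
        self.truncation_fractions = tuple(self.truncation_fractions)
        if any(not 0 < f < 1 for f in self.truncation_fractions):
            raise ValueError("truncation fractions must be in (0, 1)")
        if self.truncation_count < 0:
            raise ValueError("truncation_count must be >= 0")
        if self.truncation_count > self.n_copies:
            raise ValueError("truncation_count exceeds n_copies")
        if self.truncation_count > 0 and not self.truncation_fractions:
            raise ValueError("truncation_count > 0 requires truncation_fractions")


@dataclass
class GroundTruthRecord:
    chromosome: str
    start: int
    end: int
    label: str
    truncated: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GroundTruth:
    """Non-overlapping, per-chromosome sorted monomer occurrence records."""

    records: list[GroundTruthRecord] = field(default_factory=list)

    def for_chromosome(self, chromosome: str) -> list[GroundTruthRecord]:
        return [r for r in self.records if r.chromosome == chromosome]

    def to_bed(self) -> list[IntervalRecord]:
        return [
            IntervalRecord(r.chromosome, r.start, r.end, name=r.label, strand="+")
            for r in self.records
        ]

    def shift(self, chromosome: str, offset: int) -> "GroundTruth":
        return GroundTruth(
            [
                GroundTruthRecord(
                    chromosome, r.start + offset, r.end + offset, r.label, r.truncated
                )
                for r in self.records
            ]
        )


def make_variants(
    consensus: str,
    labels: Sequence[str],
    divergence: float,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Fixed marker-substitution variant per label.

    The first-seen label is the unmodified consensus; each later label gets
    its own random marker set (positions hit with probability `divergence`),
    drawn once, so the HOR phase is detectable above copy-level noise.
    """
    variants: dict[str, str] = {}
    for label in labels:
        if label in variants:
            continue
        if not variants:
            variants[label] = consensus
            continue
        arr = np.frombuffer(consensus.encode(), dtype=np.uint8).copy()
        hits = np.nonzero(rng.random(arr.size) < divergence)[0]
        for pos in hits:
            choices = BASES[BASES != arr[pos]]
            arr[pos] = rng.choice(choices)
        variants[label] = arr.tobytes().decode()
    return variants


def _mutate(seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    if sub_rate > 0:
        hits = np.nonzero(rng.random(arr.size) < sub_rate)[0]
        for pos in hits:
            choices = BASES[BASES != arr[pos]]
            arr[pos] = rng.choice(choices)
    if indel_rate == 0:
        return arr.tobytes().decode()
    out = bytearray()
    for b in arr:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        if r < indel_rate:
            out.append(rng.choice(BASES))  # insertion before the base
        out.append(b)
    if not out:
        out.append(rng.choice(BASES))
    return bytes(out).decode()


def build_hor_array(
    config: SimulationConfig,
    consensus: str | None = None,
    variants: Mapping[str, str] | None = None,
    chromosome: str = "array",
) -> tuple[str, GroundTruth]:
    """Emit a tandem array following the HOR pattern cyclically.

    Returns the array sequence and the exact ground-truth coordinates of
    every emitted monomer copy (truncated copies flagged).
    """
    rng = np.random.default_rng(config.seed)
    if consensus is None:
        consensus = rng.choice(BASES, size=config.monomer_length).tobytes().decode()
    elif len(consensus) != config.monomer_length:
        raise ValueError("consensus length does not match config.monomer_length")
    if variants is None:
        variants = make_variants(
            consensus, config.hor_pattern, config.variant_divergence, rng
        )
    missing = set(config.hor_pattern) - set(variants)
    if missing:
        raise ValueError(f"no variant sequence for labels {sorted(missing)}")

    truncated_at: dict[int, float] = {}
    if config.truncation_count:
        # truncated units sit inside the array (never the first copy):
        # the study's partial units are internal to the HOR structure, and
        # a leading truncation is indistinguishable from an array-boundary
        # artifact
        candidates = (
            np.arange(1, config.n_copies)
            if config.truncation_count < config.n_copies
            else np.arange(config.n_copies)
        )
        idx = np.sort(
            rng.choice(candidates, size=config.truncation_count, replace=False)
        )
        for j, copy_index in enumerate(idx):
            truncated_at[int(copy_index)] = config.truncation_fractions[
                j % len(config.truncation_fractions)
            ]

    parts: list[str] = []
    records: list[GroundTruthRecord] = []
    cursor = 0
    unit = len(config.hor_pattern)
    for i in range(config.n_copies):
        label = config.hor_pattern[i % unit]
        copy = _mutate(variants[label], config.sub_rate, config.indel_rate, rng)
        truncated = i in truncated_at
        if truncated:
            keep = round(truncated_at[i] * config.monomer_length)
            copy = copy[: max(1, min(len(copy), keep))]
        parts.append(copy)
        records.append(
            GroundTruthRecord(chromosome, cursor, cursor + len(copy), label, truncated)
        )
        cursor += len(copy)
    return "".join(parts), GroundTruth(records)


@dataclass
class ChromosomeSpec:
    """HOR configuration of one synthetic chromosome.

    A chromosome carries one satellite array made of 1 or 2 consecutive
    segments; two segments model the chromosomes on which two HOR variants
    with different unit sizes coexist.
    """

    name: str
    family: str = "CentGm-4"
    segments: tuple[tuple[str, ...], ...] = (("A",),)
    n_copies: tuple[int, ...] = (36,)
    truncation_fractions: tuple[float, ...] = ()
    truncation_count: int = 0

    def __post_init__(self) -> None:
        self.segments = tuple(tuple(s) for s in self.segments)
        self.n_copies = tuple(self.n_copies)
        if len(self.segments) not in (1, 2):
            raise ValueError("a chromosome carries 1 or 2 HOR segments")
        if len(self.n_copies) != len(self.segments):
            raise ValueError("n_copies must have one entry per segment")

    @property
    def hor_classes(self) -> tuple[int, ...]:
        """Generating HOR unit size(s), after collapsing the cyclic pattern
        to its minimal period."""
        sizes = []
        for pattern in self.segments:
            k = len(pattern)
            for p in range(1, k + 1):
                if k % p == 0 and pattern == pattern[:p] * (k // p):
                    sizes.append(p)
                    break
        return tuple(sizes)


def default_karyotype_specs(n_chromosomes: int = 20) -> list[ChromosomeSpec]:
    """The default 20-chromosome-set karyotype.

    Class counts follow the rank order reported for the soybean CentGm-4
    HOR classes (monomeric arrays most common, a single pentamer chromosome)
    plus one two-variant chromosome and three chromosomes carrying the
    209/252/317-bp partial units.
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    M: tuple[tuple[str, ...], ...] = (("A",),)
    D: tuple[tuple[str, ...], ...] = (("A", "B"),)
    T: tuple[tuple[str, ...], ...] = (("A", "B", "C"),)
    Q: tuple[tuple[str, ...], ...] = (("A", "B", "C", "D"),)
    P: tuple[tuple[str, ...], ...] = (("A", "B", "C", "D", "E"),)
    TWO: tuple[tuple[str, ...], ...] = (("A",), ("A", "B", "C"))
    # 8 monomer + 5 dimer + 3 trimer + 2 tetramer + 1 pentamer + 1
    # two-variant chromosome, interleaved so truncated karyotypes keep a
    # mix of classes
    patterns = [M, D, T, Q, P, M, D, T, TWO, M, D, Q, M, T, D, M, M, D, M, M]
    specs = []
    truncated_chromosomes = {2, 10, 15}
    for i in range(n_chromosomes):
        segs = patterns[i % len(patterns)]
        n_copies = (36,) if len(segs) == 1 else (24, 24)
        trunc = i + 1 in truncated_chromosomes
        specs.append(
            ChromosomeSpec(
                name=f"chr{i + 1:02d}",
                segments=segs,
                n_copies=n_copies,
                truncation_fractions=PARTIAL_FRACTIONS if trunc else (),
                truncation_count=3 if trunc else 0,
            )
        )
    return specs


def build_karyotype(
    specs: Sequence[ChromosomeSpec],
    consensus_by_family: Mapping[str, str] | None = None,
    sub_rate: float = 0.05,
    indel_rate: float = 0.0,
    variant_divergence: float = 0.08,
    flank_frac: float = 0.2,
    flank_length: int | None = None,
    seed: int = 0,
) -> tuple[list[SeqRecord], GroundTruth]:
    """Assemble a genome of one record per chromosome.

    Each chromosome is flank + satellite array + flank; flanks are
    uniform-random non-repetitive sequence totalling `flank_frac` of the
    array length (or exactly `flank_length` bp per side when given).
    Variant marker sets are drawn once per chromosome so that segments of a
    two-variant chromosome share their base variants.
    """
    if not specs:
        raise ValueError("at least one chromosome spec is required")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names in karyotype specs")
    if consensus_by_family is None:
        consensus_by_family = default_family_consensus()

    records: list[SeqRecord] = []
    truth = GroundTruth()
    master = np.random.default_rng(seed)
    for spec in specs:
        chrom_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(chrom_seed)
        if spec.family not in consensus_by_family:
            raise ValueError(f"{spec.name}: no consensus for family {spec.family!r}")
        consensus = consensus_by_family[spec.family]
        all_labels = [lab for seg in spec.segments for lab in seg]
        variants = make_variants(consensus, all_labels, variant_divergence, rng)

        array_parts: list[str] = []
        chrom_truth: list[GroundTruthRecord] = []
        cursor = 0
        for seg_index, (pattern, n_copies) in enumerate(
            zip(spec.segments, spec.n_copies)
        ):
            cfg = SimulationConfig(
                monomer_length=len(consensus),
                n_copies=n_copies,
                sub_rate=sub_rate,
                indel_rate=indel_rate,
                hor_pattern=pattern,
                variant_divergence=variant_divergence,
                truncation_fractions=(
                    spec.truncation_fractions if seg_index == 0 else ()
                ),
                truncation_count=spec.truncation_count if seg_index == 0 else 0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            seg_seq, seg_truth = build_hor_array(
                cfg, consensus=consensus, variants=variants, chromosome=spec.name
            )
            array_parts.append(seg_seq)
            for r in seg_truth.records:
                chrom_truth.append(
                    GroundTruthRecord(
                        spec.name, r.start + cursor, r.end + cursor, r.label, r.truncated
                    )
                )
            cursor += len(seg_seq)

        array = "".join(array_parts)
        side = (
            flank_length
            if flank_length is not None
            else max(1, round(flank_frac * len(array) / 2))
        )
        left = rng.choice(BASES, size=side).tobytes().decode()
        right = rng.choice(BASES, size=side).tobytes().decode()
        records.append(SeqRecord(id=spec.name, sequence=left + array + right))
        for r in chrom_truth:
            truth.records.append(
                GroundTruthRecord(
                    spec.name, r.start + side, r.end + side, r.label, r.truncated
                )
            )
    return records, truth


@dataclass
class ReadSimConfig:
    """MiSeq-like paired-end read simulation parameters.

    enrichment rho is the fold oversampling of fragment midpoints inside
    ground-truth repeat intervals in the ChIP library; rho = 1 makes ChIP
    and input draws identically distributed.
    """

    read_length: int = 300
    n_pairs: int = 1000
    insert_mean: int = 500
    insert_sd: int = 50
    enrichment: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.insert_mean < self.read_length:
            raise ValueError("insert_mean must be >= read_length")
        if self.enrichment <= 0:
            raise ValueError("enrichment factor rho must be positive")


def repeat_weight_fraction(
    records: Sequence[SeqRecord], ground_truth: GroundTruth, rho: float
) -> float:
    """Expected fraction of fragment midpoints falling in repeat intervals
    under rho-fold oversampling (computed from the exact weight vector)."""
    total = sum(len(r.sequence) for r in records)
    repeat = sum(rec.length for rec in ground_truth.records)
    return (rho * repeat) / (rho * repeat + (total - repeat))


def simulate_reads(
    records: Sequence[SeqRecord],
    ground_truth: GroundTruth,
    config: ReadSimConfig,
    library: str,
) -> tuple[list[FastqRead], list[FastqRead]]:
    """Simulate a paired-end library (R1, R2) over the genome.

    The input library samples fragment midpoints uniformly; the chip library
    weights midpoints inside ground-truth repeat intervals by rho. Read ids
    encode the true fragment origin and whether its midpoint lies inside a
    repeat interval, so downstream assignment can be scored exactly.
    """
    if library not in {"chip", "input"}:
        raise ValueError("library must be 'chip' or 'input'")
    if not records:
        raise ValueError("empty genome")
    rho = config.enrichment if library == "chip" else 1.0
    rng = np.random.default_rng(config.seed)

    offsets: dict[str, int] = {}
    total = 0
    for rec in records:
        offsets[rec.id] = total
        total += len(rec.sequence)
    genome = "".join(rec.sequence for rec in records)
    bounds = np.array([offsets[r.id] for r in records] + [total])

    in_repeat = np.zeros(total, dtype=bool)
    for gt in ground_truth.records:
        off = offsets[gt.chromosome]
        in_repeat[off + gt.start : off + gt.end] = True
    weights = np.where(in_repeat, rho, 1.0)
    p = weights / weights.sum()

    midpoints = rng.choice(total, size=config.n_pairs, p=p)
    inserts = np.clip(
        np.rint(rng.normal(config.insert_mean, config.insert_sd, config.n_pairs)),
        config.read_length,
        None,
    ).astype(int)

    r1: list[FastqRead] = []
    r2: list[FastqRead] = []
    qual = "I" * config.read_length
    for i in range(config.n_pairs):
        mid = int(midpoints[i])
        chrom_idx = int(np.searchsorted(bounds, mid, side="right") - 1)
        lo, hi = int(bounds[chrom_idx]), int(bounds[chrom_idx + 1])
        insert = min(int(inserts[i]), hi - lo)
        start = mid - insert // 2
        start = max(lo, min(start, hi - insert))
        end = start + insert
        rep = int(in_repeat[mid])
        chrom = records[chrom_idx].id
        rid = (
            f"{library}:{i}|{chrom}:{start - lo}-{end - lo}|rep={rep}"
        )
        fwd = genome[start : start + config.read_length]
        rev = reverse_complement(genome[end - config.read_length : end])
        r1.append(FastqRead(id=rid + "/1", sequence=fwd, quality=qual))
        r2.append(FastqRead(id=rid + "/2", sequence=rev, quality=qual))
    return r1, r2


def simulate_qpcr_counts(
    fold_by_target: Mapping[str, float | tuple[float, float]],
    n_replicates: int = 4,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic ChIP-qPCR amounts for antibody and mock fractions.

    Each target's mock amount is lognormal around 1; the antibody amount is
    the target's true fold enrichment times its own lognormal noise, giving
    per-replicate relative enrichment centered on the configured fold. A
    target may carry its own noise level as a (fold, sigma) pair --
    assay variability differs between target amplicons.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    rows = []
    for target, spec in fold_by_target.items():
        fold, sigma = spec if isinstance(spec, tuple) else (spec, noise_sd)
        if fold <= 0:
            raise ValueError(f"fold for {target!r} must be positive")
        for rep in range(1, n_replicates + 1):
            mock = float(rng.lognormal(mean=0.0, sigma=sigma))
            antibody = float(fold * mock * rng.lognormal(mean=0.0, sigma=sigma))
            rows.append(
                {
                    "target": target,
                    "replicate": rep,
                    "antibody": antibody,
                    "mock": mock,
                }
            )
    return pd.DataFrame(rows)
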