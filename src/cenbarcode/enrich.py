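"""ChIP enrichment statistics for repeat families.

Read pairs are assigned to repeat families by exact canonical k-mer
sharing against reference monomers (the tandem context is captured by
indexing the circularized monomer). The enrichment ratio (ER) of a
family is its ChIP read proportion over its input read proportion;
families below the abundance floor (0.01% of either library) are
dropped, and families with ER strictly greater than 2.0 are retained as
CENH3-associated. qPCR-style relative enrichment (RE = antibody amount /
mock amount per replicate) is compared between targets with a Welch
t-test, with the figure-legend significance labels (** for P < 0.01,
* for P < 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .repeatio import FastqRead, read_fastq

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


@dataclass
class EnrichParams:
    kmer_size: int = 21
    abundance_floor: float = 0.0001  # 0.01% of the library
    er_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if self.kmer_size < 11 or self.kmer_size % 2 == 0:
            raise ValueError("kmer_size must be odd and >= 11")
        if not 0 <= self.abundance_floor < 1:
            raise ValueError("abundance_floor must be in [0, 1)")


def _encode_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical k-mer integers for one encoded sequence (code 255 = N)."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    valid = codes != 255
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = windows.astype(np.int64) @ powers
    rc_codes = (3 - codes[::-1]) % 4
    rc_windows = np.lib.stride_tricks.sliding_window_view(rc_codes, k)
    rev = (rc_windows.astype(np.int64) @ powers)[::-1]
    return np.minimum(fwd, rev)[ok]


def sequence_kmers(seq: str, k: int) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    return _encode_kmers(codes, k)


def build_family_index(
    references: Mapping[str, str], params: EnrichParams
) -> dict[str, np.ndarray]:
    """Sorted unique canonical k-mer sets per family.

    Each reference monomer is circularized (monomer + first k-1 bases) so
    junction-spanning k-mers of a tandem array are indexed too; k-mers
    shared between families are removed from every family.
    """
    k = params.kmer_size
    raw: dict[str, np.ndarray] = {}
    for name, seq in references.items():
        if len(seq) < k:
            raise ValueError(f"reference {name!r} shorter than k={k}")
        circular = seq + seq[: k - 1]
        raw[name] = np.unique(sequence_kmers(circular, k))
    if len(raw) > 1:
        all_kmers = np.concatenate(list(raw.values()))
        values, counts = np.unique(all_kmers, return_counts=True)
        shared = values[counts > 1]
        raw = {name: kmers[~np.isin(kmers, shared)] for name, kmers in raw.items()}
    for name, kmers in raw.items():
        if kmers.size == 0:
            raise ValueError(
                f"family {name!r} has no distinguishing k-mers at k={k}"
            )
    return raw


def _batch_kmers(seqs: Sequence[str], k: int) -> list[np.ndarray]:
    return [sequence_kmers(s, k) for s in seqs]


def assign_reads(
    r1: Sequence[FastqRead] | str | Path,
    r2: Sequence[FastqRead] | str | Path | None,
    references: Mapping[str, str],
    params: EnrichParams | None = None,
) -> dict[str, int]:
    """Assign read pairs to families by shared canonical k-mers.

    A pair goes to the family sharing the most exact k-mers with either
    mate; zero shared k-mers or a tie between families leaves the pair
    unassigned (key "unassigned").
    """
    if params is None:
        params = EnrichParams()
    if isinstance(r1, (str, Path)):
        r1 = read_fastq(r1)
    if isinstance(r2, (str, Path)):
        r2 = read_fastq(r2)
    if r2 is not None and len(r1) != len(r2):
        raise ValueError("R1/R2 read counts differ")
    k = params.kmer_size
    for read in list(r1[:1]) + (list(r2[:1]) if r2 else []):
        if len(read.sequence) < k:
            raise ValueError(f"k={k} larger than read length {len(read.sequence)}")
    index = build_family_index(references, params)
    families = list(index)
    counts = {name: 0 for name in families}
    counts["unassigned"] = 0

    kmers1 = _batch_kmers([r.sequence for r in r1], k)
    kmers2 = (
        _batch_kmers([r.sequence for r in r2], k) if r2 is not None else [None] * len(r1)
    )
    for km1, km2 in zip(kmers1, kmers2):
        pair = km1 if km2 is None else np.concatenate([km1, km2])
        best_name, best_hits, tie = None, 0, False
        for name in families:
            hits = int(
                np.count_nonzero(
                    index[name][
                        np.searchsorted(index[name], pair).clip(0, index[name].size - 1)
                    ]
                    == pair
                )
            )
            if hits > best_hits:
                best_name, best_hits, tie = name, hits, False
            elif hits == best_hits and hits > 0:
                tie = True
        if best_name is None or tie:
            counts["unassigned"] += 1
        else:
            counts[best_name] += 1
    return counts


def enrichment_ratio(
    chip_counts: Mapping[str, int],
    input_counts: Mapping[str, int],
    params: EnrichParams | None = None,
    chip_total: int | None = None,
    input_total: int | None = None,
) -> pd.DataFrame:
    """Per-family enrichment table.

    ER = (chip_count / chip_total) / (input_count / input_total); totals
    default to the sum of the supplied counts (including any "unassigned"
    mass). Families whose proportion is below the abundance floor in both
    libraries are dropped; `retained` is ER strictly greater than the
    cutoff. A family present in ChIP but absent from input gets ER = +inf.
    """
    if params is None:
        params = EnrichParams()
    families = [f for f in chip_counts.keys() | input_counts.keys() if f != "unassigned"]
    chip_total = chip_total if chip_total is not None else sum(chip_counts.values())
    input_total = input_total if input_total is not None else sum(input_counts.values())
    if chip_total <= 0 or input_total <= 0:
        raise ValueError("both libraries must contain reads")
    rows = []
    for fam in sorted(families):
        c = chip_counts.get(fam, 0)
        i = input_counts.get(fam, 0)
        chip_prop = c / chip_total
        input_prop = i / input_total
        if chip_prop < params.abundance_floor and input_prop < params.abundance_floor:
            continue
        if input_prop > 0:
            er = chip_prop / input_prop
        elif chip_prop > 0:
            er = math.inf
        else:
            continue
        rows.append(
            {
                "family": fam,
                "chip_count": c,
                "input_count": i,
                "chip_total": chip_total,
                "input_total": input_total,
                "chip_prop": chip_prop,
                "input_prop": input_prop,
                "ER": er,
                "retained": er > params.er_cutoff,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family",
            "chip_count",
            "input_count",
            "chip_total",
            "input_total",
            "chip_prop",
            "input_prop",
            "ER",
            "retained",
        ],
    )


def relative_enrichment(
    antibody: Sequence[float], mock: Sequence[float]
) -> dict[str, object]:
    """Per-replicate RE = antibody amount / mock amount, with mean and SE."""
    if len(antibody) != len(mock) or not antibody:
        raise ValueError("antibody and mock must be equal-length, non-empty")
    for idx, m in enumerate(mock, 1):
        if m <= 0:
            raise ValueError(f"mock amount is zero (or negative) in replicate {idx}")
    re = [a / m for a, m in zip(antibody, mock)]
    n = len(re)
    mean = sum(re) / n
    se = (sum((x - mean) ** 2 for x in re) / (n - 1)) ** 0.5 / n**0.5 if n > 1 else 0.0
    return {"RE": re, "mean_RE": mean, "se_RE": se, "n": n}


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Welch unequal-variance two-sample t-test (two-sided).

    Degenerate conventions: zero variance in both groups gives p = 1 for
    equal means and p = 0 (flagged) for unequal means.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(na + nb - 2), 1.0, degenerate=True)
        t = math.inf if a.mean() > b.mean() else -math.inf
        return WelchResult(t, float(na + nb - 2), 0.0, degenerate=True)
    sa, sb = va / na, vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def significance_label(p: float) -> str:
    """Figure-legend style labels: ** for P < 0.01, * for P < 0.05."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def qpcr_table(
    counts: pd.DataFrame, control: str
) -> pd.DataFrame:
    """Per-target RE summary plus Welch t-test against the control target.

    `counts` columns: target, replicate, antibody, mock (one row per
    replicate)."""
    required = {"target", "replicate", "antibody", "mock"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    targets = list(dict.fromkeys(counts["target"]))
    if control not in targets:
        raise ValueError(f"control target {control!r} not in table")
    re_by_target = {}
    for target in targets:
        sub = counts[counts["target"] == target].sort_values("replicate")
        re_by_target[target] = relative_enrichment(
            sub["antibody"].tolist(), sub["mock"].tolist()
        )
    control_re = re_by_target[control]["RE"]
    rows = []
    for target in targets:
        summary = re_by_target[target]
        if target == control:
            t, df, p, label = 0.0, float("nan"), 1.0, ""
        else:
            t, df, p, _ = welch_t_test(summary["RE"], control_re)
            label = significance_label(p)
        rows.append(
            {
                "target": target,
                "n": summary["n"],
                "mean_RE": summary["mean_RE"],
                "se_RE": summary["se_RE"],
                "t": t,
                "df": df,
                "p": p,
                "significance": label,
            }
        )
    return pd.DataFrame(rows)
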