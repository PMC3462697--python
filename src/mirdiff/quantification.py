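"""RPKM normalization and pairwise expression contrasts.

Counts are scaled to RPKM (reads per kilobase per million mapped reads)

    rpkm = count * 1e9 / (effective_length_nt * library_total)

where the effective length of a miRNA is the count-weighted mean length of
its isoMIR variants (~18–19 nt in practice) and the library total is the
raw read count of the library. For a two-library contrast each miRNA gets

    M = log2(x1 / x2)        (zeros replaced by a pseudo-RPKM first)
    D = |x1 - x2|            (on the raw RPKM values)

which are the axes of the volcano plot and the inputs of the
no-replicate differential-expression statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .annotation import LibraryProfile

M_DECIMALS = 3
D_DECIMALS = 2
RPKM_DECIMALS = 3


@dataclass(frozen=True)
class ExpressionRecord:
    """Count, effective length and RPKM of one miRNA in one library."""

    name: str
    library_id: str
    count: int
    effective_length_nt: float
    rpkm: float


@dataclass(frozen=True)
class PairwiseContrast:
    """M/D contrast of one miRNA between two libraries (x_i in RPKM)."""

    name: str
    x1: float
    x2: float
    M: float
    D: float


def effective_length(isomir_breakdown: Mapping[str, int]) -> float:
    """Count-weighted mean isoMIR length, in nucleotides."""
    total = sum(isomir_breakdown.values())
    if total <= 0:
        raise ValueError("empty isoMIR breakdown")
    return sum(len(v) * c for v, c in isomir_breakdown.items()) / total


def rpkm(count: int, effective_length_nt: float, library_total: int) -> float:
    """Reads per kilobase per million mapped reads."""
    if effective_length_nt <= 0:
        raise ValueError(f"effective length must be positive, got {effective_length_nt}")
    if library_total <= 0:
        raise ValueError(f"library total must be positive, got {library_total}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return count * 1e9 / (effective_length_nt * library_total)


def m_d_values(x1: float, x2: float, pseudo: float = 1.0) -> tuple[float, float]:
    """M = log2 ratio (zeros -> pseudo), D = absolute difference (raw)."""
    if x1 < 0 or x2 < 0:
        raise ValueError("expression values must be non-negative")
    if pseudo <= 0:
        raise ValueError("pseudo must be positive")
    x1p = x1 if x1 > 0 else pseudo
    x2p = x2 if x2 > 0 else pseudo
    return math.log2(x1p / x2p), abs(x1 - x2)


class RpkmNormalizer(BaseEstimator):
    """Turn a :class:`LibraryProfile` into per-miRNA expression records.

    Parameters
    ----------
    length_mode : {"effective", "mature"}
        "effective" (default) uses the count-weighted mean isoMIR length;
        "mature" uses the catalog mature-sequence length (requires a
        catalog mapping passed to ``transform``).
    total_mode : {"raw", "clean"}
        Which library total goes into the per-million denominator; raw
        sequencing depth is the default.
    """

    def __init__(self, length_mode: str = "effective", total_mode: str = "raw"):
        self.length_mode = length_mode
        self.total_mode = total_mode

    def fit(self, X=None, y=None) -> "RpkmNormalizer":
        if self.length_mode not in ("effective", "mature"):
            raise ValueError(f"unknown length_mode {self.length_mode!r}")
        if self.total_mode not in ("raw", "clean"):
            raise ValueError(f"unknown total_mode {self.total_mode!r}")
        return self

    def transform(self, profile: LibraryProfile,
                  mature_lengths: Mapping[str, int] | None = None,
                  names: Sequence[str] | None = None) -> list[ExpressionRecord]:
        self.fit()
        total = (profile.total_raw_reads if self.total_mode == "raw"
                 else profile.total_clean_reads)
        if names is None:
            names = sorted(profile.per_mirna)
        records = []
        for name in names:
            count = profile.per_mirna.get(name, 0)
            if self.length_mode == "mature":
                if mature_lengths is None or name not in mature_lengths:
                    raise ValueError(f"no mature length for {name}")
                length = float(mature_lengths[name])
            else:
                breakdown = profile.isomir_breakdown.get(name)
                if breakdown:
                    length = effective_length(breakdown)
                elif mature_lengths and name in mature_lengths:
                    length = float(mature_lengths[name])
                else:
                    raise ValueError(f"no isoMIR breakdown or length for {name}")
            records.append(ExpressionRecord(
                name=name, library_id=profile.library_id, count=count,
                effective_length_nt=length,
                rpkm=rpkm(count, length, total),
            ))
        return records


def expression_table(records_1: Sequence[ExpressionRecord],
                     records_2: Sequence[ExpressionRecord]) -> pd.DataFrame:
    """Join two libraries' records into a counts/RPKM table (one row per miRNA)."""
    if not records_1 or not records_2:
        raise ValueError("both libraries need at least one record")
    lib1 = records_1[0].library_id
    lib2 = records_2[0].library_id
    r1 = {r.name: r for r in records_1}
    r2 = {r.name: r for r in records_2}
    names = [n for n in r1 if n in r2]
    return pd.DataFrame(
        {
            f"counts_{lib1}": [r1[n].count for n in names],
            f"rpkm_{lib1}": [r1[n].rpkm for n in names],
            f"counts_{lib2}": [r2[n].count for n in names],
            f"rpkm_{lib2}": [r2[n].rpkm for n in names],
        },
        index=pd.Index(names, name="mirna"),
    )


def contrast_table(expr: pd.DataFrame, lib1: str, lib2: str,
                   pseudo: float | np.ndarray = 1.0) -> list[PairwiseContrast]:
    """Compute per-miRNA M/D contrasts from an expression table.

    ``pseudo`` may be a scalar or a per-miRNA array of substitution RPKMs
    used when a value is exactly zero.
    """
    x1 = expr[f"rpkm_{lib1}"].to_numpy(dtype=float)
    x2 = expr[f"rpkm_{lib2}"].to_numpy(dtype=float)
    pseudo_arr = np.broadcast_to(np.asarray(pseudo, dtype=float), x1.shape)
    out = []
    for name, a, b, p in zip(expr.index, x1, x2, pseudo_arr):
        m, d = m_d_values(a, b, pseudo=float(p))
        out.append(PairwiseContrast(name=name, x1=a, x2=b, M=m, D=d))
    return out


def implied_effective_length(count: int, rpkm_value: float,
                             library_total: int) -> float:
    """Back-solve the effective length from a printed (count, RPKM) pair."""
    if rpkm_value <= 0 or count <= 0 or library_total <= 0:
        raise ValueError("count, RPKM and total must be positive")
    return 1e9 * count / (rpkm_value * library_total)
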