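"""FASTQ cleaning for small-RNA libraries.

Raw small-RNA reads (adapters already removed) pass through four stages:

1. whole-read quality filter — discard reads in which at least 80% of
   positions are below Q20;
2. end trimming — strip low-quality bases, homopolymer runs and perfect
   dinucleotide repeats from either end, iteratively until stable;
3. collapsing — group identical sequences into (sequence, count) pairs;
4. length filter — keep sequences of 10–28 nt, the small-RNA size range.

Quality strings may be Phred+64 (classic Illumina, the default here) or
Phred+33; scores are expected in 0–40.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

_FASTQ_FORMAT = {33: "fastq-sanger", 64: "fastq-illumina"}

QUALITY_MAX = 40


@dataclass
class QualityRead:
    """A sequencing read with per-base Phred quality scores."""

    read_id: str
    seq: str
    qual: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


class CollapsedSeq(NamedTuple):
    """A distinct sequence and the number of identical reads it collapses."""

    seq: str
    count: int


@dataclass
class PreprocessStats:
    """Read accounting through the cleaning stages."""

    n_raw: int = 0
    n_pass_quality: int = 0
    n_after_trim: int = 0
    n_in_length_range: int = 0
    n_unique: int = 0

    def to_dict(self) -> dict[str, int]:
        return {
            "n_raw": self.n_raw,
            "n_pass_quality": self.n_pass_quality,
            "n_after_trim": self.n_after_trim,
            "n_in_length_range": self.n_in_length_range,
            "n_unique": self.n_unique,
        }


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_fastq(path: str | Path, quality_offset: int = 64) -> Iterator[QualityRead]:
    """Stream reads from a (possibly gzipped) FASTQ file.

    Qualities are decoded as ``ord(char) - quality_offset`` and must land in
    0–40; a score outside that range raises with a hint to try the other
    offset, which is the usual cause.
    """
    if quality_offset not in _FASTQ_FORMAT:
        raise ValueError(f"quality_offset must be 33 or 64, got {quality_offset}")
    fmt = _FASTQ_FORMAT[quality_offset]
    other = 97 - quality_offset
    with _open_maybe_gzip(path) as handle:
        records = SeqIO.parse(handle, fmt)
        index = 0
        while True:
            try:
                record = next(records)
            except StopIteration:
                return
            except ValueError as exc:
                msg = f"malformed FASTQ record {index}: {exc}"
                if "qualit" in str(exc).lower():
                    msg += f"; is the file Phred+{other}?"
                raise ValueError(msg) from exc
            qual = record.letter_annotations["phred_quality"]
            bad = [q for q in qual if q < 0 or q > QUALITY_MAX]
            if bad:
                raise ValueError(
                    f"record {index} ({record.id!r}): decoded quality {bad[0]} "
                    f"outside 0-{QUALITY_MAX} at offset {quality_offset}; "
                    f"is the file Phred+{other}?"
                )
            yield QualityRead(record.id, str(record.seq).upper(), list(qual))
            index += 1


def write_fastq(reads: Iterable[QualityRead], path: str | Path,
                quality_offset: int = 64) -> int:
    """Write reads as FASTQ at the given offset; returns the number written."""
    if quality_offset not in _FASTQ_FORMAT:
        raise ValueError(f"quality_offset must be 33 or 64, got {quality_offset}")
    fmt = _FASTQ_FORMAT[quality_offset]
    n = 0
    with _open_maybe_gzip(path, "wt") as handle:
        for read in reads:
            record = SeqRecord(Seq(read.seq), id=read.read_id, description="")
            record.letter_annotations["phred_quality"] = list(read.qual)
            SeqIO.write(record, handle, fmt)
            n += 1
    return n


def passes_quality(read: QualityRead, q_min: int = 20,
                   bad_fraction: float = 0.8) -> bool:
    """Whole-read quality rule.

    Returns False (read eliminated) when the fraction of positions with
    quality below ``q_min`` is at least ``bad_fraction``. N bases count as
    low quality regardless of their score.
    """
    if len(read) == 0:
        raise ValueError("empty read")
    n_bad = sum(
        1 for base, q in zip(read.seq, read.qual) if q < q_min or base == "N"
    )
    return n_bad / len(read) < bad_fraction


def _leading_low_quality(seq: str, qual: list[int], q_min: int) -> int:
    i = 0
    while i < len(seq) and (qual[i] < q_min or seq[i] == "N"):
        i += 1
    return i


def _leading_homopolymer(seq: str, min_run: int) -> int:
    if not seq:
        return 0
    i = 1
    while i < len(seq) and seq[i] == seq[0]:
        i += 1
    return i if i >= min_run else 0


def _leading_dimer_repeat(seq: str, min_units: int) -> int:
    # perfect dinucleotide repeat like ACACAC...: units of 2 nt, head only
    if len(seq) < 2 * min_units:
        return 0
    unit = seq[:2]
    if unit[0] == unit[1]:
        return 0  # that is a homopolymer, handled separately
    units = 1
    while 2 * (units + 1) <= len(seq) and seq[2 * units:2 * units + 2] == unit:
        units += 1
    return 2 * units if units >= min_units else 0


def trim_ends(read: QualityRead, q_min: int = 20, homopolymer_min: int = 5,
              dimer_units_min: int = 3) -> QualityRead:
    """Strip terminal artifacts from both ends, iterating until stable.

    Three end-anchored rules, each applied to the head of the read and to
    the head of its reversal: (a) bases below ``q_min``; (b) homopolymer
    runs of >= ``homopolymer_min`` bases; (c) perfect dinucleotide repeats
    of >= ``dimer_units_min`` units. Interior bases are never touched, so
    the result is a contiguous substring of the input (possibly empty).
    """
    seq, qual = read.seq, list(read.qual)

    def head_cut(s: str, q: list[int]) -> int:
        cut = _leading_low_quality(s, q, q_min)
        if cut == 0:
            cut = _leading_homopolymer(s, homopolymer_min)
        if cut == 0:
            cut = _leading_dimer_repeat(s, dimer_units_min)
        return cut

    changed = True
    while changed and seq:
        changed = False
        cut = head_cut(seq, qual)
        if cut:
            seq, qual = seq[cut:], qual[cut:]
            changed = True
        if seq:
            cut = head_cut(seq[::-1], qual[::-1])
            if cut:
                seq, qual = seq[:-cut], qual[:-cut]
                changed = True
    return QualityRead(read.read_id, seq, qual)


def collapse(seqs: Iterable[str]) -> list[CollapsedSeq]:
    """Group identical sequences into counts.

    Output is sorted by descending count, ties broken lexicographically, so
    repeated runs produce identical files.
    """
    counts = Counter(seqs)
    return [
        CollapsedSeq(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def length_filter(seqs: Iterable[CollapsedSeq], min_len: int = 10,
                  max_len: int = 28) -> list[CollapsedSeq]:
    """Keep sequences whose length is within [min_len, max_len] inclusive."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [cs for cs in seqs if min_len <= len(cs.seq) <= max_len]


class FastqPreprocessor(BaseEstimator):
    """Clean raw small-RNA reads into unique (sequence, count) pairs.

    A stateless transformer: `transform` accepts an iterable of
    :class:`QualityRead` (or a FASTQ path) and returns the collapsed,
    length-filtered sequences. Read accounting for the last transform is
    stored in ``stats_``.

    Parameters
    ----------
    quality_offset : int, 33 or 64
        FASTQ quality encoding (used only when transforming from a path).
    q_min : int
        Phred threshold under which a base counts as low quality.
    bad_fraction : float
        A read is discarded when >= this fraction of its bases is below
        ``q_min``.
    homopolymer_min, dimer_units_min : int
        End-trimming thresholds, see :func:`trim_ends`.
    min_len, max_len : int
        Inclusive length window of sequences kept after collapsing.
    """

    def __init__(self, quality_offset: int = 64, q_min: int = 20,
                 bad_fraction: float = 0.8, homopolymer_min: int = 5,
                 dimer_units_min: int = 3, min_len: int = 10,
                 max_len: int = 28):
        self.quality_offset = quality_offset
        self.q_min = q_min
        self.bad_fraction = bad_fraction
        self.homopolymer_min = homopolymer_min
        self.dimer_units_min = dimer_units_min
        self.min_len = min_len
        self.max_len = max_len

    def fit(self, X=None, y=None) -> "FastqPreprocessor":
        return self

    def transform(self, X: Iterable[QualityRead] | str | Path) -> list[CollapsedSeq]:
        if isinstance(X, (str, Path)):
            X = parse_fastq(X, quality_offset=self.quality_offset)
        stats = PreprocessStats()
        surviving: list[str] = []
        for read in X:
            stats.n_raw += 1
            if not passes_quality(read, self.q_min, self.bad_fraction):
                continue
            stats.n_pass_quality += 1
            trimmed = trim_ends(read, self.q_min, self.homopolymer_min,
                                self.dimer_units_min)
            if len(trimmed) == 0:
                continue
            stats.n_after_trim += 1
            surviving.append(trimmed.seq)
        collapsed = collapse(surviving)
        kept = length_filter(collapsed, self.min_len, self.max_len)
        stats.n_in_length_range = sum(cs.count for cs in kept)
        stats.n_unique = len(kept)
        self.stats_ = stats
        return kept

    def fit_transform(self, X, y=None) -> list[CollapsedSeq]:
        return self.fit(X).transform(X)


def preprocess_fastq(path: str | Path, **params) -> tuple[list[CollapsedSeq], PreprocessStats]:
    """Run the full cleaning stage on one FASTQ file."""
    pre = FastqPreprocessor(**params)
    kept = pre.transform(path)
    return kept, pre.stats_


def write_collapsed_fasta(seqs: Iterable[CollapsedSeq], path: str | Path) -> None:
    """Write collapsed sequences in the ``>seq<i>_x<count>`` FASTA dialect."""
    with _open_maybe_gzip(path, "wt") as handle:
        for i, cs in enumerate(seqs, start=1):
            handle.write(f">seq{i}_x{cs.count}\n{cs.seq}\n")


def read_collapsed_fasta(path: str | Path) -> list[CollapsedSeq]:
    """Read the ``>seq<i>_x<count>`` dialect back into CollapsedSeq pairs."""
    out: list[CollapsedSeq] = []
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            try:
                count = int(record.id.rsplit("_x", 1)[1])
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"header {record.id!r} is not in seq<i>_x<count> form"
                ) from exc
            out.append(CollapsedSeq(str(record.seq).upper(), count))
    return out


def write_collapsed_tsv(seqs: Iterable[CollapsedSeq], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("seq\tcount\n")
        for cs in seqs:
            handle.write(f"{cs.seq}\t{cs.count}\n")
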