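"""Canonical-miRNA assignment by anchored seed matching.

Clean sequences are first screened against contaminant references
(exact substring on both strands), then assigned to mature miRNAs from a
miRBase-style catalog. The matching rule is 5'-anchored and exact: the
seed is the first 17 nt of the mature sequence, a read of >= 17 nt matches
when its first 17 nt equal the seed with zero mismatches (extra 3' bases
are isoMIR tolerance and are not checked), and a shorter read matches when
it equals the same-length prefix of the seed. Length variants (isoMIRs) of
one miRNA are merged into a single count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from sklearn.base import BaseEstimator

from .io_preprocess import CollapsedSeq, _open_maybe_gzip

logger = logging.getLogger(__name__)

SEED_LENGTH = 17
MIN_QUERY, MAX_QUERY = 10, 28

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

AmbiguityPolicy = Literal["discard", "all", "first"]


def _normalize(seq: str) -> str:
    """Uppercase and store RNA as DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A catalog entry: name, mature sequence (U stored as T) and its seed."""

    name: str
    seq: str

    @property
    def seed(self) -> str:
        return self.seq[:SEED_LENGTH]


def load_catalog(path: str | Path) -> list[MatureMiRNA]:
    """Read a mature-miRNA FASTA (miRBase dialect, first header token = name).

    Entries shorter than the 17-nt seed cannot be matched under the anchored
    rule and are rejected with a warning.
    """
    catalog: list[MatureMiRNA] = []
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            seq = _normalize(str(record.seq))
            if len(seq) < SEED_LENGTH:
                logger.warning(
                    "catalog entry %s is %d nt (< %d); rejected",
                    record.id, len(seq), SEED_LENGTH,
                )
                continue
            catalog.append(MatureMiRNA(record.id, seq))
    return catalog


@dataclass
class LibraryProfile:
    """Per-library, isoMIR-merged miRNA counts plus read accounting."""

    library_id: str
    total_raw_reads: int = 0
    total_clean_reads: int = 0
    per_mirna: dict[str, int] = field(default_factory=dict)
    isomir_breakdown: dict[str, dict[str, int]] = field(default_factory=dict)
    unassigned: int = 0
    ambiguous_discarded: int = 0

    def validate(self) -> None:
        for name, merged in self.per_mirna.items():
            variants = self.isomir_breakdown.get(name, {})
            if merged != sum(variants.values()):
                raise ValueError(f"{name}: merged count != sum of variants")


class ContaminantIndex:
    """Exact-substring membership over a set of reference sequences.

    Built for short queries (the 10–28 nt small-RNA window): every substring
    of the references in that length band is enumerated into hash sets, one
    per length, so lookup is O(1). References' reverse complements are
    included when ``both_strands`` is true.
    """

    def __init__(self, references: Iterable[tuple[str, str]],
                 both_strands: bool = True,
                 min_query: int = MIN_QUERY, max_query: int = MAX_QUERY):
        self.source_labels: list[str] = []
        self.both_strands = both_strands
        self.min_query = min_query
        self.max_query = max_query
        self._by_length: dict[int, set[str]] = {
            k: set() for k in range(min_query, max_query + 1)
        }
        n_refs = 0
        for label, seq in references:
            seq = _normalize(seq)
            self.source_labels.append(label)
            strands = [seq, reverse_complement(seq)] if both_strands else [seq]
            for s in strands:
                for k, bucket in self._by_length.items():
                    for i in range(len(s) - k + 1):
                        bucket.add(s[i:i + k])
            n_refs += 1
        if n_refs == 0:
            raise ValueError("empty contaminant reference set")

    def __contains__(self, seq: str) -> bool:
        seq = _normalize(seq)
        bucket = self._by_length.get(len(seq))
        return bucket is not None and seq in bucket


def build_contaminant_index(fastas: Sequence[str | Path],
                            both_strands: bool = True) -> ContaminantIndex:
    """Index one or more contaminant FASTA files for substring screening."""

    def _iter_refs():
        for path in fastas:
            with _open_maybe_gzip(path) as handle:
                for record in SeqIO.parse(handle, "fasta"):
                    yield record.id, str(record.seq)

    return ContaminantIndex(_iter_refs(), both_strands=both_strands)


def screen_contaminants(
    seqs: Iterable[CollapsedSeq], index: ContaminantIndex | None
) -> tuple[list[CollapsedSeq], list[CollapsedSeq]]:
    """Partition sequences into (kept, removed) by contaminant membership."""
    if index is None:
        return list(seqs), []
    kept: list[CollapsedSeq] = []
    removed: list[CollapsedSeq] = []
    for cs in seqs:
        (removed if cs.seq in index else kept).append(cs)
    return kept, removed


class _SeedIndex:
    """Anchored prefix lookup: seed (or seed prefix) -> catalog names."""

    def __init__(self, catalog: Sequence[MatureMiRNA], max_5p_offset: int = 0):
        names = [m.name for m in catalog]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate catalog names: {dupes}")
        self.max_5p_offset = max_5p_offset
        # one dict per query length; offset alignments share the same tables
        self._tables: dict[int, dict[str, list[str]]] = {
            k: {} for k in range(MIN_QUERY, MAX_QUERY + 1)
        }
        for m in catalog:
            mseq = _normalize(m.seq)
            for off in range(max_5p_offset + 1):
                region = mseq[off:off + SEED_LENGTH]
                if len(region) < SEED_LENGTH:
                    break
                for k in range(MIN_QUERY, SEED_LENGTH):
                    self._tables[k].setdefault(region[:k], []).append(m.name)
                for k in range(SEED_LENGTH, MAX_QUERY + 1):
                    self._tables[k].setdefault(region, []).append(m.name)

    def lookup(self, seq: str) -> list[str]:
        n = len(seq)
        if not (MIN_QUERY <= n <= MAX_QUERY):
            raise ValueError(f"query length {n} outside [{MIN_QUERY}, {MAX_QUERY}]")
        key = seq if n < SEED_LENGTH else seq[:SEED_LENGTH]
        hits = self._tables[n].get(key, [])
        # preserve catalog order, deduplicate (offset variants can repeat)
        seen: dict[str, None] = {}
        for name in hits:
            seen.setdefault(name)
        return list(seen)


def match_mirna(seq: str, catalog: Sequence[MatureMiRNA],
                max_5p_offset: int = 0) -> list[str]:
    """Return every catalog name the sequence matches under the seed rule.

    Matching is case-insensitive and treats U and T as identical; N never
    matches. Convenience wrapper building a fresh index per call — use
    :class:`MiRNAAnnotator` for whole libraries.
    """
    seq = _normalize(seq)
    if "N" in seq:
        if not (MIN_QUERY <= len(seq) <= MAX_QUERY):
            raise ValueError(
                f"query length {len(seq)} outside [{MIN_QUERY}, {MAX_QUERY}]")
        return []
    return _SeedIndex(catalog, max_5p_offset).lookup(seq)


class MiRNAAnnotator(BaseEstimator):
    """Assign clean sequences to catalog miRNAs, merging isoMIRs.

    ``fit`` indexes the catalog (and contaminants, if any); ``transform``
    annotates one library's collapsed sequences into a
    :class:`LibraryProfile`.

    Parameters
    ----------
    catalog : sequence of MatureMiRNA, or FASTA path
    contaminants : sequence of FASTA paths, optional
    both_strands : bool
        Screen contaminants on both strands.
    ambiguity : {"discard", "all", "first"}
        What to do with a sequence matching several catalog entries:
        drop it (default, logged), count it toward every hit, or toward
        the first hit in catalog order.
    max_5p_offset : int
        Allow the read to start up to this many nt inside the mature
        sequence (0 = strict 5' anchoring).
    """

    def __init__(self, catalog=None, contaminants: Sequence[str | Path] | None = None,
                 both_strands: bool = True, ambiguity: AmbiguityPolicy = "discard",
                 max_5p_offset: int = 0):
        self.catalog = catalog
        self.contaminants = contaminants
        self.both_strands = both_strands
        self.ambiguity = ambiguity
        self.max_5p_offset = max_5p_offset

    def fit(self, X=None, y=None) -> "MiRNAAnnotator":
        if self.catalog is None:
            raise ValueError("catalog is required")
        if self.ambiguity not in ("discard", "all", "first"):
            raise ValueError(f"unknown ambiguity policy {self.ambiguity!r}")
        if isinstance(self.catalog, (str, Path)):
            catalog = load_catalog(self.catalog)
        else:
            catalog = [
                m if isinstance(m, MatureMiRNA) else MatureMiRNA(*m)
                for m in self.catalog
            ]
        if not catalog:
            raise ValueError("catalog is empty")
        self.catalog_ = catalog
        self.seed_index_ = _SeedIndex(catalog, self.max_5p_offset)
        if self.contaminants:
            self.contaminant_index_ = build_contaminant_index(
                list(self.contaminants), both_strands=self.both_strands)
        else:
            self.contaminant_index_ = None
        return self

    def transform(self, X: Iterable[CollapsedSeq], library_id: str = "library",
                  total_raw_reads: int | None = None) -> LibraryProfile:
        if not hasattr(self, "seed_index_"):
            self.fit()
        seqs = [cs if isinstance(cs, CollapsedSeq) else CollapsedSeq(*cs) for cs in X]
        kept, removed = screen_contaminants(seqs, self.contaminant_index_)
        total_clean = sum(cs.count for cs in kept)
        profile = LibraryProfile(
            library_id=library_id,
            total_raw_reads=(total_raw_reads if total_raw_reads is not None
                             else sum(cs.count for cs in seqs)),
            total_clean_reads=total_clean,
        )
        for cs in kept:
            seq = _normalize(cs.seq)
            names = [] if "N" in seq else self.seed_index_.lookup(seq)
            if not names:
                profile.unassigned += cs.count
                continue
            if len(names) > 1:
                if self.ambiguity == "discard":
                    logger.debug("ambiguous sequence %s matches %s; discarded",
                                 seq, names)
                    profile.ambiguous_discarded += cs.count
                    continue
                if self.ambiguity == "first":
                    names = names[:1]
            for name in names:
                profile.per_mirna[name] = profile.per_mirna.get(name, 0) + cs.count
                profile.isomir_breakdown.setdefault(name, {})
                profile.isomir_breakdown[name][seq] = (
                    profile.isomir_breakdown[name].get(seq, 0) + cs.count)
        self.n_removed_contaminant_ = sum(cs.count for cs in removed)
        return profile

    def fit_transform(self, X, y=None, **kwargs) -> LibraryProfile:
        return self.fit().transform(X, **kwargs)


def annotate_library(seqs: Iterable[CollapsedSeq],
                     catalog: Sequence[MatureMiRNA],
                     ambiguity: AmbiguityPolicy = "discard",
                     library_id: str = "library",
                     total_raw_reads: int | None = None,
                     max_5p_offset: int = 0) -> LibraryProfile:
    """Annotate one library against a catalog (no contaminant screen)."""
    ann = MiRNAAnnotator(catalog=catalog, ambiguity=ambiguity,
                         max_5p_offset=max_5p_offset)
    return ann.fit().transform(seqs, library_id=library_id,
                               total_raw_reads=total_raw_reads)


def low_abundance_filter(profiles: Sequence[LibraryProfile],
                         pool_fraction: float = 0.0001,
                         mode: Literal["pool", "per_mirna"] = "pool",
                         ) -> tuple[list[str], list[str]]:
    """Drop the poorest-represented miRNAs.

    In ``pool`` mode (default) miRNAs are ordered by ascending total count
    across libraries and the longest low-count prefix whose cumulative sum
    stays within ``pool_fraction`` of the total raw reads is eliminated —
    i.e. the dropped miRNAs *together* account for at most that share. In
    ``per_mirna`` mode each miRNA is dropped when its own share is below
    ``pool_fraction``. The kept set is common to all libraries.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    names = sorted({n for p in profiles for n in p.per_mirna})
    summed = {n: sum(p.per_mirna.get(n, 0) for p in profiles) for n in names}
    total = sum(p.total_raw_reads for p in profiles)
    budget = pool_fraction * total
    dropped: list[str] = []
    if mode == "pool":
        cumulative = 0
        for name in sorted(names, key=lambda n: (summed[n], n)):
            if len(dropped) == len(names) - 1:
                break  # never empty the profile
            if cumulative + summed[name] <= budget:
                cumulative += summed[name]
                dropped.append(name)
            else:
                break
    elif mode == "per_mirna":
        dropped = [n for n in names if summed[n] < budget]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    dropped_set = set(dropped)
    kept = [n for n in names if n not in dropped_set]
    return kept, sorted(dropped_set)
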