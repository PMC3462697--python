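"""Synthetic two-library small-RNA experiments with known ground truth.

Raw reads of the original nymphal libraries were never deposited, so the
pipeline is exercised on generated data that emulates their statistical
structure: ~60 mature miRNAs with log-normal abundances spanning the
observed dynamic range (hundreds to a million counts), 3' isoMIR length
variants, a planted fold-change on a fraction of miRNAs, a contaminant
read fraction drawn from decoy references, and a fraction of low-quality
reads that the quality filter should remove. Every read's origin is
recorded in its FASTQ id (``|src=<label>``), and per-miRNA expected
proportions are written as a ground-truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import MatureMiRNA, SEED_LENGTH
from .io_preprocess import _open_maybe_gzip

_BASES = np.array(list("ACGT"))

DEFAULT_ISOMIR_OFFSETS = {-2: 0.10, -1: 0.15, 0: 0.50, 1: 0.15, 2: 0.10}


@dataclass(frozen=True)
class SynthSpec:
    """Generator settings; defaults emulate the nymphal two-library design."""

    n_mirnas: int = 60
    abundance_mu: float = 6.0      # natural-log scale
    abundance_sigma: float = 2.0
    de_fraction: float = 0.3
    fold_change: float = 4.0
    isomir_offsets: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ISOMIR_OFFSETS))
    contaminant_fraction: float = 0.05
    lowq_fraction: float = 0.02
    reads_per_library: int = 500_000
    quality_offset: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 2:
            raise ValueError("need at least 2 miRNAs")
        for name in ("de_fraction", "contaminant_fraction", "lowq_fraction"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.fold_change <= 1:
            raise ValueError("fold_change must be > 1")
        if abs(sum(self.isomir_offsets.values()) - 1) > 1e-9:
            raise ValueError("isomir offset probabilities must sum to 1")
        if self.quality_offset not in (33, 64):
            raise ValueError("quality_offset must be 33 or 64")


@dataclass
class GroundTruth:
    """Planted truth: per-miRNA abundances, proportions and directions."""

    table: pd.DataFrame  # index mirna; base_abundance, direction,
    #                      expected_prop_1, expected_prop_2
    contaminant_fraction: float
    lowq_fraction: float
    seed: int

    @property
    def de_names(self) -> list[str]:
        return list(self.table.index[self.table["direction"] != "null"])

    def validate(self) -> None:
        # miRNA mass plus contaminant mass accounts for every clean read
        for col in ("expected_prop_1", "expected_prop_2"):
            total = self.table[col].sum() + self.contaminant_fraction
            if abs(total - 1) > 1e-9:
                raise ValueError(f"{col} + contaminant mass = {total} != 1")


def _has_low_complexity_end(seq: str, run: int = 4, dimer_units: int = 3) -> bool:
    """True when the sequence contains a homopolymer run >= ``run`` or a
    perfect dinucleotide repeat of >= ``dimer_units`` units anywhere.

    Catalog sequences are rejection-sampled against this so that end
    trimming never eats into genuine miRNA reads.
    """
    n = len(seq)
    count = 1
    for i in range(1, n):
        count = count + 1 if seq[i] == seq[i - 1] else 1
        if count >= run:
            return True
    for i in range(n - 2 * dimer_units + 1):
        unit = seq[i:i + 2]
        if unit[0] == unit[1]:
            continue
        if seq[i:i + 2 * dimer_units] == unit * dimer_units:
            return True
    return False


def _random_mature(rng: np.random.Generator) -> str:
    length = int(rng.integers(20, 24))
    return "".join(rng.choice(_BASES, size=length))


def generate_catalog(n: int, seed: int | np.random.Generator = 0,
                     pair_fraction: float = 0.2) -> list[MatureMiRNA]:
    """Random mature-miRNA catalog with pairwise-distinct 17-nt seeds.

    A subset of entries comes as -5p/-3p pairs of the same family name to
    exercise dual-strand accounting; all sequences are 20–23 nt, free of
    low-complexity stretches, and unique within their first 17 nt.
    """
    if n < 2:
        raise ValueError("need at least 2 catalog entries")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    seqs: list[str] = []
    seeds_seen: set[str] = set()
    while len(seqs) < n:
        seq = _random_mature(rng)
        if _has_low_complexity_end(seq):
            continue
        if seq[:SEED_LENGTH] in seeds_seen:
            continue
        seeds_seen.add(seq[:SEED_LENGTH])
        seqs.append(seq)
    n_pairs = int(n * pair_fraction / 2)
    names: list[str] = []
    family = 0
    for _ in range(n_pairs):
        family += 1
        names += [f"mir-s{family}-5p", f"mir-s{family}-3p"]
    while len(names) < n:
        family += 1
        names.append(f"mir-s{family}-5p")
    return [MatureMiRNA(name, seq) for name, seq in zip(names, seqs)]


def simulate_expression(spec: SynthSpec,
                        catalog: Sequence[MatureMiRNA] | None = None,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Draw per-library miRNA counts with planted fold-changes.

    Base abundances are log-normal; a ``de_fraction`` of miRNAs gets the
    fold-change planted (direction random per miRNA, both directions
    present). The planting is mass-balanced: the two direction groups'
    expected proportions are rescaled so that the planted set carries the
    same total mass in both libraries. Null miRNAs therefore keep
    *identical* expected proportions across libraries and every planted
    miRNA realizes its fold-change exactly in expectation — planted
    effects do not leak into the null set through renormalization.
    Counts are multinomial at the clean (non-contaminant) depth.
    Returns (counts_1, counts_2, truth) aligned to catalog order.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if catalog is None:
        catalog = generate_catalog(spec.n_mirnas, rng)
    names = [m.name for m in catalog]
    n = len(catalog)
    fold = spec.fold_change
    base = rng.lognormal(spec.abundance_mu, spec.abundance_sigma, size=n)
    direction = np.array(["null"] * n, dtype=object)
    n_de = int(round(spec.de_fraction * n))
    de_idx = rng.permutation(n)[:n_de]
    if n_de == 1:
        direction[de_idx] = "up_in_1" if rng.random() < 0.5 else "up_in_2"
    elif n_de >= 2:
        # random half/half split keeps both direction groups non-empty
        half = n_de // 2
        direction[de_idx[:half]] = "up_in_1"
        direction[de_idx[half:]] = "up_in_2"

    up1 = direction == "up_in_1"
    up2 = direction == "up_in_2"
    null = ~(up1 | up2)
    p1 = base.astype(float).copy()
    p2 = base.astype(float).copy()
    de_mass = base[up1 | up2].sum()
    if up1.any() and up2.any():
        # allocate the (shared) DE mass so that group totals satisfy
        #   fold*a*A0 + (b/fold)*B0 = a*A0 + b*B0 = de_mass
        a0, b0 = base[up1].sum(), base[up2].sum()
        a = de_mass / ((1 + fold) * a0)
        b = fold * de_mass / ((1 + fold) * b0)
        p2[up1] = base[up1] * a
        p2[up2] = base[up2] * b
        p1[up1] = p2[up1] * fold
        p1[up2] = p2[up2] / fold
    elif up1.any() or up2.any():
        # single planted miRNA: split the fold symmetrically around base
        p1[up1] = base[up1] * np.sqrt(fold)
        p2[up1] = base[up1] / np.sqrt(fold)
        p1[up2] = base[up2] / np.sqrt(fold)
        p2[up2] = base[up2] * np.sqrt(fold)
    total_1, total_2 = p1.sum(), p2.sum()
    if abs(total_1 - total_2) > 1e-6 * total_1:  # single-miRNA fallback only
        p1 /= total_1
        p2 /= total_2
    else:
        p1 /= total_1
        p2 /= total_1

    mirna_mass = 1.0 - spec.contaminant_fraction
    n_clean = int(round(spec.reads_per_library * mirna_mass))
    counts_1 = rng.multinomial(n_clean, p1 / p1.sum())
    counts_2 = rng.multinomial(n_clean, p2 / p2.sum())
    p1 = p1 / p1.sum() * mirna_mass
    p2 = p2 / p2.sum() * mirna_mass

    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "base_abundance": base,
                "direction": direction,
                "expected_prop_1": p1,
                "expected_prop_2": p2,
            },
            index=pd.Index(names, name="mirna"),
        ),
        contaminant_fraction=spec.contaminant_fraction,
        lowq_fraction=spec.lowq_fraction,
        seed=spec.seed,
    )
    truth.validate()
    return counts_1, counts_2, truth


def generate_decoys(rng: np.random.Generator, n_refs: int = 5,
                    length: int = 300) -> list[tuple[str, str]]:
    """Random decoy references standing in for contaminant databases.

    Synthetic stand-ins (no real rRNA/genome data are bundled); reads
    sampled from them are exact substrings, so the substring screen
    removes them completely.
    """
    return [
        (f"decoy{i + 1}", "".join(rng.choice(_BASES, size=length)))
        for i in range(n_refs)
    ]


def _write_fasta(records: Sequence[tuple[str, str]], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


class _FastqWriter:
    """Buffered plain-text FASTQ writer (offset 33 or 64)."""

    def __init__(self, path: Path, offset: int):
        self.handle = _open_maybe_gzip(path, "wt")
        self.offset = offset

    def write(self, read_id: str, seq: str, qual: Sequence[int]) -> None:
        qstr = "".join(chr(q + self.offset) for q in qual)
        self.handle.write(f"@{read_id}\n{seq}\n+\n{qstr}\n")

    def close(self) -> None:
        self.handle.close()


def generate_libraries(spec: SynthSpec, out_dir: str | Path,
                       catalog: Sequence[MatureMiRNA] | None = None,
                       gzip_fastq: bool = False) -> dict[str, Path]:
    """Write two FASTQ libraries plus catalog, decoys and ground truth.

    Each read id carries ``|src=<mirna name|contaminant|lowq>`` so that
    recovery can be scored read by read. Returns the paths written
    (keys: fastq_1, fastq_2, catalog, decoys, ground_truth).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    if catalog is None:
        catalog = generate_catalog(spec.n_mirnas, rng)
    counts_1, counts_2, truth = simulate_expression(spec, catalog, rng)
    decoys = generate_decoys(rng)
    # fixed per-miRNA 3' extension bases keep +1/+2 isoMIRs consistent
    # across reads while never extending a terminal homopolymer
    extension: dict[str, str] = {}
    for m in catalog:
        choices = [b for b in "ACGT" if b != m.seq[-1]]
        extension[m.name] = "".join(rng.choice(choices, size=2))

    offsets = np.array(sorted(spec.isomir_offsets))
    offset_probs = np.array([spec.isomir_offsets[o] for o in offsets])

    suffix = ".fastq.gz" if gzip_fastq else ".fastq"
    paths = {
        "fastq_1": out_dir / f"library_1{suffix}",
        "fastq_2": out_dir / f"library_2{suffix}",
        "catalog": out_dir / "catalog.fasta",
        "decoys": out_dir / "decoys.fasta",
        "ground_truth": out_dir / "ground_truth.tsv",
    }
    _write_fasta([(m.name, m.seq) for m in catalog], paths["catalog"])
    _write_fasta(decoys, paths["decoys"])
    truth.table.to_csv(paths["ground_truth"], sep="\t")

    for lib, counts, fq_path in (
        (1, counts_1, paths["fastq_1"]),
        (2, counts_2, paths["fastq_2"]),
    ):
        writer = _FastqWriter(fq_path, spec.quality_offset)
        # source of each read: miRNA catalog index, or -1 for a contaminant
        sources = np.repeat(np.arange(len(counts)), counts)
        n_cont = spec.reads_per_library - len(sources)
        sources = np.concatenate([sources, np.full(n_cont, -1, dtype=int)])
        rng.shuffle(sources)
        n_reads = len(sources)
        n_lowq = int(round(spec.lowq_fraction * n_reads))
        lowq_flags = np.zeros(n_reads, dtype=bool)
        lowq_flags[rng.choice(n_reads, size=n_lowq, replace=False)] = True
        iso_draw = rng.choice(len(offsets), size=n_reads, p=offset_probs)
        for read_no, (idx, is_lowq) in enumerate(zip(sources, lowq_flags)):
            if idx >= 0:
                m = catalog[idx]
                off = int(offsets[iso_draw[read_no]])
                seq = m.seq[:len(m.seq) + off] if off <= 0 else \
                    m.seq + extension[m.name][:off]
                src = m.name
            else:
                ref = decoys[int(rng.integers(len(decoys)))][1]
                length = int(rng.integers(15, 29))
                start = int(rng.integers(0, len(ref) - length + 1))
                seq = ref[start:start + length]
                src = "contaminant"
            if is_lowq:
                src = "lowq"
                n_low = int(np.ceil(0.9 * len(seq)))
                qual = np.concatenate([
                    rng.integers(2, 20, size=n_low),
                    rng.integers(25, 41, size=len(seq) - n_low),
                ])
                rng.shuffle(qual)
            else:
                qual = rng.integers(25, 41, size=len(seq))
            writer.write(f"L{lib}r{read_no}|src={src}", seq,
                         [int(q) for q in qual])
        writer.close()
    return paths
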