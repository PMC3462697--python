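# Methods

This note documents the models and procedures implemented in `mirdiff`,
the parameter choices that matter, and what the synthetic benchmark does
and does not show. It describes only behaviour that the test suite and
`scripts/acceptance.py` actually compute.

## Read preprocessing

Reads are expected adapter-trimmed. Four stages run in fixed order:
quality filter → end trimming → collapsing → length filter.

**Quality filter.** A read is eliminated when the fraction of positions
with Phred quality below `q_min` (default 20) is at least `bad_fraction`
(default 0.8). The boundary is inclusive: a read with exactly 80% of its
bases below Q20 is removed. `N` bases count as low-quality regardless of
their score. Qualities are decoded at offset 64 by default (classic
Illumina encoding, scores 0–40); offset 33 is a flag away, and a decoded
score outside 0–40 raises an error suggesting the other offset, since a
wrong offset is almost always the cause.

**End trimming.** The description "remove repetitive nucleotides, short
motifs and low-quality regions at either end" is operationalised as three
end-anchored rules applied iteratively to both ends until stable:
(a) terminal bases below `q_min`; (b) terminal homopolymer runs of
≥ `homopolymer_min` bases (default 5); (c) terminal perfect dinucleotide
repeats of ≥ `dimer_units_min` units (default 3). Interior bases are never
touched, so the result is a contiguous substring of the input and the
operation is idempotent (both property-tested). The thresholds are
declared defaults, not values inferred from data; all are configurable.

**Collapsing and length filter.** Identical sequences are merged into
(sequence, count) pairs — counts are conserved exactly — and sequences of
10–28 nt (inclusive) are kept, the small-RNA size window. Collapsed output
is ordered by descending count with lexicographic tie-breaks so repeated
runs are byte-identical.

## Annotation

**Contaminant screen.** References (stand-ins for rRNA/repeat databases,
endosymbiont and viral genomes, *E. coli*) are indexed by enumerating all
substrings in the 10–28 nt query band, on both strands by default. A clean
sequence is removed iff it occurs exactly. This replaces an alignment step
whose parameters were not part of the original description; exact matching
is the conservative reading.

**Seed matching.** The seed is the **first 17 nt of the mature sequence**
(note: this is the whole-read anchor used for assignment, not the 2–8 nt
targeting seed of miRNA biology). A read of ≥ 17 nt matches iff its first
17 nt equal the seed with zero mismatches; bases beyond the seed are not
checked, which is what tolerates 3′ isoMIR variation. Reads shorter than
17 nt must equal the same-length seed prefix exactly. Matching is
case-insensitive, U ≡ T, and `N` never matches. Reads are 5′-anchored
(read position 1 = mature position 1) because a fixed 5′ anchor is what
makes a "first 17 nt" seed well-defined; `max_5p_offset` optionally allows
reads starting inside the mature sequence. Catalog entries shorter than
17 nt cannot carry a seed and are rejected with a warning.

**isoMIR merging and ambiguity.** All variants matching one miRNA are
summed into a single count; the per-variant breakdown is kept for the
effective-length calculation. A read matching several catalog entries
(identical seeds) is discarded and logged by default — counting it toward
all or toward the first entry are available policies — so counts are never
created: assigned + unassigned + ambiguous always equals the input total
(property-tested).

**Low-abundance pool.** miRNAs are sorted by ascending total count across
both libraries and the longest prefix whose *cumulative* count stays
within `pool_fraction` (default 1e-4) of the total raw reads is dropped —
the dropped miRNAs together represent ≤ 0.01% of reads. A per-miRNA
variant (each share < 0.01%) is also implemented; the cumulative rule is
the default because several retained rows of the reference table sit below
a per-miRNA 0.01% of clean reads. The dropped prefix is always proper
(the filter never empties the profile), and the kept set is common to both
libraries.

## Quantification

RPKM is `count × 1e9 / (effective_length_nt × library_total)`. Two
choices deserve justification:

* **Library total = raw sequencing depth** (not clean reads). Back-solving
  `L = 1e9·c/(RPKM·N)` from the bundled reference table yields miRNA-sized
  lengths (~17–21 nt) only under the raw totals (38,399,972 and
  23,689,204); under clean totals the implied lengths are off by ~17×.
  The clean-total mode remains available.
* **Effective length = count-weighted mean isoMIR length**, consistent
  with the ~18–19 nt back-solved values (mature-sequence length is the
  alternative mode, and the fallback for a miRNA absent from one library).

Three reference rows are numerically inconsistent with this normalization:
miR-275-3p in N5 (implied length 8.8 nt, flagged as a probable typo and
excluded from consistency checks) and, marginally, miR-2-3p (14.4 nt) and
miR-184-3p (16.65 nt) in N5; N6 has one marginal row (miR-276-5p,
21.5 nt). The tests pin these outlier sets exactly.

The pairwise contrast per miRNA is `M = log2(x1/x2)` and `D = |x1 − x2|`
on RPKM values. Zeros are replaced **only inside the ratio** by a
pseudo-expression equivalent to 0.5 counts (converted to RPKM with the
miRNA's own scale factor); D uses the raw values. This keeps M finite
without disturbing D. M is antisymmetric and D symmetric under swapping
libraries (property-tested). Reported precision follows the reference
tables: M to 3 decimals, D to 2, RPKM to 3.

## Differential expression without replicates

With one library per condition there is no dispersion to estimate, so
technical replicates are simulated and pure resampling noise serves as the
null reference:

1. For each library, `nss` replicates (default 5) are drawn from a
   multinomial over the library's count proportions with size
   `round(depth_r × Σcounts)`, `depth_r` uniform in `[pnr − v, pnr + v]`
   (defaults `pnr = 0.2`, `v = 0.02`). The defaults are the published
   defaults of the simulated-replicate method this stage reimplements.
2. Simulated counts are mapped to the observed RPKM scale with each
   miRNA's observed RPKM/count ratio, depth-corrected, so the expectation
   of a simulated RPKM equals the observed RPKM. Features observed at zero
   fall back to the median per-count factor.
3. Every within-condition pair of replicates contributes one (|M|, D)
   point per miRNA; both conditions are pooled into one noise cloud of
   `n_features × 2 × C(nss, 2)` points (pooling is a design choice; a
   one-condition cloud is easily obtained from the building blocks).
4. `P(DE) = fraction of noise points (m, d) with m < |M_obs| and
   d < D_obs` — strict on both coordinates, so ties favour "not DE".
   Calls require `P > threshold` (default 0.8), the sign of M giving the
   direction.

P is an empirical exceedance probability against simulated technical
noise, **not a p-value**; no multiple-testing correction applies. It is
monotone in |M| and D and invariant under common rescaling of all RPKM
values (both property-tested). The probability is the only quantity that
depends on the simulation seed; M and D are deterministic. On the bundled
reference table the stage calls exactly the three expected miRNAs up in
N5 on every seed tried, and 37–41 (median 39 over seeds) up in N6 —
the published direction split up to a few borderline P ≈ 0.8 calls,
consistent with the published borderline probabilities (0.813–0.852).

## Synthetic data generator

The generator emulates the statistical structure of the reference
experiment: 60 miRNAs (a subset as -5p/-3p pairs), log-normal base
abundances (μ = 6, σ = 2 on the natural-log scale, spanning roughly
1e2–1e6 counts like the reference table), 30% of miRNAs with a planted
4-fold change, 3′ isoMIR length offsets in {−2…+2} (probabilities
0.1/0.15/0.5/0.15/0.1), 5% contaminant reads drawn as exact substrings of
random decoy references, 2% low-quality reads (≥ 80% sub-Q20 bases), and
500,000 reads per library written as FASTQ at offset 64. Every read id
carries its source label, and per-miRNA expected proportions are written
as a ground-truth table.

**Mass-balanced planting.** Planted fold-changes are applied so that the
planted set carries the same total expected mass in both libraries (the
two direction groups are rescaled accordingly). Null miRNAs therefore
keep *identical* expected proportions in both libraries, and every planted
miRNA realizes its fold-change exactly in expectation. Without this, the
planted changes would shift the whole composition — with a log-normal
σ = 2 the most abundant miRNA can carry half the library — and null
miRNAs would acquire real proportion differences, confounding
false-discovery measurement. This is a property of the benchmark design,
not of the inference.

**Catalog construction.** Mature sequences (20–23 nt) are
rejection-sampled to have pairwise-distinct 17-nt seeds and no
low-complexity stretches (homopolymer ≥ 4, dinucleotide repeat ≥ 3 units),
so end-trimming never eats genuine miRNA reads and every isoMIR variant
(≥ 18 nt) maps unambiguously. Only 3′ isoMIR variation is generated —
5′ variation would violate the seed anchor by construction and is the
annotation-loss scenario, not the recovery scenario.

**What passing tests show — and don't.** The generator covers multinomial
sampling noise, isoMIR structure, contaminants and quality artifacts. It
does not model sequencing errors inside reads, PCR duplication, adapter
remnants, true 5′ heterogeneity, or biological replicate variance — so
recovery results bound what the pipeline does under its own assumptions,
not its robustness to violations of them.

**Recovery benchmark.** The planted-DE recovery tests run at ~2.2 million
clean reads per library — the depth of the reference libraries, which is
the regime the DE stage is meant for — over 20 fixed seeds: pooled
sensitivity ≥ 0.9 and false-discovery proportion ≤ 0.1 at the 0.8
threshold. The planted 4-fold is recovered within [3, 5.33] in RPKM ratio
for miRNAs with ≥ 400 counts in the lower library; that window is a
3-standard-error binomial bound (`3·√(1/c1+1/c2) ≤ log(4/3)`), so
poorly-covered miRNAs legitimately fall outside it by sampling error
alone. Sensitivity is abundance-dependent by construction: a weakly
expressed miRNA has a small D and cannot dominate noise points from
abundant features, which mirrors the method's behaviour on real data
(the smallest published D among DE calls sits right at a borderline
probability).

## Numerical and degenerate-input choices

* Ties in `de_probability` are excluded (strict dominance): conservative.
* A simulated replicate with zero depth, an empty noise cloud, an empty
  catalog, all-zero counts, or a non-positive length/total raise
  immediately with the offending quantity named.
* The volcano plot draws D on a log axis (D spans ~5 orders of magnitude)
  with values floored at 1e-2; the floor is stated on the axis label.
* All tables are TSV with '.' decimals; re-reading a written table
  reproduces the in-memory values at the printed precision, and repeated
  runs with the same seed are byte-identical.
* RNG: a single `numpy.random.Generator` per estimator/run, seeded from
  `random_state` (or the pipeline `seed`); the manifest records the seed.

## Known limitations

* The seed-match annotation cannot separate miRNAs sharing their first
  17 nt (discarded as ambiguous by default) and ignores 5′ isoforms
  unless `max_5p_offset` is raised.
* The DE probability depends on the full feature set through the pooled
  noise cloud: adding or removing features changes probabilities for all.
* Exact-substring contaminant screening does not emulate mismatch-tolerant
  alignment against real databases; it is exact by design.
* With the probability threshold at 0.8 and simulated technical noise as
  the only null, calls are anti-conservative relative to a replicated
  design — the original method's known trade-off, reproduced faithfully.
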