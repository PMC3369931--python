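# Methods

This document describes the scoring models, algorithms and parameter
choices implemented in `antarscan`, and the reasoning behind the
non-obvious ones.

## 1. The dual stem-loop motif model

### Topology

The motif is modelled with a fixed secondary-structure topology: two
hairpins (P1, P2) joined by a single-stranded linker. Each hairpin has a
stem of 3–8 contiguous base pairs enclosing an exactly 6-nt loop. The
seed alignment encodes this topology in its `SS_cons` line (`<`/`>` for
stem 1, `(`/`)` for stem 2, `.` elsewhere); the training code derives
the paired columns, loop columns and linker columns from bracket
matching, and rejects alignments whose structure line is unbalanced,
non-contiguous, or missing either stem.

### Emission and pairing distributions

From the seed alignment the trainer estimates, with Laplace smoothing
(pseudocount 0.5 by default):

- **Loop emissions** — a per-position nucleotide distribution for each of
  the six columns of each loop:
  `P(x) = (count(x) + pc) / (total + 4·pc)`.
- **Stem pair distributions** — a joint 16-state distribution over
  ordered base pairs for each aligned stem depth:
  `P(a,b) = (count(a,b) + pc) / (total + 16·pc)`, outermost pair first.
  Because a scan may place stems deeper than the alignment's 3 aligned
  pair columns, pair counts are also pooled into a single *generic pair
  distribution* used for any stem depth beyond the aligned ones; the
  aligned depths map inner-aligned (the innermost aligned pair scores
  the innermost placed pair), since the closing pair is the conserved
  one.
- **Linker lengths** — the empirical distribution of realised
  (ungapped) linker lengths across seed rows.

### Log-odds scoring

A candidate placement is scored in bits against a background model:

```
score = Σ_loops Σ_pos log2 P(x_pos) / Q(x_pos)
      + Σ_stems Σ_depth log2 P(a,b) / (Q(a)·Q(b))
      + log2( P(linker_len) · W )
```

where `Q` is the background nucleotide distribution and `W` the number
of allowed linker lengths, so the linker term compares the observed
length distribution against a uniform choice among allowed lengths.
Background `Q` comes from the scanned sequence's own composition by
default (`background="sequence"`); `"uniform"` and `"model"` (training
composition) are also available. Uniform background with flat
distributions yields a score of exactly 0, which anchors the bit scale.

### Candidate enumeration

`enumerate_candidates` lists every structurally legal placement: both
stems formed of contiguous Watson-Crick (optionally G-U wobble) pairs of
depth 3 up to 8, loops exactly 6 nt, and a linker within the model's
bounds. Windows containing non-ACGT characters are skipped. The scanner
scores all candidates on both strands, applies the 10-bit reporting
cutoff, and greedily deduplicates overlapping placements per strand,
keeping the highest-scoring registration.

### Linker bounds

The enumeration bounds for the linker are the range realised in the
seed alignment (5–12 nt). Widening the window beyond the observed range
is counterproductive rather than merely permissive: an out-of-range
linker can often "donate" stem pairs to re-register as an in-range
placement with deeper stems, so looser bounds mostly add shifted
duplicates of the same physical element while admitting spurious
placements elsewhere. The bounds are configurable (`linker_min`,
`linker_max`) for substrate families with different geometry.

## 2. Intrinsic terminator screen

A terminator is a hairpin followed by a uridine run. The screen is a
deterministic additive one:

- **Hairpin**: stems of 4–20 pairs scored per pair — G-C 3, A-U 2, G-U
  wobble 1, mismatch −2 — with at most 1 mismatch and a minimum hairpin
  score of 8. Loops may be 3–26 nt; the unusually large cap exists
  because antiterminator-coupled terminators can hold the upstream
  element's arm inside their loop.
- **U-tract**: the 12 nt downstream of the hairpin score
  `Σ 0.9^i · [x_i = U]`, so uridines closest to the hairpin matter most;
  minimum 3.0.

Enumeration is U-tract-first: candidate hairpin end positions are
prefiltered by tail score before stems and loops are enumerated, which
makes whole-genome screening fast without changing the result (verified
against brute force). Overlapping placements are deduplicated greedily
per strand by total score; per-strand deduplication matters because an
antisense structure must never displace a sense terminator that a
sense-strand motif needs to couple to.

## 3. Attenuation classification

Hits are classified against a GFF3 annotation, deterministically and
independently of input order:

1. **discarded** — the hit overlaps a CDS (`in_coding_region`).
2. **attenuator** — a same-strand terminator's transcript-5' arm shares
   at least 1 nt with the hit's P2 footprint and the hairpin begins
   downstream of loop 1 in transcript orientation. Ties break by shared
   length, then terminator score.
3. **translational candidate** — the hit covers a Shine-Dalgarno-like
   match (≥4 consecutive nt of AGGAGG, 4–16 nt upstream of the
   downstream same-strand gene start). This codifies what is otherwise
   a manual-inspection judgement; the match length and spacing window
   are stated, configurable defaults.
4. **orphan** — everything else above the cutoff.

`extract_scan_regions` restricts scanning to intergenic intervals, which
is equivalent to the in-coding discard but cheaper; the classifier also
applies the discard rule directly so whole-genome scans classify
identically.

## 4. Synthetic fixtures

`generate_genome` builds screened genomes that guarantee their own truth
tables. Elements (true motifs with optional terminator coupling, four
decoy classes, in-CDS motifs) are first drawn until each is *self-clean*
in isolation (padded with non-pairing A runs, it produces exactly its
expected hits and nothing else). Elements are then placed into
intergenic regions with ≥15-nt spacing (wider than any linker window, so
neighbouring elements cannot couple into a chance motif), and every
background region is rejection-resampled — deterministically, from
integer seeds derived from the master seed — until a reference scan of
the assembled genome shows (i) no hit anywhere outside the embedded
motif spans at a threshold one bit *below* the reporting cutoff, (ii) a
sense-strand hit at or above the cutoff over every embedded motif, and
(iii) a linkable terminator for every motif-terminator couple. The
generator raises rather than silently emitting a genome that violates
its truth table.

The embedded terminators reuse the motif's P2 3' arm as the hairpin 5'
arm (the mutual-exclusivity geometry), extend it with A/U pairs that
cannot cross-pair with the G/C-rich motif stems, and use an odd
(5-nt) terminal loop so partial unpairing can never present a 6-nt
pseudo-loop to the motif scanner.

The mutant panel (`mutant_series`) derives named variants from a
synthetic leader: hairpin deletion, stem breaks, out-of-range linkers,
conserved-loop point mutations, a compensatory stem restoration, and a
pairing-preserving closing-pair sequence swap. Expected qualitative
outcomes are recorded in `MUTANT_EXPECTATIONS`. One subtlety: a stem
disruption of outer pairs can leave a shifted registration alive, so its
expectation is "hit with lower score" rather than "no placement".

## 5. Binding isotherms

The single-site model is `f(c) = c / (Kd + c)`, so `f = 0.5` at
`c = Kd`. `fit_kd` performs unweighted nonlinear least squares in
`log10(Kd)` space, which enforces positivity and makes the fit
scale-invariant; the standard error of Kd is propagated from the
log-space covariance by the delta method
(`SE(Kd) = ln(10) · Kd · SE(log10 Kd)`). Fits require at least 4 points
spanning both sides of half-saturation. A Hill coefficient can be
co-fitted on request (default fixed at n = 1). `simulate_isotherm`
produces titrations with multiplicative Gaussian noise clipped to
[0, 1], reproducible per seed.

## 6. Numerical and interface conventions

- All genomic coordinates are 0-based half-open on the forward strand
  internally; GFF3 I/O converts to/from 1-based inclusive at the file
  boundary. Minus-strand features keep forward-strand spans.
- Sequences are DNA internally (`U → T` on input); loop sequences are
  reported as RNA.
- Scores are written with `%.17g` so TSV round trips are exact.
- All randomness flows through `numpy.random.default_rng` with explicit
  integer seeds; derived streams use seed sequences
  (`default_rng([seed, index, attempt])`) so regions resample
  independently and reproducibly.

## 7. Limitations

- The motif model has a fixed topology (exact 6-nt loops, contiguous
  stems); bulged stems or non-canonical loop lengths are not scored.
- The terminator screen is a filter, not a thermodynamic folder; scores
  are not free energies.
- Shine-Dalgarno detection is a stated heuristic, not a model of
  initiation strength.
- Classification depends on annotation completeness: missing CDS
  features inflate orphans, and the degraded scan-only mode performs no
  classification at all.
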