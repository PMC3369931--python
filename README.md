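# antarscan

Discovery of ANTAR-protein RNA substrates in bacterial genomes: a
probabilistic scanner for the dual stem-loop antiterminator motif, a
rho-independent terminator screen, and a classifier that joins the two
into transcription-attenuation calls. A synthetic-fixture generator and a
single-site binding-isotherm fitter round out the toolkit so that every
stage can be exercised end to end without external data.

## What it does

ANTAR-domain response regulators bind a conserved RNA element in the 5'
leader of their target transcripts: two short hairpins (P1 and P2), each
presenting a hexanucleotide loop with a conserved adenine at loop
position 1 and guanine at position 4, separated by a flexible linker.
When the second hairpin overlaps the 5' arm of an intrinsic terminator,
the two structures are mutually exclusive, and protein binding to the
dual stem-loop element prevents terminator formation — transcription
antitermination.

`antarscan` implements that logic as a pipeline:

1. **Train** a fixed-topology log-odds model from a structured seed
   alignment (Stockholm with a `SS_cons` line marking both stems).
2. **Scan** genome sequences on both strands for placements of the dual
   stem-loop element, enumerating every structurally legal registration
   (contiguous stems of at least 3 bp, exact 6-nt loops, linker lengths
   within the range observed in the seed) and reporting those at or
   above a 10-bit log-odds cutoff.
3. **Predict terminators** — GC-rich hairpins followed by a uridine run —
   with an additive pair score and a geometrically weighted U-tract
   score. The terminal loop may reach 26 nt, because
   antiterminator-coupled terminators can carry the upstream element's
   arm inside their loop.
4. **Classify** each motif hit against a GFF3 annotation: *attenuator*
   (P2 overlaps the 5' arm of a same-strand downstream terminator),
   *translational candidate* (the hit covers the downstream gene's
   Shine-Dalgarno sequence), *orphan*, or *discarded* (inside a coding
   region).
5. **Fit dissociation constants** from fractional-saturation titrations
   under the single-site model `f(c) = c / (Kd + c)`.

See `docs/methods.md` for scoring details and parameter rationale.

## Command-line usage

```sh
# build a synthetic fixture bundle (genome, annotation, truth table, seed)
antarscan simulate fixtures/ --seed 7

# train a model from the seed alignment
antarscan train fixtures/seed_alignment.sto -o model.json

# scan a genome
antarscan scan fixtures/genome.fasta -m model.json -o hits.tsv

# predict terminators
antarscan terminators fixtures/genome.fasta -o terminators.tsv

# full chain: scan, terminators, classification, summary
antarscan run fixtures/genome.fasta \
    -a fixtures/annotation.gff3 \
    -s fixtures/seed_alignment.sto \
    -o results/

# fit a Kd from a titration table (TSV: concentration, fraction_bound)
antarscan fit-kd titration.tsv
```

`run` writes `hits.gff3`, `classified.tsv`, `summary.json`,
`config_used.yaml` and `run.log` (plus `model.json` when training from a
seed alignment, and `correlation.tsv` when a per-genome ANTAR-presence
table is supplied via `--presence`). Omitting `-a` runs a scan-only
degraded mode in which hits are reported unclassified.

All thresholds and parameters can be set in a YAML config file
(`--config`); see `antarscan.config.PipelineConfig` for the full key list
and defaults. Exit codes: 0 success, 1 input/format/configuration error,
2 usage error.

## Library usage

```python
from antarscan.motif import train_model, scan_sequence
from antarscan.terminator import find_terminators
from antarscan.classify import classify_hits
from antarscan.simulate import packaged_seed_alignment
from antarscan.io import read_fasta, read_gff3

model = train_model(packaged_seed_alignment())
genome = read_fasta("genome.fasta")[0]
features = read_gff3("annotation.gff3")
hits = scan_sequence(model, genome)
calls = classify_hits(hits, find_terminators(genome), features, genome)
```

Coordinates are 0-based half-open on the forward strand throughout the
library; GFF3 output converts to 1-based inclusive at the file boundary.
Sequences are held as DNA internally; loop sequences are reported as RNA.

## Reproducibility

Every stochastic component (seed-alignment generation, fixture genomes,
titration noise) is driven by explicit integer seeds and is deterministic
per seed. `scripts/acceptance.py --seed N --out report.json` runs the
self-contained acceptance targets and writes a JSON report.

## Testing

```sh
python -m pytest -q tests/
```

The suite covers unit oracles (hand-computed scores, bracket-matching,
coordinate conversions), property tests against independent brute-force
enumerators for both the motif scanner and the terminator finder, the
mutant-panel ordering, and an end-to-end synthetic-genome round trip
checked against its truth table.
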