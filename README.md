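# gstack

Sequence-bias diagnosis and calibration for short-oligonucleotide expression
arrays. `gstack` quantifies how short sequence motifs (1–4 adjacent bases) at
every position of a 25-mer probe modulate its intensity, diagnoses
motif-specific lack of fit, and removes the biases — in particular the strong
poly-G / (GGG)₁ intensity spike of probes whose sequence starts with three
guanines — with a hybrid-rank NN+GGG correction applied at the probe-intensity
level, before any standard preprocessing.

## What it does

- **chip_io** — reads/writes Affymetrix-style probe-tab annotation, ASCII CEL
  v3 and plain TSV intensity files; assembles an in-memory chip model; pairs
  PM probes with their MM partners (complemented middle base, position 13).
- **hybridization** — two-species Langmuir intensity model
  `I = I_min + L/(1 + L/I_max)` with exact linearization, MAS5-like zone
  background (lowest 2% per zone), absent/present calling (Gaussian-mixture
  stand-in or an override calls file), and empirical/theoretical hybridization
  isotherms (scenarios A/B/C).
- **sensitivity** — positional motif models of rank 1–4 (N, NN, NNN, NNNN):
  probe-set-centered experimental sensitivities, sparse centered design
  matrices, deterministic minimum-norm least-squares fits, integral
  sensitivities over position ranges, and affine profile-shape similarity.
- **diagnostics** — parameter counts, nested-model F values, motif- and
  position-resolved SSR / quality-of-fit (systematic bias) / standard error
  tables, the Δσ(GGG) summary, and log-increment → intensity-fold conversion.
- **correction** — the NN+GGG hybrid-rank pipeline: split absent sets into
  GGG-free and GGG-containing sub-ensembles, fit the basal rank-2 profile on
  the former, per-position GGG excess terms on the latter, correct absent and
  present probes (specific-side profile / weighted combination), and export
  corrected intensities as CEL/TSV.
- **synthetic** — fully specified synthetic chips with known generating
  profiles, Langmuir intensities, log-normal concentrations, injectable GGG
  excess, and bit-reproducible seeding — the ground-truth surface all tests
  run against (no downloads needed).

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (parameter counts,
fold conversions, exact-model recovery, (GGG)₁ bias removal with ablation
ordering, SSR decomposition identities, dense-solver equivalence, isotherm
scenario contracts, F-value pattern).

## CLI

```sh
gstack simulate --n-sets 1000 --seed 3 --out-dir sim/
gstack fit      --probes sim/probes.tab --cel sim/chip.cel --rank 2 --out profile.tsv
gstack diag     --probes sim/probes.tab --cel sim/chip.cel --rank 2 \
                --motif-length 3 --stat qf --out qf.tsv
gstack isotherm --probes sim/probes.tab --cel sim/chip.cel \
                --expression expr.tsv --subset ggg1 --window 1000 --out iso.tsv
gstack correct  --probes sim/probes.tab --cel sim/chip.cel \
                --calls sim/calls.tsv --model nn+ggg --out corrected.cel
gstack io convert --in chip.cel --out chip.tsv --informat cel_ascii --outformat tsv
```

Every run writes a `manifest.json` (resolved config, package version, input
SHA-256 checksums); identical inputs and flags give byte-identical outputs.

### Formats

- **Probe table**: tab-separated with header columns `Probe Set Name`,
  `Probe X`, `Probe Y`, `Probe Sequence` (optional `Probe Type` PM/MM and
  `Pair Id`). Coordinates are 0-based, x = column, y = row; position k = 1 of a
  sequence is the solution end.
- **Intensities**: ASCII CEL v3 (`[CEL]`/`[HEADER]`/`[INTENSITY]` sections,
  MEAN column) or TSV (`x`, `y`, `intensity`). Binary CEL is rejected.
- **Calls override**: TSV `probe_set_id`, `call` ∈ {A, P}.

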