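# urocpm

A 2D Cellular Potts (Glazier–Graner–Hogeweg) simulation of the healthy human
urothelium. The package simulates tissue regeneration and homeostasis on a
640×120 lattice (800 μm × 150 μm at 0.8 px/μm) under 16 alternative
proliferation/differentiation lineage models, scores snapshots with
arrangement/volume fitness functions, and classifies whole-run tissue
development.

## Model summary

* **Engine** — Metropolis pixel-copy dynamics minimising
  `E = EV + ES + λA·EA` (volume, surface and differential-adhesion terms),
  2nd-order (Moore) neighbourhood, periodic x boundary, frozen basal
  membrane, 500 MCS per simulated day. The inner loop is numba-compiled.
* **Lineage models** — the triple `<SSD|SPA>/<BPA|BCD|BPCD|BSD>/<ICD|IPCD>`
  selects a progenitor, basal and intermediate rule (2·4·2 = 16 models):
  stem-like asymmetric division, population asymmetry
  (0.05/0.9/0.05 symmetric-renewal/asymmetric/symmetric-differentiation),
  symmetric proliferation, and contact-driven differentiation
  (basal→intermediate on loss of basal-membrane contact,
  intermediate→umbrella on contact with the medium). Differentiation is
  strictly one-way along P→B→I→U.
* **Biology schedule** — growth with ×50 contact-inhibition release for
  cells not completely surrounded, mitosis at the type's maximal volume,
  apoptosis per type (0.1–180 ×10⁻⁶/day), and voiding every 6 h washing out
  2% of the cells in contact with the lumen.
* **Fitness** — column-wise arrangement score over 31 windows spaced 25 μm
  apart (layer order B/P → I layers → U, 3–7 stacked cells), a volume score
  per cell group against 10%/67%/23% of an 85 μm reference thickness, and
  their pointwise mean, time-averaged over a run.
* **Classification** — stable / chaotic / linear growth / exponential
  growth / atrophy from the cell-count and fitness series.
* **Experiment layer** — seeded replicate batches, run summaries (median /
  span / quartiles of the time-averaged fitness, healing time, steady
  state), box-plot and table reports.
* **Fixtures** — synthetic layered lattices and count series with known
  ground truth, used heavily by the test-suite and exposed on the CLI.

Initial condition: a damaged urothelium — bare basal membrane with ~12% of
columns covered by progenitor cells.

## CLI

```bash
urocpm run --model SPA/BPCD/ICD --days 720 --seed 7 --out runs/spa-bpcd-icd
urocpm batch --models all --n 25 --days 720 --out runs/batch
urocpm summarize runs/batch
urocpm score --labels snap_labels.csv --cells snap_cells.csv
urocpm classify --series runs/spa-bpcd-icd/series_seed7.csv
urocpm init --seed 1 --out runs/init
urocpm fixtures --kind ideal --out fixtures/
```

Runs write a per-sample CSV series (`day, n_P, n_B, n_I, n_U, total_cells,
fA, fV, f, covered`) and optional snapshots (lossless label CSV + cell
table CSV + type-map PNG).

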