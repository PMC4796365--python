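# micropassage

Quantification of single-cell migration through micro-fabricated
constrictions, for labs studying how the nucleus limits confined
migration of fast amoeboid cells (dendritic cells and other leukocytes).
The package turns two-channel fluorescence time-lapse movies — an actin
reporter (e.g. LifeAct) and a DNA stain (e.g. Hoechst) — into the
standard readouts of the assay:

- **Passage events**: the four transit phases (cell entry, nuclear entry,
  nuclear exit, cell exit), the outcome partition
  passed / reversed / censored, and the percentage of passage
  = passed / encountered (censored excluded from both sides).
- **Kinematics**: mask-centroid velocities and the normalized velocity
  variation (v − v̄_pre)/v̄_pre, where v̄_pre is the mean cell velocity
  before the nucleus touched the constriction.
- **Perinuclear actin enrichment**: the mean actin intensity in the cell
  cortex mask (dilate-1 minus erode-6 of the cell mask) restricted to the
  nucleus' axial span, normalized by the whole-cell mean; a baseline +
  2 s.d. criterion (absolute floor 1.2) scores each transit as
  accumulating actin around the nucleus or not. The same machinery
  quantifies actin around internalized rigid beads.
- **Nuclear shape**: circularity 4πA/P² with a sub-pixel
  marching-squares perimeter, and the per-column DNA-thickness /
  cortex-actin relation with its least-squares fit.
- **Lamina rupture morphometry** on fixed-cell stills: 360-bin angular
  intensity profiles of the perinuclear lamina ring, gap detection
  (below α·median over ≥ θ_min degrees), rupture arc-length perimeter,
  and leading-pole (tip) localization.
- **Statistics**: exact two-sided Fisher and Mann–Whitney tests
  implemented from first principles, plus mean ± s.e.m. summaries.

Because the source experiments deposit no raw data, the package also
ships a **calibrated synthetic-movie generator** (`micropassage.synthgen`)
that renders single-cell transits with full ground truth: truncated-normal
free speeds (cohort mean 4.48, s.d. 3.93 µm/min), width-dependent passage
probabilities (4% at 1 µm, 40% at 1.5 µm, 78% at ≥ 3 µm), a 41% velocity
drop during nuclear transit, perinuclear-ring probabilities of 0.93 for
passers vs 0.25 for engaged non-passers, lamina-rupture frequencies of
87/43/7% by condition with 97% tip localization, and peribead actin
accumulation in 85% of width-matched bead transits — all behind
PSF blur and Poisson + Gaussian camera noise. Every stage of the
measurement chain is validated by recovering these encoded statistics
blind. See `docs/methods.md` for the full model.

## Worked example

Simulate a small cohort at a 1.5-µm constriction and run the full
pipeline (segmentation → tracking → events → summary):

```python
from micropassage import run_pipeline

summary = run_pipeline({
    "condition": "W1.5",
    "simulate": {"n_cells": 8, "seed": 42, "constriction_width_um": 1.5},
}, output_dir="demo_out")
```

which writes `events.csv`, `tracks.csv`, `summary.json` and
`manifest.json` (every row carries cell id, condition and config hash),
and returns:

```json
{
  "condition": "W1.5",
  "n_analyzed": 8,
  "passage": {
    "n_encountered": 7,
    "n_passed": 3,
    "n_reversed": 4,
    "n_censored": 1,
    "percent_passage": 42.86,
    "cell_passage_time_min": {"mean": 12.67, "sem": 5.93, "n": 3},
    "nuc_passage_time_min":  {"mean": 8.67,  "sem": 3.71, "n": 3},
    "non_passage_time_min":  {"mean": 10.0,  "sem": 1.41, "n": 4}
  }
}
```

Of the 7 cells whose fate was observed, 3 passed (43%, consistent with
the encoded 40% rate at this width at n = 7), taking on average 12.7 min
from front entry to back exit; the 4 reversing cells dwelt 10 min in the
constriction before turning; one cell was still engaged when the movie
ended and is excluded from the percentage. The same interface analyses
real movies: read them with `micropassage.read_movie` (multi-page TIFF +
JSON sidecar with the channel map, pixel size and frame interval) and
pass them to `micropassage.analyze_movie` with your device's
`ChannelGeometry`.

A command-line surface mirrors the library:

```bash
micropassage simulate --config cfg.json --out movies/
micropassage track movie.tif --geometry device.json --out track.csv
micropassage events movie.tif --geometry device.json
micropassage stats --fisher 35 5 12 28
micropassage run --config cfg.json --out results/
```

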