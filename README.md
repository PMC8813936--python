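# cyclim

**Cyclic immunofluorescence imaging, from raw exposure series to
single-cell statistics.**

Cyclic staining–imaging–erasure microscopy images hundreds of protein
markers on one specimen by repeating rounds of antibody staining, widefield
acquisition, and signal erasure (photobleaching or label release). Turning
the raw frames into trustworthy per-cell measurements takes a chain of
corrections — exposure fusion, flatfielding, defective-pixel repair,
registration across cycles, spectral unmixing, pre-stain subtraction — and
a cytometry layer that segments objects, subtracts an interpolated
background, and compares populations. `cyclim` implements this chain as a
tested Python library plus CLI, together with a ground-truth simulator so
every stage can be validated without instrument data. It is aimed at
people building or auditing multiplexed-imaging pipelines and at anyone
who wants the image-cytometry recipes (local-median masks, grid-median
backgrounds, arcsinh normalization, separation statistics) as reusable,
specified components.

## The model in brief

A camera frame at exposure *t* records
`counts = offset + gain·t·flatfield·rate + N(0, σ)` clipped at saturation.
An exposure series is fused into a high-dynamic-range rate estimate by
per-pixel inverse-variance weighting with saturated frames excluded
(weights ∝ t² under the read-noise model). Channel crosstalk is linear and
inverted with a calibrated matrix; residual autofluorescence and
incomplete erasure are removed by subtracting the pre-stain image.

Cytometry statistics follow standard practice for stain-titration
benchmarks. Integrated intensities *I* are mapped to
`y = arcsinh(aI − b)/ln 10` — asymptotically log₁₀ but defined for the
negative values honest background subtraction produces — with *a*, *b*
fitted per dataset so the blank population has mean 0 and the brightest
population mean 2. Two-population resolvability is the separation
parameter

    s = |μ₂ − μ₁| / √(σ₁² + σ₂²)

from a two-component Gaussian (EM) fit, and stoichiometric linearity is
the log–log slope of mean intensity versus labeled fraction
(slope 1 = ideal).

## Worked example

Fit the arcsinh normalization on a blank + titration dataset, then measure
how well the dim stained population separates from the blank:

```python
import numpy as np
from cyclim import (fit_arcsinh_scale, arcsinh_transform, fit_two_gaussians,
                    expected_labeled_epitopes)

rng = np.random.default_rng(0)
blank = rng.normal(60.0, 25.0, 5000)          # unstained cells, raw integrals
stained = rng.normal(2500.0, 900.0, 5000)     # dim stained population
top = rng.normal(80_000.0, 12_000.0, 5000)    # brightest titration level

scale = fit_arcsinh_scale(blank, top)         # pins blank->0, top->2
y = arcsinh_transform(np.concatenate([blank, stained]), scale)
fit = fit_two_gaussians(y, seed=0)
print(f"a = {scale.a:.3e}, b = {scale.b:.4f}")
print(f"separation s = {fit.s:.2f}")
print(f"expected labeled epitopes at 10% of 57,000: "
      f"{expected_labeled_epitopes(10.0):.0f}")
```

Output:

```
a = 6.319e-04, b = 0.0378
separation s = 3.66
expected labeled epitopes at 10% of 57,000: 5700
```

The fitted scale maps the blank mean to 0 (to 1e−18 here) and the top mean
to 2. The dim population sits at 0.52 arcsinh units with the blank
squeezed near zero width, giving a separation of 3.7 — comfortably
resolvable (two populations blur together below s ≈ 1). The expectation
helper converts a stoichiometric labeling percentage into labeled epitopes
per cell given the 57,000-copy reference abundance.

The same chain runs end to end from the command line on simulated beads:

```sh
cyclim run --config run.yaml --out results/
```

with a `run.yaml` like

```yaml
seed: 5
levels: [0.5]                  # labeled fraction per titration level
scene: {n_beads: 4, saturating_epitopes: 20000, bead_radius: 40,
        field_size: [448, 448]}
noise: {read_offset: 100.0, read_sigma: 2.0, saturation_level: 1.0e9}
background: {quadrant_size: 128}
```

which simulates, corrects, segments, quantifies and summarises (
`stats.json` reports 4 objects with mean integral ≈ 10,000 — the expected
20,000 × 0.5 labeled epitopes). Stages are cached by config hash; rerunning
with the same config skips completed stages, and two runs with the same
seed produce byte-identical outputs. Individual subcommands (`simulate`,
`process`, `segment`, `quantify`, `stats`, `cluster`) expose each stage
separately.

See `docs/methods.md` for the full model, parameter defaults, and design
rationale.

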