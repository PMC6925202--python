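# mps-scope

Quantitative analysis of the **axonal membrane-associated periodic scaffold
(MPS)** — the lattice of circumferential actin rings spaced ~185–190 nm by
spectrin tetramers under the axonal membrane — from single-molecule
localization microscopy (SMLM) and platinum-replica electron microscopy
(PREM) data, including correlative SMLM/PREM registration. It is aimed at
labs quantifying scaffold periodicity and actin-braid ultrastructure, and at
anyone needing a tested, scriptable replacement for the usual
ImageJ/Prism manual workflow.

## What it computes

Given a localization table and a traced axon path, the periodicity of the
scaffold is measured from the normalized autocorrelation of the intensity
profile *v(x)* along the trace (16 nm/pixel histogram reconstruction):

    AC(k) = Σᵢ (vᵢ − v̄)(vᵢ₊ₖ − v̄) / Σᵢ (vᵢ − v̄)²

* **Spacing _s_** — position of the first non-zero autocorrelation peak,
  refined by a Gaussian-plus-offset least-squares fit (± standard error).
* **Amplitude** — AC(192 nm) − AC(96 nm), the first-peak/first-valley
  contrast used to compare periodicity strength between conditions
  (Mann–Whitney for two groups, Kruskal–Wallis + Dunn/Holm for more).
* **Braid morphometry** on PREM-style images — braid spacing via the
  five-line averaging protocol, filament width as full width at half
  maximum above local background, braid length as traced arc length,
  summarized as mean ± SEM.
* **Correlative registration** — least-squares 6-parameter affine from
  control-point pairs, with RMS residual in the EM frame and two-channel
  overlays.
* **Synthetic scenes** — seeded generators for periodic-ring localization
  tables, braid images and correlative pairs with full ground truth, so the
  entire pipeline is testable without microscope data.

Localization tables are read/written in two delimited-text dialects
(N-STORM-style TSV and ThunderSTORM-style CSV, coordinates in nm) with
lossless translation of the shared fields and inclusive photon-count
filtering.

## Worked example

Simulate a scaffold, reconstruct it at the 16 nm analysis grid and measure
its periodicity:

```python
import numpy as np
from mps_scope import (SceneParams, make_mps_localizations, reconstruct,
                       Polyline)
from mps_scope.periodicity import analyze_tracings

params = SceneParams(period=185.0, seed=1)          # ~185 nm actin rings
table, truth = make_mps_localizations(params)       # 1121 localizations
image = reconstruct(table, pixel_size=16.0,
                    bounds=((-120, 4120), (-270, 270)))
trace = Polyline(np.array([[0.0, 0.0], [4000.0, 0.0]]), band_width=160.0)
result, mean_curve, curves = analyze_tracings(image, [trace])
print(f"spacing s = {result.spacing_s:.1f} ± {result.spacing_error:.2f} nm, "
      f"amplitude = {result.amplitude:.2f}")
```

```
spacing s = 185.2 ± 0.10 nm, amplitude = 1.01
```

The fitted spacing recovers the generating 185 nm period to a fraction of a
pixel, and the amplitude (first autocorrelation peak minus first valley)
reflects a strongly periodic profile; on a non-periodic scene the spacing
fit raises a no-peak error instead.

The same steps are available from the shell:

```sh
mps-scope simulate mps --seed 1 --out scene/
mps-scope render --pixel-size 16 scene/locs.csv scene/img.tif
mps-scope periodicity --image scene/img.tif --traces traces.json --out results/
```

plus `convert`, `filter`, `morpho`, `register` and `compare` subcommands for
the remaining operations.

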