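# sptmix

Single-particle-tracking mobility analysis for live-cell PALM experiments,
built around the question: *what fraction of a DNA-repair protein's
population is immobile (DNA-engaged), and does a perturbation change it?*

In sparse photoactivated localization microscopy (PALM) a protein such as
UvrB, fused to a photoactivatable fluorophore, is followed one molecule at
a time in bacterial cells. Tracks are short (photobleaching-limited, a few
frames), so per-molecule mobility is summarized by the apparent diffusion
coefficient over a fixed number of steps,

    D* = MSD / (4 Δt),    MSD = (1/n) Σᵢ |r(i+1) − r(i)|²,  n = 4 steps,

at Δt = 15 ms. For a single freely diffusing species with mobility D, D*
follows a gamma distribution with shape n and scale D/n. A cell population
containing several diffusive states therefore produces a gamma mixture

    p(x) = Σⱼ fⱼ · Gamma(x; shape n, scale Dⱼ/n),

and fitting {Dⱼ, fⱼ} by maximum likelihood (EM with restarts) decomposes
the D* distribution into species — typically immobile (DNA-bound), slowly
diffusing, and fast-diffusing. The occupancy of the lowest-mobility species
is the *immobile fraction*, compared across conditions and biological
replicates with an unpaired two-tailed t-test.

The package provides, as composable modules and a `spt` command line:

- `sptmix.simulate` — synthetic data generator: multi-species Brownian
  motion reflected inside 2-D spherocylindrical (rod-shaped) cells,
  Gaussian localization noise, Poisson photoactivation, geometric
  photobleaching (mean track length 2.5 frames at the default survival
  probability 0.6), with ground-truth labels.
- `sptmix.linking` — conservative greedy mutual-nearest-neighbour track
  linking with a hard displacement gate, plus the ≥4-step track filter.
- `sptmix.mixture` — D* computation, the gamma sampling density, the EM
  mixture fitter (free or with species mobilities held fixed), D*
  classification (immobile < 0.2 < slow < 1.5 < fast, µm²/s) and immobile-
  fraction estimators.
- `sptmix.replicates` — per-replicate summaries (mean ± SD) and the
  pooled-variance unpaired two-tailed t-test (Welch behind a flag).
- `sptmix.io`, `sptmix.pipeline`, `sptmix.cli` — plain-text formats
  (CSV/TSV/JSON), YAML configuration, and seeded end-to-end orchestration.

## Worked example

Simulate 20,000 four-step tracks from a three-species model with a 35%
immobile population (apparent mobilities 0.11 / 0.41 / 1.24 µm²/s), then
recover the species by the free mixture fit:

```python
import sptmix as sx
from sptmix.mixture import compute_dstars, fit_mixture

tracks, _ = sx.sample_tracks(20_000, sx.DART_SPECIES, frame_interval=0.015, rng=1)
dstars = compute_dstars(tracks, 0.015)
fit = fit_mixture(dstars, k=3, seed=1)
for d, f in fit.species:
    print(f"D = {d:.3f} um^2/s   occupancy = {f:.3f}")
print(f"immobile fraction: {sx.immobile_fraction(fit):.1f}%")
```

prints

```
D = 0.109 um^2/s   occupancy = 0.347
D = 0.409 um^2/s   occupancy = 0.334
D = 1.236 um^2/s   occupancy = 0.319
immobile fraction: 34.7%
```

i.e. the fitted mobilities land on the simulated 0.11 / 0.41 / 1.24 µm²/s
and the immobile occupancy on the simulated 35%, from four steps per track.

The same analysis from the shell, end to end (simulate → link → filter →
fit → replicate comparison for a control and a treated condition):

```sh
spt run --config config.yaml --replicates 4 --out results/
```

writes per-replicate localization, track, D* and fit files plus a
`report.json` with each condition's mean ± SD immobile percentage and the
between-condition t-test.

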