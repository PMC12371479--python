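# mesopipe

Headless analysis of mesoscale widefield imaging projects — from raw
multi-channel movies and event logs to hemodynamic-corrected ΔF/F,
event-triggered response metrics, seed-pixel correlation maps, ROI
connectivity matrices, image registration and longitudinal group
statistics.

Widefield calcium imaging records cortex-wide activity of fluorescent
indicators (e.g. GCaMP) at millimetre fields of view. The fluorescence is
contaminated by hemodynamics — absorption by blood changes with volume and
oxygenation — which is why such rigs interleave reflectance channels with
the fluorescence channel. Typical studies are longitudinal: many mice, in
groups, imaged over weeks, with sensory stimulation and resting-state
sessions. `mesopipe` is built for exactly that shape of dataset: a project
manifest indexes subjects/groups/acquisitions, processing pipelines run in
batch over every acquisition, and per-ROI metrics aggregate into tables
ready for statistics.

## What it computes

| stage | model / statistic |
|---|---|
| hemodynamic correction | per-pixel OLS of fluorescence on reflectance, `F = Xβ + ε`, corrected = residual + mean; ratiometric `F/F̄ ÷ R/R̄`; modified Beer–Lambert `ΔOD(λ) = ε_HbO(λ)D(λ)ΔHbO + ε_HbR(λ)D(λ)ΔHbR` |
| signal cleaning | global-signal regression, zero-phase Butterworth filtering, ΔF/F = (F−F₀)/F₀ |
| evoked responses | event-triggered trial averaging; per-pixel peak amplitude/latency, onset latency (first crossing of baseline mean + k·SD), trapezoidal AUC |
| connectivity | seed-pixel Pearson maps, ROI-pair correlation matrices, Fisher z = arctanh r, per-pixel SD maps, subtraction vs a reference session |
| registration | landmark (closed-form similarity / Umeyama), automatic (mutual-information maximisation), inter-subject (scale + translation anchored on Bregma) |
| statistics | automatic dispatch: t-test / Welch / Mann–Whitney U, paired t / Wilcoxon, one-way ANOVA / Kruskal–Wallis, two-way group×time ANOVA with per-timepoint + Holm fallback, gated on Shapiro–Wilk and Levene |

A synthetic-data module generates recordings with known ground truth for
every stage (hemodynamic coupling coefficients, analytic response metrics,
closed-form correlation structure, known image displacements), which is
what the test suite and the reproduction script verify against.

## Worked example

```python
import numpy as np
import mesopipe as mp
from mesopipe import synthetic as syn

# a recording in which fluorescence = 0.2–0.8 × reflectance + clean signal
fluo, reflectance, truth = syn.make_hemo_recording(syn.HemoSpec(seed=0))
result = mp.regress_hemodynamics(fluo, reflectance)

err = np.abs(result.coefficients[:, :, :2] - truth["coefficients"])
print(f"pixels within ±0.02 of true coupling: {100*(err <= 0.02).all(axis=2).mean():.1f}%")
```

prints

```
pixels within ±0.02 of true coupling: 100.0%
```

meaning the per-pixel regression recovered the generative hemodynamic
coupling coefficients to better than ±0.02 at essentially every one of the
64×64 pixels, at the default sensor-noise level (σ = 0.01, 1000 frames).
The `examples/` directory has one short narrative script per capability
(hemodynamic correction, evoked metrics, connectivity, registration, batch
processing + statistics); each prints the numbers it computes and says what
they mean.

There is also a thin CLI:

```bash
mesopipe synth --kind evoked --out-dir rec/
mesopipe events metrics rec/fluo rec/events.csv --pre-s 1 --post-s 3 --out-dir maps/
mesopipe render maps/peak_amplitude.tif peak.png --colormap viridis
mesopipe run pipeline.json project.json --skip-existing
```

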