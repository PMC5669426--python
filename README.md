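# memdentropy

Multiscale, multivariate signal-complexity analysis for multichannel
neurophysiological recordings (EEG, iEEG and similar), built around
multivariate empirical mode decomposition (MEMD) and Rényi quadratic
entropy, with the discriminability and synchrony statistics needed to turn
per-recording complexity values into group-level findings.

It is aimed at researchers who want to quantify how "complex" a biosignal
is as a function of temporal scale — for example to discriminate cognitive
or emotional states across subjects — without the smoothing bias of
coarse-graining multiscale entropy.

## What it computes

**Scales from the data, not from averaging.** A d-channel recording is
decomposed jointly by MEMD into intrinsic mode functions (IMFs): narrow-band
components ordered fast → slow, with the same oscillatory scale aligned at
the same mode index in every channel. Under dyadic spacing mode *i* peaks
near `rate / 2^(i+1)` Hz. Cumulative modes `CIMF_j = IMF_1 + … + IMF_j`
give partial reconstructions of growing bandwidth.

**Entropy per scale.** The windowed track at each scale is z-scored per
channel and cut into short non-overlapping snippets (default 100 ms). Per
snippet one of three estimators is applied:

* **MMRQE** — Rényi quadratic entropy `H₂ = −log₂ IP₂`, with the
  information potential estimated by the Gaussian-kernel pair sum
  `IP₂ = (1/n²) Σᵢⱼ k((xᵢ−xⱼ)/σ)` and Silverman's bandwidth
  `σ = σ_X (4/(n(2d+1)))^{1/(d+4)}`; univariate per channel, averaged over
  channels.
* **MMShE** — resubstitution kernel-Shannon entropy, same structure.
* **MMSE** — multivariate sample entropy `−ln(A^{m+1}/B^m)` on composite
  delay vectors (Chebyshev distance, tolerance r = 15% of SD).

The snippet mean ± standard error per scale is the multiscale entropy
curve; the undecomposed window supplies the "raw" uniscale reference.

**From curves to statistics.** Krippendorff's interval alpha measures how
well per-subject entropy values agree across subjects within condition
(with block bootstrap, per-channel maps, a greedy channel-subset search,
and a group t-test); phase-locking values with IAAFT surrogate ensembles
test scale-resolved synchrony between signal pairs.

A seeded synthetic module generates band-limited recordings, cohorts with
planted complexity orderings, phase-coupled pairs, and ratings matrices
with target agreement, so the full pipeline runs and is tested without any
recorded data.

## Worked example

```python
from memdentropy.synthetic import gen_complexity_conditions
from memdentropy.multiscale import multiscale_curve

recs, ordering = gen_complexity_conditions(
    n_subjects=2, n_items=2, effect=[0.2, 0.8], duration=30.0, seed=7)
for it in (0, 1):
    curve = multiscale_curve(recs[(0, it)], estimator="mmrqe",
                             scale_mode="cimf", window=None, seed=it)
    v, se = curve.at_scale(6)
    print(f"item {it}: CIMF_6 MMRQE = {v:.3f} +/- {se:.4f} bits "
          f"(raw = {curve.raw_value:.3f}, {curve.n_scales} modes)")
```

prints

```
item 0: CIMF_6 MMRQE = 2.266 +/- 0.0084 bits (raw = 2.081, 12 modes)
item 1: CIMF_6 MMRQE = 2.426 +/- 0.0080 bits (raw = 2.367, 13 modes)
```

Item 1 was generated with a higher white-noise mixing weight (0.8 vs 0.2),
i.e. more broadband randomness; its entropy at scale 6 (the cumulative
mode spanning roughly 1–32 Hz at 128 Hz sampling) is higher by ~20 snippet
standard errors, exactly the planted ordering. The "raw" values show the
same ordering but with a smaller margin — the usual motivation for going
multiscale.

The same analyses are scriptable from the shell:

```bash
memdentropy synth cohort --seed 1 --out cohort/
memdentropy mscurve --in cohort/subject0_item0.csv --rate-in 128 \
    --estimator mmrqe --scales cimf --window all --out curve.csv
memdentropy pipeline run --config cfg.yaml --out results/
```

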