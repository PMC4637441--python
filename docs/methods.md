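# Methods

## Signal model and pipeline

The pipeline treats scalp EEG as a superposition of band-limited
oscillations in the four classical rhythms — δ (deep states), θ
(drowsiness), α (relaxation, suppressed by external stimuli) and β
(alert/excited cognition) — riding on broadband noise and a common-mode
reference signal. Records are 8-channel traces at fs = 128 Hz from the
10–20 positions Fp1, Fp2, T3, T4, C3, C4, O1, O2 (odd = left hemisphere,
even = right; Fp = frontal, T/C = parietal in this montage's grouping,
O = occipital), delivered as 13-column delimited tables (tester, event,
minutes, seconds, 8 voltages, baseline).

Processing order: epoching → common average reference (CAR) → wavelet
low-pass at 30 Hz → packet decomposition → band energies → ratios →
contrasts. CAR precedes filtering; since both operations are linear, the
zero-channel-sum invariant survives the filter.

### Timestamps

The seconds column is cumulative absolute time and is authoritative; the
minutes column is redundant (seconds/60) and only checked for consistency
within 1 s, with a warning otherwise. Sampling is validated by requiring
the median inter-sample interval to lie within 5% of 1/fs.

### The baseline column

The record format carries a per-sample "baseline" voltage whose physical
meaning (reference electrode vs amplifier offset) is not defined by the
format; the reader stores it opaquely and the pipeline does not use it.
Re-referencing replaces it functionally: each channel has the 8-channel
instantaneous mean subtracted, and that mean is kept as the reference
series. The stored baseline is *not* subtracted before averaging.

## Wavelet machinery

The transform is an orthogonal two-channel filter bank iterated to depth
4, with periodized boundary handling. Analysis is circular correlation
with the db5 scaling/wavelet filters (10 taps, taken from PyWavelets)
followed by dyadic downsampling; synthesis is the adjoint. Periodization
keeps the transform exactly orthogonal at every even length, which gives
machine-precision Parseval (leaf energies sum to signal energy) and
perfect reconstruction — both are asserted in tests rather than assumed.

Epochs are zero-padded to the next multiple of 2⁴ = 16 samples and the
pad is cut after reconstruction. The pad carries no energy, so band
energies are unaffected; the low-pass re-applied to its own output is an
exact projection on multiple-of-16 lengths and approximate otherwise
(the truncation discards the pad's reconstruction).

### Frequency ordering

A full packet tree at level 4 yields 16 leaves, but in natural (Paley)
order the high-pass branches are spectrally mirrored by downsampling
aliasing, so the natural index is not frequency-monotone. The
binary-reflected Gray code gives the frequency-ordered position; leaf k
then spans [k·4, (k+1)·4) Hz. The ordering is verified two ways: sinusoid
probes at known frequencies must dominate the predicted leaf, and the
leaf energies must match PyWavelets' frequency-ordered packet tree on the
same signals (they agree to the printed digit).

### Band map

δ → leaf 0 (0–4 Hz), θ → leaf 1 (4–8), α → leaf 2 (8–12),
β → leaves 3–7 (12–32); leaves 8–15 (32–64 Hz) belong to no rhythm band
and are residual. These 4 Hz tiles deliberately differ from the nominal
physiological edges (δ 0.5–3.5, θ 4–7, α 8–13, β 14–30 Hz): a dyadic
tiling cannot realize 13 or 30 Hz edges, so the tile sets are the
computable approximation, while the nominal edges drive the synthetic
generator. The mismatch at 12–14 Hz (upper α assigned to β tiles) and
28–32 Hz (kept in β rather than cut at 30 Hz) is inherent to the tiling.

### Filter selectivity (known limitation)

The iterated 10-tap db5 filters have wide transition bands at level 4. A
mid-band tone therefore leaks measurably into neighbouring leaves: a 6 Hz
tone places 88.5% and a 10 Hz tone 85.9% of the four-band energy in its
own (single-leaf) band; the single-leaf δ band (99.5%) and the five-leaf
β band (>90%) are less affected. Likewise the 30 Hz low-pass implemented
by zeroing leaves 8–15 leaves ~11% of a 40 Hz tone's energy in the
output — aliased into the kept leaves, not above 32 Hz (spectral content
above 32 Hz after filtering is ~1% of input). These figures match an
independent packet implementation exactly and are properties of the
prescribed wavelet, not of this implementation; tests assert the measured
values. Longer filters would sharpen the bands but change the method.

## Features

For one channel of one epoch, band energy is the sum of squared packet
coefficients over the band's leaf set. Two normalisations:

* rhythm energy = band energy / total 16-leaf energy;
* energy ratio = band energy / four-band energy (the four ratios sum
  to 1 exactly).

Both are scale-invariant. After the 30 Hz low-pass the residual leaves
are exactly zero, so in-pipeline the two coincide; they differ on signals
that still carry energy above 32 Hz (e.g. unfiltered data — the published
reference table's four energies sum to 0.66–0.85, implying such a
residual share).

Epochs of one task are combined by the unweighted mean of per-epoch
values, so each scene counts equally regardless of amplitude; means
across subjects are taken inside the contrast functions. (An
energy-weighted mean would couple ratios to amplitude and break
gain-invariance across scenes.)

The package embeds a published reference feature table for the two-task
(online payment vs online chat) session as a regression fixture. Its
task-1 ratio columns satisfy ratio = band/Σ(four bands) within ±0.0002 —
a tolerance that absorbs mixed rounding/truncation at 4 decimals — except
channel O1; O1 task 1 and all task-2 ratio columns are internally
inconsistent with their printed energies and are excluded from numeric
checks (directional checks still include them).

## Contrasts

All contrasts are descriptive: group means, paired differences
(homologous electrode pairs for hemispheres, channels for tasks,
subjects for training groups) and a direction flag. No p-values are
attached — the underlying observations are directional claims without
inferential statistics, and inventing a test model (epochs are neither
independent nor identically distributed across channels) would suggest
more than the data supports. "More active" for the trained group is
operationalised as a higher β energy ratio, β being the alertness marker
throughout.

## Synthetic cohort generator

The generator emulates the acquisition protocol: 12 subjects (4 trained),
9 stimulus scenes of 8 s each (scene duration is not fixed by the
protocol; 8 s gives 1024 samples, a comfortable dyadic-friendly length),
separated by 1–2 s uniform inter-stimulus gaps. Scenes alternate between
the payment task (odd events) and the chat task (even events) by default.

Each channel of each scene is a sum over bands of sinusoid banks (24
random frequencies inside the band's nominal edges, random phases),
normalised to exact per-band energy shares, scaled to 40 µV RMS (a
mid-range scalp amplitude), plus white Gaussian noise at 5% of total
energy by default and an optional 50 Hz line component; pink noise is
available but off by default so that band-fraction recovery stays
interpretable. Gap samples carry the same mixture at 0.3× amplitude under
the reserved event id 0 (a dialect extension: recorded tables number
scenes from 1). The baseline column is the per-sample channel mean, and
timestamps are n/fs. A seed fully determines every output byte.

Base band fractions default to δ 0.47, θ 0.20, α 0.08, β 0.25 — chosen to
mirror the reference table's measured task-1 composition (δ ≈ 0.46–0.51,
θ ≈ 0.20, α ≈ 0.06–0.08, β ≈ 0.21–0.26). Condition effects multiply the β
fraction (left hemisphere ×1.3, payment task ×1.25, trained subject ×1.2
in the headline preset) followed by renormalisation to sum 1, so ratios
remain comparable across conditions. The preset effect sizes produce
β-ratio differences of ≈0.04 — the same order as the task differences in
the reference table (0.05–0.09) — large enough to be direction-stable
across seeds at 5% noise without being caricatures.

What the generator does *not* emulate: 1/f background by default, ocular
or muscle artifacts, volume-conduction correlation between channels,
event-locked transients, or non-stationarity within a scene. Passing
tests therefore demonstrate that the pipeline recovers band compositions
and injected contrasts from band-limited oscillatory mixtures — not that
it is robust to real-world artifacts, which the denoising steps here
(CAR + low-pass) only partially address.

## Numerical choices

* Tolerances: Parseval and reconstruction identities at 1e-8 relative
  (achieved: ~1e-15); CAR residual at 1e-9 µV; ratio identities at 1e-9.
* Record round trips are exact to 10 significant digits (`%.10g`).
* Epochs shorter than 16 samples (the minimum for a 4-level
  decomposition) are dropped with a warning rather than padded: a
  sub-125 ms scene carries no usable rhythm information.
* Degenerate inputs raise: zero total energy (ratios undefined),
  non-finite voltages (named sample), interleaved event labels,
  out-of-range node indices.
* Problem sizes in the validation runs: band-fraction recovery uses
  single-subject cohorts over 5 seeds; the headline-effect checks use
  full 12-subject cohorts over 20 seeds (tests) / 10 seeds (acceptance
  script), sizes at which every directional effect is stable while the
  whole suite stays quick on one CPU.
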