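# eegrhythm

Wavelet-packet rhythm-band analysis of 8-channel EEG record tables, built
for studying how cognitive alertness — for example while judging risky
online-payment scenes versus neutral online-chat scenes — expresses itself
in the relative power of the classical EEG rhythms.

The package takes tabular voltage records (one row per sample: tester,
event scene, timestamps, eight electrode voltages in µV from the 10–20
positions Fp1, Fp2, T3, T4, C3, C4, O1, O2, and a baseline column, sampled
at 128 Hz), and computes for every channel and task the energy share of
the four rhythm bands δ, θ, α and β, plus descriptive contrasts: left vs
right hemisphere, task vs task, trained vs untrained subject group, and
scalp-region summaries. A deterministic synthetic-cohort generator with
controllable band composition and injected effects provides ground truth
for validating every stage.

## Method

1. **Epoching** — each contiguous run of one event scene becomes an epoch;
   inter-stimulus gap samples (event id 0) are discarded.
2. **Common average reference (CAR)** — every channel is re-referenced to
   the instantaneous mean over the 8 channels, so the channel sum is zero
   at every sample.
3. **Wavelet low-pass** — a 4-level Daubechies-5 (db5) wavelet-packet
   decomposition tiles 0–64 Hz into 16 subbands of Δf = fs/2/2⁴ = 4 Hz;
   the leaves at and above 32 Hz are zeroed and the signal reconstructed,
   removing the non-physiological high-frequency content.
4. **Rhythm extraction** — the frequency-ordered leaves are assigned
   δ → S(4,0) (0–4 Hz), θ → S(4,1) (4–8 Hz), α → S(4,2) (8–12 Hz),
   β → S(4,3)…S(4,7) (12–32 Hz). Raw packet nodes come out in natural
   (Paley) order; a Gray-code permutation restores frequency-monotone
   indexing. The transform is an orthogonal periodized filter bank, so
   leaf energies sum exactly to the signal energy (Parseval) and the
   Mallat pyramid identity f₀ = f_N + Σ d_k holds to machine precision.
5. **Features** — per channel and band, the *rhythm energy* (band energy /
   total 16-leaf energy) and the *energy ratio* (band energy / four-band
   energy, summing to 1); both are invariant under amplifier gain.
6. **Contrasts** — descriptive group means and paired differences of the
   β energy ratio across hemispheres (homologous pairs Fp1–Fp2, T3–T4,
   C3–C4, O1–O2), tasks, training groups and scalp regions.

## Worked example

```python
from dataclasses import replace
from eegrhythm import (headline_preset, generate_cohort, default_task_map,
                       recordings_to_features, hemispheric_contrast)

cfg = replace(headline_preset(seed=1), n_subjects=4, n_trained=2)
recordings, groups = generate_cohort(cfg)
table = recordings_to_features(recordings, default_task_map())
print(hemispheric_contrast(table, "beta").summary())
```

prints

```
hemisphere contrast, beta band:
  left: mean ratio 0.3413 (n=4)
  right: mean ratio 0.2976 (n=4)
  Fp1-Fp2: +0.0454
  T3-T4: +0.0447
  C3-C4: +0.0416
  O1-O2: +0.0428
  larger: left
```

i.e. on this synthetic cohort (whose generator boosts the β fraction of
left-hemisphere channels by 1.3×) the estimated β energy ratio is higher
on the left at every homologous electrode pair — the pipeline recovers the
injected hemispheric asymmetry.

The same workflow is available from the shell:

```bash
eegrhythm simulate --preset headline --seed 1 --out-dir sim/
eegrhythm run --in-dir sim/ --out-dir results/ --groups sim/groups.yaml
```

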