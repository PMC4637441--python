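"""Synthetic multichannel EEG with known band composition and effects.

The generator emulates the acquisition protocol the pipeline targets:
8 scalp channels sampled at 128 Hz, nine stimulus scenes per subject with
inter-stimulus gaps drawn uniformly from 1-2 s, a cohort of 12 subjects of
whom 4 are flagged as trained.  Each channel of each scene is a weighted
sum of four band-limited oscillations (randomised-phase sinusoid banks
inside the conventional delta/theta/alpha/beta edges), plus white noise and
an optional 50 Hz line component.  The band weights are energy fractions,
so the analysis pipeline's estimated energy ratios can be compared against
the requested composition directly; condition effects (hemisphere, task,
training group) are injected by multiplying the beta fraction and
renormalising, keeping ratios comparable across conditions.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import yaml

from .record_io import Montage, Recording, default_montage

__all__ = [
    "GeneratorConfig",
    "default_task_map",
    "generate_band_signal",
    "generate_cohort",
    "generate_recording",
    "headline_preset",
    "load_config",
    "save_config",
]

TASK_PAYMENT = "online payment"
TASK_CHAT = "online chat"

#: Conventional band edges (Hz) and typical scalp amplitudes (uV) of the
#: four basic EEG rhythms; the amplitude ranges scale standalone band
#: signals, the edges bound the sinusoid banks.
BAND_EDGES_HZ: Dict[str, Tuple[float, float]] = {
    "delta": (0.5, 3.5),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
}
BAND_AMPLITUDES_UV: Dict[str, Tuple[float, float]] = {
    "delta": (20.0, 200.0),
    "theta": (100.0, 150.0),
    "alpha": (20.0, 200.0),
    "beta": (5.0, 20.0),
}


def default_task_map(n_events: int = 9) -> Dict[int, str]:
    """Alternating scene-to-task assignment: odd scenes are payment trials,
    even scenes are chat trials."""
    return {e: (TASK_PAYMENT if e % 2 else TASK_CHAT)
            for e in range(1, n_events + 1)}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort; the seed fully determines output.

    ``band_fractions`` are target shares of the four-band energy and must
    sum to 1.  The three beta boosts act multiplicatively on the beta
    fraction (then renormalised) for left-hemisphere channels, payment-task
    scenes, and trained subjects respectively; 1.0 disables an effect.
    ``noise_fraction`` is the white-noise share of total signal energy.
    """

    fs: float = 128.0
    n_subjects: int = 12
    n_trained: int = 4
    n_events: int = 9
    epoch_duration_s: float = 8.0
    inter_stimulus_ms: Tuple[float, float] = (1000.0, 2000.0)
    band_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "delta": 0.47, "theta": 0.20, "alpha": 0.08, "beta": 0.25,
        }
    )
    band_edges: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(BAND_EDGES_HZ)
    )
    left_beta_boost: float = 1.0
    task1_beta_boost: float = 1.0
    trained_beta_boost: float = 1.0
    noise_fraction: float = 0.05
    line_noise_hz: Optional[float] = None
    pink_noise: bool = False
    gap_amplitude_scale: float = 0.3
    rms_uv: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = self.band_fractions
        if set(fracs) != set(BAND_EDGES_HZ):
            raise ValueError(
                f"band_fractions must name exactly {sorted(BAND_EDGES_HZ)}"
            )
        if any(v <= 0 for v in fracs.values()):
            raise ValueError("band fractions must be positive")
        if abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise ValueError("band fractions must sum to 1")
        for band, (low, high) in self.band_edges.items():
            if not 0.0 < low < high < self.fs / 2:
                raise ValueError(
                    f"band {band!r} edges ({low}, {high}) outside (0, fs/2)"
                )
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if not 0 <= self.n_trained <= self.n_subjects:
            raise ValueError("n_trained must be between 0 and n_subjects")
        if not 0 <= self.noise_fraction < 1:
            raise ValueError("noise_fraction must be in [0, 1)")


def headline_preset(seed: int = 0) -> GeneratorConfig:
    """Cohort settings that realise the three headline effects by
    construction: alpha carries the smallest band fraction, and the beta
    fraction is boosted on left-hemisphere channels, in payment-task
    scenes, and for trained subjects."""
    return GeneratorConfig(
        band_fractions={
            "delta": 0.47, "theta": 0.20, "alpha": 0.08, "beta": 0.25,
        },
        left_beta_boost=1.30,
        task1_beta_boost=1.25,
        trained_beta_boost=1.20,
        noise_fraction=0.05,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Signal building blocks
# ---------------------------------------------------------------------------

def generate_band_signal(
    band_edges: Tuple[float, float],
    duration_s: float,
    fs: float,
    rng: np.random.Generator,
    amplitude_uv: Optional[Tuple[float, float]] = None,
    n_components: int = 24,
) -> np.ndarray:
    """A band-limited oscillation: a bank of randomised-phase sinusoids.

    Frequencies are drawn uniformly inside ``band_edges`` and phases
    uniformly on the circle, so essentially all spectral energy lies inside
    the band.  When ``amplitude_uv`` is given the waveform is scaled so its
    RMS sits inside that peak-amplitude range (RMS = peak / sqrt(2) of an
    equivalent single sinusoid).
    """
    low, high = band_edges
    if not 0.0 < low < high < fs / 2:
        raise ValueError(f"invalid band edges ({low}, {high}) for fs={fs}")
    n = int(round(duration_s * fs))
    if n < 1:
        raise ValueError(f"duration {duration_s} s yields no samples at fs={fs}")
    t = np.arange(n) / fs
    freqs = rng.uniform(low, high, size=n_components)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_components)
    x = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :]
               + phases[:, None]).sum(axis=0)
    if amplitude_uv is not None:
        peak = rng.uniform(*amplitude_uv)
        x *= (peak / np.sqrt(2.0)) / max(np.sqrt(np.mean(x**2)), 1e-12)
    return x


def _unit_energy(x: np.ndarray) -> np.ndarray:
    e = float(np.sum(x**2))
    return x if e == 0 else x / np.sqrt(e)


def _band_mixture(
    n_samples: int,
    config: GeneratorConfig,
    fractions: Mapping[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """One channel's oscillatory content with exact band-energy shares."""
    duration = n_samples / config.fs
    x = np.zeros(n_samples)
    for band, frac in fractions.items():
        comp = generate_band_signal(
            tuple(config.band_edges[band]), duration, config.fs, rng
        )[:n_samples]
        x += np.sqrt(frac) * _unit_energy(comp)
    # unit total energy so far; scale to the target RMS
    x *= config.rms_uv * np.sqrt(n_samples)
    if config.noise_fraction > 0:
        sig_e = float(np.sum(x**2))
        noise = rng.standard_normal(n_samples)
        if config.pink_noise:
            spec = np.fft.rfft(noise)
            f = np.fft.rfftfreq(n_samples, 1.0 / config.fs)
            f[0] = f[1] if n_samples > 1 else 1.0
            noise = np.fft.irfft(spec / np.sqrt(f), n=n_samples)
        # noise share of *total* energy equals noise_fraction
        target = config.noise_fraction / (1.0 - config.noise_fraction) * sig_e
        x += _unit_energy(noise) * np.sqrt(target)
    if config.line_noise_hz is not None:
        t = np.arange(n_samples) / config.fs
        x += 0.05 * config.rms_uv * np.sin(
            2.0 * np.pi * config.line_noise_hz * t + rng.uniform(0, 2 * np.pi)
        )
    return x


def _effective_fractions(
    config: GeneratorConfig, channel: str, task: str, trained: bool,
    montage: Montage,
) -> Dict[str, float]:
    """Base fractions with the applicable beta boosts, renormalised."""
    fracs = dict(config.band_fractions)
    boost = 1.0
    if montage.hemisphere[channel] == "left":
        boost *= config.left_beta_boost
    if task == TASK_PAYMENT:
        boost *= config.task1_beta_boost
    if trained:
        boost *= config.trained_beta_boost
    fracs["beta"] *= boost
    total = sum(fracs.values())
    return {b: v / total for b, v in fracs.items()}


# ---------------------------------------------------------------------------
# Recording and cohort assembly
# ---------------------------------------------------------------------------

def generate_recording(
    config: GeneratorConfig,
    subject_id: int,
    task_schedule: Optional[Mapping[int, str]] = None,
    trained: bool = False,
) -> Recording:
    """One subject's full session in the tabular record layout.

    Scenes 1..n_events each last ``epoch_duration_s`` and are preceded by
    an inter-stimulus gap (uniform 1-2 s by default) carrying the same band
    mixture at reduced amplitude and the reserved event id 0.  Timestamps
    are sample_index / fs; the baseline column holds the per-sample channel
    average.
    """
    task_schedule = dict(task_schedule or default_task_map(config.n_events))
    missing = [e for e in range(1, config.n_events + 1)
               if e not in task_schedule]
    if missing:
        raise ValueError(f"task schedule lacks events {missing}")
    montage = default_montage()
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(subject_id,))
    )
    n_epoch = int(round(config.epoch_duration_s * config.fs))
    if n_epoch < 16:
        raise ValueError("epoch duration too short for a 4-level decomposition")

    blocks_v: List[np.ndarray] = []
    blocks_id: List[np.ndarray] = []
    for event in range(1, config.n_events + 1):
        gap_ms = rng.uniform(*config.inter_stimulus_ms)
        n_gap = int(round(gap_ms / 1000.0 * config.fs))
        task = task_schedule[event]
        for n_block, event_id, scale in (
            (n_gap, 0, config.gap_amplitude_scale),
            (n_epoch, event, 1.0),
        ):
            chans = []
            for channel in montage.channels:
                fracs = _effective_fractions(
                    config, channel, task, trained, montage
                )
                chans.append(scale * _band_mixture(n_block, config, fracs, rng))
            blocks_v.append(np.column_stack(chans))
            blocks_id.append(np.full(n_block, event_id, dtype=int))

    voltages = np.vstack(blocks_v)
    event_ids = np.concatenate(blocks_id)
    n = len(event_ids)
    return Recording(
        tester_id=subject_id,
        event_ids=event_ids,
        time_s=np.arange(n) / config.fs,
        voltages=voltages,
        baseline=voltages.mean(axis=1),
        fs=config.fs,
    )


def generate_cohort(
    config: GeneratorConfig,
    task_schedule: Optional[Mapping[int, str]] = None,
) -> Tuple[List[Recording], Dict[int, str]]:
    """All subjects' recordings plus the subject -> group assignment.

    Subjects are numbered from 1; the first ``n_trained`` are the trained
    group.
    """
    groups = {
        sid: ("trained" if sid <= config.n_trained else "untrained")
        for sid in range(1, config.n_subjects + 1)
    }
    recordings = [
        generate_recording(config, sid, task_schedule,
                           trained=groups[sid] == "trained")
        for sid in range(1, config.n_subjects + 1)
    ]
    return recordings, groups


# ---------------------------------------------------------------------------
# Sidecar configuration files
# ---------------------------------------------------------------------------

def save_config(config: GeneratorConfig, path: str | Path) -> None:
    """Record every generator parameter (including the seed) as YAML."""
    data = asdict(config)
    data["band_fractions"] = dict(data["band_fractions"])
    data["band_edges"] = {b: list(e) for b, e in data["band_edges"].items()}
    data["inter_stimulus_ms"] = list(data["inter_stimulus_ms"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_config(path: str | Path) -> GeneratorConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["band_edges"] = {b: tuple(e) for b, e in data["band_edges"].items()}
    data["inter_stimulus_ms"] = tuple(data["inter_stimulus_ms"])
    return GeneratorConfig(**data)
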