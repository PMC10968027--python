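"""Synthetic two-class multichannel EEG with controllable band-power structure.

Each channel is 1/f^gamma background noise plus one narrowband stochastic
oscillation per canonical EEG band: band-pass-filtered white noise
normalised to the band's amplitude, with a slowly varying envelope. The
"ADHD" class multiplies selected band powers on selected electrode sites —
by default theta up by (1+delta) and beta down by (1-delta) on the
fronto-central channels. The template gives the site search and the
feature selectors something true to find; it makes no claim about ADHD
neurophysiology, and delta=0 produces classes that are distributionally
identical draw-for-draw.

The oscillations are stationary noise processes rather than fixed-frequency
sinusoids on purpose: a fixed tone frequency would fingerprint each record,
and segment-level cross-validation would then "classify" records instead of
classes, so the delta=0 null would not sit at chance. With exchangeable
segments the null stays at chance unless the pipeline itself leaks.

Records are deterministic per (config, subject seed); the dataset derives
per-subject seeds from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import EEGRecord
from .montage import CHANNELS_1020, SITES

__all__ = ["SimConfig", "simulate_record", "simulate_dataset"]

#: plausible scalp-EEG oscillation amplitudes per band, microvolts
DEFAULT_BAND_AMPS: dict[str, float] = {
    "delta": 8.0, "theta": 6.0, "alpha": 8.0, "beta": 4.0, "gamma": 1.5,
}

_BAND_EDGES = {
    "delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0), "gamma": (30.0, 55.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings for a two-class EEG study.

    ``effect`` is the multiplicative power-shift knob delta in [0, 1):
    the ADHD class gets theta power x(1+delta) and beta power x(1-delta)
    on the channels of ``affected_sites``. ``noise_exponent`` is the
    1/f^gamma background slope and ``noise_amp`` its standard deviation
    in microvolts.
    """

    n_subjects_per_class: int = 20
    duration_s: float = 60.0
    fs: float = 128.0
    channels: tuple[str, ...] = CHANNELS_1020
    effect: float = 0.5
    affected_sites: tuple[str, ...] = ("frontal", "central")
    boosted_band: str = "theta"
    suppressed_band: str = "beta"
    band_amps: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPS))
    noise_exponent: float = 1.0
    noise_amp: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.effect < 1:
            raise ValueError("effect must lie in [0, 1)")
        if self.fs <= 0 or self.duration_s <= 0 or self.noise_amp <= 0:
            raise ValueError("fs, duration_s and noise_amp must be positive")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        for s in self.affected_sites:
            if s not in SITES:
                raise ValueError(f"unknown site {s!r}")


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                exponent: float, amp: float) -> np.ndarray:
    """1/f^exponent noise of standard deviation ``amp`` via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x * (amp / sd) if sd > 0 else x


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-variance noise band-limited to [lo, hi] Hz (spectral masking
    with smooth cosine edges)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    width = max(0.25, 0.1 * (hi - lo))  # transition half-width, Hz
    mask = np.clip((f - (lo - width)) / (2 * width), 0, 1) * \
        np.clip(((hi + width) - f) / (2 * width), 0, 1)
    x = np.fft.irfft(spec * np.sqrt(mask), n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_record(cfg: SimConfig, class_label: int,
                    subject_seed: int) -> EEGRecord:
    """One labeled 19-channel recording, bit-reproducible per seed.

    The random draws are identical for both class labels; the label only
    scales the boosted/suppressed band amplitudes on affected channels,
    so ``effect=0`` makes the classes coincide exactly.
    """
    rng = np.random.default_rng(subject_seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    affected = {ch for s in cfg.affected_sites for ch in SITES[s]}

    data = np.empty((len(cfg.channels), n))
    for c, ch in enumerate(cfg.channels):
        x = _pink_noise(rng, n, cfg.fs, cfg.noise_exponent, cfg.noise_amp)
        for band, amp in cfg.band_amps.items():
            lo, hi = _BAND_EDGES[band]
            osc = _band_noise(rng, n, cfg.fs, lo, hi)
            slow_f = rng.uniform(0.05, 0.25)
            slow_ph = rng.uniform(0, 2 * np.pi)
            gain = 1.0
            if class_label == 1 and ch in affected:
                if band == cfg.boosted_band:
                    gain = np.sqrt(1.0 + cfg.effect)
                elif band == cfg.suppressed_band:
                    gain = np.sqrt(1.0 - cfg.effect)
            env = 1.0 + 0.3 * np.sin(2 * np.pi * slow_f * t + slow_ph)
            x = x + gain * amp * env * osc
        data[c] = x

    return EEGRecord(
        subject_id=f"sim-{class_label}-{subject_seed}",
        channels=cfg.channels,
        fs=cfg.fs,
        data=data,
        label=class_label,
    )


def simulate_dataset(cfg: SimConfig) -> list[EEGRecord]:
    """``n_subjects_per_class`` records per class with derived subject seeds."""
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(2 * cfg.n_subjects_per_class)
    records = []
    for i in range(cfg.n_subjects_per_class):
        records.append(simulate_record(cfg, 0, int(seeds[2 * i])))
        records.append(simulate_record(cfg, 1, int(seeds[2 * i + 1])))
    return records
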