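"""Synthetic LFP sessions emulating the study conditions.

The generator realizes the signal class the predictive model targets: a
second-order autoregressive source — a conjugate pole pair at radius A and
frequency f0, so a single spectral peak whose bandwidth shrinks as A
approaches 1 — observed on several channels through independent additive
Gaussian noise.  The two default condition presets differ in dominant
frequency and bandwidth the way saline and levodopa sessions of
dopamine-depleted animals do: the "saline-like" preset has a narrow peak
near 12.2 Hz (A = 0.995) and the "levodopa-like" preset a broader peak near
14.2 Hz (A = 0.985), matching the reported 11.7-12.8 vs 13.8-14.7 Hz ranges
and the observation that levodopa broadens the striatal spectrum.  Sessions
default to 4 channels, 40 minutes, 1 kHz.

A separate helper builds amplitude-modulated test tones with a prescribed
phase-amplitude coupling depth for validating the coupling metrics.

Seed discipline: a master seed plus fixed (condition, subject) counters feed
``numpy.random.default_rng``, so any subset of a dataset is reproducible
regardless of generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import Recording

__all__ = [
    "SynthSpec",
    "SALINE_LIKE",
    "LEVODOPA_LIKE",
    "ar2_coefficients",
    "gen_ar2_source",
    "gen_session",
    "gen_condition_pair",
    "gen_pac_signal",
]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic session.

    pole_radius (A) sets the sharpness of the spectral peak (closer to 1 =
    narrower); f0_hz its location; snr_db the power ratio of the shared
    source to each channel's private Gaussian noise (np.inf = no noise).
    """

    pole_radius: float
    f0_hz: float
    fs: float = 1000.0
    duration_min: float = 40.0
    n_channels: int = 4
    snr_db: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pole_radius < 1:
            raise ValueError(
                f"pole_radius must lie in (0, 1) for a stationary source, "
                f"got {self.pole_radius}"
            )
        if not 0 < self.f0_hz < self.fs / 2:
            raise ValueError(f"f0_hz must lie in (0, fs/2), got {self.f0_hz}")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        n = self.duration_min * 60.0 * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration_min * 60 * fs = {n} is not an integer sample count"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_min * 60.0 * self.fs))


#: narrow ~12.2 Hz peak (saline-analogue condition)
SALINE_LIKE = SynthSpec(pole_radius=0.995, f0_hz=12.2)
#: broader ~14.2 Hz peak (levodopa-analogue condition)
LEVODOPA_LIKE = SynthSpec(pole_radius=0.985, f0_hz=14.2)


def ar2_coefficients(pole_radius: float, f0_hz: float, fs: float) -> tuple[float, float]:
    """Predictor coefficients of a conjugate pole pair A exp(±j 2 pi f0/fs).

    a1 = 2 A cos(2 pi f0 / fs), a2 = -A^2.
    """
    theta = 2.0 * np.pi * f0_hz / fs
    return 2.0 * pole_radius * np.cos(theta), -(pole_radius**2)


def gen_ar2_source(spec: SynthSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """One realization of x(n) = a1 x(n-1) + a2 x(n-2) + e(n).

    Innovations are unit-variance Gaussian; the first 10/(1-A) samples are
    discarded as burn-in so the output is (approximately) stationary from
    its first sample.  Deterministic given (spec, rng/seed).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    a1, a2 = ar2_coefficients(spec.pole_radius, spec.f0_hz, spec.fs)
    burn = int(np.ceil(10.0 / (1.0 - spec.pole_radius)))
    e = rng.standard_normal(spec.n_samples + burn)
    x = sps.lfilter([1.0], [1.0, -a1, -a2], e)
    return x[burn:]


def gen_session(
    spec: SynthSpec,
    subject_id: str = "synth",
    condition: str = "unlabeled",
    rng: np.random.Generator | None = None,
) -> Recording:
    """A multi-channel session: one shared source plus per-channel noise.

    Every channel is the same AR(2) source with independent additive
    Gaussian noise scaled so the source-to-noise power ratio is
    ``spec.snr_db`` (infinite SNR gives identical channels), emulating one
    oscillatory field seen by several nearby electrodes.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    source = gen_ar2_source(spec, rng)
    if np.isinf(spec.snr_db):
        channels = np.tile(source, (spec.n_channels, 1))
    else:
        sigma = float(np.sqrt(np.mean(source**2) * 10.0 ** (-spec.snr_db / 10.0)))
        noise = rng.standard_normal((spec.n_channels, spec.n_samples))
        channels = source[None, :] + sigma * noise
    return Recording(
        channels=channels,
        fs=spec.fs,
        subject_id=subject_id,
        condition=condition,
        meta={
            "synthetic": True,
            "pole_radius": spec.pole_radius,
            "f0_hz": spec.f0_hz,
            "snr_db": spec.snr_db,
        },
    )


def gen_condition_pair(
    n_subjects: int = 4,
    spec_a: SynthSpec = SALINE_LIKE,
    spec_b: SynthSpec = LEVODOPA_LIKE,
    seed: int = 0,
    condition_a: str = "saline",
    condition_b: str = "levodopa",
) -> list[Recording]:
    """A two-condition dataset: n_subjects sessions per condition.

    With the defaults (4 subjects, 40-min sessions) 3-minute segmentation
    yields 13 epochs per session and 52 per condition.  Each session's
    generator stream is seeded by (master seed, condition index, subject
    index), so the dataset is reproducible session-by-session.
    """
    recordings = []
    for ci, (spec, cond) in enumerate([(spec_a, condition_a), (spec_b, condition_b)]):
        for si in range(n_subjects):
            rng = np.random.default_rng([seed, ci, si])
            recordings.append(
                gen_session(
                    dataclasses.replace(spec, seed=seed),
                    subject_id=f"m{si + 1}",
                    condition=cond,
                    rng=rng,
                )
            )
    return recordings


def gen_pac_signal(
    fs: float,
    duration_s: float,
    f_phase: float,
    f_amp: float,
    depth: float,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """A tone whose fast-component envelope rides the slow component's phase.

    s(t) = cos(2 pi f_phase t)
         + 0.5 * (1 + depth * cos(2 pi f_phase t)) * cos(2 pi f_amp t)
         + Gaussian noise.

    ``depth`` in [0, 1] is the coupling strength: 0 gives an envelope
    independent of phase, 1 a fully modulated fast component.
    """
    if not f_phase < f_amp < fs / 2:
        raise ValueError(
            f"need f_phase < f_amp < fs/2, got {f_phase}, {f_amp}, fs={fs}"
        )
    if not 0 <= depth <= 1:
        raise ValueError(f"depth must lie in [0, 1], got {depth}")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * fs))) / fs
    slow = np.cos(2.0 * np.pi * f_phase * t)
    fast = np.cos(2.0 * np.pi * f_amp * t)
    return slow + 0.5 * (1.0 + depth * slow) * fast + noise_sd * rng.standard_normal(len(t))
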