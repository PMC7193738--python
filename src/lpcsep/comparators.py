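"""Benchmark biomarkers: band-power fraction, phase-amplitude coupling (PAC)
modulation indices, the 6x6 PAC grid, and a canonical-correlation composite.

These are the established adaptive-stimulation trigger candidates that the
predictive-coding feature is compared against: the beta-band (12-30 Hz) power
fraction, single-pair PAC modulation indices (beta-phase/gamma-amplitude and
low-beta-phase/high-frequency-oscillation-amplitude pairings), and a grid of
36 modulation indices over six sub-bands of 3-60 Hz combined into a single
composite by canonical correlation against the condition labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.cross_decomposition import CCA

__all__ = [
    "BandSpec",
    "PacGridResult",
    "CcaComposite",
    "welch_psd",
    "beta_power",
    "pac_mi",
    "pac_mi_from_phase_amp",
    "pac_grid",
    "cca_composite",
    "SUBBANDS_3_60",
    "BETA_BAND",
    "DEHEMPTINNE_PHASE",
    "DEHEMPTINNE_AMP",
    "LOPEZ_PHASE",
    "LOPEZ_AMP",
]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"need 0 < lo < hi, got {self.lo}, {self.hi}")


#: six sub-bands of 3-60 Hz used for the 36-index PAC grid
SUBBANDS_3_60 = (
    BandSpec("delta", 3, 4),
    BandSpec("theta", 5, 7),
    BandSpec("alpha", 8, 11),
    BandSpec("low_beta", 12, 19),
    BandSpec("high_beta", 20, 30),
    BandSpec("gamma", 31, 60),
)

BETA_BAND = BandSpec("beta", 12, 30)
#: beta-phase / gamma-amplitude pairing
DEHEMPTINNE_PHASE = BandSpec("beta_phase", 13, 30)
DEHEMPTINNE_AMP = BandSpec("gamma_amp", 50, 200)
#: low-beta-phase / high-frequency-oscillation-amplitude pairing
LOPEZ_PHASE = BandSpec("low_beta_phase", 12, 30)
LOPEZ_AMP = BandSpec("hfo_amp", 200, 350)

#: amplitude-band power below this fraction of total power triggers a warning
#: (the band is physically empty, e.g. above an acquisition low-pass)
_AMP_POWER_FLOOR = 1e-4


def welch_psd(
    x: np.ndarray, fs: float, window_s: float = 2.0, overlap: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density (Hamming taper).

    Defaults (2-s windows, 50% overlap) give 0.5 Hz resolution and stable
    estimates on epochs of a few minutes.  The integral over (0, fs/2)
    approximately conserves signal power (Parseval).
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    if nperseg > len(x):
        raise ValueError(
            f"window of {nperseg} samples exceeds series length {len(x)}"
        )
    return sps.welch(
        x, fs=fs, window="hamming", nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
    )


def beta_power(
    x: np.ndarray, fs: float, band: BandSpec = BETA_BAND,
    window_s: float = 2.0, overlap: float = 0.5,
) -> float:
    """Band power as a fraction of total power in (0, fs/2).

    Gain-invariant by construction (a ratio of integrals of the same PSD).
    """
    f, psd = welch_psd(x, fs, window_s, overlap)
    total = psd.sum()
    if total == 0:
        raise ValueError("zero-power series has no band-power fraction")
    mask = (f >= band.lo) & (f <= band.hi)
    return float(psd[mask].sum() / total)


def _bandpass_fir(x: np.ndarray, fs: float, band: BandSpec, cycles: float = 3.0) -> np.ndarray:
    """Zero-phase FIR bandpass sized to >= ``cycles`` cycles of the low edge."""
    if band.hi >= fs / 2:
        raise ValueError(
            f"band {band.name} [{band.lo}, {band.hi}] Hz exceeds Nyquist {fs/2} Hz"
        )
    numtaps = int(round(cycles * fs / band.lo))
    numtaps += 1 - numtaps % 2  # odd
    if numtaps >= len(x):
        raise ValueError(
            f"series too short for a {numtaps}-tap filter on band {band.name}"
        )
    h = sps.firwin(numtaps, [band.lo, band.hi], pass_zero=False, window="hamming", fs=fs)
    return sps.oaconvolve(x, h, mode="same")


def pac_mi_from_phase_amp(
    phase: np.ndarray, amp: np.ndarray, nbins: int = 18
) -> float:
    """Modulation index from precomputed instantaneous phase and envelope.

    The envelope is averaged within ``nbins`` phase bins, the bin means are
    normalized to a distribution p, and the index is the Kullback-Leibler
    divergence of p from uniform, normalized by log(nbins) so it lies in
    [0, 1]: 0 for a phase-independent envelope, 1 when the envelope is
    concentrated in a single bin.
    """
    phase = np.asarray(phase, dtype=float)
    amp = np.asarray(amp, dtype=float)
    if phase.shape != amp.shape:
        raise ValueError("phase and amplitude series must have equal length")
    edges = np.linspace(-np.pi, np.pi, nbins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, nbins - 1)
    sums = np.bincount(idx, weights=amp, minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    means = np.divide(sums, counts, out=np.zeros(nbins), where=counts > 0)
    total = means.sum()
    if total == 0:
        raise ValueError("amplitude envelope is identically zero")
    p = means / total
    nz = p > 0
    kl = float(np.sum(p[nz] * np.log(p[nz] * nbins)))
    return kl / np.log(nbins)


def pac_mi(
    x: np.ndarray, fs: float, phase_band: BandSpec, amp_band: BandSpec,
    nbins: int = 18,
) -> float:
    """Phase-amplitude coupling modulation index of one series.

    Phase comes from the analytic signal of the phase-band-filtered series,
    the envelope from the analytic signal of the amplitude-band-filtered
    series; see :func:`pac_mi_from_phase_amp` for the binning and the
    Kullback-Leibler normalization.

    Requires at least 10 cycles of the phase band's low edge.  If the
    amplitude band holds essentially no power (for instance a band above an
    acquisition low-pass), a warning is emitted and the index — dominated by
    numerical noise — is still returned.
    """
    x = np.asarray(x, dtype=float)
    n_cycles = len(x) / fs * phase_band.lo
    if n_cycles < 10:
        raise ValueError(
            f"series holds only {n_cycles:.1f} cycles of {phase_band.lo} Hz; "
            "need >= 10 for a stable phase distribution"
        )
    xp = _bandpass_fir(x, fs, phase_band)
    xa = _bandpass_fir(x, fs, amp_band)
    total_power = float(np.mean(x**2))
    amp_power = float(np.mean(xa**2))
    if total_power > 0 and amp_power < _AMP_POWER_FLOOR * total_power:
        warnings.warn(
            f"amplitude band {amp_band.name} [{amp_band.lo}, {amp_band.hi}] Hz "
            f"holds < {_AMP_POWER_FLOOR:g} of total power; the modulation "
            "index reflects numerical noise",
            stacklevel=2,
        )
    phase = np.angle(sps.hilbert(xp))
    amp = np.abs(sps.hilbert(xa))
    return pac_mi_from_phase_amp(phase, amp, nbins)


@dataclass
class PacGridResult:
    """Modulation indices for every (phase band, amplitude band) pair."""

    mi: np.ndarray  # shape (n_phase_bands, n_amp_bands)
    phase_bands: tuple[BandSpec, ...]
    amp_bands: tuple[BandSpec, ...]
    signal_id: str = ""

    @property
    def flat(self) -> np.ndarray:
        """Row-major flattened indices (phase-major ordering)."""
        return self.mi.ravel()


def pac_grid(
    signals,
    fs: float,
    bands: tuple[BandSpec, ...] = SUBBANDS_3_60,
    nbins: int = 18,
    signal_ids=None,
) -> list[PacGridResult]:
    """Full coupling grid: modulation index for every band pair.

    With the default six sub-bands this yields 6 x 6 = 36 indices per
    signal.  Phase and envelope series per band are computed once and
    reused across pairs.
    """
    signals = [np.asarray(s, dtype=float) for s in signals]
    if len(signals) == 0:
        raise ValueError("need at least one signal")
    if signal_ids is None:
        signal_ids = [str(i) for i in range(len(signals))]
    out = []
    for sig, sid in zip(signals, signal_ids):
        phases, amps = [], []
        for b in bands:
            xb = _bandpass_fir(sig, fs, b)
            analytic = sps.hilbert(xb)
            phases.append(np.angle(analytic))
            amps.append(np.abs(analytic))
        mi = np.empty((len(bands), len(bands)))
        for i in range(len(bands)):
            for j in range(len(bands)):
                mi[i, j] = pac_mi_from_phase_amp(phases[i], amps[j], nbins)
        out.append(
            PacGridResult(mi=mi, phase_bands=tuple(bands), amp_bands=tuple(bands), signal_id=sid)
        )
    return out


@dataclass
class CcaComposite:
    """First canonical direction between a feature block and the labels."""

    weights: np.ndarray
    composite: np.ndarray
    conditions: tuple[str, str]
    canonical_r: float


def cca_composite(mi_matrix: np.ndarray, labels) -> CcaComposite:
    """Weight a block of coupling indices into one composite per signal.

    Computes the first canonical direction between the (signals x features)
    index matrix and a binary condition indicator — with a one-column
    indicator this degenerates to a discriminant direction.  The composite
    is each signal's projection on that direction; the sign is fixed so the
    second condition (later in sorted label order) has the larger mean
    composite.

    Requires strictly more signals than features and a full-rank
    (centered) feature block.
    """
    x = np.asarray(mi_matrix, dtype=float)
    labels = np.asarray(labels)
    if x.ndim != 2:
        raise ValueError("mi_matrix must be 2-D (signals x features)")
    n, p = x.shape
    if len(labels) != n:
        raise ValueError("one label per signal is required")
    if n <= p:
        raise ValueError(
            f"the total number of signals ({n}) must be greater than the "
            f"number of coupling measurements ({p})"
        )
    conditions = tuple(sorted(np.unique(labels).tolist()))
    if len(conditions) != 2:
        raise ValueError(f"need exactly two conditions, got {conditions}")
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < p:
        raise np.linalg.LinAlgError(
            "feature block is rank-deficient; canonical weights are not "
            "identifiable"
        )
    y = (labels == conditions[1]).astype(float).reshape(-1, 1)
    cca = CCA(n_components=1, scale=True, max_iter=1000)
    xs, _ = cca.fit_transform(x, y)
    composite = xs[:, 0]
    weights = cca.x_rotations_[:, 0].copy()
    if composite[y[:, 0] == 1].mean() < composite[y[:, 0] == 0].mean():
        composite = -composite
        weights = -weights
    r = float(np.corrcoef(composite, y[:, 0])[0, 1])
    return CcaComposite(
        weights=weights, composite=composite,
        conditions=(str(conditions[0]), str(conditions[1])), canonical_r=r,
    )
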