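"""Validation experiments: oracle equivalences, parameter-recovery rates,
null calibration, and the end-to-end two-condition emulation.

Every function here recomputes its quantity from scratch by running the
package on freshly generated inputs, seeded through a single integer, so the
same routines back both the test suite and the reproduction script.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import signal as sps

from . import lpc, preprocess, separation
from .synthlfp import (
    LEVODOPA_LIKE,
    SALINE_LIKE,
    ar2_coefficients,
    gen_condition_pair,
)

__all__ = [
    "levinson_vs_toeplitz_max_relerr",
    "streaming_vs_batch_max_relerr",
    "brute_force_ranksum_p",
    "exact_ranksum_vs_bruteforce_max_err",
    "ar1_recovery_rates",
    "ar2_frequency_recovery_rate",
    "null_rejection_rate",
    "end_to_end_separation",
]


def _batch_ar(
    denom: np.ndarray, n_series: int, length: int, burn: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """n_series independent AR realizations (rows), burn-in discarded."""
    e = rng.standard_normal((n_series, length + burn))
    return sps.lfilter([1.0], denom, e, axis=-1)[:, burn:]


def levinson_vs_toeplitz_max_relerr(
    n_cases: int = 1000, order: int = 8, length: int = 64, seed: int = 0
) -> float:
    """Largest relative gap between the order-recursive and the direct
    Toeplitz solution over random positive-definite autocorrelation sets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        x = rng.standard_normal(length)
        ac = lpc.autocorr(x, order)
        a_direct = lpc.yule_walker(ac, order)
        a_ld = lpc.levinson_durbin(ac, order)[0][-1]
        rel = np.max(np.abs(a_ld - a_direct)) / max(np.max(np.abs(a_direct)), 1e-300)
        worst = max(worst, float(rel))
    return worst


def streaming_vs_batch_max_relerr(
    duration_s: float = 240.0, fs: float = 1000.0, order: int = 1,
    chunk_s: float = 1.0, seed: int = 0,
) -> float:
    """Largest relative coefficient gap between the constant-cost streaming
    estimator and batch fits on every expanding-window prefix."""
    rng = np.random.default_rng(seed)
    spec = SALINE_LIKE
    a1, a2 = ar2_coefficients(spec.pole_radius, spec.f0_hz, fs)
    x = _batch_ar(np.array([1.0, -a1, -a2]), 1, int(duration_s * fs), 2000, rng)[0]
    stream = lpc.StreamingLpc(order=order, fs=fs)
    worst = 0.0
    chunk = int(round(chunk_s * fs))
    for start in range(0, len(x), chunk):
        stream.update(x[start : start + chunk])
        a_stream = stream.model().coeffs
        a_batch = lpc.fit_lpc(x[: start + chunk], fs, order).coeffs
        rel = np.max(np.abs(a_stream - a_batch)) / np.max(np.abs(a_batch))
        worst = max(worst, float(rel))
    return worst


def brute_force_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Enumerates every way of labelling the pooled, tie-free values, computes
    the Mann-Whitney U of each, and returns
    ``min(1, 2 * min(P(U <= u_obs), P(U >= u_obs)))``.  Independent oracle
    for the exact branch of :func:`lpcsep.separation.ranksum_test`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if len(np.unique(pooled)) < len(pooled):
        raise ValueError("brute-force enumeration assumes tie-free data")
    n1 = len(a)
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    total = comb(len(pooled), n1)
    le = ge = 0
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        if u <= u_obs:
            le += 1
        if u >= u_obs:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def exact_ranksum_vs_bruteforce_max_err(
    max_n: int = 7, n_random: int = 30, seed: int = 0
) -> float:
    """Largest |p_exact - p_bruteforce| over random tie-free small samples."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_random):
        n1 = int(rng.integers(2, max_n + 1))
        n2 = int(rng.integers(2, max_n + 1))
        vals = rng.permutation(np.arange(1, n1 + n2 + 1)).astype(float)
        a, b = vals[:n1], vals[n1:]
        p_pkg = separation.ranksum_test(a, b).pvalue
        p_oracle = brute_force_ranksum_p(a, b)
        worst = max(worst, abs(p_pkg - p_oracle))
    return worst


def ar1_recovery_rates(
    a_values=(0.5, 0.9, 0.99), length: int = 60_000, n_replicates: int = 500,
    seed: int = 0,
) -> dict[float, float]:
    """Fraction of replicates whose order-1 coefficient estimate lands
    within 3 asymptotic standard deviations sqrt((1 - a^2) / L) of truth."""
    rng = np.random.default_rng(seed)
    rates = {}
    for a in a_values:
        burn = int(np.ceil(10.0 / (1.0 - a)))
        x = _batch_ar(np.array([1.0, -a]), n_replicates, length, burn, rng)
        r0 = np.mean(x**2, axis=1)
        r1 = np.sum(x[:, 1:] * x[:, :-1], axis=1) / length
        a_hat = r1 / r0
        tol = 3.0 * np.sqrt((1.0 - a**2) / length)
        rates[a] = float(np.mean(np.abs(a_hat - a) < tol))
    return rates


def _batch_ar2_freq(x: np.ndarray, fs: float) -> np.ndarray:
    """Dominant-frequency estimate per row via the order-2 pole phase."""
    n = x.shape[1]
    r0 = np.mean(x**2, axis=1)
    r1 = np.sum(x[:, 1:] * x[:, :-1], axis=1) / n
    r2 = np.sum(x[:, 2:] * x[:, :-2], axis=1) / n
    det = r0**2 - r1**2
    a1 = r1 * (r0 - r2) / det
    a2 = (r0 * r2 - r1**2) / det
    disc = a1**2 + 4.0 * a2
    freq = np.full(len(a1), np.nan)
    cplx = disc < 0
    freq[cplx] = (
        np.arctan2(np.sqrt(-disc[cplx]) / 2.0, a1[cplx] / 2.0) * fs / (2.0 * np.pi)
    )
    return freq


def ar2_frequency_recovery_rate(
    radii=(0.9, 0.95, 0.995), freqs=(10.0, 12.0, 14.0, 20.0),
    duration_s: float = 60.0, fs: float = 1000.0, n_replicates: int = 40,
    tol_hz: float = 0.5, seed: int = 0,
) -> float:
    """Fraction of replicates (over the radius x frequency grid) whose
    order-2 pole-phase frequency lands within ``tol_hz`` of the truth."""
    rng = np.random.default_rng(seed)
    length = int(round(duration_s * fs))
    hits = trials = 0
    for radius in radii:
        burn = int(np.ceil(10.0 / (1.0 - radius)))
        for f0 in freqs:
            a1, a2 = ar2_coefficients(radius, f0, fs)
            x = _batch_ar(np.array([1.0, -a1, -a2]), n_replicates, length, burn, rng)
            f_hat = _batch_ar2_freq(x, fs)
            hits += int(np.sum(np.abs(f_hat - f0) < tol_hz))
            trials += n_replicates
    return hits / trials


def null_rejection_rate(
    n_epochs: int = 13, n_replicates: int = 1000, segment_s: float = 2.0,
    fs: float = 1000.0, pole_radius: float = 0.95, f0_hz: float = 13.0,
    alpha: float = 0.05, seed: int = 0, batch: int = 200,
) -> float:
    """Type-I error of the rank-sum comparison under identical conditions.

    Both "conditions" of every replicate draw their per-epoch features from
    the same generator parameters (the healthy-control analogue), so the
    fraction of replicates rejected at level ``alpha`` estimates the false
    trigger rate.  The test is rank-based, hence distribution-free under
    this exchangeable null, so short segments give the same rate as
    full-length epochs at a fraction of the cost.
    """
    rng = np.random.default_rng(seed)
    a1, a2 = ar2_coefficients(pole_radius, f0_hz, fs)
    denom = np.array([1.0, -a1, -a2])
    burn = int(np.ceil(10.0 / (1.0 - pole_radius)))
    length = int(round(segment_s * fs))
    rejections = 0
    done = 0
    while done < n_replicates:
        nrep = min(batch, n_replicates - done)
        x = _batch_ar(denom, nrep * 2 * n_epochs, length, burn, rng)
        r0 = np.mean(x**2, axis=1)
        r1 = np.sum(x[:, 1:] * x[:, :-1], axis=1) / length
        feats = (1.0 - r1 / r0) * 1e3
        feats = feats.reshape(nrep, 2, n_epochs)
        for k in range(nrep):
            p = separation.ranksum_test(feats[k, 0], feats[k, 1]).pvalue
            if p < alpha:
                rejections += 1
        done += nrep
    return rejections / n_replicates


def end_to_end_separation(
    seed: int = 0,
    n_subjects: int = 4,
    epoch_min: float = 3.0,
    spec_a=SALINE_LIKE,
    spec_b=LEVODOPA_LIKE,
) -> dict:
    """Full pipeline on the default synthetic condition pair.

    Generates the two-condition dataset, preprocesses, segments, extracts
    the order-1 predictive feature per epoch, fits the midpoint threshold
    on even-indexed epochs and classifies the held-out odd-indexed epochs.
    Also records the full-session order-2 dominant frequency per condition.

    Returns a dict with epoch counts, margin, held-out accuracy, both
    p-values on the pooled epochs, and mean dominant frequencies.
    """
    recordings = gen_condition_pair(
        n_subjects=n_subjects, spec_a=spec_a, spec_b=spec_b, seed=seed
    )
    conditions = (recordings[0].condition, recordings[-1].condition)

    feats: dict[str, list[float]] = {c: [] for c in conditions}
    dom_freqs: dict[str, list[float]] = {c: [] for c in conditions}
    for rec in recordings:
        series = preprocess.preprocess_session(rec)
        epochs = preprocess.segment(series, rec.fs, epoch_min)
        for ep in epochs:
            model = lpc.fit_lpc(ep.samples, rec.fs, order=1)
            feats[rec.condition].append(lpc.separation_feature(model))
        full = lpc.fit_lpc(series, rec.fs, order=2)
        if full.dominant_freq_hz is not None:
            dom_freqs[rec.condition].append(full.dominant_freq_hz)

    a = np.asarray(feats[conditions[0]])
    b = np.asarray(feats[conditions[1]])
    train_res = separation.midpoint_threshold(
        a[::2], b[::2], conditions[0], conditions[1]
    )
    held_a = a[1::2]
    held_b = b[1::2]
    correct = sum(
        separation.classify(v, train_res) == conditions[0] for v in held_a
    ) + sum(separation.classify(v, train_res) == conditions[1] for v in held_b)
    accuracy = correct / (len(held_a) + len(held_b))

    full_res = separation.analyze_separation(a, b, conditions[0], conditions[1])
    return {
        "conditions": conditions,
        "epochs_per_condition": (len(a), len(b)),
        "threshold": full_res.threshold,
        "margin": full_res.margin,
        "complete_separation": full_res.complete_separation,
        "holdout_accuracy": accuracy,
        "wilcoxon_p": full_res.wilcoxon_p,
        "kruskal_p": full_res.kruskal_p,
        "mean_dominant_freq_hz": {
            c: float(np.mean(v)) for c, v in dom_freqs.items()
        },
        "features": {conditions[0]: a, conditions[1]: b},
    }
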