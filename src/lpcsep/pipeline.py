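"""End-to-end feature extraction: recordings -> per-epoch feature table.

Ties the preprocessing chain, the predictive-coding features and the
comparator biomarkers together behind one call, producing the long-format
:class:`~lpcsep.signal_io.FeatureTable` that the separation layer consumes.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from . import comparators, lpc, preprocess
from .signal_io import Config, FeatureTable, Recording

__all__ = ["extract_features", "METHODS", "grid_composite_features"]


def _lpc1_feature(x: np.ndarray, fs: float, cfg: Config) -> float:
    return lpc.separation_feature(lpc.fit_lpc(x, fs, order=1))


def _lpc2_feature(x: np.ndarray, fs: float, cfg: Config) -> float:
    model = lpc.fit_lpc(x, fs, order=2)
    f0 = model.dominant_freq_hz
    return float("nan") if f0 is None else f0


def _beta_feature(x: np.ndarray, fs: float, cfg: Config) -> float:
    band = comparators.BandSpec("beta", *cfg.beta_band)
    return comparators.beta_power(x, fs, band)


def _pac_dehemptinne(x: np.ndarray, fs: float, cfg: Config) -> float:
    return comparators.pac_mi(
        x, fs, comparators.DEHEMPTINNE_PHASE, comparators.DEHEMPTINNE_AMP,
        cfg.pac_nbins,
    )


def _pac_lopez(x: np.ndarray, fs: float, cfg: Config) -> float:
    return comparators.pac_mi(
        x, fs, comparators.LOPEZ_PHASE, comparators.LOPEZ_AMP, cfg.pac_nbins
    )


#: scalar feature extractors by method name
METHODS: dict[str, Callable[[np.ndarray, float, Config], float]] = {
    "lpc1": _lpc1_feature,
    "lpc2": _lpc2_feature,
    "beta": _beta_feature,
    "pac-dehemptinne": _pac_dehemptinne,
    "pac-lopez": _pac_lopez,
}


def extract_features(
    recordings: Sequence[Recording],
    methods: Sequence[str] = ("lpc1",),
    epoch_lengths_min: Sequence[float] = (3.0,),
    config: Config | None = None,
    preprocessed: bool = False,
) -> FeatureTable:
    """Per-epoch scalar features for every recording, method and epoch length.

    Each recording is passed through the preprocessing chain (bandpass,
    unit-power normalization, channel averaging) unless ``preprocessed``
    is set, segmented at each requested epoch length, and each epoch is
    reduced to one scalar per method.  The ``pac-grid`` method expands to
    36 rows per epoch, one per (phase band, amplitude band) pair, with
    method names ``pac-grid:<phase>/<amp>``.
    """
    cfg = (config or Config()).validate()
    known = set(METHODS) | {"pac-grid"}
    unknown = [m for m in methods if m not in known]
    if unknown:
        raise ValueError(
            f"unknown method(s) {unknown}; available: {sorted(known)}"
        )
    rows = []
    for rec in recordings:
        if preprocessed:
            series = preprocess.average_channels(rec)
        else:
            series = preprocess.preprocess_session(
                rec, cfg.band_lo_hz, cfg.band_hi_hz
            )
        for elen in epoch_lengths_min:
            for ep in preprocess.segment(series, rec.fs, elen):
                for method in methods:
                    if method == "pac-grid":
                        grid = comparators.pac_grid(
                            [ep.samples], rec.fs, nbins=cfg.pac_nbins
                        )[0]
                        for i, pb in enumerate(grid.phase_bands):
                            for j, ab in enumerate(grid.amp_bands):
                                rows.append(
                                    _row(rec, ep, f"pac-grid:{pb.name}/{ab.name}",
                                         grid.mi[i, j])
                                )
                    else:
                        if method not in METHODS:
                            raise ValueError(
                                f"unknown method {method!r}; available: "
                                f"{sorted(METHODS) + ['pac-grid']}"
                            )
                        rows.append(
                            _row(rec, ep, method,
                                 METHODS[method](ep.samples, rec.fs, cfg))
                        )
    if not rows:
        return FeatureTable.empty()
    return FeatureTable.from_rows(rows)


def _row(rec: Recording, ep, method: str, value: float) -> dict:
    return {
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "epoch_index": ep.epoch_index,
        "epoch_length_s": ep.epoch_length_s,
        "method": method,
        "value": float(value),
    }


def grid_composite_features(features: FeatureTable) -> FeatureTable:
    """Collapse per-epoch ``pac-grid:*`` rows into one composite per epoch.

    Pivots the 36 grid indices into a (signals x 36) block, projects it on
    the first canonical direction against the condition labels, and returns
    a new table with method ``pac-grid-composite``.  Requires more signals
    than grid cells.
    """
    df = features.df
    grid = df[df["method"].str.startswith("pac-grid:")]
    if grid.empty:
        raise ValueError("no pac-grid features present")
    wide = grid.pivot_table(
        index=["subject_id", "condition", "epoch_index", "epoch_length_s"],
        columns="method", values="value",
    )
    labels = wide.index.get_level_values("condition").to_numpy()
    res = comparators.cca_composite(wide.to_numpy(), labels)
    rows = [
        {
            "subject_id": sid, "condition": cond, "epoch_index": ei,
            "epoch_length_s": elen, "method": "pac-grid-composite",
            "value": float(v),
        }
        for (sid, cond, ei, elen), v in zip(wide.index, res.composite)
    ]
    return FeatureTable.from_rows(rows)
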