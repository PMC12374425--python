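"""Per-period activity and circadian feature extraction.

For each recording day (a 22:00-anchored 24-hour period) and each of the
three clock periods (full / night 00-06 / day 09-21), the extractor
computes per-activity-category features (mean time fraction, percentage
of windows above 5/10/25% time in category, intra-daily variability) and
intensity-count features (mean, mean during sitting-modal windows,
intra-daily variability, and — for the full period only — M10/L5 with
their onsets and the relative amplitude).  Sit-to-stand and step-count
event signals get a mean and an IV per period.  Per-day vectors are then
summarized per subject by the across-day average and unbiased variance.

Circadian indices
-----------------
IV (intra-daily variability) for a sequence x of length n:

    IV = n * sum_{i=2..n} (x_i - x_{i-1})^2
         / ((n - 1) * sum_i (x_i - mean(x))^2)

which is ~2 for white noise and small for a smooth rhythm.  M10 / L5 are
the mean counts over the most active contiguous 10 hours / least active
contiguous 5 hours of the full period (blocks stepped one window at a
time, no wrap past the period boundary, earliest start on ties), and the
relative amplitude is RA = (M10 - L5) / (M10 + L5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ingest import (
    CATEGORIES,
    FULL_PERIOD,
    WindowSeries,
    n_full_periods,
    slice_period,
    validate_day,
)

logger = logging.getLogger(__name__)

PCT_THRESHOLDS = (0.05, 0.10, 0.25)


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def intradaily_variability(x: Sequence[float]) -> float:
    """Intra-daily variability of a numeric sequence.

    Returns NaN (propagated as missing) for a constant sequence, whose
    denominator vanishes; sequences shorter than 3 raise.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("IV requires at least 3 observations")
    num = n * np.sum(np.diff(x) ** 2)
    den = (n - 1) * np.sum((x - x.mean()) ** 2)
    if den == 0:
        return float("nan")
    return float(num / den)


def pct_windows_above(fracs: Sequence[float], threshold: float) -> float:
    """Percentage of windows with time fraction strictly above threshold."""
    fracs = np.asarray(fracs, dtype=float)
    if fracs.size == 0:
        return float("nan")
    return float(100.0 * np.mean(fracs > threshold))


@dataclass
class CircadianIndices:
    m10: float
    l5: float
    m10_onset: float        # clock hour of winning 10-h block start
    l5_onset: float
    ra: float


def _block_means(counts: np.ndarray, block: int) -> np.ndarray:
    """Means of all contiguous blocks of ``block`` windows (no wrap)."""
    c = np.cumsum(np.concatenate(([0.0], counts)))
    return (c[block:] - c[:-block]) / block


def m10_l5(counts: Sequence[float], window_length: int = 15,
           period_start_hour: float = 22.0) -> CircadianIndices:
    """M10 / L5 indices of one full 24-hour period of window counts.

    ``counts`` must cover the period at the given window length; up to
    10% of windows may be missing (NaN), in which case block means ignore
    them.  Ties between equal blocks go to the earliest start.
    """
    counts = np.asarray(counts, dtype=float)
    per_day = (24 * 60) // window_length
    if counts.size != per_day:
        raise ValueError(
            f"expected {per_day} windows for a full period, got {counts.size}")
    missing = np.isnan(counts)
    if missing.mean() > 0.10:
        raise ValueError("more than 10% of windows missing")
    b10 = int(10 * 60 / window_length)
    b5 = int(5 * 60 / window_length)
    if counts.size < b10:
        raise ValueError("period shorter than the 10-hour block")
    if missing.any():
        filled = counts.copy()
        filled[missing] = 0.0
        obs = (~missing).astype(float)
        sums10 = _block_means(filled, b10) * b10
        n10 = _block_means(obs, b10) * b10
        means10 = np.where(n10 > 0, sums10 / np.maximum(n10, 1), np.nan)
        sums5 = _block_means(filled, b5) * b5
        n5 = _block_means(obs, b5) * b5
        means5 = np.where(n5 > 0, sums5 / np.maximum(n5, 1), np.nan)
    else:
        means10 = _block_means(counts, b10)
        means5 = _block_means(counts, b5)
    i10 = int(np.nanargmax(means10))
    i5 = int(np.nanargmin(means5))
    m10 = float(means10[i10])
    l5 = float(means5[i5])
    step_h = window_length / 60.0
    m10_onset = (period_start_hour + i10 * step_h) % 24.0
    l5_onset = (period_start_hour + i5 * step_h) % 24.0
    return CircadianIndices(m10, l5, m10_onset, l5_onset,
                            relative_amplitude(m10, l5))


def relative_amplitude(m10: float, l5: float) -> float:
    """(M10 - L5) / (M10 + L5); NaN when both are zero."""
    if np.isnan(m10) or np.isnan(l5):
        return float("nan")
    if m10 + l5 == 0:
        return float("nan")
    return float((m10 - l5) / (m10 + l5))


# ---------------------------------------------------------------------------
# Feature registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    period: str      # full | night | day
    signal: str      # frac_<cat> | count | sit_to_stand | step_count
    statistic: str   # mean | pct_above_5/10/25 | iv | mean_sitting | m10 ...

    @property
    def name(self) -> str:
        return f"{self.period}__{self.signal}__{self.statistic}"


@dataclass
class FeatureRegistry:
    """Ordered collection of per-day feature definitions.

    The per-subject summary applies ``avg`` and ``var`` across days to
    every per-day feature, so the summary feature count is exactly twice
    the per-day count.
    """

    specs: list[FeatureSpec]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in registry")

    def __len__(self) -> int:
        return len(self.specs)

    @property
    def day_feature_names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def summary_feature_names(self) -> list[str]:
        return ([f"avg__{s.name}" for s in self.specs]
                + [f"var__{s.name}" for s in self.specs])

    @property
    def n_summary(self) -> int:
        return 2 * len(self.specs)


def default_registry(categories: Sequence[str] = CATEGORIES,
                     include_counts: bool = True,
                     include_events: bool = True,
                     periods: Sequence[str] = ("full", "night", "day"),
                     ) -> FeatureRegistry:
    """The default feature registry.

    Per period and category: mean fraction, percentage of windows above
    5/10/25% time in category, and IV of the fraction sequence.  The
    intensity count adds mean, mean during sitting-modal windows and IV
    per period plus full-period M10/L5 (with onsets) and RA.  Event
    signals (sit-to-stand, steps) get mean and IV per period.
    """
    specs: list[FeatureSpec] = []
    for period in periods:
        for cat in categories:
            sig = f"frac_{cat}"
            specs.append(FeatureSpec(period, sig, "mean"))
            for thr in PCT_THRESHOLDS:
                specs.append(FeatureSpec(period, sig,
                                         f"pct_above_{int(thr * 100)}"))
            specs.append(FeatureSpec(period, sig, "iv"))
        if include_counts:
            specs.append(FeatureSpec(period, "count", "mean"))
            specs.append(FeatureSpec(period, "count", "mean_sitting"))
            specs.append(FeatureSpec(period, "count", "iv"))
            if period == "full":
                for stat in ("m10", "m10_onset", "l5", "l5_onset", "ra"):
                    specs.append(FeatureSpec(period, "count", stat))
        if include_events:
            for sig in ("sit_to_stand", "step_count"):
                specs.append(FeatureSpec(period, sig, "mean"))
                specs.append(FeatureSpec(period, sig, "iv"))
    return FeatureRegistry(specs)


# ---------------------------------------------------------------------------
# Per-day extraction
# ---------------------------------------------------------------------------

def _signal_array(ws: WindowSeries, signal: str) -> np.ndarray:
    if signal == "count":
        return ws.counts
    if signal in ("sit_to_stand", "step_count"):
        return ws.data[signal].to_numpy(dtype=float)
    return ws.data[signal].to_numpy(dtype=float)


def extract_day_features(full_ws: WindowSeries,
                         registry: FeatureRegistry) -> pd.Series:
    """Per-day feature vector for one validated full period."""
    slices = {"full": full_ws}
    # night/day sub-slices by clock time within the single full period
    starts = full_ws.data["window_start"]
    hours = starts.dt.hour + starts.dt.minute / 60.0
    slices["night"] = WindowSeries(
        full_ws.subject_id, full_ws.window_length,
        full_ws.data.loc[(hours >= 0) & (hours < 6)])
    slices["day"] = WindowSeries(
        full_ws.subject_id, full_ws.window_length,
        full_ws.data.loc[(hours >= 9) & (hours < 21)])

    modal = {p: s.modal_categories() for p, s in slices.items()}
    circ: CircadianIndices | None = None
    values = np.empty(len(registry))
    for j, spec in enumerate(registry.specs):
        ws = slices[spec.period]
        if len(ws) == 0:
            values[j] = np.nan
            continue
        if spec.signal == "count" and spec.statistic in (
                "m10", "m10_onset", "l5", "l5_onset", "ra"):
            if circ is None:
                circ = _full_period_indices(full_ws)
            values[j] = getattr(circ, spec.statistic if spec.statistic != "ra"
                                else "ra")
            continue
        x = _signal_array(ws, spec.signal)
        stat = spec.statistic
        if stat == "mean":
            values[j] = float(np.mean(x))
        elif stat.startswith("pct_above_"):
            thr = int(stat.rsplit("_", 1)[1]) / 100.0
            values[j] = pct_windows_above(x, thr)
        elif stat == "iv":
            values[j] = (intradaily_variability(x) if x.size >= 3
                         else np.nan)
        elif stat == "mean_sitting":
            sit = modal[spec.period] == "sitting"
            values[j] = float(np.mean(x[sit])) if sit.any() else np.nan
        else:
            raise ValueError(f"unknown statistic {stat!r}")
    return pd.Series(values, index=registry.day_feature_names)


def _full_period_indices(full_ws: WindowSeries) -> CircadianIndices:
    """M10/L5/RA on the full period's count series, aligned to the 22:00
    grid with missing windows as NaN."""
    per_day = (24 * 60) // full_ws.window_length
    counts = np.full(per_day, np.nan)
    starts = full_ws.data["window_start"]
    if len(starts):
        anchor = starts.iloc[0].normalize() + pd.Timedelta(hours=22)
        if starts.iloc[0] < anchor:
            anchor -= pd.Timedelta(days=1)
        idx = ((starts - anchor).dt.total_seconds()
               // (full_ws.window_length * 60)).astype(int).to_numpy()
        ok = (idx >= 0) & (idx < per_day)
        counts[idx[ok]] = full_ws.counts[ok]
    try:
        return m10_l5(counts, full_ws.window_length)
    except ValueError:
        nan = float("nan")
        return CircadianIndices(nan, nan, nan, nan, nan)


# ---------------------------------------------------------------------------
# Subject summarization and table assembly
# ---------------------------------------------------------------------------

def summarize_subject(day_vectors: Sequence[pd.Series]) -> pd.Series:
    """Across-day average and unbiased variance of per-day features.

    Averages ignore missing days per feature; the variance needs at
    least two non-missing days and is missing otherwise.
    """
    if len(day_vectors) == 0:
        raise ValueError("no valid days to summarize")
    mat = pd.concat(day_vectors, axis=1).to_numpy(dtype=float)  # (feat, days)
    names = list(day_vectors[0].index)
    with np.errstate(invalid="ignore"):
        nvalid = np.sum(~np.isnan(mat), axis=1)
        sums = np.nansum(mat, axis=1)
        avg = np.where(nvalid > 0, sums / np.maximum(nvalid, 1), np.nan)
        dev = (mat - avg[:, None]) ** 2
        ssq = np.nansum(np.where(np.isnan(mat), np.nan, dev), axis=1)
        var = np.where(nvalid >= 2, ssq / np.maximum(nvalid - 1, 1), np.nan)
    out = np.concatenate([avg, var])
    idx = [f"avg__{n}" for n in names] + [f"var__{n}" for n in names]
    return pd.Series(out, index=idx)


def extract_features(window_series: Iterable[WindowSeries],
                     manifest: pd.DataFrame | None = None,
                     registry: FeatureRegistry | None = None,
                     min_wear: float = 0.8) -> pd.DataFrame:
    """Subjects x summary-features table from per-subject window series.

    Days failing the wear-time validation are excluded; subjects with no
    valid day are dropped (logged).  Manifest labels/covariates, when
    given, are joined on subject_id.
    """
    registry = registry or default_registry()
    rows = {}
    for ws in window_series:
        days = []
        for d in range(n_full_periods(ws)):
            full = slice_period(ws, FULL_PERIOD, d)
            if not validate_day(full, min_wear=min_wear):
                logger.info("subject %s day %d excluded (wear below %.2f)",
                            ws.subject_id, d, min_wear)
                continue
            days.append(extract_day_features(full, registry))
        if not days:
            logger.warning("subject %s excluded: no valid days", ws.subject_id)
            continue
        rows[ws.subject_id] = summarize_subject(days)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table[registry.summary_feature_names]
    table.index.name = "subject_id"
    if manifest is not None:
        meta = manifest.set_index("subject_id")
        table = table.join(meta, how="left")
    return table.reset_index()
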