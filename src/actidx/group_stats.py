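"""Group-level descriptive statistics and figures.

Kruskal-Wallis comparisons of features across diagnostic groups,
group-average 24-hour intensity curves smoothed within the closest hour,
actogram rendering, and an ordinary-least-squares probe of whether the
classifier's output probabilities are confounded by age, sex or
medication use.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import FULL_PERIOD, WindowSeries, n_full_periods, slice_period

logger = logging.getLogger(__name__)


def kruskal_wallis(values: Sequence[float], groups: Sequence
                   ) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p across groups.

    All-identical values are degenerate and return (0, 1).  A group whose
    values are all missing raises an error naming it.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    samples = []
    for g in pd.unique(groups):
        v = values[groups == g]
        v = v[~np.isnan(v)]
        if v.size == 0:
            raise ValueError(f"group {g!r} has no non-missing values")
        samples.append(v)
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    flat = np.concatenate(samples)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def group_table(features: pd.DataFrame, columns: Sequence[str],
                group_col: str = "diagnosis") -> pd.DataFrame:
    """Per-feature group means +/- SD with Kruskal-Wallis H and p."""
    rows = []
    groups = features[group_col]
    for col in columns:
        v = features[col].to_numpy(dtype=float)
        entry = {"feature": col}
        for g, sub in features.groupby(group_col, sort=False):
            x = sub[col].to_numpy(dtype=float)
            x = x[~np.isnan(x)]
            entry[f"{g}_mean"] = float(np.mean(x)) if x.size else float("nan")
            entry[f"{g}_sd"] = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
        try:
            h, p = kruskal_wallis(v, groups)
        except ValueError:
            h, p = float("nan"), float("nan")
        entry["H"] = h
        entry["p_value"] = p
        rows.append(entry)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group-average 24-hour intensity curve
# ---------------------------------------------------------------------------

def _circular_hour_smooth(x: np.ndarray) -> np.ndarray:
    """Centered 1-hour moving average at 15-minute resolution.

    Four equal taps at offsets (-2, -1, 0, +1) windows, wrapping across
    the 24-hour boundary; the kernel sums to one so the daily mean is
    conserved.
    """
    return (np.roll(x, 2) + np.roll(x, 1) + x + np.roll(x, -1)) / 4.0


def subject_daily_profile(ws: WindowSeries) -> np.ndarray:
    """Mean count per clock window over a subject's recording (from
    midnight, 96 values at 15-minute resolution); NaN where never
    observed."""
    per_day = (24 * 60) // ws.window_length
    starts = ws.data["window_start"]
    idx = ((starts.dt.hour * 60 + starts.dt.minute)
           // ws.window_length).to_numpy()
    sums = np.bincount(idx, weights=ws.counts, minlength=per_day)
    cnts = np.bincount(idx, minlength=per_day)
    with np.errstate(invalid="ignore"):
        return np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)


def group_mean_curve(window_series: Sequence[WindowSeries],
                     groups: Sequence[str]) -> pd.DataFrame:
    """Smoothed group-average 24-hour intensity curves with SE bands.

    Each subject contributes its across-days mean profile; profiles are
    smoothed within the closest hour (circular four-window average) and
    averaged within group; the band is the across-subject standard error.
    Columns: clock_hour, group, mean, se, n.
    """
    groups = list(groups)
    if len(groups) != len(list(window_series)):
        raise ValueError("one group label per window series required")
    profs: dict[str, list[np.ndarray]] = {}
    for ws, g in zip(window_series, groups):
        profs.setdefault(g, []).append(
            _circular_hour_smooth(np.nan_to_num(subject_daily_profile(ws))))
    rows = []
    for g, plist in profs.items():
        if not plist:
            raise ValueError(f"group {g!r} is empty")
        mat = np.vstack(plist)
        n = mat.shape[0]
        mean = mat.mean(axis=0)
        se = (mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1
              else np.zeros(mat.shape[1]))
        wl_h = 24.0 / mat.shape[1]
        for i in range(mat.shape[1]):
            rows.append({"clock_hour": i * wl_h, "group": g,
                         "mean": float(mean[i]), "se": float(se[i]), "n": n})
    return pd.DataFrame(rows)


def plot_group_curves(curve: pd.DataFrame, out_path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for g, sub in curve.groupby("group", sort=False):
        ax.plot(sub["clock_hour"], sub["mean"], label=g)
        ax.fill_between(sub["clock_hour"], sub["mean"] - sub["se"],
                        sub["mean"] + sub["se"], alpha=0.25)
    ax.set_xlabel("clock hour")
    ax.set_ylabel("intensity count per window")
    ax.set_xlim(0, 24)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Output-probability confounder probe
# ---------------------------------------------------------------------------

def confounder_probe(probabilities: pd.Series | np.ndarray,
                     manifest: pd.DataFrame,
                     subject_ids: Sequence[str],
                     subgroup: Sequence[str] | None = None,
                     logit_response: bool = False) -> pd.DataFrame:
    """OLS of the classifier's output probability on covariates.

    Regresses each subject's out-of-fold probability on age, sex and the
    four medication flags within the chosen diagnosis subgroup.  A
    constant or collinear covariate is dropped with a warning.  With
    ``logit_response`` the (clipped) logit of the probability is modeled
    instead of the identity scale.
    """
    import statsmodels.api as sm

    df = pd.DataFrame({"subject_id": [str(s) for s in subject_ids],
                       "prob": np.asarray(probabilities, dtype=float)})
    meta = manifest.copy()
    meta["subject_id"] = meta["subject_id"].astype(str)
    df = df.merge(meta, on="subject_id", how="left")
    if subgroup is not None:
        df = df[df["diagnosis"].isin(list(subgroup))]
    if len(df) < 2:
        raise ValueError("subgroup has fewer than two subjects")
    yv = df["prob"].to_numpy(dtype=float)
    if logit_response:
        q = np.clip(yv, 1e-6, 1 - 1e-6)
        yv = np.log(q / (1 - q))
    covs = pd.DataFrame({
        "age": df["age"].astype(float),
        "sex_male": (df["sex"] == "M").astype(float),
        "antidepressant": df["antidepressant"].astype(float),
        "antipsychotic": df["antipsychotic"].astype(float),
        "hypnotic": df["hypnotic"].astype(float),
        "sedative_analgesic": df["sedative_analgesic"].astype(float),
    })
    keep = [c for c in covs.columns if covs[c].nunique() > 1]
    dropped = sorted(set(covs.columns) - set(keep))
    if dropped:
        warnings.warn(f"dropping constant covariates: {dropped}",
                      stacklevel=2)
    Xd = sm.add_constant(covs[keep])
    fit = sm.OLS(yv, Xd).fit()
    return pd.DataFrame({
        "covariate": Xd.columns,
        "coef": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "p_value": fit.pvalues.to_numpy(),
    })


# ---------------------------------------------------------------------------
# Actogram
# ---------------------------------------------------------------------------

#: Fixed category colors keyed by name so renders are reproducible.
ACTOGRAM_COLORS = {
    "lying_rest": "#1f3b73",
    "lying_movement": "#4c6bb0",
    "sitting": "#b0b0b0",
    "upright_standing": "#ffd166",
    "sporadic_walking": "#f4a261",
    "walking": "#e76f51",
    "moderate_intensity": "#d62828",
    "running": "#9d0208",
    "cycling": "#2a9d8f",
    "": "#ffffff",        # no wear
}


def render_actogram(ws: WindowSeries, out_path) -> None:
    """One row per recording day, colored by the modal window category."""
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib.colors import ListedColormap
    import matplotlib.pyplot as plt

    n_days = max(1, n_full_periods(ws))
    per_day = (24 * 60) // ws.window_length
    names = list(ACTOGRAM_COLORS)
    code = {c: i for i, c in enumerate(names)}
    grid = np.full((n_days, per_day), code[""], dtype=int)
    for d in range(n_days):
        day = slice_period(ws, FULL_PERIOD, d)
        if len(day) == 0:
            continue
        starts = day.data["window_start"]
        anchor = starts.iloc[0]
        idx = ((starts - anchor).dt.total_seconds()
               // (ws.window_length * 60)).astype(int).to_numpy()
        modal = day.modal_categories()
        ok = (idx >= 0) & (idx < per_day)
        grid[d, idx[ok]] = [code[m] for m in modal[ok]]
    cmap = ListedColormap([ACTOGRAM_COLORS[c] for c in names])
    fig, ax = plt.subplots(figsize=(10, 0.5 + 0.4 * n_days))
    ax.imshow(grid, aspect="auto", cmap=cmap, vmin=0, vmax=len(names) - 1,
              interpolation="nearest")
    ax.set_yticks(range(n_days), [f"day {d}" for d in range(n_days)])
    ax.set_xticks(np.linspace(0, per_day, 7),
                  [f"{int(22 + 4 * i) % 24:02d}:00" for i in range(7)])
    ax.set_xlabel("clock time (period anchored at 22:00)")
    ax.set_title(f"actogram: {ws.subject_id}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
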