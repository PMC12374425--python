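"""Synthetic rest-activity cohort generator.

Generates per-subject epoch-level activity series (category + intensity
count every 5 seconds) with group-level circadian and composition
structure, so that the whole downstream pipeline — windowing, feature
extraction, group statistics and the nested-cross-validated classifier —
can be exercised without any recorded data.

Generative model (per subject)
------------------------------
The expected intensity count of the 15-minute window starting at clock
hour h is a clipped cosinor plus an optional late-afternoon Gaussian
bump (present in the healthy-control preset only):

    drive(h) = max(0, mesor + amplitude * cos(2*pi*(h - acrophase)/24)
                     + bump_height * exp(-(h - bump_center)^2 /
                                          (2 * bump_width^2)))

A binary behavioural state (rest / active) follows the circadian drive:
the baseline state is active when the drive exceeds the mesor, and each
window independently flips state with probability ``frag_rate`` — the
fragmentation dial.  The window's expected count is the rest level
(mesor - amplitude) in rest windows and the circadian drive in active
windows, so fragmentation flips translate into count-level jumps and a
higher intra-daily variability.  Additional nighttime wake windows
(00:00-06:00) are injected at ``night_wake_rate`` expected windows per
night; wake windows also receive a count boost of half the mesor so that
fragmented sleepers show an elevated least-active-5-hour (L5) level.

Each window draws a dominant category from the state-conditional
category mix; walking windows come in geometric bouts with mean
``walk_bout_mean`` windows.  Within a window, epochs take the dominant
category with probability 0.75 and are redrawn from the state mix
otherwise.  The window's realized count target (drive x multiplicative
log-normal noise with log-SD ``noise_sd``) is then distributed over its
epochs proportionally to per-category intensity weights, which keeps
category composition and counts consistent.

The bundled group presets encode only the direction and coarse magnitude
of published group contrasts (overall intensity HC > AD > DLB > vascular
groups; elevated nighttime activity and fragmentation in DLB and
vascular disease; a late-afternoon activity peak only in controls); they
are not a fit to any recorded cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ingest import CATEGORIES, _CAT_INDEX, EpochSeries

WINDOWS_PER_DAY = 96          # at 15-minute resolution
EPOCHS_PER_WINDOW = 180       # at 5-second epochs

#: Relative intensity weight of one epoch in each category, used to
#: allocate a window's count target over its epochs.
CATEGORY_INTENSITY_WEIGHT = {
    "lying_rest": 0.5,
    "lying_movement": 4.0,
    "sitting": 3.0,
    "upright_standing": 10.0,
    "sporadic_walking": 30.0,
    "walking": 60.0,
    "moderate_intensity": 100.0,
    "running": 150.0,
    "cycling": 80.0,
}


@dataclass
class GroupProfile:
    """Generative parameters of one diagnostic group."""

    name: str
    mesor: float                 # mean window count (counts / 15 min)
    amplitude: float             # cosinor amplitude, <= mesor
    acrophase: float = 14.0      # clock hour of circadian peak
    afternoon_bump: tuple[float, float, float] | None = None  # (height, center h, width h)
    frag_rate: float = 0.05      # per-window state-flip probability
    night_wake_rate: float = 1.0  # expected wake windows per night (00-06)
    category_mix: dict[str, dict[str, float]] = field(default_factory=dict)
    walk_bout_mean: float = 2.0  # mean walking bout length, windows
    noise_sd: float = 0.3        # log-SD of multiplicative count noise
    between_subject_cv: float = 0.25  # subject-level CV of the count level
    mix_concentration: float = 60.0   # Dirichlet concentration of per-subject
                                      # category-mix draws (higher = tighter)
    age_mean: float = 75.0
    age_sd: float = 7.0
    female_prop: float = 0.5
    med_prev: dict[str, float] = field(default_factory=dict)
    mmse_mean: float = 27.0
    mmse_sd: float = 2.5

    def __post_init__(self) -> None:
        if not self.category_mix:
            self.category_mix = {
                "rest": {"lying_rest": 0.92, "lying_movement": 0.04,
                         "sitting": 0.04},
                "active": {"sitting": 0.42, "upright_standing": 0.18,
                           "sporadic_walking": 0.16, "walking": 0.12,
                           "moderate_intensity": 0.05, "lying_rest": 0.04,
                           "lying_movement": 0.01, "running": 0.005,
                           "cycling": 0.015},
            }
        for state, mix in self.category_mix.items():
            tot = sum(mix.values())
            if not np.isclose(tot, 1.0):
                raise ValueError(
                    f"category_mix[{state!r}] sums to {tot}, expected 1")
            unknown = set(mix) - set(CATEGORIES)
            if unknown:
                raise ValueError(f"unknown categories in mix: {unknown}")
        if self.mesor - self.amplitude < 0:
            raise ValueError("amplitude must not exceed mesor")
        if self.frag_rate < 0 or self.night_wake_rate < 0:
            raise ValueError("rates must be nonnegative")

    def mix_vector(self, state: str) -> np.ndarray:
        v = np.zeros(len(CATEGORIES))
        for c, p in self.category_mix[state].items():
            v[_CAT_INDEX[c]] = p
        return v


@dataclass
class CohortConfig:
    """A cohort as a list of (profile, group size) with a master seed."""

    groups: list[tuple[GroupProfile, int]]
    days: int = 7
    window_length: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        names = [p.name for p, _ in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        if any(n < 1 for _, n in self.groups):
            raise ValueError("group sizes must be >= 1")


def _subject_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed,
                                  spawn_key=(index,))


def drive_curve(profile: GroupProfile, hours: np.ndarray) -> np.ndarray:
    """Expected window count at each clock hour (before noise)."""
    d = profile.mesor + profile.amplitude * np.cos(
        2 * np.pi * (hours - profile.acrophase) / 24.0)
    if profile.afternoon_bump is not None:
        height, center, width = profile.afternoon_bump
        d = d + height * np.exp(-((hours - center) ** 2) / (2 * width ** 2))
    return np.maximum(d, 0.0)


def generate_subject(profile: GroupProfile, days: int, seed,
                     subject_id: str = "S000",
                     start_time: str | pd.Timestamp = "2024-01-01 00:00:00",
                     ) -> EpochSeries:
    """Generate one subject's complete 5-second epoch series."""
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    n_win = days * WINDOWS_PER_DAY
    hours = (np.arange(n_win) % WINDOWS_PER_DAY) * 0.25

    # subject-level heterogeneity: activity level, fragmentation and
    # nighttime wake propensity vary between subjects of a group
    bs = profile.between_subject_cv
    level = rng.lognormal(-0.5 * bs * bs, bs) if bs > 0 else 1.0
    subj = replace(profile,
                   mesor=profile.mesor * level,
                   amplitude=profile.amplitude * level,
                   afternoon_bump=None if profile.afternoon_bump is None
                   else (profile.afternoon_bump[0] * level,
                         profile.afternoon_bump[1],
                         profile.afternoon_bump[2]))
    frag = profile.frag_rate * (rng.lognormal(-0.045, 0.3) if bs > 0 else 1.0)
    wake_rate = profile.night_wake_rate
    if bs > 0 and wake_rate > 0:
        wake_rate = rng.gamma(4.0, wake_rate / 4.0)
    if bs > 0:
        subj = replace(subj, acrophase=subj.acrophase + rng.normal(0, 0.75))
    walk_bout = profile.walk_bout_mean
    if bs > 0:
        walk_bout = max(1.0, walk_bout * rng.lognormal(-0.03, 0.25))
    drive = drive_curve(subj, hours)

    def _jitter_mix(vec: np.ndarray) -> np.ndarray:
        if bs <= 0 or profile.mix_concentration <= 0:
            return vec
        out = np.zeros_like(vec)
        nz = vec > 0
        out[nz] = rng.dirichlet(vec[nz] * profile.mix_concentration)
        return out

    # behavioural state: circadian baseline with fragmentation flips
    base_active = drive > subj.mesor
    flips = rng.random(n_win) < frag
    active = base_active ^ flips
    night = hours < 6.0
    wake_p = min(1.0, wake_rate / 24.0)
    wakes = night & (rng.random(n_win) < wake_p)
    active = active | wakes

    # dominant category per window from the (subject-jittered) state mix
    mix_rest = _jitter_mix(profile.mix_vector("rest"))
    mix_active = _jitter_mix(profile.mix_vector("active"))
    u = rng.random(n_win)
    cdf_rest = np.cumsum(mix_rest)
    cdf_active = np.cumsum(mix_active)
    dom = np.where(active,
                   np.searchsorted(cdf_active, u, side="right"),
                   np.searchsorted(cdf_rest, u, side="right"))
    dom = np.minimum(dom, len(CATEGORIES) - 1)

    # walking bouts: a walking window extends over a geometric bout
    walk_code = _CAT_INDEX["walking"]
    if walk_bout > 1:
        p_cont = 1.0 - 1.0 / walk_bout
        i = 0
        while i < n_win:
            if dom[i] == walk_code and active[i]:
                j = i + 1
                while (j < n_win and active[j]
                       and rng.random() < p_cont):
                    dom[j] = walk_code
                    j += 1
                i = j
            else:
                i += 1

    # window count targets: rest level when resting, circadian drive when
    # active, multiplicative log-normal noise, and a boost for injected
    # nighttime wakes
    rest_level = max(subj.mesor - subj.amplitude, 0.0)
    noise = rng.lognormal(mean=-0.5 * profile.noise_sd ** 2,
                          sigma=profile.noise_sd, size=n_win)
    target = (rest_level + (drive - rest_level) * active) * noise
    target[wakes] += 0.5 * subj.mesor * noise[wakes]

    # epoch categories: dominant with prob 0.75, else redraw from mix
    n_ep = n_win * EPOCHS_PER_WINDOW
    ep_state = np.repeat(active, EPOCHS_PER_WINDOW)
    ep_dom = np.repeat(dom, EPOCHS_PER_WINDOW)
    redraw = rng.random(n_ep) >= 0.75
    u2 = rng.random(n_ep)
    alt = np.where(ep_state,
                   np.searchsorted(cdf_active, u2, side="right"),
                   np.searchsorted(cdf_rest, u2, side="right"))
    alt = np.minimum(alt, len(CATEGORIES) - 1)
    cats = np.where(redraw, alt, ep_dom).astype(np.int64)

    # allocate window count targets over epochs by category weight
    weights = np.zeros(len(CATEGORIES))
    for c, w in CATEGORY_INTENSITY_WEIGHT.items():
        weights[_CAT_INDEX[c]] = w
    ep_w = weights[cats].reshape(n_win, EPOCHS_PER_WINDOW)
    w_sum = ep_w.sum(axis=1, keepdims=True)
    alloc = ep_w / np.maximum(w_sum, 1e-12) * target[:, None]
    intensity = rng.poisson(alloc.reshape(-1)).astype(np.int64)

    return EpochSeries(
        subject_id=subject_id,
        sensor_site="thigh",
        start_time=pd.Timestamp(start_time),
        categories=cats,
        intensity=intensity,
        epoch_length=5.0,
    )


def generate_cohort(config: CohortConfig
                    ) -> tuple[list[EpochSeries], pd.DataFrame]:
    """Generate all subjects plus a manifest table.

    Subjects are generated independently with per-subject seeds derived
    from the master seed, so the output is reproducible and insensitive
    to generation order.
    """
    series: list[EpochSeries] = []
    rows = []
    idx = 0
    for profile, n in config.groups:
        for _ in range(n):
            sid = f"{profile.name}_{idx:03d}"
            ss = _subject_seed(config.seed, idx)
            child, cov = ss.spawn(2)
            series.append(generate_subject(profile, config.days, child,
                                           subject_id=sid))
            crng = np.random.default_rng(cov)
            rows.append({
                "subject_id": sid,
                "diagnosis": profile.name,
                "age": float(np.round(np.clip(
                    crng.normal(profile.age_mean, profile.age_sd), 50, 95), 1)),
                "sex": "F" if crng.random() < profile.female_prop else "M",
                "antidepressant": bool(
                    crng.random() < profile.med_prev.get("antidepressant", 0.1)),
                "antipsychotic": bool(
                    crng.random() < profile.med_prev.get("antipsychotic", 0.02)),
                "hypnotic": bool(
                    crng.random() < profile.med_prev.get("hypnotic", 0.01)),
                "sedative_analgesic": bool(
                    crng.random() < profile.med_prev.get("sedative_analgesic", 0.03)),
                "mmse": int(np.clip(np.round(
                    crng.normal(profile.mmse_mean, profile.mmse_sd)), 0, 30)),
            })
            idx += 1
    return series, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group presets
# ---------------------------------------------------------------------------

def _preset_profile(name: str, overall_per_min: float, l5_target: float,
                    **kw) -> GroupProfile:
    """Profile whose mean window count targets ``overall_per_min`` counts
    per minute and whose circadian trough targets ``l5_target`` counts
    per window (before nighttime wakes).

    The expected window count of the generative model,

        E = rest + amplitude * mean[(1 + cos) * P(active)]
            + mean[bump * P(active)] + wake boost,

    is linear in the amplitude once the rest level is pinned at the L5
    target, so the mesor/amplitude pair is obtained by inverting that
    expectation on the discrete window grid.
    """
    hours = np.arange(WINDOWS_PER_DAY) * 0.25
    acro = kw.get("acrophase", 14.0)
    c = np.cos(2 * np.pi * (hours - acro) / 24.0)
    b = c > 0.0                                  # baseline active windows
    f = kw.get("frag_rate", 0.05)
    p_active = np.where(b, 1.0 - f, f)
    bump = kw.get("afternoon_bump")
    bump_mass = 0.0
    if bump is not None:
        height, center, width = bump
        bump_mass = float(np.mean(
            height * np.exp(-((hours - center) ** 2) / (2 * width ** 2))
            * p_active))
    wake = 0.5 * kw.get("night_wake_rate", 1.0) / WINDOWS_PER_DAY
    gain = float(np.mean((1.0 + c) * p_active))
    target = overall_per_min * 15.0
    amplitude = (target - l5_target - bump_mass - wake * l5_target) / (
        gain + wake)
    amplitude = min(max(amplitude, 0.0), target * 2)
    return GroupProfile(name=name, mesor=l5_target + amplitude,
                        amplitude=amplitude, **kw)


def paper_like_cohort(days: int = 7, seed: int = 0,
                      sizes: dict[str, int] | None = None) -> CohortConfig:
    """Cohort preset mirroring the direction and coarse magnitude of the
    published group contrasts.

    Controls are the most active with a robust rhythm and a late-
    afternoon activity bump; Alzheimer's disease is moderately less
    active with a preserved rhythm; Lewy-body and vascular groups are
    less active with fragmented rhythms and elevated nighttime activity.
    Default sizes are the study's group sizes.
    """
    if sizes is None:
        sizes = {"AD": 70, "DLB": 29, "MixedAD": 8, "VCD": 15, "HC": 48}

    active_mix = {
        "HC": {"sitting": 0.38, "upright_standing": 0.17,
               "sporadic_walking": 0.17, "walking": 0.15,
               "moderate_intensity": 0.06, "lying_rest": 0.03,
               "lying_movement": 0.01, "running": 0.008, "cycling": 0.022},
        "AD": {"sitting": 0.41, "upright_standing": 0.18,
               "sporadic_walking": 0.18, "walking": 0.12,
               "moderate_intensity": 0.04, "lying_rest": 0.05,
               "lying_movement": 0.01, "running": 0.005, "cycling": 0.005},
        "DLB": {"sitting": 0.41, "upright_standing": 0.18,
                "sporadic_walking": 0.15, "walking": 0.10,
                "moderate_intensity": 0.04, "lying_rest": 0.09,
                "lying_movement": 0.012, "running": 0.005, "cycling": 0.013},
        "MixedAD": {"sitting": 0.46, "upright_standing": 0.22,
                    "sporadic_walking": 0.14, "walking": 0.08,
                    "moderate_intensity": 0.02, "lying_rest": 0.06,
                    "lying_movement": 0.013, "running": 0.001,
                    "cycling": 0.006},
        "VCD": {"sitting": 0.48, "upright_standing": 0.15,
                "sporadic_walking": 0.13, "walking": 0.08,
                "moderate_intensity": 0.02, "lying_rest": 0.12,
                "lying_movement": 0.012, "running": 0.001, "cycling": 0.007},
    }
    rest_mix = {"lying_rest": 0.92, "lying_movement": 0.04, "sitting": 0.04}

    def mk(name, overall, l5, frag, wake, bump, walk_bout, age, female,
           mmse):
        return _preset_profile(
            name, overall, l5,
            afternoon_bump=bump,
            frag_rate=frag,
            night_wake_rate=wake,
            category_mix={"rest": dict(rest_mix),
                          "active": dict(active_mix[name])},
            walk_bout_mean=walk_bout,
            age_mean=age, age_sd=7.0, female_prop=female,
            mmse_mean=mmse, mmse_sd=2.5,
        )

    profiles = {
        # name  overall/min  L5  frag  wakes/night  bump           bout  age  %F   mmse
        "HC": mk("HC", 39.1, 24.5, 0.04, 1.0, (200.0, 17.0, 1.5), 3.0,
                 71.1, 0.62, 29.1),
        "AD": mk("AD", 31.7, 22.2, 0.05, 1.0, None, 2.5, 75.3, 0.47, 25.5),
        "DLB": mk("DLB", 29.1, 36.0, 0.12, 4.0, None, 2.0, 76.2, 0.14, 26.2),
        "MixedAD": mk("MixedAD", 19.5, 43.5, 0.14, 5.0, None, 1.5,
                      81.8, 0.50, 22.6),
        "VCD": mk("VCD", 21.4, 34.9, 0.13, 4.0, None, 1.5, 78.5, 0.33, 26.5),
    }
    groups = [(profiles[g], n) for g, n in sizes.items() if n > 0]
    return CohortConfig(groups=groups, days=days, seed=seed)


def null_cohort(n_per_group: int = 10,
                groups: tuple[str, ...] = ("AD", "DLB", "HC"),
                days: int = 7, seed: int = 0) -> CohortConfig:
    """All groups share one profile: no true group differences."""
    base = _preset_profile("AD", 30.0, 25.0, frag_rate=0.08,
                           night_wake_rate=2.0, walk_bout_mean=2.0)
    gs = [(replace(base, name=g), n_per_group) for g in groups]
    return CohortConfig(groups=gs, days=days, seed=seed)
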