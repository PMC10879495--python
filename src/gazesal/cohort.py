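"""Synthetic cohorts of free-viewing scanpaths with group structure.

The generator emulates a two-group eye-tracking study (schizophrenia
patients, ``SCHZ``, vs. healthy controls, ``HC``) in which each subject
freely views a set of color stimuli for a fixed trial duration while their
fixations are recorded.  Everything downstream of acquisition — cleaning,
saliency scoring, mixed-model inference — can therefore be exercised and
validated without access to clinical recordings.

The statistical structure generated per trial:

* the fixation **count** is a rounded normal draw truncated at one, with
  group-specific mean/SD;
* fixation **durations** follow a piecewise-linear curve over fixation
  index (baseline -> peak -> convergence value) plus a per-subject shift
  and i.i.d. Gaussian noise;
* fixation **locations** are sampled from a pixel-level mixture of a
  bottom-up saliency map and an object-prior map, blended with a fixed
  center-bias kernel; the bottom-up mixing weight switches from an early
  to a late value at a configurable fixation index, emulating the shift
  from stimulus-driven to semantically driven viewing;
* each trial is preceded by a fixation-cross event at one of the eight
  off-center cross positions of the acquisition protocol, tagged in the
  output so the cleaning stage can be validated exactly.

Reproducibility: one root seed; the RNG stream of subject ``i`` viewing
stimulus ``j`` is ``numpy.random.SeedSequence(seed, spawn_key=(i, j))``,
so any subset of trials can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

CATEGORIES: tuple[str, ...] = (
    "congruent",
    "incongruent",
    "physically_salient",
    "social_interaction",
    "social_landscape",
)

GROUPS: tuple[str, ...] = ("SCHZ", "HC")

#: Screen geometry of the acquisition setup (4K presentation monitor).
SCREEN_W = 3840
SCREEN_H = 2160
TRIAL_DURATION_MS = 5000

#: Fixation-cross placement: (distance from screen center in px, angle in
#: degrees, math convention with y pointing up).  Eight possible positions.
CROSS_POLAR: tuple[tuple[float, float], ...] = (
    (1275.0, 155.0),
    (1275.0, -155.0),
    (1275.0, 25.0),
    (1275.0, -25.0),
    (542.0, 90.0),
    (542.0, -90.0),
    (1150.0, 0.0),
    (1150.0, 180.0),
)
CROSS_SIZE_PX = 183
CROSS_STROKE_PX = 7


def cross_positions(screen_w: int = SCREEN_W, screen_h: int = SCREEN_H) -> np.ndarray:
    """The eight fixation-cross centers in screen coordinates (x right, y down)."""
    cx, cy = screen_w / 2.0, screen_h / 2.0
    pos = []
    for dist, ang in CROSS_POLAR:
        rad = math.radians(ang)
        pos.append((cx + dist * math.cos(rad), cy - dist * math.sin(rad)))
    return np.asarray(pos)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of one synthetic stimulus.

    ``object_regions`` are circular patches standing in for semantically
    meaningful objects; their ``prior_weight`` sets the mass of the
    object-prior map.  ``salient_region`` marks a physically conspicuous
    patch rendered with elevated local contrast.
    """

    stimulus_id: str
    category: str
    width_px: int
    height_px: int
    object_regions: tuple[tuple[float, float, float, float], ...]  # (cx, cy, r, w)
    salient_region: tuple[float, float, float, float] | None  # (cx, cy, r, boost)
    background_seed: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("stimulus must have positive area")
        for cx, cy, r, w in self.object_regions:
            if not (0 <= cx < self.width_px and 0 <= cy < self.height_px):
                raise ValueError(f"object region center ({cx}, {cy}) outside stimulus")
            if w < 0:
                raise ValueError("prior_weight must be nonnegative")
        if self.salient_region is not None:
            cx, cy, r, boost = self.salient_region
            if not (0 <= cx < self.width_px and 0 <= cy < self.height_px):
                raise ValueError("salient region center outside stimulus")
            if boost <= 0:
                raise ValueError("contrast_boost must be positive")
        if self.category == "physically_salient" and self.salient_region is None:
            raise ValueError("physically_salient stimuli require a salient_region")


@dataclass(frozen=True)
class GroupParams:
    """Generator parameters for one subject group.

    Durations (ms) follow a piecewise-linear curve over fixation index:
    ``dur_baseline_ms`` at index 1, rising to ``dur_peak_ms`` at
    ``dur_peak_index``, then decaying linearly to ``dur_converge_ms`` at
    ``dur_converge_index`` and staying there.  ``dur_subject_sd_ms`` is the
    SD of a per-subject additive shift of the whole curve;
    ``dur_noise_sd_ms`` is i.i.d. per-fixation noise.

    ``w_bottomup_early``/``w_bottomup_late`` weight the bottom-up map in
    the location mixture before/after fixation ``w_switch_index``;
    ``spread_sd_px`` is the per-axis SD of the default isotropic
    object-prior used when a stimulus defines no object regions.
    """

    group_label: str
    n_fix_mean: float
    n_fix_sd: float
    dur_baseline_ms: float
    dur_peak_ms: float
    dur_peak_index: int
    dur_converge_index: int
    dur_converge_ms: float
    dur_noise_sd_ms: float = 50.0
    dur_subject_sd_ms: float = 20.0
    spread_sd_px: float = 500.0
    w_bottomup_early: float = 0.6
    w_bottomup_late: float = 0.3
    w_switch_index: int = 6

    def __post_init__(self) -> None:
        if self.n_fix_mean <= 0:
            raise ValueError("n_fix_mean must be positive")
        if self.n_fix_sd < 0:
            raise ValueError("n_fix_sd must be nonnegative")
        for w in (self.w_bottomup_early, self.w_bottomup_late):
            if not 0.0 <= w <= 1.0:
                raise ValueError("bottom-up weights must lie in [0, 1]")
        if self.dur_peak_index < 1:
            raise ValueError("dur_peak_index must be >= 1")
        if self.dur_converge_index <= self.dur_peak_index:
            raise ValueError("dur_converge_index must exceed dur_peak_index")

    def replace(self, **kwargs) -> "GroupParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class CohortConfig:
    """Study-level configuration of the synthetic cohort.

    Defaults mirror the emulated study: 28 SCHZ + 25 HC subjects, 250
    stimuli in five categories (50 each), 5-s free viewing on a
    3840x2160 screen.
    """

    n_schz: int = 28
    n_hc: int = 25
    n_stimuli: int = 250
    categories: tuple[str, ...] = CATEGORIES
    trial_duration_ms: int = TRIAL_DURATION_MS
    screen_w: int = SCREEN_W
    screen_h: int = SCREEN_H
    seed: int = 0
    group_params: dict[str, GroupParams] = field(default_factory=lambda: study_group_params())
    #: weight of the fixed central Gaussian blended into every location mixture
    center_bias_weight: float = 0.2
    #: per-axis SD of the center-bias kernel, as a fraction of each dimension
    center_bias_sd_frac: float = 0.25
    #: resolution at which location mixtures are sampled (cells); fixation
    #: coordinates get continuous within-cell jitter and are reported in
    #: screen pixels, so this only bounds the spatial quantization
    map_w: int = 240
    map_h: int = 135
    min_duration_ms: float = 60.0

    def __post_init__(self) -> None:
        if self.n_schz < 0 or self.n_hc < 0 or self.n_schz + self.n_hc == 0:
            raise ValueError("need at least one subject")
        if self.n_stimuli <= 0:
            raise ValueError("n_stimuli must be positive")
        unknown = set(self.categories) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        if self.screen_w <= 0 or self.screen_h <= 0:
            raise ValueError("screen must have positive area")


# ---------------------------------------------------------------------------
# Study parameter helpers
# ---------------------------------------------------------------------------

#: Duration-curve shape anchors (ms) before calibration: controls show a
#: modest early rise then stay flat; patients start higher, peak around the
#: fifth fixation and converge to the control level by the fifteenth.
_CURVE_SHAPES = {
    "SCHZ": dict(dur_baseline_ms=300.0, dur_peak_ms=380.0, dur_peak_index=5,
                 dur_converge_index=15, dur_converge_ms=290.0),
    "HC": dict(dur_baseline_ms=240.0, dur_peak_ms=290.0, dur_peak_index=5,
               dur_converge_index=15, dur_converge_ms=290.0),
}

#: Printed oculomotor summaries of the emulated study; used to calibrate
#: the generator defaults.
STUDY_SUMMARIES = {
    "SCHZ": dict(n_fix_mean=8.92, n_fix_sd=1.28, mean_duration_ms=326.12, sdd_px=678.28),
    "HC": dict(n_fix_mean=9.22, n_fix_sd=0.75, mean_duration_ms=254.83, sdd_px=727.56),
}


def duration_curve(params: GroupParams, indices) -> np.ndarray:
    """Expected fixation duration (ms) at 1-based fixation ``indices``."""
    k = np.asarray(indices, dtype=float)
    base, peak = params.dur_baseline_ms, params.dur_peak_ms
    kp, kc = params.dur_peak_index, params.dur_converge_index
    conv = params.dur_converge_ms
    if kp > 1:
        rise = base + (peak - base) * (k - 1) / (kp - 1)
    else:
        rise = np.full_like(k, peak)
    decay = peak + (conv - peak) * (k - kp) / (kc - kp)
    out = np.where(k <= kp, rise, np.where(k <= kc, decay, conv))
    return out


def count_pmf(n_fix_mean: float, n_fix_sd: float, k_max: int | None = None) -> np.ndarray:
    """PMF of the per-trial fixation count ``K = max(1, round(N(mean, sd)))``.

    Entry ``i`` is ``P(K = i + 1)``; the support is truncated at a point
    where the residual upper tail is numerically negligible.
    """
    if n_fix_sd == 0:
        k = max(1, round(n_fix_mean))
        pmf = np.zeros(k)
        pmf[k - 1] = 1.0
        return pmf
    if k_max is None:
        k_max = int(math.ceil(n_fix_mean + 10 * n_fix_sd)) + 1
    ks = np.arange(1, k_max + 1)
    upper = stats.norm.cdf((ks + 0.5 - n_fix_mean) / n_fix_sd)
    lower = stats.norm.cdf((ks - 0.5 - n_fix_mean) / n_fix_sd)
    pmf = upper - lower
    pmf[0] = upper[0]  # all mass below 1.5 rounds/truncates to one fixation
    pmf[-1] += 1.0 - upper[-1]
    return pmf


def expected_mean_duration(params: GroupParams) -> float:
    """Expected per-fixation mean duration over many trials.

    Pooling all fixations of all trials, the mean duration converges to
    ``sum_k P(K >= k) curve(k) / E[K]``; noise terms are mean-zero.
    """
    pmf = count_pmf(params.n_fix_mean, params.n_fix_sd)
    surv = 1.0 - np.concatenate([[0.0], np.cumsum(pmf[:-1])])  # P(K >= k)
    ks = np.arange(1, len(pmf) + 1)
    return float(np.sum(surv * duration_curve(params, ks)) / np.sum(surv * 1.0))


def calibrate_duration_curve(params: GroupParams, target_mean_ms: float) -> GroupParams:
    """Rescale the duration curve so its expected mean equals ``target_mean_ms``.

    The baseline, peak and convergence values are scaled by a common factor
    (the expectation is linear in them), preserving the curve's shape.
    """
    current = expected_mean_duration(params)
    if current <= 0:
        raise ValueError("duration curve has nonpositive expectation")
    f = target_mean_ms / current
    return params.replace(
        dur_baseline_ms=params.dur_baseline_ms * f,
        dur_peak_ms=params.dur_peak_ms * f,
        dur_converge_ms=params.dur_converge_ms * f,
    )


def _truncated_axis_var(sigma: float, half_extent: float) -> float:
    """Variance of N(0, sigma^2) truncated to [-half_extent, half_extent]."""
    a = half_extent / sigma
    z = 2.0 * stats.norm.cdf(a) - 1.0
    if z <= 0:
        return half_extent**2 / 3.0  # effectively uniform
    return sigma**2 * (1.0 - 2.0 * a * stats.norm.pdf(a) / z)


def expected_sdd(sigma: float, screen_w: int | None = None, screen_h: int | None = None) -> float:
    """Expected standard distance deviation of centered isotropic Gaussian
    fixations with per-axis SD ``sigma``.

    Without screen bounds this is the closed form ``sigma * sqrt(2)``.  With
    bounds, each axis is truncated at the screen half-extent, which shrinks
    the spread (materially so once the half-extent drops below ~3 sigma).
    """
    if screen_w is None or screen_h is None:
        return sigma * math.sqrt(2.0)
    vx = _truncated_axis_var(sigma, screen_w / 2.0)
    vy = _truncated_axis_var(sigma, screen_h / 2.0)
    return math.sqrt(vx + vy)


def sigma_for_target_sdd(target_sdd: float, screen_w: int | None = None,
                         screen_h: int | None = None) -> float:
    """Per-axis SD such that centered isotropic Gaussian fixations have the
    given expected SDD, inverting :func:`expected_sdd`.

    Without screen bounds this is ``target_sdd / sqrt(2)``.
    """
    if target_sdd <= 0:
        raise ValueError("target SDD must be positive")
    if screen_w is None or screen_h is None:
        return target_sdd / math.sqrt(2.0)
    hi = math.sqrt(screen_w**2 + screen_h**2)
    if expected_sdd(hi, screen_w, screen_h) < target_sdd:
        raise ValueError("target SDD unreachable on this screen")
    return float(optimize.brentq(
        lambda s: expected_sdd(s, screen_w, screen_h) - target_sdd, 1e-3, hi))


def study_group_params(screen_w: int = SCREEN_W, screen_h: int = SCREEN_H) -> dict[str, GroupParams]:
    """Default group parameters calibrated to the emulated study's printed
    oculomotor summaries (counts, mean durations, SDD spread)."""
    out = {}
    for g in GROUPS:
        s = STUDY_SUMMARIES[g]
        p = GroupParams(
            group_label=g,
            n_fix_mean=s["n_fix_mean"],
            n_fix_sd=s["n_fix_sd"],
            spread_sd_px=sigma_for_target_sdd(s["sdd_px"], screen_w, screen_h),
            **_CURVE_SHAPES[g],
        )
        out[g] = calibrate_duration_curve(p, s["mean_duration_ms"])
    return out


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------


def generate_stimulus_set(config: CohortConfig, rng_seed: int | None = None) -> list[StimulusSpec]:
    """Draw ``config.n_stimuli`` stimulus specs, balanced over categories."""
    cats = tuple(config.categories)
    n_cat = len(cats)
    rem = config.n_stimuli % n_cat
    if rem:
        raise ValueError(
            f"n_stimuli={config.n_stimuli} not divisible by {n_cat} categories "
            f"(remainder {rem})")
    per_cat = config.n_stimuli // n_cat
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    w, h = config.screen_w, config.screen_h
    specs: list[StimulusSpec] = []
    for cat in cats:
        for i in range(per_cat):
            n_obj = int(rng.integers(1, 4))
            regions = []
            for _ in range(n_obj):
                cx = rng.uniform(0.15 * w, 0.85 * w)
                cy = rng.uniform(0.15 * h, 0.85 * h)
                r = rng.uniform(0.03, 0.08) * w
                wt = rng.uniform(0.5, 1.5)
                regions.append((cx, cy, r, wt))
            salient = None
            if cat == "physically_salient":
                salient = (
                    rng.uniform(0.2 * w, 0.8 * w),
                    rng.uniform(0.2 * h, 0.8 * h),
                    rng.uniform(0.03, 0.06) * w,
                    rng.uniform(1.5, 3.0),
                )
            specs.append(StimulusSpec(
                stimulus_id=f"{cat}_{i:03d}",
                category=cat,
                width_px=w,
                height_px=h,
                object_regions=tuple(regions),
                salient_region=salient,
                background_seed=int(rng.integers(0, 2**31 - 1)),
            ))
    return specs


def _disk_mask(h: int, w: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def render_stimulus(spec: StimulusSpec, scale: float = 1.0) -> np.ndarray:
    """Render a spec to a 3-channel float image in [0, 1].

    ``scale`` < 1 renders at reduced resolution (coordinates scale with it).
    The background is smoothed noise; object regions are distinct-hue
    patches; the salient region gets high-frequency, high-contrast texture.
    """
    h = max(1, int(round(spec.height_px * scale)))
    w = max(1, int(round(spec.width_px * scale)))
    if h * w == 0:
        raise ValueError("zero-area stimulus")
    rng = np.random.default_rng(spec.background_seed)
    base = rng.normal(0.0, 1.0, size=(h, w))
    base = ndimage.gaussian_filter(base, sigma=max(1.0, 0.01 * w))
    base = (base - base.min()) / max(float(np.ptp(base)), 1e-12)
    img = np.stack([0.35 + 0.3 * base] * 3, axis=-1)

    hues = [(0.85, 0.45, 0.25), (0.3, 0.6, 0.85), (0.45, 0.75, 0.35),
            (0.8, 0.7, 0.3), (0.6, 0.4, 0.75)]
    for i, (cx, cy, r, _wt) in enumerate(spec.object_regions):
        mask = _disk_mask(h, w, cx * scale, cy * scale, r * scale)
        img[mask] = 0.6 * np.asarray(hues[i % len(hues)]) + 0.4 * img[mask]

    if spec.salient_region is not None:
        cx, cy, r, boost = spec.salient_region
        mask = _disk_mask(h, w, cx * scale, cy * scale, r * scale)
        tex = rng.normal(0.0, 1.0, size=(h, w))  # unsmoothed: high local contrast
        patch = 0.5 + 0.5 * np.tanh(boost * tex)
        for c in range(3):
            ch = img[..., c]
            ch[mask] = patch[mask]
    return np.clip(img, 0.0, 1.0)


def _gauss_2d(h: int, w: int, cx: float, cy: float, sx: float, sy: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return np.exp(-((xx - cx) ** 2 / (2 * sx**2) + (yy - cy) ** 2 / (2 * sy**2)))


def object_prior_map(spec: StimulusSpec, shape: tuple[int, int],
                     fallback_sd_px: float | None = None) -> np.ndarray:
    """Object-prior map on ``shape = (h, w)`` cells: Gaussian blobs at the
    object regions, weighted by their prior weights; unit sum.

    Stands in for a semantic "top-down" prior over plausibly interesting
    objects.  If the spec has no object regions, an isotropic central
    Gaussian of per-axis SD ``fallback_sd_px`` (in stimulus pixels) is used.
    """
    h, w = shape
    fx, fy = w / spec.width_px, h / spec.height_px
    out = np.zeros((h, w))
    for cx, cy, r, wt in spec.object_regions:
        out += wt * _gauss_2d(h, w, cx * fx, cy * fy, max(r * fx, 0.5), max(r * fy, 0.5))
    if out.sum() == 0:
        sd = fallback_sd_px if fallback_sd_px is not None else 0.2 * spec.width_px
        out = _gauss_2d(h, w, (spec.width_px / 2) * fx, (spec.height_px / 2) * fy,
                        max(sd * fx, 0.5), max(sd * fy, 0.5))
    return out / out.sum()


def bottom_up_proxy_map(spec: StimulusSpec, shape: tuple[int, int]) -> np.ndarray:
    """Cheap generator-side stand-in for a bottom-up saliency map.

    A broad uniform floor plus, where present, a Gaussian at the physically
    salient region weighted by its contrast boost.  The actual graph-based
    saliency model (:func:`gazesal.saliency.gbvs_saliency`) is what gets
    *scored*; this proxy only drives the sampling of synthetic gaze.
    """
    h, w = shape
    out = np.full((h, w), 1.0 / (h * w))
    if spec.salient_region is not None:
        cx, cy, r, boost = spec.salient_region
        fx, fy = w / spec.width_px, h / spec.height_px
        g = _gauss_2d(h, w, cx * fx, cy * fy, max(r * fx, 0.5), max(r * fy, 0.5))
        out = out + boost * g / g.sum()  # blob carries `boost` units of mass
    return out / out.sum()


# ---------------------------------------------------------------------------
# Scanpaths
# ---------------------------------------------------------------------------


def _draw_count(params: GroupParams, rng: np.random.Generator) -> int:
    return max(1, int(round(rng.normal(params.n_fix_mean, params.n_fix_sd))))


def generate_scanpath(
    spec: StimulusSpec | None,
    bottom_up_map: np.ndarray,
    object_prior: np.ndarray,
    params: GroupParams,
    trial_duration_ms: float,
    rng: np.random.Generator,
    *,
    screen_w: int = SCREEN_W,
    screen_h: int = SCREEN_H,
    center_bias_weight: float = 0.2,
    center_bias_sd_frac: float = 0.25,
    min_duration_ms: float = 60.0,
    subject_dur_offset_ms: float = 0.0,
) -> pd.DataFrame:
    """Sample one trial's ordered fixations.

    Locations: fixation ``k`` is drawn from the cell distribution
    ``(1 - cb) * [w_k * BU + (1 - w_k) * OP] + cb * CB`` where ``w_k`` is the
    early weight for ``k < w_switch_index`` and the late weight after, and
    ``CB`` is a fixed central Gaussian; a uniform within-cell jitter maps
    cells to continuous screen pixels.  Durations: the group curve plus the
    subject shift plus Gaussian noise, floored at ``min_duration_ms``.  The
    fixation sequence is capped so cumulative duration stays within the
    trial; at least one fixation is always returned.
    """
    bu = np.asarray(bottom_up_map, dtype=float)
    op = np.asarray(object_prior, dtype=float)
    if bu.shape != op.shape:
        raise ValueError(f"map shapes differ: {bu.shape} vs {op.shape}")
    h, w = bu.shape
    if bu.sum() <= 0 and op.sum() <= 0:
        raise ValueError("mixture distribution sums to zero (all-zero maps)")
    bu = bu / bu.sum() if bu.sum() > 0 else bu
    op = op / op.sum() if op.sum() > 0 else op

    if center_bias_weight > 0:
        cb = _gauss_2d(h, w, (w - 1) / 2.0, (h - 1) / 2.0,
                       center_bias_sd_frac * w, center_bias_sd_frac * h)
        cb /= cb.sum()
    else:
        cb = None

    def mixture_cdf(w_bu: float) -> np.ndarray:
        p = w_bu * bu + (1.0 - w_bu) * op
        if cb is not None:
            p = (1.0 - center_bias_weight) * p + center_bias_weight * cb
        s = p.sum()
        if s <= 0:
            raise ValueError("mixture distribution sums to zero")
        return np.cumsum(p.ravel() / s)

    n_fix = _draw_count(params, rng)
    ks = np.arange(1, n_fix + 1)
    durs = duration_curve(params, ks) + subject_dur_offset_ms
    durs = durs + rng.normal(0.0, params.dur_noise_sd_ms, size=n_fix)
    durs = np.maximum(durs, min_duration_ms)

    cdf_early = mixture_cdf(params.w_bottomup_early)
    cdf_late = (mixture_cdf(params.w_bottomup_late)
                if params.w_bottomup_late != params.w_bottomup_early else cdf_early)

    rows = []
    onset = 0.0
    cell_w, cell_h = screen_w / w, screen_h / h
    for k in range(1, n_fix + 1):
        d = float(durs[k - 1])
        if k > 1 and onset + d > trial_duration_ms:
            break
        cdf = cdf_early if k < params.w_switch_index else cdf_late
        idx = int(np.searchsorted(cdf, rng.random(), side="right"))
        idx = min(idx, h * w - 1)
        r, c = divmod(idx, w)
        x = (c + rng.random()) * cell_w
        y = (r + rng.random()) * cell_h
        rows.append((k, x, y, onset, d))
        onset += d
    return pd.DataFrame(rows, columns=["fix_index", "x_px", "y_px", "onset_ms", "duration_ms"])


FIXATION_COLUMNS = [
    "subject_id", "group", "stimulus_id", "category", "fix_index",
    "x_px", "y_px", "onset_ms", "duration_ms", "is_start_cross",
    "cross_x_px", "cross_y_px",
]


def generate_cohort(
    config: CohortConfig,
    specs: Sequence[StimulusSpec] | None = None,
    map_provider: Callable[[StimulusSpec, tuple[int, int]], Mapping[str, np.ndarray]] | None = None,
) -> tuple[pd.DataFrame, list[StimulusSpec], dict[str, dict[str, np.ndarray]]]:
    """Generate the full cohort: one scanpath per subject x stimulus.

    Returns ``(fixation_table, specs, maps)`` where ``maps[stimulus_id]``
    holds the ``bottom_up`` and ``object_prior`` arrays used for sampling.
    Each trial is preceded by a tagged start-cross fixation at one of the
    eight cross positions, so the cleaning stage has something to remove.

    ``map_provider(spec, (map_h, map_w))`` may override the default maps
    (object-prior blobs + bottom-up proxy); it must return a mapping with
    keys ``bottom_up`` and ``object_prior``.
    """
    if specs is None:
        specs = generate_stimulus_set(config)
    shape = (config.map_h, config.map_w)
    maps: dict[str, dict[str, np.ndarray]] = {}
    for spec in specs:
        if map_provider is not None:
            m = map_provider(spec, shape)
            maps[spec.stimulus_id] = {"bottom_up": np.asarray(m["bottom_up"], dtype=float),
                                      "object_prior": np.asarray(m["object_prior"], dtype=float)}
        else:
            gp_any = config.group_params.get("HC") or next(iter(config.group_params.values()))
            maps[spec.stimulus_id] = {
                "bottom_up": bottom_up_proxy_map(spec, shape),
                "object_prior": object_prior_map(
                    spec, shape, fallback_sd_px=gp_any.spread_sd_px),
            }

    subjects = ([("SCHZ", f"schz_{i:02d}") for i in range(config.n_schz)]
                + [("HC", f"hc_{i:02d}") for i in range(config.n_hc)])
    xpos = cross_positions(config.screen_w, config.screen_h)
    frames = []
    for si, (group, sid) in enumerate(subjects):
        params = config.group_params[group]
        subj_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(si,)))
        subj_offset = float(subj_rng.normal(0.0, params.dur_subject_sd_ms))
        # object-prior fallback spread is group-specific: regenerate the
        # fallback map per group only when the spec has no object regions
        for ti, spec in enumerate(specs):
            rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(si, ti)))
            m = maps[spec.stimulus_id]
            op = m["object_prior"]
            if not spec.object_regions and map_provider is None:
                op = object_prior_map(spec, shape, fallback_sd_px=params.spread_sd_px)
            path = generate_scanpath(
                spec, m["bottom_up"], op, params,
                config.trial_duration_ms, rng,
                screen_w=config.screen_w, screen_h=config.screen_h,
                center_bias_weight=config.center_bias_weight,
                center_bias_sd_frac=config.center_bias_sd_frac,
                min_duration_ms=config.min_duration_ms,
                subject_dur_offset_ms=subj_offset,
            )
            cx, cy = xpos[rng.integers(0, len(xpos))]
            cross_dur = float(rng.uniform(150.0, 300.0))
            cross_row = pd.DataFrame({
                "fix_index": [0], "x_px": [cx + rng.normal(0, 10)],
                "y_px": [cy + rng.normal(0, 10)],
                "onset_ms": [-cross_dur], "duration_ms": [cross_dur],
            })
            trial = pd.concat([cross_row, path], ignore_index=True)
            trial["fix_index"] = np.arange(1, len(trial) + 1)
            trial["is_start_cross"] = [True] + [False] * (len(trial) - 1)
            trial["subject_id"] = sid
            trial["group"] = group
            trial["stimulus_id"] = spec.stimulus_id
            trial["category"] = spec.category
            trial["cross_x_px"] = cx
            trial["cross_y_px"] = cy
            frames.append(trial)
    table = pd.concat(frames, ignore_index=True)[FIXATION_COLUMNS]
    return table, list(specs), maps


# ---------------------------------------------------------------------------
# Duration-only fast path
# ---------------------------------------------------------------------------


def simulate_duration_table(
    group_params: Mapping[str, GroupParams],
    n_subjects: Mapping[str, int],
    n_trials: int,
    rng: np.random.Generator,
    min_duration_ms: float = 60.0,
) -> pd.DataFrame:
    """Simulate per-subject mean fixation durations by fixation index.

    Durations are independent of the spatial sampling by construction, so
    duration-level analyses (e.g. the sequential testing procedure) can be
    simulated without rendering stimuli or sampling locations.  Returns a
    tidy frame: group, subject_id, fix_index, mean_duration_ms, n_trials
    (trials of that subject reaching the index).
    """
    frames = []
    for group, params in group_params.items():
        ns = n_subjects[group]
        if ns == 0:
            continue
        k_max = int(math.ceil(params.n_fix_mean + 6 * params.n_fix_sd)) + 1
        counts = np.maximum(
            1, np.rint(rng.normal(params.n_fix_mean, params.n_fix_sd, size=(ns, n_trials)))
        ).astype(int)
        counts = np.minimum(counts, k_max)
        ks = np.arange(1, k_max + 1)
        curve = duration_curve(params, ks)
        subj = rng.normal(0.0, params.dur_subject_sd_ms, size=ns)
        durs = (curve[None, None, :] + subj[:, None, None]
                + rng.normal(0.0, params.dur_noise_sd_ms, size=(ns, n_trials, k_max)))
        durs = np.maximum(durs, min_duration_ms)
        mask = ks[None, None, :] <= counts[:, :, None]
        with np.errstate(invalid="ignore"):
            sums = np.where(mask, durs, 0.0).sum(axis=1)
            nobs = mask.sum(axis=1)
            means = np.divide(sums, nobs, out=np.full_like(sums, np.nan), where=nobs > 0)
        for i in range(ns):
            valid = nobs[i] > 0
            frames.append(pd.DataFrame({
                "group": group,
                "subject_id": f"{group.lower()}_{i:02d}",
                "fix_index": ks[valid],
                "mean_duration_ms": means[i, valid],
                "n_trials": nobs[i, valid],
            }))
    return pd.concat(frames, ignore_index=True)
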