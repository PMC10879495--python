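"""Ground-truth fixation maps and saliency scoring.

The evaluation metric is the normalized scanpath saliency (NSS): the
saliency map is z-normalized over all pixels (population SD) and averaged
at the fixated locations.  Zero is chance level; positive values mean the
map assigns above-average saliency to where gaze actually landed.  NSS is
invariant to affine rescaling of the map, so unit-sum and z-scored maps
give identical scores.

Fixation *density* maps (Gaussian-smoothed fixation histograms, optionally
weighted by fixation duration) are the ground-truth heatmaps used for
visualization and export; NSS itself evaluates the map at the discrete
fixation pixels, matching the binary-fixation-map formulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DensityMap", "fixation_density_map", "nss_score", "signed_sqrt",
    "sdd", "build_nss_table",
]


@dataclass
class DensityMap:
    """Smoothed fixation density; sums to the total weight placed on it."""

    values: np.ndarray
    weighting: str  # "count" | "duration"
    smoothing_sigma_px: float


def fixation_density_map(fixations: pd.DataFrame, resolution: tuple[int, int],
                         sigma_px: float = 64.0, weighting: str = "duration"
                         ) -> DensityMap:
    """Sum of truncated Gaussian kernels at the fixation pixels.

    ``resolution`` is ``(height, width)``.  Each kernel is truncated at
    4 sigma and renormalized over its on-image support, so mass clipped at
    the borders is restored and the map's total equals the total weight
    (fixation count, or summed durations in ms).
    """
    if len(fixations) == 0:
        raise ValueError("empty fixation list")
    if weighting not in ("count", "duration"):
        raise ValueError(f"unknown weighting {weighting!r}")
    h, w = resolution
    out = np.zeros((h, w))
    half = max(1, int(math.ceil(4 * sigma_px)))
    ax = np.arange(-half, half + 1)
    kernel1d = np.exp(-(ax**2) / (2 * sigma_px**2))
    xs = fixations["x_px"].to_numpy(dtype=float)
    ys = fixations["y_px"].to_numpy(dtype=float)
    wts = (fixations["duration_ms"].to_numpy(dtype=float)
           if weighting == "duration" else np.ones(len(fixations)))
    for x, y, wt in zip(xs, ys, wts):
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(0, cx - half), min(w, cx + half + 1)
        y0, y1 = max(0, cy - half), min(h, cy + half + 1)
        if x0 >= x1 or y0 >= y1:
            raise ValueError(f"fixation ({x}, {y}) outside map bounds {w}x{h}")
        kx = kernel1d[x0 - (cx - half): x1 - (cx - half)]
        ky = kernel1d[y0 - (cy - half): y1 - (cy - half)]
        patch = np.outer(ky, kx)
        out[y0:y1, x0:x1] += wt * patch / patch.sum()
    return DensityMap(out, weighting, sigma_px)


def nss_score(saliency, fixations: pd.DataFrame,
              screen: tuple[int, int] | None = None) -> float:
    """Mean z-normalized saliency at the fixated pixels.

    ``saliency`` is a 2-D array or a :class:`gazesal.saliency.SaliencyMap`.
    If the map's grid differs from the screen resolution, fixation
    coordinates are scaled onto the grid and looked up nearest-pixel —
    equivalent to nearest-neighbour upsampling of the map to the screen
    (which leaves the z statistics unchanged).  A degenerate map (zero SD)
    scores 0 with a warning.
    """
    values = getattr(saliency, "values", saliency)
    values = np.asarray(values, dtype=float)
    if len(fixations) == 0:
        raise ValueError("empty fixation list")
    h, w = values.shape
    sw, sh = (w, h) if screen is None else screen
    xs = fixations["x_px"].to_numpy(dtype=float)
    ys = fixations["y_px"].to_numpy(dtype=float)
    if np.any((xs < 0) | (xs >= sw) | (ys < 0) | (ys >= sh)):
        raise ValueError("fixation outside map bounds (clean the table first)")
    sd = values.std()  # population SD
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("degenerate saliency map (zero SD); NSS set to 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    z = (values - values.mean()) / sd
    cols = np.minimum((xs * w / sw).astype(int), w - 1)
    rows = np.minimum((ys * h / sh).astype(int), h - 1)
    return float(z[rows, cols].mean())


def signed_sqrt(x: float) -> float:
    """Odd square root ``sign(x) * sqrt(|x|)``; skew-suppressing transform
    defined on the whole real line."""
    return math.copysign(math.sqrt(abs(x)), x)


def sdd(x, y=None) -> float:
    """Standard distance deviation of a 2-D point pattern.

    ``sqrt( sum_i [(x_i - xbar)^2 + (y_i - ybar)^2] / n )`` — the RMS
    distance of the points from their centroid.
    """
    if y is None:
        pts = np.asarray(x, dtype=float)
        x, y = pts[:, 0], pts[:, 1]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("SDD of an empty point set")
    return float(np.sqrt(np.mean((x - x.mean()) ** 2 + (y - y.mean()) ** 2)))


NSS_COLUMNS = ["subject_id", "group", "stimulus_id", "category",
               "model", "period", "nss", "sqrt_nss"]


def build_nss_table(table: pd.DataFrame, saliency_store, periods=("all", "early", "late"),
                    screen: tuple[int, int] | None = None,
                    strict_negative: bool = False
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """One NSS record per subject x stimulus x model x period.

    ``saliency_store`` maps ``stimulus_id -> {model_name -> map}``.  Periods
    with no fixations in a trial are skipped and counted; degenerate maps
    yield NSS 0 and are counted.  With ``strict_negative`` a negative NSS
    raises instead of passing through the signed square root.
    """
    counters = {"records": 0, "skipped_empty": 0, "degenerate_maps": 0}
    rows = []
    for (sid, stim), trial in table.groupby(["subject_id", "stimulus_id"], observed=True):
        if "is_start_cross" in trial.columns:
            trial = trial[~trial["is_start_cross"].astype(bool)]
        try:
            models = saliency_store[stim]
        except KeyError:
            raise KeyError(f"no saliency maps for stimulus {stim!r}") from None
        group = trial["group"].iloc[0] if len(trial) else None
        category = trial["category"].iloc[0] if len(trial) else None
        for period in periods:
            if period == "all":
                sub = trial
            elif period == "early":
                sub = trial[trial["fix_index"] <= 5]
            elif period == "late":
                sub = trial[trial["fix_index"] >= 6]
            else:
                raise ValueError(f"unknown period {period!r}")
            if len(sub) == 0:
                counters["skipped_empty"] += 1
                continue
            for model in models:
                smap = models[model]
                if smap is None:
                    raise KeyError(f"missing map for stimulus {stim!r}, model {model!r}")
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    val = nss_score(smap, sub, screen=screen)
                if any(issubclass(c.category, RuntimeWarning) for c in caught):
                    counters["degenerate_maps"] += 1
                if strict_negative and val < 0:
                    raise ValueError(
                        f"negative NSS ({val:.4f}) for {sid}/{stim}/{model}/{period} "
                        "in strict mode")
                rows.append((sid, group, stim, category, model, period,
                             val, signed_sqrt(val)))
                counters["records"] += 1
    return pd.DataFrame(rows, columns=NSS_COLUMNS), counters
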