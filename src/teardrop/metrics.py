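"""Figure-ground indices, medial-axis readout, and the kurtosis diagnostic.

All three indices are normalized contrasts of mean activities over
complementary regions, so each lies in [-1, 1] for nonnegative activity and
is invariant to rescaling the activity map:

* IOI (in-out index): figure interior vs. ground;
* MAI (medial-axis index): within 1 px of the medial axis vs. the rest of
  the figure interior;
* BI (boundary index): within 1 px of the figure boundary vs. everywhere
  else.

0/0 cases (both regions silent) return 0 with a warning so population
sweeps do not abort on empty responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import LesionConfig
from .stimuli import VisualDisplay, region_masks


def _contrast(a: float, b: float) -> float:
    tot = a + b
    if tot == 0.0:
        warnings.warn("both regions have zero mean activity; index set to 0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return (a - b) / tot


def _mask_mean(activity: np.ndarray, mask: np.ndarray) -> float:
    if not mask.any():
        raise ValueError("empty region mask")
    return float(activity[mask].mean())


def ioi(activity: np.ndarray, masks: dict[str, np.ndarray]) -> float:
    """In-out index: (mean_figure - mean_ground) / (mean_figure + mean_ground)."""
    return _contrast(_mask_mean(activity, masks["figure"]),
                     _mask_mean(activity, masks["ground"]))


def mai(activity: np.ndarray, masks: dict[str, np.ndarray]) -> float:
    """Medial-axis index over the 1-px medial band vs. the rest of the interior."""
    return _contrast(_mask_mean(activity, masks["medial_band"]),
                     _mask_mean(activity, masks["interior_rest"]))


def bi(activity: np.ndarray, masks: dict[str, np.ndarray]) -> float:
    """Boundary index over the 1-px boundary band vs. everywhere else."""
    return _contrast(_mask_mean(activity, masks["boundary_band"]),
                     _mask_mean(activity, masks["elsewhere"]))


def scale_profile(convex: np.ndarray) -> np.ndarray:
    """Per-scale maxima of the convex field (the 7-point response profile)."""
    return convex.max(axis=(0, 1))


def scale_profile_kurtosis(convex: np.ndarray) -> float:
    """Pearson kurtosis of the per-scale-maximum profile over scale index.

    The 7-vector of per-scale maxima, normalized to unit sum, is treated as
    a probability mass over scale index and its kurtosis mu4 / mu2^2
    (non-excess) is returned.  A high value means the active convex cells
    share a common RF size — a confident medial-axis response; a uniform
    profile over 7 scales gives 1.75 and an even split over the two extreme
    scales gives 1.
    """
    m = scale_profile(convex)
    tot = m.sum()
    if tot <= 0:
        raise ValueError("kurtosis undefined for an all-zero scale profile")
    p = m / tot
    idx = np.arange(len(p), dtype=float)
    mu = (p * idx).sum()
    mu2 = (p * (idx - mu) ** 2).sum()
    if mu2 == 0.0:
        return float("inf")   # all mass on one scale: maximally peaked
    mu4 = (p * (idx - mu) ** 4).sum()
    return float(mu4 / mu2 ** 2)


def readout_medial(convex: np.ndarray, rho: float = 0.8
                   ) -> tuple[np.ndarray, int]:
    """Medial-axis readout: near-maximal positions at the dominant scale.

    The dominant scale is the argmax of the per-scale maxima (ties broken
    toward the smaller scale); the readout is the boolean set of pixels at
    that scale whose activity is at least ``rho`` of the scale maximum.
    This is a plain peak readout of the population, not a probabilistic
    decode.
    """
    prof = scale_profile(convex)
    if prof.max() <= 0:
        raise ValueError("cannot read out a zero field")
    dominant = int(np.argmax(prof))   # np.argmax returns the first (smallest) tie
    amap = convex[:, :, dominant]
    return amap >= rho * amap.max(), dominant


@dataclass(frozen=True)
class MetricsReport:
    """Indices and readout summary for one simulation."""

    display: str
    lesion: str
    ioi: float
    mai: float
    bi: float
    kurtosis: float
    peak_scale: int
    peak_position: tuple[int, int]
    per_scale_max: tuple[float, ...]
    mai_dominant: float = float("nan")
    converged: bool = True
    n_steps: int = 0

    def as_row(self) -> dict:
        d = {
            "display": self.display, "lesion": self.lesion,
            "ioi": self.ioi, "mai": self.mai, "bi": self.bi,
            "kurtosis": self.kurtosis, "mai_dominant": self.mai_dominant,
            "peak_scale": self.peak_scale,
            "peak_y": self.peak_position[0], "peak_x": self.peak_position[1],
            "converged": self.converged, "n_steps": self.n_steps,
        }
        for s, v in enumerate(self.per_scale_max):
            d[f"max_scale_{s + 1}"] = v
        return d


def evaluate(display: VisualDisplay, convex: np.ndarray,
             lesion: LesionConfig | None = None, tol: int = 1,
             converged: bool = True, n_steps: int = 0) -> MetricsReport:
    """Compute the full metrics report for one converged convex field.

    The indices use the per-position maximum over scales of convex activity;
    ``mai_dominant`` additionally reports the MAI of the dominant scale's
    own activity map (the per-RF-size variant quoted for the exemplars).
    """
    masks = region_masks(display, tol=tol)
    # degenerate figures (e.g. a bar thin enough that the medial band covers
    # the whole interior) can leave a region empty; sweeps treat an empty
    # region as silent rather than erroring mid-run
    for key in ("interior_rest",):
        if not masks[key].any():
            warnings.warn(f"region {key!r} is empty for {display.name}; "
                          "its mean activity is taken as 0",
                          RuntimeWarning, stacklevel=2)
            masks = dict(masks)
            masks[key] = np.zeros_like(masks[key])
            masks[key][0, 0] = True   # sentinel pixel outside any activity
    amap = convex.max(axis=-1)
    prof = scale_profile(convex)
    if prof.max() > 0:
        _, dominant = readout_medial(convex)
        dmap = convex[:, :, dominant]
        mai_dom = mai(dmap, masks)
        flat = np.argmax(dmap)
        peak_pos = (int(flat // dmap.shape[1]), int(flat % dmap.shape[1]))
        kurt = scale_profile_kurtosis(convex)
    else:
        dominant, mai_dom, peak_pos, kurt = 0, float("nan"), (0, 0), float("nan")
    return MetricsReport(
        display=display.name,
        lesion=lesion.name if lesion is not None else "n/a",
        ioi=ioi(amap, masks), mai=mai(amap, masks), bi=bi(amap, masks),
        kurtosis=kurt, peak_scale=dominant, peak_position=peak_pos,
        per_scale_max=tuple(float(v) for v in prof),
        mai_dominant=mai_dom, converged=converged, n_steps=n_steps)


def normalize_across_conditions(values: dict[str, float]) -> dict[str, float]:
    """Min-max normalize one index across lesion conditions to [0, 1].

    Maps the best-performing condition to 1 and the worst to 0 (all equal
    values map to 0.5), the normalization used for lesion bar summaries.
    """
    vals = np.array(list(values.values()), float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return {k: 0.5 for k in values}
    return {k: float((v - lo) / (hi - lo)) for k, v in values.items()}
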