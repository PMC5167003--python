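"""Analysis-side preprocessing of 4D runs.

Stages: mean image, brain masking, Gaussian spatial smoothing, surround
subtraction of control/tag series, voxel-wise temporal z-normalization, and
temporal subsampling.  Each stage takes and returns a :class:`~.synth.Run`
so stages compose freely; :func:`preprocess_run` applies the standard order
(subtract for ASL-type runs, then smooth, then normalize).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .synth import Run

__all__ = [
    "BrainMask",
    "mean_image",
    "brain_mask",
    "smooth_gaussian",
    "surround_subtract",
    "normalize_voxelwise",
    "subsample",
    "preprocess_run",
    "fwhm_to_sigma",
]

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class BrainMask:
    """Boolean brain mask plus the rule that produced it."""

    mask: np.ndarray
    rule_name: str
    rule_params: dict

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.mask.any():
            raise ValueError("brain mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def mean_image(r: Run) -> np.ndarray:
    """Voxel-wise mean volume.

    BOLD (and already-subtracted) runs average every frame; ASL/AVAST runs
    average the *control* frames only — the baseline image of the series.
    """
    if r.n_frames < 1:
        raise ValueError("run has no frames")
    if r.modality in ("asl", "avast"):
        ctrl = r.frame_roles == "control"
        if not ctrl.any():
            raise ValueError("ASL-type run has no control frames")
        return r.data[ctrl].mean(axis=0)
    return r.data.mean(axis=0)


def brain_mask(
    mean_vol: np.ndarray,
    rule_name: str = "above_mean",
    rule_params: dict | None = None,
) -> BrainMask:
    """Threshold a mean image into a brain mask.

    Rules (mu, sigma are the global mean and sample SD over all voxels):

    * ``above_mean`` (default): include voxels >= mu.
    * ``band``: include voxels with \\|value - mu\\| <= sigma.  This literal
      "within one SD of the mean" reading excludes the brightest voxels on
      bright-brain/dark-background images; kept as an option.
    * ``above_mean_minus_sd``: include voxels >= mu - sigma.
    """
    vol = np.asarray(mean_vol, dtype=float)
    if not np.all(np.isfinite(vol)):
        raise ValueError("mean volume must be finite")
    mu = vol.mean()
    sigma = vol.std(ddof=1)
    if rule_name == "above_mean":
        m = vol >= mu
    elif rule_name == "band":
        m = np.abs(vol - mu) <= sigma
    elif rule_name == "above_mean_minus_sd":
        m = vol >= mu - sigma
    else:
        raise ValueError(f"unknown mask rule {rule_name!r}")
    return BrainMask(
        mask=m,
        rule_name=rule_name,
        rule_params={"mu": float(mu), "sigma": float(sigma), **(rule_params or {})},
    )


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Convert a smoothing FWHM in mm to a Gaussian sigma in voxels."""
    return fwhm_mm / FWHM_FACTOR / voxel_size_mm


def smooth_gaussian(r: Run, fwhm_mm: float) -> Run:
    """Spatially smooth every frame with a separable 3-D Gaussian kernel.

    ``fwhm_mm`` is isotropic in millimetres; per-axis sigmas account for
    anisotropic voxels.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    out = copy.copy(r)
    if fwhm_mm == 0:
        out.data = r.data.copy()
        return out
    sigmas = [fwhm_to_sigma(fwhm_mm, vs) for vs in r.voxel_size]
    out.data = gaussian_filter(r.data, sigma=[0.0, *sigmas], mode="nearest")
    return out


def surround_subtract(r: Run) -> Run:
    """Collapse an alternating control/tag series into a tagging-signal series.

    With sign s_i = +1 for control frames and -1 for tag frames, output frame
    i (0-based raw index) is::

        out_0 = s_0 * (x_0 - x_1)
        out_i = s_i * (x_i - (x_{i-1} + x_{i+1}) / 2),   1 <= i <= N-2

    i.e. each frame minus the average of its opposite-state neighbours, sign
    flipped so the tagging signal is always positive.  This cancels any
    signal component linear in time at interior frames (drift immunity) and
    recovers a constant control-tag offset exactly.  The output has N-1
    frames ('subtracted' modality, all roles plain), keeping the raw frame
    times of frames 0..N-2.
    """
    if r.modality not in ("asl", "avast"):
        raise ValueError(f"surround subtraction needs an ASL-type run, got {r.modality!r}")
    n = r.n_frames
    if n < 3:
        raise ValueError("need at least 3 frames to surround subtract")
    x = r.data
    s = np.where(r.frame_roles == "control", 1.0, -1.0)
    out = np.empty((n - 1,) + r.grid_shape)
    out[0] = s[0] * (x[0] - x[1])
    i = np.arange(1, n - 1)
    out[1:] = s[i, None, None, None] * (x[i] - 0.5 * (x[i - 1] + x[i + 1]))
    new = copy.copy(r)
    new.data = out
    new.modality = "subtracted"
    new.frame_roles = np.full(n - 1, "plain")
    new.frame_times = r.frame_times[: n - 1].copy()
    return new


def normalize_voxelwise(r: Run) -> Run:
    """Z-score each voxel's time course (sample SD, N-1 denominator).

    Zero-variance voxels become all-zero.  Idempotent to fp tolerance.
    """
    if r.n_frames < 2:
        raise ValueError("need at least 2 frames to normalize")
    mean = r.data.mean(axis=0, keepdims=True)
    sd = r.data.std(axis=0, ddof=1, keepdims=True)
    centered = r.data - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    out = copy.copy(r)
    out.data = z
    return out


def subsample(obj, stride: int = 2, offset: int = 0):
    """Keep every ``stride``-th frame (or example), starting at ``offset``.

    Works on a :class:`Run` or an ``ExampleSet``; the effective TR becomes
    ``stride * TR``.  ``stride=1`` is the identity.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if not 0 <= offset < stride:
        raise ValueError("offset must satisfy 0 <= offset < stride")
    sel = slice(offset, None, stride)
    if isinstance(obj, Run):
        out = copy.copy(obj)
        out.data = obj.data[sel].copy()
        out.frame_roles = obj.frame_roles[sel].copy()
        out.frame_times = obj.frame_times[sel].copy()
        out.tr = obj.tr * stride
        return out
    # duck-typed ExampleSet (avoids an import cycle)
    from .dataset import ExampleSet

    if isinstance(obj, ExampleSet):
        return ExampleSet(
            features=obj.features[sel].copy(),
            labels=obj.labels[sel].copy(),
            frame_times=obj.frame_times[sel].copy(),
            voxel_index=obj.voxel_index,
            mask=obj.mask,
        )
    raise TypeError(f"cannot subsample object of type {type(obj)!r}")


def preprocess_run(
    r: Run,
    fwhm_mm: float = 8.0,
    order: tuple[str, ...] | None = None,
) -> Run:
    """Standard preprocessing chain for one run.

    Default order: ``subtract`` (ASL-type runs only) -> ``smooth`` ->
    ``normalize``; BOLD runs skip the subtraction.  Pass ``order`` to
    rearrange or drop stages.
    """
    if order is None:
        order = ("subtract", "smooth", "normalize")
    out = r
    for step in order:
        if step == "subtract":
            if out.modality in ("asl", "avast"):
                out = surround_subtract(out)
        elif step == "smooth":
            out = smooth_gaussian(out, fwhm_mm)
        elif step == "normalize":
            out = normalize_voxelwise(out)
        else:
            raise ValueError(f"unknown preprocessing step {step!r}")
    return out
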