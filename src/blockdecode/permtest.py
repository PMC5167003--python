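"""Permutation-test significance of linear SVM weight maps.

The discriminating weight vector w maps back into brain space; its
large-magnitude entries localize the regions driving classification.  To
ask which voxel weights are reproducibly nonzero rather than noise, the
class labels are randomly permuted many times, the SVM retrained each time,
and each permuted weight vector normalized to unit standard deviation.  A
voxel's empirical p-value is the fraction of permutations in which its
(normalized) weight meets or exceeds its value under the true labels; with
2,000 permutations an exceedance count below 20 corresponds to p < .01.

Two exceedance statistics ship: ``"absolute"`` (default; two-sided on |w|,
matching "the magnitude of the weight determines its importance") and
``"signed"`` (one-sided on the raw weight).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExampleSet
from .svm import train_svm

__all__ = [
    "PermResult",
    "normalize_weights",
    "permutation_null",
    "significance_threshold",
]


def normalize_weights(w: np.ndarray) -> np.ndarray:
    """Scale a weight vector to unit sample SD (N-1 denominator).

    An all-zero (zero-variance) vector is returned unchanged.
    """
    w = np.asarray(w, dtype=float)
    if w.size < 2:
        raise ValueError("need at least 2 weights to normalize")
    sd = w.std(ddof=1)
    if sd == 0:
        return w.copy()
    return w / sd


@dataclass
class PermResult:
    """Outcome of a label-permutation null for one trained weight map."""

    w_orig_norm: np.ndarray
    exceedance_counts: np.ndarray
    n_perm: int
    p_values: np.ndarray
    alpha: float
    significant_mask: np.ndarray
    statistic_mode: str = "absolute"

    def to_frame(self, voxel_index=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "weight": self.w_orig_norm,
                "count": self.exceedance_counts,
                "p": self.p_values,
                "significant": self.significant_mask,
            }
        )
        if voxel_index is not None:
            df.insert(0, "z", np.asarray(voxel_index)[:, 2])
            df.insert(0, "y", np.asarray(voxel_index)[:, 1])
            df.insert(0, "x", np.asarray(voxel_index)[:, 0])
        return df


def _stat(w: np.ndarray, mode: str) -> np.ndarray:
    if mode == "absolute":
        return np.abs(w)
    if mode == "signed":
        return w
    raise ValueError(f"unknown statistic_mode {mode!r}")


def permutation_null(
    s: ExampleSet,
    C: float = 1.0,
    n_perm: int = 2000,
    seed=0,
    statistic_mode: str = "absolute",
    alpha: float = 0.01,
    add_one: bool = False,
    block_permute: bool = False,
    fit_bias: bool = True,
) -> PermResult:
    """Empirical per-voxel null for SVM weights by label permutation.

    Trains once with the true labels, then ``n_perm`` times with labels
    permuted uniformly at random (class counts preserved; duplicates across
    draws allowed, standard for n_perm << n!).  Only running exceedance
    counts are kept, never the permuted weight vectors, so memory is
    O(n_features).

    p = count / n_perm exactly (``add_one=True`` switches to the smoothed
    (count+1)/(n_perm+1) for users needing strictly positive p-values).
    ``block_permute=True`` permutes contiguous same-label segments as units
    instead of individual examples, an option for strongly autocorrelated
    series.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _stat(np.zeros(2), statistic_mode)  # validate mode early
    rng = np.random.default_rng(seed)
    w0 = normalize_weights(train_svm(s, C=C, fit_bias=fit_bias).w)
    stat0 = _stat(w0, statistic_mode)

    labels = s.labels
    if block_permute:
        # contiguous same-label segments permuted as units
        change = np.flatnonzero(np.diff(labels)) + 1
        segments = np.split(np.arange(len(labels)), change)
        seg_labels = np.array([labels[seg[0]] for seg in segments])

    counts = np.zeros(s.n_features, dtype=np.int64)
    perm_set = ExampleSet(
        features=s.features,
        labels=labels,
        frame_times=s.frame_times,
        voxel_index=s.voxel_index,
        mask=s.mask,
    )
    for _ in range(n_perm):
        if block_permute:
            perm_labels = np.empty_like(labels)
            for seg, lab in zip(segments, rng.permutation(seg_labels)):
                perm_labels[seg] = lab
            if len(np.unique(perm_labels)) < 2:  # degenerate rearrangement
                perm_labels = rng.permutation(labels)
        else:
            perm_labels = rng.permutation(labels)
        perm_set.labels = perm_labels
        wp = normalize_weights(train_svm(perm_set, C=C, fit_bias=fit_bias).w)
        counts += _stat(wp, statistic_mode) >= stat0

    if add_one:
        p = (counts + 1) / (n_perm + 1)
    else:
        p = counts / n_perm
    return PermResult(
        w_orig_norm=w0,
        exceedance_counts=counts,
        n_perm=n_perm,
        p_values=p,
        alpha=alpha,
        significant_mask=p < alpha,
        statistic_mode=statistic_mode,
    )


def significance_threshold(pr: PermResult, alpha: float) -> np.ndarray:
    """Voxels significant at level ``alpha`` (strict p < alpha).

    Equivalently, exceedance count < alpha * n_perm when that product is an
    integer: at n_perm = 2000 and alpha = .01, counts 0-19 are significant.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return pr.p_values < alpha
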