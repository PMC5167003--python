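"""Labeled example sets: masked frames as feature vectors.

Each retained frame of a preprocessed run becomes one example whose features
are the in-mask voxel intensities, flattened in a fixed documented order
(ascending (z, y, x) lexicographic) so that weight vectors map back into
brain space bit-exactly.  Labels come from the paradigm; transition-period
frames can be excluded symmetrically for training and testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .paradigm import Paradigm
from .preprocess import BrainMask
from .synth import Run

__all__ = ["ExampleSet", "build_examples", "mask_voxel_order", "vector_to_volume"]


def mask_voxel_order(mask: np.ndarray) -> np.ndarray:
    """(n_features, 3) array of (x, y, z) voxel coordinates of the True
    voxels, sorted ascending-(z, y, x) lexicographic."""
    zyx = np.argwhere(np.transpose(mask, (2, 1, 0)))  # rows sorted by (z,y,x)
    return zyx[:, ::-1].copy()  # -> (x, y, z)


@dataclass
class ExampleSet:
    """Feature matrix plus labels, times and the voxel bookkeeping.

    features: (n_examples, n_features); labels in {+1, -1}; voxel_index maps
    feature column -> (x, y, z).
    """

    features: np.ndarray
    labels: np.ndarray
    frame_times: np.ndarray
    voxel_index: np.ndarray
    mask: BrainMask | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        n = self.features.shape[0]
        if len(self.labels) != n or len(self.frame_times) != n:
            raise ValueError("labels/frame_times must match example count")
        if not np.all(np.isin(self.labels, (1, -1))):
            raise ValueError("labels must be +1 or -1")
        if self.voxel_index.shape != (self.features.shape[1], 3):
            raise ValueError("voxel_index must be (n_features, 3)")

    @property
    def n_examples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def same_feature_space(self, other: "ExampleSet") -> bool:
        return self.n_features == other.n_features and np.array_equal(
            self.voxel_index, other.voxel_index
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: time, label, then one column per feature."""
        df = pd.DataFrame(
            self.features,
            columns=[f"v{x}_{y}_{z}" for x, y, z in self.voxel_index],
        )
        df.insert(0, "label", self.labels)
        df.insert(0, "time", self.frame_times)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_examples(
    r: Run,
    p: Paradigm,
    m: BrainMask,
    k_ignore: int = 0,
) -> ExampleSet:
    """Assemble the labeled example set of one (normalized) run.

    Frames inside the ``k_ignore``-point transition windows are dropped;
    every retained frame contributes one row of masked voxel intensities and
    the label of the block containing its frame time.
    """
    if m.mask.shape != r.grid_shape:
        raise ValueError(
            f"mask grid {m.mask.shape} does not match run grid {r.grid_shape}"
        )
    excluded = p.excluded_frame_indices(r.frame_times, k_ignore)
    keep = np.array(
        [i for i in range(r.n_frames) if i not in excluded], dtype=int
    )
    if len(keep) == 0:
        raise ValueError("all frames excluded; nothing to build")
    order = mask_voxel_order(m.mask)
    xs, ys, zs = order[:, 0], order[:, 1], order[:, 2]
    features = r.data[keep][:, xs, ys, zs]
    times = r.frame_times[keep]
    labels = np.array([p.label_at_time(t) for t in times], dtype=int)
    return ExampleSet(
        features=features,
        labels=labels,
        frame_times=times,
        voxel_index=order,
        mask=m,
    )


def vector_to_volume(
    vec: np.ndarray,
    voxel_index: np.ndarray,
    grid_shape: tuple[int, int, int],
    fill: float = 0.0,
) -> np.ndarray:
    """Scatter a per-feature vector (weights, p-values, ...) back into a 3-D
    volume; voxels outside the mask get ``fill``."""
    vec = np.asarray(vec)
    if len(vec) != len(voxel_index):
        raise ValueError("vector length must match voxel_index")
    vol = np.full(grid_shape, fill, dtype=float)
    vol[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]] = vec
    return vol
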