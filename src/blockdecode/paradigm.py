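"""Block-design stimulation paradigms.

A paradigm is a sequence of alternating task / rest blocks of equal duration.
It is the single source of truth for example labels (+1 task, -1 rest), for
the times at which the subject switches state, and for which acquired frames
fall inside a "transition period" around those switches and may be excluded
from training and testing.

Conventions
-----------
* Blocks are half-open intervals ``[b*block_duration, (b+1)*block_duration)``;
  a time exactly on a boundary belongs to the *later* block.
* Frame times are whatever the acquisition reports (typically ``i * TR`` for
  the i-th volume, 0-based); labeling uses the frame time as given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

TASK: int = 1
REST: int = -1

__all__ = ["TASK", "REST", "Paradigm", "build_paradigm"]


@dataclass(frozen=True)
class Paradigm:
    """Alternating equal-length task/rest block schedule.

    Parameters
    ----------
    block_duration:
        Duration of one block in seconds (> 0).
    n_cycles:
        Number of task+rest cycles (>= 1); the run has ``2 * n_cycles`` blocks.
    first_state:
        State of the first block, ``+1`` (task) or ``-1`` (rest).
    """

    block_duration: float
    n_cycles: int
    first_state: int = TASK

    def __post_init__(self) -> None:
        if not self.block_duration > 0:
            raise ValueError(f"block_duration must be > 0, got {self.block_duration}")
        if int(self.n_cycles) != self.n_cycles or self.n_cycles < 1:
            raise ValueError(f"n_cycles must be an integer >= 1, got {self.n_cycles}")
        if self.first_state not in (TASK, REST):
            raise ValueError(f"first_state must be +1 or -1, got {self.first_state}")

    # -- derived schedule quantities -------------------------------------

    @property
    def n_blocks(self) -> int:
        return 2 * self.n_cycles

    @property
    def total_duration(self) -> float:
        return 2 * self.n_cycles * self.block_duration

    @property
    def n_transitions(self) -> int:
        """Number of state switches inside the run (block count minus one)."""
        return 2 * self.n_cycles - 1

    def block_state(self, block: int) -> int:
        """State (+1/-1) of 0-based block ``block``; states strictly alternate."""
        if not 0 <= block < self.n_blocks:
            raise ValueError(f"block {block} outside [0, {self.n_blocks})")
        return self.first_state if block % 2 == 0 else -self.first_state

    def block_index(self, t: float) -> int:
        """0-based index of the half-open block containing time ``t``."""
        if not (0 <= t < self.total_duration):
            raise ValueError(
                f"time {t} outside run [0, {self.total_duration})"
            )
        return int(np.floor(t / self.block_duration))

    def label_at_time(self, t: float) -> int:
        """State label (+1 task / -1 rest) at time ``t`` seconds."""
        return self.block_state(self.block_index(t))

    def transition_times(self) -> np.ndarray:
        """Interior block-boundary times, strictly increasing.

        Excludes t=0 and t=total_duration; length is ``2*n_cycles - 1``.
        """
        return self.block_duration * np.arange(1, self.n_blocks)

    # -- transition-period exclusion -------------------------------------

    def excluded_frame_indices(self, frame_times, k: int) -> set[int]:
        """Frame indices falling in the k-point transition windows.

        For each of the ``2*n_cycles - 1`` transitions, the last ``k`` frames
        (by frame time) of the preceding block and the first ``k`` frames of
        the following block are excluded.  ``k=0`` excludes nothing.  A frame
        caught by two adjacent transitions is counted once.

        Parameters
        ----------
        frame_times:
            Sorted ascending acquisition times, all within ``[0, total)``.
        k:
            Number of time points to drop on each side of every transition.
        """
        times = np.asarray(frame_times, dtype=float)
        if times.ndim != 1:
            raise ValueError("frame_times must be 1-D")
        if np.any(np.diff(times) < 0):
            raise ValueError("frame_times must be sorted ascending")
        if int(k) != k or k < 0:
            raise ValueError(f"k must be a nonnegative integer, got {k}")
        k = int(k)
        if k == 0:
            return set()

        blocks = np.floor(times / self.block_duration).astype(int)
        excluded: set[int] = set()
        for b in range(self.n_blocks - 1):  # transition between b and b+1
            prev = np.flatnonzero(blocks == b)
            nxt = np.flatnonzero(blocks == b + 1)
            if k > len(prev) or k > len(nxt):
                warnings.warn(
                    f"k={k} exceeds frames-per-block at transition {b}; "
                    "entire block side excluded",
                    stacklevel=2,
                )
            excluded.update(prev[-k:].tolist())
            excluded.update(nxt[:k].tolist())
        return excluded

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Paradigm":
        return cls(
            block_duration=d["block_duration"],
            n_cycles=d["n_cycles"],
            first_state=d.get("first_state", TASK),
        )


def build_paradigm(
    block_duration: float, n_cycles: int, first_state: int = TASK
) -> Paradigm:
    """Validate and construct a :class:`Paradigm` (functional alias)."""
    return Paradigm(block_duration, n_cycles, first_state)
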