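"""Task geometry: target circles and ordered reaching sequences."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Target", "SequenceGeometry"]


@dataclass(frozen=True)
class Target:
    """A circular target on the table (center in mm)."""

    center: tuple[float, float]
    radius: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("target radius must be positive")

    @property
    def center_arr(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of ``points`` (..., 2) inside the circle (inclusive)."""
        d = np.linalg.norm(np.asarray(points, float) - self.center_arr, axis=-1)
        return d <= self.radius


@dataclass(frozen=True)
class SequenceGeometry:
    """Start position plus an ordered list of targets to reach."""

    start: tuple[float, float]
    targets: tuple[Target, ...]
    sequence_id: str = ""

    def __post_init__(self) -> None:
        if len(self.targets) < 1:
            raise ValueError("a sequence needs at least one target")

    @property
    def start_arr(self) -> np.ndarray:
        return np.asarray(self.start, dtype=float)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def centers(self) -> np.ndarray:
        """(n_targets, 2) array of target centers."""
        return np.array([t.center for t in self.targets], dtype=float)

    def waypoints(self) -> np.ndarray:
        """Start followed by all target centers, shape (n_targets + 1, 2)."""
        return np.vstack([self.start_arr, self.centers()])
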