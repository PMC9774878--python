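"""Core containers: the wavenumber axis and the hyperspectral cube.

A hyperspectral image (HSI) is a rank-3 array with two spatial axes and one
spectral axis; every pixel holds a full vibrational spectrum sampled on a
common wavenumber grid (cm^-1).  An optional integer ground-truth image of
the same spatial shape travels with the cube so segmentations can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WavenumberAxis", "make_wavenumber_axis", "HSICube"]


@dataclass(frozen=True)
class WavenumberAxis:
    """Arithmetic wavenumber grid: values[i] = start + i * step (cm^-1)."""

    start: float
    step: float
    count: int

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")
        if self.count < 2:
            raise ValueError(f"count must be >= 2, got {self.count}")

    @property
    def values(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.count, dtype=float)

    @property
    def stop(self) -> float:
        """Last grid value, start + (count-1)*step."""
        return self.start + (self.count - 1) * self.step

    def __len__(self) -> int:
        return self.count


def make_wavenumber_axis(start: float, step: float, count: int) -> WavenumberAxis:
    """Build an arithmetic wavenumber grid of `count` points spaced by `step`."""
    return WavenumberAxis(float(start), float(step), int(count))


@dataclass
class HSICube:
    """Rank-3 intensity cube (H x W x B) with its wavenumber axis.

    Parameters
    ----------
    data
        Non-negative intensities, shape (H, W, B), arbitrary units.
    axis
        Wavenumber grid; ``len(axis)`` must equal B.
    truth
        Optional (H, W) integer ground-truth label image.
    """

    data: np.ndarray
    axis: WavenumberAxis
    truth: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be rank 3, got shape {self.data.shape}")
        if self.data.shape[2] != len(self.axis):
            raise ValueError(
                f"band count {self.data.shape[2]} != axis length {len(self.axis)}"
            )
        if self.truth is not None:
            self.truth = np.asarray(self.truth)
            if self.truth.shape != self.data.shape[:2]:
                raise ValueError(
                    f"truth shape {self.truth.shape} != spatial shape {self.data.shape[:2]}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]
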