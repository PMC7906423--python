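"""Snapshot container for gridded flow fields.

A :class:`FieldSnapshot` holds cell-centred fields on a uniform structured
grid (2-D or 3-D): velocity components, pressure, the recirculation-phase
fraction and the shear-rate magnitude.  Solver snapshots additionally keep
the staggered face velocities so that the discrete divergence can be
checked in the same algebra in which it was enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["FieldSnapshot"]


@dataclass
class FieldSnapshot:
    """Fields on a uniform grid at one time instant.

    ``velocity`` has shape ``(ncomp, *grid)``; grid axis ``k`` corresponds
    to coordinate ``x_k`` with cell centres at ``origin[k] + (i + 1/2) h``.
    ``phi_r`` is the volume fraction of the recirculation (filtered-blood)
    phase and must lie in [0, 1] everywhere.
    """

    time: float
    h: float
    velocity: np.ndarray
    pressure: np.ndarray | None = None
    phi_r: np.ndarray | None = None
    shear_rate: np.ndarray | None = None
    origin: tuple[float, ...] | None = None
    u_face: np.ndarray | None = None  # staggered x-face velocity (nx+1, ny)
    v_face: np.ndarray | None = None  # staggered y-face velocity (nx, ny+1)
    ground_truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.velocity.ndim < 3 or self.velocity.ndim > 4:
            raise ValueError("velocity must have shape (ncomp, *grid) with 2-D or 3-D grid")
        if self.h <= 0:
            raise ValueError("grid spacing must be positive")
        if self.origin is None:
            self.origin = (0.0,) * self.ndim
        for name in ("pressure", "phi_r", "shear_rate"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.grid_shape:
                    raise ValueError(f"{name} shape {arr.shape} != grid {self.grid_shape}")
                setattr(self, name, arr)
        if self.phi_r is not None and (self.phi_r.min() < 0 or self.phi_r.max() > 1):
            raise ValueError(
                f"phi_r out of [0, 1]: min {self.phi_r.min()}, max {self.phi_r.max()}"
            )

    @property
    def ndim(self) -> int:
        return self.velocity.ndim - 1

    @property
    def ncomp(self) -> int:
        return self.velocity.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.velocity.shape[1:]

    def cell_centers(self) -> list[np.ndarray]:
        """1-D arrays of cell-centre coordinates along each axis."""
        return [
            self.origin[k] + (np.arange(n) + 0.5) * self.h
            for k, n in enumerate(self.grid_shape)
        ]

    def divergence(self) -> np.ndarray:
        """Discrete divergence.

        Uses the staggered face velocities (the algebra the projection
        enforces) when present, otherwise central differences of the
        cell-centred components.
        """
        if self.u_face is not None and self.v_face is not None:
            return (
                np.diff(self.u_face, axis=0) + np.diff(self.v_face, axis=1)
            ) / self.h
        grads = [
            np.gradient(self.velocity[k], self.h, axis=k) for k in range(self.ncomp)
        ]
        return sum(grads[: self.ndim])
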