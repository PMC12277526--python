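"""Diffusion acquisition schemes (b-values and gradient directions)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

#: Multi-shell protocol used throughout: 12 b-values (s/mm²) including b=0.
DEFAULT_SHELLS = (0, 300, 350, 650, 950, 1000, 1350, 1650, 1700, 2000, 2700, 3000)
#: Default directions per non-zero shell: 9 × 11 shells = 99 gradient
#: directions total, the size of the acquisition protocol being emulated.
DEFAULT_N_DIRECTIONS = 9


@dataclass(frozen=True)
class AcquisitionScheme:
    """One b-value and one unit gradient direction per measurement.

    ``b_values`` are in s/mm²; directions are unit 3-vectors for b>0
    measurements and zero vectors for b=0 measurements.
    """

    b_values: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        g = np.asarray(self.directions, dtype=float)
        if b.ndim != 1 or g.shape != (b.size, 3):
            raise ValueError("b_values must be 1-D and directions (n, 3)")
        if np.any(b < 0):
            raise ValueError("negative b-value")
        nz = b > 0
        norms = np.linalg.norm(g[nz], axis=1)
        if nz.any() and np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("non-unit gradient direction at b > 0")
        if not np.any(b == 0):
            raise ValueError("scheme needs at least one b=0 measurement")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)

    def __len__(self) -> int:
        return int(self.b_values.size)

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique b-values."""
        return np.unique(self.b_values)

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.b_values == 0))

    def design_matrix(self) -> np.ndarray:
        """Log-linear tensor design: columns [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
        b = self.b_values
        gx, gy, gz = self.directions.T
        return np.column_stack([
            np.ones_like(b),
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ])


def fibonacci_directions(n: int, seed: int = 0) -> np.ndarray:
    """Quasi-uniform unit vectors from a spherical Fibonacci lattice.

    The lattice is rotated by a seed-derived random rotation so distinct
    seeds give distinct (but equally uniform) direction sets.
    """
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
    return pts @ rot.T


def make_scheme(
    shells=DEFAULT_SHELLS,
    n_directions: int = DEFAULT_N_DIRECTIONS,
    seed: int = 0,
) -> AcquisitionScheme:
    """Build a multi-shell scheme: one b=0 entry per zero shell listed, and
    ``n_directions`` lattice directions for every non-zero shell.

    Raises if ``n_directions`` < 6 (the tensor would be under-determined).
    """
    shells = list(shells)
    if not shells:
        raise ValueError("shells must be non-empty")
    if any(s < 0 for s in shells):
        raise ValueError("negative b-value shell")
    if n_directions < 6:
        raise ValueError("n_directions must be >= 6: tensor fit is under-determined")
    # one lattice over all non-zero shells, interleaved so every shell gets
    # its own quasi-uniform subset and the union covers the sphere densely
    n_nonzero = sum(1 for s in shells if s > 0)
    if n_directions == 6 and n_nonzero == 1:
        # the 6-point Fibonacci set is degenerate for tensor estimation
        # (rank 6 of 7); use the classic icosahedral-style six-direction set
        rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
        lattice = (
            np.array(
                [[1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1], [0, 1, 1], [0, 1, -1]],
                dtype=float,
            )
            / np.sqrt(2.0)
        ) @ rot.T
    else:
        lattice = fibonacci_directions(max(n_directions * n_nonzero, n_directions), seed=seed)
    b_out: list[float] = []
    g_out: list[np.ndarray] = []
    shell_idx = 0
    for s in shells:
        if s == 0:
            b_out.append(0.0)
            g_out.append(np.zeros((1, 3)))
        else:
            b_out.extend([float(s)] * n_directions)
            g_out.append(lattice[shell_idx::n_nonzero][:n_directions])
            shell_idx += 1
    return AcquisitionScheme(np.array(b_out), np.vstack(g_out))
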