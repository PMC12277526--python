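"""Shell selection, per-voxel diffusion tensor fitting, and scalar maps.

The tensor is estimated by weighted linear least squares (WLLS) on
log-signals: an ordinary least-squares pass on ln S provides predicted
signals, whose squares serve as weights for one refinement pass. On
noise-free data the log-linear system is exact, so any SPD tensor is
recovered to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dtialps.scheme import AcquisitionScheme


@dataclass
class DWIDataset:
    """4-D diffusion-weighted signal plus its acquisition scheme.

    ``signal`` has shape (x, y, z, n_measurements); ``mask`` marks voxels
    to fit. ``affine`` is the voxel-to-world matrix carried through I/O.
    """

    signal: np.ndarray
    scheme: AcquisitionScheme
    voxel_size: float = 1.0
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, measurement)")
        if self.signal.shape[-1] != len(self.scheme):
            raise ValueError(
                f"signal has {self.signal.shape[-1]} measurements but scheme "
                f"has {len(self.scheme)}"
            )
        if np.any(self.signal < 0):
            raise ValueError("negative signal")
        if self.mask is None:
            self.mask = np.ones(self.signal.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.signal.shape[:3]:
            raise ValueError("mask shape must equal spatial shape")
        if self.affine is None:
            self.affine = np.diag([self.voxel_size] * 3 + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor (mm²/s), lower-triangle storage.

    ``components`` has shape grid + (6,), ordered
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz). ``flags`` marks voxels excluded from the
    fit (non-positive signals) or degenerate; ``residual`` is the per-voxel
    weighted residual norm of the log-linear fit.
    """

    components: np.ndarray
    mask: np.ndarray
    flags: np.ndarray
    residual: np.ndarray
    voxel_size: float = 1.0
    affine: np.ndarray | None = None

    def as_matrices(self) -> np.ndarray:
        """Dense (…, 3, 3) symmetric tensor array."""
        c = self.components
        out = np.empty(c.shape[:-1] + (3, 3), dtype=c.dtype)
        out[..., 0, 0] = c[..., 0]
        out[..., 1, 1] = c[..., 1]
        out[..., 2, 2] = c[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = c[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = c[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = c[..., 5]
        return out


@dataclass
class DiffusivityMaps:
    """Scalar maps derived from a tensor field.

    dxx/dyy/dzz are the tensor diagonal (apparent diffusivity along the
    template axes); eigenvalues are sorted λ1 ≥ λ2 ≥ λ3; FA ∈ [0, 1];
    MD = trace/3; AD = λ1; RD = (λ2 + λ3)/2. ``flags`` marks voxels where
    the fit failed or eigenvalues were clamped to zero.
    """

    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    eigenvalues: np.ndarray
    flags: np.ndarray
    mask: np.ndarray
    voxel_size: float = 1.0
    affine: np.ndarray | None = None


def select_shells(dataset: DWIDataset, b_max: float, inclusive: bool = False) -> DWIDataset:
    """Keep measurements with b < b_max (or ≤ b_max when inclusive) plus all b=0.

    Raises if the reduced design has no b=0 or fewer than 6 distinct
    non-zero-b directions.
    """
    b = dataset.scheme.b_values
    keep = (b <= b_max) if inclusive else (b < b_max)
    keep |= b == 0
    sub = AcquisitionScheme(b[keep], dataset.scheme.directions[keep])
    if sub.n_b0 == 0:
        raise ValueError("shell selection removed all b=0 measurements")
    if _n_distinct_directions(sub) < 6:
        raise ValueError("fewer than 6 distinct non-zero-b directions after selection")
    return DWIDataset(
        signal=dataset.signal[..., keep],
        scheme=sub,
        voxel_size=dataset.voxel_size,
        mask=dataset.mask,
        affine=dataset.affine,
    )


def _n_distinct_directions(scheme: AcquisitionScheme) -> int:
    g = scheme.directions[scheme.b_values > 0]
    if g.size == 0:
        return 0
    # antipodal directions probe the same tensor projection
    g = np.where(g[:, [0]] < 0, -g, g)
    return np.unique(np.round(g, 9), axis=0).shape[0]


def _averaged_b0_design(dataset: DWIDataset):
    """Average the b=0 volumes into one and return (signal, scheme)."""
    b = dataset.scheme.b_values
    is0 = b == 0
    if is0.sum() <= 1:
        return dataset.signal, dataset.scheme
    s0_mean = dataset.signal[..., is0].mean(axis=-1, keepdims=True)
    sig = np.concatenate([s0_mean, dataset.signal[..., ~is0]], axis=-1)
    sch = AcquisitionScheme(
        np.concatenate([[0.0], b[~is0]]),
        np.vstack([np.zeros(3), dataset.scheme.directions[~is0]]),
    )
    return sig, sch


def fit_tensor(dataset: DWIDataset) -> TensorField:
    """Weighted linear least-squares tensor fit per masked voxel.

    Multiple b=0 volumes are averaged before fitting. Voxels containing a
    non-positive signal are flagged and excluded. Raises when the global
    design is insufficient (< 6 distinct directions or no b=0).
    """
    if dataset.scheme.n_b0 == 0:
        raise ValueError("no b=0 measurement")
    if _n_distinct_directions(dataset.scheme) < 6:
        raise ValueError("fewer than 6 distinct non-zero-b directions: tensor under-determined")

    signal, scheme = _averaged_b0_design(dataset)
    grid = dataset.shape
    A = scheme.design_matrix()  # (m, 7)
    if np.linalg.matrix_rank(A) < 7:
        raise ValueError(
            "rank-deficient tensor design: directions do not span the "
            "6-dimensional space of symmetric tensors"
        )

    mask = dataset.mask
    vox = signal[mask]  # (v, m)
    ok = np.all(vox > 0, axis=1)
    flags = np.zeros(grid, dtype=bool)
    flags[mask] = ~ok

    comps = np.zeros(grid + (6,), dtype=float)
    resid = np.zeros(grid, dtype=float)
    if ok.any():
        y = np.log(vox[ok])  # (v, m)
        # OLS pass
        beta = y @ np.linalg.pinv(A).T  # (v, 7)
        # one WLLS refinement with weights = squared predicted signal
        w = np.exp(2.0 * (beta @ A.T))  # (v, m)
        K = A[:, :, None] * A[:, None, :]  # (m, 7, 7)
        M = np.tensordot(w, K, axes=(1, 0))  # (v, 7, 7)
        r = np.einsum("vm,mi->vi", w * y, A)  # (v, 7)
        beta = np.linalg.solve(M, r[..., None])[..., 0]
        res = y - beta @ A.T
        rnorm = np.sqrt(np.einsum("vm,vm->v", w * res, res))

        full_beta = np.zeros((vox.shape[0], 7))
        full_beta[ok] = beta
        full_res = np.zeros(vox.shape[0])
        full_res[ok] = rnorm
        comps[mask] = full_beta[:, 1:7]
        resid[mask] = full_res

    return TensorField(
        components=comps,
        mask=mask & ~flags,
        flags=flags,
        residual=resid,
        voxel_size=dataset.voxel_size,
        affine=dataset.affine,
    )


def fractional_anisotropy(evals: np.ndarray) -> np.ndarray:
    """FA from eigenvalues (…, 3); all-zero tensors give FA = 0."""
    lam = np.asarray(evals, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sum((lam - mean) ** 2, axis=-1)
    den = np.sum(lam**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(np.where(den > 0, num / np.where(den > 0, den, 1), 0.0))
    return np.clip(fa, 0.0, 1.0)


def eigen_maps(field: TensorField) -> DiffusivityMaps:
    """Symmetric eigendecomposition per voxel and derived scalar maps.

    Eigenvalues are sorted descending; negative eigenvalues are clamped to
    zero before map computation and the voxel flagged. All-zero (degenerate)
    tensors get FA = 0 and a flag.
    """
    mats = field.as_matrices()
    if not np.all(np.isfinite(mats[field.mask])):
        raise ValueError("non-finite tensor inside mask")
    evals = np.linalg.eigvalsh(mats)[..., ::-1]  # descending
    clamped = evals < 0
    flags = field.flags | np.any(clamped, axis=-1)
    evals = np.maximum(evals, 0.0)
    degenerate = np.all(evals == 0, axis=-1) & field.mask
    flags = flags | degenerate

    c = field.components
    return DiffusivityMaps(
        dxx=c[..., 0].copy(),
        dyy=c[..., 1].copy(),
        dzz=c[..., 2].copy(),
        fa=fractional_anisotropy(evals),
        md=evals.mean(axis=-1),
        ad=evals[..., 0].copy(),
        rd=evals[..., 1:].mean(axis=-1),
        eigenvalues=evals,
        flags=flags,
        mask=field.mask,
        voxel_size=field.voxel_size,
        affine=field.affine,
    )
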