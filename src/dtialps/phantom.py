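"""Template-space DWI phantoms and whole cohorts with known ground truth.

Geometry: an ellipsoidal "brain" mask on a regular grid containing the four
perivascular ALPS ROIs (left/right × projection/association) and two
ellipsoidal hippocampal labels. Each ROI region carries one diffusion
tensor per subject; subject-to-subject variation enters at the
ROI-diffusivity level (drawn from the group preset) and measurement noise
enters per voxel through a Rician channel at a configurable SNR.

Signal model is monoexponential (Stejskal–Tanner): S = S0 · exp(−b gᵀDg).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from dtialps.scheme import AcquisitionScheme
from dtialps.tensor import DWIDataset, TensorField, eigen_maps, fractional_anisotropy
from dtialps.alps import ROISpec, compute_alps, default_rois, reduced_rois, sphere_offsets
from dtialps.hippocampus import HIPPOCAMPUS_LEFT, HIPPOCAMPUS_RIGHT, LabelVolume

SIDES = ("left", "right")

#: Off-fiber (denominator) diffusivity at the ALPS ROIs, mm²/s.
DEFAULT_DENOMINATOR_DIFFUSIVITY = 0.65e-3
#: Diffusivity along the dominant fiber axis at the ALPS ROIs, mm²/s.
DEFAULT_FIBER_DIFFUSIVITY = 1.4e-3
#: Isotropic background (parenchyma) diffusivity, mm²/s.
DEFAULT_BACKGROUND_DIFFUSIVITY = 0.75e-3


# --------------------------------------------------------------------------
# geometry


def _ellipsoid(grid_shape, center, semi_axes) -> np.ndarray:
    idx = np.indices(grid_shape, dtype=float)
    c = np.asarray(center, dtype=float).reshape(3, 1, 1, 1)
    a = np.asarray(semi_axes, dtype=float).reshape(3, 1, 1, 1)
    return np.sum(((idx - c) / a) ** 2, axis=0) <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise settings of a single-subject phantom.

    ``rois`` are the four ALPS ROIs on this grid; ``hippocampi`` maps label
    ID → (center, semi_axes) for the two hippocampal ellipsoids; ``snr`` is
    s0/σ of the Rician noise channel.
    """

    grid_shape: tuple[int, int, int]
    voxel_size: float
    rois: tuple[ROISpec, ...]
    hippocampi: dict[int, tuple[tuple, tuple]]
    mask_center: tuple[float, float, float]
    mask_semi_axes: tuple[float, float, float]
    background_diffusivity: float = DEFAULT_BACKGROUND_DIFFUSIVITY
    s0: float = 1000.0
    snr: float = 20.0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        shape = np.asarray(self.grid_shape)
        for roi in self.rois:
            offs = sphere_offsets(roi.diameter, self.voxel_size)
            idx = offs + np.asarray(roi.center)
            if np.any(idx < 0) or np.any(idx >= shape):
                raise ValueError(f"ROI {roi.name!r} extends outside the phantom grid")
        for rid, (center, axes) in self.hippocampi.items():
            lo = np.asarray(center) - np.asarray(axes)
            hi = np.asarray(center) + np.asarray(axes)
            if np.any(lo < 0) or np.any(hi >= shape):
                raise ValueError(f"hippocampal label {rid} extends outside the grid")

    @property
    def sigma(self) -> float:
        """Rician channel standard deviation (signal units)."""
        return self.s0 / self.snr

    def brain_mask(self) -> np.ndarray:
        return _ellipsoid(self.grid_shape, self.mask_center, self.mask_semi_axes)

    def label_volume(self) -> LabelVolume:
        lab = np.zeros(self.grid_shape, dtype=np.int16)
        for rid, (center, axes) in self.hippocampi.items():
            lab[_ellipsoid(self.grid_shape, center, axes)] = rid
        return LabelVolume(labels=lab, voxel_size=self.voxel_size)

    @classmethod
    def reduced(cls, snr: float = 20.0, s0: float = 1000.0) -> "PhantomSpec":
        """64×64×32 grid at 1 mm with re-homed ROIs — fast tests and smoke runs."""
        return cls(
            grid_shape=(64, 64, 32),
            voxel_size=1.0,
            rois=reduced_rois(),
            hippocampi={
                HIPPOCAMPUS_LEFT: ((44, 40, 15), (5, 8, 5)),
                HIPPOCAMPUS_RIGHT: ((19, 40, 15), (5, 8, 5)),
            },
            mask_center=(31.5, 31.5, 15.5),
            mask_semi_axes=(28.0, 28.0, 14.0),
            snr=snr,
            s0=s0,
        )

    @classmethod
    def template(cls, snr: float = 20.0, s0: float = 1000.0) -> "PhantomSpec":
        """182×218×182 grid at 1 mm matching the template the published ROI
        coordinates index. Memory-hungry; prefer ``reduced`` for testing."""
        return cls(
            grid_shape=(182, 218, 182),
            voxel_size=1.0,
            rois=default_rois(),
            hippocampi={
                HIPPOCAMPUS_LEFT: ((116, 104, 56), (8, 14, 7)),
                HIPPOCAMPUS_RIGHT: ((64, 104, 56), (8, 14, 7)),
            },
            mask_center=(90.5, 108.5, 90.5),
            mask_semi_axes=(82.0, 100.0, 82.0),
            snr=snr,
            s0=s0,
        )


# --------------------------------------------------------------------------
# group presets


@dataclass(frozen=True)
class GroupPreset:
    """Population-level ground truth for one cohort group.

    ``alps_mean``/``alps_sd`` give the target mean and SD of the
    per-hemisphere ALPS ratio; subjects draw a mean-one lognormal factor per
    hemisphere that scales both numerator (x-axis) diffusivities, so the
    ground-truth ratio is lognormal with exactly that mean and SD.
    Hippocampal tensors are prolate axisymmetric, parameterized by axial
    (AD) and radial (RD) diffusivity; RD is negatively coupled to the
    hemisphere's ALPS factor with correlation ``alps_rd_coupling``.
    ``covariates`` maps column name → distribution tuple (see
    ``_sample_covariate``).
    """

    name: str
    alps_mean: dict[str, float]
    alps_sd: dict[str, float]
    denominator_diffusivity: float = DEFAULT_DENOMINATOR_DIFFUSIVITY
    fiber_diffusivity: float = DEFAULT_FIBER_DIFFUSIVITY
    hippo_ad_mean: float = 1.00e-3
    hippo_ad_sd: float = 0.05e-3
    hippo_rd_mean: float = 0.78e-3
    hippo_rd_sd: float = 0.04e-3
    alps_rd_coupling: float = 0.0
    alps_avlt_coupling: float = 0.0
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for side in SIDES:
            if self.alps_sd[side] < 0:
                raise ValueError("alps_sd must be non-negative")
            if self.alps_mean[side] <= 0:
                raise ValueError("alps_mean must be positive")
        if not -1.0 <= self.alps_rd_coupling <= 1.0:
            raise ValueError("coupling must be a correlation in [-1, 1]")

    def lognormal_sigma(self, side: str) -> float:
        """Moment-matched lognormal shape: sigma² = ln(1 + CV²)."""
        cv = self.alps_sd[side] / self.alps_mean[side]
        return float(np.sqrt(np.log1p(cv * cv)))


def _sample_covariate(dist: tuple, rng: np.random.Generator) -> float:
    """Draw one covariate value.

    Supported distribution tuples:
      ("normal", mean, sd)                — Gaussian
      ("normal_iqr", median, q1, q3)      — Gaussian, sd = IQR/1.349
      ("lognormal_iqr", median, q1, q3)   — lognormal matched to quartiles
      ("bernoulli", p)                    — 0/1
      ("missing",)                        — NaN (e.g. disease duration in HC)
    """
    kind = dist[0]
    if kind == "normal":
        _, m, s = dist
        return float(rng.normal(m, s))
    if kind == "normal_iqr":
        _, med, q1, q3 = dist
        sd = max((q3 - q1) / 1.349, 1e-6)
        return float(rng.normal(med, sd))
    if kind == "lognormal_iqr":
        _, med, q1, q3 = dist
        if q1 <= 0:
            raise ValueError("lognormal quartiles must be positive")
        sigma = (np.log(q3) - np.log(q1)) / (2 * 0.6745)
        return float(np.exp(rng.normal(np.log(med), max(sigma, 1e-6))))
    if kind == "bernoulli":
        return float(rng.random() < dist[1])
    if kind == "missing":
        return float("nan")
    raise ValueError(f"unknown covariate distribution {kind!r}")


# --------------------------------------------------------------------------
# subject-level truth


def _axisymmetric_metrics(ad: float, rd: float) -> dict[str, float]:
    ev = np.array([ad, rd, rd])
    return {
        "fa": float(fractional_anisotropy(ev)),
        "md": float(ev.mean()),
        "ad": float(ad),
        "rd": float(rd),
    }


def draw_subject_truth(preset: GroupPreset, rng: np.random.Generator) -> dict:
    """Draw one subject's ground-truth diffusivities, hippocampal tensors,
    and covariates from the group preset."""
    truth: dict = {"group": preset.name}
    den = preset.denominator_diffusivity
    z_by_side = {}
    for side in SIDES:
        sigma = preset.lognormal_sigma(side)
        z = rng.standard_normal()
        z_by_side[side] = z
        factor = np.exp(sigma * z - 0.5 * sigma * sigma)  # mean-one lognormal
        ratio = preset.alps_mean[side] * factor
        truth[f"dx_proj_{side}"] = ratio * den
        truth[f"dx_assoc_{side}"] = ratio * den
        truth[f"dy_proj_{side}"] = den
        truth[f"dz_assoc_{side}"] = den
        truth[f"alps_{side}"] = ratio
    truth["alps_mean"] = 0.5 * (truth["alps_left"] + truth["alps_right"])

    rho = preset.alps_rd_coupling
    for side in SIDES:
        ad = max(rng.normal(preset.hippo_ad_mean, preset.hippo_ad_sd), 1e-5)
        eps = rng.standard_normal()
        z_rd = -rho * z_by_side[side] + np.sqrt(max(0.0, 1 - rho * rho)) * eps
        rd = max(preset.hippo_rd_mean + preset.hippo_rd_sd * z_rd, 1e-5)
        rd = min(rd, ad)  # prolate tensor: AD is the largest eigenvalue
        truth[f"hippo_ad_truth_{side}"] = ad
        truth[f"hippo_rd_truth_{side}"] = rd
        m = _axisymmetric_metrics(ad, rd)
        for k in ("fa", "md", "ad", "rd"):
            truth[f"hippo_{k}_{side}"] = m[k]

    for name, dist in preset.covariates.items():
        truth[name] = _sample_covariate(dist, rng)
    if preset.alps_avlt_coupling and "avlt_immediate" in truth:
        # mild coupling between immediate-recall memory and mean ALPS
        rho_c = preset.alps_avlt_coupling
        z_mean = 0.5 * (z_by_side["left"] + z_by_side["right"]) / np.sqrt(0.5)
        dist = preset.covariates["avlt_immediate"]
        sd = dist[2] if dist[0] == "normal" else 1.0
        truth["avlt_immediate"] += sd * rho_c * z_mean
    return truth


# --------------------------------------------------------------------------
# signal synthesis


def simulate_signal(tensor: np.ndarray, scheme: AcquisitionScheme, s0: float = 1.0) -> np.ndarray:
    """Noise-free Stejskal–Tanner signal S = s0 · exp(−b gᵀDg) per measurement."""
    D = np.asarray(tensor, dtype=float)
    if D.shape != (3, 3) or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("tensor must be symmetric 3×3")
    if np.linalg.eigvalsh(D).min() < -1e-15:
        raise ValueError("tensor must be positive semidefinite")
    b = scheme.b_values
    g = scheme.directions
    bq = b * np.einsum("mi,ij,mj->m", g, D, g)
    return s0 * np.exp(-bq)


def add_rician_noise(signal: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Magnitude-MRI noise: |S + n1 + i·n2| with n1, n2 ~ N(0, σ²).

    σ = 0 returns the input unchanged; output is deterministic given seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


# --------------------------------------------------------------------------
# subject phantom


@dataclass
class SubjectPhantom:
    """A synthesized subject: noisy DWI plus the generating ground truth."""

    subject_id: str
    dwi: DWIDataset
    true_field: TensorField
    ground_truth: dict
    labels: LabelVolume
    spec: PhantomSpec


def _region_tensors(spec: PhantomSpec, truth: dict) -> tuple[np.ndarray, list[np.ndarray]]:
    """Paint a region-ID map and list one tensor per region ID.

    Region 0 = outside mask (zero signal), 1 = background, 2.. = ALPS ROIs,
    then the hippocampal labels.
    """
    grid = spec.grid_shape
    region = np.zeros(grid, dtype=np.int8)
    mask = spec.brain_mask()
    region[mask] = 1
    tensors = [np.zeros((3, 3)), np.eye(3) * spec.background_diffusivity]

    fiber = truth.get("fiber_diffusivity", DEFAULT_FIBER_DIFFUSIVITY)
    next_id = 2
    for roi in spec.rois:
        side = roi.side
        if roi.fiber == "projection":
            # fiber along z; perivascular x; off-fiber y
            diag = (truth[f"dx_proj_{side}"], truth[f"dy_proj_{side}"], fiber)
        else:
            # association fiber along y; off-fiber z
            diag = (truth[f"dx_assoc_{side}"], fiber, truth[f"dz_assoc_{side}"])
        offs = sphere_offsets(roi.diameter, spec.voxel_size)
        idx = offs + np.asarray(roi.center)
        region[idx[:, 0], idx[:, 1], idx[:, 2]] = next_id
        tensors.append(np.diag(diag))
        next_id += 1

    side_of = {HIPPOCAMPUS_LEFT: "left", HIPPOCAMPUS_RIGHT: "right"}
    for rid, (center, axes) in spec.hippocampi.items():
        sel = _ellipsoid(grid, center, axes)
        region[sel] = next_id
        side = side_of.get(rid, "left")
        ad = truth[f"hippo_ad_truth_{side}"]
        rd = truth[f"hippo_rd_truth_{side}"]
        tensors.append(np.diag((rd, ad, rd)))  # long axis anterior–posterior
        next_id += 1
    return region, tensors


def build_subject_phantom(
    spec: PhantomSpec,
    preset: GroupPreset,
    scheme: AcquisitionScheme,
    subject_seed: int,
    subject_id: str | None = None,
    truth: dict | None = None,
) -> SubjectPhantom:
    """Draw one subject from the preset and synthesize its noisy DWI.

    ROI voxels get the subject's ROI tensors, hippocampal labels their
    hippocampal tensors, remaining brain voxels the isotropic background;
    Rician noise at spec.snr is applied inside the brain mask.
    """
    rng = np.random.default_rng(subject_seed)
    if truth is None:
        truth = draw_subject_truth(preset, rng)
    truth = dict(truth)
    truth.setdefault("fiber_diffusivity", preset.fiber_diffusivity)

    region, tensors = _region_tensors(spec, truth)
    table = np.stack([simulate_signal(D, scheme, spec.s0) for D in tensors])
    mask = region > 0

    # materialize the per-voxel signal only inside the brain mask; voxels
    # outside carry zero signal (air)
    masked_signal = table[region[mask]]
    noise_seed = int(rng.integers(0, 2**31 - 1))
    if spec.snr > 0 and np.isfinite(spec.snr):
        masked_signal = add_rician_noise(masked_signal, spec.sigma, seed=noise_seed)
    signal = np.zeros(spec.grid_shape + (len(scheme),), dtype=float)
    signal[mask] = masked_signal
    del masked_signal

    tens6 = np.stack(
        [np.array([D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]]) for D in tensors]
    )
    true_field = TensorField(
        components=tens6[region],
        mask=mask,
        flags=np.zeros(spec.grid_shape, dtype=bool),
        residual=np.zeros(spec.grid_shape),
        voxel_size=spec.voxel_size,
    )

    dwi = DWIDataset(
        signal=signal,
        scheme=scheme,
        voxel_size=spec.voxel_size,
        mask=mask,
    )
    return SubjectPhantom(
        subject_id=subject_id or f"sub-{subject_seed}",
        dwi=dwi,
        true_field=true_field,
        ground_truth=truth,
        labels=spec.label_volume(),
        spec=spec,
    )


# --------------------------------------------------------------------------
# cohorts


def recompute_ground_truth_alps(subject: SubjectPhantom):
    """Apply the ALPS formula to the subject's true tensor field.

    Must equal the stored ground-truth values to < 1e-12 — the phantom's
    defining invariant.
    """
    true_maps = eigen_maps(subject.true_field)
    return compute_alps(true_maps, subject.spec.rois)


class CohortPhantoms:
    """Lazy, deterministic sequence of SubjectPhantoms.

    Subjects are materialized on access from stored per-subject seeds and
    pre-drawn ground truth, so a whole cohort never has to be held in
    memory at once.
    """

    def __init__(self, spec, scheme, presets_per_subject, truths, seeds, ids):
        self.spec = spec
        self.scheme = scheme
        self._presets = presets_per_subject
        self._truths = truths
        self._seeds = seeds
        self._ids = ids

    def __len__(self) -> int:
        return len(self._seeds)

    def __getitem__(self, i: int) -> SubjectPhantom:
        # truth is re-drawn inside (deterministic from the stored seed) so the
        # direct and cohort construction paths are bit-identical
        return build_subject_phantom(
            self.spec,
            self._presets[i],
            self.scheme,
            subject_seed=self._seeds[i],
            subject_id=self._ids[i],
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


def _truth_rows(presets, sizes, seed):
    rows, per_preset, seeds, ids = [], [], [], []
    idx = 0
    for preset, n in zip(presets, sizes):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        for _ in range(int(n)):
            subject_seed = int(
                np.random.SeedSequence([int(seed), idx]).generate_state(1)[0] % (2**31 - 1)
            )
            rng = np.random.default_rng(subject_seed)
            truth = draw_subject_truth(preset, rng)
            sid = f"sub-{idx:03d}"
            truth["subject_id"] = sid
            rows.append(truth)
            per_preset.append(preset)
            seeds.append(subject_seed)
            ids.append(sid)
            idx += 1
    return rows, per_preset, seeds, ids


def generate_cohort(presets, sizes, spec: PhantomSpec, scheme: AcquisitionScheme, seed: int):
    """Generate a multi-group cohort: lazy imaging phantoms + truth table.

    Returns ``(CohortPhantoms, DataFrame)``; the DataFrame holds one row per
    subject with group, covariates, and ground-truth ALPS/hippocampal values.
    Bit-reproducible for a fixed seed.
    """
    rows, per_preset, seeds, ids = _truth_rows(presets, sizes, seed)
    table = pd.DataFrame(rows).set_index("subject_id").reset_index()
    cohort = CohortPhantoms(spec, scheme, per_preset, rows, seeds, ids)
    return cohort, table


def generate_cohort_table(presets, sizes, seed: int) -> pd.DataFrame:
    """Tabular-only cohort draw (ground-truth metrics, no imaging)."""
    rows, *_ = _truth_rows(presets, sizes, seed)
    return pd.DataFrame(rows).set_index("subject_id").reset_index()
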