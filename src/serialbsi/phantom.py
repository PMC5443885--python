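"""Synthetic serial-MRI phantoms and simulated cohorts.

Generates co-registered baseline/follow-up image pairs of a three-tissue
(CSF/GM/WM) spherical head phantom with a known, voxel-exact boundary shift;
adds scan-type-dependent acquisition noise and motion blurring; and draws
cohort-level direct-change tables and paired QC outcomes from the generative
linear mixed model used for the accelerated vs non-accelerated comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .bsi import ImagePair

ACCELERATED = "accelerated"
NON_ACCELERATED = "non_accelerated"
SCAN_TYPES = (ACCELERATED, NON_ACCELERATED)
DIAGNOSES = ("CN", "EMCI", "LMCI", "AD")

# fixed sub-voxel offset of all structure centers; breaks lattice-distance
# ties so that boundary shifts can be realized one voxel at a time
_CENTER_JITTER_MM = (0.137, 0.293, 0.211)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue intensities and true volume changes of one phantom pair.

    All lengths in mm; volume changes in ml.  The brain is a sphere containing
    a concentric ventricular (CSF) sphere and two ellipsoidal "hippocampi"
    (GM) embedded in white matter, with a cortical GM shell under the brain
    surface.  Atrophy shrinks the brain surface, ventricular growth expands
    the CSF sphere, hippocampal atrophy shrinks both ellipsoids.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tissue_means: tuple[float, float, float] = (20.0, 70.0, 120.0)  # CSF, GM, WM
    brain_radius: float = 25.0
    ventricle_radius: float = 8.0
    # deep in the white-matter core, clear of the cortical shell and of
    # plausible ventricular growth
    hippocampus_semiaxes: tuple[tuple[float, float, float], ...] = (
        (5.0, 3.5, 3.0),
        (5.0, 3.5, 3.0),
    )
    hippocampus_centers: tuple[tuple[float, float, float], ...] = (
        (12.0, 7.0, 0.0),
        (-12.0, 7.0, 0.0),
    )
    gm_thickness: float = 4.0
    atrophy_ml: float = 2.0
    ventricle_growth_ml: float = 1.0
    hippo_atrophy_ml: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        csf, gm, wm = self.tissue_means
        if not (csf < gm < wm):
            raise ValueError("tissue_means must be strictly increasing (CSF < GM < WM)")
        if self.brain_radius <= 0 or self.ventricle_radius <= 0:
            raise ValueError("radii must be positive")
        if self.ventricle_radius >= self.brain_radius - self.gm_thickness:
            raise ValueError("ventricle does not fit inside the white matter core")
        half_extent = min(
            s * v / 2.0 for s, v in zip(self.grid_shape, self.voxel_size)
        )
        if self.brain_radius >= half_extent - 1.0:
            raise ValueError("brain sphere overflows the grid")
        if len(self.hippocampus_semiaxes) != len(self.hippocampus_centers):
            raise ValueError("one center required per hippocampal ellipsoid")
        for ax, c in zip(self.hippocampus_semiaxes, self.hippocampus_centers):
            if min(ax) <= 0:
                raise ValueError("hippocampus semiaxes must be positive")
            if np.linalg.norm(c) + max(ax) > self.brain_radius - self.gm_thickness:
                raise ValueError("hippocampus overflows the white matter core")
        for change in (self.atrophy_ml, self.ventricle_growth_ml, self.hippo_atrophy_ml):
            if change < 0:
                raise ValueError("volume changes must be non-negative")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0


@dataclass(frozen=True)
class NoiseSpec:
    """Spatially varying acquisition noise for one scan type.

    ``snr_center`` is the signal-to-noise ratio at the grid center;
    ``snr_gradient`` is the fractional SNR increase per mm moving from the
    center outward toward the periphery (receive coils sit at the head
    surface, so accelerated acquisitions lose SNR toward the center).
    ``np.inf`` for ``snr_center`` flags a noiseless acquisition.
    """

    scan_type: str = ACCELERATED
    snr_center: float = 25.0
    snr_gradient: float = 0.0
    noise_model: str = "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_type not in SCAN_TYPES:
            raise ValueError(f"scan_type must be one of {SCAN_TYPES}")
        if not self.snr_center > 0:
            raise ValueError("snr_center must be positive")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if self.scan_type == ACCELERATED and self.snr_gradient < 0:
            raise ValueError(
                "accelerated scans require a non-negative outward SNR gradient"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Generative truth for cohort direct-change tables.

    Fixed effects are ml/yr rates: ``beta0`` the control rate on accelerated
    scans, ``beta1`` the non-accelerated offset, ``beta2..beta4`` the
    EMCI/LMCI/AD offsets.  ``sigma_b`` are per-diagnosis random-slope SDs,
    ``sigma_u`` the visit-effect SD (ml), ``sigma_eps_*`` residual SDs (ml)
    by scan type.
    """

    n_per_group: tuple[int, int, int, int] = (75, 75, 75, 75)
    visit_times: tuple[float, ...] = (0.0, 0.5, 1.0)
    beta0: float = 5.8
    beta1: float = 0.05
    beta2: float = 0.5
    beta3: float = 3.5
    beta4: float = 7.5
    sigma_b: tuple[float, float, float, float] = (2.5, 3.0, 3.5, 4.0)
    sigma_u: float = 1.5
    sigma_eps_a: float = 1.0
    sigma_eps_na: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.visit_times) < 2:
            raise ValueError("at least two visits required")
        t = np.asarray(self.visit_times)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("visit_times must be strictly increasing starting at 0")
        if sum(self.n_per_group) == 0:
            raise ValueError("cohort is empty")
        if min(self.sigma_b) < 0 or self.sigma_u < 0 or self.sigma_eps_a < 0 \
                or self.sigma_eps_na < 0:
            raise ValueError("SDs must be non-negative")

    @property
    def diagnosis_offsets(self) -> dict[str, float]:
        return {"CN": 0.0, "EMCI": self.beta2, "LMCI": self.beta3, "AD": self.beta4}


# ---------------------------------------------------------------------------
# geometry

def _coords_mm(spec: PhantomSpec) -> tuple[np.ndarray, ...]:
    """Physical coordinates (mm) of voxel centers relative to the jittered center."""
    axes = []
    for n, v, j in zip(spec.grid_shape, spec.voxel_size, _CENTER_JITTER_MM):
        c = (n - 1) / 2.0 * v + j
        axes.append(np.arange(n) * v - c)
    return tuple(np.meshgrid(*axes, indexing="ij"))


def _threshold_for_count(dist: np.ndarray, count: int, name: str) -> float:
    """Radius (in `dist` units) whose inclusive mask contains exactly `count` voxels."""
    if count < 1:
        raise ValueError(f"requested change exceeds the volume of the {name}")
    flat = np.sort(dist.ravel())
    if count > flat.size:
        raise ValueError(f"{name} overflows the grid")
    return float(flat[count - 1])


def _shift_structure(dist: np.ndarray, base_thresh: float, delta_ml: float,
                     voxel_ml: float, name: str) -> tuple[np.ndarray, np.ndarray, int]:
    """Baseline/follow-up masks whose voxel-count difference realizes delta_ml.

    Positive delta shrinks the structure; negative grows it.  Returns the two
    masks and the signed realized voxel-count change (baseline − follow-up).
    """
    mask0 = dist <= base_thresh
    n0 = int(mask0.sum())
    n_delta = int(round(delta_ml / voxel_ml))
    n1 = n0 - n_delta
    if n1 < 1:
        raise ValueError(f"requested change exceeds the volume of the {name}")
    thresh1 = _threshold_for_count(dist, n1, name)
    mask1 = dist <= thresh1
    return mask0, mask1, n0 - int(mask1.sum())


def _render(spec: PhantomSpec, brain: np.ndarray, brain_dist: np.ndarray,
            brain_thresh: float, ventricle: np.ndarray,
            hippo: np.ndarray) -> np.ndarray:
    csf, gm, wm = spec.tissue_means
    img = np.full(spec.grid_shape, csf, dtype=float)
    img[brain] = wm
    shell = brain & (brain_dist > brain_thresh - spec.gm_thickness)
    img[shell] = gm
    img[ventricle] = csf
    img[hippo] = gm
    return img


def make_phantom_pair(spec: PhantomSpec):
    """Build a noiseless phantom pair with voxel-exact ground-truth changes.

    Returns ``(pair, masks, truth)`` where ``masks`` maps structure name to
    (baseline, follow-up) boolean volumes (the brain mask is the full sphere,
    ventricles included, so its outer surface is the atrophy boundary) and
    ``truth`` records the realized voxel-quantized changes in ml.
    """
    xs = _coords_mm(spec)
    vox_ml = spec.voxel_volume_ml
    r2 = sum(x * x for x in xs)
    brain_dist = np.sqrt(r2)

    brain0, brain1, d_brain = _shift_structure(
        brain_dist, spec.brain_radius, spec.atrophy_ml, vox_ml, "brain")
    vent0, vent1, d_vent = _shift_structure(
        brain_dist, spec.ventricle_radius, -spec.ventricle_growth_ml, vox_ml,
        "ventricle")

    hippo0 = np.zeros(spec.grid_shape, dtype=bool)
    hippo1 = np.zeros(spec.grid_shape, dtype=bool)
    n_h = len(spec.hippocampus_semiaxes)
    per_h = spec.hippo_atrophy_ml / n_h
    d_hippo = 0
    for ax, c in zip(spec.hippocampus_semiaxes, spec.hippocampus_centers):
        de = np.sqrt(sum(((x - ci) / ai) ** 2 for x, ci, ai in zip(xs, c, ax)))
        m0, m1, dv = _shift_structure(de, 1.0, per_h, vox_ml, "hippocampus")
        hippo0 |= m0
        hippo1 |= m1
        d_hippo += dv

    if np.any(vent1 & hippo0):
        raise ValueError("ventricle growth reaches a hippocampus")

    # follow-up brain surface threshold for rendering the GM shell
    thresh1 = _threshold_for_count(brain_dist, int(brain1.sum()), "brain")
    base = _render(spec, brain0, brain_dist, spec.brain_radius, vent0, hippo0)
    follow = _render(spec, brain1, brain_dist, thresh1, vent1, hippo1)

    pair = ImagePair(baseline=base, followup=follow, voxel_volume=vox_ml)
    masks = {
        "brain": (brain0, brain1),
        "ventricle": (vent0, vent1),
        "hippocampus": (hippo0, hippo1),
    }
    truth = {
        "brain_loss_ml": d_brain * vox_ml,
        "ventricle_growth_ml": -d_vent * vox_ml,
        "hippo_loss_ml": d_hippo * vox_ml,
    }
    return pair, masks, truth


def phantom_visit_series(spec: PhantomSpec, brain_volumes_ml: list[float]):
    """Masks and noiseless images for a sequence of visits with given brain volumes.

    The ventricle and hippocampi stay fixed; the brain surface is thresholded
    to match each requested total brain volume (ml) to the nearest voxel.
    Returns ``(images, brain_masks, realized_ml)``.
    """
    xs = _coords_mm(spec)
    vox_ml = spec.voxel_volume_ml
    brain_dist = np.sqrt(sum(x * x for x in xs))
    vent = brain_dist <= _threshold_for_count(
        brain_dist, int((brain_dist <= spec.ventricle_radius).sum()), "ventricle")
    hippo = np.zeros(spec.grid_shape, dtype=bool)
    for ax, c in zip(spec.hippocampus_semiaxes, spec.hippocampus_centers):
        de = np.sqrt(sum(((x - ci) / ai) ** 2 for x, ci, ai in zip(xs, c, ax)))
        hippo |= de <= 1.0

    images, masks, realized = [], [], []
    for vol in brain_volumes_ml:
        n = int(round(vol / vox_ml))
        thresh = _threshold_for_count(brain_dist, n, "brain")
        mask = brain_dist <= thresh
        images.append(_render(spec, mask, brain_dist, thresh, vent, hippo))
        masks.append(mask)
        realized.append(int(mask.sum()) * vox_ml)
    return images, masks, realized


# ---------------------------------------------------------------------------
# acquisition artifacts

def _snr_field(shape: tuple[int, ...], voxel_size, snr_center: float,
               snr_gradient: float) -> np.ndarray:
    """SNR per voxel: snr_center at the grid center, scaled outward by the gradient."""
    axes = [np.abs(np.arange(n) * v - (n - 1) / 2.0 * v)
            for n, v in zip(shape, voxel_size)]
    grids = np.meshgrid(*axes, indexing="ij")
    dist_from_center = np.sqrt(sum(g * g for g in grids))
    return snr_center * (1.0 + snr_gradient * dist_from_center)


def add_acquisition_noise(image: np.ndarray, noise: NoiseSpec,
                          voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Add spatially varying noise with local SD = local signal / local SNR."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image intensities must be finite")
    if np.isinf(noise.snr_center):
        return image.copy()
    snr = _snr_field(image.shape, voxel_size, noise.snr_center, noise.snr_gradient)
    if np.any(snr <= 0):
        raise ValueError("SNR field is non-positive somewhere on the grid")
    sd = np.abs(image) / snr
    rng = np.random.default_rng(noise.seed)
    if noise.noise_model == "gaussian":
        return image + sd * rng.standard_normal(image.shape)
    re = image + sd * rng.standard_normal(image.shape)
    im = sd * rng.standard_normal(image.shape)
    return np.sqrt(re * re + im * im)


def add_motion_artifact(image: np.ndarray, severity: float, seed: int = 0,
                        axis: int | None = None) -> np.ndarray:
    """Directional motion blurring plus a faint ghost replica.

    ``severity`` in [0, 1] sets the 1-D Gaussian kernel width (up to ~3 voxels
    SD) along one axis — the phase-encode direction, chosen from the seed when
    not given — and the ghost amplitude.  The total image sum is conserved.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    image = np.asarray(image, dtype=float)
    if severity == 0.0:
        return image.copy()
    rng = np.random.default_rng(seed)
    if axis is None:
        axis = int(rng.integers(0, image.ndim))
    shift = int(rng.integers(image.shape[axis] // 4, image.shape[axis] // 2))
    blurred = ndimage.gaussian_filter1d(image, sigma=3.0 * severity, axis=axis,
                                        mode="nearest")
    amp = 0.15 * severity
    out = (1.0 - amp) * blurred + amp * np.roll(blurred, shift, axis=axis)
    total = out.sum()
    if total != 0:
        out *= image.sum() / total
    return out


# ---------------------------------------------------------------------------
# cohort-level simulation

def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a direct-change table from the generative mixed model.

    For subject i with diagnosis dx: slope b_i ~ N(0, σ²_b,dx), visit effects
    u_ij ~ N(0, σ²_u); every ordered visit pair (j, k) yields, per scan type,

        y_ijk = (β0 + β1·scantype + β_dx + b_i)·t_ijk − u_ij + u_ik + ε

    with ε ~ N(0, σ²_ε,scantype).  Both scan types of a pair share b_i and the
    u_ij (scans are acquired back-to-back in the same session).
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.visit_times)
    rows = []
    subject = 0
    eps_sd = {ACCELERATED: spec.sigma_eps_a, NON_ACCELERATED: spec.sigma_eps_na}
    for dx, n_dx, s_b in zip(DIAGNOSES, spec.n_per_group, spec.sigma_b):
        beta_dx = spec.diagnosis_offsets[dx]
        for _ in range(n_dx):
            subject += 1
            b = rng.normal(0.0, s_b)
            u = rng.normal(0.0, spec.sigma_u, size=len(t))
            for j, k in itertools.combinations(range(len(t)), 2):
                dt = t[k] - t[j]
                for st_code, st in enumerate(SCAN_TYPES):
                    # st_code: accelerated = 0, non_accelerated = 1
                    mean = (spec.beta0 + spec.beta1 * st_code + beta_dx + b) * dt
                    y = mean - u[j] + u[k] + rng.normal(0.0, eps_sd[st])
                    rows.append((f"S{subject:04d}", dx, j, k, dt, st, y))
    return pd.DataFrame(
        rows, columns=["subject_id", "diagnosis", "visit_j", "visit_k",
                       "t_years", "scan_type", "y_ml"])


def simulate_qc_labels(n: int, p_fail_a: float, p_fail_na: float,
                       odds_ratio_dependence: float = 1.0,
                       seed: int = 0) -> pd.DataFrame:
    """Paired pass/fail QC outcomes with given marginals and within-pair odds ratio.

    Returns one row per subject with boolean ``fail_accelerated`` /
    ``fail_non_accelerated`` columns.
    """
    for p in (p_fail_a, p_fail_na):
        if not 0.0 <= p <= 1.0:
            raise ValueError("failure probabilities must lie in [0, 1]")
    if odds_ratio_dependence <= 0:
        raise ValueError("odds_ratio_dependence must be positive")
    psi = odds_ratio_dependence
    pa, pb = p_fail_a, p_fail_na
    if psi == 1.0:
        p11 = pa * pb
    else:
        a = 1.0 + (pa + pb) * (psi - 1.0)
        disc = a * a - 4.0 * psi * (psi - 1.0) * pa * pb
        if disc < 0:
            raise ValueError("infeasible marginal/odds-ratio combination")
        p11 = (a - np.sqrt(disc)) / (2.0 * (psi - 1.0))
    lo, hi = max(0.0, pa + pb - 1.0), min(pa, pb)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise ValueError("infeasible marginal/odds-ratio combination")
    p11 = min(max(p11, lo), hi)
    probs = np.array([p11, pa - p11, pb - p11, 1.0 - pa - pb + p11])
    rng = np.random.default_rng(seed)
    cells = rng.choice(4, size=n, p=probs)
    fail_a = np.isin(cells, (0, 1))
    fail_na = np.isin(cells, (0, 2))
    return pd.DataFrame({
        "subject_id": [f"Q{i:04d}" for i in range(1, n + 1)],
        "fail_accelerated": fail_a,
        "fail_non_accelerated": fail_na,
    })
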