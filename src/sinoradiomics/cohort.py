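"""Fully synthetic patient cohorts calibrated to the published
group-conditional feature distributions.

Every downstream stage (shape, texture, perfusion and diffusion
extraction; SVM classification) is testable without any data download:
``sample_cohort`` draws per-patient ground-truth feature values from
group-conditional Gaussians (two outcome groups: local control / local
failure), and ``synthesize_patient`` renders them into image volumes —

* a tumor mask voxelized from a spherical-harmonic-perturbed blob hitting
  the sampled volume and sphericity;
* a T2 volume whose tumor region is a spatially correlated Gaussian field
  matched to the sampled relative mean signal, CV and GLCM contrast;
* a 12-b-value DWI series generated voxelwise from the tri-exponential
  forward model (the richest of the five fitted models, so the other four
  are exercised on deliberately mis-specified data) with Rician noise and
  the acquisition's per-band signal averaging;
* a pCASL control/label pair whose subtraction signal comes from the same
  quantification equation the perfusion module inverts (closure by
  construction), with Gaussian noise.

Ground truth is recorded twice per patient: ``sampled`` (the Gaussian
draw) and ``realized`` (what a noiseless extraction of the rendered images
would measure — e.g. the digitized mask's actual sphericity, or the ADC a
mono-exponential fit produces on the tri-exponential signal).  Round-trip
tests compare extraction against the realized record.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import sph_harm_y

from . import diffusion, perfusion, shape_texture
from .features import FEATURE_NAMES, OUTCOME_LABELS
from .volumes import B_VALUES_FULL, DWISeries, ImageVolume, RoiMask

__all__ = [
    "GroupParameterSpec",
    "AcquisitionConfig",
    "SyntheticPatient",
    "InfeasibleShapeError",
    "TABLE_CONTROL",
    "TABLE_FAILURE",
    "sample_cohort",
    "synthesize_tumor_mask",
    "synthesize_dwi",
    "synthesize_asl",
    "synthesize_t2",
    "synthesize_patient",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "validate_manifest",
    "extract_feature_table",
    "expected_truncated_means",
]


class InfeasibleShapeError(ValueError):
    """Requested sphericity cannot be realized on the given grid."""


# --------------------------------------------------------------------------
# calibration constants: group-conditional means and SDs
# --------------------------------------------------------------------------

CONTINUOUS_FEATURES: tuple[str, ...] = tuple(
    f for f in FEATURE_NAMES if f not in ("t_stage", "n_stage"))

TRI_FRACTIONS = ("tri_f1", "tri_f2", "tri_f3")
_FRACTIONS = ("ivim_f",) + TRI_FRACTIONS
_COEFFICIENTS = ("adc", "ivim_d_star", "ivim_d", "dki_d_k", "sem_ddc",
                 "tri_d1", "tri_d2", "tri_d3")


@dataclass(frozen=True)
class GroupParameterSpec:
    """Per-feature mean and SD for one outcome group.

    Units: volume mL, surface cm^2, TBF mL/100g/min, diffusion
    coefficients 1e-3 mm^2/s, fractions and GLCM features dimensionless
    (energy in natural units, i.e. the published 1.5e-3, not the 1.5 of
    the x10^-3 column).  ``correlation`` optionally imposes a correlation
    matrix over the continuous features (default: independent sampling —
    only the marginals are published).
    """

    label: str
    means: dict[str, float]
    sds: dict[str, float]
    t_stage_counts: dict[int, int]
    n_stage_counts: dict[int, int]
    correlation: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.label not in OUTCOME_LABELS:
            raise ValueError(f"label must be one of {OUTCOME_LABELS}")
        missing = [f for f in CONTINUOUS_FEATURES
                   if f not in self.means or f not in self.sds]
        if missing:
            raise ValueError(f"missing mean/SD for {missing}")
        bad = [f for f, s in self.sds.items() if s < 0]
        if bad:
            raise ValueError(f"negative SDs for {bad}")
        tri_sum = sum(self.means[f] for f in TRI_FRACTIONS)
        if abs(tri_sum - 1.0) > 0.02:
            raise ValueError(f"tri-exponential fraction means sum to {tri_sum}")
        nonpos = [f for f in _COEFFICIENTS if self.means[f] <= 0]
        if nonpos:
            raise ValueError(f"non-positive diffusion coefficients: {nonpos}")
        if self.correlation is not None:
            c = np.asarray(self.correlation)
            k = len(CONTINUOUS_FEATURES)
            if c.shape != (k, k) or not np.allclose(c, c.T):
                raise ValueError("correlation must be a symmetric KxK matrix")


def _spec(label: str, table: dict[str, tuple[float, float]],
          t_counts: dict[int, int], n_counts: dict[int, int]) -> GroupParameterSpec:
    return GroupParameterSpec(
        label=label,
        means={k: v[0] for k, v in table.items()},
        sds={k: v[1] for k, v in table.items()},
        t_stage_counts=t_counts,
        n_stage_counts=n_counts,
    )


#: Local-control group: published mean +/- SD per feature.
TABLE_CONTROL = _spec(
    "control",
    {
        "volume_ml": (25.3, 16.5), "surface_cm2": (50.4, 18.7),
        "sphericity": (0.71, 0.08),
        "relative_mean_signal": (3.8, 0.6), "cv": (0.12, 0.02),
        "contrast": (35.1, 6.0), "correlation": (0.84, 0.02),
        "energy": (1.5e-3, 0.3e-3), "homogeneity": (0.28, 0.03),
        "tbf_abs": (156.7, 32.9), "tbf_rel": (7.47, 0.83),
        "adc": (0.91, 0.10), "ivim_f": (0.16, 0.05),
        "ivim_d_star": (19.5, 7.5), "ivim_d": (0.75, 0.06),
        "dki_k": (0.73, 0.07), "dki_d_k": (1.24, 0.14),
        "sem_alpha": (0.69, 0.07), "sem_ddc": (1.14, 0.12),
        "tri_f1": (0.14, 0.04), "tri_f2": (0.23, 0.04), "tri_f3": (0.62, 0.06),
        "tri_d1": (32.9, 7.8), "tri_d2": (1.03, 0.16), "tri_d3": (0.64, 0.07),
    },
    {1: 0, 2: 1, 3: 10, 4: 11},
    {0: 18, 1: 2, 2: 2, 3: 0},
)

#: Local-failure group.
TABLE_FAILURE = _spec(
    "failure",
    {
        "volume_ml": (34.3, 28.6), "surface_cm2": (69.6, 29.7),
        "sphericity": (0.61, 0.11),
        "relative_mean_signal": (3.4, 0.6), "cv": (0.14, 0.04),
        "contrast": (41.3, 8.6), "correlation": (0.86, 0.03),
        "energy": (1.2e-3, 0.4e-3), "homogeneity": (0.26, 0.03),
        "tbf_abs": (133.7, 29.3), "tbf_rel": (6.25, 1.22),
        "adc": (0.87, 0.13), "ivim_f": (0.16, 0.07),
        "ivim_d_star": (16.7, 5.7), "ivim_d": (0.73, 0.09),
        "dki_k": (0.76, 0.08), "dki_d_k": (1.22, 0.19),
        "sem_alpha": (0.67, 0.08), "sem_ddc": (1.12, 0.17),
        "tri_f1": (0.13, 0.04), "tri_f2": (0.25, 0.05), "tri_f3": (0.61, 0.08),
        "tri_d1": (28.1, 6.5), "tri_d2": (0.92, 0.15), "tri_d3": (0.62, 0.10),
    },
    {1: 0, 2: 0, 3: 3, 4: 11},
    {0: 12, 1: 0, 2: 2, 3: 0},
)

#: Cohort composition: 22 local control, 14 local failure.
DEFAULT_N_CONTROL = 22
DEFAULT_N_FAILURE = 14


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition constants shared by all synthetic sequences.

    The 12-entry b-value schedule, the per-band signal averages (one for
    b <= 100, two for 200-800, three for 1000-2000 s/mm^2), the pCASL
    timing (labeling 1650 ms, post-label delay 1280 ms) and the DWI voxel
    size 3.59 x 3.59 x 5.0 mm follow the acquisition protocol.  Noise
    levels: b0 SNR 50 for DWI (Rician), control-image SNR 100 for ASL
    (Gaussian on the subtraction), 2% muscle-signal noise on T2; ``None``
    (or 0) disables the corresponding noise.
    """

    b_values: tuple[float, ...] = B_VALUES_FULL
    labeling_duration_ms: float = 1650.0
    post_label_delay_ms: float = 1280.0
    voxel_size_mm: tuple[float, float, float] = (3.59, 3.59, 5.0)
    snr_dwi_b0: float | None = 50.0
    snr_asl: float | None = 100.0
    asl_pairs: int = 30
    t2_noise_frac: float | None = 0.02

    def __post_init__(self) -> None:
        b = self.b_values
        if any(x < 0 for x in b) or any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("b-values must be non-negative and strictly increasing")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel size must be positive")

    def signal_averages(self, b: float) -> int:
        if b <= 100:
            return 1
        if b <= 800:
            return 2
        return 3

    def without_noise(self) -> "AcquisitionConfig":
        return replace(self, snr_dwi_b0=None, snr_asl=None, t2_noise_frac=None)

    @property
    def asl_quant(self) -> perfusion.AslQuantConfig:
        return perfusion.AslQuantConfig(
            labeling_duration_ms=self.labeling_duration_ms,
            post_label_delay_ms=self.post_label_delay_ms)


# --------------------------------------------------------------------------
# ground-truth sampling
# --------------------------------------------------------------------------

#: Physical truncation bounds applied feature-wise after Gaussian sampling.
#: Volume keeps a renderable floor (50 voxels on the default DWI grid is
#: ~3.2 mL); fractions follow the clip-then-renormalize rule.
TRUNCATION_BOUNDS: dict[str, tuple[float, float]] = {
    **{f: (0.01, 0.97) for f in _FRACTIONS},
    **{c: (1e-5, np.inf) for c in _COEFFICIENTS},
    "sem_alpha": (0.01, 1.0),
    "sphericity": (0.05, 1.0),
    "dki_k": (0.0, np.inf),
    "correlation": (-1.0, 1.0),
    "energy": (1e-6, 1.0),
    "homogeneity": (1e-6, 1.0),
    "volume_ml": (4.0, np.inf),
    "surface_cm2": (5.0, np.inf),
    "relative_mean_signal": (1e-3, np.inf),
    "cv": (0.0, np.inf),
    "contrast": (1e-3, np.inf),
    "tbf_abs": (1e-3, np.inf),
    "tbf_rel": (1e-3, np.inf),
}


def _truncate(name: str, value: float) -> float:
    lo, hi = TRUNCATION_BOUNDS[name]
    return float(np.clip(value, lo, hi))


def expected_truncated_means(spec: GroupParameterSpec) -> dict[str, float]:
    """Closed-form expectation of each feature under the sampling pipeline.

    For a Gaussian draw clipped to [a, b] the mean is
    a Phi(alpha) + b (1 - Phi(beta)) + mu (Phi(beta) - Phi(alpha))
    - sigma (phi(beta) - phi(alpha)); the tri-exponential fraction triple
    is additionally renormalized, so its expectations are the clipped
    means divided by their sum (exact to first order).  These are the
    targets the group-calibration check uses: where a published mean sits
    close to a physical bound (e.g. a tumor volume SD comparable to the
    mean), the truncated expectation — not the raw printed mean — is what
    sampling can reproduce.
    """
    from scipy.stats import norm

    out: dict[str, float] = {}
    for name in CONTINUOUS_FEATURES:
        mu, sd = spec.means[name], spec.sds[name]
        lo, hi = TRUNCATION_BOUNDS[name]
        if sd == 0:
            out[name] = float(np.clip(mu, lo, hi))
            continue
        alpha = (lo - mu) / sd
        beta = (hi - mu) / sd
        val = mu * (norm.cdf(beta) - norm.cdf(alpha)) \
            - sd * (norm.pdf(beta) - norm.pdf(alpha))
        if np.isfinite(lo):
            val += lo * norm.cdf(alpha)
        if np.isfinite(hi):
            val += hi * norm.sf(beta)
        out[name] = float(val)
    tri_sum = sum(out[f] for f in TRI_FRACTIONS)
    for f in TRI_FRACTIONS:
        out[f] = out[f] / tri_sum
    out["t_stage"] = float(np.average(sorted(spec.t_stage_counts),
                                      weights=[spec.t_stage_counts[s]
                                               for s in sorted(spec.t_stage_counts)]))
    out["n_stage"] = float(np.average(sorted(spec.n_stage_counts),
                                      weights=[spec.n_stage_counts[s]
                                               for s in sorted(spec.n_stage_counts)]))
    return out


def _sample_stage(counts: dict[int, int], rng: np.random.Generator) -> int:
    stages = sorted(counts)
    probs = np.array([counts[s] for s in stages], dtype=float)
    return int(rng.choice(stages, p=probs / probs.sum()))


def sample_cohort(control_spec: GroupParameterSpec = TABLE_CONTROL,
                  failure_spec: GroupParameterSpec = TABLE_FAILURE,
                  n_control: int = DEFAULT_N_CONTROL,
                  n_failure: int = DEFAULT_N_FAILURE,
                  seed: int = 0) -> list[dict]:
    """Draw per-patient ground-truth feature records.

    Continuous features come from group-conditional Gaussians (independent
    unless the spec carries a correlation matrix), truncated to physical
    ranges; the tri-exponential fraction triple is renormalized to sum 1;
    T/N stages are drawn from the group contingency counts.  Deterministic
    under a fixed seed.
    """
    if n_control < 1 or n_failure < 1:
        raise ValueError("need at least one patient per group")
    rng = np.random.default_rng(seed)
    records: list[dict] = []
    pid = 0
    for spec, n in ((control_spec, n_control), (failure_spec, n_failure)):
        mu = np.array([spec.means[f] for f in CONTINUOUS_FEATURES])
        sd = np.array([spec.sds[f] for f in CONTINUOUS_FEATURES])
        if spec.correlation is None:
            draws = mu + sd * rng.standard_normal((n, mu.size))
        else:
            cov = spec.correlation * np.outer(sd, sd)
            draws = rng.multivariate_normal(mu, cov, size=n,
                                            method="cholesky")
        for row in draws:
            rec = {"id": f"patient_{pid:03d}", "outcome": spec.label}
            for name, value in zip(CONTINUOUS_FEATURES, row):
                rec[name] = _truncate(name, float(value))
            tri = np.array([rec[f] for f in TRI_FRACTIONS])
            tri = tri / tri.sum()
            for name, value in zip(TRI_FRACTIONS, tri):
                rec[name] = float(value)
            rec["t_stage"] = float(_sample_stage(spec.t_stage_counts, rng))
            rec["n_stage"] = float(_sample_stage(spec.n_stage_counts, rng))
            records.append(rec)
            pid += 1
    return records


# --------------------------------------------------------------------------
# tumor mask synthesis
# --------------------------------------------------------------------------

def _real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real-valued spherical harmonic (theta polar, phi azimuth)."""
    y = sph_harm_y(l, abs(m), theta, phi)
    if m == 0:
        return y.real
    return np.sqrt(2.0) * ((-1) ** m) * (y.real if m > 0 else y.imag)


_MAX_PERTURB = 0.9    # radius modulation at irregularity 1
_MAX_ELONG = 9.0      # axis stretch factor at irregularity 1; the extreme
                      # shape reaches sphericity ~0.47 on the default grid,
                      # covering the published failure-group range


def synthesize_tumor_mask(target_volume_ml: float, target_sphericity: float,
                          cfg: AcquisitionConfig = AcquisitionConfig(),
                          seed: int = 0, sphericity_tol: float = 0.05,
                          clamp: bool = False) -> RoiMask:
    """Voxelized tumor blob hitting a target volume and sphericity.

    The shape is a ball deformed along a one-parameter irregularity path:
    the radius is modulated by a seeded random combination of degree-2..4
    spherical harmonics while the whole shape is stretched along a seeded
    random axis (volume-conserving).  The path parameter is bisected until
    the measured (mesh-based) sphericity meets the target; at every step
    the base radius is bisected so the voxel count matches the target
    volume.  Raises ``InfeasibleShapeError`` when the target cannot be
    reached on this grid (``clamp=True`` instead returns the nearest
    reachable shape — the generator uses this for extreme sampled draws).
    """
    if target_volume_ml <= 0 or not 0.0 < target_sphericity <= 1.0:
        raise ValueError("need positive volume and sphericity in (0, 1]")
    spacing = np.asarray(cfg.voxel_size_mm)
    vox_vol = float(np.prod(spacing))
    target_mm3 = target_volume_ml * 1000.0
    target_n = target_mm3 / vox_vol
    if target_n < 50:
        raise InfeasibleShapeError(
            f"{target_volume_ml} mL is under 50 voxels on this grid")

    rng = np.random.default_rng(seed)
    r0 = (3.0 * target_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    half_extent = r0 * _MAX_ELONG ** (1.0 / 3.0) * (1.0 + _MAX_PERTURB) * 1.2
    shape = tuple(int(np.ceil(2.0 * half_extent / s)) + 3 for s in spacing)
    center = (np.array(shape) - 1) / 2.0
    idx = np.indices(shape, dtype=float)
    offs = [(idx[a] - center[a]) * spacing[a] for a in range(3)]
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    harmonics = [(l, m, rng.standard_normal() / l)
                 for l in (2, 3, 4) for m in range(-l, l + 1)]
    # the harmonic field depends only on direction: tabulate it once on an
    # angular grid and look it up per voxel instead of re-evaluating
    n_th, n_ph = 181, 361
    th_grid, ph_grid = np.meshgrid(np.linspace(0.0, np.pi, n_th),
                                   np.linspace(-np.pi, np.pi, n_ph),
                                   indexing="ij")
    table = np.zeros((n_th, n_ph))
    for l, m, coef in harmonics:
        table += coef * _real_sph_harm(l, m, th_grid, ph_grid)

    # cap the stretch so the transverse radius stays >= ~2 in-plane voxels:
    # a 4 mL tumor cannot be a one-voxel thread, and threads give
    # pathological texture sampling
    min_transverse = 2.0 * float(min(spacing[0], spacing[1]))
    elong_cap = max((r0 / min_transverse) ** 3, 1.0)

    def calibrated_mask(t: float) -> np.ndarray:
        amplitude = _MAX_PERTURB * t
        stretch = min(1.0 + (_MAX_ELONG - 1.0) * t, elong_cap)
        # crop to the extent this deformation can reach
        need = r0 * stretch ** (1.0 / 3.0) * (1.0 + amplitude) * 1.2
        sl = tuple(slice(max(int(center[a] - np.ceil(need / spacing[a])) - 1, 0),
                         int(center[a] + np.ceil(need / spacing[a])) + 2)
                   for a in range(3))
        o = [offs[a][sl] for a in range(3)]
        proj = o[0] * axis[0] + o[1] * axis[1] + o[2] * axis[2]
        # squeeze coordinates along the axis: the level set becomes a shape
        # stretched by `stretch` in physical space at constant volume
        x = [o[a] + (proj / stretch - proj) * axis[a] for a in range(3)]
        radii = np.sqrt(x[0] ** 2 + x[1] ** 2 + x[2] ** 2)
        with np.errstate(invalid="ignore"):
            theta = np.arccos(np.clip(
                np.divide(x[2], radii, out=np.zeros_like(radii), where=radii > 0),
                -1, 1))
        phi = np.arctan2(x[1], x[0])
        ti = np.rint(theta / np.pi * (n_th - 1)).astype(np.intp)
        pi = np.rint((phi + np.pi) / (2.0 * np.pi) * (n_ph - 1)).astype(np.intp)
        pert = table[ti, pi]
        pert = pert / np.abs(table).max()
        lo_r, hi_r = 0.1 * r0, 2.5 * r0
        for _ in range(40):
            mid = 0.5 * (lo_r + hi_r)
            if (radii <= mid * (1.0 + amplitude * pert)).sum() < target_n:
                lo_r = mid
            else:
                hi_r = mid
        cropped = radii <= hi_r * (1.0 + amplitude * pert)
        full = np.zeros(shape, dtype=bool)
        full[sl] = cropped
        return full

    def measured_sphericity(mask: np.ndarray) -> float:
        return shape_texture.measure_morphology(
            RoiMask(mask, tuple(spacing))).sphericity

    ball = calibrated_mask(0.0)
    psi_ball = measured_sphericity(ball)
    if target_sphericity >= psi_ball:
        if target_sphericity - psi_ball > sphericity_tol and not clamp:
            raise InfeasibleShapeError(
                f"grid too coarse: digital ball reaches sphericity {psi_ball:.3f}")
        best = ball
    else:
        extreme = calibrated_mask(1.0)
        psi_min = measured_sphericity(extreme)
        if target_sphericity < psi_min - sphericity_tol and not clamp:
            raise InfeasibleShapeError(
                f"sphericity {target_sphericity} below reachable "
                f"minimum {psi_min:.3f}")
        if target_sphericity <= psi_min:
            best = extreme
        else:
            lo_t, hi_t = 0.0, 1.0
            for _ in range(9):
                mid = 0.5 * (lo_t + hi_t)
                if measured_sphericity(calibrated_mask(mid)) > target_sphericity:
                    lo_t = mid
                else:
                    hi_t = mid
            best = calibrated_mask(0.5 * (lo_t + hi_t))

    # trim to the occupied bounding box (+2 voxel margin) so downstream
    # volumes are not sized for the worst-case deformation extent
    occ = np.argwhere(best)
    lo_c = np.maximum(occ.min(axis=0) - 2, 0)
    hi_c = np.minimum(occ.max(axis=0) + 3, best.shape)
    best = best[lo_c[0]:hi_c[0], lo_c[1]:hi_c[1], lo_c[2]:hi_c[2]]

    mask = RoiMask(best, tuple(spacing))
    measured_vol = mask.count() * vox_vol / 1000.0
    if abs(measured_vol - target_volume_ml) > 0.05 * target_volume_ml:
        raise InfeasibleShapeError(
            f"volume {measured_vol:.2f} mL misses target {target_volume_ml} mL")
    return mask


# --------------------------------------------------------------------------
# sequence synthesis
# --------------------------------------------------------------------------

_TUMOR_S0 = 100.0       # arbitrary signal units at b = 0
_BACKGROUND_S0 = 60.0
_BACKGROUND_ADC = 1.0   # 1e-3 mm^2/s, generic soft tissue
_M0 = 1000.0            # equilibrium magnetization, arbitrary units
_MUSCLE_T2 = 200.0      # arbitrary T2 signal units
_BACKGROUND_T2 = 50.0


def _rician(clean: np.ndarray, sigma: float, n_avg: int,
            rng: np.random.Generator) -> np.ndarray:
    draws = [np.sqrt((clean + rng.normal(0.0, sigma, clean.shape)) ** 2
                     + rng.normal(0.0, sigma, clean.shape) ** 2)
             for _ in range(n_avg)]
    return np.mean(draws, axis=0)


def synthesize_dwi(truth: diffusion.TriExpParams | diffusion.MonoExpParams,
                   tumor_mask: RoiMask, cfg: AcquisitionConfig = AcquisitionConfig(),
                   seed: int = 0) -> DWISeries:
    """Voxelwise forward DWI series with Rician noise and signal averaging.

    Tumor voxels follow ``truth`` (tri-exponential by default; a
    mono-exponential truth selects the reduced generating model);
    background voxels decay mono-exponentially.  Noise: Rician with
    sigma = S0_tumor / snr_dwi_b0 per average; the per-band average counts
    mirror the acquisition (1x for b <= 100, 2x for 200-800, 3x above).
    """
    model = "triexp" if isinstance(truth, diffusion.TriExpParams) else "mono"
    rng = np.random.default_rng(seed)
    spacing = tumor_mask.spacing
    sel = tumor_mask.data
    volumes = []
    for b in cfg.b_values:
        tumor_sig = float(diffusion.forward(model, truth, [b])[0])
        bg_sig = float(_BACKGROUND_S0 * np.exp(-b * _BACKGROUND_ADC * 1e-3))
        clean = np.where(sel, tumor_sig, bg_sig)
        if cfg.snr_dwi_b0:
            sigma = truth.s0 / cfg.snr_dwi_b0
            clean = _rician(clean, sigma, cfg.signal_averages(b), rng)
        volumes.append(ImageVolume(clean, spacing))
    return DWISeries(tuple(float(b) for b in cfg.b_values), volumes)


def synthesize_asl(tumor_flow: float, muscle_flow: float, tumor_mask: RoiMask,
                   muscle_mask: RoiMask, cfg: AcquisitionConfig = AcquisitionConfig(),
                   seed: int = 0) -> tuple[ImageVolume, ImageVolume]:
    """pCASL control/label pair whose subtraction encodes the given flows.

    The control image carries the tissue equilibrium magnetization; the
    label image is control minus the subtraction signal the perfusion
    module's forward equation assigns to each flow.  When noise is
    enabled, Gaussian noise of SD sqrt(2) * (M0 / snr_asl) / sqrt(asl_pairs)
    is added to the label: the per-image noise of both members of a
    control/label pair, reduced by averaging over the acquisition's
    repeated pairs.
    """
    if tumor_flow < 0 or muscle_flow < 0:
        raise ValueError("flows must be non-negative")
    rng = np.random.default_rng(seed)
    spacing = tumor_mask.spacing
    flow = np.zeros(tumor_mask.shape)
    flow[tumor_mask.data] = tumor_flow
    flow[muscle_mask.data] = muscle_flow
    m0 = np.full(tumor_mask.shape, _M0)
    quant = cfg.asl_quant
    delta_m = np.asarray(perfusion.delta_m_from_flow(1.0, m0, quant)) * flow
    label = m0 - delta_m
    if cfg.snr_asl:
        sd = np.sqrt(2.0) * (_M0 / cfg.snr_asl) / np.sqrt(cfg.asl_pairs)
        label = label + rng.normal(0.0, sd, label.shape)
    return ImageVolume(m0, spacing), ImageVolume(label, spacing)


def _correlated_field(shape: tuple[int, int, int], sigma_vox: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(shape)
    if np.any(sigma_vox > 0):
        return gaussian_filter(white, sigma=sigma_vox)
    return white


def synthesize_t2(tumor_mask: RoiMask, muscle_mask: RoiMask,
                  relative_mean: float, cv: float,
                  cfg: AcquisitionConfig = AcquisitionConfig(), seed: int = 0,
                  correlation_length_mm: float = 3.0,
                  target_contrast: float | None = None,
                  glcm_levels: int = shape_texture.DEFAULT_GLCM_LEVELS,
                  ) -> ImageVolume:
    """T2 volume with controlled first-order and texture statistics.

    The tumor is a spatially correlated Gaussian field affinely rescaled
    inside the ROI so its mean is exactly ``relative_mean`` times the
    muscle signal and its SD exactly ``cv`` times that mean.  The
    correlation length sets GLCM contrast monotonically (longer = smoother
    = lower contrast); when ``target_contrast`` is given the length is
    bisected so the measured contrast matches it.
    """
    if relative_mean <= 0 or cv < 0:
        raise ValueError("need relative mean > 0 and CV >= 0")
    rng = np.random.default_rng(seed)
    spacing = np.asarray(tumor_mask.spacing)
    sel = tumor_mask.data
    n_tumor = int(sel.sum())
    muscle_mean = _MUSCLE_T2
    tumor_mean = relative_mean * muscle_mean

    def render(length_mm: float) -> np.ndarray:
        field_rng = np.random.default_rng(seed)  # same field, new length
        fld = _correlated_field(tumor_mask.shape, length_mm / spacing, field_rng)
        data = np.full(tumor_mask.shape, _BACKGROUND_T2)
        vals = fld[sel]
        sd = vals.std(ddof=0)
        if cv == 0 or n_tumor < 2 or sd == 0:
            data[sel] = tumor_mean
        else:
            data[sel] = tumor_mean + (vals - vals.mean()) / sd * (cv * tumor_mean)
        data[muscle_mask.data] = muscle_mean
        return data

    def measured_contrast(data: np.ndarray) -> float:
        vol = ImageVolume(data, tuple(spacing))
        return shape_texture.glcm_features(vol, tumor_mask,
                                           levels=glcm_levels)["contrast"]

    if target_contrast is None or cv == 0:
        data = render(correlation_length_mm)
    else:
        # contrast decreases with correlation length over the first part of
        # the curve, but can rise again for small ROIs (a heavily smoothed
        # field approaches a ramp, whose min-max quantization takes large
        # steps): scan a length grid, then bisect inside the bracketing
        # monotone segment; if the target is below everything reachable,
        # take the argmin.
        lengths = np.linspace(0.0, 3.0 * float(spacing.max()), 8)
        scanned = [measured_contrast(render(L)) for L in lengths]
        bracket = None
        for i in range(1, len(lengths)):
            if scanned[i - 1] >= target_contrast >= scanned[i]:
                bracket = (lengths[i - 1], lengths[i])
                break
        if bracket is None:
            data = render(lengths[int(np.argmin(np.abs(np.asarray(scanned)
                                                       - target_contrast)))])
        else:
            lo, hi = bracket
            for _ in range(8):
                mid = 0.5 * (lo + hi)
                if measured_contrast(render(mid)) > target_contrast:
                    lo = mid
                else:
                    hi = mid
            data = render(0.5 * (lo + hi))

    if cfg.t2_noise_frac:
        noise_sd = cfg.t2_noise_frac * muscle_mean
        noise = rng.normal(0.0, noise_sd, data.shape)
        noise[sel] = 0.0  # tumor statistics are exact by construction
        data = data + noise
    return ImageVolume(data, tuple(spacing))


# --------------------------------------------------------------------------
# whole-patient assembly
# --------------------------------------------------------------------------

@dataclass
class SyntheticPatient:
    patient_id: str
    outcome: str
    tumor_mask: RoiMask
    muscle_mask: RoiMask
    t2: ImageVolume
    dwi: DWISeries
    asl_control: ImageVolume
    asl_label: ImageVolume
    clinical: dict
    truth_sampled: dict
    truth_realized: dict

    def __post_init__(self) -> None:
        if self.tumor_mask.data[self.muscle_mask.data].any():
            raise ValueError("tumor and muscle masks must be disjoint")
        for vol in (self.t2, self.asl_control, self.asl_label, *self.dwi.volumes):
            vol.require_geometry(self.tumor_mask)


def _ordered_tri_params(rec: dict) -> diffusion.TriExpParams:
    """Generating tri-exponential parameters with D1 > D2 > D3 enforced.

    The published SDs allow occasional draws with crossing coefficients;
    the generator nudges those apart minimally (sampling itself is left
    untouched so group calibration stays unbiased).
    """
    d1, d2, d3 = rec["tri_d1"], rec["tri_d2"], rec["tri_d3"]
    d3 = min(d3, d2 * 0.95)
    d2 = min(d2, d1 * 0.95)
    return diffusion.TriExpParams.normalized(
        _TUMOR_S0, rec["tri_f1"], rec["tri_f2"], rec["tri_f3"], d1, d2, d3)


def _embed_muscle(tumor_mask: RoiMask) -> tuple[RoiMask, RoiMask]:
    """Extend the grid along axis 0 and place a reference-muscle box."""
    spacing = np.asarray(tumor_mask.spacing)
    muscle_mm = 24.0  # ~14 mL box, the scale of a medial pterygoid ROI
    m_vox = np.maximum((muscle_mm / spacing).astype(int), 2)
    gap_vox = max(int(np.ceil(8.0 / spacing[0])), 2)
    old = tumor_mask.data
    new_shape = (old.shape[0] + gap_vox + m_vox[0] + 2, *old.shape[1:])
    tumor = np.zeros(new_shape, dtype=bool)
    tumor[:old.shape[0]] = old
    muscle = np.zeros(new_shape, dtype=bool)
    y0 = max((old.shape[1] - m_vox[1]) // 2, 0)
    z0 = max((old.shape[2] - m_vox[2]) // 2, 0)
    muscle[old.shape[0] + gap_vox:old.shape[0] + gap_vox + m_vox[0],
           y0:y0 + m_vox[1], z0:z0 + m_vox[2]] = True
    sp = tuple(tumor_mask.spacing)
    return RoiMask(tumor, sp), RoiMask(muscle, sp)


def synthesize_patient(record: dict, cfg: AcquisitionConfig = AcquisitionConfig(),
                       seed: int = 0) -> SyntheticPatient:
    """Render one sampled ground-truth record into a full image dataset."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)]

    tumor_only = synthesize_tumor_mask(record["volume_ml"], record["sphericity"],
                                       cfg, seed=seeds[0], clamp=True)
    tumor_mask, muscle_mask = _embed_muscle(tumor_only)

    tri = _ordered_tri_params(record)
    dwi = synthesize_dwi(tri, tumor_mask, cfg, seed=seeds[1])

    muscle_flow = record["tbf_abs"] / record["tbf_rel"]
    control, label = synthesize_asl(record["tbf_abs"], muscle_flow,
                                    tumor_mask, muscle_mask, cfg, seed=seeds[2])

    t2 = synthesize_t2(tumor_mask, muscle_mask, record["relative_mean_signal"],
                       record["cv"], cfg, seed=seeds[3],
                       target_contrast=record["contrast"])

    morph = shape_texture.measure_morphology(tumor_mask)
    texture = shape_texture.glcm_features(t2, tumor_mask)
    noiseless_signal = diffusion.forward("triexp", tri, B_VALUES_FULL)
    reduced_idx = [B_VALUES_FULL.index(b) for b in diffusion.B_VALUES_REDUCED]
    s_red = noiseless_signal[reduced_idx]
    mono = diffusion.fit_mono(diffusion.B_VALUES_REDUCED, s_red).params
    ivim = diffusion.fit_ivim(B_VALUES_FULL, noiseless_signal).params
    sem = diffusion.fit_sem(diffusion.B_VALUES_REDUCED, s_red).params
    dki = diffusion.fit_dki(diffusion.B_VALUES_REDUCED, s_red).params

    realized = dict(record)
    realized.update({
        "volume_ml": morph.volume_ml,
        "surface_cm2": morph.surface_cm2,
        "sphericity": morph.sphericity,
        "contrast": texture["contrast"],
        "correlation": texture["correlation"],
        "energy": texture["energy"],
        "homogeneity": texture["homogeneity"],
        "adc": mono.adc,
        "ivim_f": ivim.f, "ivim_d_star": ivim.d_star, "ivim_d": ivim.d,
        "sem_alpha": sem.alpha, "sem_ddc": sem.ddc,
        "dki_k": dki.k, "dki_d_k": dki.d_k,
        "tri_f1": tri.f1, "tri_f2": tri.f2, "tri_f3": tri.f3,
        "tri_d1": tri.d1, "tri_d2": tri.d2, "tri_d3": tri.d3,
    })

    clinical = {"t_stage": int(record["t_stage"]), "n_stage": int(record["n_stage"]),
                "outcome": record["outcome"]}
    return SyntheticPatient(
        patient_id=record["id"], outcome=record["outcome"],
        tumor_mask=tumor_mask, muscle_mask=muscle_mask,
        t2=t2, dwi=dwi, asl_control=control, asl_label=label,
        clinical=clinical, truth_sampled=dict(record), truth_realized=realized,
    )


def generate_cohort(n_control: int = DEFAULT_N_CONTROL,
                    n_failure: int = DEFAULT_N_FAILURE,
                    cfg: AcquisitionConfig = AcquisitionConfig(),
                    seed: int = 0,
                    control_spec: GroupParameterSpec = TABLE_CONTROL,
                    failure_spec: GroupParameterSpec = TABLE_FAILURE,
                    ) -> list[SyntheticPatient]:
    """Sample and render a full synthetic cohort (default 22 + 14)."""
    records = sample_cohort(control_spec, failure_spec, n_control, n_failure, seed)
    ss = np.random.SeedSequence(seed + 1)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(records))]
    return [synthesize_patient(rec, cfg, seed=s) for rec, s in zip(records, seeds)]


def extract_feature_table(patients: list[SyntheticPatient],
                          cfg: AcquisitionConfig = AcquisitionConfig()):
    """Run the full extraction pipeline on every patient of a cohort.

    Returns the canonical feature table (one row per patient, 27 features
    + outcome) ready for the classification experiment.
    """
    from .features import extract_all, vectors_to_frame

    vectors = [
        extract_all(
            patient_id=p.patient_id, t2=p.t2, dwi=p.dwi,
            asl_control=p.asl_control, asl_label=p.asl_label,
            tumor_mask=p.tumor_mask, muscle_mask=p.muscle_mask,
            clinical=p.clinical, asl_cfg=cfg.asl_quant,
        )
        for p in patients
    ]
    return vectors_to_frame(vectors)


# --------------------------------------------------------------------------
# on-disk cohort layout
# --------------------------------------------------------------------------

def write_cohort(patients: list[SyntheticPatient], directory: str | Path) -> dict:
    """Write NIfTI volumes, the clinical CSV, truth sidecars and a manifest."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"n_patients": len(patients), "patients": []}
    clinical_rows = []
    for p in patients:
        pdir = root / p.patient_id
        pdir.mkdir(exist_ok=True)
        files = {}
        p.t2.to_nifti(pdir / "t2.nii")
        files["t2"] = "t2.nii"
        p.asl_control.to_nifti(pdir / "asl_control.nii")
        p.asl_label.to_nifti(pdir / "asl_label.nii")
        files["asl_control"] = "asl_control.nii"
        files["asl_label"] = "asl_label.nii"
        p.tumor_mask.to_nifti(pdir / "tumor_mask.nii")
        p.muscle_mask.to_nifti(pdir / "muscle_mask.nii")
        files["tumor_mask"] = "tumor_mask.nii"
        files["muscle_mask"] = "muscle_mask.nii"
        for b, vol in zip(p.dwi.b_values, p.dwi.volumes):
            name = f"dwi_b{int(b)}.nii"
            vol.to_nifti(pdir / name)
            files[f"dwi_b{int(b)}"] = name
        truth = {"sampled": p.truth_sampled, "realized": p.truth_realized,
                 "b_values": list(p.dwi.b_values)}
        (pdir / "truth.json").write_text(json.dumps(truth, indent=1))
        files["truth"] = "truth.json"
        manifest["patients"].append({"id": p.patient_id, "files": files})
        clinical_rows.append({"id": p.patient_id, **p.clinical})
    with open(root / "clinical.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["id", "t_stage", "n_stage", "outcome"])
        writer.writeheader()
        writer.writerows(clinical_rows)
    manifest["clinical"] = "clinical.csv"
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def validate_manifest(manifest: dict) -> None:
    """Structural validation of a cohort manifest; raises ``ValueError``
    describing the first violation."""
    if not isinstance(manifest.get("n_patients"), int):
        raise ValueError("manifest missing integer 'n_patients'")
    patients = manifest.get("patients")
    if not isinstance(patients, list) or len(patients) != manifest["n_patients"]:
        raise ValueError("'patients' must list exactly n_patients entries")
    for entry in patients:
        if not isinstance(entry.get("id"), str):
            raise ValueError("patient entry missing string 'id'")
        files = entry.get("files")
        if not isinstance(files, dict):
            raise ValueError(f"patient {entry.get('id')}: missing 'files' map")
        required = {"t2", "asl_control", "asl_label", "tumor_mask",
                    "muscle_mask", "truth"}
        missing = required - files.keys()
        if missing:
            raise ValueError(f"patient {entry['id']}: missing files {sorted(missing)}")
        if not any(k.startswith("dwi_b") for k in files):
            raise ValueError(f"patient {entry['id']}: no DWI volumes listed")
    if not isinstance(manifest.get("clinical"), str):
        raise ValueError("manifest missing 'clinical' table path")


def read_cohort(directory: str | Path) -> list[SyntheticPatient]:
    """Re-read a cohort written by :func:`write_cohort` losslessly."""
    root = Path(directory)
    manifest = json.loads((root / "manifest.json").read_text())
    validate_manifest(manifest)
    clinical_by_id = {}
    with open(root / manifest["clinical"], newline="") as fh:
        for row in csv.DictReader(fh):
            clinical_by_id[row["id"]] = {
                "t_stage": int(row["t_stage"]), "n_stage": int(row["n_stage"]),
                "outcome": row["outcome"]}
    patients = []
    for entry in manifest["patients"]:
        pdir = root / entry["id"]
        truth = json.loads((pdir / "truth.json").read_text())
        tumor = RoiMask.from_nifti(pdir / entry["files"]["tumor_mask"])
        muscle = RoiMask.from_nifti(pdir / entry["files"]["muscle_mask"])
        b_values = truth["b_values"]
        dwi = DWISeries(tuple(b_values), [
            ImageVolume.from_nifti(pdir / entry["files"][f"dwi_b{int(b)}"])
            for b in b_values])
        patients.append(SyntheticPatient(
            patient_id=entry["id"],
            outcome=clinical_by_id[entry["id"]]["outcome"],
            tumor_mask=tumor, muscle_mask=muscle,
            t2=ImageVolume.from_nifti(pdir / entry["files"]["t2"]),
            dwi=dwi,
            asl_control=ImageVolume.from_nifti(pdir / entry["files"]["asl_control"]),
            asl_label=ImageVolume.from_nifti(pdir / entry["files"]["asl_label"]),
            clinical=clinical_by_id[entry["id"]],
            truth_sampled=truth["sampled"],
            truth_realized=truth["realized"],
        ))
    return patients
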