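"""Multi-b-value diffusion models: forward signals and ROI-level fitting.

Five models are fitted to the ROI-mean signal of a 12-b-value DWI series
(b = 0 ... 2000 s/mm^2):

* mono-exponential        S(b) = S0 exp(-b ADC)
* IVIM (bi-exponential)   S(b) = S0 [ f exp(-b D*) + (1-f) exp(-b D) ]
* tri-exponential         S(b) = S0 [ f1 exp(-b D1) + f2 exp(-b D2) + f3 exp(-b D3) ]
* stretched exponential   S(b) = S0 exp(-(b DDC)^alpha)
* diffusion kurtosis      S(b) = S0 exp(-b Dk + b^2 Dk^2 K / 6)

Diffusion coefficients are expressed throughout in the radiological
convention of 1e-3 mm^2/s (so ADC = 0.91 means 0.91e-3 mm^2/s); b-values in
s/mm^2.  The perfusion-sensitive models (IVIM, tri-exponential) use the
full 12-value schedule; ADC, SEM and DKI use the reduced 6-value schedule
{0, 200, 400, 800, 1000, 2000} that excludes the low-b perfusion regime.

Fitting is ROI-mean-then-fit: the tumor ROI mean signal per b-value is
fitted once per patient.  The bi- and tri-exponential fits are seeded by a
segmented (high-b first) decomposition and refined by bounded joint
nonlinear least squares with a small multi-start jitter, because joint
multi-exponential fits from cold starts are ill-conditioned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Callable

import numpy as np
from scipy.optimize import least_squares

from .volumes import B_VALUES_FULL, B_VALUES_REDUCED, DWISeries, RoiMask

__all__ = [
    "MonoExpParams",
    "IvimParams",
    "TriExpParams",
    "SemParams",
    "DkiParams",
    "FitResult",
    "forward",
    "fit",
    "extract_diffusion_features",
    "DIFFUSION_FEATURE_NAMES",
    "model_b_values",
]

_SCALE = 1.0e-3  # coefficients are quoted in 1e-3 mm^2/s

# Fit bounds, in the 1e-3 mm^2/s convention.
BOUNDS = {
    "f": (0.0, 1.0),
    "d_star": (3.0, 300.0),
    "d": (0.05, 3.0),
    "d1": (3.0, 300.0),
    "d2": (0.3, 3.0),
    "d3": (0.05, 1.2),
    "alpha": (0.3, 1.0),
    "ddc": (0.05, 3.0),
    "k": (0.0, 3.0),
    "d_k": (0.05, 3.0),
}

_N_STARTS = 3          # multi-start count for the joint refinements
_JITTER_SD = 0.10      # log-normal jitter applied to non-first starts
_JITTER_SEED = 20190610  # fixed: fits are deterministic functions of the data


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MonoExpParams:
    s0: float
    adc: float  # 1e-3 mm^2/s

    def __post_init__(self) -> None:
        if self.adc <= 0:
            raise ValueError("ADC must be positive")


@dataclass(frozen=True)
class IvimParams:
    s0: float
    f: float        # perfusion fraction
    d_star: float   # pseudo-diffusion coefficient, 1e-3 mm^2/s
    d: float        # true diffusion coefficient, 1e-3 mm^2/s

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")
        if self.d <= 0 or self.d_star < self.d:
            raise ValueError("require D* >= D > 0")


@dataclass(frozen=True)
class TriExpParams:
    s0: float
    f1: float
    f2: float
    f3: float
    d1: float  # perfusion-related, 1e-3 mm^2/s
    d2: float  # intermediate
    d3: float  # slow

    def __post_init__(self) -> None:
        if abs(self.f1 + self.f2 + self.f3 - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if min(self.f1, self.f2, self.f3) < 0:
            raise ValueError("fractions must be non-negative")
        if not self.d1 > self.d2 > self.d3 > 0:
            raise ValueError("require D1 > D2 > D3 > 0")

    @classmethod
    def normalized(cls, s0: float, f1: float, f2: float, f3: float,
                   d1: float, d2: float, d3: float) -> "TriExpParams":
        """Build with the fraction triple renormalized to sum exactly 1."""
        tot = f1 + f2 + f3
        if tot <= 0:
            raise ValueError("fractions must have a positive sum")
        return cls(s0, f1 / tot, f2 / tot, f3 / tot, d1, d2, d3)


@dataclass(frozen=True)
class SemParams:
    s0: float
    alpha: float  # heterogeneity index, (0, 1]
    ddc: float    # distributed diffusion coefficient, 1e-3 mm^2/s

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.ddc <= 0:
            raise ValueError("DDC must be positive")


@dataclass(frozen=True)
class DkiParams:
    s0: float
    k: float    # excess kurtosis, >= 0
    d_k: float  # kurtosis-corrected coefficient, 1e-3 mm^2/s

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("K must be non-negative")
        if self.d_k <= 0:
            raise ValueError("D_k must be positive")


ModelParams = MonoExpParams | IvimParams | TriExpParams | SemParams | DkiParams


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single ROI fit; never raises on non-convergence."""

    model: str
    params: ModelParams
    residual_norm: float
    converged: bool


# --------------------------------------------------------------------------
# forward signal equations
# --------------------------------------------------------------------------

def _mono(b: np.ndarray, s0: float, adc: float) -> np.ndarray:
    return s0 * np.exp(-b * adc * _SCALE)


def _ivim(b: np.ndarray, s0: float, f: float, d_star: float, d: float) -> np.ndarray:
    return s0 * (f * np.exp(-b * d_star * _SCALE) + (1.0 - f) * np.exp(-b * d * _SCALE))


def _triexp(b: np.ndarray, s0: float, f1: float, f2: float, f3: float,
            d1: float, d2: float, d3: float) -> np.ndarray:
    return s0 * (f1 * np.exp(-b * d1 * _SCALE)
                 + f2 * np.exp(-b * d2 * _SCALE)
                 + f3 * np.exp(-b * d3 * _SCALE))


def _sem(b: np.ndarray, s0: float, alpha: float, ddc: float) -> np.ndarray:
    return s0 * np.exp(-np.power(b * ddc * _SCALE, alpha))


def _dki(b: np.ndarray, s0: float, k: float, d_k: float) -> np.ndarray:
    bd = b * d_k * _SCALE
    return s0 * np.exp(-bd + bd * bd * k / 6.0)


_FORWARD: dict[str, Callable[..., np.ndarray]] = {
    "mono": _mono, "ivim": _ivim, "triexp": _triexp, "sem": _sem, "dki": _dki,
}

_MODEL_TYPES = {
    "mono": MonoExpParams, "ivim": IvimParams, "triexp": TriExpParams,
    "sem": SemParams, "dki": DkiParams,
}


def model_b_values(model: str) -> tuple[int, ...]:
    """The b-value schedule each model is fitted on."""
    if model in ("ivim", "triexp"):
        return B_VALUES_FULL
    if model in ("mono", "sem", "dki"):
        return B_VALUES_REDUCED
    raise ValueError(f"unknown model {model!r}")


def forward(model: str, params: ModelParams, b_values) -> np.ndarray:
    """Noise-free model signal at the given b-values (s/mm^2)."""
    if not isinstance(params, _MODEL_TYPES[model]):
        raise TypeError(f"{model} expects {_MODEL_TYPES[model].__name__}")
    b = np.asarray(b_values, dtype=float)
    vals = [getattr(params, fld.name) for fld in fields(params)]
    return _FORWARD[model](b, *vals)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _loglinear(b: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Closed-form mono-exponential fit: returns (S0, ADC in 1e-3 mm^2/s)."""
    slope, intercept = np.polyfit(b, np.log(s), 1)
    return float(np.exp(intercept)), float(max(-slope / _SCALE, 1e-5))


def _check_signal(b: np.ndarray, s: np.ndarray, n_expected: int) -> None:
    if len(b) != len(s):
        raise ValueError("b-values and signal lengths differ")
    if len(b) != n_expected:
        raise ValueError(f"model expects {n_expected} b-values, got {len(b)}")
    if np.any(s <= 0):
        raise ValueError("signal must be strictly positive")


def _refine(residual: Callable[[np.ndarray], np.ndarray], x0: np.ndarray,
            lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Bounded least squares with multi-start jitter; best-of-N by residual."""
    rng = np.random.default_rng(_JITTER_SEED)
    best_x, best_cost, ok = x0, math.inf, False
    for start in range(_N_STARTS):
        x_init = np.clip(
            x0 if start == 0 else x0 * rng.lognormal(0.0, _JITTER_SD, size=x0.shape),
            lo, hi,
        )
        try:
            sol = least_squares(residual, x_init, bounds=(lo, hi), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
        except Exception:
            continue
        if sol.cost < best_cost:
            best_x, best_cost, ok = sol.x, sol.cost, bool(sol.success)
    return best_x, math.sqrt(2.0 * best_cost) if math.isfinite(best_cost) else math.inf, ok


def fit_mono(b_values, signal) -> FitResult:
    """Log-linear ADC fit on the reduced 6-b schedule (closed form)."""
    b = np.asarray(b_values, float)
    s = np.asarray(signal, float)
    _check_signal(b, s, 6)
    s0, adc = _loglinear(b, s)
    resid = _mono(b, s0, adc) - s
    return FitResult("mono", MonoExpParams(s0, adc),
                     float(np.linalg.norm(resid)), True)


def fit_ivim(b_values, signal) -> FitResult:
    """Segmented-then-joint IVIM fit on the full 12-b schedule.

    High-b segment (b >= 200) gives D and the tissue amplitude, hence f;
    D* is then estimated from the perfusion residue at low b, and all four
    parameters are refined jointly under bounds.
    """
    b = np.asarray(b_values, float)
    s = np.asarray(signal, float)
    _check_signal(b, s, 12)

    hi_seg = b >= 200
    a_t, d0 = _loglinear(b[hi_seg], s[hi_seg])
    s_meas0 = float(s[b == 0][0]) if np.any(b == 0) else float(s[0])
    f0 = float(np.clip(1.0 - a_t / s_meas0, 0.0, 0.6))
    d0 = float(np.clip(d0, *BOUNDS["d"]))

    # perfusion residue at low b -> crude D*
    low = b <= 100
    residue = s[low] - a_t * np.exp(-b[low] * d0 * _SCALE)
    dstar0 = 20.0
    if f0 > 1e-4 and np.all(residue > 0) and residue.size >= 3:
        _, dstar0 = _loglinear(b[low], residue)
    dstar0 = float(np.clip(dstar0, *BOUNDS["d_star"]))

    lo = np.array([s_meas0 * 0.2, BOUNDS["f"][0], BOUNDS["d_star"][0], BOUNDS["d"][0]])
    hi = np.array([s_meas0 * 5.0, BOUNDS["f"][1], BOUNDS["d_star"][1], BOUNDS["d"][1]])
    x0 = np.array([s_meas0, max(f0, 1e-3), dstar0, d0])

    def residual(x: np.ndarray) -> np.ndarray:
        return _ivim(b, *x) - s

    x, rnorm, ok = _refine(residual, x0, lo, hi)
    d_star = max(float(x[2]), float(x[3]))  # enforce D* >= D at the boundary
    return FitResult("ivim", IvimParams(float(x[0]), float(x[1]), d_star, float(x[3])),
                     rnorm, ok)


def fit_triexp(b_values, signal) -> FitResult:
    """Cascaded tri-exponential fit on the full 12-b schedule.

    Segments: b >= 800 -> (D3, A3); mid b after subtraction -> (D2, A2);
    low b -> (D1, A1).  The joint refinement parameterizes the fractions as
    f1 = u1, f2 = (1-u1) u2 so the simplex constraint f1+f2+f3 = 1, fi >= 0
    is maintained exactly, and the coefficient bounds keep D1 > D2 > D3.
    """
    b = np.asarray(b_values, float)
    s = np.asarray(signal, float)
    _check_signal(b, s, 12)

    seg3 = b >= 800
    a3, d3 = _loglinear(b[seg3], s[seg3])
    d3 = float(np.clip(d3, *BOUNDS["d3"]))

    seg2 = (b >= 100) & (b <= 400)
    res2 = s[seg2] - a3 * np.exp(-b[seg2] * d3 * _SCALE)
    if np.all(res2 > 0):
        a2, d2 = _loglinear(b[seg2], res2)
    else:
        a2, d2 = 0.2 * a3, 1.0
    d2 = float(np.clip(d2, *BOUNDS["d2"]))

    seg1 = b <= 50
    res1 = (s[seg1] - a3 * np.exp(-b[seg1] * d3 * _SCALE)
            - a2 * np.exp(-b[seg1] * d2 * _SCALE))
    if np.all(res1 > 0):
        a1, d1 = _loglinear(b[seg1], res1)
    else:
        a1, d1 = 0.1 * a3, 30.0
    d1 = float(np.clip(d1, *BOUNDS["d1"]))

    amp = np.array([max(a1, 1e-6), max(a2, 1e-6), max(a3, 1e-6)])
    s0_0 = float(amp.sum())
    frac = amp / s0_0
    u1 = frac[0]
    u2 = frac[1] / max(1.0 - u1, 1e-9)

    lo = np.array([s0_0 * 0.2, 0.0, 0.0, BOUNDS["d1"][0], BOUNDS["d2"][0], BOUNDS["d3"][0]])
    hi = np.array([s0_0 * 5.0, 1.0, 1.0, BOUNDS["d1"][1], BOUNDS["d2"][1], BOUNDS["d3"][1]])
    x0 = np.array([s0_0, np.clip(u1, 1e-3, 0.999), np.clip(u2, 1e-3, 0.999), d1, d2, d3])

    def unpack(x: np.ndarray) -> tuple[float, float, float, float, float, float, float]:
        s0, uu1, uu2, dd1, dd2, dd3 = x
        ff1 = uu1
        ff2 = (1.0 - uu1) * uu2
        ff3 = 1.0 - ff1 - ff2
        return s0, ff1, ff2, ff3, dd1, dd2, dd3

    def residual(x: np.ndarray) -> np.ndarray:
        return _triexp(b, *unpack(x)) - s

    x, rnorm, ok = _refine(residual, x0, lo, hi)
    s0, f1, f2, f3, d1, d2, d3 = unpack(x)
    # coefficient bounds overlap only at the shared endpoints; nudge if tied
    eps = 1e-9
    if not d1 > d2:
        d1 = d2 + eps
    if not d2 > d3:
        d2 = d3 + eps
    return FitResult("triexp",
                     TriExpParams.normalized(float(s0), float(max(f1, 0.0)),
                                             float(max(f2, 0.0)), float(max(f3, 0.0)),
                                             float(d1), float(d2), float(d3)),
                     rnorm, ok)


def fit_sem(b_values, signal) -> FitResult:
    """Stretched-exponential fit on the reduced 6-b schedule."""
    b = np.asarray(b_values, float)
    s = np.asarray(signal, float)
    _check_signal(b, s, 6)
    s0_0, adc0 = _loglinear(b, s)
    lo = np.array([s0_0 * 0.2, BOUNDS["alpha"][0], BOUNDS["ddc"][0]])
    hi = np.array([s0_0 * 5.0, BOUNDS["alpha"][1], BOUNDS["ddc"][1]])
    x0 = np.array([s0_0, 0.8, np.clip(adc0, *BOUNDS["ddc"])])

    def residual(x: np.ndarray) -> np.ndarray:
        return _sem(b, *x) - s

    x, rnorm, ok = _refine(residual, x0, lo, hi)
    return FitResult("sem", SemParams(float(x[0]), float(min(x[1], 1.0)), float(x[2])),
                     rnorm, ok)


def fit_dki(b_values, signal) -> FitResult:
    """Kurtosis fit on the reduced 6-b schedule."""
    b = np.asarray(b_values, float)
    s = np.asarray(signal, float)
    _check_signal(b, s, 6)
    s0_0, adc0 = _loglinear(b, s)
    lo = np.array([s0_0 * 0.2, BOUNDS["k"][0], BOUNDS["d_k"][0]])
    hi = np.array([s0_0 * 5.0, BOUNDS["k"][1], BOUNDS["d_k"][1]])
    x0 = np.array([s0_0, 0.5, np.clip(adc0 * 1.2, *BOUNDS["d_k"])])

    def residual(x: np.ndarray) -> np.ndarray:
        return _dki(b, *x) - s

    x, rnorm, ok = _refine(residual, x0, lo, hi)
    return FitResult("dki", DkiParams(float(x[0]), float(max(x[1], 0.0)), float(x[2])),
                     rnorm, ok)


_FITTERS = {
    "mono": fit_mono, "ivim": fit_ivim, "triexp": fit_triexp,
    "sem": fit_sem, "dki": fit_dki,
}


def fit(model: str, b_values, signal) -> FitResult:
    """Fit one model to an ROI-mean signal sampled at its b-value schedule."""
    if model not in _FITTERS:
        raise ValueError(f"unknown model {model!r}")
    return _FITTERS[model](b_values, signal)


# --------------------------------------------------------------------------
# feature extraction
# --------------------------------------------------------------------------

#: The 14 diffusion features, in report order.
DIFFUSION_FEATURE_NAMES: tuple[str, ...] = (
    "adc", "ivim_f", "ivim_d_star", "ivim_d", "dki_k", "dki_d_k",
    "sem_alpha", "sem_ddc", "tri_f1", "tri_f2", "tri_f3",
    "tri_d1", "tri_d2", "tri_d3",
)


def _features_from_signals(s_full: np.ndarray, s_red: np.ndarray) -> dict[str, float]:
    mono = fit_mono(B_VALUES_REDUCED, s_red).params
    ivim = fit_ivim(B_VALUES_FULL, s_full).params
    tri = fit_triexp(B_VALUES_FULL, s_full).params
    sem = fit_sem(B_VALUES_REDUCED, s_red).params
    dki = fit_dki(B_VALUES_REDUCED, s_red).params
    return {
        "adc": mono.adc,
        "ivim_f": ivim.f, "ivim_d_star": ivim.d_star, "ivim_d": ivim.d,
        "dki_k": dki.k, "dki_d_k": dki.d_k,
        "sem_alpha": sem.alpha, "sem_ddc": sem.ddc,
        "tri_f1": tri.f1, "tri_f2": tri.f2, "tri_f3": tri.f3,
        "tri_d1": tri.d1, "tri_d2": tri.d2, "tri_d3": tri.d3,
    }


def extract_diffusion_features(dwi: DWISeries, mask: RoiMask,
                               mode: str = "roi_mean") -> dict[str, float]:
    """Run all five model fits over the tumor ROI.

    ``mode='roi_mean'`` (default) fits each model once to the ROI-mean
    signal — the noise-robust reading used throughout the pipeline.
    ``mode='voxelwise_mean'`` fits every voxel separately and averages the
    parameters; exposed for comparison/debugging, substantially slower and
    noise-sensitive.  Returns the 14 named diffusion features
    (coefficients in 1e-3 mm^2/s, fractions dimensionless).
    """
    full = dwi.subset(B_VALUES_FULL)
    reduced = dwi.subset(B_VALUES_REDUCED)
    if mode == "roi_mean":
        return _features_from_signals(full.roi_mean_signal(mask),
                                      reduced.roi_mean_signal(mask))
    if mode != "voxelwise_mean":
        raise ValueError(f"unknown mode {mode!r}")
    sel = mask.active
    if not sel.any():
        raise ValueError("empty ROI")
    stack_full = np.stack([v.data[sel] for v in full.volumes])    # (12, n)
    stack_red = np.stack([v.data[sel] for v in reduced.volumes])  # (6, n)
    per_voxel = [_features_from_signals(stack_full[:, i], stack_red[:, i])
                 for i in range(stack_full.shape[1])]
    return {k: float(np.mean([p[k] for p in per_voxel])) for k in per_voxel[0]}
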