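"""Persistence length from tangent-correlation decay, and the derived
Young's modulus for a solid-rod cross-section.

The tangent correlation ``<cos(theta_0 - theta_l)>`` of a worm-like
chain decays as ``exp(-l / L_p)``; we estimate the curve by pooling all
same-fibril tangent pairs at each arc separation and fit ``ln`` of the
curve with an unweighted linear least-squares line (free intercept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import EstimationError, ValidationError
from .scene import Fibril, resample_uniform

logger = logging.getLogger(__name__)

BOLTZMANN_J_PER_K = 1.380649e-23
DEFAULT_TEMPERATURE_K = 295.0
DEFAULT_RADIUS_NM = 5.0


@dataclass
class CorrelationCurve:
    """Binned mean tangent cosine versus arc separation."""

    separations: np.ndarray  # nm, bin centres (multiples of the step)
    mean_cos: np.ndarray
    n_pairs: np.ndarray
    step: float

    def __post_init__(self) -> None:
        self.separations = np.asarray(self.separations, dtype=np.float64)
        self.mean_cos = np.asarray(self.mean_cos, dtype=np.float64)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)


@dataclass
class PersistenceFit:
    """Fitted persistence length and derived elastic modulus."""

    L_p: float  # nm
    ci_low: float  # nm
    ci_high: float  # nm
    fit_slope: float  # 1/nm
    fit_intercept: float
    slope_stderr: float
    slope_ci: tuple[float, float]
    E: float  # Pa
    n_bins_used: int
    excluded_bins: int
    constants: dict = field(default_factory=dict)


def unit_tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangents by central differences (one-sided at the ends)."""
    d = np.gradient(points, axis=0)
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    return d / norms


def tangent_correlation(
    fibrils: list[Fibril], step: float, max_sep: float
) -> CorrelationCurve:
    """Pooled tangent-correlation curve over an ensemble of fibrils.

    Each fibril is resampled at uniform arc spacing ``step``; for every
    ordered same-fibril point pair separated by arc length
    ``l = k * step <= max_sep`` the cosine of the 3D angle between the
    unit tangents is accumulated into bin ``k``.
    """
    if not fibrils:
        raise ValidationError("no fibrils provided")
    if not step > 0 or not max_sep >= step:
        raise ValidationError("need step > 0 and max_sep >= step")
    n_bins = int(np.floor(max_sep / step + 1e-9))
    cos_sum = np.zeros(n_bins)
    n_pairs = np.zeros(n_bins, dtype=np.int64)
    for fib in fibrils:
        if fib.length < step:
            continue
        t = unit_tangents(resample_uniform(fib, step).points)
        kmax = min(n_bins, len(t) - 1)
        for k in range(1, kmax + 1):
            c = np.einsum("ij,ij->i", t[:-k], t[k:])
            cos_sum[k - 1] += c.sum()
            n_pairs[k - 1] += c.size
    if not np.any(n_pairs):
        raise EstimationError(
            f"no tangent pairs in any bin; usable separations require fibrils "
            f"longer than {step:.3g} nm (max_sep={max_sep:.3g} nm)"
        )
    keep = n_pairs > 0
    with np.errstate(invalid="ignore"):
        mean_cos = np.where(keep, cos_sum / np.maximum(n_pairs, 1), np.nan)
    seps = (np.arange(n_bins) + 1) * step
    return CorrelationCurve(
        separations=seps[keep],
        mean_cos=mean_cos[keep],
        n_pairs=n_pairs[keep],
        step=step,
    )


def youngs_modulus(
    L_p_nm: float,
    radius_nm: float = DEFAULT_RADIUS_NM,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Young's modulus in Pa: ``E = L_p kB T / I`` with ``I = pi r^4 / 4``
    (solid rod).  Inputs in nm are converted to SI internally.
    """
    L_p_m = L_p_nm * 1e-9
    r_m = radius_nm * 1e-9
    inertia = np.pi * r_m**4 / 4.0
    return L_p_m * BOLTZMANN_J_PER_K * temperature_K / inertia


def fit_persistence_length(
    curve: CorrelationCurve,
    radius_nm: float = DEFAULT_RADIUS_NM,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    confidence: float = 0.95,
) -> PersistenceFit:
    """Fit ``ln(mean_cos)`` versus separation with unweighted linear
    least squares; ``L_p = -1/slope``.

    Bins with non-positive mean cosine are excluded (and counted);
    confidence limits are propagated from the slope's standard error
    via the Student-t quantile.  Both the slope interval and the
    corresponding ``L_p`` interval are reported.
    """
    ok = np.isfinite(curve.mean_cos) & (curve.mean_cos > 0) & (curve.n_pairs > 0)
    excluded = int(np.count_nonzero(~ok))
    if excluded:
        logger.info("excluding %d bins with non-positive mean cosine", excluded)
    x = curve.separations[ok]
    y = np.log(curve.mean_cos[ok])
    if len(x) < 3:
        raise EstimationError(
            f"need >=3 usable bins with positive mean cosine, have {len(x)}"
        )
    res = stats.linregress(x, y)
    slope, intercept, stderr = res.slope, res.intercept, res.stderr
    if slope >= 0:
        raise EstimationError(
            "no measurable decay (fibril effectively rigid at this scale)"
        )
    tq = stats.t.ppf(0.5 + confidence / 2.0, len(x) - 2)
    slope_lo = slope - tq * stderr
    slope_hi = slope + tq * stderr
    L_p = -1.0 / slope
    ci_low = -1.0 / slope_lo  # most negative slope -> stiffest lower bound
    ci_high = -1.0 / slope_hi if slope_hi < 0 else np.inf
    return PersistenceFit(
        L_p=L_p,
        ci_low=ci_low,
        ci_high=ci_high,
        fit_slope=slope,
        fit_intercept=intercept,
        slope_stderr=stderr,
        slope_ci=(slope_lo, slope_hi),
        E=youngs_modulus(L_p, radius_nm, temperature_K),
        n_bins_used=len(x),
        excluded_bins=excluded,
        constants={
            "k_B_J_per_K": BOLTZMANN_J_PER_K,
            "temperature_K": temperature_K,
            "radius_nm": radius_nm,
            "second_moment_m4": float(np.pi * (radius_nm * 1e-9) ** 4 / 4.0),
        },
    )
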