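"""Two-parameter decay model fitted to a scaling trace.

At room temperature the per-wedge scaling parameters evolve with absorbed
dose D (MGy) as

    B(D)     = B0 + beta * D                 (linear Debye-Waller growth)
    scale(D) = C * exp(-gamma^2 * D^2)       (Gaussian scale decay)

beta (Angstrom^2/MGy) and gamma (1/MGy) are the two radiation-sensitivity
parameters.  The Gaussian form is the simplest one-parameter curve whose
linear decay rate -d(scale)/dD grows with dose (it satisfies
d(scale)/dD = -2 gamma^2 D scale, a second-order kinetic form), and is
treated as an empirical parameterization valid while scale(D) > 0.6.

Both fits are linear least squares: B against D directly, and ln(scale)
against D^2.  Weighted fits use inverse-variance weights from the per-wedge
observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .exceptions import DegenerateDesignError, InsufficientDataError
from .wilson_scaling import ScalingTrace

__all__ = [
    "DecayParameters",
    "fit_b_linear",
    "fit_scale_gaussian",
    "fit_decay",
]

#: Normalized scale below which the Gaussian parameterization is outside
#: its established validity range.
SCALE_VALIDITY_LIMIT = 0.6


@dataclass
class DecayParameters:
    """(B0, beta, C, gamma) with standard errors for the fitted pair."""

    B0: float  # Angstrom^2
    beta: float  # Angstrom^2 / MGy
    C: float  # relative scale at D = 0 (dimensionless)
    gamma: float  # 1 / MGy
    se_beta: float = float("nan")
    se_gamma: float = float("nan")
    se_B0: float = float("nan")
    scale_range_valid: bool = True
    acronym: str = ""

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.C <= 0:
            raise ValueError(f"C must be > 0, got {self.C}")

    def B(self, dose) -> np.ndarray | float:
        return self.B0 + self.beta * np.asarray(dose, dtype=float)

    def scale(self, dose) -> np.ndarray | float:
        d = np.asarray(dose, dtype=float)
        return self.C * np.exp(-(self.gamma**2) * d**2)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "acronym": self.acronym,
                    "beta_A2_per_MGy": self.beta,
                    "se_beta": self.se_beta,
                    "gamma_per_MGy": self.gamma,
                    "se_gamma": self.se_gamma,
                    "B0_A2": self.B0,
                    "C": self.C,
                }
            ]
        )


def _wls(x: np.ndarray, y: np.ndarray, weights: np.ndarray):
    """Weighted least-squares line fit; returns (intercept, slope, se_slope)."""
    X = sm.add_constant(x)
    fit = sm.WLS(y, X, weights=weights).fit()
    return float(fit.params[0]), float(fit.params[1]), float(fit.bse[1]), float(fit.bse[0])


def _clean_points(doses, values, weights):
    d = np.asarray(doses, dtype=float)
    v = np.asarray(values, dtype=float)
    if weights is None:
        w = np.ones_like(d)
    else:
        w = np.asarray(weights, dtype=float)
    ok = np.isfinite(d) & np.isfinite(v) & np.isfinite(w) & (w > 0)
    return d[ok], v[ok], w[ok]


def fit_b_linear(doses, B_values, weights=None) -> tuple[float, float, float]:
    """Weighted least-squares line B(D) = B0 + beta D.

    Returns ``(B0, beta, se_beta)``.  A negative unconstrained slope is
    clipped to beta = 0 with a warning (damage cannot sharpen the lattice).
    """
    d, B, w = _clean_points(doses, B_values, weights)
    if len(d) < 3:
        raise InsufficientDataError(f"need >= 3 (dose, B) points, got {len(d)}")
    if len(np.unique(d)) < 2:
        raise DegenerateDesignError("all doses identical; slope undefined")
    b0, beta, se_beta, _ = _wls(d, B, w)
    if beta < 0:
        warnings.warn(
            f"unconstrained B slope {beta:.3g} < 0; clipping beta to 0",
            stacklevel=2,
        )
        beta = 0.0
    return b0, beta, se_beta


def fit_scale_gaussian(doses, scales, weights=None) -> tuple[float, float, float, bool]:
    """Least squares of ln(scale) against D^2.

    The model ln scale = ln C - gamma^2 D^2 is exactly linear in D^2, so the
    fit is a convex, closed-form regression.  gamma^2 is constrained >= 0.
    Non-positive scale values are excluded with a warning.

    Returns ``(C, gamma, se_gamma, range_valid)`` where ``range_valid`` is
    False when the smallest fitted scale lies below the 0.6 validity limit
    of the Gaussian parameterization.
    """
    d = np.asarray(doses, dtype=float)
    sc = np.asarray(scales, dtype=float)
    w = None if weights is None else np.asarray(weights, dtype=float)
    pos = sc > 0
    if not np.all(pos):
        warnings.warn(
            f"excluding {int((~pos).sum())} non-positive scale value(s)", stacklevel=2
        )
    d, sc = d[pos], sc[pos]
    if w is not None:
        w = w[pos]
    d, lnsc, w = _clean_points(d, np.log(sc), w)
    if len(d) < 3:
        raise InsufficientDataError(f"need >= 3 positive (dose, scale) points, got {len(d)}")
    if len(np.unique(d)) < 2:
        raise DegenerateDesignError("all doses identical; decay undefined")

    ln_c, slope, se_slope, _ = _wls(d**2, lnsc, w)
    gamma_sq = max(-slope, 0.0)
    gamma = float(np.sqrt(gamma_sq))
    # delta method: se(gamma) = se(gamma^2) / (2 gamma)
    se_gamma = float(se_slope / (2.0 * gamma)) if gamma > 0 else float("nan")
    range_valid = bool(np.exp(lnsc.min() - ln_c) >= SCALE_VALIDITY_LIMIT)
    return float(np.exp(ln_c)), gamma, se_gamma, range_valid


def fit_decay(trace: ScalingTrace, use_weights: bool = True) -> DecayParameters:
    """Compose the B-line and scale-Gaussian fits on a scaling trace.

    Inverse-variance weights are taken from the observed information of the
    per-wedge Wilson fits; uniform weights are used where unavailable.
    Wedges whose Wilson fit failed are skipped.
    """
    ok = trace.ok
    if ok.sum() < 3:
        raise InsufficientDataError(
            f"only {int(ok.sum())} usable wedges in the trace (need >= 3)"
        )
    doses = trace.doses[ok]
    B = trace.B[ok]
    scales = trace.normalized_scales[ok]

    se_B = np.array([w.se_B for w in trace.wedges])[ok]
    se_ln = np.array([w.se_ln_scale for w in trace.wedges])[ok]
    w_B = w_s = None
    if use_weights and np.all(np.isfinite(se_B)) and np.all(se_B > 0):
        w_B = 1.0 / se_B**2
    if use_weights and np.all(np.isfinite(se_ln)) and np.all(se_ln > 0):
        w_s = 1.0 / se_ln**2

    b0, beta, se_beta = fit_b_linear(doses, B, w_B)
    c, gamma, se_gamma, range_valid = fit_scale_gaussian(doses, scales, w_s)
    return DecayParameters(
        B0=b0,
        beta=beta,
        C=c,
        gamma=gamma,
        se_beta=se_beta,
        se_gamma=se_gamma,
        scale_range_valid=range_valid,
    )
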