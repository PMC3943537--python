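"""Per-wedge maximum-likelihood scaling under the acentric Wilson model.

For a narrow data wedge the expected intensity of reflection h is

    J_h = scale * g(s_h) * exp(-2 B s_h^2),

with g the empirical radial curve and B the overall isotropic
Debye-Waller factor.  Intensities are assumed to follow the acentric
Wilson (exponential) distribution with mean J_h, giving log-likelihood

    L(scale, B) = sum_h [ -ln J_h - I_h / J_h ]

over observations with I_h > 0.  Each wedge is fitted independently of the
others; the trace of (scale, B) against accumulated dose is the input to the
decay fit.

The scale factor profiles out analytically: at fixed B the maximizing scale
is mean(I_h / u_h) with u_h = g(s_h) exp(-2 B s_h^2).  Substituting back
leaves a one-dimensional score equation in B,

    mean(s^2) = sum(s^2 r) / sum(r),   r_h = I_h / u_h,

whose right-hand side is strictly increasing in B (it is an r-weighted mean
of s^2 and dr/dB = 2 s^2 r), so the root is unique and bracketed root
finding is exact.  This is the same maximizer the two-parameter gradient
ascent would find, without a line search; the two-parameter gradient is
still evaluated at the solution as a convergence diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .exceptions import ConvergenceError, InsufficientDataError
from .geometry_io import CrystalSeries, UnitCell, Wedge
from .radial_curve import RadialCurve, evaluate

__all__ = ["WedgeScaling", "ScalingTrace", "fit_wedge", "scale_series"]

#: Minimum usable reflections for a per-wedge fit.
MIN_REFLECTIONS = 10

#: Relative gradient-norm tolerance declaring convergence.
GRAD_TOL = 1e-8


@dataclass
class WedgeScaling:
    """ML estimate of (scale, B) for one wedge, with fit diagnostics."""

    dose: float  # MGy
    scale: float  # multiplicative factor, arbitrary units
    B: float  # overall isotropic B, Angstrom^2
    n_used: int  # reflections entering the likelihood
    loglik: float
    converged: bool
    se_B: float = float("nan")
    se_ln_scale: float = float("nan")
    n_excluded: int = 0  # records with I <= 0, excluded and counted
    grad_norm: float = float("nan")
    error: str | None = None

    @property
    def negative_B(self) -> bool:
        """B is unconstrained in sign; negative values are flagged, not clipped."""
        return self.B < 0


@dataclass
class ScalingTrace:
    """Dose-ordered per-wedge scaling results, normalized to the first wedge."""

    wedges: list[WedgeScaling]

    @property
    def doses(self) -> np.ndarray:
        return np.array([w.dose for w in self.wedges])

    @property
    def scales(self) -> np.ndarray:
        return np.array([w.scale for w in self.wedges])

    @property
    def normalized_scales(self) -> np.ndarray:
        return self.scales / self.wedges[0].scale

    @property
    def B(self) -> np.ndarray:
        return np.array([w.B for w in self.wedges])

    @property
    def ok(self) -> np.ndarray:
        return np.array([w.converged and w.error is None for w in self.wedges])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "dose_MGy": self.doses,
                "scale": self.scales,
                "scale_normalized": self.normalized_scales,
                "B_A2": self.B,
                "n_used": [w.n_used for w in self.wedges],
                "loglik": [w.loglik for w in self.wedges],
                "converged": [w.converged for w in self.wedges],
                "se_B_A2": [w.se_B for w in self.wedges],
                "se_ln_scale": [w.se_ln_scale for w in self.wedges],
            }
        )


def _profile_score(B: float, s2: np.ndarray, lnI_ratio: np.ndarray) -> float:
    """mean(s^2) - sum(s^2 r)/sum(r) at r = exp(lnI_ratio + 2 B s2).

    Computed in log space with a max-shift so extreme B values do not
    overflow during bracket expansion.
    """
    ln_r = lnI_ratio + 2.0 * B * s2
    ln_r = ln_r - ln_r.max()
    r = np.exp(ln_r)
    return float(np.mean(s2) - np.sum(s2 * r) / np.sum(r))


def fit_wedge(
    wedge: Wedge,
    curve: RadialCurve,
    cell: UnitCell | None = None,
) -> WedgeScaling:
    """Maximum-likelihood (scale, B) for one wedge.

    Only records with positive intensity and s inside the curve domain enter
    the likelihood; excluded records are counted in ``n_excluded``.  ``cell``
    is accepted for interface symmetry but the stored s values are used.
    """
    s = wedge.s
    lo, hi = curve.domain
    usable = (wedge.intensity > 0) & (s >= lo) & (s <= hi)
    n_used = int(usable.sum())
    n_excluded = wedge.n_reflections - n_used
    if n_used < MIN_REFLECTIONS:
        raise InsufficientDataError(
            f"wedge {wedge.index}: only {n_used} usable reflections "
            f"(need >= {MIN_REFLECTIONS})"
        )

    I = wedge.intensity[usable]
    s2 = s[usable] ** 2
    g = np.asarray(evaluate(curve, s[usable]))
    lnI_ratio = np.log(I) - np.log(g)

    # Wilson-plot start: ln(I/g) ~ const - 2 B s^2
    slope = np.polyfit(s2, lnI_ratio, 1)[0]
    B_start = -0.5 * slope

    # bracket the unique root of the monotone (decreasing) score
    half = 25.0
    B_lo, B_hi = B_start - half, B_start + half
    f_lo = _profile_score(B_lo, s2, lnI_ratio)
    f_hi = _profile_score(B_hi, s2, lnI_ratio)
    for _ in range(60):
        if f_lo > 0 and f_hi < 0:
            break
        if f_lo <= 0:
            B_lo -= half
            f_lo = _profile_score(B_lo, s2, lnI_ratio)
        if f_hi >= 0:
            B_hi += half
            f_hi = _profile_score(B_hi, s2, lnI_ratio)
        half *= 2.0
    else:
        raise ConvergenceError(f"wedge {wedge.index}: could not bracket the B score")

    B_hat = brentq(_profile_score, B_lo, B_hi, args=(s2, lnI_ratio), xtol=1e-12, rtol=1e-15)

    u = g * np.exp(-2.0 * B_hat * s2)
    k_hat = float(np.mean(I / u))
    J = k_hat * u
    t = I / J
    loglik = float(np.sum(-np.log(J) - t))

    # two-parameter gradient in (ln scale, B) as a convergence diagnostic
    g_lnk = float(np.sum(t - 1.0))
    g_B = float(np.sum(2.0 * s2 * (1.0 - t)))
    grad_norm = max(abs(g_lnk), abs(g_B)) / n_used
    converged = grad_norm < max(GRAD_TOL, 1e-10 * abs(loglik) / n_used)

    # observed information in (ln scale, B); invert for standard errors
    a = float(np.sum(t))
    b = float(np.sum(2.0 * s2 * t))
    c = float(np.sum(4.0 * s2**2 * t))
    det = a * c - b * b
    if det > 0:
        se_ln_scale = float(np.sqrt(c / det))
        se_B = float(np.sqrt(a / det))
    else:  # degenerate resolution spread
        se_ln_scale = float("nan")
        se_B = float("nan")
        converged = False

    return WedgeScaling(
        dose=wedge.dose,
        scale=k_hat,
        B=float(B_hat),
        n_used=n_used,
        loglik=loglik,
        converged=bool(converged),
        se_B=se_B,
        se_ln_scale=se_ln_scale,
        n_excluded=n_excluded,
        grad_norm=grad_norm,
    )


def scale_series(series: CrystalSeries, curve: RadialCurve) -> ScalingTrace:
    """Fit every wedge independently; scales are reported raw, with the
    first wedge serving as the normalization unit.

    A failing wedge is carried in the trace with its error message; only a
    failure of the first wedge (the normalization reference) is raised.
    """
    results: list[WedgeScaling] = []
    for i, wedge in enumerate(series.wedges):
        try:
            results.append(fit_wedge(wedge, curve))
        except (InsufficientDataError, ConvergenceError) as exc:
            if i == 0:
                raise
            results.append(
                WedgeScaling(
                    dose=wedge.dose,
                    scale=float("nan"),
                    B=float("nan"),
                    n_used=0,
                    loglik=float("nan"),
                    converged=False,
                    error=str(exc),
                )
            )
    return ScalingTrace(results)
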