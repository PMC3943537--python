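"""Total-intensity decay, half-dose solving, and the normalized half-dose.

Combining the Wilson-scaling expectation with the two-parameter decay model
and integrating over reciprocal space, the total scattered intensity at
dose D is proportional to

    I_sum(D) = exp(-gamma^2 D^2) * integral g(s) exp(-2 (B0 + beta D) s^2) s^2 ds

taken over a resolution window.  The half-dose D1/2 solves
2 I_sum(D1/2) = I_sum(0).

The window's high-resolution edge matters: truncating the integral at the
experimental d_min makes D1/2 systematically *larger* (sensitivity
underestimated) because the fastest-fading high-angle signal is excluded,
and D1/2 also grows with B0 since weakly diffracting crystals have less
high-angle signal to lose.  The normalized half-dose D1/2* removes both
effects: it is the half-dose recomputed with a standard B0 of 20 Angstrom^2
and the integral carried to convergence.  The proportionality constant of
I_sum cancels from every ratio and never needs a value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .decay_fit import DecayParameters
from .exceptions import InvalidInputError, NoDecayError
from .geometry_io import CrystalSeries
from .radial_curve import RadialCurve

__all__ = [
    "ResolutionWindow",
    "HalfDoseResult",
    "DirectSummation",
    "intensity_ratio",
    "solve_half_dose",
    "normalized_half_dose",
    "direct_summation_ratio",
    "STANDARD_B0",
]

#: Standard overall B used by the normalized half-dose (Angstrom^2).
STANDARD_B0 = 20.0

#: Default low-resolution integration limit (Angstrom).
DEFAULT_D_LOW = 12.0

#: Relative tail contribution at which the integral counts as converged.
CONVERGENCE_TOL = 1e-9

#: Grid points per integration block.
N_QUAD = 4096

#: Tolerance on |ratio - 1/2| at the half-dose solution.
RATIO_TOL = 1e-6


@dataclass(frozen=True)
class ResolutionWindow:
    """Integration window in resolution.

    ``d_low`` is the low-resolution edge in Angstrom (``None`` starts the
    integral at s = 0).  ``d_min`` is the high-resolution truncation in
    Angstrom; ``None`` extends the integral until it converges.
    """

    d_low: float | None = DEFAULT_D_LOW
    d_min: float | None = None

    def __post_init__(self) -> None:
        if self.d_low is not None and self.d_low <= 0:
            raise InvalidInputError(f"d_low must be positive, got {self.d_low}")
        if self.d_min is not None:
            if self.d_min <= 0:
                raise InvalidInputError(f"d_min must be positive, got {self.d_min}")
            if self.d_low is not None and self.d_low <= self.d_min:
                raise InvalidInputError(
                    f"d_low={self.d_low} must exceed d_min={self.d_min}"
                )

    @property
    def s_low(self) -> float:
        return 0.0 if self.d_low is None else 1.0 / (2.0 * self.d_low)

    @property
    def s_high(self) -> float | None:
        return None if self.d_min is None else 1.0 / (2.0 * self.d_min)

    @property
    def converged_mode(self) -> bool:
        return self.d_min is None


@dataclass(frozen=True)
class HalfDoseResult:
    d_half: float  # MGy
    mode: str  # "truncated" | "converged"
    b0_used: float  # Angstrom^2
    normalized: bool  # b0_used == 20 and mode == "converged"

    def __post_init__(self) -> None:
        if self.d_half <= 0:
            raise InvalidInputError(f"d_half must be positive, got {self.d_half}")


def _block_integral(curve: RadialCurve, B: float, s_lo: float, s_hi: float) -> float:
    s = np.linspace(s_lo, s_hi, N_QUAD)
    integrand = curve._value(s) * np.exp(-2.0 * B * s**2) * s**2
    return float(np.trapezoid(integrand, s))


def _window_integral(curve: RadialCurve, B: float, window: ResolutionWindow) -> float:
    """integral g(s) exp(-2 B s^2) s^2 ds over the window.

    In converged mode the upper limit is extended block-by-block until the
    last block contributes < CONVERGENCE_TOL of the running total.  The
    exponential factor guarantees rapid convergence for B > 0.
    """
    s_lo = window.s_low
    if not window.converged_mode:
        return _block_integral(curve, B, s_lo, window.s_high)

    width = max(curve.domain[1] - s_lo, 0.25)
    total = _block_integral(curve, B, s_lo, s_lo + width)
    s_edge = s_lo + width
    for _ in range(64):
        block = _block_integral(curve, B, s_edge, s_edge + width)
        total += block
        s_edge += width
        if block < CONVERGENCE_TOL * total:
            return total
    raise NoDecayError(
        f"intensity integral did not converge (B={B:.3g}); "
        "non-positive B with unbounded support?"
    )


def intensity_ratio(
    params: DecayParameters,
    curve: RadialCurve,
    D: float,
    window: ResolutionWindow = ResolutionWindow(),
) -> float:
    """I_sum(D) / I_sum(0) in (0, 1] for D >= 0.

    Equals 1 exactly at D = 0 and decreases strictly with dose whenever
    beta + gamma > 0.
    """
    if D < 0:
        raise InvalidInputError(f"dose must be >= 0, got {D}")
    if D == 0:
        return 1.0
    num = _window_integral(curve, params.B0 + params.beta * D, window)
    den = _window_integral(curve, params.B0, window)
    return float(math.exp(-(params.gamma**2) * D * D) * num / den)


def solve_half_dose(
    params: DecayParameters,
    curve: RadialCurve,
    window: ResolutionWindow = ResolutionWindow(),
) -> HalfDoseResult:
    """Solve 2 I_sum(D1/2) = I_sum(0) by bracketed root finding.

    The ratio is strictly decreasing, so a bracket found by doubling from
    [0, 1] MGy encloses a unique root; the solution satisfies
    |ratio(D1/2) - 1/2| < 1e-6.
    """
    if params.beta == 0 and params.gamma == 0:
        raise NoDecayError("beta = gamma = 0: intensity never decays")

    hi = 1.0
    for _ in range(60):
        if intensity_ratio(params, curve, hi, window) < 0.5:
            break
        hi *= 2.0
    else:
        raise NoDecayError("intensity ratio never crosses 1/2 (no effective decay)")

    d_half = brentq(
        lambda D: intensity_ratio(params, curve, D, window) - 0.5,
        0.0,
        hi,
        xtol=1e-12,
        rtol=8.9e-16,
    )
    achieved = intensity_ratio(params, curve, d_half, window)
    if abs(achieved - 0.5) > RATIO_TOL:
        raise NoDecayError(f"half-dose root imprecise: ratio {achieved:.8f}")
    mode = "converged" if window.converged_mode else "truncated"
    return HalfDoseResult(
        d_half=float(d_half),
        mode=mode,
        b0_used=params.B0,
        normalized=(mode == "converged" and params.B0 == STANDARD_B0),
    )


def normalized_half_dose(beta: float, gamma: float, curve: RadialCurve) -> float:
    """Normalized half-dose D1/2* (MGy): B0 = 20 Angstrom^2, integral to
    convergence.  Strictly decreasing in each of beta and gamma."""
    if beta < 0 or gamma < 0:
        raise InvalidInputError("beta and gamma must be >= 0")
    params = DecayParameters(B0=STANDARD_B0, beta=beta, C=1.0, gamma=gamma)
    window = ResolutionWindow(d_low=DEFAULT_D_LOW, d_min=None)
    return solve_half_dose(params, curve, window).d_half


@dataclass
class DirectSummation:
    """Per-wedge summed-intensity ratios and the interpolated half-dose."""

    doses: np.ndarray
    ratios: np.ndarray
    d_half: float | None  # None when the ratio never crosses 1/2
    crossed: bool


def direct_summation_ratio(series: CrystalSeries) -> DirectSummation:
    """Total recorded intensity per wedge divided by the first wedge's total.

    This is the classical half-dose estimate: all LP-corrected integrated
    intensities within the experimental resolution limit are summed as-is.
    The half-dose is located by monotone piecewise-linear interpolation of
    the first downward crossing of 1/2; absent a crossing the result is
    flagged.
    """
    if len(series.wedges) < 2:
        raise InvalidInputError("direct summation needs >= 2 wedges")
    doses = series.doses
    sums = np.array([float(np.sum(w.intensity)) for w in series.wedges])
    if sums[0] <= 0:
        raise InvalidInputError("first wedge has non-positive total intensity")
    ratios = sums / sums[0]

    d_half = None
    crossed = False
    for i in range(1, len(ratios)):
        if ratios[i] < 0.5 <= ratios[i - 1]:
            f = (ratios[i - 1] - 0.5) / (ratios[i - 1] - ratios[i])
            d_half = float(doses[i - 1] + f * (doses[i] - doses[i - 1]))
            crossed = True
            break
    return DirectSummation(doses=doses, ratios=ratios, d_half=d_half, crossed=crossed)
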