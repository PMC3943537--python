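"""Survey-level aggregation and trend analyses.

Individual measurements (one fitted series each) aggregate into
per-structure summaries: plain means and sample standard deviations of
beta, gamma and the normalized half-dose, mirroring the Ave/SD presentation
of a survey table.  Two cross-structure analyses follow:

* **Solvent-content trend** — radiation sensitivity rises with crystal
  solvent content.  Because the claim is a monotone trend rather than a
  linear law, Spearman rank correlation between D1/2* and solvent fraction
  is reported, alongside strict-ordering checks within declared crystal-form
  groups (different forms of the same protein).  The approximate
  proportionality D1/2* ~ (1/solvent - 1) serves only as the reference for
  outlier flagging: structures whose half-dose deviates from the robustly
  fitted proportionality by more than a configurable factor (default 3x)
  are flagged and, by default, excluded from the correlation.

* **Dose-rate independence** — across the sampled range the decay depends
  on dose, not dose rate.  An ordinary least-squares slope of D1/2* against
  log10(dose rate) is reported with a 95% confidence interval; the verdict
  is "independent" when the interval covers zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import spearmanr

from .exceptions import InsufficientDataError, InvalidInputError

__all__ = [
    "MeasurementRecord",
    "aggregate",
    "solvent_trend",
    "dose_rate_independence",
    "TrendReport",
    "DoseRateReport",
    "DEFAULT_FORM_GROUPS",
]

#: Crystal-form groups of the same protein, used for within-protein
#: monotonicity checks (ordering by solvent content).
DEFAULT_FORM_GROUPS: dict[str, tuple[str, ...]] = {
    "lysozyme": ("LYZM", "LYZT"),
    "insulin": ("INSR", "INSC"),
    "trypsin": ("BPTTR", "BPTOH", "BPTOL"),
}

MEASUREMENT_COLUMNS = ("acronym", "solvent_fraction", "dose_rate", "beta", "gamma", "d_half_norm")


@dataclass(frozen=True)
class MeasurementRecord:
    """One measurement: a fitted series reduced to its summary numbers."""

    acronym: str
    solvent_fraction: float
    dose_rate: float  # kGy/s
    beta: float  # Angstrom^2/MGy
    gamma: float  # 1/MGy
    d_half_norm: float  # MGy
    se_beta: float = float("nan")
    se_gamma: float = float("nan")

    def __post_init__(self) -> None:
        if self.d_half_norm <= 0:
            raise InvalidInputError(f"d_half_norm must be positive, got {self.d_half_norm}")


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        frame = pd.DataFrame(
            [r if isinstance(r, dict) else r.__dict__ for r in records]
        )
    missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"measurement table lacks columns {missing}")
    return frame


def aggregate(records) -> pd.DataFrame:
    """Per-structure summary: n, mean and sample SD for beta, gamma, D1/2*.

    SDs are reported only for n >= 2 (NaN otherwise, the table's "-").
    Rows are ordered deterministically by acronym; the operation is
    permutation-invariant and idempotent on singleton groups.
    """
    frame = _as_frame(records)
    if len(frame) == 0:
        raise InsufficientDataError("no measurements to aggregate")
    rows = []
    for acronym, grp in frame.groupby("acronym", sort=True):
        row = {
            "acronym": acronym,
            "n_measurements": len(grp),
            "solvent_fraction": float(grp["solvent_fraction"].iloc[0]),
        }
        for param in ("beta", "gamma", "d_half_norm"):
            row[f"{param}_ave"] = float(grp[param].mean())
            row[f"{param}_sd"] = float(grp[param].std(ddof=1)) if len(grp) >= 2 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TrendReport:
    """Solvent-content trend: rank correlation, orderings, outliers."""

    spearman_rho: float
    spearman_p: float
    outliers: tuple[str, ...]
    residual_factors: pd.Series  # per structure: d_half / (k * (1/solvent - 1))
    group_monotone: dict[str, bool]  # strict decrease of D1/2* with solvent
    n_structures: int


def solvent_trend(
    summaries: pd.DataFrame,
    form_groups: dict[str, tuple[str, ...]] | None = None,
    outlier_factor: float = 3.0,
    include_outliers_in_correlation: bool = False,
) -> TrendReport:
    """Rank-correlate D1/2* with solvent fraction and flag outliers.

    The outlier reference is the robust proportionality
    ``d_half_norm = k * (1/solvent - 1)`` with k the median of the
    per-structure ratios; a structure is flagged when its half-dose deviates
    from that reference by more than ``outlier_factor`` in either direction.
    """
    required = {"acronym", "solvent_fraction", "d_half_norm_ave"}
    if not required.issubset(summaries.columns):
        raise InvalidInputError(f"summary table needs columns {sorted(required)}")
    if len(summaries) < 3:
        raise InsufficientDataError(f"need >= 3 structures, got {len(summaries)}")
    frame = summaries.set_index("acronym")
    solvent = frame["solvent_fraction"].astype(float)
    d_half = frame["d_half_norm_ave"].astype(float)
    if np.any(solvent <= 0) or np.any(solvent >= 1) or np.any(d_half <= 0):
        raise InvalidInputError("solvent fractions must be in (0,1) and half-doses positive")

    x = 1.0 / solvent - 1.0
    k = float(np.median(d_half / x))
    factors = d_half / (k * x)
    dev = np.maximum(factors, 1.0 / factors)
    outliers = tuple(sorted(frame.index[dev > outlier_factor]))

    keep = frame.index if include_outliers_in_correlation else frame.index.difference(outliers)
    sv, dh = solvent.loc[keep], d_half.loc[keep]
    if sv.nunique() < 2 or dh.nunique() < 2:
        rho, pval = 0.0, 1.0  # constant input: no rank trend by definition
    else:
        rho, pval = spearmanr(sv, dh)

    groups = DEFAULT_FORM_GROUPS if form_groups is None else form_groups
    group_monotone: dict[str, bool] = {}
    for name, members in groups.items():
        present = [m for m in members if m in frame.index]
        if len(present) < 2:
            continue
        ordered = sorted(present, key=lambda m: solvent.loc[m])
        vals = d_half.loc[ordered].to_numpy()
        group_monotone[name] = bool(np.all(np.diff(vals) < 0))

    return TrendReport(
        spearman_rho=float(rho),
        spearman_p=float(pval),
        outliers=outliers,
        residual_factors=factors,
        group_monotone=group_monotone,
        n_structures=len(summaries),
    )


@dataclass
class DoseRateReport:
    slope: float  # MGy per decade of dose rate
    ci_low: float
    ci_high: float
    independent: bool  # 95% interval covers zero
    n_records: int
    log10_span: float


def dose_rate_independence(records, alpha: float = 0.05) -> DoseRateReport:
    """OLS slope of D1/2* against log10(dose rate) with a 95% interval.

    Requires >= 4 records spanning at least one order of magnitude in dose
    rate.  The verdict is "independent" when the interval covers zero.
    """
    frame = _as_frame(records)
    rates = frame["dose_rate"].astype(float).to_numpy()
    d_half = frame["d_half_norm"].astype(float).to_numpy()
    if len(frame) < 4:
        raise InsufficientDataError(f"need >= 4 records, got {len(frame)}")
    if np.any(rates <= 0):
        raise InvalidInputError("dose rates must be positive")
    log_rate = np.log10(rates)
    span = float(log_rate.max() - log_rate.min())
    if span < 1.0:
        raise InsufficientDataError(
            f"dose rates span {span:.2f} decades; need >= 1 for a meaningful slope"
        )
    fit = sm.OLS(d_half, sm.add_constant(log_rate)).fit()
    slope = float(fit.params[1])
    ci = fit.conf_int(alpha=alpha)
    lo, hi = float(ci[1][0]), float(ci[1][1])
    return DoseRateReport(
        slope=slope,
        ci_low=lo,
        ci_high=hi,
        independent=bool(lo <= 0.0 <= hi),
        n_records=len(frame),
        log10_span=span,
    )
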