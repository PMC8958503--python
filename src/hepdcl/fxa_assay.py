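"""Anti-Xa chromogenic assay reduction and AF-activity correlation.

Heparin potentiates antithrombin III, which inhibits coagulation factor Xa;
a heparin antidote dissociates the ternary complex and restores FXa
activity.  Residual activity is read out by HPLC as the hydrolysis of a
chromogenic peptide substrate: at each time point the cleaved-peptide and
intact-substrate peaks are integrated together with a 4-nitroaniline
internal standard.

Percent hydrolysis uses the standard-free bounded ratio

    % = 100 * Ac / (Ac + As)

which is invariant to injection volume; the internal standard serves to
validate injections, not to scale the metric.  The screen-to-activity link
is an ordinary least-squares regression of the 30-minute percent hydrolysis
on the amplification factor, with a one-pass studentized-residual rule to
flag poorly behaved ligands (e.g. sparingly soluble ones) as outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = [
    "PotencyRecord",
    "RegressionResult",
    "percent_hydrolysis",
    "timecourse_summary",
    "af_activity_regression",
]

#: Sampling schedule (minutes) of the assay time course.
ASSAY_SCHEDULE_MIN = (5, 10, 15, 20, 30, 50, 80, 120)


@dataclass(frozen=True)
class PotencyRecord:
    member_id: str
    pct_hydrolysis_30min: float
    af: float
    outlier: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_hydrolysis_30min <= 100.0:
            raise ValueError("percent hydrolysis must lie in [0, 100]")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    outliers: Tuple[str, ...]
    n_used: int


def percent_hydrolysis(
    area_cleaved: float,
    area_substrate: float,
    area_internal_standard: Optional[float] = None,
) -> float:
    """Bounded percent hydrolysis of one injection.

    ``100 * Ac / (Ac + As)``; the internal-standard area, when provided,
    must be positive (a vanished standard marks a failed injection).
    """
    if area_cleaved < 0 or area_substrate < 0:
        raise ValueError("areas must be non-negative")
    if area_internal_standard is not None and area_internal_standard <= 0:
        raise ValueError("internal-standard area must be positive")
    total = area_cleaved + area_substrate
    if total == 0:
        raise ValueError("cleaved + substrate area is zero")
    return 100.0 * area_cleaved / total


def timecourse_summary(
    timecourse: pd.DataFrame,
    t_report: float = 30.0,
    monotone_tol: float = 1.0,
) -> float:
    """Percent hydrolysis at the reporting time.

    ``timecourse`` has columns ``t_min``, ``area_cleaved``,
    ``area_substrate`` and optionally ``area_is``.  The value at
    ``t_report`` is the exact sample when one exists, otherwise linear
    interpolation between the bracketing samples.  A hydrolysis curve
    should be non-decreasing; drops larger than ``monotone_tol`` points
    raise a warning (noisy or drifted injections).
    """
    tc = timecourse.sort_values("t_min")
    t = tc["t_min"].to_numpy(dtype=float)
    if not (t[0] <= t_report <= t[-1]):
        raise ValueError(
            f"t_report {t_report} min outside sampled range [{t[0]}, {t[-1]}]"
        )
    ais = tc["area_is"] if "area_is" in tc else [None] * len(tc)
    pct = np.array(
        [
            percent_hydrolysis(ac, asub, a)
            for ac, asub, a in zip(
                tc["area_cleaved"], tc["area_substrate"], ais
            )
        ]
    )
    drops = np.diff(pct)
    if np.any(drops < -monotone_tol):
        warnings.warn(
            "hydrolysis curve decreases by more than "
            f"{monotone_tol} points between samples"
        )
    return float(np.interp(t_report, t, pct))


def af_activity_regression(
    records: Sequence[PotencyRecord],
    studentized_threshold: float = 2.0,
) -> Tuple[RegressionResult, List[PotencyRecord]]:
    """OLS of percent hydrolysis on AF with one-pass outlier flagging.

    An initial fit over all points computes externally studentized
    residuals; points exceeding ``studentized_threshold`` in absolute value
    are flagged and the regression is refit once without them.  Returns the
    final regression and the records with their outlier flags set.
    Requires at least three usable records and non-degenerate AF variance.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    af = np.array([r.af for r in records], dtype=float)
    pct = np.array([r.pct_hydrolysis_30min for r in records], dtype=float)
    if np.ptp(af) == 0:
        raise ValueError("degenerate AF variance: all AFs identical")

    def ols(x: np.ndarray, y: np.ndarray):
        return sm.OLS(y, sm.add_constant(x)).fit()

    fit0 = ols(af, pct)
    if fit0.df_resid > 1 and fit0.mse_resid > np.finfo(float).eps * np.var(pct):
        with np.errstate(divide="ignore", invalid="ignore"):
            # points exactly on the line give 0/0 -> nan (not outliers);
            # a gross outlier among exact points gives inf (flagged)
            student = OLSInfluence(fit0).resid_studentized_external
        outlier_mask = np.abs(student) > studentized_threshold
    else:
        # an (almost) exact line leaves nothing to studentize
        outlier_mask = np.zeros(len(records), dtype=bool)
    keep = ~outlier_mask
    if keep.sum() < 3:
        raise ValueError("outlier pass left fewer than 3 records")
    fit1 = ols(af[keep], pct[keep])
    r = float(np.corrcoef(af[keep], pct[keep])[0, 1])
    flagged = [
        PotencyRecord(
            member_id=rec.member_id,
            pct_hydrolysis_30min=rec.pct_hydrolysis_30min,
            af=rec.af,
            outlier=bool(out),
        )
        for rec, out in zip(records, outlier_mask)
    ]
    result = RegressionResult(
        slope=float(fit1.params[1]),
        intercept=float(fit1.params[0]),
        pearson_r=r,
        outliers=tuple(
            sorted(rec.member_id for rec in flagged if rec.outlier)
        ),
        n_used=int(keep.sum()),
    )
    return result, flagged
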