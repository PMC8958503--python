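"""Two-state (conformational-change) SPR kinetics: simulation and global fit.

The mechanism is a 1:1 encounter complex followed by a first-order
isomerization on the chip surface,

    A + B  <-> AB   (ka1, kd1)        AB <-> AB*   (ka2, kd2)

with the analyte A held at constant concentration C during association and
at zero during dissociation.  Writing x = ([AB], [AB*]) in response units,

    d[AB]/dt  = ka1 C (Rmax - AB - AB*) - kd1 AB - ka2 AB + kd2 AB*
    d[AB*]/dt = ka2 AB - kd2 AB*

is a linear constant-coefficient system within each phase, so sensorgrams
are computed exactly with the eigendecomposition propagator (no step-size
error).  The total response is AB + AB*.

The apparent dissociation constant summarizing the scheme is

    K_D^app = (kd1/ka1) * kd2 / (kd2 + ka2)

i.e. the 1:1 constant scaled by the fraction of surface complex that has
not isomerized at equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Sensorgram",
    "TwoStateParams",
    "simulate_two_state",
    "fit_sensorgrams",
    "kd_app_two_state",
    "default_start",
]

ASSOCIATION = "association"
DISSOCIATION = "dissociation"


@dataclass(frozen=True)
class TwoStateParams:
    """Rate constants and surface capacity of the two-state scheme."""

    ka1: float  # M^-1 s^-1
    kd1: float  # s^-1
    ka2: float  # s^-1
    kd2: float  # s^-1
    rmax: float  # RU

    def __post_init__(self) -> None:
        if min(self.ka1, self.kd1, self.kd2, self.rmax) <= 0 or self.ka2 < 0:
            raise ValueError("rates and rmax must be positive (ka2 may be 0)")

    @property
    def kd_app(self) -> float:
        return kd_app_two_state(self)


@dataclass(frozen=True)
class Sensorgram:
    """One SPR trace: response vs time with phase labels."""

    time: np.ndarray  # s, strictly increasing
    response: np.ndarray  # RU
    conc: float  # M, analyte concentration during association
    phase: np.ndarray  # per-sample label
    series_id: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not (len(self.time) == len(self.response) == len(self.phase)):
            raise ValueError("time, response and phase lengths differ")


def kd_app_two_state(params: TwoStateParams) -> float:
    """Overall dissociation constant of the two-state scheme (M)."""
    return (params.kd1 / params.ka1) * params.kd2 / (params.kd2 + params.ka2)


def _propagate(
    params: TwoStateParams, conc: float, times: np.ndarray, x0: np.ndarray
) -> np.ndarray:
    """Exact solution of the linear phase ODE at the given times.

    ``times`` are measured from the start of the phase; returns the state
    (AB, AB*) at each time, shape (len(times), 2).
    """
    kaC = params.ka1 * conc
    m = np.array(
        [
            [-(kaC + params.kd1 + params.ka2), -kaC + params.kd2],
            [params.ka2, -params.kd2],
        ]
    )
    f = np.array([kaC * params.rmax, 0.0])
    if conc > 0:
        xss = np.linalg.solve(m, -f)
    else:
        xss = np.zeros(2)
    w, v = np.linalg.eig(m)
    c = np.linalg.solve(v, x0 - xss)
    # x(t) = xss + V diag(exp(w t)) c   (w real negative for this scheme)
    expwt = np.exp(np.real(w)[None, :] * times[:, None])
    out = xss[None, :] + np.real(v[None, :, :] @ (expwt * c)[..., None])[..., 0]
    return out


def simulate_two_state(
    params: TwoStateParams,
    conc: float,
    t_assoc: float,
    t_dissoc: float,
    dt: float,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    series_id: str = "",
) -> Sensorgram:
    """Simulate one association/dissociation cycle on a fixed grid.

    The association phase runs on t in [0, t_assoc] at analyte
    concentration ``conc``; dissociation continues from the association
    endpoint with the analyte washed out.  Gaussian noise of standard
    deviation ``noise_sd`` RU is added when requested.
    """
    if conc < 0:
        raise ValueError("conc must be non-negative")
    if t_assoc <= 0 or t_dissoc < 0 or dt <= 0:
        raise ValueError("durations and dt must be positive")
    t_a = np.arange(0.0, t_assoc + dt / 2, dt)
    x_a = _propagate(params, conc, t_a, np.zeros(2))
    t_d = np.arange(dt, t_dissoc + dt / 2, dt)
    x_d = _propagate(params, 0.0, t_d, x_a[-1])
    time = np.concatenate([t_a, t_a[-1] + t_d])
    state = np.vstack([x_a, x_d])
    phase = np.array([ASSOCIATION] * len(t_a) + [DISSOCIATION] * len(t_d))
    response = state.sum(axis=1)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise requested without an rng")
        response = response + rng.normal(0.0, noise_sd, response.shape)
    return Sensorgram(
        time=time, response=response, conc=conc, phase=phase,
        series_id=series_id,
    )


def _model_response(params: TwoStateParams, gram: Sensorgram) -> np.ndarray:
    """Noiseless model response on the grid/phases of an observed trace."""
    a_mask = gram.phase == ASSOCIATION
    t_a = gram.time[a_mask]
    t0 = t_a[0] if t_a.size else gram.time[0]
    x_a = _propagate(params, gram.conc, t_a - t0, np.zeros(2))
    out = np.empty((len(gram.time), 2))
    out[a_mask] = x_a
    d_mask = ~a_mask
    if d_mask.any():
        t_d = gram.time[d_mask]
        x_last = x_a[-1] if t_a.size else np.zeros(2)
        t_switch = t_a[-1] if t_a.size else gram.time[0]
        out[d_mask] = _propagate(params, 0.0, t_d - t_switch, x_last)
    return out.sum(axis=1)


def default_start(series: Sequence[Sensorgram]) -> TwoStateParams:
    """Heuristic start for the global fit, derived from the traces.

    Rmax from the largest observed response, kd1 from the early
    dissociation decay of the highest-concentration trace, ka1 from a
    half-saturation guess at the middle concentration, and a slow
    isomerization (ka2 = kd2) as the generic two-state seed.
    """
    top = max(series, key=lambda g: g.conc)
    rmax0 = 1.5 * max(float(np.max(g.response)) for g in series)
    d = top.phase == DISSOCIATION
    kd1 = 1e-2
    if d.sum() >= 3:
        t = top.time[d] - top.time[d][0]
        r = np.maximum(top.response[d], 1e-9 * rmax0)
        # secant log-decay over the first third of the dissociation
        third = max(2, len(t) // 3)
        kd1 = max(float(np.log(r[0] / r[third - 1]) / max(t[third - 1], 1e-9)), 1e-5)
    concs = sorted(g.conc for g in series if g.conc > 0)
    c_mid = concs[len(concs) // 2] if concs else 1e-6
    ka1 = kd1 / c_mid  # puts the half-saturation point at the mid conc
    return TwoStateParams(ka1=ka1, kd1=kd1, ka2=1e-3, kd2=1e-3, rmax=rmax0)


def fit_sensorgrams(
    series: Sequence[Sensorgram],
    start: Optional[TwoStateParams] = None,
    flat_sv_ratio: float = 1e8,
) -> Tuple[TwoStateParams, Mapping[str, object]]:
    """Global least-squares fit of shared two-state parameters.

    All traces share (ka1, kd1, ka2, kd2, Rmax); at least three distinct
    analyte concentrations are required.  Rates are searched in log10 space.
    Returns the fitted parameters and a diagnostics mapping with the
    objective, per-parameter standard errors, the derived ``kd_app`` with
    propagated uncertainty and an identifiability flag raised when the
    Jacobian has a flat direction (singular-value ratio above
    ``flat_sv_ratio``), the classic symptom of an unresolved ka2/kd2 pair.
    """
    concs = {g.conc for g in series if g.conc > 0}
    if len(concs) < 3:
        raise ValueError("need sensorgrams at >= 3 distinct concentrations")
    if start is None:
        start = default_start(series)

    def unpack(p: np.ndarray) -> TwoStateParams:
        return TwoStateParams(
            ka1=10.0 ** p[0], kd1=10.0 ** p[1], ka2=10.0 ** p[2],
            kd2=10.0 ** p[3], rmax=10.0 ** p[4],
        )

    def resid(p: np.ndarray) -> np.ndarray:
        params = unpack(p)
        return np.concatenate(
            [_model_response(params, g) - g.response for g in series]
        )

    p0 = np.log10(
        [start.ka1, start.kd1, max(start.ka2, 1e-6), start.kd2, start.rmax]
    )
    lo = p0 - 6.0
    hi = p0 + 6.0
    sol = least_squares(
        resid, np.clip(p0, lo, hi), bounds=(lo, hi),
        xtol=1e-12, ftol=1e-12, gtol=1e-12, diff_step=1e-4,
    )
    params = unpack(sol.x)

    r = sol.fun
    dof = max(r.size - sol.x.size, 1)
    s2 = float(r @ r) / dof
    sv = np.linalg.svd(sol.jac, compute_uv=False)
    flat = bool(sv[0] / max(sv[-1], 1e-300) > flat_sv_ratio)
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se_log = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        flat = True
        se_log = np.full(5, np.nan)
    # kd_app gradient in log10-parameter space:
    # log10 kd_app = log10 kd1 - log10 ka1 + log10 kd2 - log10(kd2 + ka2)
    ka2, kd2 = params.ka2, params.kd2
    grad = np.array(
        [-1.0, 1.0, -ka2 / (ka2 + kd2), 1.0 - kd2 / (ka2 + kd2), 0.0]
    )
    if np.all(np.isfinite(se_log)):
        var_log_kd = float(grad @ cov @ grad)
        kd_se = params.kd_app * np.log(10.0) * np.sqrt(max(var_log_kd, 0.0))
    else:
        kd_se = float("nan")
    diagnostics = {
        "objective": float(2 * sol.cost),
        "residual_rms": float(np.sqrt(np.mean(r**2))),
        "converged": bool(sol.success),
        "se_log10": dict(zip(("ka1", "kd1", "ka2", "kd2", "rmax"), se_log)),
        "kd_app": params.kd_app,
        "kd_app_se": kd_se,
        "identifiability_warning": flat,
    }
    return params, diagnostics


# ---------------------------------------------------------------------------
# tabular I/O


def sensorgrams_to_frame(series: Sequence[Sensorgram]) -> pd.DataFrame:
    rows = []
    for g in series:
        rows.append(
            pd.DataFrame(
                {
                    "series_id": g.series_id,
                    "time_s": g.time,
                    "response_RU": g.response,
                    "conc_M": g.conc,
                    "phase": g.phase,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def frame_to_sensorgrams(df: pd.DataFrame) -> List[Sensorgram]:
    out = []
    for sid, grp in df.groupby("series_id", sort=True):
        grp = grp.sort_values("time_s")
        conc = float(grp["conc_M"].iloc[0])
        out.append(
            Sensorgram(
                time=grp["time_s"].to_numpy(dtype=float),
                response=grp["response_RU"].to_numpy(dtype=float),
                conc=conc,
                phase=grp["phase"].to_numpy(),
                series_id=str(sid),
            )
        )
    return out
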