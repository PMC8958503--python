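"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the speciation
oracle uses nested per-coordinate bisection on the monotone mass-balance
residuals instead of the package's 2-D Newton iteration, and the Langmuir
curve is the textbook closed form.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np

Species = Sequence[Tuple[int, int, float]]  # (l, h, log10 beta)


def _l_balance_root(
    species: Species, l_tot: float, h_free: float
) -> float:
    """Free [L] solving the L mass balance at fixed free [H], by bisection.

    L_calc([L]) = [L] + sum l beta [L]^l [H]^h is strictly increasing in
    [L], so plain bisection on ln[L] converges unconditionally.
    """
    betas = [(l, h, 10.0**b) for l, h, b in species]

    def l_calc(l_free: float) -> float:
        return l_free + sum(
            l * b * l_free**l * h_free**h for l, h, b in betas if l > 0
        )

    lo, hi = np.log(l_tot) - 700.0, np.log(l_tot)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if l_calc(np.exp(mid)) > l_tot:
            hi = mid
        else:
            lo = mid
    return float(np.exp(0.5 * (lo + hi)))


def speciation_bisect(
    species: Species, l_tot: float, h_tot: float
) -> Dict[Tuple[int, int], float]:
    """Equilibrium concentrations by nested bisection (no Newton steps).

    Outer bisection runs on ln[H]: with [L] re-solved from the L balance at
    every candidate [H], the calculated total H is increasing in [H].
    Returns free species under keys (1,0)/(0,1) plus every complex.
    """
    assert l_tot > 0 and h_tot > 0
    betas = [(l, h, 10.0**b) for l, h, b in species]

    def h_calc(h_free: float) -> float:
        l_free = _l_balance_root(species, l_tot, h_free)
        return h_free + sum(
            h * b * l_free**l * h_free**h for l, h, b in betas if h > 0
        )

    lo, hi = np.log(h_tot) - 700.0, np.log(h_tot)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if h_calc(np.exp(mid)) > h_tot:
            hi = mid
        else:
            lo = mid
    h_free = float(np.exp(0.5 * (lo + hi)))
    l_free = _l_balance_root(species, l_tot, h_free)
    out: Dict[Tuple[int, int], float] = {(1, 0): l_free, (0, 1): h_free}
    for l, h, b in betas:
        out[(l, h)] = b * l_free**l * h_free**h
    return out


def langmuir_association(
    ka: float, kd: float, conc: float, rmax: float, t: np.ndarray
) -> np.ndarray:
    """Closed-form 1:1 association curve R(t) = Req (1 - exp(-kobs t))."""
    kobs = ka * conc + kd
    req = rmax * ka * conc / kobs
    return req * (1.0 - np.exp(-kobs * t))
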