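"""Amplification-factor (AF) screening of templated dynamic libraries.

The readout of the screen is AF = A_T / A_0: the LC peak area of a library
member in the presence of the heparin template divided by its area in the
untemplated control.  AF > 1 means the template re-weights the equilibrating
mixture toward that member, i.e. it is a binder.

Two practical rules from bench experience are enforced here:

* ratios against barely detected control peaks are artificially high, so a
  per-replicate AF is only emitted when the control area clears a floor
  (default: a fraction of the median control area in the same injection);
* members appearing in several sublibraries are pooled by averaging their
  per-replicate AFs, never by taking a ratio of pooled areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PEAK_COLUMNS",
    "AmplificationRecord",
    "compute_af",
    "aggregate_af",
    "rank_members",
    "records_frame",
]

#: Schema of the long-format peak table consumed by :func:`aggregate_af`.
PEAK_COLUMNS = ["member_id", "sublibrary_id", "replicate", "condition", "area"]

LOW_CONTROL = "low_control"
SINGLE_OBS = "single_obs"


@dataclass(frozen=True)
class AmplificationRecord:
    """Pooled AF for one member; ``af`` is NaN when no usable pair exists."""

    member_id: str
    af: float
    sd: float
    n_obs: int
    flags: FrozenSet[str] = field(default_factory=frozenset)

    @property
    def defined(self) -> bool:
        return self.n_obs > 0 and math.isfinite(self.af)


def compute_af(a_t: float, a_0: float, a0_floor: float) -> Optional[float]:
    """Per-replicate amplification factor, or None for a low-control artifact.

    Returns ``a_t / a_0`` when the control area reaches ``a0_floor``;
    otherwise None (the ratio would be artificially high and is discarded).
    Negative areas are rejected.
    """
    if a_t < 0 or a_0 < 0:
        raise ValueError("peak areas must be non-negative")
    if a_0 < a0_floor or a_0 == 0:
        return None
    return a_t / a_0


def aggregate_af(
    peaks: pd.DataFrame,
    a0_floor_rel: float = 0.01,
    normalize: bool = True,
) -> List[AmplificationRecord]:
    """Reduce a long peak table to one pooled AF record per member.

    Parameters
    ----------
    peaks
        Long-format table with columns :data:`PEAK_COLUMNS`; ``condition``
        is ``"templated"`` or ``"control"`` and each (member, sublibrary,
        replicate, condition) combination appears at most once.
    a0_floor_rel
        The control-area floor, as a fraction of the median control area of
        the same (sublibrary, replicate) injection.
    normalize
        Divide each area by the total area of its injection (sublibrary,
        replicate, condition) before forming ratios.  AFs are ratios of
        areas from two injections, so this guards against injection-volume
        drift; it cancels exactly when both injections carry the same total.
    """
    df = peaks.loc[:, PEAK_COLUMNS].copy()
    bad = set(df["condition"]) - {"templated", "control"}
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    if (df["area"] < 0).any():
        raise ValueError("peak areas must be non-negative")
    keys = ["member_id", "sublibrary_id", "replicate", "condition"]
    if df.duplicated(keys).any():
        raise ValueError("duplicate (member, sublibrary, replicate, condition)")

    if normalize:
        inj = ["sublibrary_id", "replicate", "condition"]
        totals = df.groupby(inj)["area"].transform("sum")
        df["area"] = np.where(totals > 0, df["area"] / totals, 0.0)

    wide = df.pivot_table(
        index=["member_id", "sublibrary_id", "replicate"],
        columns="condition",
        values="area",
        aggfunc="first",
    ).reset_index()
    for col in ("templated", "control"):
        if col not in wide:
            wide[col] = np.nan

    # artifact floor per control injection
    med = (
        df[df["condition"] == "control"]
        .groupby(["sublibrary_id", "replicate"])["area"]
        .median()
        .rename("a0_floor")
        * a0_floor_rel
    )
    wide = wide.join(med, on=["sublibrary_id", "replicate"])
    wide["a0_floor"] = wide["a0_floor"].fillna(0.0)

    records: List[AmplificationRecord] = []
    for member_id, grp in wide.groupby("member_id", sort=True):
        afs: List[float] = []
        flags: set = set()
        for row in grp.itertuples():
            a_t, a_0 = row.templated, row.control
            if not (np.isfinite(a_t) and np.isfinite(a_0)):
                continue  # unmatched pair: one injection missing the peak
            af = compute_af(a_t, a_0, row.a0_floor)
            if af is None:
                flags.add(LOW_CONTROL)
            else:
                afs.append(af)
        n = len(afs)
        if n == 1:
            flags.add(SINGLE_OBS)
        records.append(
            AmplificationRecord(
                member_id=str(member_id),
                af=float(np.mean(afs)) if n else float("nan"),
                sd=float(np.std(afs, ddof=1)) if n > 1 else float("nan"),
                n_obs=n,
                flags=frozenset(flags),
            )
        )
    return records


def rank_members(
    records: Sequence[AmplificationRecord], top_k: Optional[int] = None
) -> List[AmplificationRecord]:
    """Order by AF descending; artifact-flagged or undefined records go last.

    Ties are broken by member id, so the ordering is stable for equal AFs.
    Records carrying the low-control artifact flag are demoted regardless of
    their nominal ratio (their AF is not trustworthy); ``single_obs`` is
    informational and does not demote.
    """
    def key(r: AmplificationRecord):
        demoted = (not r.defined) or (LOW_CONTROL in r.flags)
        af = r.af if r.defined else -math.inf
        return (demoted, -af, r.member_id)

    ordered = sorted(records, key=key)
    return ordered[:top_k] if top_k is not None else ordered


def records_frame(records: Sequence[AmplificationRecord]) -> pd.DataFrame:
    """Tabular view (member_id, af, sd, n_obs, flags) of pooled records."""
    return pd.DataFrame(
        {
            "member_id": [r.member_id for r in records],
            "af": [r.af for r in records],
            "sd": [r.sd for r in records],
            "n_obs": [r.n_obs for r in records],
            "flags": [";".join(sorted(r.flags)) for r in records],
        }
    )
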