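"""Synthetic inputs with the statistical structure the analyses assume.

Every pipeline stage consumes bench data that the generators here emulate:

* UPLC-MS peak-area tables for the templated screen (log-normal areas,
  triplicate injections, a configurable fraction of artifact members whose
  control peak is barely detectable);
* fluorescence titration matrices from the speciation forward model with
  Gaussian species spectra and additive detector noise;
* multi-concentration two-state SPR sensorgrams;
* anti-Xa hydrolysis time courses with exponential-progress kinetics
  sampled at the assay schedule 5/10/15/20/30/50/80/120 min.

Default parameter scales mirror the screening conditions the analyses were
designed for: 1 mM building blocks against ~17-18 mM heparin repeating
units in the screen, 10 uM ligand in titrations, 0.1 IU/mL heparin in the
enzymatic assay.  A single seed in :class:`ScenarioConfig` fixes every
downstream draw, so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chemlib, fluor_fit, spr_kinetics
from .speciation import BindingModel
from .sublib_design import DesignReport, design_sublibraries

__all__ = [
    "ScenarioConfig",
    "TitrationScenario",
    "SprScenario",
    "FxaScenario",
    "default_scenario",
    "gen_peak_tables",
    "gen_titration_data",
    "gen_sensorgrams",
    "gen_hydrolysis_data",
    "ground_truth_manifest",
]


def _gaussian_band(wl: np.ndarray, center: float, width: float,
                   height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((wl - center) / width) ** 2)


@dataclass(frozen=True)
class TitrationScenario:
    """Forward-model settings for the fluorescence titration generator."""

    l_tot: float = 1e-5  # M (10 uM ligand)
    max_equivalents: float = 5.0
    n_points: int = 50
    noise_sd: float = 0.0  # intensity units; peak signal is ~1e6 below
    # Constants are anchored at K1 = 2e6 M^-1 (K_D^app 0.5 uM) and chosen
    # so every postulated complex is appreciably populated over the 0-5
    # equivalent window at 10 uM ligand (peak ligand fractions ~0.5/0.76/
    # 0.45 for LH/LH2/L2H): the precondition for the titration to carry
    # information on all three formation constants.
    log_betas: Mapping[Tuple[int, int], float] = field(
        default_factory=lambda: {(1, 1): 6.301, (1, 2): 11.3, (2, 1): 11.8}
    )
    # 1 nm step: the usual emission-scan resolution of a fluorimeter
    wavelengths: Tuple[float, ...] = tuple(np.arange(290.0, 390.0, 1.0))

    def model(self) -> BindingModel:
        return BindingModel.from_dict(dict(self.log_betas))

    def spectra(self) -> Dict[str, np.ndarray]:
        """Quench/recovery spectral shapes.

        Bright free ligand; strongly quenched LH (residual monomer-like
        band); strongly quenched L2H with a weak red-shifted excimer-like
        band, as expected for stacked chromophores; partially emissive LH2.
        No two species share an exactly proportional spectrum, mirroring
        real complexes.
        """
        wl = np.asarray(self.wavelengths)
        bright = _gaussian_band(wl, 307.0, 18.0, 1e11)
        return {
            "L": bright,
            "L1H1": 0.02 * bright,
            "L2H1": 0.05 * _gaussian_band(wl, 330.0, 22.0, 1e11),
            "L1H2": 0.40 * _gaussian_band(wl, 310.0, 20.0, 1e11),
        }

    def schedule(self) -> Tuple[np.ndarray, np.ndarray]:
        eq = np.linspace(0.0, self.max_equivalents, self.n_points)
        return np.full(self.n_points, self.l_tot), eq * self.l_tot


@dataclass(frozen=True)
class SprScenario:
    """Two-state sensorgram generator settings."""

    params: spr_kinetics.TwoStateParams = field(
        default_factory=lambda: spr_kinetics.TwoStateParams(
            ka1=1e5, kd1=0.1, ka2=0.01, kd2=0.01, rmax=100.0
        )
    )
    concs: Tuple[float, ...] = (5e-8, 5e-7, 5e-6)  # 0.1x/1x/10x kd_app
    t_assoc: float = 600.0
    t_dissoc: float = 600.0
    dt: float = 2.0
    noise_sd: float = 0.0  # RU


@dataclass(frozen=True)
class FxaScenario:
    """Exponential-progress hydrolysis kinetics per assay condition.

    ``rate_constants`` maps condition ids to first-order progress constants
    k (min^-1): pct(t) = 100 (1 - exp(-k t)).  The defaults encode the
    potency ordering seen across the screen, with the heparin-only control
    slowest and the no-heparin control fastest.
    """

    rate_constants: Mapping[str, float] = field(
        default_factory=lambda: {
            "no_heparin": 0.030,
            "heparin_only": 0.001,
            "3AL": 0.004,
            "3AG": 0.005,
            "3AF": 0.008,
            "3FF": 0.012,
            "3AC": 0.018,
        }
    )
    ligand_conc: float = 1e-6  # M
    heparin_iu_per_ml: float = 0.1
    schedule_min: Tuple[float, ...] = tuple(
        float(t) for t in (5, 10, 15, 20, 30, 50, 80, 120)
    )
    noise_cv: float = 0.0  # multiplicative area noise per peak
    substrate_area: float = 1000.0  # arbitrary units at t=0
    is_area: float = 400.0


@dataclass(frozen=True)
class ScenarioConfig:
    """One reproducible end-to-end synthetic study."""

    seed: int = 0
    true_afs: Mapping[str, float] = field(default_factory=dict)
    baseline_af: float = 1.0
    replicate_cv: float = 0.10
    injection_drift_cv: float = 0.0  # common per-injection scale factor
    n_replicates: int = 3
    a0_floor_frac: float = 0.01
    zero_control_members: Tuple[str, ...] = ()
    control_area: float = 100.0
    degeneracy_tol: float = 0.02
    max_sublib_size: int = 6
    titration: TitrationScenario = field(default_factory=TitrationScenario)
    spr: SprScenario = field(default_factory=SprScenario)
    fxa: FxaScenario = field(default_factory=FxaScenario)


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """Default study: the full registry screen with a handful of binders.

    The amplified members and their AF ordering follow the screening
    outcome the pipeline is meant to resolve (3AC strongest, then 3FF,
    then the moderate ortho-phenol/naphthol combinations around 1.5-3).
    """
    true_afs = {
        "3AC": 4.0,
        "3FF": 3.5,
        "3AF": 2.5,
        "3AG": 2.0,
        "3AL": 1.5,
    }
    return ScenarioConfig(seed=seed, true_afs=true_afs)


def _rng_for(cfg: ScenarioConfig, stream: str) -> np.random.Generator:
    # hash() is salted per process; derive the stream id deterministically
    ss = np.random.SeedSequence(
        [cfg.seed, sum(ord(c) for c in stream), len(stream)]
    )
    return np.random.default_rng(ss)


def gen_peak_tables(
    cfg: ScenarioConfig,
    design: Optional[DesignReport] = None,
    blocks: Optional[Mapping[str, chemlib.BuildingBlock]] = None,
) -> pd.DataFrame:
    """Long peak table (member, sublibrary, replicate, condition, area).

    Control areas are log-normal around ``control_area`` with coefficient
    of variation ``replicate_cv``; templated areas are the member's control
    area times its true AF times independent log-normal noise.  Members in
    ``zero_control_members`` get a near-zero control level to exercise the
    artifact filter downstream.

    ``injection_drift_cv`` adds a common log-normal scale factor per
    injection (sublibrary x replicate x condition), the volume/detector
    drift that per-injection total-area normalization is meant to cancel.
    Note the generator does not conserve total material across conditions
    (templated areas are scaled member-wise), so AF recovery against this
    table is exact with normalization off; normalization trades a small
    redistribution bias for immunity to drift.
    """
    blocks = blocks if blocks is not None else chemlib.default_blocks()
    core, alds = chemlib.split_registry(blocks)
    if design is None:
        design = design_sublibraries(
            alds, core, tol=cfg.degeneracy_tol, max_size=cfg.max_sublib_size
        )
    rng = _rng_for(cfg, "peaks")
    sigma = np.sqrt(np.log1p(cfg.replicate_cv**2))
    sigma_inj = (
        np.sqrt(np.log1p(cfg.injection_drift_cv**2))
        if cfg.injection_drift_cv > 0
        else 0.0
    )
    rows = []
    for sub in design.sublibraries:
        for rep in range(1, cfg.n_replicates + 1):
            drift = {
                cond: (np.exp(rng.normal(0.0, sigma_inj)) if sigma_inj else 1.0)
                for cond in ("control", "templated")
            }
            for member in sub.members:
                true_af = cfg.true_afs.get(member.id, cfg.baseline_af)
                base = cfg.control_area
                if member.id in cfg.zero_control_members:
                    base = cfg.control_area * 1e-6
                noise_c = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                noise_t = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                a0 = base * noise_c * drift["control"]
                at = base * true_af * noise_t * drift["templated"]
                rows.append((member.id, sub.id, rep, "control", a0))
                rows.append((member.id, sub.id, rep, "templated", at))
    return pd.DataFrame(
        rows,
        columns=["member_id", "sublibrary_id", "replicate", "condition", "area"],
    )


def gen_titration_data(cfg: ScenarioConfig) -> fluor_fit.TitrationDataset:
    """Fluorescence titration from the speciation forward model."""
    sc = cfg.titration
    l_tots, h_tots = sc.schedule()
    rng = _rng_for(cfg, "titration") if sc.noise_sd > 0 else None
    return fluor_fit.simulate_titration(
        sc.model(),
        sc.spectra(),
        np.asarray(sc.wavelengths),
        l_tots,
        h_tots,
        noise_sd=sc.noise_sd,
        rng=rng,
        meta={"excitation_nm": 280.0, "buffer": "1 mM Bis-Tris pH 7.5"},
    )


def gen_sensorgrams(cfg: ScenarioConfig) -> List[spr_kinetics.Sensorgram]:
    """One two-state sensorgram per configured analyte concentration."""
    sc = cfg.spr
    rng = _rng_for(cfg, "spr") if sc.noise_sd > 0 else None
    out = []
    for i, conc in enumerate(sc.concs):
        out.append(
            spr_kinetics.simulate_two_state(
                sc.params,
                conc,
                sc.t_assoc,
                sc.t_dissoc,
                sc.dt,
                noise_sd=sc.noise_sd,
                rng=rng,
                series_id=f"s{i + 1}",
            )
        )
    return out


def gen_hydrolysis_data(cfg: ScenarioConfig) -> pd.DataFrame:
    """Anti-Xa time courses, one condition block per configured ligand.

    Progress follows pct(t) = 100 (1 - exp(-k t)); peak areas are split
    between the cleaved and substrate peaks so that the percent-hydrolysis
    reduction recovers the curve exactly at zero noise, with optional
    multiplicative log-normal noise per peak.
    """
    sc = cfg.fxa
    rng = _rng_for(cfg, "fxa")
    sigma = np.sqrt(np.log1p(sc.noise_cv**2)) if sc.noise_cv > 0 else 0.0
    rows = []
    for cond, k in sc.rate_constants.items():
        if k < 0:
            raise ValueError(f"negative rate constant for {cond}")
        heparin = 0.0 if cond == "no_heparin" else sc.heparin_iu_per_ml
        lig_conc = sc.ligand_conc if cond.startswith("3") else 0.0
        for t in sc.schedule_min:
            pct = 100.0 * (1.0 - np.exp(-k * t))
            ac = sc.substrate_area * pct / 100.0
            asub = sc.substrate_area - ac
            ais = sc.is_area
            if sigma > 0:
                ac *= np.exp(rng.normal(0.0, sigma))
                asub *= np.exp(rng.normal(0.0, sigma))
                ais *= np.exp(rng.normal(0.0, sigma))
            rows.append(
                (cond, cond if lig_conc else "", lig_conc, heparin,
                 t, ac, asub, ais)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "condition_id", "ligand", "ligand_conc_M", "heparin_IU_per_mL",
            "t_min", "area_cleaved", "area_substrate", "area_is",
        ],
    )


def ground_truth_manifest(cfg: ScenarioConfig) -> Dict[str, object]:
    """Ground-truth parameters behind the generated files, for recovery tests."""
    sc = cfg.titration
    return {
        "seed": cfg.seed,
        "true_afs": dict(cfg.true_afs),
        "baseline_af": cfg.baseline_af,
        "replicate_cv": cfg.replicate_cv,
        "injection_drift_cv": cfg.injection_drift_cv,
        "zero_control_members": list(cfg.zero_control_members),
        "titration_log_betas": {
            f"{l}:{h}": b for (l, h), b in sc.log_betas.items()
        },
        "titration_noise_sd": sc.noise_sd,
        "spr_params": {
            "ka1": cfg.spr.params.ka1,
            "kd1": cfg.spr.params.kd1,
            "ka2": cfg.spr.params.ka2,
            "kd2": cfg.spr.params.kd2,
            "rmax": cfg.spr.params.rmax,
            "kd_app": cfg.spr.params.kd_app,
        },
        "spr_concs": list(cfg.spr.concs),
        "fxa_rate_constants": dict(cfg.fxa.rate_constants),
    }


def with_noise(
    cfg: ScenarioConfig,
    titration_noise_sd: Optional[float] = None,
    spr_noise_sd: Optional[float] = None,
    fxa_noise_cv: Optional[float] = None,
) -> ScenarioConfig:
    """Copy of the scenario with selected noise levels replaced."""
    out = cfg
    if titration_noise_sd is not None:
        out = replace(out, titration=replace(out.titration,
                                             noise_sd=titration_noise_sd))
    if spr_noise_sd is not None:
        out = replace(out, spr=replace(out.spr, noise_sd=spr_noise_sd))
    if fxa_noise_cv is not None:
        out = replace(out, fxa=replace(out.fxa, noise_cv=fxa_noise_cv))
    return out
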