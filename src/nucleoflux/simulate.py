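"""Synthetic plate generator with known ground truth.

The generator emulates the statistical structure of chromosomal
position-effect reporter experiments in E. coli:

* logistic batch growth with a lag phase, an optional intermediate lag
  after a medium switch, and a 1:200 inoculum;
* growth-phase promoter programs: a *fis*-like pulse at the onset of
  exponential growth, *hns*-like constitutive expression with a slight
  late rise, and a *dps*-like program induced at the transition to
  stationary phase, transiently active during an intermediate lag, and
  inducible by an H2O2 pulse that terminates ~40 min after treatment;
* replication-associated gene dosage: an origin-to-terminus copy-number
  gradient 2^(c·(1-x)·mu(t)/mu_max) that is maximal in fast exponential
  growth and vanishes in stationary phase;
* genotype- and position-specific expression multipliers, lognormal
  between-replicate fluctuation in the HU-deficient (hupA/B) background,
  and repression of a module by an active upstream operon;
* a plate-reader measurement model: blank offset on OD, autofluorescence
  proportional to biomass, a dark-count offset and Gaussian noise on both
  channels, plus medium-only blank wells and non-fluorescent background
  wells.

Every rendered plate carries a truth record (true biomass, true reporter
amount and true per-biomass activity per well) so each pipeline stage can
be tested against known ground truth.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

from nucleoflux.errors import ValidationError
from nucleoflux.plate_io import LayoutEntry, PlateLayout, WellSeries

#: relative origin->terminus coordinate of the named insertion positions
POSITION_REL = {
    "OL": 0.1, "OR": 0.1,
    "ML": 0.5, "MLup": 0.5, "MR": 0.5, "ara": 0.5,
    "TL": 0.9, "TR": 0.9,
    "native": 0.4, "none": 0.0,
}

_FINE_DT = 0.25  # minutes, internal integration step


@dataclass
class IntermediateLag:
    """Growth pause triggered when the culture first reaches ``start_od``."""
    start_od: float
    duration_min: float


@dataclass
class GrowthParams:
    """Batch-growth parameters of one plate.

    Logistic growth at specific rate ``mu_max`` toward ``od_capacity``
    starts after ``lag_min`` minutes; the inoculum is 1:200 of capacity.
    ``od_blank_offset`` is the medium/plate absorbance added to every well.
    """
    lag_min: float = 60.0
    mu_max: float = 0.02            # 1/min, ~35 min doubling time
    od_capacity: float = 0.5
    intermediate_lag: Optional[IntermediateLag] = None
    od_blank_offset: float = 0.04

    def __post_init__(self) -> None:
        if min(self.lag_min, self.mu_max, self.od_capacity,
               self.od_blank_offset) < 0:
            raise ValidationError("growth parameters must be nonnegative")
        if self.od_capacity <= 0:
            raise ValidationError("od_capacity must be > 0")
        il = self.intermediate_lag
        if il is not None and not il.start_od < self.od_capacity:
            raise ValidationError("intermediate_lag.start_od must be below "
                                  "od_capacity")


@dataclass
class PromoterProgram:
    """Growth-phase expression program of one promoter module.

    ``base_rate`` is the per-biomass synthesis rate (fluorescence units per
    absorbance unit per minute) that the archetype gains multiply.

    Archetypes
    ----------
    fis
        Pulse of ``onset_gain`` for ``onset_window_min`` minutes from the
        onset of exponential growth, ``floor_gain`` otherwise.
    hns
        Constitutive (gain 1) with a rise of up to ``late_rise`` as growth
        slows toward stationary phase.
    dps
        ``floor_gain`` during fast growth, rising to ``stat_gain`` as the
        growth rate falls (stationary induction); ``lag_boost`` is added
        during an intermediate lag and ``pulse_gain`` during the
        ``pulse_duration`` minutes following an H2O2 treatment.
    piecewise
        Explicit piecewise-constant gain: ``segments`` is a list of
        ``(t_start_min, gain)`` pairs; gain is 0 before the first segment.
    """
    archetype: str = "dps"
    base_rate: float = 50.0
    onset_window_min: float = 150.0
    onset_gain: float = 1.0
    floor_gain: float = 0.05
    late_rise: float = 0.3
    stat_gain: float = 1.0
    lag_boost: float = 0.5
    pulse_gain: float = 5.0
    pulse_duration: float = 40.0
    segments: Optional[list] = None

    def __post_init__(self) -> None:
        if self.archetype not in ("fis", "hns", "dps", "piecewise"):
            raise ValidationError(f"unknown archetype {self.archetype!r}")
        if self.archetype == "piecewise" and not self.segments:
            raise ValidationError("piecewise archetype requires segments")
        for v in (self.base_rate, self.onset_gain, self.floor_gain,
                  self.late_rise, self.stat_gain, self.lag_boost,
                  self.pulse_gain):
            if v < 0:
                raise ValidationError("program gains must be >= 0")


@dataclass
class PositionEffect:
    """Chromosomal-position modifiers of a module's expression.

    ``rel_position`` runs from 0 at the replication origin to 1 at the
    terminus; the replication-associated copy-number multiplier is
    ``2^(dosage_coeff * (1 - rel_position) * mu(t)/mu_max)``.
    ``genotype_multiplier`` is a static position- and genotype-specific
    factor (1 in wild type); ``replicate_cv`` is the coefficient of
    variation of a mean-one lognormal factor drawn once per well
    (between-replicate fluctuation of the HU-deficient background);
    ``upstream_coupling`` multiplies activity while a configured upstream
    operon is transcribed.
    """
    rel_position: float = 0.5
    dosage_coeff: float = 1.0
    genotype_multiplier: float = 1.0
    replicate_cv: float = 0.0
    upstream_coupling: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rel_position <= 1.0:
            raise ValidationError("rel_position must lie in [0, 1]")
        if self.dosage_coeff < 0 or self.replicate_cv < 0:
            raise ValidationError("dosage_coeff and replicate_cv must be >= 0")
        if self.genotype_multiplier <= 0 or self.upstream_coupling <= 0:
            raise ValidationError("multipliers must be > 0")


@dataclass
class NoiseParams:
    od_sd: float = 0.003
    f_sd: float = 5.0
    autofluor_per_od: float = 150.0
    f_offset: float = 20.0          # instrument dark counts


@dataclass
class Grid:
    t_end_min: float = 1380.0       # 23 h
    dt_min: float = 10.0

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.t_end_min + 0.5 * self.dt_min, self.dt_min)


@dataclass
class WellSpec:
    """One well of a scenario: layout entry plus its generative model."""
    well_id: str
    role: str = "sample"
    genotype: str = "wildtype"
    module: str = "Pdps"
    position: str = "none"
    medium: str = "M9"
    replicate: int = 1
    program: Optional[PromoterProgram] = None
    effect: Optional[PositionEffect] = None
    upstream_active: bool = False

    def layout_entry(self) -> LayoutEntry:
        return LayoutEntry(self.role, self.genotype, self.module,
                           self.position, self.medium, self.replicate)


@dataclass
class ScenarioConfig:
    """Full parameterization of one simulated plate."""
    growth: GrowthParams = field(default_factory=GrowthParams)
    wells: list[WellSpec] = field(default_factory=list)
    noise: NoiseParams = field(default_factory=NoiseParams)
    fluor_gain: float = 1.0
    seed: int = 0
    grid: Grid = field(default_factory=Grid)
    treat_time: Optional[float] = None
    name: str = ""

    def replace(self, **kw) -> "ScenarioConfig":
        new = copy.deepcopy(self)
        for k, v in kw.items():
            setattr(new, k, v)
        return new


@dataclass
class GrowthCurve:
    """Biomass trajectory on a fine internal grid with samplers."""
    t: np.ndarray
    od: np.ndarray
    mu: np.ndarray
    t_growth_start: float
    intermediate_interval: Optional[tuple[float, float]]

    def od_at(self, tq: np.ndarray) -> np.ndarray:
        return np.interp(tq, self.t, self.od)

    def mu_at(self, tq: np.ndarray) -> np.ndarray:
        return np.interp(tq, self.t, self.mu)


def simulate_growth(g: GrowthParams, grid: Grid) -> GrowthCurve:
    """Integrate the growth model over the plate's time span.

    Logistic growth after the lag phase from an inoculum of
    ``od_capacity / 200``; while an intermediate lag is active the growth
    rate is zero.  Integration uses a fixed fine step so the measurement
    cadence does not affect the trajectory.
    """
    tf = np.arange(0.0, grid.t_end_min + _FINE_DT, _FINE_DT)
    od = np.empty_like(tf)
    mu = np.zeros_like(tf)
    cur = g.od_capacity / 200.0
    il = g.intermediate_lag
    pause_until = -np.inf
    triggered = False
    interval = None
    for i, ti in enumerate(tf):
        od[i] = cur
        if il is not None and not triggered and cur >= il.start_od:
            triggered = True
            pause_until = ti + il.duration_min
            interval = (ti, pause_until)
        if ti < g.lag_min or ti < pause_until:
            m = 0.0
        else:
            m = g.mu_max * max(0.0, 1.0 - cur / g.od_capacity)
        mu[i] = m
        cur = cur + m * cur * _FINE_DT
    return GrowthCurve(tf, od, mu, g.lag_min, interval)


def _phase_gain(prog: PromoterProgram, curve: GrowthCurve, mu_max: float,
                treat_time: Optional[float]) -> np.ndarray:
    """Archetype gain profile on the curve's fine grid."""
    t = curve.t
    rel_mu = curve.mu / mu_max if mu_max > 0 else np.zeros_like(curve.mu)
    if prog.archetype == "fis":
        onset = (t >= curve.t_growth_start) & \
                (t < curve.t_growth_start + prog.onset_window_min)
        gain = np.where(onset, prog.onset_gain, prog.floor_gain)
    elif prog.archetype == "hns":
        gain = 1.0 + prog.late_rise * (1.0 - rel_mu)
    elif prog.archetype == "dps":
        gain = prog.floor_gain + prog.stat_gain * (1.0 - rel_mu)
        if curve.intermediate_interval is not None:
            a, b = curve.intermediate_interval
            gain = gain + np.where((t >= a) & (t < b), prog.lag_boost, 0.0)
        if treat_time is not None:
            pulse = (t >= treat_time) & (t < treat_time + prog.pulse_duration)
            gain = gain + np.where(pulse, prog.pulse_gain, 0.0)
    else:  # piecewise
        gain = np.zeros_like(t)
        for t_start, g_val in sorted(prog.segments):
            gain = np.where(t >= t_start, g_val, gain)
    return gain


@dataclass
class ReporterTruth:
    """True reporter trajectory of one well on the fine grid."""
    t: np.ndarray
    f_true: np.ndarray
    activity: np.ndarray            # per-biomass synthesis rate a(t)
    rep_multiplier: float

    def f_at(self, tq: np.ndarray) -> np.ndarray:
        return np.interp(tq, self.t, self.f_true)

    def a_at(self, tq: np.ndarray) -> np.ndarray:
        return np.interp(tq, self.t, self.activity)


def simulate_reporter(curve: GrowthCurve, program: PromoterProgram,
                      effect: PositionEffect, mu_max: float,
                      treat_time: Optional[float] = None,
                      upstream_active: bool = False,
                      rep_multiplier: float = 1.0) -> ReporterTruth:
    """Accumulated reporter amount driven by a per-biomass activity.

    dF/dt = a(t) * OD(t) with
    a(t) = base_rate * archetype gain * 2^(c (1-x) mu/mu_max)
           * genotype_multiplier * replicate factor * upstream coupling.
    The reporter is stable (no decay or maturation delay).
    """
    rel_mu = curve.mu / mu_max if mu_max > 0 else np.zeros_like(curve.mu)
    dosage = 2.0 ** (effect.dosage_coeff * (1.0 - effect.rel_position) * rel_mu)
    a = (program.base_rate * _phase_gain(program, curve, mu_max, treat_time)
         * dosage * effect.genotype_multiplier * rep_multiplier)
    if upstream_active:
        a = a * effect.upstream_coupling
    f = cumulative_trapezoid(a * curve.od, curve.t, initial=0.0)
    return ReporterTruth(curve.t, f, a, rep_multiplier)


def _replicate_factor(cv: float, rng: np.random.Generator) -> float:
    """Mean-one lognormal factor with coefficient of variation ``cv``."""
    if cv <= 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def render_plate(cfg: ScenarioConfig):
    """Render a scenario into measured wells, a layout and a truth record.

    Measurement model per time point:
    ``od_raw = OD_true + od_blank_offset + N(0, od_sd)`` and
    ``fluor_raw = fluor_gain * F_true + autofluor_per_od * OD_true
    + f_offset + N(0, f_sd)``, clipped at zero (readers report
    nonnegative counts).  Blank wells contain medium only; background
    wells grow but carry no reporter.  Identical configs (same seed)
    render bit-identical plates.

    Returns
    -------
    (wells, layout, truth) where truth maps well_id -> dict with the
    true OD, true reporter amount, true activity a(t) (sampled on the
    measurement grid) and the replicate factor.
    """
    rng = np.random.default_rng(cfg.seed)
    curve = simulate_growth(cfg.growth, cfg.grid)
    tq = cfg.grid.times
    od_true_grid = curve.od_at(tq)
    nz = cfg.noise

    wells: dict[str, WellSeries] = {}
    entries: dict[str, LayoutEntry] = {}
    truth: dict[str, dict] = {}
    for spec in sorted(cfg.wells, key=lambda w: w.well_id):
        entries[spec.well_id] = spec.layout_entry()
        if spec.role == "blank":
            od_t = np.zeros_like(tq)
            f_t = np.zeros_like(tq)
            a_t = np.zeros_like(tq)
            rep = 1.0
        elif spec.role == "background":
            od_t = od_true_grid
            f_t = np.zeros_like(tq)
            a_t = np.zeros_like(tq)
            rep = 1.0
        else:
            prog = spec.program or PromoterProgram()
            eff = spec.effect or PositionEffect(
                rel_position=POSITION_REL.get(spec.position, 0.5))
            rep = _replicate_factor(eff.replicate_cv, rng)
            rt = simulate_reporter(curve, prog, eff, cfg.growth.mu_max,
                                   treat_time=cfg.treat_time,
                                   upstream_active=spec.upstream_active,
                                   rep_multiplier=rep)
            od_t = od_true_grid
            f_t = rt.f_at(tq)
            a_t = rt.a_at(tq)
        od_raw = od_t + cfg.growth.od_blank_offset + rng.normal(0, nz.od_sd, tq.size)
        f_raw = (cfg.fluor_gain * f_t + nz.autofluor_per_od * od_t
                 + nz.f_offset + rng.normal(0, nz.f_sd, tq.size))
        wells[spec.well_id] = WellSeries(
            spec.well_id, tq, np.clip(od_raw, 0.0, None),
            np.clip(f_raw, 0.0, None))
        truth[spec.well_id] = {"od_true": od_t, "f_true": f_t,
                               "activity": a_t, "rep_multiplier": rep}
    return wells, PlateLayout(entries), truth


# ---------------------------------------------------------------------------
# Packaged scenarios
# ---------------------------------------------------------------------------

SIX_POSITIONS = ("OL", "OR", "ML", "MR", "TL", "TR")

#: qualitative hupA/B position multipliers for the dps module (origin/middle/
#: terminus, left/right): e.g. MR stronger, TR weaker than wild type
HUP_DPS_MULTIPLIERS = {"OL": 1.2, "OR": 0.7, "ML": 1.0, "MR": 1.8,
                       "TL": 0.6, "TR": 0.4}
HUP_HNS_MULTIPLIERS = {"OL": 1.0, "OR": 1.0, "ML": 1.0, "MR": 1.5,
                       "TL": 1.0, "TR": 0.5}

#: between-replicate lognormal CV of the hupA/B background; the strong
#: fluctuation is documented for the dps induction experiments, a milder
#: value is used for the other hupA/B scenarios
HUP_REPLICATE_CV_DPS = 0.4
HUP_REPLICATE_CV_OTHER = 0.1


def _reference_wells() -> list[WellSpec]:
    return [
        WellSpec("A1", role="blank", genotype="none", module="none",
                 position="none"),
        WellSpec("A2", role="blank", genotype="none", module="none",
                 position="none"),
        WellSpec("A3", role="background", genotype="wildtype", module="none",
                 position="none"),
        WellSpec("A4", role="background", genotype="wildtype", module="none",
                 position="none"),
    ]


def _six_position_wells(genotype: str, module: str, program: PromoterProgram,
                        multipliers: dict[str, float] | None = None,
                        replicate_cv: float = 0.0,
                        medium: str = "M9_casamino") -> list[WellSpec]:
    out = []
    for i, pos in enumerate(SIX_POSITIONS):
        eff = PositionEffect(
            rel_position=POSITION_REL[pos],
            genotype_multiplier=(multipliers or {}).get(pos, 1.0),
            replicate_cv=replicate_cv)
        out.append(WellSpec(f"B{i + 1}", genotype=genotype, module=module,
                            position=pos, medium=medium,
                            program=copy.deepcopy(program), effect=eff))
    return out


def build_study_scenarios() -> dict[str, ScenarioConfig]:
    """Named scenarios mirroring the study's experimental designs.

    * ``wt_dps`` / ``hup_dps`` — the six-position dps induction plates
      (H2O2 at 170 min, measured to 340 min); the hupA/B plate carries
      position-specific multipliers and strong replicate fluctuation.
    * ``wt_hns`` / ``hup_hns`` — six-position hns plates over 23 h.
    * ``wt_fis_pair`` / ``hup_fis_pair`` — the fis module at ML and MLup
      (upstream of rrnG); in the hupA/B mutant MLup expresses 2.5x ML
      (midpoint of the observed 2–3x), in wild type the positions match.
    * ``wt_ara`` / ``hup_ara`` — the dps module downstream of the araBAD
      operon plus an origin-proximal control, with and without arabinose;
      active upstream transcription halves the module's output in the
      hupA/B mutant only.
    * ``wt_dps_casamino`` / ``wt_dps_minimal`` — the media comparison:
      the dps program runs 2.5x stronger in casamino-supplemented medium
      (midpoint of the observed 2–3x), with slightly faster growth and
      higher yield in the richer medium.
    """
    scenarios: dict[str, ScenarioConfig] = {}
    dps = PromoterProgram(archetype="dps", base_rate=50.0)
    hns = PromoterProgram(archetype="hns", base_rate=10.0)
    fis = PromoterProgram(archetype="fis", base_rate=30.0)
    growth = GrowthParams()  # M9 casamino-like defaults
    induction_grid = Grid(t_end_min=340.0, dt_min=10.0)
    full_grid = Grid(t_end_min=1380.0, dt_min=10.0)

    scenarios["wt_dps"] = ScenarioConfig(
        name="wt_dps", growth=copy.deepcopy(growth), grid=induction_grid,
        treat_time=170.0,
        wells=_reference_wells() + _six_position_wells("wildtype", "Pdps", dps))
    scenarios["hup_dps"] = ScenarioConfig(
        name="hup_dps", growth=copy.deepcopy(growth), grid=induction_grid,
        treat_time=170.0,
        wells=_reference_wells() + _six_position_wells(
            "hupAB", "Pdps", dps, HUP_DPS_MULTIPLIERS, HUP_REPLICATE_CV_DPS))

    scenarios["wt_hns"] = ScenarioConfig(
        name="wt_hns", growth=copy.deepcopy(growth), grid=full_grid,
        wells=_reference_wells() + _six_position_wells("wildtype", "Phns", hns))
    scenarios["hup_hns"] = ScenarioConfig(
        name="hup_hns", growth=copy.deepcopy(growth), grid=full_grid,
        wells=_reference_wells() + _six_position_wells(
            "hupAB", "Phns", hns, HUP_HNS_MULTIPLIERS,
            HUP_REPLICATE_CV_OTHER))

    def fis_pair(genotype: str, mlup_mult: float, cv: float) -> list[WellSpec]:
        return [
            WellSpec("B1", genotype=genotype, module="Pfis", position="ML",
                     program=copy.deepcopy(fis),
                     effect=PositionEffect(rel_position=POSITION_REL["ML"],
                                           replicate_cv=cv)),
            WellSpec("B2", genotype=genotype, module="Pfis", position="MLup",
                     program=copy.deepcopy(fis),
                     effect=PositionEffect(rel_position=POSITION_REL["MLup"],
                                           genotype_multiplier=mlup_mult,
                                           replicate_cv=cv)),
        ]

    scenarios["wt_fis_pair"] = ScenarioConfig(
        name="wt_fis_pair", growth=copy.deepcopy(growth), grid=full_grid,
        wells=_reference_wells() + fis_pair("wildtype", 1.0, 0.0))
    scenarios["hup_fis_pair"] = ScenarioConfig(
        name="hup_fis_pair", growth=copy.deepcopy(growth), grid=full_grid,
        wells=_reference_wells() + fis_pair("hupAB", 2.5,
                                            HUP_REPLICATE_CV_OTHER))

    def ara_wells(genotype: str, coupling: float, cv: float) -> list[WellSpec]:
        out = []
        wid = iter(["B1", "B2", "B3", "B4"])
        for medium, active in (("M9", False), ("M9_ara", True)):
            out.append(WellSpec(
                next(wid), genotype=genotype, module="Pdps", position="ara",
                medium=medium, program=copy.deepcopy(dps),
                effect=PositionEffect(rel_position=POSITION_REL["ara"],
                                      upstream_coupling=coupling,
                                      replicate_cv=cv),
                upstream_active=active))
            out.append(WellSpec(
                next(wid), genotype=genotype, module="Pdps", position="OR",
                medium=medium, program=copy.deepcopy(dps),
                effect=PositionEffect(rel_position=POSITION_REL["OR"],
                                      replicate_cv=cv)))
        return out

    scenarios["wt_ara"] = ScenarioConfig(
        name="wt_ara", growth=copy.deepcopy(growth), grid=full_grid,
        wells=_reference_wells() + ara_wells("wildtype", 1.0, 0.0))
    scenarios["hup_ara"] = ScenarioConfig(
        name="hup_ara", growth=copy.deepcopy(growth), grid=full_grid,
        wells=_reference_wells() + ara_wells("hupAB", 0.5,
                                             HUP_REPLICATE_CV_OTHER))

    dps_minimal = copy.deepcopy(dps)
    dps_minimal.base_rate = dps.base_rate / 2.5
    scenarios["wt_dps_casamino"] = ScenarioConfig(
        name="wt_dps_casamino",
        growth=GrowthParams(lag_min=60.0, mu_max=0.023, od_capacity=0.55),
        grid=full_grid,
        wells=_reference_wells() + _six_position_wells(
            "wildtype", "Pdps", dps, medium="M9_casamino"))
    scenarios["wt_dps_minimal"] = ScenarioConfig(
        name="wt_dps_minimal",
        growth=GrowthParams(lag_min=60.0, mu_max=0.020, od_capacity=0.45),
        grid=full_grid,
        wells=_reference_wells() + _six_position_wells(
            "wildtype", "Pdps", dps_minimal, medium="M9"))
    return scenarios


# ---------------------------------------------------------------------------
# YAML (de)serialization of scenarios
# ---------------------------------------------------------------------------

def scenario_to_dict(cfg: ScenarioConfig) -> dict:
    d = asdict(cfg)
    return d


def scenario_from_dict(d: dict) -> ScenarioConfig:
    d = copy.deepcopy(d)
    g = d.pop("growth", {})
    il = g.pop("intermediate_lag", None)
    growth = GrowthParams(**g,
                          intermediate_lag=IntermediateLag(**il) if il else None)
    wells = []
    for w in d.pop("wells", []):
        prog = w.pop("program", None)
        eff = w.pop("effect", None)
        wells.append(WellSpec(
            **w,
            program=PromoterProgram(**prog) if prog else None,
            effect=PositionEffect(**eff) if eff else None))
    noise = NoiseParams(**d.pop("noise", {}))
    grid = Grid(**d.pop("grid", {}))
    return ScenarioConfig(growth=growth, wells=wells, noise=noise,
                          grid=grid, **d)
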