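"""Pipeline orchestration: ingest -> correct -> kinetics -> induction.

``run_pipeline`` composes the analysis stages over one plate and collects
the per-well result tables plus a run manifest that echoes every parameter,
so a run can be reproduced bit-for-bit.  ``compare_groups`` summarizes
result bundles by genotype, medium or position, using the stationary-phase
end-point statistic (mean F/OD over the final 60 min of unmasked data).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from nucleoflux import plate_io
from nucleoflux.correction import (DEFAULT_OD_EPSILON, ExpressionSeries,
                                   correct_plate, expression_table)
from nucleoflux.errors import NucleofluxError, ValidationError
from nucleoflux.induction import plate_induction_table
from nucleoflux.kinetics import (activity_table, promoter_activity,
                                 synthesis_rate, synthesis_table,
                                 DEFAULT_MARGIN_MIN)
from nucleoflux.plate_io import PlateLayout, WellSeries

logger = logging.getLogger("nucleoflux")

ENDPOINT_WINDOW_MIN = 60.0


@dataclass
class RunConfig:
    """Validated parameters of one pipeline run."""
    od_epsilon: float = DEFAULT_OD_EPSILON
    n_interior: Optional[int] = None
    margin_min: float = DEFAULT_MARGIN_MIN
    t_treat: Optional[float] = None
    window: float = 40.0
    dialect: str = "long"
    out_dir: Optional[str] = None
    seed: Optional[int] = None
    log_level: str = "INFO"
    clamp_negative_f: bool = True

    def __post_init__(self) -> None:
        if self.od_epsilon <= 0:
            raise ValidationError("od_epsilon must be > 0")
        if self.margin_min < 0 or self.window <= 0:
            raise ValidationError("margin_min must be >= 0 and window > 0")
        if self.dialect not in ("long", "wide"):
            raise ValidationError("dialect must be 'long' or 'wide'")
        if self.n_interior is not None and self.n_interior < 0:
            raise ValidationError("n_interior must be >= 0")

    def as_manifest(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ResultBundle:
    """All tables produced from one plate."""
    expression: pd.DataFrame
    activity: pd.DataFrame
    synthesis: pd.DataFrame
    response: Optional[pd.DataFrame]
    manifest: dict
    exprs: dict[str, ExpressionSeries] = field(default_factory=dict, repr=False)
    layout: Optional[PlateLayout] = field(default=None, repr=False)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {"expression": self.expression, "activity": self.activity,
               "synthesis": self.synthesis}
        if self.response is not None:
            out["response"] = self.response
        return out


def _stage(name: str, well: str = ""):
    suffix = f" (well {well})" if well else ""
    return f"pipeline stage '{name}'{suffix}"


def run_pipeline(plate: str | Path | Mapping[str, WellSeries],
                 layout: str | Path | PlateLayout,
                 cfg: RunConfig | None = None) -> ResultBundle:
    """Run the full analysis over one plate.

    ``plate`` and ``layout`` may be file paths or in-memory objects (as
    produced by :func:`nucleoflux.simulate.render_plate`).  The response
    table is computed only when ``cfg.t_treat`` is set.  Any stage error
    is re-raised annotated with the stage name and well id.
    """
    cfg = cfg or RunConfig()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    warn_log: list[str] = []

    try:
        if not isinstance(plate, Mapping):
            plate = plate_io.read_plate(plate, dialect=cfg.dialect)
        if not isinstance(layout, PlateLayout):
            layout = plate_io.read_layout(layout)
    except NucleofluxError as exc:
        raise type(exc)(f"{_stage('ingest')}: {exc}") from exc

    try:
        exprs = correct_plate(plate, layout, od_epsilon=cfg.od_epsilon,
                              clamp_negative_f=cfg.clamp_negative_f)
    except NucleofluxError as exc:
        raise type(exc)(f"{_stage('correction')}: {exc}") from exc

    activities, syntheses = {}, {}
    for wid, e in exprs.items():
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                activities[wid] = promoter_activity(e)
                syntheses[wid] = synthesis_rate(e, n_interior=cfg.n_interior,
                                                margin_min=cfg.margin_min)
            for w in wlist:
                warn_log.append(str(w.message))
                logger.warning("%s", w.message)
        except NucleofluxError as exc:
            raise type(exc)(f"{_stage('kinetics', wid)}: {exc}") from exc

    response = None
    if cfg.t_treat is not None:
        try:
            response = plate_induction_table(exprs, layout,
                                             t_treat=cfg.t_treat,
                                             window=cfg.window)
        except NucleofluxError as exc:
            raise type(exc)(f"{_stage('induction')}: {exc}") from exc

    masked = {wid: int((~e.mask).sum()) for wid, e in exprs.items()}
    manifest = {"config": cfg.as_manifest(), "n_wells": len(exprs),
                "masked_points": masked, "warnings": warn_log,
                "version": __import__("nucleoflux").__version__}
    bundle = ResultBundle(expression_table(exprs), activity_table(activities),
                          synthesis_table(syntheses), response, manifest,
                          exprs=exprs, layout=layout)
    if cfg.out_dir:
        plate_io.write_results(bundle.tables(), cfg.out_dir, manifest)
    return bundle


# ---------------------------------------------------------------------------
# Summary statistics over expression series
# ---------------------------------------------------------------------------

def endpoint_fod(expr: ExpressionSeries,
                 window_min: float = ENDPOINT_WINDOW_MIN) -> float:
    """Stationary-phase end point: mean F/OD over the last unmasked window."""
    if not expr.mask.any():
        return float("nan")
    t_last = expr.time_min[expr.mask][-1]
    sel = expr.mask & (expr.time_min >= t_last - window_min)
    return float(np.nanmean(expr.fod[sel]))


def exponential_phase_mask(expr: ExpressionSeries, lo_frac: float = 0.1,
                           hi_frac: float = 0.5) -> np.ndarray:
    """Points where corrected OD lies between fractions of its maximum.

    A pragmatic exponential-phase gate: biomass above ``lo_frac`` of the
    plateau (clear of early noise) and below ``hi_frac`` (before growth
    slows toward stationary phase).
    """
    od_max = np.nanmax(np.where(expr.mask, expr.od_corr, np.nan))
    return expr.mask & (expr.od_corr >= lo_frac * od_max) & \
        (expr.od_corr <= hi_frac * od_max)


def mean_exponential_fod(expr: ExpressionSeries) -> float:
    sel = exponential_phase_mask(expr)
    if not sel.any():
        return float("nan")
    return float(np.nanmean(expr.fod[sel]))


def expression_ratio(bundle: ResultBundle, selector_a, selector_b,
                     phase: str = "exponential") -> float:
    """Ratio of mean F/OD between two well groups of one bundle.

    ``selector_a``/``selector_b`` are predicates over layout entries (or
    position-name strings).  ``phase`` is ``"exponential"`` (mean over the
    exponential-phase gate) or ``"endpoint"`` (stationary end point).
    """
    if bundle.layout is None:
        raise ValidationError("bundle carries no layout")

    def as_pred(sel):
        if callable(sel):
            return sel
        return lambda e: e.position == sel

    stat = mean_exponential_fod if phase == "exponential" else endpoint_fod
    vals = {}
    for label, pred in (("a", as_pred(selector_a)), ("b", as_pred(selector_b))):
        wells = [w for w, e in bundle.layout.entries.items()
                 if e.role == "sample" and pred(e) and w in bundle.exprs]
        if not wells:
            raise ValidationError(f"selector {label!r} matches no sample well")
        vals[label] = float(np.mean([stat(bundle.exprs[w]) for w in wells]))
    return vals["a"] / vals["b"]


def compare_groups(bundles: list[ResultBundle],
                   grouping: str = "genotype") -> pd.DataFrame:
    """Per-group mean/sd of end-point F/OD and of response fractions.

    ``grouping`` is a layout field: genotype, medium or position.
    """
    if grouping not in ("genotype", "medium", "position"):
        raise ValidationError("grouping must be genotype, medium or position")
    if not bundles:
        raise ValidationError("need at least one result bundle")
    rows = []
    for i, b in enumerate(bundles):
        if b.layout is None:
            raise ValidationError("bundle carries no layout")
        resp = b.response.set_index("well_id") if b.response is not None \
            else None
        for wid, e in b.layout.entries.items():
            if e.role != "sample" or wid not in b.exprs:
                continue
            frac = np.nan
            if resp is not None and wid in resp.index:
                frac = resp.loc[wid, "fraction_pct"]
            rows.append({"bundle": i, "group": getattr(e, grouping),
                         "endpoint_fod": endpoint_fod(b.exprs[wid]),
                         "fraction_pct": frac})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValidationError("no sample wells found in any bundle")
    agg = df.groupby("group").agg(
        n=("endpoint_fod", "size"),
        endpoint_fod_mean=("endpoint_fod", "mean"),
        endpoint_fod_sd=("endpoint_fod", lambda v: v.std(ddof=1) if len(v) > 1
                         else 0.0),
        fraction_pct_mean=("fraction_pct", "mean"),
        fraction_pct_sd=("fraction_pct", lambda v: v.std(ddof=1) if len(v) > 1
                         else 0.0),
    )
    return agg.reset_index()
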