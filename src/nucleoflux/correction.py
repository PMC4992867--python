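"""Signal correction and per-biomass expression (F/OD).

Optical density is corrected by subtracting the time-matched mean of the
blank (medium-only) wells; fluorescence is corrected by subtracting the
time-matched mean of the background wells, i.e. wells of the
non-fluorescent reference strain, which removes both cellular
autofluorescence and any instrument dark signal.  Expression is then the
ratio F/OD per time point, masked wherever the corrected OD is below a
small threshold (F/OD is numerically meaningless before detectable
growth).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from nucleoflux.errors import CorrectionError, ValidationError
from nucleoflux.plate_io import PlateLayout, WellSeries

DEFAULT_OD_EPSILON = 0.01


@dataclass
class ExpressionSeries:
    """Corrected OD, corrected F and the F/OD expression series of one well.

    ``fod`` is defined (finite) only where ``mask`` is True; masked points
    are NaN.  Wherever the mask is True, ``od_corr >= od_epsilon``.
    """

    well_id: str
    time_min: np.ndarray
    od_corr: np.ndarray
    f_corr: np.ndarray
    fod: np.ndarray
    mask: np.ndarray
    od_epsilon: float = DEFAULT_OD_EPSILON

    def __post_init__(self) -> None:
        n = self.time_min.size
        for name in ("od_corr", "f_corr", "fod", "mask"):
            if getattr(self, name).size != n:
                raise ValidationError(
                    f"well {self.well_id}: {name} length != time length")

    def __len__(self) -> int:
        return self.time_min.size


def _reference_mean(sample: WellSeries, refs: Sequence[WellSeries],
                    attr: str, kind: str) -> np.ndarray:
    if not refs:
        if kind == "background":
            raise CorrectionError(
                "no background wells: the layout must assign role=background "
                "to wells of the non-fluorescent reference strain")
        raise CorrectionError("no blank wells available for OD correction")
    for r in refs:
        if r.time_min.size != sample.time_min.size or \
                not np.allclose(r.time_min, sample.time_min):
            raise CorrectionError(
                f"time grid of {kind} well {r.well_id} does not match "
                f"sample well {sample.well_id}")
    return np.nanmean(np.vstack([getattr(r, attr) for r in refs]), axis=0)


def blank_correct_od(sample: WellSeries,
                     blanks: Sequence[WellSeries]) -> np.ndarray:
    """Subtract the time-matched mean blank OD from the sample OD.

    The result may be negative (noise around zero biomass); downstream
    masking handles that, no clipping happens here.
    """
    return sample.od_raw - _reference_mean(sample, blanks, "od_raw", "blank")


def background_correct_f(sample: WellSeries,
                         backgrounds: Sequence[WellSeries]) -> np.ndarray:
    """Subtract the time-matched mean background fluorescence.

    Backgrounds are wells of the non-fluorescent reference strain grown in
    parallel, so the subtraction removes autofluorescence at the matched
    time point (the reference and sample are assumed to grow alike).
    """
    return sample.fluor_raw - _reference_mean(sample, backgrounds,
                                              "fluor_raw", "background")


def compute_fod(well_id: str, time_min: np.ndarray, od_corr: np.ndarray,
                f_corr: np.ndarray, od_epsilon: float = DEFAULT_OD_EPSILON,
                clamp_negative_f: bool = True) -> ExpressionSeries:
    """Expression F/OD per time point, masked where OD is too small.

    A point is valid when ``od_corr >= od_epsilon`` and both corrected
    signals are finite.  Negative corrected fluorescence is clamped to 0
    before division by default (negative expression is physically
    meaningless); pass ``clamp_negative_f=False`` to keep signed values.
    """
    if od_epsilon <= 0:
        raise ValidationError("od_epsilon must be > 0")
    time_min = np.asarray(time_min, dtype=float)
    od_corr = np.asarray(od_corr, dtype=float)
    f_corr = np.asarray(f_corr, dtype=float).copy()
    if clamp_negative_f:
        f_corr = np.maximum(f_corr, 0.0)
    mask = np.isfinite(od_corr) & np.isfinite(f_corr) & (od_corr >= od_epsilon)
    fod = np.full_like(od_corr, np.nan)
    np.divide(f_corr, od_corr, out=fod, where=mask)
    return ExpressionSeries(well_id, time_min, od_corr, f_corr, fod, mask,
                            od_epsilon=od_epsilon)


def correct_plate(wells: Mapping[str, WellSeries], layout: PlateLayout,
                  od_epsilon: float = DEFAULT_OD_EPSILON,
                  clamp_negative_f: bool = True,
                  include_backgrounds: bool = False,
                  ) -> dict[str, ExpressionSeries]:
    """Correct every sample well of a plate against its blanks/backgrounds."""
    layout.require_correctable()
    missing = [w for w in layout.entries if w not in wells]
    if missing:
        raise ValidationError(f"layout wells absent from plate data: {missing}")
    blanks = [wells[w] for w in layout.blank_wells]
    backgrounds = [wells[w] for w in layout.background_wells]
    targets = list(layout.sample_wells)
    if include_backgrounds:
        targets += layout.background_wells
    out = {}
    for wid in targets:
        s = wells[wid]
        out[wid] = compute_fod(
            wid, s.time_min,
            blank_correct_od(s, blanks),
            background_correct_f(s, backgrounds),
            od_epsilon=od_epsilon, clamp_negative_f=clamp_negative_f)
    return out


def expression_table(exprs: Mapping[str, ExpressionSeries]) -> pd.DataFrame:
    """Long-format expression table (one row per well and time point)."""
    frames = []
    for wid in sorted(exprs):
        e = exprs[wid]
        frames.append(pd.DataFrame({
            "well_id": wid, "time_min": e.time_min, "od_corr": e.od_corr,
            "f_corr": e.f_corr, "fod": e.fod, "mask": e.mask}))
    if not frames:
        return pd.DataFrame(columns=["well_id", "time_min", "od_corr",
                                     "f_corr", "fod", "mask"])
    return pd.concat(frames, ignore_index=True)
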