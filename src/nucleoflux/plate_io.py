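"""Reading, validating and writing plate-reader exports and plate layouts.

Two plate dialects are supported:

* ``long`` — columns ``well_id, time_min, channel, value`` with channel in
  ``{OD, F}``; one row per reading.
* ``wide`` — a single ``time_min`` column plus, per well, a pair of columns
  named ``<well_id>_OD`` and ``<well_id>_F``.

Time is stored in minutes as floats; a reader flag converts from seconds.
Missing single readings are represented as NaN gaps and propagated, never
interpolated.  This module does no numerics beyond validation.
"""

from __future__ import annotations

import dataclasses
import json
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from nucleoflux.errors import PlateFormatError, ValidationError

ROLES = ("blank", "background", "sample")
GENOTYPES = ("wildtype", "hupAB", "hns", "none")
MODULES = ("Pdps", "Phns", "Pfis", "none")
POSITIONS = ("OL", "OR", "ML", "MR", "TL", "TR", "MLup", "ara", "native", "none")

LAYOUT_COLUMNS = ["well_id", "role", "genotype", "module", "position",
                  "medium", "replicate"]


@dataclass
class WellSeries:
    """One well's raw time course.

    Parameters
    ----------
    well_id : str
        Plate coordinate, e.g. ``"B3"``.
    time_min : ndarray
        Strictly increasing time grid in minutes.
    od_raw : ndarray
        Absorbance at 595 nm, >= 0 (NaN marks a missing reading).
    fluor_raw : ndarray
        Fluorescence 485/535 nm in instrument units, >= 0 (NaN allowed).
    """

    well_id: str
    time_min: np.ndarray
    od_raw: np.ndarray
    fluor_raw: np.ndarray

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.od_raw = np.asarray(self.od_raw, dtype=float)
        self.fluor_raw = np.asarray(self.fluor_raw, dtype=float)
        n = self.time_min.size
        if self.od_raw.size != n or self.fluor_raw.size != n:
            raise ValidationError(
                f"well {self.well_id}: time/OD/F lengths differ "
                f"({n}/{self.od_raw.size}/{self.fluor_raw.size})")
        if n and not np.all(np.diff(self.time_min) > 0):
            raise ValidationError(
                f"well {self.well_id}: time grid is not strictly increasing")
        for name, v in (("od_raw", self.od_raw), ("fluor_raw", self.fluor_raw)):
            if np.any(v[np.isfinite(v)] < 0):
                raise ValidationError(
                    f"well {self.well_id}: negative raw values in {name}")

    def __len__(self) -> int:
        return self.time_min.size


@dataclass
class LayoutEntry:
    role: str
    genotype: str
    module: str
    position: str
    medium: str
    replicate: int

    def __post_init__(self) -> None:
        for name, value, allowed in (
            ("role", self.role, ROLES),
            ("genotype", self.genotype, GENOTYPES),
            ("module", self.module, MODULES),
            ("position", self.position, POSITIONS),
        ):
            if value not in allowed:
                raise ValidationError(
                    f"unknown {name} token {value!r}; allowed: "
                    + ", ".join(allowed))
        self.replicate = int(self.replicate)
        if self.replicate < 1:
            raise ValidationError("replicate must be an integer >= 1")
        if self.role == "sample" and self.module == "none":
            raise ValidationError("sample well must carry a promoter module")


@dataclass
class PlateLayout:
    """Map well_id -> role/genotype/module/position/medium/replicate."""

    entries: dict[str, LayoutEntry] = field(default_factory=dict)

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w, e in self.entries.items() if e.role == role]

    @property
    def blank_wells(self) -> list[str]:
        return self.wells_with_role("blank")

    @property
    def background_wells(self) -> list[str]:
        return self.wells_with_role("background")

    @property
    def sample_wells(self) -> list[str]:
        return self.wells_with_role("sample")

    def require_correctable(self) -> None:
        """A plate is correctable only with >= 1 blank and >= 1 background well."""
        if not self.blank_wells:
            raise ValidationError("layout has no blank wells; OD cannot be "
                                  "blank-corrected")
        if not self.background_wells:
            raise ValidationError(
                "layout has no background wells (non-fluorescent reference "
                "strain); add wells with role=background to the layout")

    def __len__(self) -> int:
        return len(self.entries)


def _well_series_from_frame(well_id: str, sub: pd.DataFrame) -> WellSeries:
    piv = sub.pivot_table(index="time_min", columns="channel", values="value",
                          sort=True)
    for ch in ("OD", "F"):
        if ch not in piv.columns:
            raise PlateFormatError(
                f"well {well_id}: missing channel {ch!r} in long-format plate")
    return WellSeries(well_id, piv.index.to_numpy(dtype=float),
                      piv["OD"].to_numpy(dtype=float),
                      piv["F"].to_numpy(dtype=float))


def read_plate(path: str | Path, dialect: str = "long",
               time_unit: str = "min") -> dict[str, WellSeries]:
    """Read a plate-reader CSV export into one :class:`WellSeries` per well.

    Parameters
    ----------
    dialect : {"long", "wide"}
    time_unit : {"min", "s"}
        Input time unit; seconds are converted to minutes on read.
    """
    path = Path(path)
    if not path.exists():
        raise PlateFormatError(f"plate file not found: {path}")
    if time_unit not in ("min", "s"):
        raise ValidationError("time_unit must be 'min' or 's'")
    df = pd.read_csv(path)
    scale = 1.0 / 60.0 if time_unit == "s" else 1.0

    wells: dict[str, WellSeries] = {}
    if dialect == "long":
        required = {"well_id", "time_min", "channel", "value"}
        if not required.issubset(df.columns):
            raise PlateFormatError(
                f"long-format plate requires columns {sorted(required)}; "
                f"found {list(df.columns)}")
        bad = set(df["channel"].unique()) - {"OD", "F"}
        if bad:
            raise PlateFormatError(f"unknown channel token(s): {sorted(bad)}")
        df = df.assign(time_min=df["time_min"] * scale)
        for well_id, sub in df.groupby("well_id", sort=True):
            # duplicated (time, channel) readings are a format defect
            if sub.duplicated(["time_min", "channel"]).any():
                raise ValidationError(
                    f"well {well_id}: time values repeat within a channel")
            wells[str(well_id)] = _well_series_from_frame(str(well_id), sub)
    elif dialect == "wide":
        if "time_min" not in df.columns:
            raise PlateFormatError("wide-format plate requires a 'time_min' column")
        times = df["time_min"].to_numpy(dtype=float) * scale
        if not np.all(np.diff(times) > 0):
            raise ValidationError("wide-format time column is not strictly "
                                  "increasing")
        ids: dict[str, dict[str, str]] = {}
        for col in df.columns:
            if col == "time_min":
                continue
            if col.endswith("_OD") or col.endswith("_F"):
                wid, _, ch = col.rpartition("_")
                ids.setdefault(wid, {})[ch] = col
            else:
                raise PlateFormatError(
                    f"unrecognized wide-format column {col!r}; expected "
                    "'<well_id>_OD' or '<well_id>_F'")
        for wid, chans in sorted(ids.items()):
            for ch in ("OD", "F"):
                if ch not in chans:
                    raise PlateFormatError(
                        f"well {wid}: missing channel {ch} column in "
                        "wide-format plate")
            wells[wid] = WellSeries(
                wid, times,
                df[chans["OD"]].to_numpy(dtype=float),
                df[chans["F"]].to_numpy(dtype=float))
    else:
        raise ValidationError(f"unknown dialect {dialect!r}; use 'long' or 'wide'")

    grids = {tuple(np.round(w.time_min, 9)) for w in wells.values()}
    if len(grids) > 1:
        raise ValidationError("wells of one plate must share a single time grid")
    return wells


def write_plate(wells: Mapping[str, WellSeries], path: str | Path,
                dialect: str = "long") -> Path:
    """Write wells to a plate CSV in the chosen dialect."""
    path = Path(path)
    if dialect == "long":
        rows = []
        for wid in sorted(wells):
            w = wells[wid]
            for ch, v in (("OD", w.od_raw), ("F", w.fluor_raw)):
                rows.append(pd.DataFrame({
                    "well_id": wid, "time_min": w.time_min,
                    "channel": ch, "value": v}))
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    elif dialect == "wide":
        first = next(iter(wells.values()))
        data: dict[str, np.ndarray] = {"time_min": first.time_min}
        for wid in sorted(wells):
            w = wells[wid]
            data[f"{wid}_OD"] = w.od_raw
            data[f"{wid}_F"] = w.fluor_raw
        pd.DataFrame(data).to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    return path


def read_layout(path: str | Path) -> PlateLayout:
    """Read and validate a plate-layout TSV.

    The file must carry the header
    ``well_id  role  genotype  module  position  medium  replicate``.
    """
    path = Path(path)
    if not path.exists():
        raise PlateFormatError(f"layout file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("none")
    missing = set(LAYOUT_COLUMNS) - set(df.columns)
    if missing:
        raise PlateFormatError(f"layout missing columns: {sorted(missing)}")
    if df["well_id"].duplicated().any():
        dups = df.loc[df["well_id"].duplicated(), "well_id"].tolist()
        raise ValidationError(f"duplicate well_id in layout: {dups}")
    entries = {}
    for _, row in df.iterrows():
        entries[row["well_id"]] = LayoutEntry(
            role=row["role"], genotype=row["genotype"], module=row["module"],
            position=row["position"], medium=row["medium"],
            replicate=int(row["replicate"]))
    return PlateLayout(entries)


def write_layout(layout: PlateLayout, path: str | Path) -> Path:
    path = Path(path)
    rows = [{"well_id": wid, **dataclasses.asdict(e)}
            for wid, e in sorted(layout.entries.items())]
    pd.DataFrame(rows, columns=LAYOUT_COLUMNS).to_csv(path, sep="\t",
                                                      index=False)
    return path


RESULT_KINDS = ("expression", "activity", "synthesis", "response")


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  manifest: dict | None = None) -> dict[str, Path]:
    """Write one TSV per result kind plus a JSON run manifest.

    ``tables`` maps a result kind (expression/activity/synthesis/response or
    any other label) to a DataFrame; an empty frame yields a header-only TSV.
    Floats are written with 17 significant digits so a re-read reproduces the
    in-memory values.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    written: dict[str, Path] = {}
    for kind, df in tables.items():
        p = out_dir / f"{kind}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.17g")
        written[kind] = p
    mpath = out_dir / "manifest.json"
    payload = {"created": datetime.datetime.now().isoformat(timespec="seconds"),
               "tables": {k: str(v) for k, v in written.items()}}
    payload.update(manifest or {})
    mpath.write_text(json.dumps(payload, indent=2, default=str))
    written["manifest"] = mpath
    return written
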