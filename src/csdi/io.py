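"""Plain-text file formats: thickness-map grids, subfield CSVs, cohort CSVs.

The thickness-map format is a small self-describing text file — ``#``-prefixed
``key = value`` header lines followed by a whitespace-separated numeric
matrix — standing in for proprietary OCT exports.  Required header keys:
subject, laterality, n_rows, n_cols, row_spacing_mm, col_spacing_mm,
fovea_row, fovea_col; ``observer`` is optional.  Values are serialized at
repr precision so write→read round-trips are bit-exact.

The subfield CSV (columns subject, observer, subfield, area_mm2,
volume_mm3, mean_thickness_um, optionally subfoveal_thickness_um) doubles
as the direct-entry format for users who only hold device-exported subfield
numbers rather than full maps.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import LATERALITIES, SUBFIELD_LABELS, RasterSpec
from .volumetrics import SubfieldSummary, ThicknessMap

_MAP_MAGIC = "csdi thickness map v1"
_REQUIRED_KEYS = (
    "subject",
    "laterality",
    "n_rows",
    "n_cols",
    "row_spacing_mm",
    "col_spacing_mm",
    "fovea_row",
    "fovea_col",
)


def write_thickness_map(path, tmap: ThicknessMap) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {_MAP_MAGIC}\n")
        fh.write(f"# subject = {tmap.subject_id}\n")
        if tmap.observer_id is not None:
            fh.write(f"# observer = {tmap.observer_id}\n")
        fh.write(f"# laterality = {tmap.laterality}\n")
        fh.write(f"# n_rows = {tmap.raster.n_rows}\n")
        fh.write(f"# n_cols = {tmap.raster.n_cols}\n")
        fh.write(f"# row_spacing_mm = {tmap.raster.row_spacing_mm!r}\n")
        fh.write(f"# col_spacing_mm = {tmap.raster.col_spacing_mm!r}\n")
        fh.write(f"# fovea_row = {tmap.raster.fovea_row!r}\n")
        fh.write(f"# fovea_col = {tmap.raster.fovea_col!r}\n")
        np.savetxt(fh, tmap.values, fmt="%.17g")


def read_thickness_map(path, laterality: str | None = None) -> ThicknessMap:
    """Parse a thickness-map grid file.

    ``laterality`` overrides the header value when given (the CLI exposes
    this).  Errors carry the offending line number or header field.
    """
    path = Path(path)
    header: dict[str, str] = {}
    data_lines: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    header[key.strip()] = value.strip()
                continue
            data_lines.append((lineno, line))

    missing = [k for k in _REQUIRED_KEYS if k not in header]
    if missing:
        raise ValueError(
            f"{path.name}: header missing required field(s): {', '.join(missing)}"
        )
    lat = laterality if laterality is not None else header["laterality"]
    if lat not in LATERALITIES:
        raise ValueError(f"{path.name}: laterality must be one of {LATERALITIES}, got {lat!r}")
    try:
        raster = RasterSpec(
            n_rows=int(header["n_rows"]),
            n_cols=int(header["n_cols"]),
            row_spacing_mm=float(header["row_spacing_mm"]),
            col_spacing_mm=float(header["col_spacing_mm"]),
            fovea_row=float(header["fovea_row"]),
            fovea_col=float(header["fovea_col"]),
        )
    except ValueError as e:
        raise ValueError(f"{path.name}: invalid raster header: {e}") from e

    rows = []
    for lineno, line in data_lines:
        try:
            rows.append([float(tok) for tok in line.split()])
        except ValueError as e:
            raise ValueError(f"{path.name}:{lineno}: non-numeric cell: {e}") from e
    values = np.array(rows, dtype=float)
    if values.shape != raster.shape:
        raise ValueError(
            f"{path.name}: matrix shape {values.shape} does not match header "
            f"({raster.n_rows}, {raster.n_cols})"
        )
    return ThicknessMap(
        values=values,
        raster=raster,
        laterality=lat,
        subject_id=header["subject"],
        observer_id=header.get("observer"),
    )


def write_subfield_table(path, summaries: list[SubfieldSummary]) -> None:
    frames = [s.to_frame() for s in summaries]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_subfield_table(path) -> list[SubfieldSummary]:
    """Read a per-subfield CSV into one summary per (subject, observer).

    Requires the nine subfield rows per measurement; checks the
    volume ≈ mean_thickness × area / 1000 identity when all three columns
    are present (warns above 1% relative violation).
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject", "subfield", "volume_mm3"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path.name}: missing columns: {', '.join(sorted(missing_cols))}")
    if "observer" not in df.columns:
        df["observer"] = ""
    df["observer"] = df["observer"].fillna("")

    summaries = []
    for (subject, observer), g in df.groupby(["subject", "observer"], sort=False):
        labels = list(g["subfield"])
        dup = {s for s in labels if labels.count(s) > 1}
        if dup:
            raise ValueError(
                f"{path.name}: duplicate subfield rows for subject {subject!r}: "
                + ", ".join(sorted(dup))
            )
        absent = [s for s in SUBFIELD_LABELS if s not in labels]
        if absent:
            raise ValueError(
                f"{path.name}: subject {subject!r} missing subfield(s): "
                + ", ".join(absent)
            )
        g = g.set_index("subfield")
        volume = {s: float(g.loc[s, "volume_mm3"]) for s in SUBFIELD_LABELS}
        has_area = "area_mm2" in g.columns and g["area_mm2"].notna().all()
        has_mean = "mean_thickness_um" in g.columns and g["mean_thickness_um"].notna().all()
        area = (
            {s: float(g.loc[s, "area_mm2"]) for s in SUBFIELD_LABELS}
            if has_area
            else None
        )
        mean = (
            {s: float(g.loc[s, "mean_thickness_um"]) for s in SUBFIELD_LABELS}
            if has_mean
            else None
        )
        if area is None and mean is None:
            raise ValueError(
                f"{path.name}: subject {subject!r} needs area_mm2 and/or "
                "mean_thickness_um alongside volume_mm3"
            )
        if area is None:
            area = {s: 1e3 * volume[s] / mean[s] for s in SUBFIELD_LABELS}
        if mean is None:
            mean = {s: 1e3 * volume[s] / area[s] for s in SUBFIELD_LABELS}
        elif has_area:
            for s in SUBFIELD_LABELS:
                implied = mean[s] * area[s] * 1e-3
                if volume[s] > 0 and abs(implied - volume[s]) / volume[s] > 0.01:
                    warnings.warn(
                        f"{path.name}: subject {subject!r} subfield {s}: "
                        f"mean×area/1000 = {implied:.4g} differs from volume "
                        f"{volume[s]:.4g} by >1%",
                        RuntimeWarning,
                        stacklevel=2,
                    )
        subfoveal = None
        if "subfoveal_thickness_um" in g.columns:
            vals = g["subfoveal_thickness_um"].dropna()
            if len(vals):
                subfoveal = float(vals.iloc[0])
        lat = "OD"
        if "laterality" in g.columns and g["laterality"].notna().any():
            lat = str(g["laterality"].dropna().iloc[0])
        summaries.append(
            SubfieldSummary(
                volume_mm3=volume,
                mean_thickness_um=mean,
                area_mm2=area,
                subfoveal_thickness_um=subfoveal,
                subject_id=str(subject),
                observer_id=str(observer) if observer != "" else None,
                laterality=lat,
            )
        )
    return summaries


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject" not in df.columns:
        raise ValueError(f"{Path(path).name}: cohort table needs a 'subject' column")
    return df


def load_config(path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{Path(path).name}: config must be a key-value mapping")
    return cfg
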