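"""Verification reports: achieved vs. modelled concentrations, fill tables,
underfill ranges, and voxel activity-map export.

These are the "did the filled phantom realise the model?" products: a
fill-fraction table per compartment and scan in concise notation, a
deviation report with an agreement flag per entry and a mean ± SD
summary, the underfill range per compartment, and a digital ground-truth
activity map (MBq/mL per voxel) on the phantom grid.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import AlignmentError, MappingError, ParameterError
from .uvalue import UValue, format_concise, parse_concise

__all__ = [
    "FillReport",
    "UnderfillRange",
    "deviation_report",
    "underfill_range",
    "fill_table",
    "parse_fill_table",
    "export_activity_map",
    "write_activity_map_nifti",
    "load_reference_fill_fractions",
    "load_calibration_phantoms",
]


def load_reference_fill_fractions() -> pd.DataFrame:
    """Packaged reference fill-fraction table (long form).

    Columns: compartment, stl_volume_mL, scan, fraction (percent),
    fraction_u.  Transcribed design/measurement values of the printed
    phantom as shipped with the package.
    """
    ref = importlib.resources.files("phantomforge.data") / "fill_fractions.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    parsed = df["fill_fraction_pct"].map(parse_concise)
    df["fraction"] = [p.value for p in parsed]
    df["fraction_u"] = [p.u for p in parsed]
    return df.drop(columns=["fill_fraction_pct"])


def load_calibration_phantoms() -> dict:
    """Packaged calibration-phantom design values, concise strings parsed."""
    ref = importlib.resources.files("phantomforge.data") / "calibration_phantoms.yaml"
    raw = yaml.safe_load(ref.read_text())
    out = yaml.safe_load(ref.read_text())
    out["jaszczak"]["activity_MBq"] = parse_concise(
        str(raw["jaszczak"]["activity_MBq"]))
    nema = out["nema_iec_body"]
    nema["stock_concentration_MBq_per_mL"] = parse_concise(
        str(raw["nema_iec_body"]["stock_concentration_MBq_per_mL"]))
    nema["sphere_volumes_mL"] = [parse_concise(str(s))
                                 for s in raw["nema_iec_body"]["sphere_volumes_mL"]]
    return out


# ---------------------------------------------------------------------------
# deviation from model
# ---------------------------------------------------------------------------

@dataclass
class FillReport:
    """Per-(compartment, scan) deviations plus recomputable summary."""

    rows: pd.DataFrame           # compartment, scan, achieved, achieved_u,
                                 # model, deviation_pct, deviation_u, agrees
    mean_deviation: UValue       # percent; u = sample SD (SE optional)
    coverage_factor: float

    def summary_text(self) -> str:
        return (f"mean deviation from model "
                f"{format_concise(self.mean_deviation)}% over "
                f"{len(self.rows)} entries")


def deviation_report(achieved: pd.DataFrame, model: pd.DataFrame,
                     coverage_factor: float = 2.0,
                     summary_uncertainty: str = "sd") -> FillReport:
    """Compare achieved concentrations against the model.

    Both tables are long-form with columns (compartment, scan, value[,
    u]); keys must match 1:1.  Per entry the percent deviation is
    100·(achieved − model)/model with uncertainty scaled from the
    achieved value's u; the agreement flag tests |deviation| against
    ``coverage_factor`` × its uncertainty.  The summary mean carries the
    sample standard deviation of the deviations (``summary_uncertainty=
    "se"`` switches to the standard error of the mean).
    """
    def keyed(df, what):
        need = {"compartment", "scan", "value"}
        if not need <= set(df.columns):
            raise AlignmentError(f"{what} table needs columns {sorted(need)}")
        return df.set_index(["compartment", "scan"]).sort_index()

    a = keyed(achieved, "achieved")
    m = keyed(model, "model")
    missing_in_model = sorted(set(a.index) - set(m.index))
    missing_in_achieved = sorted(set(m.index) - set(a.index))
    if missing_in_model or missing_in_achieved:
        raise AlignmentError(
            "achieved/model keys differ; "
            f"missing in model: {missing_in_model}; "
            f"missing in achieved: {missing_in_achieved}"
        )
    model_vals = m.loc[a.index, "value"].to_numpy(dtype=float)
    if np.any(model_vals == 0):
        raise ParameterError("model concentrations must be nonzero")
    ach_vals = a["value"].to_numpy(dtype=float)
    ach_u = (a["u"].to_numpy(dtype=float) if "u" in a.columns
             else np.zeros(len(a)))
    dev = 100.0 * (ach_vals - model_vals) / model_vals
    dev_u = 100.0 * ach_u / np.abs(model_vals)
    agrees = np.abs(dev) <= coverage_factor * dev_u
    rows = pd.DataFrame({
        "compartment": [k[0] for k in a.index],
        "scan": [k[1] for k in a.index],
        "achieved": ach_vals,
        "achieved_u": ach_u,
        "model": model_vals,
        "deviation_pct": dev,
        "deviation_u": dev_u,
        "agrees": agrees,
    })
    mean = float(np.mean(dev))
    sd = float(np.std(dev, ddof=1)) if len(dev) > 1 else 0.0
    if summary_uncertainty == "se":
        sd = sd / math.sqrt(len(dev))
    elif summary_uncertainty != "sd":
        raise ParameterError("summary_uncertainty must be 'sd' or 'se'")
    return FillReport(rows=rows, mean_deviation=UValue(mean, sd, "%"),
                      coverage_factor=coverage_factor)


# ---------------------------------------------------------------------------
# underfill range
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnderfillRange:
    """(min, max) underfill in percent; overfilled scans listed separately."""

    min_pct: float
    max_pct: float
    overfills_pct: tuple = ()

    def __iter__(self):
        return iter((self.min_pct, self.max_pct))

    def __eq__(self, other):
        if isinstance(other, tuple):
            return (self.min_pct, self.max_pct) == other
        return (isinstance(other, UnderfillRange)
                and (self.min_pct, self.max_pct, self.overfills_pct)
                == (other.min_pct, other.max_pct, other.overfills_pct))


def _round2(x: float) -> float:
    """Round half-even to 2 decimals."""
    return float(np.round(x, 2))


def underfill_range(fill_fractions_pct) -> UnderfillRange:
    """Range of underfill (100 − fill fraction, %) over a compartment's scans.

    Overfills (fill fraction > 100%) are excluded from the range and
    reported separately as positive overfill percentages.
    """
    vals = [float(v) for v in fill_fractions_pct]
    if not vals:
        raise ParameterError("underfill_range needs at least one fill fraction")
    under = [100.0 - v for v in vals]
    kept = [u for u in under if u >= 0]
    over = tuple(_round2(-u) for u in under if u < 0)
    if not kept:
        return UnderfillRange(math.nan, math.nan, over)
    return UnderfillRange(_round2(min(kept)), _round2(max(kept)), over)


# ---------------------------------------------------------------------------
# fill-fraction table
# ---------------------------------------------------------------------------

def fill_table(fractions: pd.DataFrame) -> tuple[pd.DataFrame, str]:
    """Pivot long-form fill fractions into a design-volume × scan table.

    Input columns: compartment, stl_volume_mL, scan, fraction,
    fraction_u.  Returns the pivoted DataFrame (cells are concise
    strings) and its fixed-width text rendering.  Compartment sets must
    be consistent across scans.
    """
    need = {"compartment", "stl_volume_mL", "scan", "fraction", "fraction_u"}
    if not need <= set(fractions.columns):
        raise AlignmentError(f"fill table needs columns {sorted(need)}")
    if fractions.empty:
        raise AlignmentError("fill table input is empty")
    scans = sorted(fractions["scan"].unique())
    by_scan = {s: set(fractions.loc[fractions["scan"] == s, "compartment"])
               for s in scans}
    ref = by_scan[scans[0]]
    bad = {s: sorted(ref ^ comps) for s, comps in by_scan.items() if comps != ref}
    if bad:
        raise AlignmentError(f"inconsistent compartments across scans: {bad}")

    order = fractions.drop_duplicates("compartment")["compartment"].tolist()
    vol = fractions.drop_duplicates("compartment").set_index("compartment")[
        "stl_volume_mL"]
    cells = {}
    for s in scans:
        sub = fractions[fractions["scan"] == s].set_index("compartment")
        cells[f"scan {s}"] = [
            format_concise(UValue(sub.loc[c, "fraction"],
                                  sub.loc[c, "fraction_u"]))
            for c in order
        ]
    table = pd.DataFrame(cells, index=order)
    table.insert(0, "STL volume (mL)", [f"{vol[c]:g}" for c in order])
    table.index.name = "compartment"

    widths = [max(len(str(table.index.name)),
                  max(len(str(i)) for i in table.index))]
    for col in table.columns:
        widths.append(max(len(col), max(len(v) for v in table[col])))
    header = "  ".join(
        name.ljust(w) for name, w in zip([table.index.name, *table.columns],
                                         widths))
    lines = [header, "-" * len(header)]
    for idx, row in table.iterrows():
        lines.append("  ".join(str(v).ljust(w)
                               for v, w in zip([idx, *row.tolist()], widths)))
    return table, "\n".join(lines)


def parse_fill_table(text: str) -> pd.DataFrame:
    """Invert :func:`fill_table`'s text rendering back to long form."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("  ")
    header = [h.strip() for h in header if h.strip()]
    scan_cols = [h for h in header if h.startswith("scan ")]
    rows = []
    for ln in lines[2:]:
        parts = [p.strip() for p in ln.split("  ") if p.strip()]
        comp, vol, *cells = parts
        for col, cell in zip(scan_cols, cells):
            u = parse_concise(cell)
            rows.append({
                "compartment": comp,
                "stl_volume_mL": float(vol),
                "scan": int(col.split()[1]),
                "fraction": u.value,
                "fraction_u": u.u,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# activity map
# ---------------------------------------------------------------------------

def export_activity_map(phantom, concentrations: dict[str, float]) -> np.ndarray:
    """Paint per-role concentrations (MBq/mL) onto the phantom's voxel grid.

    ``concentrations`` maps compartment roles (the body housing accepts
    either "body" or "background") to MBq/mL.  Every labelled
    compartment must have a concentration; voxels outside the phantom
    are zero.  Total activity is conserved by construction: the sum of
    voxel values × voxel volume equals Σ concentration × compartment
    voxel volume.
    """
    conc = dict(concentrations)
    if "background" in conc and "body" not in conc:
        conc["body"] = conc.pop("background")
    out = np.zeros(phantom.shape, dtype=np.float64)
    missing = []
    for lab, organ in phantom.organ_table.items():
        key = organ.role if organ.role in conc else organ.name
        if key not in conc:
            if phantom.voxel_count(lab):
                missing.append(organ.role if organ.role != "other"
                               else organ.name)
            continue
        out[phantom.labels == lab] = conc[key]
    if missing:
        raise MappingError(
            f"no concentration for compartment(s): {sorted(set(missing))}"
        )
    return out


def write_activity_map_nifti(path, phantom, activity_map: np.ndarray):
    """Write an activity map (or mask) as NIfTI with mm spacing metadata."""
    import nibabel as nib

    affine = np.diag([*phantom.spacing, 1.0])
    affine[:3, 3] = 0.5 * np.asarray(phantom.spacing)  # voxel-center origin
    img = nib.Nifti1Image(np.asarray(activity_map, dtype=np.float32), affine)
    img.header.set_zooms(phantom.spacing)
    img.header.set_xyzt_units(xyz="mm")
    nib.save(img, str(path))
    return Path(path)
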