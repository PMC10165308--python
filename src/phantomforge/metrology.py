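"""Dispensing plans, gravimetric volumes and uncertainty bookkeeping.

The physical phantom is filled so that each compartment's activity
concentration at the (estimated) scan start time matches the
pharmacokinetic schedule.  The dispensing protocol per compartment:

1. draw 110% of the activity required at dispensing time (the scan-time
   requirement decay-corrected back to the bench) from a calibrated
   stock solution whose concentration is traceable to a primary
   activity standard;
2. pre-dilute to ≈105% of the compartment volume;
3. top up with diluent until the solution volume equals the volume at
   which the concentration is exactly on-model — 110% of the compartment
   volume — to within 0.01 mL;
4. dispense exactly one compartment volume; the 10% surplus stays in the
   beaker.

Dispensed volumes are measured gravimetrically (weight full − weight
empty, divided by the solution density); each balance reading carries a
rectangular-distribution standard uncertainty of readability/√12, and
uncertainties combine in first-order quadrature throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import (
    FeasibilityError,
    IncompleteRecordError,
    MeasurementError,
    ParameterError,
)
from .pk import decay_correct, decay_factor
from .uvalue import UValue, format_concise, parse_concise

__all__ = [
    "StockCalibration",
    "DispenseRecord",
    "FillFraction",
    "plan_dispense",
    "complete_record",
    "gravimetric_volume",
    "fill_fraction",
    "achieved_concentration",
    "UValue",
    "format_concise",
    "parse_concise",
    "DEFAULT_SOLUTION_DENSITY_G_PER_ML",
    "DEFAULT_ASSAY_REL_U",
    "DRAW_FACTOR",
    "PREDILUTION_FACTOR",
    "TOPUP_TOLERANCE_ML",
]

#: Density of the dilute HCl carrier solution (g/mL); within 0.1% of water.
DEFAULT_SOLUTION_DENSITY_G_PER_ML = 1.000

#: Default relative standard uncertainty of the calibrator assay.
DEFAULT_ASSAY_REL_U = 0.03

#: Activity surplus drawn per compartment.
DRAW_FACTOR = 1.10
#: Pre-dilution volume as a fraction of the compartment volume.
PREDILUTION_FACTOR = 1.05
#: Tolerance on the final solution volume (mL).
TOPUP_TOLERANCE_ML = 0.01


@dataclass(frozen=True)
class StockCalibration:
    """Stock-solution activity concentration at a reference time.

    ``concentration`` is a UValue in MBq/mL; ``reference_time_h`` is on
    the same clock as scan/dispense times; ``traceability`` is a free
    note (e.g. the primary standard the calibrator factor links to).
    """

    concentration: UValue
    reference_time_h: float = 0.0
    traceability: str = ""

    def __post_init__(self):
        if self.concentration.value <= 0:
            raise ParameterError("stock concentration must be positive")

    def concentration_at(self, time_h: float, half_life_h: float) -> UValue:
        f = decay_factor(time_h - self.reference_time_h, half_life_h)
        return self.concentration.scaled(f)


@dataclass
class DispenseRecord:
    """One compartment's filling plan and (once weighed) achieved state."""

    compartment: str
    target_concentration_MBq_mL: float   # at scan time
    stl_volume_mL: float
    half_life_h: float
    scan_time_h: float
    dispense_time_h: float
    # planned quantities
    required_MBq_at_dispense: float
    draw_MBq: float
    stock_draw_mL: float
    predilution_mL: float
    final_solution_mL: UValue            # beaker volume at correct concentration
    assay_rel_u: float = DEFAULT_ASSAY_REL_U
    # measured state (None until the insert is weighed)
    weight_empty_g: float | None = None
    weight_full_g: float | None = None
    readability_g: float | None = None
    density_g_mL: float = DEFAULT_SOLUTION_DENSITY_G_PER_ML
    achieved_MBq_at_scan: UValue | None = None

    @property
    def concentration_at_dispense(self) -> float:
        return self.required_MBq_at_dispense / self.stl_volume_mL

    def dispensed_volume(self) -> UValue:
        """Gravimetric dispensed volume (mL) from the recorded weights."""
        missing = [f for f, v in (("weight_empty_g", self.weight_empty_g),
                                  ("weight_full_g", self.weight_full_g),
                                  ("readability_g", self.readability_g))
                   if v is None]
        if missing:
            raise IncompleteRecordError(
                f"{self.compartment}: record lacks {', '.join(missing)}"
            )
        return gravimetric_volume(self.weight_empty_g, self.weight_full_g,
                                  self.density_g_mL, self.readability_g)


def plan_dispense(target_concentration_MBq_mL: float,
                  compartment_volume_mL: float,
                  stock: StockCalibration,
                  scan_time_h: float,
                  half_life_h: float,
                  dispense_time_h: float | None = None,
                  compartment: str = "",
                  assay_rel_u: float = DEFAULT_ASSAY_REL_U) -> DispenseRecord:
    """Compute the filling plan for one compartment.

    The activity required at scan time (target concentration × volume)
    is decay-corrected back to the dispensing time; 110% of it is drawn
    from the stock, pre-diluted to 105% of the compartment volume and
    topped up to the exactly on-model solution volume (110% of the
    compartment volume) within 0.01 mL.  By construction the planned
    concentration at scan time equals the target exactly.
    """
    if target_concentration_MBq_mL <= 0 or compartment_volume_mL <= 0:
        raise ParameterError("target concentration and volume must be positive")
    if half_life_h <= 0:
        raise ParameterError("half-life must be positive")
    if dispense_time_h is None:
        dispense_time_h = stock.reference_time_h
    if scan_time_h < dispense_time_h:
        raise ParameterError("scan time must not precede dispensing time")

    required_at_scan = target_concentration_MBq_mL * compartment_volume_mL
    required_at_dispense = decay_correct(
        required_at_scan, scan_time_h - dispense_time_h, half_life_h
    )
    draw = DRAW_FACTOR * required_at_dispense
    stock_conc = stock.concentration_at(dispense_time_h, half_life_h).value
    stock_draw = draw / stock_conc
    predilution = PREDILUTION_FACTOR * compartment_volume_mL
    if stock_draw > predilution:
        raise FeasibilityError(
            f"stock concentration {stock_conc:.4g} MBq/mL too low: drawing "
            f"{draw:.4g} MBq needs {stock_draw:.4g} mL, above the "
            f"{predilution:.4g} mL pre-dilution volume"
        )
    final_solution = UValue(DRAW_FACTOR * compartment_volume_mL,
                            TOPUP_TOLERANCE_ML / math.sqrt(3.0), "mL")
    return DispenseRecord(
        compartment=compartment,
        target_concentration_MBq_mL=target_concentration_MBq_mL,
        stl_volume_mL=compartment_volume_mL,
        half_life_h=half_life_h,
        scan_time_h=scan_time_h,
        dispense_time_h=dispense_time_h,
        required_MBq_at_dispense=required_at_dispense,
        draw_MBq=draw,
        stock_draw_mL=stock_draw,
        predilution_mL=predilution,
        final_solution_mL=final_solution,
        assay_rel_u=assay_rel_u,
    )


def complete_record(record: DispenseRecord, weight_empty_g: float,
                    weight_full_g: float, readability_g: float,
                    density_g_mL: float = DEFAULT_SOLUTION_DENSITY_G_PER_ML
                    ) -> DispenseRecord:
    """Attach the weighing of the filled insert and derive the achieved
    activity at scan time.

    The activity in the insert is the dispensed (gravimetric) volume
    times the solution concentration at dispensing, decayed to scan
    time; its uncertainty combines the calibrator assay and the
    gravimetric volume in quadrature.
    """
    rec = replace(record, weight_empty_g=weight_empty_g,
                  weight_full_g=weight_full_g, readability_g=readability_g,
                  density_g_mL=density_g_mL)
    vol = rec.dispensed_volume()
    decay = decay_factor(rec.scan_time_h - rec.dispense_time_h, rec.half_life_h)
    value = rec.concentration_at_dispense * vol.value * decay
    rel = math.hypot(rec.assay_rel_u, vol.rel_u)
    rec.achieved_MBq_at_scan = UValue(value, abs(value) * rel, "MBq")
    return rec


def gravimetric_volume(weight_empty_g: float, weight_full_g: float,
                       density_g_mL: float, readability_g: float) -> UValue:
    """Solution volume from empty/full weights: (w_full − w_empty)/ρ.

    Each reading carries a rectangular standard uncertainty of
    readability/√12; two independent readings give
    u = √2·(readability/√12)/ρ.
    """
    if density_g_mL <= 0:
        raise ParameterError(f"density must be positive, got {density_g_mL}")
    if readability_g < 0:
        raise ParameterError("readability must be >= 0")
    if weight_full_g < weight_empty_g:
        raise MeasurementError(
            f"full weight {weight_full_g} g below empty weight {weight_empty_g} g"
        )
    volume = (weight_full_g - weight_empty_g) / density_g_mL
    u = math.sqrt(2.0) * (readability_g / math.sqrt(12.0)) / density_g_mL
    return UValue(volume, u, "mL")


@dataclass(frozen=True)
class FillFraction:
    """Fill fraction in percent of the design (STL) volume."""

    fraction: UValue
    overfill: bool

    def __str__(self):
        tag = " (overfill)" if self.overfill else ""
        return f"{format_concise(self.fraction)}%{tag}"


def fill_fraction(v_fill: UValue, v_stl_mL: float) -> FillFraction:
    """Dispensed volume as a percentage of the design volume.

    Values above 100% are legitimate (e.g. a cap seating differently
    than modelled) and are flagged as overfill rather than rejected.
    """
    if v_stl_mL <= 0:
        raise ParameterError(f"STL volume must be positive, got {v_stl_mL}")
    frac = v_fill.scaled(100.0 / v_stl_mL, unit="%")
    return FillFraction(fraction=frac, overfill=frac.value > 100.0)


def achieved_concentration(record: DispenseRecord, at_time_h: float | None = None
                           ) -> UValue:
    """Achieved activity concentration (MBq/mL) at a reference time.

    The recorded achieved activity is decay-adjusted from scan time to
    ``at_time_h`` (default: scan time) and divided by the gravimetric
    volume; relative uncertainties combine in quadrature.
    """
    if record.achieved_MBq_at_scan is None:
        # derive on the fly if the weights are present
        missing_ok = all(v is not None for v in (record.weight_empty_g,
                                                 record.weight_full_g,
                                                 record.readability_g))
        if not missing_ok:
            raise IncompleteRecordError(
                f"{record.compartment}: no achieved activity and no weights"
            )
        record = complete_record(record, record.weight_empty_g,
                                 record.weight_full_g, record.readability_g,
                                 record.density_g_mL)
    vol = record.dispensed_volume()
    act = record.achieved_MBq_at_scan
    if at_time_h is not None:
        act = act.scaled(decay_factor(at_time_h - record.scan_time_h,
                                      record.half_life_h))
    value = act.value / vol.value
    rel = math.hypot(act.rel_u, vol.rel_u)
    return UValue(value, abs(value) * rel, "MBq/mL")
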