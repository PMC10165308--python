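"""Linear compartmental pharmacokinetics for a Lu-177 DOTATATE phantom.

The activity to be filled into each phantom compartment follows a linear
compartment model: an administered bolus (default 7.4 GBq) enters a
central rest-of-body compartment and exchanges with kidneys, liver,
spleen and tumour, with irreversible loss to an excreted pool.  The
system

    dA/dt = K A,     A(0) = (A0, 0, …, 0)

is solved by the classical fixed-step fourth-order Runge–Kutta scheme
(default step 1 min, horizon 100 days).  Because the system is linear
and autonomous the four RK4 stages collapse into a constant one-step
propagator

    M = I + hK + (hK)²/2 + (hK)³/6 + (hK)⁴/24,

which is applied step by step; this is algebraically identical to
evaluating k1…k4 each step and keeps the full clinical horizon cheap.

Radioactive decay is handled by solving the *biological* (decay
corrected) kinetics and attaching the physical decay constant: the
physical series is the biological one multiplied by 2^(−t/T½), which is
exactly equivalent to adding λ_phys to every diagonal of K and makes
decay-apply/decay-correct an exact inverse pair.

The kidney model has a single kinetic kidney compartment whose activity
is shared between the four anatomical sub-compartments by volume, with
the medulla concentration fixed at one third of the cortex
concentration; the background (body housing) concentration tracks the
rest-of-body concentration.

The default transfer rates are *illustrative*: the fitted patient rates
behind the published schedule are not public.  They are chosen to give
clinically plausible shapes (fast renal clearance of the central pool,
organ uptake peaking within hours to ~1 day, effective washout
half-lives of tens of hours) and every value can be overridden in the
configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DivergenceError, ParameterError, ValidationError

__all__ = [
    "LU177_HALF_LIFE_H",
    "CompartmentModel",
    "ActivitySchedule",
    "default_pk_config",
    "build_model",
    "solve_rk4",
    "concentrations_at",
    "decay_factor",
    "decay_apply",
    "decay_correct",
    "time_integrated_activity",
    "DEFAULT_TIMEPOINTS_H",
]

#: Lu-177 physical half-life in hours (6.6443 d; external nuclear data).
LU177_HALF_LIFE_H = 6.6443 * 24.0

#: Clinical imaging timepoints (hours post administration).
DEFAULT_TIMEPOINTS_H = (1.0, 4.0, 24.0, 40.0, 72.0, 144.0)

_CENTRAL = "rest_of_body"
_EXCRETED = "excreted"


def default_pk_config() -> dict:
    """Shipped illustrative configuration (all values overridable)."""
    return {
        "administered_MBq": 7400.0,
        "half_life_h": LU177_HALF_LIFE_H,
        "compartments": [_CENTRAL, "kidneys", "liver", "spleen", "tumour",
                         _EXCRETED],
        # h^-1; illustrative, not the unpublished fitted patient values
        "rates_per_h": {
            f"{_CENTRAL}->{_EXCRETED}": 0.14,
            f"{_CENTRAL}->kidneys": 0.006,
            f"{_CENTRAL}->liver": 0.004,
            f"{_CENTRAL}->spleen": 0.0012,
            f"{_CENTRAL}->tumour": 0.0015,
            f"kidneys->{_CENTRAL}": 0.014,
            f"liver->{_CENTRAL}": 0.011,
            f"spleen->{_CENTRAL}": 0.012,
            f"tumour->{_CENTRAL}": 0.006,
        },
        # compartment solution volumes (mL) = design volumes of the shells
        "volumes_mL": {
            "liver": 1306.7,
            "spleen": 124.9,
            "tumour": 15.9,
            "cortex-L": 90.9,
            "cortex-R": 75.7,
            "medulla-L": 42.9,
            "medulla-R": 35.7,
        },
        # distribution volume of the rest-of-body pool (mL); sets the
        # background concentration of the housing
        "background_volume_mL": 60000.0,
        "timepoints_h": list(DEFAULT_TIMEPOINTS_H),
    }


@dataclass(frozen=True)
class CompartmentModel:
    """Validated linear PK system.

    ``K[i, j]`` is the flow *into* compartment i *from* j (h⁻¹); the
    diagonal carries the negative total outflow, so columns sum to zero
    and biological mass is conserved exactly.
    """

    names: tuple[str, ...]
    K: np.ndarray
    administered_MBq: float
    half_life_h: float
    volumes_mL: dict[str, float]
    background_volume_mL: float

    @property
    def lambda_phys_per_h(self) -> float:
        return math.log(2.0) / self.half_life_h

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"unknown compartment {name!r}") from None


def build_model(config: dict | None = None) -> CompartmentModel:
    """Build and validate a :class:`CompartmentModel` from a config dict.

    Unspecified keys fall back to :func:`default_pk_config`.
    """
    cfg = default_pk_config()
    if config:
        for k, v in config.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict) \
                    and k != "rates_per_h":
                # partial overrides of volumes etc. merge ...
                cfg[k] = {**cfg[k], **v}
            else:
                # ... but a user-supplied rate table replaces the default
                cfg[k] = dict(v) if isinstance(v, dict) else v
    names = tuple(cfg["compartments"])
    if _CENTRAL not in names or _EXCRETED not in names:
        raise ValidationError(
            f"compartments must include {_CENTRAL!r} and {_EXCRETED!r}"
        )
    a0 = float(cfg["administered_MBq"])
    if a0 <= 0:
        raise ParameterError(f"administered activity must be > 0, got {a0}")
    t_half = float(cfg["half_life_h"])
    if t_half <= 0:
        raise ParameterError(f"half-life must be > 0, got {t_half}")
    n = len(names)
    K = np.zeros((n, n))
    for key, rate in cfg["rates_per_h"].items():
        src, _, dst = key.partition("->")
        src, dst = src.strip(), dst.strip()
        for c in (src, dst):
            if c not in names:
                raise ValidationError(
                    f"rate {key!r} references unknown compartment {c!r}"
                )
        rate = float(rate)
        if rate < 0:
            raise ParameterError(f"rate {key!r} must be >= 0, got {rate}")
        i, j = names.index(dst), names.index(src)
        K[i, j] += rate
        K[j, j] -= rate
    return CompartmentModel(
        names=names,
        K=K,
        administered_MBq=a0,
        half_life_h=t_half,
        volumes_mL={k: float(v) for k, v in cfg["volumes_mL"].items()},
        background_volume_mL=float(cfg["background_volume_mL"]),
    )


@dataclass
class ActivitySchedule:
    """Solved per-compartment activity on a uniform time grid.

    Activities are stored decay-corrected (biological); the physical
    series is obtained by multiplying with 2^(−t/T½).
    """

    times_h: np.ndarray
    activities_MBq: np.ndarray  # (T, n), biological
    names: tuple[str, ...]
    half_life_h: float
    volumes_mL: dict[str, float]
    background_volume_mL: float

    @property
    def dt_h(self) -> float:
        return float(self.times_h[1] - self.times_h[0])

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"unknown compartment {name!r}") from None

    def activity(self, compartment: str, physical: bool = False) -> np.ndarray:
        a = self.activities_MBq[:, self.index(compartment)]
        if physical:
            a = a * np.exp2(-self.times_h / self.half_life_h)
        return a

    def to_frame(self, physical: bool = False) -> pd.DataFrame:
        """Long-format export: time, compartment, activity."""
        rows = []
        for name in self.names:
            a = self.activity(name, physical=physical)
            rows.append(pd.DataFrame({
                "time_h": self.times_h,
                "compartment": name,
                "activity_MBq": a,
                "series": "physical" if physical else "decay_corrected",
            }))
        return pd.concat(rows, ignore_index=True)


def solve_rk4(model: CompartmentModel, t_end_h: float = 2400.0,
              dt_h: float = 1.0 / 60.0,
              conservation_tol: float = 1e-9) -> ActivitySchedule:
    """Integrate the biological kinetics with classical fixed-step RK4.

    All activity starts in the central compartment.  After integration
    the total (all compartments + excreted) is checked against the
    administered activity at every step to ``conservation_tol`` relative.
    """
    if t_end_h <= 0 or dt_h <= 0:
        raise ParameterError("t_end and dt must be positive")
    if dt_h > t_end_h:
        raise ParameterError(f"dt {dt_h} h exceeds horizon {t_end_h} h")
    n_steps = int(round(t_end_h / dt_h))
    times = np.arange(n_steps + 1) * dt_h
    n = len(model.names)
    hk = dt_h * model.K
    # classical RK4 stage combination for an autonomous linear system
    M = np.eye(n)
    term = np.eye(n)
    for order in (1, 2, 3, 4):
        term = term @ hk / order
        M = M + term
    traj = np.empty((n_steps + 1, n))
    a = np.zeros(n)
    a[model.index(_CENTRAL)] = model.administered_MBq
    traj[0] = a
    for s in range(1, n_steps + 1):
        a = M @ a
        traj[s] = a
    totals = traj.sum(axis=1)
    worst = np.max(np.abs(totals - model.administered_MBq)) / model.administered_MBq
    if worst > conservation_tol:
        raise ValidationError(
            f"biological mass balance violated: max relative drift {worst:.2e}"
        )
    return ActivitySchedule(
        times_h=times,
        activities_MBq=traj,
        names=model.names,
        half_life_h=model.half_life_h,
        volumes_mL=dict(model.volumes_mL),
        background_volume_mL=model.background_volume_mL,
    )


# roles reported by concentrations_at, in output order
_CONC_ROWS = ("liver", "spleen", "tumour", "cortex-L", "cortex-R",
              "medulla-L", "medulla-R", "background")

#: medulla activity concentration as a fraction of the cortex concentration
MEDULLA_CORTEX_RATIO = 1.0 / 3.0


def concentrations_at(schedule: ActivitySchedule, times_h,
                      physical: bool = False) -> pd.DataFrame:
    """Per-compartment activity concentrations (MBq/mL) at requested times.

    Rows: liver, spleen, tumour, left/right cortex, left/right medulla,
    background.  The single kinetic kidney compartment is split by
    volume with the medulla concentration at one third of the cortex
    concentration; left and right cortices share one concentration.  The
    background row is the rest-of-body activity divided by the
    configured background distribution volume.  Values are linearly
    interpolated on the solution grid (grid-point queries reproduce
    stored values exactly).
    """
    times = np.atleast_1d(np.asarray(times_h, dtype=float))
    t0, t1 = schedule.times_h[0], schedule.times_h[-1]
    if times.min() < t0 or times.max() > t1:
        raise ParameterError(
            f"requested times outside solved range [{t0}, {t1}] h"
        )
    vols = schedule.volumes_mL

    def interp(name):
        return np.interp(times, schedule.times_h,
                         schedule.activities_MBq[:, schedule.index(name)])

    # effective kidney volume: cortex counts fully, medulla at 1/3
    v_cortex = vols.get("cortex-L", 0.0) + vols.get("cortex-R", 0.0)
    v_medulla = vols.get("medulla-L", 0.0) + vols.get("medulla-R", 0.0)
    rows = {}
    if "kidneys" in schedule.names and v_cortex > 0:
        c_cortex = interp("kidneys") / (v_cortex + MEDULLA_CORTEX_RATIO * v_medulla)
        rows["cortex-L"] = c_cortex
        rows["cortex-R"] = c_cortex
        rows["medulla-L"] = MEDULLA_CORTEX_RATIO * c_cortex
        rows["medulla-R"] = MEDULLA_CORTEX_RATIO * c_cortex
    for organ in ("liver", "spleen", "tumour"):
        if organ in schedule.names:
            rows[organ] = interp(organ) / vols[organ]
    rows["background"] = interp(_CENTRAL) / schedule.background_volume_mL
    if physical:
        decay = np.exp2(-times / schedule.half_life_h)
        rows = {k: v * decay for k, v in rows.items()}
    index = [r for r in _CONC_ROWS if r in rows]
    df = pd.DataFrame([rows[r] for r in index], index=index, columns=times)
    df.index.name = "compartment"
    df.columns.name = "time_h"
    return df


# ---------------------------------------------------------------------------
# decay bookkeeping
# ---------------------------------------------------------------------------

def decay_factor(dt_h: float, half_life_h: float) -> float:
    """Physical decay factor 2^(−Δt/T½) over an elapsed time Δt."""
    if half_life_h <= 0:
        raise ParameterError(f"half-life must be > 0, got {half_life_h}")
    return 2.0 ** (-dt_h / half_life_h)


def decay_apply(value: float, dt_h: float, half_life_h: float) -> float:
    """Activity after Δt of physical decay."""
    return value * decay_factor(dt_h, half_life_h)


def decay_correct(value: float, dt_h: float, half_life_h: float) -> float:
    """Activity referred back Δt earlier (inverse of :func:`decay_apply`)."""
    return value / decay_factor(dt_h, half_life_h)


def time_integrated_activity(schedule: ActivitySchedule, compartment: str,
                             physical: bool = False,
                             tail_fraction: float = 0.1) -> float:
    """Time-integrated activity (MBq·h): trapezoid over the grid plus an
    analytic mono-exponential tail beyond the horizon.

    The tail rate is fitted log-linearly over the last ``tail_fraction``
    of the solved horizon; under linear kinetics the slowest eigenmode
    dominates there.  Raises :class:`DivergenceError` if the fitted tail
    does not decay.
    """
    a = schedule.activity(compartment, physical=physical)
    t = schedule.times_h
    integral = float(np.trapezoid(a, t))
    a_end = a[-1]
    if a_end <= 0:
        return integral
    i0 = np.searchsorted(t, t[-1] * (1.0 - tail_fraction))
    seg_t, seg_a = t[i0:], a[i0:]
    pos = seg_a > 0
    if pos.sum() < 2:
        return integral
    slope = np.polyfit(seg_t[pos], np.log(seg_a[pos]), 1)[0]
    rate = -slope
    if rate <= 0:
        raise DivergenceError(
            f"{compartment}: tail is non-decaying (fitted rate {rate:.3e}/h); "
            "the time-integrated activity diverges"
        )
    return integral + float(a_end) / rate
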