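"""Local reaction terms and therapy schedules.

Tumor proliferation follows a Gompertz law, d(phi_c)/dt = -r_c phi_c
ln(phi_c/K), where 1/r_c is the intrinsic proliferation timescale and K the
carrying capacity of the biological matrix (normalized to 1: phi_c is a
dimensionless volume fraction, so any other K merely rescales the field).
During therapy each drug j contributes a kill term -eps_pd_j * phi_dj, and
each drug concentration obeys d(phi_dj)/dt = f_j(t) m_d - eps_pk_j phi_dj,
with f_j the 0/1 regimen indicator, m_d the normalized dose rate during an
infusion and eps_pk_j the first-order clearance constant.

Unit policy: everything internal is SI (seconds, metres); constructors
accept clinical units (days, hours) and convert exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

SECONDS_PER_DAY = 86400.0
SECONDS_PER_HOUR = 3600.0

#: default infusion length; with the dose normalization below one infusion
#: delivers exactly one dimensionless dose unit per unit ROI volume.
DEFAULT_INFUSION_HOURS = 1.0

#: dimensionless steady-state tissue concentration maintained during a
#: dosing block under the sustained-exposure model (see solver docs); sets
#: the non-identifiable dose scale so the published eps_PD range spans
#: sub- to supra-therapeutic effects for the published r_c range.
DEFAULT_BLOCK_CONCENTRATION = 0.02

MAX_DRUGS = 3


class KineticsError(ValueError):
    pass


@dataclass(frozen=True)
class DrugParams:
    """Per-drug transport, pharmacodynamic and pharmacokinetic constants.

    ``eps_pk_per_hour`` is accepted in the clinical unit (1/h) and exposed
    in SI via :attr:`eps_pk`.  ``m_d`` is the normalized administered dose
    rate in 1/s; by default one infusion of :data:`DEFAULT_INFUSION_HOURS`
    delivers one dose unit, so the fitted eps_pd absorbs the absolute drug
    mass (eps_pd and m_d enter the tumor equation only through their
    product and are not separately identifiable).
    """

    name: str
    eps_pd: float  # 1/s, pharmacodynamic efficiency
    eps_pk_per_hour: float  # 1/h, clearance
    d_d: float = 1.0e-5  # m^2/s, effective diffusivity
    m_d: float = 1.0 / (DEFAULT_INFUSION_HOURS * SECONDS_PER_HOUR)  # 1/s

    def __post_init__(self) -> None:
        if self.eps_pd < 0 or self.eps_pk_per_hour < 0 or self.d_d < 0 or self.m_d < 0:
            raise KineticsError(f"drug rates must be non-negative: {self}")

    @property
    def eps_pk(self) -> float:
        """Clearance in 1/s (the single hour->second conversion)."""
        return self.eps_pk_per_hour / SECONDS_PER_HOUR

    def with_eps_pd(self, eps_pd: float) -> "DrugParams":
        return DrugParams(self.name, eps_pd, self.eps_pk_per_hour, self.d_d, self.m_d)


@dataclass(frozen=True)
class ModelParams:
    """Whole-model parameter set: growth, transport, and up to 3 drugs."""

    r_c: float  # 1/s, biological conversion rate
    k: float = 1.0  # carrying capacity (dimensionless)
    d_c: float = 1.0e-13  # m^2/s, tumor effective diffusivity
    drugs: tuple[DrugParams, ...] = ()

    def __post_init__(self) -> None:
        if self.r_c <= 0 or self.k <= 0 or self.d_c < 0:
            raise KineticsError(f"require r_c > 0, K > 0, D_c >= 0: {self}")
        if len(self.drugs) > MAX_DRUGS:
            raise KineticsError(f"at most {MAX_DRUGS} drug species supported")
        object.__setattr__(self, "drugs", tuple(self.drugs))

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    def with_r_c(self, r_c: float) -> "ModelParams":
        return ModelParams(r_c, self.k, self.d_c, self.drugs)

    def with_aggregated_eps_pd(self, eps_pd: float) -> "ModelParams":
        """Apply one aggregated pharmacodynamic efficiency to every drug
        channel (the calibration convention)."""
        return ModelParams(
            self.r_c, self.k, self.d_c, tuple(d.with_eps_pd(eps_pd) for d in self.drugs)
        )


@dataclass(frozen=True)
class Pulse:
    start_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class TherapyRegimen:
    """Pulse trains realizing the regimen indicators f_j(t).

    ``schedules[j]`` holds drug j's infusion windows; f_j is 1 on
    [start, end) of each pulse and 0 elsewhere.  ``duration_s`` is the
    therapy span Delta_t_s (end of the last treatment block).
    """

    schedules: tuple[tuple[Pulse, ...], ...]
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise KineticsError("therapy duration must be positive")
        for j, pulses in enumerate(self.schedules):
            srt = sorted(pulses, key=lambda p: p.start_s)
            for a, b in zip(srt, srt[1:]):
                if b.start_s < a.end_s:
                    raise KineticsError(f"overlapping pulses within drug {j}")
            for p in srt:
                if p.start_s < 0 or p.end_s > self.duration_s + 1e-9:
                    raise KineticsError(
                        f"pulse [{p.start_s}, {p.end_s}] s of drug {j} lies outside "
                        f"[0, {self.duration_s}] s"
                    )
            object.__setattr__(
                self,
                "schedules",
                tuple(tuple(sorted(ps, key=lambda p: p.start_s)) for ps in self.schedules),
            )

    @property
    def n_drugs(self) -> int:
        return len(self.schedules)

    @property
    def duration_days(self) -> float:
        return self.duration_s / SECONDS_PER_DAY

    def breakpoints_s(self) -> np.ndarray:
        """Sorted unique pulse edge times, in seconds."""
        times = {0.0, self.duration_s}
        for pulses in self.schedules:
            for p in pulses:
                times.add(p.start_s)
                times.add(p.end_s)
        return np.array(sorted(times))

    def block_windows(self) -> tuple[tuple[float, float], ...]:
        """Per-drug treatment-block envelope [first dose, last dose + one
        dosing interval], in seconds (used by the sustained-exposure model).

        The interval is inferred from the pulse-start spacing; a
        single-pulse schedule falls back to its infusion duration.
        """
        windows = []
        for pulses in self.schedules:
            if not pulses:
                windows.append((0.0, 0.0))
                continue
            starts = [p.start_s for p in pulses]
            if len(starts) >= 2:
                interval = float(np.median(np.diff(starts)))
            else:
                interval = pulses[0].duration_s
            windows.append((starts[0], min(starts[-1] + interval, self.duration_s)))
        return tuple(windows)


def regimen_indicator(regimen: TherapyRegimen, drug_index: int, t_s: float) -> float:
    """f_j(t): 1 during an infusion window of drug j, else 0."""
    if not 0 <= drug_index < regimen.n_drugs:
        raise KineticsError(f"drug index {drug_index} out of range")
    for p in regimen.schedules[drug_index]:
        if p.start_s <= t_s < p.end_s:
            return 1.0
    return 0.0


def build_regimen(spec: Sequence[dict]) -> TherapyRegimen:
    """Construct a regimen from per-drug schedule blocks.

    Each block is a mapping with keys ``first_dose_day``, ``interval_days``,
    ``count`` and optionally ``infusion_hours`` (default 1 h) and ``name``.
    Delta_t_s is the end of the last block, i.e. the last first-dose day
    plus count*interval (a full final cycle).
    """
    if len(spec) > MAX_DRUGS:
        raise KineticsError(f"at most {MAX_DRUGS} drugs per regimen")
    schedules: list[tuple[Pulse, ...]] = []
    end_days = 0.0
    for block in spec:
        first = float(block["first_dose_day"])
        interval = float(block["interval_days"])
        count = int(block["count"])
        infusion_h = float(block.get("infusion_hours", DEFAULT_INFUSION_HOURS))
        if interval <= 0 or count < 1 or infusion_h <= 0 or first < 0:
            raise KineticsError(f"invalid schedule block: {block}")
        if infusion_h * SECONDS_PER_HOUR > interval * SECONDS_PER_DAY:
            raise KineticsError(f"infusion longer than dosing interval in block {block}")
        pulses = tuple(
            Pulse(
                start_s=(first + i * interval) * SECONDS_PER_DAY,
                duration_s=infusion_h * SECONDS_PER_HOUR,
            )
            for i in range(count)
        )
        schedules.append(pulses)
        end_days = max(end_days, first + count * interval)
    if not schedules:
        return TherapyRegimen(schedules=(), duration_s=SECONDS_PER_DAY)
    return TherapyRegimen(schedules=tuple(schedules), duration_s=end_days * SECONDS_PER_DAY)


def load_regimen_config(path: str | Path) -> TherapyRegimen:
    """Read a regimen from a YAML config: a ``drugs:`` list of schedule
    blocks as accepted by :func:`build_regimen`."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "drugs" not in cfg:
        raise KineticsError(f"regimen config {path} must contain a 'drugs' list")
    return build_regimen(cfg["drugs"])


# --- local reaction terms ---------------------------------------------------

def gompertz_rate(phi_c, r_c: float, k: float = 1.0, phi_floor: float = 1e-12):
    """Gompertz growth rate -r_c * phi * ln(phi/K), elementwise.

    Continuous at 0 (the x ln x limit): returns exactly 0 where phi is 0.
    ``phi_floor`` (relative to K) regularizes the logarithm for tiny
    positive densities.
    """
    phi = np.asarray(phi_c, dtype=float)
    if np.any(phi < 0) or np.any(phi > k * (1 + 1e-12)):
        raise KineticsError("phi_c outside [0, K]")
    safe = np.maximum(phi, phi_floor * k)
    out = -r_c * phi * np.log(safe / k)
    return out if out.ndim else float(out)


def tumor_source(phi_c, phi_d: Sequence, params: ModelParams, mass_action: bool = False):
    """Tumor source R_c: Gompertz growth minus the drug kill term.

    The default kill term is -sum_j eps_pd_j * phi_dj, independent of
    phi_c (the update-level clamp keeps phi_c >= 0 where tumor is sparse).
    ``mass_action=True`` switches to -sum_j eps_pd_j * phi_dj * phi_c for
    sensitivity analysis.
    """
    if len(phi_d) > params.n_drugs:
        raise KineticsError(
            f"{len(phi_d)} drug fields supplied but params define {params.n_drugs}"
        )
    growth = gompertz_rate(phi_c, params.r_c, params.k)
    kill = 0.0
    for dj, drug in zip(phi_d, params.drugs):
        kill = kill + drug.eps_pd * np.asarray(dj, dtype=float)
    if mass_action:
        kill = kill * np.asarray(phi_c, dtype=float) / params.k
    out = growth - kill
    return out if np.ndim(out) else float(out)


def drug_source(phi_d, f: float, m_d: float, eps_pk: float):
    """Drug source R_d = f * m_d - eps_pk * phi_d (eps_pk in 1/s)."""
    phi = np.asarray(phi_d, dtype=float)
    if np.any(phi < 0):
        raise KineticsError("phi_d must be non-negative")
    out = f * m_d - eps_pk * phi
    return out if out.ndim else float(out)


def gompertz_closed_form(t_s, phi0: float, r_c: float, k: float = 1.0):
    """Exact solution of the Gompertz ODE from phi(0)=phi0 > 0."""
    t = np.asarray(t_s, dtype=float)
    return k * np.exp(np.log(phi0 / k) * np.exp(-r_c * t))
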