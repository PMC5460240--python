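"""Domain types of the whole-body PK model.

Amounts are carried in µmol, concentrations in µmol/l, times in hours at the
API surface (minutes internally), and doses in mg — the mg→µmol conversion
via molecular weight happens exactly once, at dosing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

ORGANS = (
    "gut_lumen",
    "gut_wall",
    "liver",
    "kidney",
    "arterial_plasma",
    "venous_plasma",
    "rest",
)
#: Perfused tissues that exchange with plasma (everything except the lumen
#: and the two plasma pools).
TISSUES = ("gut_wall", "liver", "kidney", "rest")
FLOW_KEYS = ("gut_wall", "liver", "kidney", "rest", "cardiac_output")


class ValidationError(ValueError):
    """An input violates a structural invariant."""


class ConfigurationError(ValueError):
    """Model pieces do not fit together (e.g. missing expression entry)."""


@dataclass(frozen=True)
class Physiology:
    """One individual's anthropometrics, organ volumes/flows and expression.

    ``organ_flows`` holds the plasma flow entering each perfused organ in
    l/min; ``liver`` is the hepatic-artery inflow only (the portal inflow is
    the gut-wall outflow).  ``cardiac_output`` is the bookkeeping sum of all
    tissue inflows.  ``expression`` maps (protein, organ) to a relative
    expression amount ≥ 0; absent pairs express nothing.
    """

    age: float
    body_weight: float
    body_height: float
    organ_volumes: dict[str, float]
    organ_flows: dict[str, float]
    hematocrit: float
    expression: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        if not (0.0 < self.hematocrit < 1.0):
            raise ValidationError(f"hematocrit must lie in (0,1), got {self.hematocrit}")
        if self.body_weight <= 0 or self.body_height <= 0:
            raise ValidationError("body weight and height must be positive")
        for organ in ORGANS:
            v = self.organ_volumes.get(organ)
            if v is None or v <= 0:
                raise ValidationError(f"organ volume for {organ!r} must be positive, got {v}")
        for key in FLOW_KEYS:
            q = self.organ_flows.get(key)
            if q is None or q <= 0:
                raise ValidationError(f"plasma flow for {key!r} must be positive, got {q}")
        tissue_sum = sum(self.organ_flows[k] for k in FLOW_KEYS[:-1])
        if not np.isclose(tissue_sum, self.organ_flows["cardiac_output"], rtol=1e-9):
            raise ValidationError(
                "sum of tissue inflows must equal the cardiac-output bookkeeping flow "
                f"({tissue_sum} vs {self.organ_flows['cardiac_output']})"
            )
        for (protein, organ), value in self.expression.items():
            if value < 0:
                raise ValidationError(f"expression of {protein} in {organ} is negative")
            if organ not in ORGANS:
                raise ValidationError(f"expression references unknown organ {organ!r}")

    @property
    def bmi(self) -> float:
        return self.body_weight / self.body_height**2

    @property
    def plasma_fraction(self) -> float:
        return 1.0 - self.hematocrit


@dataclass(frozen=True)
class ProcessKinetics:
    """One saturable active process (Michaelis–Menten).

    ``product=None`` for a metabolism process removes mass from the tracked
    system into the terminal-metabolism ledger (e.g. a glucuronide or a
    downstream metabolite that is not modelled explicitly).
    """

    protein: str
    kind: str  # metabolism | transport | renal_excretion
    substrate: str
    product: Optional[str]
    kcat: float  # 1/min
    km: float  # µmol/l

    def __post_init__(self) -> None:
        if self.kind not in ("metabolism", "transport", "renal_excretion"):
            raise ValidationError(f"unknown process kind {self.kind!r}")
        if self.kcat <= 0 or self.km <= 0:
            raise ValidationError(
                f"kinetic constants must be positive (kcat={self.kcat}, km={self.km})"
            )


@dataclass(frozen=True)
class DrugParams:
    """Physicochemistry and process kinetics of one compound.

    ``fraction_unbound`` is a fraction in (0,1] — percent values from
    parameter tables are converted exactly once at load.  The metabolite of a
    pair carries no absorption parameters (it is formed in tissue only).
    """

    name: str
    fraction_unbound: float
    lipophilicity: float
    molecular_weight: float  # g/mol
    intestinal_permeability: Optional[float] = None  # cm/min, parent only
    solubility_ref_ph: Optional[float] = None  # mg/ml
    processes: tuple[ProcessKinetics, ...] = ()
    renal_clearance_specific: Optional[float] = None  # l/min/kg
    endothelial_permeability_scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction_unbound <= 1.0):
            raise ValidationError(
                f"fraction_unbound must lie in (0,1], got {self.fraction_unbound}"
            )
        if self.molecular_weight <= 0:
            raise ValidationError("molecular weight must be positive")
        if self.intestinal_permeability is not None and self.intestinal_permeability <= 0:
            raise ValidationError("intestinal permeability must be positive")
        if self.renal_clearance_specific is not None and self.renal_clearance_specific < 0:
            raise ValidationError("renal clearance must be non-negative")
        for organ, scale in self.endothelial_permeability_scale.items():
            if not (0.0 < scale <= 1.0):
                raise ValidationError(
                    f"endothelial scale for {organ!r} must lie in (0,1], got {scale}"
                )

    def with_kcat(self, protein: str, kcat: float) -> "DrugParams":
        """Copy of this drug with the kcat of ``protein``'s process replaced."""
        procs = tuple(
            replace(p, kcat=kcat) if p.protein == protein else p for p in self.processes
        )
        return replace(self, processes=procs)

    def kcat_of(self, protein: str) -> Optional[float]:
        for p in self.processes:
            if p.protein == protein:
                return p.kcat
        return None


@dataclass(frozen=True)
class DoseEvent:
    """An oral dose; oral doses enter the gut lumen."""

    compound: str
    amount: float  # mg
    route: str = "oral"
    time: float = 0.0  # h

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValidationError("dose amount must be non-negative")
        if self.route != "oral":
            raise ValidationError(f"only the oral route is modelled, got {self.route!r}")
        if self.time < 0:
            raise ValidationError("dose time must be non-negative")


@dataclass(frozen=True)
class ConcentrationProfile:
    """Venous-plasma concentration–time course of one compound in one individual."""

    individual_id: str
    compound: str
    times: np.ndarray  # h, strictly increasing
    concentrations: np.ndarray  # µmol/l, ≥ 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concentrations", conc)
        if times.shape != conc.shape or times.ndim != 1:
            raise ValidationError("times and concentrations must be equal-length 1-d arrays")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(conc < 0):
            raise ValidationError("concentrations must be non-negative")

    def __len__(self) -> int:
        return int(self.times.size)


def profiles_to_frame(profiles: Iterable[ConcentrationProfile]) -> pd.DataFrame:
    """Serialize profiles to the canonical long table.

    Columns: ``individual_id, compound, time_h, conc_umol_per_l``.
    """
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.concentrations):
            rows.append((p.individual_id, p.compound, float(t), float(c)))
    return pd.DataFrame(
        rows, columns=["individual_id", "compound", "time_h", "conc_umol_per_l"]
    )


def profiles_from_frame(frame: pd.DataFrame) -> list[ConcentrationProfile]:
    """Inverse of :func:`profiles_to_frame` (order: individual, compound)."""
    required = {"individual_id", "compound", "time_h", "conc_umol_per_l"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"profile table misses columns {sorted(missing)}")
    out = []
    for (ind, comp), grp in frame.groupby(["individual_id", "compound"], sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            ConcentrationProfile(
                individual_id=str(ind),
                compound=str(comp),
                times=grp["time_h"].to_numpy(float),
                concentrations=grp["conc_umol_per_l"].to_numpy(float),
            )
        )
    return out
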