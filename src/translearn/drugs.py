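"""Mean-value drug model factories and genotype adjustments.

The two reference parameterizations (midazolam/OH-midazolam and
torsemide/OH-torsemide) ship as canonical YAML fixtures and are loaded with
strict unit validation: percent fraction unbound becomes a fraction exactly
once, catalytic constants must be declared in 1/min, Michaelis constants in
µmol/l, renal clearance in l/min/kg.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Union

import yaml

from . import constants
from .pbpk.types import DrugParams, ProcessKinetics, ValidationError

_EXPECTED_UNITS = {
    "fraction_unbound": {"%", "fraction"},
    "lipophilicity": {"log"},
    "molecular_weight": {"g/mol"},
    "intestinal_permeability": {"cm/min"},
    "solubility_ref_pH": {"mg/ml"},
    "renal_clearance": {"l/min/kg"},
    "kcat": {"1/min"},
    "km": {"umol/l"},
}


@dataclass(frozen=True)
class GenotypeRecord:
    """One individual's diplotype at one pharmacogene locus."""

    individual_id: str
    locus: str  # CYP2C9 | CYP3A4 | CYP3A5
    diplotype: str  # e.g. "*1/*1", "*3/*3"

    def __post_init__(self) -> None:
        assayed = constants.ASSAYED_DIPLOTYPES.get(self.locus)
        if assayed is None:
            raise ValidationError(f"locus {self.locus!r} is not on the genotyping panel")
        if self.diplotype not in assayed:
            raise ValidationError(
                f"diplotype {self.diplotype!r} not in the assayed set for {self.locus}"
            )


def _unit_value(entry, field: str) -> float:
    if not isinstance(entry, dict) or "value" not in entry or "unit" not in entry:
        raise ValidationError(f"{field}: expected {{value, unit}} mapping, got {entry!r}")
    unit = entry["unit"]
    if unit not in _EXPECTED_UNITS[field]:
        raise ValidationError(
            f"{field}: unit {unit!r} not accepted (expected one of "
            f"{sorted(_EXPECTED_UNITS[field])})"
        )
    value = float(entry["value"])
    if field == "fraction_unbound" and unit == "%":
        value = value / 100.0  # percent → fraction, exactly once at load
    return value


def _drug_from_spec(spec: dict) -> DrugParams:
    processes = []
    for p in spec.get("processes", []):
        processes.append(
            ProcessKinetics(
                protein=p["protein"],
                kind=p["kind"],
                substrate=spec["name"],
                product=p.get("product"),
                kcat=_unit_value(p["kcat"], "kcat"),
                km=_unit_value(p["km"], "km"),
            )
        )
    return DrugParams(
        name=spec["name"],
        fraction_unbound=_unit_value(spec["fraction_unbound"], "fraction_unbound"),
        lipophilicity=_unit_value(spec["lipophilicity"], "lipophilicity"),
        molecular_weight=_unit_value(spec["molecular_weight"], "molecular_weight"),
        intestinal_permeability=(
            _unit_value(spec["intestinal_permeability"], "intestinal_permeability")
            if "intestinal_permeability" in spec
            else None
        ),
        solubility_ref_ph=(
            _unit_value(spec["solubility_ref_pH"], "solubility_ref_pH")
            if "solubility_ref_pH" in spec
            else None
        ),
        processes=tuple(processes),
        renal_clearance_specific=(
            _unit_value(spec["renal_clearance"], "renal_clearance")
            if "renal_clearance" in spec
            else None
        ),
        endothelial_permeability_scale=dict(spec.get("endothelial_permeability_scale", {})),
    )


def load_drug_pair(source: Union[str, Path]) -> tuple[DrugParams, DrugParams]:
    """Load a (parent, metabolite) pair from a YAML fixture file."""
    text = Path(source).read_text()
    doc = yaml.safe_load(text)
    for key in ("parent", "metabolite"):
        if key not in doc:
            raise ValidationError(f"drug pair file misses the {key!r} section")
    return _drug_from_spec(doc["parent"]), _drug_from_spec(doc["metabolite"])


def _bundled(name: str) -> Path:
    return Path(importlib.resources.files("translearn").joinpath("data", name))


def midazolam_mean_model() -> tuple[DrugParams, DrugParams]:
    """The midazolam / OH-midazolam mean-value parameterization.

    Midazolam is cleared to OH-midazolam by CYP3A4 and effluxed by
    PGP/ABCB1; the metabolite is glucuronidated by UGT1A4 (terminal sink).
    Direct glucuronidation of the parent and minor CYP3A4/CYP3A5 metabolites
    are not represented.
    """
    return load_drug_pair(_bundled("midazolam.yaml"))


def torsemide_mean_model() -> tuple[DrugParams, DrugParams]:
    """The torsemide / OH-torsemide (M1) mean-value parameterization.

    Two independent CYP2C9 Michaelis–Menten steps (torsemide→M1, M1→M5 sink),
    OATP1B1 hepatic uptake for both compounds, linear renal clearances, and a
    capillary endothelial barrier (scale 0.001, liver 0.1) reflecting the
    very high plasma-protein binding.  The M3 pathway is not represented.
    """
    return load_drug_pair(_bundled("torsemide.yaml"))


def load_genotype_activity(source: Optional[Union[str, Path]] = None) -> dict:
    """Locus → diplotype → activity-multiplier table (package default table
    unless a path is given)."""
    if source is None:
        source = _bundled("genotype_activity.yaml")
    return yaml.safe_load(Path(source).read_text())


def apply_genotype(
    drug: DrugParams,
    genotype: GenotypeRecord,
    activity_table: Optional[dict] = None,
) -> DrugParams:
    """Return a copy of ``drug`` with genotype-adjusted enzyme activity.

    The kcat of the process matching the genotype locus is multiplied by the
    diplotype's activity factor; a drug without a matching process is
    returned unchanged.  The input object is never modified.
    """
    current = drug.kcat_of(genotype.locus)
    if current is None:
        return drug
    table = activity_table if activity_table is not None else load_genotype_activity()
    locus_table = table.get(genotype.locus)
    if locus_table is None or genotype.diplotype not in locus_table:
        raise ValidationError(
            f"no activity factor for {genotype.locus} {genotype.diplotype}"
        )
    return drug.with_kcat(genotype.locus, current * float(locus_table[genotype.diplotype]))


def drug_to_dict(drug: DrugParams) -> dict:
    """Plain-dict image of a drug (fractions, not percent) for JSON round-trips."""
    d = asdict(drug)
    d["processes"] = [asdict(p) for p in drug.processes]
    return d


def drug_from_dict(d: dict) -> DrugParams:
    procs = tuple(ProcessKinetics(**p) for p in d.get("processes", []))
    rest = {k: v for k, v in d.items() if k != "processes"}
    return DrugParams(processes=procs, **rest)
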