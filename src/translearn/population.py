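"""Virtual individuals and population simulations with percentile bands.

A virtual individual is an anthropometric draw (uniform within the cohort
ranges, with body-mass-index consistency enforced by rejection) plus a
parameter vector drawn from the current knowledge distributions.  Organ
volumes and flows follow the anthropometrics through fixed allometric rules;
the estimated parameters then perturb that baseline.

Parameter naming grammar (shared by the data generator, the inference layer
and this module, so learned knowledge is directly simulable):

* ``liver_volume_factor`` — multiplicative deviation of liver volume;
* ``<compound>__kcat__<protein>`` — catalytic constant of the named
  process of the named compound (1/min).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bayes import Distribution
from .pbpk.model import PbpkModel, build_model
from .pbpk.physiology import physiology_from_anthropometrics
from .pbpk.types import (
    ConcentrationProfile,
    ConfigurationError,
    DoseEvent,
    DrugParams,
    ValidationError,
)

logger = logging.getLogger(__name__)


# -- anthropometrics -------------------------------------------------------


@dataclass(frozen=True)
class AnthropometricRanges:
    """Min/max per anthropometric, one instance per cohort."""

    age: tuple[float, float]
    body_weight: tuple[float, float]  # kg
    body_height: tuple[float, float]  # m
    bmi: tuple[float, float]  # kg/m²

    def __post_init__(self) -> None:
        for name in ("age", "body_weight", "body_height", "bmi"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name} range must satisfy min < max")

    @staticmethod
    def healthy() -> "AnthropometricRanges":
        return AnthropometricRanges((18, 56), (48.5, 113), (1.54, 1.94), (18.8, 32.3))

    @staticmethod
    def diseased() -> "AnthropometricRanges":
        return AnthropometricRanges((20, 77), (52, 206), (1.56, 1.92), (19.7, 67.1))


def sample_anthropometrics(
    ranges: AnthropometricRanges,
    rng: np.random.Generator,
    obese_fraction: Optional[float] = None,
    max_tries: int = 10_000,
) -> dict:
    """One age/weight/height/BMI draw consistent with the cohort ranges.

    Weight and height are uniform within range and the draw is rejected
    until BMI = weight/height² falls inside the BMI range.  With
    ``obese_fraction`` set (obese-dominant cohorts), BMI is drawn from a
    two-component uniform mixture split at BMI 30 instead, and weight is
    derived as BMI·height².
    """
    for _ in range(max_tries):
        age = rng.uniform(*ranges.age)
        height = rng.uniform(*ranges.body_height)
        if obese_fraction is None:
            weight = rng.uniform(*ranges.body_weight)
            bmi = weight / height**2
        else:
            lo, hi = ranges.bmi
            if rng.uniform() < obese_fraction and hi > 30.0:
                bmi = rng.uniform(max(lo, 30.0), hi)
            else:
                bmi = rng.uniform(lo, min(hi, 30.0))
            weight = bmi * height**2
        if (
            ranges.bmi[0] <= bmi <= ranges.bmi[1]
            and ranges.body_weight[0] <= weight <= ranges.body_weight[1]
        ):
            return {
                "age": float(age),
                "body_weight": float(weight),
                "body_height": float(height),
                "bmi": float(bmi),
            }
    raise ValidationError(
        f"no BMI-consistent individual found in {max_tries} tries; ranges incompatible"
    )


# -- individual model assembly --------------------------------------------


def apply_parameters(
    parent: DrugParams,
    metabolite: DrugParams,
    anthropometrics: dict,
    params: dict[str, float],
) -> tuple:
    """Resolve a parameter vector into (Physiology, parent', metabolite').

    Unknown parameter names raise a configuration error listing the orphans,
    so incompatible knowledge states fail loudly at composition time.
    """
    liver_factor = 1.0
    drugs = {parent.name: parent, metabolite.name: metabolite}
    orphans = []
    for name, value in params.items():
        if name == "liver_volume_factor":
            liver_factor = float(value)
        elif "__kcat__" in name:
            compound, _, protein = name.partition("__kcat__")
            drug = drugs.get(compound)
            if drug is None or drug.kcat_of(protein) is None:
                orphans.append(name)
                continue
            drugs[compound] = drug.with_kcat(protein, float(value))
        else:
            orphans.append(name)
    if orphans:
        raise ConfigurationError(f"parameters not resolvable on this model: {orphans}")
    phys = physiology_from_anthropometrics(
        age=anthropometrics.get("age", 35.0),
        body_weight=anthropometrics["body_weight"],
        body_height=anthropometrics.get("body_height", 1.74),
        liver_volume_factor=liver_factor,
    )
    return phys, drugs[parent.name], drugs[metabolite.name]


def individual_model(
    parent: DrugParams,
    metabolite: DrugParams,
    anthropometrics: dict,
    params: dict[str, float],
) -> PbpkModel:
    phys, p, m = apply_parameters(parent, metabolite, anthropometrics, params)
    return build_model(phys, p, m)


# -- virtual individuals ---------------------------------------------------


@dataclass(frozen=True)
class VirtualIndividual:
    individual_id: str
    anthropometrics: dict
    params: dict[str, float]


def sample_virtual_individual(
    distributions: dict[str, Distribution],
    ranges: AnthropometricRanges,
    rng: np.random.Generator,
    individual_id: str = "virtual",
    obese_fraction: Optional[float] = None,
) -> VirtualIndividual:
    """Draw one virtual individual: anthropometrics within the cohort ranges
    and a parameter vector from the knowledge distributions."""
    anthro = sample_anthropometrics(ranges, rng, obese_fraction=obese_fraction)
    params = {name: float(d.sample(rng, 1)[0]) for name, d in distributions.items()}
    return VirtualIndividual(individual_id, anthro, params)


# -- population simulation -------------------------------------------------


@dataclass
class PopulationBands:
    """Pointwise population summary curves per compound plus the raw draws."""

    times: np.ndarray  # h
    summaries: dict[str, dict[str, np.ndarray]]  # compound → {mean, median, p2.5, p97.5}
    individual_profiles: list[ConcentrationProfile] = field(default_factory=list)
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for compound, s in self.summaries.items():
            for i, t in enumerate(self.times):
                rows.append(
                    {
                        "compound": compound,
                        "time_h": float(t),
                        "mean": float(s["mean"][i]),
                        "median": float(s["median"][i]),
                        "p2.5": float(s["p2.5"][i]),
                        "p97.5": float(s["p97.5"][i]),
                    }
                )
        return pd.DataFrame(rows)


def population_simulation(
    distributions: dict[str, Distribution],
    n: int,
    parent: DrugParams,
    metabolite: DrugParams,
    dose_mg: float,
    times: Sequence[float],
    seed: int,
    ranges: AnthropometricRanges,
    obese_fraction: Optional[float] = None,
    max_failure_fraction: float = 0.1,
) -> PopulationBands:
    """Simulate ``n`` virtual individuals and summarize pointwise.

    Percentiles are empirical (2.5/97.5); the mean curve is the arithmetic
    mean across individuals and the median curve is the one used for
    normalized-RMSE evaluation.  Individual simulation failures are skipped
    and logged; the run aborts if more than ``max_failure_fraction`` fail.
    """
    if n < 2:
        raise ValidationError("population bands need n ≥ 2")
    rng = np.random.default_rng(seed)
    times = np.asarray(times, float)
    curves: dict[str, list[np.ndarray]] = {parent.name: [], metabolite.name: []}
    profiles: list[ConcentrationProfile] = []
    n_failed = 0
    for i in range(n):
        ind = sample_virtual_individual(
            distributions, ranges, rng, individual_id=f"virtual{i:04d}",
            obese_fraction=obese_fraction,
        )
        try:
            model = individual_model(parent, metabolite, ind.anthropometrics, ind.params)
            result = model.solve([DoseEvent(parent.name, dose_mg)], times,
                                 individual_id=ind.individual_id)
        except Exception as exc:  # skip-and-log policy
            n_failed += 1
            logger.warning("virtual individual %s failed: %s", ind.individual_id, exc)
            if n_failed > max_failure_fraction * n:
                raise RuntimeError(
                    f"{n_failed}/{n} virtual-individual simulations failed"
                ) from exc
            continue
        for prof in result.profiles():
            curves[prof.compound].append(prof.concentrations)
            profiles.append(prof)
    summaries = {}
    for compound, rows in curves.items():
        arr = np.vstack(rows)
        summaries[compound] = {
            "mean": arr.mean(axis=0),
            "median": np.median(arr, axis=0),
            "p2.5": np.percentile(arr, 2.5, axis=0),
            "p97.5": np.percentile(arr, 97.5, axis=0),
        }
    return PopulationBands(
        times=times, summaries=summaries, individual_profiles=profiles, n_failed=n_failed
    )
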