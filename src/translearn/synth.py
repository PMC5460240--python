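"""Fully synthetic two-cohort PK studies with known ground truth.

The generator emulates the statistical structure of a cocktail-probe study:
two cohorts (healthy, and a diseased cohort dominated by obesity) whose
anthropometrics are sampled within published cohort ranges; lognormal
interindividual variability on the kinetic and physiological parameters;
a pathophysiological shift of enzyme-mediated clearances in the diseased
cohort (CYP3A4 activity down, CYP2C9 activity up); multiplicative lognormal
measurement noise on the simulated plasma concentrations; rare poor-
metabolizer genotype outliers (CYP2C9 *3/*3); and liver-histology metadata
(steatosis, activity-score components) increasing stochastically with body
weight, plus an expression surrogate correlated with the individual's true
clearance parameter.

Because the truth is retained, every pipeline stage — inference, transfer,
prediction, evaluation — can be tested for recovery without any external
data.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import constants
from .bayes import Distribution
from .pbpk.types import (
    ConcentrationProfile,
    DoseEvent,
    DrugParams,
    ValidationError,
    profiles_from_frame,
    profiles_to_frame,
)
from .population import AnthropometricRanges, individual_model, sample_anthropometrics

#: Blood-sampling schedule of the emulated study design (hours post dose).
STUDY_TIMES = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0)

#: Cocktail doses (mg) of the two probe drugs.
STUDY_DOSES_MG = {"midazolam": 1.0, "torsemide": 0.25}

#: Fraction of the diseased cohort with BMI ≥ 30.
DISEASED_OBESE_FRACTION = 0.72

#: Default pathophysiology of the diseased cohort: multiplicative shifts of
#: enzyme-mediated clearance (CYP3A4-mediated clearance decreased, CYP2C9-
#: mediated clearance increased).
DISEASED_MULTIPLIERS = {"CYP3A4": 0.7, "CYP2C9": 1.5}

#: Default interindividual geometric CV of kinetic parameters and default
#: multiplicative residual noise (lognormal sigma).
DEFAULT_PARAM_GCV = 0.30
DEFAULT_RESIDUAL_SIGMA = 0.15


@dataclass(frozen=True)
class Administration:
    """One drug pair given orally as part of the cocktail."""

    parent: DrugParams
    metabolite: DrugParams
    dose_mg: float


@dataclass(frozen=True)
class OutlierSpec:
    fraction: float = 0.0
    locus: str = "CYP2C9"
    diplotype: str = "*3/*3"


@dataclass
class CohortTruth:
    """Ground-truth description of one synthetic cohort."""

    label: str  # healthy | diseased
    n: int
    ranges: AnthropometricRanges
    population: dict[str, Distribution]  # truth distribution per parameter
    multipliers: dict[str, float] = field(default_factory=dict)  # protein → factor
    residual_sigma: float = DEFAULT_RESIDUAL_SIGMA
    outliers: OutlierSpec = field(default_factory=OutlierSpec)
    obese_fraction: Optional[float] = None
    metadata_noise: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("cohort size must be ≥ 1")
        if any(m <= 0 for m in self.multipliers.values()):
            raise ValidationError("pathophysiology multipliers must be positive")
        if not (0.0 <= self.outliers.fraction <= 1.0):
            raise ValidationError("outlier fraction must lie in [0,1]")
        if self.residual_sigma < 0:
            raise ValidationError("residual sigma must be ≥ 0")


@dataclass
class SyntheticIndividual:
    individual_id: str
    anthropometrics: dict
    genotypes: dict[str, str] = field(default_factory=dict)  # locus → diplotype
    metadata: dict = field(default_factory=dict)
    true_params: dict[str, float] = field(default_factory=dict)


@dataclass
class CohortDataset:
    """Individuals plus their observed concentration profiles per drug."""

    label: str
    individuals: list[SyntheticIndividual]
    profiles: list[ConcentrationProfile]
    times: tuple[float, ...] = STUDY_TIMES
    truth: Optional[CohortTruth] = None  # retained for recovery tests only
    noiseless: list[ConcentrationProfile] = field(default_factory=list)

    def profiles_of(self, individual_id: str) -> dict[str, ConcentrationProfile]:
        return {
            p.compound: p for p in self.profiles if p.individual_id == individual_id
        }

    def compounds(self) -> set[str]:
        return {p.compound for p in self.profiles}

    def data_hash(self) -> str:
        frame = profiles_to_frame(self.profiles)
        return hashlib.sha256(
            frame.round(12).to_csv(index=False).encode()
        ).hexdigest()[:16]


# -- truth construction ----------------------------------------------------


def estimated_parameter_names(parent: DrugParams, metabolite: DrugParams) -> dict[str, str]:
    """Default estimated-parameter set for a drug pair, with role tags.

    One physiological degree of freedom (liver volume factor) plus the
    catalytic constant of every metabolism process of parent and metabolite.
    """
    names = {"liver_volume_factor": "physiological"}
    for drug in (parent, metabolite):
        for proc in drug.processes:
            if proc.kind == "metabolism":
                names[f"{drug.name}__kcat__{proc.protein}"] = "drug_specific"
    return names


def truth_population(
    pairs: Sequence[Administration],
    gcv: float = DEFAULT_PARAM_GCV,
    liver_volume_gcv: float = 0.15,
) -> dict[str, Distribution]:
    """Truth distributions centred on the mean-value model parameters with
    the stated geometric CV."""
    out: dict[str, Distribution] = {
        "liver_volume_factor": Distribution("lognormal", 0.0, liver_volume_gcv)
    }
    for adm in pairs:
        for drug in (adm.parent, adm.metabolite):
            for proc in drug.processes:
                if proc.kind == "metabolism":
                    out[f"{drug.name}__kcat__{proc.protein}"] = Distribution(
                        "lognormal", math.log(proc.kcat), gcv
                    )
    return out


def healthy_truth(pairs: Sequence[Administration], n: int = 20, seed: int = 0,
                  outlier_fraction: float = 0.05) -> CohortTruth:
    return CohortTruth(
        label="healthy",
        n=n,
        ranges=AnthropometricRanges.healthy(),
        population=truth_population(pairs),
        outliers=OutlierSpec(fraction=outlier_fraction),
        seed=seed,
    )


def diseased_truth(pairs: Sequence[Administration], n: int = 20, seed: int = 0) -> CohortTruth:
    return CohortTruth(
        label="diseased",
        n=n,
        ranges=AnthropometricRanges.diseased(),
        population=truth_population(pairs),
        multipliers=dict(DISEASED_MULTIPLIERS),
        obese_fraction=DISEASED_OBESE_FRACTION,
        seed=seed,
    )


# -- generation ------------------------------------------------------------


def _apply_multipliers(params: dict[str, float], multipliers: dict[str, float]) -> dict:
    out = dict(params)
    for name in out:
        if "__kcat__" in name:
            protein = name.split("__kcat__", 1)[1]
            if protein in multipliers:
                out[name] *= multipliers[protein]
    return out


def generate_cohort(
    truth: CohortTruth,
    administrations: Sequence[Administration],
    times: Sequence[float] = STUDY_TIMES,
) -> CohortDataset:
    """Sample a cohort and its observed concentration data.

    Individuals are sampled from the anthropometric ranges; their parameter
    vectors from the truth distributions, then shifted by the cohort's
    pathophysiology multipliers and (for flagged outliers) by the genotype
    activity factor; plasma profiles are simulated mechanistically and
    multiplicative lognormal noise is applied.  Fully seeded; the truth and
    the noiseless profiles are retained on the dataset for recovery tests.
    """
    rng = np.random.default_rng(truth.seed)
    times = tuple(float(t) for t in times)
    individuals: list[SyntheticIndividual] = []
    observed: list[ConcentrationProfile] = []
    noiseless: list[ConcentrationProfile] = []
    n_outliers = int(round(truth.outliers.fraction * truth.n))
    outlier_ids = set(rng.choice(truth.n, size=n_outliers, replace=False)) if n_outliers else set()
    activity = constants.GENOTYPE_ACTIVITY.get(truth.outliers.locus, {})
    for i in range(truth.n):
        iid = f"{truth.label[0]}{i + 1:03d}"
        anthro = sample_anthropometrics(
            truth.ranges, rng, obese_fraction=truth.obese_fraction
        )
        params = {
            name: float(d.sample(rng, 1)[0]) for name, d in truth.population.items()
        }
        params = _apply_multipliers(params, truth.multipliers)
        genotypes = {truth.outliers.locus: "*1/*1"}
        if i in outlier_ids:
            genotypes[truth.outliers.locus] = truth.outliers.diplotype
            factor = float(activity.get(truth.outliers.diplotype, 1.0))
            params = _apply_multipliers(params, {truth.outliers.locus: factor})
        ind = SyntheticIndividual(
            individual_id=iid,
            anthropometrics=anthro,
            genotypes=genotypes,
            true_params=params,
        )
        individuals.append(ind)
        for adm in administrations:
            usable = {
                k: v
                for k, v in params.items()
                if k == "liver_volume_factor"
                or k.split("__kcat__")[0] in (adm.parent.name, adm.metabolite.name)
            }
            try:
                model = individual_model(adm.parent, adm.metabolite, anthro, usable)
                result = model.solve(
                    [DoseEvent(adm.parent.name, adm.dose_mg)], times, individual_id=iid
                )
            except Exception as exc:
                raise RuntimeError(f"simulation failed for individual {iid}") from exc
            for prof in result.profiles():
                noiseless.append(prof)
                noise = (
                    np.exp(truth.residual_sigma * rng.standard_normal(len(times)))
                    if truth.residual_sigma > 0
                    else np.ones(len(times))
                )
                observed.append(
                    ConcentrationProfile(
                        individual_id=iid,
                        compound=prof.compound,
                        times=prof.times,
                        concentrations=prof.concentrations * noise,
                    )
                )
    dataset = CohortDataset(
        label=truth.label,
        individuals=individuals,
        profiles=observed,
        times=times,
        truth=truth,
        noiseless=noiseless,
    )
    generate_metadata(dataset, rng)
    return dataset


def generate_metadata(dataset: CohortDataset, rng: np.random.Generator) -> None:
    """Attach histology metadata and expression surrogates in place.

    Steatosis and the other activity-score components follow an ordinal
    model monotone in body weight (heavier individuals receive higher
    grades, up to noise); the expression surrogate for each enzyme is the
    log of the individual's true clearance parameter plus noise, so
    correlation analyses have a known positive truth.
    """
    truth = dataset.truth
    noise = truth.metadata_noise if truth is not None else 0.6
    w_lo, w_hi = (
        (truth.ranges.body_weight) if truth is not None else (48.5, 206.0)
    )
    for ind in dataset.individuals:
        w = ind.anthropometrics["body_weight"]
        z = (w - w_lo) / max(w_hi - w_lo, 1e-9)
        steat = int(np.clip(round(3 * z + noise * rng.standard_normal()), 0, 3))
        inflam = int(np.clip(round(2.5 * z + noise * rng.standard_normal()), 0, 3))
        balloon = int(np.clip(round(2 * z + noise * rng.standard_normal()), 0, 2))
        ind.metadata.update(
            {
                "steatosis": steat,
                "lobular_inflammation": inflam,
                "ballooning": balloon,
                "nas": steat + inflam + balloon,
            }
        )
        for name, value in ind.true_params.items():
            if "__kcat__" in name:
                protein = name.split("__kcat__", 1)[1]
                key = f"expression_{protein}"
                if key not in ind.metadata:
                    ind.metadata[key] = float(
                        math.log(value) + 0.3 * rng.standard_normal()
                    )


# -- persistence -----------------------------------------------------------


def _dist_to_json(d: Distribution) -> dict:
    out = asdict(d)
    for key in ("lower_bound", "upper_bound"):
        if not math.isfinite(out[key]):
            out[key] = None  # JSON has no infinities
    return out


def _dist_from_json(d: dict) -> Distribution:
    d = dict(d)
    if d.get("lower_bound") is None:
        d["lower_bound"] = -math.inf
    if d.get("upper_bound") is None:
        d["upper_bound"] = math.inf
    return Distribution(**d)


def write_cohort(dataset: CohortDataset, out_dir) -> None:
    """Write ``individuals.csv``, ``profiles.csv``, ``metadata.csv`` and
    ``truth.json`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ind_rows, meta_rows = [], []
    for ind in dataset.individuals:
        ind_rows.append(
            {
                "individual_id": ind.individual_id,
                **ind.anthropometrics,
                **{f"genotype_{k}": v for k, v in ind.genotypes.items()},
            }
        )
        meta_rows.append({"individual_id": ind.individual_id, **ind.metadata})
    pd.DataFrame(ind_rows).to_csv(out / "individuals.csv", index=False)
    pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False)
    profiles_to_frame(dataset.profiles).to_csv(out / "profiles.csv", index=False)
    truth_doc = {"label": dataset.label, "times": list(dataset.times)}
    if dataset.truth is not None:
        t = dataset.truth
        truth_doc["truth"] = {
            "label": t.label,
            "n": t.n,
            "ranges": asdict(t.ranges),
            "population": {
                k: _dist_to_json(d) for k, d in t.population.items()
            },
            "multipliers": t.multipliers,
            "residual_sigma": t.residual_sigma,
            "outliers": asdict(t.outliers),
            "obese_fraction": t.obese_fraction,
            "metadata_noise": t.metadata_noise,
            "seed": t.seed,
            "true_params": {
                ind.individual_id: ind.true_params for ind in dataset.individuals
            },
        }
    (out / "truth.json").write_text(json.dumps(truth_doc, indent=1, allow_nan=False))


def read_cohort(in_dir) -> CohortDataset:
    """Read a dataset written by :func:`write_cohort` (lossless round trip
    up to CSV float formatting)."""
    src = Path(in_dir)
    ind_frame = pd.read_csv(src / "individuals.csv")
    meta_frame = pd.read_csv(src / "metadata.csv").set_index("individual_id")
    profiles = profiles_from_frame(pd.read_csv(src / "profiles.csv"))
    doc = json.loads((src / "truth.json").read_text())
    truth = None
    true_params: dict[str, dict] = {}
    if "truth" in doc:
        t = doc["truth"]
        truth = CohortTruth(
            label=t["label"],
            n=t["n"],
            ranges=AnthropometricRanges(
                tuple(t["ranges"]["age"]),
                tuple(t["ranges"]["body_weight"]),
                tuple(t["ranges"]["body_height"]),
                tuple(t["ranges"]["bmi"]),
            ),
            population={
                k: _dist_from_json(d) for k, d in t["population"].items()
            },
            multipliers=t["multipliers"],
            residual_sigma=t["residual_sigma"],
            outliers=OutlierSpec(**t["outliers"]),
            obese_fraction=t["obese_fraction"],
            metadata_noise=t["metadata_noise"],
            seed=t["seed"],
        )
        true_params = t.get("true_params", {})
    individuals = []
    for _, row in ind_frame.iterrows():
        iid = str(row["individual_id"])
        genotypes = {
            c.replace("genotype_", ""): row[c]
            for c in ind_frame.columns
            if c.startswith("genotype_")
        }
        anthro = {
            k: float(row[k]) for k in ("age", "body_weight", "body_height", "bmi")
        }
        metadata = meta_frame.loc[iid].to_dict() if iid in meta_frame.index else {}
        metadata = {
            k: (int(v) if k in ("steatosis", "lobular_inflammation", "ballooning", "nas") else float(v))
            for k, v in metadata.items()
        }
        individuals.append(
            SyntheticIndividual(
                individual_id=iid,
                anthropometrics=anthro,
                genotypes=genotypes,
                metadata=metadata,
                true_params=true_params.get(iid, {}),
            )
        )
    return CohortDataset(
        label=doc["label"],
        individuals=individuals,
        profiles=profiles,
        times=tuple(doc["times"]),
        truth=truth,
    )
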