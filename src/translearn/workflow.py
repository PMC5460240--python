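"""The four-step translational learning/prediction engine.

A *knowledge state* is a named set of parameter distributions — the
transferable result of a learning step — split into physiological knowledge
(properties of the population) and drug-specific knowledge (properties of a
compound pair), with an append-only provenance trail.  The canonical
workflow:

1. learn from the reference drug in the healthy cohort (state ``mh``);
2. refine the physiology with the candidate drug in the same healthy cohort
   and acquire the candidate's drug-specific knowledge (state ``th``);
3. transfer the reference drug's knowledge into the diseased cohort to
   identify its pathophysiology (state ``md``);
4. combine the candidate drug knowledge from step 2 with the
   pathophysiology from step 3 for a de-novo population prediction of the
   candidate drug in the diseased cohort — no diseased candidate-drug
   observations are consumed, which the provenance audit enforces.

Acquired knowledge is carried parametrically as the maximum-posterior
population estimates (mean and standard deviation), exactly the quantities
a virtual-population simulation needs.  Learning is quantified per
parameter by the Kullback–Leibler divergence of acquired from initial
knowledge.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .bayes import (
    DiagnosticsError,
    Distribution,
    HierarchicalModel,
    IndividualData,
    McmcResult,
    PriorSpec,
    run_mcmc,
)
from .pbpk.types import ConfigurationError, DoseEvent, ValidationError
from .population import (
    AnthropometricRanges,
    PopulationBands,
    individual_model,
    population_simulation,
)
from .synth import Administration, CohortDataset, estimated_parameter_names

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: Default prior spreads (sd of log) of the initial knowledge: broad for
#: drug-specific catalytic constants, tighter for the physiological factor.
DEFAULT_KCAT_PRIOR_SD = 0.5
DEFAULT_LIVER_PRIOR_SD = 0.25

#: Numerical-quadrature settings for cross-family KL (recorded here so a
#: result is reproducible from the package version).
KL_QUAD_LIMIT = 200


# -- knowledge states ------------------------------------------------------


@dataclass(frozen=True)
class KnowledgeState:
    """A named, transferable set of parameter distributions."""

    label: str
    physiological: dict[str, Distribution]
    drug_specific: dict[str, dict[str, Distribution]]  # compound → name → dist
    provenance: tuple[dict, ...] = ()

    def all_distributions(self) -> dict[str, Distribution]:
        out = dict(self.physiological)
        for dists in self.drug_specific.values():
            out.update(dists)
        return out

    def with_provenance(self, record: dict) -> "KnowledgeState":
        return replace(self, provenance=self.provenance + (record,))


def initial_knowledge(pairs: Sequence[Administration], label: str = "initial") -> KnowledgeState:
    """Package-default initial knowledge for the given drug pairs.

    Lognormal priors centred on the mean-value model parameters: broad for
    catalytic constants (the data are expected to inform them), tighter for
    the liver-volume factor.
    """
    phys = {"liver_volume_factor": Distribution("lognormal", 0.0, DEFAULT_LIVER_PRIOR_SD)}
    drug: dict[str, dict[str, Distribution]] = {}
    for adm in pairs:
        for d in (adm.parent, adm.metabolite):
            entries = {}
            for proc in d.processes:
                if proc.kind == "metabolism":
                    entries[f"{d.name}__kcat__{proc.protein}"] = Distribution(
                        "lognormal", math.log(proc.kcat), DEFAULT_KCAT_PRIOR_SD
                    )
            if entries:
                drug[d.name] = entries
    return KnowledgeState(label=label, physiological=phys, drug_specific=drug)


def transfer(
    state: KnowledgeState,
    select: str,
    drug: Optional[Union[str, Sequence[str]]] = None,
) -> PriorSpec:
    """Build a prior specification from the selected knowledge component.

    ``select`` is ``"physiological"`` or ``"drug_specific"`` (the latter
    requires ``drug``: one compound name or the pair).  Parameters not
    covered fall back to package defaults at model-build time; the emitted
    spec records its source state label.
    """
    if select == "physiological":
        entries = dict(state.physiological)
        if not entries:
            logger.warning("transfer from %s: empty physiological component", state.label)
        roles = {k: "physiological" for k in entries}
    elif select == "drug_specific":
        if drug is None:
            raise ValidationError("drug_specific transfer requires a drug name")
        names = [drug] if isinstance(drug, str) else list(drug)
        entries = {}
        for n in names:
            if n not in state.drug_specific:
                raise KeyError(f"state {state.label!r} has no drug-specific knowledge for {n!r}")
            entries.update(state.drug_specific[n])
        roles = {k: "drug_specific" for k in entries}
    else:
        raise ValidationError(f"unknown knowledge component {select!r}")
    return PriorSpec(entries=entries, roles=roles, source_label=state.label)


def compose_state(
    label: str,
    physiological_from: KnowledgeState,
    drug_specific_from: Sequence[tuple[KnowledgeState, Sequence[str]]] = (),
) -> KnowledgeState:
    """Assemble a knowledge state from components of other states:
    physiology from one state, drug-specific knowledge per compound list
    from others.  Provenance is the concatenation of the sources'."""
    drug: dict[str, dict[str, Distribution]] = {}
    provenance = list(physiological_from.provenance)
    for state, compounds in drug_specific_from:
        for c in compounds:
            if c in state.drug_specific:
                drug[c] = dict(state.drug_specific[c])
        provenance.extend(state.provenance)
    return KnowledgeState(
        label=label,
        physiological=dict(physiological_from.physiological),
        drug_specific=drug,
        provenance=tuple(provenance),
    )


# -- learning steps --------------------------------------------------------


@dataclass(frozen=True)
class StepConfig:
    """Settings of one Bayesian learning step."""

    label: str
    seed: int = 0
    n_iter: int = 20_000
    max_individuals: int = 20
    rhat_threshold: float = 1.1
    exclude_poor_metabolizers: bool = True
    force: bool = False  # emit a state even when R̂ has not converged
    n_segments: int = 4


def _eligible_individuals(
    cohort: CohortDataset, adm: Administration, config: StepConfig
) -> list:
    out = []
    for ind in cohort.individuals:
        if config.exclude_poor_metabolizers and any(
            g.endswith("*3/*3") or g == "*3/*3" for g in ind.genotypes.values()
        ):
            continue  # study practice: genotype-explained outliers are set aside
        profs = cohort.profiles_of(ind.individual_id)
        if adm.parent.name in profs:
            out.append((ind, profs))
        if len(out) >= config.max_individuals:
            break
    return out


def learn_step(
    initial: KnowledgeState,
    cohort: CohortDataset,
    adm: Administration,
    config: StepConfig,
) -> tuple[KnowledgeState, Optional[McmcResult]]:
    """One Bayesian learning step: initial knowledge + cohort data →
    acquired knowledge.

    The acquired distributions are the maximum-posterior population
    estimates (mean and sd of the population law, on its working scale).
    With an empty dataset the distributions pass through unchanged
    (posterior = prior).  A non-converged chain raises unless
    ``config.force`` is set.
    """
    eligible = _eligible_individuals(cohort, adm, config)
    if not eligible:
        logger.warning("learn step %s: no usable data; knowledge unchanged", config.label)
        state = replace(initial, label=config.label).with_provenance(
            {"step": config.label, "drug": adm.parent.name, "cohort": cohort.label,
             "n_individuals": 0, "note": "no data; posterior equals prior"}
        )
        return state, None

    param_roles = estimated_parameter_names(adm.parent, adm.metabolite)
    param_names = tuple(param_roles)
    merged = initial_knowledge([adm]).all_distributions()
    merged.update(initial.physiological)
    for compound in (adm.parent.name, adm.metabolite.name):
        merged.update(initial.drug_specific.get(compound, {}))
    priors = PriorSpec(
        entries={k: merged[k] for k in param_names},
        roles=param_roles,
        source_label=initial.label,
    )

    data, predict_fns = [], []
    compounds = (adm.parent.name, adm.metabolite.name)
    for ind, profs in eligible:
        obs = {c: profs[c] for c in compounds if c in profs}
        data.append(IndividualData(ind.individual_id, obs))
        times = next(iter(obs.values())).times
        anthro = ind.anthropometrics

        def predict(theta, _anthro=anthro, _times=times):
            params = dict(zip(param_names, theta))
            model = individual_model(adm.parent, adm.metabolite, _anthro, params)
            result = model.solve([DoseEvent(adm.parent.name, adm.dose_mg)], _times)
            return {c: result.venous_concentration(c) for c in compounds}

        predict_fns.append(predict)

    model = HierarchicalModel(
        param_names=param_names, priors=priors, predict_fns=predict_fns, data=data
    )
    result = run_mcmc(
        model,
        n_iter=config.n_iter,
        seed=config.seed,
        rhat_threshold=config.rhat_threshold,
        n_segments=config.n_segments,
    )
    pop_rhats = [
        v for k, v in result.rhat.items()
        if (k.startswith(("mu__", "omega__")) or k == "sigma") and np.isfinite(v)
    ]
    if pop_rhats and max(pop_rhats) >= config.rhat_threshold and not config.force:
        raise DiagnosticsError(
            f"learning step {config.label!r} has not converged "
            f"(max population R-hat {max(pop_rhats):.3f} ≥ {config.rhat_threshold}); "
            "rerun longer or pass force=True"
        )

    # point estimates of the population parameters: the joint posterior mode
    # of a hierarchical model is degenerate (population spread → 0, the
    # "funnel"), so the acquired knowledge takes each population parameter's
    # marginal posterior estimate (median) instead
    post = result.posterior()
    new_phys = dict(initial.physiological)
    new_drug = {k: dict(v) for k, v in initial.drug_specific.items()}
    for name in param_names:
        mu = np.median(post[:, result.columns.index(f"mu__{name}")])
        omega = np.median(post[:, result.columns.index(f"omega__{name}")])
        family = "lognormal" if result.log_scale[name] else "normal"
        dist = Distribution(family, float(mu), float(omega))
        if param_roles[name] == "physiological":
            new_phys[name] = dist
        else:
            compound = name.split("__kcat__")[0]
            new_drug.setdefault(compound, {})[name] = dist
    record = {
        "step": config.label,
        "drug": adm.parent.name,
        "cohort": cohort.label,
        "data_hash": cohort.data_hash(),
        "seed": config.seed,
        "n_iter": config.n_iter,
        "n_individuals": len(data),
        "burn_in": result.burn_in,
    }
    state = KnowledgeState(
        label=config.label,
        physiological=new_phys,
        drug_specific=new_drug,
        provenance=initial.provenance + (record,),
    )
    return state, result


# -- prediction ------------------------------------------------------------


def audit_no_exposure(state: KnowledgeState, drug: str, cohort_label: str) -> None:
    """Raise if the state's provenance shows it consumed observations of
    ``drug`` in ``cohort_label`` — the de-novo prediction must not have."""
    for rec in state.provenance:
        if rec.get("drug") == drug and rec.get("cohort") == cohort_label and rec.get(
            "n_individuals", 0
        ):
            raise ValidationError(
                f"state {state.label!r} already consumed {drug} data from the "
                f"{cohort_label} cohort; de-novo prediction would be circular"
            )


def predict_step(
    drug_knowledge: KnowledgeState,
    physiology_knowledge: KnowledgeState,
    adm: Administration,
    times: Sequence[float],
    n_virtual: int = 500,
    seed: int = 0,
    ranges: Optional[AnthropometricRanges] = None,
    obese_fraction: Optional[float] = None,
    target_cohort_label: str = "diseased",
) -> tuple[PopulationBands, KnowledgeState]:
    """De-novo population prediction of the candidate drug in the target
    cohort: candidate drug-specific knowledge + target-population
    physiological knowledge, composed and simulated.

    Returns the percentile bands and the composed knowledge state; both
    input states are audited for target-cohort candidate-drug exposure.
    """
    audit_no_exposure(drug_knowledge, adm.parent.name, target_cohort_label)
    audit_no_exposure(physiology_knowledge, adm.parent.name, target_cohort_label)
    composed = KnowledgeState(
        label=f"predict_{adm.parent.name}_{target_cohort_label}",
        physiological=dict(physiology_knowledge.physiological),
        drug_specific={
            c: dict(drug_knowledge.drug_specific.get(c, {}))
            for c in (adm.parent.name, adm.metabolite.name)
        },
        provenance=physiology_knowledge.provenance + drug_knowledge.provenance,
    )
    ranges = ranges if ranges is not None else AnthropometricRanges.diseased()
    bands = population_simulation(
        composed.all_distributions(),
        n=n_virtual,
        parent=adm.parent,
        metabolite=adm.metabolite,
        dose_mg=adm.dose_mg,
        times=times,
        seed=seed,
        ranges=ranges,
        obese_fraction=obese_fraction,
    )
    return bands, composed


# -- learning quantification ----------------------------------------------


def kl_divergence(acquired: Distribution, initial: Distribution) -> float:
    """Relative entropy KL(acquired ‖ initial) in nats.

    Closed form for normal‖normal and lognormal‖lognormal (untruncated);
    uniform‖uniform by support ratio; numerical quadrature otherwise.
    Disjoint supports yield +inf with a warning.  Always ≥ 0 up to
    quadrature error.
    """
    def _untruncated(d: Distribution) -> bool:
        if d.family == "lognormal":
            return d.lower_bound == 0.0 and not math.isfinite(d.upper_bound)
        return not math.isfinite(d.lower_bound) and not math.isfinite(d.upper_bound)

    untruncated = _untruncated(acquired) and _untruncated(initial)
    if acquired.family == initial.family == "uniform":
        if (
            acquired.lower_bound >= initial.lower_bound
            and acquired.upper_bound <= initial.upper_bound
        ):
            return math.log(
                (initial.upper_bound - initial.lower_bound)
                / (acquired.upper_bound - acquired.lower_bound)
            )
        logger.warning("KL: acquired support exceeds initial support; divergence infinite")
        return math.inf
    if acquired.family == initial.family and acquired.family in ("normal", "lognormal") and untruncated:
        m1, s1 = acquired.location, acquired.scale
        m2, s2 = initial.location, initial.scale
        return math.log(s2 / s1) + (s1**2 + (m1 - m2) ** 2) / (2.0 * s2**2) - 0.5
    return _kl_quadrature(acquired, initial)


def _kl_quadrature(p: Distribution, q: Distribution) -> float:
    lo = max(p.lower_bound, 0.0 if p.family == "lognormal" else -math.inf)
    hi = p.upper_bound
    if q.upper_bound < hi or q.lower_bound > lo:
        # q vanishes on part of p's support → infinite divergence
        logger.warning("KL: supports not nested; divergence infinite")
        return math.inf

    def integrand(x):
        lp = float(p.logpdf(x))
        if not math.isfinite(lp):
            return 0.0
        lq = float(q.logpdf(x))
        if not math.isfinite(lq):
            return math.inf
        return math.exp(lp) * (lp - lq)

    if not math.isfinite(lo):
        lo = min(p.location - 12 * p.scale, q.location - 12 * q.scale)
    if not math.isfinite(hi):
        if p.family == "lognormal":
            hi = math.exp(p.location + 12 * p.scale)
        else:
            hi = max(p.location + 12 * p.scale, q.location + 12 * q.scale)
    if p.family == "lognormal":
        peak_points = [math.exp(p.location + k * p.scale) for k in (-2, 0, 2)]
    else:
        peak_points = [p.location + k * p.scale for k in (-2, 0, 2)]
    points = sorted(x for x in peak_points if lo < x < hi)
    value, _ = quad(integrand, lo, hi, limit=KL_QUAD_LIMIT, points=points or None)
    return max(float(value), 0.0)


def learning_heatmap(
    states: Sequence[KnowledgeState],
    baseline: KnowledgeState,
) -> pd.DataFrame:
    """Parameter × learning-step matrix of KL(acquired ‖ initial).

    Cells are NaN where a parameter was not part of a step's model (no
    distribution in that state), mirroring the hatched not-available cells
    of a learning-progression heat map.
    """
    base = baseline.all_distributions()
    rows = sorted({name for s in states for name in s.all_distributions()} | set(base))
    out = pd.DataFrame(index=rows, columns=[s.label for s in states], dtype=float)
    for s in states:
        dists = s.all_distributions()
        for name in rows:
            if name in dists and name in base:
                out.loc[name, s.label] = kl_divergence(dists[name], base[name])
            else:
                out.loc[name, s.label] = math.nan
    return out


def plot_heatmap(matrix: pd.DataFrame, path) -> None:
    """Render the learning-progression matrix (NaN cells hatched)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(2 + matrix.shape[1], 1 + 0.4 * matrix.shape[0]))
    data = np.ma.masked_invalid(matrix.to_numpy(float))
    im = ax.imshow(data, aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=7)
    for (i, j), masked in np.ndenumerate(data.mask if data.mask.ndim else np.zeros(data.shape, bool)):
        if masked:
            ax.add_patch(
                plt.Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False, hatch="///", lw=0)
            )
    fig.colorbar(im, ax=ax, label="KL divergence (nats)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# -- persistence -----------------------------------------------------------


def _dist_doc(d: Distribution) -> dict:
    return {
        "family": d.family,
        "location": d.location,
        "scale": d.scale,
        "lower_bound": None if not math.isfinite(d.lower_bound) else d.lower_bound,
        "upper_bound": None if not math.isfinite(d.upper_bound) else d.upper_bound,
    }


def _dist_undoc(doc: dict) -> Distribution:
    return Distribution(
        family=doc["family"],
        location=doc["location"],
        scale=doc["scale"],
        lower_bound=-math.inf if doc.get("lower_bound") is None else doc["lower_bound"],
        upper_bound=math.inf if doc.get("upper_bound") is None else doc["upper_bound"],
    )


def save_state(state: KnowledgeState, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "label": state.label,
        "physiological": {k: _dist_doc(d) for k, d in state.physiological.items()},
        "drug_specific": {
            drug: {k: _dist_doc(d) for k, d in dists.items()}
            for drug, dists in state.drug_specific.items()
        },
        "provenance": list(state.provenance),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_state(path) -> KnowledgeState:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValidationError(f"unsupported knowledge-state schema {doc.get('schema_version')}")
    return KnowledgeState(
        label=doc["label"],
        physiological={k: _dist_undoc(d) for k, d in doc["physiological"].items()},
        drug_specific={
            drug: {k: _dist_undoc(d) for k, d in dists.items()}
            for drug, dists in doc["drug_specific"].items()
        },
        provenance=tuple(doc["provenance"]),
    )
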