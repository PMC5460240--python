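"""End-to-end workflow execution: generate → learn ×3 → predict → evaluate.

Produces a self-describing artifact bundle on disk: cohort tables,
knowledge states, population bands, evaluation metrics, the learning
heat map, and a manifest with a SHA-256 hash per text artifact plus the
configuration hash — rerunning with the same configuration reproduces the
manifest bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import constants
from .config import RunConfig
from .drugs import midazolam_mean_model, torsemide_mean_model
from .evalstats import normalized_rmse
from .population import AnthropometricRanges, population_simulation
from .synth import (
    Administration,
    DISEASED_OBESE_FRACTION,
    STUDY_DOSES_MG,
    STUDY_TIMES,
    diseased_truth,
    generate_cohort,
    healthy_truth,
    write_cohort,
)
from .workflow import (
    StepConfig,
    compose_state,
    initial_knowledge,
    learn_step,
    learning_heatmap,
    plot_heatmap,
    predict_step,
    save_state,
)

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def default_administrations() -> tuple[Administration, Administration]:
    mp, mm = midazolam_mean_model()
    tp, tm = torsemide_mean_model()
    return (
        Administration(mp, mm, STUDY_DOSES_MG["midazolam"]),
        Administration(tp, tm, STUDY_DOSES_MG["torsemide"]),
    )


def run_workflow(config: RunConfig) -> dict:
    """Execute the full translational workflow under one configuration.

    Returns the artifact bundle (states, bands, metrics, manifest path);
    every file written is listed in ``manifest.json`` with its hash.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    mid, tor = default_administrations()
    step = lambda label, seed: StepConfig(  # noqa: E731 - shared settings
        label=label,
        seed=seed,
        n_iter=config.n_iter,
        max_individuals=config.max_individuals,
        rhat_threshold=config.rhat_threshold,
        force=config.force,
    )

    # -- synthetic study data
    healthy = generate_cohort(
        healthy_truth(
            [mid, tor],
            n=config.n_healthy,
            seed=config.seeds["healthy_cohort"],
            outlier_fraction=config.outlier_fraction,
        ),
        [mid, tor],
    )
    diseased = generate_cohort(
        diseased_truth([mid, tor], n=config.n_diseased, seed=config.seeds["diseased_cohort"]),
        [mid, tor],
    )
    write_cohort(healthy, out / "cohorts" / "healthy")
    write_cohort(diseased, out / "cohorts" / "diseased")

    # -- learning steps
    initial = initial_knowledge([mid, tor])
    mh, _ = learn_step(initial, healthy, mid, step("mh", config.seeds["step1"]))
    th_start = compose_state("th_start", physiological_from=mh,
                             drug_specific_from=[(initial, [tor.parent.name, tor.metabolite.name])])
    th, _ = learn_step(th_start, healthy, tor, step("th", config.seeds["step2"]))
    md_phys = initial if config.step3_physiology_source == "initial" else mh
    md_start = compose_state("md_start", physiological_from=md_phys,
                             drug_specific_from=[(mh, [mid.parent.name, mid.metabolite.name])])
    md, _ = learn_step(md_start, diseased, mid, step("md", config.seeds["step3"]))

    # -- de-novo prediction of the candidate drug in the diseased cohort
    times = np.array(STUDY_TIMES)
    predicted_bands, td_state = predict_step(
        drug_knowledge=th,
        physiology_knowledge=md,
        adm=tor,
        times=times,
        n_virtual=config.n_virtual,
        seed=config.seeds["step4"],
        ranges=AnthropometricRanges.diseased(),
        obese_fraction=DISEASED_OBESE_FRACTION,
    )

    # -- benchmark: initial knowledge only ("as in step one"), i.e. the
    # pre-study mean-value state without any diseased-cohort information —
    # healthy anthropometric assumptions included
    initial_bands = population_simulation(
        initial_knowledge([tor]).all_distributions(),
        n=config.n_virtual,
        parent=tor.parent,
        metabolite=tor.metabolite,
        dose_mg=tor.dose_mg,
        times=times,
        seed=config.seeds["step4"],
        ranges=AnthropometricRanges.healthy(),
    )
    retro_start = compose_state(
        "retro_start", physiological_from=md,
        drug_specific_from=[(th, [tor.parent.name, tor.metabolite.name])],
    )
    retro, _ = learn_step(
        retro_start, diseased, tor, step("retrospective", config.seeds["retrospective"])
    )
    retro_bands = population_simulation(
        retro.all_distributions(),
        n=config.n_virtual,
        parent=tor.parent,
        metabolite=tor.metabolite,
        dose_mg=tor.dose_mg,
        times=times,
        seed=config.seeds["step4"],
        ranges=AnthropometricRanges.diseased(),
        obese_fraction=DISEASED_OBESE_FRACTION,
    )

    # -- quantitative assessment: normalized RMSE vs the initial benchmark
    metrics = {"config_hash": cfg_hash, "normalized_rmse": {}}
    for compound in (tor.parent.name, tor.metabolite.name):
        datasets = [p for p in diseased.profiles if p.compound == compound]
        ref = initial_bands.summaries[compound]["median"]
        metrics["normalized_rmse"][compound] = {
            "initial": normalized_rmse(ref, datasets, ref, times, config.weighting),
            "predicted": normalized_rmse(
                predicted_bands.summaries[compound]["median"], datasets, ref, times,
                config.weighting,
            ),
            "retrospective": normalized_rmse(
                retro_bands.summaries[compound]["median"], datasets, ref, times,
                config.weighting,
            ),
        }

    # -- learning progression
    heatmap = learning_heatmap([mh, th, md, retro], baseline=initial)

    # -- persist everything
    states_dir = out / "states"
    states_dir.mkdir(exist_ok=True)
    states = {"mh": mh, "th": th, "md": md, "td": td_state, "retrospective": retro}
    for name, st in states.items():
        save_state(st, states_dir / f"{name}.json")
    predicted_bands.to_frame().to_csv(out / "predicted_bands.csv", index=False)
    initial_bands.to_frame().to_csv(out / "initial_bands.csv", index=False)
    retro_bands.to_frame().to_csv(out / "retrospective_bands.csv", index=False)
    heatmap.to_csv(out / "learning_heatmap.csv")
    plot_heatmap(heatmap, out / "learning_heatmap.png")
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1))

    text_artifacts = sorted(
        p for p in out.rglob("*")
        if p.is_file() and p.suffix in (".csv", ".json") and p.name != "manifest.json"
    )
    manifest = {
        "config_hash": cfg_hash,
        "solver": {
            "method": constants.SOLVER_METHOD,
            "rtol": constants.SOLVER_RTOL,
            "atol": constants.SOLVER_ATOL,
        },
        "files": {str(p.relative_to(out)): _sha256(p) for p in text_artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "states": states,
        "bands": {
            "predicted": predicted_bands,
            "initial": initial_bands,
            "retrospective": retro_bands,
        },
        "metrics": metrics,
        "heatmap": heatmap,
        "manifest": manifest,
        "output_dir": str(out),
        "cohorts": {"healthy": healthy, "diseased": diseased},
    }
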