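"""Non-compartmental PK metrics, model-fit RMSE measures, and cohort statistics.

The normalized RMSE convention: the agreement of a candidate median curve
with a set of observed datasets is divided by the agreement of a reference
curve (the initial mean-value model) with the same datasets, so the
reference scores exactly 1 by construction and values below 1 mean the
candidate describes the data better than the initial knowledge did.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .pbpk.types import ConcentrationProfile, ValidationError

logger = logging.getLogger(__name__)


# -- non-compartmental analysis -------------------------------------------


def nca(profile: ConcentrationProfile, body_weight: Optional[float] = None) -> dict:
    """Cmax, tmax and linear-trapezoid AUC over the observed span.

    ``cmax`` is the maximum observed concentration, ``tmax`` its time
    (earliest on ties), ``auc_0_t`` the trapezoidal area over the sampled
    interval (µmol·h/l).  With ``body_weight`` given, weight-normalized
    variants are included (negative body-weight correlation of exposure is
    the reason cohort comparisons use them).
    """
    if len(profile) < 2:
        raise ValidationError("NCA needs at least two time points")
    t, c = profile.times, profile.concentrations
    i_max = int(np.argmax(c))  # argmax returns the earliest maximum
    out = {
        "cmax": float(c[i_max]),
        "tmax": float(t[i_max]),
        "auc_0_t": float(np.trapezoid(c, t)),
    }
    if body_weight is not None:
        if body_weight <= 0:
            raise ValidationError("body weight must be positive")
        out["cmax_per_kg"] = out["cmax"] / body_weight
        out["auc_per_kg"] = out["auc_0_t"] / body_weight
    return out


# -- RMSE measures ---------------------------------------------------------


def weighted_rmse(
    simulated: np.ndarray,
    observed: np.ndarray,
    weighting: str = "relative",
) -> float:
    """Root-mean-square error of weighted residuals.

    ``relative`` weighting divides each residual by the observed value
    (scale-invariant, the package default); ``none`` uses raw residuals.
    Observed zeros under relative weighting fall back to the raw residual
    for that point (logged), since a relative residual is undefined there.
    """
    sim = np.asarray(simulated, float)
    obs = np.asarray(observed, float)
    if sim.shape != obs.shape:
        raise ValidationError("simulated and observed grids must match")
    resid = sim - obs
    if weighting == "relative":
        zero = obs == 0.0
        if np.any(zero):
            logger.info(
                "relative weighting: %d zero observations switched to additive weight",
                int(zero.sum()),
            )
        w = np.where(zero, 1.0, obs)
        resid = resid / w
    elif weighting != "none":
        raise ValidationError(f"unknown weighting {weighting!r}")
    return float(np.sqrt(np.mean(resid**2)))


def _pooled_rmse(curve: np.ndarray, datasets: Sequence[ConcentrationProfile],
                 times: np.ndarray, weighting: str) -> float:
    sims, obs = [], []
    for ds in datasets:
        if ds.times.shape != times.shape or not np.allclose(ds.times, times):
            raise ValidationError(
                f"dataset {ds.individual_id!r} is not on the evaluation grid"
            )
        sims.append(curve)
        obs.append(ds.concentrations)
    return weighted_rmse(np.concatenate(sims), np.concatenate(obs), weighting=weighting)


def normalized_rmse(
    median_curve: np.ndarray,
    datasets: Sequence[ConcentrationProfile],
    reference_curve: np.ndarray,
    times: Optional[np.ndarray] = None,
    weighting: str = "relative",
) -> float:
    """RMSE of the candidate curve divided by RMSE of the reference curve.

    Both curves are evaluated against the pooled (individual, time)
    residuals of all datasets; the reference scores exactly 1 against
    itself by construction.
    """
    if not datasets:
        raise ValidationError("normalized RMSE needs at least one dataset")
    times = datasets[0].times if times is None else np.asarray(times, float)
    ref = _pooled_rmse(np.asarray(reference_curve, float), datasets, times, weighting)
    if ref == 0.0:
        raise ValidationError("reference RMSE is zero; normalization undefined")
    cand = _pooled_rmse(np.asarray(median_curve, float), datasets, times, weighting)
    return cand / ref


# -- cohort statistics -----------------------------------------------------


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> dict:
    """Pearson's r with the two-sided p-value of the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("correlation needs ≥3 paired finite values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("correlation inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p)}


def two_sample_t(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> dict:
    """Welch two-sample t-test; ``significant`` at the given level (default 0.05)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs n ≥ 2")
    if np.std(a) == 0 and np.std(b) == 0:
        raise ValidationError("degenerate samples: both have zero variance")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(p), "significant": bool(p < alpha)}


# -- liver-histology activity score ---------------------------------------

_GRADE_RANGES = {"steatosis": (0, 3), "lobular_inflammation": (0, 3), "ballooning": (0, 2)}


@dataclass(frozen=True)
class NasComponents:
    """Histological component grades of the NAFLD activity score."""

    steatosis: int
    lobular_inflammation: int
    ballooning: int

    def __post_init__(self) -> None:
        for name, (lo, hi) in _GRADE_RANGES.items():
            g = getattr(self, name)
            if not isinstance(g, (int, np.integer)) or not (lo <= g <= hi):
                raise ValidationError(f"{name} grade {g!r} outside valid range [{lo},{hi}]")


def nas_score(c: NasComponents) -> dict:
    """Unweighted component sum with the standard diagnostic category.

    Score ≥ 5 → NASH; 3–4 → mild steatosis; < 3 → not NASH.
    """
    score = int(c.steatosis + c.lobular_inflammation + c.ballooning)
    if score >= 5:
        category = "NASH"
    elif score >= 3:
        category = "mild steatosis"
    else:
        category = "not NASH"
    return {"score": score, "category": category}


def nca_table(
    profiles: Iterable[ConcentrationProfile],
    body_weights: Optional[dict[str, float]] = None,
):
    """NCA metrics for a collection of profiles as a tidy DataFrame."""
    import pandas as pd

    rows = []
    for p in profiles:
        bw = body_weights.get(p.individual_id) if body_weights else None
        rows.append({"individual_id": p.individual_id, "compound": p.compound, **nca(p, bw)})
    return pd.DataFrame(rows)
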