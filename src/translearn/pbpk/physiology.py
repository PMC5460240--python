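"""Construction of individual physiologies from anthropometrics.

The reference organism is a 73 kg adult; organ volumes, plasma flows and
enzyme expression are rescaled allometrically with body weight (volumes and
expression linearly, perfusion with the 3/4 power).  The mapping from
anthropometrics to physiology is deliberately simple and fully determined by
the constants module, because the population-inference layer estimates the
physiological parameters that actually matter on top of these baselines.
"""

from __future__ import annotations

from .. import constants
from .types import Physiology


def reference_expression(body_weight: float) -> dict[tuple[str, str], float]:
    """Expression map scaled linearly with body weight (organ mass)."""
    scale = body_weight / constants.REFERENCE_BODY_WEIGHT_KG
    out: dict[tuple[str, str], float] = {}
    for protein, organs in constants.REFERENCE_EXPRESSION.items():
        for organ, amount in organs.items():
            out[(protein, organ)] = amount * scale
    return out


def physiology_from_anthropometrics(
    age: float = 35.0,
    body_weight: float = constants.REFERENCE_BODY_WEIGHT_KG,
    body_height: float = 1.74,
    hematocrit: float = constants.REFERENCE_HEMATOCRIT,
    liver_volume_factor: float = 1.0,
    expression_overrides: dict[tuple[str, str], float] | None = None,
) -> Physiology:
    """Build a :class:`Physiology` from age/weight/height.

    ``liver_volume_factor`` is a multiplicative deviation of the liver volume
    from its allometric baseline — the physiological degree of freedom the
    inference layer estimates by default.  ``expression_overrides`` replaces
    individual (protein, organ) expression entries after scaling.
    """
    v_scale = (body_weight / constants.REFERENCE_BODY_WEIGHT_KG) ** (
        constants.ALLOMETRIC_EXPONENT_VOLUME
    )
    q_scale = (body_weight / constants.REFERENCE_BODY_WEIGHT_KG) ** (
        constants.ALLOMETRIC_EXPONENT_FLOW
    )
    volumes = {k: v * v_scale for k, v in constants.REFERENCE_ORGAN_VOLUMES_L.items()}
    volumes["liver"] *= liver_volume_factor
    flows = {
        k: q * q_scale for k, q in constants.REFERENCE_PLASMA_FLOWS_L_PER_MIN.items()
    }
    expression = reference_expression(body_weight)
    if expression_overrides:
        expression.update(expression_overrides)
    return Physiology(
        age=age,
        body_weight=body_weight,
        body_height=body_height,
        organ_volumes=volumes,
        organ_flows=flows,
        hematocrit=hematocrit,
        expression=expression,
    )


def default_physiology() -> Physiology:
    """The reference mean individual."""
    return physiology_from_anthropometrics()
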