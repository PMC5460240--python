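"""Run configuration: schema, validation and hashing.

Every stochastic stage of the pipeline must carry an explicit seed — there
is no hidden global random state — and every output embeds the
configuration hash so a result can be traced to the exact settings that
produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import yaml

from .pbpk.types import ValidationError

#: Stages that consume randomness; each needs a seed in the config.
SEED_STAGES = (
    "healthy_cohort",
    "diseased_cohort",
    "step1",
    "step2",
    "step3",
    "step4",
    "retrospective",
)


@dataclass(frozen=True)
class RunConfig:
    """Validated settings of one full workflow run."""

    seeds: dict[str, int]
    output_dir: str = "out"
    n_healthy: int = 20
    n_diseased: int = 20
    outlier_fraction: float = 0.05
    n_iter: int = 20_000
    max_individuals: int = 20
    rhat_threshold: float = 1.1
    force: bool = False
    n_virtual: int = 500
    weighting: str = "relative"
    step3_physiology_source: str = "initial"  # initial | step1

    def __post_init__(self) -> None:
        missing = [s for s in SEED_STAGES if s not in self.seeds]
        if missing:
            raise ValidationError(f"seeds: missing explicit seed for stage(s) {missing}")
        for stage, seed in self.seeds.items():
            if not isinstance(seed, int):
                raise ValidationError(f"seeds.{stage}: seed must be an integer, got {seed!r}")
        if self.n_healthy < 1 or self.n_diseased < 1:
            raise ValidationError("n_healthy/n_diseased: cohort sizes must be ≥ 1")
        if self.n_iter < 200:
            raise ValidationError("n_iter: need at least 200 iterations")
        if not (0.0 <= self.outlier_fraction <= 1.0):
            raise ValidationError("outlier_fraction: must lie in [0, 1]")
        if self.weighting not in ("relative", "none"):
            raise ValidationError(f"weighting: unknown scheme {self.weighting!r}")
        if self.step3_physiology_source not in ("initial", "step1"):
            raise ValidationError(
                "step3_physiology_source: must be 'initial' or 'step1'"
            )
        if self.n_virtual < 2:
            raise ValidationError("n_virtual: need at least 2 virtual individuals")

    @staticmethod
    def from_yaml(path: Union[str, Path]) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        known = set(RunConfig.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config field(s) {sorted(unknown)}")
        try:
            return RunConfig(**doc)
        except TypeError as exc:
            raise ValidationError(f"{path}: {exc}") from exc

    @staticmethod
    def demo(seed: int = 1, output_dir: str = "out") -> "RunConfig":
        """Desk-scale demonstration settings: small cohorts, short chains."""
        return RunConfig(
            seeds={s: seed * 1000 + i for i, s in enumerate(SEED_STAGES)},
            output_dir=output_dir,
            n_healthy=6,
            n_diseased=6,
            n_iter=1200,
            max_individuals=6,
            n_virtual=100,
            force=True,
        )

    def config_hash(self) -> str:
        """Hash of the scientific settings (paths excluded, so the same
        configuration run in two locations produces identical artifacts)."""
        doc = asdict(self)
        doc.pop("output_dir")
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()
        ).hexdigest()[:16]
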