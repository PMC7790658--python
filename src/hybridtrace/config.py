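"""Pipeline configuration: one object every stage reads its parameters from."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds, iteration counts and seeds for the whole pipeline.

    Defaults follow the study design: kappa >= 0.9 declares a marker
    diagnostic, admixture classes are cut at Q = 0.05/0.95, collinearity is
    pruned at |r_s| = 0.7, stepwise selection uses p_in = 0.05 / p_out = 0.10,
    and admixture LD uses 1,000 bootstrap replicates.
    """

    seed: int = 0
    kappa_threshold: float = 0.9
    q_lower: float = 0.05
    q_upper: float = 0.95
    rs_threshold: float = 0.7
    p_in: float = 0.05
    p_out: float = 0.10
    n_boot: int = 1000
    n_permutations: int = 999
    em_max_iter: int = 2000
    em_tol: float = 1e-6
    em_restarts: int = 10
    k_min: int = 1
    k_max: int = 5
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, lo, hi in [("kappa_threshold", -1, 1), ("q_lower", 0, 1),
                             ("q_upper", 0, 1), ("rs_threshold", 0, 1),
                             ("p_in", 0, 1), ("p_out", 0, 1)]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.q_lower >= self.q_upper:
            raise ValueError("q_lower must be below q_upper")
        if self.p_in > self.p_out:
            raise ValueError("p_in must not exceed p_out (cycling guard)")
        for name in ("n_boot", "n_permutations", "em_max_iter",
                     "em_restarts", "k_min", "k_max"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
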