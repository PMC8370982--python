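"""Run configuration shared by the test, the CLI and the experiments."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Knobs of one attractor-difference test run.

    Defaults follow the published protocol: 1000 permutations, alpha = 0.05,
    standardization before testing, self-exclusion for within-regime
    forecasts and no wider Theiler window.
    """

    mode: str = "univariate"
    e_max: int | None = None          # None -> min(10, n//2 - 1) per series
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int | None = None
    self_exclusion: bool = True
    theiler: int = 0
    predictor: str | None = None      # multivariate mode: embedded variable
    responses: tuple[str, ...] | None = None  # None -> all others
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("univariate", "multivariate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.theiler < 0:
            raise ValueError("theiler must be >= 0")
        if self.responses is not None:
            object.__setattr__(self, "responses", tuple(self.responses))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a flat key-value YAML document mirroring this dataclass."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
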