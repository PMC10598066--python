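"""Run configuration: every threshold the pipeline applies lives here.

Defaults mirror the screening conditions of the two-strain cataract
study: genes with signal below 5 in every sample are dropped, increases
must exceed 1.5-fold and decreases 2.25-fold, and both the two-sample
test and the homoscedasticity pre-test use alpha = 0.05.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "setup_logging"]


@dataclass
class RunConfig:
    #: minimum fold increase (test/ref ratio must exceed this, strictly)
    up_threshold: float = 1.5
    #: minimum fold decrease (ref/test ratio must exceed this, strictly)
    down_threshold: float = 2.25
    #: genes with signal strictly below this in ALL samples are excluded
    signal_floor: float = 5.0
    #: significance level of the two-sample test
    alpha_test: float = 0.05
    #: significance level of the variance-ratio pre-test
    alpha_homoscedasticity: float = 0.05
    #: master seed for simulation subcommands
    seed: int = 0
    #: panel exclusion: only count homozygous panel carriers if True
    panel_hom_only: bool = False
    #: chromosome allow-list applied when reading variant call sets
    #: (None = keep every contig)
    autosomes: list[str] | None = None
    #: expression input is log2-scale and must be de-logged before ratios
    log2_input: bool = False

    def __post_init__(self) -> None:
        if self.up_threshold <= 1 or self.down_threshold <= 1:
            raise ValueError("fold-change thresholds must be > 1")
        for name in ("alpha_test", "alpha_homoscedasticity"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must be in (0, 1), got {a}")
        if self.signal_floor <= 0:
            raise ValueError("signal_floor must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def setup_logging(level: int = logging.INFO) -> None:
    """Send stage-count logging to standard error."""
    logging.basicConfig(
        stream=sys.stderr,
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
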