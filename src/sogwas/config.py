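"""Run configuration and logging shared by all pipeline stages."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

logger = logging.getLogger("sogwas")


def setup_logging(level: str = "INFO") -> None:
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(getattr(logging, level.upper()))


@dataclass
class RunConfig:
    """Pipeline-wide options.

    Defaults follow the analysis conventions for hybrid maize panels:
    markers with panel MAF below 5% are discarded, a contrast is only
    tested when every SO class it involves has at least 5 carriers,
    discoveries are controlled at FDR 0.05, and LD windows start at
    0.5 cM, grow in 0.1 cM steps and use an r-squared threshold of 0.1.
    """

    traits: list[str] = field(default_factory=lambda: ["trait"])
    fdr_level: float = 0.05
    maf_threshold: float = 0.05
    min_so_class: int = 5
    ld_init_window_cm: float = 0.5
    ld_step_cm: float = 0.1
    ld_r2_threshold: float = 0.1
    density_filter_offset: int = 15
    outlier_filter: bool = False
    outlier_k: float = 3.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
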