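"""Configuration: documented defaults, optional YAML overrides."""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .algebra import DEFAULT_LOOP_BOUND, DEFAULT_STATE_CAP
from .engine import DEFAULT_TAU_CAP

__all__ = ["Config", "load_config", "setup_logging"]


@dataclass
class Config:
    store_path: str = "npdl.db"       # sqlite file; ":memory:" for ephemeral
    loop_bound: int = DEFAULT_LOOP_BOUND   # repetition unrollings in analyses
    state_cap: int = DEFAULT_STATE_CAP     # residual states per enumeration
    tau_cap: int = DEFAULT_TAU_CAP         # consecutive silent auto-steps
    seed: int = 0                          # seed for synthetic generation
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        for cap in ("loop_bound", "state_cap", "tau_cap"):
            if getattr(self, cap) < 1:
                raise ValueError(f"{cap} must be positive")


def load_config(path: Optional[str] = None) -> Config:
    """Load configuration from a YAML file; a missing file means defaults."""
    if path is None or not Path(path).exists():
        return Config()
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {k: v for k, v in data.items() if k in Config.__dataclass_fields__}
    return Config(**known)


def setup_logging(level: str = "WARNING") -> None:
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, level.upper()),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
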