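"""Run configuration: YAML in, validated :class:`RunConfig` out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "ASSAYS"]

log = logging.getLogger("endopolar")

#: the assays the CLI knows how to run
ASSAYS = ("simulate", "polarity", "invadopodia", "linescan", "coloc",
          "degradation", "invasion")

#: documented default used whenever a config omits the seed
DEFAULT_SEED = 0


@dataclass
class RunConfig:
    """Validated configuration of one analysis run.

    ``channels`` maps roles (e.g. ``nucleus``, ``endosome``, ``marker``)
    to channel names or indices of the input stacks; ``params`` carries
    assay-specific segmentation/analysis parameters passed through to
    the library functions.
    """

    assay: str
    inputs: list[str] = field(default_factory=list)
    channels: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    control_label: str = "control"
    out_dir: str = "results"
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; "
                             f"expected one of {ASSAYS}")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown top-level keys are rejected (they usually indicate a typo);
    omitted optional keys take their documented defaults, which are
    logged at INFO level.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "assay" not in raw:
        raise ValueError(f"{path}: missing required key 'assay'")
    cfg = RunConfig(**raw)
    for f in fields(RunConfig):
        if f.name not in raw:
            log.info("config %s: using default %s=%r", path.name, f.name,
                     getattr(cfg, f.name))
    return cfg
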