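"""Data and configuration I/O.

Time courses travel as tidy long-format CSV (``time_s`` in seconds,
``species``, ``replicate``, ``value`` in molecules per platelet) — long
format copes with uneven species coverage in inhibitor experiments.
Parameter sets serialise to flat JSON with the variant id and units
recorded; run configurations round-trip through YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .dataset import TimeCourseDataset
from .models import VARIANT_IDS, build_model

__all__ = [
    "read_timecourse",
    "write_timecourse",
    "save_parameters",
    "load_parameters",
    "RunConfig",
]


def read_timecourse(path) -> TimeCourseDataset:
    """Read and validate a tidy time-course CSV.

    Requires the header ``time_s,species,replicate,value``, the six
    observed species, non-negative values and no duplicate
    (time, species, replicate) rows; violations raise with the offending
    label.
    """
    frame = pd.read_csv(path)
    return TimeCourseDataset(frame)


def write_timecourse(dataset: TimeCourseDataset, path) -> None:
    dataset.to_csv(path)


def save_parameters(params: Mapping[str, float], variant_id: str, path) -> None:
    """Flat JSON parameter file: name -> value plus variant id and units."""
    spec = build_model(variant_id)
    payload = {
        "variant": variant_id,
        "units": spec.parameter_units(),
        "parameters": {k: float(v) for k, v in params.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_parameters(path) -> tuple[dict[str, float], str]:
    """Inverse of :func:`save_parameters`; returns (parameters, variant_id)."""
    payload = json.loads(Path(path).read_text())
    return dict(payload["parameters"]), payload["variant"]


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    All seeds are explicit; the config round-trips through YAML unchanged.
    ``dataset`` is a CSV path, or None to use the synthetic generator with
    ``noise_cv``/``noise_seed``/``n_replicates``.
    """

    variants: list[str] = field(default_factory=lambda: list(VARIANT_IDS))
    dataset: str | None = None
    noise_cv: float = 0.20
    noise_seed: int = 0
    n_replicates: int = 3
    n_starts: int = 200
    sampling_seed: int = 0
    log10_lo: float = -4.0
    log10_hi: float = 2.0
    rtol: float = 1e-6
    atol: float = 1e-3
    scenarios: list[str] = field(
        default_factory=lambda: ["reduced-plateau", "early-peak", "combined"])
    output_dir: str = "ppiflux-out"

    def __post_init__(self) -> None:
        unknown = [v for v in self.variants if v not in VARIANT_IDS]
        if unknown:
            raise ValueError(f"unknown variants in config: {unknown}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
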