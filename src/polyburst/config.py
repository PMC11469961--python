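"""Run configuration for movie-based analyses.

A :class:`RunConfig` captures the acquisition grid of a live-cell
nascent-transcription movie (frame interval, total duration), the
permissive-period gap rule, the photobleaching rate of the fluorescent
coat protein, and the average allele count per cell.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["RunConfig", "load_config"]


@dataclasses.dataclass
class RunConfig:
    """Acquisition and analysis settings shared by the pipeline stages.

    Parameters
    ----------
    frame_interval_min:
        Time between consecutive movie frames, minutes.
    movie_duration_h:
        Total movie duration, hours.
    permissive_gap_min:
        Maximum separation between consecutive ON periods that still
        places them in the same permissive period, minutes.
    bleach_rate_per_frame:
        Exponential photobleaching rate of the coat-protein signal per
        frame (dimensionless).
    n_alleles:
        Average number of alleles per cell (ES cells spend most of the
        cycle in S phase, hence the default of three).
    rng_seed:
        Seed for every stochastic step driven by this configuration.
    """

    frame_interval_min: float = 4.0
    movie_duration_h: float = 8.0
    permissive_gap_min: float = 60.0
    bleach_rate_per_frame: float = 0.05
    n_alleles: int = 3
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for field in ("frame_interval_min", "movie_duration_h", "permissive_gap_min"):
            if getattr(self, field) <= 0:
                raise ValidationError(f"{field} must be > 0, got {getattr(self, field)}")
        if not 0 < self.bleach_rate_per_frame < 1:
            raise ValidationError(
                f"bleach_rate_per_frame must lie in (0, 1), got {self.bleach_rate_per_frame}"
            )
        if self.n_alleles < 1:
            raise ValidationError(f"n_alleles must be >= 1, got {self.n_alleles}")

    @property
    def n_frames(self) -> int:
        """Number of frames on the movie grid (frame 0 included)."""
        return int(round(self.movie_duration_h * 60.0 / self.frame_interval_min))

    @property
    def movie_duration_min(self) -> float:
        return self.movie_duration_h * 60.0


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a JSON or YAML file.

    Unspecified fields take the dataclass defaults; unknown keys raise a
    :class:`~polyburst.errors.ValidationError` naming the key. YAML is a
    superset of JSON, so both dialects are parsed by the same reader.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config field(s): {sorted(unknown)}")
    return RunConfig(**data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a configuration back to disk as JSON (valid YAML too)."""
    Path(path).write_text(json.dumps(dataclasses.asdict(cfg), indent=2))
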