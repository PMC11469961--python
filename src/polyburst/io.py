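"""Readers and writers for the tabular formats used across the pipeline.

All on-disk tables are CSV with a header row (tab-separated input is
accepted by sniffing). Times are minutes, trajectory coordinates
micrometres, SPT coordinates nanometres, and frame indices 0-based.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "SpotRecord",
    "read_spot_table",
    "write_spot_table",
    "read_on_periods",
    "write_on_periods",
    "read_distribution",
    "write_distribution",
    "read_localizations",
    "write_localizations",
    "write_results",
]

SPOT_COLUMNS = (
    "cell_id",
    "frame",
    "time_min",
    "x_um",
    "y_um",
    "z_um",
    "intensity_au",
    "volume_voxels",
)


@dataclasses.dataclass
class SpotRecord:
    """One detected 3D spot in one movie frame of one cell.

    Mirrors the per-frame output of 3D object counting on background-
    subtracted coat-protein images: centre of gravity, integrated
    intensity and volume. Frames with no detected spot simply have no
    record.
    """

    cell_id: str
    frame: int
    time_min: float
    x_um: float
    y_um: float
    z_um: float
    intensity_au: float
    volume_voxels: int

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValidationError(f"frame must be >= 0, got {self.frame}")
        if self.intensity_au < 0:
            raise ValidationError(f"intensity_au must be >= 0, got {self.intensity_au}")
        if self.volume_voxels < 0:
            raise ValidationError(f"volume_voxels must be >= 0, got {self.volume_voxels}")


def _read_table(path: str | Path) -> pd.DataFrame:
    # sep=None lets pandas sniff comma vs tab from the header line
    return pd.read_csv(path, sep=None, engine="python")


def read_spot_table(
    path: str | Path, frame_interval: float = 4.0
) -> list[SpotRecord]:
    """Read a spot-detection CSV into :class:`SpotRecord`\\ s.

    Records are returned sorted by ``(cell_id, frame)``. The declared
    frame interval is checked against the ``time_min`` column.
    """
    df = _read_table(path)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"spot table {path} is missing column(s): {missing}")
    if len(df) == 0:
        return []
    if (df["intensity_au"] < 0).any():
        bad = df.loc[df["intensity_au"] < 0].iloc[0]
        raise ValidationError(
            f"negative intensity {bad['intensity_au']} at cell {bad['cell_id']} "
            f"frame {int(bad['frame'])}"
        )
    expected = df["frame"].to_numpy(float) * frame_interval
    if not np.allclose(expected, df["time_min"].to_numpy(float), atol=1e-6):
        raise ValidationError(
            f"time_min column inconsistent with frame * {frame_interval} min"
        )
    df = df.sort_values(["cell_id", "frame"], kind="stable")
    return [
        SpotRecord(
            cell_id=str(r.cell_id),
            frame=int(r.frame),
            time_min=float(r.time_min),
            x_um=float(r.x_um),
            y_um=float(r.y_um),
            z_um=float(r.z_um),
            intensity_au=float(r.intensity_au),
            volume_voxels=int(r.volume_voxels),
        )
        for r in df.itertuples(index=False)
    ]


def spots_to_frame(spots: Iterable[SpotRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in spots], columns=SPOT_COLUMNS)


def write_spot_table(spots: Sequence[SpotRecord], path: str | Path) -> None:
    spots_to_frame(spots).to_csv(path, index=False)


def group_spots_by_cell(spots: Iterable[SpotRecord]) -> dict[str, list[SpotRecord]]:
    grouped: dict[str, list[SpotRecord]] = {}
    for s in spots:
        grouped.setdefault(s.cell_id, []).append(s)
    for recs in grouped.values():
        recs.sort(key=lambda s: s.frame)
    return grouped


# ---------------------------------------------------------------------------
# ON-period tables

ON_COLUMNS = (
    "cell_id",
    "min_frame",
    "max_frame",
    "duration_min",
    "amplitude_transcripts",
    "reinit_rate",
    "reinit_interval_min",
)


def write_on_periods(periods: Sequence, path: str | Path) -> None:
    from .trajectory import OnPeriod  # local import avoids a cycle

    rows = []
    for p in periods:
        if not isinstance(p, OnPeriod):
            raise ValidationError(f"expected OnPeriod, got {type(p).__name__}")
        rows.append(
            {
                "cell_id": p.cell_id,
                "min_frame": p.min_frame,
                "max_frame": p.max_frame,
                "duration_min": p.duration_min,
                "amplitude_transcripts": p.amplitude_transcripts,
                "reinit_rate": p.reinit_rate,
                "reinit_interval_min": p.reinit_interval_min,
            }
        )
    pd.DataFrame(rows, columns=ON_COLUMNS).to_csv(path, index=False)


def read_on_periods(path: str | Path) -> list:
    from .trajectory import OnPeriod

    df = _read_table(path)
    missing = [c for c in ON_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"ON-period table {path} is missing column(s): {missing}")
    out = []
    for r in df.itertuples(index=False):
        out.append(
            OnPeriod(
                cell_id=str(r.cell_id),
                min_frame=int(r.min_frame),
                max_frame=int(r.max_frame),
                duration_min=float(r.duration_min),
                amplitude_transcripts=float(r.amplitude_transcripts),
                reinit_rate=None if pd.isna(r.reinit_rate) else float(r.reinit_rate),
                reinit_interval_min=None
                if pd.isna(r.reinit_interval_min)
                else float(r.reinit_interval_min),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Transcript-per-cell distributions (smRNA-FISH-like histograms)


def write_distribution(dist, path: str | Path) -> None:
    df = pd.DataFrame(
        {"transcripts": np.arange(len(dist.counts)), "cells": dist.counts}
    )
    df.to_csv(path, index=False)


def read_distribution(path: str | Path):
    from .expression import TranscriptDistribution

    df = _read_table(path)
    for col in ("transcripts", "cells"):
        if col not in df.columns:
            raise SchemaError(f"distribution table {path} is missing column: {col}")
    n = int(df["transcripts"].max()) + 1 if len(df) else 0
    counts = np.zeros(n, dtype=int)
    counts[df["transcripts"].to_numpy(int)] = df["cells"].to_numpy(int)
    return TranscriptDistribution(counts=counts)


# ---------------------------------------------------------------------------
# SPT localization tables

LOC_COLUMNS = ("frame", "x_nm", "y_nm")


def read_localizations(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    missing = [c for c in LOC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"localization table {path} is missing column(s): {missing}")
    return df.sort_values("frame", kind="stable").reset_index(drop=True)


def write_localizations(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in LOC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"localization frame is missing column(s): {missing}")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Generic dispatcher


def write_results(obj, path: str | Path) -> None:
    """Write any public pipeline output to ``path``.

    Dispatches on the object's type: ON-period lists, transcript
    distributions, spot tables and localization frames go to CSV;
    dataclass reports (dwell fits, mobility fits) go to JSON.
    """
    from .expression import TranscriptDistribution
    from .trajectory import OnPeriod

    path = Path(path)
    if isinstance(obj, TranscriptDistribution):
        write_distribution(obj, path)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    elif isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], OnPeriod):
        write_on_periods(obj, path)
    elif isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], SpotRecord):
        write_spot_table(obj, path)
    elif dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        path.write_text(json.dumps(dataclasses.asdict(obj), indent=2, default=float))
    elif isinstance(obj, (list, tuple)) and not obj:
        pd.DataFrame().to_csv(path, index=False)
    else:
        raise ValidationError(f"do not know how to write {type(obj).__name__}")
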