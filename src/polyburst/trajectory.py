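"""Single-allele nascent-transcription trajectories and ON-period calling.

A nascent-transcription site is followed through a movie by nearest-
neighbour spot association, its intensity trajectory is corrected for
coat-protein photobleaching and calibrated against the fluorescence of a
single pre-mRNA, and transcription ON periods (bursts) are called as
minimum-to-maximum rises of the calibrated signal. Each ON period is
characterised by its duration, its amplitude in transcripts and, when
the amplitude resolves more than 2.5 transcripts, a polymerase
re-initiation rate from a linear fit of the rising flank.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .config import RunConfig
from .errors import AmbiguousStartError, StateError, ValidationError
from .io import SpotRecord

__all__ = [
    "FluorescenceTrajectory",
    "IntensityCalibration",
    "UnitaryIntensity",
    "OnPeriod",
    "ReinitEstimate",
    "follow_site",
    "correct_photobleaching",
    "calibrate_unitary",
    "OnPeriodCaller",
    "call_on_periods",
    "estimate_reinit",
]

#: Amplitude (transcripts) above which the 4-min sampling resolves a
#: re-initiation rate from the rising flank.
REINIT_AMPLITUDE_THRESHOLD = 2.5


@dataclasses.dataclass
class FluorescenceTrajectory:
    """Intensity time series of one allele's transcription site.

    ``intensity_au`` holds one value per movie frame, 0 where no spot
    was detected. ``bleach_corrected`` records whether the exponential
    photobleaching correction has been applied.
    """

    cell_id: str
    frame_interval_min: float
    intensity_au: np.ndarray
    bleach_corrected: bool = False

    def __post_init__(self) -> None:
        self.intensity_au = np.asarray(self.intensity_au, dtype=float)
        if self.frame_interval_min <= 0:
            raise ValidationError("frame_interval_min must be > 0")
        if (self.intensity_au < 0).any():
            raise ValidationError("trajectory intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return len(self.intensity_au)

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min


@dataclasses.dataclass
class IntensityCalibration:
    """Optical corrections mapping single pre-mRNA imaging to movie units.

    Single pre-mRNAs are imaged with a higher-magnification lens that
    passes a fraction ``lens_ratio`` of the light, and with
    ``excitation_ratio``-fold stronger excitation than the movies; the
    measured intensities are multiplied by ``1/lens_ratio`` and divided
    by ``excitation_ratio`` to express them on the movie scale.
    """

    lens_ratio: float = 0.5723
    excitation_ratio: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.lens_ratio <= 1:
            raise ValidationError(f"lens_ratio must lie in (0, 1], got {self.lens_ratio}")
        if self.excitation_ratio < 1:
            raise ValidationError(
                f"excitation_ratio must be >= 1, got {self.excitation_ratio}"
            )

    @property
    def lens_factor(self) -> float:
        """Multiplicative lens correction, 1/lens_ratio (1.747 by default)."""
        return 1.0 / self.lens_ratio

    @property
    def total_factor(self) -> float:
        return self.lens_factor / self.excitation_ratio


@dataclasses.dataclass
class UnitaryIntensity:
    """Fluorescence contributed by a single nascent transcript (a.u.)."""

    mean_au: float = 330.0
    sd_au: float = 120.0

    def __post_init__(self) -> None:
        if self.mean_au <= 0:
            raise ValidationError(f"mean_au must be > 0, got {self.mean_au}")
        if self.sd_au < 0:
            raise ValidationError(f"sd_au must be >= 0, got {self.sd_au}")


@dataclasses.dataclass
class OnPeriod:
    """One called transcription burst.

    ``min_frame`` is the quiescent frame the rise starts from and
    ``max_frame`` the frame where the steep increase stops. Amplitude is
    the calibrated intensity gain over the period, in transcripts.
    ``reinit_rate`` (transcripts/min) is defined only for amplitudes
    above 2.5 transcripts.
    """

    min_frame: int
    max_frame: int
    duration_min: float
    amplitude_transcripts: float
    reinit_rate: float | None = None
    reinit_interval_min: float | None = None
    cell_id: str = ""

    def __post_init__(self) -> None:
        if self.min_frame >= self.max_frame:
            raise ValidationError(
                f"min_frame ({self.min_frame}) must precede max_frame ({self.max_frame})"
            )
        if self.amplitude_transcripts <= 0:
            raise ValidationError("amplitude must be > 0 transcripts")


@dataclasses.dataclass
class ReinitEstimate:
    """Linear-fit slope of a rising flank and its reciprocal."""

    rate_per_min: float
    interval_min: float | None


# ---------------------------------------------------------------------------
# Spot following


def follow_site(
    spots: Sequence[SpotRecord],
    n_frames: int | None = None,
    initial_choice: int | None = None,
    frame_interval_min: float = 4.0,
    max_jump_um: float | None = 5.0,
) -> FluorescenceTrajectory:
    """Assemble one allele's intensity trajectory from per-frame spots.

    At frames with several detected spots (extra transcription sites or
    diffusing single pre-mRNAs) the spot with the shortest 3D Euclidean
    distance to the spot followed in the preceding occupied frame is
    chosen, and its position becomes the new reference. Frames without
    spots contribute intensity 0 and leave the reference unchanged.

    A transcription site drifts slowly, so a nearest spot farther than
    ``max_jump_um`` from the reference (a diffusing pre-mRNA elsewhere
    in the nucleus while the site is dark) is not followed: the frame is
    recorded as empty and the reference kept. Set ``max_jump_um=None``
    to disable the gate.

    Parameters
    ----------
    spots:
        Records of a single cell, any order.
    n_frames:
        Length of the movie grid; defaults to ``max(frame) + 1``.
    initial_choice:
        Index into the first occupied frame's spot list, required only
        when that frame is ambiguous (more than one spot).
    max_jump_um:
        Maximum allowed displacement of the followed spot between
        occupied frames, micrometres.
    """
    if not spots:
        raise ValidationError("no spots supplied")
    cell_ids = {s.cell_id for s in spots}
    if len(cell_ids) > 1:
        raise ValidationError(f"spots from several cells: {sorted(cell_ids)}")
    if n_frames is None:
        n_frames = max(s.frame for s in spots) + 1

    by_frame: dict[int, list[SpotRecord]] = {}
    for s in spots:
        by_frame.setdefault(s.frame, []).append(s)

    intensity = np.zeros(n_frames)
    reference: np.ndarray | None = None
    for frame in range(n_frames):
        candidates = by_frame.get(frame)
        if not candidates:
            continue
        if reference is None:
            if len(candidates) > 1:
                if initial_choice is None:
                    raise AmbiguousStartError(
                        f"frame {frame} has {len(candidates)} spots; "
                        "supply initial_choice to pick the transcription site"
                    )
                chosen = candidates[initial_choice]
            else:
                chosen = candidates[0]
        else:
            dists = [
                math.dist(reference, (c.x_um, c.y_um, c.z_um)) for c in candidates
            ]
            nearest = int(np.argmin(dists))
            if max_jump_um is not None and dists[nearest] > max_jump_um:
                continue  # no plausible site spot this frame
            chosen = candidates[nearest]
        reference = np.array([chosen.x_um, chosen.y_um, chosen.z_um])
        intensity[frame] = chosen.intensity_au
    return FluorescenceTrajectory(
        cell_id=next(iter(cell_ids)),
        frame_interval_min=frame_interval_min,
        intensity_au=intensity,
    )


# ---------------------------------------------------------------------------
# Photobleaching and unitary-intensity calibration


def correct_photobleaching(
    traj: FluorescenceTrajectory, rate: float = 0.05
) -> FluorescenceTrajectory:
    """Undo exponential coat-protein photobleaching.

    Frame ``i`` is divided by the fitted bleach curve ``exp(-rate * i)``,
    i.e. multiplied by ``exp(rate * i)``. Applying the correction twice
    is an error.
    """
    if traj.bleach_corrected:
        raise StateError("trajectory is already bleach-corrected")
    if rate < 0:
        raise ValidationError(f"bleach rate must be >= 0, got {rate}")
    factors = np.exp(rate * np.arange(traj.n_frames))
    return FluorescenceTrajectory(
        cell_id=traj.cell_id,
        frame_interval_min=traj.frame_interval_min,
        intensity_au=traj.intensity_au * factors,
        bleach_corrected=True,
    )


def calibrate_unitary(
    raw_intensities: Sequence[float],
    cal: IntensityCalibration | None = None,
) -> UnitaryIntensity:
    """Calibrate single pre-mRNA intensities to the movie imaging scale.

    Each measured intensity is multiplied by ``1/lens_ratio`` (1.747 by
    default) and divided by ``excitation_ratio`` (3 by default); the
    corrected sample is summarised by its mean and standard deviation
    (normal fit by moments).
    """
    cal = cal or IntensityCalibration()
    x = np.asarray(raw_intensities, dtype=float)
    if x.size < 2:
        raise ValidationError(f"need >= 2 intensity samples, got {x.size}")
    corrected = x * cal.total_factor
    return UnitaryIntensity(
        mean_au=float(corrected.mean()), sd_au=float(corrected.std(ddof=1))
    )


# ---------------------------------------------------------------------------
# ON-period calling


def _classify_extrema(x: np.ndarray, max_strength: int = 3):
    """Label each frame as a candidate maximum/minimum with a strength.

    A frame is a maximum of strength ``k`` if it is at least as large as
    every frame within ``±k`` and strictly larger than its predecessor
    (so a plateau is represented by its first frame, where the steep
    rise stops). A nonzero frame is a minimum of strength ``k`` if it is
    at most every frame within ``±k`` and its successor rises (a minimal
    plateau is represented by its last frame, from which the next rise
    starts). Frames with intensity 0 — no detected spot — are set as
    global minima (strength ``max_strength``).
    """
    n = len(x)
    max_strength_of = np.zeros(n, dtype=int)
    min_strength_of = np.zeros(n, dtype=int)
    for i in range(n):
        if x[i] == 0:
            min_strength_of[i] = max_strength
            continue
        for k in range(1, max_strength + 1):
            lo, hi = max(0, i - k), min(n, i + k + 1)
            window = x[lo:hi]
            if i > 0 and x[i] > x[i - 1] and x[i] >= window.max():
                max_strength_of[i] = k
            elif i + 1 < n and x[i] < x[i + 1] and x[i] <= window.min() and (
                i == 0 or x[i] <= x[i - 1]
            ):
                min_strength_of[i] = k
            else:
                break
    return max_strength_of, min_strength_of


class OnPeriodCaller:
    """Inflection-point ON-period caller for calibrated trajectories.

    The caller classifies local extrema at three strengths, pairs each
    candidate maximum with its nearest preceding minimum (discarding
    intermediate maxima met before a minimum is found), repositions the
    maximum to the frame where the steep signal increase stops (walking
    back at most ``lookback`` frames for a rise of at least
    ``steep_rise_transcripts`` unitary intensities per frame), and
    extracts duration, amplitude and — above 2.5 transcripts — the
    re-initiation rate of each period.

    Parameters
    ----------
    unitary:
        Single-transcript intensity used to convert a.u. to transcripts.
    steep_rise_transcripts:
        Minimum per-frame rise (in transcripts) still counted as part of
        the steep increase during maximum repositioning.
    lookback:
        Number of preceding frames examined during repositioning.
    """

    def __init__(
        self,
        unitary: UnitaryIntensity,
        steep_rise_transcripts: float = 0.5,
        lookback: int = 5,
        keep_qc: bool = False,
    ) -> None:
        self.unitary = unitary
        self.steep_rise_transcripts = steep_rise_transcripts
        self.lookback = lookback
        self.keep_qc = keep_qc
        self.discarded_maxima_: list[int] = []

    def get_params(self) -> dict:
        return {
            "unitary": self.unitary,
            "steep_rise_transcripts": self.steep_rise_transcripts,
            "lookback": self.lookback,
            "keep_qc": self.keep_qc,
        }

    def call(self, traj: FluorescenceTrajectory) -> list[OnPeriod]:
        if not traj.bleach_corrected:
            raise StateError("trajectory must be bleach-corrected before calling")
        if self.unitary.mean_au <= 0:
            raise ValidationError("unitary mean must be > 0")
        x = traj.intensity_au
        if x.max() == 0:
            return []
        max_s, min_s = _classify_extrema(x)

        # pair each maximum with the nearest preceding minimum; among
        # several maxima sharing one minimum the later ones supersede the
        # earlier ("intermediate") ones, which are discarded
        pairs: list[tuple[int, int]] = []
        discarded: list[int] = []
        current_min: int | None = None
        pending_max: int | None = None
        for i in range(len(x)):
            if min_s[i] > 0:
                if pending_max is not None and current_min is not None:
                    pairs.append((current_min, pending_max))
                    pending_max = None
                current_min = i
            elif max_s[i] > 0 and current_min is not None:
                if pending_max is not None:
                    discarded.append(pending_max)
                pending_max = i
        if pending_max is not None and current_min is not None:
            pairs.append((current_min, pending_max))
        self.discarded_maxima_ = discarded if self.keep_qc else []

        periods: list[OnPeriod] = []
        last_max = -1
        for min_frame, max_frame in pairs:
            max_frame = self._reposition(x, min_frame, max_frame)
            if max_frame <= min_frame or min_frame < last_max:
                continue
            amplitude = (x[max_frame] - x[min_frame]) / self.unitary.mean_au
            if amplitude <= 0:
                continue
            duration = (max_frame - min_frame) * traj.frame_interval_min
            reinit = None
            if amplitude > REINIT_AMPLITUDE_THRESHOLD:
                reinit = estimate_reinit(
                    x[min_frame : max_frame + 1],
                    self.unitary,
                    traj.frame_interval_min,
                )
            periods.append(
                OnPeriod(
                    min_frame=min_frame,
                    max_frame=max_frame,
                    duration_min=duration,
                    amplitude_transcripts=float(amplitude),
                    reinit_rate=None if reinit is None else reinit.rate_per_min,
                    reinit_interval_min=None if reinit is None else reinit.interval_min,
                    cell_id=traj.cell_id,
                )
            )
            last_max = max_frame
        return periods

    def _reposition(self, x: np.ndarray, min_frame: int, max_frame: int) -> int:
        """Move a candidate maximum to where the steep rise stops."""
        threshold = self.steep_rise_transcripts * self.unitary.mean_au
        lo = max(min_frame + 1, max_frame - self.lookback)
        for j in range(max_frame, lo - 1, -1):
            if x[j] - x[j - 1] >= threshold:
                return j
        return max_frame


def call_on_periods(
    traj: FluorescenceTrajectory,
    unitary: UnitaryIntensity,
    cfg: RunConfig | None = None,
) -> list[OnPeriod]:
    """Call ON periods on a bleach-corrected trajectory (thin wrapper
    around :class:`OnPeriodCaller` with default settings)."""
    del cfg  # the caller needs only the trajectory's own frame interval
    return OnPeriodCaller(unitary).call(traj)


def estimate_reinit(
    segment_au: Sequence[float],
    unitary: UnitaryIntensity,
    frame_interval_min: float,
) -> ReinitEstimate | None:
    """Polymerase re-initiation rate from the rising flank of an ON period.

    The intensity segment from the paired minimum to the maximum is
    converted to transcripts and fitted with a least-squares line
    against time in minutes; the slope is the transcript production
    speed and its reciprocal the mean time between initiations. Segments
    shorter than three frames do not constrain a slope and yield
    ``None`` (reported as undefined, not an error).
    """
    y = np.asarray(segment_au, dtype=float) / unitary.mean_au
    if y.size < 3:
        return None
    t = np.arange(y.size) * frame_interval_min
    slope = float(np.polyfit(t, y, 1)[0])
    interval = (1.0 / slope) if slope > 0 else None
    return ReinitEstimate(rate_per_min=slope, interval_min=interval)
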