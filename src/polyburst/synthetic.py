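"""Synthetic-data generators with ground truth for every pipeline stage.

The generators emulate the study conditions of live-cell nascent-
transcription imaging (8-h movies at 4-min frame intervals, unitary
single-transcript intensities ~Normal(330, 120) a.u., exponential
coat-protein photobleaching), smRNA-FISH-like transcript counting,
triptolide decay series, and slow-rate SPT dwell measurements censored
by dye photobleaching. Every generator is a pure function of its
parameters and seed and emits its ground truth alongside the data.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from numpy.random import default_rng

from .config import RunConfig
from .errors import ValidationError
from .expression import ThreeStateParams, sample_amplitude
from .io import SpotRecord
from .trajectory import FluorescenceTrajectory, UnitaryIntensity

__all__ = [
    "TrajectoryTruth",
    "gen_trajectory",
    "gen_spot_table",
    "gen_dwell_data",
    "gen_localizations",
    "gen_decay_series",
]


@dataclasses.dataclass
class TrajectoryTruth:
    """Generated ON and permissive periods behind a synthetic trajectory.

    ON periods are ``(start_min, end_min, amplitude_transcripts)`` where
    ``start_min`` is the last quiescent frame before the rise and
    ``end_min`` the frame where the signal peaks — the same convention
    the ON-period caller reports. Permissive periods run from the first
    member ON period's start to the last member's end.
    """

    on_periods: list[tuple[float, float, int]]
    permissive_periods: list[tuple[float, float]]
    unitary_draws: list[list[float]] = dataclasses.field(default_factory=list)


def gen_trajectory(
    params: ThreeStateParams,
    unitary: UnitaryIntensity | None = None,
    noise_sd: float = 0.0,
    signal_persistence_min: float = 6.0,
    apply_bleach: bool = False,
    seed: int | None = None,
    config: RunConfig | None = None,
) -> tuple[FluorescenceTrajectory, TrajectoryTruth]:
    """Generate one allele's pulsatile nascent-transcription trajectory.

    With probability ``p_op`` the allele enters a permissive period with
    a zero-truncated Poisson(``lambda_on``) number of ON periods, placed
    from a uniformly chosen onset and separated by resampled empirical
    intervals. An ON period of amplitude ``k`` initiates one transcript
    per frame over ``k`` consecutive frames; each initiation adds one
    unitary-intensity draw, transcripts accumulate until the period's
    last initiation and are all released ``signal_persistence_min``
    later, producing the decay flank. Gaussian detection noise is added
    and floored at zero; with ``apply_bleach`` frame ``i`` is multiplied
    by ``exp(-bleach_rate * i)``.
    """
    cfg = config or RunConfig()
    unitary = unitary or UnitaryIntensity()
    if signal_persistence_min <= 0:
        raise ValidationError(
            f"signal_persistence_min must be > 0, got {signal_persistence_min}"
        )
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = default_rng(seed)
    dt = cfg.frame_interval_min
    n_frames = cfg.n_frames
    signal = np.zeros(n_frames)
    truth = TrajectoryTruth(on_periods=[], permissive_periods=[])

    if rng.random() < params.p_op and params.p_op > 0:
        if params.deterministic_on_counts:
            n_on = max(1, int(round(params.lambda_on)))
        else:
            n_on = 0
            while n_on < 1:
                n_on = int(rng.poisson(params.lambda_on))
        # first rise needs a preceding quiescent frame
        start_frame = int(rng.integers(1, max(2, n_frames - 2)))
        flank_frames = int(np.ceil(signal_persistence_min / dt))
        perm_start = None
        perm_end = None
        for j in range(n_on):
            if j > 0:
                gap_min = float(rng.choice(params.intervals_min))
                # a called minimum needs at least one baseline frame
                # between the decay flank and the next rise
                gap_frames = max(flank_frames + 2, int(round(gap_min / dt)))
                start_frame = last_init + gap_frames
            amp = sample_amplitude(params.amplitude, rng)
            init_frames = [start_frame + i for i in range(amp)]
            init_frames = [f for f in init_frames if f < n_frames]
            if not init_frames:
                break
            draws = [
                max(0.0, rng.normal(unitary.mean_au, unitary.sd_au))
                for _ in init_frames
            ]
            last_init = init_frames[-1]
            release_time = last_init * dt + signal_persistence_min
            for f, d in zip(init_frames, draws):
                f_end = int(np.floor(release_time / dt))
                signal[f : min(f_end + 1, n_frames)] += d
            truth.on_periods.append(
                ((init_frames[0] - 1) * dt, last_init * dt, len(init_frames))
            )
            truth.unitary_draws.append(draws)
            if perm_start is None:
                perm_start = (init_frames[0] - 1) * dt
            perm_end = last_init * dt
        if perm_start is not None:
            truth.permissive_periods.append((perm_start, perm_end))

    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=n_frames)
    signal = np.maximum(signal, 0.0)
    if apply_bleach:
        signal = signal * np.exp(-cfg.bleach_rate_per_frame * np.arange(n_frames))
    traj = FluorescenceTrajectory(
        cell_id="synthetic",
        frame_interval_min=dt,
        intensity_au=signal,
        # an unbleached trajectory needs no correction before calling
        bleach_corrected=not apply_bleach,
    )
    return traj, truth


def gen_spot_table(
    trajectory: FluorescenceTrajectory,
    distractor_rate: float = 0.0,
    seed: int | None = None,
    unitary: UnitaryIntensity | None = None,
    nucleus_um: tuple[float, float, float] = (10.0, 10.0, 5.0),
    drift_sd_um: float = 0.03,
) -> list[SpotRecord]:
    """Emit a per-frame spot table for a trajectory.

    The true transcription site drifts slowly in 3D (Gaussian steps of
    ``drift_sd_um`` per axis per frame) and appears only in frames with
    nonzero trajectory intensity. Distractor spots — single diffusing
    pre-mRNAs with intensities drawn from the unitary distribution —
    appear with per-frame probability ``distractor_rate`` at uniformly
    random nuclear positions.
    """
    if not 0 <= distractor_rate <= 1:
        raise ValidationError(f"distractor_rate must lie in [0, 1], got {distractor_rate}")
    unitary = unitary or UnitaryIntensity()
    rng = default_rng(seed)
    box = np.asarray(nucleus_um)
    pos = rng.uniform(0.25 * box, 0.75 * box)
    records: list[SpotRecord] = []
    dt = trajectory.frame_interval_min
    for frame, intensity in enumerate(trajectory.intensity_au):
        pos = np.clip(pos + rng.normal(0.0, drift_sd_um, size=3), 0.0, box)
        if intensity > 0:
            records.append(
                SpotRecord(
                    cell_id=trajectory.cell_id,
                    frame=frame,
                    time_min=frame * dt,
                    x_um=float(pos[0]),
                    y_um=float(pos[1]),
                    z_um=float(pos[2]),
                    intensity_au=float(intensity),
                    volume_voxels=int(10 + 20 * intensity / unitary.mean_au),
                )
            )
        if rng.random() < distractor_rate:
            dpos = rng.uniform(0.0, box)
            records.append(
                SpotRecord(
                    cell_id=trajectory.cell_id,
                    frame=frame,
                    time_min=frame * dt,
                    x_um=float(dpos[0]),
                    y_um=float(dpos[1]),
                    z_um=float(dpos[2]),
                    intensity_au=float(
                        max(0.0, rng.normal(unitary.mean_au, unitary.sd_au))
                    ),
                    volume_voxels=int(rng.integers(10, 30)),
                )
            )
    return records


def gen_dwell_data(
    A: float,
    tau1_s: float,
    tau2_s: float,
    tau_bleach_s: float,
    n: int,
    frame_interval_s: float = 0.5,
    seed: int | None = None,
) -> np.ndarray:
    """Bound-molecule track durations censored by dye photobleaching.

    Each duration is the minimum of a two-component exponential dwell
    draw (fraction ``A`` with mean ``tau1_s``, remainder ``tau2_s``) and
    an independent Exp(``tau_bleach_s``) photobleaching draw, rounded to
    the frame grid with a minimum of one frame. ``tau_bleach_s`` may be
    ``inf`` to disable censoring.
    """
    if not 0 <= A <= 1:
        raise ValidationError(f"A must lie in [0, 1], got {A}")
    if not 0 < tau1_s < tau2_s:
        raise ValidationError("require 0 < tau1_s < tau2_s")
    if tau_bleach_s <= 0:
        raise ValidationError(f"tau_bleach_s must be > 0, got {tau_bleach_s}")
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if frame_interval_s <= 0:
        raise ValidationError("frame_interval_s must be > 0")
    rng = default_rng(seed)
    component = rng.random(n) < A
    dwell = np.where(
        component,
        rng.exponential(tau1_s, size=n),
        rng.exponential(tau2_s, size=n),
    )
    if np.isfinite(tau_bleach_s):
        dwell = np.minimum(dwell, rng.exponential(tau_bleach_s, size=n))
    frames = np.maximum(1, np.round(dwell / frame_interval_s)).astype(int)
    return frames * frame_interval_s


def gen_localizations(
    n_molecules: int,
    frac_bound: float,
    D_free_um2s: float,
    D_bound_um2s: float,
    loc_error_nm: float = 40.0,
    frame_interval_s: float = 0.015,
    n_frames: int = 10,
    seed: int | None = None,
    field_um: float = 10.0,
) -> pd.DataFrame:
    """2D Brownian single-molecule localizations with ground-truth state.

    Each molecule is bound (diffusing with ``D_bound_um2s``) with
    probability ``frac_bound`` or free (``D_free_um2s``); per-axis step
    variance is ``2 D dt`` and localization error is added
    independently per frame. Returns a table with columns ``molecule``,
    ``state`` (ground truth), ``frame``, ``x_nm``, ``y_nm``.
    """
    if not 0 <= frac_bound <= 1:
        raise ValidationError(f"frac_bound must lie in [0, 1], got {frac_bound}")
    if D_free_um2s < 0 or D_bound_um2s < 0:
        raise ValidationError("diffusion coefficients must be >= 0")
    if D_bound_um2s > D_free_um2s:
        raise ValidationError("require D_bound_um2s <= D_free_um2s")
    if loc_error_nm < 0:
        raise ValidationError("loc_error_nm must be >= 0")
    if n_molecules < 1 or n_frames < 1:
        raise ValidationError("need at least one molecule and one frame")
    rng = default_rng(seed)
    rows = []
    for mol in range(n_molecules):
        bound = rng.random() < frac_bound
        D = D_bound_um2s if bound else D_free_um2s
        step_nm = np.sqrt(2.0 * D * frame_interval_s) * 1e3
        start = rng.uniform(0.0, field_um * 1e3, size=2)
        steps = rng.normal(0.0, step_nm, size=(n_frames - 1, 2)) if n_frames > 1 else np.empty((0, 2))
        path = np.vstack([start, start + np.cumsum(steps, axis=0)]) if n_frames > 1 else start[None, :]
        noisy = path + rng.normal(0.0, loc_error_nm, size=path.shape)
        for f in range(n_frames):
            rows.append(
                {
                    "molecule": mol,
                    "state": "bound" if bound else "free",
                    "frame": f,
                    "x_nm": noisy[f, 0],
                    "y_nm": noisy[f, 1],
                }
            )
    return pd.DataFrame(rows)


def gen_decay_series(
    n0: float,
    half_life_h: float,
    timepoints_h,
    cv: float = 0.0,
    seed: int | None = None,
) -> list[tuple[float, float]]:
    """Mean transcript counts along a transcription-block decay.

    Counts follow ``n0 * 2 ** (-t / half_life_h)`` perturbed by
    multiplicative Normal(1, cv) noise and floored at zero.
    """
    if n0 <= 0:
        raise ValidationError(f"n0 must be > 0, got {n0}")
    if half_life_h <= 0:
        raise ValidationError(f"half_life_h must be > 0, got {half_life_h}")
    if cv < 0:
        raise ValidationError(f"cv must be >= 0, got {cv}")
    rng = default_rng(seed)
    series = []
    for t in timepoints_h:
        mean = n0 * 2.0 ** (-t / half_life_h)
        if cv > 0:
            mean = max(0.0, mean * rng.normal(1.0, cv))
        series.append((float(t), float(mean)))
    return series
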