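"""Single-particle-tracking kinetics: residence times and mobility.

Slow-rate SPT movies of Halo-tagged factors yield localizations of
bound molecules; these are linked into tracks (nearest neighbour, one
permitted frame gap), track-length survival curves are fitted with a
two-component exponential, and the slow component's apparent dwell time
is corrected for dye photobleaching with an H2B control whose apparent
binding time is photobleaching-limited:

    tau_bound = (tau_H2B * tau_dwell) / (tau_H2B - tau_dwell)

Fast-rate movies yield per-track diffusion coefficients from the lag-1
mean squared displacement; mobility fractions are the weights of a
two-Gaussian mixture fitted to log10(D).
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .errors import FitError, ValidationError

__all__ = [
    "Track",
    "DwellFit",
    "PhotobleachControl",
    "MobilityFit",
    "build_tracks",
    "track_durations",
    "survival_curve",
    "BiexponentialSurvival",
    "fit_biexponential",
    "fit_exponential_dwell",
    "correct_photobleach_dwell",
    "estimate_D",
    "MobilityMixture",
    "fit_mobility_mixture",
]


@dataclasses.dataclass
class Track:
    """One linked single-molecule trajectory."""

    frames: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.y_nm = np.asarray(self.y_nm, dtype=float)
        if not (np.diff(self.frames) > 0).all():
            raise ValidationError("track frames must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        """Observation span in seconds, counting both end frames."""
        return (self.frames[-1] - self.frames[0] + 1) * self.frame_interval_s


@dataclasses.dataclass
class DwellFit:
    """Bi-exponential survival-fit parameters.

    ``A`` is the fraction of the fast component with dwell ``tau1_s``;
    ``tau2_s >= tau1_s`` is the slow (stable-binding) component. The
    model is normalized so survival equals 1 at the first timepoint
    ``t1_s``.
    """

    A: float
    tau1_s: float
    tau2_s: float
    t1_s: float
    residual_rms: float = float("nan")
    single_component: bool = False

    @property
    def tau_dwell_s(self) -> float:
        """Apparent dwell of the slow component."""
        return self.tau2_s


@dataclasses.dataclass
class PhotobleachControl:
    """Apparent H2B dwell time, assumed photobleaching-limited."""

    tau_H2B_s: float

    def __post_init__(self) -> None:
        if self.tau_H2B_s <= 0:
            raise ValidationError(f"tau_H2B_s must be > 0, got {self.tau_H2B_s}")


@dataclasses.dataclass
class MobilityFit:
    """Two-component Gaussian mixture over log10(D), ordered by mean."""

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]


# ---------------------------------------------------------------------------
# Track building


def build_tracks(
    locs: pd.DataFrame,
    max_jump_nm: float,
    allow_gap: int = 1,
    frame_interval_s: float = 0.5,
) -> list[Track]:
    """Link localizations into tracks by greedy nearest-neighbour matching.

    A localization joins the track whose last position is nearest,
    provided the jump is at most ``max_jump_nm`` and the track was last
    seen at most ``allow_gap + 1`` frames earlier (one missed frame
    bridged by default). Within a frame, candidate pairs are assigned in
    order of increasing distance; each localization joins at most one
    track.
    """
    if max_jump_nm <= 0:
        raise ValidationError(f"max_jump_nm must be > 0, got {max_jump_nm}")
    if allow_gap < 0:
        raise ValidationError(f"allow_gap must be >= 0, got {allow_gap}")
    for col in ("frame", "x_nm", "y_nm"):
        if col not in locs.columns:
            raise ValidationError(f"localization table is missing column: {col}")
    locs = locs.sort_values("frame", kind="stable")

    open_tracks: list[dict] = []  # last position/frame plus accumulated points
    done: list[dict] = []
    for frame, group in locs.groupby("frame", sort=True):
        frame = int(frame)
        # retire tracks that can no longer be extended
        still_open = []
        for tr in open_tracks:
            if frame - tr["frames"][-1] > allow_gap + 1:
                done.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        pts = group[["x_nm", "y_nm"]].to_numpy(float)
        candidates = []
        for ti, tr in enumerate(open_tracks):
            last = np.array([tr["x"][-1], tr["y"][-1]])
            d = np.hypot(pts[:, 0] - last[0], pts[:, 1] - last[1])
            for pi in range(len(pts)):
                if d[pi] <= max_jump_nm:
                    candidates.append((d[pi], ti, pi))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        used_tracks: set[int] = set()
        used_pts: set[int] = set()
        for d, ti, pi in candidates:
            if ti in used_tracks or pi in used_pts:
                continue
            tr = open_tracks[ti]
            tr["frames"].append(frame)
            tr["x"].append(pts[pi, 0])
            tr["y"].append(pts[pi, 1])
            used_tracks.add(ti)
            used_pts.add(pi)
        for pi in range(len(pts)):
            if pi not in used_pts:
                open_tracks.append(
                    {"frames": [frame], "x": [pts[pi, 0]], "y": [pts[pi, 1]]}
                )
    done.extend(open_tracks)
    done.sort(key=lambda tr: (tr["frames"][0], tr["x"][0]))
    return [
        Track(
            frames=np.array(tr["frames"]),
            x_nm=np.array(tr["x"]),
            y_nm=np.array(tr["y"]),
            frame_interval_s=frame_interval_s,
        )
        for tr in done
    ]


def track_durations(tracks: Sequence[Track]) -> np.ndarray:
    return np.array([t.duration_s for t in tracks])


# ---------------------------------------------------------------------------
# Survival curve and bi-exponential fit


def survival_curve(
    durations_s: Sequence[float], t1_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of molecules still bound at each grid time.

    The complementary cumulative distribution of track durations is
    evaluated on the frame grid from ``t1_s`` to the longest duration
    and normalized so the value at ``t1_s`` is 1 (all durations are at
    least one frame long).
    """
    d = np.asarray(durations_s, dtype=float)
    if d.size == 0:
        raise ValidationError("empty duration sample")
    if t1_s <= 0:
        raise ValidationError(f"t1_s must be > 0, got {t1_s}")
    if (d < t1_s - 1e-9).any():
        raise ValidationError("durations below the first timepoint t1")
    n_steps = int(round(d.max() / t1_s))
    times = t1_s * np.arange(1, n_steps + 1)
    frac = np.array([(d >= t - 1e-9).mean() for t in times])
    return times, frac / frac[0]


def _biexp(t, A, tau1, tau2, t1):
    return A * np.exp(-t / tau1) / np.exp(-t1 / tau1) + (1 - A) * np.exp(
        -t / tau2
    ) / np.exp(-t1 / tau2)


class BiexponentialSurvival(BaseEstimator):
    """Two-component exponential fit of a bound-molecule survival curve.

    Nonlinear least squares over ``(A, tau1, tau2)`` with ``A`` bounded
    to [0, 1] and both time constants positive, initialized from a
    log-linear split of the curve (tail slope seeds the slow component,
    head slope the fast one). When the two time constants collapse the
    fit falls back to a single exponential with a warning.

    Attributes (after fit)
    ----------------------
    A_, tau1_, tau2_, t1_ : fitted parameters (tau2_ >= tau1_)
    fit_ : the :class:`DwellFit` report
    """

    def __init__(self, t1_s: float, collapse_tol: float = 0.05):
        self.t1_s = t1_s
        self.collapse_tol = collapse_tol

    def fit(self, durations_s: Sequence[float]) -> "BiexponentialSurvival":
        times, y = survival_curve(durations_s, self.t1_s)
        return self.fit_curve(times, y)

    def fit_curve(self, times: np.ndarray, y: np.ndarray) -> "BiexponentialSurvival":
        times = np.asarray(times, dtype=float)
        y = np.asarray(y, dtype=float)
        if times.size < 3:
            raise FitError("survival curve too short for a two-component fit")
        if abs(y[0] - 1.0) > 1e-6:
            raise ValidationError("survival curve must be normalized to 1 at t1")
        t1 = self.t1_s
        pos = y > 0
        logt, logy = times[pos], np.log(y[pos])
        half = max(2, len(logt) // 2)
        tail = np.polyfit(logt[half:], logy[half:], 1) if len(logt) > half + 1 else None
        head = np.polyfit(logt[:half], logy[:half], 1)
        tau2_0 = -1.0 / tail[0] if tail is not None and tail[0] < 0 else times[-1]
        tau1_0 = -1.0 / head[0] if head[0] < 0 else t1
        tau1_0 = float(np.clip(tau1_0, t1 / 10, tau2_0))
        tau2_0 = float(max(tau2_0, tau1_0 * 1.5))

        def resid(theta):
            A, lt1, lt2 = theta
            return _biexp(times, A, np.exp(lt1), np.exp(lt2), t1) - y

        sol = optimize.least_squares(
            resid,
            x0=[0.5, np.log(tau1_0), np.log(tau2_0)],
            bounds=([0.0, np.log(t1 / 100), np.log(t1 / 100)], [1.0, 25.0, 25.0]),
        )
        if not sol.success:
            raise FitError(f"bi-exponential fit did not converge: {sol.message}")
        A, tau1, tau2 = sol.x[0], float(np.exp(sol.x[1])), float(np.exp(sol.x[2]))
        if tau1 > tau2:  # report the fast component first
            tau1, tau2, A = tau2, tau1, 1 - A
        single = False
        if abs(np.log(tau2 / tau1)) < self.collapse_tol:
            warnings.warn(
                "bi-exponential components collapsed; refitting a single "
                "exponential",
                stacklevel=2,
            )
            tau = fit_exponential_dwell_curve(times, y, t1)
            A, tau1, tau2, single = 1.0, tau, tau, True
        rms = float(np.sqrt(np.mean(resid([A, np.log(tau1), np.log(tau2)]) ** 2)))
        self.A_ = float(A)
        self.tau1_ = tau1
        self.tau2_ = tau2
        self.t1_ = t1
        self.fit_ = DwellFit(
            A=float(A),
            tau1_s=tau1,
            tau2_s=tau2,
            t1_s=t1,
            residual_rms=rms,
            single_component=single,
        )
        return self


def fit_biexponential(
    durations_s: Sequence[float], t1_s: float
) -> DwellFit:
    """Fit the two-component survival model to track durations."""
    return BiexponentialSurvival(t1_s).fit(durations_s).fit_


def fit_exponential_dwell_curve(times, y, t1_s) -> float:
    """Single-exponential least-squares fit of a normalized survival curve."""

    def resid(ltau):
        return np.exp(-(times - t1_s) / np.exp(ltau[0])) - y

    sol = optimize.least_squares(resid, x0=[np.log(max(times.mean(), t1_s))])
    if not sol.success:
        raise FitError("single-exponential fit did not converge")
    return float(np.exp(sol.x[0]))


def fit_exponential_dwell(durations_s: Sequence[float], t1_s: float) -> float:
    """Apparent dwell time from a single-exponential survival fit (used
    for the H2B photobleaching control)."""
    times, y = survival_curve(durations_s, t1_s)
    return fit_exponential_dwell_curve(times, y, t1_s)


def correct_photobleach_dwell(
    tau_dwell_s: float, control: PhotobleachControl
) -> float:
    """Photobleaching-corrected stable binding time.

    ``tau_bound = tau_H2B * tau_dwell / (tau_H2B - tau_dwell)``; valid
    only while the control's apparent dwell exceeds the protein's.
    """
    tau_h2b = control.tau_H2B_s
    if tau_dwell_s <= 0:
        raise ValidationError(f"tau_dwell_s must be > 0, got {tau_dwell_s}")
    if tau_dwell_s >= tau_h2b:
        raise ValidationError(
            f"tau_dwell ({tau_dwell_s}) must be below tau_H2B ({tau_h2b}); "
            "the correction is uninterpretable otherwise"
        )
    return tau_h2b * tau_dwell_s / (tau_h2b - tau_dwell_s)


# ---------------------------------------------------------------------------
# Mobility


def estimate_D(
    track: Track, frame_interval_s: float | None = None, min_frames: int = 4
) -> float | None:
    """Diffusion coefficient from the lag-1 mean squared displacement.

    ``D = MSD(dt) / (4 dt)`` in µm²/s for 2D tracks; only displacement
    pairs in strictly consecutive frames contribute. Tracks shorter than
    ``min_frames`` frames are excluded (``None`` signals exclusion, not
    an error).
    """
    if track.n_frames < min_frames:
        return None
    dt = frame_interval_s or track.frame_interval_s
    consecutive = np.diff(track.frames) == 1
    dx = np.diff(track.x_nm)[consecutive]
    dy = np.diff(track.y_nm)[consecutive]
    if dx.size == 0:
        return None
    msd_nm2 = float(np.mean(dx**2 + dy**2))
    return msd_nm2 / (4.0 * dt) / 1e6  # nm²/s → µm²/s


class MobilityMixture(BaseEstimator):
    """Two-Gaussian mixture over log10(D) with mobility-fraction weights.

    EM via scikit-learn with multiple restarts; components are ordered
    by mean, so the first weight is the slow (bound-like) fraction.
    """

    def __init__(self, n_init: int = 5, seed: int | None = None, min_samples: int = 50):
        self.n_init = n_init
        self.seed = seed
        self.min_samples = min_samples

    def fit(self, log10_D: Sequence[float]) -> "MobilityMixture":
        x = np.asarray(log10_D, dtype=float).reshape(-1, 1)
        if x.size < self.min_samples:
            raise ValidationError(
                f"need >= {self.min_samples} log10(D) values, got {x.size}"
            )
        if not np.isfinite(x).all():
            raise ValidationError("log10(D) values must be finite")
        gm = GaussianMixture(
            n_components=2,
            n_init=self.n_init,
            random_state=self.seed,
            covariance_type="full",
            reg_covar=1e-6,
        ).fit(x)
        order = np.argsort(gm.means_.ravel())
        means = gm.means_.ravel()[order]
        sds = np.sqrt(gm.covariances_.ravel()[order])
        weights = gm.weights_.ravel()[order]
        self.means_ = tuple(float(v) for v in means)
        self.sds_ = tuple(float(v) for v in sds)
        self.weights_ = tuple(float(v) for v in weights)
        self.fit_ = MobilityFit(means=self.means_, sds=self.sds_, weights=self.weights_)
        return self


def fit_mobility_mixture(log10_D: Sequence[float], seed: int | None = 0) -> MobilityFit:
    """Fit the two-Gaussian log10(D) mixture; returns the ordered fit."""
    return MobilityMixture(seed=seed).fit(log10_D).fit_
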