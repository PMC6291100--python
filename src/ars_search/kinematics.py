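"""Polar step kinematics and patch labelling.

Each pair of consecutive fixes defines a step with length

    r[t] = sqrt((x[t] - x[t-1])^2 + (y[t] - y[t-1])^2)

and heading angle theta[t] in (-pi, pi], the quadrant-adjusted arctangent
of the displacement. Consecutive headings define the unit-scaled turning
angle

    delta[t] = min(|theta[t] - theta[t-1]|, 2*pi - |theta[t] - theta[t-1]|) / pi

in [0, 1]: 0 is dead-straight travel, 1 a full reversal (a 90-degree right
turn and a 270-degree left turn are the same event).

Headings are undefined for near-stationary steps (displacement below a
threshold well under GPS noise); the last valid heading is carried forward
so that the next moving step still yields a turning angle, and turning
angles with no defined predecessor heading are marked invalid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .track_io import Track

#: Displacement (m) below which a step is treated as stationary and its
#: heading left undefined; half the typical GPS fix noise.
STATIONARY_EPS_M = 0.5


def angle_diff(a, b):
    """Smallest unsigned angle between headings a and b, in [0, pi]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    return np.minimum(d, 2 * np.pi - d)


@dataclass
class PolarSeries:
    """Per-step polar kinematics aligned to a track's fixes.

    ``r`` and ``theta`` have one entry per step (fix pairs), ``delta`` one
    per heading pair; ``delta[i]`` is the turn *into* step ``i`` and is
    NaN where invalid. ``E`` carries the encounter flag of the fix ending
    each step, ``E_kind`` its subtype, and ``segment`` the cadence-segment
    index so lags never cross a recording gap.
    """

    trip_id: str
    r: np.ndarray
    theta: np.ndarray
    delta: np.ndarray
    E: np.ndarray
    E_kind: np.ndarray
    valid_theta: np.ndarray
    valid_delta: np.ndarray
    segment: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.r.size

    def delta_values(self) -> np.ndarray:
        return self.delta[self.valid_delta]

    def r_values(self) -> np.ndarray:
        return self.r


def to_polar(track: Track, eps: float = STATIONARY_EPS_M) -> PolarSeries:
    """Transform a track into step lengths, headings and turning angles."""
    d = np.diff(track.xy, axis=0)
    r = np.hypot(d[:, 0], d[:, 1])
    theta = np.arctan2(d[:, 1], d[:, 0])
    moving = r >= eps
    theta = np.where(moving, theta, np.nan)

    n = r.size
    delta = np.full(n, np.nan)
    valid_delta = np.zeros(n, dtype=bool)
    segment = np.zeros(n, dtype=int)

    # steps belong to cadence segments; the step from fix i to i+1 sits in
    # the segment containing both
    seg_id = 0
    splits = set(track.cadence.split_indices)
    for i in range(n):
        if i in splits:
            seg_id += 1
        segment[i] = seg_id

    last_theta = np.nan
    last_seg = -1
    for i in range(n):
        if segment[i] != last_seg:
            last_theta = np.nan     # no heading carry-over across gaps
            last_seg = segment[i]
        if moving[i]:
            if np.isfinite(last_theta):
                delta[i] = angle_diff(theta[i], last_theta) / np.pi
                valid_delta[i] = True
            last_theta = theta[i]
        # stationary: carry last_theta forward unchanged

    return PolarSeries(
        trip_id=track.trip_id,
        r=r,
        theta=theta,
        delta=delta,
        E=track.E[1:].copy(),
        E_kind=track.E_kind[1:].copy(),
        valid_theta=moving,
        valid_delta=valid_delta,
        segment=segment,
    )


def turning_angles(theta: np.ndarray) -> np.ndarray:
    """Unit-scaled turning angles of a heading sequence (length n-1)."""
    theta = np.asarray(theta, dtype=float)
    return angle_diff(theta[1:], theta[:-1]) / np.pi


@dataclass(frozen=True)
class PatchLabels:
    """Boolean in-patch flag per step for a window of W steps."""

    in_patch: np.ndarray
    window: int


def label_patches(E: np.ndarray, W: int = 50,
                  segment: np.ndarray | None = None) -> PatchLabels:
    """Mark steps occurring within W steps after an encounter.

    The encounter step itself is not in-patch; the union of the W steps
    following each encounter is. Labels never cross segment (or trip)
    boundaries when ``segment`` is given.
    """
    if W < 1:
        raise ValueError("patch window W must be >= 1")
    E = np.asarray(E)
    n = E.size
    seg = np.zeros(n, dtype=int) if segment is None else np.asarray(segment)
    in_patch = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(E == 1):
        j = i + 1
        while j < n and j <= i + W and seg[j] == seg[i]:
            in_patch[j] = True
            j += 1
    return PatchLabels(in_patch=in_patch, window=W)


def squeeze_unit(x: np.ndarray, n: int | None = None) -> np.ndarray:
    """Map unit-interval data off the endpoints: (x*(n-1) + 0.5) / n.

    The Beta density is undefined at exactly 0 and 1; this standard
    compression keeps endpoint observations usable in the likelihood.
    """
    x = np.asarray(x, dtype=float)
    if n is None:
        n = x.size
    return (x * (n - 1) + 0.5) / n


#: Floor (m) applied to step sizes before log-likelihoods; half the
#: stationarity threshold, so stationary fixes contribute a well-defined
#: small step rather than log(0).
STEP_FLOOR_M = 0.05


def floor_steps(r: np.ndarray, floor: float = STEP_FLOOR_M) -> np.ndarray:
    return np.maximum(np.asarray(r, dtype=float), floor)
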