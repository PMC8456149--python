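"""End-to-end orchestration: segment selection, per-fly vectors,
experiment-level statistics, group comparisons and virtual flight paths.

The unit of analysis is one fly's selected flight segment: the longest
stretch of uninterrupted flight, required to last at least 70 s, with the
first 10 s discarded for acclimatization. Each segment is reduced to a
mean vector (direction + directedness r); a treatment group of such
vectors is summarized with the rank-weighted (Moore) test, the classical
Rayleigh test and bootstrap confidence intervals, and groups are compared
with the Mardia-Watson-Wheeler test, optionally after rotating every fly's
angles into a sun-relative (rectified) or clock-shift back-transformed
frame using the solar ephemeris at its experiment time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from typing import Sequence

import numpy as np

from . import circstats as cs
from .records import FlightRecord
from .solar import azimuth_shift, rectify_angles, solar_azimuth

__all__ = [
    "AnalysisConfig",
    "ExperimentRow",
    "PathTrace",
    "SelectionError",
    "select_flight_segment",
    "fly_vector",
    "analyze_experiment",
    "split_by_time",
    "compare_groups",
    "compensation_fraction",
    "normalize_deviation",
    "virtual_path",
]


class SelectionError(ValueError):
    """A recording failed the flight-segment selection rule."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds for the pipeline.

    ``min_duration_s``/``discard_s`` implement the segment-selection rule;
    ``n_sims`` is the Monte-Carlo null size for the rank-weighted test;
    ``bootstrap_B`` the resample count for mean-direction CIs; CIs are
    suppressed (reported as None) when the group is not significant at
    ``alpha``, matching the reporting convention for undirected groups.
    """

    min_duration_s: float = 70.0
    discard_s: float = 10.0
    alpha: float = 0.05
    n_sims: int = 100_000
    bootstrap_B: int = 10_000
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _subtract_intervals(segment, cuts):
    """Split one (t0, t1) interval by removing a list of cut intervals."""
    pieces = [segment]
    for c0, c1 in cuts:
        nxt = []
        for a, b in pieces:
            if c1 <= a or c0 >= b:
                nxt.append((a, b))
            else:
                if a < c0:
                    nxt.append((a, c0))
                if c1 < b:
                    nxt.append((c1, b))
        pieces = nxt
    return pieces


def select_flight_segment(
    record: FlightRecord,
    min_duration_s: float = 70.0,
    discard_s: float = 10.0,
) -> np.ndarray:
    """Apply the uninterrupted-flight selection rule to one recording.

    Finds the longest flight interval free of perturbations; raises
    :class:`SelectionError` when it is shorter than ``min_duration_s``.
    Returns the segment's samples at the native rate with the first
    ``discard_s`` seconds dropped.
    """
    if not record.flight_events:
        raise SelectionError(f"{record.fly_id}: no flight events recorded")
    clean: list[tuple[float, float]] = []
    for ev in record.flight_events:
        clean.extend(_subtract_intervals(ev, record.perturbations))
    if not clean:
        raise SelectionError(f"{record.fly_id}: no uninterrupted flight")
    t0, t1 = max(clean, key=lambda ab: (ab[1] - ab[0], -ab[0]))
    if t1 - t0 < min_duration_s:
        raise SelectionError(
            f"{record.fly_id}: longest uninterrupted flight "
            f"{t1 - t0:.1f} s < {min_duration_s:.0f} s"
        )
    times = record.times_s
    keep = (times >= t0 + discard_s) & (times < t1)
    return record.angles_deg[keep]


def fly_vector(
    record: FlightRecord, config: AnalysisConfig = AnalysisConfig()
) -> cs.MeanVector:
    """Mean vector of one fly's selected flight segment."""
    segment = select_flight_segment(record, config.min_duration_s, config.discard_s)
    if segment.size == 0:
        raise SelectionError(f"{record.fly_id}: empty selection")
    return cs.mean_vector(segment)


@dataclass(frozen=True)
class ExperimentRow:
    """One experiment's line in the summary table.

    Mirrors the reporting convention for such experiments: sample size,
    weighted (rank-weighted) and non-weighted mean directions with
    bootstrap CIs (None when the group is not significantly directed),
    Moore's R*, the Rayleigh mean resultant length r, and both p-values.
    """

    label: str
    n: int
    theta_weighted: float
    ci_weighted: tuple[float, float] | None
    theta_unweighted: float
    ci_unweighted: tuple[float, float] | None
    R_star: float
    r_rayleigh: float
    p_mmr: float
    p_mmr_bracket: str
    p_rayleigh: float
    config_hash: str = ""


def _per_fly_vectors(records, config, frame="geographic"):
    """Per-fly mean vectors, optionally in a solar-transformed frame.

    frame='rectified' rotates each fly's angles so the sun (at the fly's
    experiment time) sits at 180; frame='back_transformed' removes the
    expected full-compensation clock-shift rotation from clock-shifted
    flies only.
    """
    vectors, kept = [], []
    for rec in records:
        try:
            seg = select_flight_segment(rec, config.min_duration_s, config.discard_s)
        except SelectionError:
            continue
        if frame == "rectified":
            az = solar_azimuth(rec.site, rec.start_time)
            seg = rectify_angles(seg, az)
        elif frame == "back_transformed":
            if rec.treatment == "clock_shift":
                delta = azimuth_shift(rec.site, rec.start_time)
                seg = np.mod(seg - delta, 360.0)
        elif frame != "geographic":
            raise ValueError(f"unknown frame {frame!r}")
        vectors.append(cs.mean_vector(seg))
        kept.append(rec)
    return vectors, kept


def analyze_experiment(
    records: Sequence[FlightRecord],
    label: str = "",
    config: AnalysisConfig = AnalysisConfig(),
    frame: str = "geographic",
) -> ExperimentRow:
    """Summarize one treatment group into an :class:`ExperimentRow`."""
    vectors, _ = _per_fly_vectors(records, config, frame)
    n = len(vectors)
    if n < 2:
        raise ValueError(f"{label or 'experiment'}: fewer than 2 usable flies")
    thetas = np.array([v.theta for v in vectors])
    pairs = [(v.theta, v.r) for v in vectors]

    mmr = cs.moore_rayleigh(pairs, n_sims=config.n_sims, seed=config.seed)
    unweighted = cs.mean_vector(thetas)
    rayleigh = cs.rayleigh_test(n=n, r=unweighted.r)

    significant = mmr.p is not None and mmr.p < config.alpha
    ci_w = ci_u = None
    if significant:
        ci_w = cs.weighted_mean_ci_bootstrap(
            pairs, B=config.bootstrap_B, alpha=config.alpha, seed=config.seed
        )
        ci_u = cs.weighted_mean_ci_bootstrap(
            [(t, 1.0) for t in thetas],
            B=config.bootstrap_B,
            alpha=config.alpha,
            seed=config.seed,
        )
    return ExperimentRow(
        label=label,
        n=n,
        theta_weighted=mmr.theta_w,
        ci_weighted=ci_w,
        theta_unweighted=unweighted.theta,
        ci_unweighted=ci_u,
        R_star=mmr.R_star,
        r_rayleigh=unweighted.r,
        p_mmr=mmr.p,
        p_mmr_bracket=mmr.p_bracket,
        p_rayleigh=rayleigh.p,
        config_hash=config.config_hash(),
    )


def split_by_time(records: Sequence[FlightRecord]):
    """Median split of a group by experiment start time (early, late)."""
    recs = [r for r in records if r.start_time is not None]
    recs.sort(key=lambda r: r.start_time)
    half = len(recs) // 2
    return recs[:half], recs[half:]


def compare_groups(
    group_a: Sequence[FlightRecord],
    group_b: Sequence[FlightRecord],
    frame: str = "geographic",
    config: AnalysisConfig = AnalysisConfig(),
) -> cs.MWWResult:
    """Mardia-Watson-Wheeler comparison of two groups' per-fly means.

    ``frame`` selects the reference frame applied per fly before pooling:
    'geographic' (none), 'rectified' (sun at 180) or 'back_transformed'
    (clock-shifted flies rotated back by the expected azimuth change).
    """
    va, _ = _per_fly_vectors(group_a, config, frame)
    vb, _ = _per_fly_vectors(group_b, config, frame)
    if not va or not vb:
        raise ValueError("both groups need at least one usable fly")
    return cs.mww_test([[v.theta for v in va], [v.theta for v in vb]])


def compensation_fraction(observed_shift_deg: float, expected_shift_deg: float) -> float:
    """Fraction of the expected (full-compensation) shift actually observed.

    E.g. a 68.9-degree observed shift against a 98.1-degree expected
    azimuth change gives 0.70 — seventy percent compensation.
    """
    if expected_shift_deg == 0:
        raise ValueError("expected shift must be non-zero")
    return float(observed_shift_deg) / float(expected_shift_deg)


def normalize_deviation(deviation_deg: float) -> float:
    """Map a signed deviation in (-180, 180] onto [0, 1] by |d|/180."""
    if not -180.0 < deviation_deg <= 180.0:
        raise ValueError("deviation must lie in (-180, 180]")
    return abs(float(deviation_deg)) / 180.0


@dataclass(frozen=True)
class PathTrace:
    """Dead-reckoned virtual flight path (metres; x east, y north)."""

    positions: np.ndarray
    cumulative_distance: np.ndarray
    speed_ms: float

    @property
    def endpoint(self) -> tuple[float, float]:
        return tuple(self.positions[-1])


def virtual_path(
    angles_deg, rate_hz: float, speed_ms: float = 5.0
) -> PathTrace:
    """Reconstruct the virtual path flown at a constant ground speed.

    Euler dead reckoning: each sample contributes a step of
    ``speed/rate`` metres along its compass heading. Returns positions
    including the origin, so ``positions`` has one more row than there are
    samples.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle series")
    step = speed_ms / rate_hz
    rad = np.deg2rad(angles)
    dxy = step * np.column_stack([np.sin(rad), np.cos(rad)])
    positions = np.vstack([[0.0, 0.0], np.cumsum(dxy, axis=0)])
    cum = np.concatenate([[0.0], np.full(angles.size, step).cumsum()])
    return PathTrace(positions=positions, cumulative_distance=cum, speed_ms=speed_ms)
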