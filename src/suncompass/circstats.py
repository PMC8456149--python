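"""Circular statistics for orientation experiments.

Angles are compass bearings: degrees clockwise from geographic north, in
[0, 360). Internally everything is computed in radians on unit vectors with
north = (cos, .) and east = (sin, .) components, so ``atan2(east, north)``
maps back to the compass convention.

The centrepiece is Moore's modified Rayleigh test, a nonparametric test for
a common direction among *vectors* (direction + length): each animal's mean
direction is weighted by the rank of its mean resultant length, so strongly
directed animals count for more without assuming any distribution for the
lengths. Significance is assessed against a Monte-Carlo null (uniform
directions, ranks fixed), which reproduces the classical probability table
to sampling error while remaining fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MeanVector",
    "RayleighResult",
    "MMRResult",
    "MWWResult",
    "AxialSummary",
    "mean_vector",
    "circ_diff",
    "rayleigh_test",
    "moore_rayleigh",
    "mmr_pvalue",
    "p_bracket",
    "weighted_mean_ci_bootstrap",
    "mww_test",
    "bidirectional_analysis",
]

# Ladder of conventional significance levels used when reporting a p-value
# as a coarse bracket string such as "<0.01" (classical table style).
_BRACKET_LADDER = (0.0001, 0.001, 0.005, 0.01, 0.025, 0.05, 0.1, 0.25, 0.5, 0.9)


def wrap360(angle):
    """Wrap angle(s) in degrees onto [0, 360)."""
    return np.mod(angle, 360.0)


def wrap180(angle):
    """Wrap angle(s) in degrees onto (-180, 180]."""
    wrapped = np.mod(np.asarray(angle, dtype=float), 360.0)
    out = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    # keep +180 rather than -180
    out = np.where(out <= -180.0, out + 360.0, out)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class MeanVector:
    """Mean direction and mean resultant length of a set of angles.

    ``theta`` is the circular mean in compass degrees, ``r`` the mean
    resultant length in [0, 1] (1 = all angles identical, 0 = perfectly
    balanced). When ``r`` is numerically zero the direction is undefined
    and ``theta`` is NaN.
    """

    theta: float
    r: float
    n_obs: int

    @property
    def undefined(self) -> bool:
        return not np.isfinite(self.theta)


@dataclass(frozen=True)
class RayleighResult:
    n: int
    r: float
    Z: float
    p: float


@dataclass(frozen=True)
class MMRResult:
    """Result of Moore's modified (rank-weighted) Rayleigh test."""

    R_star: float
    theta_w: float
    n: int
    p: float | None
    p_bracket: str | None = None
    ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class MWWResult:
    """Mardia-Watson-Wheeler uniform-scores test result."""

    W: float
    df: int
    p: float
    group_sizes: tuple[int, ...]
    small_sample_warning: bool


@dataclass(frozen=True)
class AxialSummary:
    """Axial (bidirectional) version of the rank-weighted test.

    ``theta_axial`` lives on [0, 180): it is half the weighted mean of the
    doubled angles, appropriate for data meaningful only modulo 180 deg.
    """

    theta_axial: float
    R_star: float
    p: float | None
    n: int


def _unit_components(angles_deg):
    rad = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return np.cos(rad), np.sin(rad)


def mean_vector(angles_deg: Sequence[float]) -> MeanVector:
    """Circular mean direction and mean resultant length.

    Parameters
    ----------
    angles_deg : sequence of compass angles in degrees.

    Returns
    -------
    MeanVector with ``theta`` in [0, 360) (NaN when r == 0) and ``r`` in
    [0, 1].
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise ValueError("mean_vector requires at least one angle")
    north, east = _unit_components(angles)
    n_bar, e_bar = north.mean(), east.mean()
    r = float(min(np.hypot(n_bar, e_bar), 1.0))
    if r < 1e-12:
        return MeanVector(theta=float("nan"), r=0.0, n_obs=angles.size)
    theta = wrap360(np.rad2deg(np.arctan2(e_bar, n_bar)))
    return MeanVector(theta=float(theta), r=r, n_obs=int(angles.size))


def circ_diff(a: float, b: float) -> float:
    """Signed circular difference a - b in degrees, in (-180, 180].

    Positive values mean ``a`` lies clockwise of ``b`` on the compass.
    """
    return wrap180(float(a) - float(b))


def rayleigh_test(
    angles_deg: Sequence[float] | None = None,
    *,
    n: int | None = None,
    r: float | None = None,
) -> RayleighResult:
    """Rayleigh test of circular uniformity.

    Accepts either raw angles or a precomputed ``(n, r)`` summary. The
    p-value uses the standard series approximation

        p = exp(-Z) * [1 + (2Z - Z^2)/(4n)
                         - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]

    with Z = n r^2, clamped to (0, 1].
    """
    if angles_deg is not None:
        mv = mean_vector(angles_deg)
        n, r = mv.n_obs, mv.r
    if n is None or r is None:
        raise ValueError("provide either angles or both n and r")
    if n < 2:
        raise ValueError("Rayleigh test requires n >= 2")
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    Z = n * r * r
    p = np.exp(-Z) * (
        1.0
        + (2.0 * Z - Z * Z) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n * n)
    )
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return RayleighResult(n=int(n), r=float(r), Z=float(Z), p=p)


def _as_theta_r(vectors) -> tuple[np.ndarray, np.ndarray]:
    """Coerce a sequence of MeanVector or (theta, r) pairs to arrays."""
    thetas, rs = [], []
    for v in vectors:
        if isinstance(v, MeanVector):
            thetas.append(v.theta)
            rs.append(v.r)
        else:
            t, r = v[0], v[1]
            thetas.append(float(t))
            rs.append(float(r))
    return np.asarray(thetas, dtype=float), np.asarray(rs, dtype=float)


def _rank_weighted_sums(theta_deg: np.ndarray, r: np.ndarray):
    """Rank-weighted resultant components of one sample of vectors.

    Ranks are assigned to the vector lengths in ascending order (average
    ranks on ties) and divided by n^{3/2}; returns (X, Y) = (north, east).
    """
    n = theta_deg.shape[-1]
    ranks = stats.rankdata(r, axis=-1)
    rad = np.deg2rad(theta_deg)
    scale = n ** 1.5
    X = np.sum(ranks * np.cos(rad), axis=-1) / scale
    Y = np.sum(ranks * np.sin(rad), axis=-1) / scale
    return X, Y


def moore_rayleigh(
    vectors,
    n_sims: int = 100_000,
    seed: int | None = None,
    ci: bool = False,
    B: int = 10_000,
    alpha: float = 0.05,
) -> MMRResult:
    """Moore's modified Rayleigh test for a common direction among vectors.

    Each vector is an animal's (mean direction, mean resultant length).
    Lengths are ranked ascending (average ranks on ties) and the test
    statistic is

        R* = sqrt(X^2 + Y^2),  X = sum_i rank_i cos(theta_i) / n^{3/2}

    (Y likewise with sin). The weighted mean direction is the direction of
    (X, Y). The p-value comes from :func:`mmr_pvalue`; a bootstrap CI for
    the weighted mean is attached when ``ci=True``.
    """
    theta, r = _as_theta_r(vectors)
    n = theta.size
    if n < 2:
        raise ValueError("Moore's Rayleigh test requires at least 2 vectors")
    if np.any((r < 0) | (r > 1)):
        raise ValueError("vector lengths r must lie in [0, 1]")
    X, Y = _rank_weighted_sums(theta, r)
    R_star = float(np.hypot(X, Y))
    theta_w = float(wrap360(np.rad2deg(np.arctan2(Y, X))))
    p = mmr_pvalue(R_star, n, n_sims=n_sims, seed=seed)
    interval = None
    if ci:
        interval = weighted_mean_ci_bootstrap(
            list(zip(theta, r)), B=B, alpha=alpha, seed=seed
        )
    return MMRResult(
        R_star=R_star,
        theta_w=theta_w,
        n=int(n),
        p=p,
        p_bracket=p_bracket(p),
        ci=interval,
    )


def mmr_pvalue(R_star: float, n: int, n_sims: int = 100_000, seed: int | None = None) -> float:
    """Monte-Carlo p-value for Moore's R* under the uniform null.

    Under the null hypothesis directions are iid uniform and independent of
    the lengths, so the null distribution of R* is obtained by pairing the
    fixed ranks 1..n with uniform random directions. Returns the
    plus-one-corrected exceedance proportion.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = np.random.default_rng(seed)
    ranks = np.arange(1, n + 1, dtype=float)
    sims = sample_null_R_star(n, n_sims, rng, ranks=ranks)
    return float((1 + np.count_nonzero(sims >= R_star)) / (n_sims + 1))


def sample_null_R_star(
    n: int,
    n_sims: int,
    rng: np.random.Generator,
    ranks: np.ndarray | None = None,
    chunk: int = 200_000,
) -> np.ndarray:
    """Sample the null distribution of R* (uniform directions, fixed ranks)."""
    if ranks is None:
        ranks = np.arange(1, n + 1, dtype=float)
    scale = n ** 1.5
    out = np.empty(n_sims)
    for start in range(0, n_sims, chunk):
        stop = min(start + chunk, n_sims)
        m = stop - start
        phi = rng.uniform(0.0, 2.0 * np.pi, size=(m, n))
        X = (np.cos(phi) @ ranks) / scale
        Y = (np.sin(phi) @ ranks) / scale
        out[start:stop] = np.hypot(X, Y)
    return out


def p_bracket(p: float) -> str:
    """Report a p-value as a conventional table-style bracket, e.g. '<0.01'."""
    for level in _BRACKET_LADDER:
        if p < level:
            return f"<{level}"
    return "<1"


def weighted_mean_ci_bootstrap(
    vectors,
    B: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the rank-weighted mean direction.

    Animals (vectors) are resampled with replacement; lengths are re-ranked
    within each resample and the weighted mean direction recomputed. The
    interval is the (alpha/2, 1-alpha/2) percentile band of the signed
    circular deviations from the point estimate, re-centred on it, so it
    behaves correctly across the 0/360 wrap.
    """
    theta, r = _as_theta_r(vectors)
    n = theta.size
    if n < 3:
        raise ValueError("bootstrap CI requires at least 3 vectors")
    if B < 1000:
        raise ValueError("B must be >= 1000")
    X, Y = _rank_weighted_sums(theta, r)
    theta_hat = wrap360(np.rad2deg(np.arctan2(Y, X)))
    if np.allclose(theta, theta[0]):
        # degenerate: every resample has the same direction
        return (float(theta_hat), float(theta_hat))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    Xb, Yb = _rank_weighted_sums(theta[idx], r[idx])
    theta_b = np.rad2deg(np.arctan2(Yb, Xb))
    dev = wrap180(theta_b - theta_hat)
    lo, hi = np.percentile(dev, [100 * alpha / 2.0, 100 * (1 - alpha / 2.0)])
    return (float(wrap360(theta_hat + lo)), float(wrap360(theta_hat + hi)))


def mww_test(groups: Sequence[Sequence[float]]) -> MWWResult:
    """Mardia-Watson-Wheeler k-sample uniform-scores test.

    Pools all N angles, ranks them (average ranks on ties), converts ranks
    to uniform scores beta_i = 2*pi*rank_i/N and computes

        W = 2 * sum_j (C_j^2 + S_j^2) / n_j

    where C_j, S_j are per-group sums of cos(beta), sin(beta). W is
    compared to chi-squared with 2(k-1) degrees of freedom; the chi-squared
    approximation needs roughly 10 observations per group, below which a
    warning flag is set.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    sizes = tuple(a.size for a in arrays)
    if any(s == 0 for s in sizes):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    N = pooled.size
    beta = 2.0 * np.pi * stats.rankdata(wrap360(pooled)) / N
    W = 0.0
    start = 0
    for a in arrays:
        b = beta[start : start + a.size]
        W += (np.cos(b).sum() ** 2 + np.sin(b).sum() ** 2) / a.size
        start += a.size
    W = float(2.0 * W)
    df = 2 * (len(arrays) - 1)
    p = float(stats.chi2.sf(W, df))
    return MWWResult(
        W=W,
        df=df,
        p=p,
        group_sizes=sizes,
        small_sample_warning=any(s < 10 for s in sizes),
    )


def bidirectional_analysis(
    vectors, n_sims: int = 100_000, seed: int | None = None
) -> AxialSummary:
    """Axial analysis: test doubled angles, report the mean on [0, 180).

    Appropriate when opposite directions are equivalent (e.g. alignment to
    an axis such as the polarization e-vector): each vector's direction is
    doubled modulo 360 (length unchanged), the rank-weighted test is run,
    and the weighted mean is halved back onto [0, 180).
    """
    theta, r = _as_theta_r(vectors)
    doubled = wrap360(2.0 * theta)
    res = moore_rayleigh(list(zip(doubled, r)), n_sims=n_sims, seed=seed)
    axial_mean = float(np.mod(res.theta_w / 2.0, 180.0))
    return AxialSummary(theta_axial=axial_mean, R_star=res.R_star, p=res.p, n=res.n)
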