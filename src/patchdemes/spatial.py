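"""Geary's c spatial autocorrelation for quadrat-gridded samples.

Samples sit on 5 x 5 grids of 20-cm sections within square-meter quadrats,
so adjacent sections are 0.2 m apart while different quadrats are metres
apart.  Geary's c compares attribute differences between nearby samples to
the overall variance: c < 1 indicates spatial clustering, c ~ 1 randomness,
c > 1 uniform dispersion.  Significance comes from permutation of attribute
values over locations; the ``within_quadrat_only`` restriction zeroes all
cross-quadrat weights to test fine-scale structure separately from
between-quadrat differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

#: Density rank bin upper edges: 0, 1-5, 6-10, 11-50, 51-100, 101-500,
#: 501-1000 worms map to ranks 0..6.
_RANK_EDGES = np.array([0, 5, 10, 50, 100, 500, 1000])

SCHEMES = ("inverse_distance", "binary_threshold", "rook_adjacency")
RESTRICTIONS = ("all_pairs", "within_quadrat_only")


def density_rank(count: int) -> int:
    """Worm-density rank score 0-6 from a worm count (max 1000)."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if count > 1000:
        raise ValueError("count exceeds the 0-1000 range of the rank scale")
    return int(np.searchsorted(_RANK_EDGES, count, side="left"))


@dataclass
class SpatialWeights:
    """Symmetric non-negative pairwise weights with zero diagonal.

    ``quadrat_labels``, when present, carry the quadrat of each location so
    the ``within_quadrat_only`` permutation null can shuffle values within
    quadrats rather than globally.
    """

    matrix: np.ndarray
    scheme: str
    restriction: str = "all_pairs"
    quadrat_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.matrix, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal weights must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if w.sum() <= 0:
            raise ValueError("total weight must be positive")
        self.matrix = w

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> float:
        return float(self.matrix.sum())


def build_weights(coordinates: Sequence[Tuple[int, int, int]],
                  scheme: str = "inverse_distance",
                  restriction: str = "all_pairs",
                  spacing: float = 0.2,
                  between_quadrat_distance: float = 5.0,
                  threshold: float = 0.25) -> SpatialWeights:
    """Pairwise weights from (quadrat, row, col) grid coordinates.

    Within a quadrat, distance is Euclidean on the section grid at
    ``spacing`` metres per section (adjacent sections: 0.2 m); samples in
    different quadrats sit at a flat ``between_quadrat_distance`` (default
    5 m).  Schemes: ``inverse_distance`` (w = 1/d), ``binary_threshold``
    (w = 1 when d <= threshold), ``rook_adjacency`` (orthogonal grid
    neighbours within a quadrat).  ``within_quadrat_only`` zeroes every
    cross-quadrat weight.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    if restriction not in RESTRICTIONS:
        raise ValueError(f"restriction must be one of {RESTRICTIONS}")
    coords = [tuple(c) for c in coordinates]
    if len(set(coords)) != len(coords):
        raise ValueError("coordinates contain coincident points")
    q = np.array([c[0] for c in coords])
    r = np.array([c[1] for c in coords], dtype=float)
    col = np.array([c[2] for c in coords], dtype=float)
    same_quadrat = q[:, None] == q[None, :]
    grid_dist = np.hypot(r[:, None] - r[None, :], col[:, None] - col[None, :])
    dist = np.where(same_quadrat, spacing * grid_dist,
                    between_quadrat_distance)
    n = len(coords)
    off = ~np.eye(n, dtype=bool)
    if scheme == "inverse_distance":
        w = np.zeros((n, n))
        w[off] = 1.0 / dist[off]
    elif scheme == "binary_threshold":
        w = (dist <= threshold).astype(float)
        np.fill_diagonal(w, 0.0)
    else:  # rook adjacency
        manhattan = (np.abs(r[:, None] - r[None, :])
                     + np.abs(col[:, None] - col[None, :]))
        w = (same_quadrat & (manhattan == 1)).astype(float)
    if restriction == "within_quadrat_only":
        w = np.where(same_quadrat, w, 0.0)
    return SpatialWeights(matrix=w, scheme=scheme, restriction=restriction,
                          quadrat_labels=q)


def geary_c(values, weights: SpatialWeights) -> float:
    """Geary's c: (n-1) sum_ij w_ij (x_i-x_j)^2 / (2 W sum_i (x_i-xbar)^2)."""
    x = np.asarray(values, dtype=float)
    if x.size != weights.n:
        raise ValueError("values and weights must have matching length")
    ss = ((x - x.mean()) ** 2).sum()
    if ss == 0:
        raise ValueError("Geary's c is undefined for constant values")
    diff2 = (x[:, None] - x[None, :]) ** 2
    num = (x.size - 1) * (weights.matrix * diff2).sum()
    return float(num / (2.0 * weights.total * ss))


@dataclass
class GearyResult:
    """Observed Geary's c with its permutation null distribution.

    ``p_normal`` is the tail probability of the z-score under a normal
    approximation to the permutation null; ``p_empirical`` is the rank-based
    estimate (x+1)/(m+1) from the permutations themselves.
    """

    c: float
    null_mean: float
    null_sd: float
    z: float
    p_normal: float
    p_empirical: float
    n_permutations: int
    tail: str = "lower"


def geary_permutation_test(values, weights: SpatialWeights,
                           n_permutations: int = 100,
                           seed: int = 0,
                           tail: str = "lower") -> GearyResult:
    """Permutation test of Geary's c.

    Attribute values are shuffled over locations ``n_permutations`` times
    (default 100) to build the null.  With ``within_quadrat_only`` weights
    the shuffle is restricted to within each quadrat, so quadrat-level
    differences are held fixed and only fine-scale structure is tested.
    ``tail``: ``"lower"`` tests clustering (c below the null), ``"upper"``
    dispersion, ``"two_sided"`` either.
    """
    if n_permutations < 2:
        raise ValueError("n_permutations must be >= 2")
    if tail not in ("lower", "upper", "two_sided"):
        raise ValueError("tail must be lower, upper or two_sided")
    rng = np.random.default_rng(seed)
    x = np.asarray(values, dtype=float)
    c_obs = geary_c(x, weights)
    within = (weights.restriction == "within_quadrat_only"
              and weights.quadrat_labels is not None)

    def shuffle() -> np.ndarray:
        if not within:
            return rng.permutation(x)
        out = x.copy()
        for q in np.unique(weights.quadrat_labels):
            idx = np.flatnonzero(weights.quadrat_labels == q)
            out[idx] = rng.permutation(out[idx])
        return out

    null = np.array([geary_c(shuffle(), weights)
                     for _ in range(n_permutations)])
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        raise ValueError(
            "degenerate permutation null (all permuted c identical); "
            "values carry no exchangeable variation under this restriction")
    z = (c_obs - mu) / sd
    if tail == "lower":
        p_norm = float(norm.cdf(z))
        p_emp = (1 + int((null <= c_obs).sum())) / (n_permutations + 1)
    elif tail == "upper":
        p_norm = float(norm.sf(z))
        p_emp = (1 + int((null >= c_obs).sum())) / (n_permutations + 1)
    else:
        p_norm = float(2 * norm.sf(abs(z)))
        p_emp = (1 + int((np.abs(null - mu) >= abs(c_obs - mu)).sum())) \
            / (n_permutations + 1)
    return GearyResult(c=c_obs, null_mean=mu, null_sd=sd, z=float(z),
                       p_normal=p_norm, p_empirical=float(p_emp),
                       n_permutations=n_permutations, tail=tail)
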