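"""Generative model of patch founding and sex-limited proliferation.

Each patch receives C ~ Poisson(lambda_c) colonization events; event i
delivers a founder group of D_i ~ zero-truncated Poisson(lambda_d) dauers;
each founder is female independently with probability ``female_fraction``.
For an obligately outcrossing (gonochoristic) species a patch proliferates
only if its founders include at least one female and one male, so the mean
founder number of *proliferative* patches exceeds the mean group size.

``mean_founders_exact`` is a deterministic enumeration oracle over the
compound distribution, used to validate the Monte-Carlo estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln
from scipy.stats import poisson


@dataclass
class FounderSimConfig:
    """Parameters of a founder-demography simulation."""

    lambda_c: float
    lambda_d: float
    female_fraction: float = 0.5
    n_patches: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_c < 0:
            raise ValueError("lambda_c must be >= 0")
        if self.lambda_d < 0:
            raise ValueError("lambda_d must be >= 0")
        if not 0 < self.female_fraction < 1:
            raise ValueError("female_fraction must be strictly in (0, 1)")
        if self.n_patches < 1:
            raise ValueError("n_patches must be >= 1")


@dataclass
class PatchRealization:
    """Latent founding history of one simulated patch."""

    n_colonizations: int
    founder_groups: List[int]
    n_founders: int
    n_females: int
    n_males: int

    @property
    def proliferative(self) -> bool:
        return self.n_females >= 1 and self.n_males >= 1


def _ztp_cdf_table(lambda_d: float) -> np.ndarray:
    """Cumulative probabilities of the zero-truncated Poisson at 1..k_max."""
    k_max = max(30, int(lambda_d + 12 * math.sqrt(lambda_d + 1)))
    ks = np.arange(1, k_max + 1)
    logp = (ks * math.log(lambda_d) - lambda_d - gammaln(ks + 1)
            - math.log(-math.expm1(-lambda_d)))
    return np.cumsum(np.exp(logp))


def sample_zt_poisson(lambda_d: float, size=None,
                      rng: Optional[np.random.Generator] = None):
    """Draw founder-group sizes from the zero-truncated Poisson.

    Exact inverse-CDF sampling on a tabulated cumulative distribution.  The
    lambda_d -> 0 limit degenerates to groups of exactly one dauer.
    """
    if lambda_d < 0:
        raise ValueError("lambda_d must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    if lambda_d == 0:
        out = np.ones(1 if size is None else size, dtype=np.int64)
        return int(out[0]) if size is None else out
    cdf = _ztp_cdf_table(lambda_d)
    u = rng.random(1 if size is None else size) * cdf[-1]
    draws = np.searchsorted(cdf, u) + 1
    return int(draws[0]) if size is None else draws


def _compound_founders(lambda_c: float, lambda_d: float, n_patches: int,
                       rng: np.random.Generator
                       ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized compound draw: per-patch C, per-patch N, flat group sizes."""
    c = rng.poisson(lambda_c, n_patches)
    total_events = int(c.sum())
    groups = sample_zt_poisson(lambda_d, total_events, rng) \
        if total_events else np.empty(0, dtype=np.int64)
    patch_of_event = np.repeat(np.arange(n_patches), c)
    n = np.bincount(patch_of_event, weights=groups,
                    minlength=n_patches).astype(np.int64)
    return c, n, groups


def simulate_patches(config: FounderSimConfig) -> List[PatchRealization]:
    """Simulate founding histories for ``config.n_patches`` patches."""
    rng = np.random.default_rng(config.seed)
    c, n, groups = _compound_founders(config.lambda_c, config.lambda_d,
                                      config.n_patches, rng)
    females = rng.binomial(n, config.female_fraction)
    out: List[PatchRealization] = []
    offsets = np.concatenate([[0], np.cumsum(c)])
    for i in range(config.n_patches):
        gi = groups[offsets[i]:offsets[i + 1]].tolist()
        out.append(PatchRealization(
            n_colonizations=int(c[i]),
            founder_groups=[int(g) for g in gi],
            n_founders=int(n[i]),
            n_females=int(females[i]),
            n_males=int(n[i] - females[i]),
        ))
    return out


def mean_founders_proliferative(config: FounderSimConfig
                                ) -> Tuple[float, float]:
    """Monte-Carlo mean founder number of proliferative patches, with SE.

    Simulates ``config.n_patches`` patches and averages total founders over
    those containing at least one founder of each sex.
    """
    rng = np.random.default_rng(config.seed)
    count = 0
    total = 0.0
    total_sq = 0.0
    chunk = 2_000_000
    remaining = config.n_patches
    while remaining > 0:
        m = min(chunk, remaining)
        remaining -= m
        _, n, _ = _compound_founders(config.lambda_c, config.lambda_d, m, rng)
        females = rng.binomial(n, config.female_fraction)
        ok = (females >= 1) & (n - females >= 1)
        nf = n[ok].astype(float)
        count += nf.size
        total += nf.sum()
        total_sq += (nf * nf).sum()
    if count == 0:
        raise ValueError(
            "no proliferative patches realized; increase n_patches")
    mean = total / count
    var = max(total_sq / count - mean * mean, 0.0)
    se = math.sqrt(var / count)
    return mean, se


def _compound_pmf(lambda_c: float, lambda_d: float,
                  n_max: int) -> np.ndarray:
    """pmf of total founders N per patch, truncated at ``n_max``.

    N is a compound Poisson sum of zero-truncated Poisson groups; the pmf is
    the Poisson(lambda_c)-weighted sum of c-fold convolutions of the group
    pmf.
    """
    if lambda_d == 0:
        # Groups degenerate to 1, so N == C.
        return poisson.pmf(np.arange(n_max + 1), lambda_c)
    ks = np.arange(1, n_max + 1)
    group = np.zeros(n_max + 1)
    group[1:] = np.exp(ks * math.log(lambda_d) - lambda_d - gammaln(ks + 1)
                       - math.log(-math.expm1(-lambda_d)))
    c_max = int(poisson.isf(1e-16, lambda_c)) + 1
    pmf = np.zeros(n_max + 1)
    conv = np.zeros(n_max + 1)
    conv[0] = 1.0  # zero events -> zero founders
    pmf += poisson.pmf(0, lambda_c) * conv
    for c in range(1, c_max + 1):
        conv = np.convolve(conv, group)[: n_max + 1]
        pmf += poisson.pmf(c, lambda_c) * conv
    return pmf


def mean_founders_exact(lambda_c: float, lambda_d: float,
                        female_fraction: float = 0.5,
                        n_max: int = 400) -> float:
    """Exact E[N | >= 1 founder of each sex] by truncated enumeration.

    With N founders each independently female with probability q, the patch
    holds both sexes with probability ``1 - q^N - (1-q)^N``.  The truncation
    ``n_max`` must leave negligible tail mass (< 1e-12), else a warning is
    issued.
    """
    if not 0 < female_fraction < 1:
        raise ValueError("female_fraction must be strictly in (0, 1)")
    pmf = _compound_pmf(lambda_c, lambda_d, n_max)
    tail = 1.0 - pmf.sum()
    if tail > 1e-12:
        warnings.warn(
            f"compound pmf truncation leaves tail mass {tail:.2e}; "
            "increase n_max", RuntimeWarning)
    n = np.arange(n_max + 1)
    q = female_fraction
    both = 1.0 - q ** n - (1.0 - q) ** n
    both[0] = 0.0
    w = pmf * both
    return float((n * w).sum() / w.sum())


def simulate_fig_experiment(n_figs: int,
                            species_params: Sequence[Tuple[str, float, float]],
                            seed: int = 0,
                            n_replicates: int = 1,
                            rng: Optional[np.random.Generator] = None
                            ) -> np.ndarray:
    """Simulate founder counts on a spatial array of figs.

    Each species colonizes every fig independently through its own compound
    Poisson process ``(name, lambda_c, lambda_d)``.  Returns an integer
    array of shape ``(n_replicates, n_figs, n_species)``.
    """
    if n_figs < 1:
        raise ValueError("n_figs must be >= 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    cells = n_replicates * n_figs
    out = np.zeros((n_replicates, n_figs, len(species_params)), dtype=np.int64)
    for j, (_, lam_c, lam_d) in enumerate(species_params):
        _, n, _ = _compound_founders(lam_c, lam_d, cells, rng)
        out[:, :, j] = n.reshape(n_replicates, n_figs)
    return out
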