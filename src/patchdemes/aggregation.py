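"""Aggregation indices and the coexistence calculation.

Under the aggregation model of coexistence, clumped (aggregated) conspecific
distributions across ephemeral patches raise intraspecific crowding relative
to interspecific crowding, weakening effective between-species competition
and permitting competitors to coexist.  The statistics:

* Lloyd's mean crowding m* = sum n(n-1) / sum n — the mean number of
  conspecifics sharing a patch with a random individual;
* the intraspecific aggregation index J = m*/mean_density - 1, zero for
  independently placed individuals, positive under aggregation;
* the interspecific analogue C_ab, zero for independently distributed
  species;
* the proportional reduction in effective interspecific competition implied
  by those indices (see :func:`competition_reduction`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from patchdemes.simulate import simulate_fig_experiment


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for this input (e.g. no individuals)."""


def mean_crowding(counts) -> float:
    """Lloyd's mean crowding: sum n(n-1) / sum n over patches."""
    n = np.asarray(counts, dtype=float)
    total = n.sum()
    if total <= 0:
        raise UndefinedStatisticError("mean crowding needs >= 1 individual")
    return float((n * (n - 1)).sum() / total)


def ives_j(counts) -> float:
    """Intraspecific aggregation index J = m*/(sum n / P) - 1.

    The denominator is mean density over *all* P patches, empty ones
    included; this is the convention under which J has expectation ~0 for
    Poisson-placed individuals and matches the compound-process closed form
    of :func:`ives_j_asymptotic`.
    """
    n = np.asarray(counts, dtype=float)
    if n.size < 1:
        raise UndefinedStatisticError("need >= 1 patch")
    total = n.sum()
    if total <= 0:
        raise UndefinedStatisticError("J is undefined with zero individuals")
    return mean_crowding(n) / (total / n.size) - 1.0


def ives_j_asymptotic(lambda_c: float, lambda_d: float) -> float:
    """Large-sample limit of J under the compound colonization process.

    For C ~ Poisson(lambda_c) groups of zero-truncated Poisson(lambda_d)
    size D, the factorial moments give
    J_inf = E[D(D-1)] / (lambda_c E[D]^2) with
    E[D(D-1)] = lambda_d^2 / (1 - e^{-lambda_d}).
    """
    if lambda_c <= 0 or lambda_d < 0:
        raise ValueError("lambda_c must be > 0 and lambda_d >= 0")
    if lambda_d == 0:
        return 0.0
    one_m = -math.expm1(-lambda_d)
    fact2 = lambda_d ** 2 / one_m
    mean_d = lambda_d / one_m
    return fact2 / (lambda_c * mean_d ** 2)


def interspecific_crowding(counts_a, counts_b) -> float:
    """Relative interspecific crowding C_ab, zero under independence.

    ``(sum n_a n_b / sum n_a) / (sum n_b / P) - 1``: the mean number of
    heterospecifics sharing a patch with a random individual of species a,
    relative to the all-patch mean density of species b.  Symmetric in the
    two species.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must align over the same patches")
    if a.sum() <= 0 or b.sum() <= 0:
        raise UndefinedStatisticError(
            "interspecific crowding needs both species present")
    return float((a * b).sum() / a.sum() / (b.sum() / a.size) - 1.0)


def competition_reduction(j_a: float, j_b: float, c_ab: float) -> float:
    """Proportional reduction in effective interspecific competition.

    In the two-species aggregation-coexistence framework, per-capita
    intraspecific competition scales with (1 + J) and interspecific
    competition with (1 + C_ab), so aggregation multiplies the product of
    the two interspecific competition coefficients by

        (1 + C_ab)^2 / ((1 + J_a)(1 + J_b)).

    The reduction is one minus that factor: 0 when both species are
    unaggregated and independently distributed, approaching 1 when
    intraspecific aggregation dwarfs interspecific crowding.
    """
    if j_a <= -1 or j_b <= -1:
        raise ValueError("J indices must exceed -1")
    if c_ab < -1:
        raise ValueError("C_ab must be >= -1")
    return 1.0 - (1.0 + c_ab) ** 2 / ((1.0 + j_a) * (1.0 + j_b))


@dataclass
class AggregationSummary:
    """Monte-Carlo distribution of aggregation statistics over replicates."""

    species: Tuple[str, ...]
    j_mean: Dict[str, float]
    j_sd: Dict[str, float]
    c_ab_mean: Optional[float]
    c_ab_sd: Optional[float]
    reduction_mean: Optional[float]
    reduction_sd: Optional[float]
    n_replicates: int
    n_undefined_replicates: Dict[str, int] = field(default_factory=dict)


def aggregation_mc(n_figs: int,
                   species_params: Sequence[Tuple[str, float, float]],
                   n_replicates: int,
                   seed: int = 0,
                   chunk: int = 100_000) -> AggregationSummary:
    """Monte-Carlo aggregation statistics over replicate fig experiments.

    Per replicate, simulates an ``n_figs`` array colonized independently by
    each species ``(name, lambda_c, lambda_d)``, then computes J per species
    and, for the first two species, C_ab and the competition reduction.
    Replicates where a species has zero founders leave that species'
    statistics undefined; they are excluded from the averages and counted in
    ``n_undefined_replicates``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    names = [name for name, _, _ in species_params]
    rng = np.random.default_rng(seed)
    j_parts = {name: [] for name in names}
    undef = {name: 0 for name in names}
    c_parts, red_parts = [], []
    pair = names[:2] if len(names) >= 2 else None
    if pair:
        undef["pair"] = 0
    done = 0
    while done < n_replicates:
        m = min(chunk, n_replicates - done)
        done += m
        cnt = simulate_fig_experiment(n_figs, species_params,
                                      n_replicates=m, rng=rng)
        totals = cnt.sum(axis=1)  # (m, n_species)
        crowd = (cnt * (cnt - 1)).sum(axis=1)
        js = {}
        for j, name in enumerate(names):
            tot = totals[:, j].astype(float)
            ok = tot > 0
            undef[name] += int((~ok).sum())
            jval = np.full(m, np.nan)
            jval[ok] = (crowd[ok, j] / tot[ok]) / (tot[ok] / n_figs) - 1.0
            js[name] = jval
            j_parts[name].append(jval[ok])
        if pair:
            a, b = cnt[:, :, 0].astype(float), cnt[:, :, 1].astype(float)
            sa, sb = totals[:, 0].astype(float), totals[:, 1].astype(float)
            ok = (sa > 0) & (sb > 0)
            undef["pair"] += int((~ok).sum())
            cab = ((a[ok] * b[ok]).sum(axis=1) / sa[ok]) / (sb[ok] / n_figs) - 1.0
            red = 1.0 - (1.0 + cab) ** 2 / (
                (1.0 + js[names[0]][ok]) * (1.0 + js[names[1]][ok]))
            c_parts.append(cab)
            red_parts.append(red)
    j_mean, j_sd = {}, {}
    for name in names:
        vals = np.concatenate(j_parts[name]) if j_parts[name] else np.empty(0)
        j_mean[name] = float(vals.mean()) if vals.size else math.nan
        j_sd[name] = float(vals.std()) if vals.size else math.nan
    if pair:
        cab = np.concatenate(c_parts) if c_parts else np.empty(0)
        red = np.concatenate(red_parts) if red_parts else np.empty(0)
        c_mean = float(cab.mean()) if cab.size else None
        c_sd = float(cab.std()) if cab.size else None
        r_mean = float(red.mean()) if red.size else None
        r_sd = float(red.std()) if red.size else None
    else:
        c_mean = c_sd = r_mean = r_sd = None
    return AggregationSummary(
        species=tuple(names), j_mean=j_mean, j_sd=j_sd,
        c_ab_mean=c_mean, c_ab_sd=c_sd,
        reduction_mean=r_mean, reduction_sd=r_sd,
        n_replicates=n_replicates, n_undefined_replicates=undef)
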