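"""Species-richness estimation and exact 2x2 association tests.

Chao-type estimators extrapolate asymptotic species richness from the
counts of rarely detected species: f1 species seen once and f2 seen twice,
in either individual abundances (Chao1) or per-sample incidences (Chao2).
Fisher's exact test handles the small sparse contingency tables typical of
substrate- and habitat-association questions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import fisher_exact as _scipy_fisher

from patchdemes.records import ContingencyTable2x2


@dataclass
class RichnessEstimate:
    """Observed and estimated asymptotic species richness."""

    s_obs: int
    f1: int
    f2: int
    n_or_t: int
    estimate: float
    mode: str
    se: Optional[float] = None

    def __post_init__(self) -> None:
        if self.estimate < self.s_obs - 1e-9:
            raise ValueError("richness estimate cannot fall below S_obs")


def _chao(s_obs: int, f1: int, f2: int, units: int, mode: str
          ) -> RichnessEstimate:
    if units <= 1:
        extra = 0.0
    else:
        factor = (units - 1) / units
        if f2 > 0:
            extra = factor * f1 * f1 / (2.0 * f2)
        else:
            # Bias-corrected form; avoids division by zero when no species
            # was seen exactly twice.
            extra = factor * f1 * (f1 - 1) / 2.0
    return RichnessEstimate(s_obs=s_obs, f1=f1, f2=f2, n_or_t=units,
                            estimate=s_obs + extra, mode=mode)


def chao1_abundance(abundances: Sequence[int]) -> RichnessEstimate:
    """Chao1 richness from per-species individual abundances.

    Zero entries (species listed but unobserved) are ignored, so the
    estimate depends only on the observed community.
    """
    counts = np.asarray([a for a in abundances if a > 0], dtype=int)
    if counts.size == 0:
        raise ValueError("no observed species")
    n = int(counts.sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return _chao(int(counts.size), f1, f2, n, mode="abundance")


def chao2_incidence(incidence_freqs: Sequence[int],
                    n_units: int) -> RichnessEstimate:
    """Chao2 richness from per-species incidence over ``n_units`` samples.

    ``incidence_freqs[i]`` is the number of sampling units in which species
    i was detected (1..n_units); zeros are ignored.
    """
    freqs = np.asarray([f for f in incidence_freqs if f > 0], dtype=int)
    if freqs.size == 0:
        raise ValueError("no observed species")
    if np.any(freqs > n_units):
        raise ValueError("incidence frequency exceeds number of units")
    f1 = int((freqs == 1).sum())
    f2 = int((freqs == 2).sum())
    return _chao(int(freqs.size), f1, f2, n_units, mode="incidence")


def fisher_exact(table: ContingencyTable2x2, tail: str = "two_sided") -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    ``two_sided`` sums all tables whose point probability does not exceed
    the observed table's.  ``one_sided`` tests in the direction of the
    observed association (the sign of ad - bc); at exact independence the
    smaller directional tail is reported.
    """
    if tail not in ("one_sided", "two_sided"):
        raise ValueError("tail must be one_sided or two_sided")
    arr = table.as_array()
    if tail == "two_sided":
        return float(_scipy_fisher(arr, alternative="two-sided").pvalue)
    direction = table.a * table.d - table.b * table.c
    if direction > 0:
        return float(_scipy_fisher(arr, alternative="greater").pvalue)
    if direction < 0:
        return float(_scipy_fisher(arr, alternative="less").pvalue)
    return float(min(_scipy_fisher(arr, alternative="greater").pvalue,
                     _scipy_fisher(arr, alternative="less").pvalue))
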