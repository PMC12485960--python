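"""Synthetic survey and quadrat-experiment generator with a truth ledger.

Emulates the two field designs the analysis consumes: an island-wide survey
of ~400 independent substrate samples, and a fine-scale experiment of three
1-m^2 quadrats each gridded into 25 20-cm sections with one fig sampled per
section.  Worm counts are produced by the same compound colonization model
the inference assumes (Poisson colonizations, zero-truncated Poisson founder
groups, Bernoulli sexes), filtered through the field observation process:

* a lone founder cannot proliferate and is observed as exactly 1 worm;
* a patch with founders of both sexes proliferates to a large census, of
  which at most ``identification_cap`` worms are identified to species
  (5 in the survey, 10 in the spatial samples);
* a multi-founder single-sex patch cannot proliferate and is emitted with
  its (small, capped) founder count — a deliberate stressor absent from the
  inference model, which treats every single-worm patch as a lone founder.

Every generated table comes with a *truth ledger* of the latent
colonization history per patch and species, for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from patchdemes.records import PatchRecord
from patchdemes.simulate import _compound_founders
from patchdemes.spatial import density_rank

#: (region, forest_type, elevation range in m) templates for survey rows.
DEFAULT_REGION_TEMPLATES = (
    ("kolonia", "urban", (0, 50)),
    ("awak", "agroforest", (20, 200)),
    ("sokehs_ridge", "disturbed_forest", (150, 300)),
    ("nahnalaud", "rainforest", (300, 600)),
    ("summit_trail", "cloudforest", (600, 780)),
)

_SUBSTRATES = (
    ("fruit", "nihn fig"), ("fruit", "breadfruit"), ("flower", "pwuhr"),
    ("flower", "banana flower"), ("stem", "taro stem"),
    ("fungus", "bracket fungus"), ("litter", "leaf litter"),
)


@dataclass
class SpeciesParams:
    """Compound-process parameters for one species."""

    name: str
    lambda_c: float
    lambda_d: float

    def __post_init__(self) -> None:
        if self.lambda_c < 0 or self.lambda_d < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class SurveyGeneratorConfig:
    """Island-wide survey generator settings.

    ``census_range`` bounds the uniform proliferative-patch census draw;
    only its exceedance of ``identification_cap`` matters downstream.
    """

    species: Sequence[SpeciesParams]
    n_patches: int = 400
    identification_cap: int = 5
    census_range: Tuple[int, int] = (20, 1000)
    female_fraction: float = 0.5
    seed: int = 0
    region_templates: Sequence = DEFAULT_REGION_TEMPLATES

    def __post_init__(self) -> None:
        if self.identification_cap < 1:
            raise ValueError("identification_cap must be >= 1")
        if self.n_patches < 1:
            raise ValueError("n_patches must be >= 1")


@dataclass
class QuadratGeneratorConfig:
    """Quadrat fig-experiment generator settings.

    ``quadrat_density_multipliers`` scale the latent total-nematode census
    per quadrat; unequal values create purely between-quadrat spatial
    structure for exercising restricted Geary tests.  ``n_lost`` figs
    (default 1, from the second quadrat) are dropped, emulating sample loss.
    """

    species: Sequence[SpeciesParams]
    n_quadrats: int = 3
    grid_size: int = 5
    identification_cap: int = 10
    census_range: Tuple[int, int] = (20, 1000)
    female_fraction: float = 0.5
    base_density: float = 120.0
    density_dispersion: float = 0.6
    quadrat_density_multipliers: Optional[Sequence[float]] = None
    n_lost: int = 1
    seed: int = 0


def _observe(n_founders: int, females: int, cap: int, census_range,
             rng: np.random.Generator) -> Tuple[int, Optional[int]]:
    """Map a latent founding outcome to an identified-worm count."""
    if n_founders == 0:
        return 0, None
    males = n_founders - females
    if females >= 1 and males >= 1:
        census = int(rng.integers(census_range[0], census_range[1] + 1))
        return min(cap, census), census
    if n_founders == 1:
        return 1, None
    return min(cap, n_founders), None  # same-sex multi-founder group


def _species_outcomes(species: Sequence[SpeciesParams], n_patches: int,
                      cap: int, census_range, female_fraction: float,
                      rng: np.random.Generator):
    """Latent histories and observed counts for all species over patches."""
    latent: Dict[str, list] = {}
    observed: Dict[str, list] = {}
    for sp in species:
        c, n, groups = _compound_founders(sp.lambda_c, sp.lambda_d,
                                          n_patches, rng)
        females = rng.binomial(n, female_fraction)
        offsets = np.concatenate([[0], np.cumsum(c)])
        sp_latent, sp_obs = [], []
        for i in range(n_patches):
            obs, census = _observe(int(n[i]), int(females[i]), cap,
                                   census_range, rng)
            sp_latent.append({
                "n_colonizations": int(c[i]),
                "founder_groups": [int(g) for g in
                                   groups[offsets[i]:offsets[i + 1]]],
                "n_founders": int(n[i]),
                "n_females": int(females[i]),
                "n_males": int(n[i] - females[i]),
                "proliferative": bool(females[i] >= 1
                                      and n[i] - females[i] >= 1),
                "census": census,
            })
            sp_obs.append(obs)
        latent[sp.name] = sp_latent
        observed[sp.name] = sp_obs
    return latent, observed


def generate_survey(config: SurveyGeneratorConfig
                    ) -> Tuple[List[PatchRecord], Dict]:
    """Generate an island-wide survey table plus its truth ledger.

    The ledger maps patch_id -> species -> latent founding history
    (colonization count, founder groups, sexes, proliferation, census).
    """
    rng = np.random.default_rng(config.seed)
    latent, observed = _species_outcomes(
        config.species, config.n_patches, config.identification_cap,
        config.census_range, config.female_fraction, rng)
    records: List[PatchRecord] = []
    truth: Dict[str, Dict] = {}
    templates = list(config.region_templates)
    for i in range(config.n_patches):
        region, forest, (lo, hi) = templates[int(rng.integers(len(templates)))]
        elev = float(np.round(rng.uniform(lo, hi), 1))
        sub_class, sub_name = _SUBSTRATES[int(rng.integers(len(_SUBSTRATES)))]
        # Island lapse rate: ~27 degC at sea level, ~23 degC at 450 m.
        temp = float(np.round(27.0 - elev / 112.5 + rng.normal(0, 0.8), 1))
        pid = f"P{i + 1:04d}"
        counts = {sp.name: observed[sp.name][i] for sp in config.species
                  if observed[sp.name][i] > 0}
        records.append(PatchRecord(
            patch_id=pid, region=region, forest_type=forest,
            substrate_class=sub_class, substrate_name=sub_name,
            elevation=elev, substrate_temp=temp,
            elevated_position=bool(rng.random() < 0.05),
            species_counts=counts))
        truth[pid] = {sp.name: latent[sp.name][i] for sp in config.species}
    return records, truth


def generate_quadrat_experiment(config: QuadratGeneratorConfig
                                ) -> Tuple[List[PatchRecord], Dict]:
    """Generate a gridded quadrat fig experiment plus its truth ledger.

    Figs carry density ranks derived from a latent total-nematode census
    (Poisson with per-quadrat mean shifts), color stages at a matched
    intermediate decomposition state, and per-species identified counts
    capped at ``identification_cap``.
    """
    rng = np.random.default_rng(config.seed)
    q_mult = (config.quadrat_density_multipliers
              if config.quadrat_density_multipliers is not None
              else [1.0] * config.n_quadrats)
    if len(q_mult) != config.n_quadrats:
        raise ValueError("need one density multiplier per quadrat")
    g = config.grid_size
    n_figs = config.n_quadrats * g * g
    latent, observed = _species_outcomes(
        config.species, n_figs, config.identification_cap,
        config.census_range, config.female_fraction, rng)
    lost = set()
    if config.n_lost:
        # Losses drawn from the second quadrat (index 1), emulating a lost
        # field sample.
        lost_q = 1 if config.n_quadrats > 1 else 0
        pool = [lost_q * g * g + s for s in range(g * g)]
        lost = set(rng.choice(pool, size=config.n_lost, replace=False))
    records: List[PatchRecord] = []
    truth: Dict[str, Dict] = {}
    for i in range(n_figs):
        if i in lost:
            continue
        quad, sect = divmod(i, g * g)
        row, col = divmod(sect, g)
        # Lognormal-overdispersed census: real fig censuses vary far more
        # than Poisson within a quadrat.
        mu = config.base_density * q_mult[quad] * rng.lognormal(
            -config.density_dispersion ** 2 / 2, config.density_dispersion)
        census = int(rng.poisson(mu))
        pid = f"Q{quad + 1}-S{sect + 1:02d}"
        counts = {sp.name: observed[sp.name][i] for sp in config.species
                  if observed[sp.name][i] > 0}
        records.append(PatchRecord(
            patch_id=pid, region="sokehs_ridge",
            forest_type="disturbed_forest", substrate_class="fruit",
            substrate_name="nihn fig", elevation=246.0,
            species_counts=counts,
            density_rank=density_rank(min(census, 1000)),
            quadrat=quad + 1, grid_row=row + 1, grid_col=col + 1,
            color_stage=int(rng.integers(3, 5))))
        truth[pid] = {"total_census": census}
        truth[pid].update(
            {sp.name: latent[sp.name][i] for sp in config.species})
    return records, truth
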