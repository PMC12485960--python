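"""Domain types for patch-survey data and inference results.

A *patch* is a single ephemeral resource unit — one rotting fruit, flower,
stem, fungus, or litter sample.  A survey row records where the patch was,
what it was, and how many worms of each species were identified from it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

logger = logging.getLogger("patchdemes")

FOREST_TYPES = frozenset(
    {"urban", "agroforest", "disturbed_forest", "rainforest", "cloudforest"}
)
SUBSTRATE_CLASSES = frozenset(
    {"fruit", "flower", "stem", "fungus", "litter", "other"}
)


class ValidationError(ValueError):
    """A record violated the survey-table schema."""


@dataclass
class PatchRecord:
    """One sampled substrate with metadata and per-species identified counts.

    ``species_counts`` maps free-form species names to non-negative counts of
    worms identified to that species from the sample; the vocabulary is open
    because new species appear mid-survey.  Spatial fields (``quadrat``,
    ``grid_row``, ``grid_col``) are present only for gridded quadrat samples
    and must appear together.
    """

    patch_id: str
    region: str
    forest_type: str
    substrate_class: str
    substrate_name: str = ""
    elevation: float = 0.0
    substrate_temp: Optional[float] = None
    elevated_position: bool = False
    species_counts: Mapping[str, int] = field(default_factory=dict)
    density_rank: Optional[int] = None
    quadrat: Optional[int] = None
    grid_row: Optional[int] = None
    grid_col: Optional[int] = None
    color_stage: Optional[int] = None

    def __post_init__(self) -> None:
        if self.forest_type not in FOREST_TYPES:
            raise ValidationError(
                f"patch {self.patch_id!r}: forest_type {self.forest_type!r} "
                f"not one of {sorted(FOREST_TYPES)}"
            )
        if self.substrate_class not in SUBSTRATE_CLASSES:
            raise ValidationError(
                f"patch {self.patch_id!r}: substrate_class "
                f"{self.substrate_class!r} not one of {sorted(SUBSTRATE_CLASSES)}"
            )
        if self.elevation < 0:
            raise ValidationError(
                f"patch {self.patch_id!r}: elevation must be >= 0 m"
            )
        for sp, cnt in self.species_counts.items():
            if cnt < 0 or cnt != int(cnt):
                raise ValidationError(
                    f"patch {self.patch_id!r}: count for {sp!r} must be a "
                    f"non-negative integer, got {cnt!r}"
                )
        if self.density_rank is not None and not 0 <= self.density_rank <= 6:
            raise ValidationError(
                f"patch {self.patch_id!r}: density_rank must be in 0..6, "
                f"got {self.density_rank}"
            )
        spatial = (self.quadrat, self.grid_row, self.grid_col)
        if any(v is not None for v in spatial) and any(v is None for v in spatial):
            raise ValidationError(
                f"patch {self.patch_id!r}: quadrat, grid_row and grid_col "
                "must be present together"
            )
        for name, v in (("grid_row", self.grid_row), ("grid_col", self.grid_col)):
            if v is not None and not 1 <= v <= 5:
                raise ValidationError(
                    f"patch {self.patch_id!r}: {name} must be in 1..5, got {v}"
                )

    def count(self, species: str) -> int:
        return int(self.species_counts.get(species, 0))


@dataclass
class OccupancySummary:
    """Sufficient statistics of the colonization likelihoods for one species.

    ``n_single`` counts patches with exactly one identified worm of the
    species — under the colonization model these are patches that received a
    single colonization event delivering a single dauer.
    """

    species: str
    n_patches: int
    n_occupied: int
    n_single: int

    @property
    def n_empty(self) -> int:
        return self.n_patches - self.n_occupied

    def __post_init__(self) -> None:
        if not 0 <= self.n_occupied <= self.n_patches:
            raise ValidationError("n_occupied must be in [0, n_patches]")
        if not 0 <= self.n_single <= self.n_occupied:
            raise ValidationError("n_single must be in [0, n_occupied]")


@dataclass
class RateEstimate:
    """A Poisson-rate MLE with a profile-likelihood confidence interval.

    ``drop_used`` is the log-likelihood drop defining the interval (1.92, half
    the chi-square(1) 95% quantile, for a one-parameter profile).  ``boundary``
    flags degenerate data: ``"all_empty"`` when no patch is occupied (MLE
    pinned at 0) and ``"none_empty"`` when every patch is occupied (MLE
    unbounded above; reported as NaN with a one-sided interval).
    """

    mle: float
    ci_low: float
    ci_high: float
    loglik_max: float
    drop_used: float = 1.92
    method: str = "brent"
    boundary: Optional[str] = None

    def __post_init__(self) -> None:
        if self.boundary is None and not (
            self.ci_low <= self.mle <= self.ci_high
        ):
            raise ValidationError("CI must bracket the MLE")


@dataclass
class RidgePoint:
    """One point of the (lambda_c, lambda_d) likelihood ridge.

    ``expected_founders`` is the zero-truncated Poisson mean
    lambda_d / (1 - exp(-lambda_d)): the mean number of dauers delivered per
    colonization event.
    """

    lambda_c: float
    lambda_d_hat: float
    expected_founders: float
    loglik: float
    boundary: Optional[str] = None

    def __post_init__(self) -> None:
        if self.boundary is None:
            expect = self.lambda_d_hat / -math.expm1(-self.lambda_d_hat)
            if not math.isclose(self.expected_founders, expect, rel_tol=1e-6):
                raise ValidationError(
                    "expected_founders inconsistent with lambda_d_hat"
                )


@dataclass
class ContingencyTable2x2:
    """Counts (a, b / c, d); rows are groups, columns presence/absence."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("cell counts must be non-negative")
        if (self.a + self.b) == 0 or (self.c + self.d) == 0:
            raise ValidationError("both row margins must be positive")
        if (self.a + self.c) == 0 or (self.b + self.d) == 0:
            raise ValidationError("both column margins must be positive")

    def as_array(self):
        return [[self.a, self.b], [self.c, self.d]]


@dataclass
class RunConfig:
    """Run-level plumbing: seed, replicate counts, tolerances, output style."""

    seed: int = 0
    n_replicates: int = 1
    optimizer_tol: float = 1e-8
    output_decimals: int = 4
    weights_scheme: str = "inverse_distance"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")


def summarize_occupancy(
    records: Sequence[PatchRecord], species: str
) -> OccupancySummary:
    """Tally occupancy and single-worm patches for one species.

    A species absent from every record is not an error: the summary simply
    has ``n_occupied = 0`` (logged, since it often signals a typo).
    """
    if not records:
        raise ValueError("records must be non-empty")
    counts = [r.count(species) for r in records]
    n_occ = sum(1 for c in counts if c > 0)
    n_single = sum(1 for c in counts if c == 1)
    if n_occ == 0:
        logger.info("species %r not observed in any of %d records",
                    species, len(records))
    return OccupancySummary(
        species=species,
        n_patches=len(records),
        n_occupied=n_occ,
        n_single=n_single,
    )
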