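"""From replicate-level measurements to the normalized training matrix.

The pipeline mirrors standard two-channel microarray / GC-MS practice for
introgression-line panels:

1. per (entity, genotype), keep the measurement only when at least
   ``min_replicates`` technical replicates were detected, and take the log
   of the mean replicate ratio (mean-then-log);
2. drop spots failing quality flags and spots whose foreground does not
   clear background + 2 SD (transcripts);
3. keep only metabolites whose profile magnitude exceeds a log-ratio
   threshold (0.1 by default);
4. scale every pattern so the sum of squared valid log ratios equals 1;
5. append a sign-inverted twin for every pattern, which lets a single
   Euclidean SOM co-locate anti-correlated profiles (cross relations).

Genotypes failing the replicate criterion become pseudo-zeros: explicit
missing values (NaN) excluded from normalization and from all downstream
distances, never silently zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ilsom.datatypes import (
    KIND_METABOLITE,
    KIND_TRANSCRIPT,
    SIGN_INVERTED,
    SIGN_ORIGINAL,
    Pattern,
    ProfileDataset,
)
from ilsom.errors import NormalizationError

logger = logging.getLogger(__name__)

#: Quality flags that exclude a spot from analysis regardless of signal.
SPOT_QUALITY_FLAGS = frozenset(
    {"poor", "negative", "empty", "not_expressed_both_channels"}
)


@dataclass
class ReplicateTable:
    """Replicate-level relative measurements of one entity.

    ``ratios[i]`` lists the replicate measurement ratios (dimensionless,
    positive where detected) for genotype i; an empty list means the entity
    was never detected in that genotype.
    """

    entity_id: str
    kind: str
    ratios: list[list[float]]

    def __post_init__(self) -> None:
        for i, reps in enumerate(self.ratios):
            if any(r <= 0 for r in reps):
                raise ValueError(
                    f"{self.entity_id}: non-positive ratio in genotype {i}"
                )


@dataclass
class SpotRecord:
    """One array spot with the statistics used by the expression filter."""

    spot_id: str
    foreground_mean: float
    background_mean: float
    background_sd: float
    quality_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.background_sd < 0:
            raise ValueError(f"{self.spot_id}: negative background SD")
        unknown = self.quality_flags - SPOT_QUALITY_FLAGS
        if unknown:
            raise ValueError(f"{self.spot_id}: unknown quality flags {unknown}")


def average_valid_log_ratios(
    table: ReplicateTable,
    min_replicates: int = 2,
    log_base: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-genotype log of the mean replicate ratio, with a validity mask.

    A genotype with fewer than ``min_replicates`` detected replicates is
    invalid: its value is the pseudo-zero placeholder NaN and its mask entry
    False.  Returns ``(values, validity)``, both of length P.
    """
    if min_replicates < 1:
        raise ValueError("min_replicates must be >= 1")
    values = np.full(len(table.ratios), np.nan)
    validity = np.zeros(len(table.ratios), dtype=bool)
    for i, reps in enumerate(table.ratios):
        if len(reps) >= min_replicates:
            values[i] = math.log(float(np.mean(reps)), log_base)
            validity[i] = True
    return values, validity


def passes_magnitude(values: np.ndarray, threshold: float = 0.1) -> bool:
    """True when the maximum absolute valid log ratio strictly exceeds threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    valid = values[~np.isnan(values)]
    return bool(valid.size) and bool(np.max(np.abs(valid)) > threshold)


def filter_metabolites_by_magnitude(
    patterns: Iterable[Pattern], threshold: float = 0.1
) -> list[Pattern]:
    """Keep metabolites whose profile magnitude clears the threshold.

    Transcripts pass through untouched; the magnitude selection applies
    only to the metabolite component.
    """
    kept = []
    for pat in patterns:
        if pat.kind == KIND_METABOLITE and not passes_magnitude(pat.values, threshold):
            continue
        kept.append(pat)
    return kept


def detect_nonexpressed_spots(spots: Iterable[SpotRecord]) -> set[str]:
    """Spots whose foreground mean fails to clear background + 2 SD.

    The test is strict: a spot is non-expressed iff
    ``foreground_mean < background_mean + 2 * background_sd``.
    """
    return {
        s.spot_id
        for s in spots
        if s.foreground_mean < s.background_mean + 2.0 * s.background_sd
    }


def filter_spots(spots: Iterable[SpotRecord]) -> list[SpotRecord]:
    """Spots retained for analysis: quality-clean and expressed."""
    spots = list(spots)
    nonexpressed = detect_nonexpressed_spots(spots)
    return [
        s
        for s in spots
        if not s.quality_flags and s.spot_id not in nonexpressed
    ]


def normalize_unit(
    log_ratios: np.ndarray, validity: np.ndarray | None = None
) -> np.ndarray:
    """Scale a log-ratio vector so its valid sum of squares equals 1.

    x_i = logR_i / sqrt(sum over valid j of logR_j**2).  Invalid components
    (NaN, or masked out by ``validity``) are excluded from the sum and stay
    NaN in the output.  Raises :class:`NormalizationError` when no valid
    nonzero component exists.
    """
    values = np.asarray(log_ratios, dtype=float).copy()
    mask = ~np.isnan(values)
    if validity is not None:
        mask &= np.asarray(validity, dtype=bool)
    values[~mask] = np.nan
    ssq = float(np.sum(values[mask] ** 2))
    if not mask.any() or ssq == 0.0:
        raise NormalizationError(
            "cannot unit-normalize an all-zero or all-missing vector"
        )
    values[mask] = values[mask] / math.sqrt(ssq)
    return values


def augment_inverted(dataset: ProfileDataset) -> ProfileDataset:
    """Close the dataset under sign inversion.

    Every original pattern gains a sign-inverted twin with negated values
    and the same validity mask, interleaved original/inverted in file
    order.  A dataset that is already inversion-closed is returned
    unchanged (augmentation is idempotent).
    """
    has_inverted = any(p.sign == SIGN_INVERTED for p in dataset.patterns)
    if has_inverted:
        if not dataset.is_inversion_closed():
            raise ValueError(
                "dataset has inverted patterns but is not inversion-closed"
            )
        return dataset
    patterns: list[Pattern] = []
    for pat in dataset.patterns:
        patterns.append(pat)
        patterns.append(pat.inverted_twin())
    return ProfileDataset(genotypes=list(dataset.genotypes), patterns=patterns)


def build_dataset(
    tables: Sequence[ReplicateTable],
    genotypes: Sequence[str],
    min_replicates: int = 2,
    magnitude_threshold: float = 0.1,
    log_base: float = 10.0,
    augment: bool = True,
) -> ProfileDataset:
    """Full preprocessing pipeline from replicate tables to a training set.

    Entities with no valid genotype are dropped with a warning; surviving
    patterns keep their un-normalized log ratios as ``raw_values``.
    """
    patterns: list[Pattern] = []
    for table in tables:
        if len(table.ratios) != len(genotypes):
            raise ValueError(
                f"{table.entity_id}: {len(table.ratios)} genotype entries for "
                f"{len(genotypes)} genotypes"
            )
        values, validity = average_valid_log_ratios(
            table, min_replicates=min_replicates, log_base=log_base
        )
        if not validity.any():
            logger.warning("%s: no valid genotype, dropped", table.entity_id)
            continue
        if np.nansum(values**2) == 0.0:
            logger.warning("%s: all-zero profile, dropped", table.entity_id)
            continue
        patterns.append(
            Pattern(
                entity_id=table.entity_id,
                kind=table.kind,
                sign=SIGN_ORIGINAL,
                values=values,
                raw_values=values.copy(),
            )
        )
    patterns = filter_metabolites_by_magnitude(patterns, magnitude_threshold)
    for pat in patterns:
        pat.values = normalize_unit(pat.values)
    dataset = ProfileDataset(genotypes=list(genotypes), patterns=patterns)
    if augment:
        dataset = augment_inverted(dataset)
    return dataset
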