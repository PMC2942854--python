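"""Analysis operations over a trained map.

These are the questions a bench scientist asks of the clustering: where
did my metabolite land (search), which neurons mix transcripts and
metabolites (composition, optionally pooled over a visualization
neighborhood Vn), how tight is each neuron (cohesion, the intracluster
variance C_j = (1/|Omega_j|) * sum ||x_i - w_j||^2), which neurons react in
a given genotype (3-color maps), which neurons harbor pseudo-zeros, and
does the inversion-closed map show the expected 180-degree sign symmetry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ilsom.datatypes import (
    KIND_METABOLITE,
    KIND_TRANSCRIPT,
    SIGN_INVERTED,
    SIGN_ORIGINAL,
    Pattern,
    ProfileDataset,
    chromosome_of,
)
from ilsom.som import Assignment, SomMap

logger = logging.getLogger(__name__)

COMPOSITION_EMPTY = "empty"
COMPOSITION_TRANSCRIPTS = "transcripts_only"
COMPOSITION_METABOLITES = "metabolites_only"
COMPOSITION_MIXED = "mixed"

GREEN = "green"
GRAY = "gray"
WHITE = "white"


# -- search ---------------------------------------------------------------

def search(
    name: str, assignment: Assignment, dataset: ProfileDataset
) -> list[tuple[int, str]]:
    """Units holding patterns whose entity id matches ``name``.

    Exact match is tried first; otherwise a case-insensitive substring
    fallback applies (so "aspartic" finds "L-aspartic acid").  Returns
    ``(unit, sign)`` pairs in pattern order; no match yields an empty list
    with a logged message, never an exception.
    """
    hits = [
        (int(assignment.bmu[i]), pat.sign)
        for i, pat in enumerate(dataset.patterns)
        if pat.entity_id == name
    ]
    if not hits:
        needle = name.lower()
        hits = [
            (int(assignment.bmu[i]), pat.sign)
            for i, pat in enumerate(dataset.patterns)
            if needle in pat.entity_id.lower()
        ]
    if not hits:
        logger.info("no pattern matches %r", name)
    return hits


# -- neighborhoods and composition ---------------------------------------

def units_within(som: SomMap, unit: int, vn: int) -> list[int]:
    """Units within Chebyshev (square-ring) grid radius Vn of a unit."""
    if vn < 0:
        raise ValueError("Vn must be >= 0")
    r0, c0 = som.unit_position(unit)
    units = []
    for r in range(max(1, r0 - vn), min(som.config.rows, r0 + vn) + 1):
        for c in range(max(1, c0 - vn), min(som.config.cols, c0 + vn) + 1):
            units.append(som.unit_at(r, c))
    return sorted(units)


def _pooled_members(
    unit: int, assignment: Assignment, som: SomMap, vn: int
) -> np.ndarray:
    pool = units_within(som, unit, vn) if vn > 0 else [unit]
    return np.flatnonzero(np.isin(assignment.bmu, pool))


def _composition_of(patterns: list[Pattern]) -> str:
    has_t = any(p.kind == KIND_TRANSCRIPT for p in patterns)
    has_m = any(p.kind == KIND_METABOLITE for p in patterns)
    if has_t and has_m:
        return COMPOSITION_MIXED
    if has_t:
        return COMPOSITION_TRANSCRIPTS
    if has_m:
        return COMPOSITION_METABOLITES
    return COMPOSITION_EMPTY


def classify_composition(
    unit: int,
    assignment: Assignment,
    dataset: ProfileDataset,
    som: SomMap,
    vn: int = 0,
) -> str:
    """Composition class of a unit, pooling membership over radius Vn.

    With Vn > 0 every unit within the square neighborhood contributes its
    members before counting kinds, so a transcript-only unit adjacent to a
    metabolite becomes mixed at Vn = 1.
    """
    idx = _pooled_members(unit, assignment, som, vn)
    return _composition_of([dataset.patterns[i] for i in idx])


# -- cohesion -------------------------------------------------------------

def cohesion(
    unit: int, assignment: Assignment, dataset: ProfileDataset, som: SomMap
) -> float:
    """Intracluster variance of one unit: mean squared member-to-codebook
    Euclidean distance.

    With pseudo-zeros the squared distance is summed over valid components
    only and rescaled by P / n_valid so units with different missingness
    stay comparable; on fully valid data this is exactly the plain mean
    squared distance.  Raises on an empty unit (cohesion is undefined, not
    zero).
    """
    members = assignment.members_of(unit)
    if members.size == 0:
        raise ValueError(f"unit {unit} is empty; cohesion undefined")
    w = som.codebook[unit - 1]
    p = dataset.n_genotypes
    total = 0.0
    for i in members:
        x = dataset.patterns[i].values
        valid = ~np.isnan(x)
        ssq = float(np.sum((x[valid] - w[valid]) ** 2))
        total += ssq * (p / int(valid.sum()))
    return total / members.size


def all_cohesions(
    assignment: Assignment, dataset: ProfileDataset, som: SomMap
) -> dict[int, float]:
    """C_j for every nonempty unit (empty units are absent, not zero)."""
    return {
        int(u): cohesion(int(u), assignment, dataset, som)
        for u in assignment.nonempty_units()
    }


def global_compactness(cohesions: dict[int, float]) -> float:
    """Unweighted mean of the per-unit cohesions over nonempty units."""
    if not cohesions:
        raise ValueError("no nonempty units")
    return float(np.mean(list(cohesions.values())))


# -- neuron reports -------------------------------------------------------

@dataclass
class NeuronReport:
    """Membership summary of one unit (optionally Vn-pooled composition)."""

    unit: int
    members: list[int]
    n_transcripts: int
    n_metabolites: int
    composition: str
    cohesion: float | None
    annotations: dict[int, list[str]] = field(default_factory=dict)


def neuron_report(
    unit: int,
    assignment: Assignment,
    dataset: ProfileDataset,
    som: SomMap,
    vn: int = 0,
) -> NeuronReport:
    idx = _pooled_members(unit, assignment, som, vn)
    pats = [dataset.patterns[i] for i in idx]
    own = assignment.members_of(unit)
    return NeuronReport(
        unit=unit,
        members=[int(i) for i in idx],
        n_transcripts=sum(1 for p in pats if p.kind == KIND_TRANSCRIPT),
        n_metabolites=sum(1 for p in pats if p.kind == KIND_METABOLITE),
        composition=_composition_of(pats),
        cohesion=(
            cohesion(unit, assignment, dataset, som) if own.size else None
        ),
    )


# -- three-color maps -----------------------------------------------------

@dataclass
class ThreeColorMap:
    """Per-genotype green/gray/white classification of every unit.

    ``colors[p, j]`` is the class of unit j+1 in genotype dimension p:
    green when some member value exceeds the neuron mean by more than one
    standard deviation, gray when some member falls more than one standard
    deviation below it, white otherwise (empty units are always white).
    """

    genotypes: list[str]
    colors: np.ndarray  # (P, K) of {green, gray, white}

    def color(self, genotype: int | str, unit: int) -> str:
        p = (
            self.genotypes.index(genotype)
            if isinstance(genotype, str)
            else genotype
        )
        return str(self.colors[p, unit - 1])


def three_color_map(
    assignment: Assignment, dataset: ProfileDataset, som: SomMap
) -> ThreeColorMap:
    """Classify every (genotype, unit) cell by deviation from the neuron mean.

    Statistics are per unit and per genotype dimension over the valid member
    values, with the population standard deviation; green (any value above
    mean + SD) takes precedence over gray (any value below mean - SD).
    Single-member units have zero spread and stay white.
    """
    p = dataset.n_genotypes
    colors = np.full((p, som.n_units), WHITE, dtype="<U5")
    x = dataset.matrix()
    for unit in assignment.nonempty_units():
        members = assignment.members_of(int(unit))
        sub = x[members, :]
        for dim in range(p):
            vals = sub[:, dim]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            mu = float(np.mean(vals))
            sigma = float(np.std(vals))
            # Exact-boundary cases (e.g. two members, whose max sits exactly
            # at mu + sigma) must not be decided by rounding noise: the
            # strict comparison carries a tiny relative tolerance.
            tol = 1e-9 * max(float(np.max(np.abs(vals))), 1e-12)
            if np.any(vals > mu + sigma + tol):
                colors[dim, unit - 1] = GREEN
            elif np.any(vals < mu - sigma - tol):
                colors[dim, unit - 1] = GRAY
    return ThreeColorMap(genotypes=list(dataset.genotypes), colors=colors)


# -- pseudo-zeros ---------------------------------------------------------

def pseudo_zero_neurons(
    assignment: Assignment, dataset: ProfileDataset
) -> dict[int, list[tuple[str, str, list[str]]]]:
    """Units holding patterns that are missing in some genotypes but valid
    in others.

    Returns unit -> list of (entity_id, sign, invalid genotype names).
    A fully valid dataset yields an empty mapping.
    """
    out: dict[int, list[tuple[str, str, list[str]]]] = {}
    for i, pat in enumerate(dataset.patterns):
        valid = pat.validity
        if valid.all() or not valid.any():
            continue
        unit = int(assignment.bmu[i])
        bad = [dataset.genotypes[j] for j in np.flatnonzero(~valid)]
        out.setdefault(unit, []).append((pat.entity_id, pat.sign, bad))
    return out


# -- chromosome subsetting ------------------------------------------------

def chromosome_subset(dataset: ProfileDataset, chromosome: str) -> ProfileDataset:
    """Restrict the genotype panel to the ILs of one chromosome.

    Genotype names carry the chromosome tag before the first dash
    ("12-1-1" is on chromosome 12).  Unknown chromosomes raise with the
    list of available tags.
    """
    chromosome = str(chromosome)
    idx = [
        i
        for i, g in enumerate(dataset.genotypes)
        if chromosome_of(g) == chromosome
    ]
    if not idx:
        raise KeyError(
            f"no genotype on chromosome {chromosome!r}; available: "
            f"{dataset.chromosomes()}"
        )
    return dataset.restrict_genotypes(idx)


# -- inversion symmetry ---------------------------------------------------

@dataclass
class SymmetryReport:
    """How faithfully original/inverted BMU pairs mirror each other.

    ``fraction`` is the share of pairs whose inverted BMU sits exactly at
    the 180-degree rotated image of the original BMU; ``displacements``
    gives the per-entity (d_row, d_col) offset from that mirror position.
    """

    fraction: float
    displacements: dict[str, tuple[int, int]]


def symmetry_report(
    assignment: Assignment, dataset: ProfileDataset, som: SomMap
) -> SymmetryReport:
    """Measure the triangular (sign-mirror) symmetry of the trained map."""
    if not dataset.is_inversion_closed():
        raise ValueError("symmetry report requires an inversion-closed dataset")
    inv_index = {
        pat.entity_id: i
        for i, pat in enumerate(dataset.patterns)
        if pat.sign == SIGN_INVERTED
    }
    matches = 0
    displacements: dict[str, tuple[int, int]] = {}
    n_pairs = 0
    for i, pat in enumerate(dataset.patterns):
        if pat.sign != SIGN_ORIGINAL:
            continue
        n_pairs += 1
        b_orig = int(assignment.bmu[i])
        b_inv = int(assignment.bmu[inv_index[pat.entity_id]])
        mirror = som.mirror_unit(b_orig)
        mr, mc = som.unit_position(mirror)
        br, bc = som.unit_position(b_inv)
        displacements[pat.entity_id] = (br - mr, bc - mc)
        if b_inv == mirror:
            matches += 1
    if n_pairs == 0:
        raise ValueError("dataset has no original/inverted pairs")
    return SymmetryReport(fraction=matches / n_pairs, displacements=displacements)
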