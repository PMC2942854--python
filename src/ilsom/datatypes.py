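"""Core in-memory containers: genotype-indexed patterns and datasets.

A *pattern* is one row of the training matrix: the per-genotype normalized
log ratios of a single molecular entity (transcript or metabolite), either
in its original sign or as the sign-inverted twin used to expose cross
relations (up-regulated transcript with down-regulated metabolite, and so
on).  Missing measurements — genotypes without enough significantly
detected replicates, the "pseudo-zeros" — are carried as NaN in the value
vector and never treated as numeric zero.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

KIND_TRANSCRIPT = "transcript"
KIND_METABOLITE = "metabolite"
SIGN_ORIGINAL = "original"
SIGN_INVERTED = "inverted"

#: Label suffix marking a sign-inverted row, matched case-insensitively.
INVERSION_SUFFIX = "(inv)"

_INV_RE = re.compile(r"\(inv\)\s*$", re.IGNORECASE)


def split_inversion_label(label: str) -> tuple[str, str]:
    """Split a row label into ``(entity_id, sign)``.

    ``"Transcript1(inv)"`` -> ``("Transcript1", "inverted")``.
    """
    m = _INV_RE.search(label)
    if m:
        return label[: m.start()].rstrip(), SIGN_INVERTED
    return label, SIGN_ORIGINAL


def chromosome_of(genotype: str) -> str | None:
    """Chromosome tag parsed from an introgression-line name.

    IL names of the form ``"12-1-1"`` carry the chromosome number before the
    first dash.  Names without a dash (e.g. the defaulted ``"IL_3"``) carry
    no tag and yield None.
    """
    if "-" not in genotype:
        return None
    head = genotype.split("-", 1)[0]
    return head if head else None


@dataclass
class Pattern:
    """One training pattern: an entity's per-genotype profile.

    values holds the normalized log ratios; NaN marks a pseudo-zero
    (invalid) genotype.  raw_values optionally holds the un-normalized log
    ratios from the companion files.
    """

    entity_id: str
    kind: str
    sign: str = SIGN_ORIGINAL
    values: np.ndarray = field(default_factory=lambda: np.empty(0))
    raw_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in (KIND_TRANSCRIPT, KIND_METABOLITE):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.sign not in (SIGN_ORIGINAL, SIGN_INVERTED):
            raise ValueError(f"unknown sign {self.sign!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.raw_values is not None:
            self.raw_values = np.asarray(self.raw_values, dtype=float)

    @property
    def label(self) -> str:
        """Row label as written in the `.data` file."""
        if self.sign == SIGN_INVERTED:
            return self.entity_id + INVERSION_SUFFIX
        return self.entity_id

    @property
    def validity(self) -> np.ndarray:
        """Boolean mask, True where the measurement is valid."""
        return ~np.isnan(self.values)

    def inverted_twin(self) -> "Pattern":
        """The sign-inverted copy of this pattern (same validity mask)."""
        new_sign = SIGN_INVERTED if self.sign == SIGN_ORIGINAL else SIGN_ORIGINAL
        return Pattern(
            entity_id=self.entity_id,
            kind=self.kind,
            sign=new_sign,
            values=-self.values,
            raw_values=None if self.raw_values is None else -self.raw_values,
        )


@dataclass
class ProfileDataset:
    """An ordered collection of patterns over a fixed genotype panel."""

    genotypes: list[str]
    patterns: list[Pattern]

    def __post_init__(self) -> None:
        p = self.n_genotypes
        for pat in self.patterns:
            if pat.values.shape != (p,):
                raise ValueError(
                    f"pattern {pat.label!r} has {pat.values.shape[0]} values, "
                    f"expected {p}"
                )
        labels = [pat.label for pat in self.patterns]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate pattern labels: {dupes}")

    # -- basic geometry ---------------------------------------------------
    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    def __len__(self) -> int:
        return self.n_patterns

    def __iter__(self) -> Iterator[Pattern]:
        return iter(self.patterns)

    def __getitem__(self, i: int) -> Pattern:
        return self.patterns[i]

    # -- matrix views -----------------------------------------------------
    def matrix(self) -> np.ndarray:
        """(n_patterns, P) value matrix with NaN at pseudo-zeros."""
        if not self.patterns:
            return np.empty((0, self.n_genotypes))
        return np.vstack([pat.values for pat in self.patterns])

    def validity_matrix(self) -> np.ndarray:
        """(n_patterns, P) boolean validity mask."""
        return ~np.isnan(self.matrix())

    # -- lookups ----------------------------------------------------------
    def index_of(self, entity_id: str, sign: str = SIGN_ORIGINAL) -> int:
        for i, pat in enumerate(self.patterns):
            if pat.entity_id == entity_id and pat.sign == sign:
                return i
        raise KeyError(f"no pattern {entity_id!r} with sign {sign!r}")

    def originals(self) -> list[Pattern]:
        return [p for p in self.patterns if p.sign == SIGN_ORIGINAL]

    def entities(self, kind: str | None = None) -> list[str]:
        """Original entity ids, optionally restricted to one kind."""
        return [
            p.entity_id
            for p in self.originals()
            if kind is None or p.kind == kind
        ]

    def counts(self) -> tuple[int, int]:
        """(n_transcript_entities, n_metabolite_entities) over originals."""
        t = sum(1 for p in self.originals() if p.kind == KIND_TRANSCRIPT)
        m = sum(1 for p in self.originals() if p.kind == KIND_METABOLITE)
        return t, m

    # -- inversion closure ------------------------------------------------
    def is_inversion_closed(self, atol: float = 0.0) -> bool:
        """True when every original has exactly one negated inverted twin."""
        orig = {p.entity_id: p for p in self.patterns if p.sign == SIGN_ORIGINAL}
        inv = {p.entity_id: p for p in self.patterns if p.sign == SIGN_INVERTED}
        if set(orig) != set(inv):
            return False
        for eid, o in orig.items():
            i = inv[eid]
            both = o.validity & i.validity
            if not np.array_equal(o.validity, i.validity):
                return False
            if not np.allclose(o.values[both], -i.values[both], atol=atol, rtol=0.0):
                return False
        return True

    # -- genotype handling ------------------------------------------------
    def chromosomes(self) -> list[str]:
        """Distinct chromosome tags present in the panel, in panel order."""
        seen: list[str] = []
        for g in self.genotypes:
            tag = chromosome_of(g)
            if tag is not None and tag not in seen:
                seen.append(tag)
        return seen

    def restrict_genotypes(self, indices: Sequence[int]) -> "ProfileDataset":
        """Dataset restricted to a subset of genotype columns."""
        idx = list(indices)
        new_patterns = [
            replace(
                pat,
                values=pat.values[idx],
                raw_values=None if pat.raw_values is None else pat.raw_values[idx],
            )
            for pat in self.patterns
        ]
        return ProfileDataset(
            genotypes=[self.genotypes[i] for i in idx], patterns=new_patterns
        )


def default_genotype_names(p: int) -> list[str]:
    """Placeholder panel names when the file carries no comment row."""
    return [f"IL_{i + 1}" for i in range(p)]
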