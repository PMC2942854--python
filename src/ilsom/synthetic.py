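"""Synthetic introgression-line datasets with planted co-regulation.

The generator emulates the shape of a fruit transcript/metabolite panel
profiled across ~21 introgression lines: a few hundred transcripts, a few
dozen metabolites, technical replicates with log-normal noise, replicate
dropout producing pseudo-zeros, and G planted co-regulated groups.  Each
group has a latent genotype profile (groups mutually orthogonal); members
follow it up to a sign — metabolites of *cross-relation* groups follow the
negated profile, modelling transcripts that rise where a metabolite falls.
Everything is driven by one seeded generator, so a spec is a reproducible
fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ilsom.datatypes import KIND_METABOLITE, KIND_TRANSCRIPT, ProfileDataset
from ilsom.preprocess import ReplicateTable, build_dataset
from ilsom import io as ilc_io

#: Chromosomes introgressed in the kind of tomato IL panel emulated here.
PANEL_CHROMOSOMES = (1, 2, 3, 5, 8, 10, 11, 12)


def default_il_panel(p: int = 21) -> list[str]:
    """Chromosome-tagged IL names, e.g. "12-1-1".

    The default 21-line panel spans chromosomes 1, 2, 3, 5, 8, 10, 11 and
    12, with chromosome 12 carrying the four lines 12-1-1, 12-1, 12-2 and
    12-3; other panel sizes cycle through the same chromosomes.
    """
    if p == 21:
        return [
            "1-1", "1-2", "1-3",
            "2-1", "2-2",
            "3-1", "3-2",
            "5-1", "5-2", "5-3",
            "8-1", "8-2",
            "10-1", "10-2",
            "11-1", "11-2", "11-3",
            "12-1-1", "12-1", "12-2", "12-3",
        ]
    names = []
    counters = {c: 0 for c in PANEL_CHROMOSOMES}
    for i in range(p):
        chrom = PANEL_CHROMOSOMES[i % len(PANEL_CHROMOSOMES)]
        counters[chrom] += 1
        names.append(f"{chrom}-{counters[chrom]}")
    return names


@dataclass
class SynthSpec:
    """Study conditions for one synthetic dataset.

    Group sizes are derived: half of each component is spread evenly over
    the G groups (every group mixes kinds), the rest is unstructured
    background.  ``within_group_correlation`` sets the squared cosine
    between a member's direction and its group's latent profile;
    ``noise_sd`` is the replicate-level log10 noise; ``missing_rate`` is
    the per-replicate dropout probability.
    """

    p: int = 21
    n_transcripts: int = 200
    n_metabolites: int = 40
    g: int = 8
    within_group_correlation: float = 0.9
    noise_sd: float = 0.05
    missing_rate: float = 0.05
    cross_relation_fraction: float = 0.25
    amplitude: float = 1.0
    n_replicates: int = 4
    seed: int = 0
    genotypes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genotypes:
            self.genotypes = default_il_panel(self.p)
        if len(self.genotypes) != self.p:
            raise ValueError("genotypes must have length p")
        if not 0.0 < self.within_group_correlation <= 1.0:
            raise ValueError("within_group_correlation must be in (0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.g < 1:
            raise ValueError("need at least one group")
        if self.g > min(self.p, self.n_transcripts // 2):
            raise ValueError(
                f"{self.g} groups cannot be planted in {self.p} genotype "
                f"dimensions / {self.n_transcripts} transcripts"
            )
        if self.transcripts_per_group < 2:
            raise ValueError("groups would have fewer than 2 transcripts")

    @property
    def transcripts_per_group(self) -> int:
        return max(2, (self.n_transcripts // 2) // self.g)

    @property
    def metabolites_per_group(self) -> int:
        return max(1, (self.n_metabolites // 2) // self.g)

    @property
    def n_cross_groups(self) -> int:
        return int(round(self.cross_relation_fraction * self.g))


@dataclass
class GroundTruth:
    """Planted structure: entity -> group (-1 = background) and sign."""

    group: dict[str, int]
    sign: dict[str, int]
    latent: np.ndarray  # (G, P) orthonormal latent profiles
    cross_groups: set[int]

    def members(self, g: int) -> list[str]:
        return [e for e, gg in self.group.items() if gg == g]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate(spec: SynthSpec) -> tuple[list[ReplicateTable], GroundTruth]:
    """Draw replicate tables plus the ground truth behind them.

    Member log-ratio profiles are ``amplitude * sign * u`` with
    ``u = sqrt(rho) * latent + sqrt(1 - rho) * e`` (e a random unit vector
    orthogonal-ish to the latent); replicate ratios are
    ``10 ** (logR + N(0, noise_sd))`` with per-replicate dropout.
    Deterministic under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    rho = spec.within_group_correlation

    # Orthonormal latent profiles via QR of a Gaussian (P, G) matrix.
    q, _ = np.linalg.qr(rng.standard_normal((spec.p, spec.g)))
    latent = q.T  # (G, P), rows orthonormal

    cross_groups = set(range(spec.n_cross_groups))

    group: dict[str, int] = {}
    sign: dict[str, int] = {}
    profiles: dict[str, tuple[str, np.ndarray]] = {}  # id -> (kind, logR)

    def member_profile(g: int, s: int) -> np.ndarray:
        e = _unit(rng.standard_normal(spec.p))
        u = math.sqrt(rho) * latent[g] + math.sqrt(1.0 - rho) * e
        return spec.amplitude * s * _unit(u)

    t_names = [f"LE{i + 1:04d}" for i in range(spec.n_transcripts)]
    m_names = [f"met_{i + 1:03d}" for i in range(spec.n_metabolites)]

    ti = iter(t_names)
    mi = iter(m_names)
    for g in range(spec.g):
        for _ in range(spec.transcripts_per_group):
            name = next(ti)
            group[name], sign[name] = g, 1
            profiles[name] = (KIND_TRANSCRIPT, member_profile(g, 1))
        m_sign = -1 if g in cross_groups else 1
        for _ in range(spec.metabolites_per_group):
            name = next(mi)
            group[name], sign[name] = g, m_sign
            profiles[name] = (KIND_METABOLITE, member_profile(g, m_sign))
    for name in ti:
        group[name], sign[name] = -1, 1
        profiles[name] = (
            KIND_TRANSCRIPT,
            spec.amplitude * _unit(rng.standard_normal(spec.p)),
        )
    for name in mi:
        group[name], sign[name] = -1, 1
        profiles[name] = (
            KIND_METABOLITE,
            spec.amplitude * _unit(rng.standard_normal(spec.p)),
        )

    tables: list[ReplicateTable] = []
    for name in t_names + m_names:
        kind, log_r = profiles[name]
        ratios: list[list[float]] = []
        for i in range(spec.p):
            reps = []
            for _ in range(spec.n_replicates):
                if rng.random() < spec.missing_rate:
                    continue
                noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0
                reps.append(float(10.0 ** (log_r[i] + noise)))
            ratios.append(reps)
        tables.append(ReplicateTable(entity_id=name, kind=kind, ratios=ratios))

    truth = GroundTruth(
        group=group, sign=sign, latent=latent, cross_groups=cross_groups
    )
    return tables, truth


def generate_dataset(spec: SynthSpec) -> tuple[ProfileDataset, GroundTruth]:
    """Generate and push through the full preprocessing pipeline.

    Returns the normalized, inversion-closed dataset plus the ground
    truth (entities dropped by the filters simply no longer appear in the
    dataset; the truth keeps them for bookkeeping).
    """
    tables, truth = generate(spec)
    dataset = build_dataset(tables, spec.genotypes)
    return dataset, truth


def within_group_colocation(dataset, assignment, som, truth: GroundTruth,
                            vn: int = 1) -> float:
    """Fraction of within-group pairs sharing a radius-Vn neighborhood.

    Two patterns share a Vn neighborhood when some unit's square pool of
    radius Vn contains both BMUs, i.e. their Chebyshev grid distance is at
    most 2*Vn.  For each pair the sign-consistent combination is compared:
    if the planted signs differ (cross relation), the original of one is
    expected next to the *inverted* twin of the other.
    """
    from ilsom.datatypes import SIGN_INVERTED, SIGN_ORIGINAL

    index = {
        (pat.entity_id, pat.sign): i for i, pat in enumerate(dataset.patterns)
    }
    pairs = 0
    close = 0
    for g in sorted(set(truth.group.values())):
        if g < 0:
            continue
        members = [e for e in truth.members(g) if (e, SIGN_ORIGINAL) in index]
        for a_pos, a in enumerate(members):
            for b in members[a_pos + 1:]:
                sign_b = (
                    SIGN_ORIGINAL
                    if truth.sign[a] == truth.sign[b]
                    else SIGN_INVERTED
                )
                ia = index[(a, SIGN_ORIGINAL)]
                ib = index[(b, sign_b)]
                ra, ca = som.unit_position(int(assignment.bmu[ia]))
                rb, cb = som.unit_position(int(assignment.bmu[ib]))
                pairs += 1
                if max(abs(ra - rb), abs(ca - cb)) <= 2 * vn:
                    close += 1
    if pairs == 0:
        raise ValueError("ground truth contains no planted pairs")
    return close / pairs


def write_family(spec: SynthSpec, directory: str | Path,
                 dataversion: str = "1",
                 timestamp: str = "20100101T1200") -> Path:
    """Generate a dataset and emit the on-disk `.data` file family."""
    dataset, _ = generate_dataset(spec)
    return ilc_io.write_family(
        dataset, directory, dataversion=dataversion, timestamp=timestamp
    )
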