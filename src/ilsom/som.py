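"""Batch-trained two-dimensional self-organizing map.

The map is a rows x cols lattice of neurons, each carrying a codebook
(weight) vector w_j of length P.  Training is the batch algorithm: per
epoch every pattern is assigned to its best-matching unit (BMU, the neuron
with smallest Euclidean distance), and only then every codebook vector is
replaced by the neighborhood-weighted mean of all patterns,

    w_j <- sum_x g(bmu(x), j) * x  /  sum_x g(bmu(x), j),

with the Gaussian neighborhood g_ij = exp(-delta_ij^2 / (2 r^2)) on the
grid and a non-increasing radius schedule.  Initial codebooks are laid out
on the plane spanned by the first two principal components of the data, so
training is deterministic and independent of pattern input order.

Missing measurements (NaN components) are excluded per-component from both
the distances and the batch means; they are never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ilsom.datatypes import ProfileDataset

logger = logging.getLogger(__name__)

LATTICE_RECTANGULAR = "rectangular"
LATTICE_HEXAGONAL = "hexagonal"


@dataclass
class SomConfig:
    """Map topology and training schedule.

    The radius decays linearly from ``radius_start`` (default
    ``max(rows, cols) / 4``) down to ``radius_end`` over ``n_epochs``
    epochs; an explicit ``radius_schedule`` (one radius per epoch,
    non-increasing) overrides both.
    """

    rows: int = 10
    cols: int = 10
    lattice: str = LATTICE_RECTANGULAR
    n_epochs: int = 50
    radius_start: float | None = None
    radius_end: float = 1.0
    radius_schedule: list[float] | None = None
    init: str = "pca"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.rows * self.cols < 2:
            raise ValueError("map must have at least 2 units")
        if self.lattice not in (LATTICE_RECTANGULAR, LATTICE_HEXAGONAL):
            raise ValueError(f"unknown lattice {self.lattice!r}")
        if self.init not in ("pca", "random"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be positive")
        sched = self.schedule()
        if any(b > a for a, b in zip(sched, sched[1:])):
            raise ValueError("radius schedule must be non-increasing")
        if any(r < 0 for r in sched):
            raise ValueError("radii must be >= 0")

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def schedule(self) -> list[float]:
        """Radius per epoch."""
        if self.radius_schedule is not None:
            return list(self.radius_schedule)
        start = self.radius_start
        if start is None:
            start = max(self.rows, self.cols) / 4.0
        start = max(start, self.radius_end)
        if self.n_epochs == 1:
            return [start]
        return list(np.linspace(start, self.radius_end, self.n_epochs))


def default_grid(n_patterns: int) -> tuple[int, int]:
    """Square grid sized by the usual 5*sqrt(N) map-units heuristic."""
    k = max(4, math.ceil(5.0 * math.sqrt(max(n_patterns, 1))))
    side = math.ceil(math.sqrt(k))
    return side, side


@dataclass
class SomMap:
    """Grid geometry plus codebook vectors; units are numbered 1-based,
    column-major: unit = (row - 1) + rows * (col - 1) + 1."""

    config: SomConfig
    codebook: np.ndarray  # (K, P)
    _grid_sq_dist: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.codebook = np.asarray(self.codebook, dtype=float)
        if self.codebook.shape[0] != self.config.n_units:
            raise ValueError("codebook rows must equal rows * cols")

    @property
    def n_units(self) -> int:
        return self.config.n_units

    @property
    def dim(self) -> int:
        return self.codebook.shape[1]

    # -- grid geometry ----------------------------------------------------
    def unit_position(self, unit: int) -> tuple[int, int]:
        """(row, col), both 1-based, of a 1-based unit index."""
        if not 1 <= unit <= self.n_units:
            raise IndexError(f"unit {unit} outside 1..{self.n_units}")
        z = unit - 1
        return z % self.config.rows + 1, z // self.config.rows + 1

    def unit_at(self, row: int, col: int) -> int:
        if not (1 <= row <= self.config.rows and 1 <= col <= self.config.cols):
            raise IndexError(f"grid position ({row}, {col}) off the map")
        return (row - 1) + self.config.rows * (col - 1) + 1

    def mirror_unit(self, unit: int) -> int:
        """The 180-degree rotated grid image of a unit."""
        r, c = self.unit_position(unit)
        return self.unit_at(self.config.rows + 1 - r, self.config.cols + 1 - c)

    def grid_coords(self) -> np.ndarray:
        """(K, 2) planar coordinates used for the neighborhood distance."""
        rows, cols = self.config.rows, self.config.cols
        k = np.arange(self.n_units)
        r = (k % rows).astype(float)
        c = (k // rows).astype(float)
        if self.config.lattice == LATTICE_HEXAGONAL:
            x = c + 0.5 * (r % 2)
            y = r * (math.sqrt(3.0) / 2.0)
            return np.column_stack([y, x])
        return np.column_stack([r, c])

    def grid_sq_distances(self) -> np.ndarray:
        """(K, K) squared grid distances delta_ij^2 (symmetric, zero diagonal)."""
        if self._grid_sq_dist is None:
            xy = self.grid_coords()
            diff = xy[:, None, :] - xy[None, :, :]
            self._grid_sq_dist = np.sum(diff**2, axis=2)
        return self._grid_sq_dist


@dataclass
class Assignment:
    """Pattern -> BMU mapping; ``bmu`` holds 1-based unit indices and
    ``distance`` the masked Euclidean distance to that unit's codebook."""

    bmu: np.ndarray
    distance: np.ndarray

    def members_of(self, unit: int) -> np.ndarray:
        """Pattern indices assigned to a 1-based unit."""
        return np.flatnonzero(self.bmu == unit)

    def nonempty_units(self) -> np.ndarray:
        return np.unique(self.bmu)


def gaussian_neighborhood(delta: float | np.ndarray, r: float) -> float | np.ndarray:
    """g = exp(-delta^2 / (2 r^2)); at r = 0 the winner-takes-all limit."""
    delta = np.asarray(delta, dtype=float)
    if r < 0:
        raise ValueError("radius must be >= 0")
    if r == 0.0:
        out = np.where(delta == 0.0, 1.0, 0.0)
    else:
        out = np.exp(-(delta**2) / (2.0 * r * r))
    return float(out) if out.ndim == 0 else out


def _data_arrays(dataset: ProfileDataset) -> tuple[np.ndarray, np.ndarray]:
    x = dataset.matrix()
    mask = ~np.isnan(x)
    x0 = np.where(mask, x, 0.0)
    return x0, mask.astype(float)


def _masked_sq_distances(x0: np.ndarray, m: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    """d2[i, j] = sum over valid p of (x[i, p] - w[j, p])^2."""
    sx = np.sum(m * x0**2, axis=1)
    cross = (m * x0) @ codebook.T
    sw = m @ (codebook**2).T
    d2 = sx[:, None] - 2.0 * cross + sw
    np.maximum(d2, 0.0, out=d2)
    return d2


def find_bmu(values: np.ndarray, som: SomMap) -> int:
    """1-based BMU of one pattern; NaN components are skipped; ties break
    toward the lowest unit index."""
    values = np.asarray(values, dtype=float)
    mask = ~np.isnan(values)
    if not mask.any():
        raise ValueError("pattern has no valid component")
    x0 = np.where(mask, values, 0.0)[None, :]
    d2 = _masked_sq_distances(x0, mask.astype(float)[None, :], som.codebook)
    return int(np.argmin(d2[0])) + 1


def assign(dataset: ProfileDataset, som: SomMap) -> Assignment:
    """BMU and masked Euclidean distance for every pattern."""
    if dataset.n_patterns == 0:
        raise ValueError("empty dataset")
    x0, m = _data_arrays(dataset)
    d2 = _masked_sq_distances(x0, m, som.codebook)
    idx = np.argmin(d2, axis=1)
    dist = np.sqrt(d2[np.arange(len(idx)), idx])
    return Assignment(bmu=idx + 1, distance=dist)


def init_pca(dataset: ProfileDataset, config: SomConfig) -> SomMap:
    """Codebook on the grid spanned by the first two principal components.

    The grid is centered on the data mean and stretched to one standard
    deviation along each component; repeated calls are bit-identical.  With
    rank-deficient data the second axis collapses to zero with a warning.
    Pseudo-zeros enter the PCA as zeros (their pattern-level placeholder).
    """
    x0, _ = _data_arrays(dataset)
    n = x0.shape[0]
    if n < 2:
        raise ValueError("PCA initialization needs at least 2 patterns")
    mean = x0.mean(axis=0)
    xc = x0 - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # Deterministic component orientation: largest-|.| loading positive.
    for k in range(min(2, vt.shape[0])):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] = -vt[k]
    sd = s / math.sqrt(max(n - 1, 1))

    axes = []
    for k in range(2):
        if k < len(sd) and sd[k] > 1e-12:
            axes.append(sd[k] * vt[k])
        else:
            logger.warning("rank-deficient data: PCA axis %d set to zero", k + 1)
            axes.append(np.zeros(x0.shape[1]))
    pc_col, pc_row = axes[0], axes[1]  # PC1 varies along columns

    def ramp(n_steps: int) -> np.ndarray:
        if n_steps == 1:
            return np.zeros(1)
        return np.linspace(-1.0, 1.0, n_steps)

    row_ramp = ramp(config.rows)
    col_ramp = ramp(config.cols)
    codebook = np.empty((config.n_units, x0.shape[1]))
    for c in range(config.cols):
        for r in range(config.rows):
            unit = r + config.rows * c
            codebook[unit] = mean + col_ramp[c] * pc_col + row_ramp[r] * pc_row
    return SomMap(config=config, codebook=codebook)


def init_random(dataset: ProfileDataset, config: SomConfig) -> SomMap:
    """Codebook sampled from the data rows (seeded, reproducible)."""
    x0, _ = _data_arrays(dataset)
    rng = np.random.default_rng(config.seed)
    idx = rng.integers(0, x0.shape[0], size=config.n_units)
    return SomMap(config=config, codebook=x0[idx].copy())


def train_batch(
    dataset: ProfileDataset, config: SomConfig | None = None
) -> tuple[SomMap, Assignment]:
    """Train a SOM with the batch algorithm; returns the map and the final
    pattern assignment.

    Per epoch all patterns are assigned first, then every codebook becomes
    the Gaussian-weighted per-component mean over valid entries.  A unit
    receiving zero total weight in a component keeps its previous value
    there (logged); with a positive radius this cannot happen.
    """
    if dataset.n_patterns == 0:
        raise ValueError("empty dataset")
    if config is None:
        rows, cols = default_grid(dataset.n_patterns)
        config = SomConfig(rows=rows, cols=cols)
    som = init_pca(dataset, config) if config.init == "pca" else init_random(dataset, config)

    x0, m = _data_arrays(dataset)
    mx = m * x0
    d2_grid = som.grid_sq_distances()
    w = som.codebook
    starved = 0
    for radius in config.schedule():
        d2 = _masked_sq_distances(x0, m, w)
        b = np.argmin(d2, axis=1)
        if radius == 0.0:
            g = np.eye(som.n_units)
        else:
            g = np.exp(-d2_grid / (2.0 * radius * radius))
        h = g[b]  # (N, K): weight of pattern i on unit j
        num = h.T @ mx
        den = h.T @ m
        keep = den <= 0.0
        if keep.any():
            starved += int(keep.any(axis=1).sum())
        w = np.where(keep, w, num / np.where(keep, 1.0, den))
    if starved:
        logger.info("units with zero neighborhood weight kept their vectors "
                    "in %d unit-epochs", starved)
    som = SomMap(config=config, codebook=w)
    return som, assign(dataset, som)


def quantization_error(dataset: ProfileDataset, som: SomMap) -> float:
    """Mean masked Euclidean distance of each pattern to its BMU codebook."""
    return float(np.mean(assign(dataset, som).distance))


# -- serialization --------------------------------------------------------

_CONFIG_FIELDS = (
    "rows", "cols", "lattice", "n_epochs", "radius_start", "radius_end",
    "init", "seed",
)


def save_som(som: SomMap, path: str | Path) -> None:
    """Write the trained map as a tab-separated codebook with a config header."""
    path = Path(path)
    lines = ["# ilsom codebook v1"]
    for name in _CONFIG_FIELDS:
        lines.append(f"# {name}={getattr(som.config, name)}")
    sched = som.config.radius_schedule
    if sched is not None:
        lines.append("# radius_schedule=" + ",".join(repr(r) for r in sched))
    header = ["unit", "row", "col"] + [f"w_{p + 1}" for p in range(som.dim)]
    lines.append("\t".join(header))
    for unit in range(1, som.n_units + 1):
        r, c = som.unit_position(unit)
        weights = "\t".join(repr(float(v)) for v in som.codebook[unit - 1])
        lines.append(f"{unit}\t{r}\t{c}\t{weights}")
    path.write_text("\n".join(lines) + "\n")


def load_som(path: str | Path) -> SomMap:
    """Reload a map written by :func:`save_som` (bit-exact codebook)."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    for ln in path.read_text().splitlines():
        if ln.startswith("#"):
            body = ln[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
        elif ln.strip() and not ln.startswith("unit\t"):
            rows.append(ln.split("\t"))
    kwargs: dict = {
        "rows": int(meta["rows"]),
        "cols": int(meta["cols"]),
        "lattice": meta["lattice"],
        "n_epochs": int(meta["n_epochs"]),
        "radius_end": float(meta["radius_end"]),
        "init": meta["init"],
        "seed": int(meta["seed"]),
    }
    if meta.get("radius_start", "None") != "None":
        kwargs["radius_start"] = float(meta["radius_start"])
    if "radius_schedule" in meta:
        kwargs["radius_schedule"] = [float(t) for t in meta["radius_schedule"].split(",")]
    config = SomConfig(**kwargs)
    codebook = np.empty((config.n_units, len(rows[0]) - 3))
    for parts in rows:
        unit = int(parts[0])
        codebook[unit - 1] = [float(t) for t in parts[3:]]
    return SomMap(config=config, codebook=codebook)
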