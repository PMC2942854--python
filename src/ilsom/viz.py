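"""Static map views plus their lossless tabular twins.

Every rendering writes an image pair (PNG and SVG, deterministic: fixed
figure size, no timestamps) and a tab-separated table carrying exactly the
numbers the image encodes, under an output directory laid out as::

    outdir/
      maps/      activation, cohesion and 3-color images
      details/   per-neuron curve plots
      tables/    the tabular twins

Tests and downstream scripts consume the tables; the images are for eyes.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "ilsom"  # deterministic SVG ids

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from ilsom import analysis
from ilsom.datatypes import (
    KIND_METABOLITE,
    KIND_TRANSCRIPT,
    SIGN_INVERTED,
    ProfileDataset,
)
from ilsom.som import Assignment, SomMap

_COLORS = {
    analysis.COMPOSITION_TRANSCRIPTS: "red",
    analysis.COMPOSITION_METABOLITES: "blue",
    analysis.COMPOSITION_MIXED: "black",
}
_GRAYSCALE = {
    analysis.COMPOSITION_TRANSCRIPTS: "0.65",
    analysis.COMPOSITION_METABOLITES: "0.85",
    analysis.COMPOSITION_MIXED: "0.15",
}
_HIGHLIGHT_COLOR = "green"

_MIN_AREA, _MAX_AREA = 30.0, 300.0  # marker area bounds, points^2


def _dirs(outdir: str | Path) -> tuple[Path, Path, Path]:
    outdir = Path(outdir)
    maps, details, tables = outdir / "maps", outdir / "details", outdir / "tables"
    for d in (maps, details, tables):
        d.mkdir(parents=True, exist_ok=True)
    return maps, details, tables


def _save(fig: plt.Figure, stem: Path) -> list[Path]:
    paths = []
    for ext in ("png", "svg"):
        path = stem.with_suffix(f".{ext}")
        fig.savefig(path, metadata={"Date": None} if ext == "svg" else None)
        paths.append(path)
    plt.close(fig)
    return paths


def _grid_axes(som: SomMap) -> plt.Axes:
    fig, ax = plt.subplots(figsize=(6.0, 6.0))
    ax.set_xlim(0.5, som.config.cols + 0.5)
    ax.set_ylim(som.config.rows + 0.5, 0.5)  # row 1 at the top
    ax.set_xlabel("grid column")
    ax.set_ylabel("grid row")
    ax.set_aspect("equal")
    return ax


def _areas(counts: np.ndarray) -> np.ndarray:
    top = counts.max() if counts.size else 1
    return _MIN_AREA + (_MAX_AREA - _MIN_AREA) * counts / max(top, 1)


def render_activation_map(
    assignment: Assignment,
    dataset: ProfileDataset,
    som: SomMap,
    outdir: str | Path,
    vn: int = 0,
    grayscale: bool = False,
    highlight: tuple[int, ...] = (),
) -> tuple[list[Path], Path]:
    """Composition map: one marker per nonempty unit, red for transcript-only,
    blue for metabolite-only, black for mixed (Vn-pooled), marker area linear
    in the member count; ``highlight`` units are drawn green."""
    maps_dir, _, tables_dir = _dirs(outdir)
    palette = _GRAYSCALE if grayscale else _COLORS

    records = []
    for unit in assignment.nonempty_units():
        unit = int(unit)
        members = assignment.members_of(unit)
        pats = [dataset.patterns[i] for i in members]
        comp = analysis.classify_composition(unit, assignment, dataset, som, vn)
        r, c = som.unit_position(unit)
        records.append(
            {
                "unit": unit,
                "row": r,
                "col": c,
                "n_patterns": len(members),
                "n_transcripts": sum(1 for p in pats if p.kind == KIND_TRANSCRIPT),
                "n_metabolites": sum(1 for p in pats if p.kind == KIND_METABOLITE),
                "composition": comp,
            }
        )
    table = pd.DataFrame.from_records(
        records,
        columns=[
            "unit", "row", "col", "n_patterns", "n_transcripts",
            "n_metabolites", "composition",
        ],
    )
    table_path = tables_dir / f"activation_vn{vn}.tsv"
    table.to_csv(table_path, sep="\t", index=False)

    ax = _grid_axes(som)
    if len(table):
        colors = [
            _HIGHLIGHT_COLOR if u in highlight else palette[comp]
            for u, comp in zip(table["unit"], table["composition"])
        ]
        ax.scatter(
            table["col"], table["row"],
            s=_areas(table["n_patterns"].to_numpy()),
            c=colors,
        )
    ax.set_title(f"Activation map (Vn = {vn})")
    image_paths = _save(ax.figure, maps_dir / f"activation_vn{vn}")
    return image_paths, table_path


def render_detail(
    unit: int,
    assignment: Assignment,
    dataset: ProfileDataset,
    outdir: str | Path,
    raw: bool = False,
) -> tuple[list[Path], Path]:
    """Per-member curves across genotypes for one unit.

    Normalized values by default; ``raw=True`` plots the un-normalized log
    ratios and requires the raw companions to have been loaded.  Invalid
    (pseudo-zero) points are marked with red circles.
    """
    _, details_dir, tables_dir = _dirs(outdir)
    members = assignment.members_of(unit)
    if members.size == 0:
        raise ValueError(f"unit {unit} is empty")
    pats = [dataset.patterns[i] for i in members]
    if raw:
        missing = [p for p in pats if p.raw_values is None]
        if missing:
            suffix = (
                "nonormsq" if missing[0].kind == KIND_METABOLITE else "nolowess"
            )
            raise ValueError(
                f"raw values for {missing[0].label!r} not loaded; the "
                f"un-normalized companion file (suffix {suffix!r}) is missing"
            )

    fig, ax = plt.subplots(figsize=(7.0, 4.5))
    x = np.arange(1, dataset.n_genotypes + 1)
    records = []
    for pat in pats:
        values = pat.raw_values if raw else pat.values
        plotted = np.where(pat.validity, values, 0.0)
        ax.plot(x, plotted, marker=".", label=pat.label)
        invalid = ~pat.validity
        if invalid.any():
            ax.plot(
                x[invalid], plotted[invalid], "o",
                markerfacecolor="none", markeredgecolor="red",
            )
        for j, g in enumerate(dataset.genotypes):
            records.append(
                {
                    "entity": pat.entity_id,
                    "sign": pat.sign,
                    "kind": pat.kind,
                    "genotype": g,
                    "value": values[j],
                    "valid": bool(pat.validity[j]),
                }
            )
    ax.set_xticks(x)
    ax.set_xticklabels(dataset.genotypes, rotation=90, fontsize=7)
    ax.set_ylabel("log ratio" if raw else "normalized log ratio")
    ax.set_title(f"Neuron {unit} ({'raw' if raw else 'normalized'})")
    ax.legend(fontsize=7)
    fig.tight_layout()

    stem = f"neuron{unit}_{'raw' if raw else 'norm'}"
    table = pd.DataFrame.from_records(records)
    table_path = tables_dir / f"{stem}.tsv"
    table.to_csv(table_path, sep="\t", index=False)
    image_paths = _save(fig, details_dir / stem)
    return image_paths, table_path


def render_cohesion_map(
    cohesions: dict[int, float], som: SomMap, outdir: str | Path
) -> tuple[list[Path], Path]:
    """Cohesion (intracluster variance) per unit, marker area monotone in
    C_j; empty units are blank."""
    maps_dir, _, tables_dir = _dirs(outdir)
    units = sorted(cohesions)
    records = []
    for unit in units:
        r, c = som.unit_position(unit)
        records.append({"unit": unit, "row": r, "col": c, "cohesion": cohesions[unit]})
    table = pd.DataFrame.from_records(
        records, columns=["unit", "row", "col", "cohesion"]
    )
    table_path = tables_dir / "cohesion.tsv"
    table.to_csv(table_path, sep="\t", index=False)

    ax = _grid_axes(som)
    if len(table):
        values = table["cohesion"].to_numpy()
        top = values.max()
        areas = _MIN_AREA + (_MAX_AREA - _MIN_AREA) * (
            values / top if top > 0 else np.zeros_like(values)
        )
        ax.scatter(table["col"], table["row"], s=areas, c="0.3")
    ax.set_title("Per-neuron cohesion")
    image_paths = _save(ax.figure, maps_dir / "cohesion")
    return image_paths, table_path


def render_three_color(
    tcm: analysis.ThreeColorMap, som: SomMap, outdir: str | Path,
    genotypes: list[str] | None = None,
) -> tuple[list[Path], Path]:
    """One green/gray/white grid image per genotype plus a long-format table."""
    maps_dir, _, tables_dir = _dirs(outdir)
    wanted = genotypes if genotypes is not None else tcm.genotypes
    records = []
    fill = {analysis.GREEN: "green", analysis.GRAY: "0.6", analysis.WHITE: "white"}
    image_paths: list[Path] = []
    for g in wanted:
        p = tcm.genotypes.index(g)
        ax = _grid_axes(som)
        for unit in range(1, som.n_units + 1):
            r, c = som.unit_position(unit)
            color = str(tcm.colors[p, unit - 1])
            records.append({"genotype": g, "unit": unit, "row": r, "col": c,
                            "color": color})
            ax.add_patch(
                plt.Rectangle(
                    (c - 0.5, r - 0.5), 1.0, 1.0,
                    facecolor=fill[color], edgecolor="0.8", linewidth=0.3,
                )
            )
        ax.set_title(f"3-color map, IL {g}")
        safe = g.replace("/", "_")
        image_paths.extend(_save(ax.figure, maps_dir / f"three_color_{safe}"))
    table = pd.DataFrame.from_records(
        records, columns=["genotype", "unit", "row", "col", "color"]
    )
    table_path = tables_dir / "three_color.tsv"
    table.to_csv(table_path, sep="\t", index=False)
    return image_paths, table_path
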