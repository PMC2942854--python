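"""Reading and writing the `.data` file family.

The main training file is a whitespace-delimited text matrix: a first row
with the number of genotypes P, an optional second row naming the genotypes
(detected by a non-numeric first token), then one row per pattern holding P
log-ratio values followed by the row label.  A label ending in ``(inv)``
marks the sign-inverted twin of the like-named original row.

Alongside the main file (``omesom<dv>_-_<date>T<time>_-oToM.data``) the
loader searches the same directory for companions sharing the naming stem:

* ``omesom<dv>_-trs_-_<dt>_-ilexp.data`` / ``..._-mts_-_..._-ilexp.data`` —
  0/1 markers of expressed ILs, one row per original transcript/metabolite;
* ``omesom<dv>_-mts_-_<dt>_-nonormsq.data`` — un-normalized metabolites;
* ``omesom<dv>_-trs_-_<dt>_-nolowess.data`` — un-normalized transcripts.

Absent companions degrade gracefully: validity stays all-true and raw
values stay unset, so the core pipeline runs on a single file.  Values are
written in fixed notation with 6 significant digits; pseudo-zero (invalid)
entries are written as 0 and recovered from the ilexp masks on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ilsom.datatypes import (
    KIND_METABOLITE,
    KIND_TRANSCRIPT,
    SIGN_INVERTED,
    SIGN_ORIGINAL,
    Pattern,
    ProfileDataset,
    default_genotype_names,
    split_inversion_label,
)
from ilsom.errors import ConsistencyError, FormatError, NamingError

logger = logging.getLogger(__name__)

_MAIN_NAME_RE = re.compile(r"^omesom(?P<dv>.*?)_-_(?P<dt>.*)_-oToM\.data$")

_MAIN_TEMPLATE = "omesom{dv}_-_{dt}_-oToM.data"
_COMPANION_TEMPLATE = "omesom{dv}_-{comp}_-_{dt}_-{suffix}.data"


def format_value(v: float) -> str:
    """Fixed-notation rendering with 6 significant digits; NaN becomes 0."""
    if np.isnan(v):
        return "0"
    if v == 0:
        return "0"
    return np.format_float_positional(
        float(v), precision=6, unique=False, fractional=False, trim="0"
    )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _read_matrix_file(path: Path) -> tuple[int, list[str] | None, list[tuple[str, np.ndarray]]]:
    """Parse the shared layout: P, optional names row, value rows + labels."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    head = lines[0].split()
    try:
        p = int(head[0])
    except ValueError as exc:
        raise FormatError(
            f"{path}: first row must start with the genotype count, got {head[0]!r}"
        ) from exc
    if p <= 0:
        raise FormatError(f"{path}: genotype count must be positive, got {p}")

    body = lines[1:]
    names: list[str] | None = None
    if body and not _is_number(body[0].split()[0]):
        names = body[0].split()
        if len(names) != p:
            raise FormatError(
                f"{path}: comment row names {len(names)} genotypes, expected {p}"
            )
        body = body[1:]

    rows: list[tuple[str, np.ndarray]] = []
    for ln in body:
        tokens = ln.split()
        numeric = 0
        while numeric < len(tokens) and _is_number(tokens[numeric]):
            numeric += 1
        label = " ".join(tokens[numeric:])
        if numeric != p or not label:
            ref = label if label else f"row {len(rows) + 1}"
            raise FormatError(
                f"{path}: {ref!r} has {numeric} values, expected {p}"
            )
        rows.append((label, np.array([float(t) for t in tokens[:p]])))
    return p, names, rows


def read_main_data(path: str | Path, n_transcripts: int | None = None) -> ProfileDataset:
    """Read the main training matrix into a :class:`ProfileDataset`.

    Pattern order equals file row order.  Rows labelled with the ``(inv)``
    suffix are flagged sign=inverted and matched to their original by label
    stem; an inverted row whose values disagree with the negated original is
    a format error (the minus-prefixed values are authoritative only when
    they agree).

    The main file does not itself say which rows are metabolites; kinds are
    normally assigned from the ``trs``/``mts`` companions by
    :func:`read_family`.  ``n_transcripts`` optionally declares how many
    original entities, counted from the top, are transcripts (the file
    layout puts transcripts before metabolites); without it every row
    defaults to transcript.
    """
    path = Path(path)
    p, names, rows = _read_matrix_file(path)
    genotypes = names if names is not None else default_genotype_names(p)

    patterns: list[Pattern] = []
    seen_labels: set[str] = set()
    originals: dict[str, Pattern] = {}
    orig_rank = 0
    for label, values in rows:
        if label in seen_labels:
            raise FormatError(f"{path}: duplicate label {label!r}")
        seen_labels.add(label)
        entity_id, sign = split_inversion_label(label)
        if sign == SIGN_ORIGINAL:
            if n_transcripts is None:
                kind = KIND_TRANSCRIPT
            else:
                kind = KIND_TRANSCRIPT if orig_rank < n_transcripts else KIND_METABOLITE
            orig_rank += 1
            pat = Pattern(entity_id=entity_id, kind=kind, sign=sign, values=values)
            originals[entity_id] = pat
        else:
            base = originals.get(entity_id)
            if base is None:
                raise FormatError(
                    f"{path}: inverted row {label!r} has no matching original"
                )
            if not np.allclose(values, -base.values, rtol=0.0, atol=0.0):
                raise FormatError(
                    f"{path}: inverted row {label!r} is not the elementwise "
                    f"negation of its original"
                )
            pat = Pattern(
                entity_id=entity_id, kind=base.kind, sign=sign, values=values
            )
        patterns.append(pat)
    return ProfileDataset(genotypes=genotypes, patterns=patterns)


def write_main_data(dataset: ProfileDataset, path: str | Path) -> None:
    """Write the main training matrix (inverse of :func:`read_main_data`)."""
    path = Path(path)
    lines = [str(dataset.n_genotypes), " ".join(dataset.genotypes)]
    for pat in dataset.patterns:
        values = " ".join(format_value(v) for v in pat.values)
        lines.append(f"{values} {pat.label}")
    path.write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class CompanionSet:
    """Candidate companion paths for a main file; each may be absent."""

    trs_ilexp: Path
    mts_ilexp: Path
    nonormsq: Path
    nolowess: Path

    def items(self) -> list[tuple[str, Path]]:
        return [
            ("trs_ilexp", self.trs_ilexp),
            ("mts_ilexp", self.mts_ilexp),
            ("nonormsq", self.nonormsq),
            ("nolowess", self.nolowess),
        ]

    def present(self) -> dict[str, bool]:
        return {name: path.exists() for name, path in self.items()}


def resolve_companions(main_path: str | Path) -> CompanionSet:
    """Companion file candidates implied by the main file's name.

    Raises :class:`NamingError` when the main name does not follow the
    convention; absent companions are flagged, not fatal.
    """
    main_path = Path(main_path)
    m = _MAIN_NAME_RE.match(main_path.name)
    if m is None:
        raise NamingError(
            f"{main_path.name!r} does not match the expected template "
            f"{_MAIN_TEMPLATE.format(dv='<dataversion>', dt='<date>T<time>')!r}"
        )
    dv, dt = m.group("dv"), m.group("dt")
    d = main_path.parent

    def comp(comp_tag: str, suffix: str) -> Path:
        return d / _COMPANION_TEMPLATE.format(dv=dv, comp=comp_tag, dt=dt, suffix=suffix)

    return CompanionSet(
        trs_ilexp=comp("trs", "ilexp"),
        mts_ilexp=comp("mts", "ilexp"),
        nonormsq=comp("mts", "nonormsq"),
        nolowess=comp("trs", "nolowess"),
    )


def _companion_rows(
    path: Path, dataset: ProfileDataset, kind: str
) -> list[tuple[Pattern, np.ndarray]]:
    """Align companion rows with the dataset's original entities of a kind."""
    p, _, rows = _read_matrix_file(path)
    if p != dataset.n_genotypes:
        raise ConsistencyError(
            f"{path}: declares {p} genotypes, main file has {dataset.n_genotypes}"
        )
    targets = [pat for pat in dataset.originals() if pat.kind == kind]
    if len(rows) != len(targets):
        raise ConsistencyError(
            f"{path}: {len(rows)} rows for {len(targets)} {kind} entities"
        )
    out: list[tuple[Pattern, np.ndarray]] = []
    for (label, values), pat in zip(rows, targets):
        entity_id, _ = split_inversion_label(label)
        if entity_id != pat.entity_id:
            raise ConsistencyError(
                f"{path}: row {entity_id!r} does not match entity {pat.entity_id!r}"
            )
        out.append((pat, values))
    return out


def read_validity_markers(
    path: str | Path, dataset: ProfileDataset, kind: str = KIND_TRANSCRIPT
) -> ProfileDataset:
    """Apply an ``ilexp`` expressed-IL marker file to the dataset (in place).

    Marker 0 means the measurement is missing — not enough significantly
    detected replicates — and the value becomes a pseudo-zero (NaN) on both
    the original pattern and its inverted twin.
    """
    path = Path(path)
    twins = {
        (pat.entity_id): pat
        for pat in dataset.patterns
        if pat.sign == SIGN_INVERTED and pat.kind == kind
    }
    for pat, markers in _companion_rows(path, dataset, kind):
        if not np.isin(markers, (0.0, 1.0)).all():
            bad = markers[~np.isin(markers, (0.0, 1.0))][0]
            raise FormatError(f"{path}: marker value {bad} is not 0 or 1")
        invalid = markers == 0.0
        pat.values[invalid] = np.nan
        twin = twins.get(pat.entity_id)
        if twin is not None:
            twin.values[invalid] = np.nan
    return dataset


def read_raw_values(
    path: str | Path, dataset: ProfileDataset, kind: str
) -> ProfileDataset:
    """Attach un-normalized log ratios from a companion file (in place).

    Raw values inherit the pattern's validity mask; inverted twins receive
    the negated raw vector.
    """
    path = Path(path)
    twins = {
        pat.entity_id: pat
        for pat in dataset.patterns
        if pat.sign == SIGN_INVERTED and pat.kind == kind
    }
    for pat, values in _companion_rows(path, dataset, kind):
        raw = values.copy()
        raw[~pat.validity] = np.nan
        pat.raw_values = raw
        twin = twins.get(pat.entity_id)
        if twin is not None:
            twin.raw_values = -raw
    return dataset


def read_family(main_path: str | Path) -> ProfileDataset:
    """Read the main file plus whatever companions are present.

    Kinds are assigned from the companion files: entities listed in a
    ``mts`` companion become metabolites.  When no companion distinguishes
    the components, every row defaults to transcript with a warning.
    """
    main_path = Path(main_path)
    companions = resolve_companions(main_path)
    dataset = read_main_data(main_path)

    mts_ids = _companion_entity_ids(companions.mts_ilexp, companions.nonormsq)
    trs_ids = _companion_entity_ids(companions.trs_ilexp, companions.nolowess)
    if mts_ids is not None:
        for pat in dataset.patterns:
            if pat.entity_id in mts_ids:
                pat.kind = KIND_METABOLITE
    elif trs_ids is not None:
        for pat in dataset.patterns:
            if pat.entity_id not in trs_ids:
                pat.kind = KIND_METABOLITE
    else:
        logger.warning(
            "%s: no trs/mts companion found; all rows default to transcript",
            main_path.name,
        )

    if companions.trs_ilexp.exists():
        read_validity_markers(companions.trs_ilexp, dataset, KIND_TRANSCRIPT)
    if companions.mts_ilexp.exists():
        read_validity_markers(companions.mts_ilexp, dataset, KIND_METABOLITE)
    if companions.nolowess.exists():
        read_raw_values(companions.nolowess, dataset, KIND_TRANSCRIPT)
    if companions.nonormsq.exists():
        read_raw_values(companions.nonormsq, dataset, KIND_METABOLITE)
    return dataset


def _companion_entity_ids(*candidates: Path) -> set[str] | None:
    """Entity ids listed in the first existing candidate companion."""
    for path in candidates:
        if path.exists():
            _, _, rows = _read_matrix_file(path)
            return {split_inversion_label(label)[0] for label, _ in rows}
    return None


def write_family(
    dataset: ProfileDataset,
    directory: str | Path,
    dataversion: str = "1",
    timestamp: str = "20100101T1200",
) -> Path:
    """Write the main file and its companions; returns the main path.

    ``ilexp`` masks are always written for each component present in the
    dataset; raw-value companions are written only when every original of
    the component carries raw values.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    main_path = directory / _MAIN_TEMPLATE.format(dv=dataversion, dt=timestamp)
    write_main_data(dataset, main_path)
    companions = resolve_companions(main_path)

    for kind, ilexp_path, raw_path in (
        (KIND_TRANSCRIPT, companions.trs_ilexp, companions.nolowess),
        (KIND_METABOLITE, companions.mts_ilexp, companions.nonormsq),
    ):
        originals = [p for p in dataset.originals() if p.kind == kind]
        if not originals:
            continue
        _write_companion(
            ilexp_path,
            dataset,
            [(p.entity_id, p.validity.astype(float)) for p in originals],
        )
        if all(p.raw_values is not None for p in originals):
            _write_companion(
                raw_path,
                dataset,
                [(p.entity_id, p.raw_values) for p in originals],
            )
    return main_path


def _write_companion(
    path: Path, dataset: ProfileDataset, rows: list[tuple[str, np.ndarray]]
) -> None:
    lines = [str(dataset.n_genotypes), " ".join(dataset.genotypes)]
    for label, values in rows:
        rendered = " ".join(format_value(v) for v in values)
        lines.append(f"{rendered} {label}")
    path.write_text("\n".join(lines) + "\n")
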