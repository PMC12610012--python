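"""Readers and writers for the plain-text formats the pipeline touches.

Matrices travel as TSV (features x samples, first column = feature id, "NA"
for missing), gene sets as GMT, segmented-cell tables as CSV, ground truth
and run reports as JSON.  All readers validate and raise :class:`FormatError`
rather than silently coercing malformed input; every writer's output re-reads
to equal its input (up to 12-significant-digit float formatting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "GeneSetCollection",
    "CellTable",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_cells",
    "write_cells",
]

MISSING_TOKEN = "NA"
FLOAT_FMT = "%.12g"

#: required columns of a segmented-cell CSV, in canonical order
CELL_COLUMNS = ["cell_id", "image_id", "x_um", "y_um", "CK", "CD8", "FOXP3", "CD68"]

#: the four mIF markers, in staining-panel order
MARKERS = ["CK", "CD8", "FOXP3", "CD68"]

VALID_GROUPS = ("WT", "MUT")


class FormatError(ValueError):
    """Malformed input file; the message names the offending line or field."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log2-scale abundance matrix (features x samples) with group labels.

    Attributes
    ----------
    values : pandas.DataFrame
        Rows indexed by feature id, columns by sample id, float values on the
        log2 scale; NaN marks a missing quantification.
    groups : pandas.Series
        Maps each sample id to ``"WT"`` or ``"MUT"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        cols = self.values.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        missing = [s for s in cols if s not in self.groups.index]
        if missing:
            raise FormatError(f"sample {missing[0]!r} has no group label")
        bad = [s for s in cols if self.groups[s] not in VALID_GROUPS]
        if bad:
            raise FormatError(
                f"sample {bad[0]!r} has group {self.groups[bad[0]]!r}, "
                f"expected one of {VALID_GROUPS}"
            )
        self.groups = self.groups.loc[cols]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


def read_matrix(path, groups_path) -> ExpressionMatrix:
    """Read a TSV abundance matrix plus its two-column sample/group file."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN],
                     keep_default_na=False, dtype=str)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric value in {path}: {exc}") from exc
    values.index = values.index.astype(str)
    values.index.name = None
    values.columns = values.columns.astype(str)

    gdf = pd.read_csv(groups_path, sep="\t", header=None, dtype=str)
    if gdf.shape[1] != 2:
        raise FormatError(f"group file {groups_path} must have exactly 2 columns")
    if gdf[0].duplicated().any():
        dup = gdf[0][gdf[0].duplicated()].iloc[0]
        raise FormatError(f"duplicate sample id {dup!r} in group file")
    groups = pd.Series(gdf[1].values, index=gdf[0].values)
    return ExpressionMatrix(values=values, groups=groups)


def write_matrix(matrix: ExpressionMatrix, path, groups_path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=FLOAT_FMT,
                         na_rep=MISSING_TOKEN, index_label="feature_id")
    matrix.groups.to_csv(groups_path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions; GMT semantics, order-preserving."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names})


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path} line {lineno}: GMT needs >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, members = fields[0], fields[1], fields[2:]
            if name in sets:
                raise FormatError(f"{path} line {lineno}: duplicate set name {name!r}")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# segmented-cell tables
# ---------------------------------------------------------------------------

@dataclass
class CellTable:
    """Per-cell records from segmented multiplex-immunofluorescence images.

    ``cells`` holds one row per cell with the required schema columns
    (:data:`CELL_COLUMNS`) plus any extra columns (phenotype, compartment,
    latent truth, ...).  ``pixels`` optionally carries raw per-cell pixel
    intensity samples, one ``(n_cells, n_pixels)`` array per marker, row
    aligned with ``cells``; it is an in-memory payload and is not serialized.
    """

    cells: pd.DataFrame
    pixels: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for col in CELL_COLUMNS:
            if col not in self.cells.columns:
                raise FormatError(f"cell table missing required column {col!r}")
        xy = self.cells[["x_um", "y_um"]].to_numpy(float)
        if not np.isfinite(xy).all():
            raise FormatError("non-finite cell coordinate")
        dup = self.cells.duplicated(subset=["image_id", "cell_id"])
        if dup.any():
            row = self.cells[dup].iloc[0]
            raise FormatError(
                f"duplicate cell_id {row['cell_id']!r} in image {row['image_id']!r}"
            )
        if self.pixels is not None:
            n = len(self.cells)
            for marker, arr in self.pixels.items():
                if arr.shape[0] != n:
                    raise FormatError(
                        f"pixel payload for {marker!r} has {arr.shape[0]} rows, "
                        f"expected {n}"
                    )

    def __len__(self) -> int:
        return len(self.cells)

    def image_ids(self) -> list[str]:
        return list(pd.unique(self.cells["image_id"]))

    def per_image(self):
        for image_id, sub in self.cells.groupby("image_id", sort=True):
            yield image_id, sub


def read_cells(path) -> CellTable:
    df = pd.read_csv(path, dtype={"cell_id": str, "image_id": str})
    for col in CELL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    numeric = ["x_um", "y_um"] + MARKERS
    try:
        df[numeric] = df[numeric].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell value: {exc}") from exc
    return CellTable(cells=df)


def write_cells(table: CellTable, path) -> None:
    ordered = CELL_COLUMNS + [c for c in table.cells.columns if c not in CELL_COLUMNS]
    table.cells[ordered].to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# JSON sidecars
# ---------------------------------------------------------------------------

def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
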