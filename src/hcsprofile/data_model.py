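"""Core data types and file I/O shared by all pipeline stages.

The central in-memory containers are deliberately thin:

* a *cell table* is a :class:`pandas.DataFrame` in long format, one row per
  cell, with the metadata columns :data:`META_COLUMNS` followed by one numeric
  column per feature;
* a *well summary* is a DataFrame with one row per occupied
  (plate, replicate, row, col) well, a ``cell_count`` column and per-feature
  median columns;
* :class:`PlateLayout` and :class:`FeatureCatalog` describe the plate geometry
  and the feature annotations.

Well coordinates are 1-based integers (row 1..16, column 1..24 on a 384-well
plate); rows are also printable as letters (row 2 -> "B").  The ``plate``
column identifies the plate *position* within a replicate set (compounds are
split across positions); a physical plate is the pair (plate, replicate).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "META_COLUMNS",
    "CONTROL_ID",
    "PlateLayout",
    "FeatureCatalog",
    "build_default_layout",
    "well_name",
    "parse_well_name",
    "feature_columns",
    "read_cell_table",
    "write_cell_table",
    "summarize_wells",
    "read_csv_with_header",
    "write_csv_with_header",
]

#: Metadata columns of a long-format cell table, in canonical order.
META_COLUMNS = ["plate", "replicate", "row", "col", "treatment", "concentration"]

#: Treatment id used for vehicle-control wells.
CONTROL_ID = "DMSO"


class FormatError(ValueError):
    """A delimited-text input does not match the expected schema."""


def well_name(row: int, col: int) -> str:
    """1-based (row, col) -> plate-reader name, e.g. (2, 2) -> ``"B02"``."""
    return f"{chr(ord('A') + row - 1)}{col:02d}"


def parse_well_name(name: str) -> tuple[int, int]:
    """Inverse of :func:`well_name`."""
    return ord(name[0].upper()) - ord("A") + 1, int(name[1:])


@dataclass(frozen=True)
class PlateLayout:
    """Geometry of a multi-well plate and the role of every inner well.

    Parameters
    ----------
    n_rows, n_cols
        Physical plate dimensions (16 x 24 for 384-well).
    inner_rows, inner_cols
        Inclusive 1-based ranges of the analyzable region.  The outer ring is
        excluded from scanning to mitigate evaporation-driven edge effects.
    control_wells
        Set of (row, col) vehicle-control positions.  The design contract is
        that every inner row and every inner column contains at least one
        control well, so row/column positional effects are identifiable from
        controls alone.
    treatment_map
        (row, col) -> (compound id, concentration in uM, dilution index 1..7,
        1 = highest dose).  Wells in neither map are empty.
    """

    n_rows: int = 16
    n_cols: int = 24
    inner_rows: tuple[int, int] = (2, 15)
    inner_cols: tuple[int, int] = (2, 23)
    control_wells: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    treatment_map: dict[tuple[int, int], tuple[str, float, int]] = field(default_factory=dict)

    # -- geometry -----------------------------------------------------------
    def inner_row_range(self) -> range:
        return range(self.inner_rows[0], self.inner_rows[1] + 1)

    def inner_col_range(self) -> range:
        return range(self.inner_cols[0], self.inner_cols[1] + 1)

    def is_inner(self, row: int, col: int) -> bool:
        return (self.inner_rows[0] <= row <= self.inner_rows[1]
                and self.inner_cols[0] <= col <= self.inner_cols[1])

    def inner_wells(self) -> list[tuple[int, int]]:
        return [(r, c) for r in self.inner_row_range() for c in self.inner_col_range()]

    @property
    def n_inner(self) -> int:
        return len(self.inner_row_range()) * len(self.inner_col_range())

    def treatment_wells(self) -> list[tuple[int, int]]:
        return sorted(self.treatment_map)

    def well_role(self, row: int, col: int) -> str:
        """'control' | 'treatment' | 'empty' | 'outer'."""
        if not self.is_inner(row, col):
            return "outer"
        if (row, col) in self.control_wells:
            return "control"
        if (row, col) in self.treatment_map:
            return "treatment"
        return "empty"

    def validate(self) -> None:
        """Enforce the layout invariants; raise ``ValueError`` on violation."""
        for r, c in self.control_wells:
            if not self.is_inner(r, c):
                raise ValueError(f"control well {well_name(r, c)} outside inner region")
        for r, c in self.treatment_map:
            if not self.is_inner(r, c):
                raise ValueError(f"treatment well {well_name(r, c)} outside inner region")
        if self.control_wells & set(self.treatment_map):
            overlap = sorted(self.control_wells & set(self.treatment_map))
            raise ValueError(f"wells assigned as both control and treatment: {overlap}")
        rows_hit = {r for r, _ in self.control_wells}
        cols_hit = {c for _, c in self.control_wells}
        missing_r = set(self.inner_row_range()) - rows_hit
        missing_c = set(self.inner_col_range()) - cols_hit
        if missing_r or missing_c:
            raise ValueError(
                f"diagonal-placement contract violated: rows {sorted(missing_r)} / "
                f"columns {sorted(missing_c)} carry no control well"
            )

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "inner_rows": list(self.inner_rows),
            "inner_cols": list(self.inner_cols),
            "control_wells": sorted(well_name(r, c) for r, c in self.control_wells),
            "treatments": [
                {"well": well_name(r, c), "compound": cpd,
                 "concentration": float(conc), "dose_index": int(idx)}
                for (r, c), (cpd, conc, idx) in sorted(self.treatment_map.items())
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PlateLayout":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        layout = cls(
            n_rows=int(doc["n_rows"]),
            n_cols=int(doc["n_cols"]),
            inner_rows=tuple(doc["inner_rows"]),
            inner_cols=tuple(doc["inner_cols"]),
            control_wells=frozenset(parse_well_name(w) for w in doc["control_wells"]),
            treatment_map={
                parse_well_name(t["well"]): (str(t["compound"]),
                                             float(t["concentration"]),
                                             int(t["dose_index"]))
                for t in doc.get("treatments", [])
            },
        )
        layout.validate()
        return layout


def _default_control_diagonals(inner_rows: range, inner_cols: range) -> frozenset:
    """Deterministic diagonal control tiling: 55 wells on a 14 x 22 region.

    Two full wrap-around diagonals (one control per column, 2 x 22 = 44) plus
    a half-stride partial diagonal on every other column (11), so every inner
    row and every inner column carries at least one control.
    """
    rows = list(inner_rows)
    cols = list(inner_cols)
    n_r = len(rows)
    wells: set[tuple[int, int]] = set()
    for j, c in enumerate(cols):
        wells.add((rows[j % n_r], c))                  # main diagonal
        wells.add((rows[(j + n_r // 2) % n_r], c))     # offset diagonal
    for j, c in enumerate(cols):
        if j % 2 == 0:                                 # partial third diagonal
            wells.add((rows[(j + n_r // 4) % n_r], c))
    return frozenset(wells)


def build_default_layout(compounds=None, top_conc: float = 10.0,
                         n_doses: int = 7) -> PlateLayout:
    """Default 384-well screening layout.

    16 x 24 plate, inner region rows 2-15 x columns 2-23 (308 analyzable
    wells), 55 diagonally placed control wells covering every inner row and
    column, and the remaining inner wells grouped row-wise into horizontal
    7-point 2-fold dilution series (highest dose leftmost).

    Parameters
    ----------
    compounds
        Compound ids to assign to the dilution-series slots.  ``None`` names
        the slots generically (``S01``..).  If fewer compounds than slots are
        given they are recycled so every series slot is occupied; an integer
        is shorthand for that many generic ids.  253 non-control inner wells
        hold 36 series of 7 wells (the final leftover well stays empty).
    """
    layout0 = PlateLayout()
    controls = _default_control_diagonals(layout0.inner_row_range(), layout0.inner_col_range())
    free = [w for w in layout0.inner_wells() if w not in controls]
    # row-major order already; chunk into series of n_doses
    n_series = len(free) // n_doses
    if compounds is None:
        compounds = [f"S{i + 1:02d}" for i in range(n_series)]
    elif isinstance(compounds, int):
        compounds = [f"S{i + 1:02d}" for i in range(compounds)]
    compounds = list(compounds)
    tmap: dict[tuple[int, int], tuple[str, float, int]] = {}
    for s in range(n_series):
        cpd = compounds[s % len(compounds)]
        for d in range(n_doses):
            conc = top_conc / 2 ** d
            tmap[free[s * n_doses + d]] = (cpd, conc, d + 1)
    layout = PlateLayout(control_wells=controls, treatment_map=tmap)
    layout.validate()
    return layout


# ---------------------------------------------------------------------------
# Feature catalog
# ---------------------------------------------------------------------------

#: Markers whose biology is nuclear: cytoplasmic (Ring) readouts are noise.
NUCLEAR_MARKERS = frozenset({"DNA"})
#: Markers of cytoplasmic structures: nuclear (Circ) readouts are noise.
CYTOPLASMIC_MARKERS = frozenset(
    {"lysosome", "peroxisome", "lipid", "tubulin", "mitochondria", "actin", "PMG", "ER"}
)


@dataclass
class FeatureCatalog:
    """Annotation of every measured feature.

    ``table`` columns: ``feature`` (unique), ``marker`` (stained component,
    e.g. DNA / RNA / mitochondria), ``compartment`` ("Circ" = nucleus,
    "Ring" = simulated cytoplasm, "Cell" = whole object), ``feature_class``
    (intensity | shape | texture | spot) and a boolean ``relevant`` flag.

    The relevance flag encodes assay knowledge the algorithms cannot infer:
    nuclear-marker features measured in the cytoplasm (and vice versa) are
    background, and optics-driven exclusions (e.g. channel bleed-through)
    are recorded the same way.
    """

    table: pd.DataFrame

    REQUIRED = ("feature", "marker", "compartment", "feature_class", "relevant")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"feature catalog missing columns: {missing}")
        if self.table["feature"].duplicated().any():
            dups = self.table.loc[self.table["feature"].duplicated(), "feature"].tolist()
            raise ValueError(f"duplicate catalog entries: {dups}")
        self.table = self.table.reset_index(drop=True)

    @property
    def features(self) -> list[str]:
        return self.table["feature"].tolist()

    def lookup(self, feature: str) -> pd.Series:
        hit = self.table[self.table["feature"] == feature]
        if hit.empty:
            raise KeyError(f"feature not in catalog: {feature}")
        return hit.iloc[0]

    def check_covers(self, features) -> None:
        unknown = sorted(set(features) - set(self.features))
        if unknown:
            raise KeyError(f"features absent from catalog: {unknown}")

    @classmethod
    def from_records(cls, records) -> "FeatureCatalog":
        df = pd.DataFrame.from_records(records)
        if "relevant" not in df.columns:
            df = apply_default_relevance(df)
        return cls(df)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"features": self.table.to_dict("records")}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureCatalog":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(pd.DataFrame.from_records(doc["features"]))


def apply_default_relevance(table: pd.DataFrame,
                            nuclear=NUCLEAR_MARKERS,
                            cytoplasmic=CYTOPLASMIC_MARKERS,
                            extra_irrelevant=()) -> pd.DataFrame:
    """Fill the ``relevant`` column from the compartment/marker rules.

    A feature is irrelevant when a nuclear marker is measured in the Ring
    (cytoplasm) or a cytoplasmic marker in the Circ (nucleus); additional
    assay-specific exclusions (e.g. bleed-through channels) can be named
    explicitly via ``extra_irrelevant``.
    """
    table = table.copy()
    rel = np.ones(len(table), dtype=bool)
    rel &= ~(table["marker"].isin(nuclear) & (table["compartment"] == "Ring"))
    rel &= ~(table["marker"].isin(cytoplasmic) & (table["compartment"] == "Circ"))
    rel &= ~table["feature"].isin(set(extra_irrelevant))
    table["relevant"] = rel
    return table


# ---------------------------------------------------------------------------
# Cell tables
# ---------------------------------------------------------------------------

def feature_columns(cells: pd.DataFrame) -> list[str]:
    """Feature columns of a cell table = everything after the metadata block."""
    return [c for c in cells.columns if c not in META_COLUMNS]


def read_cell_table(path, catalog: FeatureCatalog | None = None,
                    layout: PlateLayout | None = None) -> pd.DataFrame:
    """Read and validate a long-format per-cell feature CSV.

    Rows outside the layout's inner region are dropped (with a summary
    warning): the outer ring carries no analyzable wells by design.

    Raises
    ------
    FormatError
        missing metadata column, or a non-numeric feature cell (the offending
        column is named).
    KeyError
        a feature column absent from the catalog.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cell table missing metadata columns: {missing}")
    df = df[META_COLUMNS + [c for c in df.columns if c not in META_COLUMNS]]
    feats = feature_columns(df)
    for c in feats:
        if not pd.api.types.is_numeric_dtype(df[c]):
            coerced = pd.to_numeric(df[c], errors="coerce")
            bad = df.index[coerced.isna() & df[c].notna()]
            raise FormatError(
                f"non-numeric value in feature column '{c}' "
                f"(first offending row index {bad[0] if len(bad) else '?'})")
    if catalog is not None:
        catalog.check_covers(feats)
    if layout is not None:
        inside = df.apply(lambda r: layout.is_inner(int(r["row"]), int(r["col"])), axis=1)
        n_out = int((~inside).sum())
        if n_out:
            warnings.warn(f"dropped {n_out} cell records outside the inner plate region",
                          stacklevel=2)
            df = df[inside].reset_index(drop=True)
    return df


def write_cell_table(cells: pd.DataFrame, path, precision: int = 10) -> None:
    """Write a cell table as CSV; numeric content round-trips at ``precision``
    significant digits through :func:`read_cell_table`."""
    cells.to_csv(path, index=False, float_format=f"%.{precision}g")


def summarize_wells(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-well cell counts and per-feature medians.

    One row per occupied (plate, replicate, row, col); medians ignore missing
    values and are NaN when every value of a feature in the well is missing.
    Record order does not affect the result.
    """
    if len(cells) == 0:
        raise ValueError("summarize_wells: empty cell table")
    feats = feature_columns(cells)
    keys = ["plate", "replicate", "row", "col"]
    grouped = cells.groupby(keys, sort=True)
    med = grouped[feats].median()
    meta = grouped[["treatment", "concentration"]].first()
    counts = grouped.size().rename("cell_count")
    out = pd.concat([meta, counts, med], axis=1).reset_index()
    return out


# ---------------------------------------------------------------------------
# CSV with '#' metadata header (all downstream tabular outputs)
# ---------------------------------------------------------------------------

def write_csv_with_header(df: pd.DataFrame, path, metadata: dict | None = None,
                          float_format: str = "%.10g") -> None:
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False, float_format=float_format)


def read_csv_with_header(path) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
            else:
                lines.append(line)
    df = pd.read_csv(io.StringIO("".join(lines)))
    return df, meta
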