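"""On-disk artifacts of the knockdown-signature pipeline and their containers.

Four plain-text formats are handled, all UTF-8 with LF newlines:

* expression matrices — tab-separated, first column gene ids, header row
  sample ids, values on a caller-declared scale (``log2`` or ``linear``);
* gene-set collections — the standard GMT dialect
  (``name TAB description TAB gene TAB gene ...``);
* clinical tables — CSV with required columns ``sample_id``, ``time``,
  ``event`` and arbitrary extra covariate columns;
* signatures — two-column TSV (``gene TAB direction``) where direction is
  ``up`` or ``down`` relative to the perturbed (knockdown) condition.

Loading validates domain invariants eagerly: duplicate gene ids are collapsed
to the highest-mean row (a common microarray-collapse convention), rows with
missing values are dropped and counted in the log, and malformed cells raise
:class:`~kdsig.exceptions.FormatError` with coordinates. Sample order is
always preserved as input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

SCALES = ("log2", "linear")
DIRECTIONS = ("up", "down")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric matrix with declared scale.

    Parameters
    ----------
    data:
        DataFrame indexed by gene id with one column per sample. Must be
        fully numeric with no missing values.
    scale:
        ``"log2"`` or ``"linear"``. Linear-scale values must be >= 0.
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:10]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:10]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if np.isnan(values).any():
            raise ValidationError("expression matrix contains missing values")
        if self.scale == "linear" and (values < 0).any():
            raise ValidationError("linear-scale expression values must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        # dedupe preserving first occurrence
        self.genes = list(dict.fromkeys(self.genes))
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    """Named gene sets, insertion-ordered."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValidationError(f"key {name!r} does not match set name {gs.name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


@dataclass
class ClinicalTable:
    """Per-sample follow-up data: time on study, event indicator, covariates.

    ``data`` holds columns ``sample_id``, ``time`` (non-negative, in
    ``time_unit``), ``event`` (1 = event observed, 0 = censored); any further
    columns are treated as covariates. Time units are metadata only — no
    conversion is ever applied.
    """

    data: pd.DataFrame
    time_unit: str = "months"

    REQUIRED = ("sample_id", "time", "event")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"clinical table missing required columns: {missing}")
        sid = self.data["sample_id"]
        if sid.duplicated().any():
            raise ValidationError(
                f"duplicate sample ids: {sid[sid.duplicated()].unique().tolist()[:10]}"
            )
        time = pd.to_numeric(self.data["time"], errors="coerce")
        bad = self.data.loc[time.isna() | (time < 0) | ~np.isfinite(time), "sample_id"]
        if len(bad):
            raise ValidationError(f"non-finite or negative times for samples: {bad.tolist()}")
        event = self.data["event"]
        bad = self.data.loc[~event.isin([0, 1]), "sample_id"]
        if len(bad):
            raise ValidationError(f"event must be 0 or 1; offending samples: {bad.tolist()}")
        self.data = self.data.assign(time=time.astype(float), event=event.astype(int))

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy()

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.REQUIRED]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class Signature:
    """Two disjoint gene lists: up- and down-regulated upon knockdown."""

    up: list[str]
    down: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.up = list(self.up)
        self.down = list(self.down)
        if len(set(self.up)) != len(self.up):
            raise ValidationError("duplicate genes in the up list")
        if len(set(self.down)) != len(self.down):
            raise ValidationError("duplicate genes in the down list")
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValidationError(f"genes in both directions: {sorted(overlap)[:10]}")
        if not self.up and not self.down:
            raise ValidationError("signature has no genes")

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    def swapped(self) -> "Signature":
        """The direction-reversed signature (up and down exchanged)."""
        return Signature(up=list(self.down), down=list(self.up), meta=dict(self.meta))


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, scale: str) -> ExpressionMatrix:
    """Load a tab-separated genes x samples matrix.

    First column is the gene id, header row carries sample ids. Duplicate
    gene ids collapse to the row with the highest mean (logged); rows with
    empty cells are dropped (logged); textual junk in a value cell raises
    :class:`FormatError` with the cell coordinates.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: empty file")
    header_fields = header.rstrip("\n").split("\t")
    if len(header_fields) < 2:
        raise FormatError(f"{path}: header must contain a gene-id column and >=1 sample")
    sample_fields = header_fields[1:]
    if any(_is_number(s) for s in sample_fields):
        raise FormatError(f"{path}: header row looks numeric — missing sample-id header?")
    dup = {s for s in sample_fields if sample_fields.count(s) > 1}
    if dup:
        raise FormatError(f"{path}: duplicate sample ids in header: {sorted(dup)}")

    # keep_default_na=False so that textual "NA" is an error, while genuinely
    # empty cells become NaN and trigger the drop-row rule
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, na_values=[""]
    )
    df.index = df.index.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        gi, sj = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[gi, sj]!r} at gene "
            f"{df.index[gi]!r}, sample {df.columns[sj]!r}"
        )

    n_missing = int(numeric.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("%s: dropped %d gene rows with missing values", path, n_missing)
        df = df[~numeric.isna().any(axis=1)]
    # astype(float) parses via Python's float(), which is exactly round-trip
    # safe for values written by to_csv (to_numeric's fast path is not)
    numeric = df.astype(float)

    if numeric.index.has_duplicates:
        means = numeric.mean(axis=1)
        # one deterministic pass: first occurrence wins ties, higher mean wins
        rows: list[int] = []
        seen: dict[str, int] = {}
        for i, g in enumerate(numeric.index):
            if g not in seen:
                seen[g] = i
                rows.append(i)
            elif means.iloc[i] > means.iloc[seen[g]]:
                rows[rows.index(seen[g])] = i
                seen[g] = i
        n_dup = len(numeric) - len(rows)
        logger.warning("%s: collapsed %d duplicate gene rows (kept highest mean)", path, n_dup)
        numeric = numeric.iloc[sorted(rows)]

    numeric.index.name = None
    return ExpressionMatrix(data=numeric.astype(float), scale=scale)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    expr.data.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")


def _is_number(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one gene set per non-empty line."""
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(name=name, description=description, genes=genes)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------


def read_clinical(path: str | Path, time_unit: str = "months") -> ClinicalTable:
    """Load a clinical CSV; extra columns become covariates."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ClinicalTable.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    return ClinicalTable(data=df, time_unit=time_unit)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------


def read_signature(path: str | Path) -> Signature:
    """Load a two-column TSV signature (gene, direction in {up, down})."""
    path = Path(path)
    up: list[str] = []
    down: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if lineno == 1 and line.lower().startswith("gene\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 fields, got {len(fields)}")
            gene, direction = fields
            if direction not in DIRECTIONS:
                raise FormatError(
                    f"{path}: line {lineno}: direction must be 'up' or 'down', got {direction!r}"
                )
            (up if direction == "up" else down).append(gene)
    return Signature(up=up, down=down, meta={"source": str(path)})


def write_signature(sig: Signature, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tdirection\n")
        for g in sig.up:
            fh.write(f"{g}\tup\n")
        for g in sig.down:
            fh.write(f"{g}\tdown\n")


# ---------------------------------------------------------------------------
# ranked lists (.rnk dialect) and group labels
# ---------------------------------------------------------------------------


def read_rnk(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a 2-column TSV of (gene, metric); returns genes and metric values
    sorted by metric descending with lexicographic gene-id tie-break."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "metric"], comment="#")
    if df["gene"].duplicated().any():
        raise FormatError(f"{path}: duplicate genes in ranked list")
    metric = pd.to_numeric(df["metric"], errors="coerce")
    if metric.isna().any():
        raise FormatError(f"{path}: non-numeric metric values")
    df = df.assign(metric=metric).sort_values(
        ["metric", "gene"], ascending=[False, True], kind="mergesort"
    )
    return df["gene"].tolist(), df["metric"].to_numpy(dtype=float)


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a 2-column CSV mapping sample_id -> group label."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if len(cols) < 2:
        raise FormatError(f"{path}: expected columns sample_id,group")
    sid, grp = cols[0], cols[1]
    if df[sid].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return dict(zip(df[sid].astype(str), df[grp].astype(str)))
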