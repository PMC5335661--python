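"""On-disk artifact handling: gene sets (GMT), expression matrices, rank
databases, ortholog maps and survival tables.

All readers validate aggressively so downstream modules can assume
well-formed in-memory objects.  The TSV dialect used throughout is UTF-8,
tab-separated, ``#``-prefixed comment lines ignored, no quoting.

Gene symbols are matched case-insensitively everywhere in the package
(mixed-species conventions such as ``Col1a1`` vs ``COL1A1`` are the norm);
original case is preserved on output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "GeneSet",
    "ExpressionMatrix",
    "RankDatabase",
    "OrthologMap",
    "SurvivalCohort",
    "read_gmt",
    "write_gmt",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_rank_database",
    "write_rank_database",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_survival_table",
    "write_survival_table",
]


class ParseError(ValueError):
    """A file could not be parsed (malformed line, bad cell value, ...)."""


class ValidationError(ValueError):
    """Parsed content violates a structural invariant."""


_READ_CSV_KW = dict(sep="\t", comment="#", dtype=str, keep_default_na=False)


def _casefold_unique(genes: Iterable[str], context: str = "") -> tuple[str, ...]:
    """Drop case-insensitive duplicate symbols, keeping first occurrence."""
    seen: set[str] = set()
    out: list[str] = []
    dropped: list[str] = []
    for g in genes:
        key = g.casefold()
        if key in seen:
            dropped.append(g)
        else:
            seen.add(key)
            out.append(g)
    if dropped:
        warnings.warn(
            f"{context}: dropped {len(dropped)} case-insensitive duplicate "
            f"gene symbol(s): {dropped[:5]}",
            stacklevel=3,
        )
    return tuple(out)


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered collection of unique gene symbols.

    Symbols are unique after case-folding; original case is preserved.
    """

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = _casefold_unique(self.genes, context=f"gene set {self.name!r}")
        object.__setattr__(self, "genes", genes)
        if len(self.genes) < 1:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: object) -> bool:
        if not isinstance(symbol, str):
            return False
        return symbol.casefold() in self.casefolded()

    def casefolded(self) -> frozenset[str]:
        return frozenset(g.casefold() for g in self.genes)


@dataclass
class ExpressionMatrix:
    """Normalized (log-scale) expression values, genes x samples, with a
    two-group sample annotation (``case`` / ``control``)."""

    values: pd.DataFrame          # index = gene ids, columns = sample ids
    groups: pd.Series             # index = sample ids, values in {case, control}

    GROUPS = ("case", "control")

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression matrix")
        if v.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in expression matrix")
        self.groups = pd.Series(self.groups)
        missing = set(v.columns) - set(self.groups.index)
        if missing:
            raise ValidationError(f"samples without group label: {sorted(missing)[:5]}")
        self.groups = self.groups.loc[v.columns]
        bad = set(self.groups.unique()) - set(self.GROUPS)
        if bad:
            raise ValidationError(f"group labels must be in {self.GROUPS}, got {sorted(bad)}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_columns(self, label: str) -> pd.Index:
        return self.samples[self.groups.to_numpy() == label]


@dataclass
class RankDatabase:
    """Perturbation rank corpus: one column per treatment instance, each a
    permutation of 1..n over a shared gene universe (rank 1 = most
    up-regulated by the treatment), plus instance metadata."""

    ranks: pd.DataFrame           # index = gene symbols, columns = instance ids, int
    metadata: pd.DataFrame        # index = instance ids; columns compound, dose, cell_line

    def __post_init__(self) -> None:
        r = self.ranks
        if r.index.duplicated().any():
            raise ValidationError("duplicate gene symbols in rank database universe")
        if r.columns.duplicated().any():
            raise ValidationError("duplicate instance ids in rank database")
        n = r.shape[0]
        expected = np.arange(1, n + 1)
        arr = r.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ParseError("rank matrix cells must be integers")
        for j, inst in enumerate(r.columns):
            if not np.array_equal(np.sort(arr[:, j]), expected):
                raise ValidationError(
                    f"instance {inst!r}: ranks are not a permutation of 1..{n}"
                )
        meta = self.metadata
        for col in ("compound", "dose", "cell_line"):
            if col not in meta.columns:
                raise ValidationError(f"metadata missing column {col!r}")
        in_ranks, in_meta = set(r.columns), set(meta.index)
        if in_ranks != in_meta:
            raise ValidationError(
                "instance ids differ between ranks and metadata: "
                f"only in ranks {sorted(in_ranks - in_meta)[:5]}, "
                f"only in metadata {sorted(in_meta - in_ranks)[:5]}"
            )
        self.metadata = meta.loc[r.columns]

    @property
    def n_genes(self) -> int:
        return self.ranks.shape[0]

    @property
    def instances(self) -> pd.Index:
        return self.ranks.columns

    @property
    def compounds(self) -> list[str]:
        return sorted(self.metadata["compound"].unique())

    def instances_of(self, compound: str) -> list[str]:
        hits = self.metadata.index[self.metadata["compound"] == compound]
        if len(hits) == 0:
            raise KeyError(f"unknown compound {compound!r}")
        return list(hits)

    def gene_rank_lookup(self) -> dict[str, np.ndarray]:
        """Case-folded gene symbol -> row position, for tag lookups."""
        return {g.casefold(): i for i, g in enumerate(self.ranks.index)}


@dataclass
class OrthologMap:
    """Cross-species gene id translation records (source id -> human symbol)."""

    records: pd.DataFrame         # columns: source, human

    def __post_init__(self) -> None:
        rec = self.records[["source", "human"]].copy()
        dup = rec.duplicated()
        if dup.any():
            warnings.warn(f"ortholog map: dropped {int(dup.sum())} exact duplicate record(s)")
            rec = rec[~dup]
        self.records = rec.reset_index(drop=True)

    @classmethod
    def identity(cls, genes: Iterable[str]) -> "OrthologMap":
        genes = list(genes)
        return cls(pd.DataFrame({"source": genes, "human": genes}))

    def partners(self) -> dict[str, list[str]]:
        """Case-folded source id -> distinct human symbols."""
        out: dict[str, list[str]] = {}
        for src, hum in self.records.itertuples(index=False):
            lst = out.setdefault(src.casefold(), [])
            if hum.casefold() not in {h.casefold() for h in lst}:
                lst.append(hum)
        return out


@dataclass
class SurvivalCohort:
    """Per-sample biomarker expression with right-censored follow-up."""

    table: pd.DataFrame           # columns: id, biomarker, time, event

    def __post_init__(self) -> None:
        t = self.table
        for col in ("id", "biomarker", "time", "event"):
            if col not in t.columns:
                raise ValidationError(f"survival table missing column {col!r}")
        if t["id"].duplicated().any():
            dups = t["id"][t["id"].duplicated()].tolist()
            raise ValidationError(f"duplicate sample id(s): {dups[:5]}")
        if (t["time"] < 0).any():
            raise ValidationError("negative follow-up time")
        if not t["event"].isin([0, 1]).all():
            bad = sorted(set(t["event"]) - {0, 1})
            raise ValidationError(f"event indicator must be 0 or 1, got {bad[:5]}")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def biomarker(self) -> np.ndarray:
        return self.table["biomarker"].to_numpy(dtype=float)

    @property
    def time(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes; one set per
    tab-separated line).  Duplicate symbols within a line are collapsed with
    a warning; duplicate set names are an error."""
    path = Path(path)
    sets: list[GeneSet] = []
    names: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name}:{lineno}: GMT line has {len(fields)} field(s); "
                    "need name, description and at least one gene"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]  # trailing tabs are tolerated
            if name in names:
                raise ParseError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            names.add(name)
            sets.append(GeneSet(name=name, description=description, genes=tuple(genes)))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrix (GCT-like TSV + two-column group-label TSV)
# ---------------------------------------------------------------------------

def read_expression_matrix(matrix_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Read a GCT-like TSV (header row = sample ids, first column = gene ids)
    plus a two-column (sample id, group) label TSV."""
    matrix_path, groups_path = Path(matrix_path), Path(groups_path)
    try:
        values = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    except ValueError as exc:
        raise ParseError(f"{matrix_path.name}: {exc}") from exc
    if not all(np.issubdtype(dt, np.number) for dt in values.dtypes):
        raise ParseError(f"{matrix_path.name}: non-numeric expression values")
    values.index.name = values.columns.name = None
    labels = pd.read_csv(groups_path, **_READ_CSV_KW)
    if labels.shape[1] < 2:
        raise ParseError(f"{groups_path.name}: expected two columns (sample id, group)")
    groups = pd.Series(labels.iloc[:, 1].values, index=labels.iloc[:, 0].values)
    return ExpressionMatrix(values=values.astype(float), groups=groups)


def write_expression_matrix(matrix: ExpressionMatrix, matrix_path: str | Path,
                            groups_path: str | Path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene")
    pd.DataFrame({"sample": matrix.samples, "group": matrix.groups.values}).to_csv(
        groups_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Rank database
# ---------------------------------------------------------------------------

def read_rank_database(rank_path: str | Path, meta_path: str | Path) -> RankDatabase:
    """Read an instances x genes rank corpus: a TSV rank matrix (first column
    gene symbols, header row instance ids) and an instance metadata TSV with
    columns instance_id, compound, dose, cell_line."""
    rank_path, meta_path = Path(rank_path), Path(meta_path)
    raw = pd.read_csv(rank_path, sep="\t", comment="#", index_col=0)
    raw.index.name = raw.columns.name = None
    try:
        ranks = raw.astype(np.int64)
    except ValueError as exc:
        raise ParseError(f"{rank_path.name}: non-integer rank cell ({exc})") from exc
    if not raw.equals(ranks.astype(raw.dtypes.iloc[0]) if len(raw.columns) else raw):
        # float column that survived the cast, e.g. 1.5 -> 1
        if not np.allclose(raw.to_numpy(dtype=float), ranks.to_numpy()):
            raise ParseError(f"{rank_path.name}: non-integer rank cell")
    meta = pd.read_csv(meta_path, **_READ_CSV_KW)
    required = ["instance_id", "compound", "dose", "cell_line"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ParseError(f"{meta_path.name}: missing metadata column(s) {missing}")
    if meta["instance_id"].duplicated().any():
        raise ValidationError(f"{meta_path.name}: duplicate instance ids")
    meta = meta.set_index("instance_id")
    return RankDatabase(ranks=ranks, metadata=meta[["compound", "dose", "cell_line"]])


def write_rank_database(db: RankDatabase, rank_path: str | Path, meta_path: str | Path) -> None:
    db.ranks.to_csv(rank_path, sep="\t", index_label="gene")
    db.metadata.to_csv(meta_path, sep="\t", index_label="instance_id")


# ---------------------------------------------------------------------------
# Ortholog map
# ---------------------------------------------------------------------------

def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column (source gene id, human gene symbol) TSV."""
    path = Path(path)
    rec = pd.read_csv(path, **_READ_CSV_KW)
    if rec.shape[1] < 2:
        raise ParseError(f"{path.name}: expected two columns (source, human)")
    rec = rec.iloc[:, :2]
    rec.columns = ["source", "human"]
    return OrthologMap(records=rec)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    omap.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Survival table
# ---------------------------------------------------------------------------

def read_survival_table(path: str | Path) -> SurvivalCohort:
    """Read a TSV with columns id, biomarker, time, event."""
    path = Path(path)
    raw = pd.read_csv(path, **_READ_CSV_KW)
    missing = [c for c in ("id", "biomarker", "time", "event") if c not in raw.columns]
    if missing:
        raise ParseError(f"{path.name}: missing column(s) {missing}")
    try:
        table = pd.DataFrame({
            "id": raw["id"],
            "biomarker": raw["biomarker"].astype(float),
            "time": raw["time"].astype(float),
            "event": raw["event"].astype(int),
        })
    except ValueError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc
    if not np.allclose(raw["event"].astype(float), table["event"]):
        raise ValidationError(f"{path.name}: event indicator must be integer 0/1")
    return SurvivalCohort(table=table)


def write_survival_table(cohort: SurvivalCohort, path: str | Path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)
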