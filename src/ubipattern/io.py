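"""Standard-format I/O: expression TSV, clinical TSV, and GMT gene sets.

Conventions
-----------
* Expression matrices are ``pandas.DataFrame`` objects, genes as rows and
  samples as columns; the first TSV column holds gene identifiers and the
  header row holds sample identifiers.
* Clinical tables are ``pandas.DataFrame`` objects with one row per sample,
  a ``sample`` column plus ``time_months`` and ``event`` columns and any
  number of covariate columns.
* Gene sets are handled through :class:`GeneSetCollection`, an ordered
  mapping of set name to member list, serialized as GMT
  (``name<TAB>description<TAB>member...``).
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping
from pathlib import Path

import pandas as pd


class SchemaError(ValueError):
    """Raised when an input file violates the expected schema."""


class GeneSetCollection(Mapping):
    """Ordered collection of named gene sets with optional descriptions."""

    def __init__(self, sets: Mapping[str, list[str]] | None = None,
                 descriptions: Mapping[str, str] | None = None) -> None:
        self._sets: dict[str, list[str]] = {}
        self._descriptions: dict[str, str] = {}
        if sets:
            for name, members in sets.items():
                desc = descriptions.get(name, "") if descriptions else ""
                self.add(name, members, desc)

    def add(self, name: str, members: list[str], description: str = "") -> None:
        if name in self._sets:
            raise SchemaError(f"duplicate gene-set name: {name!r}")
        if not members:
            raise SchemaError(f"gene set {name!r} has no members")
        self._sets[name] = list(members)
        self._descriptions[name] = description

    def description(self, name: str) -> str:
        return self._descriptions[name]

    def __getitem__(self, name: str) -> list[str]:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneSetCollection({len(self)} sets)"


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV.

    Raises :class:`SchemaError` on duplicate gene or sample ids, missing
    values, or non-numeric entries.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise SchemaError(f"duplicated gene id(s) in {path}: {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise SchemaError(f"duplicated sample id(s) in {path}: {dups}")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()[:10]
        raise SchemaError(
            f"missing expression values in {path} (genes {bad}); "
            "imputation is not supported"
        )
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"non-numeric expression values in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = "gene"
    df.columns = df.columns.astype(str)
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    out = expr.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV with columns sample, time_months, event, covariates."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "time_months", "event"):
        if col not in df.columns:
            raise SchemaError(f"clinical table {path} missing column {col!r}")
    df["sample"] = df["sample"].astype(str)
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise SchemaError(f"duplicated sample id(s) in {path}: {dups}")
    if (df["time_months"] <= 0).any():
        bad = df.loc[df["time_months"] <= 0, "sample"].tolist()[:10]
        raise SchemaError(f"non-positive survival times in {path} for {bad}")
    if not df["event"].isin([0, 1]).all():
        raise SchemaError(f"event column of {path} must be 0/1")
    df["event"] = df["event"].astype(int)
    return df


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB members...)."""
    path = Path(path)
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, members)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise SchemaError(f"{path}:{lineno}: gene set {name!r} is empty")
            try:
                coll.add(name, members, desc)
            except SchemaError as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
    return coll


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            desc = sets.description(name) or "na"
            fh.write("\t".join([name, desc, *sets[name]]) + "\n")
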