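"""Core typed containers and file I/O.

Every table the toolkit touches is plain delimited text (comma or
semicolon separated); dendrograms are exchanged as Newick and map
exports as GeoJSON.  Containers validate their invariants on
construction so that downstream statistics never have to re-check
symmetry, duplicate IDs or half-missing genotype calls.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hierarchy

from .errors import ParseError, SchemaError, ValidationError

__all__ = [
    "SampleTable",
    "GenotypeTable",
    "QuantitativeMatrix",
    "DistanceMatrix",
    "Partition",
    "MergeTree",
    "read_sample_table",
    "write_sample_table",
    "read_genotypes",
    "write_genotypes",
    "read_quantitative",
    "write_quantitative",
    "aggregate_replicates",
    "write_newick",
    "points_geojson",
    "write_geojson",
]

_DECIMAL_COMMA = re.compile(r"^\s*-?\d+,\d+\s*$")


def _sniff_sep(path: Path, dialect: str | None) -> str:
    """Return the field separator: ',' or ';' (auto-sniffed unless given)."""
    if dialect is not None:
        if dialect not in {",", ";"}:
            raise SchemaError(f"unsupported dialect {dialect!r}; use ',' or ';'")
        return dialect
    head = Path(path).read_text().splitlines()[:5]
    sample = "\n".join(head)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;").delimiter
    except csv.Error:
        return ","


def _read_delimited(path, dialect: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path, dialect)
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _to_float(series: pd.Series, column: str) -> np.ndarray:
    """Parse a string column as float, rejecting decimal commas explicitly."""
    bad = series[series.str.match(_DECIMAL_COMMA)]
    if len(bad):
        raise ParseError(
            f"column {column!r} uses a decimal comma (e.g. {bad.iloc[0]!r}); "
            "write decimals with '.'"
        )
    try:
        return series.replace("", np.nan).astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"column {column!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# SampleTable


@dataclass
class SampleTable:
    """Sample registry: ID, collection-site label and projected UTM coordinates.

    Coordinates are in metres on a projected (UTM) grid, so plain
    Euclidean distances between samples are geographic distances in
    metres.
    """

    sample_ids: list[str]
    sites: list[str]
    easting: np.ndarray
    northing: np.ndarray

    def __post_init__(self) -> None:
        self.easting = np.asarray(self.easting, dtype=float)
        self.northing = np.asarray(self.northing, dtype=float)
        n = len(self.sample_ids)
        if not (len(self.sites) == n == len(self.easting) == len(self.northing)):
            raise ValidationError("sample table fields have inconsistent lengths")
        dup = pd.Index(self.sample_ids).duplicated()
        if dup.any():
            name = self.sample_ids[int(np.flatnonzero(dup)[0])]
            raise ValidationError(f"duplicate sample ID {name!r}")
        if not (np.isfinite(self.easting).all() and np.isfinite(self.northing).all()):
            raise ValidationError("coordinates must be finite")
        if n and min(pd.Series(self.sites).value_counts()) < 1:  # pragma: no cover
            raise ValidationError("every site needs at least one sample")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of easting/northing in metres."""
        return np.column_stack([self.easting, self.northing])

    @property
    def site_labels(self) -> list[str]:
        """Distinct sites in order of first appearance."""
        return list(dict.fromkeys(self.sites))

    def site_partition(self) -> "Partition":
        """Partition of samples induced by their collection site."""
        order = {s: i for i, s in enumerate(self.site_labels)}
        return Partition(
            list(self.sample_ids),
            np.array([order[s] for s in self.sites]),
            label_names={i: s for s, i in order.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "site": self.sites,
                "easting": self.easting,
                "northing": self.northing,
            }
        )


def read_sample_table(
    path,
    dialect: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> SampleTable:
    """Read a sample table CSV.

    ``columns`` maps the canonical names (``sample_id``, ``site``,
    ``easting``, ``northing``) to the headers actually used in the file,
    since deposited datasets differ in their header spelling.
    """
    df = _read_delimited(path, dialect)
    names = {k: k for k in ("sample_id", "site", "easting", "northing")}
    if columns:
        names.update(columns)
    for canonical, actual in names.items():
        if actual not in df.columns:
            raise SchemaError(f"missing column {actual!r} (for {canonical})")
    return SampleTable(
        sample_ids=df[names["sample_id"]].tolist(),
        sites=df[names["site"]].tolist(),
        easting=_to_float(df[names["easting"]], names["easting"]),
        northing=_to_float(df[names["northing"]], names["northing"]),
    )


def write_sample_table(table: SampleTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GenotypeTable


@dataclass
class GenotypeTable:
    """Codominant diploid genotypes: two allele sizes (bp) per locus per sample.

    ``alleles`` has shape (n_samples, n_loci, 2) with ``a1 <= a2``;
    entries under ``missing`` are meaningless placeholders.  A locus
    call is either fully present or fully missing — a single blank
    allele marks the whole call missing, because a lone size cannot
    distinguish a homozygote from a half-call.
    """

    sample_ids: list[str]
    loci: list[str]
    alleles: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, L = len(self.sample_ids), len(self.loci)
        if self.alleles.shape != (n, L, 2) or self.missing.shape != (n, L):
            raise ValidationError("genotype array shapes inconsistent with IDs/loci")
        if pd.Index(self.sample_ids).duplicated().any():
            raise ValidationError("duplicate sample IDs in genotype table")
        ok = ~self.missing
        if (self.alleles[ok] <= 0).any():
            raise ValidationError("allele sizes must be positive integers")
        # normalise a1 <= a2
        self.alleles = np.sort(self.alleles, axis=2)
        self.alleles[self.missing] = 0

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def calls(self, locus: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ((n, 2) allele sizes, (n,) typed mask) for one locus."""
        j = self.locus_index(locus)
        return self.alleles[:, j, :], ~self.missing[:, j]

    def subset(self, sample_ids: Sequence[str]) -> "GenotypeTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return GenotypeTable(
            list(sample_ids), list(self.loci), self.alleles[idx], self.missing[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: sample_id plus two columns per locus (blank = missing)."""
        cols: dict[str, list] = {"sample_id": list(self.sample_ids)}
        for j, locus in enumerate(self.loci):
            for k in (0, 1):
                vals = [
                    "" if self.missing[i, j] else int(self.alleles[i, j, k])
                    for i in range(self.n_samples)
                ]
                cols[f"{locus}_{k + 1}"] = vals
        return pd.DataFrame(cols)


_SUFFIX = re.compile(r"[._ -]?(1|2|a|b|A|B)$")


def _parse_allele(raw: str, row: int, column: str) -> int | None:
    raw = raw.strip()
    if raw in {"", "NA", "na", "NaN", "nan", "0", "-"}:
        return None if raw in {"", "NA", "na", "NaN", "nan", "-"} else 0
    try:
        val = float(raw)
    except ValueError:
        raise ParseError(f"non-integer allele size {raw!r} at row {row}, column {column!r}")
    if val != int(val):
        raise ParseError(f"non-integer allele size {raw!r} at row {row}, column {column!r}")
    return int(val)


def read_genotypes(path, dialect: str | None = None, layout: str = "wide") -> GenotypeTable:
    """Read a genotype CSV.

    ``wide`` layout (canonical, GenAlEx-style): a ``sample_id`` column
    (or first column) followed by two columns per locus in consecutive
    pairs; the locus name is the first column's header with any
    ``_1``-style suffix stripped.  ``long`` layout: columns
    (sample_id, locus, a1, a2).
    """
    df = _read_delimited(path, dialect)
    if layout == "long":
        return _genotypes_from_long(df)
    if layout != "wide":
        raise SchemaError(f"unknown layout {layout!r}")
    id_col = "sample_id" if "sample_id" in df.columns else df.columns[0]
    rest = [c for c in df.columns if c != id_col]
    if len(rest) % 2:
        raise SchemaError("wide genotype layout needs two columns per locus")
    sample_ids = df[id_col].tolist()
    loci, pairs = [], []
    for a, b in zip(rest[::2], rest[1::2]):
        loci.append(_SUFFIX.sub("", a))
        pairs.append((a, b))
    n, L = len(sample_ids), len(loci)
    alleles = np.zeros((n, L, 2), dtype=np.int64)
    missing = np.zeros((n, L), dtype=bool)
    for j, (ca, cb) in enumerate(pairs):
        for i in range(n):
            a = _parse_allele(str(df[ca].iloc[i]), i, ca)
            b = _parse_allele(str(df[cb].iloc[i]), i, cb)
            if a is None or b is None or a == 0 or b == 0:
                missing[i, j] = True
            else:
                alleles[i, j] = (a, b)
    return GenotypeTable(sample_ids, loci, alleles, missing)


def _genotypes_from_long(df: pd.DataFrame) -> GenotypeTable:
    for col in ("sample_id", "locus", "a1", "a2"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in long genotype layout")
    sample_ids = list(dict.fromkeys(df["sample_id"]))
    loci = list(dict.fromkeys(df["locus"]))
    n, L = len(sample_ids), len(loci)
    alleles = np.zeros((n, L, 2), dtype=np.int64)
    missing = np.ones((n, L), dtype=bool)
    srow = {s: i for i, s in enumerate(sample_ids)}
    lcol = {l: j for j, l in enumerate(loci)}
    for r, rec in df.iterrows():
        i, j = srow[rec["sample_id"]], lcol[rec["locus"]]
        a = _parse_allele(str(rec["a1"]), r, "a1")
        b = _parse_allele(str(rec["a2"]), r, "a2")
        if a and b:
            alleles[i, j] = (a, b)
            missing[i, j] = False
    return GenotypeTable(sample_ids, loci, alleles, missing)


def write_genotypes(table: GenotypeTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# QuantitativeMatrix


@dataclass
class QuantitativeMatrix:
    """Samples x named continuous variables (morphometrics or fatty-acid %).

    With ``percent=True`` values are constrained to [0, 100]; negative
    fatty-acid abundances are always rejected.
    """

    data: pd.DataFrame
    percent: bool = False
    replicate_counts: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate variable names")
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate sample IDs")
        if self.percent:
            vals = self.data.to_numpy()
            ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 100.0))
            if not ok.all():
                raise ValidationError("percentages must lie in [0, 100]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset(self, sample_ids: Sequence[str]) -> "QuantitativeMatrix":
        return QuantitativeMatrix(self.data.loc[list(sample_ids)], percent=self.percent)


def read_quantitative(path, dialect: str | None = None, percent: bool = False) -> QuantitativeMatrix:
    df = _read_delimited(path, dialect)
    id_col = "sample_id" if "sample_id" in df.columns else df.columns[0]
    out = pd.DataFrame(index=pd.Index(df[id_col], name="sample_id"))
    for col in df.columns:
        if col == id_col:
            continue
        out[col] = _to_float(df[col], col)
    return QuantitativeMatrix(out, percent=percent)


def write_quantitative(q: QuantitativeMatrix, path) -> None:
    q.data.to_csv(path, index_label="sample_id")


def aggregate_replicates(raw: pd.DataFrame, reducer=np.mean) -> QuantitativeMatrix:
    """Collapse replicate measurements to one value per sample x variable.

    ``raw`` holds one row per replicate: a ``sample_id`` column plus one
    column per variable.  Replicate counts are retained as metadata;
    a sample x variable cell with zero non-missing replicates becomes an
    explicit NaN and triggers a warning.
    """
    if "sample_id" not in raw.columns:
        raise SchemaError("replicate table needs a 'sample_id' column")
    grouped = raw.groupby("sample_id", sort=False)
    means = grouped.agg(lambda s: reducer(s.dropna().to_numpy()) if s.notna().any() else np.nan)
    counts = grouped.count()
    if (counts.to_numpy() == 0).any() or means.isna().to_numpy().any():
        warnings.warn("some sample x variable cells have zero replicates", stacklevel=2)
    return QuantitativeMatrix(means, replicate_counts=counts)


# ---------------------------------------------------------------------------
# DistanceMatrix


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal pairwise dissimilarities with a metric tag."""

    ids: list[str]
    values: np.ndarray
    metric: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match IDs")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-8):
            raise ValidationError("distance matrix diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def subset(self, sample_ids: Sequence[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in sample_ids])
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)], self.metric)


# ---------------------------------------------------------------------------
# Partition


@dataclass
class Partition:
    """Assignment of samples to unordered integer cluster labels."""

    ids: list[str]
    labels: np.ndarray
    label_names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (len(self.ids),):
            raise ValidationError("one label per sample required")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def sizes(self) -> dict[int, int]:
        uniq, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))

    def relabel(self) -> "Partition":
        """Contiguous labels 0..k-1 in order of first appearance."""
        mapping: dict[int, int] = {}
        new = np.empty_like(self.labels)
        for i, lab in enumerate(self.labels):
            mapping.setdefault(int(lab), len(mapping))
            new[i] = mapping[int(lab)]
        return Partition(list(self.ids), new)

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for s, lab in zip(self.ids, self.labels):
            out.setdefault(int(lab), []).append(s)
        return out

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=pd.Index(self.ids, name="sample_id"), name="cluster")


# ---------------------------------------------------------------------------
# MergeTree


@dataclass
class MergeTree:
    """Agglomerative dendrogram: scipy linkage rows + leaf IDs.

    ``linkage`` follows scipy's convention: row i merges clusters
    Z[i,0] and Z[i,1] at height Z[i,2] into cluster n+i.
    """

    ids: list[str]
    linkage: np.ndarray

    def __post_init__(self) -> None:
        self.linkage = np.asarray(self.linkage, dtype=float)
        n = len(self.ids)
        if self.linkage.shape != (max(n - 1, 0), 4):
            raise ValidationError("linkage must have n-1 rows for n leaves")
        if n > 1 and (self.linkage[:, 2] < -1e-12).any():
            raise ValidationError("merge heights must be non-negative")

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> Partition:
        """Partition into exactly k clusters (nested cuts are refinements)."""
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k={k} out of range 1..{n}")
        labels = _hierarchy.cut_tree(self.linkage, n_clusters=k).ravel()
        return Partition(list(self.ids), labels)

    def to_newick(self) -> str:
        """Newick string under the midpoint (cophenetic) convention.

        A node created at merge height h sits at height h/2, so the
        path length between two leaves equals the height at which they
        merge.
        """
        root = _hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            height = 0.0 if node.is_leaf() else node.dist / 2.0
            branch = parent_height - height
            if node.is_leaf():
                return f"{self.ids[node.id]}:{branch:g}"
            left = rec(node.left, height)
            right = rec(node.right, height)
            return f"({left},{right}):{branch:g}"

        if self.n_leaves == 1:
            return f"{self.ids[0]}:0;"
        body = rec(root, root.dist / 2.0)
        # strip the root's zero-length branch
        return body.rsplit(":", 1)[0] + ";"


def write_newick(tree: MergeTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# GeoJSON export (replaces shapefile output; see docs for conversion notes)


def points_geojson(samples: SampleTable, partition: Partition | None = None) -> dict:
    """GeoJSON FeatureCollection of sample points (projected coordinates).

    Coordinates are emitted as-is (UTM metres); consumers that need
    WGS84 should reproject, which is out of scope here.
    """
    labels = None
    if partition is not None:
        pos = {s: int(l) for s, l in zip(partition.ids, partition.labels)}
        labels = [pos[s] for s in samples.sample_ids]
    feats = []
    for i, sid in enumerate(samples.sample_ids):
        props = {"sample_id": sid, "site": samples.sites[i]}
        if labels is not None:
            props["cluster"] = labels[i]
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(samples.easting[i]), float(samples.northing[i])],
                },
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def write_geojson(samples: SampleTable, path, partition: Partition | None = None) -> None:
    Path(path).write_text(json.dumps(points_geojson(samples, partition), indent=1))
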