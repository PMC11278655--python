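"""Tabular and graph IO for OTU count tables, taxonomy, metadata and networks.

All tabular files are tab-separated UTF-8 text with one header row and one
identifier column; lines starting with ``#`` are ignored.  Orientation of
count tables on disk is declared explicitly by the caller — it is never
guessed from the shape, because a silently transposed table is the classic
pipeline bug in this field.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

ORIENT_SAMPLES = "samples_as_rows"
ORIENT_OTUS = "otus_as_rows"


class TableFormatError(ValueError):
    """Raised when an input file violates the declared table contract."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique())
        raise TableFormatError(f"duplicate {what} identifier(s): {dups}")


@dataclasses.dataclass
class CountTable:
    """Integer abundance matrix, samples x OTUs.

    ``data`` is indexed by sample id with one column per OTU.  Counts are
    validated to be nonnegative integers and, unless ``allow_empty_samples``
    was requested at construction, every sample must have a positive total
    (downstream diversity indices divide by row totals).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "OTU")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise TableFormatError("counts must be integers")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise TableFormatError(
                f"negative count at sample {self.data.index[i]!r}, "
                f"OTU {self.data.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.data.sum(axis=1)
        if (totals == 0).any():
            empty = list(self.data.index[totals == 0])
            raise TableFormatError(f"sample(s) with zero total counts: {empty}")
        return self.data.div(totals, axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        ids = list(sample_ids)
        missing = set(ids) - set(self.data.index)
        if missing:
            raise KeyError(f"unknown sample id(s): {sorted(missing)}")
        return CountTable(self.data.loc[ids].copy())

    def drop_empty_samples(self) -> "CountTable":
        keep = self.data.sum(axis=1) > 0
        return CountTable(self.data.loc[keep].copy())


@dataclasses.dataclass
class TaxonomyMap:
    """OTU -> rank lineage table; missing ranks are empty strings."""

    ranks: pd.DataFrame  # indexed by otu_id, columns = RANKS

    def __post_init__(self) -> None:
        _check_unique(self.ranks.index, "OTU")
        missing = [r for r in RANKS if r not in self.ranks.columns]
        if missing:
            raise TableFormatError(f"taxonomy missing rank column(s): {missing}")
        self.ranks = self.ranks[list(RANKS)].fillna("").astype(str)
        for col in RANKS:
            if self.ranks[col].str.contains("\t").any():
                raise TableFormatError(f"tab character inside rank {col!r}")

    def rank_of(self, otu_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; valid ranks: {RANKS}")
        if otu_id not in self.ranks.index:
            return ""
        return str(self.ranks.loc[otu_id, rank])


@dataclasses.dataclass
class SampleMetadata:
    """Per-sample treatment label plus numeric soil properties.

    ``treatment`` is a categorical series over a declared finite label set;
    ``properties`` holds the measured soil variables (pH unitless, the rest
    in mass-per-mass concentrations) as finite floats.
    """

    treatment: pd.Series
    properties: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.treatment.index, "sample")
        if not self.treatment.index.equals(self.properties.index):
            raise TableFormatError("treatment and properties sample ids differ")
        vals = self.properties.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise TableFormatError("non-finite soil property value")
        self.treatment = self.treatment.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.treatment.index)

    @property
    def treatment_levels(self) -> list[str]:
        seen: list[str] = []
        for t in self.treatment:
            if t not in seen:
                seen.append(t)
        return seen

    def samples_of(self, *treatments: str) -> list[str]:
        unknown = set(treatments) - set(self.treatment)
        if unknown:
            raise KeyError(f"unknown treatment label(s): {sorted(unknown)}")
        mask = self.treatment.isin(treatments)
        return list(self.treatment.index[mask])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    df.index = pd.Index([str(i) for i in df.index], name=None)
    df.columns = pd.Index([str(c) for c in df.columns], name=None)
    return df


def _as_graph(net) -> nx.Graph:
    """Accept either a bare networkx graph or an object wrapping one."""
    if isinstance(net, nx.Graph):
        return net
    return net.graph


def read_count_table(
    path: str | Path,
    orientation: str = ORIENT_SAMPLES,
    allow_empty_samples: bool = False,
) -> CountTable:
    """Read a tab-separated count table, returning samples x OTUs.

    ``orientation`` declares how the file is laid out (``samples_as_rows``
    or ``otus_as_rows``); the returned table is always samples x OTUs.
    Samples with zero total are rejected unless ``allow_empty_samples``.
    """
    if orientation not in (ORIENT_SAMPLES, ORIENT_OTUS):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_tsv(path)
    _check_unique(raw.index, "row")
    _check_unique(raw.columns, "column")
    try:
        num = raw.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise TableFormatError(f"non-numeric cell in {path}: {exc}") from exc
    arr = num.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise TableFormatError(
            f"non-integer count at row {num.index[i]!r}, column {num.columns[j]!r}"
        )
    num = num.round().astype(np.int64)
    if orientation == ORIENT_OTUS:
        num = num.T
    table = CountTable(num)
    totals = table.data.sum(axis=1)
    if (totals == 0).any() and not allow_empty_samples:
        empty = list(table.data.index[totals == 0])
        raise TableFormatError(
            f"sample(s) with zero total counts: {empty} "
            "(pass allow_empty_samples=True to keep them)"
        )
    return table


def write_count_table(
    table: CountTable, path: str | Path, orientation: str = ORIENT_SAMPLES
) -> None:
    if orientation not in (ORIENT_SAMPLES, ORIENT_OTUS):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = table.data if orientation == ORIENT_SAMPLES else table.data.T
    df.to_csv(path, sep="\t", index_label="id")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    return TaxonomyMap(_read_tsv(path))


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    tax.ranks.to_csv(path, sep="\t", index_label="otu_id")


def read_metadata(path: str | Path, treatment_column: str = "treatment") -> SampleMetadata:
    raw = _read_tsv(path)
    if treatment_column not in raw.columns:
        raise TableFormatError(f"metadata lacks a {treatment_column!r} column")
    treatment = raw[treatment_column].astype(str)
    props = raw.drop(columns=[treatment_column]).apply(pd.to_numeric)
    return SampleMetadata(treatment=treatment, properties=props)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    out = pd.concat([meta.treatment.rename("treatment"), meta.properties], axis=1)
    out.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# rank aggregation
# ---------------------------------------------------------------------------

UNCLASSIFIED = "Unclassified"


def aggregate_by_rank(table: CountTable, tax: TaxonomyMap, rank: str) -> CountTable:
    """Sum OTU counts into taxa sharing ``rank``; unmapped OTUs go to
    ``Unclassified``.  Output columns are ordered by descending total count,
    ties broken by name, so the result is deterministic.
    """
    if rank not in RANKS:
        raise KeyError(f"unknown rank {rank!r}; valid ranks: {RANKS}")
    labels = []
    for otu in table.otu_ids:
        name = tax.rank_of(otu, rank)
        labels.append(name if name else UNCLASSIFIED)
    agg = table.data.T.groupby(pd.Index(labels, name=rank)).sum().T
    order = sorted(agg.columns, key=lambda c: (-agg[c].sum(), c))
    return CountTable(agg[order])


# ---------------------------------------------------------------------------
# network IO (GraphML and weighted edge list)
# ---------------------------------------------------------------------------

FORMAT_GRAPHML = "graphml"
FORMAT_EDGELIST = "edgelist"


def write_network(net, path: str | Path, fmt: str = FORMAT_GRAPHML) -> None:
    """Write a co-occurrence network (or bare ``networkx.Graph``).

    GraphML keeps every node/edge attribute; the edge list is three
    tab-separated columns (source, target, signed weight) with weights
    printed to 17 significant digits so a round trip is lossless.
    """
    graph = _as_graph(net)
    if fmt == FORMAT_GRAPHML:
        nx.write_graphml(graph, str(path))
    elif fmt == FORMAT_EDGELIST:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, data in sorted(graph.edges(data=True)):
                w = float(data.get("weight", 1.0))
                fh.write(f"{u}\t{v}\t{w:.17g}\n")
    else:
        raise ValueError(f"unsupported network format {fmt!r}")


def read_network(path: str | Path, fmt: str = FORMAT_GRAPHML) -> nx.Graph:
    if fmt == FORMAT_GRAPHML:
        return nx.read_graphml(str(path))
    if fmt == FORMAT_EDGELIST:
        graph = nx.Graph()
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if header.strip() != "source\ttarget\tweight":
                raise TableFormatError(f"not a weighted edge list: {path}")
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                u, v, w = line.rstrip("\n").split("\t")
                graph.add_edge(u, v, weight=float(w))
        return graph
    raise ValueError(f"unsupported network format {fmt!r}")
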