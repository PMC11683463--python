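"""Shared data model and tabular/graph I/O.

Tables are tab-separated with a mandatory header row; the canonical OTU-table
orientation is taxa as rows, samples as columns (``orientation="taxa-rows"``).
Missing cells are illegal — they are never imputed, because silent imputation
would corrupt downstream correlation estimates. Taxon and sample identifiers
are matched by exact, case-sensitive string equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from phodnet.errors import FormatError, ValidationError

#: Recognized soil-property names (pH unitless; SOC/TN/TP/TK in g/kg;
#: AN/AP/AK in mg/kg).
SOIL_PROPERTY_NAMES = ("pH", "SOC", "TN", "TP", "TK", "AN", "AP", "AK")


@dataclass
class OtuTable:
    """Taxon-by-sample count (or proportion) matrix.

    Attributes
    ----------
    taxon_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    counts : ndarray of shape (n_taxa, n_samples)
        Non-negative abundances.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"({len(self.taxon_ids)} taxa, {len(self.sample_ids)} samples)"
            )
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise FormatError("duplicate taxon ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("non-finite abundance values")
        if np.any(self.counts < 0):
            raise ValidationError("negative abundance values")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        """Column-subset the table, preserving taxon order."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(list(self.taxon_ids), list(sample_ids), self.counts[:, idx])

    def drop_empty_taxa(self) -> "OtuTable":
        """Remove taxa with no observations in any retained sample."""
        keep = self.counts.sum(axis=1) > 0
        return OtuTable(
            [t for t, k in zip(self.taxon_ids, keep) if k],
            list(self.sample_ids),
            self.counts[keep],
        )


@dataclass(frozen=True)
class SampleMetadata:
    """One sequencing sample: treatment code, sampling year, field replicate."""

    sample_id: str
    treatment: str
    year: int
    replicate: int

    def __post_init__(self) -> None:
        if self.year < 0:
            raise ValidationError(f"negative year for sample {self.sample_id}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1 for sample {self.sample_id}")


@dataclass(frozen=True)
class SoilProperties:
    """Per-sample soil chemistry: a mapping from property name to value."""

    sample_id: str
    values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if name not in SOIL_PROPERTY_NAMES:
                raise ValidationError(f"unknown soil property {name!r}")
            if not np.isfinite(v):
                raise ValidationError(f"non-finite value for {name} in {self.sample_id}")


@dataclass
class SignedNetwork:
    """Undirected co-occurrence network whose edges carry a correlation and a sign.

    Edges are (node_a, node_b, weight, sign) with sign = sign(weight); no
    self-loops, no duplicate pairs.
    """

    node_ids: list[str]
    edges: list[tuple[str, str, float, int]]

    def __post_init__(self) -> None:
        nodes = set(self.node_ids)
        if len(nodes) != len(self.node_ids):
            raise ValidationError("duplicate node ids")
        seen: set[frozenset[str]] = set()
        for a, b, w, s in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on {a}")
            if a not in nodes or b not in nodes:
                raise ValidationError(f"edge endpoint not in node set: {a}-{b}")
            key = frozenset((a, b))
            if key in seen:
                raise ValidationError(f"duplicate edge {a}-{b}")
            seen.add(key)
            if w == 0 or not (-1.0 <= w <= 1.0):
                raise ValidationError(f"edge weight {w} outside [-1,1]\\{{0}}")
            if s != (1 if w > 0 else -1):
                raise ValidationError(f"sign {s} inconsistent with weight {w}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.Graph:
        """networkx view with 'weight' and 'sign' edge attributes."""
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for a, b, w, s in self.edges:
            g.add_edge(a, b, weight=w, sign=s)
        return g

    @classmethod
    def from_graph(cls, g: nx.Graph) -> "SignedNetwork":
        edges = []
        for a, b, data in g.edges(data=True):
            w = float(data["weight"])
            s = int(data.get("sign", 1 if w > 0 else -1))
            edges.append((str(a), str(b), w, s))
        return cls([str(n) for n in g.nodes], edges)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except Exception as exc:  # malformed file, wrong separator count, ...
        raise FormatError(f"cannot parse TSV {path}: {exc}") from exc
    return df


def read_otu_table(path: str | Path, orientation: str = "taxa-rows") -> OtuTable:
    """Read a TSV abundance table into the canonical taxa × samples orientation.

    Parameters
    ----------
    path : path
        Tab-separated file; first column holds row ids, header row column ids.
    orientation : {"taxa-rows", "samples-rows"}
        Layout of the file on disk. ``samples-rows`` input is transposed.
    """
    if orientation not in ("taxa-rows", "samples-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"duplicate ids in {path}")
    if df.isna().any().any():
        raise FormatError(f"missing cells in {path}; imputation is not supported")
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    if orientation == "samples-rows":
        values = values.T
        taxa, samples = list(df.columns), list(df.index)
    else:
        taxa, samples = list(df.index), list(df.columns)
    return OtuTable([str(t) for t in taxa], [str(s) for s in samples], values)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the sample-metadata TSV (sample_id, treatment, year, replicate)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse metadata {path}: {exc}") from exc
    required = ["sample_id", "treatment", "year", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"metadata {path} missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dupes}")
    records = []
    for _, row in df.iterrows():
        try:
            year = int(row["year"])
            rep = int(row["replicate"])
        except ValueError as exc:
            raise FormatError(f"non-integer year/replicate in {path}: {exc}") from exc
        records.append(SampleMetadata(str(row["sample_id"]), str(row["treatment"]), year, rep))
    return records


def write_metadata(records: Iterable[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [(r.sample_id, r.treatment, r.year, r.replicate) for r in records],
        columns=["sample_id", "treatment", "year", "replicate"],
    ).to_csv(path, sep="\t", index=False)


def read_soil_properties(path: str | Path) -> list[SoilProperties]:
    """Read the soil-property TSV (sample_id plus any declared property columns)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot parse soil table {path}: {exc}") from exc
    if "sample_id" not in df.columns:
        raise FormatError(f"soil table {path} missing sample_id column")
    props = [c for c in df.columns if c != "sample_id"]
    unknown = [c for c in props if c not in SOIL_PROPERTY_NAMES]
    if unknown:
        raise FormatError(f"unknown soil properties in {path}: {unknown}")
    return [
        SoilProperties(str(row["sample_id"]), {p: float(row[p]) for p in props})
        for _, row in df.iterrows()
    ]


def write_soil_properties(records: Iterable[SoilProperties], path: str | Path) -> None:
    records = list(records)
    props = [p for p in SOIL_PROPERTY_NAMES if any(p in r.values for r in records)]
    rows = [[r.sample_id] + [r.values.get(p, float("nan")) for p in props] for r in records]
    pd.DataFrame(rows, columns=["sample_id"] + props).to_csv(path, sep="\t", index=False)


def write_network(net: SignedNetwork, path: str | Path, format: str = "graphml") -> None:
    """Write a signed network as GraphML or a CSV edge list.

    The edge list has columns ``source,target,weight,sign``; GraphML stores
    weight and sign as edge attributes. Both round-trip through
    :func:`read_network` exactly.
    """
    if format == "graphml":
        nx.write_graphml(net.to_graph(), path)
    elif format == "edgelist":
        pd.DataFrame(net.edges, columns=["source", "target", "weight", "sign"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> SignedNetwork:
    if format == "graphml":
        g = nx.read_graphml(path)
        return SignedNetwork.from_graph(g)
    if format == "edgelist":
        df = pd.read_csv(path)
        required = ["source", "target", "weight", "sign"]
        if list(df.columns) != required:
            raise FormatError(f"edge list {path} must have columns {required}")
        edges = [
            (str(r.source), str(r.target), float(r.weight), int(r.sign))
            for r in df.itertuples()
        ]
        nodes = sorted({n for a, b, _, _ in edges for n in (a, b)})
        return SignedNetwork(nodes, edges)
    raise ValueError(f"unknown network format {format!r}")


def relative_abundance(table: OtuTable) -> OtuTable:
    """Column-normalize counts to proportions (each sample sums to 1).

    Raises :class:`ValidationError` if any sample column is entirely zero.
    Idempotent: applying it to an already-normalized table is a no-op.
    """
    sums = table.counts.sum(axis=0)
    if np.any(sums <= 0):
        bad = [s for s, t in zip(table.sample_ids, sums) if t <= 0]
        raise ValidationError(f"all-zero sample columns: {bad}")
    return OtuTable(list(table.taxon_ids), list(table.sample_ids), table.counts / sums)
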