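"""Readers and writers for OTU tables, sample metadata and networks.

The on-disk formats are deliberately plain: delimited text for tables,
GraphML (canonical), GML or an edge-list TSV for graphs.  Everything read
is validated against the domain invariants before it enters the pipeline.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ParseError, SchemaError, ValidationError

logger = logging.getLogger("rhizonet")

TAXONOMY_COLUMN_NAMES = ("taxonomy", "Taxonomy", "lineage", "Lineage", "taxon_lineage")

#: metadata columns every analysis needs
REQUIRED_METADATA_COLUMNS = ("sample_id", "treatment", "nematode_added", "bacterivore_density")

#: the 8 factorial treatment codes; the trailing N marks nematode addition
TREATMENT_CODES = ("FO", "FOE", "FOP", "FOPE", "FON", "FOEN", "FOPN", "FOPEN")


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------

@dataclass
class OtuTable:
    """Taxa x samples abundance matrix with optional taxonomy strings.

    ``counts`` is a DataFrame indexed by taxon id with sample ids as
    columns.  ``is_relative`` flags tables whose columns each sum to one
    (relative abundances) rather than integer read counts.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None
    is_relative: bool = False

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon ids: {dupes}")
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("abundance matrix contains non-numeric entries")
        if np.isnan(values).any():
            raise ValidationError("abundance matrix contains missing values")
        if (values < 0).any():
            bad = self.counts.columns[(values < 0).any(axis=0)].tolist()
            raise ValidationError(f"negative abundances in samples: {bad}")
        if self.is_relative:
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValidationError("is_relative set but sample sums differ from 1")
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def relative(self) -> "OtuTable":
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            bad = totals.index[totals == 0].tolist()
            raise ValidationError(f"samples with zero total abundance: {bad}")
        return OtuTable(self.counts / totals, taxonomy=self.taxonomy, is_relative=True)


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_otu_table(path, orientation: str = "auto") -> OtuTable:
    """Read a delimited OTU table.

    First column holds row ids, header row holds column ids; an optional
    taxonomy column is recognised by name.  ``orientation`` is one of
    ``taxa_rows``, ``taxa_cols`` or ``auto``; automatic detection is only
    possible when a taxonomy column is present (taxonomy always attaches
    to taxa).
    """
    if orientation not in ("auto", "taxa_rows", "taxa_cols"):
        raise ParameterError(f"unknown orientation {orientation!r}")
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise SchemaError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        rows = list(csv.reader(fh, delimiter=delim))
    header = rows[0]
    width = len(header)
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ParseError(
                f"{path}: line {lineno} has {len(row)} fields, expected {width}"
            )
    df = pd.DataFrame(rows[1:], columns=header)
    df = df.set_index(header[0])

    tax_col = next((c for c in df.columns if c in TAXONOMY_COLUMN_NAMES), None)
    if orientation == "auto":
        if tax_col is None:
            raise ParameterError(
                "orientation='auto' requires a taxonomy column; pass "
                "'taxa_rows' or 'taxa_cols' explicitly"
            )
        orientation = "taxa_rows"

    taxonomy = None
    if tax_col is not None:
        taxonomy = df[tax_col].astype(str)
        df = df.drop(columns=[tax_col])

    try:
        counts = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric abundance entry ({exc})") from exc

    if orientation == "taxa_cols":
        counts = counts.T
        if taxonomy is not None:  # taxonomy row attached to taxa in the header
            taxonomy = taxonomy.reindex(counts.index)

    counts.index.name = None
    counts.columns.name = None
    sums = counts.to_numpy().sum(axis=0)
    is_relative = bool(len(sums) and np.allclose(sums, 1.0, atol=1e-9))
    return OtuTable(counts, taxonomy=taxonomy, is_relative=is_relative)


def write_otu_table(table: OtuTable, path, sep: str = "\t") -> None:
    df = table.counts.copy()
    if table.taxonomy is not None:
        df["taxonomy"] = table.taxonomy
    df.index.name = "taxon_id"
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f"}

_NUMERIC_METADATA = ("bacterivore_density", "total_nematode_density", "phoD_abundance")


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"cannot interpret {value!r} as boolean")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read a sample metadata table.

    Required columns: sample_id, treatment, nematode_added,
    bacterivore_density.  Unknown columns are preserved as optional
    covariates (soil chemistry etc.).  Returns a DataFrame indexed by
    sample_id.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise SchemaError(f"{path}: empty or undelimited metadata file") from exc
    if df.empty:
        raise SchemaError(f"{path}: metadata table has no rows")
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample ids {dupes}")

    df = df.set_index("sample_id")
    df["nematode_added"] = df["nematode_added"].map(_parse_bool)
    for col in _NUMERIC_METADATA:
        if col not in df.columns:
            continue
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-numeric {col} ({exc})") from exc
        if (df[col].dropna() < 0).any():
            raise ValidationError(f"{path}: negative values in {col}")
    return df


def write_sample_metadata(metadata: pd.DataFrame, path, sep: str = "\t") -> None:
    metadata.to_csv(path, sep=sep, index_label="sample_id")


def align_metadata(table: OtuTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Check the one-row-per-sample invariant and return metadata in table order."""
    missing = [s for s in table.sample_ids if s not in metadata.index]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")
    return metadata.loc[table.sample_ids]


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("graphml", "gml", "tsv")


def _clean_attributes(graph: nx.Graph) -> nx.Graph:
    """GraphML/GML cannot encode None; drop such attributes on a copy."""
    g = graph.copy()
    for _, data in g.nodes(data=True):
        for k in [k for k, v in data.items() if v is None]:
            del data[k]
    for _, _, data in g.edges(data=True):
        for k in [k for k, v in data.items() if v is None]:
            del data[k]
    return g


def write_network(network: nx.Graph, path, format: str = "graphml") -> None:
    """Serialise a network with its node/edge attributes.

    GraphML is the canonical format (full attribute round-trip); GML and a
    plain edge-list TSV (source, target, r, sign) are conveniences.
    """
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ParameterError(f"unsupported network format {format!r}; use one of {NETWORK_FORMATS}")
    g = _clean_attributes(network)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "gml":
        nx.write_gml(g, path)
    else:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tr\tsign\n")
            for u, v, data in g.edges(data=True):
                r = data.get("r", float("nan"))
                sign = data.get("sign", 1 if r >= 0 else -1)
                fh.write(f"{u}\t{v}\t{r:.10g}\t{sign:+d}\n")


def read_network(path, format: str = "graphml") -> nx.Graph:
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ParameterError(f"unsupported network format {format!r}; use one of {NETWORK_FORMATS}")
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "gml":
        return nx.read_gml(path)
    g = nx.Graph()
    df = pd.read_csv(path, sep="\t")
    for _, row in df.iterrows():
        g.add_edge(str(row["source"]), str(row["target"]), r=float(row["r"]), sign=int(row["sign"]))
    return g
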