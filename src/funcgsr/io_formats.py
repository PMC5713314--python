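"""Readers and writers for the standard formats the pipeline touches.

Formats handled here:

* GMT gene set collections (MSigDB dialect: name TAB description TAB genes...),
* tabular expression matrices (TSV, genes in rows, first column ``gene``) with a
  companion sample-label TSV (columns ``sample``, ``group``, ``disease``,
  ``tissue``, ``platform``),
* Gene Ontology parent-child DAGs, either as OBO-subset stanzas or as a
  two-column child TAB parent edge list (only ``is_a`` relations are used),
* GML network output.

All parsers are strict: every violation of a container invariant is rejected
with an error that locates the offending line, sample or gene rather than being
silently coerced.  Counts read are logged at INFO level.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger("funcgsr")


class ParseError(ValueError):
    """Raised when an input file violates its format or a container invariant."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with per-sample annotations.

    ``sample_labels`` maps every sample id to a dict with keys ``group``
    (``"case"`` or ``"control"``), ``disease`` and ``tissue``.  Datasets with
    missing values are rejected outright: the pipeline integrates cohorts on
    common genes and has no imputation step.
    """

    platform_id: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_labels: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.isnan(self.values).any():
            r, c = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing value at gene {self.gene_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        missing = [s for s in self.sample_ids if s not in self.sample_labels]
        if missing:
            raise ValueError(f"samples without labels: {missing[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def groups(self) -> pd.Series:
        return pd.Series(
            [self.sample_labels[s]["group"] for s in self.sample_ids],
            index=self.sample_ids,
        )

    def subset_samples(self, keep: Sequence[str]) -> "ExpressionDataset":
        keep = list(keep)
        idx = [self.sample_ids.index(s) for s in keep]
        return ExpressionDataset(
            platform_id=self.platform_id,
            gene_ids=list(self.gene_ids),
            sample_ids=keep,
            values=self.values[:, idx],
            sample_labels={s: dict(self.sample_labels[s]) for s in keep},
        )


@dataclass
class GeneSetCollection:
    """Ordered, named gene sets (GO term name, description, member symbols)."""

    sets: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, entry in self.sets.items():
            genes = entry["genes"]
            if len(set(genes)) != len(genes):
                raise ValueError(f"set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def genes_of(self, name: str) -> list[str]:
        return list(self.sets[name]["genes"])


@dataclass
class GoDag:
    """A parent-child GO hierarchy restricted to ``is_a`` edges.

    ``edges`` holds (child, parent) pairs; the graph must be acyclic and every
    edge endpoint must be a known term.
    """

    terms: dict[str, str]
    edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for child, parent in self.edges:
            if child not in self.terms:
                raise ValueError(f"edge references unknown child term {child!r}")
            if parent not in self.terms:
                raise ValueError(f"edge references unknown parent term {parent!r}")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"GO graph contains a cycle: {cycle}")

    def to_networkx(self) -> nx.DiGraph:
        """Child -> parent directed graph over all terms."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.edges)
        return g

    def ancestors_or_self(self, term: str) -> set[str]:
        g = self.to_networkx()
        return {term} | nx.descendants(g, term)  # child->parent, so "up" = descendants


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (one gene set per line: name, description, genes...).

    Duplicate genes within a line are removed keeping the first occurrence;
    duplicate set names across lines are an error.
    """
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = {"description": description, "genes": genes}
    logger.info("read %d gene sets from %s", len(sets), path)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, entry in collection.sets.items():
            fh.write("\t".join([name, entry["description"], *entry["genes"]]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices + labels
# ---------------------------------------------------------------------------

_LABEL_COLUMNS = ("sample", "group", "disease", "tissue", "platform")


def read_expression(path: str | Path, label_path: str | Path) -> ExpressionDataset:
    """Read a TSV expression table (first column ``gene``) plus a label TSV.

    Any missing-value token in the matrix is rejected with its coordinates;
    every sample in the matrix header must appear in the label file.
    """
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if table.index.name != "gene":
        raise ParseError(f"{path}: first column must be named 'gene', got {table.index.name!r}")
    values = np.empty(table.shape, dtype=float)
    for j, col in enumerate(table.columns):
        converted = pd.to_numeric(table[col], errors="coerce")
        bad = converted.index[converted.isna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric or missing value at gene {bad[0]!r}, sample {col!r}"
            )
        values[:, j] = converted.to_numpy()

    labels = pd.read_csv(label_path, sep="\t", dtype=str)
    missing_cols = [c for c in _LABEL_COLUMNS if c not in labels.columns]
    if missing_cols:
        raise ParseError(f"{label_path}: missing columns {missing_cols}")
    if labels["sample"].duplicated().any():
        dup = labels.loc[labels["sample"].duplicated(), "sample"].iloc[0]
        raise ParseError(f"{label_path}: duplicate sample {dup!r}")
    label_map = labels.set_index("sample").to_dict(orient="index")

    absent = [s for s in table.columns if s not in label_map]
    if absent:
        raise ParseError(f"{label_path}: no label row for sample {absent[0]!r}")

    platforms = {label_map[s]["platform"] for s in table.columns}
    platform_id = platforms.pop() if len(platforms) == 1 else "mixed"
    sample_labels = {
        s: {k: label_map[s][k] for k in ("group", "disease", "tissue")}
        for s in table.columns
    }
    ds = ExpressionDataset(
        platform_id=platform_id,
        gene_ids=list(table.index),
        sample_ids=list(table.columns),
        values=values,
        sample_labels=sample_labels,
    )
    logger.info(
        "read expression matrix %s: %d genes x %d samples", path, ds.n_genes, ds.n_samples
    )
    return ds


def write_expression(ds: ExpressionDataset, path: str | Path, label_path: str | Path) -> None:
    frame = pd.DataFrame(ds.values, index=pd.Index(ds.gene_ids, name="gene"), columns=ds.sample_ids)
    frame.to_csv(path, sep="\t", float_format="%.10g")
    rows = []
    for s in ds.sample_ids:
        lab = ds.sample_labels[s]
        rows.append(
            {
                "sample": s,
                "group": lab["group"],
                "disease": lab["disease"],
                "tissue": lab["tissue"],
                "platform": ds.platform_id,
            }
        )
    pd.DataFrame(rows, columns=list(_LABEL_COLUMNS)).to_csv(label_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GO DAG (OBO subset or edge list)
# ---------------------------------------------------------------------------


def read_godag(path: str | Path) -> GoDag:
    """Read a GO hierarchy from an OBO file or a 2-column child->parent TSV.

    The dialect is sniffed from the first non-blank line: OBO files open with a
    header key or a ``[Term]`` stanza.  Only ``is_a`` relations are retained.
    """
    with open(path) as fh:
        text = fh.read()
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    if first.startswith("[") or ":" in first.split("\t")[0] and "\t" not in first:
        return _read_obo(path)
    return _read_edge_list(path, text)


def _read_obo(path: str | Path) -> GoDag:
    graph = obonet.read_obo(path)
    terms = {n: (data.get("name") or n) for n, data in graph.nodes(data=True)}
    edges = [
        (child, parent)
        for child, parent, key in graph.edges(keys=True)
        if key == "is_a"
    ]
    dangling = sorted({p for _, p in edges} - set(terms))
    if dangling:
        raise ParseError(f"{path}: dangling parent id {dangling[0]!r}")
    dag = GoDag(terms=terms, edges=edges)
    logger.info("read OBO DAG %s: %d terms, %d is_a edges", path, len(terms), len(edges))
    return dag


def _read_edge_list(path: str | Path, text: str) -> GoDag:
    edges: list[tuple[str, str]] = []
    terms: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected 2 tab-separated fields (child, parent)"
            )
        child, parent = fields[0].strip(), fields[1].strip()
        terms.setdefault(child, child)
        terms.setdefault(parent, parent)
        edges.append((child, parent))
    try:
        dag = GoDag(terms=terms, edges=edges)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    logger.info("read edge-list DAG %s: %d terms, %d edges", path, len(terms), len(edges))
    return dag


def write_godag(dag: GoDag, path: str | Path) -> None:
    """Write the DAG in the edge-list dialect (child TAB parent)."""
    with open(path, "w") as fh:
        for child, parent in dag.edges:
            fh.write(f"{child}\t{parent}\n")


# ---------------------------------------------------------------------------
# GML
# ---------------------------------------------------------------------------


def write_gml(
    nodes: Sequence[tuple[str, Mapping]],
    edges: Sequence[tuple[str, str, float]],
    path: str | Path,
) -> None:
    """Write a weighted undirected graph in GML.

    Every edge endpoint must be among ``nodes``; edge weights are stored under
    the ``weight`` attribute.  The written file round-trips through
    :func:`read_gml` to identical node and edge sets.
    """
    known = {nid for nid, _ in nodes}
    for u, v, _w in edges:
        if u not in known or v not in known:
            missing = u if u not in known else v
            raise ValueError(f"edge endpoint {missing!r} is not a declared node")
    g = nx.Graph()
    for nid, attrs in nodes:
        g.add_node(nid, **{k: _gml_safe(v) for k, v in attrs.items()})
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w))
    nx.write_gml(g, str(path))


def read_gml(path: str | Path) -> nx.Graph:
    return nx.read_gml(str(path))


def _gml_safe(value):
    if isinstance(value, (bool, np.bool_)):
        return int(value)
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value


# ---------------------------------------------------------------------------
# Config / logging helpers (used by the CLI)
# ---------------------------------------------------------------------------


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config file; an absent path yields an empty config."""
    import yaml

    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: top-level YAML must be a mapping")
    return cfg
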