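"""Domain types and tabular/network I/O.

The toolkit revolves around four containers: a :class:`ProteinCatalog`
(the set of proteins under study, with family / regulatory-activity /
functional-term annotations), an :class:`InteractionNetwork` (an
undirected, unweighted PPI graph), an :class:`ExpressionMatrix`
(genes x samples), and a :class:`ProbabilisticNetwork` (a symmetric
matrix of posterior interaction probabilities, ``pin``).

All tabular inputs are UTF-8, tab-separated files; lines starting with
``#`` are comments. Identifiers are case-sensitive gene symbols and are
never remapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FAMILIES = frozenset({"SR", "hnRNP", "snRNP", "LSm", "other"})
ACTIVITIES = frozenset({"activator", "repressor", "unknown"})

EXPORT_FORMATS = ("SIF", "GraphML", "TSV")


# ---------------------------------------------------------------------------
# Protein catalog
# ---------------------------------------------------------------------------

@dataclass
class Protein:
    """One catalog entry: a protein symbol plus its annotations."""

    protein_id: str
    family: str = "other"
    activity: str = "unknown"
    functional_terms: frozenset = field(default_factory=frozenset)
    cluster_id: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r} for {self.protein_id}")
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r} for {self.protein_id}")
        self.functional_terms = frozenset(self.functional_terms)


class ProteinCatalog:
    """Ordered collection of proteins with unique identifiers.

    Parameters
    ----------
    proteins
        Iterable of :class:`Protein`.
    term_vocabulary
        Declared vocabulary of functional terms. When given, every
        protein's terms must be drawn from it; otherwise the vocabulary
        is the union of the terms seen.
    """

    def __init__(self, proteins: Iterable[Protein],
                 term_vocabulary: Iterable[str] | None = None) -> None:
        self._proteins: dict[str, Protein] = {}
        for p in proteins:
            if p.protein_id in self._proteins:
                raise ValueError(f"duplicate protein id {p.protein_id!r}")
            self._proteins[p.protein_id] = p
        seen_terms = set().union(*(p.functional_terms for p in self._proteins.values())) \
            if self._proteins else set()
        if term_vocabulary is not None:
            vocab = frozenset(term_vocabulary)
            extra = seen_terms - vocab
            if extra:
                raise ValueError(f"functional terms outside vocabulary: {sorted(extra)}")
            self.term_vocabulary = vocab
        else:
            self.term_vocabulary = frozenset(seen_terms)

    @property
    def ids(self) -> list[str]:
        return list(self._proteins)

    def __len__(self) -> int:
        return len(self._proteins)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._proteins

    def __iter__(self):
        return iter(self._proteins.values())

    def get(self, protein_id: str) -> Protein:
        return self._proteins[protein_id]

    @classmethod
    def from_tsv(cls, path) -> "ProteinCatalog":
        """Read a catalog table.

        Expected columns: ``protein_id`` and optionally ``family``,
        ``activity``, ``functional_terms`` (semicolon-separated) and
        ``cluster_id``.
        """
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if "protein_id" not in df.columns:
            raise ValueError(f"{path}: catalog requires a 'protein_id' column")
        proteins = []
        for _, row in df.iterrows():
            terms = row.get("functional_terms")
            terms = frozenset(t for t in str(terms).split(";") if t and t != "nan") \
                if pd.notna(terms) else frozenset()
            cid = row.get("cluster_id")
            proteins.append(Protein(
                protein_id=row["protein_id"],
                family=row.get("family") if pd.notna(row.get("family")) else "other",
                activity=row.get("activity") if pd.notna(row.get("activity")) else "unknown",
                functional_terms=terms,
                cluster_id=int(cid) if pd.notna(cid) else None,
            ))
        return cls(proteins)

    def to_tsv(self, path) -> None:
        rows = [{
            "protein_id": p.protein_id,
            "family": p.family,
            "activity": p.activity,
            "functional_terms": ";".join(sorted(p.functional_terms)),
            "cluster_id": "" if p.cluster_id is None else p.cluster_id,
        } for p in self]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interaction network
# ---------------------------------------------------------------------------

class InteractionNetwork:
    """Undirected, unweighted PPI network.

    Self-edges are rejected, edge (a, b) is identical to (b, a), and
    isolated nodes are first-class members of the node set. An optional
    provenance tag can be attached per edge.
    """

    def __init__(self, nodes: Iterable[str] = (),
                 edges: Iterable[tuple[str, str]] = ()) -> None:
        self._g = nx.Graph()
        self._g.add_nodes_from(nodes)
        for e in edges:
            self.add_edge(*e[:2])

    def add_node(self, a: str) -> None:
        self._g.add_node(a)

    def add_edge(self, a: str, b: str, source: str | None = None) -> None:
        if a == b:
            raise ValueError(f"self-edge {a!r} not allowed")
        if source is None:
            self._g.add_edge(a, b)
        else:
            self._g.add_edge(a, b, source=source)

    def remove_edge(self, a: str, b: str) -> None:
        self._g.remove_edge(a, b)

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self._g.edges}

    def edge_list(self) -> list[tuple[str, str]]:
        """Edges as sorted (a, b) tuples with a < b, deterministically ordered."""
        return sorted(tuple(sorted(e)) for e in self._g.edges)

    def edge_source(self, a: str, b: str) -> str | None:
        return self._g.edges[a, b].get("source")

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, a: str) -> bool:
        return self._g.has_node(a)

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def neighbors(self, a: str) -> set[str]:
        return set(self._g.neighbors(a))

    def degree(self, a: str) -> int:
        return self._g.degree(a)

    def copy(self) -> "InteractionNetwork":
        out = InteractionNetwork()
        out._g = self._g.copy()
        return out

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

class ExpressionMatrix:
    """Genes x samples expression values (arbitrary units).

    Pairs lacking data are flagged as missing downstream rather than
    fabricated; at least 3 samples are required for any correlation.
    """

    def __init__(self, gene_ids: Sequence[str], sample_ids: Sequence[str],
                 values) -> None:
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample id lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def profile(self, gene: str) -> np.ndarray:
        return self.values[self._index[gene]]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.gene_ids,
                     columns=self.sample_ids).to_csv(
            path, sep="\t", index_label="gene_id")


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a TSV expression matrix: first column gene ids, rest samples.

    Raises on duplicate gene ids, non-numeric cells, or fewer than 3
    sample columns (correlations would be undefined).
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene id(s): {sorted(set(dup))}")
    if df.shape[1] < 3:
        raise ValueError(f"expression matrix has {df.shape[1]} samples; >=3 required")
    try:
        values = df.astype(float).to_numpy()
    except (TypeError, ValueError) as err:
        raise ValueError(f"non-numeric expression value: {err}") from err
    return ExpressionMatrix(list(df.index.astype(str)),
                            list(df.columns.astype(str)), values)


# ---------------------------------------------------------------------------
# Probabilistic network
# ---------------------------------------------------------------------------

class ProbabilisticNetwork:
    """Symmetric matrix of interaction probabilities over n >= 2 proteins.

    Entries lie in [0, 1], the matrix is exactly symmetric, and the
    diagonal is structurally zero (self-interactions are excluded).
    """

    def __init__(self, protein_ids: Sequence[str], pin) -> None:
        self.protein_ids = list(protein_ids)
        n = len(self.protein_ids)
        if n < 2:
            raise ValueError("a probabilistic network needs at least 2 proteins")
        if len(set(self.protein_ids)) != n:
            raise ValueError("duplicate protein ids")
        pin = np.asarray(pin, dtype=float)
        if pin.shape != (n, n):
            raise ValueError(f"pin matrix shape {pin.shape} != ({n}, {n})")
        if not np.array_equal(pin, pin.T):
            raise ValueError("pin matrix is not symmetric")
        if np.any(np.diag(pin) != 0):
            raise ValueError("pin diagonal must be zero")
        if pin.min() < 0 or pin.max() > 1:
            raise ValueError("pin entries must lie in [0, 1]")
        self.pin = pin
        self._index = {p: i for i, p in enumerate(self.protein_ids)}

    @property
    def n(self) -> int:
        return len(self.protein_ids)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index

    def index(self, protein_id: str) -> int:
        try:
            return self._index[protein_id]
        except KeyError:
            raise KeyError(f"unknown protein {protein_id!r}") from None

    def get(self, a: str, b: str) -> float:
        return float(self.pin[self.index(a), self.index(b)])

    def pairs(self):
        """Yield (a, b, pin) over all unordered pairs, a < b in id order."""
        ids = self.protein_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                yield ids[i], ids[j], float(self.pin[i, j])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.pin, index=self.protein_ids,
                     columns=self.protein_ids).to_csv(
            path, sep="\t", index_label="protein_id", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "ProbabilisticNetwork":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        pin = df.to_numpy(dtype=float)
        # re-symmetrize exactly: text round-trips can perturb the last ulp
        pin = np.triu(pin, 1)
        pin = pin + pin.T
        return cls(list(df.index.astype(str)), pin)


# ---------------------------------------------------------------------------
# PPI table reading
# ---------------------------------------------------------------------------

_HEADER_TOKENS = {"protein_a", "protein_b", "protein1", "protein2",
                  "node1", "node2", "gene_a", "gene_b"}


def read_ppi_table(path, catalog: ProteinCatalog | None = None) -> InteractionNetwork:
    """Read an undirected PPI edge table (TSV, >=2 symbol columns).

    Duplicated edges (in either orientation) are merged; self-edges are
    dropped with a logged count. With a catalog, edges are restricted to
    catalog proteins. An optional third column is kept as the edge source
    tag. A single header line is tolerated.
    """
    rows: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n").rstrip("\r")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            rows.append((lineno, stripped.split("\t")))
    if not rows:
        raise ValueError(f"{path}: empty PPI table")
    start = 0
    first = [f.strip().lower() for f in rows[0][1][:2]]
    if any(f in _HEADER_TOKENS for f in first):
        start = 1
    bad: list[int] = []
    edges: list[tuple[str, str, str | None]] = []
    for lineno, parts in rows[start:]:
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            bad.append(lineno)
            continue
        a, b = parts[0].strip(), parts[1].strip()
        src = parts[2].strip() if len(parts) > 2 and parts[2].strip() else None
        edges.append((a, b, src))
    if bad:
        raise ValueError(f"{path}: malformed rows at line(s) {bad}")
    if not edges:
        raise ValueError(f"{path}: no edge rows found")
    net = InteractionNetwork()
    n_self = 0
    for a, b, src in edges:
        if a == b:
            n_self += 1
            continue
        if catalog is not None and (a not in catalog or b not in catalog):
            continue
        net.add_edge(a, b, source=src)
    if n_self:
        logger.info("read_ppi_table: dropped %d self-edge row(s) from %s", n_self, path)
    return net


# ---------------------------------------------------------------------------
# Thresholding and export
# ---------------------------------------------------------------------------

def threshold_network(pnet: ProbabilisticNetwork, cutoff: float) -> InteractionNetwork:
    """Deterministic network at a probability cutoff (pin >= cutoff, inclusive).

    The node set is preserved: proteins whose every probability falls
    below the cutoff remain as isolates.
    """
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    net = InteractionNetwork(nodes=pnet.protein_ids)
    ii, jj = np.nonzero(np.triu(pnet.pin, 1) >= cutoff)
    for i, j in zip(ii, jj):
        net.add_edge(pnet.protein_ids[i], pnet.protein_ids[j])
    return net


def _iter_export_edges(net, cutoff):
    """Yield (a, b, weight) plus the node list for either network kind."""
    if isinstance(net, ProbabilisticNetwork):
        lo = cutoff if cutoff is not None else 0.0
        out = [(a, b, w) for a, b, w in net.pairs()
               if (w >= lo if cutoff is not None else w > 0)]
        return net.protein_ids, out
    return sorted(net.nodes), [(a, b, 1.0) for a, b in net.edge_list()]


def export_network(net, fmt: str, path, cutoff: float | None = None) -> None:
    """Write a network in SIF, GraphML, or 3-column TSV.

    For a :class:`ProbabilisticNetwork` the edge weight is the ``pin``
    probability and only pairs with pin > 0 (or >= ``cutoff`` when
    given) are emitted; deterministic networks carry weight 1.
    """
    key = fmt.strip().lower()
    if key not in {f.lower() for f in EXPORT_FORMATS}:
        raise ValueError(f"unknown export format {fmt!r}; choose from {EXPORT_FORMATS}")
    nodes, rows = _iter_export_edges(net, cutoff)
    if key == "sif":
        covered = {x for a, b, _ in rows for x in (a, b)}
        with open(path, "w", encoding="utf-8") as fh:
            for a, b, _ in rows:
                fh.write(f"{a} pp {b}\n")
            for node in nodes:
                if node not in covered:
                    fh.write(f"{node}\n")
    elif key == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("protein_a\tprotein_b\tpin\n")
            for a, b, w in rows:
                fh.write(f"{a}\t{b}\t{w:.17g}\n")
    else:  # graphml
        g = nx.Graph()
        g.add_nodes_from(nodes)
        weighted = isinstance(net, ProbabilisticNetwork)
        for a, b, w in rows:
            if weighted:
                g.add_edge(a, b, pin=float(w))
            else:
                g.add_edge(a, b)
        nx.write_graphml(g, path)


def import_network(path, fmt: str):
    """Read back a network written by :func:`export_network`.

    Returns ``(InteractionNetwork, weights)`` where ``weights`` maps
    frozenset edges to pin values (``None`` for SIF, which is unweighted).
    """
    key = fmt.strip().lower()
    if key not in {f.lower() for f in EXPORT_FORMATS}:
        raise ValueError(f"unknown export format {fmt!r}; choose from {EXPORT_FORMATS}")
    net = InteractionNetwork()
    if key == "sif":
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.split()
                if len(parts) == 1:
                    net.add_node(parts[0])
                elif len(parts) == 3:
                    net.add_edge(parts[0], parts[2])
                elif parts:
                    raise ValueError(f"unparseable SIF line: {line!r}")
        return net, None
    if key == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        weights = {}
        for _, row in df.iterrows():
            a, b = str(row.iloc[0]), str(row.iloc[1])
            net.add_edge(a, b)
            weights[frozenset((a, b))] = float(row.iloc[2])
        return net, weights
    g = nx.read_graphml(path)
    net._g.add_nodes_from(str(n) for n in g.nodes)
    weights = {}
    for a, b, data in g.edges(data=True):
        net.add_edge(str(a), str(b))
        if "pin" in data:
            weights[frozenset((str(a), str(b)))] = float(data["pin"])
    return net, (weights or None)


# ---------------------------------------------------------------------------
# Auxiliary annotation tables
# ---------------------------------------------------------------------------

def read_term_table(path) -> dict[str, set[str]]:
    """Read protein->term annotations (TSV: protein_id, term). Returns term -> proteins."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: term table needs 2 columns (protein_id, term)")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row.iloc[1]), set()).add(str(row.iloc[0]))
    return out


def read_complex_table(path) -> dict[str, set[str]]:
    """Read complex membership (TSV: complex_id, member). Returns complex -> members."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: complex table needs 2 columns (complex_id, member)")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row.iloc[0]), set()).add(str(row.iloc[1]))
    return out


def read_ipms_table(path) -> pd.DataFrame:
    """Read an IP-MS unique-peptide count table.

    Columns: bait, ligand, condition ('nuclease'/'no_nuclease'),
    replicate, p_dox_plus, p_dox_minus.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"bait", "ligand", "condition", "replicate", "p_dox_plus", "p_dox_minus"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: IP-MS table missing column(s) {sorted(missing)}")
    return df
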