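"""Weighted gene–gene functional-linkage networks.

Reads STRING-style ``protein.links`` edge lists into an undirected,
deduplicated, weighted graph and exposes the symmetrically degree-
normalized view ``W' = D^{-1/2} W D^{-1/2}`` used by label propagation.
Node order is always lexicographic so matrix views are reproducible.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["Network", "NormalizedNetwork", "read_network", "normalize", "NetworkError"]

#: Channel names whose positive sub-score marks a physical (binding) interaction.
PHYSICAL_CHANNELS = ("binding", "physical")


class NetworkError(ValueError):
    """Malformed edge list or empty network after filtering."""


@dataclass
class Network:
    """Undirected weighted gene graph.

    Parameters
    ----------
    edges : pandas.DataFrame
        Columns ``gene1``, ``gene2``, ``weight`` plus any per-edge channel
        sub-score columns.  One row per unordered pair, ``gene1 < gene2``.

    Invariants: no self-loops, strictly positive weights, node labels
    sorted lexicographically.
    """

    edges: pd.DataFrame
    extra_nodes: tuple = ()  # isolated genes with no edges
    _nodes: tuple = field(init=False, repr=False, default=None)

    def __post_init__(self):
        e = self.edges
        if (e["weight"] <= 0).any():
            raise NetworkError("edge weights must be strictly positive")
        if (e["gene1"] == e["gene2"]).any():
            raise NetworkError("self-loops are not allowed")
        self._nodes = tuple(
            sorted(set(e["gene1"]).union(e["gene2"]).union(self.extra_nodes))
        )

    @property
    def nodes(self) -> tuple:
        """Genes in deterministic (lexicographic) order."""
        return self._nodes

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self) -> dict:
        return {g: i for i, g in enumerate(self._nodes)}

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric sparse weight matrix in node order."""
        idx = self.node_index()
        i = self.edges["gene1"].map(idx).to_numpy()
        j = self.edges["gene2"].map(idx).to_numpy()
        w = self.edges["weight"].to_numpy(dtype=float)
        n = self.n_nodes
        m = sp.coo_matrix((np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n, n))
        return m.tocsr()

    def degrees(self) -> np.ndarray:
        """Weighted degree d_i = sum_j w_ij in node order."""
        return np.asarray(self.adjacency().sum(axis=1)).ravel()

    def neighbors(self, gene: str) -> set:
        a = set(self.edges.loc[self.edges["gene1"] == gene, "gene2"])
        b = set(self.edges.loc[self.edges["gene2"] == gene, "gene1"])
        return a | b

    def to_tsv(self, path) -> None:
        """Serialize back to the STRING-dialect edge list."""
        out = self.edges.rename(columns={"gene1": "protein1", "gene2": "protein2",
                                         "weight": "combined_score"})
        out.to_csv(path, sep="\t", index=False)


@dataclass
class NormalizedNetwork:
    """A :class:`Network` together with its symmetrically normalized weights.

    ``norm_adjacency`` holds w'_ij = w_ij / sqrt(d_i d_j); its spectral
    radius is at most 1, which guarantees convergence of label
    propagation for any damping factor below 1.  Isolated nodes keep
    zero rows.
    """

    base: Network
    norm_adjacency: sp.csr_matrix

    @property
    def nodes(self) -> tuple:
        return self.base.nodes


def _looks_like_header(fields) -> bool:
    # a header row has no parseable weight in column 3
    try:
        float(fields[2])
        return False
    except (ValueError, IndexError):
        return True


def read_network(
    edge_list_source,
    min_weight: float = 0.0,
    physical_only: bool = False,
    alias_map: Optional[Mapping[str, str]] = None,
) -> Network:
    """Read a STRING-dialect edge list into a :class:`Network`.

    Parameters
    ----------
    edge_list_source : path or file-like
        Whitespace- or tab-delimited text with header
        ``protein1 protein2 combined_score [channel columns...]``.
    min_weight : float
        Edges with combined score below this are dropped (STRING scores
        are 0–1000 integers; they are used unscaled, as the downstream
        normalization is invariant to a global weight scale).
    physical_only : bool
        Keep only edges whose ``binding``/``physical`` channel sub-score
        is positive.
    alias_map : mapping, optional
        protein-ID → gene-symbol translation applied at read time.
        When two protein pairs collapse onto one symbol pair the
        max-weight edge is kept.

    Raises
    ------
    NetworkError
        On malformed rows (named by line number) or when no edges
        survive filtering.
    """
    if hasattr(edge_list_source, "read"):
        text = edge_list_source.read()
    else:
        with open(edge_list_source, "rt") as fh:
            text = fh.read()

    lines = [ln for ln in text.splitlines()]
    rows = []
    header = None
    lineno_of = []
    for lineno, ln in enumerate(lines, start=1):
        if not ln.strip():
            continue
        fields = ln.split()
        if header is None and _looks_like_header(fields):
            header = fields
            continue
        rows.append(fields)
        lineno_of.append(lineno)
    if header is None:
        header = ["protein1", "protein2", "combined_score"]
    if len(header) < 3:
        raise NetworkError(
            "edge list needs at least 3 columns: two genes and a weight"
        )

    ncol = len(header)
    channel_cols = header[3:]
    recs = []
    for fields, lineno in zip(rows, lineno_of):
        if len(fields) != ncol:
            raise NetworkError(
                f"line {lineno}: expected {ncol} fields, found {len(fields)}"
            )
        g1, g2 = fields[0], fields[1]
        try:
            w = float(fields[2])
            chans = [float(v) for v in fields[3:]]
        except ValueError as exc:
            raise NetworkError(f"line {lineno}: non-numeric weight field ({exc})")
        recs.append((g1, g2, w, *chans))

    df = pd.DataFrame(recs, columns=["gene1", "gene2", "weight", *channel_cols])

    if alias_map is not None:
        df["gene1"] = df["gene1"].map(lambda g: alias_map.get(g, g))
        df["gene2"] = df["gene2"].map(lambda g: alias_map.get(g, g))

    # drop self-loops silently (can arise from alias collapse)
    df = df[df["gene1"] != df["gene2"]]

    if physical_only:
        phys = [c for c in channel_cols if c.lower() in PHYSICAL_CHANNELS]
        if not phys:
            raise NetworkError(
                "physical_only requested but no binding/physical channel column present"
            )
        mask = np.zeros(len(df), dtype=bool)
        for c in phys:
            mask |= df[c].to_numpy() > 0
        df = df[mask]

    df = df[df["weight"] >= min_weight]

    # canonical unordered pair + dedup keeping max weight
    swap = df["gene1"] > df["gene2"]
    lo = df["gene1"].where(~swap, df["gene2"])
    hi = df["gene2"].where(~swap, df["gene1"])
    df = df.assign(gene1=lo, gene2=hi)
    df = (
        df.sort_values("weight", ascending=False)
        .drop_duplicates(subset=["gene1", "gene2"], keep="first")
        .sort_values(["gene1", "gene2"])
        .reset_index(drop=True)
    )

    if len(df) == 0:
        raise NetworkError("no edges remain after filtering")
    return Network(edges=df)


def normalize(net: Network) -> NormalizedNetwork:
    """Symmetric degree normalization w'_ij = w_ij / sqrt(d_i d_j)."""
    W = net.adjacency()
    d = np.asarray(W.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    D = sp.diags(inv_sqrt)
    Wn = (D @ W @ D).tocsr()
    return NormalizedNetwork(base=net, norm_adjacency=Wn)


def read_alias_map(source) -> dict:
    """Two-column TSV ``string_id<TAB>symbol`` → dict."""
    df = pd.read_csv(source, sep="\t", header=None, names=["string_id", "symbol"],
                     dtype=str, comment="#")
    return dict(zip(df["string_id"], df["symbol"]))
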