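"""Evidence integration: target-list merging, interaction-network degree
ranking, and docking-score thresholding.

Interaction networks are undirected simple graphs over gene/protein symbols
(uppercased, trimmed); duplicate and reversed edges collapse on load and
self-loops are dropped, matching the usual treatment of protein-protein
interaction edge lists.  Degree centrality (number of incident edges) ranks
candidate hub targets; a docking record is flagged stable-binding when its
XP GScore is below -6 or its MM-GBSA dG Bind is less than -30 kcal/mol
(strict inequalities).
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

__all__ = [
    "normalize_symbol",
    "merge_target_lists",
    "build_network",
    "load_edge_list",
    "degree_ranking",
    "isolate_filter",
    "docking_threshold_filter",
    "XP_GSCORE_MAX",
    "DG_BIND_MAX",
]

XP_GSCORE_MAX = -6.0
DG_BIND_MAX = -30.0


def normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


def merge_target_lists(lists: dict[str, object]) -> pd.DataFrame:
    """Union of several symbol lists with per-source provenance.

    ``lists`` maps a source label (e.g. ``network-pharmacology``,
    ``tpp-significant``) to an iterable of symbols.  Returns one row per
    unique normalized symbol with the comma-joined contributing sources and
    an ``n_sources`` column from which intersections are derivable.
    """
    if not lists:
        raise ValueError("at least one target list is required")
    membership: dict[str, set[str]] = {}
    for source, symbols in lists.items():
        for sym in symbols:
            membership.setdefault(normalize_symbol(sym), set()).add(source)
    rows = [
        {"symbol": sym, "sources": ",".join(sorted(srcs)), "n_sources": len(srcs)}
        for sym, srcs in sorted(membership.items())
    ]
    return pd.DataFrame(rows, columns=["symbol", "sources", "n_sources"])


def build_network(edges) -> nx.Graph:
    """Build an undirected simple graph from (symbol, symbol) pairs.

    Symbols are normalized; self-loops are discarded and duplicate or
    reversed edges collapse.
    """
    g = nx.Graph()
    for u, v in edges:
        u, v = normalize_symbol(u), normalize_symbol(v)
        if u == v:
            continue
        g.add_edge(u, v)
    return g


def load_edge_list(path) -> nx.Graph:
    """Read a two-column (plus optional ignored score column) edge-list TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("edge list needs at least two columns")
    return build_network(df.iloc[:, :2].itertuples(index=False, name=None))


def degree_ranking(network: nx.Graph) -> pd.DataFrame:
    """Nodes sorted by degree, descending; ties broken alphabetically."""
    if network.number_of_nodes() == 0:
        raise ValueError("cannot rank an empty network")
    rows = sorted(network.degree(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["symbol", "degree"])


def isolate_filter(network: nx.Graph) -> nx.Graph:
    """Copy of the network with unconnected (degree-0) nodes removed."""
    g = network.copy()
    g.remove_nodes_from(list(nx.isolates(g)))
    return g


def docking_threshold_filter(
    records: pd.DataFrame,
    xp_max: float = XP_GSCORE_MAX,
    dg_max: float = DG_BIND_MAX,
) -> pd.DataFrame:
    """Flag docking records predicted to bind stably.

    ``stable_binding`` is true when XP GScore < ``xp_max`` OR MM-GBSA dG Bind
    < ``dg_max``; the per-criterion verdicts are also reported.  Rows missing
    both scores are a validation error.
    """
    for col in ("xp_gscore", "mmgbsa_dg_bind"):
        if col not in records.columns:
            raise ValueError(f"docking records must carry a {col!r} column")
    if (records["xp_gscore"].isna() & records["mmgbsa_dg_bind"].isna()).any():
        raise ValueError("docking record with neither XP GScore nor MM-GBSA dG Bind")
    out = records.copy()
    out["xp_pass"] = records["xp_gscore"] < xp_max
    out["dg_pass"] = records["mmgbsa_dg_bind"] < dg_max
    out["stable_binding"] = out["xp_pass"] | out["dg_pass"]
    return out
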