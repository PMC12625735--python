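"""Transkingdom network construction.

Edges are candidate feature–feature associations evaluated *separately* in
each diet group (Spearman rank correlation by default), combined across
groups by Fisher's meta-analytic method, and retained only when

1. the correlation sign is identical in both groups (sign consistency),
2. the BH-adjusted combined p-value clears the FDR threshold, and
3. (optionally) the correlation sign is coherent with the product of the two
   endpoints' diet fold-change directions.

The fraction of significant, sign-consistent edges violating (3) is the PUC
(proportion of unexpected correlations) — a coherence diagnostic: on data
where diet shifts and couplings arise from the same latent causes, PUC ≈ 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .exceptions import ValidationError
from .layers import COMPARTMENT, MICROBES_A, MICROBES_B, node_id, split_node_id

__all__ = [
    "NetworkConfig",
    "pairwise_correlations",
    "fisher_combine",
    "filter_edges",
    "build_network",
]

logger = logging.getLogger(__name__)

_TINY_P = float(np.nextafter(0, 1))


@dataclass(frozen=True)
class NetworkConfig:
    """Knobs of network construction."""

    method: str = "spearman"  # or "pearson"
    fdr: float = 0.05
    require_coherence: bool = True
    exclude_cross_compartment: bool = True  # drop microbes_A × microbes_B pairs
    min_group_size: int = 4


@dataclass
class ConstructionReport:
    """Bookkeeping emitted by :func:`build_network`."""

    n_candidates: int
    n_sign_consistent: int
    n_significant: int
    n_retained: int
    puc: float  # NaN when no significant edges
    n_skipped_constant: int
    isolated_nodes: list[str] = field(default_factory=list)
    inputs_per_compartment: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_candidates": self.n_candidates,
            "n_sign_consistent": self.n_sign_consistent,
            "n_significant": self.n_significant,
            "n_retained": self.n_retained,
            "puc": None if np.isnan(self.puc) else float(self.puc),
            "n_skipped_constant": self.n_skipped_constant,
            "n_isolated": len(self.isolated_nodes),
            "inputs_per_compartment": dict(self.inputs_per_compartment),
        }


def _rank_corr(y: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix and two-sided p-values for rows of ``y``.

    Spearman = Pearson on average-tie ranks; p from the t approximation
    t = r sqrt((n−2)/(1−r²)).  Rows with zero variance yield NaN.
    """
    n = y.shape[1]
    if method == "spearman":
        y = stats.rankdata(y, axis=1)
    elif method != "pearson":
        raise ValidationError(f"unknown correlation method {method!r}")
    sd = y.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(y)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(r) >= 1.0] = 0.0  # perfect monotone association
    return r, p


def pairwise_correlations(
    tables: dict[str, pd.DataFrame],
    diet_labels,
    method: str = "spearman",
    exclude_layer_pairs: set[frozenset] | None = None,
    min_group_size: int = 4,
) -> pd.DataFrame:
    """Within-group correlations for every unordered feature pair.

    ``tables`` maps layer name → (features × samples) DataFrame, all sharing
    the same sample columns; ``diet_labels`` assigns each column to NC or
    HFD.  Pairs whose layers form a frozenset listed in
    ``exclude_layer_pairs`` are skipped; pairs where either feature is
    constant within a group are skipped and logged.

    Returns a candidate-edge DataFrame with columns node_a, node_b, layer_a,
    layer_b, r_NC, r_HFD, p_NC, p_HFD.
    """
    diet = np.asarray(diet_labels)
    layers: list[str] = []
    nodes: list[str] = []
    blocks: list[np.ndarray] = []
    ref_cols = None
    for layer, table in tables.items():
        if table.index.has_duplicates:
            raise ValidationError(f"duplicate feature ids in layer {layer}")
        if ref_cols is None:
            ref_cols = list(table.columns)
        elif list(table.columns) != ref_cols:
            raise ValidationError("all layers must share the same sample columns")
        layers.extend([layer] * len(table))
        nodes.extend(node_id(layer, f) for f in table.index)
        blocks.append(table.to_numpy(dtype=float))
    y = np.vstack(blocks)
    if y.shape[1] != diet.size:
        raise ValidationError("diet labels must match the sample columns")

    masks = {g: diet == g for g in ("NC", "HFD")}
    for g, m in masks.items():
        if m.sum() < min_group_size:
            raise ValidationError(f"group {g} has fewer than {min_group_size} samples")

    r_nc, p_nc = _rank_corr(y[:, masks["NC"]], method)
    r_hfd, p_hfd = _rank_corr(y[:, masks["HFD"]], method)

    m = len(nodes)
    iu, ju = np.triu_indices(m, k=1)
    layer_arr = np.asarray(layers)
    if exclude_layer_pairs:
        keep = np.array(
            [
                frozenset((la, lb)) not in exclude_layer_pairs
                for la, lb in zip(layer_arr[iu], layer_arr[ju])
            ]
        )
        iu, ju = iu[keep], ju[keep]

    cand = pd.DataFrame(
        {
            "node_a": np.asarray(nodes)[iu],
            "node_b": np.asarray(nodes)[ju],
            "layer_a": layer_arr[iu],
            "layer_b": layer_arr[ju],
            "r_NC": r_nc[iu, ju],
            "r_HFD": r_hfd[iu, ju],
            "p_NC": p_nc[iu, ju],
            "p_HFD": p_hfd[iu, ju],
        }
    )
    skipped = cand["r_NC"].isna() | cand["r_HFD"].isna()
    if skipped.any():
        logger.info("skipped %d pairs with a constant feature in a group", skipped.sum())
    cand = cand[~skipped].reset_index(drop=True)
    cand.attrs["n_skipped_constant"] = int(skipped.sum())
    return cand


def fisher_combine(p_values) -> float:
    """Fisher's method: X = −2 Σ ln pᵢ ~ χ²(2k) under the global null.

    p-values of exactly 0 are clamped to the smallest positive float (and
    logged); p > 1 or p < 0 is an error.
    """
    p = np.asarray(list(np.atleast_1d(p_values)), dtype=float)
    if p.size == 0:
        raise ValidationError("need at least one p-value")
    if (p > 1).any() or (p < 0).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if (p == 0).any():
        logger.warning("clamping %d zero p-values", int((p == 0).sum()))
        p = np.where(p == 0, _TINY_P, p)
    x = -2 * np.log(p).sum()
    return float(stats.chi2.sf(x, 2 * p.size))


def _fisher_combine_pairwise(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    p1 = np.where(p1 == 0, _TINY_P, p1)
    p2 = np.where(p2 == 0, _TINY_P, p2)
    x = -2 * (np.log(p1) + np.log(p2))
    return stats.chi2.sf(x, 4)


def filter_edges(
    candidates: pd.DataFrame,
    fdr: float = 0.05,
    require_coherence: bool = True,
    diff_signs: dict[str, float] | pd.Series | None = None,
) -> tuple[pd.DataFrame, float]:
    """Apply the meta-analytic retention rules to a candidate table.

    Adds combined_p, q, sign and coherent columns; returns the retained-edge
    DataFrame and the PUC.  ``diff_signs`` maps node id → fold-change
    direction sign; a node with sign 0 (or missing) can never satisfy
    coherence.  PUC is NaN when no edge passes sign consistency + FDR.
    """
    if candidates.empty:
        logger.warning("empty candidate list: returning an empty network")
        return candidates.assign(combined_p=[], q=[], sign=[], coherent=[]), float("nan")
    cand = candidates.copy()
    cand["combined_p"] = _fisher_combine_pairwise(
        cand["p_NC"].to_numpy(), cand["p_HFD"].to_numpy()
    )
    cand["q"] = bh_adjust(cand["combined_p"])
    consistent = np.sign(cand["r_NC"]) == np.sign(cand["r_HFD"])
    consistent &= np.sign(cand["r_NC"]) != 0
    cand["sign"] = np.where(consistent, np.sign(cand["r_NC"]), 0).astype(int)

    if diff_signs is not None:
        signs = pd.Series(diff_signs)
        sa = cand["node_a"].map(signs).fillna(0.0)
        sb = cand["node_b"].map(signs).fillna(0.0)
        cand["coherent"] = cand["sign"] == sa * sb
    else:
        cand["coherent"] = True

    significant = consistent & (cand["q"] < fdr)
    n_sig = int(significant.sum())
    puc = float((~cand.loc[significant, "coherent"]).mean()) if n_sig else float("nan")

    retained = significant & (cand["coherent"] if require_coherence else True)
    return cand[retained].reset_index(drop=True), puc


def _edges_to_graph(
    edges: pd.DataFrame, node_attrs: dict[str, dict] | None = None
) -> nx.Graph:
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(
            row.node_a,
            row.node_b,
            r_NC=float(row.r_NC),
            r_HFD=float(row.r_HFD),
            combined_p=float(row.combined_p),
            q=float(row.q),
            sign=int(row.sign),
        )
    if node_attrs:
        for node in g.nodes:
            g.nodes[node].update(node_attrs.get(node, {}))
    return g


def build_network(
    tables: dict[str, pd.DataFrame],
    diff_results: dict[str, pd.DataFrame],
    diet_labels,
    config: NetworkConfig = NetworkConfig(),
    screen: bool = True,
) -> tuple[nx.Graph, ConstructionReport]:
    """Orchestrate correlation → Fisher combination → filtering.

    ``diff_results`` holds each layer's :func:`two_group_differential` table
    (fold-change signs feed the coherence filter; ``pass`` flags select the
    features entering the network when ``screen`` is true).  Node attributes
    (layer, compartment, lfc, diff q, sign) are attached; isolated screened
    features are dropped from the graph but listed in the report.
    """
    if len(tables) < 2:
        raise ValidationError("need at least two layers to build a network")
    screened: dict[str, pd.DataFrame] = {}
    signs: dict[str, float] = {}
    attrs: dict[str, dict] = {}
    for layer, table in tables.items():
        diff = diff_results.get(layer)
        if diff is None:
            raise ValidationError(f"missing differential results for layer {layer}")
        keep = diff.index[diff["pass"].fillna(False)] if screen else diff.index
        sub = table.loc[table.index.intersection(keep)]
        if sub.empty:
            continue
        screened[layer] = sub
        for feat in sub.index:
            nid = node_id(layer, feat)
            row = diff.loc[feat]
            signs[nid] = float(row["sign"])
            attrs[nid] = {
                "layer": layer,
                "compartment": COMPARTMENT.get(layer, "host"),
                "lfc": float(row["lfc"]) if np.isfinite(row["lfc"]) else 0.0,
                "diff_q": float(row["q"]) if np.isfinite(row["q"]) else 1.0,
                "sign": float(row["sign"]),
            }
    if len(screened) < 2:
        raise ValidationError("fewer than two layers have features passing the screen")

    exclude = (
        {frozenset((MICROBES_A, MICROBES_B))} if config.exclude_cross_compartment else None
    )
    candidates = pairwise_correlations(
        screened,
        diet_labels,
        method=config.method,
        exclude_layer_pairs=exclude,
        min_group_size=config.min_group_size,
    )
    retained, puc = filter_edges(
        candidates,
        fdr=config.fdr,
        require_coherence=config.require_coherence,
        diff_signs=signs,
    )
    graph = _edges_to_graph(retained, attrs)

    all_nodes = set(attrs)
    isolated = sorted(all_nodes - set(graph.nodes))
    inputs = {"A": 0, "B": 0}
    for nid in all_nodes:
        comp = attrs[nid]["compartment"]
        if comp in inputs:
            inputs[comp] += 1
    n_consistent = 0
    n_significant = 0
    if not candidates.empty:
        cons = (np.sign(candidates["r_NC"]) == np.sign(candidates["r_HFD"])) & (
            np.sign(candidates["r_NC"]) != 0
        )
        n_consistent = int(cons.sum())
        cp = _fisher_combine_pairwise(
            candidates["p_NC"].to_numpy(), candidates["p_HFD"].to_numpy()
        )
        q = bh_adjust(cp)
        n_significant = int((cons & (q < config.fdr)).sum())
    report = ConstructionReport(
        n_candidates=len(candidates),
        n_sign_consistent=n_consistent,
        n_significant=n_significant,
        n_retained=len(retained),
        puc=puc,
        n_skipped_constant=candidates.attrs.get("n_skipped_constant", 0),
        isolated_nodes=isolated,
        inputs_per_compartment=inputs,
    )
    return graph, report


def compartment_nodes(graph: nx.Graph, compartment: str) -> set[str]:
    """Nodes of one gut compartment ('A' or 'B') present in the graph."""
    return {
        n for n, d in graph.nodes(data=True) if d.get("compartment") == compartment
    }


def layer_nodes(graph: nx.Graph, layer: str) -> set[str]:
    """Nodes of one omic layer present in the graph."""
    return {n for n, d in graph.nodes(data=True) if d.get("layer") == layer}


def microbe_feature_id(node: str) -> str:
    return split_node_id(node)[1]
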