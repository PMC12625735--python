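"""Compartment-comparison topology suite.

Quantifies how "close" each gut compartment's microbiota sits to a host omic
layer inside the transkingdom network: retention χ², bipartite edge counts,
degree/power-law diagnostics, bipartite betweenness centrality (BIBC), and
set-to-set shortest-path closeness compared by a Wilcoxon rank-sum test.

BIBC(v) = Σ_{s∈S1, t∈S2, s≠v≠t} σ_st(v)/σ_st, where σ_st counts shortest
s–t paths and σ_st(v) those passing through v — ordinary betweenness with
endpoints restricted to two disjoint node sets (e.g. ileal microbes vs liver
genes); high-BIBC microbes are bottlenecks of cross-kingdom information
flow.  Computed by Brandes-style dependency accumulation with sources in S1
and target credit restricted to S2; unweighted edges.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "retention_comparison",
    "bipartite_edge_count",
    "fit_powerlaw",
    "degree_powerlaw",
    "bibc",
    "top_fraction_membership",
    "set_closeness",
    "compare_closeness",
    "compartment_report",
    "SetCloseness",
    "PowerlawFit",
    "TopologyReport",
]


def retention_comparison(
    n_a_in: int, n_a_retained: int, n_b_in: int, n_b_retained: int,
    correction: bool = False,
) -> tuple[float, float]:
    """2×2 χ² test of retained/dropped × compartment (no Yates correction by
    default).  Returns (χ², p); (NaN, NaN) with a warning on a zero margin."""
    if n_a_retained > n_a_in or n_b_retained > n_b_in:
        raise ValidationError("retained counts cannot exceed input counts")
    table = np.array(
        [
            [n_a_retained, n_a_in - n_a_retained],
            [n_b_retained, n_b_in - n_b_retained],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("zero margin in retention table; chi-square undefined")
        return float("nan"), float("nan")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def bipartite_edge_count(graph: nx.Graph, set1, set2) -> int:
    """Number of edges with one endpoint in each set (sets must be disjoint)."""
    s1, s2 = set(set1), set(set2)
    if s1 & s2:
        raise ValidationError("sets must be disjoint")
    return sum(
        1
        for u, v in graph.edges
        if (u in s1 and v in s2) or (u in s2 and v in s1)
    )


@dataclass
class PowerlawFit:
    alpha: float  # discrete MLE exponent
    r_squared: float  # log-log OLS diagnostic on the degree histogram
    k_min: int
    degrees: np.ndarray
    histogram: dict[int, int]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "r_squared": self.r_squared,
            "k_min": self.k_min,
            "histogram": {int(k): int(v) for k, v in self.histogram.items()},
        }


def fit_powerlaw(degrees, k_min: int = 1) -> PowerlawFit:
    """Discrete power-law exponent by maximum likelihood,
    α̂ = 1 + n / Σ ln(kᵢ / (k_min − 0.5)), over degrees ≥ k_min, with a
    descriptive log–log OLS R² on the degree histogram."""
    k = np.asarray([d for d in degrees if d >= k_min], dtype=float)
    if k.size < 10:
        raise ValidationError("need at least 10 nodes with degree >= k_min")
    if np.unique(k).size == 1:
        raise ValidationError("all degrees equal: power-law exponent undefined")
    alpha = 1.0 + k.size / np.log(k / (k_min - 0.5)).sum()

    uniq, counts = np.unique(k.astype(int), return_counts=True)
    logk, logc = np.log(uniq), np.log(counts)
    if uniq.size >= 3:
        slope, intercept = np.polyfit(logk, logc, 1)
        pred = slope * logk + intercept
        ss_res = ((logc - pred) ** 2).sum()
        ss_tot = ((logc - logc.mean()) ** 2).sum()
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    else:
        r2 = float("nan")
    return PowerlawFit(
        alpha=float(alpha),
        r_squared=float(r2),
        k_min=k_min,
        degrees=k.astype(int),
        histogram=dict(zip(uniq.tolist(), counts.tolist())),
    )


def degree_powerlaw(graph: nx.Graph, k_min: int = 1) -> PowerlawFit:
    """Power-law diagnostics of the graph's degree distribution."""
    return fit_powerlaw([d for _, d in graph.degree()], k_min=k_min)


def bibc(graph: nx.Graph, set1, set2) -> dict[str, float]:
    """Bipartite betweenness centrality of every node.

    Brandes dependency accumulation restricted to sources in ``set1``; a
    vertex earns target credit only when the downstream endpoint lies in
    ``set2``.  Each unordered (s, t) pair contributes once (the sets are
    disjoint, so no pair is visited from both sides).  Pairs with no
    connecting path contribute nothing.
    """
    s1, s2 = set(set1), set(set2)
    if not s1 or not s2:
        raise ValidationError("both node sets must be nonempty")
    if s1 & s2:
        raise ValidationError("sets must be disjoint")
    score: dict[str, float] = dict.fromkeys(graph.nodes, 0.0)
    for s in s1:
        if s not in graph:
            continue
        # BFS from s: sigma = #shortest paths, preds, reverse finish order
        sigma = {s: 1.0}
        dist = {s: 0}
        preds: dict = {s: []}
        order: list = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in graph[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    sigma[w] = 0.0
                    preds[w] = []
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = dict.fromkeys(order, 0.0)
        for w in reversed(order):
            credit = delta[w] + (1.0 if w in s2 and w != s else 0.0)
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * credit
            if w != s:
                score[w] += delta[w]
    return score


def top_fraction_membership(
    scores: dict[str, float], groups: dict[str, str], fraction: float = 0.20
) -> dict[str, float]:
    """Share of each group among the top ⌈fraction·n⌉ nodes by score.

    Ties are broken by stable feature-id (lexicographic) order so the
    selection is deterministic.  ``groups`` maps node → group label and must
    cover every scored node.
    """
    if not scores:
        raise ValidationError("empty score table")
    missing = set(scores) - set(groups)
    if missing:
        raise ValidationError(f"{len(missing)} scored nodes lack a group label")
    n_top = math.ceil(fraction * len(scores))
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    top = [node for node, _ in ranked[:n_top]]
    out = {g: 0.0 for g in set(groups.values())}
    for node in top:
        out[groups[node]] += 1.0
    return {g: c / n_top for g, c in out.items()}


@dataclass
class SetCloseness:
    """Multiset of shortest-path lengths between two node sets."""

    lengths: np.ndarray
    n_unreachable: int

    @property
    def mean(self) -> float:
        return float(self.lengths.mean()) if self.lengths.size else float("nan")

    @property
    def n_pairs_used(self) -> int:
        return int(self.lengths.size)

    def to_dict(self) -> dict:
        return {
            "mean": None if np.isnan(self.mean) else self.mean,
            "n_pairs_used": self.n_pairs_used,
            "n_unreachable": self.n_unreachable,
            "lengths_histogram": {
                int(l): int(c)
                for l, c in zip(*np.unique(self.lengths, return_counts=True))
            }
            if self.lengths.size
            else {},
        }


def set_closeness(graph: nx.Graph, set1, set2) -> SetCloseness:
    """BFS shortest-path length for every (s, t) ∈ set1 × set2 pair.

    Unreachable pairs (including endpoints absent from the graph) are
    excluded from the distribution and counted.
    """
    s1, s2 = set(set1), set(set2)
    if not s1 or not s2:
        raise ValidationError("both node sets must be nonempty")
    if s1 & s2:
        raise ValidationError("sets must be disjoint")
    lengths: list[int] = []
    unreachable = 0
    for s in sorted(s1):
        if s not in graph:
            unreachable += len(s2)
            continue
        dist = nx.single_source_shortest_path_length(graph, s)
        for t in s2:
            if t in dist:
                lengths.append(dist[t])
            else:
                unreachable += 1
    return SetCloseness(np.asarray(lengths, dtype=float), unreachable)


def compare_closeness(dist1, dist2) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) comparison of two
    path-length distributions; exact enumeration when both n ≤ 8, otherwise
    the tie-corrected normal approximation.  Returns (U statistic, p)."""
    x = np.asarray(dist1.lengths if isinstance(dist1, SetCloseness) else dist1, float)
    y = np.asarray(dist2.lengths if isinstance(dist2, SetCloseness) else dist2, float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both distributions must be nonempty")
    method = "exact" if (x.size <= 8 and y.size <= 8) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class TopologyReport:
    """Every per-panel statistic of the compartment comparison, serialisable
    to JSON."""

    compartments: dict[str, dict] = field(default_factory=dict)
    retention_chi2: float = float("nan")
    retention_p: float = float("nan")
    powerlaw: dict | None = None
    wilcoxon: dict[str, dict[str, float]] = field(default_factory=dict)
    bibc_top_share: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, float) and np.isnan(x):
                return None
            return x

        return {
            "compartments": self.compartments,
            "retention_chi2": clean(self.retention_chi2),
            "retention_p": clean(self.retention_p),
            "powerlaw": self.powerlaw,
            "wilcoxon": self.wilcoxon,
            "bibc_top_share": self.bibc_top_share,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_json(cls, text: str) -> "TopologyReport":
        d = json.loads(text)
        rep = cls(
            compartments=d["compartments"],
            retention_chi2=d["retention_chi2"] if d["retention_chi2"] is not None else float("nan"),
            retention_p=d["retention_p"] if d["retention_p"] is not None else float("nan"),
            powerlaw=d.get("powerlaw"),
            wilcoxon=d.get("wilcoxon", {}),
            bibc_top_share=d.get("bibc_top_share", {}),
        )
        return rep


def compartment_report(
    graph: nx.Graph,
    inputs_per_compartment: dict[str, int],
    host_layers: list[str] | None = None,
    top_fraction: float = 0.20,
    bibc_layer: str | None = None,
) -> TopologyReport:
    """Assemble the full compartment-vs-compartment topology comparison.

    For each compartment ("A"/"B", from node attributes) and each host layer
    present: retained node counts and retention proportion, cross-layer edge
    counts, closeness distributions and their pairwise Wilcoxon comparison.
    BIBC is computed with sources = all microbes of both compartments and
    targets = ``bibc_layer`` (default: the first host layer present); the
    top-``top_fraction`` membership is broken down by compartment.
    Deterministic given the network.
    """
    node_layer = nx.get_node_attributes(graph, "layer")
    node_comp = nx.get_node_attributes(graph, "compartment")
    if len(node_layer) != graph.number_of_nodes():
        raise ValidationError("every node needs a 'layer' attribute")
    if host_layers is None:
        host_layers = sorted(
            {l for n, l in node_layer.items() if node_comp.get(n) == "host"}
        )
    comp_sets = {
        c: {n for n, cc in node_comp.items() if cc == c} for c in ("A", "B")
    }
    layer_sets = {
        l: {n for n, ll in node_layer.items() if ll == l} for l in host_layers
    }

    report = TopologyReport()
    closeness: dict[str, dict[str, SetCloseness]] = {}
    for comp, nodes in comp_sets.items():
        n_in = inputs_per_compartment.get(comp, len(nodes))
        entry: dict = {
            "n_input_features": int(n_in),
            "n_retained": len(nodes),
            "retention_proportion": len(nodes) / n_in if n_in else float("nan"),
            "edges_to_layer": {},
            "closeness": {},
        }
        closeness[comp] = {}
        for layer in host_layers:
            if not nodes or not layer_sets[layer]:
                entry["edges_to_layer"][layer] = 0
                entry["closeness"][layer] = SetCloseness(np.array([]), 0).to_dict()
                continue
            entry["edges_to_layer"][layer] = bipartite_edge_count(
                graph, nodes, layer_sets[layer]
            )
            sc = set_closeness(graph, nodes, layer_sets[layer])
            closeness[comp][layer] = sc
            entry["closeness"][layer] = sc.to_dict()
        report.compartments[comp] = entry

    chi2, p = retention_comparison(
        report.compartments["A"]["n_input_features"],
        report.compartments["A"]["n_retained"],
        report.compartments["B"]["n_input_features"],
        report.compartments["B"]["n_retained"],
    ) if comp_sets["A"] or comp_sets["B"] else (float("nan"), float("nan"))
    report.retention_chi2, report.retention_p = chi2, p

    try:
        report.powerlaw = degree_powerlaw(graph).to_dict()
        report.powerlaw.pop("histogram", None)
    except ValidationError:
        report.powerlaw = None

    for layer in host_layers:
        sc_a = closeness["A"].get(layer)
        sc_b = closeness["B"].get(layer)
        if sc_a and sc_b and sc_a.lengths.size and sc_b.lengths.size:
            u, p = compare_closeness(sc_a, sc_b)
            report.wilcoxon[layer] = {"U": u, "p": p}

    microbes = comp_sets["A"] | comp_sets["B"]
    if bibc_layer is None:
        bibc_layer = next((l for l in host_layers if layer_sets[l]), None)
    if bibc_layer and microbes and layer_sets.get(bibc_layer):
        scores = bibc(graph, microbes, layer_sets[bibc_layer])
        micro_scores = {n: scores[n] for n in microbes}
        shares = top_fraction_membership(
            micro_scores, {n: node_comp[n] for n in microbes}, fraction=top_fraction
        )
        report.bibc_top_share[bibc_layer] = shares
    return report
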