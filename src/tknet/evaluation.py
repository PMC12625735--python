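"""End-to-end validation experiments on synthetic data with planted truth.

Each function runs the package against an independent oracle or a planted
ground truth and returns the measured quantities.  The test suite asserts on
them; ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .model import TranskingdomModel
from .simulate import SimulationConfig, generate_dataset
from .topology import bibc, fit_powerlaw

__all__ = [
    "bibc_oracle_deviation",
    "compartment_win_rates",
    "permutation_null_edge_rate",
    "anova_null_pass_rate",
    "module_recovery",
    "powerlaw_recovery",
    "puc_on_truth",
]


def _bibc_exhaustive(graph: nx.Graph, set1, set2) -> dict:
    """Independent oracle: enumerate every shortest path explicitly."""
    score = dict.fromkeys(graph.nodes, 0.0)
    for s in set1:
        for t in set2:
            try:
                paths = list(nx.all_shortest_paths(graph, s, t))
            except nx.NetworkXNoPath:
                continue
            for path in paths:
                for v in path[1:-1]:
                    score[v] += 1.0 / len(paths)
    return score


def bibc_oracle_deviation(n_graphs: int = 100, seed: int = 0) -> dict[str, float]:
    """Compare Brandes-restricted BIBC with exhaustive enumeration on random
    graphs (n <= 30, random disjoint source/target sets).

    Returns the largest per-node deviation and the largest deviation of
    Σ_v BIBC(v) from Σ_{reachable pairs}(d(s,t) − 1).
    """
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    max_sum_dev = 0.0
    for _ in range(n_graphs):
        n = int(rng.integers(5, 31))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.5)),
                                seed=int(rng.integers(0, 2**31)))
        nodes = list(g.nodes)
        rng.shuffle(nodes)
        k1 = int(rng.integers(1, max(2, n // 3)))
        k2 = int(rng.integers(1, max(2, n // 3)))
        s1, s2 = set(nodes[:k1]), set(nodes[k1 : k1 + k2])
        fast = bibc(g, s1, s2)
        brute = _bibc_exhaustive(g, s1, s2)
        max_dev = max(max_dev, max(abs(fast[v] - brute[v]) for v in g.nodes))
        expected_total = 0.0
        for s in s1:
            dist = nx.single_source_shortest_path_length(g, s)
            expected_total += sum(dist[t] - 1 for t in s2 if t in dist)
        max_sum_dev = max(max_sum_dev, abs(sum(fast.values()) - expected_total))
    return {"max_node_deviation": max_dev, "max_sum_identity_deviation": max_sum_dev}


def _compare_once(config: SimulationConfig, seed: int) -> dict[str, int]:
    """One synthetic study: which compartment wins each topology metric."""
    ds, _ = generate_dataset(config.with_seed(seed))
    res = TranskingdomModel.from_dataset(ds, seed=seed).fit()
    c = res.topology.compartments
    ra = c["A"]["retention_proportion"] or 0.0
    rb = c["B"]["retention_proportion"] or 0.0
    ea = c["A"]["edges_to_layer"]["genes"]
    eb = c["B"]["edges_to_layer"]["genes"]
    pa = c["A"]["closeness"]["genes"]["mean"]
    pb = c["B"]["closeness"]["genes"]["mean"]
    pa = np.inf if pa is None else pa  # empty distribution = unreachable
    pb = np.inf if pb is None else pb
    out = {
        "ret_A": int(ra > rb), "ret_B": int(rb > ra),
        "edges_A": int(ea > eb), "edges_B": int(eb > ea),
        "path_A": 0, "path_B": 0,
    }
    if np.isfinite(pa) or np.isfinite(pb):
        out["path_A"] = int(pa < pb)
        out["path_B"] = int(pb < pa)
    return out


def compartment_win_rates(
    n_seeds: int, seed0: int, symmetric: bool = False
) -> dict[str, float]:
    """Win rates of each compartment over ``n_seeds`` synthetic studies.

    Default config plants loading_A=0.8 vs loading_B=0.3; ``symmetric`` sets
    both to 0.8 (exchangeable compartments).  Ties count as a win for neither.
    """
    config = SimulationConfig(loading_B=0.8) if symmetric else SimulationConfig()
    tally = {k: 0 for k in ("ret_A", "ret_B", "edges_A", "edges_B", "path_A", "path_B")}
    for i in range(n_seeds):
        wins = _compare_once(config, seed0 + i)
        for k, v in wins.items():
            tally[k] += v
    return {k: v / n_seeds for k, v in tally.items()}


def permutation_null_edge_rate(
    n_permutations: int = 10, n_features: int = 200, n_per_group: int = 12,
    fdr: float = 0.05, seed: int = 0,
) -> float:
    """Average retained-edge fraction under the global null.

    Each feature's sample order is permuted independently, destroying every
    inter-feature association; the network is then built (screen disabled) and
    the retained/candidate ratio recorded.
    """
    from .network import NetworkConfig, build_network

    rng = np.random.default_rng(seed)
    n_samples = 2 * n_per_group
    diet = np.array(["NC"] * n_per_group + ["HFD"] * n_per_group)
    samples = [f"s{i}" for i in range(n_samples)]
    rates = []
    for _ in range(n_permutations):
        y = rng.normal(size=(n_features, n_samples))
        y = np.array([rng.permutation(row) for row in y])
        half = n_features // 2
        tables = {
            "genes": pd.DataFrame(y[:half], columns=samples,
                                  index=[f"g{i}" for i in range(half)]),
            "metab_serum": pd.DataFrame(y[half:], columns=samples,
                                        index=[f"m{i}" for i in range(n_features - half)]),
        }
        diff = {
            layer: pd.DataFrame(
                {"lfc": 1.0, "q": 0.01, "sign": 1.0, "pass": True, "p": 0.01,
                 "mean_NC": 0.0, "mean_HFD": 1.0, "stat": 0.0},
                index=t.index,
            )
            for layer, t in tables.items()
        }
        _, report = build_network(
            tables, diff, diet,
            NetworkConfig(fdr=fdr, require_coherence=False), screen=False,
        )
        rates.append(report.n_retained / report.n_candidates)
    return float(np.mean(rates))


def anova_null_pass_rate(
    n_features: int = 1000, n_per_cell: int = 6, fdr: float = 0.05, seed: int = 0
) -> float:
    """Interaction discovery rate under a purely additive two-factor model."""
    from .differential import two_way_anova

    rng = np.random.default_rng(seed)
    n = 4 * n_per_cell
    diet = np.repeat(["NC", "HFD"], n // 2)
    seg = np.tile(np.repeat(["A", "B"], n_per_cell), 2)
    y = (
        rng.normal(size=(n_features, n))
        + rng.normal(size=(n_features, 1)) * (diet == "HFD")
        + rng.normal(size=(n_features, 1)) * (seg == "B")
    )
    table = pd.DataFrame(y, index=[f"f{i}" for i in range(n_features)],
                         columns=[f"s{j}" for j in range(n)])
    res = two_way_anova(table, diet, seg, fdr=fdr)
    return float(res["pass"].mean())


def module_recovery(n_seeds: int = 10, seed0: int = 0) -> dict[str, float]:
    """Detect the two planted gene modules (two latent factors, equal
    couplings) and report per-seed minimum Jaccard with the planted blocks,
    plus the largest deviation of reported densities from 2e/(n(n−1))."""
    jaccards = []
    density_dev = 0.0
    n_two_found = 0
    for i in range(n_seeds):
        seed = seed0 + i
        cfg = SimulationConfig(seed=seed, n_factors=2, loading_B=0.8)
        ds, truth = generate_dataset(cfg)
        res = TranskingdomModel.from_dataset(ds, seed=seed).fit()
        blocks = list(truth.gene_blocks().values())
        if len(res.subnetworks) == 2:
            n_two_found += 1
        best = []
        for sn in res.subnetworks:
            best.append(max(len(sn.members & b) / len(sn.members | b) for b in blocks))
            sub = res.network.subgraph(sn.members)
            e, n = sub.number_of_edges(), sn.n_nodes
            density_dev = max(density_dev, abs(sn.density - 2 * e / (n * (n - 1))))
        jaccards.append(min(best) if len(best) == 2 else 0.0)
    return {
        "seeds_with_min_jaccard_ge_0.9": float(np.mean([j >= 0.9 for j in jaccards])),
        "median_min_jaccard": float(np.median(jaccards)),
        "max_density_deviation": density_dev,
        "fraction_two_modules_found": n_two_found / n_seeds,
    }


def powerlaw_recovery(
    alpha: float = 2.5, n: int = 5000, k_min_fit: int = 4, seed: int = 0
) -> float:
    """Simulate degrees from an exact discrete power law and re-estimate the
    exponent.  The fit uses k_min where the shifted-continuous MLE
    approximation is accurate."""
    rng = np.random.default_rng(seed)
    k = np.arange(1, 10**6 + 1)
    p = k**-alpha
    p /= p.sum()
    draws = rng.choice(k, size=n, p=p)
    return fit_powerlaw(draws, k_min=k_min_fit).alpha


def puc_on_truth(seed: int = 0) -> float:
    """PUC of the default-config network: the generator plants coherent signs,
    so the proportion of unexpected correlations should be ~0."""
    ds, _ = generate_dataset(SimulationConfig(seed=seed))
    res = TranskingdomModel.from_dataset(ds, seed=seed).fit()
    return float(res.construction.puc)
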