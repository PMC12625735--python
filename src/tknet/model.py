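"""Statsmodels-style model/results interface to the whole analysis.

:class:`TranskingdomModel` holds the multi-omics tables and every analysis
setting; :meth:`TranskingdomModel.fit` runs the full chain —

    CLR → differential screen → meta-analytic correlation network →
    compartment topology comparison → dense gene subnetworks

— and returns a :class:`TranskingdomResults` carrying the network, the
per-layer differential tables, the topology report, the subnetworks and a
``summary()`` verdict table answering the study's question: which gut
compartment's microbiota is topologically closer to the host?
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as tkio
from .differential import (
    align_union,
    clr_transform,
    compartment_specific_features,
    shannon_diversity,
    two_group_differential,
    two_way_anova,
)
from .exceptions import ValidationError
from .layers import (
    COUNT_LAYERS,
    GENES,
    HOST_LAYERS,
    MICROBES_A,
    MICROBES_B,
)
from .network import NetworkConfig, build_network
from .simulate import MultiOmicsDataset
from .subnetworks import (
    Subnetwork,
    compartment_to_subnetwork_closeness,
    detect_dense_subnetworks,
)
from .topology import TopologyReport, compare_closeness, compartment_report

__all__ = ["TranskingdomModel", "TranskingdomResults"]


class TranskingdomModel:
    """Transkingdom network analysis of a paired-compartment multi-omics study.

    Parameters
    ----------
    tables : dict[str, DataFrame]
        Features × samples matrix per layer (microbes_A/microbes_B counts,
        continuous host layers), all sharing the same sample columns.
    metadata : DataFrame
        Indexed by sample id with a ``diet`` column in {NC, HFD}.
    diff_test, diff_fdr, pseudocount
        Two-group screen settings (Mann–Whitney or Welch; CLR pseudocount).
    network : NetworkConfig
        Correlation method, edge FDR, coherence and cross-compartment flags.
    top_fraction, bibc_layer
        BIBC hub-extraction settings (top 20% by default; target layer
        defaults to the gene layer when present).
    subnet_layer, subnet_k, subnet_min_size, seed
        Dense-subnetwork detection settings (Louvain is seeded).
    """

    def __init__(
        self,
        tables: dict[str, pd.DataFrame],
        metadata: pd.DataFrame,
        *,
        diff_test: str = "mannwhitney",
        diff_fdr: float = 0.05,
        pseudocount: float = 0.5,
        network: NetworkConfig | None = None,
        screen: bool = True,
        top_fraction: float = 0.20,
        bibc_layer: str | None = None,
        subnet_layer: str = GENES,
        subnet_k: int = 2,
        subnet_min_size: int = 10,
        seed: int = 0,
    ) -> None:
        if "diet" not in metadata.columns:
            raise ValidationError("metadata needs a 'diet' column")
        self.tables = dict(tables)
        self.metadata = metadata
        self.diff_test = diff_test
        self.diff_fdr = diff_fdr
        self.pseudocount = pseudocount
        self.network_config = network or NetworkConfig()
        self.screen = screen
        self.top_fraction = top_fraction
        self.bibc_layer = bibc_layer
        self.subnet_layer = subnet_layer
        self.subnet_k = subnet_k
        self.subnet_min_size = subnet_min_size
        self.seed = seed

    @classmethod
    def from_dataset(cls, dataset: MultiOmicsDataset, **kwargs) -> "TranskingdomModel":
        return cls(dataset.tables, dataset.metadata, **kwargs)

    @classmethod
    def from_directory(cls, directory: str | Path, **kwargs) -> "TranskingdomModel":
        return cls.from_dataset(tkio.read_dataset(directory), **kwargs)

    # ------------------------------------------------------------------ fit
    def fit(self) -> "TranskingdomResults":
        diet = self.metadata["diet"].to_numpy()

        # 1. normalise: CLR on compositional microbial counts
        analysis_tables: dict[str, pd.DataFrame] = {}
        for layer, table in self.tables.items():
            if layer in COUNT_LAYERS:
                analysis_tables[layer] = clr_transform(table, self.pseudocount)
            else:
                analysis_tables[layer] = table

        # 2. per-layer two-group screen (fold-change signs feed coherence)
        diff: dict[str, pd.DataFrame] = {}
        for layer, table in analysis_tables.items():
            diff[layer] = two_group_differential(
                table,
                diet,
                method=self.diff_test,
                fdr=self.diff_fdr,
                pseudocount=self.pseudocount,
                log_scale=layer in COUNT_LAYERS,
            )

        # 3. network
        graph, construction = build_network(
            analysis_tables,
            diff,
            diet,
            config=self.network_config,
            screen=self.screen,
        )

        # 4. topology comparison
        host_present = [l for l in HOST_LAYERS if l in self.tables]
        bibc_layer = self.bibc_layer or (GENES if GENES in self.tables else None)
        topology = compartment_report(
            graph,
            construction.inputs_per_compartment,
            host_layers=host_present,
            top_fraction=self.top_fraction,
            bibc_layer=bibc_layer,
        )

        # 5. dense subnetworks within the chosen host layer + closeness
        subnets: list[Subnetwork] = []
        subnet_closeness: dict[int, dict[str, dict]] = {}
        try:
            subnets = detect_dense_subnetworks(
                graph,
                self.subnet_layer,
                k=self.subnet_k,
                min_size=self.subnet_min_size,
                seed=self.seed,
            )
        except ValidationError as exc:
            warnings.warn(f"subnetwork detection skipped: {exc}")
        comp_sets = {
            c: {n for n, d in graph.nodes(data=True) if d.get("compartment") == c}
            for c in ("A", "B")
        }
        for sn in subnets:
            subnet_closeness[sn.id] = {}
            for comp, nodes in comp_sets.items():
                if not nodes:
                    continue
                sc = compartment_to_subnetwork_closeness(graph, nodes, sn)
                subnet_closeness[sn.id][comp] = sc.to_dict()
                subnet_closeness[sn.id][comp]["_lengths"] = sc.lengths

        # 6. descriptive microbiome statistics
        shannon = {
            layer: shannon_diversity(self.tables[layer])
            for layer in (MICROBES_A, MICROBES_B)
            if layer in self.tables
            and (self.tables[layer].to_numpy().sum(axis=0) > 0).all()
        }
        specific: tuple[set, set] | None = None
        anova: pd.DataFrame | None = None
        if MICROBES_A in self.tables and MICROBES_B in self.tables:
            ta, tb = align_union(self.tables[MICROBES_A], self.tables[MICROBES_B])
            specific = compartment_specific_features(ta, tb)
            anova = self._shared_genus_anova(diet)

        return TranskingdomResults(
            model=self,
            network=graph,
            construction=construction,
            diff=diff,
            topology=topology,
            subnetworks=subnets,
            subnetwork_closeness=subnet_closeness,
            shannon=shannon,
            specific_genera=specific,
            anova=anova,
        )

    def _shared_genus_anova(self, diet: np.ndarray) -> pd.DataFrame | None:
        """Diet×segment two-way ANOVA on genera measured in both compartments.

        The two compartment tables are stacked column-wise (each mouse
        contributes one column per segment) on the shared genus namespace and
        CLR-normalised per (sample, segment)."""
        shared = self.tables[MICROBES_A].index.intersection(
            self.tables[MICROBES_B].index
        )
        if len(shared) < 2:
            return None
        a = self.tables[MICROBES_A].loc[shared]
        b = self.tables[MICROBES_B].loc[shared]
        clr_a = clr_transform(a, self.pseudocount)
        clr_b = clr_transform(b, self.pseudocount)
        stacked = pd.concat(
            [clr_a.add_suffix("_A"), clr_b.add_suffix("_B")], axis=1
        )
        diet_labels = np.concatenate([diet, diet])
        seg_labels = np.array(["A"] * clr_a.shape[1] + ["B"] * clr_b.shape[1])
        return two_way_anova(stacked, diet_labels, seg_labels, fdr=self.diff_fdr)


@dataclass
class TranskingdomResults:
    """Everything the fit produced; see :meth:`summary` for the verdict."""

    model: TranskingdomModel
    network: nx.Graph
    construction: object
    diff: dict[str, pd.DataFrame]
    topology: TopologyReport
    subnetworks: list[Subnetwork]
    subnetwork_closeness: dict[int, dict[str, dict]] = field(default_factory=dict)
    shannon: dict[str, pd.Series] = field(default_factory=dict)
    specific_genera: tuple[set, set] | None = None
    anova: pd.DataFrame | None = None

    # ------------------------------------------------------------- queries
    def compare_table(self) -> pd.DataFrame:
        """Per-host-layer A-vs-B comparison: retention, cross edges, average
        shortest path, Wilcoxon p, and which compartment is closer."""
        rows = []
        comp = self.topology.compartments
        for layer in sorted(
            set(comp.get("A", {}).get("edges_to_layer", {}))
            | set(comp.get("B", {}).get("edges_to_layer", {}))
        ):
            mean_a = comp["A"]["closeness"].get(layer, {}).get("mean")
            mean_b = comp["B"]["closeness"].get(layer, {}).get("mean")
            wil = self.topology.wilcoxon.get(layer, {})
            closer = None
            if mean_a is not None and mean_b is not None and mean_a != mean_b:
                closer = "A" if mean_a < mean_b else "B"
            rows.append(
                {
                    "host_layer": layer,
                    "edges_A": comp["A"]["edges_to_layer"].get(layer, 0),
                    "edges_B": comp["B"]["edges_to_layer"].get(layer, 0),
                    "avg_path_A": mean_a,
                    "avg_path_B": mean_b,
                    "wilcoxon_p": wil.get("p"),
                    "closer": closer,
                }
            )
        return pd.DataFrame(rows).set_index("host_layer")

    def summary(self) -> str:
        """Human-readable verdict table in the spirit of a model summary."""
        c = self.construction
        comp = self.topology.compartments
        puc_txt = f"{c.puc:.4f}" if np.isfinite(c.puc) else "n/a"
        lines = [
            "Transkingdom Network Analysis Results",
            "=" * 72,
            f"Nodes: {self.network.number_of_nodes()}   "
            f"Edges: {self.network.number_of_edges()}   "
            f"Candidates: {c.n_candidates}   PUC: {puc_txt}",
            "-" * 72,
            "Retention (features with >=1 edge / screened features):",
        ]
        for label in ("A", "B"):
            if label in comp:
                e = comp[label]
                lines.append(
                    f"  compartment {label}: {e['n_retained']}/{e['n_input_features']}"
                    f" = {e['retention_proportion']:.3f}"
                )
        if np.isfinite(self.topology.retention_chi2):
            lines.append(
                f"  chi2 = {self.topology.retention_chi2:.3f}, "
                f"p = {self.topology.retention_p:.3g}"
            )
        lines.append("-" * 72)
        table = self.compare_table()
        if not table.empty:
            lines.append(table.to_string(float_format=lambda v: f"{v:.4g}"))
        if self.topology.bibc_top_share:
            lines.append("-" * 72)
            for layer, shares in self.topology.bibc_top_share.items():
                share_txt = ", ".join(f"{k}: {v:.2f}" for k, v in sorted(shares.items()))
                lines.append(f"Top-{self.model.top_fraction:.0%} BIBC vs {layer}: {share_txt}")
        if self.subnetworks:
            lines.append("-" * 72)
            for sn in self.subnetworks:
                lines.append(
                    f"Subnetwork {sn.id}: n={sn.n_nodes}, density={sn.density:.3f}"
                )
                for compartment, d in sorted(self.subnetwork_closeness.get(sn.id, {}).items()):
                    m = d.get("mean")
                    lines.append(
                        f"  distance from {compartment}: "
                        + (f"{m:.3f}" if m is not None else "unreachable")
                    )
        lines.append("=" * 72)
        return "\n".join(lines)

    def subnetwork_wilcoxon(self, subnet_id: int) -> tuple[float, float] | None:
        """Wilcoxon comparison of the two compartments' distances to one
        subnetwork (None when either distribution is empty)."""
        d = self.subnetwork_closeness.get(subnet_id, {})
        if "A" not in d or "B" not in d:
            return None
        la, lb = d["A"]["_lengths"], d["B"]["_lengths"]
        if la.size == 0 or lb.size == 0:
            return None
        return compare_closeness(la, lb)

    def report_dict(self) -> dict:
        """JSON-safe bundle of every headline number."""
        out = {
            "construction": self.construction.to_dict(),
            "topology": self.topology.to_dict(),
            "subnetworks": [sn.to_dict() for sn in self.subnetworks],
            "subnetwork_closeness": {
                str(i): {
                    c: {k: v for k, v in d.items() if k != "_lengths"}
                    for c, d in by_comp.items()
                }
                for i, by_comp in self.subnetwork_closeness.items()
            },
            "shannon_mean": {k: float(v.mean()) for k, v in self.shannon.items()},
        }
        if self.specific_genera is not None:
            out["n_specific_A"] = len(self.specific_genera[0])
            out["n_specific_B"] = len(self.specific_genera[1])
        if self.anova is not None:
            out["n_interaction_taxa"] = int(self.anova["pass"].sum())
        return out

    def save(self, directory: str | Path) -> dict[str, Path]:
        """Write every artifact (GraphML, edge list, differential TSVs,
        topology JSON, subnetwork tables, combined report)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["network"] = directory / "network.graphml"
        tkio.write_graphml(
            self.network,
            paths["network"],
            inputs_A=self.construction.inputs_per_compartment.get("A", 0),
            inputs_B=self.construction.inputs_per_compartment.get("B", 0),
            puc=self.construction.puc if np.isfinite(self.construction.puc) else -1.0,
        )
        paths["edges"] = directory / "edges.tsv"
        tkio.write_edge_list(self.network, paths["edges"])
        for layer, table in self.diff.items():
            p = directory / f"diff_{layer}.tsv"
            table.to_csv(p, sep="\t")
            paths[f"diff_{layer}"] = p
        if self.anova is not None:
            paths["anova"] = directory / "anova_shared_genera.tsv"
            self.anova.to_csv(paths["anova"], sep="\t")
        paths["topology"] = directory / "topology.json"
        paths["topology"].write_text(self.topology.to_json(indent=2))
        if self.subnetworks:
            rows = [
                {"node": n, "subnetwork_id": sn.id}
                for sn in self.subnetworks
                for n in sorted(sn.members)
            ]
            paths["subnetworks"] = directory / "subnetworks.tsv"
            pd.DataFrame(rows).to_csv(paths["subnetworks"], sep="\t", index=False)
        paths["report"] = directory / "report.json"
        paths["report"].write_text(json.dumps(self.report_dict(), indent=2))
        paths["summary"] = directory / "summary.txt"
        paths["summary"].write_text(self.summary() + "\n")
        return paths
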