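"""Readers/writers and pipeline configuration.

Feature tables are TSV: header row of sample ids, first column feature ids,
numeric cells.  Networks interchange as GraphML (attribute-rich) plus a
grep-able edge-list TSV.  The pipeline configuration is a strict YAML
mapping — unknown keys are errors, so a typo'd threshold cannot silently
fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, ValidationError
from .layers import ALL_LAYERS
from .simulate import MultiOmicsDataset

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "read_dataset",
    "write_graphml",
    "read_graphml",
    "write_edge_list",
    "PipelineConfig",
    "load_pipeline_config",
]


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a features × samples TSV; duplicate feature ids and non-numeric
    cells are errors naming the offender."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature ids in {path.name}: {dups[:5]}")
    if df.columns.has_duplicates:
        raise ValidationError(f"duplicate sample ids in {path.name}")
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str))
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"non-numeric value in {path.name} at row {row!r}, column {col!r}"
            )
        out[col] = converted
    out.index.name = df.index.name
    return out.astype(float)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table = table.copy()
    if table.index.name is None:
        table.index.name = "feature_id"
    table.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "diet" not in meta.columns:
        raise ValidationError("metadata must have a 'diet' column")
    return meta


def read_dataset(directory: str | Path) -> MultiOmicsDataset:
    """Load every recognised layer TSV plus metadata.tsv from a directory."""
    directory = Path(directory)
    meta = read_metadata(directory / "metadata.tsv")
    tables: dict[str, pd.DataFrame] = {}
    for layer in ALL_LAYERS:
        path = directory / f"{layer}.tsv"
        if path.exists():
            table = read_feature_table(path)
            missing = set(meta.index) - set(table.columns)
            if missing:
                raise ValidationError(
                    f"layer {layer} lacks samples {sorted(missing)[:5]}"
                )
            tables[layer] = table[list(meta.index)]
    if not tables:
        raise ValidationError(f"no layer tables found in {directory}")
    # integer counts for microbial layers round-trip exactly
    for layer in ("microbes_A", "microbes_B"):
        if layer in tables:
            t = tables[layer]
            if np.allclose(t.to_numpy(), np.round(t.to_numpy())):
                tables[layer] = t.round().astype(np.int64)
    return MultiOmicsDataset(tables=tables, metadata=meta)


def write_graphml(graph: nx.Graph, path: str | Path, **graph_attrs) -> None:
    g = graph.copy()
    g.graph.update({k: v for k, v in graph_attrs.items() if v is not None})
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    rows = [
        {"node_a": u, "node_b": v, **d} for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(
        rows, columns=["node_a", "node_b", "r_NC", "r_HFD", "combined_p", "q", "sign"]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class PipelineConfig:
    """Validated end-to-end pipeline settings (see package README)."""

    data_dir: str
    output_dir: str
    seed: int = 0
    # differential
    diff_test: str = "mannwhitney"
    diff_fdr: float = 0.05
    pseudocount: float = 0.5
    # network
    corr_method: str = "spearman"
    network_fdr: float = 0.05
    require_coherence: bool = True
    exclude_cross_compartment: bool = True
    screen: bool = True
    # topology
    top_fraction: float = 0.20
    bibc_layer: str | None = None
    # subnetworks
    subnet_layer: str = "genes"
    subnet_k: int = 2
    subnet_min_size: int = 10

    def validate(self, check_paths: bool = True) -> None:
        for name in ("diff_fdr", "network_fdr"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
        if not (0 < self.top_fraction <= 1):
            raise ConfigurationError("top_fraction must lie in (0, 1]")
        if self.diff_test not in ("mannwhitney", "welch"):
            raise ConfigurationError(f"unknown diff_test {self.diff_test!r}")
        if self.corr_method not in ("spearman", "pearson"):
            raise ConfigurationError(f"unknown corr_method {self.corr_method!r}")
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed must be an integer")
        if check_paths and not Path(self.data_dir).is_dir():
            raise ConfigurationError(f"data_dir does not exist: {self.data_dir}")


def load_pipeline_config(path: str | Path, check_paths: bool = True) -> PipelineConfig:
    """Load and strictly validate a YAML pipeline config (unknown keys error)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a YAML mapping")
    known = {f.name for f in dc_fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "data_dir" not in raw or "output_dir" not in raw:
        raise ConfigurationError("config needs data_dir and output_dir")
    cfg = PipelineConfig(**raw)
    cfg.validate(check_paths=check_paths)
    return cfg
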