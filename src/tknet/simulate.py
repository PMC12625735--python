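"""Synthetic paired-compartment multi-omics generator with planted ground truth.

Emulates the design of a diet-induced-obesity mouse study: two diet groups
(normal chow ``NC`` vs high-fat diet ``HFD``), two gut compartments whose
microbiota are profiled by compositional counts, plus continuous host layers
(liver transcriptome, serum and liver metabolome, metabolic phenotypes).

The generative model is a latent Gaussian factor model.  Each sample draws
``n_factors`` independent standard-normal factors; every feature loads on
exactly one factor, drawn uniformly.  Both compartments' microbes couple to
the same host physiology axes: compartment-A microbes load with magnitude
``loading_A``, compartment-B microbes with ``loading_B``.  Two features
sharing a factor are therefore correlated with a sign equal to the product
of their loading signs — these are the planted "coupled pairs" the
downstream network is expected to recover.  Setting
``loading_A > loading_B`` plants the compartment asymmetry (one compartment's
microbes couple more strongly to the host); ``loading_A == loading_B`` makes
the compartments exactly exchangeable.

Host features load on their factor with a fixed magnitude
(``HOST_LOADING`` = 0.8): the compartment coupling strengths act on the
microbial side, so the microbe–host correlation scales with the compartment's
loading while host–host structure (e.g. gene co-expression modules) stays
intact even for a weakly coupled compartment.

Microbial latents are softmax-normalised per sample and counts drawn
multinomially at a fixed sequencing depth, so microbial tables are
compositional integer counts.  Genes and metabolites are log-normal; the
phenotypes are linear in the factors.  Diet-effect signs are assigned per
factor so that for every coupled pair the product of the two endpoints'
diet-effect signs equals the planted correlation sign — the fold-change
coherence filter (PUC) is then ≈ 0 on truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .layers import (
    ALL_LAYERS,
    COMPARTMENT,
    GENES,
    HOST_LAYERS,
    METAB_LIVER,
    METAB_SERUM,
    MICROBES_A,
    MICROBES_B,
    PHENOTYPES,
    node_id,
)

#: loading magnitude of host features on their latent factor
HOST_LOADING = 0.8

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "MultiOmicsDataset",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    ``loading_A``/``loading_B`` are the cross-kingdom coupling strengths of
    the two gut compartments (dimensionless factor loadings);
    ``diet_effect_sd`` is the magnitude of the diet shift on the latent scale
    (latent residual SD is ``noise_sd``); ``sequencing_depth`` is the total
    microbial count per sample.  ``n_shared_microbes`` genera are measured in
    both compartments under the same genus id (needed for the diet×segment
    ANOVA and the compartment-specific genus screen); the remaining genera
    are resident in one compartment only.
    """

    n_per_group: int = 12
    n_microbes_A: int = 30
    n_microbes_B: int = 30
    n_genes: int = 40
    n_metab_serum: int = 20
    n_metab_liver: int = 20
    n_phenotypes: int = 8
    n_factors: int = 4
    loading_A: float = 0.8
    loading_B: float = 0.3
    diet_effect_sd: float = 2.0
    sequencing_depth: int = 10_000
    noise_sd: float = 0.4
    n_shared_microbes: int | None = None
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_microbes_A": self.n_microbes_A,
            "n_microbes_B": self.n_microbes_B,
            "n_genes": self.n_genes,
            "n_metab_serum": self.n_metab_serum,
            "n_metab_liver": self.n_metab_liver,
            "n_phenotypes": self.n_phenotypes,
            "n_factors": self.n_factors,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {value}")
        if self.n_per_group < 4:
            raise ConfigurationError("n_per_group must be >= 4")
        if self.loading_A < 0 or self.loading_B < 0:
            raise ConfigurationError("loadings must be >= 0")
        if self.sequencing_depth < 100:
            raise ConfigurationError("sequencing_depth must be >= 100")
        if self.noise_sd < 0 or self.diet_effect_sd < 0:
            raise ConfigurationError("scale parameters must be >= 0")
        if self.n_shared_microbes is not None and not (
            0 <= self.n_shared_microbes <= min(self.n_microbes_A, self.n_microbes_B)
        ):
            raise ConfigurationError(
                "n_shared_microbes must lie in [0, min(n_microbes_A, n_microbes_B)]"
            )

    @property
    def shared_microbes(self) -> int:
        if self.n_shared_microbes is not None:
            return self.n_shared_microbes
        return min(self.n_microbes_A, self.n_microbes_B) // 3

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticTruth:
    """Planted ground truth: what a perfect analysis should recover.

    ``coupled_pairs`` lists every (microbe node, host node, expected
    correlation sign) sharing a latent factor.  ``factor_loadings`` is a
    per-node table with the factor index, signed loading, diet-effect sign
    and layer.  ``diet_effect_sign`` maps node -> planted
    sign of the HFD-vs-NC shift (0 when diet_effect_sd == 0).
    """

    coupled_pairs: pd.DataFrame  # columns: microbe, host, sign
    factor_loadings: pd.DataFrame  # index: node; layer, factor, loading, diet_sign
    diet_effect_sign: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.diet_effect_sign is None:
            self.diet_effect_sign = self.factor_loadings["diet_sign"].copy()

    def gene_blocks(self) -> dict[int, set[str]]:
        """Gene nodes grouped by their latent factor (the planted modules)."""
        genes = self.factor_loadings[self.factor_loadings["layer"] == GENES]
        return {int(f): set(idx) for f, idx in genes.groupby("factor").groups.items()}


@dataclass
class MultiOmicsDataset:
    """One feature table per omic layer plus sample metadata.

    Tables are features × samples DataFrames sharing the same sample columns;
    microbial tables hold non-negative integer counts whose columns each sum
    to the sequencing depth.  ``metadata`` is indexed by sample id with a
    ``diet`` column in {NC, HFD}.
    """

    tables: dict[str, pd.DataFrame]
    metadata: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.metadata.index)

    @property
    def diet(self) -> pd.Series:
        return self.metadata["diet"]

    def layer(self, name: str) -> pd.DataFrame:
        return self.tables[name]


def _feature_names(config: SimulationConfig) -> dict[str, list[str]]:
    n_shared = config.shared_microbes
    shared = [f"g{j:04d}" for j in range(n_shared)]
    only_a = [f"gA{j:04d}" for j in range(config.n_microbes_A - n_shared)]
    only_b = [f"gB{j:04d}" for j in range(config.n_microbes_B - n_shared)]
    return {
        MICROBES_A: shared + only_a,
        MICROBES_B: shared + only_b,
        GENES: [f"gene{j:04d}" for j in range(config.n_genes)],
        METAB_SERUM: [f"ms{j:04d}" for j in range(config.n_metab_serum)],
        METAB_LIVER: [f"ml{j:04d}" for j in range(config.n_metab_liver)],
        PHENOTYPES: [f"pheno{j:02d}" for j in range(config.n_phenotypes)],
    }


def generate_dataset(config: SimulationConfig) -> tuple[MultiOmicsDataset, SyntheticTruth]:
    """Draw one synthetic study from the latent factor model.

    A single RNG stream (seeded from ``config.seed``) is consumed in a fixed
    order — factors, per-layer feature parameters, per-layer noise, microbial
    count draws — so the output is bit-reproducible across calls and
    platforms.

    Returns the dataset and the planted truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_samples = 2 * config.n_per_group
    samples = [f"S{j + 1:03d}" for j in range(n_samples)]
    diet = np.array(["NC"] * config.n_per_group + ["HFD"] * config.n_per_group)
    hfd = (diet == "HFD").astype(float)
    metadata = pd.DataFrame({"diet": diet}, index=pd.Index(samples, name="sample_id"))

    k = config.n_factors
    all_factors = np.arange(k)
    z = rng.standard_normal((n_samples, k))
    factor_diet_sign = rng.choice([-1.0, 1.0], size=k)

    names = _feature_names(config)
    truth_rows: list[dict] = []
    tables: dict[str, pd.DataFrame] = {}

    def draw_latent(layer: str, feats: list[str], factor_pool: np.ndarray,
                    magnitude: float) -> np.ndarray:
        """Latent matrix (features × samples); records truth rows as a side effect."""
        m = len(feats)
        factors = rng.choice(factor_pool, size=m)
        # loading signs alternate within each factor so compositional closure
        # (softmax + CLR centring) cannot cancel the planted couplings or the
        # diet shifts: the per-sample mean of the latents stays ~0
        signs = np.empty(m)
        for f in np.unique(factors):
            idx = np.flatnonzero(factors == f)
            signs[idx] = np.where(np.arange(idx.size) % 2 == 0, 1.0, -1.0)
        loadings = signs * magnitude
        baseline = rng.normal(0.0, 1.5, size=m)
        diet_sign = factor_diet_sign[factors] * signs
        if config.diet_effect_sd == 0:
            diet_sign = np.zeros(m)
        # standardised effect: diet_effect_sd is in units of the feature's
        # latent SD, so screen power does not depend on coupling strength
        latent_sd = np.sqrt(magnitude**2 + config.noise_sd**2)
        effect = diet_sign * config.diet_effect_sd * latent_sd
        noise = rng.normal(0.0, config.noise_sd, size=(m, n_samples))
        latent = (
            baseline[:, None]
            + effect[:, None] * hfd[None, :]
            + loadings[:, None] * z[:, factors].T
            + noise
        )
        for j, feat in enumerate(feats):
            truth_rows.append(
                {
                    "node": node_id(layer, feat),
                    "layer": layer,
                    "factor": int(factors[j]),
                    "loading": float(loadings[j]),
                    "diet_sign": float(np.sign(diet_sign[j])),
                }
            )
        return latent

    # microbial layers: softmax -> multinomial at fixed depth
    for layer, mag in (
        (MICROBES_A, config.loading_A),
        (MICROBES_B, config.loading_B),
    ):
        latent = draw_latent(layer, names[layer], all_factors, mag)
        expl = np.exp(latent - latent.max(axis=0, keepdims=True))
        probs = expl / expl.sum(axis=0, keepdims=True)
        counts = np.empty_like(latent, dtype=np.int64)
        for s in range(n_samples):
            counts[:, s] = rng.multinomial(config.sequencing_depth, probs[:, s])
        tables[layer] = pd.DataFrame(counts, index=names[layer], columns=samples)

    # host layers: genes/metabolites log-normal, phenotypes linear
    for layer in (GENES, METAB_SERUM, METAB_LIVER):
        latent = draw_latent(layer, names[layer], all_factors, HOST_LOADING)
        tables[layer] = pd.DataFrame(
            np.exp(latent + 3.0), index=names[layer], columns=samples
        )
    latent = draw_latent(PHENOTYPES, names[PHENOTYPES], all_factors, HOST_LOADING)
    tables[PHENOTYPES] = pd.DataFrame(
        latent + 10.0, index=names[PHENOTYPES], columns=samples
    )

    loadings = pd.DataFrame(truth_rows).set_index("node")

    # coupled pairs: every (microbe, host) sharing a factor, expected sign =
    # product of the two loading signs
    microbes = loadings[loadings["layer"].isin((MICROBES_A, MICROBES_B))]
    hosts = loadings[loadings["layer"].isin(HOST_LAYERS)]
    pairs: list[dict] = []
    for f, micro_group in microbes.groupby("factor"):
        host_group = hosts[hosts["factor"] == f]
        if host_group.empty:
            continue
        for m_node, m_load in micro_group["loading"].items():
            for h_node, h_load in host_group["loading"].items():
                pairs.append(
                    {
                        "microbe": m_node,
                        "host": h_node,
                        "sign": int(np.sign(m_load) * np.sign(h_load)),
                    }
                )
    coupled = pd.DataFrame(pairs, columns=["microbe", "host", "sign"])

    truth = SyntheticTruth(coupled_pairs=coupled, factor_loadings=loadings)
    return MultiOmicsDataset(tables=tables, metadata=metadata), truth


def write_dataset(
    dataset: MultiOmicsDataset, truth: SyntheticTruth | None, directory: str | Path
) -> list[Path]:
    """Write one TSV per layer, the metadata TSV, and the truth tables.

    Round-trips losslessly through :func:`tknet.io.read_dataset`.
    """
    from . import io as tkio  # local import to avoid a cycle

    if str(directory) == "":
        raise OSError("output directory must be a non-empty path")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for layer in ALL_LAYERS:
        if layer in dataset.tables:
            path = directory / f"{layer}.tsv"
            tkio.write_feature_table(dataset.tables[layer], path)
            written.append(path)
    meta_path = directory / "metadata.tsv"
    dataset.metadata.to_csv(meta_path, sep="\t")
    written.append(meta_path)
    if truth is not None:
        pairs_path = directory / "truth_pairs.tsv"
        truth.coupled_pairs.to_csv(pairs_path, sep="\t", index=False)
        loadings_path = directory / "truth_loadings.tsv"
        truth.factor_loadings.to_csv(loadings_path, sep="\t")
        written.extend([pairs_path, loadings_path])
    return written


def compartment_sets(dataset: MultiOmicsDataset) -> dict[str, set[str]]:
    """Node-id sets of the two microbial compartments (for topology calls)."""
    return {
        COMPARTMENT[layer]: {node_id(layer, f) for f in dataset.tables[layer].index}
        for layer in (MICROBES_A, MICROBES_B)
        if layer in dataset.tables
    }
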