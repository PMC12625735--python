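"""End-to-end pipeline orchestration from a validated configuration."""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from . import io as tkio
from .model import TranskingdomModel, TranskingdomResults
from .network import NetworkConfig

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def model_from_config(config: tkio.PipelineConfig) -> TranskingdomModel:
    return TranskingdomModel.from_directory(
        config.data_dir,
        diff_test=config.diff_test,
        diff_fdr=config.diff_fdr,
        pseudocount=config.pseudocount,
        network=NetworkConfig(
            method=config.corr_method,
            fdr=config.network_fdr,
            require_coherence=config.require_coherence,
            exclude_cross_compartment=config.exclude_cross_compartment,
        ),
        screen=config.screen,
        top_fraction=config.top_fraction,
        bibc_layer=config.bibc_layer,
        subnet_layer=config.subnet_layer,
        subnet_k=config.subnet_k,
        subnet_min_size=config.subnet_min_size,
        seed=config.seed,
    )


def run_pipeline(config: tkio.PipelineConfig) -> TranskingdomResults:
    """Run every stage and write all artifacts plus a run log to
    ``config.output_dir``.  Deterministic for fixed inputs and seed."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = model_from_config(config)
    results = model.fit()
    results.save(out)
    log = {
        "tknet_version": __version__,
        "config": {k: getattr(config, k) for k in vars(config)},
    }
    (out / "run.json").write_text(json.dumps(log, indent=2, default=str))
    logger.info("pipeline complete: %s", out)
    return results
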