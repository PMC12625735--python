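"""Over-representation analysis (ORA) of gene hit lists against caller-supplied
gene-set collections (GMT format).

The p-value is the hypergeometric upper tail P[X >= observed overlap] with the
universe as population, the gene set as successes and the hit list as draws;
q-values are BH across sets.  The universe defaults to all genes that entered
network construction — the statistically defensible background for network
modules — not the genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .exceptions import ValidationError

__all__ = ["GeneSetCollection", "ora", "read_gmt", "write_gmt"]


@dataclass
class GeneSetCollection:
    """Named gene sets intersected with a universe."""

    sets: dict[str, frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValidationError("empty universe")
        if len(self.sets) != len(set(self.sets)):
            raise ValidationError("gene set names must be unique")
        self.sets = {
            name: frozenset(s) & self.universe for name, s in self.sets.items()
        }

    @classmethod
    def from_gmt(cls, path: str | Path, universe) -> "GeneSetCollection":
        return cls(sets=read_gmt(path), universe=frozenset(universe))


def read_gmt(path: str | Path) -> dict[str, frozenset]:
    """Read a GMT file: one set per line, tab-separated
    ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, frozenset] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"malformed GMT line: {line[:60]!r}")
        name = parts[0]
        if name in sets:
            raise ValidationError(f"duplicate gene set name {name!r}")
        sets[name] = frozenset(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, frozenset], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(genes)]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def ora(hits, collection: GeneSetCollection, fdr: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each gene set.

    Returns a DataFrame indexed by set name with overlap, set size, p, BH q,
    fold enrichment and a pass flag at ``fdr``, sorted by p.  Hits outside
    the universe are dropped with a warning.
    """
    hits = frozenset(hits)
    outside = hits - collection.universe
    if outside:
        warnings.warn(f"dropping {len(outside)} hits outside the universe")
        hits = hits & collection.universe
    if not hits:
        raise ValidationError("no hits remain inside the universe")
    m_pop = len(collection.universe)
    n_draws = len(hits)
    rows = []
    for name, genes in collection.sets.items():
        k = len(hits & genes)
        n_set = len(genes)
        # P[X >= k] for X ~ Hypergeom(M=m_pop, n=n_set, N=n_draws)
        p = float(stats.hypergeom.sf(k - 1, m_pop, n_set, n_draws)) if n_set else 1.0
        expected = n_set * n_draws / m_pop
        fold = k / expected if expected > 0 else float("nan")
        rows.append(
            {"set": name, "overlap": k, "size": n_set, "p": min(p, 1.0), "fold": fold}
        )
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = bh_adjust(out["p"])
    out["pass"] = out["q"] < fdr
    return out.sort_values("p")
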