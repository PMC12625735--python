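"""Feature screening: CLR normalisation, two-way ANOVA, two-group tests,
compartment-specific genus detection and Shannon diversity.

Microbial count tables are compositional; the centred log-ratio (CLR)
transform, ln(x) minus the per-sample mean of ln(x), maps them onto a scale
where Euclidean statistics apply.  The diet×segment interaction of a two-way
ANOVA on CLR values is the screen for taxa whose diet response differs
between gut compartments; a plain two-group test (Mann–Whitney by default,
Welch optional) supplies per-feature fold-change direction for every layer,
which the network module's coherence filter consumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DesignError, ValidationError

__all__ = [
    "clr_transform",
    "two_way_anova",
    "two_group_differential",
    "compartment_specific_features",
    "shannon_diversity",
    "bh_adjust",
    "align_union",
]


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN p-values stay NaN and do not
    count toward the family size."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def clr_transform(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centred log-ratio transform of a features × samples count table.

    Per sample: ``x -> ln(x + pseudocount) - mean_features ln(x + pseudocount)``.
    Every output column sums to zero.  ``pseudocount`` may be 0 only when all
    counts are strictly positive.
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("CLR requires non-negative counts")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    shifted = values + pseudocount
    if (shifted <= 0).any():
        raise ValidationError(
            "zero counts present: a positive pseudocount is required"
        )
    logx = np.log(shifted)
    clr = logx - logx.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=counts.index, columns=counts.columns)


def _rss(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each row of ``y`` regressed on columns of ``x``."""
    q, _ = np.linalg.qr(x)
    fitted_ss = (y @ q) ** 2
    return (y**2).sum(axis=1) - fitted_ss.sum(axis=1)


def two_way_anova(
    clr: pd.DataFrame,
    diet_labels,
    segment_labels,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-feature 2×2 two-way ANOVA (diet × segment) with type-II sums of squares.

    Returns a DataFrame indexed by feature with F and p for the diet, segment
    and interaction terms; interaction p-values are BH-adjusted across
    features and ``pass`` flags q < ``fdr``.  Features with zero residual
    variance get missing p-values (never 0 or 1).

    Type-II SS are computed by model comparison: each main effect is tested
    against the additive model, the interaction against the full model, so
    mildly unbalanced designs are tolerated; on a balanced design type II
    coincides with the other types.
    """
    y = clr.to_numpy(dtype=float)
    diet = np.asarray(diet_labels)
    seg = np.asarray(segment_labels)
    if y.shape[1] != diet.size or diet.size != seg.size:
        raise ValidationError("label lengths must match the number of sample columns")
    d = (diet == diet[0]).astype(float)  # 0/1 coding; contrast choice cancels in SS
    s = (seg == seg[0]).astype(float)
    if len(np.unique(diet)) != 2 or len(np.unique(seg)) != 2:
        raise DesignError("two-way ANOVA needs exactly two levels per factor")
    for dv in (0.0, 1.0):
        for sv in (0.0, 1.0):
            if ((d == dv) & (s == sv)).sum() < 2:
                raise DesignError("every diet×segment cell needs >= 2 samples")

    one = np.ones_like(d)
    x_full = np.column_stack([one, d, s, d * s])
    x_add = np.column_stack([one, d, s])
    x_d = np.column_stack([one, d])
    x_s = np.column_stack([one, s])

    rss_full = _rss(y, x_full)
    rss_add = _rss(y, x_add)
    rss_d = _rss(y, x_d)
    rss_s = _rss(y, x_s)

    n = y.shape[1]
    df_resid = n - 4
    with np.errstate(divide="ignore", invalid="ignore"):
        mse = rss_full / df_resid
        f_diet = (rss_s - rss_add) / mse
        f_seg = (rss_d - rss_add) / mse
        f_int = (rss_add - rss_full) / mse
    # negative rounding noise from the QR projections
    f_diet = np.clip(f_diet, 0, None)
    f_seg = np.clip(f_seg, 0, None)
    f_int = np.clip(f_int, 0, None)

    degenerate = mse <= np.finfo(float).eps * (y**2).sum(axis=1).clip(min=1.0)
    p_diet = stats.f.sf(f_diet, 1, df_resid)
    p_seg = stats.f.sf(f_seg, 1, df_resid)
    p_int = stats.f.sf(f_int, 1, df_resid)
    for arr in (f_diet, f_seg, f_int, p_diet, p_seg, p_int):
        arr[degenerate] = np.nan

    q_int = bh_adjust(p_int)
    out = pd.DataFrame(
        {
            "F_diet": f_diet,
            "p_diet": p_diet,
            "F_segment": f_seg,
            "p_segment": p_seg,
            "F_interaction": f_int,
            "p_interaction": p_int,
            "q_interaction": q_int,
            "degenerate": degenerate,
        },
        index=clr.index,
    )
    out["pass"] = out["q_interaction"] < fdr
    return out


def two_group_differential(
    table: pd.DataFrame,
    diet_labels,
    method: str = "mannwhitney",
    fdr: float = 0.05,
    pseudocount: float = 0.5,
    counts: bool = False,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Per-feature HFD-vs-NC statistics for one layer.

    ``method`` is ``"mannwhitney"`` (default, rank-based) or ``"welch"``.
    Returns group means, log2 fold change of group means (pseudocount added
    when ``counts``; for ``log_scale`` inputs such as CLR values the lfc is
    the mean difference divided by ln 2), the test statistic, raw p, BH q,
    direction sign (sign of mean(HFD) − mean(NC)) and a ``pass`` flag at
    ``fdr``.  Constant features get missing p and sign 0.
    """
    diet = np.asarray(diet_labels)
    groups = set(diet)
    if groups != {"NC", "HFD"}:
        raise ValidationError(f"diet labels must be NC/HFD, got {sorted(groups)}")
    y = table.to_numpy(dtype=float)
    y_nc = y[:, diet == "NC"]
    y_hfd = y[:, diet == "HFD"]
    if y_nc.shape[1] < 3 or y_hfd.shape[1] < 3:
        raise DesignError("each diet group needs >= 3 samples")

    mean_nc = y_nc.mean(axis=1)
    mean_hfd = y_hfd.mean(axis=1)
    diff = mean_hfd - mean_nc
    sign = np.sign(diff)

    if log_scale:
        lfc = diff / np.log(2)
    else:
        pc = pseudocount if counts else 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            num, den = mean_hfd + pc, mean_nc + pc
            lfc = np.where((num > 0) & (den > 0), np.log2(num / den), np.nan)

    constant = (y.std(axis=1) == 0) | (
        (y_nc.std(axis=1) == 0) & (y_hfd.std(axis=1) == 0) & (diff == 0)
    )
    if method == "mannwhitney":
        res = stats.mannwhitneyu(y_hfd, y_nc, axis=1, alternative="two-sided")
        stat, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
    elif method == "welch":
        res = stats.ttest_ind(y_hfd, y_nc, axis=1, equal_var=False)
        stat, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
    else:
        raise ValidationError(f"unknown method {method!r}")
    p = np.where(constant, np.nan, p)
    sign = np.where(constant, 0.0, sign)

    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "mean_NC": mean_nc,
            "mean_HFD": mean_hfd,
            "lfc": lfc,
            "stat": stat,
            "p": p,
            "q": q,
            "sign": sign,
        },
        index=table.index,
    )
    out["pass"] = out["q"] < fdr
    return out


def align_union(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reindex two genus tables onto their union namespace, filling absent
    genera with zero counts (a genus not measured in a compartment is absent
    from it)."""
    union = table_a.index.union(table_b.index)
    return (
        table_a.reindex(union, fill_value=0),
        table_b.reindex(union, fill_value=0),
    )


def compartment_specific_features(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    prevalence_min: float = 0.5,
    max_other_prevalence: float = 0.0,
) -> tuple[set[str], set[str]]:
    """Genera specific to one compartment.

    A genus is specific to A iff present (count > 0) in at least
    ``prevalence_min`` of A samples and in at most ``max_other_prevalence``
    of B samples (default: ≥50% prevalence in A, complete absence in B).
    Both tables must share the same genus namespace (use :func:`align_union`
    first when they do not).  Returns the two disjoint sets.
    """
    if not table_a.index.equals(table_b.index):
        raise ValidationError(
            "tables must share the same genus namespace; align_union() first"
        )
    prev_a = (table_a.to_numpy() > 0).mean(axis=1)
    prev_b = (table_b.to_numpy() > 0).mean(axis=1)
    idx = table_a.index
    set_a = set(idx[(prev_a >= prevalence_min) & (prev_b <= max_other_prevalence)])
    set_b = set(idx[(prev_b >= prevalence_min) & (prev_a <= max_other_prevalence)])
    return set_a, set_b


def shannon_diversity(counts: pd.DataFrame) -> pd.Series:
    """Shannon index H = −Σ p ln p per sample (natural log, zero-count taxa
    contribute nothing)."""
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("counts must be non-negative")
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        raise ValidationError("every sample needs at least one positive count")
    p = values / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-plogp.sum(axis=0), index=counts.columns, name="shannon")
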