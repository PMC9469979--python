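"""Negative-binomial Wald differential expression.

Counts for gene *g* in sample *j* are modelled as NB with mean
``s_j * q_gj`` and constant dispersion ``alpha_g`` (variance
``mu + alpha * mu**2``), where ``s_j`` is the sample's median-of-ratios
size factor and ``q_gj`` depends only on the sample's group. Per gene the
two group means are estimated on normalized counts, the dispersion by
method of moments pooled within groups and shrunk toward a fitted
mean-dispersion trend, and the Wald statistic is
``log2FC / SE(log2FC)`` with a two-sided p from the standard normal.
Benjamini-Hochberg adjustment runs over the genes that pass independent
filtering (mean normalized count >= ``min_count_mean``); filtered genes
get ``padj = 1``.

A gene is called differentially expressed (DEG) when ``padj < 0.05`` and
``|log2FC| > 1``. This engine deliberately simplifies the dispersion
treatment of full GLM-based tools (no MAP estimation, no Cook's
filtering), so its gene lists are validated on simulations with known
planted effects rather than against any particular tool's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .readwrite import CountMatrix, size_factors

__all__ = [
    "DE_PADJ_THRESHOLD",
    "DE_LFC_THRESHOLD",
    "DEGSets",
    "nb_wald_test",
    "one_vs_rest_degs",
    "tumor_vs_normal_degs",
    "common_and_specific",
    "deg_count",
]

#: DEG definition used throughout: padj < 0.05 and |log2FC| > 1.
DE_PADJ_THRESHOLD = 0.05
DE_LFC_THRESHOLD = 1.0

_DISPERSION_FLOOR = 1e-8
_DISPERSION_CAP = 10.0


class DesignError(ValueError):
    """Raised when a contrast has too few samples per side."""


def _trend_fit(mean: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Fit the parametric mean-dispersion trend a1/mu + a0.

    Ordinary least squares on genes with a positive moment estimate and
    informative mean; coefficients are clipped at zero. Falls back to a
    flat trend at the median moment estimate when the fit is degenerate.
    """
    ok = (alpha_mom > 0) & (mean > 0)
    if ok.sum() >= 10:
        x = 1.0 / mean[ok]
        X = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(X, alpha_mom[ok], rcond=None)
        a1, a0 = max(coef[0], 0.0), max(coef[1], 0.0)
        if a1 > 0 or a0 > 0:
            with np.errstate(divide="ignore"):
                trend = a1 / np.maximum(mean, 1e-12) + a0
            return np.clip(trend, _DISPERSION_FLOOR, _DISPERSION_CAP)
    fallback = np.median(alpha_mom[alpha_mom > 0]) if (alpha_mom > 0).any() else _DISPERSION_FLOOR
    return np.full_like(mean, np.clip(fallback, _DISPERSION_FLOOR, _DISPERSION_CAP))


def _wald_core(
    y: np.ndarray,
    inv_s: np.ndarray,
    a_idx: np.ndarray,
    b_idx: np.ndarray,
    *,
    min_count_mean: float = 1.0,
    mom_weight: float = 0.5,
    pseudocount: float = 0.5,
) -> dict[str, np.ndarray]:
    """Vectorized NB Wald test on a normalized count matrix.

    ``y`` is counts / size factor (genes x samples), ``inv_s`` the vector
    of reciprocal size factors. Returns raw arrays; the public wrappers
    attach gene IDs and thresholds.
    """
    A, B = y[:, a_idx], y[:, b_idx]
    n_a, n_b = A.shape[1], B.shape[1]
    mu_a, mu_b = A.mean(axis=1), B.mean(axis=1)
    # Var(k/s) = mu/s + alpha*mu^2 on the normalized scale
    m_a, m_b = inv_s[a_idx].mean(), inv_s[b_idx].mean()

    var_a = A.var(axis=1, ddof=1)
    var_b = B.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (var_a - mu_a * m_a) / np.square(mu_a)
        alpha_b = (var_b - mu_b * m_b) / np.square(mu_b)
    alpha_a = np.nan_to_num(alpha_a, nan=0.0, posinf=0.0, neginf=0.0)
    alpha_b = np.nan_to_num(alpha_b, nan=0.0, posinf=0.0, neginf=0.0)
    w_a, w_b = n_a - 1, n_b - 1
    alpha_mom = np.clip(
        (w_a * alpha_a + w_b * alpha_b) / (w_a + w_b), 0.0, _DISPERSION_CAP
    )
    mean_all = y[:, np.concatenate([a_idx, b_idx])].mean(axis=1)
    alpha_trend = _trend_fit(mean_all, alpha_mom)
    alpha = np.clip(
        mom_weight * alpha_mom + (1.0 - mom_weight) * alpha_trend,
        _DISPERSION_FLOOR,
        _DISPERSION_CAP,
    )

    ln2 = np.log(2.0)
    lfc = np.log2((mu_a + pseudocount) / (mu_b + pseudocount))
    var_mean_a = (mu_a * m_a + alpha * np.square(mu_a)) / n_a
    var_mean_b = (mu_b * m_b + alpha * np.square(mu_b)) / n_b
    se2 = (
        var_mean_a / np.square((mu_a + pseudocount) * ln2)
        + var_mean_b / np.square((mu_b + pseudocount) * ln2)
    )
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(se > 0, p, 1.0)

    tested = mean_all >= min_count_mean
    padj = np.ones_like(p)
    if tested.any():
        padj[tested] = multipletests(p[tested], method="fdr_bh")[1]
    return {
        "log2fc": lfc,
        "p": p,
        "padj": padj,
        "tested": tested,
        "base_mean": mean_all,
    }


def nb_wald_test(
    cm: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    *,
    factors: pd.Series | None = None,
    padj_threshold: float = DE_PADJ_THRESHOLD,
    lfc_threshold: float = DE_LFC_THRESHOLD,
    min_count_mean: float = 1.0,
    mom_weight: float = 0.5,
    contrast_name: str = "",
) -> pd.DataFrame:
    """NB Wald test of ``group_a`` vs ``group_b`` (positive log2FC = higher
    in ``group_a``).

    Returns a DEG table indexed by gene with columns ``log2fc, p, padj,
    direction, is_deg, base_mean``; ``df.attrs['contrast']`` names the
    contrast.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise DesignError(
            "each side of a contrast needs >= 2 samples for dispersion "
            f"estimation (got {len(group_a)} vs {len(group_b)})"
        )
    if set(group_a) & set(group_b):
        raise DesignError("contrast groups must be disjoint")
    if factors is None:
        factors = size_factors(cm)
    sf = factors.loc[cm.sample_ids].to_numpy(dtype=float)
    y = cm.counts.to_numpy(dtype=float) / sf
    pos = {s: i for i, s in enumerate(cm.sample_ids)}
    a_idx = np.array([pos[s] for s in group_a])
    b_idx = np.array([pos[s] for s in group_b])
    res = _wald_core(
        y, 1.0 / sf, a_idx, b_idx,
        min_count_mean=min_count_mean, mom_weight=mom_weight,
    )
    df = pd.DataFrame(
        {
            "log2fc": res["log2fc"],
            "p": res["p"],
            "padj": res["padj"],
            "base_mean": res["base_mean"],
        },
        index=cm.gene_ids,
    )
    df["direction"] = np.where(df["log2fc"] < 0, "down", "up")
    df["is_deg"] = (df["padj"] < padj_threshold) & (
        df["log2fc"].abs() > lfc_threshold
    )
    df.attrs["contrast"] = contrast_name
    return df


def one_vs_rest_degs(
    cm: CountMatrix,
    *,
    factors: pd.Series | None = None,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """One-vs-rest DEG table per subtype (subtype vs all others pooled)."""
    labels = cm.subtypes
    subtypes = sorted(labels.unique())
    if len(subtypes) < 2:
        raise DesignError("need >= 2 subtypes for one-vs-rest contrasts")
    if factors is None:
        factors = size_factors(cm)
    out: dict[str, pd.DataFrame] = {}
    for st in subtypes:
        a = list(labels.index[labels == st])
        b = list(labels.index[labels != st])
        out[st] = nb_wald_test(
            cm, a, b, factors=factors, contrast_name=f"{st}_vs_rest", **kwargs
        )
    return out


def tumor_vs_normal_degs(
    cm_tumor: CountMatrix,
    cm_normal: CountMatrix,
    *,
    contrast_name: str = "tumor_vs_normal",
    **kwargs,
) -> pd.DataFrame:
    """DEGs of tumor vs normal on the shared gene universe (up = higher
    in tumor)."""
    shared = cm_tumor.gene_ids.intersection(cm_normal.gene_ids)
    if len(shared) == 0:
        raise ValueError("tumor and normal matrices share no gene IDs")
    counts = pd.concat(
        [cm_tumor.counts.loc[shared], cm_normal.counts.loc[shared]], axis=1
    )
    md = pd.concat(
        [
            pd.DataFrame({"subtype": "tumor"}, index=cm_tumor.sample_ids),
            pd.DataFrame({"subtype": "normal"}, index=cm_normal.sample_ids),
        ]
    )
    merged = CountMatrix(counts, md)
    return nb_wald_test(
        merged,
        list(cm_tumor.sample_ids),
        list(cm_normal.sample_ids),
        contrast_name=contrast_name,
        **kwargs,
    )


@dataclass
class DEGSets:
    """Up/down DEG sets per subtype with shared/specific set algebra."""

    up: dict[str, set[str]]
    down: dict[str, set[str]]
    shared_up: set[str] = field(default_factory=set)
    shared_down: set[str] = field(default_factory=set)
    specific_up: dict[str, set[str]] = field(default_factory=dict)
    specific_down: dict[str, set[str]] = field(default_factory=dict)

    def degs(self, subtype: str, *, specific: bool = False) -> set[str]:
        if specific:
            return self.specific_up[subtype] | self.specific_down[subtype]
        return self.up[subtype] | self.down[subtype]


def common_and_specific(deg_tables: dict[str, pd.DataFrame]) -> DEGSets:
    """Shared (intersection across subtypes) and subtype-specific up/down
    DEG sets from per-subtype DEG tables."""
    if len(deg_tables) < 2:
        raise ValueError("need DEG tables for >= 2 subtypes")
    up: dict[str, set[str]] = {}
    down: dict[str, set[str]] = {}
    for st, tab in deg_tables.items():
        deg = tab[tab["is_deg"]]
        up[st] = set(deg.index[deg["direction"] == "up"])
        down[st] = set(deg.index[deg["direction"] == "down"])
    shared_up = set.intersection(*up.values())
    shared_down = set.intersection(*down.values())
    specific_up = {st: s - shared_up for st, s in up.items()}
    specific_down = {st: s - shared_down for st, s in down.items()}
    return DEGSets(up, down, shared_up, shared_down, specific_up, specific_down)


def deg_count(table: pd.DataFrame) -> int:
    """Number of DEGs in a table (padj and |log2FC| thresholds applied)."""
    return int(table["is_deg"].sum())
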