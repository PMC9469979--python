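"""Single-gene and gene-pair subtype marker screens.

A clinically useful marker must separate *every* sample: a gene is a
single marker for a subtype when its lowest normalized expression among
the subtype's samples is at least ``fold`` (default 2.0) times its
highest expression in every sample of the other subtypes. Where no
single gene achieves this, gene pairs are screened at a relaxed fold
(default 1.8): a pair qualifies when each outside sample is separated by
at least one of the two genes (the "cover" rule). A stricter reading —
one gene of the pair must clear the fold against the outside *maximum* —
is available as ``rule="strict-max"``. Pairs in which a single gene
already achieves full separation at the pair fold are reported
separately as degenerate.

Fold ratios are taken on linear-scale normalized expression; zero
denominators are floored at a small epsilon.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .readwrite import ExpressionMatrix

__all__ = ["screen_single_markers", "screen_marker_pairs"]

_EPS = 1e-8


def _split(em: ExpressionMatrix, labels: pd.Series, subtype: str,
           candidates) -> tuple[list[str], np.ndarray, np.ndarray]:
    labels = labels.loc[em.sample_ids]
    if subtype not in set(labels):
        raise ValueError(f"subtype {subtype!r} not present in labels")
    if candidates is None:
        genes = [str(g) for g in em.gene_ids]
    else:
        genes = [str(g) for g in candidates if g in em.gene_ids]
    in_mask = (labels == subtype).to_numpy()
    vals = em.values.loc[genes].to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError(
            "marker screening expects linear-scale normalized expression "
            "(nonnegative values)"
        )
    return genes, vals[:, in_mask], vals[:, ~in_mask]


def screen_single_markers(
    em: ExpressionMatrix,
    labels: pd.Series,
    subtype: str,
    fold: float = 2.0,
    candidates: list[str] | None = None,
) -> pd.DataFrame:
    """Genes whose minimum expression in ``subtype`` is at least ``fold``
    times their maximum in every other sample.

    Returns a DataFrame (gene, min_target, max_other, achieved_fold)
    sorted by descending achieved fold. An empty candidate set yields an
    empty result.
    """
    genes, target, other = _split(em, labels, subtype, candidates)
    if not genes:
        return pd.DataFrame(
            columns=["gene", "min_target", "max_other", "achieved_fold"]
        )
    min_t = target.min(axis=1)
    max_o = other.max(axis=1) if other.shape[1] else np.zeros(len(genes))
    achieved = min_t / np.maximum(max_o, _EPS)
    hit = achieved >= fold
    df = pd.DataFrame(
        {
            "gene": np.asarray(genes, dtype=object)[hit],
            "min_target": min_t[hit],
            "max_other": max_o[hit],
            "achieved_fold": achieved[hit],
        }
    )
    return df.sort_values(
        ["achieved_fold", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def screen_marker_pairs(
    em: ExpressionMatrix,
    labels: pd.Series,
    subtype: str,
    fold: float = 1.8,
    candidates: list[str] | None = None,
    rule: str = "cover",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene pairs jointly separating ``subtype`` from all other samples.

    Under the default ``cover`` rule a pair (a, b) qualifies when, for
    every outside sample, at least one of the two genes has its subtype
    minimum >= ``fold`` times that sample's value. Under ``strict-max``
    at least one gene must clear the fold against the outside maximum
    (equivalent to that gene being a single marker at this fold).

    Returns ``(pairs, degenerate)`` DataFrames with columns
    (gene_a, gene_b, n_covered_by_a, n_covered_by_b); pairs where one
    gene alone covers every outside sample land in ``degenerate``.
    """
    if rule not in {"cover", "strict-max"}:
        raise ValueError("rule must be 'cover' or 'strict-max'")
    genes, target, other = _split(em, labels, subtype, candidates)
    cols = ["gene_a", "gene_b", "n_covered_by_a", "n_covered_by_b"]
    if not genes:
        return pd.DataFrame(columns=cols), pd.DataFrame(columns=cols)
    min_t = target.min(axis=1)
    n_out = other.shape[1]
    # separates[g, s]: gene g separates outside sample s at this fold
    separates = min_t[:, None] >= fold * np.maximum(other, _EPS)
    full = separates.all(axis=1)

    rows, degen = [], []
    for i, j in combinations(range(len(genes)), 2):
        if rule == "cover":
            qualifies = bool(np.all(separates[i] | separates[j]))
        else:
            qualifies = bool(full[i] or full[j])
        if not qualifies:
            continue
        a, b = sorted((genes[i], genes[j]))
        rec = {
            "gene_a": a,
            "gene_b": b,
            "n_covered_by_a": int(separates[i if genes[i] == a else j].sum()),
            "n_covered_by_b": int(separates[j if genes[j] == b else i].sum()),
        }
        (degen if (full[i] or full[j]) else rows).append(rec)
    mk = lambda r: pd.DataFrame(r, columns=cols).sort_values(
        ["gene_a", "gene_b"], kind="mergesort"
    ).reset_index(drop=True)
    return mk(rows), mk(degen)
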