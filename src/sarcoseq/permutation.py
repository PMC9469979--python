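"""Label-permutation significance of subtype-specific DEG counts.

A large one-vs-rest DEG count for a subtype could in principle arise by
chance from the multiplicity of genes tested; this module calibrates it
by shuffling subtype labels (preserving group sizes), recomputing the
focal subtype's DEG count under identical thresholds, and reporting the
add-one empirical p-value

    p = (1 + #{null counts >= observed}) / (n_perm + 1),

which is never exactly zero and has resolution 1/(n_perm + 1). Size
factors do not depend on labels and are computed once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import (
    DE_LFC_THRESHOLD,
    DE_PADJ_THRESHOLD,
    _wald_core,
)
from .readwrite import CountMatrix, size_factors

__all__ = ["PermutationResult", "permute_deg_count"]


@dataclass
class PermutationResult:
    subtype: str
    observed_count: int
    null_counts: list[int]
    p_empirical: float
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "subtype": self.subtype,
            "observed_count": self.observed_count,
            "p_empirical": self.p_empirical,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "null_counts": self.null_counts,
        }


def _count_degs(y, inv_s, a_idx, b_idx, padj_threshold, lfc_threshold,
                **core_kwargs) -> int:
    res = _wald_core(y, inv_s, a_idx, b_idx, **core_kwargs)
    return int(
        ((res["padj"] < padj_threshold)
         & (np.abs(res["log2fc"]) > lfc_threshold)).sum()
    )


def permute_deg_count(
    cm: CountMatrix,
    subtype: str,
    n_perm: int = 999,
    seed: int = 0,
    *,
    padj_threshold: float = DE_PADJ_THRESHOLD,
    lfc_threshold: float = DE_LFC_THRESHOLD,
    min_count_mean: float = 1.0,
    mom_weight: float = 0.5,
) -> PermutationResult:
    """Permutation test of the one-vs-rest DEG count for ``subtype``.

    Each of ``n_perm`` permutations shuffles the subtype labels uniformly
    at random (group sizes preserved), recomputes the focal subtype's DEG
    count with identical thresholds, and records it.
    """
    if n_perm < 19:
        raise ValueError(
            "n_perm must be >= 19 to resolve p < 0.05 "
            f"(got {n_perm})"
        )
    labels = cm.subtypes.to_numpy()
    if subtype not in labels:
        raise ValueError(f"subtype {subtype!r} not present in metadata")
    sf = size_factors(cm).to_numpy(dtype=float)
    y = cm.counts.to_numpy(dtype=float) / sf
    inv_s = 1.0 / sf
    core_kwargs = dict(min_count_mean=min_count_mean, mom_weight=mom_weight)

    focal = labels == subtype
    observed = _count_degs(
        y, inv_s, np.flatnonzero(focal), np.flatnonzero(~focal),
        padj_threshold, lfc_threshold, **core_kwargs,
    )
    rng = np.random.default_rng(seed)
    n = len(labels)
    null_counts = []
    for _ in range(n_perm):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[: focal.sum()]] = True
        null_counts.append(
            _count_degs(
                y, inv_s, np.flatnonzero(mask), np.flatnonzero(~mask),
                padj_threshold, lfc_threshold, **core_kwargs,
            )
        )
    p = (1 + sum(c >= observed for c in null_counts)) / (n_perm + 1)
    return PermutationResult(
        subtype=subtype,
        observed_count=observed,
        null_counts=null_counts,
        p_empirical=float(p),
        n_perm=n_perm,
        seed=seed,
    )
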