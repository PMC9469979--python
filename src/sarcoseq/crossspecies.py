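"""Cross-species similarity by information-criterion model comparison.

Given the mean log expression profile of one canine subtype's DEGs and a
panel of mean log expression columns for candidate human sarcoma
subtypes, each human subtype is treated as a candidate explanatory model:
an ordinary least-squares fit ``canine_i = b0 + b1 * human_i + e`` over
the shared genes, scored by the small-sample corrected Akaike criterion

    AICc = n * ln(RSS / n) + 2k + 2k(k + 1) / (n - k - 1),   k = 3

(two regression coefficients plus the error variance). Relative support
is expressed as Akaike weights ``w_h ~ exp(-delta_h / 2)`` normalized
over human subtypes; the best match is the max-weight subtype. Weights
are invariant to adding any constant to all AICc values. The stability
of the top match is assessed by bootstrap over genes: the fraction of
resamples in which the top subtype stays on top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AkaikeComparison", "akaike_similarity"]

_K_PARAMS = 3  # intercept, slope, error variance


class InsufficientOverlapError(ValueError):
    pass


@dataclass
class AkaikeComparison:
    canine_subtype: str
    table: pd.DataFrame  # index human subtype; aicc, delta, weight
    n_genes_used: int
    best: str
    bootstrap_stability: float | None = None

    def to_dict(self) -> dict:
        return {
            "canine_subtype": self.canine_subtype,
            "n_genes_used": self.n_genes_used,
            "best": self.best,
            "bootstrap_stability": self.bootstrap_stability,
            "table": self.table.round(10).to_dict(orient="index"),
        }


def _ic_per_column(y: np.ndarray, X: np.ndarray, ic: str) -> np.ndarray:
    """IC of the OLS fit y ~ 1 + x for each column x of X."""
    n, m = X.shape
    ics = np.empty(m)
    ones = np.ones(n)
    for j in range(m):
        A = np.column_stack([ones, X[:, j]])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        rss = max(float(resid @ resid), 1e-300)
        k = _K_PARAMS
        aic = n * np.log(rss / n) + 2 * k
        if ic == "aicc":
            aic += 2 * k * (k + 1) / (n - k - 1)
        ics[j] = aic
    return ics


def akaike_similarity(
    canine_profile: pd.Series,
    panel: pd.DataFrame,
    *,
    canine_subtype: str = "",
    ic: str = "aicc",
    n_bootstrap: int = 0,
    seed: int = 0,
    min_shared: int = 10,
) -> AkaikeComparison:
    """Akaike weights of each human subtype as a model of a canine
    subtype's DEG expression profile.

    ``canine_profile`` holds per-gene mean log expression over the
    subtype's DEGs; ``panel`` has one mean log expression column per
    human subtype. Gene universes are intersected (>= ``min_shared``
    genes required).
    """
    if ic not in {"aic", "aicc"}:
        raise ValueError("ic must be 'aic' or 'aicc'")
    if panel.columns.duplicated().any():
        raise ValueError("duplicate human subtype names in panel")
    shared = canine_profile.index.intersection(panel.index)
    if len(shared) < min_shared:
        raise InsufficientOverlapError(
            f"only {len(shared)} genes shared between canine profile and "
            f"panel (need >= {min_shared})"
        )
    y = canine_profile.loc[shared].to_numpy(dtype=float)
    X = panel.loc[shared].to_numpy(dtype=float)
    n = len(shared)
    if ic == "aicc" and n - _K_PARAMS - 1 <= 0:
        raise ValueError(f"AICc undefined at n={n} with k={_K_PARAMS}")

    def _weights(yb: np.ndarray, Xb: np.ndarray) -> np.ndarray:
        ics = _ic_per_column(yb, Xb, ic)
        delta = ics - ics.min()
        w = np.exp(-delta / 2.0)
        return w / w.sum(), ics, delta

    w, ics, delta = _weights(y, X)
    table = pd.DataFrame(
        {"aicc": ics, "delta": delta, "weight": w}, index=panel.columns
    )
    best = str(table["weight"].idxmax())

    stability = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        best_idx = int(np.argmax(w))
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            wb, *_ = _weights(y[idx], X[idx])
            hits += int(np.argmax(wb) == best_idx)
        stability = hits / n_bootstrap
    return AkaikeComparison(
        canine_subtype=canine_subtype,
        table=table,
        n_genes_used=n,
        best=best,
        bootstrap_stability=stability,
    )
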