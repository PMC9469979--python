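"""Over-representation analysis (ORA) against local GMT libraries.

Enrichment of a DEG list in a gene set is scored with the exact
hypergeometric upper tail: with a universe of ``N`` genes, a set of size
``K``, a query of size ``n`` and overlap ``k``,
``p = P(X >= k), X ~ Hypergeom(N, K, n)``. p-values are BH-adjusted
within each library. The universe is the set of genes actually tested by
the DE engine for the contrast, which avoids inflating enrichment with
genes that were never measured.

Transcription-factor target sets may encode a regulatory direction in
their name (``<TF>_activated_targets`` / ``<TF>_repressed_targets``).
Combining that tag with the direction of the query DEG list yields an
inferred TF *activity* direction: e.g. up-regulated DEGs enriched in a
TF's repressed targets imply the TF's activity went *down*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GeneSetLibrary",
    "read_gmt",
    "write_gmt",
    "hypergeom_ora",
    "tf_direction",
    "select_normal_reference",
    "top_enrichments",
]

_ACTIVATED_SUFFIX = "_activated_targets"
_REPRESSED_SUFFIX = "_repressed_targets"


def _direction_tag(set_name: str) -> str:
    if set_name.endswith(_ACTIVATED_SUFFIX):
        return "activates"
    if set_name.endswith(_REPRESSED_SUFFIX):
        return "represses"
    return "neutral"


@dataclass
class GeneSetLibrary:
    """Named gene sets with an optional activity-direction tag per set.

    Direction tags are parsed from set-name suffixes:
    ``_activated_targets`` -> activates, ``_repressed_targets`` ->
    represses, anything else -> neutral.
    """

    library_name: str
    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, genes in self.sets.items():
            fs = frozenset(str(g) for g in genes)
            if not fs:
                raise ValueError(f"gene set {name!r} is empty")
            if name in clean:
                raise ValueError(f"duplicate set name {name!r}")
            clean[name] = fs
        self.sets = clean

    def direction_tag(self, set_name: str) -> str:
        return _direction_tag(set_name)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, library_name: str | None = None) -> GeneSetLibrary:
    """Read a standard GMT file (name, description, tab-separated genes)."""
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, description, genes = parts[0], parts[1], parts[2:]
            sets[name] = frozenset(g for g in genes if g)
            desc[name] = description
    return GeneSetLibrary(library_name or Path(path).stem, sets, desc)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in sorted(library.sets):
            desc = library.descriptions.get(name, "")
            genes = sorted(library.sets[name])
            fh.write("\t".join([name, desc] + genes) + "\n")


def hypergeom_ora(
    query: set[str],
    library: GeneSetLibrary,
    universe: set[str],
    *,
    lfc: pd.Series | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each library set.

    Sets are intersected with the universe before testing; the query must
    be a subset of the universe (it is intersected and deduplicated).
    ``lfc`` (log2 fold changes indexed by gene) orders the reported
    overlap genes by decreasing |log2FC|; without it they are
    alphabetical.

    Returns a DataFrame indexed by set name with columns ``overlap,
    set_size, query_size, universe_size, p, padj, direction_tag,
    overlap_genes``.
    """
    universe = {str(g) for g in universe}
    query = {str(g) for g in query} & universe
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query after intersection with universe")
    N, n = len(universe), len(query)
    rows = []
    for name in sorted(library.sets):
        genes = set(library.sets[name]) & universe
        overlap_genes = sorted(genes & query)
        k, K = len(overlap_genes), len(genes)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        if lfc is not None:
            overlap_genes.sort(
                key=lambda g: (-abs(float(lfc.get(g, 0.0))), g)
            )
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p": min(p, 1.0),
                "direction_tag": _direction_tag(name),
                "overlap_genes": ",".join(overlap_genes),
            }
        )
    df = pd.DataFrame(rows).set_index("set_name")
    from statsmodels.stats.multitest import multipletests

    df["padj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df.attrs["library"] = library.library_name
    return df


def tf_direction(result: pd.DataFrame, query_direction: str) -> pd.DataFrame:
    """Infer TF activity direction from set direction tags and the query's
    DEG direction.

    ``query_direction`` is ``"up_degs"`` or ``"down_degs"``. Up-DEGs in a
    TF's activated targets imply the TF's activity is up; up-DEGs in its
    repressed targets imply activity down; down-DEG queries mirror both
    rules. Neutral sets get ``"n/a"``.
    """
    if query_direction not in {"up_degs", "down_degs"}:
        raise ValueError("query_direction must be 'up_degs' or 'down_degs'")
    flip = query_direction == "down_degs"
    mapping = {
        "activates": "down" if flip else "up",
        "represses": "up" if flip else "down",
        "neutral": "n/a",
    }
    out = result.copy()
    out["inferred_activity"] = out["direction_tag"].map(mapping)
    return out


def top_enrichments(results: pd.DataFrame, n: int) -> pd.DataFrame:
    """The ``n`` most significant results, ordered by ascending p with
    ties broken by descending overlap then set name."""
    if n < 1:
        raise ValueError("n must be >= 1")
    df = results.reset_index()
    df = df.sort_values(
        ["p", "overlap", "set_name"], ascending=[True, False, True],
        kind="mergesort",
    ).set_index("set_name")
    return df.head(n)


def select_normal_reference(
    cm_tumor,
    candidate_panels: dict[str, "object"],
    sarcoma_set: set[str],
    *,
    de_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Rank candidate normal-tissue panels for a tumor group.

    For each panel, tumor-vs-panel DEGs are called and the up-regulated
    DEG list is tested for enrichment of ``sarcoma_set`` (a sarcoma-
    expressed phenotype set); panels are ranked by ascending enrichment p
    and the top panel is the selected reference. A panel yielding zero
    up-DEGs is ranked last with p = 1.
    """
    from .de import tumor_vs_normal_degs

    if not candidate_panels:
        raise ValueError("need at least one candidate panel")
    if not sarcoma_set:
        raise ValueError("sarcoma_set must be nonempty")
    de_kwargs = de_kwargs or {}
    lib = GeneSetLibrary("sarcoma", {"sarcoma_expressed": frozenset(sarcoma_set)})
    rows = []
    for name in sorted(candidate_panels):
        panel = candidate_panels[name]
        tab = tumor_vs_normal_degs(
            cm_tumor, panel, contrast_name=f"tumor_vs_normal:{name}",
            **de_kwargs,
        )
        up = set(tab.index[tab["is_deg"] & (tab["direction"] == "up")])
        universe = set(tab.index)
        if up:
            res = hypergeom_ora(up, lib, universe)
            p = float(res["p"].iloc[0])
            k = int(res["overlap"].iloc[0])
        else:
            p, k = 1.0, 0
        rows.append(
            {"panel": name, "n_up_degs": len(up), "overlap": k, "p": p}
        )
    df = pd.DataFrame(rows).sort_values(
        ["p", "panel"], kind="mergesort"
    ).reset_index(drop=True)
    df.attrs["selected"] = df["panel"].iloc[0]
    return df
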