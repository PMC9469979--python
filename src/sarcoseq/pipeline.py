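"""End-to-end pipeline: from count files to a reproducible report bundle.

Stages run in the order the analysis was designed: load, initial
PCA/k-means views, one-vs-rest DEGs, permutation significance, outlier
counting, reassignment, final DEGs with permutation significance, marker
screens, normal-reference selection, tumor-vs-normal DEGs,
common/specific set algebra, over-representation analysis (common then
subtype-specific TFs), and cross-species Akaike weights. Every artifact
is written as TSV/JSON under a run directory together with a manifest
recording the config hash, seed, package version and per-stage completion
state, so a rerun with the same config reproduces the outputs
byte-for-byte.

Randomness is drawn from per-stage streams salted with the stage name, so
adding a stage never perturbs the draws of earlier ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crossspecies import akaike_similarity
from .de import common_and_specific, deg_count, one_vs_rest_degs, tumor_vs_normal_degs
from .enrichment import (
    GeneSetLibrary,
    hypergeom_ora,
    read_gmt,
    select_normal_reference,
    tf_direction,
    top_enrichments,
)
from .markers import screen_marker_pairs, screen_single_markers
from .permutation import permute_deg_count
from .readwrite import (
    CountMatrix,
    log_normalized,
    normalized,
    read_counts,
    top_variable_genes,
)
from .reassign import count_outlier_degs, kmeans_view, pca_view, reassign

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("sarcoseq")

STAGES = (
    "load",
    "initial_views",
    "initial_degs",
    "initial_permutation",
    "outlier_counts",
    "reassignment",
    "final_degs",
    "markers",
    "normal_reference",
    "tumor_vs_normal",
    "common_specific",
    "ora",
    "cross_species",
)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run. Threshold defaults are the
    analysis constants used throughout: padj < 0.05 and |log2FC| > 1 for
    DEGs, 2.0 / 1.8 fold for single / pair markers, 185 most variable
    DEGs per subtype for reassignment clustering, 500 / 250 genes for the
    initial / final PCA views, and top 12 / 14 common / specific TFs."""

    counts: str = ""
    metadata: str = ""
    normal_panels: dict[str, str] = field(default_factory=dict)
    human_panel: str = ""
    gmt_tf: str = ""
    gmt_phenotype: str = ""
    sarcoma_set_name: str = "SARCOMA_EXPRESSED"

    padj_threshold: float = 0.05
    lfc_threshold: float = 1.0
    single_fold: float = 2.0
    pair_fold: float = 1.8
    pair_rule: str = "cover"
    k_per_type: int = 185
    top_pca: int = 250
    top_initial: int = 500
    top_tf_common: int = 12
    top_tf_specific: int = 14
    min_count_mean: float = 1.0

    n_perm: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "padj_threshold", "lfc_threshold", "single_fold", "pair_fold",
            "k_per_type", "top_pca", "top_initial", "top_tf_common",
            "top_tf_specific",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_perm < 19:
            raise ValueError(
                f"n_perm must be >= 19 to resolve p < 0.05 (got {self.n_perm})"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        return int((self.seed * 1000003 + zlib.crc32(stage.encode())) % 2**31)

    def de_kwargs(self) -> dict:
        return {
            "padj_threshold": self.padj_threshold,
            "lfc_threshold": self.lfc_threshold,
            "min_count_mean": self.min_count_mean,
        }


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", lineterminator="\n", float_format="%.10g")


def _write_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _load_normal_panel(path: str, name: str) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    md = pd.DataFrame(
        {"subtype": "normal"},
        index=pd.Index(counts.columns.astype(str), name="sample_id"),
    )
    return CountMatrix(counts, md)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages and write the report bundle under ``outdir``.

    Returns the manifest dict. Any stage error halts the run; partial
    outputs are retained and the manifest marks the completion state of
    each stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {s: "pending" for s in STAGES},
    }
    state: dict = {}

    def _finish(stage: str) -> None:
        manifest["stages"][stage] = "complete"
        _write_json(manifest, outdir / "manifest.json")

    try:
        for stage in STAGES:
            t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            _STAGE_FUNCS[stage](config, outdir, state)
            _finish(stage)
            log.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)
    except Exception as err:
        manifest["stages"][stage] = f"failed: {err}"
        _write_json(manifest, outdir / "manifest.json")
        raise RuntimeError(f"pipeline halted at stage {stage!r}: {err}") from err
    return manifest


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_load(config: PipelineConfig, outdir: Path, state: dict) -> None:
    cm = read_counts(config.counts, config.metadata)
    state["cm"] = cm
    state["em_log"] = log_normalized(cm)
    state["em_lin"] = normalized(cm)
    state["subtypes"] = sorted(cm.subtypes.unique())


def _stage_initial_views(config: PipelineConfig, outdir: Path, state: dict) -> None:
    em = state["em_log"]
    genes = top_variable_genes(em, min(config.top_initial, len(em.gene_ids)))
    coords, evr = pca_view(em, genes)
    _write_tsv(coords, outdir / "initial_pca_coords.tsv")
    clusters = kmeans_view(
        em, genes, k=len(state["subtypes"]),
        seed=config.stage_seed("initial_views"),
    )
    _write_tsv(clusters.to_frame(), outdir / "initial_kmeans.tsv")
    _write_json(
        {"explained_variance_fraction": [float(v) for v in evr]},
        outdir / "initial_pca_variance.json",
    )


def _stage_initial_degs(config: PipelineConfig, outdir: Path, state: dict) -> None:
    tables = one_vs_rest_degs(state["cm"], **config.de_kwargs())
    state["initial_tables"] = tables
    for st, tab in tables.items():
        _write_tsv(tab, outdir / f"initial_degs_{st}.tsv")
    _write_json(
        {st: deg_count(t) for st, t in tables.items()},
        outdir / "initial_deg_counts.json",
    )


def _stage_initial_permutation(config: PipelineConfig, outdir: Path, state: dict) -> None:
    out = {}
    for st in state["subtypes"]:
        res = permute_deg_count(
            state["cm"], st, n_perm=config.n_perm,
            seed=config.stage_seed(f"initial_permutation:{st}"),
            padj_threshold=config.padj_threshold,
            lfc_threshold=config.lfc_threshold,
            min_count_mean=config.min_count_mean,
        )
        out[st] = res.to_dict()
    state["p_initial"] = {st: v["p_empirical"] for st, v in out.items()}
    _write_json(out, outdir / "initial_permutation.json")


def _stage_outlier_counts(config: PipelineConfig, outdir: Path, state: dict) -> None:
    sets = common_and_specific(state["initial_tables"])
    table = count_outlier_degs(
        state["em_log"], sets, state["cm"].subtypes
    )
    state["outliers"] = table
    _write_tsv(table.table, outdir / "outlier_counts.tsv")


def _stage_reassignment(config: PipelineConfig, outdir: Path, state: dict) -> None:
    report = reassign(
        state["cm"], state["outliers"].flagged,
        k_per_type=config.k_per_type,
        n_perm=config.n_perm,
        seed=config.stage_seed("reassignment"),
        de_kwargs=config.de_kwargs(),
    )
    state["report"] = report
    state["cm_final"] = state["cm"].relabel(
        {s: lab for s, (_, lab) in report.changed.items()}
    )
    _write_json(report.to_dict(), outdir / "reassignment.json")


def _stage_final_degs(config: PipelineConfig, outdir: Path, state: dict) -> None:
    cm = state["cm_final"]
    tables = one_vs_rest_degs(cm, **config.de_kwargs())
    state["final_tables"] = tables
    for st, tab in tables.items():
        _write_tsv(tab, outdir / f"final_degs_{st}.tsv")
    _write_json(
        {st: deg_count(t) for st, t in tables.items()},
        outdir / "final_deg_counts.json",
    )
    # final PCA view on the most significant DEGs per subtype
    em = log_normalized(cm)
    genes: list[str] = []
    for st, tab in tables.items():
        deg = tab[tab["is_deg"]].sort_values("padj")
        genes.extend(deg.index[: config.top_pca])
    genes = sorted(set(genes))
    if len(genes) >= 2:
        coords, evr = pca_view(em, genes)
        _write_tsv(coords, outdir / "final_pca_coords.tsv")
        _write_json(
            {"explained_variance_fraction": [float(v) for v in evr]},
            outdir / "final_pca_variance.json",
        )


def _stage_markers(config: PipelineConfig, outdir: Path, state: dict) -> None:
    cm = state["cm_final"]
    em = normalized(cm)
    labels = cm.subtypes
    rows = []
    for st, tab in state["final_tables"].items():
        up = sorted(tab.index[tab["is_deg"] & (tab["direction"] == "up")])
        singles = screen_single_markers(
            em, labels, st, fold=config.single_fold, candidates=up
        )
        for _, r in singles.iterrows():
            rows.append((st, "single", r["gene"], "", r["min_target"],
                         r["max_other"], r["achieved_fold"]))
        # pairs are only sought among candidates that are not already
        # single markers for this subtype
        single_set = set(singles["gene"])
        pair_cands = [g for g in up if g not in single_set]
        if len(pair_cands) >= 2:
            pairs, degen = screen_marker_pairs(
                em, labels, st, fold=config.pair_fold,
                candidates=pair_cands, rule=config.pair_rule,
            )
            for kind, df in (("pair", pairs), ("degenerate_pair", degen)):
                for _, r in df.iterrows():
                    rows.append((st, kind, r["gene_a"], r["gene_b"],
                                 np.nan, np.nan, np.nan))
    out = pd.DataFrame(
        rows,
        columns=["subtype", "marker_type", "gene_a", "gene_b",
                 "min_target", "max_other", "achieved_fold"],
    )
    state["markers"] = out
    _write_tsv(out.set_index("subtype"), outdir / "markers.tsv")


def _load_resources(config: PipelineConfig, state: dict) -> None:
    if "panels" not in state:
        state["panels"] = {
            name: _load_normal_panel(path, name)
            for name, path in sorted(config.normal_panels.items())
        }
    if "tf_library" not in state:
        state["tf_library"] = read_gmt(config.gmt_tf, "tf_targets")
    if "sarcoma_set" not in state:
        pheno = read_gmt(config.gmt_phenotype, "phenotype")
        state["sarcoma_set"] = set(pheno.sets[config.sarcoma_set_name])
    if "human_panel" not in state:
        hp = pd.read_csv(config.human_panel, index_col=0)
        hp.index = hp.index.astype(str)
        state["human_panel"] = hp


def _stage_normal_reference(config: PipelineConfig, outdir: Path, state: dict) -> None:
    _load_resources(config, state)
    cm = state["cm_final"]
    selections = {}
    ranking_all = []
    for st in state["subtypes"]:
        sub = cm.subset_samples(
            list(cm.sample_ids[(cm.subtypes == st).to_numpy()])
        )
        ranking = select_normal_reference(
            sub, state["panels"], state["sarcoma_set"],
            de_kwargs=config.de_kwargs(),
        )
        selections[st] = ranking.attrs["selected"]
        ranking["subtype"] = st
        ranking_all.append(ranking)
    state["selected_panels"] = selections
    _write_tsv(
        pd.concat(ranking_all, ignore_index=True).set_index("subtype"),
        outdir / "normal_reference_ranking.tsv",
    )
    _write_json(selections, outdir / "normal_reference_selection.json")


def _stage_tumor_vs_normal(config: PipelineConfig, outdir: Path, state: dict) -> None:
    cm = state["cm_final"]
    tables = {}
    for st in state["subtypes"]:
        sub = cm.subset_samples(
            list(cm.sample_ids[(cm.subtypes == st).to_numpy()])
        )
        panel = state["panels"][state["selected_panels"][st]]
        tab = tumor_vs_normal_degs(
            sub, panel,
            contrast_name=f"{st}_vs_normal:{state['selected_panels'][st]}",
            **config.de_kwargs(),
        )
        tables[st] = tab
        _write_tsv(tab, outdir / f"tumor_vs_normal_{st}.tsv")
    state["tvn_tables"] = tables
    summary = {
        st: {
            "n_up": int((t["is_deg"] & (t["direction"] == "up")).sum()),
            "n_down": int((t["is_deg"] & (t["direction"] == "down")).sum()),
        }
        for st, t in tables.items()
    }
    for st, s in summary.items():
        total = s["n_up"] + s["n_down"]
        s["up_fraction_pct"] = round(100.0 * s["n_up"] / total, 2) if total else float("nan")
    _write_json(summary, outdir / "tumor_vs_normal_counts.json")


def _stage_common_specific(config: PipelineConfig, outdir: Path, state: dict) -> None:
    sets = common_and_specific(state["tvn_tables"])
    state["tvn_sets"] = sets
    _write_json(
        {
            "shared_up": len(sets.shared_up),
            "shared_down": len(sets.shared_down),
            "specific_up": {st: len(s) for st, s in sets.specific_up.items()},
            "specific_down": {st: len(s) for st, s in sets.specific_down.items()},
        },
        outdir / "common_specific_counts.json",
    )


def _stage_ora(config: PipelineConfig, outdir: Path, state: dict) -> None:
    sets = state["tvn_sets"]
    lib = state["tf_library"]
    frames = []

    def _run(query: set[str], universe: set[str], direction: str,
             label: str, n_top: int):
        if not query:
            return
        res = hypergeom_ora(query, lib, universe)
        res = tf_direction(res, direction)
        res = top_enrichments(res, n_top)
        res["analysis"] = label
        frames.append(res.reset_index())

    # common TFs: union universe across contrasts
    universe = set.union(*(set(t.index) for t in state["tvn_tables"].values()))
    _run(sets.shared_up, universe, "up_degs", "common_up", config.top_tf_common)
    _run(sets.shared_down, universe, "down_degs", "common_down", config.top_tf_common)
    for st, tab in state["tvn_tables"].items():
        uni = set(tab.index)
        _run(sets.specific_up[st], uni, "up_degs", f"{st}_up",
             config.top_tf_specific)
        _run(sets.specific_down[st], uni, "down_degs", f"{st}_down",
             config.top_tf_specific)
    if frames:
        out = pd.concat(frames, ignore_index=True).set_index("analysis")
        _write_tsv(out, outdir / "tf_enrichment.tsv")


def _stage_cross_species(config: PipelineConfig, outdir: Path, state: dict) -> None:
    cm = state["cm_final"]
    em = log_normalized(cm)
    out = {}
    for st, tab in state["final_tables"].items():
        degs = [g for g in tab.index[tab["is_deg"]]]
        if len(degs) < 10:
            continue
        members = list(cm.sample_ids[(cm.subtypes == st).to_numpy()])
        profile = em.values.loc[degs, members].mean(axis=1)
        comp = akaike_similarity(
            profile, state["human_panel"], canine_subtype=st,
            n_bootstrap=1000,
            seed=config.stage_seed(f"cross_species:{st}"),
        )
        out[st] = comp.to_dict()
    _write_json(out, outdir / "cross_species.json")


_STAGE_FUNCS = {
    "load": _stage_load,
    "initial_views": _stage_initial_views,
    "initial_degs": _stage_initial_degs,
    "initial_permutation": _stage_initial_permutation,
    "outlier_counts": _stage_outlier_counts,
    "reassignment": _stage_reassignment,
    "final_degs": _stage_final_degs,
    "markers": _stage_markers,
    "normal_reference": _stage_normal_reference,
    "tumor_vs_normal": _stage_tumor_vs_normal,
    "common_specific": _stage_common_specific,
    "ora": _stage_ora,
    "cross_species": _stage_cross_species,
}
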