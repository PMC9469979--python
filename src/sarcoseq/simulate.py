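"""Synthetic count data with the structure the pipeline assumes.

The generator emulates a small archival-tumor RNA-seq study: ~16 samples
in three histological subtype groups, negative-binomial counts
(``Var = mu + alpha * mu**2``), per-sample library-size factors drawn
log-uniformly, subtype-specific planted DEGs of configurable log2 effect
size, optional mislabeled samples (a sample generated from one subtype's
expression profile but carrying another subtype's label), planted
single-gene and gene-pair markers, matched "normal tissue" count panels
(one of which shares the tumor baseline and is therefore the correct
reference), a mean-expression panel of "human analog" subtypes in which
exactly one column tracks each canine subtype's planted profile, and GMT
gene-set libraries (tissue-like sets, TF target sets with direction
suffixes, a sarcoma-expressed phenotype set) salted with random decoys.

Every draw flows from ``config.seed`` through purpose-salted
``numpy.random.default_rng`` streams, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import GeneSetLibrary
from .readwrite import CountMatrix

__all__ = [
    "MarkerConfig",
    "SimulationConfig",
    "SimulationTruth",
    "ReferencePanels",
    "simulate_counts",
    "simulate_reference_panels",
    "write_study",
]

#: Human sarcoma subtype abbreviations used for panel columns
#: (dedifferentiated liposarcoma, fibromyxosarcoma, leiomyosarcoma,
#: undifferentiated pleomorphic sarcoma, malignant peripheral nerve
#: sheath tumor, synovial sarcoma, undifferentiated sarcoma).
HUMAN_SUBTYPE_NAMES = ("DL", "FM", "LMS", "MFH", "MPNST", "SSC", "US")

DEFAULT_SUBTYPE_NAMES = ("FS", "PNST", "PWT")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerConfig:
    """Planted marker structure per subtype.

    ``n_single`` genes get a clean log2 separation of ``single_log2_sep``
    above every other subtype. Each of ``n_pairs`` pairs consists of two
    genes, each elevated by ``pair_log2_sep`` in the focal subtype but
    each also elevated in one (different) other subtype, so that only the
    pair jointly separates the focal subtype from all outside samples.
    """

    n_single: int = 2
    n_pairs: int = 1
    single_log2_sep: float = 4.0
    pair_log2_sep: float = 3.5

    @property
    def genes_per_subtype(self) -> int:
        return self.n_single + 2 * self.n_pairs


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults mirror the study design this
    pipeline targets (16 tumors in subtype groups of 6/5/5, NB counts
    with dispersion 0.1, 100 planted DEGs per subtype at |log2FC| = 2)."""

    n_genes: int = 2000
    group_sizes: tuple[int, ...] = (6, 5, 5)
    subtype_names: tuple[str, ...] | None = None
    baseline_mean_log_range: tuple[float, float] = (3.0, 9.0)  # log2 scale
    dispersion: float = 0.1
    dispersion_jitter_sd: float = 0.0  # lognormal sd of optional per-gene jitter
    n_degs_per_group: int = 100
    deg_log2fc: float = 2.0
    n_mislabeled: int = 0
    marker_config: MarkerConfig = field(default_factory=MarkerConfig)
    library_size_range: tuple[float, float] = (0.7, 1.4)
    n_normal_samples: int = 4
    n_decoy_panels: int = 3
    n_human_subtypes: int = 7
    human_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if any(g <= 0 for g in self.group_sizes):
            raise ConfigurationError("group sizes must be positive")
        if sum(self.group_sizes) < 3:
            raise ConfigurationError("need at least 3 samples in total")
        for name, (lo, hi) in (
            ("baseline_mean_log_range", self.baseline_mean_log_range),
            ("library_size_range", self.library_size_range),
        ):
            if lo > hi:
                raise ConfigurationError(f"{name} must have low <= high")
        if self.library_size_range[0] <= 0:
            raise ConfigurationError("library sizes must be positive")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if self.n_degs_per_group < 0 or self.n_mislabeled < 0:
            raise ConfigurationError("counts must be nonnegative")
        if self.deg_log2fc < 0:
            raise ConfigurationError("deg_log2fc must be nonnegative")
        k = len(self.group_sizes)
        per_group = self.n_degs_per_group + self.marker_config.genes_per_subtype
        if per_group * k > self.n_genes:
            raise ConfigurationError(
                f"{per_group} planted genes per group x {k} groups exceeds "
                f"n_genes={self.n_genes}"
            )
        if self.n_mislabeled > sum(self.group_sizes):
            raise ConfigurationError("more mislabeled samples than samples")
        if self.n_human_subtypes < k:
            raise ConfigurationError(
                "need at least one human subtype per canine subtype"
            )

    @property
    def subtypes(self) -> tuple[str, ...]:
        if self.subtype_names is not None:
            return self.subtype_names
        k = len(self.group_sizes)
        if k <= len(DEFAULT_SUBTYPE_NAMES):
            return DEFAULT_SUBTYPE_NAMES[:k]
        return tuple(f"G{i + 1}" for i in range(k))


@dataclass
class SimulationTruth:
    """Ground truth of one simulated study, including generator state
    needed to build matched reference resources."""

    true_labels: pd.Series  # sample id -> generating subtype
    planted_deg_ids: dict[str, dict[str, int]]  # subtype -> gene -> sign
    mislabeled_sample_ids: list[str]
    planted_marker_ids: dict[str, dict[str, list]]  # subtype -> {single, pairs}
    baseline_log2_mean: pd.Series  # gene -> baseline log2 mean
    effects_log2: pd.DataFrame  # genes x subtypes planted log2 offsets
    dispersion: pd.Series  # gene -> NB dispersion used

    def up_degs(self, subtype: str) -> set[str]:
        return {g for g, s in self.planted_deg_ids[subtype].items() if s > 0}

    def down_degs(self, subtype: str) -> set[str]:
        return {g for g, s in self.planted_deg_ids[subtype].items() if s < 0}


@dataclass
class ReferencePanels:
    """Companion resources for a simulated study."""

    normal_panels: dict[str, CountMatrix]
    correct_panel: str
    human_panel: pd.DataFrame  # genes x human subtypes, mean log2 expression
    matched_human: dict[str, str]  # canine subtype -> generating human column
    libraries: dict[str, GeneSetLibrary]
    sarcoma_set_name: str = "SARCOMA_EXPRESSED"

    @property
    def sarcoma_set(self) -> set[str]:
        return set(self.libraries["phenotype"].sets[self.sarcoma_set_name])


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, salt])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             alpha: np.ndarray) -> np.ndarray:
    """NB(mu, alpha) draws with Var = mu + alpha*mu^2 (gamma-Poisson)."""
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _plan_genes(config: SimulationConfig, rng: np.random.Generator):
    """Allocate disjoint planted-gene indices per subtype.

    Returns per subtype: (deg indices with signs, single-marker indices,
    pair index tuples).
    """
    k = len(config.group_sizes)
    mc = config.marker_config
    per_group = config.n_degs_per_group + mc.genes_per_subtype
    chosen = rng.choice(config.n_genes, size=per_group * k, replace=False)
    plan = []
    off = 0
    for _ in range(k):
        block = chosen[off:off + per_group]
        off += per_group
        singles = block[: mc.n_single]
        pair_genes = block[mc.n_single: mc.n_single + 2 * mc.n_pairs]
        pairs = [
            (pair_genes[2 * i], pair_genes[2 * i + 1])
            for i in range(mc.n_pairs)
        ]
        degs = block[mc.genes_per_subtype:]
        signs = np.where(np.arange(len(degs)) % 2 == 0, 1, -1)
        plan.append((degs, signs, singles, pairs))
    return plan


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, SimulationTruth]:
    """Simulate a tumor count matrix with planted structure.

    Counts are NB with mean ``library_factor * baseline * 2**effect``
    where the effect is the planted log2 offset of the sample's
    *generating* subtype. Mislabeled samples are pure members of their
    generating subtype whose metadata carries a different label.
    """
    subtypes = config.subtypes
    k = len(subtypes)
    n_samples = sum(config.group_sizes)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]

    rng_genes = _rng(config, 1)
    lo, hi = config.baseline_mean_log_range
    baseline_log2 = rng_genes.uniform(lo, hi, size=config.n_genes)
    if config.dispersion_jitter_sd > 0:
        disp = config.dispersion * rng_genes.lognormal(
            0.0, config.dispersion_jitter_sd, size=config.n_genes
        )
    else:
        disp = np.full(config.n_genes, config.dispersion)

    plan = _plan_genes(config, _rng(config, 2))
    effects = np.zeros((config.n_genes, k))
    planted_deg_ids: dict[str, dict[str, int]] = {}
    planted_marker_ids: dict[str, dict[str, list]] = {}
    mc = config.marker_config
    for si, st in enumerate(subtypes):
        degs, signs, singles, pairs = plan[si]
        effects[degs, si] = signs * config.deg_log2fc
        gene_sign = {genes[g]: int(s) for g, s in zip(degs, signs)}
        # markers are additional planted up-DEGs of their subtype
        effects[singles, si] = mc.single_log2_sep
        for g in singles:
            gene_sign[genes[g]] = 1
        others = [j for j in range(k) if j != si]
        for pi, (a, b) in enumerate(pairs):
            effects[a, si] = mc.pair_log2_sep
            effects[b, si] = mc.pair_log2_sep
            gene_sign[genes[a]] = 1
            gene_sign[genes[b]] = 1
            if others:
                # each pair gene is also elevated in one different outside
                # subtype, spoiling it as a single marker
                spoil_a = others[pi % len(others)]
                spoil_b = others[(pi + 1) % len(others)] if len(others) > 1 else None
                effects[a, spoil_a] += mc.pair_log2_sep - 0.5
                if spoil_b is not None:
                    effects[b, spoil_b] += mc.pair_log2_sep - 0.5
        planted_deg_ids[st] = gene_sign
        planted_marker_ids[st] = {
            "single": [genes[g] for g in singles],
            "pairs": [tuple(sorted((genes[a], genes[b]))) for a, b in pairs],
        }

    # sample bookkeeping: generating group assignment, then mislabeling
    true_idx = np.repeat(np.arange(k), config.group_sizes)
    sample_ids = []
    for si, st in enumerate(subtypes):
        for j in range(config.group_sizes[si]):
            sample_ids.append(f"{st}_{j + 1:02d}")
    assigned_idx = true_idx.copy()
    rng_mis = _rng(config, 3)
    mislabeled: list[str] = []
    if config.n_mislabeled:
        group_members = [
            np.flatnonzero(true_idx == si) for si in range(k)
        ]
        for i in range(config.n_mislabeled):
            donor = i % k
            pool = [
                s for s in group_members[donor]
                if sample_ids[s] not in mislabeled
            ]
            if not pool:
                raise ConfigurationError(
                    "cannot place requested mislabeled samples"
                )
            s = int(rng_mis.choice(pool))
            # wrong labels cycle over the other subtypes so that impostors
            # land in distinct assigned groups (the cleanly-reassignable
            # scenario this generator emulates)
            wrong = (donor + 1 + i // k) % k
            assigned_idx[s] = wrong
            mislabeled.append(sample_ids[s])

    rng_counts = _rng(config, 4)
    lib_lo, lib_hi = config.library_size_range
    lib = np.exp(
        rng_counts.uniform(np.log(lib_lo), np.log(lib_hi), size=n_samples)
    )
    base_mu = np.exp2(baseline_log2)
    mu = base_mu[:, None] * np.exp2(effects[:, true_idx]) * lib[None, :]
    counts = _nb_draw(rng_counts, mu, disp[:, None])

    batch = np.where(np.arange(n_samples) % 2 == 0, "batch1", "batch2")
    metadata = pd.DataFrame(
        {
            "subtype": [subtypes[i] for i in assigned_idx],
            "batch": batch,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                     columns=sample_ids),
        metadata,
    )
    truth = SimulationTruth(
        true_labels=pd.Series(
            [subtypes[i] for i in true_idx], index=cm.sample_ids,
            name="true_subtype",
        ),
        planted_deg_ids=planted_deg_ids,
        mislabeled_sample_ids=mislabeled,
        planted_marker_ids=planted_marker_ids,
        baseline_log2_mean=pd.Series(baseline_log2, index=cm.gene_ids),
        effects_log2=pd.DataFrame(effects, index=cm.gene_ids,
                                  columns=list(subtypes)),
        dispersion=pd.Series(disp, index=cm.gene_ids),
    )
    return cm, truth


def _random_sets(rng, genes, n_sets, size, prefix):
    out = {}
    for i in range(n_sets):
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        out[f"{prefix}_{i + 1:02d}"] = frozenset(str(g) for g in members)
    return out


def _subset(rng, pool: list[str], frac: float, minimum: int = 5):
    pool = sorted(pool)
    if not pool:
        return []
    n = max(min(minimum, len(pool)), int(math.ceil(frac * len(pool))))
    n = min(n, len(pool))
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in idx]


def simulate_reference_panels(
    config: SimulationConfig, truth: SimulationTruth
) -> ReferencePanels:
    """Companion normal-tissue panels, human analog panel and GMT
    libraries matched to a simulated study.

    The correct normal panel shares the tumor baseline means (so
    tumor-vs-it DEGs are the planted effects); decoy panels have
    gene-permuted baselines. One human panel column per canine subtype is
    generated from that subtype's planted expression profile plus
    Gaussian noise; remaining columns are gene-permuted decoys.
    """
    genes = truth.baseline_log2_mean.index
    n_genes = len(genes)
    subtypes = config.subtypes
    k = len(subtypes)
    base_mu = np.exp2(truth.baseline_log2_mean.to_numpy())
    disp = truth.dispersion.to_numpy()

    # --- normal-tissue count panels -------------------------------------
    rng = _rng(config, 5)
    lib_lo, lib_hi = config.library_size_range
    panels: dict[str, CountMatrix] = {}

    def _make_panel(name: str, mu_gene: np.ndarray) -> CountMatrix:
        nn = config.n_normal_samples
        lib = np.exp(rng.uniform(np.log(lib_lo), np.log(lib_hi), size=nn))
        mu = mu_gene[:, None] * lib[None, :]
        counts = _nb_draw(rng, mu, disp[:, None])
        ids = [f"{name}_{j + 1:02d}" for j in range(nn)]
        md = pd.DataFrame({"subtype": "normal"}, index=pd.Index(ids, name="sample_id"))
        return CountMatrix(
            pd.DataFrame(counts, index=genes, columns=ids), md
        )

    correct_name = "normal_matched"
    panels[correct_name] = _make_panel(correct_name, base_mu)
    for d in range(config.n_decoy_panels):
        perm = rng.permutation(n_genes)
        panels[f"normal_decoy_{d + 1}"] = _make_panel(
            f"normal_decoy_{d + 1}", base_mu[perm]
        )

    # --- human analog mean-expression panel -----------------------------
    rng_h = _rng(config, 6)
    m = config.n_human_subtypes
    names = list(HUMAN_SUBTYPE_NAMES[:m])
    if m > len(HUMAN_SUBTYPE_NAMES):
        names += [f"HS{i + 1}" for i in range(m - len(HUMAN_SUBTYPE_NAMES))]
    cols = {}
    matched: dict[str, str] = {}
    base_log2 = truth.baseline_log2_mean.to_numpy()
    for si, st in enumerate(subtypes):
        profile = base_log2 + truth.effects_log2[st].to_numpy()
        cols[names[si]] = profile + rng_h.normal(
            0.0, config.human_noise_sd, size=n_genes
        )
        matched[st] = names[si]
    for j in range(k, m):
        donor = cols[names[j % k]]
        cols[names[j]] = donor[rng_h.permutation(n_genes)]
    human_panel = pd.DataFrame(cols, index=genes)[names]

    # --- GMT libraries ---------------------------------------------------
    rng_g = _rng(config, 7)
    all_genes = [str(g) for g in genes]
    tissue_sets: dict[str, frozenset[str]] = {}
    tf_sets: dict[str, frozenset[str]] = {}
    up_union: set[str] = set()
    for st in subtypes:
        up = sorted(truth.up_degs(st))
        down = sorted(truth.down_degs(st))
        up_union |= set(up)
        enriched = set(_subset(rng_g, up, 0.7)) | set(
            rng_g.choice(all_genes, size=5, replace=False)
        )
        if enriched:
            tissue_sets[f"{st}_like_tissue"] = frozenset(enriched)
        act = _subset(rng_g, up, 0.6)
        rep = _subset(rng_g, down, 0.6)
        if act:
            tf_sets[f"TF_{st}_activated_targets"] = frozenset(act)
        if rep:
            tf_sets[f"TF_{st}_repressed_targets"] = frozenset(rep)
    tissue_sets.update(_random_sets(rng_g, all_genes, 10, 30, "decoy_tissue"))
    tf_sets.update(_random_sets(rng_g, all_genes, 10, 30, "decoy_tf"))
    phenotype_sets: dict[str, frozenset[str]] = {}
    if up_union:
        phenotype_sets["SARCOMA_EXPRESSED"] = frozenset(up_union)
    else:  # null configuration: exchangeable random set
        phenotype_sets["SARCOMA_EXPRESSED"] = frozenset(
            str(g) for g in rng_g.choice(all_genes, size=min(50, n_genes),
                                         replace=False)
        )
    phenotype_sets.update(
        _random_sets(rng_g, all_genes, 5, 50, "decoy_phenotype")
    )
    libraries = {
        "tissues": GeneSetLibrary("tissues", tissue_sets),
        "tf_targets": GeneSetLibrary("tf_targets", tf_sets),
        "phenotype": GeneSetLibrary("phenotype", phenotype_sets),
    }
    return ReferencePanels(
        normal_panels=panels,
        correct_panel=correct_name,
        human_panel=human_panel,
        matched_human=matched,
        libraries=libraries,
    )


def write_study(config: SimulationConfig, outdir) -> dict:
    """Simulate a full study and write it as a text fixture bundle.

    Writes counts.tsv, metadata.csv, one TSV per normal panel,
    human_panel.csv, one GMT per library, truth.json, and a ready-to-run
    pipeline config.yaml. Returns the dict of written paths.
    """
    import json
    from pathlib import Path

    import yaml

    from .enrichment import write_gmt
    from .readwrite import write_counts

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, truth = simulate_counts(config)
    refs = simulate_reference_panels(config, truth)

    paths: dict[str, str] = {}

    def _reg(key: str, name: str) -> Path:
        paths[key] = str(outdir / name)
        return outdir / name

    write_counts(cm, _reg("counts", "counts.tsv"), _reg("metadata", "metadata.csv"))
    panel_paths = {}
    for name, panel in refs.normal_panels.items():
        p = outdir / f"{name}.tsv"
        write_counts(panel, p)
        panel_paths[name] = str(p)
    paths["normal_panels"] = panel_paths
    hp = refs.human_panel.copy()
    hp.index.name = "gene_id"
    hp.to_csv(_reg("human_panel", "human_panel.csv"), lineterminator="\n",
              float_format="%.6g")
    for lib_name, lib in refs.libraries.items():
        write_gmt(lib, _reg(f"gmt_{lib_name}", f"{lib_name}.gmt"))
    truth_obj = {
        "true_labels": truth.true_labels.to_dict(),
        "mislabeled_sample_ids": truth.mislabeled_sample_ids,
        "planted_deg_ids": truth.planted_deg_ids,
        "planted_marker_ids": {
            st: {"single": v["single"], "pairs": [list(p) for p in v["pairs"]]}
            for st, v in truth.planted_marker_ids.items()
        },
        "correct_panel": refs.correct_panel,
        "matched_human": refs.matched_human,
    }
    with open(_reg("truth", "truth.json"), "w", encoding="utf-8",
              newline="\n") as fh:
        json.dump(truth_obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    cfg = {
        "counts": paths["counts"],
        "metadata": paths["metadata"],
        "normal_panels": panel_paths,
        "human_panel": paths["human_panel"],
        "gmt_tf": paths["gmt_tf_targets"],
        "gmt_phenotype": paths["gmt_phenotype"],
        "seed": config.seed,
    }
    with open(_reg("config", "config.yaml"), "w", encoding="utf-8",
              newline="\n") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths
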