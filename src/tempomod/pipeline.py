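"""End-to-end orchestration: dynamic features -> modules -> characterization.

Convenience layer used by the CLI, the test-suite integration checks and the
acceptance script. Each function is a thin composition of the stage modules
and returns plain containers, so any stage can still be run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st
from sklearn.metrics import adjusted_rand_score

from .characterization import (
    Pwm,
    mean_conservation,
    motif_density,
    nearest_tss_link,
    promoter_windows,
    sequence_entropy,
)
from .clustering import ClusterModel, GapResult, gap_select_k, kmeans_fit, log_zscore
from .core import FeatureMatrix, overlap_any
from .dynamic import FilterSpec, select_dynamic_features
from .patterns import (
    assign_patterns,
    build_pattern_library,
    module_profiles,
    normalize_accessibility,
)
from .specificity import cluster_specificity
from .synthdata import SynthConfig, SyntheticStudy


@dataclass
class ModuleDiscovery:
    dynamic_ids: set
    gap: GapResult
    model: ClusterModel


def discover_modules(
    matrix: FeatureMatrix,
    stats: pd.DataFrame,
    filter_spec: FilterSpec,
    k_grid=range(1, 7),
    B: int = 60,
    gap_starts: int = 5,
    kmeans_starts: int = 100,
    seed: int = 0,
    k: int | None = None,
) -> ModuleDiscovery:
    """Select dynamic features, transform, choose k by gap, fit k-means.

    Pass ``k`` to skip gap selection (``gap`` is then a 1-point result).
    """
    dynamic = select_dynamic_features(stats, matrix, filter_spec)
    sub = matrix.values.loc[sorted(dynamic)]
    transformed = log_zscore(sub)
    if k is None:
        gap = gap_select_k(transformed, k_grid=k_grid, B=B, seed=seed, n_starts=gap_starts)
        k = gap.chosen_k
    else:
        gap = GapResult([k], np.zeros(1), np.zeros(1), k, B)
    model = kmeans_fit(transformed, k=k, n_starts=kmeans_starts, seed=seed)
    return ModuleDiscovery(dynamic_ids=dynamic, gap=gap, model=model)


def module_truth_ari(assignment: pd.Series, truth_labels: dict) -> float:
    """Adjusted Rand index between discovered modules and planted labels,
    over the planted features present in the assignment."""
    shared = [f for f in assignment.index if f in truth_labels]
    if not shared:
        return float("nan")
    return float(
        adjusted_rand_score(
            [truth_labels[f] for f in shared], assignment.loc[shared].to_list()
        )
    )


def assign_module_patterns(
    matrix: FeatureMatrix,
    model: ClusterModel,
    max_union_length: int | None = None,
):
    """Label discovered modules with temporal/cell-type patterns.

    The raw matrix rows are 95th-quantile normalized, averaged per module,
    and matched by cosine against the default pattern library built from the
    condition metadata (conditions act as the "cell clusters").
    """
    meta = matrix.conditions.copy()
    meta = meta.rename(columns={"cell_type": "cell_class"})
    library = build_pattern_library(meta, max_union_length=max_union_length)
    profile = normalize_accessibility(matrix.values.loc[model.assignment.index])
    profiles = module_profiles(profile, model.assignment)
    return assign_patterns(profiles, library)


def majority_truth_label(members, truth_labels: dict) -> str | None:
    labels = [truth_labels[f] for f in members if f in truth_labels]
    if not labels:
        return None
    return pd.Series(labels).mode().iloc[0]


# ---------------------------------------------------------------------------
# Built-in PWM library for synthetic characterization
# ---------------------------------------------------------------------------

def default_pwm_library() -> list[Pwm]:
    """Three toy motifs spanning the GC/CpG spectrum.

    A CpG-repeat motif and a GC-box reward the CpG-enriched, GC-rich
    sequences planted in "early" modules; an AT-rich homeodomain-like motif
    is their control. Motifs are 8 bp: under a uniform background a single
    L-mer carries probability 4^-L, so L >= 7 is needed before any score
    threshold can reach a 1e-4 tail.
    """
    def sharp(cols):
        m = np.full((4, len(cols)), 0.02)
        for j, b in enumerate(cols):
            m["ACGT".index(b), j] = 0.94
        return m

    return [
        Pwm(matrix=sharp("CGCGCGCG"), id="cpg_repeat"),
        Pwm(matrix=sharp("GGGGCGGG"), id="gc_box"),
        Pwm(matrix=sharp("TTAATTAA"), id="at_homeo"),
    ]


# ---------------------------------------------------------------------------
# Per-region characterization table + early/late contrast
# ---------------------------------------------------------------------------

def region_metrics_table(
    annotation,
    panels,
    pwms: list[Pwm] | None = None,
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Per-region metrics: promoter/CGI overlap, motif density, entropy,
    conservation, panel tau (through the paired gene)."""
    pwms = pwms or default_pwm_library()
    regions = annotation.regions
    rec = regions.records
    prom = promoter_windows(annotation.tss)
    metrics = pd.DataFrame(index=rec["id"].values)
    metrics["promoter"] = overlap_any(rec, prom).astype(float)
    metrics["cgi"] = overlap_any(rec, annotation.cgi.records).astype(float)
    metrics["motif_density"] = motif_density(
        regions, annotation.sequences, pwms, p_threshold
    )
    metrics["entropy"] = [
        sequence_entropy(annotation.sequences[rid]) for rid in metrics.index
    ]
    metrics["conservation"] = mean_conservation(regions, annotation.conservation)["mean"]
    # region r{i} is paired with gene g{i}; tau comes from the tissue panel
    genes = ["g" + rid[1:] for rid in metrics.index]
    tau_vals, _ = cluster_specificity(
        [g for g in genes if g in panels.tissue_expression.columns],
        panels.tissue_expression,
    )
    metrics["tau"] = [tau_vals.get("g" + rid[1:], np.nan) for rid in metrics.index]
    return metrics


#: expected direction of each metric for shared-early vs shared-late modules
EARLY_GREATER = {"promoter": True, "cgi": True, "motif_density": True,
                 "entropy": False, "conservation": True, "tau": False}


def early_late_contrast(
    metrics: pd.DataFrame,
    region_to_truth: dict,
    early_label: str = "early",
    late_label: str = "late",
) -> pd.DataFrame:
    """One-sided Mann-Whitney tests of the early-vs-late metric orderings.

    For each metric the alternative follows ``EARLY_GREATER``; returns per
    metric the two group means and the one-sided p-value.
    """
    truth = pd.Series(region_to_truth)
    early_ids = truth.index[truth == early_label]
    late_ids = truth.index[truth == late_label]
    rows = {}
    for metric, greater in EARLY_GREATER.items():
        if metric not in metrics.columns:
            continue
        a = metrics.loc[metrics.index.intersection(early_ids), metric].dropna()
        b = metrics.loc[metrics.index.intersection(late_ids), metric].dropna()
        alt = "greater" if greater else "less"
        _, p = st.mannwhitneyu(a, b, alternative=alt)
        rows[metric] = {
            "early_mean": float(a.mean()),
            "late_mean": float(b.mean()),
            "alternative": alt,
            "p": float(p),
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Full synthetic run
# ---------------------------------------------------------------------------

def run_synthetic_study(
    study: SyntheticStudy,
    k_grid=range(1, 7),
    B: int = 60,
    gap_starts: int = 5,
    kmeans_starts: int = 100,
    seed: int = 0,
):
    """Discover gene and region modules on a synthetic study and score them
    against the planted truth. Returns a dict of stage results."""
    ds = study.dataset
    rna_stats = ds.diff_stats[ds.diff_stats["modality"] == "rna"]
    atac_stats = ds.diff_stats[ds.diff_stats["modality"] == "atac"]

    genes = discover_modules(
        ds.expression, rna_stats, FilterSpec.for_rna(),
        k_grid=k_grid, B=B, gap_starts=gap_starts,
        kmeans_starts=kmeans_starts, seed=seed,
    )
    regions = discover_modules(
        ds.accessibility, atac_stats, FilterSpec.for_atac(),
        k_grid=k_grid, B=B, gap_starts=gap_starts,
        kmeans_starts=kmeans_starts, seed=seed,
    )
    truth = ds.truth_labels
    return {
        "genes": genes,
        "regions": regions,
        "gene_ari": module_truth_ari(genes.model.assignment, truth),
        "region_ari": module_truth_ari(regions.model.assignment, truth),
        "gene_patterns": assign_module_patterns(ds.expression, genes.model),
        "region_patterns": assign_module_patterns(ds.accessibility, regions.model),
    }
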