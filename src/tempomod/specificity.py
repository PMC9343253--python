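"""Tissue/cell-type specificity: the tau index and reference peak panels.

tau = sum_i (1 - x_i / max(x)) / (n - 1) over n tissues: 0 for a uniformly
expressed gene, 1 for expression confined to a single tissue. Region-level
specificity uses reference open-chromatin panels: per-tissue replicate peak
sets are collapsed into a size-standardized union peak set with a binary
presence matrix, against which module regions are scored as per-tissue
overlap fractions, or matched to externally scored regions.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .core import GenomicRegionSet, UndefinedInputError, merge_intervals, overlap_any


@dataclass
class UnionPeakPanel:
    peaks: GenomicRegionSet  # size-standardized union peaks
    presence: pd.DataFrame  # peaks x tissues, binary
    width: int = 350


# ---------------------------------------------------------------------------
# tau
# ---------------------------------------------------------------------------

def tau(x, log1p: bool = False) -> float:
    """Tissue-specificity index in [0, 1] of a nonnegative expression vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs a 1-D vector over at least two tissues")
    if (x < 0).any():
        raise ValueError("tau is defined for nonnegative expression values")
    if log1p:
        x = np.log1p(x)
    top = x.max()
    if top == 0:
        raise UndefinedInputError("tau undefined for the all-zero vector")
    return float((1.0 - x / top).sum() / (x.size - 1))


def cluster_specificity(
    genes,
    panel: pd.DataFrame,
    log1p: bool = False,
) -> tuple[pd.Series, list[str]]:
    """Per-gene tau over a tissues x genes reference panel.

    Returns (tau per present gene, missing gene ids). Raises when no queried
    gene is present in the panel.
    """
    genes = list(genes)
    present = [g for g in genes if g in panel.columns]
    missing = [g for g in genes if g not in panel.columns]
    if not present:
        raise UndefinedInputError("no queried gene is present in the panel")
    values = pd.Series(
        {g: tau(panel[g].to_numpy(), log1p=log1p) for g in present}, name="tau"
    )
    return values, missing


def specificity_summary(tau_by_cluster: dict[str, pd.Series]) -> pd.DataFrame:
    """Quartile summary of per-cluster tau distributions (box-plot style)."""
    rows = {
        name: {
            "n": len(vals),
            "q25": vals.quantile(0.25),
            "median": vals.median(),
            "q75": vals.quantile(0.75),
            "mean": vals.mean(),
        }
        for name, vals in tau_by_cluster.items()
    }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Union peak panel
# ---------------------------------------------------------------------------

def _replicate_consensus(replicates: list[GenomicRegionSet], min_replicates: int) -> pd.DataFrame:
    """Merged tissue peak set: bases supported by >= min_replicates replicates.

    Each replicate's intervals are merged first, then a sweep over interval
    endpoints keeps the genomic stretches covered by enough replicates.
    """
    per_rep = [merge_intervals(r.records) for r in replicates if len(r.records)]
    if not per_rep:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    need = min(min_replicates, len(per_rep))
    events: dict[str, list[tuple[int, int]]] = {}
    for rep in per_rep:
        for chrom, s, e in rep.itertuples(index=False):
            events.setdefault(chrom, []).append((int(s), 1))
            events.setdefault(chrom, []).append((int(e), -1))
    rows = []
    for chrom, evs in events.items():
        evs.sort()
        depth, open_start = 0, None
        for pos, delta in evs:
            new_depth = depth + delta
            if depth < need <= new_depth:
                open_start = pos
            elif depth >= need > new_depth and open_start is not None:
                if pos > open_start:
                    rows.append((chrom, open_start, pos))
                open_start = None
            depth = new_depth
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return merge_intervals(out) if len(out) else out


def build_union_peaks(
    replicate_peaks: dict[str, list[GenomicRegionSet]],
    width: int = 350,
    min_replicates: int = 2,
) -> UnionPeakPanel:
    """Cross-tissue union peak set, size-standardized, with binary presence.

    Per tissue, peaks must be supported by >= ``min_replicates`` replicates
    (tissues with fewer replicate sets are kept, with a warning, using what
    is available). Tissue sets are union-reduced across tissues, each union
    peak standardized to ``width`` bp around its midpoint (clipped at
    position 0, flagged by a shorter width), and presence records whether
    the standardized peak overlaps each tissue's peak set.
    """
    tissue_sets = {}
    for tissue, reps in replicate_peaks.items():
        if len(reps) < min_replicates:
            warnings.warn(
                f"tissue {tissue!r} has {len(reps)} replicate set(s); "
                f"using all available"
            )
        tissue_sets[tissue] = _replicate_consensus(reps, min_replicates)

    all_rows = pd.concat(
        [df for df in tissue_sets.values() if len(df)], ignore_index=True
    ) if any(len(df) for df in tissue_sets.values()) else pd.DataFrame()
    if all_rows.empty:
        raise UndefinedInputError("union peak set is empty")
    union = merge_intervals(all_rows)
    mid = (union["start"] + union["end"]) // 2
    half = width // 2
    std = pd.DataFrame(
        {
            "chrom": union["chrom"],
            "start": np.maximum(mid - half, 0),
            "end": mid + (width - half),
        }
    )
    std["id"] = [f"up{i:05d}" for i in range(len(std))]
    std["strand"] = "."
    peaks = GenomicRegionSet(records=std[["chrom", "start", "end", "id", "strand"]])

    presence = pd.DataFrame(index=std["id"].values, columns=list(tissue_sets), dtype=int)
    for tissue, tdf in tissue_sets.items():
        presence[tissue] = overlap_any(std, tdf).astype(int)
    return UnionPeakPanel(peaks=peaks, presence=presence, width=width)


def panel_overlap_fraction(
    cluster_regions: GenomicRegionSet, panel: UnionPeakPanel
) -> pd.Series:
    """Fraction of cluster regions overlapping each tissue's present peaks."""
    n = len(cluster_regions)
    out = {}
    peak_rec = panel.peaks.records
    for tissue in panel.presence.columns:
        present_ids = panel.presence.index[panel.presence[tissue] == 1]
        tissue_peaks = peak_rec[peak_rec["id"].isin(set(present_ids))]
        hits = overlap_any(cluster_regions.records, tissue_peaks)
        out[tissue] = float(hits.sum()) / n if n else 0.0
    return pd.Series(out, name="overlap_fraction")


# ---------------------------------------------------------------------------
# External panel specificity lookup
# ---------------------------------------------------------------------------

def panel_specificity_lookup(
    cluster_regions: GenomicRegionSet,
    scored_regions: GenomicRegionSet,
    scores: pd.Series,
) -> tuple[pd.Series, int]:
    """Externally computed specificity of the scored region overlapping each
    cluster region.

    A cluster region overlapping several scored regions takes the partner
    with maximal overlap length, ties to the leftmost. Returns
    (region id -> matched score, unmatched count).
    """
    matched = {}
    srec = scored_regions.records
    by_chrom = {c: sub.sort_values("start") for c, sub in srec.groupby("chrom")}
    for row in cluster_regions.records.itertuples(index=False):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        ov = np.minimum(e, row.end) - np.maximum(s, row.start)
        best = None
        for j in np.where(ov > 0)[0]:
            key = (ov[j], -s[j])  # max overlap, ties to leftmost start
            if best is None or key > best[0]:
                best = (key, sub.iloc[j]["id"])
        if best is not None:
            matched[row.id] = float(scores[best[1]])
    unmatched = len(cluster_regions) - len(matched)
    return pd.Series(matched, name="specificity", dtype=float), unmatched
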