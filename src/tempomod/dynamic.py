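"""Dynamic-feature selection and DMR merge/filter rules.

A gene or peak is "dynamic" when some pairwise comparison shows a
significant change (q below threshold, |log2 fold change| above threshold)
and the feature is adequately expressed/enriched in at least one condition
of that comparison. Candidate differentially methylated regions (DMRs) from
per-comparison callers are collapsed (>= 1 bp overlap), quantified as
coverage-weighted CpG methylation per sample, filtered on read coverage and
flagged differential on replicate-averaged methylation differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicRegionSet, SchemaError, UndefinedInputError, merge_intervals

#: thresholds the study applies to gene expression comparisons
RNA_FILTER_DEFAULTS = dict(q_threshold=0.05, min_abs_log2fc=1.5, min_level=10.0)
#: thresholds for chromatin accessibility peaks
ATAC_FILTER_DEFAULTS = dict(q_threshold=0.01, min_abs_log2fc=1.5, min_level=1.0)


@dataclass
class FilterSpec:
    q_threshold: float = 0.05
    min_abs_log2fc: float = 1.5
    min_level: float = 10.0
    level_scope: str = "comparison"  # or "overall"

    def __post_init__(self) -> None:
        if self.q_threshold <= 0 or self.min_abs_log2fc <= 0 or self.min_level <= 0:
            raise ValueError("thresholds must be positive")
        if self.level_scope not in ("comparison", "overall"):
            raise ValueError("level_scope must be 'comparison' or 'overall'")

    @classmethod
    def for_rna(cls) -> "FilterSpec":
        return cls(**RNA_FILTER_DEFAULTS)

    @classmethod
    def for_atac(cls) -> "FilterSpec":
        return cls(**ATAC_FILTER_DEFAULTS)


@dataclass
class DmrParams:
    delta: float = 0.3
    p_threshold: float = 0.01
    min_cg: int = 3
    dis_merge: int = 400
    min_size: int = 100
    min_reads: int = 5
    min_samples: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.delta <= 1.0:
            raise ValueError("delta must lie in (0, 1]")
        for name in ("min_cg", "dis_merge", "min_size", "min_reads", "min_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DmrSet:
    regions: GenomicRegionSet
    methylation: pd.DataFrame  # regions x samples, coverage-weighted mean in [0,1]
    coverage: pd.DataFrame  # regions x samples, summed CpG reads
    differential: pd.Series  # region id -> bool


# ---------------------------------------------------------------------------
# select_dynamic_features
# ---------------------------------------------------------------------------

def select_dynamic_features(stats: pd.DataFrame, levels, spec: FilterSpec) -> set[str]:
    """Feature ids passing the significance + fold-change + level rule.

    ``stats`` needs columns feature, comparison, cond_a, cond_b, log2fc, q.
    ``levels`` is a FeatureMatrix (or plain DataFrame) of per-condition
    abundances. A feature is selected when some comparison satisfies
    ``q <= q_threshold`` and ``|log2fc| >= min_abs_log2fc`` and the feature's
    level reaches ``min_level`` in at least one condition of that comparison
    (or any condition at all under ``level_scope='overall'``).
    """
    values = levels.values if hasattr(levels, "feature_ids") else levels
    required = {"feature", "comparison", "cond_a", "cond_b", "log2fc", "q"}
    missing = required - set(stats.columns)
    if missing:
        raise SchemaError(f"stats table missing columns: {sorted(missing)}")
    unknown = set(stats["feature"]) - set(values.index)
    if unknown:
        raise SchemaError(f"{len(unknown)} stats features absent from levels matrix")

    sig = stats[
        (stats["q"] <= spec.q_threshold)
        & (stats["log2fc"].abs() >= spec.min_abs_log2fc)
    ]
    if sig.empty:
        return set()
    if spec.level_scope == "overall":
        ok = values.max(axis=1) >= spec.min_level
        return set(sig.loc[ok.reindex(sig["feature"]).to_numpy(), "feature"])
    lv = values.to_numpy()
    row_of = {f: i for i, f in enumerate(values.index)}
    col_of = {c: j for j, c in enumerate(values.columns)}
    ri = sig["feature"].map(row_of).to_numpy()
    ca = sig["cond_a"].map(col_of).to_numpy()
    cb = sig["cond_b"].map(col_of).to_numpy()
    passed = np.maximum(lv[ri, ca], lv[ri, cb]) >= spec.min_level
    return set(sig.loc[passed, "feature"])


# ---------------------------------------------------------------------------
# merge_and_filter_dmrs
# ---------------------------------------------------------------------------

def merge_and_filter_dmrs(
    candidates: list[GenomicRegionSet] | GenomicRegionSet,
    meth_calls: pd.DataFrame,
    params: DmrParams = DmrParams(),
    sample_groups: dict[str, str] | None = None,
    proximity_merge: bool = False,
) -> DmrSet:
    """Collapse candidate DMRs, quantify, coverage-filter and flag differential.

    ``meth_calls`` columns: chrom, pos, meth, total, sample. Per-sample region
    methylation is the coverage-weighted mean of CpG levels, i.e.
    sum(meth)/sum(total) over CpGs in the region; region coverage is the
    summed read count. Regions are kept when coverage exceeds ``min_reads``
    in at least ``min_samples`` samples. The differential flag compares
    replicate-averaged methylation (``sample_groups`` maps sample -> group;
    identity when omitted): max pairwise |difference| >= delta and region
    size strictly above ``min_size``. ``proximity_merge`` optionally applies
    a second merge pass joining regions closer than ``dis_merge`` bp.
    """
    if isinstance(candidates, GenomicRegionSet):
        candidates = [candidates]
    all_rec = pd.concat([c.records for c in candidates], ignore_index=True)
    if all_rec.empty:
        raise UndefinedInputError("no candidate DMRs supplied")
    merged = merge_intervals(all_rec)
    if proximity_merge:
        grown = merged.copy()
        grown["end"] = grown["end"] + params.dis_merge
        regrown = merge_intervals(grown)
        regrown["end"] = regrown["end"] - params.dis_merge
        # trailing shrink can only shorten the padded tail, never below a real end
        merged = regrown[regrown["end"] > regrown["start"]].reset_index(drop=True)
    merged["id"] = [f"dmr_{i:05d}" for i in range(len(merged))]
    merged["strand"] = "."
    regions = GenomicRegionSet(
        records=merged[["chrom", "start", "end", "id", "strand"]],
        assembly=candidates[0].assembly,
    )

    req = {"chrom", "pos", "meth", "total", "sample"}
    if req - set(meth_calls.columns):
        raise SchemaError("meth_calls needs chrom/pos/meth/total/sample columns")
    if len(meth_calls) and (meth_calls["meth"] > meth_calls["total"]).any():
        raise ValueError("methylated reads exceed total reads")

    samples = sorted(meth_calls["sample"].unique())
    meth_sum = pd.DataFrame(0.0, index=merged["id"], columns=samples)
    total_sum = pd.DataFrame(0.0, index=merged["id"], columns=samples)
    # CpGs outside every merged region are ignored by construction
    for chrom, sub in meth_calls.groupby("chrom"):
        reg = merged[merged["chrom"] == chrom]
        if reg.empty:
            continue
        starts = reg["start"].to_numpy()
        ends = reg["end"].to_numpy()
        ids = reg["id"].to_numpy()
        pos = sub["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        hit = sub[inside].copy()
        hit["region"] = ids[idx[inside]]
        agg = hit.groupby(["region", "sample"])[["meth", "total"]].sum()
        for (region, sample), row in agg.iterrows():
            meth_sum.loc[region, sample] += row["meth"]
            total_sum.loc[region, sample] += row["total"]

    with np.errstate(invalid="ignore", divide="ignore"):
        level = meth_sum / total_sum  # NaN where a sample has zero reads
    covered_enough = (total_sum > params.min_reads).sum(axis=1) >= params.min_samples
    keep_ids = covered_enough[covered_enough].index

    regions = regions.subset(keep_ids)
    level = level.loc[keep_ids]
    total_sum = total_sum.loc[keep_ids]

    groups = sample_groups or {s: s for s in samples}
    group_level = level.T.groupby(pd.Series(groups)).mean().T
    span = group_level.max(axis=1) - group_level.min(axis=1)
    sizes = regions.records.set_index("id")["end"] - regions.records.set_index("id")["start"]
    differential = (span >= params.delta) & (sizes.reindex(span.index) > params.min_size)

    return DmrSet(
        regions=regions,
        methylation=level,
        coverage=total_sum,
        differential=differential.fillna(False),
    )


# ---------------------------------------------------------------------------
# global_methylation
# ---------------------------------------------------------------------------

def global_methylation(meth_calls: pd.DataFrame) -> float:
    """Fraction of methylated calls over all detected calls: sum(meth)/sum(total)."""
    total = float(meth_calls["total"].sum())
    if total <= 0:
        raise UndefinedInputError("no detected CpGs")
    return float(meth_calls["meth"].sum()) / total
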