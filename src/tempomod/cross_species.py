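"""Cross-species comparison of gene and open-chromatin module systems.

Gene modules from two species are aligned through an ortholog table
(one-to-many pairs dropped), then every module pair is tested for
overrepresentation with a one-sided Fisher exact test over the union of all
mappable clustered genes. Region modules lifted between assemblies are
filtered on mapped size (>= 100 bp) and expansion ratio (< 1.2) before
pairwise overlap percentages are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st

from .core import GenomicRegionSet, UndefinedInputError, overlap_any

MIN_MAPPED_LENGTH = 100
MAX_SIZE_RATIO = 1.2


@dataclass
class OrthologMap:
    pairs: pd.DataFrame  # gene_a, gene_b (one-to-one)
    dropped_a: list
    dropped_b: list

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame) -> "OrthologMap":
        """Keep only one-to-one pairs; genes with multiple partners are
        dropped entirely and counted."""
        multi_a = set(pairs.loc[pairs["gene_a"].duplicated(keep=False), "gene_a"])
        multi_b = set(pairs.loc[pairs["gene_b"].duplicated(keep=False), "gene_b"])
        keep = ~(pairs["gene_a"].isin(multi_a) | pairs["gene_b"].isin(multi_b))
        return cls(
            pairs=pairs[keep].reset_index(drop=True),
            dropped_a=sorted(multi_a),
            dropped_b=sorted(multi_b),
        )

    def a_to_b(self) -> dict:
        return dict(zip(self.pairs["gene_a"], self.pairs["gene_b"]))


# ---------------------------------------------------------------------------
# Gene-module alignment and Fisher tests
# ---------------------------------------------------------------------------

def map_gene_modules(
    modules_a: pd.Series,
    modules_b: pd.Series,
    orthologs: OrthologMap,
) -> tuple[pd.Series, pd.Series, set]:
    """Restrict both module systems to orthologous genes on a shared id space.

    Species-A gene ids are translated to species-B ids. Returns the two
    restricted systems plus the background: the union of all mappable and
    clustered genes from either species.
    """
    a2b = orthologs.a_to_b()
    mapped_a = modules_a[modules_a.index.isin(a2b)].rename(index=a2b)
    mappable_b = set(orthologs.pairs["gene_b"])
    mapped_b = modules_b[modules_b.index.isin(mappable_b)]
    background = set(mapped_a.index) | set(mapped_b.index)
    if not background:
        raise UndefinedInputError("no shared orthologous gene space")
    return mapped_a, mapped_b, background


def gene_module_fisher(
    modules_a: pd.Series,
    modules_b: pd.Series,
    background: set,
) -> pd.DataFrame:
    """One-sided (greater) Fisher exact test per module pair over the background.

    Returns a table with the 2x2 cells, p-value and sample odds ratio,
    sorted by odds ratio then p ("most similar pairs" first). The sample OR
    is a*d/(b*c), infinite when b*c = 0 with a*d > 0.
    """
    stray = (set(modules_a.index) | set(modules_b.index)) - background
    if stray:
        raise ValueError(f"{len(stray)} module genes outside the background")
    N = len(background)
    sets_a = {m: set(idx) for m, idx in modules_a.groupby(modules_a).groups.items()}
    sets_b = {m: set(idx) for m, idx in modules_b.groupby(modules_b).groups.items()}
    rows = []
    for ma, ga in sets_a.items():
        for mb, gb in sets_b.items():
            a = len(ga & gb)
            b = len(ga) - a
            c = len(gb) - a
            d = N - a - b - c
            orv, p = st.fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append(
                {
                    "module_a": ma, "module_b": mb,
                    "a": a, "b": b, "c": c, "d": d,
                    "p": float(p),
                    "odds_ratio": float(orv),
                }
            )
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["odds_ratio", "p"], ascending=[False, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Lifted-region filtering and overlap
# ---------------------------------------------------------------------------

def filter_mapped_regions(
    region_map: pd.DataFrame,
    min_length: int = MIN_MAPPED_LENGTH,
    max_ratio: float = MAX_SIZE_RATIO,
) -> GenomicRegionSet:
    """Retain mappings with mapped length >= ``min_length`` and size ratio
    strictly below ``max_ratio``."""
    req = {"source_id", "chrom", "start", "end", "mapped_length", "size_ratio"}
    missing = req - set(region_map.columns)
    if missing:
        raise ValueError(f"region map missing columns: {sorted(missing)}")
    keep = (region_map["mapped_length"] >= min_length) & (
        region_map["size_ratio"] < max_ratio
    )
    kept = region_map[keep]
    records = pd.DataFrame(
        {
            "chrom": kept["chrom"],
            "start": kept["start"],
            "end": kept["end"],
            "id": kept["source_id"],
            "strand": ".",
        }
    ).reset_index(drop=True)
    return GenomicRegionSet(records=records)


def region_module_overlap(
    modules_a_mapped: dict[str, GenomicRegionSet],
    modules_b: dict[str, GenomicRegionSet],
) -> pd.DataFrame:
    """Percent of each A-module's mapped regions overlapping each B-module.

    Rows: A modules; columns: B modules; values in [0, 100].
    """
    out = {}
    for ma, regs_a in modules_a_mapped.items():
        row = {}
        for mb, regs_b in modules_b.items():
            if len(regs_a) == 0:
                row[mb] = 0.0
            else:
                hits = overlap_any(regs_a.records, regs_b.records)
                row[mb] = 100.0 * float(hits.sum()) / len(regs_a)
        out[ma] = row
    return pd.DataFrame(out).T
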