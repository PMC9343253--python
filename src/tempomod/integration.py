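"""Cross-modality concordance and sample-divergence analyses.

Region modules are projected into gene space through region-gene links and
tested for overrepresentation against gene expression modules with a
one-sided hypergeometric test, BH-adjusted, reporting odds ratios capped at
10 for pairs with q < 0.001. Gene-set methylation summarizes DMR methylation
over signature gene sets. Sample divergence uses classical (Torgerson) MDS
on 1 - |Pearson r| distances with a one-sided Welch test that inter-cell-type
distances grow from early to late timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st
from statsmodels.stats.multitest import multipletests

from .core import UndefinedInputError

OR_CAP = 10.0
REPORT_Q = 0.001


@dataclass
class EnrichmentTable:
    table: pd.DataFrame  # region_module, gene_module, k, K, n, N, p, q, odds_ratio, reported


@dataclass
class MdsResult:
    coordinates: pd.DataFrame  # samples x (dim1, dim2)
    distances: pd.DataFrame  # 1 - |r| matrix
    eigenvalues: np.ndarray
    inter_type_distances: pd.DataFrame  # timepoint, pair, distance
    divergence_p: float


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Hypergeometric module-overlap enrichment
# ---------------------------------------------------------------------------

def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """One-sided overrepresentation p-value P(X >= k), X ~ Hypergeom(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(st.hypergeom.sf(k - 1, N, K, n))


def odds_ratio_capped(k: int, K: int, n: int, N: int, cap: float = OR_CAP) -> float:
    """Sample odds ratio of the 2x2 overlap table, Haldane-corrected, capped.

    Table cells: a=k, b=n-k, c=K-k, d=N-K-n+k; 0.5 is added to every cell
    when any cell is zero.
    """
    a, b, c, d = k, n - k, K - k, N - K - n + k
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent margins for odds ratio")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(min((a * d) / (b * c), cap))


def module_overlap_enrichment(
    region_to_gene: pd.Series,
    region_modules: pd.Series,
    gene_modules: pd.Series,
    universe,
) -> EnrichmentTable:
    """Hypergeometric overlap of region modules vs gene modules in gene space.

    ``region_to_gene`` maps region id -> linked gene; regions without a link
    are absent from the map and are not considered. For each pair, the draw
    is the region module's linked gene set (restricted to the universe), the
    successes are the gene module's genes, and N is the universe size.
    """
    universe = set(universe)
    if not universe:
        raise UndefinedInputError("empty gene universe")
    stray = (set(region_to_gene.values) | set(gene_modules.index)) - universe
    if stray:
        raise ValueError(f"{len(stray)} genes outside the declared universe")
    N = len(universe)

    gene_sets = {
        m: set(idx) & universe for m, idx in gene_modules.groupby(gene_modules).groups.items()
    }
    region_gene_sets = {}
    for m, regions in region_modules.groupby(region_modules).groups.items():
        linked = region_to_gene.reindex(regions).dropna()
        region_gene_sets[m] = set(linked.values) & universe

    rows = []
    for rm, r_genes in region_gene_sets.items():
        n = len(r_genes)
        for gm, g_genes in gene_sets.items():
            K = len(g_genes)
            k = len(r_genes & g_genes)
            rows.append(
                {
                    "region_module": rm,
                    "gene_module": gm,
                    "k": k, "K": K, "n": n, "N": N,
                    "p": hypergeom_tail(k, N, K, n),
                    "odds_ratio": odds_ratio_capped(k, K, n, N),
                }
            )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["reported"] = table["q"] < REPORT_Q
    return EnrichmentTable(table=table)


# ---------------------------------------------------------------------------
# Gene-set methylation
# ---------------------------------------------------------------------------

def geneset_methylation(
    dmr_methylation: pd.DataFrame,
    region_to_gene: pd.Series,
    gene_sets: dict[str, set],
) -> pd.DataFrame:
    """Mean methylation of DMRs linked to each gene set, per sample.

    ``dmr_methylation`` is DMRs x samples. Sets with no linked DMR yield NaN
    rows (reported, not an error).
    """
    if any(len(s) == 0 for s in gene_sets.values()):
        raise ValueError("gene sets must be nonempty")
    rows = {}
    for name, genes in gene_sets.items():
        dmrs = region_to_gene[region_to_gene.isin(set(genes))].index
        dmrs = [d for d in dmrs if d in dmr_methylation.index]
        rows[name] = (
            dmr_methylation.loc[dmrs].mean(axis=0)
            if dmrs
            else pd.Series(np.nan, index=dmr_methylation.columns)
        )
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Classical MDS and divergence
# ---------------------------------------------------------------------------

def correlation_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """1 - |Pearson r| between sample rows of a samples x features matrix."""
    x = profiles.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = list(profiles.index[sd == 0])
        raise UndefinedInputError(f"constant profiles (correlation undefined): {bad}")
    r = np.corrcoef(x)
    d = 1.0 - np.abs(r)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def classical_mds(distances: pd.DataFrame, n_dim: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Torgerson MDS: double-center -0.5 D^2, eigendecompose, embed.

    Returns (coordinates on the top ``n_dim`` positive eigenvalues, full
    eigenvalue spectrum in decreasing order).
    """
    d = distances.to_numpy(dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, n_dim))
    for i in range(n_dim):
        if i < len(vals) and vals[i] > 0:
            coords[:, i] = vecs[:, i] * np.sqrt(vals[i])
    return (
        pd.DataFrame(coords, index=distances.index, columns=[f"dim{i+1}" for i in range(n_dim)]),
        vals,
    )


def mds_divergence(
    profiles: pd.DataFrame,
    sample_meta: pd.DataFrame,
    early_timepoints=(),
    late_timepoints=(),
) -> MdsResult:
    """MDS embedding plus a test that cell types drift apart over time.

    ``sample_meta`` (indexed like ``profiles``) needs ``cell_type`` and
    ``timepoint`` columns. For every timepoint, 2-D Euclidean distances are
    computed between samples of different cell types; a one-sided Welch
    t-test asks whether late-timepoint inter-type distances exceed
    early-timepoint ones.
    """
    if len(profiles) < 3:
        raise ValueError("MDS needs at least three samples")
    dist = correlation_distance(profiles)
    coords, eigenvalues = classical_mds(dist, n_dim=2)

    rows = []
    for tp, sub in sample_meta.groupby("timepoint"):
        ids = list(sub.index)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if sub.loc[a, "cell_type"] != sub.loc[b, "cell_type"]:
                    d2 = float(np.linalg.norm(coords.loc[a] - coords.loc[b]))
                    rows.append({"timepoint": tp, "pair": f"{a}|{b}", "distance": d2})
    inter = pd.DataFrame(rows)

    divergence_p = float("nan")
    if len(inter) and early_timepoints and late_timepoints:
        early = inter.loc[inter["timepoint"].isin(set(early_timepoints)), "distance"]
        late = inter.loc[inter["timepoint"].isin(set(late_timepoints)), "distance"]
        if len(early) >= 2 and len(late) >= 2:
            _, divergence_p = st.ttest_ind(
                late, early, equal_var=False, alternative="greater"
            )
            divergence_p = float(divergence_p)
    return MdsResult(
        coordinates=coords,
        distances=dist,
        eigenvalues=eigenvalues,
        inter_type_distances=inter,
        divergence_p=divergence_p,
    )


# ---------------------------------------------------------------------------
# MDS input preparation
# ---------------------------------------------------------------------------

def prepare_mds_inputs(
    expression=None,
    accessibility=None,
    methylation=None,
    min_fpkm: float = 10.0,
) -> dict[str, pd.DataFrame]:
    """Assemble samples x features inputs per modality for MDS.

    Expression: log2(x+1) FPKM over genes expressed >= ``min_fpkm`` in >= 1
    condition. Accessibility: log2(x+1) then quantile normalization across
    samples (rank-mean form). Methylation: used as-is (fractions).
    """
    out = {}
    if expression is not None:
        v = expression.values
        expressed = v.max(axis=1) >= min_fpkm
        out["rna"] = np.log2(v[expressed] + 1.0).T
    if accessibility is not None:
        v = np.log2(accessibility.values + 1.0)
        ranks = v.rank(axis=0, method="average")
        mean_sorted = np.sort(v.to_numpy(), axis=0).mean(axis=1)
        qn = ranks.apply(lambda col: np.interp(col, np.arange(1, len(col) + 1), mean_sorted))
        out["atac"] = qn.T
    if methylation is not None:
        out["meth"] = methylation.values.T
    return out
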