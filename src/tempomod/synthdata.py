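"""Synthetic multi-omic data with planted temporal/cell-type module structure.

Emulates the shapes of a cortical-neuron development study: pseudo-bulk
expression (FPKM-like), chromatin accessibility (TMM-like) and CpG
methylation (fractions) over cell-type x timepoint conditions, together with
per-comparison differential statistics, genome annotation (TSS, CpG islands,
sequences, conservation), tissue reference panels with planted tau
specificity, and cross-species homology maps with controlled retention.

Every generator draws from its own RNG stream derived from the master seed
by a stable label, so adding one generator never perturbs another. Planted
features follow ``effect x prototype + N(0, noise_sd)`` on log/z scale;
unplanted features are pure noise. Defaults encode the study conditions the
package is exercised under: two projection-neuron classes across four
postnatal timepoints, three planted modules (shared-early, shared-late,
cell-type-specific) of 80 features each at effect size 2 and noise 0.2.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import FeatureMatrix, GenomicRegionSet, ScoreTrack, write_fasta

DNA = np.array(["A", "C", "G", "T"])


class ConfigurationError(ValueError):
    pass


def _rng(seed: int, label: str) -> np.random.Generator:
    """Independent stream per generator op: master seed + CRC32 of the label."""
    return np.random.default_rng([int(seed), zlib.crc32(label.encode())])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_CELL_CLUSTERS = [
    ("CPN", "P1"), ("CPN", "P7"), ("CPN", "P21"), ("CPN", "P48"),
    ("CThPN", "P1"), ("CThPN", "P7"), ("CThPN", "P21"), ("CThPN", "P48"),
]

DEFAULT_MODULES = [("early", 80, 2.0), ("late", 80, 2.0), ("CPN", 80, 2.0)]


@dataclass
class SynthConfig:
    """Ground-truth parameters for the synthetic study.

    Per-module dicts are keyed by the planted pattern label; features outside
    any planted module use the ``background_*`` value.
    """

    n_genes: int = 600
    n_regions: int = 600
    cell_clusters: list = field(default_factory=lambda: list(DEFAULT_CELL_CLUSTERS))
    planted_modules: list = field(default_factory=lambda: list(DEFAULT_MODULES))
    noise_sd: float = 0.2
    panel_tissues: int = 30
    planted_tau: dict = field(
        default_factory=lambda: {"early": 0.2, "late": 0.8, "CPN": 0.6}
    )
    background_tau: float = 0.5
    genome_length: int = 2_400_000
    promoter_frac_by_module: dict = field(
        default_factory=lambda: {"early": 0.7, "late": 0.2, "CPN": 0.3}
    )
    cgi_frac_by_module: dict = field(
        default_factory=lambda: {"early": 0.6, "late": 0.1, "CPN": 0.2}
    )
    conservation_means_by_module: dict = field(
        default_factory=lambda: {"early": 1.0, "late": 0.0, "CPN": 0.3}
    )
    gc_by_module: dict = field(
        default_factory=lambda: {"early": 0.7, "late": 0.45, "CPN": 0.5}
    )
    cpg_boost_by_module: dict = field(
        default_factory=lambda: {"early": 0.5, "late": 0.0, "CPN": 0.1}
    )
    panel_breadth_by_module: dict = field(
        default_factory=lambda: {"early": 0.8, "late": 0.15, "CPN": 0.3}
    )
    background_promoter_frac: float = 0.2
    background_cgi_frac: float = 0.1
    background_conservation_mean: float = 0.0
    background_gc: float = 0.5
    background_cpg_boost: float = 0.0
    background_panel_breadth: float = 0.3
    homolog_retention: float = 0.8
    region_map_bad_ratio_frac: float = 0.2
    region_map_short_frac: float = 0.05
    early_timepoints: tuple = ("P1", "P7")
    late_timepoints: tuple = ("P21", "P48")
    region_width: int = 350
    conservation_tile: int = 10
    conservation_base_sd: float = 0.1
    replicate_sd: float | None = None  # defaults to noise_sd
    n_replicates: int = 2
    replicate_dropout: float = 0.1
    panel_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_regions <= 0 or self.panel_tissues <= 0:
            raise ConfigurationError("counts must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        total = sum(n for _, n, _ in self.planted_modules)
        if total > min(self.n_genes, self.n_regions):
            raise ConfigurationError(
                "planted module sizes exceed n_genes/n_regions"
            )
        for d in (
            self.promoter_frac_by_module,
            self.cgi_frac_by_module,
            self.planted_tau,
            self.panel_breadth_by_module,
            self.gc_by_module,
        ):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ConfigurationError("fractions must lie in [0, 1]")
        if not 0.0 <= self.homolog_retention <= 1.0:
            raise ConfigurationError("homolog_retention must lie in [0, 1]")
        # each region needs room for its body plus flanking TSS placement
        if self.genome_length < self.n_regions * (self.region_width + 3000):
            raise ConfigurationError("genome too short for requested regions")

    # per-module lookups -----------------------------------------------------

    def module_labels(self) -> list[str]:
        return [label for label, _, _ in self.planted_modules]

    def _lookup(self, d: dict, label: str | None, background: float) -> float:
        if label is None:
            return background
        return d.get(label, background)

    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        data["cell_clusters"] = [list(c) for c in self.cell_clusters]
        data["planted_modules"] = [list(m) for m in self.planted_modules]
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["cell_clusters"] = [tuple(c) for c in data["cell_clusters"]]
        data["planted_modules"] = [tuple(m) for m in data["planted_modules"]]
        for key in ("early_timepoints", "late_timepoints"):
            data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# Prototypes
# ---------------------------------------------------------------------------

def prototype_vector(label: str, config: SynthConfig) -> np.ndarray:
    """Binary activity prototype over conditions for a planted pattern label.

    ``early``/``late`` activate the configured timepoint groups across all
    cell types; a cell-type label activates all conditions of that cell type;
    a timepoint label activates that timepoint across cell types.
    """
    cell_types = [ct for ct, _ in config.cell_clusters]
    timepoints = [tp for _, tp in config.cell_clusters]
    if label == "early":
        active = [tp in config.early_timepoints for tp in timepoints]
    elif label == "late":
        active = [tp in config.late_timepoints for tp in timepoints]
    elif label in cell_types:
        active = [ct == label for ct in cell_types]
    elif label in timepoints:
        active = [tp == label for tp in timepoints]
    else:
        raise ConfigurationError(f"cannot derive a prototype for pattern {label!r}")
    v = np.asarray(active, dtype=float)
    if v.sum() == 0:
        raise ConfigurationError(f"pattern {label!r} activates no condition")
    return v


def _feature_modules(config: SynthConfig, n_features: int) -> list[str | None]:
    """Module label per feature index: planted modules occupy leading blocks."""
    labels: list[str | None] = []
    for label, count, _ in config.planted_modules:
        labels.extend([label] * count)
    labels.extend([None] * (n_features - len(labels)))
    return labels


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    expression: FeatureMatrix
    accessibility: FeatureMatrix
    methylation: FeatureMatrix
    diff_stats: pd.DataFrame  # modality, feature, comparison, cond_a, cond_b, log2fc, p, q
    truth_labels: dict  # feature id -> planted pattern label


@dataclass
class AnnotationBundle:
    regions: GenomicRegionSet
    tss: pd.DataFrame  # gene_id, chrom, pos, strand
    cgi: GenomicRegionSet
    sequences: dict  # region id -> DNA string
    conservation: ScoreTrack
    region_to_truth: dict  # region id -> planted module label


@dataclass
class PanelBundle:
    tissue_expression: pd.DataFrame  # tissues x genes, nonnegative
    tissue_open: pd.DataFrame  # tissues x regions, binary
    replicate_peaks: dict  # tissue -> list of GenomicRegionSet


@dataclass
class HomologyBundle:
    gene_orthologs: pd.DataFrame  # gene_a, gene_b
    region_map: pd.DataFrame  # source_id, chrom, start, end, mapped_length, size_ratio


# ---------------------------------------------------------------------------
# gen_feature_matrices
# ---------------------------------------------------------------------------

def gen_feature_matrices(config: SynthConfig) -> SyntheticDataset:
    """Expression/accessibility/methylation matrices plus differential stats.

    Log-scale signal per feature is ``base + effect * prototype + noise``;
    abundance is ``2**signal - 1`` so the clustering transform (log2(x+1),
    row z-score) recovers the planted prototype shape. Differential stats
    simulate ``n_replicates`` per condition and a Welch t-test per pairwise
    comparison, with BH adjustment per modality and comparison — mimicking
    the per-comparison output of upstream differential callers.
    """
    from .integration import bh_adjust

    conditions = [f"{ct}_{tp}" for ct, tp in config.cell_clusters]
    cond_meta = pd.DataFrame(
        {
            "cell_type": [ct for ct, _ in config.cell_clusters],
            "timepoint": [tp for _, tp in config.cell_clusters],
        },
        index=pd.Index(conditions, name="condition"),
    )
    n_cond = len(conditions)

    protos = {
        label: prototype_vector(label, config) for label in config.module_labels()
    }
    effects = {label: eff for label, _, eff in config.planted_modules}

    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    region_ids = [f"r{i:05d}" for i in range(config.n_regions)]
    gene_modules = _feature_modules(config, config.n_genes)
    region_modules = _feature_modules(config, config.n_regions)

    def signal_matrix(modules, rng, base_lo, base_hi):
        n = len(modules)
        base = rng.uniform(base_lo, base_hi, size=n)[:, None]
        sig = np.zeros((n, n_cond))
        for i, label in enumerate(modules):
            if label is not None:
                sig[i] = effects[label] * protos[label]
        noise = rng.normal(0.0, config.noise_sd, size=(n, n_cond)) if config.noise_sd > 0 else 0.0
        return base + sig + noise

    rng_expr = _rng(config.seed, "expression")
    rng_acc = _rng(config.seed, "accessibility")
    rng_meth = _rng(config.seed, "methylation")

    log_expr = signal_matrix(gene_modules, rng_expr, 4.0, 8.0)
    log_acc = signal_matrix(region_modules, rng_acc, 1.0, 5.0)
    expression = FeatureMatrix(
        pd.DataFrame(2.0 ** log_expr - 1.0, index=gene_ids, columns=conditions),
        cond_meta,
    )
    accessibility = FeatureMatrix(
        pd.DataFrame(2.0 ** log_acc - 1.0, index=region_ids, columns=conditions),
        cond_meta,
    )

    # methylation: logit-normal, anti-correlated with activity
    logit0 = rng_meth.normal(1.0, 0.3, size=config.n_regions)[:, None]
    meth_sig = np.zeros((config.n_regions, n_cond))
    for i, label in enumerate(region_modules):
        if label is not None:
            meth_sig[i] = -effects[label] * protos[label]
    meth_noise = (
        rng_meth.normal(0.0, config.noise_sd, size=(config.n_regions, n_cond))
        if config.noise_sd > 0
        else 0.0
    )
    methylation = FeatureMatrix(
        pd.DataFrame(
            _sigmoid(logit0 + meth_sig + meth_noise), index=region_ids, columns=conditions
        ),
        cond_meta,
    )

    diff_stats = _gen_diff_stats(
        config,
        {"rna": (gene_ids, log_expr), "atac": (region_ids, log_acc)},
        conditions,
        bh_adjust,
    )

    truth = {}
    for fid, label in zip(gene_ids, gene_modules):
        if label is not None:
            truth[fid] = label
    for fid, label in zip(region_ids, region_modules):
        if label is not None:
            truth[fid] = label

    return SyntheticDataset(expression, accessibility, methylation, diff_stats, truth)


def _gen_diff_stats(config, modalities, conditions, bh_adjust) -> pd.DataFrame:
    from scipy import stats as st

    rep_sd = config.replicate_sd if config.replicate_sd is not None else config.noise_sd
    nrep = config.n_replicates
    frames = []
    for modality, (ids, log_values) in modalities.items():
        rng = _rng(config.seed, f"diffstats:{modality}")
        n = len(ids)
        # replicate draws around the per-condition log signal
        reps = log_values[:, :, None] + (
            rng.normal(0.0, rep_sd, size=(n, len(conditions), nrep)) if rep_sd > 0 else 0.0
        )
        for a in range(len(conditions)):
            for b in range(a + 1, len(conditions)):
                xa, xb = reps[:, a, :], reps[:, b, :]
                log2fc = xa.mean(axis=1) - xb.mean(axis=1)
                if rep_sd > 0:
                    # moderated test: variance pooled across features, as the
                    # upstream differential callers do, so n=2 replicates
                    # retain power at realistic effect sizes
                    per_feature_var = xa.var(axis=1, ddof=1) / nrep + xb.var(
                        axis=1, ddof=1
                    ) / nrep
                    se = np.sqrt(per_feature_var.mean())
                    p = 2.0 * st.norm.sf(np.abs(log2fc) / se)
                else:
                    p = np.where(np.abs(log2fc) > 0, 0.0, 1.0)
                frames.append(
                    pd.DataFrame(
                        {
                            "modality": modality,
                            "feature": ids,
                            "comparison": f"{conditions[a]}__vs__{conditions[b]}",
                            "cond_a": conditions[a],
                            "cond_b": conditions[b],
                            "log2fc": log2fc,
                            "p": p,
                            "q": bh_adjust(p),
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# gen_genome_annotation
# ---------------------------------------------------------------------------

def gen_genome_annotation(config: SynthConfig) -> AnnotationBundle:
    """Regions, TSS table, CGIs, sequences and a conservation track.

    Regions are placed deterministically on an even grid of one synthetic
    chromosome (so companion generators can address them without sharing RNG
    state). Region ``r{i}`` is paired with gene ``g{i}``: its TSS falls inside
    the +-1 kb promoter window with the module's promoter fraction, otherwise
    2-50 kb away — still linkable within 100 kb, preserving the planted
    region-gene module concordance.
    """
    rng = _rng(config.seed, "annotation")
    chrom = "chrS"
    width = config.region_width
    spacing = config.genome_length // config.n_regions
    region_modules = _feature_modules(config, config.n_regions)

    records = []
    tss_rows = []
    cgi_rows = []
    sequences = {}
    cons_rows = []

    for i, label in enumerate(region_modules):
        start = i * spacing + 1500  # flank room for promoter/CGI placement
        end = start + width
        rid = f"r{i:05d}"
        records.append((chrom, start, end, rid, "."))

        pf = config._lookup(config.promoter_frac_by_module, label, config.background_promoter_frac)
        gid = f"g{i:05d}" if i < config.n_genes else f"gx{i:05d}"
        if rng.random() < pf:
            pos = int(rng.integers(start - 900, end + 900))
        else:
            offset = int(rng.integers(2000, min(50_000, spacing - width - 1100)))
            pos = end + offset if rng.random() < 0.5 else max(0, start - offset)
        strand = "+" if rng.random() < 0.5 else "-"
        tss_rows.append((gid, chrom, pos, strand))

        cf = config._lookup(config.cgi_frac_by_module, label, config.background_cgi_frac)
        if rng.random() < cf:
            center = int(rng.integers(start, end))
            cgi_rows.append((chrom, max(0, center - 150), center + 150, f"cgi_{rid}", "."))

        gc = config._lookup(config.gc_by_module, label, config.background_gc)
        boost = config._lookup(config.cpg_boost_by_module, label, config.background_cpg_boost)
        sequences[rid] = _gen_sequence(rng, width, gc, boost)

        mean = config._lookup(
            config.conservation_means_by_module, label, config.background_conservation_mean
        )
        tile = config.conservation_tile
        tile_starts = np.arange(start, end, tile)
        tile_ends = np.minimum(tile_starts + tile, end)
        values = rng.normal(mean, config.conservation_base_sd, size=len(tile_starts))
        for s, e, v in zip(tile_starts, tile_ends, values):
            cons_rows.append((chrom, int(s), int(e), float(v)))

    regions = GenomicRegionSet(
        records=pd.DataFrame(records, columns=["chrom", "start", "end", "id", "strand"])
    )
    cgi = GenomicRegionSet(
        records=pd.DataFrame(
            cgi_rows or None, columns=["chrom", "start", "end", "id", "strand"]
        )
    )
    tss = pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "pos", "strand"])
    conservation = ScoreTrack(
        intervals=pd.DataFrame(cons_rows, columns=["chrom", "start", "end", "value"])
    )
    region_to_truth = {
        f"r{i:05d}": label for i, label in enumerate(region_modules) if label is not None
    }
    return AnnotationBundle(regions, tss, cgi, sequences, conservation, region_to_truth)


def _gen_sequence(rng: np.random.Generator, length: int, gc: float, cpg_boost: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    idx = rng.choice(4, size=length, p=p)
    if cpg_boost > 0 and length > 1:
        after_c = idx[:-1] == 1
        flip = rng.random(length - 1) < cpg_boost
        idx[1:][after_c & flip] = 2  # force G after C -> CpG dinucleotide
    return "".join(DNA[idx])


# ---------------------------------------------------------------------------
# gen_reference_panels
# ---------------------------------------------------------------------------

def gen_reference_panels(config: SynthConfig) -> PanelBundle:
    """Tissue expression panel with planted tau, binary open-chromatin panel
    and per-tissue replicate peak sets.

    A gene with planted tau t gets one maximal tissue at level M and the
    remaining tissues at ``M * (1 - t)`` with multiplicative noise scaled by
    ``4 t (1 - t)`` — exactly zero at both extremes, so tau 1 yields a single
    nonzero tissue and tau 0 a constant profile.
    """
    rng = _rng(config.seed, "panels")
    tissues = [f"tissue_{j:02d}" for j in range(config.panel_tissues)]
    gene_modules = _feature_modules(config, config.n_genes)
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]

    n_t = config.panel_tissues
    expr = np.zeros((n_t, config.n_genes))
    for i, label in enumerate(gene_modules):
        t = config._lookup(config.planted_tau, label, config.background_tau)
        m = rng.uniform(50.0, 500.0)
        top = int(rng.integers(0, n_t))
        base = m * (1.0 - t)
        eps_sd = config.panel_noise * 4.0 * t * (1.0 - t)
        eps = rng.normal(0.0, eps_sd, size=n_t) if eps_sd > 0 else np.zeros(n_t)
        vals = base * np.clip(1.0 + eps, 0.0, None)
        vals = np.minimum(vals, m)  # keep the designated tissue maximal
        vals[top] = m
        expr[:, i] = vals
    tissue_expression = pd.DataFrame(expr, index=tissues, columns=gene_ids)

    region_modules = _feature_modules(config, config.n_regions)
    region_ids = [f"r{i:05d}" for i in range(config.n_regions)]
    breadth = np.array(
        [
            config._lookup(config.panel_breadth_by_module, label, config.background_panel_breadth)
            for label in region_modules
        ]
    )
    open_mat = (rng.random((n_t, config.n_regions)) < breadth[None, :]).astype(int)
    # a region absent everywhere breaks nothing, but keep each present somewhere
    empty = open_mat.sum(axis=0) == 0
    if empty.any():
        open_mat[rng.integers(0, n_t, size=int(empty.sum())), np.where(empty)[0]] = 1
    tissue_open = pd.DataFrame(open_mat, index=tissues, columns=region_ids)

    # replicate peak sets: tissue peaks are the open regions, each replicate
    # jittered a few bp with random dropout
    chrom = "chrS"
    width = config.region_width
    spacing = config.genome_length // config.n_regions
    starts = np.arange(config.n_regions) * spacing + 1500
    replicate_peaks = {}
    for j, tissue in enumerate(tissues):
        present = np.where(open_mat[j] == 1)[0]
        reps = []
        for r in range(config.n_replicates):
            keep = rng.random(len(present)) >= config.replicate_dropout
            idx = present[keep]
            jit = rng.integers(-20, 21, size=len(idx))
            rows = [
                (chrom, int(starts[i] + d), int(starts[i] + d + width), f"{tissue}_rep{r}_pk{i}", ".")
                for i, d in zip(idx, jit)
            ]
            reps.append(
                GenomicRegionSet(
                    records=pd.DataFrame(
                        rows or None, columns=["chrom", "start", "end", "id", "strand"]
                    )
                )
            )
        replicate_peaks[tissue] = reps
    return PanelBundle(tissue_expression, tissue_open, replicate_peaks)


# ---------------------------------------------------------------------------
# gen_homology_maps
# ---------------------------------------------------------------------------

def gen_homology_maps(config: SynthConfig) -> HomologyBundle:
    """Ortholog table (partial bijection) and a liftover-style region map.

    Each gene is retained with probability ``homolog_retention``. Region
    mappings fall into three configured classes: ratio >= 1.2 (fails the
    expansion filter), mapped length < 100 bp (fails the size filter), and
    clean mappings with ratio in [0.85, 1.15).
    """
    rng = _rng(config.seed, "homology")
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    kept = rng.random(config.n_genes) < config.homolog_retention
    pairs = pd.DataFrame(
        {
            "gene_a": [g for g, k in zip(gene_ids, kept) if k],
            "gene_b": [f"h{i:05d}" for i, k in enumerate(kept) if k],
        }
    )

    width = config.region_width
    n = config.n_regions
    u = rng.random(n)
    bad = u < config.region_map_bad_ratio_frac
    short = (~bad) & (u < config.region_map_bad_ratio_frac + config.region_map_short_frac)
    mapped_len = np.empty(n, dtype=int)
    mapped_len[bad] = np.round(width * rng.uniform(1.2, 1.6, size=int(bad.sum()))).astype(int)
    mapped_len[short] = rng.integers(30, 100, size=int(short.sum()))
    good = ~(bad | short)
    mapped_len[good] = np.round(
        width * rng.uniform(0.85, 1.15, size=int(good.sum()))
    ).astype(int)
    # guarantee class membership after rounding
    mapped_len[bad] = np.maximum(mapped_len[bad], int(np.ceil(width * 1.2)))
    mapped_len[good] = np.clip(mapped_len[good], 100, int(np.ceil(width * 1.2)) - 1)

    starts = np.cumsum(np.concatenate([[1000], mapped_len[:-1] + 500]))
    region_map = pd.DataFrame(
        {
            "source_id": [f"r{i:05d}" for i in range(n)],
            "chrom": "chrB",
            "start": starts,
            "end": starts + mapped_len,
            "mapped_length": mapped_len,
            "size_ratio": mapped_len / float(width),
        }
    )
    return HomologyBundle(pairs, region_map)


# ---------------------------------------------------------------------------
# Full dataset + disk round-trip
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    config: SynthConfig
    dataset: SyntheticDataset
    annotation: AnnotationBundle
    panels: PanelBundle
    homology: HomologyBundle


def generate_all(config: SynthConfig) -> SyntheticStudy:
    return SyntheticStudy(
        config=config,
        dataset=gen_feature_matrices(config),
        annotation=gen_genome_annotation(config),
        panels=gen_reference_panels(config),
        homology=gen_homology_maps(config),
    )


def write_all(study: SyntheticStudy, out_dir) -> None:
    """Emit every artifact as plain text: TSV/BED6/FASTA/bedGraph/YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.config.to_yaml(out / "config.yaml")
    ds = study.dataset
    ds.expression.to_tsv(out / "expression.tsv", out / "conditions.tsv")
    ds.accessibility.to_tsv(out / "accessibility.tsv")
    ds.methylation.to_tsv(out / "methylation.tsv")
    ds.diff_stats.to_csv(out / "diff_stats.tsv", sep="\t", index=False)
    pd.Series(ds.truth_labels, name="module").rename_axis("feature").to_csv(
        out / "truth_labels.tsv", sep="\t"
    )
    ann = study.annotation
    ann.regions.to_bed(out / "regions.bed")
    ann.cgi.to_bed(out / "cgi.bed")
    ann.tss.to_csv(out / "tss.tsv", sep="\t", index=False)
    write_fasta(ann.sequences, out / "sequences.fasta")
    ann.conservation.to_bedgraph(out / "conservation.bedgraph")
    study.panels.tissue_expression.to_csv(out / "panel_expression.tsv", sep="\t")
    study.panels.tissue_open.to_csv(out / "panel_open.tsv", sep="\t")
    study.homology.gene_orthologs.to_csv(out / "orthologs.tsv", sep="\t", index=False)
    study.homology.region_map.to_csv(out / "region_map.tsv", sep="\t", index=False)
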