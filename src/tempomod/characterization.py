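"""Genomic and sequence characterization of region modules.

Per module: fraction of regions in promoter windows (TSS +- 1 kb) and CpG
islands, nearest-TSS gene links within 100 kb, motif-match density against a
PWM library at an exact background p-value threshold, mononucleotide Shannon
entropy, and mean per-base conservation — assembled into a min-max
normalized radar-style summary.

PWM thresholds are computed by exact dynamic programming over the
discretized log-odds score distribution under the background model
(FIMO-style): scores are rounded to a fixed granularity, the distribution
of the rounded position score is built by convolution over motif columns,
and the threshold is the smallest score whose upper tail probability does
not exceed the requested p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicRegionSet, ScoreTrack, UndefinedInputError, overlap_any

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}

#: log-odds scores are rounded to this granularity before DP / scanning
SCORE_GRANULARITY = 1e-3
#: probability pseudocount applied to PWM columns
PSEUDOCOUNT = 1e-4


@dataclass
class Pwm:
    """Position probability matrix (4 x L, rows A/C/G/T) with background."""

    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    id: str = "pwm"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.ndim != 2:
            raise ValueError("PWM matrix must be 4 x L")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """Integer log2-odds score per (base, position) at fixed granularity.

        A pseudocount regularizes zero probabilities before the ratio.
        """
        p = (self.matrix + PSEUDOCOUNT) / (1.0 + 4.0 * PSEUDOCOUNT)
        lo = np.log2(p / self.background[:, None])
        return np.round(lo / SCORE_GRANULARITY).astype(np.int64)

    def reverse_complement(self) -> "Pwm":
        rc = self.matrix[::-1, ::-1].copy()
        return Pwm(matrix=rc, background=self.background[::-1].copy(), id=f"{self.id}_rc")


def read_meme_pwms(path) -> list[Pwm]:
    """Load PWMs from a MEME (minimal) motif file via Bio.motifs."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
        probs = counts / counts.sum(axis=0, keepdims=True)
        bg = np.array([m.background[b] for b in "ACGT"], dtype=float)
        out.append(Pwm(matrix=probs, background=bg, id=m.name or "pwm"))
    return out


# ---------------------------------------------------------------------------
# Promoter / CGI overlap and nearest-TSS linking
# ---------------------------------------------------------------------------

def promoter_windows(tss: pd.DataFrame, flank: int = 1000) -> pd.DataFrame:
    """TSS +- ``flank`` windows, strand-independent, clipped at 0."""
    return pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": np.maximum(tss["pos"] - flank, 0),
            "end": tss["pos"] + flank,
        }
    )


def promoter_cgi_overlap(
    regions: GenomicRegionSet,
    tss: pd.DataFrame,
    cgi: GenomicRegionSet,
    flank: int = 1000,
) -> tuple[float, float]:
    """(promoter_frac, cgi_frac): share of regions overlapping >= 1 bp."""
    if len(regions) == 0:
        raise UndefinedInputError("empty region set")
    prom = promoter_windows(tss, flank)
    prom_hits = overlap_any(regions.records, prom)
    cgi_hits = overlap_any(regions.records, cgi.records)
    n = len(regions)
    return float(prom_hits.sum()) / n, float(cgi_hits.sum()) / n


def nearest_tss_link(
    regions: GenomicRegionSet,
    tss: pd.DataFrame,
    max_dist: int = 100_000,
) -> pd.Series:
    """Region id -> gene id of the nearest TSS within ``max_dist`` bp.

    Distance is 0 when the TSS lies inside the region, otherwise the gap to
    the nearer region edge. Regions whose nearest TSS exceeds ``max_dist``
    are omitted (unlinked).
    """
    if tss.empty:
        raise UndefinedInputError("TSS table is empty")
    links = {}
    for chrom, sub in regions.records.groupby("chrom"):
        t = tss[tss["chrom"] == chrom].sort_values("pos")
        if t.empty:
            continue
        pos = t["pos"].to_numpy()
        genes = t["gene_id"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # candidates: TSS just left of start, inside, or just right of end
        left = np.searchsorted(pos, starts, side="left") - 1
        right = np.searchsorted(pos, ends - 1, side="right")
        inside_lo = np.searchsorted(pos, starts, side="left")
        for i, rid in enumerate(sub["id"]):
            if inside_lo[i] < len(pos) and pos[inside_lo[i]] < ends[i]:
                links[rid] = genes[inside_lo[i]]
                continue
            best_d, best_g = None, None
            for j in (left[i], right[i]):
                if 0 <= j < len(pos):
                    d = starts[i] - pos[j] if pos[j] < starts[i] else pos[j] - (ends[i] - 1)
                    if best_d is None or d < best_d:
                        best_d, best_g = d, genes[j]
            if best_d is not None and best_d <= max_dist:
                links[rid] = best_g
    return pd.Series(links, name="gene_id", dtype=object)


# ---------------------------------------------------------------------------
# PWM threshold (exact DP) and motif scanning
# ---------------------------------------------------------------------------

def pwm_score_distribution(pwm: Pwm) -> dict[int, float]:
    """Exact distribution of the rounded log-odds score under the background.

    Convolution over motif columns: after column j the dict maps each
    attainable integer score sum to its background probability.
    """
    scores = pwm.log_odds()
    dist = {0: 1.0}
    for j in range(pwm.length):
        nxt: dict[int, float] = {}
        for s, p in dist.items():
            for b in range(4):
                key = s + int(scores[b, j])
                nxt[key] = nxt.get(key, 0.0) + p * pwm.background[b]
        dist = nxt
    return dist


def pwm_threshold(pwm: Pwm, p_threshold: float = 1e-4) -> int:
    """Smallest integer score t with P_bg(score >= t) <= p_threshold.

    Among thresholds meeting the bound this has the largest tail p. When
    ``p_threshold >= 1`` the minimum attainable score is returned, so every
    position passes.
    """
    dist = pwm_score_distribution(pwm)
    items = sorted(dist.items(), reverse=True)
    if p_threshold >= 1.0:
        return items[-1][0]
    tail = 0.0
    threshold = items[0][0] + 1  # above max score: nothing passes
    for s, p in items:
        if tail + p > p_threshold:
            break
        tail += p
        threshold = s
    return threshold


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(arr.shape, -1, dtype=np.int64)
    for base, i in BASE_INDEX.items():
        code[arr == ord(base)] = i
    return code


def scan_sequence(seq: str, pwm: Pwm, threshold: int) -> int:
    """Count positions on both strands whose rounded score meets threshold.

    Windows containing N (or any non-ACGT letter) are skipped.
    """
    code = _encode(seq)
    L = pwm.length
    if len(code) < L:
        return 0
    total = 0
    for mat in (pwm.log_odds(), pwm.reverse_complement().log_odds()):
        window = np.lib.stride_tricks.sliding_window_view(code, L)
        valid = (window >= 0).all(axis=1)
        idx = np.where(valid)[0]
        if len(idx) == 0:
            continue
        scores = mat[window[idx], np.arange(L)].sum(axis=1)
        total += int((scores >= threshold).sum())
    return total


def motif_density(
    regions: GenomicRegionSet,
    sequences: dict[str, str],
    pwms: list[Pwm],
    p_threshold: float = 1e-4,
) -> pd.Series:
    """Motif matches per kb per region, summed over the PWM library."""
    thresholds = {pwm.id: pwm_threshold(pwm, p_threshold) for pwm in pwms}
    out = {}
    for row in regions.records.itertuples(index=False):
        seq = sequences.get(row.id)
        if seq is None or len(seq) != row.end - row.start:
            raise ValueError(f"sequence missing or length mismatch for region {row.id}")
        count = sum(scan_sequence(seq, pwm, thresholds[pwm.id]) for pwm in pwms)
        out[row.id] = count / ((row.end - row.start) / 1000.0)
    return pd.Series(out, name="motif_density")


# ---------------------------------------------------------------------------
# Entropy and conservation
# ---------------------------------------------------------------------------

def sequence_entropy(seq: str) -> float:
    """Mononucleotide Shannon entropy in bits; N excluded from counts."""
    code = _encode(seq)
    counts = np.bincount(code[code >= 0], minlength=4).astype(float)
    total = counts.sum()
    if total == 0:
        raise UndefinedInputError("sequence has no A/C/G/T bases")
    f = counts[counts > 0] / total
    return float(-(f * np.log2(f)).sum())


def mean_conservation(
    regions: GenomicRegionSet,
    track: ScoreTrack,
    flag_uncovered_frac: float = 0.5,
) -> pd.DataFrame:
    """Per-region mean of per-base scores; uncovered bases are excluded.

    Columns: mean (NaN when fully uncovered), covered_frac, flagged (more
    than ``flag_uncovered_frac`` of bases uncovered).
    """
    rows = {}
    for row in regions.records.itertuples(index=False):
        mean, covered = track.region_mean(row.chrom, row.start, row.end)
        frac = covered / (row.end - row.start)
        rows[row.id] = {
            "mean": mean,
            "covered_frac": frac,
            "flagged": frac < (1.0 - flag_uncovered_frac),
        }
    return pd.DataFrame(rows).T.astype({"mean": float, "covered_frac": float, "flagged": bool})


# ---------------------------------------------------------------------------
# Radar summary
# ---------------------------------------------------------------------------

def summarize_modules(metrics: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize per-module metrics across modules to [0, 1].

    Input is modules x metrics; a metric constant across modules normalizes
    to 0.5 everywhere (there is no contrast to display) and is flagged via
    the returned frame's ``attrs['constant_metrics']``.
    """
    if len(metrics) < 2:
        raise ValueError("radar normalization needs at least two modules")
    lo = metrics.min(axis=0)
    hi = metrics.max(axis=0)
    span = hi - lo
    constant = span == 0
    norm = (metrics - lo) / span.where(~constant, 1.0)
    norm.loc[:, constant] = 0.5
    norm.attrs["constant_metrics"] = list(metrics.columns[constant])
    return norm
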