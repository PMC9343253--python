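"""Shared containers: feature matrices, genomic interval sets, score tracks.

Coordinates are 0-based half-open throughout, the BED convention. Interval
algebra (merge, overlap, nearest) is implemented on sorted numpy arrays;
merged sets are disjoint and sorted, so membership and overlap queries reduce
to ``searchsorted``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "id", "score", "strand"]


class SchemaError(ValueError):
    """An input table is missing required columns or violates invariants."""


class UndefinedInputError(ValueError):
    """The requested quantity is undefined for this input (e.g. all-zero vector)."""


# ---------------------------------------------------------------------------
# FeatureMatrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Features x conditions abundance matrix with condition metadata.

    ``values`` is indexed by feature id with one column per condition;
    ``conditions`` carries one row per condition with at least ``cell_type``
    and ``timepoint`` columns (``replicate`` optional).
    """

    values: pd.DataFrame
    conditions: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.conditions.index)
        if missing:
            raise SchemaError(f"conditions metadata missing for columns: {sorted(missing)}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def condition_names(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, matrix_path, conditions_path=None) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="feature")
        if conditions_path is not None:
            self.conditions.to_csv(conditions_path, sep="\t", index_label="condition")

    @classmethod
    def from_tsv(cls, matrix_path, conditions_path) -> "FeatureMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col="feature")
        values.index.name = None
        conditions = pd.read_csv(conditions_path, sep="\t", index_col="condition")
        return cls(values=values, conditions=conditions)


# ---------------------------------------------------------------------------
# GenomicRegionSet
# ---------------------------------------------------------------------------

@dataclass
class GenomicRegionSet:
    """Strand-aware intervals with unique ids on a named assembly."""

    records: pd.DataFrame  # chrom, start, end, id, strand
    assembly: str = "synth1"

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "id", "strand"}
        missing = req - set(self.records.columns)
        if missing:
            raise SchemaError(f"region records missing columns: {sorted(missing)}")
        rec = self.records
        if len(rec) and not (rec["start"] < rec["end"]).all():
            raise ValueError("regions must satisfy 0 <= start < end")
        if len(rec) and (rec["start"] < 0).any():
            raise ValueError("negative start coordinate")
        if rec["id"].duplicated().any():
            raise ValueError("region ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        assembly: str = "synth1",
    ) -> "GenomicRegionSet":
        df = pd.DataFrame(records, columns=["chrom", "start", "end", "id", "strand"])
        return cls(records=df, assembly=assembly)

    @property
    def lengths(self) -> pd.Series:
        s = self.records["end"] - self.records["start"]
        s.index = self.records["id"].values
        return s

    def subset(self, ids: Iterable[str]) -> "GenomicRegionSet":
        ids = set(ids)
        return GenomicRegionSet(
            records=self.records[self.records["id"].isin(ids)].reset_index(drop=True),
            assembly=self.assembly,
        )

    # ---- BED I/O ----

    def to_bed(self, path) -> None:
        df = self.records.copy()
        df["score"] = 0
        df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path, assembly: str = "synth1") -> "GenomicRegionSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.iloc[:, : len(BED_COLUMNS)]
        df.columns = BED_COLUMNS[: df.shape[1]]
        if "id" not in df.columns:
            df["id"] = [f"r{i}" for i in range(len(df))]
        if "strand" not in df.columns:
            df["strand"] = "."
        return cls(records=df[["chrom", "start", "end", "id", "strand"]], assembly=assembly)

    # ---- interval algebra ----

    def merged(self) -> "GenomicRegionSet":
        """Collapse intervals that overlap by >= 1 bp into single intervals."""
        merged = merge_intervals(self.records)
        merged["id"] = [f"m{i}" for i in range(len(merged))]
        merged["strand"] = "."
        return GenomicRegionSet(
            records=merged[["chrom", "start", "end", "id", "strand"]],
            assembly=self.assembly,
        )

    def overlaps_any(self, other: "GenomicRegionSet") -> pd.Series:
        """Boolean per record: overlaps (>=1 bp) any interval of ``other``."""
        flags = overlap_any(self.records, other.records)
        return pd.Series(flags, index=self.records["id"].values)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals per chromosome; >=1 bp overlap collapses (bookended
    intervals sharing only an endpoint stay separate under half-open coords)."""
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s < cur_e:  # overlap of at least one base
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def overlap_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Per query interval: does it overlap >=1 bp with any subject interval?

    Subjects are merged first, then a searchsorted test against the resulting
    disjoint sorted intervals decides overlap.
    """
    result = np.zeros(len(query), dtype=bool)
    if len(subject) == 0 or len(query) == 0:
        return result
    merged = merge_intervals(subject)
    for chrom, sub in merged.groupby("chrom"):
        mask = (query["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        qs = query.loc[mask, "start"].to_numpy()
        qe = query.loc[mask, "end"].to_numpy()
        # candidate: last subject interval starting before query end
        idx = np.searchsorted(starts, qe, side="left") - 1
        ok = idx >= 0
        hit = np.zeros(len(qs), dtype=bool)
        hit[ok] = ends[idx[ok]] > qs[ok]
        result[mask] = hit
    return result


# ---------------------------------------------------------------------------
# ScoreTrack (bedGraph-style per-base scores)
# ---------------------------------------------------------------------------

@dataclass
class ScoreTrack:
    """Per-base score track stored as disjoint sorted intervals per chromosome."""

    intervals: pd.DataFrame  # chrom, start, end, value

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "value"}
        if req - set(self.intervals.columns):
            raise SchemaError("score track needs chrom/start/end/value columns")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.intervals.groupby("chrom"):
            sub = sub.sort_values("start")
            self._by_chrom[chrom] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["value"].to_numpy(float),
            )

    def region_mean(self, chrom: str, start: int, end: int) -> tuple[float, int]:
        """Length-weighted mean score over covered bases of [start, end).

        Returns (mean, covered_bases); mean is NaN when nothing is covered.
        """
        if chrom not in self._by_chrom:
            return float("nan"), 0
        starts, ends, values = self._by_chrom[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return float("nan"), 0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        w = (e - s).astype(float)
        keep = w > 0
        if not keep.any():
            return float("nan"), 0
        w = w[keep]
        v = values[lo:hi][keep]
        return float(np.average(v, weights=w)), int(w.sum())

    def to_bedgraph(self, path) -> None:
        self.intervals[["chrom", "start", "end", "value"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def from_bedgraph(cls, path) -> "ScoreTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
        )
        return cls(intervals=df)


# ---------------------------------------------------------------------------
# FASTA helpers (Bio.SeqIO-backed)
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
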