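"""Pattern assignment: prototype indicator library + cosine similarity.

Discovered modules are labelled by comparing their average normalized
profile over cell clusters against a binary prototype library (one column
per candidate temporal / cell-class / per-cluster pattern); the label with
maximal cosine similarity wins. Temporal labels are then folded into the
early/late partition of timepoints to produce shared-early / shared-late /
cell-type-specific categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FeatureMatrix


@dataclass
class PatternLibrary:
    matrix: pd.DataFrame  # cell clusters x patterns, binary

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("pattern library entries must be 0/1")
        if (vals.sum(axis=0) == 0).any():
            empty = list(self.matrix.columns[vals.sum(axis=0) == 0])
            raise ValueError(f"all-zero pattern columns: {empty}")

    @property
    def labels(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class NormalizedProfile:
    values: pd.DataFrame  # features x cell clusters, in [0, 1]


@dataclass
class PatternAssignment:
    table: pd.DataFrame  # module -> pattern, cosine
    scores: pd.DataFrame  # module x pattern full cosine matrix


# ---------------------------------------------------------------------------
# 95th-quantile normalization
# ---------------------------------------------------------------------------

def normalize_accessibility(pseudo_bulk) -> NormalizedProfile:
    """Divide each row by its 95th quantile across cell clusters, cap at 1.

    The quantile uses linear interpolation with plotting position
    h = (n - 1) p. Rows whose 95th quantile is zero map to all-zero.
    """
    values = pseudo_bulk.values if isinstance(pseudo_bulk, FeatureMatrix) else pseudo_bulk
    x = values.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("accessibility values must be nonnegative")
    q95 = np.quantile(x, 0.95, axis=1, method="linear")
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(q95[:, None] > 0, np.minimum(x / np.where(q95 > 0, q95, 1.0)[:, None], 1.0), 0.0)
    return NormalizedProfile(
        values=pd.DataFrame(norm, index=values.index, columns=values.columns)
    )


# ---------------------------------------------------------------------------
# Library construction
# ---------------------------------------------------------------------------

def build_pattern_library(
    cell_cluster_metadata: pd.DataFrame,
    pattern_specs: dict[str, list[str]] | None = None,
    max_union_length: int | None = None,
) -> PatternLibrary:
    """Binary prototype indicator matrix over cell clusters.

    ``cell_cluster_metadata`` is indexed by cell cluster with columns
    ``timepoint`` and optionally ``cell_class`` (values like
    excitatory/inhibitory) — the timepoint order of first appearance defines
    temporal adjacency. When ``pattern_specs`` (pattern -> member cell
    clusters) is given it is used verbatim; otherwise the default library is
    generated: one pattern per timepoint, every contiguous union of >= 2
    timepoints (up to ``max_union_length``), one pattern per cell class, and
    one per individual cell cluster.
    """
    clusters = list(cell_cluster_metadata.index)
    if pattern_specs is not None:
        cols = {}
        for label, members in pattern_specs.items():
            missing = set(members) - set(clusters)
            if missing:
                raise ValueError(f"pattern {label!r} references unknown clusters {sorted(missing)}")
            if not members:
                raise ValueError(f"pattern {label!r} is empty")
            cols[label] = [1 if c in members else 0 for c in clusters]
        return PatternLibrary(matrix=pd.DataFrame(cols, index=clusters))

    timepoints = list(dict.fromkeys(cell_cluster_metadata["timepoint"]))
    cols: dict[str, list[int]] = {}

    def indicator(member_clusters):
        member_clusters = set(member_clusters)
        return [1 if c in member_clusters else 0 for c in clusters]

    for tp in timepoints:
        cols[str(tp)] = indicator(
            cell_cluster_metadata.index[cell_cluster_metadata["timepoint"] == tp]
        )
    top = len(timepoints) if max_union_length is None else max_union_length
    for length in range(2, min(top, len(timepoints)) + 1):
        for i in range(len(timepoints) - length + 1):
            window = timepoints[i : i + length]
            label = "_".join(str(t) for t in window)
            cols[label] = indicator(
                cell_cluster_metadata.index[
                    cell_cluster_metadata["timepoint"].isin(window)
                ]
            )
    if "cell_class" in cell_cluster_metadata.columns:
        for cls in dict.fromkeys(cell_cluster_metadata["cell_class"]):
            cols[str(cls)] = indicator(
                cell_cluster_metadata.index[cell_cluster_metadata["cell_class"] == cls]
            )
    for c in clusters:
        cols[f"cluster:{c}"] = indicator([c])
    return PatternLibrary(matrix=pd.DataFrame(cols, index=clusters))


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def module_profiles(profile: NormalizedProfile, assignment: pd.Series) -> pd.DataFrame:
    """Average normalized profile per module (modules x cell clusters)."""
    values = profile.values.loc[assignment.index]
    return values.groupby(assignment).mean()


def assign_patterns(profiles: pd.DataFrame, library: PatternLibrary) -> PatternAssignment:
    """Cosine similarity of module profiles against the pattern library.

    Labels are the argmax pattern; exact ties break toward the pattern with
    fewest active clusters, then lexicographically. All-zero profiles are
    labelled ``other`` with score 0.
    """
    lib = library.matrix
    if list(profiles.columns) != list(lib.index):
        profiles = profiles[list(lib.index)]
    p = profiles.to_numpy(dtype=float)
    m = lib.to_numpy(dtype=float)
    p_norm = np.linalg.norm(p, axis=1)
    m_norm = np.linalg.norm(m, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (p @ m) / np.outer(np.where(p_norm > 0, p_norm, 1.0), m_norm)
    cos = np.where(p_norm[:, None] > 0, cos, 0.0)
    scores = pd.DataFrame(cos, index=profiles.index, columns=lib.columns)

    sizes = lib.sum(axis=0)
    rows = []
    for module in scores.index:
        row = scores.loc[module]
        if p_norm[scores.index.get_loc(module)] == 0:
            rows.append((module, "other", 0.0))
            continue
        best = row.max()
        tied = [c for c in scores.columns if row[c] == best]
        tied.sort(key=lambda c: (sizes[c], c))
        rows.append((module, tied[0], float(best)))
    table = pd.DataFrame(rows, columns=["module", "pattern", "cosine"]).set_index("module")
    return PatternAssignment(table=table, scores=scores)


def categorize_patterns(
    assignment: PatternAssignment,
    early_timepoints,
    late_timepoints,
    cell_types=(),
) -> pd.Series:
    """Map assigned temporal patterns onto shared-early / shared-late /
    cell-type-specific / other categories.

    A temporal pattern label is a timepoint or an underscore-joined union of
    timepoints; it is shared-early (resp. -late) when all its timepoints fall
    in the early (resp. late) group. Labels matching a cell type or a
    ``cluster:`` pattern are cell-type-specific.
    """
    early = set(map(str, early_timepoints))
    late = set(map(str, late_timepoints))
    cell_types = set(map(str, cell_types))

    def categorize(label: str) -> str:
        if label in cell_types or label.startswith("cluster:"):
            return "cell-type-specific"
        parts = set(label.split("_"))
        if parts and parts <= early:
            return "shared-early"
        if parts and parts <= late:
            return "shared-late"
        return "other"

    return assignment.table["pattern"].map(categorize).rename("category")
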