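"""Relating samples and finding the features that separate groups.

Samples are compared as vectors of feature integration values. The distance
of choice is the cosine distance d(x, y) = 1 − x·y/(‖x‖‖y‖), which is
scale-invariant per sample (robust to differences in loading or total ion
current) and bounded in [0, 1] for non-negative data. Samples are related
by agglomerative hierarchical clustering (average linkage / UPGMA by
default), and the faithfulness of the resulting dendrogram to the distance
matrix is quantified by the cophenetic correlation coefficient — the
Pearson correlation between original pairwise distances and the merge
heights at which pairs first co-cluster.

Group differences are probed feature-by-feature with the Kruskal–Wallis
rank test (equivalent to the two-sample Wilcoxon rank-sum for two groups),
with Benjamini–Hochberg control of the false discovery rate across all
tested features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as sps
from scipy.spatial.distance import squareform

from .bucket import BucketTable, parse_key
from .errors import ValidationError

__all__ = [
    "LinkageResult",
    "FeatureRanking",
    "cosine_distance_matrix",
    "hierarchical_cluster",
    "cophenetic_coefficient",
    "select_features",
    "prominent_features",
    "linkage_to_newick",
]

_LINKAGES = ("average", "single", "complete")


@dataclass
class LinkageResult:
    """A hierarchical clustering of samples.

    ``merge_table`` is the (n−1)×4 agglomeration schedule in scipy
    convention: each row merges nodes a and b at the given distance into a
    cluster of the given size, new nodes numbered from n upward.
    """

    merge_table: np.ndarray
    leaf_labels: list[str]
    method: str
    cophenetic_coefficient: float | None = None

    @property
    def newick(self) -> str:
        return linkage_to_newick(self.merge_table, self.leaf_labels)

    def merge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merge_table,
            columns=["node_a", "node_b", "merge_distance", "cluster_size"],
        )

    def leaf_order(self) -> list[str]:
        """Leaf labels in dendrogram display order."""
        order = sch.leaves_list(self.merge_table)
        return [self.leaf_labels[i] for i in order]


@dataclass
class FeatureRanking:
    """Per-feature group-difference statistics, strongest first."""

    frame: pd.DataFrame  # feature_key, statistic, p_value, q_value, direction

    def top(self, n: int) -> pd.DataFrame:
        return self.frame.head(n)


def cosine_distance_matrix(table: BucketTable) -> pd.DataFrame:
    """Pairwise cosine distances between sample rows of a bucket table."""
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    values = table.values
    norms = np.linalg.norm(values, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        names = [table.sample_ids[i] for i in zero]
        raise ValidationError(f"all-zero sample rows: {names}")
    unit = values / norms[:, None]
    sim = unit @ unit.T
    dist = 1.0 - np.clip(sim, -1.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return pd.DataFrame(dist, index=table.sample_ids, columns=table.sample_ids)


def _as_square(dist) -> tuple[np.ndarray, list[str]]:
    if isinstance(dist, pd.DataFrame):
        labels = [str(i) for i in dist.index]
        matrix = dist.to_numpy(dtype=float)
    else:
        matrix = np.asarray(dist, dtype=float)
        labels = [str(i) for i in range(matrix.shape[0])]
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(matrix), 0.0, atol=1e-10):
        raise ValidationError("distance matrix must have a zero diagonal")
    return matrix, labels


def hierarchical_cluster(dist, method: str = "average") -> LinkageResult:
    """Agglomerative clustering of a symmetric distance matrix.

    Average linkage (UPGMA) is the default; single and complete are also
    offered. The cophenetic correlation is attached when n ≥ 3 and defined.
    """
    if method not in _LINKAGES:
        raise ValidationError(f"linkage must be one of {_LINKAGES}")
    matrix, labels = _as_square(dist)
    n = matrix.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 samples to cluster")
    condensed = squareform(matrix, checks=False)
    merge_table = sch.linkage(condensed, method=method)
    result = LinkageResult(merge_table=merge_table, leaf_labels=labels, method=method)
    if n >= 3:
        try:
            result.cophenetic_coefficient = cophenetic_coefficient(result, matrix)
        except ValidationError:
            result.cophenetic_coefficient = None
    return result


def cophenetic_coefficient(linkage: LinkageResult, dist) -> float:
    """Pearson correlation between original and tree-implied distances.

    Undefined (raises) for n = 2 or when either distance vector has zero
    variance; equals 1 exactly when the input distances are ultrametric.
    """
    if isinstance(dist, (pd.DataFrame, np.ndarray)) and np.ndim(dist) == 2:
        matrix, _ = _as_square(dist)
        condensed = squareform(matrix, checks=False)
    else:
        condensed = np.asarray(dist, dtype=float)
    n = len(linkage.leaf_labels)
    if n < 3:
        raise ValidationError("cophenetic correlation is undefined for n < 3")
    coph = sch.cophenet(linkage.merge_table)
    if np.std(condensed) == 0 or np.std(coph) == 0:
        raise ValidationError("zero variance: cophenetic correlation undefined")
    return float(np.corrcoef(condensed, coph)[0, 1])


def linkage_to_newick(merge_table: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage as a Newick tree with ultrametric branch lengths.

    Each node sits at half its merge distance from the leaves, so a child's
    branch length is (parent height − child height)/2 and leaf-to-leaf path
    lengths equal cophenetic distances.
    """
    tree = sch.to_tree(merge_table)

    def render(node, parent_height: float) -> str:
        length = (parent_height - node.dist) / 2.0
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    body = render(tree, tree.dist)
    return body.rsplit(":", 1)[0] + ";"


def select_features(
    table: BucketTable,
    groups: dict[str, str],
    alpha: float = 0.05,
    statistic: str = "kruskal",
) -> FeatureRanking:
    """Rank features by how strongly they differ between sample groups.

    Kruskal–Wallis across groups per feature by default (``statistic=
    "anova"`` switches to the one-way ANOVA F test), Benjamini–Hochberg
    q-values over all features, ranking by statistic descending.
    ``direction`` names the group with the largest mean. Features with
    identical values in all samples get statistic 0 and p = 1.

    Note that rank tests have a smallest attainable p-value set by the
    group sizes; with few samples per group even a perfectly separating
    feature may not reach a small q after multiplicity correction.
    """
    if statistic not in ("kruskal", "anova"):
        raise ValidationError("statistic must be 'kruskal' or 'anova'")
    missing = [s for s in table.sample_ids if s not in groups]
    if missing:
        raise ValidationError(f"samples without a group label: {missing}")
    labels = [groups[s] for s in table.sample_ids]
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    counts = {g: labels.count(g) for g in uniq}
    small = [g for g, c in counts.items() if c < 2]
    if small:
        raise ValidationError(f"groups with fewer than 2 samples: {small}")
    idx_by_group = {g: [i for i, l in enumerate(labels) if l == g] for g in uniq}

    values = table.values
    rows = []
    for j, key in enumerate(table.feature_keys):
        col = values[:, j]
        per_group = [col[idx_by_group[g]] for g in uniq]
        if np.ptp(col) == 0:
            stat, p = 0.0, 1.0
        elif statistic == "kruskal":
            stat, p = sps.kruskal(*per_group)
        else:
            stat, p = sps.f_oneway(*per_group)
        means = [g_vals.mean() for g_vals in per_group]
        rows.append((key, float(stat), float(p), uniq[int(np.argmax(means))]))

    frame = pd.DataFrame(rows, columns=["feature_key", "statistic", "p_value", "direction"])
    frame["q_value"] = sps.false_discovery_control(frame["p_value"].to_numpy(), method="bh")
    frame = frame[["feature_key", "statistic", "p_value", "q_value", "direction"]]
    frame = frame.sort_values(
        ["statistic", "feature_key"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return FeatureRanking(frame)


def prominent_features(
    table: BucketTable,
    n: int,
    per_group: dict[str, str] | None = None,
) -> pd.DataFrame:
    """List the most prominent features by summed integration value.

    Without ``per_group``, features are ranked by their sum over all
    samples; with it, rankings are computed within each group (the returned
    frame gains a ``group`` column). Ties break toward lower m/z. Asking
    for more features than exist returns them all.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    n = min(n, table.n_features)

    def mz_of(key: str) -> float:
        try:
            return parse_key(key)[0]
        except Exception:
            return float("inf")

    def ranked(sum_over: pd.DataFrame) -> pd.DataFrame:
        sums = sum_over.sum(axis=0)
        order = sorted(
            sum_over.columns, key=lambda k: (-sums[k], mz_of(str(k)), str(k))
        )[:n]
        return pd.DataFrame(
            {
                "feature_key": [str(k) for k in order],
                "summed_value": [float(sums[k]) for k in order],
                **{
                    str(sid): [float(table.data.loc[sid, k]) for k in order]
                    for sid in table.sample_ids
                },
            }
        )

    if per_group is None:
        return ranked(table.data)
    missing = [s for s in table.sample_ids if s not in per_group]
    if missing:
        raise ValidationError(f"samples without a group label: {missing}")
    pieces = []
    for group in sorted(set(per_group[s] for s in table.sample_ids)):
        members = [s for s in table.sample_ids if per_group[s] == group]
        piece = ranked(table.data.loc[members])
        piece.insert(0, "group", group)
        pieces.append(piece)
    return pd.concat(pieces, ignore_index=True)
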