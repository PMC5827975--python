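"""Functional-residue and subfamily detectors operating on one MSA.

Five detectors are provided, each as a scikit-learn-style estimator with a
``fit(X)`` method (``X`` is an :class:`~sdpbench.msa.Alignment`, a list of
sequence strings, or an (N, L) character matrix) and fitted attributes
``scores_`` (one score per column, NaN where the column is unscorable) and
``selected_`` (sorted column indices passing the method's threshold):

``ConservationDetector``
    fully conserved positions — columns whose non-gap residues are a single
    type, with a cap on the gap fraction;
``XdetDetector``
    mutational-behaviour correlation: Spearman rank correlation between the
    per-position residue-similarity pattern and the overall sequence-similarity
    pattern (high correlation marks candidate SDPs);
``EvolutionaryTraceDetector``
    integer trace ranks from hierarchical tree cuts: a column's score is the
    shallowest level at which it is invariant within every group;
``TeaODetector``
    two-entropies consensus: global column entropy against the tree-level
    average of within-group entropies, scored as distance to the ideal SDP
    corner of that plane;
``S3detDetector``
    correspondence analysis of the MSA indicator coding, k-means subfamily
    detection in the reduced space, and per-column SDP scores as the adjusted
    Rand agreement between the residue-induced and detected partitions.

Gap policy (shared): gaps are a 21st symbol for entropies, excluded pairwise
for similarity matrices, and columns with more than 50% gaps are unscorable by
every method (reported with a missing score, never dropped).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .msa import AMINO_ACIDS, Alignment

LOG2_21 = float(np.log2(21))
#: columns with a gap fraction above this are unscorable by every method
UNSCORABLE_GAP_FRACTION = 0.5


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class ScoreTable:
    """Per-column scores and the thresholded selection for one method."""

    method: str
    scores: np.ndarray  # float; NaN = unscorable
    selected: np.ndarray  # sorted column indices

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.selected = np.asarray(sorted(int(c) for c in self.selected), dtype=int)
        if self.selected.size and (
            self.selected.min() < 0 or self.selected.max() >= self.scores.size
        ):
            raise ValueError("selected columns outside scored range")

    @property
    def n_columns(self) -> int:
        return int(self.scores.size)


@dataclass
class SubfamilyPartition:
    """Assignment of MSA sequences to detected (or planted) subfamilies."""

    cluster_of: dict[str, int]
    n_clusters: int

    def __post_init__(self) -> None:
        if not self.cluster_of:
            raise ValueError("empty partition")
        if self.n_clusters < 1 or len(set(self.cluster_of.values())) != self.n_clusters:
            raise ValueError("n_clusters inconsistent with labels")


def subfamily_count(partition: SubfamilyPartition) -> int:
    """Number of distinct subfamily labels in a partition."""
    return len(set(partition.cluster_of.values()))


@dataclass
class TreeLevels:
    """A rooted tree plus its ordered leaf partitions from root to leaves.

    ``partitions[l-1]`` is level ``l``: the grouping of leaves obtained after
    opening the ``l-1`` internal nodes closest to the root (ties broken by the
    lexicographically smallest leaf name under the node).  Level 1 is a single
    group of all leaves and the partitions refine monotonically.  Groups are
    stored as index arrays into ``leaf_order``.
    """

    tree: TreeNode
    leaf_order: list[str]
    partitions: list[list[np.ndarray]]

    @property
    def n_levels(self) -> int:
        return len(self.partitions)


def tree_levels(tree: TreeNode, leaf_order: Sequence[str] | None = None) -> TreeLevels:
    """Derive the root-to-leaves partition sequence of a rooted tree."""
    leaves = [t.name for t in tree.tips()]
    if leaf_order is None:
        leaf_order = leaves
    if set(leaf_order) != set(leaves):
        raise ValueError("leaf_order does not match the tree's leaves")
    pos = {name: i for i, name in enumerate(leaf_order)}

    depth: dict[int, float] = {id(tree): 0.0}
    minleaf: dict[int, str] = {}
    under: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            under[id(node)] = np.array([pos[node.name]], dtype=int)
            minleaf[id(node)] = node.name
        else:
            under[id(node)] = np.sort(
                np.concatenate([under[id(c)] for c in node.children])
            )
            minleaf[id(node)] = min(minleaf[id(c)] for c in node.children)
    for node in tree.preorder(include_self=False):
        depth[id(node)] = depth[id(node.parent)] + max(float(node.length or 0.0), 0.0)

    frontier: list[TreeNode] = [tree]
    partitions = [[under[id(tree)]]]
    while True:
        internals = [n for n in frontier if not n.is_tip()]
        if not internals:
            break
        nxt = min(internals, key=lambda n: (depth[id(n)], minleaf[id(n)]))
        i = frontier.index(nxt)
        frontier[i : i + 1] = list(nxt.children)
        partitions.append([under[id(n)] for n in frontier])
    return TreeLevels(tree=tree, leaf_order=list(leaf_order), partitions=partitions)


def build_tree(X) -> TreeLevels:
    """Neighbor-joining tree from identity distances, midpoint-rooted.

    Distances are ``1 - pairwise_identity``; negative NJ branch-length
    estimates are clamped to zero before rooting.  Deterministic given the
    input order.
    """
    aln = as_alignment(X)
    if aln.n_sequences < 3:
        raise ValueError("tree building needs at least 3 sequences")
    from .snapshots import _identity_matrix  # local import: avoid module cycle

    dist = 1.0 - _identity_matrix(aln)
    np.fill_diagonal(dist, 0.0)
    tree = nj(DistanceMatrix(dist, ids=aln.ids))
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    rooted = tree.root_at_midpoint()
    return tree_levels(rooted, leaf_order=aln.ids)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def as_alignment(X) -> Alignment:
    """Coerce detector input (Alignment, strings, char matrix) to an Alignment."""
    if isinstance(X, Alignment):
        return X
    if isinstance(X, np.ndarray):
        return Alignment([f"seq{i + 1}" for i in range(X.shape[0])], X)
    seqs = list(X)
    if seqs and isinstance(seqs[0], str):
        return Alignment.from_records(
            (f"seq{i + 1}", s) for i, s in enumerate(seqs)
        )
    return Alignment.from_records(seqs)


def _counts21(sub: np.ndarray) -> np.ndarray:
    """(21, L) symbol counts of an encoded block, gap mapped to symbol 20."""
    g = np.where(sub < 0, 20, sub)
    L = sub.shape[1]
    counts = np.zeros((21, L), dtype=float)
    np.add.at(counts, (g, np.broadcast_to(np.arange(L), g.shape)), 1.0)
    return counts


def _entropy_bits(counts: np.ndarray) -> np.ndarray:
    """Column-wise Shannon entropy in bits from a (n_symbols, L) count table."""
    tot = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / tot
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -(p * logp).sum(axis=0)


def column_entropy(column) -> float:
    """Shannon entropy (bits) of one column, gaps counted as a 21st symbol."""
    if isinstance(column, str):
        symbols = list(column)
    else:
        symbols = list(column)
    if not symbols:
        raise ValueError("empty column")
    _, counts = np.unique(np.asarray(symbols, dtype="U1"), return_counts=True)
    return float(_entropy_bits(counts[:, None].astype(float))[0])


def _gap_fraction(aln: Alignment) -> np.ndarray:
    return (aln.encoded() < 0).mean(axis=0)


@lru_cache(maxsize=4)
def _substitution_array(name: str) -> np.ndarray:
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load(name)
    out = np.zeros((20, 20), dtype=float)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = m[a, b]
    return out


def sequence_similarity_matrix(
    X, substitution_matrix: str = "BLOSUM62"
) -> np.ndarray:
    """N x N matrix of overall sequence similarities.

    Entry (i, j) sums the substitution scores of the residue pairs over the
    columns where both sequences have residues (gap-versus-residue columns
    contribute nothing) and divides by the number of columns where at least
    one of the two has a residue.  Symmetric; the diagonal is the self score.
    """
    aln = as_alignment(X)
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    B = _substitution_array(substitution_matrix)
    codes = aln.encoded()
    n = aln.n_sequences
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i, n):
            xi, yj = codes[i], codes[j]
            both = (xi >= 0) & (yj >= 0)
            either = (xi >= 0) | (yj >= 0)
            denom = int(either.sum())
            val = float(B[xi[both], yj[both]].sum()) / denom if denom else np.nan
            out[i, j] = out[j, i] = val
    return out


def position_similarity_matrix(
    X, column: int, substitution_matrix: str = "BLOSUM62"
) -> np.ndarray:
    """N x N residue-similarity matrix for one column (NaN where gapped)."""
    aln = as_alignment(X)
    if not 0 <= column < aln.n_columns:
        raise ValueError(f"column {column} out of range")
    B = _substitution_array(substitution_matrix)
    col = aln.encoded()[:, column].astype(int)
    n = col.size
    out = np.full((n, n), np.nan)
    ok = col >= 0
    idx = np.flatnonzero(ok)
    if idx.size:
        out[np.ix_(idx, idx)] = B[np.ix_(col[idx], col[idx])]
    return out


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class _ColumnDetector(BaseEstimator):
    """Shared fit plumbing for the per-column detectors."""

    method: str = ""

    def fit(self, X, y=None):
        aln = as_alignment(X)
        self._fit_alignment(aln)
        self.n_columns_ = aln.n_columns
        return self

    def _fit_alignment(self, aln: Alignment) -> None:  # pragma: no cover
        raise NotImplementedError

    def score_table(self) -> ScoreTable:
        return ScoreTable(self.method, self.scores_, self.selected_)


class ConservationDetector(_ColumnDetector):
    """Fully conserved positions (zero-entropy columns).

    ``scores_`` is the per-column Shannon entropy in bits with gaps as a 21st
    symbol.  A column is selected when its non-gap residues are a single type
    and its gap fraction does not exceed ``gap_cap`` (a column of one residue
    plus many gaps is not treated as fully conserved).
    """

    method = "conservation"

    def __init__(self, gap_cap: float = 0.10):
        self.gap_cap = gap_cap

    def _fit_alignment(self, aln: Alignment) -> None:
        codes = aln.encoded()
        counts = _counts21(codes)
        scores = _entropy_bits(counts)
        gapfrac = _gap_fraction(aln)
        n_res_types = (counts[:20] > 0).sum(axis=0)
        unscorable = gapfrac > UNSCORABLE_GAP_FRACTION
        scores[unscorable] = np.nan
        sel = (n_res_types == 1) & (gapfrac <= self.gap_cap) & ~unscorable
        self.scores_ = scores
        self.selected_ = np.flatnonzero(sel)


class XdetDetector(_ColumnDetector):
    """Spearman correlation of positional vs whole-sequence similarity.

    For each column, the upper-triangle entries of the position similarity
    matrix (over sequence pairs where both have a residue at the column) are
    rank-correlated (average-rank ties) with the matching entries of the
    overall sequence-similarity matrix.  Columns with correlation at or above
    ``rho_min`` are selected; constant vectors are unscorable.
    """

    method = "xdet"

    def __init__(self, rho_min: float = 0.8, substitution_matrix: str = "BLOSUM62"):
        self.rho_min = rho_min
        self.substitution_matrix = substitution_matrix

    def _fit_alignment(self, aln: Alignment) -> None:
        if aln.n_sequences < 3:
            raise ValueError("xdet needs at least 3 sequences")
        B = _substitution_array(self.substitution_matrix)
        codes = aln.encoded()
        seq_sim = sequence_similarity_matrix(aln, self.substitution_matrix)
        iu, ju = np.triu_indices(aln.n_sequences, k=1)
        seq_vec = seq_sim[iu, ju]
        gapfrac = _gap_fraction(aln)
        scores = np.full(aln.n_columns, np.nan)
        for p in range(aln.n_columns):
            if gapfrac[p] > UNSCORABLE_GAP_FRACTION:
                continue
            ci, cj = codes[iu, p].astype(int), codes[ju, p].astype(int)
            valid = (ci >= 0) & (cj >= 0)
            if int(valid.sum()) < 3:
                continue
            pos_vec = B[ci[valid], cj[valid]]
            sv = seq_vec[valid]
            if np.ptp(pos_vec) == 0 or np.ptp(sv) == 0:
                continue
            scores[p] = spearmanr(pos_vec, sv).statistic
        self.scores_ = scores
        with np.errstate(invalid="ignore"):
            self.selected_ = np.flatnonzero(scores >= self.rho_min)


def _group_invariance(codes: np.ndarray, groups: Sequence[np.ndarray]) -> np.ndarray:
    """Per-column: single non-gap residue type within every group."""
    inv = np.ones(codes.shape[1], dtype=bool)
    for g in groups:
        sub = codes[g]
        m = sub >= 0
        has = m.any(axis=0)
        mx = np.where(m, sub, -1).max(axis=0)
        mn = np.where(m, sub, 99).min(axis=0)
        inv &= ~has | (mx == mn)
        if not inv.any():
            break
    return inv


class EvolutionaryTraceDetector(_ColumnDetector):
    """Integer trace ranks from hierarchical tree cuts.

    A column's score is the smallest level at which it is invariant (a single
    non-gap residue type) within every group of that level; score 1 is
    equivalent to full conservation, and the score-1 columns of the report are
    conserved positions rather than SDPs.  Columns never invariant get
    ``n_levels + 1``.  Columns with score at or below ``score_max`` are
    selected.  Pass ``tree_levels`` to score against a given tree (e.g. a
    known true tree); otherwise an NJ tree is built from the MSA.
    """

    method = "et"

    def __init__(self, score_max: float = 2.0, tree_levels: TreeLevels | None = None):
        self.score_max = score_max
        self.tree_levels = tree_levels

    def _fit_alignment(self, aln: Alignment) -> None:
        levels = self.tree_levels if self.tree_levels is not None else build_tree(aln)
        if set(levels.leaf_order) != set(aln.ids):
            raise ValueError("tree leaves do not match the MSA members")
        row_of = {sid: i for i, sid in enumerate(aln.ids)}
        perm = np.array([row_of[n] for n in levels.leaf_order], dtype=int)
        codes = aln.encoded()
        scores = np.full(aln.n_columns, float(levels.n_levels + 1))
        unassigned = np.ones(aln.n_columns, dtype=bool)
        for lvl, groups in enumerate(levels.partitions, start=1):
            inv = _group_invariance(codes, [perm[g] for g in groups])
            newly = inv & unassigned
            scores[newly] = lvl
            unassigned &= ~inv
            if not unassigned.any():
                break
        gapfrac = _gap_fraction(aln)
        scores[gapfrac > UNSCORABLE_GAP_FRACTION] = np.nan
        self.tree_levels_ = levels
        self.scores_ = scores
        with np.errstate(invalid="ignore"):
            self.selected_ = np.flatnonzero(scores <= self.score_max)


def teao_score_from_entropies(h_global: float, h_within_mean: float) -> float:
    """Distance to the ideal SDP corner (1, 0) of the two-entropies plane,
    scaled by 1/sqrt(2) into [0, 1]."""
    return float(
        np.sqrt((1.0 - h_global) ** 2 + h_within_mean**2) / np.sqrt(2.0)
    )


class TeaODetector(_ColumnDetector):
    """Two-entropies consensus score across tree levels.

    For every column the global normalized entropy (entropy over all sequences
    divided by log2 21) is paired with the average, over levels 2..L of the
    tree, of the mean normalized within-group entropy.  An ideal SDP has high
    global entropy but zero within-group entropy at every granularity, so the
    score is the scaled distance to that corner; columns scoring at or below
    ``score_max`` are selected.
    """

    method = "teao"

    def __init__(self, score_max: float = 0.3, tree_levels: TreeLevels | None = None):
        self.score_max = score_max
        self.tree_levels = tree_levels

    def _fit_alignment(self, aln: Alignment) -> None:
        levels = self.tree_levels if self.tree_levels is not None else build_tree(aln)
        if set(levels.leaf_order) != set(aln.ids):
            raise ValueError("tree leaves do not match the MSA members")
        row_of = {sid: i for i, sid in enumerate(aln.ids)}
        perm = np.array([row_of[n] for n in levels.leaf_order], dtype=int)
        codes = aln.encoded()
        h_global = _entropy_bits(_counts21(codes)) / LOG2_21

        per_level = []
        for groups in levels.partitions[1:]:
            group_h = [
                _entropy_bits(_counts21(codes[perm[g]])) / LOG2_21 for g in groups
            ]
            per_level.append(np.mean(group_h, axis=0))
        h_within = (
            np.mean(per_level, axis=0) if per_level else np.zeros(aln.n_columns)
        )
        scores = np.sqrt((1.0 - h_global) ** 2 + h_within**2) / np.sqrt(2.0)
        gapfrac = _gap_fraction(aln)
        scores[gapfrac > UNSCORABLE_GAP_FRACTION] = np.nan
        self.h_global_ = h_global
        self.h_within_ = h_within
        self.tree_levels_ = levels
        self.scores_ = scores
        with np.errstate(invalid="ignore"):
            self.selected_ = np.flatnonzero(scores <= self.score_max)


def correspondence_analysis(indicator: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row coordinates and singular values of a correspondence analysis.

    The SVD is taken of the standardized residual matrix
    ``(P - r c^T) / sqrt(r c^T)`` of the relative-frequency table ``P``;
    principal row coordinates are ``D_r^{-1/2} U S``.
    """
    X = np.asarray(indicator, dtype=float)
    total = X.sum()
    if total <= 0:
        raise ValueError("indicator table has no mass")
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r == 0).any():
        raise ValueError("indicator table has an empty row")
    keep = c > 0
    P, c = P[:, keep], c[keep]
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, _ = np.linalg.svd(S, full_matrices=False)
    coords = (U * sv) / np.sqrt(r)[:, None]
    return coords, sv


def _scree_gap_axes(sv: np.ndarray, cap: int) -> int:
    """Number of leading CA axes before the largest drop in the scree plot.

    A family with k well-separated sequence clusters shows k-1 dominant
    singular values followed by a sharp drop to the axes describing finer
    (sub-cluster and noise) structure; the largest consecutive gap in the
    sorted spectrum therefore marks the dominant separation level.
    """
    m = int(min(cap, sv.size - 1))
    if m < 1:
        return 1
    drops = sv[:m] - sv[1 : m + 1]
    return int(np.argmax(drops)) + 1


class S3detDetector(_ColumnDetector):
    """Subfamily detection in a reduced sequence space plus SDP scoring.

    The MSA is coded as a sequence x (column, residue) binary indicator table
    and embedded by correspondence analysis; the leading axes before the
    largest drop in the singular-value scree are retained (the dominant
    cluster-separation level of the sequence space).  Sequence coordinates
    are clustered with k-means over candidate cluster counts 2..min(10, N-1),
    keeping the count with the best mean silhouette (a single cluster when the
    best silhouette is below ``silhouette_min``, ties toward fewer clusters).
    The SDP score of a column is the adjusted Rand index between the detected
    partition and the partition induced by residue identity at that column
    (gapped sequences excluded); columns scoring at or above ``ari_min`` are
    selected.  Columns with a single residue class or more than 50% gaps are
    unscorable.
    """

    method = "s3det"

    def __init__(
        self,
        ari_min: float = 0.8,
        max_clusters: int = 10,
        silhouette_min: float = 0.25,
        n_init: int = 10,
        random_state: int = 0,
    ):
        self.ari_min = ari_min
        self.max_clusters = max_clusters
        self.silhouette_min = silhouette_min
        self.n_init = n_init
        self.random_state = random_state

    def _fit_alignment(self, aln: Alignment) -> None:
        codes = aln.encoded()
        n, L = codes.shape
        indicator = np.zeros((n, L * 20), dtype=float)
        rows = np.repeat(np.arange(n), L)
        cols = codes.ravel().astype(int)
        flat = np.arange(L)[None, :].repeat(n, axis=0).ravel() * 20 + cols
        ok = cols >= 0
        indicator[rows[ok], flat[ok]] = 1.0
        coords, sv = correspondence_analysis(indicator)
        k_axes = _scree_gap_axes(sv, cap=min(self.max_clusters, max(n - 2, 1)))
        emb = coords[:, :k_axes]

        labels = np.zeros(n, dtype=int)
        best_sil = -np.inf
        if n - 1 >= 2 and np.ptp(emb, axis=0).max() > 1e-12:
            for k in range(2, min(self.max_clusters, n - 1) + 1):
                km = KMeans(
                    n_clusters=k,
                    n_init=self.n_init,
                    random_state=self.random_state,
                ).fit(emb)
                if len(set(km.labels_)) < 2:
                    continue
                sil = silhouette_score(emb, km.labels_)
                if sil > best_sil + 1e-12:  # ties toward fewer clusters
                    best_sil, labels = sil, km.labels_.copy()
            if best_sil < self.silhouette_min:
                labels = np.zeros(n, dtype=int)

        gapfrac = _gap_fraction(aln)
        scores = np.full(L, np.nan)
        for p in range(L):
            if gapfrac[p] > UNSCORABLE_GAP_FRACTION:
                continue
            col = codes[:, p]
            mask = col >= 0
            if len(set(col[mask].tolist())) < 2:
                continue
            scores[p] = adjusted_rand_score(labels[mask], col[mask])

        self.embedding_ = emb
        self.singular_values_ = sv
        self.labels_ = labels
        self.n_clusters_ = len(set(labels.tolist()))
        self.silhouette_ = best_sil if np.isfinite(best_sil) else float("nan")
        self.scores_ = scores
        with np.errstate(invalid="ignore"):
            self.selected_ = np.flatnonzero(scores >= self.ari_min)

    def partition(self, aln: Alignment | None = None) -> SubfamilyPartition:
        ids = self.ids_
        return SubfamilyPartition(
            cluster_of={sid: int(l) for sid, l in zip(ids, self.labels_)},
            n_clusters=self.n_clusters_,
        )

    def fit(self, X, y=None):
        aln = as_alignment(X)
        self.ids_ = list(aln.ids)
        self._fit_alignment(aln)
        self.n_columns_ = aln.n_columns
        return self


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def conserved_positions(X, gap_cap: float = 0.10) -> ScoreTable:
    return ConservationDetector(gap_cap=gap_cap).fit(X).score_table()


def xdet_scores(
    X, substitution_matrix: str = "BLOSUM62", rho_min: float = 0.8
) -> ScoreTable:
    return (
        XdetDetector(rho_min=rho_min, substitution_matrix=substitution_matrix)
        .fit(X)
        .score_table()
    )


def et_scores(X, tree_levels: TreeLevels, score_max: float = 2.0) -> ScoreTable:
    return (
        EvolutionaryTraceDetector(score_max=score_max, tree_levels=tree_levels)
        .fit(X)
        .score_table()
    )


def teao_scores(X, tree_levels: TreeLevels, score_max: float = 0.3) -> ScoreTable:
    return (
        TeaODetector(score_max=score_max, tree_levels=tree_levels)
        .fit(X)
        .score_table()
    )


def s3det_like(
    X,
    ari_min: float = 0.8,
    random_state: int = 0,
    max_clusters: int = 10,
    silhouette_min: float = 0.25,
) -> tuple[SubfamilyPartition, ScoreTable]:
    det = S3detDetector(
        ari_min=ari_min,
        random_state=random_state,
        max_clusters=max_clusters,
        silhouette_min=silhouette_min,
    ).fit(X)
    return det.partition(), det.score_table()
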