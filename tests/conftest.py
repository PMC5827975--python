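"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import sdpbench as sb

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_family() -> sb.BenchmarkFamily:
    """One benchmark family under the default study conditions."""
    return sb.make_benchmark_family("fam_default", seed=1)


@pytest.fixture(scope="session")
def default_alignment(default_family) -> sb.Alignment:
    return sb.Alignment.from_timed(default_family.sequences)


@pytest.fixture(scope="session")
def two_clade_family() -> sb.BenchmarkFamily:
    """Strong-signal family with two subfamilies of 16 sequences."""
    return sb.make_benchmark_family(
        "fam_two", seed=3, n_subfamilies=2, seqs_per_subfamily=16
    )


def random_alignment(rng: np.random.Generator, n: int, length: int,
                     gap_p: float = 0.1) -> sb.Alignment:
    """An i.i.d. random alignment (no phylogenetic structure)."""
    letters = np.array(list(sb.AMINO_ACIDS + sb.GAP))
    probs = np.full(21, (1 - gap_p) / 20)
    probs[-1] = gap_p
    chars = rng.choice(letters, size=(n, length), p=probs)
    return sb.Alignment([f"s{i+1}" for i in range(n)], chars)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def average_ranks(v: np.ndarray) -> np.ndarray:
    """Average-rank transform with ties, written from scratch."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="mergesort")
    sv = v[order]
    ranks_sorted = np.empty(len(v), dtype=float)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks_sorted[i : j + 1] = (i + j) / 2.0 + 1.0
        i = j + 1
    out = np.empty(len(v), dtype=float)
    out[order] = ranks_sorted
    return out


def spearman_oracle(x, y) -> float:
    """Brute-force Spearman with average-rank ties: Pearson on the ranks."""
    rx, ry = average_ranks(np.asarray(x)), average_ranks(np.asarray(y))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    return float((rx @ ry) / denom) if denom > 0 else float("nan")


def et_partitions_oracle(levels) -> list[list[set[str]]]:
    """Rebuild the level partitions by direct cut enumeration.

    Opens internal nodes in (depth-from-root, smallest-leaf-name) order; the
    groups after opening the first l-1 nodes are the leaf sets under unopened
    nodes whose parent is opened (the root counts as opened at level >= 2).
    Independent of the package's frontier construction.
    """
    tree = levels.tree
    depth, minleaf, leafset = {}, {}, {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            leafset[id(node)] = {node.name}
            minleaf[id(node)] = node.name
        else:
            leafset[id(node)] = set().union(*(leafset[id(c)] for c in node.children))
            minleaf[id(node)] = min(minleaf[id(c)] for c in node.children)
    depth[id(tree)] = 0.0
    for node in tree.preorder(include_self=False):
        depth[id(node)] = depth[id(node.parent)] + max(float(node.length or 0.0), 0.0)

    internals = [n for n in tree.traverse(include_self=True) if not n.is_tip()]
    internals.sort(key=lambda n: (depth[id(n)], minleaf[id(n)]))

    out = [[leafset[id(tree)]]]
    opened: set[int] = set()
    for nxt in internals:
        # only nodes whose parent is already opened can be opened next
        assert nxt is tree or id(nxt.parent) in opened
        opened.add(id(nxt))
        groups = []
        for node in tree.traverse(include_self=False):
            if id(node) not in opened and id(node.parent) in opened:
                groups.append(leafset[id(node)])
        out.append(groups)
    return out


def et_scores_oracle(aln: sb.Alignment, levels) -> np.ndarray:
    """Naive ET ranks: test invariance within every group at every level."""
    parts = et_partitions_oracle(levels)
    row = {sid: i for i, sid in enumerate(aln.ids)}
    scores = np.empty(aln.n_columns)
    for p in range(aln.n_columns):
        col = aln.column(p)
        score = len(parts) + 1
        for lvl, groups in enumerate(parts, start=1):
            ok = True
            for g in groups:
                residues = {col[row[name]] for name in g} - {sb.GAP}
                if len(residues) > 1:
                    ok = False
                    break
            if ok:
                score = lvl
                break
        scores[p] = score
    return scores


def teao_scores_oracle(aln: sb.Alignment, levels) -> np.ndarray:
    """Naive reimplementation of the two-entropies consensus score."""
    import collections
    import math

    row = {sid: i for i, sid in enumerate(aln.ids)}

    def entropy(symbols) -> float:
        counts = collections.Counter(symbols)
        n = sum(counts.values())
        return -sum((c / n) * math.log2(c / n) for c in counts.values())

    norm = math.log2(21)
    scores = np.empty(aln.n_columns)
    for p in range(aln.n_columns):
        col = aln.column(p)
        hg = entropy(col) / norm
        level_means = []
        for groups in levels.partitions[1:]:
            hs = [
                entropy([col[row[levels.leaf_order[k]]] for k in g]) / norm
                for g in groups
            ]
            level_means.append(sum(hs) / len(hs))
        hw = sum(level_means) / len(level_means) if level_means else 0.0
        scores[p] = math.sqrt((1 - hg) ** 2 + hw**2) / math.sqrt(2)
    return scores


def quartiles_oracle(values) -> tuple[float, float, float]:
    """Sort-and-linearly-interpolate quartiles, written from scratch."""
    v = sorted(values)
    n = len(v)

    def q(f: float) -> float:
        h = (n - 1) * f
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    return q(0.25), q(0.5), q(0.75)
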