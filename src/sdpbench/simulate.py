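"""Synthetic protein families with planted subfamily structure and ground truth.

The generator produces everything the downstream benchmark consumes, with known
truth at every layer:

* a rooted tree whose root carries one monophyletic clade per subfamily;
* an aligned family evolved on that tree with three planted column classes —
  fully conserved, subfamily-specific (SDP) and neutral;
* publication years following a geometric accumulation model over a
  1994–2014-style timeline, optionally with discovery order following the
  subfamily structure (early database content concentrated in a subset of
  clades, later years adding new clades);
* a synthetic structure in which binding-site residues form a compact pocket,
  designated "near" columns sit just outside it, and all remaining residues lie
  on a self-avoiding random walk far from the pocket.

Sequences are generated pre-aligned; there is no indel process.  Gaps can be
injected at a configurable per-column rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .msa import AMINO_ACIDS, GAP, TimedSequence
from .evaluation import StructureModel

#: SDP planting mode: each subfamily fixed to its own residue (all distinct).
MODE_ONE_RESIDUE_PER_SUBFAMILY = "one-residue-per-subfamily"
#: SDP planting mode: one designated subfamily conserved, the rest evolve freely.
MODE_CONSERVED_IN_ONE = "conserved-in-one-subfamily"

CONSERVED, SDP, NEUTRAL = "conserved", "sdp", "neutral"


class SimulationParameterError(ValueError):
    """Raised for invalid generator parameters."""


@dataclass(frozen=True)
class SiteClassProfile:
    """Planted site classes for one family.

    ``conserved_cols``, ``sdp_cols`` (with a per-column planting mode) and
    ``neutral_cols`` must partition ``range(n_columns)``.  ``substitution_rate``
    is the expected number of substitution events per site per unit branch
    length for neutral columns.
    """

    n_columns: int
    conserved_cols: frozenset[int]
    sdp_cols: Mapping[int, str]
    neutral_cols: frozenset[int]
    substitution_rate: float

    def __post_init__(self) -> None:
        if self.n_columns <= 0:
            raise SimulationParameterError("n_columns must be positive")
        if self.substitution_rate < 0:
            raise SimulationParameterError("substitution_rate must be >= 0")
        cons, sdp, neut = (
            set(self.conserved_cols),
            set(self.sdp_cols),
            set(self.neutral_cols),
        )
        if len(cons) + len(sdp) + len(neut) > self.n_columns:
            raise SimulationParameterError("more planted classes than columns")
        allcols = cons | sdp | neut
        if (cons & sdp) or (cons & neut) or (sdp & neut):
            raise SimulationParameterError("site-class column sets overlap")
        if allcols != set(range(self.n_columns)):
            raise SimulationParameterError(
                "site classes must partition 0..n_columns-1"
            )
        for col, mode in self.sdp_cols.items():
            if mode not in (MODE_ONE_RESIDUE_PER_SUBFAMILY, MODE_CONSERVED_IN_ONE):
                raise SimulationParameterError(f"unknown SDP mode {mode!r} at {col}")

    @classmethod
    def random(
        cls,
        n_columns: int,
        n_conserved: int,
        n_sdp: int,
        substitution_rate: float,
        rng: np.random.Generator,
        sdp_mode: str = MODE_ONE_RESIDUE_PER_SUBFAMILY,
    ) -> "SiteClassProfile":
        """Place the planted classes at random column positions."""
        if n_conserved + n_sdp > n_columns:
            raise SimulationParameterError("more planted classes than columns")
        perm = rng.permutation(n_columns)
        cons = frozenset(int(c) for c in perm[:n_conserved])
        sdp = {int(c): sdp_mode for c in perm[n_conserved : n_conserved + n_sdp]}
        neut = frozenset(int(c) for c in perm[n_conserved + n_sdp :])
        return cls(n_columns, cons, sdp, neut, substitution_rate)


@dataclass
class GroundTruth:
    """Truth layer for parameter-recovery tests."""

    subfamily_of: dict[str, str]
    site_class_of: dict[int, str]
    binding_cols: frozenset[int] = field(default_factory=frozenset)

    @property
    def conserved_cols(self) -> set[int]:
        return {c for c, k in self.site_class_of.items() if k == CONSERVED}

    @property
    def sdp_cols(self) -> set[int]:
        return {c for c, k in self.site_class_of.items() if k == SDP}

    @property
    def neutral_cols(self) -> set[int]:
        return {c for c, k in self.site_class_of.items() if k == NEUTRAL}


@dataclass(frozen=True)
class AccumulationModel:
    """Geometric growth of database content between two calendar years.

    The expected cumulative number of sequences available at year ``y`` is
    proportional to ``growth_rate**(y - start_year)`` (normalised so the count
    at ``end_year`` equals ``n_final``), emulating the exponential accumulation
    of database sequences.
    """

    start_year: int
    end_year: int
    growth_rate: float
    n_final: int

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise SimulationParameterError("end_year must exceed start_year")
        if self.growth_rate <= 1.0:
            raise SimulationParameterError("growth_rate must be > 1")
        if self.n_final <= 0:
            raise SimulationParameterError("n_final must be positive")

    def year_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """Years ``start..end`` and the probability a sequence is dated each."""
        years = np.arange(self.start_year, self.end_year + 1)
        w = self.growth_rate ** (years - self.start_year).astype(float)
        return years, w / w.sum()

    def expected_cumulative(self, year: int) -> float:
        years, pmf = self.year_pmf()
        return float(self.n_final * pmf[years <= year].sum())


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(
    n_subfamilies: int,
    seqs_per_subfamily: int,
    within_depth: float,
    between_depth: float,
    seed: int,
) -> TreeNode:
    """Rooted tree with one monophyletic clade per subfamily.

    The root has ``n_subfamilies`` children, each a random bifurcating clade of
    ``seqs_per_subfamily`` leaves.  Clade stems have length ``between_depth``;
    every within-clade edge is ``within_depth`` scaled by a uniform jitter in
    [0.5, 1.5].  Leaves are named ``sf<k>_s<i>`` so the subfamily assignment is
    recoverable from the name.  Deterministic given the seed.
    """
    if n_subfamilies < 2 or seqs_per_subfamily < 2:
        raise SimulationParameterError("counts must be >= 2")
    if within_depth <= 0 or between_depth <= 0:
        raise SimulationParameterError("depths must be > 0")
    rng = np.random.default_rng(seed)

    def edge() -> float:
        return float(within_depth * rng.uniform(0.5, 1.5))

    clades = []
    for k in range(n_subfamilies):
        nodes = [
            TreeNode(name=f"sf{k + 1}_s{i + 1}", length=edge())
            for i in range(seqs_per_subfamily)
        ]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            b = nodes.pop(j)
            a = nodes.pop(i)
            nodes.append(TreeNode(children=[a, b], length=edge()))
        clade = nodes[0]
        clade.length = float(between_depth)
        clades.append(clade)
    return TreeNode(children=clades, length=0.0)


def subfamily_from_leaf_name(name: str) -> str:
    """Subfamily label encoded in a simulated leaf name (``sf3_s2`` -> ``sf3``)."""
    return name.rsplit("_s", 1)[0]


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def evolve_family(
    tree: TreeNode,
    profile: SiteClassProfile,
    seed: int,
    subfamily_of: Mapping[str, str] | None = None,
    gap_fraction: float = 0.0,
) -> tuple[list[TimedSequence], GroundTruth]:
    """Evolve an aligned family on ``tree`` with the planted site classes.

    Conserved columns carry a single residue everywhere.  SDP columns in
    one-residue-per-subfamily mode fix one distinct residue per subfamily;
    conserved-in-one mode fixes a residue in one designated subfamily and lets
    the column evolve neutrally elsewhere.  Neutral columns evolve by uniform
    replacement at exponential waiting times scaled by branch length (the
    number of events per edge is Poisson with mean rate x length; after at
    least one event the state is uniform over the 20 letters).

    Returns undated :class:`TimedSequence` objects in leaf order plus the
    :class:`GroundTruth`.
    """
    rng = np.random.default_rng(seed)
    leaves = list(tree.tips())
    names = [lf.name for lf in leaves]
    if len(set(names)) != len(names) or any(n is None for n in names):
        raise SimulationParameterError("tree leaves must carry unique labels")
    if subfamily_of is None:
        subfamily_of = {n: subfamily_from_leaf_name(n) for n in names}
    labels = sorted(set(subfamily_of[n] for n in names))
    n_leaves, L = len(names), profile.n_columns

    one_per = sorted(
        c for c, m in profile.sdp_cols.items() if m == MODE_ONE_RESIDUE_PER_SUBFAMILY
    )
    cons_one = sorted(
        c for c, m in profile.sdp_cols.items() if m == MODE_CONSERVED_IN_ONE
    )
    if one_per and len(labels) > 20:
        raise SimulationParameterError(
            "one-residue-per-subfamily planting needs <= 20 subfamilies"
        )

    codes = np.empty((n_leaves, L), dtype=np.int8)
    leaf_index = {n: i for i, n in enumerate(names)}

    # fully conserved columns: one residue type family-wide
    cons_cols = sorted(profile.conserved_cols)
    for c in cons_cols:
        codes[:, c] = rng.integers(0, 20)

    # one-residue-per-subfamily SDPs: distinct residue for every subfamily
    for c in one_per:
        res = rng.choice(20, size=len(labels), replace=False)
        per_label = dict(zip(labels, res))
        for n in names:
            codes[leaf_index[n], c] = per_label[subfamily_of[n]]

    # dynamic columns: neutral ones plus the free part of conserved-in-one SDPs
    dyn = sorted(profile.neutral_cols) + cons_one
    if dyn:
        rate = profile.substitution_rate
        state: dict[int, np.ndarray] = {}
        root_state = rng.integers(0, 20, size=len(dyn)).astype(np.int8)
        state[id(tree)] = root_state
        for node in tree.preorder(include_self=False):
            parent_state = state[id(node.parent)]
            child = parent_state.copy()
            t = float(node.length or 0.0)
            if t > 0 and rate > 0:
                hit = rng.poisson(rate * t, size=len(dyn)) > 0
                if hit.any():
                    child[hit] = rng.integers(0, 20, size=int(hit.sum()))
            state[id(node)] = child
            if node.is_tip():
                codes[leaf_index[node.name], dyn] = child

    # conserved-in-one SDPs: overwrite the designated subfamily with its residue
    for c in cons_one:
        designated = labels[int(rng.integers(0, len(labels)))]
        res = int(rng.integers(0, 20))
        for n in names:
            if subfamily_of[n] == designated:
                codes[leaf_index[n], c] = res

    chars = np.array(list(AMINO_ACIDS), dtype="U1")[codes]
    if gap_fraction > 0:
        gaps = rng.random(chars.shape) < gap_fraction
        chars[gaps] = GAP

    seqs = [
        TimedSequence(seq_id=n, residues="".join(chars[leaf_index[n]]))
        for n in names
    ]
    site_class = {c: CONSERVED for c in cons_cols}
    site_class.update({c: SDP for c in profile.sdp_cols})
    site_class.update({c: NEUTRAL for c in profile.neutral_cols})
    truth = GroundTruth(
        subfamily_of={n: subfamily_of[n] for n in names},
        site_class_of=site_class,
    )
    return seqs, truth


# ---------------------------------------------------------------------------
# publication dates
# ---------------------------------------------------------------------------

def assign_dates(
    seqs: Sequence[TimedSequence],
    model: AccumulationModel,
    seed: int,
    discovery_order: Sequence[str] | None = None,
) -> list[TimedSequence]:
    """Attach publication years drawn from the accumulation model.

    Years are sampled i.i.d. from the geometric year distribution, so the
    cumulative count curve is geometric in expectation and always reaches
    ``n_final`` at ``end_year``.  If ``n_final`` is smaller than the family,
    a seeded random subset of that size is dated and returned.

    ``discovery_order`` (one sortable key per sequence, e.g. the subfamily
    label) optionally correlates the id-to-date pairing with family structure:
    the sampled years are sorted and the earliest ones assigned to the first
    groups, emulating databases whose early content is concentrated in a few
    clades.  The marginal distribution of years is unchanged by this pairing.
    """
    if not seqs:
        raise SimulationParameterError("no sequences to date")
    if model.n_final > len(seqs):
        raise SimulationParameterError("n_final exceeds number of sequences")
    if discovery_order is not None and len(discovery_order) != len(seqs):
        raise SimulationParameterError("discovery_order length mismatch")
    rng = np.random.default_rng(seed)

    idx = np.arange(len(seqs))
    if model.n_final < len(seqs):
        idx = np.sort(rng.choice(len(seqs), size=model.n_final, replace=False))
    years_grid, pmf = model.year_pmf()
    sampled = rng.choice(years_grid, size=len(idx), p=pmf)

    if discovery_order is None:
        years_for = dict(zip(idx.tolist(), sampled.tolist()))
    else:
        keys = [discovery_order[i] for i in idx]
        tiebreak = rng.permutation(len(idx))
        order = sorted(range(len(idx)), key=lambda j: (keys[j], tiebreak[j]))
        sorted_years = np.sort(sampled)
        years_for = {
            int(idx[j]): int(sorted_years[r]) for r, j in enumerate(order)
        }

    return [
        TimedSequence(seqs[i].seq_id, seqs[i].residues, int(years_for[i]))
        for i in idx.tolist()
    ]


# ---------------------------------------------------------------------------
# synthetic structure
# ---------------------------------------------------------------------------

def synth_structure(
    n_columns: int,
    binding_cols: Sequence[int],
    near_cols: Sequence[int],
    seed: int,
    pocket_radius: float = 5.0,
    step: float = 3.8,
    clearance: float = 2.0,
) -> StructureModel:
    """One representative 3-D point per column, with a planted binding pocket.

    Binding columns are placed inside a ball of radius ``pocket_radius / 2``
    around the origin (so every pair is within the pocket radius); near columns
    lie between 1 and 1.5 pocket radii of the pocket centroid; every other
    column is placed on a self-avoiding random walk constrained to stay at
    least three pocket radii away from the pocket, so far columns are always
    farther than near columns.
    """
    binding = sorted(set(int(c) for c in binding_cols))
    near = sorted(set(int(c) for c in near_cols))
    if set(binding) & set(near):
        raise SimulationParameterError("binding_cols and near_cols overlap")
    for c in binding + near:
        if not 0 <= c < n_columns:
            raise SimulationParameterError(f"column {c} outside 0..{n_columns - 1}")
    rng = np.random.default_rng(seed)
    r_p = float(pocket_radius)

    def direction() -> np.ndarray:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    coords = np.zeros((n_columns, 3), dtype=float)
    for c in binding:
        coords[c] = direction() * (r_p / 2.0) * rng.random() ** (1.0 / 3.0)
    for c in near:
        coords[c] = direction() * rng.uniform(r_p, 1.5 * r_p)

    placed = [coords[c] for c in binding + near]
    far_cols = [c for c in range(n_columns) if c not in set(binding) | set(near)]
    pos = direction() * 6.0 * r_p
    for c in far_cols:
        trial_step = step
        for _ in range(200):
            cand = pos + direction() * trial_step
            if np.linalg.norm(cand) < 3.0 * r_p:
                continue
            if placed and min(
                float(np.linalg.norm(cand - p)) for p in placed[-50:]
            ) < clearance:
                trial_step *= 1.2
                continue
            pos = cand
            break
        coords[c] = pos
        placed.append(pos.copy())

    binding_flags = np.zeros(n_columns, dtype=bool)
    binding_flags[binding] = True
    return StructureModel(
        coords=coords,
        binding_flags=binding_flags,
        column_map={c: c for c in range(n_columns)},
    )


# ---------------------------------------------------------------------------
# complete benchmark families
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkFamily:
    """Everything the benchmark needs for one synthetic family."""

    family_id: str
    sequences: list[TimedSequence]
    structure: StructureModel
    truth: GroundTruth
    tree: TreeNode


#: default study conditions for the synthetic benchmark families
DEFAULTS = dict(
    n_subfamilies=4,
    seqs_per_subfamily=8,
    n_columns=200,
    n_conserved=10,
    n_sdp=10,
    sdp_mode=MODE_ONE_RESIDUE_PER_SUBFAMILY,
    within_depth=0.3,
    between_depth=3.0,
    substitution_rate=0.45,
    gap_fraction=0.0,
    start_year=1994,
    end_year=2014,
    growth_rate=1.2,
    pocket_radius=5.0,
    n_binding=5,
    staggered_discovery=True,
)


def make_benchmark_family(
    family_id: str = "fam", seed: int = 0, **overrides
) -> BenchmarkFamily:
    """Generate one complete family under the default study conditions.

    Binding-site columns are a subset of the planted conserved columns (the
    pocket is the family's invariant core) and the planted SDP columns sit just
    outside the pocket, so closeness-to-binding-site evaluation has signal to
    find.  All randomness derives from ``seed``.
    """
    p = dict(DEFAULTS)
    unknown = set(overrides) - set(p)
    if unknown:
        raise SimulationParameterError(f"unknown parameters: {sorted(unknown)}")
    p.update(overrides)
    if p["n_binding"] > p["n_conserved"]:
        raise SimulationParameterError("n_binding cannot exceed n_conserved")

    master = np.random.default_rng(seed)
    sub = [int(s) for s in master.integers(0, 2**31 - 1, size=5)]

    profile = SiteClassProfile.random(
        p["n_columns"],
        p["n_conserved"],
        p["n_sdp"],
        p["substitution_rate"],
        np.random.default_rng(sub[0]),
        sdp_mode=p["sdp_mode"],
    )
    tree = simulate_tree(
        p["n_subfamilies"],
        p["seqs_per_subfamily"],
        p["within_depth"],
        p["between_depth"],
        seed=sub[1],
    )
    seqs, truth = evolve_family(
        tree, profile, seed=sub[2], gap_fraction=p["gap_fraction"]
    )
    model = AccumulationModel(
        p["start_year"], p["end_year"], p["growth_rate"], n_final=len(seqs)
    )
    order = (
        [truth.subfamily_of[s.seq_id] for s in seqs]
        if p["staggered_discovery"]
        else None
    )
    dated = assign_dates(seqs, model, seed=sub[3], discovery_order=order)

    rng_struct = np.random.default_rng(sub[4])
    conserved_sorted = sorted(profile.conserved_cols)
    binding = rng_struct.choice(
        conserved_sorted, size=p["n_binding"], replace=False
    )
    structure = synth_structure(
        p["n_columns"],
        binding_cols=[int(b) for b in binding],
        near_cols=sorted(profile.sdp_cols),
        seed=sub[4],
        pocket_radius=p["pocket_radius"],
    )
    truth.binding_cols = frozenset(int(b) for b in binding)
    return BenchmarkFamily(family_id, dated, structure, truth, tree)
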