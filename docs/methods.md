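# Methods

This note records the models, conventions and numerical choices behind
`sdpbench`, and what the synthetic benchmark does and does not show.

## Historical snapshots

A family is a set of aligned sequences, each carrying an integer publication
year.  The snapshot at cutoff year *y* contains exactly the members dated at
or before *y*; snapshots are therefore nested across years.  Each snapshot is
made non-redundant with a greedy keep-first sweep in input order: a sequence
is kept iff its identity to every previously kept sequence is at most the
threshold (default 0.95).  Input order is publication date with sequence-id
tiebreaks, so the sweeps of different years are mutually consistent.  Greedy
keep-first is deterministic and idempotent; an alternative (unimplemented)
convention would re-rank candidates per year, which can keep different
representatives when retrieval order varies.

Pairwise identity over a gapped alignment is not standard; we fix: the
denominator is the number of columns where at least one of the two sequences
has a residue, matches require equal residues (gap–residue pairs are
mismatches), and double-gap columns are excluded.  A pair with no countable
column has identity 0.

A snapshot is *workable* when it retains at least `min_sequences` members
(default 15; 10 is the standard alternative).  Coverage counts (workable
families per year) are exactly monotone on the raw date snapshots because the
snapshots are nested; after greedy redundancy removal monotonicity holds only
in expectation, since a greedy sweep over a superset is not guaranteed to keep
a superset of survivors.

## Detectors

All five detectors share one gap policy: gaps are a 21st symbol for entropy
calculations, gapped pairs are excluded from similarity matrices, and a
column with more than 50% gaps is unscorable by every method.  Unscorable
columns are reported with missing scores, never dropped from the table.

**Conservation.**  Score = Shannon entropy (bits, 21 symbols).  Selected:
columns whose non-gap residues are a single type *and* whose gap fraction is
at most `conservation_gap_cap` (default 10%) — a column of one residue plus
many gaps is not treated as fully conserved.

**Xdet-style similarity correlation.**  The pattern of changes at one column
is the matrix of BLOSUM62 scores of the residue pairs; the family pattern is
the matrix of overall sequence similarities (sum of BLOSUM62 scores over
columns where both sequences have residues, divided by the number of columns
where at least one does; gap-versus-residue columns therefore count in the
denominator and contribute nothing to the numerator).  The column score is
Spearman's ρ — average ranks for ties — between the two matrices'
corresponding upper-triangle entries, restricted to pairs where the column
has residues on both sides; ρ ≥ 0.8 selects.  Constant vectors (e.g. a fully
conserved column) are unscorable.

**Tree construction.**  Tree-based detectors use a neighbor-joining tree on
distances 1 − identity, midpoint-rooted, with negative NJ length estimates
clamped to zero.  This replaces a guide-tree convention that cannot be
reproduced bit-for-bit; the synthetic tests only require that well-separated
clades are recovered, which NJ guarantees at these depths.  *Levels* are the
partitions obtained by opening internal nodes one at a time in order of
distance from the root (ties broken by smallest leaf name): level 1 is one
group of all leaves, and each opening replaces a node by its children.  A
multifurcating node adds all its children at once, so the level list of the
generator's true trees reaches the k-clade partition at level 2.

**Evolutionary-trace ranks.**  The score of a column is the smallest level at
which it is invariant (one non-gap residue type) within every group; rank 1
is exactly full conservation, and the method's SDP report is its selection
minus the rank-1 columns.  Ranks are integers; the selection threshold is
score ≤ 2.0.  Columns never invariant get `n_levels + 1` (unreachable in
practice since singleton groups are always invariant).

**Two-entropies consensus.**  For each column, H_global is the 21-symbol
entropy over all sequences divided by log2 21, and H̄_within is the mean over
levels 2..L of the mean normalized within-group entropy at that level.  The
score is the Euclidean distance from (H_global, H̄_within) to the ideal SDP
corner (1, 0), scaled by 1/√2 into [0, 1]; score ≤ 0.3 selects.  The corner
distance is a reconstruction — the consensus scoring of the original tool is
not published in a reproducible form — so threshold semantics may differ from
the original; the formula is monotone (lowering any within-group entropy at
fixed global entropy never raises the score) and places a fully conserved
column at exactly 1/√2 ≈ 0.707.

**Correspondence-analysis subfamilies (S3det-style).**  The MSA is coded as a
binary sequence × (column, residue) indicator table (20 residue categories
per column; gaps code as all-zero).  Correspondence analysis is the SVD of
the standardized residual matrix (P − rcᵀ)/√(rcᵀ); principal row coordinates
are D_r^{-1/2} U S.  The retained dimensionality is the number of leading
axes before the largest consecutive drop in the singular-value scree.  We
initially used "singular values above the mean", but that rule retains the
axes describing within-clade substructure (which is real, not noise, under a
tree model), the silhouette criterion then prefers the finer clustering, and
the planted subfamily partition is not recovered; the scree gap identifies
the dominant separation level and recovers the planted partition exactly in
the test conditions.  Sequence coordinates are clustered with k-means
(10 restarts, fixed seed) for candidate counts 2..min(10, N−1); the count
with the best mean silhouette wins, ties toward fewer clusters, and a single
cluster is declared when the best silhouette is below 0.25.  The SDP score of
a column is the adjusted Rand index between the detected partition and the
partition of (non-gap) sequences by residue identity at that column;
ARI ≥ 0.8 selects.  Columns with one residue class or >50% gaps are
unscorable.

## Structure evaluation

Each residue has one representative 3-D point (a Cα stand-in).  The distance
of a residue to the binding sites is the minimum Euclidean distance to any
binding residue's point — the natural convention when sites are residue sets;
the alternative (mean over all binding residues) would shift but not reorder
the statistic.  The relative distance of a prediction is the mean site
distance of the mapped selected residues divided by the mean over all mapped
residues; the all-columns selection scores exactly 1 by construction, a
selection of binding residues scores 0, and empty or unmapped selections are
recorded as missing rather than imputed, so the per-year distributions carry
explicit *n*.  Quartiles in all summaries use linear interpolation.

Closeness to binding sites is a proxy for functional relevance, not a
definition of it; the benchmark reads *relative, temporal* changes of the
statistic, not absolute values.

## Synthetic study conditions

The default family has 4 subfamilies × 8 sequences and 200 columns with
10 fully conserved, 10 SDP (one distinct residue per subfamily) and 180
neutral columns.  Sequences evolve pre-aligned on a simulated tree (no
indels; gaps can be injected at a configurable per-column rate, default 0):
the root carries one clade per subfamily with stem length `between_depth`
(default 3.0) and within-clade edges of `within_depth` (default 0.3, jittered
±50%), a 10:1 separation that makes subfamily recovery well-posed.  Neutral
columns evolve by uniform 20-letter replacement at exponential waiting times
(`substitution_rate` = 0.45 events/site per unit branch length); after at
least one event on an edge the state is uniform, which the generator exploits
for exactness.  The rate is set so that a neutral column is essentially never
invariant across the whole family (expected substitutions ≈ 8–12 on the full
tree) yet occasionally invariant across a small early snapshot.

Publication years are drawn i.i.d. from a geometric year distribution
(growth 1.2/year over 1994–2014), so cumulative counts are exponential in
expectation.  In the default conditions the sampled years are paired to
sequences in subfamily order: the earliest years go to the first clades,
emulating databases whose early content concentrated in a few well-studied
clades, with new clades appearing later.  The year *marginal* is unchanged by
this pairing.

The synthetic structure places binding residues (5, drawn from the conserved
columns — the invariant core is the pocket) inside a ball of half the pocket
radius (default 5 Å), the SDP columns between 1 and 1.5 pocket radii of the
pocket centre, and every remaining residue on a self-avoiding random walk
(3.8 Å steps, 2 Å clearance) constrained to stay at least 3 pocket radii
away.  Far columns are therefore always farther than near columns, by
construction rather than in expectation.

What the generator does *not* emulate: indel evolution, rate variation
across neutral sites, empirical substitution preferences, hierarchical
relatedness between subfamilies (the clades are equidistant), alignment
error, or database redundancy bursts.  Passing tests show that the methods
recover planted signal under clean conditions and that the pipeline's
bookkeeping, thresholds and statistics behave as documented — not that the
detectors perform equally on real families.

## Known limitations

* With k equidistant subfamilies of equal size, the Spearman score of even a
  perfect one-residue-per-subfamily SDP is bounded well below 1: the position
  vector is tied in blocks while any jitter in sequence similarity fully
  spreads its ranks, capping ρ near √(3p(1−p)) where p is the
  within-subfamily pair fraction (≈0.72 for 4×8).  The ρ ≥ 0.8 threshold is
  therefore attainable mainly in effectively two-level families (measured
  ρ ≈ 0.81–0.87 for 2×16), and the correlation detector reports few or no
  positions on balanced many-subfamily families — visible in the benchmark
  output as small `n_selected` with many missing relative distances.
* Integer trace ranks through a strictly binary NJ tree open one clade at a
  time, so a k-subfamily SDP ranks k, not 2; at the published threshold the
  tree-cut detector's selections on such families reduce to the conserved
  core unless scored against a tree whose root is the k-furcation (the
  generator's true trees are; parameter-recovery tests use them).
* The two-entropies reconstruction selects high-global-entropy columns whose
  within-group entropies fall quickly along the level sequence; on the
  synthetic families these are predominantly neutral columns, and its
  relative distances sit above 1 — the one detector for which the
  binding-proximity proxy is known to be unflattering.
* Chance subfamily-aligned neutral columns (clade-invariant by drift) are
  genuine family-dependent conservation and are selected by the
  partition-agreement detector; they dilute its relative-distance signal
  relative to the planted-only set.
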