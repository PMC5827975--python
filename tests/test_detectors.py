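"""Tests for the five detectors, their oracles and invariants."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import sdpbench as sb
from sdpbench.detectors import (
    TreeLevels,
    UNSCORABLE_GAP_FRACTION,
    teao_score_from_entropies,
    tree_levels,
)

from conftest import (
    et_scores_oracle,
    random_alignment,
    spearman_oracle,
    teao_scores_oracle,
)


class TestColumnEntropy:
    @pytest.mark.parametrize(
        "column,expected",
        [("AAAA", 0.0), ("AACC", 1.0), ("ACDE", 2.0), ("AA--", 1.0)],
    )
    def test_known_values_with_gap_as_symbol(self, column, expected):
        assert sb.column_entropy(column) == pytest.approx(expected)

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError):
            sb.column_entropy("")


class TestConservation:
    def test_recovers_planted_conserved_columns(self, default_family, default_alignment):
        table = sb.conserved_positions(default_alignment)
        assert set(table.selected.tolist()) == default_family.truth.conserved_cols

    def test_two_identical_sequences_select_everything(self):
        aln = sb.Alignment.from_records([("a", "ACDEF"), ("b", "ACDEF")])
        assert len(sb.conserved_positions(aln).selected) == 5

    def test_gappy_single_residue_column_not_conserved(self):
        # one residue plus many gaps fails the gap cap
        seqs = [("a", "A"), ("b", "A"), ("c", "-"), ("d", "-")]
        aln = sb.Alignment.from_records(seqs)
        table = sb.conserved_positions(aln, gap_cap=0.10)
        assert len(table.selected) == 0


class TestSimilarityMatrices:
    def test_sequence_matrix_hand_example(self):
        # BLOSUM62: AA=4, CC=9, AC=0, AD=-2, CD=-3, DD=6
        aln = sb.Alignment.from_records([("a", "ACD"), ("b", "ACD"), ("c", "CAD")])
        m = sb.sequence_similarity_matrix(aln)
        assert m[0, 1] == pytest.approx((4 + 9 + 6) / 3)
        assert m[0, 2] == pytest.approx((0 + 0 + 6) / 3)
        assert np.allclose(m, m.T)

    def test_gap_columns_in_sequence_matrix(self):
        # gap-vs-residue contributes 0 but counts; double gap excluded
        aln = sb.Alignment.from_records([("a", "A-D-"), ("b", "AC--")])
        m = sb.sequence_similarity_matrix(aln)
        assert m[0, 1] == pytest.approx(4 / 3)

    def test_position_matrix_conserved_column_is_constant(self):
        aln = sb.Alignment.from_records([("a", "A"), ("b", "A"), ("c", "A")])
        m = sb.position_similarity_matrix(aln, 0)
        assert (m == 4).all()  # BLOSUM62 A-A

    def test_position_matrix_hand_checked_and_gaps_missing(self):
        aln = sb.Alignment.from_records(
            [("a", "A"), ("b", "C"), ("c", "D"), ("d", "-")]
        )
        m = sb.position_similarity_matrix(aln, 0)
        assert m[0, 1] == 0 and m[0, 2] == -2 and m[1, 2] == -3
        assert np.isnan(m[3]).all() and np.isnan(m[:, 3]).all()

    def test_all_gap_column_entirely_missing(self):
        aln = sb.Alignment.from_records([("a", "-A"), ("b", "-C"), ("c", "-D")])
        assert np.isnan(sb.position_similarity_matrix(aln, 0)).all()


class TestXdet:
    def test_matches_bruteforce_spearman_oracle(self):
        """Module scores equal a from-scratch rank-correlation on random MSAs."""
        rng = np.random.default_rng(7)
        checked = 0
        for rep in range(10):
            aln = random_alignment(rng, 6, 12, gap_p=0.05)
            table = sb.xdet_scores(aln)
            seq = sb.sequence_similarity_matrix(aln)
            codes = aln.encoded()
            iu, ju = np.triu_indices(6, k=1)
            from sdpbench.detectors import _substitution_array

            B = _substitution_array("BLOSUM62")
            for p in range(aln.n_columns):
                ci, cj = codes[iu, p].astype(int), codes[ju, p].astype(int)
                valid = (ci >= 0) & (cj >= 0)
                if valid.sum() < 3:
                    continue
                pos = B[ci[valid], cj[valid]]
                sv = seq[iu, ju][valid]
                if np.ptp(pos) == 0 or np.ptp(sv) == 0:
                    assert np.isnan(table.scores[p])
                    continue
                assert table.scores[p] == pytest.approx(
                    spearman_oracle(pos, sv), abs=1e-12
                )
                checked += 1
        assert checked > 20

    def test_planted_sdp_in_two_subfamily_family_scores_high(self, two_clade_family):
        """In a strong two-subfamily family a planted SDP correlates > 0.8."""
        aln = sb.Alignment.from_timed(two_clade_family.sequences)
        table = sb.xdet_scores(aln)
        sdp = sorted(two_clade_family.truth.sdp_cols)
        assert (table.scores[sdp] > 0.8).all()
        assert set(sdp) <= set(table.selected.tolist())

    def test_conserved_columns_unscorable(self, default_family, default_alignment):
        table = sb.xdet_scores(default_alignment)
        cons = sorted(default_family.truth.conserved_cols)
        assert np.isnan(table.scores[cons]).all()

    def test_scores_bounded(self, default_alignment):
        s = sb.xdet_scores(default_alignment).scores
        finite = s[~np.isnan(s)]
        assert ((finite >= -1) & (finite <= 1)).all()


class TestBuildTree:
    def test_two_clades_recovered_at_level_two(self, two_clade_family):
        aln = sb.Alignment.from_timed(two_clade_family.sequences)
        levels = sb.build_tree(aln)
        groups = [
            {levels.leaf_order[i] for i in g} for g in levels.partitions[1]
        ]
        truth = two_clade_family.truth.subfamily_of
        expected = [
            {sid for sid in aln.ids if truth[sid] == lab} for lab in ("sf1", "sf2")
        ]
        assert groups in ([expected[0], expected[1]], [expected[1], expected[0]])

    def test_hand_computed_nj_topology_on_four_leaves(self):
        """Additive 4-leaf distances force the (a,b)|(c,d) split."""
        fam = sb.make_benchmark_family(
            "t", seed=5, n_subfamilies=2, seqs_per_subfamily=2,
            n_columns=60, n_conserved=5, n_sdp=5,
        )
        aln = sb.Alignment.from_timed(fam.sequences)
        levels = sb.build_tree(aln)
        pairs = {
            frozenset(levels.leaf_order[i] for i in g)
            for g in levels.partitions[1]
        }
        truth = fam.truth.subfamily_of
        expected = {
            frozenset(s for s in aln.ids if truth[s] == lab)
            for lab in ("sf1", "sf2")
        }
        assert pairs == expected

    def test_level_count_reaches_leaves(self, default_alignment):
        levels = sb.build_tree(default_alignment)
        assert len(levels.partitions[-1]) == default_alignment.n_sequences
        assert len(levels.partitions[0]) == 1

    def test_partitions_refine_monotonically(self, default_alignment):
        levels = sb.build_tree(default_alignment)
        for prev, nxt in zip(levels.partitions, levels.partitions[1:]):
            prev_sets = [set(g.tolist()) for g in prev]
            for g in nxt:
                assert any(set(g.tolist()) <= s for s in prev_sets)

    def test_too_few_sequences_rejected(self):
        aln = sb.Alignment.from_records([("a", "AC"), ("b", "AD")])
        with pytest.raises(ValueError):
            sb.build_tree(aln)


class TestEvolutionaryTrace:
    def test_fully_conserved_scores_exactly_one(self, default_family, default_alignment):
        levels = sb.build_tree(default_alignment)
        table = sb.et_scores(default_alignment, levels)
        cons = sorted(default_family.truth.conserved_cols)
        assert (table.scores[cons] == 1).all()
        # conversely: score 1 implies a single residue type
        for c in np.flatnonzero(table.scores == 1):
            assert len(set(default_alignment.column(int(c))) - {sb.GAP}) == 1

    def test_two_clade_sdp_scores_two_and_is_selected(self, two_clade_family):
        aln = sb.Alignment.from_timed(two_clade_family.sequences)
        levels = sb.build_tree(aln)
        table = sb.et_scores(aln, levels)
        sdp = sorted(two_clade_family.truth.sdp_cols)
        assert (table.scores[sdp] == 2).all()
        assert set(sdp) <= set(table.selected.tolist())

    def test_matches_bruteforce_cut_enumeration(self):
        """ET ranks equal a naive enumeration of cuts on small trees."""
        rng = np.random.default_rng(3)
        for rep in range(8):
            aln = random_alignment(rng, rng.integers(4, 13), 15, gap_p=0.05)
            levels = sb.build_tree(aln)
            table = sb.et_scores(aln, levels)
            oracle = et_scores_oracle(aln, levels)
            finite = ~np.isnan(table.scores)
            assert np.array_equal(table.scores[finite], oracle[finite])

    def test_random_columns_rarely_selected(self):
        """An i.i.d. 20-symbol column on 20 sequences almost never ranks <= 2."""
        rng = np.random.default_rng(9)
        aln = random_alignment(rng, 20, 1000, gap_p=0.0)
        levels = sb.build_tree(aln)
        table = sb.et_scores(aln, levels)
        assert len(table.selected) / 1000 < 0.05

    def test_true_tree_levels_accept_multifurcating_root(self, default_family):
        aln = sb.Alignment.from_timed(default_family.sequences)
        levels = tree_levels(default_family.tree, leaf_order=aln.ids)
        assert len(levels.partitions[1]) == 4  # the four subfamily clades
        table = sb.et_scores(aln, levels)
        sdp = sorted(default_family.truth.sdp_cols)
        assert (table.scores[sdp] == 2).all()


class TestTeaO:
    def test_perfect_sdp_limit_scores_near_zero(self):
        assert teao_score_from_entropies(1.0, 0.0) == 0.0

    def test_fully_conserved_scores_inverse_sqrt_two(self, default_family, default_alignment):
        levels = sb.build_tree(default_alignment)
        table = sb.teao_scores(default_alignment, levels)
        cons = sorted(default_family.truth.conserved_cols)
        assert table.scores[cons] == pytest.approx(1 / np.sqrt(2))

    def test_matches_naive_reimplementation(self):
        rng = np.random.default_rng(5)
        for rep in range(10):
            aln = random_alignment(rng, 6, 10, gap_p=0.05)
            levels = sb.build_tree(aln)
            table = sb.teao_scores(aln, levels)
            oracle = teao_scores_oracle(aln, levels)
            finite = ~np.isnan(table.scores)
            assert table.scores[finite] == pytest.approx(oracle[finite], abs=1e-12)

    def test_scores_in_unit_interval(self, default_alignment):
        levels = sb.build_tree(default_alignment)
        s = sb.teao_scores(default_alignment, levels).scores
        finite = s[~np.isnan(s)]
        assert ((finite >= 0) & (finite <= 1 + 1e-12)).all()

    def test_score_monotone_in_within_group_entropy(self):
        """Lowering the within-group entropy never increases the score."""
        for hg in np.linspace(0, 1, 6):
            scores = [teao_score_from_entropies(hg, hw) for hw in np.linspace(1, 0, 11)]
            assert all(b <= a + 1e-15 for a, b in zip(scores, scores[1:]))


class TestS3det:
    def test_recovers_three_planted_subfamilies_exactly(self):
        fam = sb.make_benchmark_family("f3", seed=6, n_subfamilies=3,
                                       seqs_per_subfamily=8)
        aln = sb.Alignment.from_timed(fam.sequences)
        part, _ = sb.s3det_like(aln)
        truth = [fam.truth.subfamily_of[s] for s in aln.ids]
        detected = [part.cluster_of[s] for s in aln.ids]
        assert adjusted_rand_score(truth, detected) == 1.0
        assert part.n_clusters == 3

    def test_planted_sdp_has_unit_ari_and_is_selected(self, default_family, default_alignment):
        part, table = sb.s3det_like(default_alignment)
        sdp = sorted(default_family.truth.sdp_cols)
        assert table.scores[sdp] == pytest.approx(1.0)
        assert set(sdp) <= set(table.selected.tolist())

    def test_conserved_columns_unscorable(self, default_family, default_alignment):
        _, table = sb.s3det_like(default_alignment)
        cons = sorted(default_family.truth.conserved_cols)
        assert np.isnan(table.scores[cons]).all()

    def test_silhouette_gate_yields_single_cluster_on_unstructured_msa(self):
        """An i.i.d. alignment with weak silhouette collapses to one cluster."""
        rng = np.random.default_rng(2)
        aln = random_alignment(rng, 20, 100, gap_p=0.0)
        det = sb.S3detDetector().fit(aln)
        assert det.silhouette_ < det.silhouette_min
        assert det.n_clusters_ == 1
        # with a single cluster no column can reach the SDP threshold
        assert len(det.selected_) == 0

    def test_correspondence_analysis_matches_direct_svd(self):
        """Row coordinates reproduce the singular values of the standardized
        residual matrix on a hand-computable 3x3 indicator toy."""
        X = np.array([[2.0, 0.0, 1.0], [0.0, 3.0, 1.0], [1.0, 1.0, 1.0]])
        coords, sv = sb.correspondence_analysis(X)
        P = X / X.sum()
        r, c = P.sum(1), P.sum(0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        expected = np.linalg.svd(S, compute_uv=False)
        assert sv == pytest.approx(expected, abs=1e-10)
        # coordinates reproduce chi-square geometry: weighted mean is zero
        assert (r @ coords) == pytest.approx(np.zeros(coords.shape[1]), abs=1e-10)

    def test_subfamily_count(self):
        part = sb.SubfamilyPartition({"a": 0, "b": 1, "c": 2}, 3)
        assert sb.subfamily_count(part) == 3
        singletons = sb.SubfamilyPartition({f"s{i}": i for i in range(7)}, 7)
        assert sb.subfamily_count(singletons) == 7
        with pytest.raises(ValueError):
            sb.SubfamilyPartition({}, 0)


class TestPermutationEquivariance:
    def test_selected_sets_invariant_under_sequence_permutation(self, default_family):
        fam = default_family
        aln = sb.Alignment.from_timed(fam.sequences)
        rng = np.random.default_rng(4)
        perm = rng.permutation(aln.n_sequences)
        paln = aln.take(perm.tolist())

        def selections(a):
            levels = sb.build_tree(a)
            _, s3 = sb.s3det_like(a)
            return {
                "conservation": set(sb.conserved_positions(a).selected.tolist()),
                "xdet": set(sb.xdet_scores(a).selected.tolist()),
                "et": set(sb.et_scores(a, levels).selected.tolist()),
                "teao": set(sb.teao_scores(a, levels).selected.tolist()),
                "s3det": set(s3.selected.tolist()),
            }

        assert selections(aln) == selections(paln)


class TestGapPolicy:
    def test_majority_gap_column_unscorable_by_every_method(self):
        rng = np.random.default_rng(2)
        fam = sb.make_benchmark_family("g", seed=2, n_columns=60,
                                       n_conserved=5, n_sdp=5)
        aln = sb.Alignment.from_timed(fam.sequences)
        chars = aln.chars.copy()
        gap_col = sorted(fam.truth.neutral_cols)[0]
        rows = rng.choice(aln.n_sequences, size=int(aln.n_sequences * 0.7),
                          replace=False)
        chars[rows, gap_col] = sb.GAP
        gappy = sb.Alignment(aln.ids, chars)
        levels = sb.build_tree(gappy)
        _, s3 = sb.s3det_like(gappy)
        for table in (
            sb.conserved_positions(gappy),
            sb.xdet_scores(gappy),
            sb.et_scores(gappy, levels),
            sb.teao_scores(gappy, levels),
            s3,
        ):
            assert np.isnan(table.scores[gap_col])
            assert gap_col not in table.selected
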