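"""The replacement engine: ranking, cluster qualification, variant building."""

import pytest

from oracles import brute_force_best_donor

from orthoswap.design import (
    Substitution,
    TargetSpec,
    apply_substitutions,
    design_variant,
    find_cluster_replacement,
    rank_homologs,
    variation_profile,
)
from orthoswap.errors import DesignError, TargetSpecError
from orthoswap.report import render_report
from orthoswap.seqio import SequenceRecord
from orthoswap.synth import (
    STUDY_CLUSTERS,
    CYSTEINE_POSITIONS,
    generate_homolog,
    random_protein,
)


@pytest.fixture(scope="module")
def study_target():
    return TargetSpec("C", STUDY_CLUSTERS)


@pytest.fixture(scope="module")
def study_result(family, study_target, default_params):
    return design_variant(family.query, family.database, study_target, default_params)


class TestTargetSpec:
    def test_overlapping_clusters_rejected(self):
        with pytest.raises(TargetSpecError, match="more than one cluster"):
            TargetSpec("C", (frozenset({1, 2}), frozenset({2, 3})))

    def test_empty_cluster_rejected(self):
        with pytest.raises(TargetSpecError, match="empty cluster"):
            TargetSpec("C", (frozenset(),))

    def test_forbidden_residue_must_be_canonical(self):
        with pytest.raises(TargetSpecError):
            TargetSpec("X", (frozenset({1}),))

    def test_position_must_carry_forbidden_residue(self):
        query = SequenceRecord("q", "MKACD")
        spec = TargetSpec("C", (frozenset({2}),))  # position 2 is K
        with pytest.raises(TargetSpecError, match="position 2"):
            spec.validate_for(query)

    def test_position_out_of_range(self):
        query = SequenceRecord("q", "MKC")
        with pytest.raises(TargetSpecError, match="outside"):
            TargetSpec("C", (frozenset({9}),)).validate_for(query)


class TestRankHomologs:
    def test_query_itself_ranks_first_with_full_identity(self, default_params):
        query = random_protein(80, seed=1)
        decoy, _ = generate_homolog(query, 0.7, seed=2, record_id="decoy")
        ranked = rank_homologs(query, [decoy, query], default_params)
        assert ranked[0].record.id == query.id
        assert ranked[0].alignment.identity_pct == pytest.approx(100.0)
        assert [h.rank for h in ranked] == [1, 2]

    def test_ranking_follows_construction_identity(self, default_params):
        query = random_protein(200, seed=3)
        db = [
            generate_homolog(query, t, seed=s, record_id=f"id{int(t*100)}")[0]
            for t, s in ((0.5, 4), (0.9, 5), (0.7, 6))
        ]
        ranked = rank_homologs(query, db, default_params)
        assert [h.record.id for h in ranked] == ["id90", "id70", "id50"]
        identities = [h.alignment.identity_pct for h in ranked]
        assert identities == sorted(identities, reverse=True)

    def test_empty_database_is_an_error(self, default_params):
        with pytest.raises(DesignError, match="empty"):
            rank_homologs(random_protein(20, seed=1), [], default_params)

    def test_unalignable_records_rank_last_with_zero_identity(self, default_params):
        query = SequenceRecord("q", "WWWWWWWW")
        near = SequenceRecord("near", "WWWWWWWW")
        hopeless = SequenceRecord("far", "PPPPPPPP")  # W/P scores -4
        ranked = rank_homologs(query, [hopeless, near], default_params)
        assert ranked[-1].record.id == "far"
        assert ranked[-1].alignment.is_empty
        assert ranked[-1].alignment.identity_pct == 0.0


class TestFindClusterReplacement:
    def test_planted_donor_recovered_for_every_cluster(self, family, default_params):
        ranked = rank_homologs(family.query, family.database, default_params)
        for cluster, (donor_id, replacements) in family.expected_donors.items():
            suggestion = find_cluster_replacement(ranked, cluster, "C")
            assert suggestion is not None
            assert suggestion.source_id == donor_id
            assert {s.position: s.to_residue for s in suggestion.substitutions} == replacements

    def test_agrees_with_brute_force_scan(self, family, default_params):
        ranked = rank_homologs(family.query, family.database, default_params)
        for cluster in family.clusters:
            suggestion = find_cluster_replacement(ranked, cluster, "C")
            expected = brute_force_best_donor(ranked, cluster, "C")
            assert suggestion.source_id == expected

    def test_suggested_residues_match_donor_alignment(self, family, default_params):
        from orthoswap.alignment import map_position

        ranked = rank_homologs(family.query, family.database, default_params)
        by_id = {h.record.id: h for h in ranked}
        for cluster in family.clusters:
            suggestion = find_cluster_replacement(ranked, cluster, "C")
            donor = by_id[suggestion.source_id]
            for sub in suggestion.substitutions:
                mapped = map_position(donor.alignment, sub.position)
                assert mapped.residue == sub.to_residue
                assert mapped.hit_position == sub.hit_coordinate

    def test_none_when_every_homolog_keeps_forbidden_residue(self, default_params):
        query = random_protein(60, seed=7, exclude="C")
        query = SequenceRecord("q", query.residues[:29] + "C" + query.residues[30:])
        keeper, _ = generate_homolog(query, 0.9, planted=((30, "C"),), seed=8,
                                     record_id="keeper")
        ranked = rank_homologs(query, [keeper], default_params)
        assert find_cluster_replacement(ranked, {30}, "C") is None

    def test_gap_at_position_disqualifies_donor(self):
        # donor whose optimal alignment must delete the target position:
        # 19 matching residues comfortably pay for one cheap gap
        from orthoswap.alignment import AlignParams, MappingKind, map_position

        query = SequenceRecord("q", "MKLVNCAEFGHIKLMNPQRS")
        deleted = SequenceRecord("gapper", "MKLVNAEFGHIKLMNPQRS")  # C6 removed
        params = AlignParams(gap_open=5.0, gap_extend=0.5)
        ranked = rank_homologs(query, [deleted], params)
        assert map_position(ranked[0].alignment, 6).kind is MappingKind.GAP
        assert find_cluster_replacement(ranked, {6}, "C") is None

    def test_ambiguity_letter_disqualifies_donor(self, default_params):
        query = SequenceRecord("q", "MKLVNCAEFGHIKLMNPQRS")
        fuzzy = SequenceRecord("fuzzy", "MKLVNXAEFGHIKLMNPQRS")
        clean = SequenceRecord("clean", "MKLVNSAEFGHIKLMNPQRS")
        ranked = rank_homologs(query, [fuzzy, clean], default_params)
        suggestion = find_cluster_replacement(ranked, {6}, "C")
        assert suggestion.source_id == "clean"
        assert suggestion.substitutions[0].to_residue == "S"

    def test_cluster_coupling_forces_lower_identity_donor(self, family, default_params):
        """The closest homolog replacing only one of three coupled positions
        must lose to a more distant homolog replacing all three."""
        ranked = rank_homologs(family.query, family.database, default_params)
        singleton = find_cluster_replacement(ranked, {140}, "C")
        full = find_cluster_replacement(ranked, {140, 470, 484}, "C")
        assert singleton.source_id == "ortho_eq_partial"
        assert full.source_id == "ortho_eq"
        assert full.source_identity_pct < singleton.source_identity_pct


class TestApplySubstitutions:
    def test_empty_substitution_list_is_identity(self):
        query = SequenceRecord("q", "MKC")
        assert apply_substitutions(query, []).residues == "MKC"

    def test_single_substitution(self):
        variant = apply_substitutions(
            SequenceRecord("q", "MKC"), [Substitution(3, "C", "S")]
        )
        assert variant.residues == "MKS"
        assert variant.id != "q"  # marked as a variant

    def test_mismatched_from_residue_names_position(self):
        with pytest.raises(DesignError, match="position 2.*'K'"):
            apply_substitutions(SequenceRecord("q", "MKC"), [Substitution(2, "C", "S")])

    def test_duplicate_positions_rejected(self):
        with pytest.raises(DesignError, match="duplicate"):
            apply_substitutions(
                SequenceRecord("q", "MKC"),
                [Substitution(3, "C", "S"), Substitution(3, "C", "A")],
            )


class TestDesignVariant:
    def test_seven_substitutions_recovered(self, study_result):
        notations = {s.notation() for s in study_result.substitutions}
        assert notations == {
            "C140M", "C470Y", "C484T", "C237E", "C286V", "C359V", "C393S",
        }
        assert study_result.complete

    def test_variant_clean_and_otherwise_identical(self, family, study_result):
        variant = study_result.variant
        assert len(variant) == len(family.query)
        changed = {
            pos for pos in range(1, len(variant) + 1)
            if variant.residues[pos - 1] != family.query.residues[pos - 1]
        }
        assert changed == set(CYSTEINE_POSITIONS)
        assert all(variant.residues[p - 1] != "C" for p in CYSTEINE_POSITIONS)

    def test_unresolved_cluster_leaves_position_unchanged(self, default_params):
        query = random_protein(120, seed=31, exclude="C")
        query = SequenceRecord("q", query.residues[:59] + "C" + query.residues[60:])
        keeper, _ = generate_homolog(query, 0.9, planted=((60, "C"),), seed=32,
                                     record_id="keeper")
        result = design_variant(
            query, [keeper], TargetSpec("C", (frozenset({60}),)), default_params
        )
        assert not result.complete
        assert result.unresolved_clusters == (frozenset({60}),)
        assert result.variant.residues[59] == "C"

    def test_manual_override_is_applied_and_flagged(self, family, study_target,
                                                    default_params):
        result = design_variant(
            family.query, family.database, study_target, default_params,
            overrides={393: "A"},
        )
        sub393 = {s.position: s for s in result.substitutions}[393]
        assert sub393.to_residue == "A" and sub393.override
        assert result.variant.residues[392] == "A"

    def test_override_validation(self, family, study_target, default_params):
        with pytest.raises(TargetSpecError, match="reintroduces"):
            design_variant(family.query, family.database, study_target,
                           default_params, overrides={393: "C"})
        with pytest.raises(TargetSpecError, match="not a target"):
            design_variant(family.query, family.database, study_target,
                           default_params, overrides={100: "S"})
        with pytest.raises(TargetSpecError, match="canonical"):
            design_variant(family.query, family.database, study_target,
                           default_params, overrides={393: "X"})

    def test_precondition_checked_before_alignment(self, family, default_params):
        bad = TargetSpec("C", (frozenset({141}),))  # 141 is not a cysteine
        with pytest.raises(TargetSpecError):
            design_variant(family.query, family.database, bad, default_params)

    def test_reports_are_deterministic(self, family, study_target, default_params):
        first = design_variant(family.query, family.database, study_target,
                               default_params)
        second = design_variant(family.query, family.database, study_target,
                                default_params)
        assert render_report(first) == render_report(second)
        assert first.variant == second.variant


class TestVariationProfile:
    def test_query_only_database_shows_query_residues(self, default_params):
        query = random_protein(50, seed=41)
        ranked = rank_homologs(query, [query], default_params)
        profile = variation_profile(ranked, positions=(5, 25), top_n=1)
        for pos in (5, 25):
            assert profile.tally(pos) == {query.residue(pos): 1}

    def test_planted_residue_tally_matches_construction(self, default_params):
        query = random_protein(150, seed=42, exclude="C")
        query = SequenceRecord("q", query.residues[:74] + "C" + query.residues[75:])
        db = []
        for k in range(8):
            planted = ((75, "S"),) if k % 2 == 0 else ((75, "C"),)
            rec, _ = generate_homolog(query, 0.85, planted=planted, seed=50 + k,
                                      record_id=f"h{k}")
            db.append(rec)
        ranked = rank_homologs(query, db, default_params)
        profile = variation_profile(ranked, positions=(75,), top_n=8)
        assert profile.tally(75)["S"] == 4
        assert profile.tally(75)["C"] == 4

    def test_fully_conserved_position_is_flagged_and_unresolvable(self, default_params):
        query = random_protein(90, seed=43, exclude="C")
        query = SequenceRecord("q", query.residues[:44] + "C" + query.residues[45:])
        db = [
            generate_homolog(query, 0.8, planted=((45, "C"),), seed=60 + k,
                             record_id=f"h{k}")[0]
            for k in range(4)
        ]
        ranked = rank_homologs(query, db, default_params)
        profile = variation_profile(ranked, positions=(45,))
        assert profile.is_conserved(45, "C")
        assert find_cluster_replacement(ranked, {45}, "C") is None

    def test_rows_follow_rank_order(self, family, default_params):
        ranked = rank_homologs(family.query, family.database, default_params)
        profile = variation_profile(ranked, positions=(393,), top_n=5)
        assert [row.rank for row in profile.rows] == [1, 2, 3, 4, 5]

    def test_top_n_must_be_positive(self, family, default_params):
        ranked = rank_homologs(family.query, family.database, default_params)
        with pytest.raises(DesignError):
            variation_profile(ranked, positions=(393,), top_n=0)
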