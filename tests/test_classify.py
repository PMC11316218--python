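import dataclasses

import numpy as np
import pytest

from pks3.classify import (
    GAP,
    align_to_reference,
    check_triad,
    classify_sequence,
    extract_pks_domain,
    find_signature_motif,
    map_position,
)
from pks3.errors import EmptyInputError, NoDomainError
from pks3.io import SequenceRecord

from conftest import AA, random_protein


def _mutate(residues: str, pos: int, new: str) -> str:
    return residues[: pos - 1] + new + residues[pos:]


class TestNumberingTransfer:
    def test_identity_alignment_maps_every_position_to_itself(self, small_profile):
        aln = align_to_reference(small_profile.record, small_profile)
        assert aln.score > 0
        assert all(
            map_position(aln, i) == i for i in range(1, len(small_profile.record) + 1)
        )

    def test_insertion_before_position_shifts_mapping_by_one(self, small_profile):
        ref = small_profile.record.residues
        query = SequenceRecord(id="q", residues=ref[:9] + "W" + ref[9:])
        aln = align_to_reference(query, small_profile)
        assert map_position(aln, 5) == 5       # before the insertion
        assert map_position(aln, 10) == 11     # after the insertion point
        assert map_position(aln, 30) == 31

    def test_leading_deletion_maps_to_gap(self, small_profile):
        query = SequenceRecord(id="q", residues=small_profile.record.residues[5:])
        aln = align_to_reference(query, small_profile)
        assert map_position(aln, 2) == GAP

    def test_out_of_range_position_rejected(self, small_profile):
        aln = align_to_reference(small_profile.record, small_profile)
        with pytest.raises(ValueError):
            map_position(aln, 0)
        with pytest.raises(ValueError):
            map_position(aln, len(small_profile.record) + 1)

    def test_empty_query_rejected(self, small_profile):
        rec = SequenceRecord(id="q", residues="M")
        rec.residues = ""  # bypass construction-time validation
        with pytest.raises(EmptyInputError):
            align_to_reference(rec, small_profile)

    def test_degapping_reproduces_inputs(self, small_profile):
        query = SequenceRecord(id="q", residues=small_profile.record.residues[3:] + "AAA")
        aln = align_to_reference(query, small_profile)
        assert aln.aligned_ref.replace("-", "") == small_profile.record.residues
        assert aln.aligned_query.replace("-", "") == query.residues

    def test_mapping_strictly_increasing(self, small_profile, rng):
        query = SequenceRecord(id="q", residues=random_protein(rng, 60))
        aln = align_to_reference(query, small_profile)
        pairs = sorted(aln.ref_to_query.items())
        refs = [r for r, _ in pairs]
        qs = [q for _, q in pairs]
        assert refs == sorted(refs) and qs == sorted(set(qs))


class TestSignatureMotif:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("MKGFGPGQ", [3]),
            ("AFGPG", [1]),
            ("SFGPG", []),
            ("GFGPGFGPG", [1, 5]),
            ("XFGPG", []),   # X never satisfies a requirement
            ("GFGP", []),
        ],
    )
    def test_examples(self, seq, expected):
        assert find_signature_motif(seq) == expected

    def test_agrees_with_brute_force_windows(self, rng):
        first = set("GA")
        rest = "FGPG"
        for _ in range(200):
            seq = random_protein(rng, int(rng.integers(5, 60)))
            brute = [
                i + 1
                for i in range(len(seq) - 4)
                if seq[i] in first and seq[i + 1 : i + 5] == rest
            ]
            assert find_signature_motif(seq) == brute


class TestTriad:
    def test_identical_query_satisfies_triad(self, small_profile):
        aln = align_to_reference(small_profile.record, small_profile)
        assert check_triad(small_profile.record, small_profile, aln).ok

    def test_mutated_cysteine_fails(self, small_profile):
        query = SequenceRecord(
            id="q", residues=_mutate(small_profile.record.residues, 5, "S")
        )
        aln = align_to_reference(query, small_profile)
        ev = check_triad(query, small_profile, aln)
        assert not ev.ok
        assert ev.sites[0].observed == "S" and not ev.sites[0].satisfied

    def test_deletion_spanning_histidine_reports_gap(self, small_profile):
        ref = small_profile.record.residues
        query = SequenceRecord(id="q", residues=ref[:15] + ref[24:])  # drops 16..24
        aln = align_to_reference(query, small_profile)
        ev = check_triad(query, small_profile, aln)
        assert not ev.ok
        his = [s for s in ev.sites if s.ref_position == 20][0]
        assert his.query_position == GAP and his.observed == "-"


class TestClassification:
    def test_shipped_profiles_self_classify(self, default_profiles):
        for profile in default_profiles:
            result = classify_sequence(profile.record, default_profiles)
            assert result.label == profile.class_tag

    def test_no_profiles_rejected(self, small_profile):
        with pytest.raises(ValueError):
            classify_sequence(small_profile.record, [])

    def test_valid_pks_without_diagnostics_is_other(self, scaffolds):
        profiles = [scaffolds[c] for c in ("ASCL", "ORS", "other_PKSIII")]
        ascl = scaffolds["ASCL"].record
        broken = SequenceRecord(id="q", residues=_mutate(ascl.residues, 225, "D"))
        result = classify_sequence(broken, profiles)
        assert result.label == "other_PKSIII"
        assert result.triad_ok and result.motif_hits

    def test_both_diagnostic_sets_is_ambiguous(self, scaffolds):
        profiles = [scaffolds[c] for c in ("ASCL", "ORS", "other_PKSIII")]
        seq = list(scaffolds["ASCL"].record.residues)
        for pos, res in ((218, "Q"), (277, "V"), (286, "A")):
            seq[pos - 1] = res
        result = classify_sequence(SequenceRecord(id="q", residues="".join(seq)), profiles)
        assert result.label == "ambiguous"

    def test_monotone_degradation_of_diagnostics(self, scaffolds):
        """Breaking any single diagnostic site demotes ASCL to other;
        touching an unannotated site does not change the label."""
        profiles = [scaffolds[c] for c in ("ASCL", "ORS", "other_PKSIII")]
        ascl = scaffolds["ASCL"]
        for site in ascl.diagnostic_positions:
            mutated = SequenceRecord(
                id="q", residues=_mutate(ascl.record.residues, site.position, "D")
            )
            assert classify_sequence(mutated, profiles).label == "other_PKSIII"
        neutral = SequenceRecord(
            id="q", residues=_mutate(ascl.record.residues, 100, "D")
        )
        assert classify_sequence(neutral, profiles).label == "ASCL"

    def test_x_at_diagnostic_position_never_satisfies(self, scaffolds):
        profiles = [scaffolds[c] for c in ("ASCL", "ORS", "other_PKSIII")]
        ascl = scaffolds["ASCL"]
        masked = SequenceRecord(
            id="q", residues=_mutate(ascl.record.residues, 225, "X")
        )
        assert classify_sequence(masked, profiles).label == "other_PKSIII"

    def test_unalignable_sequence_flagged_not_pks(self, scaffolds, rng):
        profiles = [scaffolds[c] for c in ("ASCL", "ORS", "other_PKSIII")]
        junk = SequenceRecord(id="junk", residues="K" * 200)
        result = classify_sequence(junk, profiles, min_alignment_score=100.0)
        assert result.label == "not_PKSIII"
        assert "no usable alignment" in result.note


class TestDomainExtraction:
    def test_embedded_reference_recovered(self, small_profile, rng):
        flank1 = random_protein(rng, 40)
        flank2 = random_protein(rng, 40)
        fusion = SequenceRecord(
            id="fus",
            residues=flank1 + small_profile.record.residues + flank2,
            is_fusion=True,
        )
        out = extract_pks_domain(fusion, small_profile, margin=5, score_floor=50.0)
        assert small_profile.record.residues in out.residues
        assert out.id.endswith("|pksdomain")

    def test_no_similarity_rejected(self, small_profile):
        junk = SequenceRecord(id="k", residues="K" * 120, is_fusion=True)
        with pytest.raises(NoDomainError):
            extract_pks_domain(junk, small_profile)

    def test_n_terminal_match_clips_margin_to_sequence_start(self, small_profile, rng):
        fusion = SequenceRecord(
            id="fus",
            residues=small_profile.record.residues + random_protein(rng, 60),
            is_fusion=True,
        )
        out = extract_pks_domain(fusion, small_profile, margin=10, score_floor=50.0)
        assert out.residues.startswith(small_profile.record.residues)
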