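"""Occurrence counting, A/B parameters and the release frequency A_E."""

import numpy as np
import pytest

from legumepep import (
    BioactiveFragment,
    BioactiveFragmentDB,
    CleavageRule,
    ProteinRecord,
    count_occurrences,
    parameter_A,
    parameter_AE,
    parameter_B,
    profile_peptide,
    round_reported,
)
from tests.conftest import random_protein_string

TRYPSIN = CleavageRule("trypsin", "3.4.21.4", frozenset("KR"), frozenset("P"))


def db_of(activity, fragments, ec50s=None):
    ec50s = ec50s or {}
    return BioactiveFragmentDB(
        [BioactiveFragment(f, activity, ec50s.get(f)) for f in fragments]
    )


class TestCountOccurrences:
    @pytest.mark.parametrize(
        "peptide,fragment,expected",
        [
            ("EEEDEDEPR", "EE", 2),  # overlapping occurrences both count
            ("EEEDEDEPR", "EEE", 1),
            ("PVNRPGEPQ", "PV", 1),
            ("PVNRPGEPQ", "QQ", 0),
            ("AAAA", "AA", 3),
        ],
    )
    def test_overlap_inclusive_counting(self, peptide, fragment, expected):
        assert count_occurrences(peptide, fragment) == expected

    def test_empty_fragment_rejected(self):
        with pytest.raises(ValueError):
            count_occurrences("PVNRPGEPQ", "")


class TestParameterA:
    def test_dppiv_profile_of_PVNRPGEPQ(self):
        db = db_of("DPP-IV inhibitor", ["RP", "EP", "GE", "NR", "PG", "PQ", "PV", "VN"])
        prof = parameter_A("PVNRPGEPQ", db, "DPP-IV inhibitor")
        assert prof.a == 8
        assert round_reported(prof.A) == 0.89

    def test_stimulating_profile_of_EEEDEDEPR_requires_overlaps(self):
        db = db_of("stimulating", ["EEE", "EE"])
        prof = parameter_A("EEEDEDEPR", db, "stimulating")
        assert prof.a == 3
        assert round_reported(prof.A) == 0.33

    def test_ace_profile_of_LDNINALEPDH(self):
        db = db_of("ACE inhibitor", ["ALEP"])
        prof = parameter_A("LDNINALEPDH", db, "ACE inhibitor")
        assert round_reported(prof.A) == 0.09

    def test_unknown_activity_gives_empty_profile(self, tiny_db):
        prof = parameter_A("PVNRPGEPQ", tiny_db, "no such activity")
        assert prof.A == 0 and prof.matches == ()

    def test_a_equals_sum_of_match_positions(self, tiny_db):
        prof = parameter_A("EEEDEDEPR", tiny_db, "stimulating")
        assert prof.a == sum(len(pos) for _, pos in prof.matches)

    def test_regression_against_all_printed_values(self, screening_reference):
        """Every published A value is reproduced at its printed precision."""
        for row in screening_reference.itertuples(index=False):
            db = db_of(row.activity, row.fragments.split(","))
            prof = parameter_A(row.peptide, db, row.activity)
            decimals = len(row.a_printed.split(".")[1])
            assert round_reported(prof.A, decimals) == pytest.approx(
                float(row.a_printed)
            ), (row.peptide, row.activity)

    def test_brute_force_substring_oracle(self):
        """A matches an enumerate-every-substring oracle on random inputs."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            pep = random_protein_string(rng, int(rng.integers(2, 15)))
            frags = {
                random_protein_string(rng, int(rng.integers(1, 4)))
                for _ in range(int(rng.integers(1, 8)))
            }
            db = db_of("antioxidant", sorted(frags))
            prof = parameter_A(pep, db, "antioxidant")
            # oracle: count every substring of pep equal to a db fragment
            a_oracle = sum(
                1
                for i in range(len(pep))
                for j in range(i + 1, len(pep) + 1)
                if pep[i:j] in frags
            )
            assert prof.a == a_oracle
            assert prof.A == a_oracle / len(pep)

    def test_invariant_under_db_record_order(self):
        frags = ["EE", "EEE", "PR", "DE"]
        fwd = db_of("stimulating", frags)
        rev = db_of("stimulating", frags[::-1])
        a1 = parameter_A("EEEDEDEPR", fwd, "stimulating")
        a2 = parameter_A("EEEDEDEPR", rev, "stimulating")
        assert a1.A == a2.A and a1.B == a2.B


class TestParameterB:
    def test_hand_evaluated_single_fragment(self):
        db = db_of("ACE inhibitor", ["PR"], ec50s={"PR": 4.0})
        assert parameter_B("NYDEGSEPR", db, "ACE inhibitor") == pytest.approx(
            (1 / 4.0) / 9
        )

    def test_missing_when_no_matched_fragment_has_ec50(self):
        db = db_of("ACE inhibitor", ["PR"])
        assert parameter_B("NYDEGSEPR", db, "ACE inhibitor") is None

    def test_missing_when_no_matches(self, tiny_db):
        prof = parameter_A("GGGG", tiny_db, "ACE inhibitor")
        assert prof.B is None and prof.A == 0

    def test_linear_in_reciprocal_ec50(self):
        b1 = parameter_B(
            "NYDEGSEPR", db_of("ACE inhibitor", ["PR"], {"PR": 4.0}), "ACE inhibitor"
        )
        b2 = parameter_B(
            "NYDEGSEPR", db_of("ACE inhibitor", ["PR"], {"PR": 2.0}), "ACE inhibitor"
        )
        assert b2 == pytest.approx(2 * b1)

    def test_fragments_without_ec50_contribute_nothing(self):
        with_extra = db_of(
            "ACE inhibitor", ["PR", "NY"], ec50s={"PR": 4.0}
        )  # NY matched but has no EC50
        only_pr = db_of("ACE inhibitor", ["PR"], ec50s={"PR": 4.0})
        assert parameter_B("NYDEGSEPR", with_extra, "ACE inhibitor") == parameter_B(
            "NYDEGSEPR", only_pr, "ACE inhibitor"
        )


class TestProfilePeptide:
    def test_TETWNPNHPE_activity_profiles(self):
        db = BioactiveFragmentDB(
            [BioactiveFragment(f, "ACE inhibitor") for f in ["TE", "HP"]]
            + [BioactiveFragment("TW", "antioxidant")]
            + [
                BioactiveFragment(f, "DPP-IV inhibitor")
                for f in ["HP", "NP", "WN", "ET", "NH", "PN", "TE", "TW"]
            ]
        )
        profiles = {p.activity: p for p in profile_peptide("TETWNPNHPE", db)}
        assert round_reported(profiles["ACE inhibitor"].A, 1) == 0.2
        assert round_reported(profiles["antioxidant"].A, 1) == 0.1
        assert round_reported(profiles["DPP-IV inhibitor"].A, 1) == 0.8

    def test_sorted_by_activity_and_only_matched(self, tiny_db):
        profiles = profile_peptide("EEEDEDEPRG", tiny_db)
        names = [p.activity for p in profiles]
        assert names == sorted(names)
        assert all(p.matches for p in profiles)

    def test_no_matches_gives_empty_list(self, tiny_db):
        assert profile_peptide("HHHH", tiny_db) == []

    def test_VVIPTEPPH_reproduces_all_reference_rows(self, screening_reference):
        sub = screening_reference[screening_reference.peptide == "VVIPTEPPH"]
        records = [
            BioactiveFragment(f, row.activity)
            for row in sub.itertuples(index=False)
            for f in row.fragments.split(",")
        ]
        db = BioactiveFragmentDB(records)
        profiles = {p.activity: p for p in profile_peptide("VVIPTEPPH", db)}
        assert len(profiles) == len(sub)
        for row in sub.itertuples(index=False):
            decimals = len(row.a_printed.split(".")[1])
            assert round_reported(profiles[row.activity].A, decimals) == float(
                row.a_printed
            )


class TestParameterAE:
    def test_zero_when_digestion_yields_no_db_fragments(self, tiny_db):
        protein = ProteinRecord("X", "AAAA")
        assert parameter_AE(protein, [TRYPSIN], tiny_db, "antioxidant") == 0

    def test_hand_evaluated_release_frequency(self, tiny_db):
        # AKPRG -> {AKPR, G}; db has (G, antioxidant) -> 1 released / 5 residues
        protein = ProteinRecord("X", "AKPRG")
        assert parameter_AE(protein, [TRYPSIN], tiny_db, "antioxidant") == pytest.approx(0.2)

    def test_whole_fragment_matches_only(self):
        # GK fragment contains G but is not equal to it: no credit
        db = BioactiveFragmentDB([BioactiveFragment("G", "antioxidant")])
        protein = ProteinRecord("X", "GKAR")
        assert parameter_AE(protein, [TRYPSIN], db, "antioxidant") == 0

    def test_invariant_under_protein_doubling(self):
        """Concatenating a protein with itself across a cleavable junction
        leaves the per-residue release frequency unchanged."""
        rng = np.random.default_rng(7)
        db = BioactiveFragmentDB(
            [BioactiveFragment(f, "antioxidant") for f in ("G", "AK", "TR")]
        )
        for _ in range(25):
            seq = random_protein_string(rng, 30) + "R"  # R-terminal: junction cleaves
            single = parameter_AE(ProteinRecord("S", seq), [TRYPSIN], db, "antioxidant")
            double = parameter_AE(
                ProteinRecord("D", seq + seq), [TRYPSIN], db, "antioxidant"
            )
            assert double == pytest.approx(single)


class TestDatabase:
    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError):
            BioactiveFragmentDB(
                [BioactiveFragment("PR", "ACE inhibitor")] * 2
            )

    def test_nonpositive_ec50_rejected(self):
        with pytest.raises(ValueError):
            BioactiveFragment("PR", "ACE inhibitor", ec50_uM=0.0)

    def test_table_roundtrip(self, tmp_path, tiny_db):
        path = tmp_path / "db.tsv"
        tiny_db.to_frame().to_csv(path, sep="\t", index=False)
        back = BioactiveFragmentDB.from_table(path)
        assert back.to_frame().equals(tiny_db.to_frame())

    def test_packaged_study_fragments_load(self):
        from legumepep import load_study_fragments

        db = load_study_fragments()
        assert ("PR", "ACE inhibitor") in {(r.sequence, r.activity) for r in db.records}
        assert len(db.activities) == 10


class TestRounding:
    @pytest.mark.parametrize(
        "value,decimals,expected",
        [(0.625, 2, 0.63), (0.445, 2, 0.45), (0.4444, 2, 0.44), (0.875, 2, 0.88)],
    )
    def test_half_away_from_zero(self, value, decimals, expected):
        assert round_reported(value, decimals) == expected
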