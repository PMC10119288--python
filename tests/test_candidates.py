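"""Target isoform enumeration and decoy generation."""

import itertools

import numpy as np
import pandas as pd
import pytest

import phosflr as pf
from phosflr.candidates import (
    DecoyGenerationError,
    build_candidate_database,
    decoy_method1,
    decoy_method2,
    enumerate_isoforms,
)
from phosflr.peptide_core import Peptidoform

from conftest import make_random_peptidoform


class TestIsoformEnumeration:
    def test_adjacent_site_monophospho_gives_two_isoforms(self):
        p = pf.parse_modified_sequence("pSTLVLHDLLK", 2)
        isoforms = enumerate_isoforms(p)
        assert [pf.format_modified_sequence(i) for i in isoforms] == [
            "S[Phospho]TLVLHDLLK",
            "ST[Phospho]LVLHDLLK",
        ]

    def test_single_candidate_site_gives_one_isoform(self):
        p = pf.parse_modified_sequence("S[Phospho]AK", 2)
        assert len(enumerate_isoforms(p)) == 1

    def test_diphospho_combinatorics(self):
        p = pf.parse_modified_sequence("S[Phospho]AS[Phospho]TYK", 2)
        assert len(enumerate_isoforms(p)) == 6  # C(4, 2)

    def test_counts_match_bruteforce_subsets(self, rng):
        # counts equal C(c, m) for all c <= 8, m <= min(c, 2) by construction
        for c in range(1, 9):
            for m in range(1, min(c, 4) + 1):
                seq = "S" * c + "AGK"
                p = Peptidoform(seq, tuple((i + 1, "Phospho") for i in range(m)), 2)
                expected = sum(
                    1 for _ in itertools.combinations(range(c), m)
                )
                assert len(enumerate_isoforms(p)) == expected

    def test_non_phospho_mods_stay_fixed(self):
        p = pf.parse_modified_sequence("oxMS[Phospho]TK", 2)
        for iso in enumerate_isoforms(p):
            assert (1, "Oxidation") in iso.mods


class TestDecoyMethods:
    def test_method1_swaps_residue_and_phosphate(self, rng):
        target = pf.parse_modified_sequence("S[Phospho]TLVLHDLLK", 2)
        decoys = decoy_method1(target, rng)
        assert len(decoys) == 1
        d = decoys[0]
        assert sorted(d.sequence) == sorted(target.sequence)  # permutation
        assert d.sequence != target.sequence
        phospho_pos = d.phospho_positions[0]
        assert d.sequence[phospho_pos - 1] == "S"  # phosphate travelled with S

    def test_method1_two_decoys_for_diphospho_target(self, rng):
        target = pf.parse_modified_sequence("S[Phospho]AT[Phospho]GHEK", 2)
        assert len(decoy_method1(target, rng)) == 2

    def test_all_candidate_residue_sequence_fails(self, rng):
        target = Peptidoform("SSTY", ((1, "Phospho"),), 2)
        with pytest.raises(DecoyGenerationError):
            decoy_method1(target, rng)
        with pytest.raises(DecoyGenerationError):
            decoy_method2(target, rng)

    def test_method2_keeps_sequence_and_moves_phosphate(self, rng):
        target = pf.parse_modified_sequence("S[Phospho]TLVLHDLLK", 2)
        decoys = decoy_method2(target, rng)
        assert len(decoys) == 1
        d = decoys[0]
        assert d.sequence == target.sequence
        assert d.phospho_positions != target.phospho_positions
        assert d.sequence[d.phospho_positions[0] - 1] not in "STY"

    @pytest.mark.parametrize("method", [decoy_method1, decoy_method2])
    def test_decoys_are_isobaric_with_target(self, method, rng):
        for _ in range(200):
            target = make_random_peptidoform(rng, n_phospho=int(rng.integers(1, 3)))
            if all(aa in "STY" for aa in target.sequence):
                continue
            for d in method(target, rng):
                assert abs(pf.precursor_mz(d) - pf.precursor_mz(target)) < 1e-6

    def test_method1_moves_stranded_mods_with_their_residue(self, rng):
        # an oxidation at the swap position travels to the phospho's old spot
        target = Peptidoform("SM", ((1, "Phospho"), (2, "Oxidation")), 2)
        d = decoy_method1(target, rng)[0]
        assert d.sequence == "MS"
        assert d.mods == ((1, "Oxidation"), (2, "Phospho"))

    def test_preserve_cterm_flag(self, rng):
        target = pf.parse_modified_sequence("S[Phospho]TAK", 2)
        for _ in range(20):
            for d in decoy_method1(target, rng, preserve_cterm=True):
                assert d.sequence.endswith("K")


class TestDatabaseBuild:
    @pytest.fixture
    def table(self):
        return pd.DataFrame(
            [
                {
                    "spectrum_id": "scan=1",
                    "sequence": "STLVLHDLLK",
                    "modified_sequence": "S[Phospho]TLVLHDLLK",
                    "charge": 2,
                    "localization_probability": 0.6,
                }
            ]
        )

    def test_single_spectrum_tallies(self, table):
        db = build_candidate_database(table, method=1, seed=0)
        assert db.N_target == 2
        assert db.N_decoy == 2  # one decoy per (target, phosphate)
        assert db.sets[0].reanalyzable

    def test_non_reanalyzable_rows_pass_through(self):
        table = pd.DataFrame(
            [
                {
                    "spectrum_id": "scan=2",
                    "sequence": "SAGK",
                    "modified_sequence": "S[Phospho]AGK",
                    "charge": 2,
                    "localization_probability": 0.9,
                }
            ]
        )
        db = build_candidate_database(table, method=1, seed=0)
        assert not db.sets
        assert len(db.passthrough) == 1
        assert not db.passthrough[0].reanalyzable

    def test_excess_phospho_rows_dropped(self, table):
        extra = pd.DataFrame(
            [
                {
                    "spectrum_id": "scan=3",
                    "sequence": "STYSAGHK",
                    "modified_sequence": "S[Phospho]T[Phospho]Y[Phospho]SAGHK",
                    "charge": 3,
                    "localization_probability": 0.9,
                }
            ]
        )
        db = build_candidate_database(
            pd.concat([table, extra], ignore_index=True), method=1, seed=0
        )
        assert db.n_dropped_multiphospho == 1
        assert len(db.sets) == 1

    def test_same_seed_reproduces_database(self, table):
        db1 = build_candidate_database(table, method=1, seed=42)
        db2 = build_candidate_database(table, method=1, seed=42)
        for a, b in zip(db1.sets, db2.sets):
            assert [str(t) for t in a.targets] == [str(t) for t in b.targets]
            assert [str(d) for d, _ in a.decoys] == [str(d) for d, _ in b.decoys]

    def test_malformed_rows_counted_not_fatal(self, table):
        bad = pd.DataFrame(
            [
                {
                    "spectrum_id": "scan=4",
                    "sequence": "XXXX",
                    "modified_sequence": "B[Junk]K",
                    "charge": 2,
                    "localization_probability": 0.5,
                }
            ]
        )
        db = build_candidate_database(
            pd.concat([table, bad], ignore_index=True), method=1, seed=0
        )
        assert db.n_malformed == 1
        assert len(db.sets) == 1

    def test_empty_database_is_an_error(self):
        table = pd.DataFrame(
            columns=[
                "spectrum_id",
                "sequence",
                "modified_sequence",
                "charge",
                "localization_probability",
            ]
        )
        with pytest.raises(ValueError):
            build_candidate_database(table, method=1, seed=0)

    def test_decoys_generated_for_every_target_isoform(self, table):
        db = build_candidate_database(table, method=2, seed=1)
        parents = {ti for _, ti in db.sets[0].decoys}
        assert parents == {0, 1}
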