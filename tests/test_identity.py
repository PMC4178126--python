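"""Gap-excluded identity, all-pairs matrices, sessions and determinism."""

from __future__ import annotations

import numpy as np
import pytest

from demarcate import (Dataset, IdentityError, PairRecord,
                       PairwiseAlignment, Session, SessionError, all_pairs,
                       extend_session, load_session, make_synthetic_family,
                       num_pairs, pair_identity, save_session, to_distance)
from demarcate.identity import format_pairs_csv
from demarcate.seqio import NUCLEOTIDE

from conftest import nt_dataset, nt_record


class TestNumPairs:
    @pytest.mark.parametrize("s,expected", [
        (0, 0), (1, 0), (2, 1), (25, 300), (1000, 499500),
    ])
    def test_counts(self, s, expected):
        assert num_pairs(s) == expected

    def test_negative_rejected(self):
        with pytest.raises(IdentityError):
            num_pairs(-1)


class TestPairIdentity:
    @pytest.mark.parametrize("ga,gb,m,n,ident", [
        ("ACGT", "ACGA", 1, 4, 0.75),
        ("AC-GT", "ACCGT", 0, 4, 1.0),
        ("A-CG", "ATCG", 0, 3, 1.0),
    ])
    def test_m_n_counting(self, ga, gb, m, n, ident):
        al = PairwiseAlignment("a", "b", ga, gb, 0.0)
        rec = pair_identity(al)
        assert (rec.M, rec.N) == (m, n)
        assert rec.identity == ident

    def test_no_comparable_columns_errors(self):
        al = PairwiseAlignment("a", "b", "A-", "-C", 0.0)
        with pytest.raises(IdentityError, match="no comparable columns"):
            pair_identity(al)

    def test_identity_is_exactly_one_minus_m_over_n(self):
        rec = PairRecord("a", "b", 7, 13)
        assert rec.identity == 1.0 - 7 / 13


class TestAllPairs:
    def test_identical_sequences_give_all_ones(self):
        ds = nt_dataset(("a", "ACGTAC"), ("b", "ACGTAC"), ("c", "ACGTAC"))
        matrix = all_pairs(ds).matrix()
        assert np.array_equal(matrix.values, np.ones((3, 3)))

    def test_pair_count_for_25_sequences(self):
        fam = make_synthetic_family(n=25, length=120, divergence=0.05,
                                    indel_rate=0.002, seed=9)
        session = all_pairs(fam)
        assert len(session.pairs) == 300

    def test_matrix_invariants(self, small_family):
        matrix = all_pairs(small_family).matrix()
        assert matrix.ids == small_family.ids
        assert np.array_equal(matrix.values, matrix.values.T)
        assert np.array_equal(np.diag(matrix.values), np.ones(len(matrix.ids)))
        assert ((matrix.values >= 0) & (matrix.values <= 1)).all()

    def test_worker_count_does_not_change_output(self, small_family):
        csv1 = format_pairs_csv(all_pairs(small_family, workers=1).pairs.values())
        csv4 = format_pairs_csv(all_pairs(small_family, workers=4).pairs.values())
        assert csv1 == csv4

    def test_single_sequence_rejected(self):
        ds = Dataset([nt_record("a", "ACGT")], NUCLEOTIDE)
        with pytest.raises(IdentityError):
            all_pairs(ds)


class TestDatasetSizeInvariance:
    def test_identity_is_independent_of_companion_sequences(self):
        """A pair's identity must not move when the dataset around it grows."""
        core = make_synthetic_family(n=4, length=250, divergence=0.08,
                                     indel_rate=0.003, seed=13)
        extra = make_synthetic_family(n=8, length=250, divergence=0.15,
                                      indel_rate=0.003, seed=14,
                                      id_prefix="other")
        alone = all_pairs(core)
        embedded = all_pairs(Dataset(core.records + extra.records, NUCLEOTIDE))
        for key, rec in alone.pairs.items():
            other = embedded.pairs[key]
            assert (rec.M, rec.N) == (other.M, other.N)


class TestToDistance:
    def test_entrywise_complement(self, small_family):
        matrix = all_pairs(small_family).matrix()
        dist = to_distance(matrix)
        assert np.array_equal(dist.values, 1.0 - matrix.values)
        assert np.array_equal(np.diag(dist.values), np.zeros(5))
        assert np.array_equal(dist.values, dist.values.T)


class TestSessions:
    @pytest.fixture
    def session(self, small_family):
        return all_pairs(small_family)

    def test_round_trip_preserves_everything(self, session, tmp_path):
        path = tmp_path / "run.sdt.zip"
        save_session(session, path)
        back = load_session(path)
        assert back.params == session.params
        assert back.dataset.ids == session.dataset.ids
        assert [r.residues for r in back.dataset] == \
            [r.residues for r in session.dataset]
        assert back.pairs == session.pairs

    def test_csv_export_survives_round_trip(self, session, tmp_path):
        path = tmp_path / "run.sdt.zip"
        save_session(session, path)
        assert format_pairs_csv(load_session(path).pairs.values()) == \
            format_pairs_csv(session.pairs.values())

    def test_truncated_archive_is_rejected(self, session, tmp_path):
        path = tmp_path / "run.sdt.zip"
        save_session(session, path)
        path.write_bytes(path.read_bytes()[:100])
        with pytest.raises(SessionError, match="corrupt"):
            load_session(path)

    def test_tampered_member_fails_checksum(self, session, tmp_path):
        import zipfile

        path = tmp_path / "run.sdt.zip"
        save_session(session, path)
        with zipfile.ZipFile(path) as zf:
            manifest = zf.read("manifest.json")
            fasta = zf.read("sequences.fasta")
            pairs = zf.read("pairs.csv")
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("manifest.json", manifest)
            zf.writestr("sequences.fasta", fasta)
            zf.writestr("pairs.csv", pairs.replace(b"0", b"1", 1))
        with pytest.raises(SessionError, match="checksum"):
            load_session(path)

    def test_incomplete_pair_table_rejected(self, small_family):
        session = all_pairs(small_family)
        pairs = dict(session.pairs)
        pairs.popitem()
        with pytest.raises(SessionError, match="incomplete"):
            Session(session.params, small_family, pairs)


class TestExtendSession:
    def test_extension_equals_full_recompute(self):
        fam = make_synthetic_family(n=12, length=200, divergence=0.07,
                                    indel_rate=0.002, seed=21)
        base = Dataset(fam.records[:9], NUCLEOTIDE)
        extended = extend_session(all_pairs(base), fam.records[9:])
        full = all_pairs(fam)
        assert format_pairs_csv(extended.pairs.values()) == \
            format_pairs_csv(full.pairs.values())
        assert extended.dataset.ids == full.dataset.ids

    def test_new_alignment_count_is_k_times_s_plus_choose_k(self, small_family):
        session = all_pairs(small_family)  # S = 5
        new = [nt_record(f"new{i}", "ACGTACGTAC") for i in range(3)]
        extended = extend_session(session, new)
        # 3*5 + 3 = 18 new pairs on top of the original 10
        assert len(extended.pairs) - len(session.pairs) == 18

    def test_duplicate_id_rejected(self, small_family):
        session = all_pairs(small_family)
        clash = nt_record(small_family.ids[0], "ACGT")
        with pytest.raises(SessionError, match="already present"):
            extend_session(session, [clash])

    def test_alphabet_mismatch_rejected(self, small_family):
        from demarcate import SequenceRecord
        from demarcate.seqio import AMINO_ACID

        session = all_pairs(small_family)
        with pytest.raises(SessionError, match="alphabet"):
            extend_session(session, [SequenceRecord("p", "MKVL", AMINO_ACID)])


class TestRandomPairIdentityFloor:
    def test_unrelated_random_pairs_stay_above_forty_percent(self, rng):
        """Gap-excluded identity of random pairs is inflated well above 25%."""
        from demarcate.seqio import random_nucleotide_sequence

        idents = []
        for k in range(20):
            a = nt_record("a", random_nucleotide_sequence(500, rng))
            b = nt_record("b", random_nucleotide_sequence(500, rng))
            session = all_pairs(Dataset([a, b], NUCLEOTIDE))
            idents.append(next(iter(session.pairs.values())).identity)
        assert float(np.mean(idents)) >= 0.40
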