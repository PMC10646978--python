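import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunoloop import chemlib
from immunoloop.chemlib import (LINK_TOKEN, PAD_TOKEN, CandidateLibrary,
                                ConfigurationError, DimensionError,
                                EncodingError, InputError, Molecule,
                                TokenVocabulary, decode_selfies,
                                ecfp4_fingerprint, load_library,
                                nearest_training_similarity, one_hot_decode,
                                one_hot_encode, tanimoto, to_selfies)

# frozen reference value: popcount of the 2048-bit ECFP4 of ethanol, computed
# once with RDKit 2024.09.2 GetMorganFingerprintAsBitVect(radius=2)
CCO_POPCOUNT = 6


def _write_csv(tmp_path, rows, columns=("id", "smiles", "vendor")):
    path = tmp_path / "lib.csv"
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)
    return path


class TestLoadLibrary:
    def test_three_valid_rows(self, tmp_path):
        path = _write_csv(tmp_path, [("a", "CCO", "v"), ("b", "c1ccccc1", "v"),
                                     ("c", "CC(=O)O", "v")])
        lib = load_library(path)
        assert len(lib) == 3
        assert lib.rejects == []

    def test_bad_row_logged_not_dropped_silently(self, tmp_path):
        path = _write_csv(tmp_path, [("a", "CCO", "v"), ("b", "not_a_smiles", "v"),
                                     ("c", "CCN", "v"), ("d", "CCC", "v")])
        lib = load_library(path)
        assert len(lib) == 3
        assert len(lib.rejects) == 1
        assert lib.rejects[0]["row"] == 1
        assert lib.rejects[0]["smiles"] == "not_a_smiles"

    def test_missing_column_is_configuration_error(self, tmp_path):
        path = _write_csv(tmp_path, [("a", "CCO", "v")])
        with pytest.raises(ConfigurationError):
            load_library(path, smiles_column="structure")

    def test_zero_parseable_rows_is_input_error(self, tmp_path):
        path = _write_csv(tmp_path, [("a", "xx", "v"), ("b", "yy", "v")])
        with pytest.raises(InputError):
            load_library(path)

    def test_ids_generated_from_row_order_when_absent(self, tmp_path):
        path = tmp_path / "noid.csv"
        pd.DataFrame({"smiles": ["CCO", "CCC"]}).to_csv(path, index=False)
        lib = load_library(path)
        assert lib.ids == ["MOL-000000", "MOL-000001"]

    def test_deterministic(self, tmp_path):
        path = _write_csv(tmp_path, [("a", "OCC", "v"), ("b", "C(C)C", "v")])
        f1 = load_library(path).to_frame()
        f2 = load_library(path).to_frame()
        pd.testing.assert_frame_equal(f1, f2)
        assert f1.to_csv() == f2.to_csv()


class TestSelfies:
    def test_methane_single_token_round_trips(self):
        m = Molecule.from_smiles("m", "C")
        assert to_selfies(m) == ["[C]"]
        assert decode_selfies(to_selfies(m)) == "C"

    def test_two_component_salt_has_one_link(self):
        m = Molecule.from_smiles("m", "CCO.Cl")
        toks = to_selfies(m)
        assert toks.count(LINK_TOKEN) == 1
        # components sorted by descending heavy atoms: CCO before Cl
        split = toks.index(LINK_TOKEN)
        assert decode_selfies(toks[:split]) == "CCO"
        assert decode_selfies(toks[split + 1:]) == "Cl"

    def test_component_order_is_canonical(self):
        a = Molecule.from_smiles("a", "Cl.CCO")
        b = Molecule.from_smiles("b", "CCO.Cl")
        assert a.selfies_tokens == b.selfies_tokens
        assert a.smiles == b.smiles

    def test_round_trip_full_toy_library(self, toy_library):
        # oracle: canonicalize(decode(encode(x))) == canonicalize(x), 200 seeds-fixed molecules
        ok = 0
        for m in toy_library.molecules:
            assert m.encodable
            if decode_selfies(m.selfies_tokens) == m.smiles:
                ok += 1
        assert ok == len(toy_library)


class TestOneHot:
    def _vocab(self):
        return TokenVocabulary(tokens=["[C]", "[O]", "[N]", LINK_TOKEN, PAD_TOKEN],
                               max_len=4)

    def test_shape_and_popcount(self):
        v = self._vocab()
        m = Molecule(id="m", smiles="CO", components=["CO"],
                     selfies_tokens=["[C]", "[O]"])
        vec = one_hot_encode(m, v)
        assert vec.shape == (4 * 5,)
        assert vec.sum() == 4  # 2 tokens + 2 PAD

    def test_no_pad_when_length_equals_max_len(self):
        v = self._vocab()
        m = Molecule(id="m", smiles="x", components=["x"],
                     selfies_tokens=["[C]", "[O]", "[C]", "[O]"])
        vec = one_hot_encode(m, v).reshape(4, 5)
        assert vec[:, v.pad_index].sum() == 0

    def test_oov_token_named_in_error(self):
        v = self._vocab()
        m = Molecule(id="m", smiles="x", components=["x"],
                     selfies_tokens=["[S]"])
        with pytest.raises(EncodingError, match=r"\[S\]"):
            one_hot_encode(m, v)

    def test_decode_inverts_encode_on_library(self, toy_library, toy_vocab):
        for m in toy_library.molecules[:100]:
            vec = one_hot_encode(m, toy_vocab)
            # independent oracle: direct index arithmetic on the flat vector
            expected = []
            width = len(toy_vocab)
            for pos in range(toy_vocab.max_len):
                j = int(np.flatnonzero(vec[pos * width:(pos + 1) * width])[0])
                tok = toy_vocab.tokens[j]
                if tok != PAD_TOKEN:
                    expected.append(tok)
            assert one_hot_decode(vec, toy_vocab) == expected == m.selfies_tokens

    def test_injective_up_to_max_len(self, toy_vocab, rng):
        seen = {}
        toks = [t for t in toy_vocab.tokens if t != PAD_TOKEN]
        for _ in range(50):
            n = int(rng.integers(1, toy_vocab.max_len + 1))
            seq = [toks[i] for i in rng.integers(0, len(toks), n)]
            m = Molecule(id="m", smiles="x", components=["x"], selfies_tokens=seq)
            key = one_hot_encode(m, toy_vocab).tobytes()
            if key in seen:
                assert seen[key] == seq
            seen[key] = seq


class TestFingerprintAndTanimoto:
    def test_deterministic(self):
        assert np.array_equal(ecfp4_fingerprint("CCO"), ecfp4_fingerprint("CCO"))

    def test_distinct_structures_differ(self):
        assert not np.array_equal(ecfp4_fingerprint("C"),
                                  ecfp4_fingerprint("c1ccccc1"))

    def test_cco_popcount_matches_reference(self):
        assert int(ecfp4_fingerprint("CCO").sum()) == CCO_POPCOUNT

    def test_default_width_2048(self):
        assert ecfp4_fingerprint("CCO").shape == (2048,)

    def test_tanimoto_identity(self):
        fp = ecfp4_fingerprint("CCO")
        assert tanimoto(fp, fp) == 1.0

    def test_tanimoto_disjoint(self):
        a = np.array([1, 1, 0, 0]); b = np.array([0, 0, 1, 1])
        assert tanimoto(a, b) == 0.0

    def test_tanimoto_one_third(self):
        assert tanimoto(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0])) \
            == pytest.approx(1 / 3)

    def test_all_zero_convention(self):
        z = np.zeros(8)
        assert tanimoto(z, z) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            tanimoto(np.zeros(4), np.zeros(8))

    @given(st.lists(st.booleans(), min_size=1, max_size=64),
           st.lists(st.booleans(), min_size=1, max_size=64))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        n = max(len(a), len(b))
        va = np.array(a + [False] * (n - len(a)))
        vb = np.array(b + [False] * (n - len(b)))
        s = tanimoto(va, vb)
        assert 0.0 <= s <= 1.0
        assert s == tanimoto(vb, va)
        # brute-force oracle
        inter = sum(x and y for x, y in zip(va, vb))
        union = sum(x or y for x, y in zip(va, vb))
        assert s == pytest.approx(1.0 if union == 0 else inter / union)


class TestNearestTrainingSimilarity:
    def test_verbatim_query_scores_one(self):
        refs = [Molecule.from_smiles(f"r{i}", s)
                for i, s in enumerate(["CCO", "CCN", "c1ccccc1"])]
        res = nearest_training_similarity([refs[1]], refs)
        assert res["similarity"].iloc[0] == 1.0
        assert res["reference_id"].iloc[0] == "r1"

    def test_matches_brute_force(self):
        qs = [Molecule.from_smiles(f"q{i}", s)
              for i, s in enumerate(["CCCl", "c1ccncc1", "CC(=O)O"])]
        rs = [Molecule.from_smiles(f"r{i}", s)
              for i, s in enumerate(["CCO", "CCBr", "c1ccccc1", "CC(=O)N", "CCCC"])]
        res = nearest_training_similarity(qs, rs)
        for qi, q in enumerate(qs):  # O(nm) oracle
            sims = [tanimoto(ecfp4_fingerprint(q), ecfp4_fingerprint(r)) for r in rs]
            assert res["similarity"].iloc[qi] == pytest.approx(max(sims))

    def test_empty_reference_is_input_error(self):
        q = [Molecule.from_smiles("q", "CCO")]
        with pytest.raises(InputError):
            nearest_training_similarity(q, [])


class TestLibraryPartition:
    def test_tested_untested_partition(self):
        mols = [Molecule.from_smiles(f"m{i}", s)
                for i, s in enumerate(["C", "CC", "CCC"])]
        lib = CandidateLibrary(molecules=mols)
        lib.mark_tested(["m0"])
        assert lib.tested_ids | lib.untested_ids == set(lib.ids)
        assert lib.tested_ids & lib.untested_ids == set()

    def test_unknown_id_rejected(self):
        lib = CandidateLibrary(molecules=[Molecule.from_smiles("m0", "C")])
        with pytest.raises(InputError):
            lib.mark_tested(["nope"])

    def test_duplicate_ids_rejected(self):
        mols = [Molecule.from_smiles("m", "C"), Molecule.from_smiles("m", "CC")]
        with pytest.raises(InputError):
            CandidateLibrary(molecules=mols)
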