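"""Domain model, corpus I/O round-trips, and the split protocol."""

import warnings

import pytest

from fragvec import (
    AnalogueSeries,
    Corpus,
    Fragment,
    SplitSpec,
    read_corpus,
    split_corpus,
    write_corpus,
)
from fragvec.corpus import CorpusFormatError, canonicalize_smiles


class TestFragment:
    def test_canonicalization_is_idempotent(self):
        for s in ["[*]CC", "C([*])C", "[*]c1ccccc1", "[*:1]OC"]:
            once = canonicalize_smiles(s)
            assert canonicalize_smiles(once) == once

    def test_mapped_wildcard_normalized_to_unmapped(self):
        assert Fragment.from_smiles("[*:1]CC") == Fragment.from_smiles("[*]CC")

    def test_invalid_smiles_rejected(self):
        with pytest.raises(ValueError, match="unparsable"):
            Fragment.from_smiles("not-a-smiles")

    @pytest.mark.parametrize("smiles", ["CC", "[*]C[*]"])
    def test_wrong_attachment_count_rejected(self, smiles):
        with pytest.raises(ValueError, match="attachment"):
            Fragment.from_smiles(smiles)


class TestAnalogueSeries:
    def test_members_sorted_ascending_and_terminal_is_most_potent(self):
        members = [
            (Fragment.from_smiles("[*]C"), 7.0),
            (Fragment.from_smiles("[*]O"), 5.0),
            (Fragment.from_smiles("[*]N"), 9.0),
        ]
        s = AnalogueSeries("a", members)
        assert s.potencies == (5.0, 7.0, 9.0)
        assert s.terminal == Fragment.from_smiles("[*]N")
        assert s.substituent(0) == s.terminal
        assert s.substituent(2) == Fragment.from_smiles("[*]O")
        assert s.potency(1) == 7.0

    def test_too_short_and_duplicates_rejected(self):
        f = [Fragment.from_smiles(s) for s in ("[*]C", "[*]O", "[*]N")]
        with pytest.raises(ValueError, match="at least 3"):
            AnalogueSeries("a", [(f[0], 5.0), (f[1], 6.0)])
        with pytest.raises(ValueError, match="duplicate"):
            AnalogueSeries("a", [(f[0], 5.0), (f[1], 6.0), (f[0], 7.0)])

    def test_potency_ties_keep_input_order(self):
        f = [Fragment.from_smiles(s) for s in ("[*]C", "[*]O", "[*]N")]
        s = AnalogueSeries("a", [(f[0], 5.0), (f[1], 6.0), (f[2], 6.0)])
        assert s.terminal == f[2]


class TestCorpusIO:
    def test_long_table_roundtrip(self, tmp_path, small_corpus):
        path = tmp_path / "corpus.csv"
        write_corpus(small_corpus, path)
        back = read_corpus(path)
        assert len(back) == len(small_corpus)
        for a, b in zip(small_corpus, back):
            assert a.series_id == b.series_id
            assert a.fragments == b.fragments
            assert all(
                abs(pa - pb) < 5e-3 + 1e-9
                for pa, pb in zip(a.potencies, b.potencies)
            )
        assert back.vocabulary == small_corpus.vocabulary

    def test_series_lines_roundtrip(self, tmp_path, small_corpus):
        path = tmp_path / "corpus.txt"
        write_corpus(small_corpus, path, format="series-lines")
        back = read_corpus(path, format="series-lines")
        assert [s.fragments for s in back] == [
            s.fragments for s in small_corpus
        ]

    def test_minimal_long_table(self, tmp_path):
        path = tmp_path / "one.csv"
        path.write_text(
            "series_id,smiles,pic50\n"
            "s1,[*]C,5.0\ns1,[*]O,6.0\ns1,[*]N,7.0\n"
        )
        corpus = read_corpus(path)
        assert len(corpus) == 1
        assert len(corpus.vocabulary) == 3

    def test_descending_input_order_is_normalized(self, tmp_path):
        asc = tmp_path / "asc.csv"
        desc = tmp_path / "desc.csv"
        rows = ["s1,[*]C,5.0", "s1,[*]O,6.0", "s1,[*]N,7.0"]
        asc.write_text("series_id,smiles,pic50\n" + "\n".join(rows) + "\n")
        desc.write_text(
            "series_id,smiles,pic50\n" + "\n".join(reversed(rows)) + "\n"
        )
        a, d = read_corpus(asc), read_corpus(desc)
        assert a.series[0].members == d.series[0].members

    def test_eleven_member_series_terminal_has_max_potency(
        self, tmp_path, example_series
    ):
        path = tmp_path / "eleven.csv"
        write_corpus(Corpus([example_series]), path)
        back = read_corpus(path)
        s = back.series[0]
        assert len(s) == 11
        assert s.potency(0) == max(s.potencies)

    def test_unparsable_smiles_reported_with_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "series_id,smiles,pic50\n"
            "s1,[*]C,5.0\ns1,XYZ###,6.0\ns1,[*]N,7.0\n"
        )
        with pytest.raises(CorpusFormatError, match="line 3"):
            read_corpus(path)

    def test_short_series_rejected_with_warning(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text(
            "series_id,smiles,pic50\n"
            "s1,[*]C,5.0\ns1,[*]O,6.0\n"
            "s2,[*]C,5.0\ns2,[*]O,6.0\ns2,[*]N,7.0\n"
        )
        with pytest.warns(UserWarning, match="rejected series"):
            corpus = read_corpus(path)
        assert [s.series_id for s in corpus] == ["s2"]


class TestSplit:
    def test_floor_arithmetic_and_partition(self, small_corpus):
        spec = SplitSpec(
            train_fraction=0.9, n_test_series=5,
            min_test_series_length=5, seed=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            train, test = split_corpus(small_corpus, spec)
        assert len(train) == int(0.9 * len(small_corpus))
        train_ids = {s.series_id for s in train}
        assert all(s.series_id not in train_ids for s in test)

    def test_test_fragments_all_in_train_vocabulary(self, small_corpus):
        spec = SplitSpec(n_test_series=3, min_test_series_length=5, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            train, test = split_corpus(small_corpus, spec)
        for s in test:
            assert all(f in train.vocabulary for f in s.fragments)

    def test_same_seed_gives_identical_split(self, small_corpus):
        spec = SplitSpec(n_test_series=5, min_test_series_length=5, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t1 = split_corpus(small_corpus, spec)
            t2 = split_corpus(small_corpus, spec)
        assert [s.series_id for s in t1[0]] == [s.series_id for s in t2[0]]
        assert [s.series_id for s in t1[1]] == [s.series_id for s in t2[1]]

    def test_shortfall_warns_and_returns_all_qualifying(self, small_corpus):
        spec = SplitSpec(n_test_series=1000, min_test_series_length=5, seed=0)
        with pytest.warns(UserWarning, match="qualifying"):
            _, test = split_corpus(small_corpus, spec)
        assert 0 < len(test) < 1000
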