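"""Substructure-vocabulary learning and encoding."""

import numpy as np
import pytest

from crossdti.tokenizer import (
    PairsExhausted,
    TokenizedCorpus,
    VocabularyParseError,
    encode_sequence,
    fit_vocabulary,
    initialize_vocabulary,
    load_vocabulary,
    merge_pair,
    most_frequent_pair,
    reconstruct,
    save_vocabulary,
)


def brute_force_merge_sequence(corpus, min_frequency, max_size):
    """Independent reference: recount all adjacent pairs after every merge.

    Uses its own counting/merging code so it checks the production path
    rather than mirroring it.
    """
    seqs = [list(s) for s in corpus]
    tokens = []
    for s in corpus:
        for ch in s:
            if ch not in tokens:
                tokens.append(ch)
    merges = []
    while len(tokens) < max_size:
        counts, order = {}, {}
        pos = 0
        for seq in seqs:
            for i in range(len(seq) - 1):
                pr = (seq[i], seq[i + 1])
                counts[pr] = counts.get(pr, 0) + 1
                order.setdefault(pr, pos)
                pos += 1
        if not counts:
            break
        best, best_c = None, -1
        for pr in sorted(counts, key=order.get):
            if counts[pr] > best_c:
                best, best_c = pr, counts[pr]
        if best_c < min_frequency:
            break
        merged = best[0] + best[1]
        new_seqs = []
        for seq in seqs:
            out, i = [], 0
            while i < len(seq):
                if i + 1 < len(seq) and (seq[i], seq[i + 1]) == best:
                    out.append(merged)
                    i += 2
                else:
                    out.append(seq[i])
                    i += 1
            new_seqs.append(out)
        seqs = new_seqs
        merges.append((best[0], best[1], merged))
        if merged not in tokens:
            tokens.append(merged)
    return merges, tokens


class TestInitialize:
    @pytest.mark.parametrize(
        "corpus, expected",
        [
            (["AB", "BC"], {"A", "B", "C"}),
            (["AAAA"], {"A"}),
            (["MKV", "KVL"], {"M", "K", "V", "L"}),
        ],
    )
    def test_character_inventory(self, corpus, expected):
        vocab = initialize_vocabulary(corpus)
        assert set(vocab.tokens) == expected
        assert vocab.merges == []

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            initialize_vocabulary([])
        with pytest.raises(ValueError):
            initialize_vocabulary(["AB", ""])


class TestPairScanning:
    def test_counts_every_adjacent_position(self):
        corpus = TokenizedCorpus([list("AABAA"), list("AAB")])
        pair, freq = most_frequent_pair(corpus)
        assert pair == ("A", "A") and freq == 3

    def test_tie_broken_by_scan_order(self):
        corpus = TokenizedCorpus([list("AB"), list("AB")])
        pair, freq = most_frequent_pair(corpus)
        assert pair == ("A", "B") and freq == 2

    def test_exhaustion_signalled(self):
        with pytest.raises(PairsExhausted):
            most_frequent_pair(TokenizedCorpus([["A"]]))

    def test_merge_leftmost_non_overlapping(self):
        out = merge_pair(TokenizedCorpus([list("AAA")]), ("A", "A"))
        assert out.sequences == [["AA", "A"]]
        out = merge_pair(TokenizedCorpus([list("ABAB")]), ("A", "B"))
        assert out.sequences == [["AB", "AB"]]

    def test_merge_absent_pair_is_noop(self):
        out = merge_pair(TokenizedCorpus([list("BC")]), ("A", "A"))
        assert out.sequences == [["B", "C"]]


class TestFit:
    def test_repeated_motif_corpus(self):
        vocab = fit_vocabulary(["ABAB", "ABAB"], min_frequency=2, max_size=10)
        assert set(vocab.tokens) == {"A", "B", "AB", "ABAB"}
        assert [(a, b) for a, b, _ in vocab.merges] == [("A", "B"), ("AB", "AB")]

    def test_threshold_stops_merging(self):
        vocab = fit_vocabulary(["ABC"], min_frequency=2, max_size=10)
        assert set(vocab.tokens) == {"A", "B", "C"}
        assert vocab.merges == []

    def test_all_pairs_below_threshold_leaves_alphabet(self):
        # every adjacent pair of AABB occurs once, below the threshold of 2,
        # so the loop stops immediately regardless of the size cap
        vocab = fit_vocabulary(["AABB"], min_frequency=2, max_size=4)
        assert set(vocab.tokens) == {"A", "B"}
        assert vocab.merges == []

    def test_size_cap_respected(self):
        vocab = fit_vocabulary(["ABABABAB"] * 3, min_frequency=1, max_size=3)
        assert vocab.size == 3

    def test_merge_counts_respect_threshold(self):
        corpus = ["ABABXY", "ABAB", "XYAB"]
        d = 2
        vocab = fit_vocabulary(corpus, min_frequency=d, max_size=50)
        # replay and recount: every recorded merge was frequent at merge time
        seqs = [list(s) for s in corpus]
        for a, b, merged in vocab.merges:
            count = sum(
                1 for seq in seqs for i in range(len(seq) - 1)
                if (seq[i], seq[i + 1]) == (a, b)
            )
            assert count >= d
            seqs = merge_pair(TokenizedCorpus(seqs), (a, b)).sequences

    def test_oracle_equivalence_random_corpora(self):
        rng = np.random.default_rng(99)
        for trial in range(60):
            n_seq = int(rng.integers(1, 31))
            corpus = [
                "".join(rng.choice(list("ABCD"), size=rng.integers(1, 21)))
                for _ in range(n_seq)
            ]
            d = int(rng.integers(1, 4))
            theta = int(rng.integers(4, 30))
            theta = max(theta, len({c for s in corpus for c in s}))
            vocab = fit_vocabulary(corpus, d, theta)
            ref_merges, ref_tokens = brute_force_merge_sequence(corpus, d, theta)
            assert vocab.merges == ref_merges
            assert vocab.tokens == ref_tokens

    def test_determinism(self):
        corpus = ["CCNOS", "NOSCC", "CCNO"]
        v1 = fit_vocabulary(corpus, 2, 20)
        v2 = fit_vocabulary(corpus, 2, 20)
        assert v1 == v2

    def test_vocabulary_size_monotone_and_capped(self):
        corpus = ["ABABABAB", "BABABA", "ABBA"]
        theta = 6
        vocab = fit_vocabulary(corpus, 1, theta)
        assert vocab.size <= theta
        assert len(vocab.tokens) == len(set(vocab.tokens))

    def test_separate_corpora_share_only_common_substructures(self):
        drug = fit_vocabulary(["CCOCCO", "CCOCC"], 2, 20, kind="drug")
        prot = fit_vocabulary(["MKVMKV", "MKVMK"], 2, 20, kind="protein")
        multi_d = {t for t in drug.tokens if len(t) > 1}
        multi_p = {t for t in prot.tokens if len(t) > 1}
        assert not (multi_d & multi_p)


class TestEncode:
    def test_merge_replay(self):
        vocab = fit_vocabulary(["ABAB", "ABAB"], 2, 10)
        enc = encode_sequence("ABABA", vocab)
        assert enc.tokens == ["ABAB", "A"]
        assert reconstruct(enc) == "ABABA"

    def test_all_unknown_passthrough(self):
        vocab = fit_vocabulary(["AB"], 2, 10)
        enc = encode_sequence("XYZ", vocab)
        assert enc.tokens == ["X", "Y", "Z"]
        assert all(i == 1 for i in enc.indices)  # reserved UNK index
        assert reconstruct(enc) == "XYZ"

    def test_character_fallback_without_merges(self):
        vocab = fit_vocabulary(["AB"], 2, 10)
        assert encode_sequence("AB", vocab).tokens == ["A", "B"]

    def test_empty_sequence_rejected(self):
        vocab = fit_vocabulary(["AB"], 2, 10)
        with pytest.raises(ValueError):
            encode_sequence("", vocab)

    def test_reconstruction_identity_random_strings(self):
        rng = np.random.default_rng(5)
        corpus = [
            "".join(rng.choice(list("ABCDE"), size=rng.integers(2, 25)))
            for _ in range(40)
        ]
        vocab = fit_vocabulary(corpus, 2, 60)
        # encode strings that also contain out-of-alphabet symbols
        for _ in range(300):
            s = "".join(rng.choice(list("ABCDExz#"), size=rng.integers(1, 40)))
            enc = encode_sequence(s, vocab)
            assert reconstruct(enc) == s
            assert len(enc.tokens) == len(enc.indices)


class TestPersistence:
    def test_round_trip(self, tmp_path):
        vocab = fit_vocabulary(["ABABAB", "BABA"], 2, 30, kind="drug")
        path = tmp_path / "v.mimm"
        save_vocabulary(vocab, path)
        assert load_vocabulary(path) == vocab

    def test_round_trip_without_merges(self, tmp_path):
        vocab = fit_vocabulary(["ABC"], 5, 30)
        path = tmp_path / "v.mimm"
        save_vocabulary(vocab, path)
        assert load_vocabulary(path) == vocab

    def test_corrupt_file_names_line(self, tmp_path):
        vocab = fit_vocabulary(["ABABAB", "BABA"], 2, 30)
        path = tmp_path / "v.mimm"
        save_vocabulary(vocab, path)
        lines = path.read_text().splitlines()
        lines[-1] = "A\tB"  # truncated merge line
        path.write_text("\n".join(lines))
        with pytest.raises(VocabularyParseError, match=r"line \d+"):
            load_vocabulary(path)

    def test_wrong_header_rejected(self, tmp_path):
        path = tmp_path / "bad.mimm"
        path.write_text("not a vocabulary\n")
        with pytest.raises(VocabularyParseError):
            load_vocabulary(path)
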