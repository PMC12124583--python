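"""Frequent-substructure vocabularies for SMILES and protein sequences.

Drugs (SMILES strings) and proteins (amino-acid strings) are decomposed into
ordered, non-overlapping subsequences by an iterative pair-merging procedure in
the byte-pair-encoding family: starting from single characters, the most
frequent adjacent token pair in the corpus is repeatedly merged into a new
token until the best pair's frequency drops below a threshold ``d`` or the
vocabulary reaches a cap ``max_size``. The resulting decomposition of any
sequence reconstructs it exactly, and adjacent substructures never overlap, so
the model sees both a substructure view and the untouched original sequence.

Drugs and proteins each get their own vocabulary; nothing here attempts
chemically aware SMILES parsing — sequences are plain character strings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "Vocabulary",
    "TokenizedCorpus",
    "SubstructureEncoding",
    "PairsExhausted",
    "VocabularyParseError",
    "PAD_INDEX",
    "UNK_INDEX",
    "initialize_vocabulary",
    "most_frequent_pair",
    "merge_pair",
    "fit_vocabulary",
    "encode_sequence",
    "reconstruct",
    "save_vocabulary",
    "load_vocabulary",
]

#: Reserved embedding indices. Real tokens start at index 2.
PAD_INDEX = 0
UNK_INDEX = 1


class PairsExhausted(Exception):
    """No adjacent token pair exists anywhere in the corpus."""


class VocabularyParseError(ValueError):
    """A vocabulary file could not be parsed; the message names the line."""


@dataclass
class Vocabulary:
    """A learned substructure token set with its replayable merge history.

    ``tokens`` lists the alphabet (in first-occurrence corpus order) followed
    by merged tokens in the order they were learned. ``merges`` stores
    ``(left, right, merged)`` triples; replaying them in order regenerates
    ``tokens`` from ``alphabet``.
    """

    tokens: list[str]
    merges: list[tuple[str, str, str]]
    alphabet: list[str]
    min_frequency: int
    max_size: int
    kind: str = "generic"
    token_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self.token_index:
            self.token_index = {
                t: i + 2 for i, t in enumerate(self.tokens)  # 0=pad, 1=unk
            }
        self._alphabet_set = set(self.alphabet)

    @property
    def size(self) -> int:
        return len(self.tokens)

    def index_of(self, token: str) -> int:
        return self.token_index.get(token, UNK_INDEX)

    def __eq__(self, other):
        if not isinstance(other, Vocabulary):
            return NotImplemented
        return (
            self.tokens == other.tokens
            and self.merges == other.merges
            and self.alphabet == other.alphabet
            and self.min_frequency == other.min_frequency
            and self.max_size == other.max_size
            and self.kind == other.kind
        )


@dataclass
class TokenizedCorpus:
    """A corpus as lists of tokens; concatenating each list reproduces the
    original string and adjacent tokens never overlap."""

    sequences: list[list[str]]
    source: str = "generic"


@dataclass
class SubstructureEncoding:
    """One sequence decomposed into substructure tokens.

    ``tokens`` concatenate exactly to ``original``; ``indices`` map each token
    into the vocabulary (UNK for characters outside the training alphabet,
    whose text still passes through so reconstruction holds).
    """

    tokens: list[str]
    indices: list[int]
    original: str

    def __post_init__(self):
        assert len(self.tokens) == len(self.indices)


def initialize_vocabulary(corpus: list[str], min_frequency: int = 1,
                          max_size: int = 10_000, kind: str = "generic") -> Vocabulary:
    """Character inventory of the corpus, in first-occurrence order."""
    if not corpus:
        raise ValueError("corpus must be non-empty")
    alphabet: list[str] = []
    seen: set[str] = set()
    for seq in corpus:
        if not seq:
            raise ValueError("every corpus sequence must be non-empty")
        for ch in seq:
            if ch not in seen:
                seen.add(ch)
                alphabet.append(ch)
    return Vocabulary(
        tokens=list(alphabet),
        merges=[],
        alphabet=alphabet,
        min_frequency=min_frequency,
        max_size=max_size,
        kind=kind,
    )


def most_frequent_pair(corpus: TokenizedCorpus) -> tuple[tuple[str, str], int]:
    """The adjacent pair with maximal total count across all sequences.

    Every adjacent position counts (so ``AAA`` contributes 2 to ``(A, A)``).
    Ties break toward the pair first encountered in a left-to-right,
    sequence-order scan. Raises :class:`PairsExhausted` when no sequence has
    two tokens.
    """
    if not corpus.sequences:
        raise ValueError("corpus must be non-empty")
    counts: dict[tuple[str, str], int] = {}
    first_seen: dict[tuple[str, str], int] = {}
    pos = 0
    for seq in corpus.sequences:
        for a, b in zip(seq, seq[1:]):
            pair = (a, b)
            counts[pair] = counts.get(pair, 0) + 1
            if pair not in first_seen:
                first_seen[pair] = pos
            pos += 1
    if not counts:
        raise PairsExhausted("no adjacent token pairs remain")
    best = max(counts, key=lambda p: (counts[p], -first_seen[p]))
    return best, counts[best]


def merge_pair(corpus: TokenizedCorpus, pair: tuple[str, str]) -> TokenizedCorpus:
    """Replace every leftmost non-overlapping occurrence of ``pair`` with the
    concatenated token. Sequences without the pair are unchanged."""
    a, b = pair
    merged = a + b
    out: list[list[str]] = []
    for seq in corpus.sequences:
        new: list[str] = []
        i, n = 0, len(seq)
        while i < n:
            if i + 1 < n and seq[i] == a and seq[i + 1] == b:
                new.append(merged)
                i += 2
            else:
                new.append(seq[i])
                i += 1
        out.append(new)
    return TokenizedCorpus(out, corpus.source)


def fit_vocabulary(corpus: list[str], min_frequency: int, max_size: int,
                   kind: str = "generic") -> Vocabulary:
    """Learn a substructure vocabulary by iterative pair merging.

    Merging stops when the most frequent adjacent pair occurs fewer than
    ``min_frequency`` times, when the vocabulary reaches ``max_size`` tokens,
    or when no adjacent pairs remain. The procedure is fully deterministic.
    """
    if min_frequency < 1:
        raise ValueError("min_frequency must be >= 1")
    vocab = initialize_vocabulary(corpus, min_frequency, max_size, kind)
    if max_size < vocab.size:
        raise ValueError(
            f"max_size={max_size} smaller than alphabet size {vocab.size}"
        )
    tokenized = TokenizedCorpus([list(s) for s in corpus], kind)
    while vocab.size < max_size:
        try:
            pair, freq = most_frequent_pair(tokenized)
        except PairsExhausted:
            break
        if freq < min_frequency:
            break
        tokenized = merge_pair(tokenized, pair)
        merged = pair[0] + pair[1]
        vocab.merges.append((pair[0], pair[1], merged))
        if merged not in vocab.token_index:
            vocab.tokens.append(merged)
            vocab.token_index[merged] = len(vocab.tokens) + 1
    return vocab


def encode_sequence(seq: str, vocab: Vocabulary) -> SubstructureEncoding:
    """Decompose ``seq`` by replaying the vocabulary's merges in learned order.

    Characters outside the training alphabet become singleton pass-through
    tokens mapped to the reserved UNK index, so concatenating the emitted
    token texts always reproduces ``seq`` exactly.
    """
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    known = vocab._alphabet_set
    # (text, is_known) pairs; merges never touch unknown passthrough tokens
    work: list[tuple[str, bool]] = [(ch, ch in known) for ch in seq]
    present = {t for t, k in work if k}
    for a, b, merged in vocab.merges:
        if a not in present or b not in present:
            continue
        new: list[tuple[str, bool]] = []
        i, n = 0, len(work)
        changed = False
        while i < n:
            if (
                i + 1 < n
                and work[i][1]
                and work[i + 1][1]
                and work[i][0] == a
                and work[i + 1][0] == b
            ):
                new.append((merged, True))
                i += 2
                changed = True
            else:
                new.append(work[i])
                i += 1
        if changed:
            work = new
            present = {t for t, k in work if k}
    tokens = [t for t, _ in work]
    indices = [vocab.token_index[t] if k else UNK_INDEX for t, k in work]
    return SubstructureEncoding(tokens=tokens, indices=indices, original=seq)


def reconstruct(enc: SubstructureEncoding) -> str:
    """Concatenation of the encoding's token texts (the identity inverse of
    :func:`encode_sequence`)."""
    return "".join(enc.tokens)


# ---------------------------------------------------------------------------
# persistence: plain-text, line-oriented vocabulary files
# ---------------------------------------------------------------------------

_MAGIC = "#crossdti-vocabulary\tv1"


def save_vocabulary(vocab: Vocabulary, path) -> None:
    """Write a vocabulary as text: a header (kind, alphabet in order,
    min_frequency, max_size) then one ``left<TAB>right<TAB>merged`` line per
    merge in learned order."""
    lines = [
        _MAGIC,
        f"#kind\t{vocab.kind}",
        f"#alphabet\t{''.join(vocab.alphabet)}",
        f"#min_frequency\t{vocab.min_frequency}",
        f"#max_size\t{vocab.max_size}",
    ]
    for a, b, m in vocab.merges:
        lines.append(f"{a}\t{b}\t{m}")
    with open(path, "w", encoding="ascii") as fh:
        fh.write("\n".join(lines) + "\n")


def load_vocabulary(path) -> Vocabulary:
    """Inverse of :func:`save_vocabulary`; round-trips exactly."""
    with open(path, encoding="ascii") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _MAGIC:
        raise VocabularyParseError("line 1: missing vocabulary file header")
    header: dict[str, str] = {}
    merges: list[tuple[str, str, str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split("\t", 1)
            if len(parts) != 2:
                raise VocabularyParseError(f"line {lineno}: malformed header line")
            header[parts[0]] = parts[1]
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise VocabularyParseError(
                f"line {lineno}: expected 3 tab-separated fields, got {len(parts)}"
            )
        a, b, m = parts
        if a + b != m:
            raise VocabularyParseError(
                f"line {lineno}: merged token {m!r} != {a!r} + {b!r}"
            )
        merges.append((a, b, m))
    for key in ("alphabet", "min_frequency", "max_size"):
        if key not in header:
            raise VocabularyParseError(f"missing required header field '#{key}'")
    try:
        min_frequency = int(header["min_frequency"])
        max_size = int(header["max_size"])
    except ValueError as exc:
        raise VocabularyParseError(f"non-integer header value: {exc}") from exc
    alphabet = list(header["alphabet"])
    tokens = list(alphabet)
    index = {t: i + 2 for i, t in enumerate(tokens)}
    available = set(tokens)
    for lineno_offset, (a, b, m) in enumerate(merges):
        if a not in available or b not in available:
            warnings.warn(
                f"merge ({a!r},{b!r}) references tokens never produced; kept as-is"
            )
        if m not in index:
            tokens.append(m)
            index[m] = len(tokens) + 1
        available.add(m)
    return Vocabulary(
        tokens=tokens,
        merges=merges,
        alphabet=alphabet,
        min_frequency=min_frequency,
        max_size=max_size,
        kind=header.get("kind", "generic"),
        token_index=index,
    )
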