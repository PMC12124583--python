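"""Embedding tables and 1-D CNN branches for the four feature streams.

Each drug-target pair yields four index sequences — drug substructures, drug
original characters, protein substructures, protein original characters.
Every stream has its own content embedding (a learnable dictionary lookup, one
row per vocabulary entry) plus a learnable position embedding (one row per
sequence position); the two are summed. Each embedded stream then passes
through its own block of three consecutive 1-D convolutions: kernel sizes
(4, 6, 8) for the two drug branches and (4, 8, 12) for the two protein
branches, reflecting the coarser local patterns of protein sequences. No
weights are shared between streams.

Sequences are right-truncated or zero-padded to a per-stream maximum length
``MaxL``; a boolean mask records the real positions, masked embeddings are
zeroed so padding cannot leak into the convolutions, and every later softmax
or max-pool excludes masked positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .tokenizer import PAD_INDEX, UNK_INDEX, Vocabulary, encode_sequence

__all__ = [
    "DRUG_KERNELS",
    "PROTEIN_KERNELS",
    "SMILES_ALPHABET",
    "PROTEIN_ALPHABET",
    "CnnBranchConfig",
    "EmbeddingTable",
    "CnnBranch",
    "FeatureMap",
    "EncodedPair",
    "pad_or_truncate",
    "embed_substructure",
    "embed_original",
    "cnn_encode",
    "encode_pair",
    "char_indices",
]

#: Per-branch kernel sizes for the three stacked convolutions.
DRUG_KERNELS = (4, 6, 8)
PROTEIN_KERNELS = (4, 8, 12)

#: Character inventories for the original-sequence streams. The SMILES set is
#: a fixed 24-symbol subset of legal SMILES characters; anything outside
#: either set maps to the UNK index.
SMILES_ALPHABET = "CNOPSFIBcnos123456=#()[]"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class CnnBranchConfig:
    """Hyper-parameters of one three-layer convolution block."""

    kernel_sizes: tuple[int, int, int]
    channels: tuple[int, int, int]
    activation: str = "relu"
    padding_mode: str = "same"


@dataclass
class FeatureMap:
    """Length x channel features for one stream, with its validity mask."""

    values: Tensor  # (B, L, C)
    mask: np.ndarray  # (B, L) bool


@dataclass
class EncodedPair:
    """Index sequences + masks for one batch of drug-target pairs."""

    drug_sub: np.ndarray
    drug_sub_mask: np.ndarray
    drug_ori: np.ndarray
    drug_ori_mask: np.ndarray
    protein_sub: np.ndarray
    protein_sub_mask: np.ndarray
    protein_ori: np.ndarray
    protein_ori_mask: np.ndarray


def pad_or_truncate(indices, max_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Fix a 1-D index sequence to length ``max_len``.

    Overlong inputs are truncated from the right; short inputs are padded with
    the reserved pad index 0. The returned mask is True exactly at the real
    (non-pad) positions.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    idx = np.asarray(list(indices), dtype=np.int64)
    n = min(len(idx), max_len)
    out = np.full(max_len, PAD_INDEX, dtype=np.int64)
    out[:n] = idx[:max_len]
    mask = np.zeros(max_len, dtype=bool)
    mask[:n] = True
    return out, mask


def char_indices(seq: str, alphabet: str) -> list[int]:
    """Character-level indices into ``alphabet`` (reserved pad=0, unk=1)."""
    table = {ch: i + 2 for i, ch in enumerate(alphabet)}
    return [table.get(ch, UNK_INDEX) for ch in seq]


class EmbeddingTable:
    """Content + position dictionary lookups for one stream.

    ``content`` has one row per vocabulary index (including the two reserved
    indices); ``position`` one row per sequence position up to ``max_len``.
    Row lookup is equivalent to multiplying the transposed weight matrix by a
    one-hot selector.
    """

    def __init__(self, vocab_size: int, max_len: int, dim: int,
                 rng: np.random.Generator):
        scale = 1.0 / np.sqrt(dim)
        self.content = ag.parameter(
            rng.normal(0.0, scale, size=(vocab_size + 2, dim))
        )
        self.position = ag.parameter(rng.normal(0.0, scale, size=(max_len, dim)))
        self.max_len = max_len
        self.dim = dim

    def parameters(self):
        return [self.content, self.position]

    def __call__(self, indices: np.ndarray) -> Tensor:
        return embed_substructure(indices, self)


def _embed(indices: np.ndarray, table: EmbeddingTable) -> Tensor:
    idx = np.asarray(indices)
    if idx.max(initial=0) >= table.content.data.shape[0]:
        raise IndexError(
            f"index {int(idx.max())} out of range for vocabulary of size "
            f"{table.content.data.shape[0] - 2}"
        )
    seq_len = idx.shape[-1]
    if seq_len > table.max_len:
        raise IndexError(f"sequence length {seq_len} exceeds table max {table.max_len}")
    content = ag.embedding(table.content, idx)
    position = ag.embedding(table.position, np.arange(seq_len))
    return ag.add(content, position)


def embed_substructure(indices, table: EmbeddingTable) -> Tensor:
    """Row i = content embedding of index i plus position embedding of i."""
    return _embed(indices, table)


def embed_original(indices, table: EmbeddingTable) -> Tensor:
    """Same lookup scheme over a character-level vocabulary."""
    return _embed(indices, table)


class CnnBranch:
    """Three stacked 1-D convolutions with per-layer activation."""

    def __init__(self, cfg: CnnBranchConfig, in_channels: int,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        cin = in_channels
        for k, cout in zip(cfg.kernel_sizes, cfg.channels):
            bound = np.sqrt(6.0 / (k * cin + k * cout))
            self.weights.append(ag.parameter(rng.uniform(-bound, bound, (k, cin, cout))))
            self.biases.append(ag.parameter(np.zeros(cout)))
            cin = cout
        self.out_channels = cin

    def parameters(self):
        return self.weights + self.biases


def _activation(name: str):
    if name == "relu":
        return ag.relu
    if name == "leaky_relu":
        return ag.leaky_relu
    if name == "identity":
        return lambda t: t
    raise ValueError(f"unknown activation {name!r}")


def cnn_encode(embedded: Tensor, branch: CnnBranch, mask: np.ndarray) -> FeatureMap:
    """Run one stream through its convolution block.

    With ``same`` padding the mask carries through unchanged; with ``valid``
    padding each layer shrinks the mask from the right by kernel-1 positions.
    Masked input rows are zeroed first so padding content never reaches any
    output.
    """
    act = _activation(branch.cfg.activation)
    mode = branch.cfg.padding_mode
    x = ag.mul(embedded, mask[..., None].astype(float))
    m = mask
    for w, b in zip(branch.weights, branch.biases):
        x = act(ag.conv1d(x, w, b, padding=mode))
        if mode == "valid":
            k = w.data.shape[0]
            m = m[..., : m.shape[-1] - (k - 1)]
    return FeatureMap(values=x, mask=m)


@dataclass
class StreamEncoder:
    """Embedding table + CNN branch for one of the four streams."""

    table: EmbeddingTable
    branch: CnnBranch

    def parameters(self):
        return self.table.parameters() + self.branch.parameters()

    def __call__(self, indices: np.ndarray, mask: np.ndarray,
                 original: bool = False) -> FeatureMap:
        embed = embed_original if original else embed_substructure
        return cnn_encode(embed(indices, self.table), self.branch, mask)


def encode_pair(pair: EncodedPair, encoders: dict[str, StreamEncoder]
                ) -> dict[str, FeatureMap]:
    """Process the four streams with their own tables and branches.

    ``encoders`` maps stream names ``protein_ori | drug_ori | protein_sub |
    drug_sub`` to independent :class:`StreamEncoder` instances (no weight
    sharing). Streams absent from ``encoders`` (ablations) are skipped.
    """
    out: dict[str, FeatureMap] = {}
    specs = {
        "protein_ori": (pair.protein_ori, pair.protein_ori_mask, True),
        "drug_ori": (pair.drug_ori, pair.drug_ori_mask, True),
        "protein_sub": (pair.protein_sub, pair.protein_sub_mask, False),
        "drug_sub": (pair.drug_sub, pair.drug_sub_mask, False),
    }
    for name, (idx, mask, is_ori) in specs.items():
        if name in encoders:
            out[name] = encoders[name](idx, mask, original=is_ori)
    return out


def encode_records(smiles_list, protein_list, drug_vocab: Vocabulary | None,
                   protein_vocab: Vocabulary | None, max_lens: dict[str, int]
                   ) -> EncodedPair:
    """Turn raw sequence pairs into fixed-length index arrays + masks.

    ``max_lens`` needs keys ``drug_sub, drug_ori, protein_sub, protein_ori``.
    When a vocabulary is None (the no-substructure ablation) the corresponding
    substructure arrays are filled with padding.
    """
    def stack(seqs, max_len):
        idx = np.empty((len(seqs), max_len), dtype=np.int64)
        msk = np.empty((len(seqs), max_len), dtype=bool)
        for i, s in enumerate(seqs):
            idx[i], msk[i] = pad_or_truncate(s, max_len)
        return idx, msk

    n = len(smiles_list)
    d_ori, d_ori_m = stack(
        [char_indices(s, SMILES_ALPHABET) for s in smiles_list], max_lens["drug_ori"]
    )
    p_ori, p_ori_m = stack(
        [char_indices(p, PROTEIN_ALPHABET) for p in protein_list],
        max_lens["protein_ori"],
    )
    if drug_vocab is not None:
        d_sub, d_sub_m = stack(
            [encode_sequence(s, drug_vocab).indices for s in smiles_list],
            max_lens["drug_sub"],
        )
    else:
        d_sub = np.full((n, max_lens["drug_sub"]), PAD_INDEX, dtype=np.int64)
        d_sub_m = np.zeros_like(d_sub, dtype=bool)
    if protein_vocab is not None:
        p_sub, p_sub_m = stack(
            [encode_sequence(p, protein_vocab).indices for p in protein_list],
            max_lens["protein_sub"],
        )
    else:
        p_sub = np.full((n, max_lens["protein_sub"]), PAD_INDEX, dtype=np.int64)
        p_sub_m = np.zeros_like(p_sub, dtype=bool)
    return EncodedPair(
        drug_sub=d_sub, drug_sub_mask=d_sub_m,
        drug_ori=d_ori, drug_ori_mask=d_ori_m,
        protein_sub=p_sub, protein_sub_mask=p_sub_m,
        protein_ori=p_ori, protein_ori_mask=p_ori_m,
    )
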