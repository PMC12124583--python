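"""Cross co-attention fusion of original and substructure features.

Per stacked layer, four multi-head attention units run over the concatenated
(substructure, original) feature maps of each molecule:

* DA — drug self-attention: queries, keys and values all from the drug matrix,
  fusing the drug's substructure and original views;
* PA — protein self-attention, the mirror image;
* PDA — protein-drug cross-attention: queries from the protein features, keys
  and values from the drug features, measuring how drug components influence
  each protein position;
* DPA — drug-protein cross-attention, the reciprocal unit.

Each unit is scaled dot-product attention, softmax(QK^T / sqrt(d_k)) V, with h
parallel heads concatenated and projected, followed by a feed-forward layer
with dropout, a residual connection and per-row layer normalisation. PDA and
DPA within a layer both read the same (Yp, Yd) produced by that layer's
self-attention units. After the last layer the attended features are blended
half-and-half with the pre-attention CNN feature maps:
Y = 0.5 * Y_attention + 0.5 * Y_cnn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .encoder import FeatureMap

__all__ = [
    "AttentionConfig",
    "AttentionUnit",
    "CpaStack",
    "scaled_dot_attention",
    "multi_head_attention",
    "drug_self_attention",
    "protein_self_attention",
    "protein_drug_attention",
    "drug_protein_attention",
    "residual_ffn",
    "blend_residual",
    "run_cpa_stack",
    "run_stack_features",
]


@dataclass
class AttentionConfig:
    """Shape and regularisation parameters shared by the four units."""

    model_dim: int
    heads: int = 8
    head_dim: int = 16
    dropout_rate: float = 0.1
    num_stacked_layers: int = 1
    ffn_mult: int = 4


def _as3d(t: Tensor) -> tuple[Tensor, bool]:
    if t.ndim == 2:
        return t.reshape((1,) + t.shape), True
    return t, False


def scaled_dot_attention(q, k, v, key_mask=None) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V with masked keys excluded.

    Accepts (L, d) or batched (..., L, d) inputs. ``key_mask`` is boolean over
    the key axis; masked keys get -inf logits before the softmax. A query row
    whose keys are all masked comes out as zeros.
    """
    q, k, v = ag.astensor(q), ag.astensor(k), ag.astensor(v)
    dk = q.shape[-1]
    # scaling Q is algebraically identical to scaling the logits and touches
    # the far smaller array
    logits = ag.matmul(ag.mul(q, 1.0 / np.sqrt(dk)), k.swapaxes(-1, -2))
    mask = None
    if key_mask is not None:
        key_mask = np.asarray(key_mask, dtype=bool)
        mask = np.broadcast_to(
            key_mask[..., None, :], logits.shape
        )
    weights = ag.masked_softmax(logits, mask)
    return ag.matmul(weights, v)


class AttentionUnit:
    """One multi-head attention unit with its feed-forward/normalisation tail."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        self.cfg = cfg
        d, h, dh = cfg.model_dim, cfg.heads, cfg.head_dim
        proj = h * dh

        def linear(nin, nout):
            bound = np.sqrt(6.0 / (nin + nout))
            return (
                ag.parameter(rng.uniform(-bound, bound, (nin, nout))),
                ag.parameter(np.zeros(nout)),
            )

        self.wq, self.bq = linear(d, proj)
        self.wk, self.bk = linear(d, proj)
        self.wv, self.bv = linear(d, proj)
        self.wo, self.bo = linear(proj, d)
        hidden = cfg.ffn_mult * d
        self.w1, self.b1 = linear(d, hidden)
        self.w2, self.b2 = linear(hidden, d)
        self.ln_gain = ag.parameter(np.ones(d))
        self.ln_bias = ag.parameter(np.zeros(d))

    def parameters(self):
        return [
            self.wq, self.bq, self.wk, self.bk, self.wv, self.bv,
            self.wo, self.bo, self.w1, self.b1, self.w2, self.b2,
            self.ln_gain, self.ln_bias,
        ]

    def __call__(self, queries_src: Tensor, kv_src: Tensor,
                 key_mask: np.ndarray | None = None, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        attended = multi_head_attention(queries_src, kv_src, self, self.cfg,
                                        key_mask)
        return residual_ffn(attended, self, self.cfg.dropout_rate, training, rng)


def multi_head_attention(queries_src, kv_src, weights: AttentionUnit,
                         cfg: AttentionConfig, key_mask=None) -> Tensor:
    """Project, attend per head, concatenate the heads, project with W_O."""
    q_src, squeeze = _as3d(ag.astensor(queries_src))
    kv, _ = _as3d(ag.astensor(kv_src))
    h, dh = cfg.heads, cfg.head_dim
    b, lq, _ = q_src.shape
    lk = kv.shape[1]

    def split_heads(t, length):
        # (B, L, h*dh) -> (B, h, L, dh)
        return t.reshape((b, length, h, dh)).swapaxes(1, 2)

    q = split_heads(ag.add(ag.matmul(q_src, weights.wq), weights.bq), lq)
    k = split_heads(ag.add(ag.matmul(kv, weights.wk), weights.bk), lk)
    v = split_heads(ag.add(ag.matmul(kv, weights.wv), weights.bv), lk)
    mask = None
    if key_mask is not None:
        key_mask = np.asarray(key_mask, dtype=bool)
        if key_mask.ndim == 1:
            key_mask = key_mask[None, :]
        mask = key_mask[:, None, :]  # (B, 1, Lk) broadcast over heads/queries
    att = scaled_dot_attention(q, k, v, key_mask=mask)
    merged = att.swapaxes(1, 2).reshape((b, lq, h * dh))
    out = ag.add(ag.matmul(merged, weights.wo), weights.bo)
    if squeeze:
        out = out.reshape(out.shape[1:])
    return out


def residual_ffn(y_update: Tensor, weights: AttentionUnit, dropout_rate: float,
                 training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
    """Layernorm(Y_update + Dropout(FC(Y_update))), rows normalised last-axis."""
    y_update = ag.astensor(y_update)
    hidden = ag.relu(ag.add(ag.matmul(y_update, weights.w1), weights.b1))
    branch = ag.add(ag.matmul(hidden, weights.w2), weights.b2)
    if training and dropout_rate > 0.0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        branch = ag.dropout(branch, dropout_rate, rng, training=True)
    return ag.layer_norm(ag.add(y_update, branch), weights.ln_gain,
                         weights.ln_bias)


def _concat_fm(sub: FeatureMap, ori: FeatureMap) -> FeatureMap:
    """Concatenate (substructure, original) along the length axis."""
    if sub.values.shape[-1] != ori.values.shape[-1]:
        raise ValueError("channel dimensions differ between sub and ori streams")
    values = ag.concat([sub.values, ori.values], axis=-2)
    mask = np.concatenate([sub.mask, ori.mask], axis=-1)
    return FeatureMap(values=values, mask=mask)


def drug_self_attention(d_sub: FeatureMap, d_ori: FeatureMap,
                        weights: AttentionUnit, cfg: AttentionConfig,
                        training: bool = False, rng=None) -> FeatureMap:
    """Fuse the drug's substructure and original views by self-attention over
    their concatenation (substructure rows first)."""
    dcnn = _concat_fm(d_sub, d_ori)
    y = weights(dcnn.values, dcnn.values, key_mask=dcnn.mask,
                training=training, rng=rng)
    return FeatureMap(values=y, mask=dcnn.mask)


def protein_self_attention(p_sub: FeatureMap, p_ori: FeatureMap,
                           weights: AttentionUnit, cfg: AttentionConfig,
                           training: bool = False, rng=None) -> FeatureMap:
    """Mirror of :func:`drug_self_attention` for the protein."""
    return drug_self_attention(p_sub, p_ori, weights, cfg, training, rng)


def protein_drug_attention(yp: FeatureMap, yd: FeatureMap,
                           weights: AttentionUnit, cfg: AttentionConfig,
                           training: bool = False, rng=None) -> FeatureMap:
    """Queries from the protein features; keys and values from the drug."""
    y = weights(yp.values, yd.values, key_mask=yd.mask,
                training=training, rng=rng)
    return FeatureMap(values=y, mask=yp.mask)


def drug_protein_attention(yd: FeatureMap, yp: FeatureMap,
                           weights: AttentionUnit, cfg: AttentionConfig,
                           training: bool = False, rng=None) -> FeatureMap:
    """Queries from the drug features; keys and values from the protein."""
    y = weights(yd.values, yp.values, key_mask=yp.mask,
                training=training, rng=rng)
    return FeatureMap(values=y, mask=yd.mask)


def blend_residual(y_attention: Tensor, y_cnn: Tensor) -> Tensor:
    """The final half-and-half residual blend of attended and CNN features."""
    y_attention, y_cnn = ag.astensor(y_attention), ag.astensor(y_cnn)
    if y_attention.shape != y_cnn.shape:
        raise ValueError(
            f"shape mismatch in residual blend: {y_attention.shape} vs {y_cnn.shape}"
        )
    return ag.add(ag.mul(y_attention, 0.5), ag.mul(y_cnn, 0.5))


class CpaStack:
    """The stacked four-unit cross co-attention weights.

    ``layers`` holds per-layer dicts with units ``da, pa, pda, dpa``. A stack
    with zero layers is the pass-through used to build the no-attention
    ablation semantics explicitly.
    """

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.layers = [
            {
                "da": AttentionUnit(cfg, rng),
                "pa": AttentionUnit(cfg, rng),
                "pda": AttentionUnit(cfg, rng),
                "dpa": AttentionUnit(cfg, rng),
            }
            for _ in range(cfg.num_stacked_layers)
        ]

    def parameters(self):
        params = []
        for layer in self.layers:
            for unit in layer.values():
                params.extend(unit.parameters())
        return params


def run_cpa_stack(p_sub: FeatureMap, p_ori: FeatureMap, d_sub: FeatureMap,
                  d_ori: FeatureMap, weights: CpaStack, cfg: AttentionConfig,
                  training: bool = False, rng=None
                  ) -> tuple[FeatureMap, FeatureMap]:
    """Run the full cross co-attention cascade; returns (Pf, Df).

    Layer flow: DA and PA fuse each molecule's two views; PDA and DPA then
    exchange information across molecules, both reading the same (Yp, Yd);
    every unit ends in its residual feed-forward. After the final layer the
    outputs are blended 0.5/0.5 with the pre-attention concatenated CNN maps.
    With zero layers the CNN maps pass through untouched.
    """
    pcnn = _concat_fm(p_sub, p_ori)
    dcnn = _concat_fm(d_sub, d_ori)
    return run_stack_features(pcnn, dcnn, weights, cfg, training, rng)


def run_stack_features(pcnn: FeatureMap, dcnn: FeatureMap, weights: CpaStack,
                       cfg: AttentionConfig, training: bool = False, rng=None
                       ) -> tuple[FeatureMap, FeatureMap]:
    """Core cascade over already-concatenated per-molecule feature maps.

    Used directly by the no-substructure ablation, whose self-attention runs
    over the original streams alone.
    """
    if not weights.layers:
        return pcnn, dcnn
    yp, yd = pcnn, dcnn
    for layer in weights.layers:
        yd_sa = FeatureMap(
            layer["da"](yd.values, yd.values, key_mask=yd.mask,
                        training=training, rng=rng),
            yd.mask,
        )
        yp_sa = FeatureMap(
            layer["pa"](yp.values, yp.values, key_mask=yp.mask,
                        training=training, rng=rng),
            yp.mask,
        )
        yp = protein_drug_attention(yp_sa, yd_sa, layer["pda"], cfg,
                                    training, rng)
        yd = drug_protein_attention(yd_sa, yp_sa, layer["dpa"], cfg,
                                    training, rng)
    pf = FeatureMap(blend_residual(yp.values, pcnn.values), pcnn.mask)
    df = FeatureMap(blend_residual(yd.values, dcnn.values), dcnn.mask)
    return pf, df
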