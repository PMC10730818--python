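"""The segmentation network: invariant-point-attention encoder with rotary
positional encoding and bi-GRU transitions, a masked transformer decoder with
ALiBi positional penalties, an NDR head and a pIoU confidence head.

The encoder repurposes the AlphaFold2-style IPA block in an input-reversed
fashion: backbone frames are read-only inputs that condition attention, never
updated.  Six weight-shared encoder iterations refine a 512-dimensional
single representation; the decoder appends k learnable domain-mask embedding
tokens, runs a 10-block multi-head attention stack, and scores residues
against conditioned mask embeddings by inner product, giving per-residue
domain probability distributions of shape [N, k] that are invariant to global
rigid motions of the input structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn.autograd import Tensor, concat, softmax
from .nn.layers import BiGRU, LayerNorm, Linear, Module
from .postprocess import (apply_ndr_mask, clean_domain_map, relabel_consecutive,
                          split_disjoint)
from .structio import (BackboneFrames, DomainMap, ProteinChain, build_frames,
                       pairwise_ca_distances)


@dataclass
class ModelConfig:
    """Every architectural hyperparameter.

    Dimensions stated for the published architecture: 512-d single
    representation, 32-d pair embedding, six weight-shared IPA blocks with
    16 heads, k = 20 mask embeddings, a 10-block decoder, NDR bi-GRU hidden
    256 and pIoU bi-GRU hidden 512.  The remaining dimensions (IPA head
    channels, transition GRU hidden size, decoder inner width, projection
    widths) are free hyperparameters pinned so that the trainable parameter
    count reconciles with the published 20.4 M / 16.8 M encoder/decoder
    split.
    """

    single_dim: int = 512
    pair_dim: int = 32
    n_ipa_blocks: int = 6          # weight-shared iterations
    ipa_heads: int = 16
    k_masks: int = 20
    decoder_blocks: int = 10
    decoder_heads: int = 16
    decoder_inner: int = 368       # 16 heads x 23 channels
    ndr_gru_hidden: int = 256
    piou_gru_hidden: int = 512
    transition_gru_hidden: int = 806
    ipa_scalar_dim: int = 16       # scalar channels per head
    ipa_point_qk: int = 4          # query/key points per head
    ipa_point_v: int = 8           # value points per head
    seed: int = 0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if f.name != "seed" and getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        if self.ipa_scalar_dim % 2 != 0:
            raise ValueError("ipa_scalar_dim must be even for rotary encoding")

    @classmethod
    def full(cls, **kw) -> "ModelConfig":
        return cls(**kw)

    @classmethod
    def tiny(cls, **kw) -> "ModelConfig":
        """Desk-scale configuration for CPU training experiments."""
        defaults = dict(
            single_dim=64, pair_dim=8, n_ipa_blocks=3, ipa_heads=4, k_masks=8,
            decoder_blocks=2, decoder_heads=4, decoder_inner=64,
            ndr_gru_hidden=32, piou_gru_hidden=32, transition_gru_hidden=64,
            ipa_scalar_dim=8, ipa_point_qk=4, ipa_point_v=4,
        )
        defaults.update(kw)
        return cls(**defaults)

    def to_dict(self):
        return dataclasses.asdict(self)


@dataclass
class NetworkOutputs:
    domain_logits: Tensor   # [N, k]
    domain_probs: Tensor    # [N, k], rows sum to 1
    ndr_logits: Tensor      # [N, 2]; argmax 0 => NDR
    updated_single: Tensor  # [N, single_dim] (decoder-updated, s'')
    encoder_single: Tensor  # [N, single_dim] (encoder output)


@dataclass
class SegmentationResult:
    domain_map: DomainMap
    ndr_mask: np.ndarray
    piou_per_domain: dict
    ndom: int


# ------------------------------------------------------------ positional enc


def rope_cache(n: int, dim: int, base: float = 10_000.0):
    """cos/sin tables for rotary encoding of `dim`-channel heads."""
    half = dim // 2
    freqs = base ** (-np.arange(half) * 2.0 / dim)
    ang = np.arange(n)[:, None] * freqs[None, :]
    return np.cos(ang), np.sin(ang)


def rope_apply(x: Tensor, cos: np.ndarray, sin: np.ndarray) -> Tensor:
    """Rotate head channels by position (rotate-half convention). x: [h,N,c]."""
    half = x.shape[-1] // 2
    x1 = x[..., :half]
    x2 = x[..., half:]
    c = Tensor(cos)
    s = Tensor(sin)
    return concat([x1 * c - x2 * s, x1 * s + x2 * c], axis=-1)


def alibi_slopes(n_heads: int) -> np.ndarray:
    """Geometric slope sequence 2^(-8 i / h), i = 1..h."""
    return 2.0 ** (-8.0 * np.arange(1, n_heads + 1) / n_heads)


def alibi_bias(n_res: int, k_masks: int, n_heads: int) -> np.ndarray:
    """[h, N+k, N+k] additive attention penalties.

    bias = -slope * |i - j| between residue tokens; zero to/from mask
    tokens, which carry no sequence position.
    """
    m = n_res + k_masks
    bias = np.zeros((n_heads, m, m))
    idx = np.arange(n_res)
    dist = np.abs(idx[:, None] - idx[None, :])
    for h, slope in enumerate(alibi_slopes(n_heads)):
        bias[h, :n_res, :n_res] = -slope * dist
    return bias


# ------------------------------------------------------------------ modules


class Featurizer(Module):
    def __init__(self, cfg: ModelConfig, rng):
        self.single_embed = Linear(20, cfg.single_dim, rng)
        self.pair_embed = Linear(1, cfg.pair_dim, rng)

    def __call__(self, chain: ProteinChain):
        single = self.single_embed(Tensor(chain.one_hot()))
        dist = pairwise_ca_distances(chain).values
        pair = self.pair_embed(Tensor(dist[:, :, None]))
        return single, pair, build_frames(chain)


class IPABlock(Module):
    """AlphaFold2-style invariant point attention (frames read-only)."""

    def __init__(self, cfg: ModelConfig, rng):
        d, h = cfg.single_dim, cfg.ipa_heads
        c, pq, pv = cfg.ipa_scalar_dim, cfg.ipa_point_qk, cfg.ipa_point_v
        self.cfg = cfg
        self.ln = LayerNorm(d)
        self.to_q = Linear(d, h * c, rng)
        self.to_k = Linear(d, h * c, rng)
        self.to_v = Linear(d, h * c, rng)
        self.to_q_pts = Linear(d, h * pq * 3, rng)
        self.to_k_pts = Linear(d, h * pq * 3, rng)
        self.to_v_pts = Linear(d, h * pv * 3, rng)
        self.pair_bias = Linear(cfg.pair_dim, h, rng)
        self.head_gamma = Tensor(np.full(h, 0.5413), requires_grad=True)  # softplus -> ~1
        self.out = Linear(h * (c + cfg.pair_dim + 4 * pv), d, rng)

    def __call__(self, s: Tensor, z: Tensor, frames: BackboneFrames,
                 rope: tuple) -> Tensor:
        cfg = self.cfg
        n = s.shape[0]
        h, c, pq, pv = cfg.ipa_heads, cfg.ipa_scalar_dim, cfg.ipa_point_qk, cfg.ipa_point_v
        R = frames.rotations          # [N,3,3] constants
        t = frames.translations

        sn = self.ln(s)
        q = rope_apply(self.to_q(sn).reshape(n, h, c).transpose(1, 0, 2), *rope)
        k = rope_apply(self.to_k(sn).reshape(n, h, c).transpose(1, 0, 2), *rope)
        v = self.to_v(sn).reshape(n, h, c).transpose(1, 0, 2)

        RT = Tensor(np.transpose(R, (0, 2, 1))[None])  # [1,N,3,3]
        Rc = Tensor(R[None])
        tc = Tensor(t[None, :, None, :])               # [1,N,1,3]

        def to_global(pts_flat, npts):
            local = pts_flat.reshape(n, h, npts, 3).transpose(1, 0, 2, 3)
            return local @ RT + tc                     # row vectors

        qp = to_global(self.to_q_pts(sn), pq)          # [h,N,pq,3]
        kp = to_global(self.to_k_pts(sn), pq)
        vp = to_global(self.to_v_pts(sn), pv)

        qf = qp.reshape(h, n, pq * 3)
        kf = kp.reshape(h, n, pq * 3)
        q2 = (qf * qf).sum(axis=-1, keepdims=True)     # [h,N,1]
        k2 = (kf * kf).sum(axis=-1, keepdims=True).transpose(0, 2, 1)
        d2 = q2 + k2 - 2.0 * (qf @ kf.transpose(0, 2, 1))

        b = self.pair_bias(z).transpose(2, 0, 1)       # [h,N,N]
        gamma = self.head_gamma.softplus().reshape(h, 1, 1)
        w_c = np.sqrt(2.0 / (9.0 * pq))
        w_l = np.sqrt(1.0 / 3.0)
        logits = w_l * (q @ k.transpose(0, 2, 1) * (1.0 / np.sqrt(c))
                        + b - gamma * (w_c / 2.0) * d2)
        attn = softmax(logits, axis=-1)                # [h,N,N]

        o_s = (attn @ v).transpose(1, 0, 2).reshape(n, h * c)
        o_z = (attn.transpose(1, 0, 2) @ z).reshape(n, h * cfg.pair_dim)
        o_p = (attn @ vp.reshape(h, n, pv * 3)).reshape(h, n, pv, 3)
        o_p_local = (o_p - tc) @ Rc                    # back to query frames
        norms = ((o_p_local * o_p_local).sum(axis=-1) + 1e-8).sqrt()
        o_p_flat = o_p_local.transpose(1, 0, 2, 3).reshape(n, h * pv * 3)
        o_n_flat = norms.transpose(1, 0, 2).reshape(n, h * pv)

        return s + self.out(concat([o_s, o_z, o_p_flat, o_n_flat], axis=-1))


class Transition(Module):
    """Bi-GRU transition replacing the transformer feed-forward block."""

    def __init__(self, cfg: ModelConfig, rng):
        self.ln = LayerNorm(cfg.single_dim)
        self.gru = BiGRU(cfg.single_dim, cfg.transition_gru_hidden, rng, n_layers=2)
        self.proj = Linear(2 * cfg.transition_gru_hidden, cfg.single_dim, rng)

    def __call__(self, s: Tensor) -> Tensor:
        return s + self.proj(self.gru(self.ln(s)))


class DecoderBlock(Module):
    def __init__(self, cfg: ModelConfig, rng):
        d, inner = cfg.single_dim, cfg.decoder_inner
        self.cfg = cfg
        self.ln = LayerNorm(d)
        self.to_q = Linear(d, inner, rng)
        self.to_k = Linear(d, inner, rng)
        self.to_v = Linear(d, inner, rng)
        self.out = Linear(inner, d, rng)

    def __call__(self, u: Tensor, bias: np.ndarray) -> Tensor:
        cfg = self.cfg
        m = u.shape[0]
        h = cfg.decoder_heads
        dh = cfg.decoder_inner // h
        un = self.ln(u)
        q = self.to_q(un).reshape(m, h, dh).transpose(1, 0, 2)
        k = self.to_k(un).reshape(m, h, dh).transpose(1, 0, 2)
        v = self.to_v(un).reshape(m, h, dh).transpose(1, 0, 2)
        logits = q @ k.transpose(0, 2, 1) * (1.0 / np.sqrt(dh)) + Tensor(bias)
        attn = softmax(logits, axis=-1)
        o = (attn @ v).transpose(1, 0, 2).reshape(m, h * dh)
        return u + self.out(o)


class NdrHead(Module):
    def __init__(self, cfg: ModelConfig, rng):
        self.gru = BiGRU(cfg.single_dim, cfg.ndr_gru_hidden, rng, n_layers=2)
        self.proj = Linear(2 * cfg.ndr_gru_hidden, 2, rng)

    def __call__(self, s: Tensor) -> Tensor:
        return self.proj(self.gru(s))


class PiouHead(Module):
    def __init__(self, cfg: ModelConfig, rng):
        self.gru = BiGRU(cfg.k_masks, cfg.piou_gru_hidden, rng, n_layers=2)
        self.proj = Linear(2 * cfg.piou_gru_hidden, 1, rng)

    def __call__(self, probs_rows: Tensor) -> Tensor:
        out = self.gru(probs_rows)
        return self.proj(self.gru.final_state(out).reshape(1, -1)).sigmoid().reshape(())


class Decoder(Module):
    def __init__(self, cfg: ModelConfig, rng):
        d = cfg.single_dim
        self.cfg = cfg
        self.mask_embed = Tensor(rng.normal(0.0, 1.0 / np.sqrt(d), (cfg.k_masks, d)),
                                 requires_grad=True)
        self.blocks = [DecoderBlock(cfg, rng) for _ in range(cfg.decoder_blocks)]
        self.proj_s = Linear(d, d, rng)
        self.ln_s = LayerNorm(d)
        self.proj_d = Linear(d, d, rng)
        self.ln_d = LayerNorm(d)
        self.ndr_head = NdrHead(cfg, rng)

    def __call__(self, single: Tensor) -> NetworkOutputs:
        cfg = self.cfg
        n = single.shape[0]
        u = concat([single, self.mask_embed], axis=0)
        bias = alibi_bias(n, cfg.k_masks, cfg.decoder_heads)
        for block in self.blocks:
            u = block(u, bias)
        s2 = self.ln_s(self.proj_s(u[:n]))             # s'': [N, d]
        d2 = self.ln_d(self.proj_d(u[n:]))             # d':  [k, d]
        logits = s2 @ d2.transpose(1, 0) * (1.0 / np.sqrt(cfg.single_dim))
        probs = softmax(logits, axis=-1)
        ndr_logits = self.ndr_head(s2)
        return NetworkOutputs(domain_logits=logits, domain_probs=probs,
                              ndr_logits=ndr_logits, updated_single=s2,
                              encoder_single=single)


class SegmentationNetwork(Module):
    """Full encoder-decoder model; minibatch of one chain per forward pass."""

    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.featurizer = Featurizer(cfg, rng)
        self.ipa = IPABlock(cfg, rng)            # single shared block
        self.transition = Transition(cfg, rng)
        self.decoder = Decoder(cfg, rng)
        self.piou_head = PiouHead(cfg, rng)
        # training-only auxiliary affinity head on the encoder output
        self.aux_head = Linear(cfg.single_dim, cfg.k_masks, rng)

    # --------------------------------------------------------------- stages
    def featurize(self, chain: ProteinChain):
        return self.featurizer(chain)

    def encode(self, single: Tensor, pair: Tensor, frames: BackboneFrames) -> Tensor:
        rope = rope_cache(single.shape[0], self.cfg.ipa_scalar_dim)
        s = single
        for _ in range(self.cfg.n_ipa_blocks):      # same weights every pass
            s = self.ipa(s, pair, frames, rope)
            s = self.transition(s)
        return s

    def decode(self, encoded: Tensor) -> NetworkOutputs:
        return self.decoder(encoded)

    def forward(self, chain: ProteinChain) -> NetworkOutputs:
        single, pair, frames = self.featurize(chain)
        return self.decode(self.encode(single, pair, frames))

    __call__ = forward

    def predict_piou(self, domain_probs: Tensor, dmap: DomainMap) -> dict:
        """Per-domain pIoU from the cleaned assignment's probability rows."""
        out = {}
        for label in sorted(set(dmap.labels[dmap.labels > 0])):
            idx = np.flatnonzero(dmap.labels == label)
            if len(idx) == 0:
                import warnings
                warnings.warn(f"empty domain {label} skipped")
                continue
            rows = domain_probs[idx]
            out[int(label)] = self.piou_head(rows)
        return out

    # ------------------------------------------------------------ inference
    def segment(self, chain: ProteinChain, min_domain: int = 30,
                min_segment: int = 10, contact_thresh: float = 10.0) -> SegmentationResult:
        outputs = self.forward(chain)
        raw = DomainMap(labels=np.argmax(outputs.domain_probs.data, axis=1) + 1)
        cleaned = clean_domain_map(raw, min_domain=min_domain, min_segment=min_segment)
        piou = {k: float(v.data.ravel()[0])
                for k, v in self.predict_piou(outputs.domain_probs, cleaned).items()}
        ndr_mask = np.argmax(outputs.ndr_logits.data, axis=1) == 0
        masked = apply_ndr_mask(cleaned, ndr_mask)
        dist = pairwise_ca_distances(chain)
        split = split_disjoint(masked, dist, contact_thresh=contact_thresh)
        # carry each split component's pIoU over from its parent label
        parent = {}
        for new_lab in set(split.labels[split.labels > 0]):
            src = masked.labels[split.labels == new_lab][0]
            parent[int(new_lab)] = piou.get(int(src), 0.0)
        final = relabel_consecutive(split)
        piou_final = {}
        for new_lab in sorted(set(final.labels[final.labels > 0])):
            old = split.labels[final.labels == new_lab][0]
            piou_final[int(new_lab)] = parent[int(old)]
        return SegmentationResult(domain_map=final,
                                  ndr_mask=ndr_mask,
                                  piou_per_domain=piou_final,
                                  ndom=final.ndom)


# ----------------------------------------------------------- parameter count


def count_parameters(cfg: ModelConfig) -> dict:
    """Trainable parameter totals per component.

    The encoder counts its shared IPA block once regardless of the number of
    encoder iterations.  The training-only auxiliary affinity head is
    reported separately and excluded from the encoder/decoder/total split.
    """
    model = SegmentationNetwork(cfg)
    enc = (model.featurizer.n_parameters() + model.ipa.n_parameters()
           + model.transition.n_parameters())
    dec = model.decoder.n_parameters() + model.piou_head.n_parameters()
    aux = model.aux_head.n_parameters()
    return {"encoder": enc, "decoder": dec, "total": enc + dec, "auxiliary": aux}


# ----------------------------------------------------------------- weights IO


def save_checkpoint(model: SegmentationNetwork, path):
    """Weight archive (.npz) plus a JSON sidecar with the configuration."""
    path = Path(path)
    state = {k: v for k, v in model.state_dict().items()}
    np.savez(path, **state)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"config": model.cfg.to_dict()}, fh, indent=1)


def load_checkpoint(path) -> SegmentationNetwork:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        cfg = ModelConfig(**json.load(fh)["config"])
    model = SegmentationNetwork(cfg)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
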