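"""GAN-based CT protocol harmonization.

The generator is an encoder-decoder with hierarchical feature synthesis:
each scale is reached by pixel unshuffling (a lossless space-to-depth move
used instead of average pooling, so no spatial information is discarded),
residual blocks at every scale apply spatial then channel attention in
sequence, and features from *all* scales are shuffled back to full
resolution and fused before the output projection.  The generator is
residual — it predicts a correction added to its input — so a zero-
initialized output head is exactly the identity map, a natural starting
point for near-identity harmonization.

The discriminator is U-Net-style: an encoder bottleneck yields a global
realness scalar while a skip-connected decoder yields a per-pixel realness
map, giving the generator pixel-wise adversarial feedback.  Training uses
least-squares adversarial terms plus an L1 reconstruction term against the
target protocol (the iterative-reconstruction image by default).
"""

from __future__ import annotations

import hashlib
import json
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .phantom import ProtocolStack, DEFAULT_TARGET


@dataclass(frozen=True)
class HarmonizerSpec:
    base_channels: int = 8
    n_scales: int = 2          # downsampling stages below full resolution
    unshuffle_factor: int = 2
    blocks_per_scale: int = 1
    lambda_rec: float = 100.0
    # quadratic reconstruction term, relative to lambda_rec: the L1 gradient
    # is magnitude-blind, so rare large errors (iodine mapping) need a
    # quadratic pull to be corrected within a short training budget
    lambda_rec_l2: float = 100.0
    lambda_adv: float = 1.0
    lr_generator: float = 2.5e-3
    lr_discriminator: float = 2.5e-3
    patch_size: int = 64
    steps: int = 500
    batch_size: int = 4
    hu_scale: float = 400.0    # HU normalisation divisor
    hu_clip: Tuple[float, float] = (-1100.0, 3000.0)
    target_label: str = DEFAULT_TARGET
    map_target_too: bool = True  # pass the target image through the generator
    seed: int = 0

    def __post_init__(self) -> None:
        if self.unshuffle_factor < 2:
            raise ValueError("unshuffle_factor must be >= 2")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.lambda_rec < 0 or self.lambda_rec_l2 < 0 or self.lambda_adv < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.patch_size % self.unshuffle_factor**self.n_scales:
            raise ValueError(
                "patch size must be divisible by unshuffle_factor ** n_scales"
            )

    @property
    def div(self) -> int:
        return self.unshuffle_factor**self.n_scales

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class AttentionResBlock:
    """Residual block with sequential spatial -> channel attention."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(channels, channels, 3, rng)
        self.conv2 = nn.Conv2d(channels, channels, 3, rng)
        # spatial gate: single-channel sigmoid map from the channel-pooled image
        self.spatial = nn.Conv2d(1, 1, 3, rng)
        # channel gate: squeeze (global average) and excite
        hidden = max(channels // 2, 1)
        self.squeeze = nn.Conv2d(channels, hidden, 1, rng)
        self.excite = nn.Conv2d(hidden, channels, 1, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        y = self.conv2(nn.leaky_relu(self.conv1(x)))
        gate_s = nn.sigmoid(self.spatial(nn.mean_channel(y)))
        y = nn.mul(y, gate_s)
        gate_c = nn.sigmoid(self.excite(nn.leaky_relu(self.squeeze(nn.mean_hw(y)))))
        y = nn.mul(y, gate_c)
        return nn.add(x, y)

    def params(self) -> List[nn.Tensor]:
        return nn.collect_params(
            self.conv1, self.conv2, self.spatial, self.squeeze, self.excite
        )


class Generator:
    def __init__(self, spec: HarmonizerSpec, rng: np.random.Generator):
        self.spec = spec
        c, r = spec.base_channels, spec.unshuffle_factor
        self.stem = nn.Conv2d(1, c, 3, rng)
        self.blocks: List[List[AttentionResBlock]] = []
        self.reducers: List[nn.Conv2d] = []
        self.fusers: List[nn.Conv2d] = []
        ch = c
        for s in range(spec.n_scales + 1):
            self.blocks.append(
                [AttentionResBlock(ch, rng) for _ in range(spec.blocks_per_scale)]
            )
            # project this scale's features to c * r^(2s) channels so pixel
            # shuffling restores full resolution with c channels
            self.fusers.append(nn.Conv2d(ch, c * (r * r) ** s, 1, rng))
            if s < spec.n_scales:
                self.reducers.append(nn.Conv2d(ch * r * r, ch * 2, 1, rng))
                ch *= 2
        self.fuse_conv = nn.Conv2d(c * (spec.n_scales + 1), c, 3, rng)
        self.head = nn.Conv2d(c, 1, 3, rng, zero_init=True)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        r = self.spec.unshuffle_factor
        feats: List[nn.Tensor] = []
        h = nn.leaky_relu(self.stem(x))
        for s in range(self.spec.n_scales + 1):
            for blk in self.blocks[s]:
                h = blk(h)
            up = self.fusers[s](h)
            for _ in range(s):
                up = nn.pixel_shuffle(up, r)
            feats.append(up)
            if s < self.spec.n_scales:
                h = nn.leaky_relu(self.reducers[s](nn.pixel_unshuffle(h, r)))
        fused = nn.leaky_relu(self.fuse_conv(nn.concat_channels(feats)))
        return nn.add(x, self.head(fused))

    def params(self) -> List[nn.Tensor]:
        mods = [self.stem, self.fuse_conv, self.head] + self.reducers + self.fusers
        out = nn.collect_params(*mods)
        for scale in self.blocks:
            for blk in scale:
                out.extend(blk.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())


class Discriminator:
    """U-Net discriminator: a global realness scalar and a per-pixel map."""

    def __init__(self, spec: HarmonizerSpec, rng: np.random.Generator):
        self.spec = spec
        c, r = spec.base_channels, spec.unshuffle_factor
        self.e0 = nn.Conv2d(1, c, 3, rng)
        self.e1 = nn.Conv2d(c * r * r, c * 2, 1, rng)
        self.e2 = nn.Conv2d(c * 2 * r * r, c * 4, 1, rng)
        self.scalar_head = nn.Conv2d(c * 4, 1, 1, rng)
        self.up1 = nn.Conv2d(c * 4, c * 2 * r * r, 1, rng)
        self.d1 = nn.Conv2d(c * 4, c * 2, 3, rng)
        self.up0 = nn.Conv2d(c * 2, c * r * r, 1, rng)
        self.d0 = nn.Conv2d(c * 2, c, 3, rng)
        self.pixel_head = nn.Conv2d(c, 1, 3, rng)

    def __call__(self, x: nn.Tensor) -> Tuple[nn.Tensor, nn.Tensor]:
        r = self.spec.unshuffle_factor
        e0 = nn.leaky_relu(self.e0(x))
        e1 = nn.leaky_relu(self.e1(nn.pixel_unshuffle(e0, r)))
        e2 = nn.leaky_relu(self.e2(nn.pixel_unshuffle(e1, r)))
        scalar = nn.mean(self.scalar_head(nn.mean_hw(e2)))
        u1 = nn.pixel_shuffle(self.up1(e2), r)
        d1 = nn.leaky_relu(self.d1(nn.concat_channels([u1, e1])))
        u0 = nn.pixel_shuffle(self.up0(d1), r)
        d0 = nn.leaky_relu(self.d0(nn.concat_channels([u0, e0])))
        return scalar, self.pixel_head(d0)

    def params(self) -> List[nn.Tensor]:
        return nn.collect_params(
            self.e0, self.e1, self.e2, self.scalar_head,
            self.up1, self.d1, self.up0, self.d0, self.pixel_head,
        )


def build_generator(spec: HarmonizerSpec,
                    rng: Optional[np.random.Generator] = None) -> Generator:
    return Generator(spec, rng or np.random.default_rng(spec.seed))


def build_discriminator(spec: HarmonizerSpec,
                        rng: Optional[np.random.Generator] = None) -> Discriminator:
    return Discriminator(spec, rng or np.random.default_rng(spec.seed + 1))


@dataclass
class TrainedHarmonizer:
    spec: HarmonizerSpec
    generator: Generator
    history: Dict[str, List[float]] = field(default_factory=dict)

    @property
    def target_label(self) -> str:
        return self.spec.target_label

    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = {
            "spec": asdict(self.spec),
            "spec_hash": self.spec.hash(),
            "weights": [p.data for p in self.generator.params()],
            "history": self.history,
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedHarmonizer":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        spec_d = state["spec"]
        spec_d["hu_clip"] = tuple(spec_d["hu_clip"])
        spec = HarmonizerSpec(**spec_d)
        gen = build_generator(spec)
        for p, w in zip(gen.params(), state["weights"]):
            p.data = np.asarray(w, dtype=np.float64)
        return cls(spec, gen, state.get("history", {}))


def _sample_patch(
    stack: ProtocolStack, spec: HarmonizerSpec, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    sources = [l for l in stack.images if l != spec.target_label]
    src = sources[rng.integers(len(sources))]
    h, w = stack.shape
    ps = spec.patch_size
    target = stack.images[spec.target_label]
    # half the patches are centred on enhancing tissue (vessels, kidneys):
    # those pixels define the monoenergetic mapping but are rare, so uniform
    # sampling underweights them badly
    bright = None
    if rng.random() < 0.5:
        rows, cols = np.nonzero(stack.images[src] > 150.0)
        if rows.size:
            j = int(rng.integers(rows.size))
            r0 = int(np.clip(rows[j] - ps // 2, 0, h - ps))
            c0 = int(np.clip(cols[j] - ps // 2, 0, w - ps))
            bright = (r0, c0)
    if bright is None:
        # otherwise bias toward the body: air-only patches carry no
        # information about the soft-tissue mapping
        for _ in range(10):
            r0 = int(rng.integers(0, h - ps + 1))
            c0 = int(rng.integers(0, w - ps + 1))
            if target[r0 : r0 + ps, c0 : c0 + ps].mean() > -300.0:
                break
    x = stack.images[src][r0 : r0 + ps, c0 : c0 + ps]
    y = target[r0 : r0 + ps, c0 : c0 + ps]
    return x / spec.hu_scale, y / spec.hu_scale


def train(
    cohort: Sequence[Tuple[ProtocolStack, object]] | Sequence[ProtocolStack],
    spec: Optional[HarmonizerSpec] = None,
) -> TrainedHarmonizer:
    """Train the generator/discriminator pair on a cohort of protocol stacks.

    Each step samples a batch of (source-protocol, target-protocol) patch
    pairs, updates the discriminator on real/fake least-squares targets
    (both heads, equally weighted), then updates the generator on
    ``lambda_rec * L1 + lambda_adv * adversarial``.  With both weights zero
    no gradient flows and the weights stay untouched.  Deterministic for a
    fixed spec seed.
    """
    spec = spec or HarmonizerSpec()
    stacks = [c[0] if isinstance(c, tuple) else c for c in cohort]
    if not stacks:
        raise ValueError("empty cohort")
    for s in stacks:
        if spec.target_label not in s.images:
            raise ValueError(
                f"stack {s.subject_id} lacks target protocol {spec.target_label!r}"
            )
        if len(s.images) < 2:
            raise ValueError("stacks must contain a source protocol besides the target")

    rng = np.random.default_rng(spec.seed)
    gen = build_generator(spec, np.random.default_rng(spec.seed))
    disc = build_discriminator(spec, np.random.default_rng(spec.seed + 1))
    opt_g = nn.Adam(gen.params(), lr=spec.lr_generator)
    opt_d = nn.Adam(disc.params(), lr=spec.lr_discriminator)
    history: Dict[str, List[float]] = {"rec_l1": [], "gen_adv": [], "disc": []}

    null_objective = (
        spec.lambda_rec == 0 and spec.lambda_rec_l2 == 0 and spec.lambda_adv == 0
    )
    for _ in range(spec.steps):
        xs, ys = zip(
            *(
                _sample_patch(stacks[rng.integers(len(stacks))], spec, rng)
                for _ in range(spec.batch_size)
            )
        )
        x = nn.Tensor(np.stack(xs)[:, None])
        y = nn.Tensor(np.stack(ys)[:, None])
        if null_objective:
            fake = gen(x)
            history["rec_l1"].append(nn.l1_loss(fake, y).item())
            history["gen_adv"].append(0.0)
            history["disc"].append(0.0)
            continue

        fake = gen(x)
        fake_detached = nn.Tensor(fake.data)

        if spec.lambda_adv > 0:
            rs, rp = disc(y)
            fs, fp = disc(fake_detached)
            d_loss = nn.mul_scalar(
                nn.add(
                    nn.add(nn.lsgan_loss(rs, 1.0), nn.lsgan_loss(rp, 1.0)),
                    nn.add(nn.lsgan_loss(fs, 0.0), nn.lsgan_loss(fp, 0.0)),
                ),
                0.5,
            )
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()
            history["disc"].append(d_loss.item())
        else:
            history["disc"].append(0.0)

        rec = nn.l1_loss(fake, y)
        g_loss = nn.mul_scalar(rec, spec.lambda_rec)
        if spec.lambda_rec_l2 > 0:
            g_loss = nn.add(
                g_loss, nn.mul_scalar(nn.l2_loss(fake, y), spec.lambda_rec_l2)
            )
        if spec.lambda_adv > 0:
            gs, gp = disc(fake)
            adv = nn.mul_scalar(
                nn.add(nn.lsgan_loss(gs, 1.0), nn.lsgan_loss(gp, 1.0)), 0.5
            )
            g_loss = nn.add(g_loss, nn.mul_scalar(adv, spec.lambda_adv))
            history["gen_adv"].append(adv.item())
        else:
            history["gen_adv"].append(0.0)
        opt_g.zero_grad()
        # discriminator weights must not absorb generator gradients
        for p in disc.params():
            p.grad = None
        g_loss.backward()
        opt_g.step()
        history["rec_l1"].append(rec.item())

    return TrainedHarmonizer(spec, gen, history)


def _tile_window(ps: int) -> np.ndarray:
    # separable raised-cosine blending window, strictly positive
    w = np.hanning(ps + 2)[1:-1]
    return np.outer(w, w) + 1e-6


def _apply_image(model: TrainedHarmonizer, image: np.ndarray) -> np.ndarray:
    """Tiled inference at the training patch size with overlap blending.

    The attention gates pool over their receptive window, so inference must
    present the generator with patches of the same size it was trained on.
    Tiles overlap by half a patch; the predicted *corrections* are blended
    with a raised-cosine window, which keeps a zero-correction generator an
    exact identity.
    """
    spec = model.spec
    h, w = image.shape
    ps = spec.patch_size
    ph_, pw = max(ps - h, 0), max(ps - w, 0)
    x = image / spec.hu_scale
    if ph_ or pw:
        x = np.pad(x, ((0, ph_), (0, pw)), mode="symmetric")
    hh, ww = x.shape
    stride = ps // 2
    r_starts = sorted({*range(0, hh - ps + 1, stride), hh - ps})
    c_starts = sorted({*range(0, ww - ps + 1, stride), ww - ps})
    win = _tile_window(ps)
    acc = np.zeros_like(x)
    wsum = np.zeros_like(x)
    tiles = [
        (r0, c0, x[r0 : r0 + ps, c0 : c0 + ps]) for r0 in r_starts for c0 in c_starts
    ]
    batch = np.stack([t[2] for t in tiles])[:, None]
    out = model.generator(nn.Tensor(batch)).data[:, 0]
    for (r0, c0, tile), o in zip(tiles, out):
        acc[r0 : r0 + ps, c0 : c0 + ps] += win * (o - tile)
        wsum[r0 : r0 + ps, c0 : c0 + ps] += win
    corr = (acc / wsum)[:h, :w] * spec.hu_scale
    # add in HU space: a zero correction reproduces the input bit-exactly
    return np.clip(image + corr, *spec.hu_clip)


def harmonize(model: TrainedHarmonizer, stack: ProtocolStack) -> ProtocolStack:
    """Map every protocol image of a stack through the trained generator.

    The target image is mapped too by default (a config flag keeps it
    unchanged instead), so the output stack is a fully synthetic set of
    mutually consistent images.
    """
    stack_labels = set(stack.images)
    if model.target_label not in stack_labels:
        raise KeyError(
            f"stack {stack.subject_id} lacks model target {model.target_label!r}"
        )
    images = {}
    for label, img in stack.images.items():
        if label == model.target_label and not model.spec.map_target_too:
            images[label] = img.copy()
        else:
            images[label] = _apply_image(model, img)
    return ProtocolStack(
        subject_id=stack.subject_id,
        images=images,
        target_label=stack.target_label,
        pixel_spacing_mm=stack.pixel_spacing_mm,
    )


def identity_harmonizer(spec: Optional[HarmonizerSpec] = None) -> TrainedHarmonizer:
    """Untrained model: the zero-initialized head makes the generator exact identity."""
    spec = spec or HarmonizerSpec()
    return TrainedHarmonizer(spec, build_generator(spec))
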