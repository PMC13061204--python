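"""HACR-Net: hybrid-attention, channel-retention CNN for MRI super-resolution.

The network maps a low-resolution slice to a x2 or x4 super-resolved one:

* a Hybrid Attention Module (HAM) extracts shallow features and refines them
  with channel attention (squeeze-style gating from globally pooled channel
  descriptors) followed by spatial attention (a 7x7 wide-receptive-field mask
  broadcast across channels);
* a stack of Context-Aware Aggregation Modules (CAAMs), each a residual block
  feeding a shared 3x3 convolution whose output is processed in parallel by a
  Multiscale Feature Aggregation Block (MFAB) and a Channel Retention
  Attention Block (CRAB), fused by a 1x1 projection and added back to the
  module input;
* a reconstruction head: a 3x3 convolution, a global skip from the HAM
  output, PixelShuffle sub-pixel upsampling, and a final 3x3 convolution.

CRAB differs from a classical squeeze-excitation block in that its bottleneck
keeps a deliberately wide intermediate channel width (>= C/2 rather than the
usual C/16), trading parameters for less aggressive descriptor compression.

The published architecture leaves the base width C, the attention reduction
ratios, and the CRAB bottleneck width unstated while printing a total of
1,674k trainable parameters; :func:`calibrate_config` resolves the widths by
exhaustive search against that total, and the result is frozen as
:data:`REFERENCE_CONFIG`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "ConfigError",
    "ModelConfig",
    "REFERENCE_CONFIG",
    "ChannelAttention",
    "SpatialAttention",
    "HAM",
    "ResidualBlock",
    "MFAB",
    "CRAB",
    "CAAM",
    "HACRNet",
    "build_model",
    "count_parameters",
    "parameter_shapes",
    "calibrate_config",
    "conv_macs",
    "save_checkpoint",
    "load_checkpoint",
]


class ConfigError(ValueError):
    """A model configuration violates one of its invariants."""


CONFIG_KEYS = (
    "in_channels",
    "out_channels",
    "base_channels",
    "caam_count",
    "scale",
    "ca_reduction",
    "sa_reduction",
    "crab_width",
    "use_ham",
    "use_mfab",
    "use_crab",
    "seed",
)


@dataclass(frozen=True)
class ModelConfig:
    """All architectural hyperparameters of the network.

    ``crab_width`` is the retained bottleneck width Cw of the CRAB; the
    contract ``Cw >= base_channels / 2`` encodes the block's purpose of
    avoiding narrow squeeze-excitation-style compression.
    """

    in_channels: int = 1
    out_channels: int = 1
    base_channels: int = 46
    caam_count: int = 10
    scale: int = 2
    ca_reduction: int = 2
    sa_reduction: int = 2
    crab_width: int = 51
    use_ham: bool = True
    use_mfab: bool = True
    use_crab: bool = True
    seed: int = 0
    cascade_upsampler: bool = True  # x4 as two x2 PixelShuffle stages

    def validate(self) -> None:
        c = self.base_channels
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigError("in_channels and out_channels must be >= 1")
        if c < 1:
            raise ConfigError("base_channels must be >= 1")
        if self.caam_count < 1:
            raise ConfigError("caam_count must be >= 1")
        if self.scale not in (2, 4):
            raise ConfigError(f"scale must be 2 or 4, got {self.scale}")
        if c % self.ca_reduction:
            raise ConfigError(
                f"base_channels ({c}) must be divisible by ca_reduction "
                f"({self.ca_reduction})"
            )
        if c % self.sa_reduction:
            raise ConfigError(
                f"base_channels ({c}) must be divisible by sa_reduction "
                f"({self.sa_reduction})"
            )
        if self.use_crab and 2 * self.crab_width < c:
            raise ConfigError(
                f"crab_width ({self.crab_width}) must be >= base_channels/2 "
                f"({c}/2): the bottleneck is retained-width by design"
            )
        if not (self.use_mfab or self.use_crab):
            raise ConfigError("at least one of use_mfab/use_crab must be enabled")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in CONFIG_KEYS}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        unknown = set(d) - set(CONFIG_KEYS) - {"cascade_upsampler"}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------


class ChannelAttention(nn.Module):
    """Squeeze-style channel gate: sigmoid(W2 PReLU(W1 GAP(F)))."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if channels % reduction:
            raise ConfigError(
                f"channels ({channels}) not divisible by reduction ({reduction})"
            )
        mid = channels // reduction
        self.reduce = nn.Conv2d(channels, mid, 1, rng)
        self.act = nn.PReLU(mid)
        self.expand = nn.Conv2d(mid, channels, 1, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return nn.sigmoid(self.expand(self.act(self.reduce(nn.global_avg_pool(x)))))


class SpatialAttention(nn.Module):
    """Per-pixel gate from a wide receptive field.

    1x1 channel reduction, a 7x7 convolution over the reduced maps, PReLU,
    then a 1x1 projection to a single-channel sigmoid mask broadcast over all
    channels by the caller.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if channels % reduction:
            raise ConfigError(
                f"channels ({channels}) not divisible by sa_reduction ({reduction})"
            )
        mid = channels // reduction
        self.reduce = nn.Conv2d(channels, mid, 1, rng)
        self.wide = nn.Conv2d(mid, mid, 7, rng)  # padding 3, same size
        self.act = nn.PReLU(mid)
        self.project = nn.Conv2d(mid, 1, 1, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return nn.sigmoid(self.project(self.act(self.wide(self.reduce(x)))))


class HAM(nn.Module):
    """Shallow feature extractor with hybrid (channel then spatial) attention.

    F = PReLU(Conv3x3(I)); F' = CA(F) * F; F1 = SA(F') * F'.
    With attention disabled (ablation) it degrades to the bare shallow conv.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.conv = nn.Conv2d(cfg.in_channels, c, 3, rng)
        self.act = nn.PReLU(c)
        self.enabled = cfg.use_ham
        if cfg.use_ham:
            self.ca = ChannelAttention(c, cfg.ca_reduction, rng)
            self.sa = SpatialAttention(c, cfg.sa_reduction, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        f = self.act(self.conv(x))
        if not self.enabled:
            return f
        fp = nn.mul(self.ca(f), f)
        return nn.mul(self.sa(fp), fp)


class ResidualBlock(nn.Module):
    """f + Conv3x3(PReLU(Conv3x3(PReLU(f))))."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.act1 = nn.PReLU(channels)
        self.conv1 = nn.Conv2d(channels, channels, 3, rng)
        self.act2 = nn.PReLU(channels)
        self.conv2 = nn.Conv2d(channels, channels, 3, rng)

    def forward(self, f: nn.Tensor) -> nn.Tensor:
        return nn.add(f, self.conv2(self.act2(self.conv1(self.act1(f)))))


class MFAB(nn.Module):
    """Multiscale Feature Aggregation Block.

    Two parallel branches over the shared input (3x3->3x3 and 3x3->1x1, each
    pre-activated), summed, re-weighted by a pooled channel attention, plus a
    1x1 high-frequency path:

        A1 = Conv3x3(PReLU(Conv3x3(PReLU(cin))))
        A2 = Conv1x1(PReLU(Conv3x3(PReLU(cin))))
        att = sigmoid(Conv1x1(PReLU(Conv1x1(GAP(A1 + A2)))))
        out = (A1 + A2) * att + Conv1x1(cin)
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        c = channels
        self.a1_act1 = nn.PReLU(c)
        self.a1_conv1 = nn.Conv2d(c, c, 3, rng)
        self.a1_act2 = nn.PReLU(c)
        self.a1_conv2 = nn.Conv2d(c, c, 3, rng)
        self.a2_act1 = nn.PReLU(c)
        self.a2_conv1 = nn.Conv2d(c, c, 3, rng)
        self.a2_act2 = nn.PReLU(c)
        self.a2_conv2 = nn.Conv2d(c, c, 1, rng)
        mid = c // reduction
        self.att_reduce = nn.Conv2d(c, mid, 1, rng)
        self.att_act = nn.PReLU(mid)
        self.att_expand = nn.Conv2d(mid, c, 1, rng)
        self.hf = nn.Conv2d(c, c, 1, rng)

    def forward(self, cin: nn.Tensor) -> nn.Tensor:
        a1 = self.a1_conv2(self.a1_act2(self.a1_conv1(self.a1_act1(cin))))
        a2 = self.a2_conv2(self.a2_act2(self.a2_conv1(self.a2_act1(cin))))
        s = nn.add(a1, a2)
        att = nn.sigmoid(
            self.att_expand(self.att_act(self.att_reduce(nn.global_avg_pool(s))))
        )
        return nn.add(nn.mul(s, att), self.hf(cin))


class CRAB(nn.Module):
    """Channel Retention Attention Block.

    h = Conv3x3(cin); z = GAP(h);
    mask = sigmoid(W_d W_c PReLU(W_b W_a z)) with W_a: C->Cw, W_b, W_c: Cw->Cw,
    W_d: Cw->C; out = h * mask + h.  Cw stays >= C/2 so the channel
    descriptor is never crushed to the narrow widths of classical
    squeeze-excitation.
    """

    def __init__(self, channels: int, width: int, rng: np.random.Generator):
        self.conv = nn.Conv2d(channels, channels, 3, rng)
        self.fc_a = nn.Conv2d(channels, width, 1, rng)
        self.fc_b = nn.Conv2d(width, width, 1, rng)
        self.act = nn.PReLU(width)
        self.fc_c = nn.Conv2d(width, width, 1, rng)
        self.fc_d = nn.Conv2d(width, channels, 1, rng)

    def forward(self, cin: nn.Tensor) -> nn.Tensor:
        h = self.conv(cin)
        z = nn.global_avg_pool(h)
        mask = nn.sigmoid(self.fc_d(self.fc_c(self.act(self.fc_b(self.fc_a(z))))))
        return nn.add(nn.mul(h, mask), h)


class CAAM(nn.Module):
    """Context-Aware Aggregation Module.

    res = ResidualBlock(f); cin = Conv3x3(res);
    out = Conv1x1(concat(MFAB(cin), CRAB(cin))) + f.
    With one branch disabled the fusion projects only the remaining branch.
    Zeroing the fusion projection makes the whole module an exact identity.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.res = ResidualBlock(c, rng)
        self.shared = nn.Conv2d(c, c, 3, rng)
        self.mfab = MFAB(c, cfg.ca_reduction, rng) if cfg.use_mfab else None
        self.crab = CRAB(c, cfg.crab_width, rng) if cfg.use_crab else None
        n_branches = int(cfg.use_mfab) + int(cfg.use_crab)
        # near-zero fusion init: each CAAM starts close to identity so the
        # residual stack does not amplify noise before training (zero-init-
        # residual practice; kept nonzero so gradients reach both branches)
        self.fusion = nn.Conv2d(n_branches * c, c, 1, rng, weight_scale=0.01)

    def forward(self, f: nn.Tensor) -> nn.Tensor:
        cin = self.shared(self.res(f))
        branches = []
        if self.mfab is not None:
            branches.append(self.mfab(cin))
        if self.crab is not None:
            branches.append(self.crab(cin))
        fused = branches[0] if len(branches) == 1 else nn.concat(branches, axis=1)
        return nn.add(self.fusion(fused), f)


class Upsampler(nn.Module):
    """Reconstruction head: Conv3x3 + global skip, PixelShuffle stage(s),
    final Conv3x3 to the output channel count."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        c = cfg.base_channels
        self.pre = nn.Conv2d(c, c, 3, rng)
        # ICNR init: sub-pixel convolutions start as nearest-neighbour
        # upsamplers, the standard checkerboard-free initialization
        if cfg.scale == 2 or cfg.cascade_upsampler:
            n_stages = 1 if cfg.scale == 2 else 2
            self.stages = [
                nn.Conv2d(c, 4 * c, 3, rng, icnr_factor=2) for _ in range(n_stages)
            ]
            self.factors = [2] * n_stages
        else:  # single-stage x4
            self.stages = [nn.Conv2d(c, 16 * c, 3, rng, icnr_factor=4)]
            self.factors = [4]
        self.final = nn.Conv2d(c, cfg.out_channels, 3, rng)

    def forward(self, f: nn.Tensor, f_skip: nn.Tensor) -> nn.Tensor:
        if f.shape != f_skip.shape:
            raise ValueError(
                f"deep features {f.shape} and skip features {f_skip.shape} "
                "must have identical shapes"
            )
        x = nn.add(self.pre(f), f_skip)
        for conv, r in zip(self.stages, self.factors):
            x = nn.pixel_shuffle(conv(x), r)
        return self.final(x)


class HACRNet(nn.Module):
    """The full network; see the module docstring for the dataflow."""

    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.ham = HAM(cfg, rng)
        self.caams = [CAAM(cfg, rng) for _ in range(cfg.caam_count)]
        self.upsampler = Upsampler(cfg, rng)

    def forward(self, x) -> nn.Tensor:
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(x)
        if x.data.ndim != 4:
            raise ValueError(f"expected B x C x H x W input, got shape {x.shape}")
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"input has {x.shape[1]} channels, model expects "
                f"{self.cfg.in_channels}"
            )
        if not np.isfinite(x.data).all():
            raise ValueError("input contains non-finite values")
        f1 = self.ham(x)
        f = f1
        for caam in self.caams:
            f = caam(f)
        return self.upsampler(f, f1)

    def predict(self, x) -> np.ndarray:
        """Inference without tape recording; returns a plain array."""
        with nn.no_grad():
            return self.forward(x).data


def build_model(cfg: ModelConfig) -> HACRNet:
    """Build a seeded, fully initialized network from a validated config."""
    return HACRNet(cfg)


def count_parameters(model: nn.Module) -> int:
    """Exact number of learnable scalars (conv weights, biases, PReLU slopes)."""
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# parameter accounting without building (used by calibration)
# ---------------------------------------------------------------------------


def parameter_shapes(cfg: ModelConfig) -> list[tuple[str, tuple[int, ...]]]:
    """Enumerate every parameter tensor's (name, shape) from the config alone.

    Mirrors the builder layer-for-layer; tests assert that the enumeration
    matches ``count_parameters(build_model(cfg))`` exactly.
    """
    cfg.validate()
    c = cfg.base_channels
    shapes: list[tuple[str, tuple[int, ...]]] = []

    def conv(name: str, cin: int, cout: int, k: int) -> None:
        shapes.append((f"{name}.weight", (cout, cin, k, k)))
        shapes.append((f"{name}.bias", (cout,)))

    def act(name: str, n: int) -> None:
        shapes.append((f"{name}.slope", (n,)))

    conv("ham.conv", cfg.in_channels, c, 3)
    act("ham.act", c)
    if cfg.use_ham:
        mid = c // cfg.ca_reduction
        conv("ham.ca.reduce", c, mid, 1)
        act("ham.ca.act", mid)
        conv("ham.ca.expand", mid, c, 1)
        sm = c // cfg.sa_reduction
        conv("ham.sa.reduce", c, sm, 1)
        conv("ham.sa.wide", sm, sm, 7)
        act("ham.sa.act", sm)
        conv("ham.sa.project", sm, 1, 1)

    for i in range(cfg.caam_count):
        p = f"caams.{i}"
        act(f"{p}.res.act1", c)
        conv(f"{p}.res.conv1", c, c, 3)
        act(f"{p}.res.act2", c)
        conv(f"{p}.res.conv2", c, c, 3)
        conv(f"{p}.shared", c, c, 3)
        if cfg.use_mfab:
            act(f"{p}.mfab.a1_act1", c)
            conv(f"{p}.mfab.a1_conv1", c, c, 3)
            act(f"{p}.mfab.a1_act2", c)
            conv(f"{p}.mfab.a1_conv2", c, c, 3)
            act(f"{p}.mfab.a2_act1", c)
            conv(f"{p}.mfab.a2_conv1", c, c, 3)
            act(f"{p}.mfab.a2_act2", c)
            conv(f"{p}.mfab.a2_conv2", c, c, 1)
            mid = c // cfg.ca_reduction
            conv(f"{p}.mfab.att_reduce", c, mid, 1)
            act(f"{p}.mfab.att_act", mid)
            conv(f"{p}.mfab.att_expand", mid, c, 1)
            conv(f"{p}.mfab.hf", c, c, 1)
        if cfg.use_crab:
            w = cfg.crab_width
            conv(f"{p}.crab.conv", c, c, 3)
            conv(f"{p}.crab.fc_a", c, w, 1)
            conv(f"{p}.crab.fc_b", w, w, 1)
            act(f"{p}.crab.act", w)
            conv(f"{p}.crab.fc_c", w, w, 1)
            conv(f"{p}.crab.fc_d", w, c, 1)
        n_branches = int(cfg.use_mfab) + int(cfg.use_crab)
        conv(f"{p}.fusion", n_branches * c, c, 1)

    conv("upsampler.pre", c, c, 3)
    if cfg.scale == 2 or cfg.cascade_upsampler:
        for s in range(1 if cfg.scale == 2 else 2):
            conv(f"upsampler.stages.{s}", c, 4 * c, 3)
    else:
        conv("upsampler.stages.0", c, 16 * c, 3)
    conv("upsampler.final", c, cfg.out_channels, 3)
    return shapes


def count_from_config(cfg: ModelConfig) -> int:
    """Parameter total from the shape enumeration (no weights allocated)."""
    return int(sum(int(np.prod(s)) for _, s in parameter_shapes(cfg)))


def default_search_space(caam_count: int = 10, scale: int = 2):
    """Candidate (C, rho, rho_s, Cw) grid used to resolve the unstated widths.

    Cw ranges over every integer in [C/2, 3C/2]: the retained-width contract
    sets the floor, and the ceiling admits bottlenecks moderately wider than
    C, which the block's channel-retention rationale permits.  Reduction
    ratios below the classical 8/16 are included because the printed total
    lies between the counts reachable with widths divisible by 8.
    """
    for c in range(32, 65):
        for rho in (2, 3, 4, 6, 8, 16):
            if c % rho:
                continue
            for rho_s in (2, 3, 4, 6, 8, 16):
                if c % rho_s:
                    continue
                for cw in range((c + 1) // 2, 3 * c // 2 + 1):
                    yield ModelConfig(
                        base_channels=c,
                        caam_count=caam_count,
                        scale=scale,
                        ca_reduction=rho,
                        sa_reduction=rho_s,
                        crab_width=cw,
                    )


def calibrate_config(
    target_params: int,
    caam_count: int = 10,
    scale: int = 2,
    search_space=None,
) -> tuple[ModelConfig, int]:
    """Pick the config whose parameter total is nearest ``target_params``.

    Ties break toward smaller base width, then smaller CRAB width.  Returns
    the winning config and its achieved count.
    """
    if search_space is None:
        search_space = default_search_space(caam_count, scale)
    best = None
    for cfg in search_space:
        n = count_from_config(cfg)
        key = (abs(n - target_params), cfg.base_channels, cfg.crab_width)
        if best is None or key < best[0]:
            best = (key, cfg, n)
    if best is None:
        raise ConfigError("empty search space")
    return best[1], best[2]


def conv_macs(cfg: ModelConfig, height: int, width: int) -> int:
    """Informational multiply-accumulate count for one forward pass.

    Convention: one MAC per (output position x kernel element x input
    channel) for every convolution, spatial maps at the LR resolution until
    each PixelShuffle stage doubles them; attention 1x1 convolutions on
    pooled descriptors contribute at 1x1 resolution.  Reported for context
    only, never asserted against published FLOP figures whose convention is
    unknown.
    """
    cfg.validate()
    total = 0
    hw = height * width
    for name, shape in parameter_shapes(cfg):
        if not name.endswith("weight"):
            continue
        cout, cin, k, _ = shape
        pooled = ".ca." in name or ".att_" in name or ".fc_" in name
        if pooled:
            area = 1
        elif name.startswith("upsampler.final"):
            area = hw * cfg.scale**2
        elif name.startswith("upsampler.stages.1"):
            area = hw * 4
        else:
            area = hw
        total += cout * cin * k * k * area
    return int(total)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(model: HACRNet, path) -> None:
    """Write the weights (npz blob) plus a JSON config sidecar."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(path.suffix + ".config.json")
    sidecar.write_text(json.dumps(model.cfg.to_dict(), indent=1))


def load_checkpoint(path, cfg: ModelConfig | None = None) -> HACRNet:
    """Rebuild a model from a checkpoint; if ``cfg`` is given it must match
    the sidecar config exactly (the first mismatched key is reported)."""
    path = Path(path)
    if path.suffix != ".npz" and not path.exists():
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = path.with_suffix(path.suffix + ".config.json")
    stored = ModelConfig.from_dict(json.loads(sidecar.read_text()))
    if cfg is not None:
        for key in CONFIG_KEYS:
            if getattr(cfg, key) != getattr(stored, key):
                raise ConfigError(
                    f"checkpoint config mismatch on '{key}': "
                    f"expected {getattr(cfg, key)}, stored {getattr(stored, key)}"
                )
    model = HACRNet(stored)
    with np.load(path) as blob:
        model.load_state_dict({k: blob[k] for k in blob.files})
    return model


#: Widths resolved by ``calibrate_config(1_674_000)`` over the default search
#: space (achieved count 1,674,251) and frozen as the package reference
#: configuration (x2, 10 CAAMs).  The dataclass defaults above are this
#: configuration, so ``ModelConfig()`` is the reference model.
REFERENCE_CONFIG = ModelConfig()
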