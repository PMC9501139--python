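"""Two-path fully convolutional segmentation network for lateral spine
radiographs.

The architecture couples a U-Net-style encoder/decoder (the downsampling
path) with a shallow spatial path of stride-2 convolutions that preserves
high-resolution detail, fusing the two with feature fusion modules (FFM):
concatenate -> project -> normalize -> global pool -> sigmoid weight ->
multiply -> add.  Skip connections copy encoder features to the matching
decoder blocks, a dropout layer sits between the two bridge convolutions,
and the final layer is a 1x1 convolution with per-channel sigmoid output.

Layer apportionment in the default configuration:

====================  =====
4 encoder blocks x 2      8
bridge                    2
4 decoder blocks x 2      8
spatial path              3
FFM projections           3
decoder up-projections    4
final 1x1                 1
total                    29
====================  =====

Training minimizes the weighted pixel-wise cross entropy
``E = -sum_x w(x) log p(x)`` with p the softmax probability of the true
class and w a per-pixel weight map (uniform 1 by default), using the Adam
optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import autograd as ag
from .autograd import Adam, BatchNorm2d, Conv2d, Param, Tensor

_ENCODER_DEPTH = 4  # fixed number of 2x2 poolings; input must divide by 16


class ConfigError(ValueError):
    """Configuration cannot realize the declared architecture."""


@dataclass(frozen=True)
class NetConfig:
    """Architecture configuration.

    The default realizes the reference design: 512x512x3 input, 5 output
    channels and 29 convolution layers overall.  ``output_channels=3``
    selects the collapsed background/vertebra/sacrum class dialect used by
    the detection pipeline; per-vertebra identity is then recovered
    downstream by connected components.
    """

    input_height: int = 512
    input_width: int = 512
    input_channels: int = 3
    output_channels: int = 5
    spatial_path_layers: int = 3
    dropout_rate: float = 0.5
    base_filters: int = 16
    expected_conv_layers: int | None = None

    def validate(self) -> None:
        if not 1 <= self.spatial_path_layers <= _ENCODER_DEPTH - 1:
            raise ConfigError(
                f"spatial_path_layers must be in 1..{_ENCODER_DEPTH - 1} so every "
                "spatial level has an encoder skip to fuse with"
            )
        if self.output_channels < 2:
            raise ConfigError("output_channels must be >= 2")
        div = 2 ** _ENCODER_DEPTH
        if self.input_height % div or self.input_width % div:
            raise ConfigError(f"input size must be divisible by {div}")
        if self.expected_conv_layers is not None and (
            self.expected_conv_layers != self.conv_layer_count
        ):
            raise ConfigError(
                f"layer allocation yields {self.conv_layer_count} convolutions, "
                f"not the declared {self.expected_conv_layers}"
            )

    @property
    def conv_layer_count(self) -> int:
        # encoder 8 + bridge 2 + decoder 8 + up-projections 4 + final 1 = 23,
        # plus one spatial-path conv and one FFM projection per fusion level
        return 23 + 2 * self.spatial_path_layers


@dataclass
class TrainSpec:
    """Training hyper-parameters.

    ``weight_map`` is the per-pixel loss weight w(x); None means uniform 1.
    """

    learning_rate: float = 1e-4
    epochs: int = 200
    optimizer: str = "adam"
    weight_map: np.ndarray | None = None
    seed: int = 0
    batch_size: int = 4

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adaptive-moment optimizer is supported")


class _DoubleConv:
    def __init__(self, cin, cout, rng):
        self.c1 = Conv2d(cin, cout, 3, rng=rng)
        self.n1 = BatchNorm2d(cout)
        self.c2 = Conv2d(cout, cout, 3, rng=rng)
        self.n2 = BatchNorm2d(cout)

    def __call__(self, x, training):
        x = ag.relu(self.n1(self.c1(x), training))
        return ag.relu(self.n2(self.c2(x), training))

    def convs(self):
        return [self.c1, self.c2]

    def params(self):
        return self.c1.params() + self.n1.params() + self.c2.params() + self.n2.params()


class _FFM:
    """Feature fusion: concat -> 1x1 projection -> BN/ReLU -> global pool
    -> sigmoid channel weight -> multiply -> add."""

    def __init__(self, cin, cout, rng):
        self.proj = Conv2d(cin, cout, 1, rng=rng)
        self.norm = BatchNorm2d(cout)

    def __call__(self, skip, spatial, training):
        z = ag.concat(skip, spatial, axis=1)
        z = ag.relu(self.norm(self.proj(z), training))
        w = ag.sigmoid(ag.global_avg_pool(z))
        return ag.add(ag.mul(z, w), z)

    def convs(self):
        return [self.proj]

    def params(self):
        return self.proj.params() + self.norm.params()


class SpineSegNet:
    """The assembled network.  Fully convolutional: any input whose sides
    divide by 16 maps to an output of the same spatial size."""

    def __init__(self, config: NetConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        self._rng = np.random.default_rng(seed + 1)  # dropout stream
        f = config.base_filters
        cin = config.input_channels

        enc_ch = [f, 2 * f, 4 * f, 8 * f]
        self.encoder = []
        c = cin
        for ch in enc_ch:
            self.encoder.append(_DoubleConv(c, ch, rng))
            c = ch
        self.bridge_c1 = Conv2d(8 * f, 16 * f, 3, rng=rng)
        self.bridge_n1 = BatchNorm2d(16 * f)
        self.bridge_c2 = Conv2d(16 * f, 16 * f, 3, rng=rng)
        self.bridge_n2 = BatchNorm2d(16 * f)

        # spatial path: stride-2 convs at 1/2, 1/4, ... resolution
        self.spatial = []
        c = cin
        for k in range(config.spatial_path_layers):
            ch = enc_ch[min(k, len(enc_ch) - 1)]
            self.spatial.append(Conv2d(c, ch, 3, stride=2, rng=rng))
            c = ch
        self.spatial_norms = [BatchNorm2d(layer.cout) for layer in self.spatial]

        # FFMs fuse spatial-path output k (at 1/2^(k+1)) with encoder skip k+1
        self.ffms = []
        for k in range(config.spatial_path_layers):
            skip_ch = enc_ch[k + 1] if k + 1 < len(enc_ch) else 16 * f
            sp_ch = self.spatial[k].cout
            self.ffms.append(_FFM(skip_ch + sp_ch, skip_ch, rng))

        self.upconvs = []
        self.decoder = []
        c = 16 * f
        for ch in reversed(enc_ch):
            self.upconvs.append(Conv2d(c, ch, 1, rng=rng))
            self.decoder.append(_DoubleConv(2 * ch, ch, rng))
            c = ch
        self.final = Conv2d(f, config.output_channels, 1, rng=rng)

    # -- introspection -----------------------------------------------------
    def conv_layers(self) -> dict[str, list[Conv2d]]:
        paths = {
            "encoder": [c for blk in self.encoder for c in blk.convs()],
            "bridge": [self.bridge_c1, self.bridge_c2],
            "spatial_path": list(self.spatial),
            "ffm": [c for m in self.ffms for c in m.convs()],
            "decoder_up": list(self.upconvs),
            "decoder": [c for blk in self.decoder for c in blk.convs()],
            "final": [self.final],
        }
        return paths

    def summary(self) -> dict:
        paths = self.conv_layers()
        return {
            "conv_layer_count": sum(len(v) for v in paths.values()),
            "paths": {k: [f"{c.cin}->{c.cout} k{c.kernel} s{c.stride}" for c in v]
                      for k, v in paths.items()},
            "spatial_path": {
                "layers": len(self.spatial),
                "stride": 2,
                "batch_norm": True,
                "activation": "relu",
            },
            "input_shape": [self.config.input_height, self.config.input_width,
                            self.config.input_channels],
            "output_shape": [self.config.input_height, self.config.input_width,
                             self.config.output_channels],
            "final_activation": "sigmoid (per channel)",
            "dropout": {"rate": self.config.dropout_rate,
                        "location": "between the two bridge convolutions"},
        }

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for blk in self.encoder + self.decoder:
            ps += blk.params()
        ps += self.bridge_c1.params() + self.bridge_n1.params()
        ps += self.bridge_c2.params() + self.bridge_n2.params()
        for layer, norm in zip(self.spatial, self.spatial_norms):
            ps += layer.params() + norm.params()
        for m in self.ffms:
            ps += m.params()
        for up in self.upconvs:
            ps += up.params()
        ps += self.final.params()
        return ps

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray | Tensor, training: bool = False) -> Tensor:
        """Logits (N, C, H, W) for an NCHW input batch."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        skips = []
        h = x
        for blk in self.encoder:
            h = blk(h, training)
            skips.append(h)
            h = ag.maxpool2x2(h)
        h = ag.relu(self.bridge_n1(self.bridge_c1(h), training))
        h = ag.dropout(h, self.config.dropout_rate, self._rng, training)
        h = ag.relu(self.bridge_n2(self.bridge_c2(h), training))

        sp = x
        for k, (layer, norm) in enumerate(zip(self.spatial, self.spatial_norms)):
            sp = ag.relu(norm(layer(sp), training))
            if k + 1 < len(skips):
                skips[k + 1] = self.ffms[k](skips[k + 1], sp, training)

        for up, blk, skip in zip(self.upconvs, self.decoder, reversed(skips)):
            h = up(ag.upsample_nearest2(h))
            h = blk(ag.concat(h, skip, axis=1), training)
        return self.final(h)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-channel sigmoid probabilities in [0, 1]."""
        logits = self.forward(x, training=False)
        return 1.0 / (1.0 + np.exp(-np.clip(logits.data, -60, 60)))


def build_network(config: NetConfig | None = None, seed: int = 0
                  ) -> tuple[SpineSegNet, dict]:
    """Construct the network and return it with its architecture summary."""
    config = config if config is not None else NetConfig()
    net = SpineSegNet(config, seed=seed)
    summary = net.summary()
    if summary["conv_layer_count"] != config.conv_layer_count:
        raise ConfigError("realized architecture disagrees with the allocation")
    return net, summary


# ---------------------------------------------------------------------------
# data preparation, training, inference


def collapse_mask(mask: np.ndarray) -> np.ndarray:
    """7-label mask (1..5 vertebrae, 6 sacrum) -> 3-class (0/1/2)."""
    out = np.zeros_like(mask)
    out[(mask >= 1) & (mask <= 5)] = 1
    out[mask == 6] = 2
    return out


def _prep_image(image: np.ndarray, config: NetConfig) -> np.ndarray:
    """To float CHW in [0, 1] at network size."""
    img = np.asarray(image, dtype=np.float64)
    if img.dtype != np.float64:
        img = img.astype(np.float64)
    if img.max() > 1.5:
        img = img / 255.0
    if img.ndim == 2:
        img = np.repeat(img[None], config.input_channels, axis=0)
    elif img.ndim == 3:
        img = img.transpose(2, 0, 1)[: config.input_channels]
    if img.shape[1:] != (config.input_height, config.input_width):
        img = np.stack([
            resize(ch, (config.input_height, config.input_width),
                   preserve_range=True, anti_aliasing=True)
            for ch in img
        ])
    return img


def _prep_mask(mask: np.ndarray, config: NetConfig) -> np.ndarray:
    m = np.asarray(mask)
    if m.max(initial=0) > 2 and config.output_channels <= 6:
        m = collapse_mask(m)
    if int(m.max(initial=0)) >= config.output_channels:
        raise ValueError(
            f"mask label {int(m.max())} exceeds {config.output_channels} channels"
        )
    if m.shape != (config.input_height, config.input_width):
        m = resize(m.astype(float), (config.input_height, config.input_width),
                   order=0, preserve_range=True, anti_aliasing=False)
    return m.astype(np.int64)


def train(net: SpineSegNet, cases, spec: TrainSpec | None = None
          ) -> tuple[SpineSegNet, list[float]]:
    """Train in place; returns the network and per-epoch mean loss.

    ``cases`` is a list of phantom cases or of (image, mask) pairs; masks
    may use either dialect (7-label masks are collapsed when the network
    has fewer output channels).
    """
    spec = spec if spec is not None else TrainSpec()
    spec.validate()
    config = net.config
    images, masks = [], []
    for case in cases:
        if hasattr(case, "image") and hasattr(case, "mask"):
            img, msk = case.image, case.mask
        else:
            img, msk = case
        images.append(_prep_image(img, config))
        masks.append(_prep_mask(msk, config))
    x = np.stack(images)
    y = np.stack(masks)

    rng = np.random.default_rng(spec.seed)
    opt = Adam(net.params(), lr=spec.learning_rate)
    history: list[float] = []
    n = len(x)
    bs = min(spec.batch_size, n)
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            sel = order[start:start + bs]
            logits = net.forward(x[sel], training=True)
            loss = ag.softmax_cross_entropy(logits, y[sel], spec.weight_map)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    return net, history


def predict_mask(net: SpineSegNet, image: np.ndarray) -> np.ndarray:
    """Segment one image (2-D grayscale or H x W x C) into a label mask.

    The input is resized to the network size, classified per pixel by
    argmax over the channel probabilities, and the label map is rescaled
    back to the original size with nearest-neighbor interpolation.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    orig_shape = image.shape[:2]
    x = _prep_image(image, net.config)[None]
    probs = net.predict_proba(x)[0]
    labels = probs.argmax(axis=0).astype(np.uint8)
    if labels.shape != orig_shape:
        labels = resize(labels.astype(float), orig_shape, order=0,
                        preserve_range=True, anti_aliasing=False).astype(np.uint8)
    return labels


def predict_masks(net: SpineSegNet, images) -> list[np.ndarray]:
    return [predict_mask(net, im) for im in images]


def pixel_cross_entropy(probs: np.ndarray, labels: np.ndarray,
                        weights: np.ndarray | None = None,
                        eps: float = 1e-12) -> float:
    """Reference weighted cross entropy E = -sum w(x) log p(x) on given
    class probabilities (C, H, W); used for loss-identity checks."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    h, w = labels.shape
    p_true = probs[labels, np.arange(h)[:, None], np.arange(w)[None, :]]
    wmap = np.ones_like(p_true) if weights is None else np.asarray(weights, float)
    return float(-(wmap * np.log(np.clip(p_true, eps, 1.0))).sum())
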