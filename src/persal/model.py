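"""Saliency-prediction models: universal generator and personalized variant.

The universal model (``UsmModel``) is a VGG16-style convolutional encoder
(13 conv layers, 4 stride-2 max poolings, so the feature grid is 1/16 of
the input) followed by a mirrored convolutional decoder (4 nearest-
neighbour upsamplings back to input size) with a final 1-channel ReLU
layer, trained with MSE against universal saliency maps.

The personalized model (``PsmModel``) shares the encoder/decoder and adds
a user-encoding mechanism: the subject's binary interest vector I_n
(length M) is mapped by a Linear layer to a single C-channel token, passed
through a stack of Transformer encoder blocks, and supplied as the
key/value context to Transformer decoder blocks whose queries are the
(W*H) image-feature tokens.  Because there is exactly one key, each
cross-attention softmax collapses to weight 1 and the attention output
broadcasts the (projected) user value to every image token — the
conditioning signal enters purely through this broadcast and the residual
stream.

``channel_scale`` scales every layer depth by a common fraction so tiny
desk-scale instances (e.g. 1/16 width, C = 32) run the identical graph as
the full-width model (C = 512).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .nn import (
    Conv2d,
    Linear,
    Module,
    MultiHeadAttention,
    TransformerDecoderBlock,
    TransformerEncoderBlock,
    trunc_normal,
)
from .saliency import SaliencyMap

__all__ = [
    "PsmModelConfig",
    "FeatureTensor",
    "UserToken",
    "UsmModel",
    "PsmModel",
    "cross_attend",
    "save_checkpoint",
    "load_checkpoint",
    "describe_layers",
]

# Table-ordered layer depths at full width; "M" = 2x2 max pool, "U" = 2x upsample
ENCODER_SPEC = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
                512, 512, 512, "M", 512, 512, 512]
DECODER_SPEC = [512, 512, 512, "U", 512, 512, 512, "U", 256, 256, 256, "U",
                128, 128, "U", 64, 64]
FULL_CHANNELS = 512  # encoder output depth C at channel_scale 1


def _scaled(depth: int, scale: float) -> int:
    return max(1, int(round(depth * scale)))


@dataclass
class PsmModelConfig:
    """Architecture hyperparameters shared by the USM and PSM models.

    Defaults are the full-scale optimum: C = 512 feature channels, a
    4-layer Transformer encoder, 9-layer Transformer decoder and 256
    attention heads, with an 800-dimensional user vector.
    """

    # (W0, H0): 1/4 of a 1920x1080 capture, height padded to the next
    # multiple of 16 so four stride-2 poolings divide evenly
    input_size: tuple[int, int] = (480, 272)
    channel_scale: float = 1.0
    M: int = 800
    enc_layers: int = 4
    dec_layers: int = 9
    heads: int = 256
    seed: int = 0
    logit_scale: str = "sqrt_dk"  # "sqrt_dk" | "dk"
    decoder_self_attention: bool = True
    positional_embedding: bool = False

    @property
    def C(self) -> int:
        return _scaled(FULL_CHANNELS, self.channel_scale)

    @property
    def d_k(self) -> int:
        return self.C // self.heads

    def __post_init__(self):
        w, h = self.input_size
        if w % 16 or h % 16:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 16; "
                f"pad to ({16 * ((w + 15) // 16)}, {16 * ((h + 15) // 16)})"
            )
        if self.C % self.heads:
            raise ValueError(f"C={self.C} not divisible by heads={self.heads}")
        if self.enc_layers < 0 or self.dec_layers < 1:
            raise ValueError("enc_layers must be >= 0 and dec_layers >= 1")


@dataclass
class FeatureTensor:
    """Encoder output: C channels on a (H/16, W/16) grid.

    ``as_matrix`` flattens the grid row-major (row y, then column x) to a
    (W*H) x C matrix whose row y*W + x is the C-vector of pixel (x, y);
    ``from_matrix`` inverts it losslessly.
    """

    tensor: Tensor  # (C, H, W)

    @property
    def C(self) -> int:
        return self.tensor.shape[0]

    @property
    def H(self) -> int:
        return self.tensor.shape[1]

    @property
    def W(self) -> int:
        return self.tensor.shape[2]

    def as_matrix(self) -> Tensor:
        c, h, w = self.tensor.shape
        return self.tensor.reshape(c, h * w).transpose()

    @staticmethod
    def from_matrix(mat: Tensor, H: int, W: int) -> "FeatureTensor":
        c = mat.shape[1]
        return FeatureTensor(mat.transpose().reshape(c, H, W))


@dataclass
class UserToken:
    """The user-encoding output: a single C-channel token (1 x C)."""

    tensor: Tensor

    def __post_init__(self):
        if self.tensor.shape[0] != 1:
            raise ValueError(f"user token must have exactly one row, got {self.tensor.shape}")


def _image_to_tensor(image: np.ndarray) -> Tensor:
    """(H, W, 3) or (H, W) array in [0, 1] -> (3, H, W) Tensor."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got shape {image.shape}")
    return Tensor(image.transpose(2, 0, 1))


class _ConvStack(Module):
    def __init__(self, spec, in_ch: int, scale: float, rng, final_1x1: bool = False):
        layers = []
        ch = in_ch
        for item in spec:
            if item in ("M", "U"):
                layers.append(item)
            else:
                out_ch = _scaled(item, scale)
                layers.append(Conv2d(ch, out_ch, 3, 1, rng))
                ch = out_ch
        if final_1x1:
            head = Conv2d(ch, 1, 1, 0, rng)
            # output head starts near-flat positive: every ReLU output unit
            # is alive at step 0 (so gradients reach the whole stack) and
            # the bias first learns the base rate
            head.weight.data *= 0.1
            head.bias.data[:] = 0.1
            layers.append(head)
            ch = 1
        self.layers = layers
        self.out_channels = ch

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            if layer == "M":
                x = x.maxpool2()
            elif layer == "U":
                x = x.upsample2()
            else:
                x = layer(x).relu()
        return x


class UsmModel(Module):
    """Universal saliency generator: convolutional encoder + decoder."""

    def __init__(self, config: PsmModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = _ConvStack(ENCODER_SPEC, 3, config.channel_scale, rng)
        self.decoder = _ConvStack(
            DECODER_SPEC, self.encoder.out_channels, config.channel_scale, rng,
            final_1x1=True,
        )

    def encode_image(self, image: np.ndarray) -> FeatureTensor:
        x = _image_to_tensor(image)
        if x.shape[1] % 16 or x.shape[2] % 16:
            h, w = x.shape[1], x.shape[2]
            raise ValueError(
                f"image {w}x{h} not divisible by 16; pad to "
                f"{16 * ((w + 15) // 16)}x{16 * ((h + 15) // 16)}"
            )
        return FeatureTensor(self.encoder(x))

    def decode_features(self, features: FeatureTensor) -> Tensor:
        out = self.decoder(features.tensor)
        return out.reshape(out.shape[1], out.shape[2])  # (H, W), non-negative

    def forward(self, image: np.ndarray) -> Tensor:
        return self.decode_features(self.encode_image(image))

    def predict(self, image: np.ndarray) -> SaliencyMap:
        return SaliencyMap(values=self.forward(image).data.copy(), kind="predicted")


class PsmModel(Module):
    """Personalized saliency model: UsmModel graph + user-encoding mechanism."""

    def __init__(self, config: PsmModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = _ConvStack(ENCODER_SPEC, 3, config.channel_scale, rng)
        self.decoder = _ConvStack(
            DECODER_SPEC, self.encoder.out_channels, config.channel_scale, rng,
            final_1x1=True,
        )
        C = config.C
        # user-encoding mechanism
        self.user_linear = Linear(config.M, C, rng, init="trunc_normal")
        self.user_encoder = [
            TransformerEncoderBlock(C, config.heads, rng, config.logit_scale)
            for _ in range(config.enc_layers)
        ]
        self.fusion_decoder = [
            TransformerDecoderBlock(
                C, config.heads, rng, config.logit_scale,
                self_attention=config.decoder_self_attention,
            )
            for _ in range(config.dec_layers)
        ]
        if config.positional_embedding:
            w0, h0 = config.input_size
            n_tokens = (w0 // 16) * (h0 // 16)
            self.pos_embedding = Tensor(
                trunc_normal(rng, (n_tokens, C)), requires_grad=True
            )
        else:
            self.pos_embedding = None

    # -- pieces ----------------------------------------------------------

    def encode_image(self, image: np.ndarray) -> FeatureTensor:
        return UsmModel.encode_image(self, image)  # type: ignore[arg-type]

    def decode_features(self, features: FeatureTensor) -> Tensor:
        return UsmModel.decode_features(self, features)  # type: ignore[arg-type]

    def embed_user(self, interest: np.ndarray) -> UserToken:
        """Linear M -> C map of the interest vector (EmbUserCharacteristics)."""
        interest = np.asarray(interest, dtype=float).reshape(-1)
        if interest.size != self.config.M:
            raise ValueError(
                f"interest vector has length {interest.size}, expected M={self.config.M}"
            )
        return UserToken(self.user_linear(Tensor(interest.reshape(1, -1))))

    def encode_user(self, interest: np.ndarray) -> UserToken:
        """Full user encoding: Linear embedding then Transformer encoder
        self-attention over the single token (EncUserCharacteristics)."""
        token = self.embed_user(interest).tensor
        for block in self.user_encoder:
            token = block(token)
        return UserToken(token)

    def fuse(self, features: FeatureTensor, user: UserToken) -> FeatureTensor:
        """Run the Transformer decoder stack: image tokens query the user token."""
        x = features.as_matrix()
        if self.pos_embedding is not None:
            x = x + self.pos_embedding
        for block in self.fusion_decoder:
            x = block(x, user.tensor)
        return FeatureTensor.from_matrix(x, features.H, features.W)

    # -- full paths -------------------------------------------------------

    def forward(self, image: np.ndarray, interest: np.ndarray) -> Tensor:
        features = self.encode_image(image)
        user = self.encode_user(interest)
        return self.decode_features(self.fuse(features, user))

    def predict_psm(self, image: np.ndarray, interest: np.ndarray) -> SaliencyMap:
        return SaliencyMap(
            values=self.forward(image, interest).data.copy(), kind="predicted"
        )

    def enc_output_tap(self, image: np.ndarray) -> SaliencyMap:
        """Diagnostic map: encoder features straight to the decoder,
        bypassing the user-encoding mechanism entirely."""
        out = self.decode_features(self.encode_image(image))
        return SaliencyMap(values=out.data.copy(), kind="predicted")

    def probe_user_characteristics(
        self, interest: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """(post-Linear, post-Transformer-encoder) user vectors, each 1 x C."""
        emb = self.embed_user(interest).tensor.data.copy()
        enc = self.encode_user(interest).tensor.data.copy()
        return emb, enc


def cross_attend(
    features: FeatureTensor, user: UserToken, attn: MultiHeadAttention
) -> FeatureTensor:
    """Single cross-attention application: image-feature queries against the
    one-row user token as key and value.  With exactly one key every softmax
    weight is 1, so each head's output is its projected V broadcast over all
    W*H query rows."""
    out = attn(features.as_matrix(), user.tensor)
    return FeatureTensor.from_matrix(out, features.H, features.W)


# -- checkpointing --------------------------------------------------------


def save_checkpoint(model: Module, path: str | Path) -> None:
    """Save weights plus full config and seed as an .npz archive."""
    config = asdict(model.config)
    config["__class__"] = type(model).__name__
    state = model.state_dict()
    np.savez(path, __config__=json.dumps(config), **state)


def load_checkpoint(path: str | Path):
    data = np.load(path, allow_pickle=False)
    config = json.loads(str(data["__config__"]))
    cls_name = config.pop("__class__")
    config["input_size"] = tuple(config["input_size"])
    cfg = PsmModelConfig(**config)
    model = {"UsmModel": UsmModel, "PsmModel": PsmModel}[cls_name](cfg)
    model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model


def describe_layers(model: Module) -> str:
    """Layer table (name, depth, kernel, padding) for visual comparison."""
    lines = [f"{type(model).__name__}  C={model.config.C}  "
             f"input={model.config.input_size}"]
    for part in ("encoder", "decoder"):
        stack = getattr(model, part)
        lines.append(f"[{part}]")
        for layer in stack.layers:
            if layer == "M":
                lines.append("  MaxPool2D   2x2 stride 2")
            elif layer == "U":
                lines.append("  UpSample    2x nearest")
            else:
                o, i, kh, kw = layer.weight.shape
                lines.append(f"  Conv2D      {o:<4d} {kh}x{kw} pad {layer.padding} ReLU")
    if isinstance(model, PsmModel):
        c = model.config
        lines.append(
            f"[user encoding] Linear {c.M}->{c.C}; {c.enc_layers} encoder "
            f"blocks; {c.dec_layers} decoder blocks; {c.heads} heads (d_k={c.d_k})"
        )
    return "\n".join(lines)
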