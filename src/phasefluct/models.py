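"""Fusion network architectures for two-class cell classification.

Three families share the same building blocks:

* **single path** — one backbone on one modality (morphology map,
  fluctuation map, or their 2-channel early-fusion stack);
* **double path (late fusion)** — independent backbones per modality whose
  feature vectors are concatenated;
* **triple path** — morphology, fluctuation and 2-channel paths; the
  2-channel feature vector is added element-wise to each single-modality
  vector and the two sums are concatenated.

The fused vector passes through two fully connected layers that shrink it to
a 2-way softmax; the positive class is *metastatic*.  Each backbone is a CNN
truncated after global average pooling.  Two backbones are provided: a
50-layer bottleneck residual network (feature length 2048) mirroring the
published architecture, and a 3-block ``small-cnn`` (feature length 128)
that trains in seconds on a CPU and is used throughout the test-scale
protocol.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import transform

from . import nn

__all__ = [
    "FusionModelSpec",
    "FusionModel",
    "BACKBONES",
    "build_model",
    "build_backbone",
    "make_two_channel",
    "fuse_double",
    "fuse_triple",
    "adapt_input_channels",
    "prepare_input",
]

MODALITIES = ("morphology", "fluctuations", "two_channel")

#: backbone registry: name -> (feature_len, default input size)
BACKBONES = {
    "resnet50-style": (2048, 64),
    "small-cnn": (128, 16),
}


@dataclass
class FusionModelSpec:
    """Architecture description for :func:`build_model`.

    ``inputs`` must match the variant arity: one modality for ``single``,
    two for ``double``, and all three for ``triple``.
    """

    variant: str = "single"
    inputs: tuple[str, ...] = ("morphology",)
    backbone: str = "resnet50-style"
    head_dims: tuple[int, ...] = (256, 2)
    pretrained: bool = False
    input_size: int | None = None

    def __post_init__(self):
        self.inputs = tuple(sorted(self.inputs, key=MODALITIES.index))
        if self.variant not in ("single", "double", "triple"):
            raise ValueError(f"unknown variant '{self.variant}'")
        for m in self.inputs:
            if m not in MODALITIES:
                raise ValueError(f"unknown input modality '{m}'")
        arity = {"single": 1, "double": 2, "triple": 3}[self.variant]
        if len(set(self.inputs)) != len(self.inputs) or len(self.inputs) != arity:
            raise ValueError(
                f"variant '{self.variant}' requires {arity} distinct inputs, "
                f"got {self.inputs}")
        if self.variant == "triple" and set(self.inputs) != set(MODALITIES):
            raise ValueError("triple variant requires all three modalities")
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone '{self.backbone}'")
        dims = tuple(self.head_dims)
        if dims[-1] != 2 or any(a <= b for a, b in zip(dims, dims[1:])):
            raise ValueError("head_dims must be strictly decreasing and end at 2")
        self.head_dims = dims
        if self.input_size is None:
            self.input_size = BACKBONES[self.backbone][1]

    @property
    def feature_len(self) -> int:
        return BACKBONES[self.backbone][0]


def make_two_channel(morph: np.ndarray, fluct: np.ndarray) -> np.ndarray:
    """Stack morphology (channel 0) and fluctuation map (channel 1)."""
    morph = np.asarray(morph, dtype=np.float32)
    fluct = np.asarray(fluct, dtype=np.float32)
    if morph.shape != fluct.shape or morph.ndim != 2:
        raise ValueError("modalities must be 2D arrays of identical shape")
    return np.stack([morph, fluct])


def fuse_double(v_morph: np.ndarray, v_fluct: np.ndarray) -> np.ndarray:
    """Late fusion: concatenate (morphology, fluctuations) feature vectors."""
    v_morph = np.asarray(v_morph)
    v_fluct = np.asarray(v_fluct)
    if v_morph.shape != v_fluct.shape:
        raise ValueError("feature vectors must have equal length")
    return np.concatenate([v_morph, v_fluct], axis=-1)


def fuse_triple(v_morph: np.ndarray, v_fluct: np.ndarray,
                v_2ch: np.ndarray) -> np.ndarray:
    """Triple-path fusion: concat(v_morph + v_2ch, v_fluct + v_2ch).

    Reduces exactly to :func:`fuse_double` when ``v_2ch`` is zero.
    """
    v_morph = np.asarray(v_morph)
    v_fluct = np.asarray(v_fluct)
    v_2ch = np.asarray(v_2ch)
    if v_morph.shape != v_fluct.shape or v_morph.shape != v_2ch.shape:
        raise ValueError("feature vectors must have equal length")
    return np.concatenate([v_morph + v_2ch, v_fluct + v_2ch], axis=-1)


def adapt_input_channels(image: np.ndarray, k: int = 3) -> np.ndarray:
    """Adapt a 1-, 2- or 3-channel image to a ``k=3``-channel backbone.

    1 channel is replicated; for 2 channels the third is their mean;
    3 channels pass through unchanged.
    """
    if k != 3:
        raise ValueError("backbones expect 3 input channels")
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3:
        raise ValueError("expected a (C, H, W) image")
    c = image.shape[0]
    if c == 1:
        return np.repeat(image, 3, axis=0)
    if c == 2:
        return np.concatenate([image, image.mean(axis=0, keepdims=True)])
    if c == 3:
        return image
    raise ValueError(f"cannot adapt {c}-channel input")


def prepare_input(image: np.ndarray, size: int) -> np.ndarray:
    """Min-max normalize a 2D modality image to [0, 1] and resize to size^2."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    img = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
    if img.shape != (size, size):
        img = transform.resize(img, (size, size), order=1, preserve_range=True,
                               anti_aliasing=size < min(img.shape), mode="reflect")
    return img.astype(np.float32)


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------

def _small_cnn(rng: np.random.Generator) -> nn.Sequential:
    """3 conv blocks (conv-BN-ReLU[-pool]) + GAP -> 128 features."""
    return nn.Sequential(
        nn.Conv2d(3, 8, 3, rng=rng), nn.BatchNorm2d(8), nn.ReLU(), nn.MaxPool2d(2),
        nn.Conv2d(8, 16, 3, rng=rng), nn.BatchNorm2d(16), nn.ReLU(), nn.MaxPool2d(2),
        nn.Conv2d(16, 128, 3, rng=rng), nn.BatchNorm2d(128), nn.ReLU(),
        nn.GlobalAvgPool(),
    )


def _bottleneck(c_in: int, mid: int, c_out: int, stride: int,
                rng: np.random.Generator) -> nn.Residual:
    main = nn.Sequential(
        nn.Conv2d(c_in, mid, 1, stride=stride, pad=0, rng=rng), nn.BatchNorm2d(mid), nn.ReLU(),
        nn.Conv2d(mid, mid, 3, rng=rng), nn.BatchNorm2d(mid), nn.ReLU(),
        nn.Conv2d(mid, c_out, 1, pad=0, rng=rng), nn.BatchNorm2d(c_out),
    )
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = nn.Sequential(
            nn.Conv2d(c_in, c_out, 1, stride=stride, pad=0, rng=rng),
            nn.BatchNorm2d(c_out))
    return nn.Residual(main, shortcut)


def _resnet50(rng: np.random.Generator) -> nn.Sequential:
    """50-layer bottleneck residual backbone truncated after average pooling."""
    layers: list[nn.Layer] = [
        nn.Conv2d(3, 64, 7, stride=2, pad=3, rng=rng), nn.BatchNorm2d(64),
        nn.ReLU(), nn.MaxPool2d(3, stride=2, pad=1),
    ]
    c_in = 64
    for n_blocks, mid, c_out, stride in ((3, 64, 256, 1), (4, 128, 512, 2),
                                         (6, 256, 1024, 2), (3, 512, 2048, 2)):
        for b in range(n_blocks):
            layers.append(_bottleneck(c_in, mid, c_out, stride if b == 0 else 1, rng))
            c_in = c_out
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(*layers)


def build_backbone(name: str, rng: np.random.Generator) -> nn.Sequential:
    if name == "small-cnn":
        return _small_cnn(rng)
    if name == "resnet50-style":
        return _resnet50(rng)
    raise ValueError(f"unknown backbone '{name}'")


# ---------------------------------------------------------------------------
# fusion model
# ---------------------------------------------------------------------------

class FusionModel:
    """A fusion classifier: per-path backbones, a fusion rule, and an FC head.

    ``forward`` maps a dict of modality batches (each ``(N, 3, H, W)``) to
    logits; ``predict_proba`` applies the softmax.  ``backward`` propagates a
    logits gradient through head, fusion and every backbone, accumulating
    parameter gradients.
    """

    def __init__(self, spec: FusionModelSpec, seed: int = 0):
        self.spec = spec
        if spec.pretrained:
            warnings.warn("pretrained weights are not bundled; "
                          "falling back to seeded random initialization")
        rng = np.random.default_rng(seed)
        self.backbones = {m: build_backbone(spec.backbone, rng)
                          for m in spec.inputs}
        fused_len = spec.feature_len * (2 if spec.variant in ("double", "triple") else 1)
        head_layers: list[nn.Layer] = []
        d_in = fused_len
        for d_out in spec.head_dims:
            head_layers.append(nn.Linear(d_in, d_out, rng=rng))
            if d_out != spec.head_dims[-1]:
                head_layers.append(nn.ReLU())
            d_in = d_out
        self.head = nn.Sequential(*head_layers)
        self._cache_features: dict[str, np.ndarray] | None = None

    # -- parameter access ---------------------------------------------------
    def params(self) -> list[nn.Param]:
        out = []
        for m in self.spec.inputs:
            out += self.backbones[m].params()
        return out + self.head.params()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def backbone_n_parameters(self) -> int:
        return sum(p.size for p in self.backbones[self.spec.inputs[0]].params())

    # -- forward / backward -------------------------------------------------
    def features(self, inputs: dict[str, np.ndarray], train: bool = True) -> dict[str, np.ndarray]:
        return {m: self.backbones[m].forward(np.ascontiguousarray(inputs[m], dtype=np.float32), train)
                for m in self.spec.inputs}

    def _fuse(self, feats: dict[str, np.ndarray]) -> np.ndarray:
        v = self.spec.variant
        if v == "single":
            return feats[self.spec.inputs[0]]
        if v == "double":
            a, b = (feats[m] for m in self.spec.inputs)
            return fuse_double(a, b)
        return fuse_triple(feats["morphology"], feats["fluctuations"],
                           feats["two_channel"])

    def forward(self, inputs: dict[str, np.ndarray], train: bool = True) -> np.ndarray:
        missing = [m for m in self.spec.inputs if m not in inputs]
        if missing:
            raise ValueError(f"missing input modalities: {missing}")
        feats = self.features(inputs, train)
        self._cache_features = feats
        return self.head.forward(self._fuse(feats), train)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits)
        v = self.spec.variant
        L = self.spec.feature_len
        if v == "single":
            self.backbones[self.spec.inputs[0]].backward(dfused)
            return
        g1, g2 = dfused[:, :L], dfused[:, L:]
        if v == "double":
            a, b = self.spec.inputs
            self.backbones[a].backward(np.ascontiguousarray(g1))
            self.backbones[b].backward(np.ascontiguousarray(g2))
            return
        self.backbones["morphology"].backward(np.ascontiguousarray(g1))
        self.backbones["fluctuations"].backward(np.ascontiguousarray(g2))
        self.backbones["two_channel"].backward(np.ascontiguousarray(g1 + g2))

    def predict_proba(self, inputs: dict[str, np.ndarray]) -> np.ndarray:
        return nn.softmax(self.forward(inputs, train=False))

    # -- (de)serialization --------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.value for p in self.params()]
        for m in self.spec.inputs:
            arrays += self.backbones[m].state()
        arrays += self.head.state()
        return arrays

    def snapshot(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def load_snapshot(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("snapshot does not match architecture")
        for dst, src in zip(own, arrays):
            dst[...] = src

    def save(self, path) -> None:
        meta = dict(variant=self.spec.variant, inputs=",".join(self.spec.inputs),
                    backbone=self.spec.backbone,
                    head_dims=",".join(map(str, self.spec.head_dims)),
                    input_size=self.spec.input_size)
        import json
        np.savez(path, _meta=np.array(json.dumps(meta)),
                 **{f"arr_{i}": a for i, a in enumerate(self.state_arrays())})

    @classmethod
    def load(cls, path) -> "FusionModel":
        import json
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["_meta"]))
        spec = FusionModelSpec(variant=meta["variant"],
                               inputs=tuple(meta["inputs"].split(",")),
                               backbone=meta["backbone"],
                               head_dims=tuple(int(d) for d in meta["head_dims"].split(",")),
                               input_size=int(meta["input_size"]))
        model = cls(spec)
        n = len(model.state_arrays())
        model.load_snapshot([data[f"arr_{i}"] for i in range(n)])
        return model


def build_model(spec: FusionModelSpec, seed: int = 0) -> FusionModel:
    """Instantiate the model described by ``spec`` with seeded initialization."""
    return FusionModel(spec, seed=seed)


def spec_from_dict(d: dict) -> FusionModelSpec:
    """Build a :class:`FusionModelSpec` from a YAML-style mapping."""
    kwargs = dict(d)
    if "inputs" in kwargs:
        kwargs["inputs"] = tuple(kwargs["inputs"])
    if "head_dims" in kwargs:
        kwargs["head_dims"] = tuple(int(x) for x in kwargs["head_dims"])
    return FusionModelSpec(**kwargs)
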