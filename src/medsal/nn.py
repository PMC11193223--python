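"""Minimal convolutional network with explicit reverse-mode differentiation.

Attribution operators need three things a plain classifier API does not
expose: gradients of a class score with respect to the input image,
activations of a named convolutional layer, and gradients of the score with
respect to those activations.  The network here is written directly in numpy
with hand-coded forward and backward passes so that all three are available,
deterministic, and fast enough for 64x64 phantoms on a single CPU.

Layout is channels-last (B, H, W, C) throughout.  All layers are stateless
with respect to a single forward pass: ``forward`` returns ``(output, cache)``
and ``backward`` consumes the cache, so nested or batched evaluations never
clobber each other.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Conv3x3:
    """3x3 convolution, stride 1, zero ('same') padding."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (9 * cin))  # He initialisation
        self.W = rng.normal(0.0, scale, size=(cin, 3, 3, cout))
        self.b = np.zeros(cout)

    def forward(self, x: np.ndarray):
        B, H, Wd, _ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        # (B, H, W, Cin, 3, 3)
        cols = sliding_window_view(xp, (3, 3), axis=(1, 2))
        # cols flatten order is (Cin, kh, kw), matching the kernel layout
        out = cols.reshape(B, H, Wd, -1) @ self.W.reshape(-1, self.W.shape[-1])
        return out + self.b, cols

    def backward(self, dY: np.ndarray, cache, want_params: bool):
        cols = cache
        B, H, Wd, cout = dY.shape
        grads = None
        if want_params:
            dW = np.einsum("bhwckl,bhwo->cklo", cols, dY, optimize=True)
            db = dY.sum(axis=(0, 1, 2))
            grads = {"W": dW, "b": db}
        dYp = np.pad(dY, ((0, 0), (1, 1), (1, 1), (0, 0)))
        dcols = sliding_window_view(dYp, (3, 3), axis=(1, 2))  # (B,H,W,Cout,3,3)
        # dX[p,q,c] = sum_{ah,aw,o} dYp[p+ah, q+aw, o] * W[c, 2-ah, 2-aw, o]
        Wrot = self.W[:, ::-1, ::-1, :]  # (Cin,3,3,Cout)
        K2 = Wrot.transpose(3, 1, 2, 0).reshape(-1, self.W.shape[0])  # (Cout*9, Cin)
        dX = dcols.reshape(B, H, Wd, -1) @ K2
        return dX, grads

    def params(self):
        return {"W": self.W, "b": self.b}


class ReLU:
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, dY, cache, want_params):
        return dY * cache, None

    def params(self):
        return {}


class MaxPool2:
    """2x2 max pooling, stride 2; argmax routing with first-index tie-break."""

    def forward(self, x):
        B, H, Wd, C = x.shape
        r = (
            x.reshape(B, H // 2, 2, Wd // 2, 2, C)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(B, H // 2, Wd // 2, C, 4)
        )
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        return out, (idx, x.shape)

    def backward(self, dY, cache, want_params):
        idx, shape = cache
        B, H, Wd, C = shape
        d4 = np.zeros((B, H // 2, Wd // 2, C, 4))
        np.put_along_axis(d4, idx[..., None], dY[..., None], axis=-1)
        dX = (
            d4.reshape(B, H // 2, Wd // 2, C, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(B, H, Wd, C)
        )
        return dX, None

    def params(self):
        return {}


class Flatten:
    def forward(self, x):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, dY, cache, want_params):
        return dY.reshape(cache), None

    def params(self):
        return {}


class Dense:
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / fin)
        self.W = rng.normal(0.0, scale, size=(fin, fout))
        self.b = np.zeros(fout)

    def forward(self, x):
        return x @ self.W + self.b, x

    def backward(self, dY, cache, want_params):
        grads = None
        if want_params:
            grads = {"W": cache.T @ dY, "b": dY.sum(axis=0)}
        return dY @ self.W.T, grads

    def params(self):
        return {"W": self.W, "b": self.b}


class SmallCNN:
    """Three conv blocks + dense softmax head for small grayscale/RGB images.

    ``conv1``..``conv3`` name the post-activation feature maps of each block;
    these are the layers the CAM-family operators target (``conv3`` is the
    final convolutional layer).
    """

    def __init__(
        self,
        image_shape: tuple[int, int, int] = (64, 64, 1),
        num_classes: int = 3,
        channels: Sequence[int] = (8, 16, 16),
        seed: int = 0,
    ):
        if len(channels) != 3:
            raise ValueError("channels must list three conv-block widths")
        H, Wd, C = image_shape
        if H % 8 or Wd % 8:
            raise ValueError("image height and width must be divisible by 8")
        self.image_shape = (H, Wd, C)
        self.num_classes = int(num_classes)
        self.channels = tuple(int(c) for c in channels)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        c1, c2, c3 = self.channels
        self.layers: list[tuple[str, object]] = [
            ("conv1_pre", Conv3x3(C, c1, rng)),
            ("conv1", ReLU()),
            ("pool1", MaxPool2()),
            ("conv2_pre", Conv3x3(c1, c2, rng)),
            ("conv2", ReLU()),
            ("pool2", MaxPool2()),
            ("conv3_pre", Conv3x3(c2, c3, rng)),
            ("conv3", ReLU()),
            ("pool3", MaxPool2()),
            ("flatten", Flatten()),
            ("dense", Dense((H // 8) * (Wd // 8) * c3, num_classes, rng)),
        ]

    # ---- naming -------------------------------------------------------
    @property
    def conv_layer_names(self) -> list[str]:
        return ["conv1", "conv2", "conv3"]

    @property
    def last_conv_layer(self) -> str:
        return "conv3"

    def _layer_index(self, name: str) -> int:
        for i, (n, _) in enumerate(self.layers):
            if n == name:
                return i
        raise KeyError(f"unknown layer {name!r}")

    # ---- forward / backward ------------------------------------------
    def forward(self, x: np.ndarray):
        """Return (logits, tape); tape holds (output, cache) per layer."""
        tape = []
        out = x
        for _, layer in self.layers:
            out, cache = layer.forward(out)
            tape.append((out, cache))
        return out, tape

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(
        self,
        dlogits: np.ndarray,
        tape,
        capture: set[str] | None = None,
        want_params: bool = False,
    ):
        """Backpropagate dlogits; return (dinput, captured layer grads, param grads)."""
        capture = capture or set()
        captured: dict[str, np.ndarray] = {}
        param_grads: dict[str, dict] = {}
        d = dlogits
        for i in range(len(self.layers) - 1, -1, -1):
            name, layer = self.layers[i]
            if name in capture:
                captured[name] = d
            d, grads = layer.backward(d, tape[i][1], want_params)
            if grads is not None:
                param_grads[name] = grads
        return d, captured, param_grads

    def layer_output(self, x: np.ndarray, name: str) -> np.ndarray:
        idx = self._layer_index(name)
        out = x
        for _, layer in self.layers[: idx + 1]:
            out, _ = layer.forward(out)
        return out

    def logits_from_layer(self, name: str, activations: np.ndarray) -> np.ndarray:
        """Run the tail of the network starting from a named layer's output."""
        idx = self._layer_index(name)
        out = activations
        for _, layer in self.layers[idx + 1 :]:
            out, _ = layer.forward(out)
        return out

    # ---- parameters ---------------------------------------------------
    def named_params(self):
        for name, layer in self.layers:
            for key, arr in layer.params().items():
                yield f"{name}.{key}", layer, key, arr

    # ---- serialization ------------------------------------------------
    def save(self, path: str) -> None:
        arch = {
            "image_shape": list(self.image_shape),
            "num_classes": self.num_classes,
            "channels": list(self.channels),
            "seed": self.seed,
        }
        arrays = {pname: arr for pname, _, _, arr in self.named_params()}
        np.savez(path, __arch__=np.frombuffer(json.dumps(arch).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "SmallCNN":
        with np.load(path) as data:
            arch = json.loads(bytes(data["__arch__"]).decode())
            net = cls(
                image_shape=tuple(arch["image_shape"]),
                num_classes=arch["num_classes"],
                channels=arch["channels"],
                seed=arch["seed"],
            )
            for pname, layer, key, arr in net.named_params():
                arr[...] = data[pname]
        return net


class AdamOptimizer:
    """Adam over a SmallCNN's parameter set."""

    def __init__(self, net: SmallCNN, lr: float = 3e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {p: np.zeros_like(a) for p, _, _, a in net.named_params()}
        self.v = {p: np.zeros_like(a) for p, _, _, a in net.named_params()}

    def step(self, param_grads: dict[str, dict]) -> None:
        self.t += 1
        for pname, layer, key, arr in self.net.named_params():
            lname = pname.split(".")[0]
            g = param_grads.get(lname, {}).get(key)
            if g is None:
                continue
            m = self.m[pname] = self.beta1 * self.m[pname] + (1 - self.beta1) * g
            v = self.v[pname] = self.beta2 * self.v[pname] + (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
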