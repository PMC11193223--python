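"""Framework-agnostic classifier contract used by every attribution operator.

The contract is the public API: an attribution method only ever sees a
:class:`ModelHandle`, which exposes probabilistic predictions, input
gradients, and activations/gradients of a named convolutional layer.  Two
concrete handles ship with the package — :class:`CNNModelHandle` wrapping the
numpy CNN fixture, and :class:`LinearModelHandle`, a closed-form linear
scorer used for axiomatic oracle checks.  Swapping in another autodiff
backend means writing one new handle, not touching attribution code.

Images are channels-last ``(H, W, C)`` with intensities in [0, 1]; batches
are ``(B, H, W, C)``.  Gradient entry points count their invocations via
``gradient_calls`` so gradient-free methods can prove they never touch them.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass

import numpy as np

from .nn import SmallCNN, softmax


class ShapeError(ValueError):
    """Input does not match the model's expected spatial shape."""


def validate_image(image: np.ndarray) -> np.ndarray:
    """Check an (H, W, C) image: finite, in [0, 1], C in {1, 3}."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[..., None]
    if image.ndim != 3 or image.shape[-1] not in (1, 3):
        raise ShapeError(f"expected (H, W, C) with C in {{1,3}}, got {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image intensities must lie in [0, 1]")
    return image


def as_batch(images) -> np.ndarray:
    """Stack one image or a sequence of images into a (B, H, W, C) batch."""
    arr = np.asarray(images, dtype=float)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise ShapeError(f"expected image batch, got shape {arr.shape}")
    return arr


@dataclass
class ClassScore:
    """Probability and logit of one class for one image."""

    class_index: int
    probability: float
    logit: float


class ModelHandle(abc.ABC):
    """Contract every attribution and evaluation operation programs against."""

    num_classes: int
    image_shape: tuple[int, int, int]
    gradient_calls: int = 0

    # -- forward -------------------------------------------------------
    @abc.abstractmethod
    def logits(self, images) -> np.ndarray:
        """(B, num_classes) pre-softmax scores."""

    def predict(self, images) -> np.ndarray:
        """(B, num_classes) softmax probabilities (rows sum to 1)."""
        return softmax(self.logits(images))

    def class_score(self, image: np.ndarray, class_index: int) -> ClassScore:
        z = self.logits(as_batch(image))[0]
        p = softmax(z)
        return ClassScore(class_index, float(p[class_index]), float(z[class_index]))

    # -- gradients -----------------------------------------------------
    @abc.abstractmethod
    def input_gradients(self, images, class_index: int, of: str = "logit") -> np.ndarray:
        """(B, H, W, C) gradient of the class score w.r.t. each input."""

    # -- layer access (optional; CAM methods require it) ---------------
    @property
    def conv_layer_names(self) -> list[str]:
        return []

    def layer_output(self, images, layer: str) -> np.ndarray:
        raise KeyError(f"model exposes no layer {layer!r}")

    def layer_activations_and_gradients(self, image, class_index: int, layer: str):
        raise KeyError(f"model exposes no layer {layer!r}")

    # -- housekeeping --------------------------------------------------
    def _check_shape(self, batch: np.ndarray) -> None:
        if batch.shape[1:] != self.image_shape:
            raise ShapeError(
                f"model expects {self.image_shape}, got {batch.shape[1:]}"
            )

    def _check_class(self, class_index: int) -> None:
        if not 0 <= class_index < self.num_classes:
            raise IndexError(f"class index {class_index} out of range")


class CNNModelHandle(ModelHandle):
    """Adapter over the numpy :class:`~medsal.nn.SmallCNN`."""

    def __init__(self, net: SmallCNN):
        self.net = net
        self.num_classes = net.num_classes
        self.image_shape = net.image_shape
        self.gradient_calls = 0

    # -- forward -------------------------------------------------------
    def logits(self, images) -> np.ndarray:
        batch = as_batch(images)
        self._check_shape(batch)
        if not np.all(np.isfinite(batch)):
            raise ValueError("non-finite input")
        return self.net.logits(batch)

    # -- gradients -----------------------------------------------------
    def _seed_gradient(self, logits: np.ndarray, class_index: int, of: str) -> np.ndarray:
        """Gradient of the chosen score w.r.t. the logits, per sample."""
        B, K = logits.shape
        if of == "logit":
            d = np.zeros((B, K))
            d[:, class_index] = 1.0
            return d
        if of in ("probability", "prob"):
            p = softmax(logits)
            onehot = np.zeros(K)
            onehot[class_index] = 1.0
            # dp_c/dz = p_c * (e_c - p)
            return p[:, class_index : class_index + 1] * (onehot[None, :] - p)
        raise ValueError(f"of must be 'logit' or 'probability', got {of!r}")

    def input_gradients(self, images, class_index: int, of: str = "logit") -> np.ndarray:
        self._check_class(class_index)
        batch = as_batch(images)
        self._check_shape(batch)
        if not np.all(np.isfinite(batch)):
            raise ValueError("non-finite input")
        self.gradient_calls += 1
        logits, tape = self.net.forward(batch)
        dlogits = self._seed_gradient(logits, class_index, of)
        dx, _, _ = self.net.backward(dlogits, tape)
        return dx

    # -- layer access --------------------------------------------------
    @property
    def conv_layer_names(self) -> list[str]:
        return self.net.conv_layer_names

    @property
    def last_conv_layer(self) -> str:
        return self.net.last_conv_layer

    def _check_layer(self, layer: str) -> None:
        if layer not in self.net.conv_layer_names:
            raise KeyError(
                f"unknown or non-spatial layer {layer!r}; "
                f"available: {self.net.conv_layer_names}"
            )

    def layer_output(self, images, layer: str) -> np.ndarray:
        self._check_layer(layer)
        batch = as_batch(images)
        self._check_shape(batch)
        return self.net.layer_output(batch, layer)

    def layer_activations_and_gradients(self, image, class_index: int, layer: str):
        """(activations, gradients), both (h', w', K), for one image."""
        self._check_class(class_index)
        self._check_layer(layer)
        batch = as_batch(image)
        self._check_shape(batch)
        self.gradient_calls += 1
        logits, tape = self.net.forward(batch)
        dlogits = self._seed_gradient(logits, class_index, "logit")
        _, captured, _ = self.net.backward(dlogits, tape, capture={layer})
        acts = tape[self.net._layer_index(layer)][0]
        return acts[0], captured[layer][0]

    def logits_from_layer(self, layer: str, activations: np.ndarray) -> np.ndarray:
        self._check_layer(layer)
        acts = activations[None] if activations.ndim == 3 else activations
        return self.net.logits_from_layer(layer, acts)

    # -- serialization -------------------------------------------------
    def save(self, path: str) -> None:
        self.net.save(path)

    @classmethod
    def load(cls, path: str) -> "CNNModelHandle":
        return cls(SmallCNN.load(path))


class LinearModelHandle(ModelHandle):
    """Linear scorer ``logit_c = <w_c, x> + b_c`` with closed-form gradients.

    Used as an analytic oracle: vanilla gradient must equal ``w_c`` and
    integrated gradients must equal ``w_c * (x - x0)`` exactly.
    """

    def __init__(self, weights: np.ndarray, biases: np.ndarray | None = None):
        weights = np.asarray(weights, dtype=float)  # (K, H, W, C)
        if weights.ndim != 4:
            raise ShapeError("weights must be (num_classes, H, W, C)")
        self.weights = weights
        self.num_classes = weights.shape[0]
        self.image_shape = weights.shape[1:]
        self.biases = np.zeros(self.num_classes) if biases is None else np.asarray(biases, float)
        self.gradient_calls = 0

    def logits(self, images) -> np.ndarray:
        batch = as_batch(images)
        self._check_shape(batch)
        return np.tensordot(batch, self.weights, axes=([1, 2, 3], [1, 2, 3])) + self.biases

    def input_gradients(self, images, class_index: int, of: str = "logit") -> np.ndarray:
        self._check_class(class_index)
        batch = as_batch(images)
        self._check_shape(batch)
        self.gradient_calls += 1
        if of == "logit":
            return np.broadcast_to(self.weights[class_index], batch.shape).copy()
        p = softmax(self.logits(batch))  # (B, K)
        onehot = np.zeros(self.num_classes)
        onehot[class_index] = 1.0
        coef = p[:, class_index : class_index + 1] * (onehot[None, :] - p)  # (B, K)
        return np.tensordot(coef, self.weights, axes=(1, 0))


# ---- module-level operations (thin wrappers over the contract) --------

def predict(model: ModelHandle, images) -> np.ndarray:
    """Softmax probability vectors, one row per image."""
    return model.predict(images)


def input_gradient(
    model: ModelHandle, image: np.ndarray, class_index: int, of: str = "logit"
) -> np.ndarray:
    """Gradient of the chosen class score w.r.t. one (H, W, C) image."""
    return model.input_gradients(as_batch(image), class_index, of=of)[0]


def layer_activations_and_gradients(
    model: ModelHandle, image: np.ndarray, class_index: int, layer: str
):
    """Activations and score gradients at a named convolutional layer."""
    return model.layer_activations_and_gradients(image, class_index, layer)
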