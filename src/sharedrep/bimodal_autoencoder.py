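"""Bimodal autoencoders: mixed-input and two-stage frameworks.

Both variants reconstruct a visual and an auditory input from a shared
hidden code of sigmoid units and differ only in how the encoder reaches
that code:

* ``mixed``: the two modalities are concatenated at the input layer and
  pass through 1-4 modality-combined encoding layers of ``width``
  sigmoid units.
* ``two_stage``: each modality is encoded separately for 3 layers, and
  a fourth, modality-combined layer merges the two streams (the
  classical separate-then-merge design this package compares against).

The decoder is identical in both: two parallel 3-layer paths, one per
modality, ending in sigmoid reconstruction layers at each modality's
input dimension. Training minimizes binary cross-entropy summed over
the two reconstruction branches with AdaDelta at its default settings;
the summed squared reconstruction error is logged alongside as a
monitoring metric. Targets are always the original arrays, so on
modality-dropout examples the network must reconstruct both modalities
from one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import (
    DTYPE,
    Dense,
    backward_chain,
    bce_grad_dz,
    binary_cross_entropy,
    forward_chain,
)
from .dataset_builder import StimulusSet
from .info_analysis import ActivationMatrix


class ConfigurationError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class NetworkSpec:
    """Topology of a bimodal autoencoder.

    ``encoder_depth`` is the number of modality-combined encoding
    layers in the mixed framework (1-4); the two-stage framework always
    has 3 per-modality stages plus 1 merged layer. ``width`` is the
    hidden-layer size (64 throughout the study).
    """

    framework: str = "mixed"
    encoder_depth: int = 4
    width: int = 64
    input_dims: tuple[int, int] = (784, 784)
    decoder_depth: int = 3

    def __post_init__(self) -> None:
        if self.framework not in ("mixed", "two_stage"):
            raise ConfigurationError(f"unknown framework {self.framework!r}")
        if self.framework == "mixed" and self.encoder_depth not in (1, 2, 3, 4):
            raise ConfigurationError("mixed encoder_depth must be in 1..4")
        if self.width < 1 or self.decoder_depth < 1:
            raise ConfigurationError("width and decoder_depth must be >= 1")
        if any(d < 1 for d in self.input_dims):
            raise ConfigurationError("input dims must be positive")

    @property
    def n_encoding_layers(self) -> int:
        """Total encoding stages (two-stage counts its merged layer as the 4th)."""
        return self.encoder_depth if self.framework == "mixed" else 4


class BimodalAutoencoder:
    """A buildable, trainable bimodal autoencoder (see module docstring)."""

    def __init__(self, spec: NetworkSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        self.training_log: list[float] = []
        self.sq_error_log: list[float] = []
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 23)))
        d_v, d_a = spec.input_dims
        w = spec.width
        if spec.framework == "mixed":
            dims = [d_v + d_a] + [w] * spec.encoder_depth
            self.encoder = [Dense(dims[i], dims[i + 1], "sigmoid", rng)
                            for i in range(spec.encoder_depth)]
        else:
            self.encoder_v = [Dense(d_v if i == 0 else w, w, "sigmoid", rng)
                              for i in range(3)]
            self.encoder_a = [Dense(d_a if i == 0 else w, w, "sigmoid", rng)
                              for i in range(3)]
            self.merge = Dense(2 * w, w, "sigmoid", rng)
        self.decoder_v = self._make_decoder(w, d_v, rng)
        self.decoder_a = self._make_decoder(w, d_a, rng)

    def _make_decoder(self, w: int, d_out: int, rng) -> list[Dense]:
        layers = [Dense(w, w, "sigmoid", rng) for _ in range(self.spec.decoder_depth - 1)]
        layers.append(Dense(w, d_out, "sigmoid", rng))
        return layers

    # -- forward ----------------------------------------------------------

    def _encode_code(self, x_v: np.ndarray, x_a: np.ndarray,
                     cache: bool = True) -> np.ndarray:
        if self.spec.framework == "mixed":
            return forward_chain(self.encoder, np.concatenate([x_v, x_a], axis=1),
                                 cache=cache)
        h_v = forward_chain(self.encoder_v, x_v, cache=cache)
        h_a = forward_chain(self.encoder_a, x_a, cache=cache)
        return self.merge.forward(np.concatenate([h_v, h_a], axis=1), cache=cache)

    def reconstruct(self, x_v: np.ndarray, x_a: np.ndarray,
                    cache: bool = False) -> tuple[np.ndarray, np.ndarray]:
        h = self._encode_code(x_v.astype(DTYPE), x_a.astype(DTYPE), cache=cache)
        y_v = forward_chain(self.decoder_v, h, cache=cache)
        y_a = forward_chain(self.decoder_a, h, cache=cache)
        return y_v, y_a

    # -- training ---------------------------------------------------------

    def _train_step(self, x_v, x_a, t_v, t_a) -> float:
        y_v, y_a = self.reconstruct(x_v, x_a, cache=True)
        loss = binary_cross_entropy(y_v, t_v) + binary_cross_entropy(y_a, t_a)
        g_v = backward_chain(self.decoder_v, bce_grad_dz(y_v, t_v),
                             first_grad_is_dz=True)
        g_a = backward_chain(self.decoder_a, bce_grad_dz(y_a, t_a),
                             first_grad_is_dz=True)
        g_h = g_v + g_a
        if self.spec.framework == "mixed":
            backward_chain(self.encoder, g_h)
        else:
            g_cat = self.merge.backward(g_h)
            w = self.spec.width
            backward_chain(self.encoder_v, g_cat[:, :w])
            backward_chain(self.encoder_a, g_cat[:, w:])
        return loss

    def train(self, data: StimulusSet, epochs: int,
              batch_size: int | None = 128) -> "BimodalAutoencoder":
        """Train in place for ``epochs`` passes over ``data``.

        Training order is reshuffled each epoch from the model seed.
        Raises :class:`TrainingError` with the epoch index if the loss
        turns non-finite.
        """
        x_v = data.x_v.astype(DTYPE)
        x_a = data.x_a.astype(DTYPE)
        t_v = data.t_v.astype(DTYPE)
        t_a = data.t_a.astype(DTYPE)
        n = len(x_v)
        bs = n if batch_size is None else min(batch_size, n)
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 29)))
        for epoch in range(epochs):
            order = rng.permutation(n)
            total, count = 0.0, 0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                loss = self._train_step(x_v[idx], x_a[idx], t_v[idx], t_a[idx])
                total += loss * len(idx)
                count += len(idx)
            epoch_loss = total / count
            if not np.isfinite(epoch_loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            self.training_log.append(epoch_loss)
            y_v, y_a = self.reconstruct(x_v, x_a)
            self.sq_error_log.append(self.squared_error(y_v, y_a, t_v, t_a))
        return self

    @staticmethod
    def squared_error(y_v, y_a, t_v, t_a) -> float:
        """Summed-squared reconstruction error over both modalities,
        averaged over samples (the monitoring metric)."""
        return float(((y_v - t_v) ** 2).sum(axis=1).mean()
                     + ((y_a - t_a) ** 2).sum(axis=1).mean())

    # -- analysis surface -------------------------------------------------

    def encode(self, data: StimulusSet, layer_index: int | None = None) -> ActivationMatrix:
        """Hidden-unit responses to every pair in ``data``.

        ``layer_index`` counts encoding stages from 1; default is the
        final stage. For the two-stage framework, stages 1-3 expose the
        two per-modality streams concatenated (2*width units) and stage
        4 the merged code. Rows carry the pair's digit label (the
        presented modality's label on single-modality pairs) and the
        condition tag.
        """
        n_layers = self.spec.n_encoding_layers
        if layer_index is None:
            layer_index = n_layers
        if not 1 <= layer_index <= n_layers:
            raise ConfigurationError(
                f"layer_index {layer_index} outside 1..{n_layers}")
        x_v = data.x_v.astype(DTYPE)
        x_a = data.x_a.astype(DTYPE)
        if self.spec.framework == "mixed":
            h = np.concatenate([x_v, x_a], axis=1)
            for layer in self.encoder[:layer_index]:
                h = layer.forward(h, cache=False)
        elif layer_index == 4:
            h = self._encode_code(x_v, x_a, cache=False)
        else:
            h_v, h_a = x_v, x_a
            for i in range(layer_index):
                h_v = self.encoder_v[i].forward(h_v, cache=False)
                h_a = self.encoder_a[i].forward(h_a, cache=False)
            h = np.concatenate([h_v, h_a], axis=1)
        labels = np.where(data.condition == "audio_only", data.label_a, data.label_v)
        return ActivationMatrix(responses=np.asarray(h, dtype=float),
                                labels=labels.copy(),
                                conditions=data.condition.copy())

    def encoder_checksum(self) -> float:
        """Aggregate of encoder weight magnitudes; used to verify the
        frozen-encoder contract during head training."""
        if self.spec.framework == "mixed":
            layers = list(self.encoder)
        else:
            layers = [*self.encoder_v, *self.encoder_a, self.merge]
        return float(sum(l.checksum() for l in layers))


def build(spec: NetworkSpec, seed: int) -> BimodalAutoencoder:
    """Construct an untrained model with seeded initial weights."""
    return BimodalAutoencoder(spec, seed)


def train(model: BimodalAutoencoder, data: StimulusSet, epochs: int,
          batch_size: int | None = 128) -> BimodalAutoencoder:
    return model.train(data, epochs, batch_size=batch_size)


def encode(model: BimodalAutoencoder, data: StimulusSet,
           layer_index: int | None = None) -> ActivationMatrix:
    return model.encode(data, layer_index)
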