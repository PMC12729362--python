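"""Minimal array-level neural-network primitives with explicit reverse-mode
gradients.

Every layer is a :class:`Module` exposing ``forward`` and ``backward``; the
backward pass consumes the gradient of the loss with respect to the layer
output and returns the gradient with respect to the input, accumulating
parameter gradients on the way.  Caches required by the backward pass are
stored on the module between the two calls, so a module instance processes
one batch at a time (sufficient for plain SGD-style training loops).

All computation is float32 by default; gradient-check tests run the same
code in float64 via the ``dtype`` argument of the constructors.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = ["Param", "Module", "fan_in_normal"]


class Param:
    """A trainable tensor together with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Param({self.name or 'unnamed'}, shape={self.value.shape})"


class Module:
    """Base class: tracks child modules and own :class:`Param` attributes."""

    def params(self) -> Iterator[Param]:
        """Yield all trainable parameters of this module and its children."""
        seen: set[int] = set()
        yield from self._params(seen)

    def _params(self, seen: set[int]) -> Iterator[Param]:
        for attr in self.__dict__.values():
            if isinstance(attr, Param):
                if id(attr) not in seen:
                    seen.add(id(attr))
                    yield attr
            elif isinstance(attr, Module):
                yield from attr._params(seen)
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield from item._params(seen)
                    elif isinstance(item, Param) and id(item) not in seen:
                        seen.add(id(item))
                        yield item

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = list(self.params())
        if len(own) != len(state):
            raise ValueError(
                f"checkpoint has {len(state)} tensors, model has {len(own)}"
            )
        for i, p in enumerate(own):
            value = state[f"p{i}"]
            if value.shape != p.value.shape:
                raise ValueError(
                    f"shape mismatch for tensor {i}: "
                    f"{value.shape} vs {p.value.shape}"
                )
            p.value[...] = value

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def fan_in_normal(
    rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype=np.float32
) -> np.ndarray:
    """Gaussian init scaled by 1/sqrt(fan_in) (He-style without the gain)."""
    scale = 1.0 / np.sqrt(max(fan_in, 1))
    return (rng.standard_normal(shape) * scale).astype(dtype)
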