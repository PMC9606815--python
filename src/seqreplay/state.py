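"""Network state containers: item catalog, per-region state, full network.

Items (percepts) are represented by single neurons, one per region, sharing
one index space across the cortex and the hippocampus (the two regions are
joined by fixed one-to-one projections).  The catalog only grows: a novel
percept allocates a new index in both regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = ["ItemCatalog", "RegionState", "NetworkState", "reset_transients"]


class ItemCatalog:
    """Ordered bijection between percept labels and neuron indices."""

    def __init__(self, labels: Iterable[str] = ()) -> None:
        self._labels: list[str] = []
        self._index: dict[str, int] = {}
        for lab in labels:
            self.add(lab)

    def add(self, label: str) -> int:
        """Allocate (or look up) the index of a label."""
        if label in self._index:
            return self._index[label]
        idx = len(self._labels)
        self._labels.append(label)
        self._index[label] = idx
        return idx

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown item label {label!r}") from None

    def label(self, idx: int) -> str:
        return self._labels[idx]

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __len__(self) -> int:
        return len(self._labels)

    def __iter__(self):
        return iter(self._labels)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self._labels)


@dataclass
class RegionState:
    """Activations, inactivation currents and adaptive weights of one region.

    ``W[x, y]`` is the directional weight from presynaptic item ``x`` to
    postsynaptic item ``y``; ``exists`` masks which links have been
    instantiated (no self-links; weights outside the mask stay 0).
    """

    region: str                    # "HC" or "CTX"
    a: np.ndarray                  # activations, in [0, 1]
    g: np.ndarray                  # inactivation currents, in [0, 1]
    W: np.ndarray                  # adaptive weights, in [0, 1]
    exists: np.ndarray             # bool link mask
    learning_enabled: bool = True

    @classmethod
    def empty(cls, region: str, n: int = 0) -> "RegionState":
        return cls(
            region=region,
            a=np.zeros(n),
            g=np.zeros(n),
            W=np.zeros((n, n)),
            exists=np.zeros((n, n), dtype=bool),
        )

    @property
    def n(self) -> int:
        return self.a.shape[0]

    def grow(self, n_new: int) -> None:
        """Expand all arrays to hold ``n_new`` items (state of new items is 0)."""
        n_old = self.n
        if n_new <= n_old:
            return
        a = np.zeros(n_new)
        g = np.zeros(n_new)
        W = np.zeros((n_new, n_new))
        ex = np.zeros((n_new, n_new), dtype=bool)
        a[:n_old] = self.a
        g[:n_old] = self.g
        W[:n_old, :n_old] = self.W
        ex[:n_old, :n_old] = self.exists
        self.a, self.g, self.W, self.exists = a, g, W, ex

    def validate(self) -> None:
        if self.a.shape != self.g.shape or self.W.shape != (self.n, self.n):
            raise ValueError("inconsistent state array shapes")
        if np.any((self.a < 0) | (self.a > 1)):
            raise ValueError("activations out of [0, 1]")
        if np.any((self.g < 0) | (self.g > 1)):
            raise ValueError("inactivation currents out of [0, 1]")
        if np.any((self.W < 0) | (self.W > 1)):
            raise ValueError("weights out of [0, 1]")
        if np.any(np.diag(self.exists)):
            raise ValueError("self-links are not allowed")
        if np.any(self.W[~self.exists] != 0):
            raise ValueError("non-zero weight outside the link mask")

    def copy(self) -> "RegionState":
        return RegionState(self.region, self.a.copy(), self.g.copy(),
                           self.W.copy(), self.exists.copy(),
                           self.learning_enabled)


@dataclass
class NetworkState:
    """Both regions plus salience, clock, mode and lesion flags."""

    catalog: ItemCatalog = field(default_factory=ItemCatalog)
    ctx: RegionState = field(default_factory=lambda: RegionState.empty("CTX"))
    hc: RegionState = field(default_factory=lambda: RegionState.empty("HC"))
    salience: np.ndarray = field(default_factory=lambda: np.zeros(0))
    clock: float = 0.0
    mode: str = "wake"             # "wake" | "sleep"
    hc_to_ctx_enabled: bool = True

    @property
    def n(self) -> int:
        return len(self.catalog)

    def add_item(self, label: str) -> int:
        """Allocate a new item in the catalog and both regions."""
        idx = self.catalog.add(label)
        n = len(self.catalog)
        if n > self.ctx.n:
            self.ctx.grow(n)
            self.hc.grow(n)
            s = np.zeros(n)
            s[: self.salience.shape[0]] = self.salience
            self.salience = s
        return idx

    def add_items(self, labels: Iterable[str]) -> list[int]:
        return [self.add_item(lab) for lab in labels]

    def advance_clock(self, elapsed: float) -> None:
        if elapsed < 0:
            raise ValueError("the clock cannot run backwards")
        self.clock += elapsed

    def validate(self) -> None:
        self.ctx.validate()
        self.hc.validate()
        if self.salience.shape[0] != self.n:
            raise ValueError("salience vector size does not match catalog")
        if np.any(self.salience < 0):
            raise ValueError("negative salience")
        if self.mode not in ("wake", "sleep"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def copy(self) -> "NetworkState":
        new = NetworkState(
            catalog=ItemCatalog(self.catalog.labels),
            ctx=self.ctx.copy(),
            hc=self.hc.copy(),
            salience=self.salience.copy(),
            clock=self.clock,
            mode=self.mode,
            hc_to_ctx_enabled=self.hc_to_ctx_enabled,
        )
        return new


def reset_transients(state: NetworkState) -> NetworkState:
    """Zero all activations and inactivation currents in place.

    Weights and salience are untouched.  Applied at the start of each
    experiment, at the end of every UP state, and when skipping idle gaps.
    """
    state.ctx.a[:] = 0.0
    state.ctx.g[:] = 0.0
    state.hc.a[:] = 0.0
    state.hc.g[:] = 0.0
    return state
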