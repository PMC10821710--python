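"""Epoch-portion reloading for collections too large to hold in memory.

Each reload period draws ``ceil(portion_fraction * N)`` records without
replacement from a seeded permutation; successive periods continue the
permutation, so every record is visited before any repeats — full coverage is
guaranteed within ``ceil(1 / portion_fraction)`` reload periods.
"""

from __future__ import annotations

import math
from typing import Iterator, Sequence

import numpy as np


class PortionLoader:
    def __init__(
        self,
        dataset: Sequence,
        portion_fraction: float,
        reload_every: int,
        rng: np.random.Generator,
    ):
        n = len(dataset)
        if not (0 < portion_fraction <= 1):
            raise ValueError("portion_fraction must be in (0, 1]")
        if portion_fraction * n < 1:
            raise ValueError(
                f"portion_fraction={portion_fraction} selects no records (n={n})"
            )
        self.dataset = dataset
        self.n = n
        self.k = math.ceil(portion_fraction * n)
        self.reload_every = max(1, int(reload_every))
        self.rng = rng
        self._perm: list[int] = []
        self._periods: list[list[int]] = []

    def _draw_period(self) -> list[int]:
        chosen: list[int] = []
        while len(chosen) < self.k:
            if not self._perm:
                self._perm = self.rng.permutation(self.n).tolist()
            cand = self._perm.pop(0)
            if cand in chosen:  # only possible right after a reshuffle
                continue
            chosen.append(cand)
        return chosen

    def epoch_indices(self, epoch: int) -> list[int]:
        """Record indices active during the given (0-based) epoch."""
        period = epoch // self.reload_every
        while len(self._periods) <= period:
            self._periods.append(self._draw_period())
        return list(self._periods[period])

    def epochs(self) -> Iterator[list]:
        """Yield, per epoch, the list of active records."""
        epoch = 0
        while True:
            idx = self.epoch_indices(epoch)
            yield [self.dataset[i] for i in idx]
            epoch += 1


def portion_loader(
    dataset, portion_fraction: float, reload_every: int, rng: np.random.Generator
) -> PortionLoader:
    return PortionLoader(dataset, portion_fraction, reload_every, rng)
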