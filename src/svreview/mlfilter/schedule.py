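"""Cosine annealing with warm restarts (SGDR).

The learning rate decays from ``initial_lr`` to ``min_lr`` along a cosine
over each restart cycle; cycles start at 2 epochs and double after each
restart, so with 50 total epochs the restarts fall at epoch boundaries
2, 6, 14 and 30.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class TrainingSchedule:
    initial_lr: float = 0.2
    min_lr: float = 0.0
    initial_restart_period: int = 2
    period_multiplier: int = 2
    total_epochs: int = 50
    batch_size: int = 32
    momentum: float = 0.9

    def restart_epochs(self) -> list[int]:
        """Epoch boundaries at which the learning rate resets, within
        total_epochs (e.g. [2, 6, 14, 30] for the defaults)."""
        out = []
        start, period = 0, self.initial_restart_period
        while start + period < self.total_epochs:
            start += period
            out.append(start)
            period *= self.period_multiplier
        return out

    def cycle_at(self, epoch: float) -> tuple[float, int]:
        """(epochs into the current cycle, cycle length)."""
        if epoch < 0:
            raise ValueError("epoch must be >= 0")
        start, period = 0, self.initial_restart_period
        while epoch >= start + period:
            start += period
            period *= self.period_multiplier
        return epoch - start, period

    def lr_at(self, epoch: float) -> float:
        """Closed-form learning rate at a (fractional) epoch position."""
        t_cur, t_i = self.cycle_at(epoch)
        return self.min_lr + 0.5 * (self.initial_lr - self.min_lr) * (
            1 + math.cos(math.pi * t_cur / t_i)
        )
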