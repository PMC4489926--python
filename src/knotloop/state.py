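"""The evolving state of one simulated chain."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["ChainState", "RunOutcome"]


@dataclass
class ChainState:
    """Positions, velocities and adhesion-bond status of an N-bead chain.

    Adhesion flags are monotone: once ``bonded_termini`` or
    ``bonded_internal`` is set by the engine it is never unset — adhesion
    is permanent.
    """

    positions: np.ndarray  # (N, 3)
    velocities: np.ndarray  # (N, 3)
    bonded_termini: bool = False
    bonded_internal: bool = False
    step_count: int = 0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        if self.positions.shape != self.velocities.shape or self.positions.ndim != 2:
            raise ValueError("positions and velocities must both have shape (N, 3)")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "ChainState":
        return ChainState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            bonded_termini=self.bonded_termini,
            bonded_internal=self.bonded_internal,
            step_count=self.step_count,
        )


@dataclass
class RunOutcome:
    """Per-run record returned by the engine.

    A run ends either by circularization (terminal pair adhered) or by
    censoring (step cap hit, or an integration failure recorded in
    ``error``); the two are mutually exclusive.
    ``internal_loop_closed_at_end`` records whether the internal sticky
    pair was adhered when the run terminated.
    """

    final_positions: np.ndarray
    circularized: bool
    internal_loop_closed_at_end: bool
    censored: bool
    steps_elapsed: int
    seed: int
    error: Optional[str] = None

    def __post_init__(self) -> None:
        if self.circularized == self.censored:
            raise ValueError("a run ends either circularized or censored, not both")
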