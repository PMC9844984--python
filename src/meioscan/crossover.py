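"""Meiotic crossover discovery from imputed haplotype-of-origin paths.

A crossover is called wherever a gamete's inferred path transitions from one
donor haplotype to the other.  Calls are reported as intervals bounded by
the last site assigned to the outgoing haplotype and the first site assigned
to the incoming haplotype; the true exchange happened somewhere in between.
Discovery must run on the smoothed imputation output (without superimposed
raw observations), since raw genotyping errors would otherwise masquerade as
recombination events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import NA
from .imputation import ImputedMatrix


class SuperimposedInputError(ValueError):
    """Crossover discovery was handed a matrix with superimposed observations."""


@dataclass
class BreakpointInterval:
    """One crossover call: the interval bracketing a haplotype transition."""

    gamete_id: str
    start_pos: int  # position of the last site on the outgoing haplotype
    end_pos: int  # position of the first site on the incoming haplotype
    start_index: int
    end_index: int
    direction: str  # "H1->H2" or "H2->H1"

    def __post_init__(self) -> None:
        if not self.start_pos < self.end_pos:
            raise ValueError("breakpoint interval must satisfy start_pos < end_pos")

    @property
    def resolution(self) -> int:
        """Width of the interval (bp for genomic positions)."""
        return int(self.end_pos - self.start_pos)


def gamete_crossovers(path: np.ndarray, positions: np.ndarray, gamete_id: str) -> list[BreakpointInterval]:
    """Crossover intervals for a single gamete's state path.

    NA runs are squeezed out, so an interval spans any unassigned tract
    between the flanking assigned states.  A constant path yields no calls.
    """
    idx = np.flatnonzero(np.asarray(path) != NA)
    if idx.size < 2:
        return []
    states = np.asarray(path)[idx]
    change = np.flatnonzero(states[1:] != states[:-1])
    intervals = []
    for c in change:
        i, j = int(idx[c]), int(idx[c + 1])
        direction = "H1->H2" if states[c] == 0 else "H2->H1"
        intervals.append(
            BreakpointInterval(
                gamete_id=gamete_id,
                start_pos=int(positions[i]),
                end_pos=int(positions[j]),
                start_index=i,
                end_index=j,
                direction=direction,
            )
        )
    return intervals


def discover_crossovers(imp: ImputedMatrix) -> dict[str, list[BreakpointInterval]]:
    """Per-gamete crossover intervals from a smoothed imputed matrix."""
    if imp.superimposed:
        raise SuperimposedInputError(
            "crossover discovery requires the smoothed imputed matrix; "
            "rerun imputation with superimpose=False (raw genotyping errors "
            "would otherwise manifest as false crossovers)"
        )
    return {
        gid: gamete_crossovers(imp.paths[:, j], imp.positions, gid)
        for j, gid in enumerate(imp.gamete_ids)
    }


def crossovers_to_frame(calls: dict[str, list[BreakpointInterval]]) -> pd.DataFrame:
    """Flatten crossover calls into a tidy table."""
    rows = [
        {
            "gamete": bp.gamete_id,
            "start_pos": bp.start_pos,
            "end_pos": bp.end_pos,
            "direction": bp.direction,
            "resolution_bp": bp.resolution,
        }
        for intervals in calls.values()
        for bp in intervals
    ]
    return pd.DataFrame(rows, columns=["gamete", "start_pos", "end_pos", "direction", "resolution_bp"])
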