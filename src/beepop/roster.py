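"""Population rosters: which breeder populations enter the study and how many
colonies each contributes.

A *population* is the set of colonies headed by queens from one breeder
location; its latitude of origin is carried along because the downstream
pathway analysis regresses expression against absolute latitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["PopulationSpec", "STUDY_ROSTER", "simulate_roster", "roster_frame"]


@dataclass(frozen=True)
class PopulationSpec:
    """One source population: short label, colony count, origin latitude."""

    name: str
    n_colonies: int
    latitude_deg: float

    def __post_init__(self) -> None:
        if self.n_colonies < 1:
            raise ValueError(f"population {self.name!r}: n_colonies must be >= 1")
        if abs(self.latitude_deg) > 90:
            raise ValueError(f"population {self.name!r}: |latitude| must be <= 90")


#: The eight commercial populations of the midgut study: 58 colonies in all,
#: each sampled in triplicate. Latitudes are those of the breeder towns.
STUDY_ROSTER: tuple[PopulationSpec, ...] = (
    PopulationSpec("SK1", 4, 52.75),
    PopulationSpec("SK2", 4, 52.75),
    PopulationSpec("ON", 4, 45.23),
    PopulationSpec("NZ", 8, -39.65),
    PopulationSpec("HI", 8, 19.50),
    PopulationSpec("CH", 10, -33.45),
    PopulationSpec("CA1", 11, 39.14),
    PopulationSpec("CA2", 9, 39.75),
)


def simulate_roster(
    n_populations: int,
    colonies_per_pop: int | Sequence[int],
    latitude_range: tuple[float, float] = (-45.0, 55.0),
    seed: int = 0,
) -> list[PopulationSpec]:
    """Draw a synthetic roster of ``n_populations`` populations.

    ``colonies_per_pop`` may be a single count applied to every population or
    a per-population sequence. Latitudes are uniform on ``latitude_range``.
    Deterministic for a fixed seed.
    """
    if n_populations < 2:
        raise ValueError("need at least 2 populations")
    if isinstance(colonies_per_pop, (int, np.integer)):
        counts = [int(colonies_per_pop)] * n_populations
    else:
        counts = [int(c) for c in colonies_per_pop]
        if len(counts) != n_populations:
            raise ValueError("colonies_per_pop length must match n_populations")
    if any(c < 1 for c in counts):
        raise ValueError("every population needs at least one colony")
    lo, hi = latitude_range
    if not (-90 <= lo <= hi <= 90):
        raise ValueError("latitude_range must be ordered and within [-90, 90]")
    rng = np.random.default_rng(seed)
    lats = rng.uniform(lo, hi, size=n_populations)
    return [
        PopulationSpec(f"P{i + 1}", counts[i], round(float(lats[i]), 2))
        for i in range(n_populations)
    ]


def roster_frame(roster: Sequence[PopulationSpec]) -> pd.DataFrame:
    """Roster as a DataFrame (population, n_colonies, latitude_deg)."""
    return pd.DataFrame(
        {
            "population": [p.name for p in roster],
            "n_colonies": [p.n_colonies for p in roster],
            "latitude_deg": [p.latitude_deg for p in roster],
        }
    )
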