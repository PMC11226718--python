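"""Energy-group structure for multigroup electron transport.

Boundaries are strictly increasing, ``b[0] < b[1] < ... < b[G]`` in reduced
units, with group ``g`` (0-based) spanning ``[b[g], b[g+1]]``.  The group
index therefore *increases with energy*; the solver sweeps from the top
group downward.  Spacing is logarithmic: electrons slow over up to six
decades of energy and a constant ratio gives uniform relative resolution.

The lowest boundary is the transport cutoff (1 keV by default): electrons
falling below it are considered stopped and deposit their residual energy
locally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_CUTOFF_MEV, MEC2


@dataclass(frozen=True)
class GroupStructure:
    bounds: np.ndarray     # reduced units, shape (G+1,), strictly increasing

    def __post_init__(self):
        b = np.asarray(self.bounds, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("need at least two group boundaries")
        if np.any(np.diff(b) <= 0):
            raise ValueError("group boundaries must be strictly increasing")
        object.__setattr__(self, "bounds", b)

    @property
    def G(self) -> int:
        return self.bounds.size - 1

    @property
    def cutoff(self) -> float:
        return float(self.bounds[0])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bounds)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bounds[:-1] + self.bounds[1:])

    @property
    def bounds_mev(self) -> np.ndarray:
        return self.bounds * MEC2

    @property
    def midpoints_mev(self) -> np.ndarray:
        return self.midpoints * MEC2

    def group_of(self, e) -> int:
        """Group index containing reduced energy ``e``.

        An energy equal to a shared boundary is assigned to the *lower*
        group (deterministic tie-break).  Returns -1 below the cutoff and
        G-1 at (or above) the top boundary.
        """
        b = self.bounds
        if e < b[0]:
            return -1
        idx = int(np.searchsorted(b, e, side="left")) - 1
        return min(max(idx, 0), self.G - 1)

    def same_as(self, other: "GroupStructure", tol=0.0) -> bool:
        if self.G != other.G:
            return False
        return np.allclose(self.bounds, other.bounds, rtol=tol, atol=0.0)


def build_group_structure(G: int,
                          e_min_mev: float = DEFAULT_CUTOFF_MEV,
                          e_max_mev: float = 100.0) -> GroupStructure:
    """Logarithmically spaced structure with ``G`` groups.

    At least three groups are required: the catastrophic-collision rule
    (a scattered electron must skip past two group boundaries) is empty
    otherwise.
    """
    if G < 3:
        raise ValueError("need at least 3 groups for the catastrophic rule")
    if not (0 < e_min_mev < e_max_mev):
        raise ValueError("require 0 < e_min < e_max")
    bounds_mev = np.geomspace(e_min_mev, e_max_mev, G + 1)
    bounds_mev[-1] = e_max_mev  # exact top edge
    return GroupStructure(bounds_mev / MEC2)
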