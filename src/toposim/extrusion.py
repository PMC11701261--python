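"""Stochastic loop-extrusion kinetics on the bead chain.

Extruders are two-anchor entities loaded at (i, i+3); each end translocates
outward independently at speed ``v_extr`` (in kbp per tau), halting at an
active CTCF boundary bead of opposing orientation (or a bidirectional one),
at a bead occupied by another extruder's anchor, or at the chain end.
CTCF / chain-end arrest is permanent until the extruder unbinds; collision
arrest is re-tested every sweep, since the obstacle may move.  Extruders
unbind at rate ``k_off`` and instantly rebind at a fresh random position,
keeping the bound count constant.  The processivity lambda = v_extr / k_off
(160 kbp at the defaults) sets the collision-free loop-size scale.

Orientation convention (convergent-loop geometry): a *forward* (+ strand)
motif blocks ends travelling leftward (toward decreasing coordinates), a
*backward* motif blocks ends travelling rightward, and a bidirectional
boundary blocks both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

REASONS = ("none", "ctcf", "collision", "chain_end")
_NONE, _CTCF, _COLLISION, _CHAIN_END = range(4)
_STICKY = (_CTCF, _CHAIN_END)

LOAD_SPAN = 3  # anchors at (i, i+3): a crumple spring may already join (i, i+2)


@dataclass
class ExtrusionParams:
    density: float = 10.0          # extruders per Mbp (7.5 during pre-relaxation)
    v_extr: float = 4.0e-3         # translocation speed, kbp per tau
    k_off: float = 2.5e-5          # unbinding rate, per tau
    event_interval: int = 100      # MD steps between extrusion-event sweeps

    def __post_init__(self) -> None:
        if self.density <= 0 or self.v_extr <= 0 or self.k_off < 0:
            raise ValueError("density and v_extr must be positive, k_off >= 0")
        if self.event_interval < 1:
            raise ValueError("event_interval must be >= 1")

    @property
    def processivity_kbp(self) -> float:
        """lambda = v_extr / k_off."""
        if self.k_off == 0:
            return float("inf")
        return self.v_extr / self.k_off


@dataclass(frozen=True)
class Extruder:
    """Read-only view of one extruder's state."""

    left_anchor: int
    right_anchor: int
    blocked_left: str = "none"
    blocked_right: str = "none"


class ExtruderSystem:
    """All extruders on one fragment, with boundary logic and turnover."""

    def __init__(
        self,
        n_beads: int,
        params: ExtrusionParams,
        boundaries: Optional[Mapping[int, str]] = None,
    ) -> None:
        if n_beads <= LOAD_SPAN + 1:
            raise ValueError("fragment too small for extrusion")
        self.n_beads = n_beads
        self.params = params
        self.blocks_leftward = np.zeros(n_beads, dtype=bool)
        self.blocks_rightward = np.zeros(n_beads, dtype=bool)
        self.set_boundaries(boundaries or {})
        self.left = np.empty(0, dtype=np.int64)
        self.right = np.empty(0, dtype=np.int64)
        self._bl = np.empty(0, dtype=np.int64)  # blocked reason per end
        self._br = np.empty(0, dtype=np.int64)
        self.occupied = np.zeros(n_beads, dtype=bool)
        self.birth_time = np.empty(0, dtype=float)
        self.clock = 0.0
        #: (lifetime tau, loop size in beads at unbinding) per completed lifetime
        self.unbind_log: list[tuple[float, int]] = []

    # -- boundaries ---------------------------------------------------------

    def set_boundaries(self, boundaries: Mapping[int, str]) -> None:
        """Install the active boundary set for this run (bead -> orientation)."""
        self.blocks_leftward[:] = False
        self.blocks_rightward[:] = False
        for bead, orientation in boundaries.items():
            if not 0 <= bead < self.n_beads:
                raise ValueError(f"boundary bead {bead} outside fragment")
            if orientation in ("forward", "bidirectional"):
                self.blocks_leftward[bead] = True
            if orientation in ("backward", "bidirectional"):
                self.blocks_rightward[bead] = True
            if orientation not in ("forward", "backward", "bidirectional"):
                raise ValueError(f"unknown orientation {orientation!r}")

    # -- loading ------------------------------------------------------------

    def _place_one(self, rng: np.random.Generator) -> tuple[int, int]:
        for _ in range(200 * self.n_beads):
            i = int(rng.integers(0, self.n_beads - LOAD_SPAN))
            if not self.occupied[i] and not self.occupied[i + LOAD_SPAN]:
                return i, i + LOAD_SPAN
        raise RuntimeError("could not place extruder: fragment too crowded")

    def seed(self, count: int, rng: np.random.Generator) -> None:
        if 2 * count > self.n_beads:
            raise ValueError(
                f"fragment of {self.n_beads} beads too small for {count} extruders"
            )
        lefts, rights = [], []
        for _ in range(count):
            i, j = self._place_one(rng)
            self.occupied[i] = self.occupied[j] = True
            lefts.append(i)
            rights.append(j)
        self.left = np.array(lefts, dtype=np.int64)
        self.right = np.array(rights, dtype=np.int64)
        self._bl = np.zeros(count, dtype=np.int64)
        self._br = np.zeros(count, dtype=np.int64)
        self.birth_time = np.full(count, self.clock)

    # -- kinetics -----------------------------------------------------------

    def _advance_end(self, k: int, side: str, p_step: float,
                     rng: np.random.Generator) -> None:
        blocked = self._bl if side == "left" else self._br
        if blocked[k] in _STICKY:
            return
        anchors = self.left if side == "left" else self.right
        step = -1 if side == "left" else +1
        cand = anchors[k] + step
        if cand < 0 or cand >= self.n_beads:
            blocked[k] = _CHAIN_END
            return
        blocks = self.blocks_rightward if side == "right" else self.blocks_leftward
        if blocks[cand]:
            blocked[k] = _CTCF
            return
        if self.occupied[cand]:
            blocked[k] = _COLLISION
            return
        blocked[k] = _NONE
        if rng.random() < p_step:
            self.occupied[anchors[k]] = False
            self.occupied[cand] = True
            anchors[k] = cand

    def translocate(self, dt: float, rng: np.random.Generator) -> None:
        """One extrusion sweep over dt tau; at most one bead step per end."""
        p_step = self.params.v_extr * dt
        if p_step > 1.0 + 1e-12:
            raise ValueError("dt * v_extr must not exceed 1 kbp per sweep")
        for k in rng.permutation(len(self.left)):
            self._advance_end(k, "left", p_step, rng)
            self._advance_end(k, "right", p_step, rng)

    def unbind_rebind(self, dt: float, rng: np.random.Generator) -> None:
        """Each extruder unbinds with probability k_off*dt and is instantly
        re-seeded at a fresh random position (constant count)."""
        p_off = self.params.k_off * dt
        if p_off == 0.0:
            return
        for k in range(len(self.left)):
            if rng.random() < p_off:
                self.unbind_log.append(
                    (self.clock - self.birth_time[k],
                     int(self.right[k] - self.left[k]))
                )
                self.occupied[self.left[k]] = False
                self.occupied[self.right[k]] = False
                i, j = self._place_one(rng)
                self.occupied[i] = self.occupied[j] = True
                self.left[k], self.right[k] = i, j
                self._bl[k] = self._br[k] = _NONE
                self.birth_time[k] = self.clock

    def sweep(self, dt: float, rng: np.random.Generator) -> None:
        """Translocation followed by turnover; advances the extrusion clock."""
        self.translocate(dt, rng)
        self.clock += dt
        self.unbind_rebind(dt, rng)

    # -- views --------------------------------------------------------------

    @property
    def extruders(self) -> list[Extruder]:
        return [
            Extruder(int(l), int(r), REASONS[bl], REASONS[br])
            for l, r, bl, br in zip(self.left, self.right, self._bl, self._br)
        ]

    def bonds(self) -> np.ndarray:
        """Current (left, right) anchor pairs as an (n, 2) int array for the
        force field; regenerated after every sweep."""
        return np.stack([self.left, self.right], axis=1) if len(self.left) else \
            np.empty((0, 2), dtype=np.int64)

    def loop_sizes(self) -> np.ndarray:
        return self.right - self.left

    def log_row(self) -> list[tuple]:
        """Rows (clock, id, left, right, blocked_left, blocked_right) for TSV logs."""
        return [
            (self.clock, k, int(self.left[k]), int(self.right[k]),
             REASONS[self._bl[k]], REASONS[self._br[k]])
            for k in range(len(self.left))
        ]


def extruder_count(n_beads: int, density: float) -> int:
    """Number of bound extruders: round(density per Mbp x fragment Mbp)."""
    return int(round(density * n_beads / 1000.0))


def seed_extruders(
    n_beads: int,
    params: ExtrusionParams,
    rng: np.random.Generator | int,
    boundaries: Optional[Mapping[int, str]] = None,
) -> ExtruderSystem:
    """Create and populate an ExtruderSystem at the parameterized density."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    system = ExtruderSystem(n_beads, params, boundaries)
    system.seed(extruder_count(n_beads, params.density), rng)
    return system


def write_trajectory_tsv(path, rows) -> None:
    """Dump accumulated extruder log rows as a TSV (debugging / analysis aid)."""
    with open(path, "w") as fh:
        fh.write("time_tau\textruder\tleft\tright\tblocked_left\tblocked_right\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
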