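"""Force-field terms for the heteromorphic chromatin polymer model.

The chromatin fiber is a bead-and-spring polymer at 1 kbp/bead (bead
diameter sigma is the length unit, kBT the energy unit).  Excluded volume
is the Weeks-Chandler-Andersen (WCA) potential, chain connectivity a FENE
spring, stiffness a Kratky-Porod bending term.  Multivalent
chromatin-binding proteins attract marked beads through a truncated-and-
shifted Lennard-Jones well whose depth is set by an affinity table, and
loop extruders are harmonic springs with a short-range WCA core.  Every
energy here is a pure function of separation (or angle), so each term is
testable in isolation; the matching analytic forces live alongside and are
checked against numerical gradients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from scipy.optimize import minimize_scalar

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)  # minimum of the 12-6 potential, in sigma

MARKS = ("atac", "h3k27ac", "h3k27me3", "h3k9me3")
SPECIES = ("active", "polycomb", "hp1")


@dataclass
class SimulationUnits:
    """Simulation units: sigma (= 1 kbp of chromatin), kBT, tau = sigma*sqrt(m/kBT).

    ``physical_sigma_nm`` is only used when converting to physical lengths
    (FISH fits, density rules); the simulation itself is agnostic to it.
    """

    sigma_length: float = 1.0
    energy_unit: float = 1.0
    time_unit: float = 1.0
    timestep: float = 0.01
    physical_sigma_nm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.physical_sigma_nm is not None and not (
            15.0 <= self.physical_sigma_nm <= 40.0
        ):
            raise ValueError(
                "physical_sigma_nm outside the plausible 15-40 nm window"
            )


@dataclass
class ForceFieldParams:
    """Interaction constants, in kBT / sigma units."""

    fene_k: float = 30.0
    fene_r0: float = 1.6
    bend_lp: float = 4.0
    tf_cutoff: float = 1.8
    extruder_k: float = 40.0
    extruder_r0: float = 1.5
    crumple_k: float = 200.0
    crumple_r0: float = 1.1
    chromatin_self_eps: float = 0.4

    def __post_init__(self) -> None:
        for name in (
            "fene_k",
            "fene_r0",
            "bend_lp",
            "tf_cutoff",
            "extruder_k",
            "extruder_r0",
            "crumple_k",
            "crumple_r0",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.chromatin_self_eps < 0:
            raise ValueError("chromatin_self_eps must be non-negative")
        if self.extruder_r0 >= self.fene_r0 * 2:
            raise ValueError("extruder_r0 implausibly large")


def _default_affinities() -> dict:
    return {
        ("active", "atac"): 7.0,
        ("active", "h3k27ac"): 3.0,
        ("polycomb", "h3k27me3"): 7.0,
        ("hp1", "h3k9me3"): 3.0,
    }


@dataclass
class AffinityTable:
    """Protein-species x chromatin-mark binding well depths (kBT).

    Unlisted pairs are purely steric (depth 0).  Active proteins bind
    accessible (ATAC) beads strongly and acetylated beads weakly; polycomb-
    like proteins bind H3K27me3; HP1-like proteins bind H3K9me3.
    """

    table: dict = field(default_factory=_default_affinities)

    def __post_init__(self) -> None:
        for (species, mark), eps in self.table.items():
            if species not in SPECIES:
                raise ValueError(f"unknown protein species: {species!r}")
            if mark not in MARKS:
                raise ValueError(f"unknown mark: {mark!r}")
            if eps < 0:
                raise ValueError("affinities must be non-negative")

    def get(self, species: str, mark: str) -> float:
        if species not in SPECIES:
            raise ValueError(f"unknown protein species: {species!r}")
        if mark not in MARKS:
            raise ValueError(f"unknown mark: {mark!r}")
        return self.table.get((species, mark), 0.0)


# ---------------------------------------------------------------------------
# pair / bond / angle energies (sigma = 1, kBT = 1)
# ---------------------------------------------------------------------------


def wca_energy(r: float) -> float:
    """Purely repulsive WCA potential: 4[(1/r)^12 - (1/r)^6 + 1/4] below 2^(1/6)."""
    if r <= 0:
        raise ValueError("separation must be positive")
    if r >= WCA_CUTOFF:
        return 0.0
    inv6 = r ** -6
    return 4.0 * (inv6 * inv6 - inv6 + 0.25)


def wca_force(r: float) -> float:
    """Radial force -dU/dr of the WCA potential (positive = repulsive)."""
    if r <= 0:
        raise ValueError("separation must be positive")
    if r >= WCA_CUTOFF:
        return 0.0
    inv6 = r ** -6
    return 24.0 * (2.0 * inv6 * inv6 - inv6) / r


def fene_energy(r: float, k: float = 30.0, r0: float = 1.6) -> float:
    """FENE spring -(k r0^2/2) ln[1 - (r/r0)^2]; diverges at the maximum extension."""
    if r < 0:
        raise ValueError("separation must be non-negative")
    if r >= r0:
        raise FloatingPointError(
            f"FENE bond overstretched: r={r:.4f} >= r0={r0} (bond blow-up)"
        )
    return -0.5 * k * r0 * r0 * math.log(1.0 - (r / r0) ** 2)


def fene_force(r: float, k: float = 30.0, r0: float = 1.6) -> float:
    """Radial force of the FENE spring (negative: always pulls inward)."""
    if r < 0:
        raise ValueError("separation must be non-negative")
    if r >= r0:
        raise FloatingPointError(
            f"FENE bond overstretched: r={r:.4f} >= r0={r0} (bond blow-up)"
        )
    return -k * r / (1.0 - (r / r0) ** 2)


def bending_energy(theta: float, lp: float = 4.0) -> float:
    """Kratky-Porod bending term (lp/sigma)(1 - cos theta) for successive bonds."""
    if not 0.0 <= theta <= math.pi:
        raise ValueError("theta must lie in [0, pi]")
    return lp * (1.0 - math.cos(theta))


_LJ_NORM_CACHE: dict = {}


def lj_normalization(rc: float) -> float:
    """Normalization N of the truncated-shifted LJ so its well depth is exactly -eps.

    Computed by bracketed 1-D minimization of the eps=1 potential and cached
    per cutoff.  Requires the cutoff beyond the LJ minimum (else there is no
    attractive well to normalize).
    """
    if rc <= WCA_CUTOFF:
        raise ValueError("cutoff must exceed 2^(1/6) sigma for an attractive well")
    key = round(rc, 12)
    if key in _LJ_NORM_CACHE:
        return _LJ_NORM_CACHE[key]
    shift = -(rc ** -12) + rc ** -6

    def bracket(d: float) -> float:
        inv6 = d ** -6
        return inv6 * inv6 - inv6 + shift

    res = minimize_scalar(bracket, bounds=(0.5, rc), method="bounded",
                          options={"xatol": 1e-12})
    depth = -4.0 * res.fun  # depth of the unnormalized eps=1 potential
    norm = 1.0 / depth
    _LJ_NORM_CACHE[key] = norm
    return norm


def tf_chromatin_energy(d: float, eps: float, rc: float = 1.8) -> float:
    """Truncated-and-shifted LJ attraction between a protein and a marked bead.

    4*eps*N [ (1/d)^12 - (1/d)^6 - (1/rc)^12 + (1/rc)^6 ] below the cutoff,
    zero beyond; N ensures the minimum is exactly -eps.  The steric-only
    limit eps=0 falls back to the plain WCA potential (the non-binding
    protein branch), which is the convention asserted in the tests.
    """
    if d <= 0:
        raise ValueError("separation must be positive")
    if eps < 0:
        raise ValueError("well depth must be non-negative")
    if eps == 0.0:
        return wca_energy(d)
    if d >= rc:
        return 0.0
    norm = lj_normalization(rc)
    inv6 = d ** -6
    shift = -(rc ** -12) + rc ** -6
    return 4.0 * eps * norm * (inv6 * inv6 - inv6 + shift)


def tf_chromatin_force(d: float, eps: float, rc: float = 1.8) -> float:
    """Radial force of :func:`tf_chromatin_energy`."""
    if d <= 0:
        raise ValueError("separation must be positive")
    if eps == 0.0:
        return wca_force(d)
    if d >= rc:
        return 0.0
    norm = lj_normalization(rc)
    inv6 = d ** -6
    return 4.0 * eps * norm * (12.0 * inv6 * inv6 - 6.0 * inv6) / d


def extruder_bond_energy(r: float, k: float = 40.0, r0: float = 1.5) -> float:
    """Loop-extruder spring: WCA core plus harmonic k (r - r0)^2."""
    if r <= 0:
        raise ValueError("separation must be positive")
    return wca_energy(r) + k * (r - r0) ** 2


def extruder_bond_force(r: float, k: float = 40.0, r0: float = 1.5) -> float:
    if r <= 0:
        raise ValueError("separation must be positive")
    return wca_force(r) - 2.0 * k * (r - r0)


def crumple_bond_energy(r: float, k: float = 200.0, r0: float = 1.1) -> float:
    """Next-nearest-neighbor compaction spring k (r - r0)^2 (heteromorphism)."""
    if r < 0:
        raise ValueError("separation must be non-negative")
    return k * (r - r0) ** 2


def crumple_bond_force(r: float, k: float = 200.0, r0: float = 1.1) -> float:
    if r < 0:
        raise ValueError("separation must be non-negative")
    return -2.0 * k * (r - r0)


def pair_affinity(
    species: str,
    binding: bool,
    marks: frozenset | set,
    affinities: Optional[AffinityTable] = None,
) -> float:
    """Well depth for a protein-chromatin pair.

    A non-binding protein is purely steric (depth 0).  A binding protein
    sees the *maximum* affinity among the marks the bead carries: a single
    pairwise potential needs a single depth, and the maximum preserves
    strong-site semantics on multiply-marked beads (an ATAC+H3K27ac bead
    binds active proteins at the full 7 kBT).
    """
    if species not in SPECIES:
        raise ValueError(f"unknown protein species: {species!r}")
    for m in marks:
        if m not in MARKS:
            raise ValueError(f"unknown mark: {m!r}")
    if not binding:
        return 0.0
    if affinities is None:
        affinities = AffinityTable()
    depths = [affinities.get(species, m) for m in marks]
    return max(depths, default=0.0)


def chromatin_pair_eps(
    marks_a: frozenset | set,
    marks_b: frozenset | set,
    self_eps: float = 0.4,
) -> float:
    """Direct chromatin-chromatin attraction: weak (0.4 kBT by default) between
    beads where *neither* carries the active H3K27ac mark, steric otherwise."""
    for m in set(marks_a) | set(marks_b):
        if m not in MARKS:
            raise ValueError(f"unknown mark: {m!r}")
    if "h3k27ac" in marks_a or "h3k27ac" in marks_b:
        return 0.0
    return self_eps
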