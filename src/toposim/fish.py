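"""Simulated two-color FISH: probe separations and physical bead-size fitting.

Each probe maps to the beads its genomic interval overlaps; its position in
a structure is the center of mass of those beads (on unwrapped coordinates,
so probes straddling the periodic box are handled correctly).  The
distribution of pair separations across the ensemble, in sigma, is compared
with an experimental nm-valued sample by the two-sample Kolmogorov-Smirnov
statistic; the physical bead size sigma (nm) is the scale factor minimizing
that distance, searched on a grid over 10-50 nm and refined locally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .annotation import GenomeFragment, _beads_overlapping

SIGMA_BRACKET_NM = (10.0, 50.0)
SIGMA_GRID_NM = 0.5


@dataclass
class ProbePair:
    """Two non-overlapping genomic intervals on a fragment."""

    fragment: GenomeFragment
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    label: str = ""
    beads_a: np.ndarray = field(init=False)
    beads_b: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        (a0, a1), (b0, b1) = self.interval_a, self.interval_b
        if a0 < b1 and b0 < a1:
            raise ValueError("probe intervals must not overlap")
        for lo, hi in (self.interval_a, self.interval_b):
            if lo < self.fragment.start or hi > self.fragment.end:
                raise ValueError("probe interval outside fragment")
        self.beads_a = np.array(list(_beads_overlapping(self.fragment, a0, a1)))
        self.beads_b = np.array(list(_beads_overlapping(self.fragment, b0, b1)))
        if len(self.beads_a) == 0 or len(self.beads_b) == 0:
            raise ValueError("each probe must cover at least one bead")


def probe_separation(structure: np.ndarray, pair: ProbePair) -> float:
    """Euclidean distance between the two probes' bead centers of mass (sigma)."""
    structure = np.asarray(structure)
    if structure.shape[0] < pair.fragment.n_beads:
        raise ValueError("structure has fewer beads than the fragment")
    com_a = structure[pair.beads_a].mean(axis=0)
    com_b = structure[pair.beads_b].mean(axis=0)
    return float(np.linalg.norm(com_a - com_b))


def separation_distribution(ensemble: np.ndarray, pair: ProbePair) -> np.ndarray:
    """One separation per structure, in sigma."""
    ensemble = np.asarray(ensemble)
    if ensemble.ndim != 3 or ensemble.shape[0] == 0:
        raise ValueError("ensemble must be a non-empty (F, n, 3) array")
    return np.array([probe_separation(s, pair) for s in ensemble])


def fit_sigma_nm(
    sim_sigma: Sequence[float],
    exp_nm: Sequence[float],
    bracket: tuple[float, float] = SIGMA_BRACKET_NM,
    grid_nm: float = SIGMA_GRID_NM,
) -> tuple[float, float, float]:
    """Fit the physical bead size: the sigma (nm) minimizing the two-sample
    KS distance between (sim x sigma) and the experimental distances.

    Returns (sigma_nm, ks_statistic, p_value at the optimum).  The search is
    a coarse grid over the bracket followed by bounded local refinement.
    """
    sim = np.asarray(sim_sigma, dtype=float)
    exp = np.asarray(exp_nm, dtype=float)
    if len(sim) < 10 or len(exp) < 10:
        raise ValueError("need at least 10 values per sample")
    if np.std(exp) == 0:
        raise ValueError("experimental sample is degenerate (zero variance)")

    def ks(s: float) -> float:
        return stats.ks_2samp(sim * s, exp).statistic

    grid = np.arange(bracket[0], bracket[1] + grid_nm / 2, grid_nm)
    stats_grid = [ks(s) for s in grid]
    best = int(np.argmin(stats_grid))
    lo = grid[max(0, best - 1)]
    hi = grid[min(len(grid) - 1, best + 1)]
    res = optimize.minimize_scalar(ks, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-3})
    sigma = float(res.x) if res.fun <= stats_grid[best] else float(grid[best])
    result = stats.ks_2samp(sim * sigma, exp)
    return sigma, float(result.statistic), float(result.pvalue)


def normalized_separation(values: Sequence[float], sigma: float) -> np.ndarray:
    """(x - median(x)) / sigma: median-centered separations in bead-size units."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(values, dtype=float)
    return (x - np.median(x)) / sigma


def read_distance_file(path: str | Path, column: Optional[str] = None) -> np.ndarray:
    """Read experimental distances (nm) from a single-column text file or a
    TSV with a header naming the wanted column."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    try:
        float(first.split("\t")[0])
        return np.loadtxt(path, ndmin=1)
    except ValueError:
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        col = column or df.columns[-1]
        return df[col].to_numpy(dtype=float)
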