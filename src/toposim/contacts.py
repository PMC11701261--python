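"""In-silico contact maps and comparison statistics.

Simulated Hi-C / Micro-C-like maps are built by the crosslinking-inspired
read sampler: pick a structure, pick a random bead pair, accept it as a
read with probability exp(-r/rt), where rt is the crosslinking distance
scale (3.5 sigma Hi-C-like, 1.5 sigma Micro-C-like).  Maps can be binned,
ICE-balanced, and compared either directly (Pearson of the upper triangles)
or through the directionality score D(i), the difference between upstream
and downstream aggregated contacts in a 20-500 kbp window, which cancels
the genomic-distance dependence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats


@dataclass
class ContactMap:
    """Symmetric binned read-count (or balanced) matrix."""

    matrix: np.ndarray
    bin_kb: int = 1
    start_bp: int = 0
    chrom: str = "synthetic"
    normalization: str = "raw"
    mask: np.ndarray = field(default=None)  # True = masked-out bin
    attempts: int = 0  # valid sampling trials behind the counts (0 = unknown)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        if (m < 0).any():
            raise ValueError("contact matrix must be non-negative")
        self.matrix = m
        if self.mask is None:
            self.mask = np.zeros(m.shape[0], dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def total_reads(self) -> float:
        # each read is stored twice (symmetric accumulation), so the grand
        # sum is twice the read count regardless of binning
        return float(self.matrix.sum()) / 2.0

    def sum(self) -> float:
        return float(self.matrix.sum())


def _min_image(d: np.ndarray, box: Optional[np.ndarray]) -> np.ndarray:
    if box is not None:
        d = d - box * np.rint(d / box)
    return d


def pairwise_acceptance(r: np.ndarray | float, rt: float) -> np.ndarray | float:
    """Read-acceptance probability exp(-r/rt)."""
    if rt <= 0:
        raise ValueError("rt must be positive")
    return np.exp(-np.asarray(r) / rt)


def sample_reads(
    ensemble: np.ndarray,
    n_reads: int,
    rt: float = 3.5,
    rng: np.random.Generator | int = 0,
    box: Optional[np.ndarray] = None,
    batch: int = 100_000,
) -> ContactMap:
    """Monte-Carlo read sampling over a structure ensemble (F, n, 3).

    Self-pairs are excluded; counts accumulate symmetrically at 1 kbp
    (1 bead) resolution until exactly n_reads are registered.
    """
    ensemble = np.asarray(ensemble)
    if ensemble.ndim != 3 or ensemble.shape[0] == 0:
        raise ValueError("ensemble must be a non-empty (F, n, 3) array")
    if rt <= 0:
        raise ValueError("rt must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_struct, n, _ = ensemble.shape
    counts = np.zeros((n, n))
    accepted = 0
    attempts = 0
    while accepted < n_reads:
        m = batch
        s = rng.integers(0, n_struct, m)
        i = rng.integers(0, n, m)
        j = rng.integers(0, n, m)
        keep = i != j
        s, i, j = s[keep], i[keep], j[keep]
        d = _min_image(ensemble[s, i] - ensemble[s, j], box)
        r = np.sqrt((d ** 2).sum(axis=1))
        acc = rng.random(len(r)) < np.exp(-r / rt)
        ai, aj = i[acc], j[acc]
        room = n_reads - accepted
        if len(ai) > room:
            # count only the trials consumed up to the last kept read
            attempts += np.flatnonzero(acc)[room - 1] + 1 if room else 0
            ai, aj = ai[:room], aj[:room]
        else:
            attempts += len(r)
        np.add.at(counts, (ai, aj), 1.0)
        np.add.at(counts, (aj, ai), 1.0)
        accepted += len(ai)
    return ContactMap(matrix=counts, bin_kb=1, attempts=attempts)


def bin_map(cmap: ContactMap, target_kb: int) -> ContactMap:
    """Block-sum aggregation to a coarser bin size (reads conserved exactly)."""
    if target_kb % cmap.bin_kb != 0:
        raise ValueError("target bin size must be a multiple of the source bin")
    f = target_kb // cmap.bin_kb
    if f == 1:
        return ContactMap(cmap.matrix.copy(), cmap.bin_kb, cmap.start_bp,
                          cmap.chrom, cmap.normalization)
    n = cmap.n_bins
    n_out = math.ceil(n / f)
    padded = np.zeros((n_out * f, n_out * f))
    padded[:n, :n] = cmap.matrix
    out = padded.reshape(n_out, f, n_out, f).sum(axis=(1, 3))
    return ContactMap(out, target_kb, cmap.start_bp, cmap.chrom, cmap.normalization)


def ice_normalize(cmap: ContactMap, max_iter: int = 500, tol: float = 1e-8) -> ContactMap:
    """Iterative correction (matrix balancing): divide by bias vectors until
    all non-masked marginals are equal.  Bins with zero marginal are masked."""
    M = cmap.matrix.copy()
    marg = M.sum(axis=1)
    mask = marg == 0
    active = ~mask
    if not active.any():
        raise ValueError("all bins empty; nothing to balance")
    b = np.ones(cmap.n_bins)
    residual = np.inf
    for _ in range(max_iter):
        W = M / np.outer(b, b)
        W[mask, :] = 0.0
        W[:, mask] = 0.0
        s = W.sum(axis=1)
        mean_s = s[active].mean()
        residual = float(np.std(s[active]) / mean_s) if mean_s > 0 else np.inf
        if residual < tol:
            break
        upd = np.where(active & (s > 0), s / mean_s, 1.0)
        b *= np.sqrt(upd)
    else:
        raise RuntimeError(
            f"ICE did not converge in {max_iter} iterations (residual {residual:.3e})"
        )
    W = M / np.outer(b, b)
    W[mask, :] = 0.0
    W[:, mask] = 0.0
    W = (W + W.T) / 2
    return ContactMap(W, cmap.bin_kb, cmap.start_bp, cmap.chrom, "ICE", mask=mask)


def map_correlation(
    map_a: ContactMap, map_b: ContactMap, exclude_band_bins: int = 0
) -> tuple[float, float]:
    """Pearson r (and p) over the vectorized upper triangles of jointly
    unmasked bins, optionally excluding |i-j| below a near-diagonal band."""
    if map_a.matrix.shape != map_b.matrix.shape or map_a.bin_kb != map_b.bin_kb:
        raise ValueError("maps must share shape and binning")
    n = map_a.n_bins
    iu, ju = np.triu_indices(n, k=max(1, exclude_band_bins))
    ok = ~(map_a.mask[iu] | map_a.mask[ju] | map_b.mask[iu] | map_b.mask[ju])
    xa, xb = map_a.matrix[iu[ok], ju[ok]], map_b.matrix[iu[ok], ju[ok]]
    if len(xa) < 3:
        raise ValueError("fewer than 3 jointly unmasked bin pairs")
    r, p = stats.pearsonr(xa, xb)
    return float(r), float(p)


def directionality_score(
    cmap: ContactMap, lower_kb: int = 20, upper_kb: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """D(i) = sum of contacts to the left minus to the right of bin i within
    the [lower, upper] genomic window.  Returns (D, untruncated mask); bins
    whose window spills over a fragment edge are flagged truncated.
    """
    if not upper_kb > lower_kb >= cmap.bin_kb:
        raise ValueError("need upper > lower >= bin size")
    n = cmap.n_bins
    if n * cmap.bin_kb < 2 * lower_kb:
        raise ValueError("fragment shorter than twice the lower threshold")
    lo = lower_kb // cmap.bin_kb
    hi = upper_kb // cmap.bin_kb
    D = np.zeros(n)
    untruncated = np.zeros(n, dtype=bool)
    M = cmap.matrix
    for i in range(n):
        left = M[i, max(0, i - hi): max(0, i - lo + 1)].sum()
        right = M[i, min(n, i + lo): min(n, i + hi + 1)].sum()
        D[i] = left - right
        untruncated[i] = (i - hi >= 0) and (i + hi <= n - 1)
    return D, untruncated


def directionality_correlation(
    map_a: ContactMap, map_b: ContactMap,
    lower_kb: int = 20, upper_kb: int = 500,
) -> tuple[float, float]:
    """Pearson r (and p) of the two D(i) profiles on untruncated bins."""
    da, ua = directionality_score(map_a, lower_kb, upper_kb)
    db, ub = directionality_score(map_b, lower_kb, upper_kb)
    if len(da) != len(db):
        raise ValueError("maps must share binning")
    ok = ua & ub
    if ok.sum() < 3:
        raise ValueError("fewer than 3 untruncated bins")
    r, p = stats.pearsonr(da[ok], db[ok])
    return float(r), float(p)


# ---------------------------------------------------------------------------
# text I/O (dense TSV and sparse triplets)
# ---------------------------------------------------------------------------


def write_dense_tsv(cmap: ContactMap, path) -> None:
    header = f"# bin_kb={cmap.bin_kb} start_bp={cmap.start_bp} " \
             f"chrom={cmap.chrom} normalization={cmap.normalization}\n"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, cmap.matrix, delimiter="\t", fmt="%.8g")


def read_dense_tsv(path) -> ContactMap:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                k, _, v = tok.partition("=")
                meta[k] = v
            matrix = np.loadtxt(fh, delimiter="\t", ndmin=2)
        else:
            fh.seek(0)
            matrix = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return ContactMap(
        matrix,
        bin_kb=int(meta.get("bin_kb", 1)),
        start_bp=int(meta.get("start_bp", 0)),
        chrom=meta.get("chrom", "synthetic"),
        normalization=meta.get("normalization", "raw"),
    )


def write_triplets(cmap: ContactMap, path) -> None:
    """Sparse upper-triangle triplet text: i, j, count."""
    with open(path, "w") as fh:
        fh.write(f"# n_bins={cmap.n_bins} bin_kb={cmap.bin_kb}\n")
        iu, ju = np.nonzero(np.triu(cmap.matrix))
        for i, j in zip(iu, ju):
            fh.write(f"{i}\t{j}\t{cmap.matrix[i, j]:.8g}\n")


def read_triplets(path) -> ContactMap:
    with open(path) as fh:
        header = fh.readline()
        meta = {}
        for tok in header[1:].split():
            k, _, v = tok.partition("=")
            meta[k] = v
        n = int(meta["n_bins"])
        matrix = np.zeros((n, n))
        for line in fh:
            i, j, v = line.split("\t")
            i, j, v = int(i), int(j), float(v)
            matrix[i, j] = v
            matrix[j, i] = v
    return ContactMap(matrix, bin_kb=int(meta.get("bin_kb", 1)))
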