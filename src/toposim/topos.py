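"""Topos mining: promoter partners, influential nodes, networks, diversity.

A promoter's ATAC partners are the accessible-chromatin beads within 3.5
sigma of it (minimum image, strict inequality) in at least 10% of the
structure ensemble; influential nodes clear a 50% bar.  The topos is the
genomic span of promoter plus partners.  Per structure, the subset of
partners simultaneously in contact is that structure's interaction network;
the catalog of networks over the ensemble is summarized by the structural
diversity H = S/(q+1), the Shannon entropy of network frequencies
normalized by partner count plus one (well-defined at q = 0; the number of
distinct networks is bounded by 2^q).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .annotation import GenomeFragment

CONTACT_THRESHOLD_SIGMA = 3.5
PARTNER_THRESHOLD = 0.10
INFLUENTIAL_THRESHOLD = 0.50


def _pair_distances(
    ensemble: np.ndarray, bead: int, candidates: np.ndarray,
    box: Optional[np.ndarray],
) -> np.ndarray:
    """(F, C) minimum-image distances from one bead to candidate beads."""
    d = ensemble[:, candidates] - ensemble[:, [bead]]
    if box is not None:
        d = d - box * np.rint(d / box)
    return np.sqrt((d ** 2).sum(axis=2))


def contact_frequency(
    ensemble: np.ndarray,
    promoter_bead: int,
    candidates: Sequence[int],
    threshold: float = CONTACT_THRESHOLD_SIGMA,
    box: Optional[np.ndarray] = None,
) -> dict[int, float]:
    """Fraction of structures with bead-center distance < threshold, per candidate."""
    ensemble = np.asarray(ensemble)
    if ensemble.ndim != 3 or ensemble.shape[0] == 0:
        raise ValueError("ensemble must be a non-empty (F, n, 3) array")
    candidates = np.asarray(sorted(candidates), dtype=np.int64)
    if len(candidates) == 0:
        return {}
    dist = _pair_distances(ensemble, promoter_bead, candidates, box)
    freq = (dist < threshold).mean(axis=0)
    return {int(b): float(f) for b, f in zip(candidates, freq)}


def call_partners(
    frequencies: Mapping[int, float], threshold: float = PARTNER_THRESHOLD
) -> set[int]:
    """Beads with contact frequency >= threshold (inclusive)."""
    return {b for b, f in frequencies.items() if f >= threshold}


def call_influential(
    frequencies: Mapping[int, float], threshold: float = INFLUENTIAL_THRESHOLD
) -> set[int]:
    """Partners in contact in at least half the structures (inclusive)."""
    return call_partners(frequencies, threshold)


def topos_extent(
    promoter_bead: int, partners: Sequence[int], fragment: GenomeFragment
) -> tuple[tuple[int, int], float]:
    """Genomic interval spanned by promoter plus partners, and its size in kbp.

    With no partners the topos degenerates to the promoter bead's own 1 kbp.
    """
    beads = sorted(set(partners) | {promoter_bead})
    lo, hi = beads[0], beads[-1]
    start_bp = fragment.interval_of(lo)[0]
    end_bp = fragment.interval_of(hi)[1]
    return (start_bp, end_bp), float(hi - lo + 1)


@dataclass
class NetworkCatalog:
    """Catalog of interaction networks (partner subsets) over an ensemble."""

    counts: dict = field(default_factory=dict)  # frozenset(partners) -> count
    n_structures: int = 0

    @property
    def N(self) -> int:
        return len(self.counts)

    @property
    def fractions(self) -> dict:
        if self.n_structures == 0:
            raise ValueError("empty catalog")
        return {k: c / self.n_structures for k, c in self.counts.items()}


def enumerate_networks(
    ensemble: np.ndarray,
    promoter_bead: int,
    partners: Sequence[int],
    threshold: float = CONTACT_THRESHOLD_SIGMA,
    box: Optional[np.ndarray] = None,
) -> NetworkCatalog:
    """Per structure, the subset of partners in contact with the promoter.

    The empty subset is a valid network; N <= min(2^q, n_structures).
    """
    ensemble = np.asarray(ensemble)
    if ensemble.ndim != 3 or ensemble.shape[0] == 0:
        raise ValueError("ensemble must be a non-empty (F, n, 3) array")
    partners = np.asarray(sorted(partners), dtype=np.int64)
    catalog = NetworkCatalog(n_structures=ensemble.shape[0])
    if len(partners) == 0:
        catalog.counts[frozenset()] = ensemble.shape[0]
        return catalog
    contact = _pair_distances(ensemble, promoter_bead, partners, box) < threshold
    for row in contact:
        key = frozenset(int(b) for b in partners[row])
        catalog.counts[key] = catalog.counts.get(key, 0) + 1
    return catalog


def diversity_score(catalog: NetworkCatalog | Sequence[float], q: int) -> float:
    """Normalized Shannon diversity H = (1/(q+1)) sum_i -n_i ln n_i.

    q is the partner count; the +1 keeps H finite for partner-less genes.
    H = 0 when a single network absorbs all structures; the maximum
    ln(min(2^q, n_structures))/(q+1) needs uniform network occupancy.
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    if isinstance(catalog, NetworkCatalog):
        fracs = np.array(list(catalog.fractions.values()))
    else:
        fracs = np.asarray(catalog, dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("network fractions must sum to 1")
    nz = fracs[fracs > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return entropy / (q + 1)


@dataclass
class ToposReport:
    """Everything mined for one promoter."""

    gene: str
    promoter_bead: int
    frequencies: dict
    partners: list
    influential: list
    extent_bp: tuple
    size_kbp: float
    catalog: NetworkCatalog
    H: float

    @property
    def q(self) -> int:
        return len(self.partners)

    def to_json_dict(self) -> dict:
        return {
            "gene": self.gene,
            "promoter_bead": self.promoter_bead,
            "q": self.q,
            "partners": list(self.partners),
            "influential": list(self.influential),
            "frequencies": {str(k): v for k, v in self.frequencies.items()},
            "extent_bp": list(self.extent_bp),
            "size_kbp": self.size_kbp,
            "n_networks": self.catalog.N,
            "network_fractions": {
                ",".join(str(b) for b in sorted(k)) or "-": v
                for k, v in self.catalog.fractions.items()
            },
            "diversity": self.H,
        }


def build_report(
    ensemble: np.ndarray,
    fragment: GenomeFragment,
    gene: str,
    promoter_bead: int,
    atac_beads: Sequence[int],
    contact_threshold: float = CONTACT_THRESHOLD_SIGMA,
    partner_threshold: float = PARTNER_THRESHOLD,
    influential_threshold: float = INFLUENTIAL_THRESHOLD,
    box: Optional[np.ndarray] = None,
) -> ToposReport:
    """Full per-promoter pipeline: frequencies -> partners -> influential ->
    extent -> network catalog -> diversity."""
    candidates = [b for b in atac_beads if b != promoter_bead]
    freqs = contact_frequency(ensemble, promoter_bead, candidates,
                              contact_threshold, box)
    partners = sorted(call_partners(freqs, partner_threshold))
    influential = sorted(call_influential(freqs, influential_threshold))
    extent, size_kbp = topos_extent(promoter_bead, partners, fragment)
    catalog = enumerate_networks(ensemble, promoter_bead, partners,
                                 contact_threshold, box)
    H = diversity_score(catalog, len(partners))
    return ToposReport(gene, promoter_bead, freqs, partners, influential,
                       extent, size_kbp, catalog, H)


def diversity_vs_influential(
    reports: Sequence[ToposReport],
) -> dict:
    """Spearman correlation of diversity H against the influential fraction
    (percent of partners that are influential), overall and per partner-count
    bin.  Follows the mining filter: genes with at least one influential
    node and not all partners influential.
    """
    kept = [r for r in reports
            if r.q > 0 and 0 < len(r.influential) < r.q]
    if len(kept) < 10:
        raise ValueError("need at least 10 reports passing the filter")
    H = np.array([r.H for r in kept])
    x = np.array([100.0 * len(r.influential) / r.q for r in kept])
    if np.std(H) == 0 or np.std(x) == 0:
        return {"overall": (float("nan"), float("nan")), "degenerate": True,
                "n": len(kept), "bins": {}}
    r_all, p_all = stats.spearmanr(H, x)
    bins: dict[int, tuple[float, float]] = {}
    qs = np.array([r.q for r in kept])
    for q in sorted(set(qs)):
        sel = qs == q
        if sel.sum() >= 5 and np.std(H[sel]) > 0 and np.std(x[sel]) > 0:
            rb, pb = stats.spearmanr(H[sel], x[sel])
            bins[int(q)] = (float(rb), float(pb))
    return {"overall": (float(r_all), float(p_all)), "degenerate": False,
            "n": len(kept), "bins": bins}


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def reports_to_tsv(reports: Sequence[ToposReport], path: str | Path) -> None:
    """Genome-wide summary: gene, q, influential count, extent, N, H."""
    with open(path, "w") as fh:
        fh.write("gene\tq\tn_influential\tsize_kbp\tn_networks\tdiversity\n")
        for r in reports:
            fh.write(f"{r.gene}\t{r.q}\t{len(r.influential)}\t{r.size_kbp:g}\t"
                     f"{r.catalog.N}\t{r.H:.6f}\n")


def report_to_json(report: ToposReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2)


def extents_to_bed(
    reports: Sequence[ToposReport], fragment: GenomeFragment, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for r in reports:
            fh.write(f"{fragment.chrom}\t{r.extent_bp[0]}\t{r.extent_bp[1]}\t"
                     f"{r.gene}\n")
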