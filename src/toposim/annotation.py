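"""Per-bead annotation of a genome fragment from peak-interval files.

A fragment is discretized into 1 kbp beads (matching the polymer
resolution).  Peak tracks for ATAC / H3K27ac / H3K27me3 / H3K9me3 flag
beads that overlap a peak by at least 1 bp; CTCF boundary beads require
co-occurring CTCF and RAD21 peaks plus an oriented binding motif, and are
activated stochastically per run with probability proportional to the peak
score.  All interval I/O is 0-based half-open (BED convention).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

BEAD_BP = 1000
ASSAYS = ("atac", "h3k27ac", "h3k27me3", "h3k9me3")
ORIENTATIONS = ("forward", "backward", "bidirectional")

#: fractional score difference below which opposite-strand motifs
#: "score similarly" and the site is called bidirectional
BIDIRECTIONAL_TIE_FRACTION = 0.10


@dataclass(frozen=True)
class GenomeFragment:
    """A chromosome fragment [start, end) in bp, discretized at 1 kbp/bead."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("fragment end must exceed start")
        if self.n_beads < 10:
            raise ValueError("fragment must span at least 10 beads (10 kbp)")

    @property
    def n_beads(self) -> int:
        return math.ceil((self.end - self.start) / BEAD_BP)

    def bead_of(self, bp: int) -> int:
        """Bead index containing genomic position bp (must lie in the fragment)."""
        if not self.start <= bp < self.end:
            raise ValueError(f"position {bp} outside fragment")
        return (bp - self.start) // BEAD_BP

    def interval_of(self, bead: int) -> tuple[int, int]:
        """Genomic interval [start, end) covered by a bead."""
        if not 0 <= bead < self.n_beads:
            raise ValueError(f"bead {bead} outside fragment")
        lo = self.start + BEAD_BP * bead
        return lo, min(lo + BEAD_BP, self.end)


@dataclass(frozen=True)
class PeakRecord:
    chrom: str
    start: int
    end: int
    score: float = 0.0
    strand: Optional[str] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("peak end must exceed start")
        if self.score < 0:
            raise ValueError("peak score must be non-negative")


@dataclass(frozen=True)
class MotifHit:
    """A CTCF-motif occurrence inside a peak (FIMO-style TSV row)."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float
    peak_id: str


@dataclass
class CTCFOutcomes:
    """Distribution over boundary orientations for one bead; the probability
    mass not assigned to an orientation is the inactive outcome."""

    probs: dict = field(default_factory=dict)  # orientation -> probability

    def __post_init__(self) -> None:
        total = 0.0
        for o, p in self.probs.items():
            if o not in ORIENTATIONS:
                raise ValueError(f"unknown orientation {o!r}")
            if not 0.0 <= p <= 1.0 + 1e-12:
                raise ValueError("probabilities must lie in [0, 1]")
            total += p
        if total > 1.0 + 1e-9:
            raise ValueError("orientation probabilities must sum to <= 1")

    @property
    def p_active(self) -> float:
        return sum(self.probs.values())


@dataclass
class BeadTrack:
    """Per-bead annotation of a fragment: mark flags, promoters, CTCF sites."""

    fragment: GenomeFragment
    marks: dict = field(default_factory=dict)  # assay -> bool array
    promoters: dict = field(default_factory=dict)  # gene -> bead index
    ctcf: dict = field(default_factory=dict)  # bead -> CTCFOutcomes

    def __post_init__(self) -> None:
        n = self.fragment.n_beads
        for assay in ASSAYS:
            if assay not in self.marks:
                self.marks[assay] = np.zeros(n, dtype=bool)

    def mark_flags(self, assay: str) -> np.ndarray:
        if assay not in ASSAYS:
            raise ValueError(f"unknown assay {assay!r}")
        return self.marks[assay]

    @property
    def promoter_flags(self) -> np.ndarray:
        out = np.zeros(self.fragment.n_beads, dtype=bool)
        for bead in self.promoters.values():
            out[bead] = True
        return out

    def type_codes(self) -> np.ndarray:
        """Bitmask per bead: bit0 atac, bit1 h3k27ac, bit2 h3k27me3, bit3 h3k9me3."""
        n = self.fragment.n_beads
        codes = np.zeros(n, dtype=np.int64)
        for bit, assay in enumerate(ASSAYS):
            codes |= self.marks[assay].astype(np.int64) << bit
        return codes


# ---------------------------------------------------------------------------
# file parsing
# ---------------------------------------------------------------------------


def parse_peak_file(path: str | Path, dialect: str = "bed") -> list[PeakRecord]:
    """Parse a BED3+/BED6 or ENCODE narrowPeak file into sorted PeakRecords.

    For narrowPeak the signalValue column (7th) is used as the score.
    Comment / track / browser lines are skipped.
    """
    if dialect not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            try:
                if dialect == "narrowPeak":
                    if len(cols) < 10:
                        raise ValueError("narrowPeak needs 10 columns")
                    rec = PeakRecord(
                        chrom=cols[0],
                        start=int(cols[1]),
                        end=int(cols[2]),
                        name=cols[3] if cols[3] != "." else None,
                        strand=cols[5] if cols[5] in "+-" else None,
                        score=float(cols[6]),  # signalValue
                    )
                else:
                    if len(cols) < 3:
                        raise ValueError("BED needs at least 3 columns")
                    score = 0.0
                    if len(cols) >= 5 and cols[4] not in (".", ""):
                        score = float(cols[4])
                    strand = None
                    if len(cols) >= 6 and cols[5] in "+-":
                        strand = cols[5]
                    rec = PeakRecord(
                        chrom=cols[0],
                        start=int(cols[1]),
                        end=int(cols[2]),
                        name=(cols[3] if len(cols) >= 4 and cols[3] != "." else None),
                        score=score,
                        strand=strand,
                    )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
            records.append(rec)
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def parse_motif_file(path: str | Path) -> list[MotifHit]:
    """Parse a TSV of motif occurrences: chrom, start, end, strand, score, peak_id."""
    hits: list[MotifHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                hits.append(
                    MotifHit(
                        chrom=cols[0],
                        start=int(cols[1]),
                        end=int(cols[2]),
                        strand=cols[3],
                        score=float(cols[4]),
                        peak_id=cols[5],
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
    return hits


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def _beads_overlapping(fragment: GenomeFragment, start: int, end: int) -> range:
    """Beads of the fragment overlapping [start, end) by >= 1 bp."""
    lo = max(start, fragment.start)
    hi = min(end, fragment.end)
    if hi <= lo:
        return range(0)
    first = (lo - fragment.start) // BEAD_BP
    last = (hi - 1 - fragment.start) // BEAD_BP
    return range(first, last + 1)


def annotate_marks(
    fragment: GenomeFragment,
    peaks_by_assay: Mapping[str, Sequence[PeakRecord]],
    track: Optional[BeadTrack] = None,
) -> BeadTrack:
    """Flag beads that overlap (>= 1 bp) a peak of each assay."""
    for assay in peaks_by_assay:
        if assay not in ASSAYS:
            raise ValueError(f"unknown assay {assay!r}")
    if track is None:
        track = BeadTrack(fragment)
    for assay, peaks in peaks_by_assay.items():
        flags = track.marks[assay]
        for peak in peaks:
            if peak.chrom != fragment.chrom:
                continue
            for bead in _beads_overlapping(fragment, peak.start, peak.end):
                flags[bead] = True
    return track


def _peak_key(peak: PeakRecord) -> str:
    return peak.name or f"{peak.chrom}:{peak.start}-{peak.end}"


def _peak_orientation(hits: Sequence[MotifHit]) -> str:
    """Orientation from the best-scoring motif; bidirectional on a near-tie
    between the best opposite-strand motifs."""
    best = {"+": None, "-": None}
    for h in hits:
        if h.strand not in "+-":
            continue
        if best[h.strand] is None or h.score > best[h.strand]:
            best[h.strand] = h.score
    if best["+"] is None and best["-"] is None:
        raise ValueError("no stranded motif hit")
    if best["+"] is None:
        return "backward"
    if best["-"] is None:
        return "forward"
    hi, lo = max(best["+"], best["-"]), min(best["+"], best["-"])
    if hi <= 0 or (hi - lo) < BIDIRECTIONAL_TIE_FRACTION * hi:
        return "bidirectional"
    return "forward" if best["+"] > best["-"] else "backward"


def _combine_orientations(active: Sequence[str]) -> Optional[str]:
    if not active:
        return None
    s = set(active)
    if "bidirectional" in s or ("forward" in s and "backward" in s):
        return "bidirectional"
    return s.pop()


def call_ctcf_beads(
    fragment: GenomeFragment,
    ctcf_peaks: Sequence[PeakRecord],
    rad21_peaks: Sequence[PeakRecord],
    motif_hits: Sequence[MotifHit],
    track: Optional[BeadTrack] = None,
) -> BeadTrack:
    """Mark candidate loop-extrusion boundary beads.

    A CTCF peak qualifies when it overlaps a RAD21 peak and contains at
    least one motif hit; its orientation comes from the best-scoring motif
    (bidirectional on near-ties between strands) and its per-run activation
    probability is its score divided by the best qualifying score on the
    fragment.  Beads covered by several qualifying peaks get an enumerated
    outcome distribution over the joint activations.
    """
    if track is None:
        track = BeadTrack(fragment)
    hits_by_peak: dict[str, list[MotifHit]] = {}
    peaks_by_key = { _peak_key(p): p for p in ctcf_peaks }
    for hit in motif_hits:
        peak = peaks_by_key.get(hit.peak_id)
        if peak is None:
            warnings.warn(f"motif hit references unknown peak {hit.peak_id!r}; skipped")
            continue
        if hit.chrom != peak.chrom or hit.start < peak.start or hit.end > peak.end:
            warnings.warn(f"motif hit outside peak {hit.peak_id!r}; skipped")
            continue
        hits_by_peak.setdefault(hit.peak_id, []).append(hit)

    rad21 = [p for p in rad21_peaks if p.chrom == fragment.chrom]

    def overlaps_rad21(peak: PeakRecord) -> bool:
        return any(p.start < peak.end and peak.start < p.end for p in rad21)

    qualifying: list[tuple[PeakRecord, str]] = []
    for peak in ctcf_peaks:
        if peak.chrom != fragment.chrom:
            continue
        key = _peak_key(peak)
        if key not in hits_by_peak or not overlaps_rad21(peak):
            continue
        qualifying.append((peak, _peak_orientation(hits_by_peak[key])))

    if not qualifying:
        return track
    max_score = max(p.score for p, _ in qualifying)
    by_bead: dict[int, list[tuple[float, str]]] = {}
    for peak, orientation in qualifying:
        p_act = 1.0 if max_score == 0 else min(1.0, peak.score / max_score)
        for bead in _beads_overlapping(fragment, peak.start, peak.end):
            by_bead.setdefault(bead, []).append((p_act, orientation))

    for bead, sites in by_bead.items():
        probs: dict[str, float] = {}
        # enumerate joint activation outcomes of the (few) peaks on this bead
        for mask in range(1 << len(sites)):
            p = 1.0
            active = []
            for j, (p_act, orientation) in enumerate(sites):
                if mask >> j & 1:
                    p *= p_act
                    active.append(orientation)
                else:
                    p *= 1.0 - p_act
            combined = _combine_orientations(active)
            if combined is not None and p > 0:
                probs[combined] = probs.get(combined, 0.0) + p
        track.ctcf[bead] = CTCFOutcomes(probs)
    return track


def sample_ctcf_activation(
    track: BeadTrack, rng: np.random.Generator | int
) -> dict[int, str]:
    """Draw one boundary realization: bead -> active orientation.

    Each CTCF bead samples independently from its outcome distribution
    (remaining mass = inactive).  Deterministic under a fixed seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    boundaries: dict[int, str] = {}
    for bead in sorted(track.ctcf):
        outcomes = track.ctcf[bead]
        u = rng.random()
        acc = 0.0
        for orientation in ORIENTATIONS:
            acc += outcomes.probs.get(orientation, 0.0)
            if u < acc:
                boundaries[bead] = orientation
                break
    return boundaries


def annotate_promoters(
    fragment: GenomeFragment,
    promoter_intervals: Iterable[tuple[str, str, int, int]] | Sequence[PeakRecord],
    track: Optional[BeadTrack] = None,
) -> BeadTrack:
    """Assign one promoter bead per gene: the bead containing the interval midpoint.

    Accepts (gene, chrom, start, end) tuples or named PeakRecords.  Genes
    whose promoter midpoint falls outside the fragment are dropped with a
    warning; a duplicate gene id on the fragment is an error.
    """
    if track is None:
        track = BeadTrack(fragment)
    for item in promoter_intervals:
        if isinstance(item, PeakRecord):
            if item.name is None:
                raise ValueError("promoter records must carry a gene identifier")
            gene, chrom, start, end = item.name, item.chrom, item.start, item.end
        else:
            gene, chrom, start, end = item
        mid = (start + end) // 2
        if chrom != fragment.chrom or not fragment.start <= mid < fragment.end:
            warnings.warn(f"promoter of {gene!r} outside fragment; dropped")
            continue
        if gene in track.promoters:
            raise ValueError(f"duplicate gene id {gene!r} on fragment")
        track.promoters[gene] = fragment.bead_of(mid)
    return track


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def _flags_to_intervals(fragment: GenomeFragment, flags: np.ndarray):
    """Merge runs of flagged beads into genomic intervals."""
    out = []
    start_bead = None
    for i, f in enumerate(flags):
        if f and start_bead is None:
            start_bead = i
        elif not f and start_bead is not None:
            out.append((fragment.interval_of(start_bead)[0], fragment.interval_of(i - 1)[1]))
            start_bead = None
    if start_bead is not None:
        out.append((fragment.interval_of(start_bead)[0],
                    fragment.interval_of(len(flags) - 1)[1]))
    return out


def export_track_beds(track: BeadTrack, outdir: str | Path, prefix: str = "track") -> dict:
    """Write one BED file per mark (merged flagged-bead runs) plus a JSON
    sidecar recording the annotation rules; returns {assay: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for assay in ASSAYS:
        path = outdir / f"{prefix}.{assay}.bed"
        with open(path, "w") as fh:
            for start, end in _flags_to_intervals(track.fragment, track.marks[assay]):
                fh.write(f"{track.fragment.chrom}\t{start}\t{end}\n")
        paths[assay] = str(path)
    sidecar = {
        "fragment": {
            "chrom": track.fragment.chrom,
            "start": track.fragment.start,
            "end": track.fragment.end,
        },
        "bead_bp": BEAD_BP,
        "overlap_rule": ">=1bp",
        "coordinates": "0-based half-open",
        "bidirectional_tie_fraction": BIDIRECTIONAL_TIE_FRACTION,
        "files": paths,
    }
    with open(outdir / f"{prefix}.provenance.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return paths
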