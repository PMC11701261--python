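"""Synthetic epigenomic fixtures, oracle ensembles, and structure export.

`synth_epigenome` writes a full input stack (ATAC/H3K27ac/H3K27me3/H3K9me3
peaks, CTCF + RAD21 co-peaks, motif hits, promoters) for a made-up locus so
the whole pipeline runs without any external download.  `toy_ensemble`
builds coordinate sets realizing a prescribed contact plan exactly — the
independent oracle for partner frequencies and network catalogs.  Structure
snapshots export as mmCIF (via gemmi) or XYZ with mark classes in the
label fields.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .annotation import (
    BeadTrack,
    GenomeFragment,
    annotate_marks,
    annotate_promoters,
    call_ctcf_beads,
    parse_motif_file,
    parse_peak_file,
)

MOTIF_LEN = 19


@dataclass
class SyntheticLocusSpec:
    """Declarative description of a synthetic locus (all coordinates in bp)."""

    length_kbp: int = 150
    chrom: str = "chrS"
    genes: list = field(default_factory=list)        # (name, promoter_bp)
    enhancers: list = field(default_factory=list)    # (pos_bp, strength)
    h3k27ac_blocks: list = field(default_factory=list)   # (start, end)
    h3k27me3_domains: list = field(default_factory=list)
    h3k9me3_domains: list = field(default_factory=list)
    ctcf_sites: list = field(default_factory=list)   # (pos_bp, orientation, score)
    peak_halfwidth: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        end = self.length_kbp * 1000
        names = [g[0] for g in self.genes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate gene names")
        for name, pos in self.genes:
            if not 0 <= pos < end:
                raise ValueError(f"promoter of {name!r} outside fragment")
        for pos, _ in self.enhancers:
            if not 0 <= pos < end:
                raise ValueError("enhancer outside fragment")
        for blocks in (self.h3k27ac_blocks, self.h3k27me3_domains,
                       self.h3k9me3_domains):
            for lo, hi in blocks:
                if not (0 <= lo < hi <= end):
                    raise ValueError("mark domain outside fragment")
        for pos, orientation, score in self.ctcf_sites:
            if not 0 <= pos < end:
                raise ValueError("CTCF site outside fragment")
            if orientation not in ("forward", "backward", "bidirectional"):
                raise ValueError(f"unknown CTCF orientation {orientation!r}")
            if score < 0:
                raise ValueError("CTCF score must be non-negative")

    @property
    def fragment(self) -> GenomeFragment:
        return GenomeFragment(self.chrom, 0, self.length_kbp * 1000)


def default_locus(seed: int = 0) -> SyntheticLocusSpec:
    """The standard toy locus: one gene, two strong enhancers and one weak
    distal ATAC site inside a convergent CTCF pair, with flanking polycomb
    and heterochromatin domains."""
    return SyntheticLocusSpec(
        length_kbp=150,
        genes=[("geneA", 75_500)],
        enhancers=[(67_500, 10.0), (85_500, 10.0), (120_500, 2.0)],
        h3k27ac_blocks=[(74_000, 78_000)],
        h3k27me3_domains=[(10_000, 30_000)],
        h3k9me3_domains=[(125_000, 145_000)],
        ctcf_sites=[(55_500, "forward", 20.0), (105_500, "backward", 20.0)],
        seed=seed,
    )


def _narrowpeak_line(chrom, start, end, name, signal, strand=".") -> str:
    return (f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\t{signal:g}"
            f"\t-1\t-1\t{(end - start) // 2}\n")


def synth_epigenome(spec: SyntheticLocusSpec, outdir: str | Path) -> dict:
    """Write the locus as peak/motif/promoter files; returns {key: path}.

    Output is deterministic (byte-identical) for a given spec.  Promoters
    are emitted as ATAC peaks too (promoters are accessible chromatin).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hw = spec.peak_halfwidth
    chrom = spec.chrom
    end_bp = spec.length_kbp * 1000
    clip = lambda x: max(0, min(end_bp, x))
    paths = {}

    atac = outdir / "atac.narrowPeak"
    with open(atac, "w") as fh:
        k = 0
        for name, pos in spec.genes:
            fh.write(_narrowpeak_line(chrom, clip(pos - hw), clip(pos + hw),
                                      f"ATAC_p{k}", 8.0))
            k += 1
        for pos, strength in spec.enhancers:
            fh.write(_narrowpeak_line(chrom, clip(pos - hw), clip(pos + hw),
                                      f"ATAC_e{k}", strength))
            k += 1
    paths["atac"] = atac

    for key, blocks in (("h3k27ac", spec.h3k27ac_blocks),
                        ("h3k27me3", spec.h3k27me3_domains),
                        ("h3k9me3", spec.h3k9me3_domains)):
        path = outdir / f"{key}.bed"
        with open(path, "w") as fh:
            for lo, hi in blocks:
                fh.write(f"{chrom}\t{lo}\t{hi}\n")
        paths[key] = path

    ctcf = outdir / "ctcf.narrowPeak"
    rad21 = outdir / "rad21.narrowPeak"
    motifs = outdir / "motifs.tsv"
    with open(ctcf, "w") as cf, open(rad21, "w") as rf, open(motifs, "w") as mf:
        mf.write("#chrom\tstart\tend\tstrand\tscore\tpeak_id\n")
        for k, (pos, orientation, score) in enumerate(spec.ctcf_sites):
            name = f"CTCF_{k}"
            cf.write(_narrowpeak_line(chrom, clip(pos - hw), clip(pos + hw),
                                      name, score))
            rf.write(_narrowpeak_line(chrom, clip(pos - hw + 100),
                                      clip(pos + hw + 100), f"RAD21_{k}", score))
            m0 = clip(pos - MOTIF_LEN // 2)
            m1 = m0 + MOTIF_LEN
            if orientation == "bidirectional":
                mf.write(f"{chrom}\t{m0}\t{m1}\t+\t15.0\t{name}\n")
                mf.write(f"{chrom}\t{m0}\t{m1}\t-\t15.0\t{name}\n")
            else:
                strand = "+" if orientation == "forward" else "-"
                mf.write(f"{chrom}\t{m0}\t{m1}\t{strand}\t15.0\t{name}\n")
    paths["ctcf"] = ctcf
    paths["rad21"] = rad21
    paths["motifs"] = motifs

    promoters = outdir / "promoters.bed"
    with open(promoters, "w") as fh:
        for name, pos in spec.genes:
            fh.write(f"{chrom}\t{clip(pos - 500)}\t{clip(pos + 500)}\t{name}\n")
    paths["promoters"] = promoters

    locus = outdir / "locus.json"
    with open(locus, "w") as fh:
        json.dump(
            {
                "chrom": chrom, "start": 0, "end": end_bp,
                "genes": spec.genes, "enhancers": spec.enhancers,
                "seed": spec.seed,
            },
            fh, indent=2,
        )
    paths["locus"] = locus
    return {k: str(v) for k, v in paths.items()}


def annotate_locus_dir(indir: str | Path) -> tuple[GenomeFragment, BeadTrack]:
    """Round-trip a synth_epigenome directory through the real parsers."""
    indir = Path(indir)
    with open(indir / "locus.json") as fh:
        locus = json.load(fh)
    fragment = GenomeFragment(locus["chrom"], locus["start"], locus["end"])
    peaks = {
        "atac": parse_peak_file(indir / "atac.narrowPeak", "narrowPeak"),
        "h3k27ac": parse_peak_file(indir / "h3k27ac.bed", "bed"),
        "h3k27me3": parse_peak_file(indir / "h3k27me3.bed", "bed"),
        "h3k9me3": parse_peak_file(indir / "h3k9me3.bed", "bed"),
    }
    track = annotate_marks(fragment, peaks)
    call_ctcf_beads(
        fragment,
        parse_peak_file(indir / "ctcf.narrowPeak", "narrowPeak"),
        parse_peak_file(indir / "rad21.narrowPeak", "narrowPeak"),
        parse_motif_file(indir / "motifs.tsv"),
        track,
    )
    annotate_promoters(fragment, parse_peak_file(indir / "promoters.bed", "bed"),
                       track)
    return fragment, track


# ---------------------------------------------------------------------------
# oracle ensembles
# ---------------------------------------------------------------------------


def _directions(n: int) -> np.ndarray:
    """n well-separated unit vectors (golden-spiral points on the sphere)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = math.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def toy_ensemble(
    n_structures: int,
    n_beads: int,
    promoter_bead: int,
    contact_counts: Optional[Mapping[int, int]] = None,
    subsets: Optional[Sequence[set]] = None,
    contact_dist: float = 1.5,
    far_dist: float = 20.0,
) -> np.ndarray:
    """Coordinate ensemble realizing a contact plan exactly (no dynamics).

    Either `contact_counts` (candidate bead -> number of structures in
    contact; structures 0..count-1 are the contacting ones) or `subsets`
    (per-structure candidate sets) must be given.  Contacting candidates
    sit at `contact_dist` < 3.5 sigma from the promoter along distinct
    directions; everything else is parked far away.
    """
    if (contact_counts is None) == (subsets is None):
        raise ValueError("give exactly one of contact_counts or subsets")
    if contact_counts is not None:
        for bead, count in contact_counts.items():
            if not 0 <= count <= n_structures:
                raise ValueError("unrealizable plan: count outside [0, n]")
            if bead == promoter_bead or not 0 <= bead < n_beads:
                raise ValueError("invalid candidate bead")
        plans = [
            {b for b, c in contact_counts.items() if s < c}
            for s in range(n_structures)
        ]
    else:
        if len(subsets) != n_structures:
            raise ValueError("need one subset per structure")
        plans = [set(sub) for sub in subsets]
        for sub in plans:
            for bead in sub:
                if bead == promoter_bead or not 0 <= bead < n_beads:
                    raise ValueError("invalid candidate bead")
    candidates = sorted(set().union(*plans)) if plans else []
    dirs = {b: d for b, d in zip(candidates, _directions(max(1, len(candidates))))}
    ensemble = np.zeros((n_structures, n_beads, 3))
    base = np.zeros((n_beads, 3))
    base[:, 0] = far_dist * (np.arange(n_beads) - promoter_bead)
    base[promoter_bead] = 0.0
    for s, plan in enumerate(plans):
        ensemble[s] = base
        for b in candidates:
            ensemble[s, b] = dirs[b] * (contact_dist if b in plan else far_dist)
    return ensemble


# ---------------------------------------------------------------------------
# structure export
# ---------------------------------------------------------------------------

_CLASS_ELEMENTS = {"UNM": "C", "ATA": "N", "ACE": "O", "PCG": "S", "HET": "P"}


def _bead_class(code: int) -> str:
    """Dominant mark class for labeling: ATAC > H3K27ac > H3K27me3 > H3K9me3."""
    if code & 1:
        return "ATA"
    if code & 2:
        return "ACE"
    if code & 4:
        return "PCG"
    if code & 8:
        return "HET"
    return "UNM"


def export_structure(
    structure: np.ndarray,
    path: str | Path,
    fmt: str = "cif",
    track: Optional[BeadTrack] = None,
    scale_nm: float = 25.0,
) -> None:
    """Write one conformation as mmCIF or XYZ, one pseudo-atom per bead.

    Residue/label fields carry the bead index and mark class; coordinates
    are scaled to nm (Angstrom/10 in the CIF convention is not meaningful
    for pseudo-atoms, so nm values are stored verbatim).
    """
    structure = np.asarray(structure)
    n = structure.shape[0]
    codes = track.type_codes() if track is not None else np.zeros(n, dtype=int)
    classes = [_bead_class(int(c)) for c in codes[:n]]
    path = Path(path)
    if fmt == "xyz":
        with open(path, "w") as fh:
            fh.write(f"{n}\n")
            fh.write("chromatin beads; columns: element x y z bead_index mark_class\n")
            for i in range(n):
                el = _CLASS_ELEMENTS[classes[i]]
                x, y, z = structure[i] * scale_nm
                fh.write(f"{el}\t{x:.6f}\t{y:.6f}\t{z:.6f}\t{i}\t{classes[i]}\n")
        return
    if fmt != "cif":
        raise ValueError(f"unknown format {fmt!r}")
    import gemmi

    st = gemmi.Structure()
    st.name = "chromatin"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i in range(n):
        res = gemmi.Residue()
        res.name = classes[i]
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element(_CLASS_ELEMENTS[classes[i]])
        x, y, z = structure[i] * scale_nm
        atom.pos = gemmi.Position(x, y, z)
        atom.b_iso = float(i)
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))


def read_xyz(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read back an XYZ export: (coordinates, mark classes)."""
    with open(path) as fh:
        n = int(fh.readline())
        fh.readline()
        coords = np.empty((n, 3))
        classes = []
        for i in range(n):
            parts = fh.readline().split()
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            classes.append(parts[5] if len(parts) > 5 else "UNM")
    return coords, classes
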