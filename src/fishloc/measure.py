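"""Per-nucleus locus measurements.

Turns segmented probe spots and nuclear cross-section masks into the two
quantities of the analysis:

* **d² (µm²)** — squared 3D Euclidean distance between the two probe
  centroids.  The square is used because in interphase nuclei the mean
  squared physical distance between two points grows linearly with their
  genomic separation, so d² at fixed separation reads out local chromatin
  compaction.
* **fractional radius f** — shortest in-slice distance from the position
  probe's centroid to the nuclear boundary, divided by the nuclear radius
  (half the maximum Feret diameter of the cross-section): f = 0 at the
  periphery, f = 1 only at the centre of a circular section.

Genomic separation between the fosmid probes flanking a locus is computed
from BED coordinates as the gap between inner probe ends (kb).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull
from shapely.geometry import Point, Polygon

from .segmentation import (ImageStack, NucleusROI, SpotSegment, NucleusMask2D,
                           SegmentationError, segment_spot,
                           segment_nucleus_slice)

__all__ = [
    "FosmidProbe",
    "LocusPanel",
    "ProbePairMeasurement",
    "MeasurementError",
    "genomic_separation",
    "read_fosmid_bed",
    "write_fosmid_bed",
    "panel_from_probes",
    "interprobe_distance",
    "fractional_radius",
    "measure_nucleus",
]


class MeasurementError(RuntimeError):
    """A nucleus could not be measured; carries the rejection reason."""

    def __init__(self, nucleus_id: str, reason: str):
        super().__init__(f"{nucleus_id}: {reason}")
        self.nucleus_id = nucleus_id
        self.reason = reason


# ---------------------------------------------------------------------------
# Fosmid probes and genomic separation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FosmidProbe:
    """A fosmid FISH probe: 0-based half-open genomic interval."""

    name: str
    chrom: str
    start: int
    end: int
    label: Optional[str] = None  # digoxigenin | biotin

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"probe {self.name}: start must be < end")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def genomic_separation(a: FosmidProbe, b: FosmidProbe, mode: str = "gap") -> float:
    """Genomic separation of a fosmid pair, in kb.

    ``mode="gap"`` (default) measures the gap between inner probe ends —
    end of the upstream probe to start of the downstream probe — matching
    the convention of quoting the separation of sequences *flanking* a gene.
    ``mode="midpoint"`` measures midpoint to midpoint.

    Raises
    ------
    ValueError
        If the probes sit on different chromosomes or overlap.
    """
    if a.chrom != b.chrom:
        raise ValueError(f"probes {a.name}/{b.name} on different chromosomes")
    first, second = (a, b) if a.start <= b.start else (b, a)
    if second.start < first.end:
        raise ValueError(f"probes {a.name}/{b.name} overlap")
    if mode == "gap":
        return (second.start - first.end) / 1000.0
    if mode == "midpoint":
        return abs(b.midpoint - a.midpoint) / 1000.0
    raise ValueError("mode must be 'gap' or 'midpoint'")


@dataclass(frozen=True)
class LocusPanel:
    """A named fosmid pair with its genomic separation g (kb)."""

    gene: str
    probe_a: FosmidProbe
    probe_b: FosmidProbe
    g: float

    def __post_init__(self):
        if not self.g > 0:
            raise ValueError(f"panel {self.gene}: g must be > 0 (got {self.g})")


def panel_from_probes(gene: str, probe_a: FosmidProbe, probe_b: FosmidProbe,
                      mode: str = "gap") -> LocusPanel:
    return LocusPanel(gene, probe_a, probe_b,
                      genomic_separation(probe_a, probe_b, mode=mode))


def read_fosmid_bed(path) -> list:
    """Read fosmid probes from a BED file (chrom, start, end, name[, label]).

    Coordinates are 0-based half-open, as in BED.  A fifth column, when
    present and textual, is taken as the hapten label.
    """
    probes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"BED line has fewer than 4 columns: {line!r}")
            label = None
            if len(parts) >= 5 and not parts[4].lstrip("-").isdigit():
                label = parts[4]
            probes.append(FosmidProbe(parts[3], parts[0], int(parts[1]),
                                      int(parts[2]), label))
    return probes


def write_fosmid_bed(probes, path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            cols = [p.chrom, str(p.start), str(p.end), p.name]
            if p.label:
                cols.append(p.label)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Physical measurements
# ---------------------------------------------------------------------------

@dataclass
class ProbePairMeasurement:
    """The unit record of the analysis: one nucleus, one probe pair."""

    nucleus_id: str
    embryo_id: str
    region: str
    condition: str
    d_um: float
    d2_um2: float
    frac_radius: float
    flags: list = field(default_factory=list)
    spots: list = field(default_factory=list, repr=False)  # [SpotSegment, ...]


def interprobe_distance(spot_a: SpotSegment, spot_b: SpotSegment):
    """3D Euclidean distance between two probe centroids and its square.

    Returns ``(d, d²)`` in (µm, µm²).  Both centroids must belong to the
    same nucleus ROI (same stack frame).
    """
    if spot_a.roi.nucleus_id != spot_b.roi.nucleus_id:
        raise ValueError("centroids come from different nuclei")
    delta = np.asarray(spot_a.centroid_um) - np.asarray(spot_b.centroid_um)
    d = float(np.linalg.norm(delta))
    return d, d * d


def fractional_radius(spot: SpotSegment, nucleus: NucleusMask2D):
    """Nuclear fractional radius of a spot in a nuclear cross-section.

    f = e / R with e the shortest Euclidean distance (µm) from the spot's
    (y, x) centroid to the boundary polygon and R half the maximum pairwise
    boundary distance (max Feret diameter).  f = 0 on the periphery; f = 1
    is reachable only at the centre of a circular section.  For non-convex
    sections e can exceed R; such records are flagged ``f_gt_1``, never
    clamped.

    Returns ``(f, e_um, R_um, flags)``.
    """
    boundary = nucleus.boundary_um
    if len(boundary) < 4:
        raise ValueError("degenerate nuclear boundary")
    poly = Polygon(boundary)
    if poly.area == 0:
        raise ValueError("degenerate nuclear mask (zero area)")
    pt = Point(spot.centroid_um[1], spot.centroid_um[2])
    if not poly.covers(pt):
        raise ValueError("spot centroid outside nuclear mask")
    e = float(poly.exterior.distance(pt))
    hull_pts = boundary[ConvexHull(boundary).vertices]
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    feret = float(np.sqrt((diff ** 2).sum(axis=2)).max())
    if feret == 0:
        raise ValueError("degenerate nuclear mask (zero Feret diameter)")
    r = feret / 2.0
    f = e / r
    flags = list(nucleus.flags)
    if f > 1.0:
        flags.append("f_gt_1")
    return f, e, r, flags


def measure_nucleus(stack: ImageStack, roi: NucleusROI,
                    position_channel: str = "probeB",
                    presmooth_sigma: float = 1.0,
                    nucleus_margin_um: float = 4.5,
                    weighting: str = "intensity") -> ProbePairMeasurement:
    """Measure one nucleus: segment both probe spots, compute d and d², and
    the fractional radius of the position probe (the biotin-labelled probe by
    convention) in the z-slice of its centroid.

    Raises
    ------
    MeasurementError
        With the nucleus id and a reason if any stage fails; QC flags from
        successful stages are propagated on the returned record.
    """
    try:
        spot_a = segment_spot(stack, roi, "probeA",
                              presmooth_sigma=presmooth_sigma, weighting=weighting)
        spot_b = segment_spot(stack, roi, "probeB",
                              presmooth_sigma=presmooth_sigma, weighting=weighting)
    except SegmentationError as e:
        raise MeasurementError(roi.nucleus_id, f"no spot: {e}") from e
    d, d2 = interprobe_distance(spot_a, spot_b)
    pos_spot = spot_a if position_channel == "probeA" else spot_b
    # "sharp focus" proxy: the slice containing the spot's centroid z
    z = int(round(pos_spot.centroid_um[0] / stack.voxel_size[0]))
    z = min(max(z, roi.box[0]), roi.box[1] - 1)
    try:
        nuc = segment_nucleus_slice(stack, roi, z, margin_um=nucleus_margin_um,
                                    inside_yx_um=pos_spot.centroid_um[1:],
                                    presmooth_sigma=presmooth_sigma)
        f, e, r, nflags = fractional_radius(pos_spot, nuc)
    except (SegmentationError, ValueError) as e:
        raise MeasurementError(roi.nucleus_id, f"no nucleus section: {e}") from e
    flags = sorted(set(spot_a.flags) | set(spot_b.flags) | set(nflags))
    return ProbePairMeasurement(
        nucleus_id=roi.nucleus_id,
        embryo_id=roi.embryo_id,
        region=roi.region,
        condition=roi.condition,
        d_um=d,
        d2_um2=d2,
        frac_radius=f,
        flags=flags,
        spots=[spot_a, spot_b],
    )
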