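"""End-to-end orchestration: simulate or ingest a cohort, register channels,
segment, measure, compare, and write a reproducible output bundle.

A run is fully described by a :class:`RunConfig` (usually loaded from YAML).
``simulate`` mode streams synthetic stacks through the analysis one
embryo x region field at a time (rendered fields are large; nothing but the
measurement table is retained); ``analyse`` mode reads a cohort from disk in
the same formats the generator writes (multi-channel TIFF + YAML sidecars,
ROI CSV, fosmid BED).  Identical config + seed gives byte-identical
measurement tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .measure import (FosmidProbe, MeasurementError, measure_nucleus,
                      read_fosmid_bed, write_fosmid_bed, genomic_separation)
from .segmentation import ImageStack, NucleusROI, align_channels
from .synthetic import (ChainModel, CohortConfig, ImagingModel, NucleusModel,
                        RadialModel, RegionSpec, StackBundle, iter_cohort)

logger = logging.getLogger("fishloc")

__all__ = ["RunConfig", "RunResult", "demo_config", "load_config",
           "validate_inputs", "run_pipeline", "write_cohort", "read_cohort"]

MEASUREMENT_COLUMNS = ["nucleus_id", "embryo_id", "region", "condition",
                       "d_um", "d2_um2", "frac_radius", "flags"]
SPOT_COLUMNS = ["nucleus_id", "channel", "z_um", "y_um", "x_um",
                "voxel_count", "threshold", "flags"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str                       # simulate | analyse
    out_dir: str
    seed: int = 0
    cohort: Optional[CohortConfig] = None   # simulate mode
    cohort_dir: Optional[str] = None        # analyse mode
    plan: list = field(default_factory=list)
    position_channel: str = "probeB"
    presmooth_sigma: float = 1.0
    nucleus_margin_um: float = 4.5
    correction: str = "none"
    make_plots: bool = True
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _plainify(d)


def _plainify(obj):
    if isinstance(obj, dict):
        return {str(k): _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Config loading
# ---------------------------------------------------------------------------

def _cohort_from_dict(d: dict, seed: int) -> CohortConfig:
    regions = []
    for r in d["regions"]:
        radial = r.get("radial", {"family": "uniform_volume"})
        regions.append(RegionSpec(
            region=r["region"], condition=r.get("condition", "control"),
            chain=ChainModel(c=float(r["c"]), g=float(r["g"])),
            radial=RadialModel(family=radial["family"],
                               a=float(radial.get("a", 1.0)),
                               b=float(radial.get("b", 1.0)))))
    imaging = ImagingModel(**{k: (tuple(v) if isinstance(v, list) else v)
                              for k, v in d.get("imaging", {}).items()})
    nucleus = NucleusModel(**{k: (tuple(v) if isinstance(v, list) else v)
                              for k, v in d.get("nucleus", {}).items()})
    return CohortConfig(regions=tuple(regions),
                        n_embryos=int(d.get("n_embryos", 3)),
                        n_nuclei=int(d.get("n_nuclei", 50)),
                        imaging=imaging, nucleus=nucleus,
                        seed=int(d.get("seed", seed)))


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    seed = int(raw.get("seed", 0))
    cohort = (_cohort_from_dict(raw["cohort"], seed)
              if "cohort" in raw and raw["cohort"] else None)
    analysis = raw.get("analysis", {})
    return RunConfig(
        mode=raw["mode"],
        out_dir=raw["out_dir"],
        seed=seed,
        cohort=cohort,
        cohort_dir=raw.get("cohort_dir"),
        plan=analysis.get("plan", []),
        position_channel=analysis.get("position_channel", "probeB"),
        presmooth_sigma=float(analysis.get("presmooth_sigma", 1.0)),
        nucleus_margin_um=float(analysis.get("nucleus_margin_um", 4.5)),
        correction=analysis.get("correction", "none"),
        make_plots=bool(analysis.get("make_plots", True)),
        log_level=raw.get("log_level", "INFO"),
    )


def demo_config(out_dir, seed: int = 0, n_embryos: int = 3,
                n_nuclei: int = 50) -> RunConfig:
    """The default demonstration run: a two-region cohort contrasting a
    compact, peripherally located locus (stem-zone-like) against a two-fold
    decompacted, more central one (neural-tube-like), at the study's
    sampling design of 3 embryos x 50 nuclei per region."""
    regions = (
        RegionSpec("stem_zone", "control",
                   ChainModel(c=0.0015, g=65.0),
                   RadialModel("beta", a=1.6, b=2.6)),
        RegionSpec("neural_tube", "control",
                   ChainModel(c=0.0030, g=65.0),
                   RadialModel("beta", a=2.8, b=1.8)),
    )
    imaging = ImagingModel(channel_shift={"probeA": (0, 0), "probeB": (0, 3)})
    cohort = CohortConfig(regions=regions, n_embryos=n_embryos,
                          n_nuclei=n_nuclei, imaging=imaging, seed=seed)
    plan = [
        {"metric": "d2_um2", "group_a": "stem_zone", "group_b": "neural_tube",
         "per_embryo": True},
        {"metric": "frac_radius", "group_a": "stem_zone", "group_b": "neural_tube"},
    ]
    return RunConfig(mode="simulate", out_dir=str(out_dir), seed=seed,
                     cohort=cohort, plan=plan)


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

def _dummy_panel_probes(cohort: CohortConfig) -> list:
    """Synthetic fosmid pairs reproducing each distinct genomic separation."""
    probes = []
    seen = []
    for spec in cohort.regions:
        g = spec.chain.g
        if g in seen or g <= 0:
            continue
        seen.append(g)
        start_a = 3_000_000
        end_a = start_a + 40_000
        start_b = end_a + int(round(g * 1000))
        probes.append(FosmidProbe(f"sim_g{g:g}_A", "chr2", start_a, end_a,
                                  "digoxigenin"))
        probes.append(FosmidProbe(f"sim_g{g:g}_B", "chr2", start_b,
                                  start_b + 40_000, "biotin"))
    return probes


def write_cohort(cohort: CohortConfig, out_dir) -> Path:
    """Generate a cohort and write it to disk, one stack at a time.

    Layout: ``<region>_<condition>_<embryo>.tif`` (axes CZYX, uint16) with a
    YAML sidecar per stack (channels, voxel sizes, applied shifts), plus
    ``rois.csv``, ``ground_truth.csv``, ``fosmids.bed`` and a ``cohort.yaml``
    manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack_entries, roi_frames, truth_frames = [], [], []
    for b in iter_cohort(cohort, render=True):
        name = f"{b.region}_{b.condition}_{b.embryo_id}.tif"
        tifffile.imwrite(out / name, b.stack.data)
        sidecar = {
            "axes": "CZYX",
            "channels": list(b.stack.channels),
            "voxel_size_um": [float(v) for v in b.stack.voxel_size],
            "channel_shift": {k: [float(s) for s in v] for k, v in
                              cohort.imaging.channel_shift.items()},
        }
        with open(out / (name + ".yaml"), "w") as fh:
            yaml.safe_dump(sidecar, fh, sort_keys=True)
        stack_entries.append({"file": name, "region": b.region,
                              "condition": b.condition, "embryo_id": b.embryo_id})
        roi_frames.append(b.rois)
        truth_frames.append(b.truth)
        logger.info("wrote %s (%s nuclei)", name, len(b.rois))
    pd.concat(roi_frames, ignore_index=True).to_csv(out / "rois.csv", index=False)
    pd.concat(truth_frames, ignore_index=True).to_csv(out / "ground_truth.csv",
                                                      index=False)
    write_fosmid_bed(_dummy_panel_probes(cohort), out / "fosmids.bed")
    with open(out / "cohort.yaml", "w") as fh:
        yaml.safe_dump({"seed": cohort.seed, "stacks": stack_entries}, fh,
                       sort_keys=False)
    return out


def read_cohort(cohort_dir):
    """Iterate StackBundles from a cohort directory written by write_cohort."""
    root = Path(cohort_dir)
    with open(root / "cohort.yaml") as fh:
        manifest = yaml.safe_load(fh)
    rois = pd.read_csv(root / "rois.csv")
    for entry in manifest["stacks"]:
        with open(root / (entry["file"] + ".yaml")) as fh:
            sidecar = yaml.safe_load(fh)
        data = tifffile.imread(root / entry["file"])
        stack = ImageStack(data, tuple(sidecar["channels"]),
                           tuple(sidecar["voxel_size_um"]))
        sub = rois[(rois["region"] == entry["region"])
                   & (rois["condition"] == entry["condition"])
                   & (rois["embryo_id"] == entry["embryo_id"])].reset_index(drop=True)
        yield StackBundle(entry["region"], entry["condition"], entry["embryo_id"],
                          stack, sub, pd.DataFrame()), sidecar.get("channel_shift", {})


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_inputs(config: RunConfig) -> List[str]:
    """Check a run configuration and its referenced inputs.

    Returns a list of human-readable issues (prefixed ERROR/WARNING); an
    empty list means the run can proceed.  Never raises.
    """
    issues: List[str] = []
    if config.mode not in ("simulate", "analyse"):
        return [f"ERROR: unknown mode {config.mode!r}"]
    if config.mode == "simulate":
        if config.cohort is None:
            issues.append("ERROR: simulate mode needs a cohort section")
        return issues
    if not config.cohort_dir:
        return ["ERROR: analyse mode needs cohort_dir"]
    root = Path(config.cohort_dir)
    if not root.is_dir():
        return [f"ERROR: cohort_dir {root} does not exist"]
    for req in ("cohort.yaml", "rois.csv", "fosmids.bed"):
        if not (root / req).exists():
            issues.append(f"ERROR: missing {req} in {root}")
    if issues:
        return issues
    with open(root / "cohort.yaml") as fh:
        manifest = yaml.safe_load(fh)
    rois = pd.read_csv(root / "rois.csv")
    for entry in manifest.get("stacks", []):
        path = root / entry["file"]
        if not path.exists():
            issues.append(f"ERROR: stack {entry['file']} missing")
            continue
        try:
            with tifffile.TiffFile(path) as tf:
                shape = tf.series[0].shape
        except Exception as e:  # unreadable TIFF
            issues.append(f"ERROR: stack {entry['file']} unreadable: {e}")
            continue
        if len(shape) != 4 or shape[0] != 3:
            issues.append(f"ERROR: stack {entry['file']} is not 3-channel CZYX "
                          f"(shape {shape})")
            continue
        sub = rois[(rois["region"] == entry["region"])
                   & (rois["condition"] == entry["condition"])
                   & (rois["embryo_id"] == entry["embryo_id"])]
        for _, r in sub.iterrows():
            for lo, hi, n, ax in ((r.z0, r.z1, shape[1], "z"),
                                  (r.y0, r.y1, shape[2], "y"),
                                  (r.x0, r.x1, shape[3], "x")):
                if lo < 0 or hi > n or lo >= hi:
                    issues.append(f"ERROR: ROI {r.nucleus_id} out of bounds on "
                                  f"axis {ax} ({lo}:{hi} vs {n})")
    try:
        probes = read_fosmid_bed(root / "fosmids.bed")
    except Exception as e:
        issues.append(f"ERROR: fosmids.bed unreadable: {e}")
        probes = []
    for i in range(0, len(probes) - 1, 2):
        a, b = probes[i], probes[i + 1]
        try:
            genomic_separation(a, b)
        except ValueError as e:
            issues.append(f"ERROR: fosmid pair {a.name}/{b.name}: {e}")
    ends = {p.end for p in probes}
    if any(p.start == e + 1 for p in probes for e in ends):
        issues.append("WARNING: BED starts equal to a neighbouring end + 1 — "
                      "coordinates may be 1-based; BED must be 0-based half-open")
    return issues


# ---------------------------------------------------------------------------
# Run
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    measurements: pd.DataFrame
    report: pd.DataFrame
    manifest: dict
    out_dir: Path


def _measure_bundle(bundle: StackBundle, shifts: dict, config: RunConfig,
                    rows: list, rejections: list, spot_rows: list):
    stack = bundle.stack
    if shifts and any(tuple(s) != (0, 0) for s in shifts.values()):
        stack = align_channels(stack, {k: tuple(v) for k, v in shifts.items()})
    for _, r in bundle.rois.iterrows():
        roi = NucleusROI(str(r.nucleus_id), str(r.embryo_id), str(r.region),
                         str(r.condition),
                         (int(r.z0), int(r.z1), int(r.y0), int(r.y1),
                          int(r.x0), int(r.x1)))
        try:
            m = measure_nucleus(stack, roi,
                                position_channel=config.position_channel,
                                presmooth_sigma=config.presmooth_sigma,
                                nucleus_margin_um=config.nucleus_margin_um)
        except MeasurementError as e:
            logger.warning("rejected %s: %s", e.nucleus_id, e.reason)
            rejections.append({"nucleus_id": e.nucleus_id,
                               "reason": e.reason.split(":")[0]})
            continue
        rows.append((m.nucleus_id, m.embryo_id, m.region, m.condition,
                     m.d_um, m.d2_um2, m.frac_radius, "|".join(m.flags)))
        for s in m.spots:
            spot_rows.append((m.nucleus_id, s.channel, *s.centroid_um,
                              s.voxel_count, s.threshold, "|".join(s.flags)))


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute a full run: (simulate|load) -> align -> segment -> measure ->
    compare -> write outputs.

    Writes ``measurements.csv``, ``report.csv``/``report.json``,
    ``manifest.json`` and plot files into ``config.out_dir`` and returns the
    in-memory tables.  Identical config + seed produce identical measurement
    tables and reports (manifest timestamps aside).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    issues = validate_inputs(config)
    errors = [i for i in issues if i.startswith("ERROR")]
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(errors))
    rows: list = []
    rejections: list = []
    spot_rows: list = []
    n_rois = 0
    if config.mode == "simulate":
        cohort = config.cohort
        probes = _dummy_panel_probes(cohort)
        for bundle in iter_cohort(cohort, render=True):
            n_rois += len(bundle.rois)
            _measure_bundle(bundle, cohort.imaging.channel_shift, config,
                            rows, rejections, spot_rows)
            logger.info("measured %s/%s/%s", bundle.region, bundle.condition,
                        bundle.embryo_id)
    else:
        probes = read_fosmid_bed(Path(config.cohort_dir) / "fosmids.bed")
        for bundle, shifts in read_cohort(config.cohort_dir):
            n_rois += len(bundle.rois)
            _measure_bundle(bundle, shifts, config, rows, rejections, spot_rows)
    # genomic separation of each fosmid pair (consecutive BED entries)
    panel_g = {}
    for i in range(0, len(probes) - 1, 2):
        try:
            panel_g[probes[i].name.rsplit("_", 1)[0]] = genomic_separation(
                probes[i], probes[i + 1])
        except ValueError:
            pass
    measurements = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    measurements.to_csv(out / "measurements.csv", index=False)
    pd.DataFrame(spot_rows, columns=SPOT_COLUMNS).to_csv(out / "spots.csv",
                                                         index=False)

    report = pd.DataFrame()
    if config.plan:
        from .stats import compare_design
        report = compare_design(measurements, config.plan,
                                correction=config.correction)
        report.to_csv(out / "report.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(_plainify(report.to_dict(orient="records")), fh, indent=1)
    if config.make_plots and not measurements.empty:
        from .plots import plot_boxes, plot_radial
        groups = {f"{r}/{c}": g["d2_um2"].to_numpy() for (r, c), g in
                  measurements.groupby(["region", "condition"], sort=True)}
        plot_boxes(groups, out / "box_d2.png", ylabel="d² (µm²)")
        fr = {f"{r}/{c}": g["frac_radius"].to_numpy() for (r, c), g in
              measurements.groupby(["region", "condition"], sort=True)}
        fr = {k: v[(v >= 0) & (v <= 1)] for k, v in fr.items()}
        plot_radial(fr, out / "radial.png")

    reasons: dict = {}
    for rj in rejections:
        reasons[rj["reason"]] = reasons.get(rj["reason"], 0) + 1
    manifest = {
        "config_hash": config_hash(config),
        "version": __version__,
        "seed": config.seed,
        "panel_genomic_separation_kb": panel_g,
        "counts": {"rois_in": n_rois, "measured": len(measurements),
                   "rejected": len(rejections)},
        "rejection_reasons": reasons,
        "rejected_nuclei": [rj["nucleus_id"] for rj in rejections],
        "started": t0,
        "elapsed_s": round(time.time() - t0, 3),
    }
    assert manifest["counts"]["rois_in"] == (manifest["counts"]["measured"]
                                             + manifest["counts"]["rejected"])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return RunResult(measurements, report, manifest, out)
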