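"""Readers and writers for the package's on-disk formats.

Formats are deliberately plain: trace sets as CSV (``frame`` column plus one
``roi<k>`` column per ROI) with a YAML metadata sidecar; correlation matrices
and edge lists as CSV; graphs as GraphML; images as TIFF with the um-per-px
scale in both the resolution tags and a JSON image description; run
manifests as JSON.  Every writer's output round-trips through the matching
reader.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import networkx as nx
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .exceptions import InputError
from .morphometry import AnnotatedImage, Boundary, MorphometryReport
from .network import CorrelationResult, PairFractionReport
from .simulate import SyntheticGroundTruth
from .traces import PreprocessParams, ProcessedTraceSet, RawTraceSet

__all__ = [
    "write_trace_set",
    "read_trace_set",
    "write_correlation_matrix",
    "read_correlation_matrix",
    "write_edge_list",
    "write_graphml",
    "write_pair_fraction_report",
    "write_image",
    "read_image",
    "write_ground_truth",
    "write_morphometry_report",
    "write_manifest",
]

TraceSet = Union[RawTraceSet, ProcessedTraceSet]


def _meta_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".meta.yaml")


def write_trace_set(
    ts: TraceSet,
    csv_path: Union[str, Path],
    community_of: Optional[Dict[int, int]] = None,
) -> Path:
    """Write traces as CSV plus a ``.meta.yaml`` sidecar; returns the sidecar path."""
    csv_path = Path(csv_path)
    df = ts.to_frame().reset_index()
    df.to_csv(csv_path, index=False)

    rois: Dict[str, dict] = {}
    for k in ts.roi_ids:
        entry: dict = {}
        if k in ts.compartment_of:
            entry["compartment"] = ts.compartment_of[k]
        if ts.centroid_of is not None and k in ts.centroid_of:
            entry["centroid"] = [float(c) for c in ts.centroid_of[k]]
        if community_of is not None and k in community_of:
            entry["community"] = int(community_of[k])
        rois[str(k)] = entry
    meta: dict = {
        "frame_interval_s": float(ts.frame_interval_s),
        "centroid_unit": ts.centroid_unit,
        "processed": isinstance(ts, ProcessedTraceSet),
        "rois": rois,
    }
    if isinstance(ts, ProcessedTraceSet):
        meta["params"] = asdict(ts.params)
        meta["params"]["smooth_window"] = list(ts.params.smooth_window)
        meta["degenerate_rois"] = sorted(ts.degenerate_rois)
    mp = _meta_path(csv_path)
    mp.write_text(yaml.safe_dump(meta, sort_keys=True))
    return mp


def read_trace_set(
    csv_path: Union[str, Path],
) -> Tuple[TraceSet, Dict[int, int]]:
    """Read a trace CSV plus sidecar; returns ``(trace set, community_of)``."""
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise InputError(f"trace file not found: {csv_path}")
    df = pd.read_csv(csv_path)
    roi_cols = [c for c in df.columns if c.startswith("roi")]
    if not roi_cols:
        raise InputError(f"no roi<k> columns in {csv_path}")
    traces = {int(c[3:]): df[c].to_numpy(dtype=float) for c in roi_cols}

    mp = _meta_path(csv_path)
    meta = yaml.safe_load(mp.read_text()) if mp.exists() else {}
    rois = meta.get("rois", {})
    compartment_of = {
        int(k): v["compartment"] for k, v in rois.items() if "compartment" in v
    }
    centroid_of = {
        int(k): tuple(v["centroid"]) for k, v in rois.items() if "centroid" in v
    }
    community_of = {int(k): int(v["community"]) for k, v in rois.items() if "community" in v}
    common = dict(
        traces=traces,
        frame_interval_s=float(meta.get("frame_interval_s", 1.29)),
        compartment_of=compartment_of,
        centroid_of=centroid_of or None,
        centroid_unit=meta.get("centroid_unit", "um"),
    )
    if meta.get("processed"):
        p = dict(meta.get("params", {}))
        if "smooth_window" in p:
            p["smooth_window"] = tuple(p["smooth_window"])
        ts: TraceSet = ProcessedTraceSet(
            params=PreprocessParams(**p) if p else PreprocessParams(),
            degenerate_rois=frozenset(meta.get("degenerate_rois", [])),
            **common,
        )
    else:
        ts = RawTraceSet(**common)
    return ts, community_of


def write_correlation_matrix(result: CorrelationResult, path: Union[str, Path]) -> None:
    result.to_frame().to_csv(path, index=True, index_label="roi")


def read_correlation_matrix(path: Union[str, Path]) -> CorrelationResult:
    df = pd.read_csv(path, index_col=0)
    ids = [int(c[3:]) for c in df.columns]
    return CorrelationResult(roi_ids=ids, r=df.to_numpy(dtype=float))


def write_edge_list(result: CorrelationResult, path: Union[str, Path]) -> None:
    """Correlated pairs as CSV: roi_i, roi_j, r, pair_class."""
    rows = []
    pairs = result.correlated_pairs or frozenset()
    for (i, j) in sorted(pairs):
        rows.append(
            {
                "roi_i": i,
                "roi_j": j,
                "r": result.r_of(i, j),
                "pair_class": result.pair_class_of.get((i, j), ""),
            }
        )
    pd.DataFrame(rows, columns=["roi_i", "roi_j", "r", "pair_class"]).to_csv(
        path, index=False
    )


def write_graphml(graph: nx.Graph, path: Union[str, Path]) -> None:
    nx.write_graphml(graph, path)


def write_pair_fraction_report(
    report: PairFractionReport,
    csv_path: Union[str, Path],
    txt_path: Optional[Union[str, Path]] = None,
) -> None:
    report.to_frame().to_csv(csv_path, index=False)
    if txt_path is not None:
        Path(txt_path).write_text(report.summary() + "\n")


def write_image(image: AnnotatedImage, path: Union[str, Path]) -> None:
    """Write an annotated image as TIFF (channels stacked on axis 0)."""
    channels = [image.signal]
    names = ["signal"]
    if image.nuclei is not None:
        channels.append(image.nuclei)
        names.append("nuclei")
    stack = np.stack(channels).astype(np.float32)
    desc = {
        "um_per_px": image.um_per_px,
        "channels": names,
        "boundary": {
            "orientation": image.boundary.orientation,
            "position_um": image.boundary.position_um,
            "host_side": image.boundary.host_side,
        },
        "detection_threshold": image.detection_threshold,
    }
    px_per_cm = 1e4 / image.um_per_px
    tifffile.imwrite(
        path,
        stack,
        photometric="minisblack",
        description=json.dumps(desc, sort_keys=True),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def read_image(path: Union[str, Path]) -> AnnotatedImage:
    path = Path(path)
    if not path.exists():
        raise InputError(f"image not found: {path}")
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc) if desc else {}
    if stack.ndim == 2:
        stack = stack[None]
    names = meta.get("channels", ["signal"] + (["nuclei"] if stack.shape[0] > 1 else []))
    signal = stack[names.index("signal")]
    nuclei = stack[names.index("nuclei")] if "nuclei" in names else None
    b = meta.get("boundary", {})
    boundary = Boundary(
        orientation=b.get("orientation", "vertical"),
        position_um=float(b.get("position_um", 0.0)),
        host_side=int(b.get("host_side", 1)),
    )
    return AnnotatedImage(
        signal=np.asarray(signal, dtype=float),
        nuclei=None if nuclei is None else np.asarray(nuclei, dtype=float),
        um_per_px=float(meta["um_per_px"]),
        boundary=boundary,
        detection_threshold=meta.get("detection_threshold"),
    )


def write_ground_truth(truth: SyntheticGroundTruth, path: Union[str, Path]) -> None:
    """Planted scene/recording truth as a tidy CSV table."""
    rows = []
    for d, y in truth.migrated_cell_positions_um:
        rows.append({"item": "migrated_cell", "distance_um": d, "y_um": y, "value": ""})
    for d, y in truth.distractor_positions_um:
        rows.append({"item": "distractor_cell", "distance_um": d, "y_um": y, "value": ""})
    rows.append(
        {"item": "outgrowth_um", "distance_um": "", "y_um": "", "value": truth.planted_outgrowth_um}
    )
    rows.append(
        {"item": "implant_fill_fraction", "distance_um": "", "y_um": "", "value": truth.implant_fill_fraction}
    )
    if truth.outgrowth_stripe_um is not None:
        rows.append(
            {
                "item": "outgrowth_stripe_um",
                "distance_um": truth.outgrowth_stripe_um[0],
                "y_um": truth.outgrowth_stripe_um[1],
                "value": "",
            }
        )
    for roi, cid in sorted(truth.community_of.items()):
        rows.append({"item": "community", "distance_um": roi, "y_um": "", "value": cid})
    pd.DataFrame(rows, columns=["item", "distance_um", "y_um", "value"]).to_csv(
        path, index=False
    )


def write_morphometry_report(report: MorphometryReport, path: Union[str, Path]) -> None:
    row = {
        "outgrowth_um": report.outgrowth_um,
        "migrated_count": report.migrated_count,
        "migrated_density_per_0.1mm2": report.migrated_density_per_field,
        "band_lo_um": report.band_um[0],
        "band_hi_um": report.band_um[1],
        "band_area_mm2": report.band_area_mm2,
        "rfp_coverage_pct": report.rfp_coverage_pct,
    }
    pd.DataFrame([row]).to_csv(path, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    path: Union[str, Path],
    parameters: dict,
    seed: Optional[int] = None,
    inputs: Optional[Dict[str, Union[str, Path]]] = None,
) -> None:
    """Machine-readable run manifest: parameters, seed, version, input checksums."""
    manifest = {
        "package": "neurograft",
        "version": __version__,
        "seed": seed,
        "parameters": parameters,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (inputs or {}).items()
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
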