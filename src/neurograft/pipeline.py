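"""End-to-end analysis tracks composing the per-stage modules.

``full_calcium`` runs preprocessing -> Pearson matrix -> pair calls ->
compartment-stratified fractions (plus ordering and network) on a raw trace
set; ``full_morphology`` runs profile -> outgrowth, migrated-cell counting
and coverage on an annotated image.  Both are pure library functions; the
CLI and the reproduction script are thin wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import networkx as nx
import numpy as np

from .morphometry import (
    DEFAULT_BAND_UM,
    AnnotatedImage,
    IntensityProfile,
    MorphometryReport,
    count_migrated_cells,
    intensity_profile,
    outgrowth_distance,
    rfp_coverage,
)
from .network import (
    DEFAULT_THRESHOLD,
    CorrelationResult,
    PairFractionReport,
    build_network,
    call_correlated_pairs,
    pair_fractions,
    pearson_matrix,
    similarity_matrix_ordering,
)
from .traces import PreprocessParams, ProcessedTraceSet, RawTraceSet, preprocess

__all__ = ["CalciumRunResult", "full_calcium", "full_morphology"]


@dataclass
class CalciumRunResult:
    """All artefacts of one calcium-connectivity run."""

    processed: ProcessedTraceSet
    correlation: CorrelationResult
    report: PairFractionReport
    ordering: List[int]
    ordered_matrix: np.ndarray
    graph: nx.Graph


def full_calcium(
    raw: RawTraceSet,
    params: Optional[PreprocessParams] = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> CalciumRunResult:
    """Run the full connectivity track on a raw trace set."""
    processed = preprocess(raw, params)
    corr = pearson_matrix(processed)
    call_correlated_pairs(corr, threshold)
    report = pair_fractions(corr, processed.compartment_of)
    ordering, ordered = similarity_matrix_ordering(corr)
    graph = build_network(corr, processed.centroid_of or {}, processed.compartment_of)
    return CalciumRunResult(
        processed=processed,
        correlation=corr,
        report=report,
        ordering=ordering,
        ordered_matrix=ordered,
        graph=graph,
    )


def full_morphology(
    image: AnnotatedImage,
    profile_box_um: Optional[Tuple[float, float, float, float]] = None,
    band_um: Tuple[float, float] = DEFAULT_BAND_UM,
    coverage_region_um: Optional[Tuple[float, float, float, float]] = None,
    threshold: Optional[float] = None,
) -> Tuple[MorphometryReport, IntensityProfile]:
    """Run the full morphometry track on an annotated image.

    ``profile_box_um`` defaults to the full image; ``coverage_region_um``
    defaults to the implant-side slab (coverage of the labelled area within
    the implant compartment).  ``threshold`` overrides the image's detection
    threshold for all three measurements.
    """
    h, w = image.shape
    s = image.um_per_px
    thr = image.effective_threshold() if threshold is None else float(threshold)

    if profile_box_um is None:
        profile_box_um = (0.0, w * s, 0.0, h * s)
    profile = intensity_profile(image, profile_box_um)
    outgrowth = outgrowth_distance(profile, thr)

    migration = count_migrated_cells(image, band_um=band_um, threshold=thr)

    coverage: Optional[float] = None
    if coverage_region_um is None and image.boundary.orientation == "vertical":
        # implant-side slab (host_side=+1 puts the implant at x < position)
        if image.boundary.host_side == 1 and image.boundary.position_um > 0:
            coverage_region_um = (0.0, image.boundary.position_um, 0.0, h * s)
    if coverage_region_um is not None:
        coverage = rfp_coverage(image, coverage_region_um, threshold=thr)

    report = MorphometryReport(
        outgrowth_um=outgrowth,
        migrated_count=migration.count,
        migrated_density_per_field=migration.density_per_field,
        band_um=migration.band_um,
        band_area_mm2=migration.band_area_mm2,
        rfp_coverage_pct=coverage,
    )
    return report, profile
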