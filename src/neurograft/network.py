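"""Pairwise Pearson connectivity across the implant-host interface.

All-pairs Pearson correlation is computed on fully preprocessed traces; an
unordered ROI pair is *correlated* when r > 0.1 (strict, one-sided — negative
correlations never qualify).  Pairs are stratified by their endpoints'
compartment labels (host-host, host-implant, implant-implant) and the
fraction of correlated pairs per class is the headline interface statistic.

A similarity-matrix ordering (average-linkage hierarchical clustering on
1 - r, densest cluster first) and a spatial correlation graph round out the
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .exceptions import InsufficientDataError, LabelingError
from .traces import ProcessedTraceSet

__all__ = [
    "CorrelationResult",
    "PairFractionReport",
    "pearson_matrix",
    "call_correlated_pairs",
    "pair_fractions",
    "pair_class",
    "similarity_matrix_ordering",
    "build_network",
    "permutation_null_rate",
]

DEFAULT_THRESHOLD = 0.1

Pair = Tuple[int, int]


def pair_class(label_i: str, label_j: str) -> str:
    """Canonical unordered pair-class label, e.g. ``host-implant``."""
    a, b = sorted((label_i, label_j))
    return f"{a}-{b}"


@dataclass
class CorrelationResult:
    """Symmetric Pearson matrix over non-degenerate ROIs plus pair calls."""

    roi_ids: List[int]
    r: np.ndarray
    degenerate_rois: frozenset = frozenset()
    threshold: float = DEFAULT_THRESHOLD
    correlated_pairs: Optional[FrozenSet[Pair]] = None
    pair_class_of: Dict[Pair, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.roi_ids)
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix shape does not match roi_ids")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def r_of(self, i: int, j: int) -> float:
        """Correlation between ROI ids i and j."""
        ii, jj = self.roi_ids.index(i), self.roi_ids.index(j)
        return float(self.r[ii, jj])

    def all_pairs(self) -> List[Pair]:
        ids = self.roi_ids
        return [(ids[a], ids[b]) for a in range(len(ids)) for b in range(a + 1, len(ids))]

    def to_frame(self) -> pd.DataFrame:
        labels = [f"roi{k}" for k in self.roi_ids]
        return pd.DataFrame(self.r, index=labels, columns=labels)


@dataclass
class PairFractionReport:
    """Per pair-class counts and correlated fraction (percent).

    ``classes`` maps a class label (e.g. ``host-host``) to a dict with
    ``n_possible``, ``n_correlated`` and ``fraction_pct``.  Possible-pair
    counts over all classes sum to C(n, 2) for n usable ROIs.
    """

    classes: Dict[str, Dict[str, float]]
    threshold: float = DEFAULT_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pair_class": k, **v} for k, v in sorted(self.classes.items())
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Correlated-pair fractions (Pearson r > {self.threshold:g})"]
        for k, v in sorted(self.classes.items()):
            lines.append(
                f"  {k:>16s}: {int(v['n_correlated']):4d} / {int(v['n_possible']):4d} "
                f"pairs = {v['fraction_pct']:6.2f}%"
            )
        return "\n".join(lines)


def _stack(processed: ProcessedTraceSet) -> Tuple[List[int], np.ndarray]:
    ids = processed.usable_roi_ids
    if len(ids) < 2:
        raise InsufficientDataError(
            f"need >= 2 non-degenerate ROIs for correlation, got {len(ids)}"
        )
    return ids, np.vstack([processed.traces[k] for k in ids])


def pearson_matrix(processed: ProcessedTraceSet) -> CorrelationResult:
    """All-pairs sample Pearson correlation over non-degenerate ROIs.

    Degenerate (constant) ROIs are omitted from the matrix and reported in
    ``degenerate_rois``.
    """
    ids, data = _stack(processed)
    r = np.corrcoef(data)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationResult(roi_ids=ids, r=r, degenerate_rois=processed.degenerate_rois)


def call_correlated_pairs(
    result: CorrelationResult, threshold: float = DEFAULT_THRESHOLD
) -> FrozenSet[Pair]:
    """Call correlated pairs at r > threshold (strict, one-sided).

    A pair at exactly the threshold is excluded; anticorrelated pairs never
    qualify.  The call set is stored on the result and returned.
    """
    ids = result.roi_ids
    pairs = set()
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if result.r[a, b] > threshold:
                pairs.add((ids[a], ids[b]))
    result.threshold = threshold
    result.correlated_pairs = frozenset(pairs)
    return result.correlated_pairs


def pair_fractions(
    result: CorrelationResult, compartment_of: Dict[int, str]
) -> PairFractionReport:
    """Stratify pairs by endpoint compartments and report correlated fractions.

    Each unordered pair belongs to exactly one class; the fraction is
    100 * n_correlated / n_possible within the class.
    """
    if result.correlated_pairs is None:
        call_correlated_pairs(result, result.threshold)
    for roi in result.roi_ids:
        if roi not in compartment_of:
            raise LabelingError(f"ROI {roi} has no compartment label")
    classes: Dict[str, Dict[str, float]] = {}
    # make sure every class among the labels present appears, even at 0 pairs
    labels = sorted({compartment_of[k] for k in result.roi_ids})
    for i, a in enumerate(labels):
        for b in labels[i:]:
            classes[pair_class(a, b)] = {"n_possible": 0, "n_correlated": 0}
    for (i, j) in result.all_pairs():
        cls = pair_class(compartment_of[i], compartment_of[j])
        classes[cls]["n_possible"] += 1
        if (min(i, j), max(i, j)) in result.correlated_pairs:
            classes[cls]["n_correlated"] += 1
        result.pair_class_of[(min(i, j), max(i, j))] = cls
    for v in classes.values():
        v["fraction_pct"] = (
            100.0 * v["n_correlated"] / v["n_possible"] if v["n_possible"] else 0.0
        )
    return PairFractionReport(classes=classes, threshold=result.threshold)


def _subtree_leaves(node) -> List[int]:
    return node.pre_order(lambda leaf: leaf.id)


def _ordered_leaves(node, r: np.ndarray) -> List[int]:
    """Recursive leaf order: at each merge, the subtree with the higher mean
    internal correlation comes first; ties broken by smallest leaf index."""
    if node.is_leaf():
        return [node.id]
    children = [node.get_left(), node.get_right()]

    def density(child) -> Tuple[float, int]:
        leaves = _subtree_leaves(child)
        if len(leaves) == 1:
            mean_r = 1.0
        else:
            sub = r[np.ix_(leaves, leaves)]
            iu = np.triu_indices(len(leaves), k=1)
            mean_r = float(np.mean(sub[iu]))
        return (-mean_r, min(leaves))

    children.sort(key=density)
    out: List[int] = []
    for child in children:
        out.extend(_ordered_leaves(child, r))
    return out


def similarity_matrix_ordering(
    result: CorrelationResult,
) -> Tuple[List[int], np.ndarray]:
    """Order ROIs so strongly correlated groups form top-left blocks.

    Average-linkage hierarchical clustering on distance 1 - r; at every merge
    the denser subtree (higher mean within-subtree r) is placed first, so the
    most mutually correlated cluster ends up in the top-left of the reordered
    matrix.  Deterministic: ties are broken by ROI id.

    Returns ``(ordered roi ids, reordered matrix)``.
    """
    n = result.n_rois
    if n < 2:
        return list(result.roi_ids), result.r.copy()
    d = 1.0 - result.r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = linkage(squareform(d, checks=False), method="average")
    order = _ordered_leaves(to_tree(z), result.r)
    perm_ids = [result.roi_ids[i] for i in order]
    reordered = result.r[np.ix_(order, order)]
    return perm_ids, reordered


def build_network(
    result: CorrelationResult,
    centroid_of: Dict[int, Tuple[float, float]],
    compartment_of: Optional[Dict[int, str]] = None,
) -> nx.Graph:
    """Spatial correlation graph: nodes are ROIs at their centroids, edges are
    correlated pairs weighted by r."""
    if result.correlated_pairs is None:
        call_correlated_pairs(result, result.threshold)
    g = nx.Graph(threshold=result.threshold)
    for roi in result.roi_ids:
        attrs = {}
        if centroid_of is not None and roi in centroid_of:
            x, y = centroid_of[roi]
            attrs["x"], attrs["y"] = float(x), float(y)
        if compartment_of is not None and roi in compartment_of:
            attrs["compartment"] = compartment_of[roi]
        g.add_node(roi, **attrs)
    for (i, j) in sorted(result.correlated_pairs):
        g.add_edge(i, j, r=result.r_of(i, j))
    return g


def permutation_null_rate(
    raw,
    params=None,
    threshold: float = DEFAULT_THRESHOLD,
    n_perm: int = 1000,
    seed: int = 0,
) -> Tuple[float, np.ndarray]:
    """Empirical null rate of pair calls under independent time-shuffling.

    Each permutation independently shuffles every ROI's *raw* time axis
    (destroying all cross-trace structure while preserving marginals), then
    re-runs the full preprocessing and Pearson matrix, and records the
    fraction of pairs with r > threshold.  Shuffling before preprocessing
    matters: smoothing and the indicator decay autocorrelate processed
    traces, and the null must carry the same processing-induced
    autocorrelation as the observed statistic.

    ``raw`` is a RawTraceSet; ``params`` the PreprocessParams used for the
    observed analysis.  Returns ``(mean null fraction, per-permutation
    fractions)``.
    """
    from .traces import RawTraceSet, preprocess

    rng = np.random.default_rng(seed)
    ids = raw.roi_ids
    data = np.vstack([raw.traces[k] for k in ids])
    n, t = data.shape
    fractions = np.empty(n_perm)
    for p in range(n_perm):
        shuffled = {
            ids[row]: data[row, rng.permutation(t)] for row in range(n)
        }
        perm_raw = RawTraceSet(
            traces=shuffled,
            frame_interval_s=raw.frame_interval_s,
            compartment_of=raw.compartment_of,
        )
        processed = preprocess(perm_raw, params)
        usable = processed.usable_roi_ids
        if len(usable) < 2:
            fractions[p] = 0.0
            continue
        r = np.corrcoef(np.vstack([processed.traces[k] for k in usable]))
        iu = np.triu_indices(len(usable), k=1)
        fractions[p] = float(np.mean(r[iu] > threshold))
    return float(np.mean(fractions)), fractions
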