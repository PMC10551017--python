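"""Synthetic calcium recordings and morphology scenes with known ground truth.

Every downstream stage of the package is testable offline against data this
module generates:

* ``simulate_traces`` emulates multi-ROI spontaneous calcium recordings
  (Fluo-4-like transients at a slow frame rate): per-frame Bernoulli events,
  a single-exponential indicator decay with instantaneous rise, planted
  correlated communities that share event times across the host-implant
  divide, plus private events and additive Gaussian noise.
* ``simulate_morphology_image`` draws a two-compartment fluorescence scene:
  a bright implant slab, a labelled-process ramp decaying linearly from the
  implant edge and falling below the detection threshold exactly at the
  planted outgrowth distance, and discrete somata (with coincident nuclear
  blobs) at known distances from the boundary.

Identical seed and configuration give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import ConfigurationError
from .morphometry import AnnotatedImage, Boundary
from .traces import HOST, IMPLANT, RawTraceSet

__all__ = [
    "SimConfig",
    "SyntheticGroundTruth",
    "simulate_traces",
    "simulate_morphology_image",
    "IMPLANT_INTENSITY",
    "DETECTION_THRESHOLD",
]

# grayscale rendering levels for morphology scenes (8-bit-like units)
IMPLANT_INTENSITY = 200.0
DETECTION_THRESHOLD = 20.0
CELL_INTENSITY = 230.0
NUCLEUS_INTENSITY = 180.0
SUBTHRESHOLD_TAIL_PEAK = 8.0


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic multi-ROI calcium recording.

    ROIs 0 .. n_host-1 are host cells, the rest implant cells.
    ``communities`` is a list of ``(member ROI ids, shared event rate per
    frame)``; members of one community fire together (same event frames) on
    top of their private events at ``background_event_rate``.  The calcium
    kernel is ``amplitude * exp(-t / kernel_tau_s)`` from the event frame on.
    """

    n_host: int = 30
    n_implant: int = 20
    n_frames: int = 300
    frame_interval_s: float = 1.29
    communities: Sequence[Tuple[Sequence[int], float]] = ()
    background_event_rate: float = 0.02
    kernel_tau_s: float = 3.0
    transient_amplitude: float = 20.0
    baseline_f0: float = 100.0
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_host <= 0 or self.n_implant <= 0 or self.n_frames <= 0:
            raise ConfigurationError("n_host, n_implant and n_frames must be > 0")
        if not (0.0 <= self.background_event_rate <= 1.0):
            raise ConfigurationError("background_event_rate must be in [0, 1]")
        if self.kernel_tau_s <= 0:
            raise ConfigurationError("kernel_tau_s must be > 0")
        if self.baseline_f0 <= 0:
            raise ConfigurationError("baseline_f0 must be > 0")
        if self.noise_sd < 0 or self.transient_amplitude < 0:
            raise ConfigurationError("noise_sd and transient_amplitude must be >= 0")
        n = self.n_host + self.n_implant
        seen: set = set()
        for members, rate in self.communities:
            if not (0.0 <= rate <= 1.0):
                raise ConfigurationError("community event rate must be in [0, 1]")
            for m in members:
                if not (0 <= int(m) < n):
                    raise ConfigurationError(
                        f"community member {m} outside ROI range [0, {n})"
                    )
                if m in seen:
                    raise ConfigurationError(f"ROI {m} appears in two communities")
                seen.add(m)

    @property
    def n_rois(self) -> int:
        return self.n_host + self.n_implant


@dataclass
class SyntheticGroundTruth:
    """Planted structure of a synthetic recording or morphology scene."""

    community_of: Dict[int, int] = field(default_factory=dict)
    compartment_of: Dict[int, str] = field(default_factory=dict)
    planted_outgrowth_um: float = 0.0
    migrated_cell_positions_um: List[Tuple[float, float]] = field(default_factory=list)
    distractor_positions_um: List[Tuple[float, float]] = field(default_factory=list)
    implant_fill_fraction: float = 1.0
    outgrowth_stripe_um: Optional[Tuple[float, float]] = None


def simulate_traces(config: SimConfig) -> Tuple[RawTraceSet, SyntheticGroundTruth]:
    """Generate a raw multi-ROI calcium recording with planted communities.

    Each trace is ``baseline_f0 + amplitude * sum_events exp(-(t - t_e)/tau)
    + N(0, noise_sd)``, clipped at zero.  Members of one community share the
    same event frames (plus private events); other ROIs have only private
    events.  Host ROIs receive centroids at x > 0, implant ROIs at x < 0
    (boundary at x = 0), in micrometres.
    """
    rng = np.random.default_rng(config.seed)
    n, t = config.n_rois, config.n_frames
    dt = config.frame_interval_s

    events = np.zeros((n, t))
    community_of: Dict[int, int] = {}
    for cid, (members, rate) in enumerate(config.communities):
        shared = (rng.random(t) < rate).astype(float)
        for m in members:
            events[int(m)] += shared
            community_of[int(m)] = cid
    events += (rng.random((n, t)) < config.background_event_rate).astype(float)

    # single-exponential indicator kernel, instantaneous rise
    klen = min(t, max(1, int(np.ceil(10.0 * config.kernel_tau_s / dt))))
    kernel = np.exp(-np.arange(klen) * dt / config.kernel_tau_s)
    response = np.empty_like(events)
    for i in range(n):
        response[i] = np.convolve(events[i], kernel)[:t]
    traces = config.baseline_f0 + config.transient_amplitude * response

    compartment_of = {i: (HOST if i < config.n_host else IMPLANT) for i in range(n)}
    cx = np.empty(n)
    cx[: config.n_host] = rng.uniform(20.0, 280.0, config.n_host)
    cx[config.n_host :] = rng.uniform(-280.0, -20.0, config.n_implant)
    cy = rng.uniform(0.0, 300.0, n)
    centroid_of = {i: (float(cx[i]), float(cy[i])) for i in range(n)}

    if config.noise_sd > 0:
        traces = traces + rng.normal(0.0, config.noise_sd, traces.shape)
    traces = np.clip(traces, 0.0, None)

    raw = RawTraceSet(
        traces={i: traces[i] for i in range(n)},
        frame_interval_s=dt,
        compartment_of=compartment_of,
        centroid_of=centroid_of,
        centroid_unit="um",
    )
    truth = SyntheticGroundTruth(
        community_of=community_of, compartment_of=dict(compartment_of)
    )
    return raw, truth


def _disk_mask(xg: np.ndarray, yg: np.ndarray, cx: float, cy: float, r: float) -> np.ndarray:
    return (xg - cx) ** 2 + (yg - cy) ** 2 <= r * r


def simulate_morphology_image(
    width_um: float,
    height_um: float,
    um_per_px: float,
    boundary_x_um: float,
    outgrowth_um: float,
    n_migrated_cells: int,
    migration_band_um: Tuple[float, float] = (200.0, 400.0),
    decay_length_um: float = 50.0,
    seed: int = 0,
    *,
    implant_fill_fraction: float = 1.0,
    extra_cell_distances_um: Sequence[float] = (),
    n_nucleus_free_blobs: int = 0,
    orientation: str = "vertical",
    cell_radius_um: float = 5.0,
    nucleus_radius_um: float = 3.0,
    stripe_frac: Tuple[float, float] = (0.35, 0.65),
) -> Tuple[AnnotatedImage, SyntheticGroundTruth]:
    """Render a two-compartment scene with planted integration metrics.

    The implant occupies x < ``boundary_x_um`` (host side positive-x).  The
    labelled-process signal decays linearly from the implant intensity at the
    boundary to the detection threshold exactly at ``boundary + outgrowth_um``
    inside a horizontal stripe (``stripe_frac`` of the image height); beyond
    that endpoint only a faint sub-threshold tail with scale
    ``decay_length_um`` remains, so the farthest detectable signal is the
    planted outgrowth by construction.  Migrated somata (disks with
    coincident nuclear blobs) are placed outside the stripe at uniform
    distances in ``migration_band_um``; ``extra_cell_distances_um`` plants
    nucleus-colocalised distractor somata at given distances, and
    ``n_nucleus_free_blobs`` plants in-band somata lacking a nucleus.

    ``implant_fill_fraction`` fills only the boundary-adjacent fraction of
    the implant slab with label, so area-coverage readouts have a planted
    truth.  ``orientation="horizontal"`` transposes the scene (boundary
    becomes a horizontal line).
    """
    if outgrowth_um < 0:
        raise ConfigurationError("outgrowth_um must be >= 0")
    if outgrowth_um > width_um - boundary_x_um:
        raise ConfigurationError("planted outgrowth exceeds the host-side field")
    lo, hi = migration_band_um
    if not (0 <= lo < hi):
        raise ConfigurationError("migration band must satisfy 0 <= lo < hi")
    if not (0.0 <= implant_fill_fraction <= 1.0):
        raise ConfigurationError("implant_fill_fraction must be in [0, 1]")
    total_cells = n_migrated_cells + len(extra_cell_distances_um) + n_nucleus_free_blobs
    if total_cells > 0 and boundary_x_um + hi + cell_radius_um > width_um:
        raise ConfigurationError("migration band does not fit in the field")

    rng = np.random.default_rng(seed)
    w = int(round(width_um / um_per_px))
    h = int(round(height_um / um_per_px))
    x = (np.arange(w) + 0.5) * um_per_px
    y = (np.arange(h) + 0.5) * um_per_px
    xg, yg = np.meshgrid(x, y)

    signal = np.zeros((h, w))
    nuclei = np.zeros((h, w))

    # implant slab: filled fraction adjacent to the boundary
    fill_from = boundary_x_um * (1.0 - implant_fill_fraction)
    signal[(xg < boundary_x_um) & (xg >= fill_from)] = IMPLANT_INTENSITY

    # process-outgrowth ramp, restricted to a horizontal stripe
    stripe_lo = stripe_frac[0] * height_um
    stripe_hi = stripe_frac[1] * height_um
    in_stripe = (yg >= stripe_lo) & (yg < stripe_hi)
    d = xg - boundary_x_um
    if outgrowth_um > 0:
        ramp = in_stripe & (d > 0) & (d <= outgrowth_um)
        signal[ramp] = (
            IMPLANT_INTENSITY
            - (IMPLANT_INTENSITY - DETECTION_THRESHOLD) * d[ramp] / outgrowth_um
        )
    if decay_length_um > 0:
        tail = in_stripe & (d > outgrowth_um)
        signal[tail] = np.maximum(
            signal[tail],
            SUBTHRESHOLD_TAIL_PEAK * np.exp(-(d[tail] - outgrowth_um) / decay_length_um),
        )

    def sample_y() -> float:
        """y outside the outgrowth stripe, clear of image edges."""
        margin = cell_radius_um + 2.0
        lower = (margin, max(margin, stripe_lo - margin))
        upper = (min(stripe_hi + margin, height_um - margin), height_um - margin)
        spans = [s for s in (lower, upper) if s[1] > s[0]]
        if not spans:
            raise ConfigurationError("no room outside the outgrowth stripe for cells")
        widths = np.array([s[1] - s[0] for s in spans])
        pick = rng.integers(len(spans)) if len(spans) > 1 else 0
        return float(rng.uniform(*spans[pick]))

    placed: List[Tuple[float, float]] = []

    def place(dist: float, with_nucleus: bool) -> Tuple[float, float]:
        cxp = boundary_x_um + dist
        for _ in range(1000):
            cyp = sample_y()
            if all(
                (cxp - px) ** 2 + (cyp - py) ** 2 > (3.0 * cell_radius_um) ** 2
                for px, py in placed
            ):
                break
        else:
            raise ConfigurationError("could not place non-overlapping cells")
        placed.append((cxp, cyp))
        signal[_disk_mask(xg, yg, cxp, cyp, cell_radius_um)] = CELL_INTENSITY
        if with_nucleus:
            nuclei[_disk_mask(xg, yg, cxp, cyp, nucleus_radius_um)] = NUCLEUS_INTENSITY
        return (dist, cyp)

    migrated: List[Tuple[float, float]] = []
    for _ in range(n_migrated_cells):
        migrated.append(place(float(rng.uniform(lo, hi)), with_nucleus=True))
    distractors: List[Tuple[float, float]] = []
    for dist in extra_cell_distances_um:
        distractors.append(place(float(dist), with_nucleus=True))
    for _ in range(n_nucleus_free_blobs):
        distractors.append(place(float(rng.uniform(lo, hi)), with_nucleus=False))

    boundary = Boundary(orientation="vertical", position_um=boundary_x_um, host_side=1)
    if orientation == "horizontal":
        signal = signal.T.copy()
        nuclei = nuclei.T.copy()
        boundary = Boundary(
            orientation="horizontal", position_um=boundary_x_um, host_side=1
        )
    elif orientation != "vertical":
        raise ConfigurationError(f"unknown orientation {orientation!r}")

    image = AnnotatedImage(
        signal=signal,
        nuclei=nuclei,
        um_per_px=um_per_px,
        boundary=boundary,
        detection_threshold=DETECTION_THRESHOLD,
    )
    truth = SyntheticGroundTruth(
        planted_outgrowth_um=float(outgrowth_um),
        migrated_cell_positions_um=migrated,
        distractor_positions_um=distractors,
        implant_fill_fraction=implant_fill_fraction,
        outgrowth_stripe_um=(stripe_lo, stripe_hi),
    )
    return image, truth
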