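"""Orientation analysis of helix-pair ensembles and binding-mode discovery.

A bound helix pair is described by two angles on a 360-periodic torus:

* **beta** — where partner B sits *around* A: the in-membrane-plane angle,
  measured about A's axis, from A's reference-residue wheel direction to the
  projected A-to-B inter-axis displacement;
* **chi** — which face of B points at A: the same construction evaluated on
  chain B toward A.

With this convention (0, 0) is the configuration in which the two reference
faces touch. Binding modes are catchment basins of the smoothed (beta, chi)
density of bound samples, segmented by a watershed transform with periodic
boundary handling (3x3 tiling, center-tile crop, relabeling across seams).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from ._angles import torus_dist_deg, vector_angle_deg, wrap_deg
from .helix_geometry import crossing_angle, fit_helix_axis, tilt_angle
from .structure_io import Frame, minimum_image

__all__ = [
    "OrientationSample",
    "ModeMap",
    "compute_beta_chi",
    "build_mode_map",
    "assign_frames",
    "populations_over_time",
    "select_representative",
]

UNBOUND = -1
UNASSIGNED = -2
MEMBRANE_NORMAL = np.array([0.0, 0.0, 1.0])


@dataclass
class OrientationSample:
    """Per-frame orientation descriptors of one helix pair."""

    beta: float  # deg in [0, 360)
    chi: float  # deg in [0, 360)
    crossing: float  # signed deg
    tilt_a: float  # deg
    tilt_b: float  # deg
    com_distance: float  # nm
    bound: bool
    time: float  # ns
    replica_id: int = 0

    def __post_init__(self):
        if not (0.0 <= self.beta < 360.0 and 0.0 <= self.chi < 360.0):
            raise ValueError("beta/chi must lie in [0, 360)")


def _reference_direction(frame: Frame, chain: int, topology, axis) -> np.ndarray:
    """In-plane unit vector from the axis to the reference residue bead."""
    idx = topology.index_of(topology.reference_residue)
    coords = frame.chain_coordinates(chain)
    bead = coords[idx]
    radial = bead - (axis.centroid + axis.residue_projections[idx] * axis.direction)
    radial[2] = 0.0  # project into the membrane plane
    n = np.linalg.norm(radial[:2])
    if n < 1e-9:
        raise ValueError("reference residue lies on the helix axis")
    return radial / n


def compute_beta_chi(
    frame: Frame,
    chain_a: int,
    chain_b: int,
    topologies,
    bound: bool | None = None,
    replica_id: int = 0,
) -> OrientationSample:
    """Orientation sample (beta, chi, tilts, crossing, COM distance) of a pair.

    ``bound`` is normally decided by the energetic dimer criterion upstream;
    when ``None`` a center-of-mass surface-gap fallback (<= 1.2 nm beyond
    helix contact) is used.
    """
    axis_a = fit_helix_axis(frame, chain_a)
    axis_b = fit_helix_axis(frame, chain_b)
    d = minimum_image(axis_b.centroid - axis_a.centroid, frame.box)
    dist = float(np.linalg.norm(d))
    if dist < 0.1:
        raise ValueError("chain centroids overlap: orientation undefined")
    d_plane = d[:2]
    if np.linalg.norm(d_plane) < 1e-9:
        raise ValueError("chains are stacked along the normal: beta undefined")

    ref_a = _reference_direction(frame, chain_a, topologies[chain_a], axis_a)
    ref_b = _reference_direction(frame, chain_b, topologies[chain_b], axis_b)
    beta = wrap_deg(vector_angle_deg(d_plane) - vector_angle_deg(ref_a[:2]))
    chi = wrap_deg(vector_angle_deg(-d_plane) - vector_angle_deg(ref_b[:2]))

    cross, _ = crossing_angle(axis_a, axis_b, d)
    if bound is None:
        bound = dist <= 1.2 + 0.94  # surface-gap fallback: 2 x 0.47 nm radius
    return OrientationSample(
        float(beta),
        float(chi),
        float(cross),
        tilt_angle(axis_a, MEMBRANE_NORMAL),
        tilt_angle(axis_b, MEMBRANE_NORMAL),
        dist,
        bool(bound),
        float(frame.time),
        replica_id,
    )


# ---------------------------------------------------------------------------
# mode maps


@dataclass
class ModeMap:
    """Periodic (beta, chi) density with watershed mode labels.

    ``labels`` maps every bin to a mode id (0..K-1) or -1 for *unassigned*:
    bins whose density does not rise significantly above the flat bound-state
    background belong to no mode, so mode populations are well-local and do
    not depend on an arbitrary watershed boundary through the background.
    Populations over modes plus the unassigned fraction sum to one.
    """

    bin_width: float
    density: np.ndarray  # smoothed density, shape (nbins, nbins)
    counts: np.ndarray  # raw histogram of bound samples
    labels: np.ndarray  # per-bin mode id, -1 = unassigned background
    peaks: list[tuple[float, float]]
    populations: np.ndarray  # per-mode fraction of bound samples
    unassigned_fraction: float = 0.0
    density_threshold: float = 0.0
    smoothing_sigma: float = 10.0
    edges: np.ndarray = field(default=None)

    @property
    def n_modes(self) -> int:
        return len(self.peaks)

    def bin_of(self, beta: float, chi: float) -> tuple[int, int]:
        n = self.labels.shape[0]
        i = int(wrap_deg(beta) // self.bin_width) % n
        j = int(wrap_deg(chi) // self.bin_width) % n
        return i, j

    def mode_of(self, beta: float, chi: float) -> int:
        i, j = self.bin_of(beta, chi)
        return int(self.labels[i, j])


def _significance_threshold(
    density: np.ndarray, smoothing_sigma_bins: float, peak_significance: float
) -> float:
    """Density level separating modes from the flat background.

    For a Gaussian-smoothed count histogram at background level ``b`` the
    Poisson counting noise is ``sqrt(b / (4 pi sigma_bins^2))``; bins below
    ``median + z * noise`` are treated as background.
    """
    background = float(np.median(density))
    kernel_sq_sum = 1.0 / (4.0 * np.pi * max(smoothing_sigma_bins, 0.5) ** 2)
    noise = np.sqrt(max(background, 0.0) * kernel_sq_sum)
    return background + peak_significance * noise


def _periodic_watershed(
    density: np.ndarray,
    threshold: float,
    peak_prominence: float = 0.02,
) -> np.ndarray:
    """Watershed basins of a periodic 2D density (one label per density peak).

    The density is tiled 3x3 and candidate maxima are found by h-maxima
    reconstruction (``peak_prominence`` as a fraction of the density range);
    candidates below the background significance ``threshold`` are dropped.
    The marker-based non-periodic watershed is applied, the center tile is
    cropped, and labels are canonicalized by their wrapped peak position so
    basins straddling the seam are merged.
    """
    from skimage.morphology import h_maxima

    n = density.shape[0]
    tiled = np.tile(density, (3, 3))
    rng_d = tiled.max() - tiled.min()
    if rng_d <= 0:
        return np.zeros_like(density, dtype=int)
    maxima = h_maxima(tiled, peak_prominence * rng_d)
    markers, n_markers = ndimage.label(maxima)
    if n_markers == 0:
        return np.zeros_like(density, dtype=int)
    kept = [
        lab
        for lab in range(1, n_markers + 1)
        if tiled[markers == lab].max() >= threshold
    ]
    if not kept:  # degenerate: keep the strongest maximum
        peak_vals = ndimage.labeled_comprehension(
            tiled, markers, range(1, n_markers + 1), np.max, float, -np.inf
        )
        kept = [int(np.argmax(peak_vals)) + 1]
    markers = np.where(np.isin(markers, kept), markers, 0)
    seg = watershed(-tiled, markers=markers)
    center = seg[n : 2 * n, n : 2 * n]
    # canonicalize: labels whose density peak wraps to the same bin are one basin
    out = np.zeros_like(center)
    peak_to_id: dict[tuple[int, int], int] = {}
    for lab in np.unique(center):
        mask = center == lab
        # the basin's true peak may sit outside the crop; use tiled argmax
        mask3 = seg == lab
        flat3 = np.where(mask3, tiled, -np.inf)
        i3, j3 = np.unravel_index(np.argmax(flat3), flat3.shape)
        key = (i3 % n, j3 % n)
        if key not in peak_to_id:
            peak_to_id[key] = len(peak_to_id)
        out[mask] = peak_to_id[key]
    return out


def _merge_small_basins(labels, counts, mask, min_fraction):
    """Merge basins below the population floor into their closest neighbor.

    Populations count only significant (non-background) bins.
    """
    total = counts.sum()
    counts = np.where(mask, counts, 0.0)
    while True:
        ids = np.unique(labels)
        if len(ids) <= 1:
            break
        pops = {k: counts[labels == k].sum() / total for k in ids}
        small = [k for k in ids if pops[k] < min_fraction]
        if not small:
            break
        k = min(small, key=lambda x: pops[x])
        # neighbor sharing the longest boundary (periodic)
        mask = labels == k
        best, best_len = None, -1
        for shift_axis in (0, 1):
            for shift in (1, -1):
                rolled = np.roll(labels, shift, axis=shift_axis)
                boundary = mask & (rolled != k)
                if boundary.any():
                    neigh, counts_n = np.unique(rolled[boundary], return_counts=True)
                    for nb, c in zip(neigh, counts_n):
                        if nb != k and c > best_len:
                            best, best_len = nb, c
        if best is None:
            break
        labels[mask] = best
    # compact ids
    remap = {k: i for i, k in enumerate(np.unique(labels))}
    return np.vectorize(remap.get)(labels)


def build_mode_map(
    samples,
    bin_width: float = 5.0,
    smoothing_sigma: float = 10.0,
    min_population: float = 0.05,
    peak_prominence: float = 0.02,
    peak_significance: float = 4.0,
) -> ModeMap:
    """Histogram bound samples on the (beta, chi) torus and segment modes.

    The raw histogram is smoothed with a wrapped Gaussian (sigma in degrees)
    and segmented by the periodic watershed seeded at maxima with relative
    prominence above ``peak_prominence`` that rise ``peak_significance``
    Poisson standard deviations above the median density. Bins below that
    significance level are left unassigned (flat bound-state background);
    basins holding less than ``min_population`` of the bound samples are
    merged into their largest neighbor.
    """
    if 360.0 % bin_width != 0:
        raise ValueError("bin_width must divide 360")
    bound = [s for s in samples if s.bound]
    if not bound:
        raise ValueError("no bound samples: cannot build a mode map")
    n = int(360.0 // bin_width)
    edges = np.linspace(0.0, 360.0, n + 1)
    beta = np.array([s.beta for s in bound])
    chi = np.array([s.chi for s in bound])
    counts, _, _ = np.histogram2d(beta, chi, bins=[edges, edges])
    density = ndimage.gaussian_filter(counts, sigma=smoothing_sigma / bin_width, mode="wrap")
    threshold = _significance_threshold(
        density, smoothing_sigma / bin_width, peak_significance
    )
    basins = _periodic_watershed(density, threshold, peak_prominence)
    significant = density >= threshold
    basins = _merge_small_basins(basins, counts, significant, min_population)
    labels = np.where(significant, basins, -1)

    peaks, pops = [], []
    total = counts.sum()
    centers = edges[:-1] + bin_width / 2.0
    for k in np.unique(basins):
        mask = labels == k
        if not mask.any():  # basin entirely below threshold: keep its peak bin
            mask = basins == k
        flat = np.where(mask, density, -np.inf)
        i, j = np.unravel_index(np.argmax(flat), flat.shape)
        labels[i, j] = k  # a mode always owns its own peak bin
        peaks.append((float(centers[i]), float(centers[j])))
        pops.append(counts[labels == k].sum() / total)
    pops = np.asarray(pops)
    return ModeMap(
        bin_width,
        density,
        counts,
        labels,
        peaks,
        pops,
        float(1.0 - pops.sum()),
        float(threshold),
        smoothing_sigma,
        edges,
    )


def assign_frames(samples, mode_map: ModeMap, window: float | None = None):
    """Mode label per sample (:data:`UNBOUND` for unbound samples,
    :data:`UNASSIGNED` for bound samples in the background region).

    ``window`` restricts assignment to samples within the trailing window
    (ns before the last sample time); earlier samples get ``None``.
    """
    samples = list(samples)
    if window is not None:
        t_end = max(s.time for s in samples)
        cut = t_end - window
    out = []
    for s in samples:
        if window is not None and s.time <= cut:
            out.append(None)
        elif not s.bound:
            out.append(UNBOUND)
        else:
            label = mode_map.mode_of(s.beta, s.chi)
            out.append(UNASSIGNED if label < 0 else label)
    return out


def populations_over_time(samples, mode_map: ModeMap, time_grid=None):
    """Fraction of replicas in each mode (plus unassigned and unbound) over time.

    At each grid time a replica contributes its most recent sample. Returns
    ``(times, fractions)`` where fractions has one column per mode, then an
    unassigned column, then a final unbound column; rows sum to one.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("empty ensemble")
    replicas = sorted({s.replica_id for s in samples})
    if len(replicas) < 2:
        raise ValueError("populations need >= 2 replicas")
    by_replica = {r: sorted((s for s in samples if s.replica_id == r), key=lambda s: s.time) for r in replicas}
    if time_grid is None:
        time_grid = np.unique([s.time for s in samples])
    time_grid = np.asarray(time_grid, dtype=float)
    k = mode_map.n_modes
    frac = np.zeros((len(time_grid), k + 2))  # modes..., unassigned, unbound
    for r in replicas:
        seq = by_replica[r]
        times = np.array([s.time for s in seq])
        for ti, t in enumerate(time_grid):
            idx = np.searchsorted(times, t, side="right") - 1
            if idx < 0:
                idx = 0
            s = seq[idx]
            if not s.bound:
                frac[ti, k + 1] += 1
            else:
                label = mode_map.mode_of(s.beta, s.chi)
                frac[ti, k if label < 0 else label] += 1
    frac /= len(replicas)
    return time_grid, frac


def select_representative(samples, mode_map: ModeMap, mode: int):
    """Bound sample closest (wrapped distance) to a mode's density peak.

    Ties break to the earliest time, then the lowest replica id.
    """
    peak = np.array(mode_map.peaks[mode])
    members = [
        s
        for s in samples
        if s.bound and mode_map.mode_of(s.beta, s.chi) == mode
    ]
    if not members:
        raise ValueError(f"mode {mode} has no bound samples")
    return min(
        members,
        key=lambda s: (torus_dist_deg([s.beta, s.chi], peak), s.time, s.replica_id),
    )
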