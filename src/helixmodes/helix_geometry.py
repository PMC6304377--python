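"""Geometric descriptors of membrane helices and helix pairs.

Helix axes are fitted as the principal component of the backbone bead cloud
and canonically oriented from the N- to the C-terminus. Tilt is measured
against the membrane normal (z by convention), the helix-pair crossing angle
is the signed dihedral about the inter-axis connection, and helical-wheel
positions advance 100 degrees per residue.

Sign convention: a right-handed helix crossing carries a *negative* crossing
angle (the common membrane-protein convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from ._angles import wrap_deg
from .structure_io import ChainTopology, Frame, Trajectory, minimum_image

__all__ = [
    "HelixAxis",
    "WheelPosition",
    "fit_helix_axis",
    "tilt_angle",
    "crossing_angle",
    "wheel_position",
    "classify_face",
    "load_face_definition",
    "superpose",
    "superpose_rmsd",
    "rmsd_trace",
]

_DATA_DIR = Path(__file__).parent / "data"

WHEEL_STEP_DEG = 100.0  # canonical alpha-helix: 3.6 residues/turn


@dataclass
class HelixAxis:
    """Principal axis of a helix, oriented N -> C."""

    direction: np.ndarray  # unit 3-vector
    centroid: np.ndarray  # nm
    residue_projections: np.ndarray  # per-residue axial coordinate, nm

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("axis direction must be a unit vector")


@dataclass(frozen=True)
class WheelPosition:
    residue_number: int
    angle: float  # degrees in [0, 360) relative to the reference residue


def _refine_cylinder_axis(centered: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Gauss-Newton refinement of the axis direction and offset so that the
    bead distances to the axis line have minimal variance (a cylinder fit).

    An ideal helix lies exactly on a cylinder, so this recovers its
    construction axis to machine precision where plain PCA is biased by the
    incomplete final turn.
    """
    d = direction / np.linalg.norm(direction)
    offset = np.zeros(2)
    for _ in range(60):
        # orthonormal basis of the plane normal to the current axis
        e1 = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(e1) < 1e-8:
            e1 = np.cross(d, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)

        def radial_residuals(p):
            dd = d + p[0] * e1 + p[1] * e2
            dd = dd / np.linalg.norm(dd)
            origin = p[2] * e1 + p[3] * e2
            rel = centered - origin
            perp = rel - np.outer(rel @ dd, dd)
            r = np.linalg.norm(perp, axis=1)
            return r - r.mean()

        p0 = np.zeros(4)
        f0 = radial_residuals(p0)
        # numerical Jacobian (4 params, cheap at helix sizes)
        eps = 1e-7
        jac = np.empty((len(f0), 4))
        for j in range(4):
            dp = np.zeros(4)
            dp[j] = eps
            jac[:, j] = (radial_residuals(dp) - f0) / eps
        step, *_ = np.linalg.lstsq(jac, -f0, rcond=None)
        d = d + step[0] * e1 + step[1] * e2
        d /= np.linalg.norm(d)
        offset = offset + step[2:]
        if np.linalg.norm(step[:2]) < 1e-12:
            break
    return d


def fit_helix_axis(frame: Frame, chain: int, refine: bool = True) -> HelixAxis:
    """Fit a chain's axis: principal component of the bead cloud, optionally
    refined by a cylinder fit (exact for ideal helices).

    The direction is canonicalized to point from the N-terminal toward the
    C-terminal half of the chain.
    """
    coords = frame.chain_coordinates(chain)
    if len(coords) < 5:
        raise ValueError(f"chain {chain}: need >= 5 beads to fit an axis")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-12 or s[1] < 1e-12:
        raise ValueError("degenerate bead cloud: no helix axis")
    direction = vt[0]
    if refine:
        direction = _refine_cylinder_axis(centered, direction)
    half = len(coords) // 2
    nc = coords[half:].mean(axis=0) - coords[:half].mean(axis=0)
    if np.dot(direction, nc) < 0:
        direction = -direction
    projections = centered @ direction
    return HelixAxis(direction, centroid, projections)


def tilt_angle(axis: HelixAxis | np.ndarray, membrane_normal=(0.0, 0.0, 1.0)) -> float:
    """Angle in [0, 90] degrees between a helix axis and the membrane normal.

    Antiparallel axes give the same tilt (the membrane has no preferred
    axial sign for this descriptor).
    """
    d = axis.direction if isinstance(axis, HelixAxis) else np.asarray(axis, float)
    n = np.asarray(membrane_normal, dtype=float)
    dn, nn = np.linalg.norm(d), np.linalg.norm(n)
    if dn < 1e-12 or nn < 1e-12:
        raise ValueError("tilt undefined for zero vectors")
    cos = abs(np.dot(d, n) / (dn * nn))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def crossing_angle(
    axis_a: HelixAxis, axis_b: HelixAxis, contact_vector: np.ndarray | None = None
) -> tuple[float, str]:
    """Signed helix-pair crossing angle in (-90, 90] and its handedness.

    The magnitude is the inter-axis angle measured as the dihedral about the
    connection between the two axes; the sign follows the membrane-protein
    convention: negative = right-handed packing. Parallel axes return
    ``(0.0, "none")``.
    """
    a = axis_a.direction
    b = axis_b.direction
    if contact_vector is None:
        contact_vector = axis_b.centroid - axis_a.centroid
    d = np.asarray(contact_vector, dtype=float)
    dn = np.linalg.norm(d)
    if dn < 1e-12:
        raise ValueError("contact vector undefined (coincident centroids)")
    d = d / dn
    cross = np.cross(a, b)
    if np.linalg.norm(cross) < 1e-9:
        return 0.0, "none"
    # dihedral of b relative to a about the connection direction d
    a_perp = a - np.dot(a, d) * d
    b_perp = b - np.dot(b, d) * d
    angle = np.degrees(
        np.arctan2(np.dot(d, np.cross(a_perp, b_perp)), np.dot(a_perp, b_perp))
    )
    # fold into (-90, 90]: helix axes have no preferred N->C sign here
    if angle > 90.0:
        angle -= 180.0
    elif angle <= -90.0:
        angle += 180.0
    if angle == 0.0:
        return 0.0, "none"
    handedness = "right" if angle < 0 else "left"
    return float(angle), handedness


def wheel_position(topology: ChainTopology, residue_number: int) -> WheelPosition:
    """Helical-wheel angle of a residue: 100 deg/residue from the reference."""
    topology.index_of(residue_number)  # raises KeyError if absent
    angle = wrap_deg(WHEEL_STEP_DEG * (residue_number - topology.reference_residue))
    return WheelPosition(residue_number, float(angle))


def load_face_definition(path: str | Path | None = None) -> dict:
    """Load a face definition (wheel sectors for the TM-C/TM-S helix faces).

    The packaged default encodes the conserved (TM-C) and class-specific
    (TM-S) faces of the IgM heavy-chain transmembrane helix.
    """
    path = _DATA_DIR / "mu_faces.yaml" if path is None else Path(path)
    return yaml.safe_load(path.read_text())


def _in_sector(angle: float, start: float, end: float) -> bool:
    angle, start, end = wrap_deg(angle), wrap_deg(start), wrap_deg(end)
    if start <= end:
        return start <= angle < end
    return angle >= start or angle < end


def classify_face(topology: ChainTopology, face_definition: dict) -> dict[int, str]:
    """Label each residue by the wheel sector containing it.

    ``face_definition`` holds half-open angular ``sectors`` (may wrap through
    360) and optionally its own ``reference_residue``; residues outside every
    sector are labeled ``"other"``. Overlapping sectors are a configuration
    error.
    """
    sectors = face_definition.get("sectors", {})
    for label_a, (s1, e1) in sectors.items():
        for label_b, (s2, e2) in sectors.items():
            if label_a >= label_b:
                continue
            for probe in np.arange(0.0, 360.0, 0.5):
                if _in_sector(probe, s1, e1) and _in_sector(probe, s2, e2):
                    raise ValueError(
                        f"face sectors {label_a!r} and {label_b!r} overlap"
                    )
    ref = face_definition.get("reference_residue", topology.reference_residue)
    labels: dict[int, str] = {}
    for res in topology.residues:
        angle = wrap_deg(WHEEL_STEP_DEG * (res.number - ref))
        label = "other"
        for sector_label, (start, end) in sectors.items():
            if _in_sector(angle, start, end):
                label = sector_label
                break
        labels[res.number] = label
    return labels


# ---------------------------------------------------------------------------
# superposition / RMSD


def superpose(
    mobile: np.ndarray, reference: np.ndarray, min_beads: int = 3
) -> tuple[Rotation, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of two matched bead sets (nm).

    Returns ``(rotation, translation, rmsd_angstrom)`` such that
    ``rotation.apply(mobile) + translation`` best fits ``reference``.
    RMSD is reported in angstrom to match the usual stability phrasing.
    ``min_beads`` guards against underdetermined fits; pass 2 explicitly to
    superpose a bare segment.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    if len(mob) < min_beads:
        raise ValueError(f"need >= {min_beads} beads for a rigid superposition")
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    a = mob - mob_c
    b = ref - ref_c
    u, _, vt = np.linalg.svd(a.T @ b)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign])
    rot_mat = (u @ d @ vt).T
    rot = Rotation.from_matrix(rot_mat)
    fitted = a @ rot_mat.T
    rmsd_nm = np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1)))
    translation = ref_c - rot.apply(mob_c)
    return rot, translation, float(rmsd_nm * 10.0)


def superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """RMSD (angstrom) after optimal rigid superposition."""
    return superpose(mobile, reference)[2]


def rmsd_trace(
    trajectory: Trajectory,
    reference: Frame,
    selection: np.ndarray | None = None,
    summary_fraction: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-frame superposed RMSD (angstrom) against a reference frame.

    Returns ``(times, rmsd, summary)`` where the stability summary is the
    mean over the trailing ``summary_fraction`` of frames.
    """
    if selection is None:
        selection = np.arange(reference.n_beads)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    ref = reference.coordinates[selection]
    values = np.array(
        [superpose_rmsd(f.coordinates[selection], ref) for f in trajectory.frames]
    )
    n_tail = max(1, int(round(summary_fraction * len(values))))
    return trajectory.times, values, float(values[-n_tail:].mean())


def pair_com_distance(frame: Frame, chain_a: int, chain_b: int) -> float:
    """Minimum-image center-of-mass distance between two chains (nm)."""
    ca = frame.chain_coordinates(chain_a).mean(axis=0)
    cb = frame.chain_coordinates(chain_b).mean(axis=0)
    return float(np.linalg.norm(minimum_image(cb - ca, frame.box)))
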