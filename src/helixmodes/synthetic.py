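"""Synthetic generators: ideal CG helices, replica association ensembles with
planted binding modes, and a surrogate ternary lipid-mixture simulator.

The association simulator is a membrane-confined overdamped rigid-body model,
not bead-resolved MD: two upright helices translate in the membrane plane and
spin about their own axes under (i) an isotropic attraction with a short-range
contact well, and (ii) an orientation potential with wrapped-Gaussian wells at
*planted* (beta, chi) binding modes. Each coordinate follows overdamped
Langevin dynamics with matching mobility and noise, so the bound-state
(beta, chi) distribution converges to the Boltzmann weight of the planted
potential — which makes mode recovery by the analysis pipeline verifiable
against ground truth.

The lipid surrogate is Metropolis swap dynamics on a periodic lattice of
DPPC/DIPC/CHOL sites (40:30:30 by default, initially randomly mixed) with
species-pair couplings (DPPC-CHOL attractive, DPPC-DIPC repulsive) and
optional fixed protein sites carrying per-species affinities.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._angles import signed_diff_deg, wrap_deg
from .domains import CHOL, DIPC, DPPC, PROTEIN, LatticeSeries, LipidLattice
from .structure_io import ChainTopology, Frame, Residue, Trajectory, minimum_image

__all__ = [
    "MIGM_TMD_SEQUENCE",
    "IGA_TMD_SEQUENCE",
    "IGB_TMD_SEQUENCE",
    "PlantedMode",
    "EnsembleSpec",
    "EnsembleResult",
    "build_ideal_helix",
    "init_replica",
    "simulate_association",
    "planted_potential",
    "boltzmann_mode_populations",
    "simulate_lipid_mixture",
]

# Transmembrane-domain sequences of the IgM B-cell receptor components
# (mu heavy chain residues 442-473; Ig-alpha 135-170; Ig-beta 151-186).
MIGM_TMD_SEQUENCE = "GFENLWATASTFIVLFLLSLFYSTTVTLFKVK"
MIGM_FIRST_RESIDUE = 442
IGA_TMD_SEQUENCE = "DMGEGTKNRIITAEGIILLFCAVVPGTLLLFRKRWQ"
IGA_FIRST_RESIDUE = 135
IGB_TMD_SEQUENCE = "LKQRNTLKDGIIMIQTLLIILFIIVPIFLLLDKDDS"
IGB_FIRST_RESIDUE = 151

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# residue class -> (bead type, charge); one bead per residue
_CLASS = {
    "ALA": "C", "VAL": "C", "LEU": "C", "ILE": "C", "MET": "C", "PRO": "C",
    "CYS": "C", "PHE": "N", "TRP": "N", "TYR": "N", "HIS": "N", "GLY": "P",
    "SER": "P", "THR": "P", "ASN": "P", "GLN": "P",
    "LYS": ("Q", 1.0), "ARG": ("Q", 1.0), "ASP": ("Q", -1.0), "GLU": ("Q", -1.0),
}


def build_ideal_helix(
    sequence: str,
    rise: float = 0.15,
    twist: float = 100.0,
    radius: float = 0.23,
    chain_id: str = "A",
    first_residue: int = 1,
    reference_residue: int | None = None,
    box=(15.0, 15.0, 10.0),
) -> tuple[Frame, ChainTopology]:
    """Ideal alpha-helix along +z, one backbone bead per residue.

    The N-terminus sits at low z; bead i lies at azimuth ``twist * i`` and
    height ``rise * i``, centered in the box.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty sequence")
    residues = []
    for k, aa in enumerate(sequence):
        if aa not in ONE_TO_THREE:
            raise ValueError(f"invalid one-letter residue code {aa!r}")
        name = ONE_TO_THREE[aa]
        cls = _CLASS[name]
        bead, charge = cls if isinstance(cls, tuple) else (cls, 0.0)
        residues.append(Residue(first_residue + k, name, bead, charge))
    n = len(sequence)
    i = np.arange(n)
    ang = np.radians(twist * i)
    coords = np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), rise * i]
    )
    box = np.asarray(box, dtype=float)
    coords = coords - coords.mean(axis=0) + box / 2.0
    topo = ChainTopology(chain_id, residues, reference_residue)
    frame = Frame(coords, box, np.zeros(n, dtype=int))
    return frame, topo


# ---------------------------------------------------------------------------
# association ensembles


@dataclass(frozen=True)
class PlantedMode:
    """A (beta, chi) binding-mode well of the surrogate energy landscape."""

    beta_star: float  # deg
    chi_star: float  # deg
    well_depth: float  # kJ/mol, > 0 (depth below the bound baseline)
    angular_width: float = 15.0  # deg (wrapped-Gaussian sigma)

    def __post_init__(self):
        if self.well_depth <= 0 or self.angular_width <= 0:
            raise ValueError("well depth and width must be positive")


KT_310K = 2.577  # kJ/mol at 310 K

DEFAULT_MODES = (
    PlantedMode(60.0, 120.0, well_depth=6.0 * KT_310K, angular_width=15.0),
    PlantedMode(240.0, 300.0, well_depth=3.0 * KT_310K, angular_width=15.0),
)


@dataclass(frozen=True)
class EnsembleSpec:
    """Conditions of a replica association ensemble.

    Replicas start as two upright helices at ``initial_com_distance`` (5 nm)
    with independent uniform in-plane rotations and a random azimuthal
    placement of the partner, mirroring unbiased self-assembly setups.
    """

    n_replicas: int = 100
    t_total: float = 1000.0  # ns (toy time)
    stride: float = 1.0  # ns between stored frames
    substeps: int = 100  # integrator substeps per stored frame
    initial_com_distance: float = 5.0  # nm
    seed: int = 0
    modes: tuple[PlantedMode, ...] = DEFAULT_MODES
    kT: float = KT_310K  # noise temperature, kJ/mol
    reversible: bool = True
    sequence_a: str = MIGM_TMD_SEQUENCE
    sequence_b: str = MIGM_TMD_SEQUENCE
    first_residue_a: int = MIGM_FIRST_RESIDUE
    first_residue_b: int = MIGM_FIRST_RESIDUE
    box: tuple[float, float, float] = (15.0, 15.0, 10.0)
    # surrogate dynamics parameters
    d_trans: float = 0.03  # nm^2/ns in-plane diffusion per helix
    d_rot: float = 1000.0  # deg^2/ns spin diffusion per helix
    contact_distance: float = 0.95  # nm: radial position of the bound well
    bind_depth_kt: float = 10.0  # radial well depth in units of kT (doubled if irreversible)
    bind_width: float = 0.08  # nm radial well sigma
    k_attract: float = 0.8  # kJ/mol/nm^2 long-range attraction
    core_distance: float = 0.85  # nm hard-core onset
    bound_distance: float = 1.1  # nm truth threshold for "bound"
    noise_scale: float = 1.0  # 0 turns thermal noise off (gradient descent)

    def __post_init__(self):
        if self.n_replicas < 1 or self.t_total <= 0:
            raise ValueError("need n_replicas >= 1 and t_total > 0")
        if self.initial_com_distance < 2.0 * 0.47:
            raise ValueError("initial COM distance smaller than combined helix radii")
        for a in self.modes:
            for b in self.modes:
                if a is b:
                    continue
                sep = math.hypot(
                    float(signed_diff_deg(a.beta_star, b.beta_star)),
                    float(signed_diff_deg(a.chi_star, b.chi_star)),
                )
                if sep < 2.0 * max(a.angular_width, b.angular_width):
                    raise ValueError(
                        "planted modes must be separated by >= 2x their width"
                    )


def _template(spec: EnsembleSpec):
    """Template helices centered at the origin with axis +z, plus the azimuth
    of each reference-residue direction (so spins can be planted exactly)."""
    out = []
    for seq, first, cid in (
        (spec.sequence_a, spec.first_residue_a, "A"),
        (spec.sequence_b, spec.first_residue_b, "B"),
    ):
        frame, topo = build_ideal_helix(seq, chain_id=cid, first_residue=first, box=spec.box)
        coords = frame.coordinates - frame.coordinates.mean(axis=0)
        ref_idx = topo.index_of(topo.reference_residue)
        psi = math.degrees(math.atan2(coords[ref_idx, 1], coords[ref_idx, 0]))
        out.append((coords, topo, psi))
    return out


def _rot_z(angle_deg):
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _assemble_frame(spec, templates, pos_a, pos_b, phi_a, phi_b, time):
    (ca, _, psi_a), (cb, _, psi_b) = templates
    box = np.asarray(spec.box)
    z_mid = box[2] / 2.0
    # wrap chain *centers* into the box but keep each helix whole, so axis
    # and centroid fits never see a chain split across the boundary
    center_a = np.mod(pos_a, box[:2])
    center_b = np.mod(pos_b, box[:2])
    a = ca @ _rot_z(phi_a - psi_a).T + np.array([center_a[0], center_a[1], z_mid])
    b = cb @ _rot_z(phi_b - psi_b).T + np.array([center_b[0], center_b[1], z_mid])
    coords = np.vstack([a, b])
    chain_index = np.concatenate([np.zeros(len(ca), int), np.ones(len(cb), int)])
    return Frame(coords, box, chain_index, time=time)


def init_replica(spec: EnsembleSpec, replica_index: int) -> Frame:
    """Deterministic initial frame: COM separation exactly the spec distance,
    independent uniform spins, random azimuth of the partner placement."""
    rng = np.random.default_rng((spec.seed, int(replica_index)))
    box = np.asarray(spec.box)
    center = box[:2] / 2.0
    azimuth = rng.uniform(0.0, 360.0)
    half = spec.initial_com_distance / 2.0
    u = np.array([math.cos(math.radians(azimuth)), math.sin(math.radians(azimuth))])
    pos_a = center - half * u
    pos_b = center + half * u
    phi_a = rng.uniform(0.0, 360.0)
    phi_b = rng.uniform(0.0, 360.0)
    templates = _template(spec)
    return _assemble_frame(spec, templates, pos_a, pos_b, phi_a, phi_b, 0.0)


def planted_potential(spec: EnsembleSpec, beta, chi):
    """Orientation potential W(beta, chi) in kJ/mol (wells are negative)."""
    beta = np.asarray(beta, dtype=float)
    chi = np.asarray(chi, dtype=float)
    w = np.zeros(np.broadcast(beta, chi).shape)
    for m in spec.modes:
        db = signed_diff_deg(beta, m.beta_star)
        dc = signed_diff_deg(chi, m.chi_star)
        w -= m.well_depth * np.exp(-(db * db + dc * dc) / (2.0 * m.angular_width**2))
    return w


def _planted_gradients(spec, beta, chi):
    """(W, dW/dbeta, dW/dchi) in kJ/mol and kJ/mol/deg."""
    w = np.zeros_like(beta)
    wb = np.zeros_like(beta)
    wc = np.zeros_like(beta)
    for m in spec.modes:
        db = signed_diff_deg(beta, m.beta_star)
        dc = signed_diff_deg(chi, m.chi_star)
        g = np.exp(-(db * db + dc * dc) / (2.0 * m.angular_width**2))
        w -= m.well_depth * g
        wb += m.well_depth * g * db / m.angular_width**2
        wc += m.well_depth * g * dc / m.angular_width**2
    return w, wb, wc


def _radial_force(spec, d):
    """-dU_r/dd (kJ/mol/nm): long-range attraction toward the contact well,
    short-range Gaussian well at contact, hard-core repulsion."""
    e_bind = (spec.bind_depth_kt if spec.reversible else 2 * spec.bind_depth_kt) * spec.kT
    f = -spec.k_attract * (d - spec.contact_distance)  # pulls toward contact
    dd = d - spec.contact_distance
    f += -e_bind * dd / spec.bind_width**2 * np.exp(-dd * dd / (2 * spec.bind_width**2))
    core = d < spec.core_distance
    f = np.where(core, f + 80.0 * spec.kT * (spec.core_distance - d), f)
    return f


def _envelope(spec, d):
    """Smooth on/off of the orientation potential with separation."""
    d_on, d_off = spec.bound_distance, spec.bound_distance + 0.5
    x = np.clip((d - d_on) / (d_off - d_on), 0.0, 1.0)
    s = 1.0 - x * x * x * (x * (6.0 * x - 15.0) + 10.0)
    ds = -30.0 * x * x * (x - 1.0) * (x - 1.0) / (d_off - d_on)
    return s, ds


@dataclass
class EnsembleResult:
    """Replica trajectories of the surrogate simulator plus planted truth."""

    spec: EnsembleSpec
    times: np.ndarray  # (n_frames,) ns
    pos_a: np.ndarray  # (n_replicas, n_frames, 2) nm
    pos_b: np.ndarray
    phi_a: np.ndarray  # (n_replicas, n_frames) deg
    phi_b: np.ndarray
    truth_beta: np.ndarray  # (n_replicas, n_frames) deg
    truth_chi: np.ndarray
    truth_bound: np.ndarray  # bool
    truth_mode: np.ndarray  # nearest planted mode when bound, else -1
    _templates: list = field(default=None, repr=False)

    @property
    def n_replicas(self) -> int:
        return self.pos_a.shape[0]

    @property
    def n_frames(self) -> int:
        return self.pos_a.shape[1]

    @property
    def topologies(self) -> list[ChainTopology]:
        return [t for _, t, _ in self._templates]

    def frame(self, replica: int, frame_index: int) -> Frame:
        return _assemble_frame(
            self.spec,
            self._templates,
            self.pos_a[replica, frame_index],
            self.pos_b[replica, frame_index],
            self.phi_a[replica, frame_index],
            self.phi_b[replica, frame_index],
            float(self.times[frame_index]),
        )

    def trajectory(self, replica: int, frame_indices=None) -> Trajectory:
        idx = range(self.n_frames) if frame_indices is None else frame_indices
        return Trajectory([self.frame(replica, i) for i in idx], self.topologies)


def simulate_association(spec: EnsembleSpec) -> EnsembleResult:
    """Run the replica ensemble (vectorized overdamped Langevin dynamics).

    Ground truth per stored frame: ``bound`` when the axis separation is
    below the spec's bound distance, and the index of the wrapped-nearest
    planted mode (else -1).
    """
    if not spec.modes and spec.k_attract == 0:
        import warnings

        warnings.warn("no planted modes and no attraction: no binding expected")
    rng = np.random.default_rng((spec.seed, 2**20))
    n = spec.n_replicas
    n_frames = int(round(spec.t_total / spec.stride)) + 1
    dt = spec.stride / spec.substeps
    box2 = np.asarray(spec.box[:2])

    pos_a = np.empty((n, 2))
    pos_b = np.empty((n, 2))
    phi_a = np.empty(n)
    phi_b = np.empty(n)
    for r in range(n):
        r_rng = np.random.default_rng((spec.seed, r))
        center = box2 / 2.0
        azimuth = r_rng.uniform(0.0, 360.0)
        half = spec.initial_com_distance / 2.0
        u = np.array([math.cos(math.radians(azimuth)), math.sin(math.radians(azimuth))])
        pos_a[r] = center - half * u
        pos_b[r] = center + half * u
        phi_a[r] = r_rng.uniform(0.0, 360.0)
        phi_b[r] = r_rng.uniform(0.0, 360.0)

    mu_t = spec.d_trans / spec.kT
    mu_r = spec.d_rot / spec.kT
    sig_t = spec.noise_scale * math.sqrt(2.0 * spec.d_trans * dt)
    sig_r = spec.noise_scale * math.sqrt(2.0 * spec.d_rot * dt)

    shape = (n, n_frames)
    out = {
        "pa": np.empty(shape + (2,)),
        "pb": np.empty(shape + (2,)),
        "fa": np.empty(shape),
        "fb": np.empty(shape),
        "beta": np.empty(shape),
        "chi": np.empty(shape),
        "bound": np.empty(shape, dtype=bool),
        "mode": np.empty(shape, dtype=int),
    }
    mode_centers = np.array([[m.beta_star, m.chi_star] for m in spec.modes]).reshape(-1, 2)

    def record(k):
        delta = minimum_image(pos_b - pos_a, box2)
        d = np.linalg.norm(delta, axis=1)
        theta = np.degrees(np.arctan2(delta[:, 1], delta[:, 0]))
        beta = wrap_deg(theta - phi_a)
        chi = wrap_deg(theta + 180.0 - phi_b)
        bound = d < spec.bound_distance
        out["pa"][:, k] = pos_a
        out["pb"][:, k] = pos_b
        out["fa"][:, k] = wrap_deg(phi_a)
        out["fb"][:, k] = wrap_deg(phi_b)
        out["beta"][:, k] = beta
        out["chi"][:, k] = chi
        out["bound"][:, k] = bound
        if len(mode_centers):
            db = signed_diff_deg(beta[:, None], mode_centers[None, :, 0])
            dc = signed_diff_deg(chi[:, None], mode_centers[None, :, 1])
            nearest = np.argmin(db * db + dc * dc, axis=1)
        else:
            nearest = np.full(n, -1)
        out["mode"][:, k] = np.where(bound, nearest, -1)

    record(0)
    for k in range(1, n_frames):
        for _ in range(spec.substeps):
            delta = minimum_image(pos_b - pos_a, box2)
            d = np.maximum(np.linalg.norm(delta, axis=1), 1e-9)
            unit = delta / d[:, None]
            theta = np.degrees(np.arctan2(delta[:, 1], delta[:, 0]))
            beta = wrap_deg(theta - phi_a)
            chi = wrap_deg(theta + 180.0 - phi_b)
            w, wb, wc = _planted_gradients(spec, beta, chi)
            s, ds = _envelope(spec, d)
            f_rad = _radial_force(spec, d) - ds * w  # kJ/mol/nm along +unit on B
            # angular force from theta-dependence (deg -> nm via 180/pi/d)
            tang = np.column_stack([-unit[:, 1], unit[:, 0]])
            f_ang = -s * (wb + wc) * (180.0 / math.pi) / d  # kJ/mol/nm
            force_b = f_rad[:, None] * unit + f_ang[:, None] * tang
            force_a = -force_b
            torque_a = s * wb  # kJ/mol/deg (dU/dphi_a = -s*wb)
            torque_b = s * wc

            pos_a += mu_t * force_a * dt + sig_t * rng.standard_normal((n, 2))
            pos_b += mu_t * force_b * dt + sig_t * rng.standard_normal((n, 2))
            phi_a += mu_r * torque_a * dt + sig_r * rng.standard_normal(n)
            phi_b += mu_r * torque_b * dt + sig_r * rng.standard_normal(n)
            pos_a %= box2
            pos_b %= box2
        record(k)

    times = np.arange(n_frames) * spec.stride
    return EnsembleResult(
        spec,
        times,
        out["pa"],
        out["pb"],
        out["fa"],
        out["fb"],
        out["beta"],
        out["chi"],
        out["bound"],
        out["mode"],
        _template(spec),
    )


def surrogate_potential(spec: EnsembleSpec, d, beta, chi):
    """Total surrogate potential (kJ/mol) at separation d and angles (beta, chi).

    Radial part (attraction + contact well + core repulsion) plus the
    envelope-gated orientation potential; the integrator's forces are exactly
    its negative gradient.
    """
    d = np.asarray(d, dtype=float)
    e_bind = (spec.bind_depth_kt if spec.reversible else 2 * spec.bind_depth_kt) * spec.kT
    dd = d - spec.contact_distance
    u = 0.5 * spec.k_attract * dd * dd
    u -= e_bind * np.exp(-dd * dd / (2.0 * spec.bind_width**2))
    u = u + np.where(
        d < spec.core_distance,
        40.0 * spec.kT * (spec.core_distance - d) ** 2,
        0.0,
    )
    s, _ = _envelope(spec, d)
    return u + s * planted_potential(spec, beta, chi)


def boltzmann_mode_populations(
    spec: EnsembleSpec, grid_step: float = 1.0, basins=None
) -> np.ndarray:
    """Long-run bound-state mode populations by numerical integration.

    Integrates ``exp(-W/kT)`` of the planted orientation potential over the
    torus. By default the torus is partitioned by wrapped-nearest planted
    peak; passing a fitted mode map as ``basins`` integrates over its
    watershed basins instead (the comparison then uses the same partition as
    the measured populations, so an arbitrary basin boundary through the
    flat inter-well background does not bias it). Returns per-partition
    fractions.
    """
    if not spec.modes:
        raise ValueError("no planted modes")
    g = np.arange(0.0, 360.0, grid_step) + grid_step / 2.0
    beta, chi = np.meshgrid(g, g, indexing="ij")
    w = planted_potential(spec, beta, chi)
    weight = np.exp(-w / spec.kT)
    z = weight.sum()
    if basins is not None:
        nbins = basins.labels.shape[0]
        bi = (beta // basins.bin_width).astype(int) % nbins
        bj = (chi // basins.bin_width).astype(int) % nbins
        labels = basins.labels[bi, bj]
        return np.array(
            [weight[labels == k].sum() / z for k in range(basins.n_modes)]
        )
    centers = np.array([[m.beta_star, m.chi_star] for m in spec.modes])
    db = signed_diff_deg(beta[..., None], centers[None, None, :, 0])
    dc = signed_diff_deg(chi[..., None], centers[None, None, :, 1])
    nearest = np.argmin(db * db + dc * dc, axis=-1)
    return np.array([weight[nearest == k].sum() / z for k in range(len(spec.modes))])


# ---------------------------------------------------------------------------
# lipid mixture surrogate


@njit(cache=True)
def _metropolis_kernel(grid, jmat, steps, inv_t, seed, snap_every, snaps):  # pragma: no cover
    np.random.seed(seed)
    h, w = grid.shape
    snap_i = 0
    for step in range(steps):
        i1 = np.random.randint(h)
        j1 = np.random.randint(w)
        i2 = np.random.randint(h)
        j2 = np.random.randint(w)
        s1 = grid[i1, j1]
        s2 = grid[i2, j2]
        if s1 != s2 and s1 != 3 and s2 != 3:
            # skip adjacent pairs (keeps the swap energetics exact)
            di = min((i1 - i2) % h, (i2 - i1) % h)
            dj = min((j1 - j2) % w, (j2 - j1) % w)
            if di + dj > 1:
                e_before = 0.0
                e_after = 0.0
                for di2, dj2 in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    nb1 = grid[(i1 + di2) % h, (j1 + dj2) % w]
                    nb2 = grid[(i2 + di2) % h, (j2 + dj2) % w]
                    e_before += jmat[s1, nb1] + jmat[s2, nb2]
                    e_after += jmat[s2, nb1] + jmat[s1, nb2]
                de = e_after - e_before
                if de <= 0.0 or np.random.random() < math.exp(-de * inv_t):
                    grid[i1, j1] = s2
                    grid[i2, j2] = s1
        if snap_every > 0 and (step + 1) % snap_every == 0 and snap_i < snaps.shape[0]:
            snaps[snap_i] = grid
            snap_i += 1
    return snap_i


def _base_couplings() -> np.ndarray:
    """Species-pair couplings (kJ/mol-like toy units): DPPC-CHOL attract,
    DPPC-DIPC repel, CHOL mildly avoids DIPC."""
    j = np.zeros((4, 4))
    j[DPPC, DIPC] = j[DIPC, DPPC] = 1.0
    j[DPPC, CHOL] = j[CHOL, DPPC] = -0.5
    j[DIPC, CHOL] = j[CHOL, DIPC] = 0.5
    return j


def simulate_lipid_mixture(
    grid_size: int = 64,
    composition: tuple[float, float, float] = (0.4, 0.3, 0.3),
    coupling: float = 1.0,
    steps: int = 2_000_000,
    seed: int = 0,
    protein_affinities: dict | None = None,
    protein_size: int = 3,
    temperature: float = 1.0,
    n_snapshots: int = 40,
    t_total: float = 2000.0,
) -> LatticeSeries:
    """Metropolis swap dynamics of the ternary DPPC/DIPC/CHOL lattice.

    ``composition`` is (DPPC, DIPC, CHOL) and must sum to 1; the initial
    snapshot realizes it exactly (largest-remainder rounding) on a randomly
    shuffled lattice. ``coupling`` scales the base coupling matrix (0 = ideal
    mixing). With ``protein_affinities`` a fixed ``protein_size`` x
    ``protein_size`` block of sites interacts with neighboring lipids via
    per-species couplings. Snapshot times map the step count linearly onto
    ``t_total`` ns of toy time.
    """
    comp = np.asarray(composition, dtype=float)
    if abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("composition must sum to 1")
    rng = np.random.default_rng((seed, 3**10))
    h = w = int(grid_size)
    grid = np.empty(h * w, dtype=np.int64)

    protein_sites = 0
    if protein_affinities is not None:
        protein_sites = protein_size * protein_size
    n_lipid = h * w - protein_sites
    counts = np.floor(comp * n_lipid).astype(int)
    remainder = comp * n_lipid - counts
    for _ in range(n_lipid - counts.sum()):
        k = int(np.argmax(remainder))
        counts[k] += 1
        remainder[k] = -1
    lipids = np.repeat(np.arange(3), counts)
    rng.shuffle(lipids)

    grid2 = np.empty((h, w), dtype=np.int64)
    if protein_sites:
        mask = np.zeros((h, w), dtype=bool)
        c0 = (h - protein_size) // 2
        mask[c0 : c0 + protein_size, c0 : c0 + protein_size] = True
        grid2[mask] = PROTEIN
        grid2[~mask] = lipids
    else:
        grid2[:, :] = lipids.reshape(h, w)

    jmat = coupling * _base_couplings()
    if protein_affinities is not None:
        for name, code in (("DPPC", DPPC), ("DIPC", DIPC), ("CHOL", CHOL)):
            jmat[PROTEIN, code] = jmat[code, PROTEIN] = protein_affinities.get(name, 0.0)

    snap_every = max(1, steps // n_snapshots)
    snaps = np.empty((steps // snap_every, h, w), dtype=np.int64)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    initial = grid2.copy()
    n_written = _metropolis_kernel(
        grid2, jmat, steps, 1.0 / temperature, kernel_seed, snap_every, snaps
    )

    dt = t_total / max(1, n_written)
    lattices = [
        LipidLattice(initial, 0.0, jmat, protein_affinities)
    ] + [
        LipidLattice(snaps[i].copy(), (i + 1) * dt, jmat, protein_affinities)
        for i in range(n_written)
    ]
    from .domains import demixing_order_parameter

    trace = np.array([demixing_order_parameter(s) for s in lattices])
    return LatticeSeries(lattices, trace)
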