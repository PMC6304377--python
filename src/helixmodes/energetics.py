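"""Coarse-grained pair energetics, contact maps, profiles, SASA and BSA.

The interaction energy between two bead groups is the sum of switched
Lennard-Jones and cutoff Coulomb terms over all inter-group pairs under the
minimum-image convention. Lennard-Jones interactions are switched smoothly to
zero between ``r_switch`` (0.9 nm) and ``r_cut`` (1.2 nm); Coulomb
interactions are scaled by a smooth switch from zero separation to the
Coulomb cutoff (1.2 nm) with a uniform relative dielectric (default 15).

Two association criteria are built on these energies:

* **dimer**: inter-monomer energy <= -200 kJ/mol (boundary counts as bound),
* **oligomer**: energy <= -800 kJ/mol *and* buried surface area strictly
  greater than 10% of the complex surface.

Solvent-accessible surface areas use deterministic Shrake-Rupley sphere-point
sampling with a Fibonacci point set (default 2000 points per bead).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .structure_io import ChainTopology, Frame, Trajectory, minimum_image

__all__ = [
    "EnergyModel",
    "ContactMap",
    "EnergyProfile",
    "load_energy_model",
    "pair_energy",
    "is_dimer",
    "is_oligomer",
    "contact_map",
    "residue_energy_profile",
    "detect_salt_bridges",
    "sasa",
    "buried_surface_area",
]

_DATA_DIR = Path(__file__).parent / "data"

COULOMB_CONSTANT = 138.935458  # kJ mol^-1 nm e^-2


@dataclass
class EnergyModel:
    """Per-bead-class LJ parameters plus the association thresholds."""

    beads: dict[str, dict]  # type -> {epsilon kJ/mol, sigma nm, radius nm}
    r_switch: float = 0.9
    r_cut: float = 1.2
    coulomb_cutoff: float = 1.2
    relative_dielectric: float = 15.0
    dimer_cutoff: float = -200.0
    oligomer_cutoff: float = -800.0
    bsa_fraction_cutoff: float = 0.10

    def __post_init__(self):
        for t, p in self.beads.items():
            if p["epsilon"] < 0 or p["sigma"] <= 0:
                raise ValueError(f"bead {t!r}: need epsilon >= 0 and sigma > 0")
        if not self.r_switch < self.r_cut:
            raise ValueError("require r_switch < r_cut")
        if self.dimer_cutoff >= 0 or self.oligomer_cutoff >= 0:
            raise ValueError("association cutoffs must be negative energies")

    def lj_params(self, types_a, types_b):
        """Lorentz-Berthelot epsilon/sigma matrices for two type lists."""
        try:
            eps_a = np.array([self.beads[t]["epsilon"] for t in types_a])
            eps_b = np.array([self.beads[t]["epsilon"] for t in types_b])
            sig_a = np.array([self.beads[t]["sigma"] for t in types_a])
            sig_b = np.array([self.beads[t]["sigma"] for t in types_b])
        except KeyError as exc:
            raise KeyError(f"bead type {exc.args[0]!r} not in energy model") from None
        eps = np.sqrt(np.outer(eps_a, eps_b))
        sig = 0.5 * (sig_a[:, None] + sig_b[None, :])
        return eps, sig

    def radii(self, types):
        try:
            return np.array([self.beads[t]["radius"] for t in types])
        except KeyError as exc:
            raise KeyError(f"bead type {exc.args[0]!r} not in energy model") from None


def load_energy_model(path: str | Path | None = None) -> EnergyModel:
    """Load the packaged default (or a user) bead parameter table."""
    path = _DATA_DIR / "energy_model.yaml" if path is None else Path(path)
    doc = yaml.safe_load(path.read_text())
    return EnergyModel(**doc)


def _smoothstep(r: np.ndarray, r_on: float, r_off: float) -> np.ndarray:
    """Quintic switch: 1 below r_on, 0 above r_off, C2-continuous between."""
    x = np.clip((r - r_on) / (r_off - r_on), 0.0, 1.0)
    return 1.0 - x * x * x * (x * (6.0 * x - 15.0) + 10.0)


def _group_types_charges(topologies, chain_index, group):
    """Bead types and charges for a list of bead indices."""
    types_all, charges_all = [], []
    for c, topo in enumerate(topologies):
        for res in topo.residues:
            types_all.append(res.bead_type)
            charges_all.append(res.charge)
    types_all = np.array(types_all)
    charges_all = np.array(charges_all)
    return types_all[group], charges_all[group]


def _pbc_distances(coords_a, coords_b, box):
    """Minimum-image distance matrix between two coordinate sets."""
    diff = coords_a[:, None, :] - coords_b[None, :, :]
    diff = minimum_image(diff, box)
    return np.sqrt(np.sum(diff * diff, axis=-1))


def pair_energy_matrix(
    frame: Frame,
    group_a: np.ndarray,
    group_b: np.ndarray,
    topologies: list[ChainTopology],
    model: EnergyModel,
) -> np.ndarray:
    """Per-bead-pair interaction energy (kJ/mol) between two disjoint groups."""
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups must be disjoint")
    types_a, q_a = _group_types_charges(topologies, frame.chain_index, group_a)
    types_b, q_b = _group_types_charges(topologies, frame.chain_index, group_b)
    eps, sig = model.lj_params(types_a, types_b)
    r = _pbc_distances(frame.coordinates[group_a], frame.coordinates[group_b], frame.box)
    r = np.maximum(r, 1e-6)

    sr6 = (sig / r) ** 6
    lj = 4.0 * eps * (sr6 * sr6 - sr6) * _smoothstep(r, model.r_switch, model.r_cut)
    lj[r >= model.r_cut] = 0.0

    qq = np.outer(q_a, q_b)
    coul = (
        COULOMB_CONSTANT
        * qq
        / (model.relative_dielectric * r)
        * _smoothstep(r, 0.0, model.coulomb_cutoff)
    )
    coul[r >= model.coulomb_cutoff] = 0.0
    return lj + coul


def pair_energy(
    frame: Frame,
    group_a: np.ndarray,
    group_b: np.ndarray,
    topologies: list[ChainTopology],
    model: EnergyModel,
) -> float:
    """Total switched LJ + Coulomb interaction energy (kJ/mol) between groups."""
    return float(pair_energy_matrix(frame, group_a, group_b, topologies, model).sum())


def chain_group(frame: Frame, chains) -> np.ndarray:
    """Bead indices of one chain or a list of chains."""
    chains = np.atleast_1d(chains)
    return np.flatnonzero(np.isin(frame.chain_index, chains))


def is_dimer(energy: float, model: EnergyModel | None = None) -> bool:
    """Dimer criterion: interaction energy <= -200 kJ/mol (boundary bound)."""
    cutoff = -200.0 if model is None else model.dimer_cutoff
    if not np.isfinite(energy):
        raise ValueError("energy must be finite")
    return bool(energy <= cutoff)


def is_oligomer(
    energy: float, bsa_fraction: float, model: EnergyModel | None = None
) -> bool:
    """Oligomer criterion: energy <= -800 kJ/mol and BSA strictly > 10%."""
    e_cut = -800.0 if model is None else model.oligomer_cutoff
    f_cut = 0.10 if model is None else model.bsa_fraction_cutoff
    if not np.isfinite(energy):
        raise ValueError("energy must be finite")
    if not 0.0 <= bsa_fraction <= 1.0:
        raise ValueError("bsa_fraction must lie in [0, 1]")
    return bool(energy <= e_cut and bsa_fraction > f_cut)


# ---------------------------------------------------------------------------
# contact maps and energy profiles


@dataclass
class ContactMap:
    """Average minimum inter-bead distance (nm) per inter-chain residue pair."""

    values: pd.DataFrame  # rows: group A residues, cols: group B residues

    def to_tsv(self, path):
        self.values.to_csv(path, sep="\t")


@dataclass
class EnergyProfile:
    """Per-residue relative interaction-energy contributions (sum to 1).

    ``raw`` keeps the signed per-residue energies (kJ/mol) before
    normalization; residues with net repulsive (positive) averages are
    clamped to zero contribution and listed in ``clamped``.
    """

    relative: pd.Series
    raw: pd.Series
    clamped: list[str] = field(default_factory=list)


def _residue_bead_slices(topologies, frame, chains):
    """(residue label, bead indices) pairs for the given chains."""
    out = []
    for c in np.atleast_1d(chains):
        topo = topologies[c]
        idx = np.flatnonzero(frame.chain_index == c)
        if len(idx) != len(topo):
            raise ValueError(
                f"chain {c}: {len(idx)} beads vs {len(topo)} residues"
            )
        for k, res in enumerate(topo.residues):
            out.append((f"{topo.chain_id}:{res.name}{res.number}", idx[k : k + 1]))
    return out


def contact_map(window: Trajectory, chains_a, chains_b) -> ContactMap:
    """Average minimum residue-residue distance over an analysis window.

    Used with the trailing 50 ns window to locate binding interfaces.
    """
    if len(window) == 0:
        raise ValueError("empty analysis window")
    topos = window.topologies
    first = window.frames[0]
    res_a = _residue_bead_slices(topos, first, chains_a)
    res_b = _residue_bead_slices(topos, first, chains_b)
    for label, beads in res_a + res_b:
        if beads.size == 0:
            raise ValueError(f"residue {label} has no beads")
    acc = np.zeros((len(res_a), len(res_b)))
    for frame in window.frames:
        ga = np.concatenate([b for _, b in res_a])
        gb = np.concatenate([b for _, b in res_b])
        r = _pbc_distances(frame.coordinates[ga], frame.coordinates[gb], frame.box)
        # one bead per residue in this package, but reduce generally
        pos_a = np.cumsum([0] + [b.size for _, b in res_a])
        pos_b = np.cumsum([0] + [b.size for _, b in res_b])
        for i in range(len(res_a)):
            block = r[pos_a[i] : pos_a[i + 1]]
            for j in range(len(res_b)):
                acc[i, j] += block[:, pos_b[j] : pos_b[j + 1]].min()
    acc /= len(window)
    df = pd.DataFrame(
        acc, index=[lab for lab, _ in res_a], columns=[lab for lab, _ in res_b]
    )
    return ContactMap(df)


def residue_energy_profile(
    window: Trajectory, chains_a, chains_b, model: EnergyModel
) -> EnergyProfile:
    """Average relative interaction-energy contribution per residue.

    Per-residue inter-group energies (sum of LJ and Coulomb) are averaged over
    the window frames; attractive (negative) averages are normalized by the
    total attractive magnitude so contributions sum to one. Net repulsive
    residues are clamped to zero and flagged.
    """
    if len(window) == 0:
        raise ValueError("empty analysis window")
    topos = window.topologies
    first = window.frames[0]
    res_a = _residue_bead_slices(topos, first, chains_a)
    res_b = _residue_bead_slices(topos, first, chains_b)
    labels = [lab for lab, _ in res_a] + [lab for lab, _ in res_b]
    ga = np.concatenate([b for _, b in res_a])
    gb = np.concatenate([b for _, b in res_b])
    pos_a = np.cumsum([0] + [b.size for _, b in res_a])
    pos_b = np.cumsum([0] + [b.size for _, b in res_b])

    acc = np.zeros(len(labels))
    for frame in window.frames:
        em = pair_energy_matrix(frame, ga, gb, topos, model)
        per_a = np.add.reduceat(em.sum(axis=1), pos_a[:-1])
        per_b = np.add.reduceat(em.sum(axis=0), pos_b[:-1])
        acc += np.concatenate([per_a, per_b])
    acc /= len(window)

    raw = pd.Series(acc, index=labels)
    attractive = np.where(acc < 0, -acc, 0.0)
    total = attractive.sum()
    if total <= 0:
        raise ValueError("no attractive interaction energy: profile undefined")
    clamped = [labels[i] for i in np.flatnonzero(acc > 0)]
    return EnergyProfile(pd.Series(attractive / total, index=labels), raw, clamped)


def detect_salt_bridges(
    frame: Frame,
    chains_a,
    chains_b,
    topologies: list[ChainTopology],
    distance_cutoff: float = 0.6,
) -> list[tuple[str, str, float]]:
    """Oppositely charged residue pairs within the charged-bead cutoff (nm)."""
    res_a = _residue_bead_slices(topologies, frame, chains_a)
    res_b = _residue_bead_slices(topologies, frame, chains_b)
    charges = np.concatenate(
        [[r.charge for r in topologies[c].residues] for c in range(len(topologies))]
    )
    bridges = []
    for lab_a, beads_a in res_a:
        qa = charges[beads_a[0]]
        if qa == 0:
            continue
        for lab_b, beads_b in res_b:
            qb = charges[beads_b[0]]
            if qb == 0 or qa * qb > 0:
                continue
            r = _pbc_distances(
                frame.coordinates[beads_a], frame.coordinates[beads_b], frame.box
            ).min()
            if r <= distance_cutoff:
                bridges.append((lab_a, lab_b, float(r)))
    return bridges


# ---------------------------------------------------------------------------
# surface areas


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(
    coordinates: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 0.19,
    sphere_points: int = 2000,
) -> float:
    """Shrake-Rupley solvent-accessible surface area (nm^2).

    Deterministic: test points are a Fibonacci lattice on each bead's
    solvent-extended sphere; a point is accessible when outside every other
    bead's extended sphere.
    """
    coords = np.asarray(coordinates, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0) or probe_radius < 0:
        raise ValueError("radii must be positive and probe nonnegative")
    unit = _fibonacci_sphere(sphere_points)
    extended = radii + probe_radius
    total = 0.0
    for i in range(len(coords)):
        pts = coords[i] + extended[i] * unit
        accessible = np.ones(sphere_points, dtype=bool)
        d_neigh = np.linalg.norm(coords - coords[i], axis=1)
        neigh = np.flatnonzero((d_neigh < extended + extended[i]) & (d_neigh > 0))
        for j in neigh:
            accessible &= (
                np.linalg.norm(pts - coords[j], axis=1) >= extended[j]
            )
            if not accessible.any():
                break
        frac = accessible.mean()
        total += frac * 4.0 * np.pi * extended[i] ** 2
    return float(total)


def buried_surface_area(
    frame: Frame,
    group_a: np.ndarray,
    group_b: np.ndarray,
    topologies: list[ChainTopology],
    model: EnergyModel,
    probe_radius: float = 0.19,
    sphere_points: int = 2000,
) -> tuple[float, float, float]:
    """BSA = SASA(A) + SASA(B) - SASA(A union B), in nm^2.

    Returns ``(bsa, fraction_of_complex, fraction_of_monomers)``: the buried
    area divided by the complex surface (the reported criterion denominator)
    and, for reference, by the summed monomer surfaces.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    types_a, _ = _group_types_charges(topologies, frame.chain_index, group_a)
    types_b, _ = _group_types_charges(topologies, frame.chain_index, group_b)
    ra = model.radii(types_a)
    rb = model.radii(types_b)
    ca = frame.coordinates[group_a]
    cb = frame.coordinates[group_b]
    sasa_a = sasa(ca, ra, probe_radius, sphere_points)
    sasa_b = sasa(cb, rb, probe_radius, sphere_points)
    sasa_ab = sasa(
        np.vstack([ca, cb]), np.concatenate([ra, rb]), probe_radius, sphere_points
    )
    bsa = max(0.0, sasa_a + sasa_b - sasa_ab)
    return bsa, bsa / sasa_ab, bsa / (sasa_a + sasa_b)
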