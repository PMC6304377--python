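"""Lipid phase analysis and protein domain-preference classification.

The membrane surrogate is a 2D periodic lattice of species DPPC, DIPC,
cholesterol (CHOL) and optionally fixed PROTEIN sites. Phases are assigned
compositionally: a lipid site is *ordered* when its local neighborhood is
majority DPPC+CHOL (the raft-like mixture), otherwise *disordered*. Demixing
is quantified by a contact-based segregation index, and a protein's domain
preference is classified from its ordered-contact fraction and its relative
interaction-energy shares with DPPC and DIPC over a trailing analysis window
(500 ns by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SPECIES",
    "LipidLattice",
    "LatticeSeries",
    "DomainPreference",
    "assign_lipid_phase",
    "demixing_order_parameter",
    "protein_domain_preference",
]

SPECIES = {"DPPC": 0, "DIPC": 1, "CHOL": 2, "PROTEIN": 3}
DPPC, DIPC, CHOL, PROTEIN = 0, 1, 2, 3


@dataclass
class LipidLattice:
    """One snapshot of the ternary lipid field (2D periodic grid)."""

    grid: np.ndarray  # (H, W) int species codes
    time: float = 0.0  # ns
    couplings: np.ndarray | None = None
    protein_affinities: dict | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("lattice grid must be 2D")
        if self.grid.size == 0:
            raise ValueError("empty lattice")

    def composition(self) -> dict[str, float]:
        lipid = self.grid[self.grid != PROTEIN]
        n = lipid.size
        return {
            name: float(np.count_nonzero(lipid == code) / n)
            for name, code in SPECIES.items()
            if code != PROTEIN
        }


@dataclass
class LatticeSeries:
    """Time-ordered lattice snapshots from the mixture simulator."""

    snapshots: list[LipidLattice]
    order_parameter_trace: np.ndarray = field(default=None)

    def __post_init__(self):
        if not self.snapshots:
            raise ValueError("empty lattice series")

    @property
    def times(self):
        return np.array([s.time for s in self.snapshots])

    def __len__(self):
        return len(self.snapshots)


@dataclass
class DomainPreference:
    """Protein lipid-domain preference report."""

    dppc_energy_share: float  # in [0,1], shares sum to 1
    dipc_energy_share: float
    ordered_contact_fraction: float
    disordered_contact_fraction: float
    phase_class: str  # ordered | disordered | interface


def _circular_footprint(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    return (x * x + y * y) <= r * r


def assign_lipid_phase(lattice: LipidLattice, radius: int = 2) -> np.ndarray:
    """Per-site phase labels: 1 ordered, 0 disordered, -1 protein.

    A lipid site is ordered when DPPC+CHOL occupy more than half of the lipid
    sites within the (periodic) circular neighborhood of the given radius.
    """
    grid = lattice.grid
    foot = _circular_footprint(radius)
    is_lipid = (grid != PROTEIN).astype(float)
    is_raft = np.isin(grid, (DPPC, CHOL)).astype(float)
    n_lipid = ndimage.convolve(is_lipid, foot.astype(float), mode="wrap")
    n_raft = ndimage.convolve(is_raft, foot.astype(float), mode="wrap")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_lipid > 0, n_raft / n_lipid, 0.0)
    labels = (frac > 0.5).astype(int)
    labels[grid == PROTEIN] = -1
    return labels


def _neighbor_pairs(grid: np.ndarray):
    """Periodic nearest-neighbor pairs as two stacked arrays (site, right/down)."""
    right = np.roll(grid, -1, axis=1)
    down = np.roll(grid, -1, axis=0)
    a = np.concatenate([grid.ravel(), grid.ravel()])
    b = np.concatenate([right.ravel(), down.ravel()])
    return a, b


def demixing_order_parameter(lattice: LipidLattice) -> float:
    """Contact-based segregation index in [0, 1].

    ``1 - f_obs / f_exp`` where ``f_obs`` is the observed DPPC-DIPC fraction
    of lipid-lipid neighbor contacts and ``f_exp`` the expectation under
    random mixing at the current composition; 0 for an ideal mixture, ~1 for
    full phase separation (contacts only along the seam).
    """
    grid = lattice.grid
    present = {int(s) for s in np.unique(grid)} - {PROTEIN}
    if DPPC not in present or DIPC not in present:
        raise ValueError("order parameter needs both DPPC and DIPC present")
    a, b = _neighbor_pairs(grid)
    lipid_pair = (a != PROTEIN) & (b != PROTEIN)
    a, b = a[lipid_pair], b[lipid_pair]
    f_obs = np.mean(((a == DPPC) & (b == DIPC)) | ((a == DIPC) & (b == DPPC)))
    comp = lattice.composition()
    f_exp = 2.0 * comp["DPPC"] * comp["DIPC"]
    if f_exp <= 0:
        raise ValueError("degenerate composition")
    return float(np.clip(1.0 - f_obs / f_exp, 0.0, 1.0))


def _protein_contacts(grid: np.ndarray):
    """Species of lipid sites adjacent (4-neighborhood) to protein sites."""
    prot = grid == PROTEIN
    contact_mask = np.zeros_like(prot)
    for axis in (0, 1):
        for shift in (1, -1):
            contact_mask |= np.roll(prot, shift, axis=axis)
    contact_mask &= ~prot
    return grid[contact_mask], contact_mask


def protein_domain_preference(
    series: LatticeSeries,
    window: float = 500.0,
    ordered_threshold: float = 0.6,
    disordered_threshold: float = 0.4,
    phase_radius: int = 2,
) -> DomainPreference:
    """Classify a protein's lipid-domain preference over a trailing window.

    Relative protein-DPPC and protein-DIPC interaction energies are averaged
    over snapshots with ``time > t_end - window`` and normalized to shares.
    The phase class follows the ordered-contact fraction: ordered above
    ``ordered_threshold``, disordered below ``disordered_threshold``,
    interface between.
    """
    t_end = series.times[-1]
    snaps = [s for s in series.snapshots if s.time > t_end - window]
    if not snaps:
        snaps = [series.snapshots[-1]]
    if not np.any(snaps[0].grid == PROTEIN):
        raise ValueError("no protein sites in lattice")

    aff = snaps[0].protein_affinities or {"DPPC": -1.0, "DIPC": -1.0, "CHOL": 0.0}
    e_dppc = e_dipc = 0.0
    ordered = disordered = 0.0
    for snap in snaps:
        contacts, mask = _protein_contacts(snap.grid)
        phases = assign_lipid_phase(snap, radius=phase_radius)[mask]
        n_dppc = np.count_nonzero(contacts == DPPC)
        n_dipc = np.count_nonzero(contacts == DIPC)
        e_dppc += aff.get("DPPC", 0.0) * n_dppc
        e_dipc += aff.get("DIPC", 0.0) * n_dipc
        ordered += np.count_nonzero(phases == 1)
        disordered += np.count_nonzero(phases == 0)

    mag = abs(e_dppc) + abs(e_dipc)
    if mag == 0:
        share_dppc = share_dipc = 0.5
    else:
        share_dppc = abs(e_dppc) / mag
        share_dipc = abs(e_dipc) / mag
    n_contacts = ordered + disordered
    f_ordered = ordered / n_contacts if n_contacts else 0.0
    f_disordered = disordered / n_contacts if n_contacts else 0.0
    if f_ordered > ordered_threshold:
        cls = "ordered"
    elif f_ordered < disordered_threshold:
        cls = "disordered"
    else:
        cls = "interface"
    return DomainPreference(share_dppc, share_dipc, f_ordered, f_disordered, cls)
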