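"""Structures, trajectories and chain topologies for coarse-grained helix systems.

Unit conventions enforced at every boundary of the package:

* coordinates and box lengths in **nm** (GRO native; PDB is converted
  from/to angstrom with an exact factor of 10),
* times in **ns**,
* energies in **kJ/mol**,
* angles in **degrees**.

Boxes are orthorhombic and all distances use the minimum-image convention.

File parsing and writing is delegated to MDAnalysis; this module wraps it in
lightweight containers (:class:`Frame`, :class:`Trajectory`,
:class:`ChainTopology`) that carry the unit conventions above.

Dialect decisions (GRO has no chain field, and no mandatory time):

* chains are split on a *decrease* of the residue number between consecutive
  residues (each helix in our files is numbered monotonically),
* a frame time is taken from a ``t= <value>`` token in the GRO title line and
  interpreted as **ns**; when absent, times default to frame index times a
  configurable stride.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Residue",
    "ChainTopology",
    "Frame",
    "Trajectory",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "trailing_window",
    "read_topology",
    "write_topology",
    "minimum_image",
    "default_residue_beads",
]

_DATA_DIR = Path(__file__).parent / "data"


class StructureParseError(ValueError):
    """A structure or trajectory file could not be parsed."""


@dataclass(frozen=True)
class Residue:
    number: int
    name: str  # 3-letter residue code
    bead_type: str
    charge: float = 0.0


@dataclass
class ChainTopology:
    """One helical chain: identity, residues (one bead each) and wheel anchor.

    ``reference_residue`` is the residue number used as the 0-degree anchor of
    the helical wheel; it defaults to the first residue.
    """

    chain_id: str
    residues: list[Residue]
    reference_residue: int | None = None

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"chain {self.chain_id!r} has no residues")
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError(
                f"chain {self.chain_id!r}: residue numbers must be strictly increasing"
            )
        if self.reference_residue is None:
            self.reference_residue = numbers[0]
        elif self.reference_residue not in numbers:
            raise ValueError(
                f"chain {self.chain_id!r}: reference residue "
                f"{self.reference_residue} not in chain"
            )

    def __len__(self):
        return len(self.residues)

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.array([r.number for r in self.residues])

    def sequence3(self) -> list[str]:
        return [r.name for r in self.residues]

    def index_of(self, residue_number: int) -> int:
        numbers = [r.number for r in self.residues]
        try:
            return numbers.index(residue_number)
        except ValueError:
            raise KeyError(
                f"residue {residue_number} not in chain {self.chain_id!r}"
            ) from None


@dataclass
class Frame:
    """Bead coordinates (nm) in an orthorhombic periodic box.

    ``chain_index[i]`` maps bead ``i`` to its chain; one bead per residue, in
    topology order within each chain.
    """

    coordinates: np.ndarray  # (n_beads, 3) nm
    box: np.ndarray  # (3,) nm
    chain_index: np.ndarray  # (n_beads,) int
    time: float = 0.0  # ns

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.chain_index = np.asarray(self.chain_index, dtype=int)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_beads, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths (nm)")
        if self.chain_index.shape != (self.coordinates.shape[0],):
            raise ValueError("chain_index must map every bead to a chain")

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[0]

    def chain_coordinates(self, chain: int) -> np.ndarray:
        return self.coordinates[self.chain_index == chain]


@dataclass
class Trajectory:
    """Time-ordered frames over a constant topology."""

    frames: list[Frame]
    topologies: list[ChainTopology] = field(default_factory=list)

    def __post_init__(self):
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        n = self.frames[0].n_beads
        for i, f in enumerate(self.frames):
            if f.n_beads != n:
                raise ValueError(
                    f"inconsistent bead count at frame {i}: {f.n_beads} != {n}"
                )
        times = self.times
        if np.any(np.diff(times) <= 0) and len(times) > 1:
            raise ValueError("frame times must be strictly increasing")

    def __len__(self):
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


def minimum_image(displacement: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vector(s) (..., 3) or (..., 2) into the central image."""
    d = np.asarray(displacement, dtype=float)
    b = np.asarray(box, dtype=float)[: d.shape[-1]]
    return d - b * np.round(d / b)


# ---------------------------------------------------------------------------
# residue -> bead class assignment


def default_residue_beads() -> dict[str, tuple[str, float]]:
    """Map 3-letter residue code -> (bead_type, charge in e).

    Four bead classes: C apolar, N aromatic, P polar, Q charged.
    """
    with open(_DATA_DIR / "residue_beads.yaml") as fh:
        raw = yaml.safe_load(fh)
    return {k: (v["bead_type"], float(v["charge"])) for k, v in raw.items()}


def _assign_beads(resnames: Sequence[str], bead_map=None):
    bead_map = bead_map if bead_map is not None else default_residue_beads()
    types, charges = [], []
    for name in resnames:
        bead, q = bead_map.get(name.upper(), ("C", 0.0))
        types.append(bead)
        charges.append(q)
    return types, charges


# ---------------------------------------------------------------------------
# reading


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in {"gro", "pdb", "xtc"}:
        return suffix
    raise ValueError(f"cannot infer format of {path}; pass format= explicitly")


def _validate_gro_text(lines: list[str], offset: int = 0):
    """Cheap structural validation so errors carry a line number."""
    if len(lines) < 3:
        raise StructureParseError("GRO file too short (need title, count, box)")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError:
        raise StructureParseError(
            f"line {offset + 2}: expected atom count, got {lines[1]!r}"
        ) from None
    if len(lines) < n_atoms + 3:
        raise StructureParseError(
            f"GRO frame at line {offset + 1} declares {n_atoms} atoms but the "
            f"file ends early (missing box line?)"
        )
    for i in range(2, 2 + n_atoms):
        line = lines[i].rstrip("\n")
        if len(line) < 44:
            raise StructureParseError(
                f"line {offset + i + 1}: truncated coordinate record"
            )
        for lo, hi in ((20, 28), (28, 36), (36, 44)):
            try:
                float(line[lo:hi])
            except ValueError:
                raise StructureParseError(
                    f"line {offset + i + 1}: malformed coordinate field "
                    f"{line[lo:hi]!r}"
                ) from None
    box_line = lines[2 + n_atoms].split()
    if len(box_line) < 3:
        raise StructureParseError(
            f"line {offset + n_atoms + 3}: missing or incomplete box record"
        )
    return n_atoms


def _gro_title_time(title: str) -> float | None:
    """Extract ``t= <value>`` (ns by package convention) from a GRO title."""
    if "t=" not in title:
        return None
    try:
        return float(title.split("t=")[-1].split()[0])
    except (ValueError, IndexError):
        return None


def _universe_from_text(text: str, fmt: str):
    import MDAnalysis as mda
    from MDAnalysis.lib.util import NamedStream

    stream = NamedStream(io.StringIO(text), f"stream.{fmt}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(stream)


def _split_chains(resids: np.ndarray, chain_ids: np.ndarray | None) -> np.ndarray:
    """Per-residue chain index from PDB chain ids or resid discontinuity."""
    n = len(resids)
    out = np.zeros(n, dtype=int)
    if chain_ids is not None and len(set(chain_ids)) > 1:
        seen: dict[str, int] = {}
        for i, c in enumerate(chain_ids):
            out[i] = seen.setdefault(c, len(seen))
        return out
    chain = 0
    for i in range(1, n):
        if resids[i] <= resids[i - 1]:
            chain += 1
        out[i] = chain
    return out


def _structure_from_universe(u, fmt: str, bead_map=None, time: float | None = None):
    ag = u.atoms
    if u.dimensions is None or np.any(np.asarray(u.dimensions[:3]) <= 0):
        raise StructureParseError("structure has no valid periodic box")
    coords = ag.positions * 0.1  # A -> nm (MDAnalysis is angstrom internally)
    box = np.asarray(u.dimensions[:3], dtype=float) * 0.1
    resids = ag.resids
    try:
        chain_labels = ag.chainIDs if fmt == "pdb" else None
    except AttributeError:
        chain_labels = None
    per_bead_chain = _split_chains(resids, chain_labels)
    resnames = ag.resnames

    topologies = []
    for c in range(per_bead_chain.max() + 1):
        mask = per_bead_chain == c
        bead_types, charges = _assign_beads(resnames[mask], bead_map)
        if chain_labels is not None:
            cid = str(chain_labels[mask][0])
        else:
            cid = chr(ord("A") + c) if c < 26 else f"chain{c}"
        residues = [
            Residue(int(num), str(name).upper(), bt, q)
            for num, name, bt, q in zip(
                resids[mask], resnames[mask], bead_types, charges
            )
        ]
        topologies.append(ChainTopology(cid, residues))

    frame = Frame(coords, box, per_bead_chain, time=0.0 if time is None else time)
    return frame, topologies


def read_structure(path: str | Path, format: str | None = None, bead_map=None):
    """Read a single structure file into a (:class:`Frame`, topologies) pair.

    PDB coordinates (angstrom) are converted to nm on read. GRO chains are
    split on residue-number decrease (GRO has no chain field).
    """
    import MDAnalysis as mda

    fmt = _infer_format(path, format)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "gro":
        lines = path.read_text().splitlines()
        _validate_gro_text(lines)
        time = _gro_title_time(lines[0])
    elif fmt == "pdb":
        time = None
    else:
        raise ValueError(f"read_structure supports gro/pdb, not {fmt!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001 - surface parser failures uniformly
        raise StructureParseError(f"{path}: {exc}") from exc
    return _structure_from_universe(u, fmt, bead_map, time)


# ---------------------------------------------------------------------------
# writing


def _gro_text(frame: Frame, topologies: Sequence[ChainTopology], title: str) -> str:
    if not topologies:
        raise ValueError("cannot write a structure without chain topologies")
    lines = [title, f"{frame.n_beads:5d}"]
    atom_serial = 0
    for c, topo in enumerate(topologies):
        coords = frame.chain_coordinates(c)
        if len(coords) != len(topo):
            raise ValueError(
                f"chain {topo.chain_id!r}: {len(coords)} beads but "
                f"{len(topo)} residues in topology"
            )
        for res, xyz in zip(topo.residues, coords):
            atom_serial += 1
            lines.append(
                f"{res.number % 100000:5d}{res.name:<5s}{'BB':>5s}"
                f"{atom_serial % 100000:5d}"
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            )
    lines.append(
        f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}"
    )
    return "\n".join(lines) + "\n"


def _pdb_text(frame: Frame, topologies: Sequence[ChainTopology]) -> str:
    if not topologies:
        raise ValueError("cannot write a structure without chain topologies")
    bx = frame.box * 10.0
    lines = [
        f"CRYST1{bx[0]:9.3f}{bx[1]:9.3f}{bx[2]:9.3f}"
        f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
    ]
    serial = 0
    for c, topo in enumerate(topologies):
        coords = frame.chain_coordinates(c) * 10.0  # nm -> angstrom
        if len(coords) != len(topo):
            raise ValueError(
                f"chain {topo.chain_id!r}: bead/residue count mismatch"
            )
        chain_char = (topo.chain_id or "A")[0]
        for res, xyz in zip(topo.residues, coords):
            serial += 1
            # strict PDB columns: name 13-16, resName 18-20, chainID 22,
            # resSeq 23-26, x/y/z 31-54
            lines.append(
                f"ATOM  {serial % 100000:5d}  BB  {res.name[:3]:>3s} "
                f"{chain_char}{res.number % 10000:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            )
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_structure(
    frame: Frame,
    topologies: Sequence[ChainTopology],
    path: str | Path,
    format: str | None = None,
) -> None:
    """Write a frame as GRO (nm) or PDB (angstrom). Output is bit-stable:
    identical input produces identical bytes (no timestamps)."""
    fmt = _infer_format(path, format)
    if fmt == "gro":
        text = _gro_text(frame, topologies, f"helixmodes t= {frame.time:.6f}")
    elif fmt == "pdb":
        text = _pdb_text(frame, topologies)
    else:
        raise ValueError(f"write_structure supports gro/pdb, not {fmt!r}")
    Path(path).write_text(text)


def write_trajectory(
    trajectory: Trajectory, path: str | Path, format: str | None = None
) -> None:
    """Write a trajectory as a multi-frame GRO file (frame times in titles)."""
    fmt = _infer_format(path, format)
    if fmt != "gro":
        raise ValueError("trajectory writing supports multi-frame GRO only")
    chunks = [
        _gro_text(f, trajectory.topologies, f"helixmodes t= {f.time:.6f}")
        for f in trajectory.frames
    ]
    Path(path).write_text("".join(chunks))


# ---------------------------------------------------------------------------
# trajectories


def read_trajectory(
    path: str | Path,
    format: str | None = None,
    structure: str | Path | None = None,
    default_stride: float = 1.0,
    bead_map=None,
) -> Trajectory:
    """Read a multi-frame GRO or XTC trajectory.

    XTC carries no topology, so ``structure`` (a GRO/PDB path) is required
    for that format. Frames without times get ``index * default_stride`` ns.
    """
    import MDAnalysis as mda

    fmt = _infer_format(path, format)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    frames: list[Frame] = []
    topologies: list[ChainTopology] = []

    if fmt == "gro":
        lines = path.read_text().splitlines()
        pos = 0
        idx = 0
        n_expected = None
        while pos < len(lines):
            if not lines[pos].strip() and pos == len(lines) - 1:
                break
            n_atoms = _validate_gro_text(lines[pos:], offset=pos)
            if n_expected is None:
                n_expected = n_atoms
            elif n_atoms != n_expected:
                raise StructureParseError(
                    f"line {pos + 1}: frame has {n_atoms} beads, expected "
                    f"{n_expected}"
                )
            chunk = "\n".join(lines[pos : pos + n_atoms + 3]) + "\n"
            u = _universe_from_text(chunk, "gro")
            t = _gro_title_time(lines[pos])
            frame, topos = _structure_from_universe(
                u, "gro", bead_map, idx * default_stride if t is None else t
            )
            frames.append(frame)
            if not topologies:
                topologies = topos
            pos += n_atoms + 3
            idx += 1
    elif fmt == "xtc":
        if structure is None:
            raise ValueError("XTC trajectories need a structure= topology file")
        ref_frame, topologies = read_structure(structure)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(structure), str(path))
        for idx, ts in enumerate(u.trajectory):
            t = float(ts.time) if ts.time is not None else idx * default_stride
            frames.append(
                Frame(
                    u.atoms.positions * 0.1,
                    np.asarray(ts.dimensions[:3], dtype=float) * 0.1,
                    ref_frame.chain_index,
                    time=t,
                )
            )
    else:
        raise ValueError(f"read_trajectory supports gro/xtc, not {fmt!r}")

    return Trajectory(frames, topologies)


def trailing_window(trajectory: Trajectory, duration: float) -> Trajectory:
    """Frames with ``time > t_end - duration`` (the trailing analysis window).

    Contact maps and interaction-energy profiles use a 50 ns window; lipid
    interaction energies use 500 ns.
    """
    if duration <= 0:
        raise ValueError("window duration must be positive")
    times = trajectory.times
    span = times[-1] - times[0]
    # a window covering the whole span returns the trajectory unchanged,
    # which also makes the operation idempotent
    if duration >= span:
        return Trajectory(trajectory.frames, trajectory.topologies)
    cut = times[-1] - duration
    kept = [f for f in trajectory.frames if f.time > cut]
    if not kept:  # single-frame trajectory: keep the frame
        kept = [trajectory.frames[-1]]
    return Trajectory(kept, trajectory.topologies)


# ---------------------------------------------------------------------------
# topology sidecar (structured text)


def write_topology(topologies: Sequence[ChainTopology], path: str | Path) -> None:
    doc = [
        {
            "chain_id": t.chain_id,
            "reference_residue": int(t.reference_residue),
            "residues": [
                {
                    "number": int(r.number),
                    "name": r.name,
                    "bead_type": r.bead_type,
                    "charge": float(r.charge),
                }
                for r in t.residues
            ],
        }
        for t in topologies
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_topology(path: str | Path) -> list[ChainTopology]:
    doc = yaml.safe_load(Path(path).read_text())
    return [
        ChainTopology(
            d["chain_id"],
            [
                Residue(r["number"], r["name"], r["bead_type"], r.get("charge", 0.0))
                for r in d["residues"]
            ],
            d.get("reference_residue"),
        )
        for d in doc
    ]
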