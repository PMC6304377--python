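"""Workflow orchestration: ensemble generation, binding-mode discovery,
energetics, stability, lipid-domain preference, and a machine-readable report.

A run is driven by a :class:`RunConfig` (plain YAML on disk). Every threshold
of the analysis (dimer/oligomer energies, BSA fraction, analysis windows) is
a named, defaulted option. Runs are deterministic given the global seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .domains import protein_domain_preference
from .energetics import (
    EnergyModel,
    buried_surface_area,
    chain_group,
    contact_map,
    is_dimer,
    is_oligomer,
    load_energy_model,
    pair_energy,
    residue_energy_profile,
)
from .helix_geometry import rmsd_trace
from .modes import (
    ModeMap,
    OrientationSample,
    build_mode_map,
    compute_beta_chi,
    populations_over_time,
    select_representative,
)
from .structure_io import Trajectory, read_trajectory, trailing_window
from .synthetic import (
    EnsembleResult,
    EnsembleSpec,
    PlantedMode,
    simulate_association,
    simulate_lipid_mixture,
)

logger = logging.getLogger("helixmodes")

STEPS = ("assembly", "modes", "energetics", "stability", "domains", "oligomers", "report")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Configuration of a pipeline run (YAML-serializable)."""

    steps: list[str] = field(default_factory=lambda: list(STEPS))
    outdir: str = "helixmodes_out"
    seed: int = 0
    # synthetic ensemble spec overrides (None -> package defaults)
    ensemble: dict = field(default_factory=dict)
    trajectory_path: str | None = None  # analyse an external trajectory instead
    # analysis options, defaults mirror the published thresholds
    contact_window: float = 50.0  # ns
    lipid_window: float = 500.0  # ns
    dimer_cutoff: float = -200.0  # kJ/mol
    oligomer_cutoff: float = -800.0  # kJ/mol
    bsa_fraction_cutoff: float = 0.10
    bin_width: float = 5.0  # deg
    smoothing_sigma: float = 10.0  # deg
    min_mode_population: float = 0.05
    orientation_stride: int = 10  # analyse every n-th frame for populations
    lattice: dict = field(default_factory=dict)
    figures: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate(self):
        for s in self.steps:
            if s not in STEPS:
                raise ConfigError(f"unknown step {s!r}")
        needs_ensemble = {"modes", "energetics", "stability", "oligomers"}
        if needs_ensemble & set(self.steps) and "assembly" not in self.steps and self.trajectory_path is None:
            raise ConfigError(
                "mode/energetics/stability steps need the assembly step or a trajectory_path"
            )
        if self.trajectory_path is not None and not Path(self.trajectory_path).exists():
            raise ConfigError(f"trajectory not found: {self.trajectory_path}")


def build_energy_model(config: RunConfig) -> EnergyModel:
    model = load_energy_model()
    model.dimer_cutoff = config.dimer_cutoff
    model.oligomer_cutoff = config.oligomer_cutoff
    model.bsa_fraction_cutoff = config.bsa_fraction_cutoff
    return model


def ensemble_spec_from_config(config: RunConfig) -> EnsembleSpec:
    opts = dict(config.ensemble)
    if "modes" in opts:
        opts["modes"] = tuple(PlantedMode(**m) for m in opts["modes"])
    opts.setdefault("seed", config.seed)
    return EnsembleSpec(**opts)


def ensemble_orientation_samples(
    result: EnsembleResult,
    model: EnergyModel,
    window: float | None = None,
    stride: int = 1,
    bound_criterion: str = "energy",
) -> list[OrientationSample]:
    """Orientation samples of every replica over (a window of) the ensemble.

    ``bound`` is decided per frame by the energetic dimer criterion
    (``bound_criterion="energy"``) or by the center-of-mass surface-gap
    fallback (``"distance"``) for inputs without an energy model.
    """
    t_end = result.times[-1]
    keep = np.arange(0, result.n_frames, stride)
    if window is not None:
        keep = keep[result.times[keep] > t_end - window]
    topos = result.topologies
    samples = []
    for r in range(result.n_replicas):
        for i in keep:
            frame = result.frame(r, int(i))
            bound = None
            if bound_criterion == "energy":
                e = pair_energy(
                    frame, chain_group(frame, 0), chain_group(frame, 1), topos, model
                )
                bound = is_dimer(e, model)
            samples.append(
                compute_beta_chi(frame, 0, 1, topos, bound=bound, replica_id=r)
            )
    return samples


def trajectory_orientation_samples(
    trajectory: Trajectory,
    model: EnergyModel | None = None,
    chain_a: int = 0,
    chain_b: int = 1,
    replica_id: int = 0,
) -> list[OrientationSample]:
    """Orientation samples of one helix pair along an external trajectory."""
    samples = []
    for frame in trajectory.frames:
        bound = None
        if model is not None:
            e = pair_energy(
                frame,
                chain_group(frame, chain_a),
                chain_group(frame, chain_b),
                trajectory.topologies,
                model,
            )
            bound = is_dimer(e, model)
        samples.append(
            compute_beta_chi(
                frame, chain_a, chain_b, trajectory.topologies, bound=bound,
                replica_id=replica_id,
            )
        )
    return samples


def _save_mode_map(mode_map: ModeMap, outdir: Path):
    np.savetxt(outdir / "mode_density.tsv", mode_map.density, delimiter="\t")
    np.savetxt(outdir / "mode_labels.tsv", mode_map.labels, fmt="%d", delimiter="\t")
    peaks = [
        {"mode": k, "beta": b, "chi": c, "population": float(p)}
        for k, ((b, c), p) in enumerate(zip(mode_map.peaks, mode_map.populations))
    ]
    (outdir / "mode_peaks.json").write_text(json.dumps(peaks, indent=2))


def _plot_mode_map(mode_map: ModeMap, outdir: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.5))
    extent = (0, 360, 0, 360)
    ax.imshow(
        mode_map.density.T, origin="lower", extent=extent, cmap="viridis", aspect="auto"
    )
    ax.contour(
        mode_map.labels.T, levels=np.arange(mode_map.n_modes) + 0.5,
        extent=extent, colors="w", linewidths=0.7,
    )
    for b, c in mode_map.peaks:
        ax.plot(b, c, "o", color="lime", ms=6)
    ax.set_xlabel("beta (deg)")
    ax.set_ylabel("chi (deg)")
    fig.tight_layout()
    fig.savefig(outdir / "mode_map.png", dpi=150)
    plt.close(fig)


def run(config: RunConfig) -> dict:
    """Execute the configured steps; returns the JSON-ready summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    model = build_energy_model(config)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "dimer_cutoff_kJ_mol": config.dimer_cutoff,
            "oligomer_cutoff_kJ_mol": config.oligomer_cutoff,
            "bsa_fraction_cutoff": config.bsa_fraction_cutoff,
        },
        "steps": {},
    }

    result: EnsembleResult | None = None
    mode_map: ModeMap | None = None
    window_samples: list[OrientationSample] | None = None

    if "assembly" in config.steps:
        spec = ensemble_spec_from_config(config)
        logger.info("assembly: %d replicas x %.0f ns", spec.n_replicas, spec.t_total)
        result = simulate_association(spec)
        bound_frac = float(result.truth_bound[:, -1].mean())
        summary["steps"]["assembly"] = {
            "n_replicas": spec.n_replicas,
            "t_total_ns": spec.t_total,
            "bound_fraction_final": bound_frac,
        }
    elif config.trajectory_path is not None:
        traj = read_trajectory(config.trajectory_path)
        summary["steps"]["input"] = {"trajectory": config.trajectory_path, "n_frames": len(traj)}

    if "modes" in config.steps:
        if result is None:
            raise ConfigError("modes step needs the assembly step")
        window_samples = ensemble_orientation_samples(
            result, model, window=config.contact_window
        )
        mode_map = build_mode_map(
            window_samples,
            bin_width=config.bin_width,
            smoothing_sigma=config.smoothing_sigma,
            min_population=config.min_mode_population,
        )
        _save_mode_map(mode_map, outdir)
        if config.figures:
            _plot_mode_map(mode_map, outdir)
        coarse = ensemble_orientation_samples(
            result, model, stride=config.orientation_stride
        )
        tgrid, frac = populations_over_time(coarse, mode_map)
        header = [f"mode_{k}" for k in range(mode_map.n_modes)] + ["unassigned", "unbound"]
        np.savetxt(
            outdir / "populations_over_time.tsv",
            np.column_stack([tgrid, frac]),
            delimiter="\t",
            header="time_ns\t" + "\t".join(header),
            comments="",
        )
        reps = {}
        for k in range(mode_map.n_modes):
            s = select_representative(window_samples, mode_map, k)
            reps[k] = {"replica": s.replica_id, "time_ns": s.time,
                       "beta": s.beta, "chi": s.chi}
        (outdir / "representatives.json").write_text(json.dumps(reps, indent=2))
        summary["steps"]["modes"] = {
            "n_modes": mode_map.n_modes,
            "peaks": mode_map.peaks,
            "populations": mode_map.populations.tolist(),
            "final_unbound_fraction": float(frac[-1, -1]),
            "representatives": reps,
        }

    if "energetics" in config.steps:
        if result is None or mode_map is None or window_samples is None:
            raise ConfigError("energetics step needs assembly and modes steps")
        s = select_representative(window_samples, mode_map, int(np.argmax(mode_map.populations)))
        n_tail = min(
            result.n_frames,
            1 + int(round(config.contact_window / result.spec.stride)),
        )
        traj = result.trajectory(s.replica_id, range(result.n_frames - n_tail, result.n_frames))
        win = trailing_window(traj, min(config.contact_window, traj.times[-1] - traj.times[0]))
        cmap = contact_map(win, 0, 1)
        cmap.to_tsv(outdir / "contact_map.tsv")
        profile = residue_energy_profile(win, 0, 1, model)
        profile.relative.to_csv(outdir / "energy_profile.tsv", sep="\t", header=["relative"])
        summary["steps"]["energetics"] = {
            "representative_replica": s.replica_id,
            "min_contact_distance_nm": float(cmap.values.values.min()),
            "top_residues": profile.relative.nlargest(5).index.tolist(),
        }

    if "stability" in config.steps:
        if result is None:
            raise ConfigError("stability step needs the assembly step")
        replica = 0 if window_samples is None else max(
            (s.replica_id for s in window_samples if s.bound), default=0
        )
        n_tail = max(2, int(round(config.contact_window / result.spec.stride)))
        traj = result.trajectory(replica, range(result.n_frames - n_tail, result.n_frames))
        times, values, summ = rmsd_trace(traj, traj.frames[0])
        np.savetxt(
            outdir / "rmsd_trace.tsv",
            np.column_stack([times, values]),
            delimiter="\t",
            header="time_ns\trmsd_A",
            comments="",
        )
        summary["steps"]["stability"] = {
            "replica": int(replica),
            "rmsd_summary_A": summ,
        }

    if "domains" in config.steps:
        opts = dict(config.lattice)
        opts.setdefault("seed", config.seed)
        opts.setdefault("protein_affinities", {"DPPC": -8.0, "DIPC": -4.0, "CHOL": 0.0})
        series = simulate_lipid_mixture(**opts)
        pref = protein_domain_preference(series, window=config.lipid_window)
        np.savetxt(
            outdir / "lattice_final.tsv", series.snapshots[-1].grid, fmt="%d", delimiter="\t"
        )
        np.savetxt(
            outdir / "demixing_trace.tsv",
            np.column_stack([series.times, series.order_parameter_trace]),
            delimiter="\t",
            header="time_ns\torder_parameter",
            comments="",
        )
        report = {
            "dppc_energy_share": pref.dppc_energy_share,
            "dipc_energy_share": pref.dipc_energy_share,
            "ordered_contact_fraction": pref.ordered_contact_fraction,
            "phase_class": pref.phase_class,
            "final_order_parameter": float(series.order_parameter_trace[-1]),
        }
        (outdir / "domain_preference.json").write_text(json.dumps(report, indent=2))
        summary["steps"]["domains"] = report

    if "oligomers" in config.steps:
        if result is None:
            raise ConfigError("oligomer step needs the assembly step")
        topos = result.topologies
        n_dimer = n_oligomer = 0
        energies = []
        for r in range(result.n_replicas):
            frame = result.frame(r, result.n_frames - 1)
            ga, gb = chain_group(frame, 0), chain_group(frame, 1)
            e = pair_energy(frame, ga, gb, topos, model)
            energies.append(e)
            if is_dimer(e, model):
                n_dimer += 1
                _, frac, _ = buried_surface_area(
                    frame, ga, gb, topos, model, sphere_points=240
                )
                if is_oligomer(e, frac, model):
                    n_oligomer += 1
        summary["steps"]["oligomers"] = {
            "n_replicas": result.n_replicas,
            "n_dimers_final": n_dimer,
            "n_oligomers_final": n_oligomer,
            "median_energy_kJ_mol": float(np.median(energies)),
        }

    if "report" in config.steps or True:
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
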