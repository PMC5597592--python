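"""Config-driven orchestration of the full analysis graph.

A run configuration (YAML) lists simulations (structure + trajectory +
residue name + temperature + resolution tag), an optional atoms-to-beads
mapping for AA simulations, and analysis settings.  ``run_pipeline``
executes, per simulation: extract -> two-pass reference -> align ->
(AA) map to bead space -> covariance -> PCA; then pairwise comparison
statistics and joint-basis dynamics, all written as CSV.

Cross-resolution comparisons follow both routes: map the trajectory and
then do PCA, and do PCA first and then map the eigenvectors.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cgmap, compare, pca, superpose, trajio
from .errors import ConfigError, PipelineStageError, UnresolvedTimescaleError

__all__ = ["SimulationSpec", "AnalysisSettings", "RunConfig", "load_config", "run_pipeline"]

log = logging.getLogger("crossres.pipeline")


@dataclass
class SimulationSpec:
    label: str
    structure: str
    trajectory: str
    residue_name: str
    temperature: float = 300.0
    resolution: str = "AA"  # AA | CG
    mapping: str | None = None


@dataclass
class AnalysisSettings:
    modes: int = 5
    lags: list[int] = field(default_factory=lambda: [1, 2, 5, 10, 20, 50])
    density_bin: float = compare.DEFAULT_DENSITY_BIN
    rdf_bin: float = compare.DEFAULT_RDF_BIN
    fit_threshold: float = 0.7
    align: bool = True
    selection: list[int] | None = None
    uniform_ladder: list[int] = field(default_factory=list)
    unresolved_policy: str = "strict"
    max_lag: int | None = None
    rmsd_stride: int = 1


@dataclass
class RunConfig:
    simulations: list[SimulationSpec]
    analysis: AnalysisSettings
    output_dir: str
    mapping: str | None = None
    seed: int = 0

    def validate(self) -> None:
        labels = [s.label for s in self.simulations]
        if len(set(labels)) != len(labels):
            raise ConfigError("simulation labels must be unique")
        if not self.simulations:
            raise ConfigError("at least one simulation is required")
        if self.analysis.modes < 1:
            raise ConfigError("analysis.modes must be >= 1")
        for sim in self.simulations:
            if sim.resolution not in ("AA", "CG"):
                raise ConfigError(f"{sim.label}: resolution must be AA or CG")
            if sim.resolution == "AA" and not (sim.mapping or self.mapping):
                if len(self.simulations) > 1:
                    raise ConfigError(
                        f"{sim.label}: AA simulation in a multi-simulation comparison needs a mapping"
                    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"'{path}' is not a mapping")
    try:
        sims = [SimulationSpec(**s) for s in raw.get("simulations", [])]
        analysis = AnalysisSettings(**raw.get("analysis", {}))
        cfg = RunConfig(
            simulations=sims,
            analysis=analysis,
            output_dir=raw.get("output_dir", "crossres_out"),
            mapping=raw.get("mapping"),
            seed=int(raw.get("seed", 0)),
        )
    except TypeError as exc:
        raise ConfigError(f"bad configuration key: {exc}") from exc
    cfg.validate()
    return cfg


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(
        {
            "simulations": [vars(s) for s in cfg.simulations],
            "analysis": vars(cfg.analysis),
            "mapping": cfg.mapping,
            "seed": cfg.seed,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class _SimState:
    spec: SimulationSpec
    aligned: superpose.AlignedEnsemble
    model: pca.PCAModel  # native representation
    common_conformations: np.ndarray  # common (bead) representation
    common_model: pca.PCAModel
    mapping: cgmap.MappingScheme | None


def _matrix_csv(mat: np.ndarray, labels, path) -> None:
    pd.DataFrame(np.asarray(mat), index=labels, columns=labels).to_csv(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis graph; returns a result summary dict."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": _config_hash(config), "seed": config.seed, "stages": []}
    a = config.analysis
    states: list[_SimState] = []
    common_refs: dict[int, np.ndarray] = {}

    def _stage(name: str, label: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"].append({"stage": name, "label": label, "status": "failed"})
            (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
            raise PipelineStageError(name, label, exc) from exc
        log.info("stage %s [%s] done in %.3fs", name, label, time.perf_counter() - t0)
        manifest["stages"].append({"stage": name, "label": label, "status": "ok"})
        return result

    for sim in config.simulations:
        simdir = outdir / sim.label
        simdir.mkdir(exist_ok=True)
        mapping_path = sim.mapping or config.mapping
        mapping = None
        if sim.resolution == "AA" and mapping_path:
            mapping = _stage("read_mapping", sim.label, lambda p=mapping_path: trajio.read_mapping(p))

        def _load(sim=sim):
            table, _ = trajio.read_structure(sim.structure)
            traj = trajio.read_trajectory(sim.trajectory, table)
            return trajio.extract_molecule_ensemble(traj, sim.residue_name, heavy_only=True)

        ensemble = _stage("extract", sim.label, _load)

        def _align(ens=ensemble):
            sel = np.asarray(a.selection, int) if a.selection else None
            if a.align:
                return superpose.build_reference(ens, selection=sel)
            return superpose.AlignedEnsemble(
                ens.conformations, ens.conformations.mean(axis=0), np.arange(ens.n_particles),
                None, ens.n_copies, ens.frame_interval,
            )

        aligned = _stage("align", sim.label, _align)
        model = _stage("pca", sim.label, lambda al=aligned: pca.pca_from_ensemble(al))

        if mapping is not None:
            common_conf = cgmap.map_coordinates(aligned.conformations, mapping)
        else:
            common_conf = aligned.conformations
        # cross-simulation covariance elements are frame-dependent: every
        # simulation's common-representation conformations are aligned to
        # the reference defined by the first compatible simulation
        dim = common_conf.shape[1]
        if a.align:
            if dim in common_refs:
                common_conf = superpose.align_ensemble(common_conf, common_refs[dim]).conformations
            else:
                common_refs[dim] = common_conf.mean(axis=0)
        common_model = pca.pca_from_ensemble(common_conf) if mapping is not None or a.align else model
        states.append(_SimState(sim, aligned, model, common_conf, common_model, mapping))

        def _report(st=states[-1], simdir=simdir):
            m = st.model
            pd.DataFrame(
                {
                    "mode": np.arange(m.n_modes),
                    "eigenvalue": m.eigenvalues,
                    "normalized": pca.normalized_eigenvalues(m),
                    "cumulative": pca.cumulative_variance(m),
                }
            ).to_csv(simdir / "eigenvalues.csv", index=False)
            series = pca.project(st.aligned, m, modes=min(a.modes, m.n_modes))
            series.to_frame().to_csv(simdir / "projections.csv", index=False)
            for mode in series.mode_ids:
                dens = compare.projection_density(series, mode, bin_width=a.density_bin)
                dens = compare.effective_potential(dens, st.spec.temperature)
                pd.DataFrame(
                    {
                        "center": dens.bin_centers,
                        "density": dens.probability_density,
                        "energy_kBT": dens.effective_energy,
                    }
                ).to_csv(simdir / f"density_mode{mode}.csv", index=False)
            if st.mapping is not None:
                prof = cgmap.conservation_profile(
                    m.eigenvectors[:, : a.modes], st.mapping, label="mapping"
                )
                prof.to_csv(simdir / "conservation.csv")
                for ratio in a.uniform_ladder:
                    scheme = cgmap.uniform_mapping(m.particle_count, ratio)
                    cgmap.conservation_profile(
                        m.eigenvectors[:, : a.modes], scheme, label=f"uniform_{ratio}"
                    ).to_csv(simdir / f"conservation_uniform{ratio}.csv")
            lags = [l for l in a.lags if l < st.aligned.n_conformations // st.aligned.n_copies]
            curve = compare.rmsd_lag(
                st.aligned.per_copy(), lags, superpose=True,
                frame_interval=st.aligned.frame_interval or 1.0, t_stride=a.rmsd_stride,
            )
            rmsd_eq = float(curve.rmsd.max())
            fit = {}
            if rmsd_eq > 0:
                try:
                    c1, c2 = compare.fit_nrmsd(curve, rmsd_eq, threshold=a.fit_threshold)
                    fit = {"c1": c1, "c2": c2}
                except Exception:
                    pass
            pd.DataFrame({"lag": curve.lags, "rmsd": curve.rmsd}).to_csv(
                simdir / "rmsd_lag.csv", index=False
            )
            if fit:
                pd.DataFrame([fit]).to_csv(simdir / "nrmsd_fit.csv", index=False)

        _stage("report", sim.label, _report)

    # pairwise covariance PCC in the common representation
    n = len(states)
    labels = [s.spec.label for s in states]
    pcc = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if states[i].common_model.covariance.shape != states[j].common_model.covariance.shape:
                raise PipelineStageError(
                    "pcc", f"{labels[i]}/{labels[j]}",
                    ValueError("common representations have different dimensions"),
                )
            pcc[i, j] = pcc[j, i] = pca.covariance_pcc(
                states[i].common_model.covariance, states[j].common_model.covariance
            )
    _matrix_csv(pcc, labels, outdir / "pcc_matrix.csv")
    manifest["stages"].append({"stage": "pcc", "label": "*", "status": "ok"})

    # dot-product matrices, both cross-resolution routes
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            si, sj = states[i], states[j]
            k = min(a.modes, si.common_model.n_modes, sj.common_model.n_modes)
            route1 = pca.dot_product_matrix(si.common_model, sj.common_model, k)
            np.savetxt(outdir / f"dotprod_{labels[i]}_{labels[j]}_mapped_traj.csv", route1, delimiter=",")
            if si.mapping is not None:
                route2 = pca.dot_product_matrix(si.model, sj.common_model, k, mapping=si.mapping)
                np.savetxt(outdir / f"dotprod_{labels[i]}_{labels[j]}_mapped_modes.csv", route2, delimiter=",")

    # joint basis, timescales and speedups
    frame_counts = {st.aligned.n_conformations // st.aligned.n_copies for st in states}
    if len(frame_counts) != 1:
        raise PipelineStageError(
            "joint_pca", "*", ConfigError("joint PCA requires equal frame counts per simulation")
        )
    dims = {st.common_conformations.shape[1] for st in states}
    if len(dims) != 1:
        raise PipelineStageError(
            "joint_pca", "*", ConfigError("joint PCA requires a common representation")
        )
    pooled = np.concatenate([st.common_conformations for st in states], axis=0)
    joint = pca.pca_from_ensemble(pooled)
    k = min(a.modes, joint.n_modes)
    times = np.full((n, k), np.nan)
    for i, st in enumerate(states):
        series = pca.project(
            st.common_conformations, joint, modes=k,
            n_copies=st.aligned.n_copies, frame_interval=st.aligned.frame_interval,
        )
        for mode in range(k):
            try:
                ac = compare.autocorrelation(series, mode, max_lag=a.max_lag)
                times[i, mode] = compare.characteristic_time(ac).characteristic_time
            except UnresolvedTimescaleError:
                if a.unresolved_policy == "strict":
                    raise PipelineStageError(
                        "timescales", labels[i],
                        UnresolvedTimescaleError(f"mode {mode} unresolved"),
                    )
    pd.DataFrame(times, index=labels, columns=[f"mode{m}" for m in range(k)]).to_csv(
        outdir / "timescales.csv"
    )
    speedup = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            speedup[i, j] = compare.speedup_ratio(
                times[i], times[j], joint.eigenvalues[:k],
                policy="exclude" if a.unresolved_policy != "strict" else "strict",
            ).ratio
    _matrix_csv(speedup, labels, outdir / "speedup_matrix.csv")
    manifest["stages"].append({"stage": "timescales", "label": "*", "status": "ok"})
    manifest["complete"] = True
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
    return {"pcc": pcc, "speedup": speedup, "timescales": times, "labels": labels, "joint": joint}
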