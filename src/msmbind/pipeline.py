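"""Config-driven orchestration of the analysis stages.

Stages (``simulate -> featurize -> cluster -> msm -> lump -> analyze ->
report``) communicate exclusively through plain-text artifacts in the output
directory, so each stage can be rerun or inspected in isolation.  A manifest
records parameters, seeds and a config hash per stage; reruns with identical
inputs are byte-identical for the deterministic stages, and the synthetic
stages derive one random generator per trajectory so results do not depend on
generation order.

Configuration is YAML with one block per stage; unknown keys are rejected.
Defaults reproduce the published analysis parameters (50/5000 and 10/100
cluster counts, 5 A regime threshold, 6 ns lag, 300 ps residence filter, the
stated density-level ladders, 100 bootstrap resamples, 10 flux pathways).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import discretize, kinetics, lump, msm, synthdata
from .featurize import FeatureTrajectory

__all__ = ["PipelineConfig", "PipelineError", "run", "STAGES"]

STAGES = ("simulate", "featurize", "cluster", "msm", "lump", "analyze", "report")


class PipelineError(RuntimeError):
    pass


@dataclass
class SynthConfig:
    scenario: str = "lao-like"
    n_traj: int = 65
    n_frames: int = 10000
    seed: int = 1
    include_misbound: bool = True


@dataclass
class DiscretizeConfig:
    threshold_A: float = 5.0
    k_protein_high: int = 50
    k_ligand_high: int = 5000
    k_protein_low: int = 10
    k_ligand_low: int = 100
    seed_index: int = 0


@dataclass
class MsmConfig:
    lag_ns: float = 6.0
    min_residence_ps: float = 300.0
    dt_ps: float = 20.0
    lag_scan_ns: list = field(default_factory=lambda: [2.0, 4.0, 6.0, 8.0])
    n_timescales: int = 5


@dataclass
class LumpConfig:
    levels_high: list = field(default_factory=lambda: list(lump.DEFAULT_LEVELS_HIGH))
    levels_low: list = field(default_factory=lambda: list(lump.DEFAULT_LEVELS_LOW))
    max_clusters: int = 5
    seed: int = 0
    # lag (frames) of the kinetic-coupling graph used for lumping; the finest
    # available connectivity (one frame) resolves transitional microstates best
    coupling_lag_frames: int = 1


@dataclass
class KineticsConfig:
    n_boot: int = 100
    n_draw: int | None = None
    n_paths: int = 10
    T_K: float = 318.0
    c0_molar: float = 0.0049
    source_macros: list | None = None   # default: all diffusing-regime macrostates
    target_macros: list | None = None   # default: the most populated macrostate
    bootstrap_seed: int = 0


@dataclass
class PipelineConfig:
    output_dir: str = "msmbind_out"
    synth: SynthConfig = field(default_factory=SynthConfig)
    discretize: DiscretizeConfig = field(default_factory=DiscretizeConfig)
    msm: MsmConfig = field(default_factory=MsmConfig)
    lump: LumpConfig = field(default_factory=LumpConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)

    _SECTIONS = {
        "synth": SynthConfig, "discretize": DiscretizeConfig, "msm": MsmConfig,
        "lump": LumpConfig, "kinetics": KineticsConfig,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        kwargs = {}
        if "output_dir" in data:
            kwargs["output_dir"] = str(data.pop("output_dir"))
        for name, section_cls in cls._SECTIONS.items():
            block = data.pop(name, {}) or {}
            known = {f.name for f in dataclasses.fields(section_cls)}
            unknown = set(block) - known
            if unknown:
                raise ValueError(f"unknown keys in config section '{name}': {sorted(unknown)}")
            kwargs[name] = section_cls(**block)
        if data:
            raise ValueError(f"unknown top-level config keys: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        out = {"output_dir": self.output_dir}
        for name in self._SECTIONS:
            out[name] = dataclasses.asdict(getattr(self, name))
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _to_builtin(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _json_dump(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_to_builtin)
        fh.write("\n")


def _json_load(path: Path, stage: str):
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path.name}: run the '{stage}' stage first")
    with open(path) as fh:
        return json.load(fh)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(f"missing artifact {path}: run the '{stage}' stage first")
    return path


def _manifest_update(outdir: Path, stage: str, config: PipelineConfig) -> None:
    path = outdir / "manifest.json"
    manifest = json.load(open(path)) if path.exists() else {}
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    manifest[stage] = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.synth.seed,
    }
    _json_dump(manifest, path)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    s = cfg.synth
    if s.scenario != "lao-like":
        raise PipelineError(f"unknown synthetic scenario '{s.scenario}'")
    spec = synthdata.lao_like(include_misbound=s.include_misbound, seed=s.seed)
    trajs, labels = synthdata.generate_dataset(spec, s.n_traj, s.n_frames, seed=s.seed)
    fdir, ldir = outdir / "features", outdir / "true_labels"
    fdir.mkdir(parents=True, exist_ok=True)
    ldir.mkdir(parents=True, exist_ok=True)
    for i, (t, lab) in enumerate(zip(trajs, labels)):
        t.to_tsv(fdir / f"traj_{i:03d}.tsv")
        synthdata.write_labels(lab, ldir / f"traj_{i:03d}.txt")
    _json_dump({
        "scenario": s.scenario, "n_traj": s.n_traj, "n_frames": s.n_frames,
        "seed": s.seed, "dt_ps": spec.dt_ps,
        "state_names": list(spec.state_names or []),
        "stationary": spec.stationary.tolist(),
    }, outdir / "scenario.json")


def _load_features(outdir: Path) -> list[FeatureTrajectory]:
    fdir = _require(outdir / "features", "simulate")
    files = sorted(fdir.glob("traj_*.tsv"))
    if not files:
        raise PipelineError("no feature tables found: run the 'simulate' stage first")
    return [FeatureTrajectory.from_tsv(f) for f in files]


def _stage_featurize(cfg: PipelineConfig, outdir: Path) -> None:
    # synthetic scenarios emit feature tables directly; this stage validates
    # them (lengths, invariants) and records the feature summary
    trajs = _load_features(outdir)
    _json_dump({
        "n_traj": len(trajs),
        "n_frames": [t.n_frames for t in trajs],
        "opening_deg_range": [float(min(t.opening_deg.min() for t in trajs)),
                              float(max(t.opening_deg.max() for t in trajs))],
        "min_dist_range": [float(min(t.min_dist_A.min() for t in trajs)),
                           float(max(t.min_dist_A.max() for t in trajs))],
    }, outdir / "features_summary.json")


def _stage_cluster(cfg: PipelineConfig, outdir: Path) -> None:
    trajs = _load_features(outdir)
    _require(outdir / "features_summary.json", "featurize")
    d = cfg.discretize
    assignment = discretize.two_regime_assign(
        trajs, threshold_A=d.threshold_A,
        k_protein_high=d.k_protein_high, k_ligand_high=d.k_ligand_high,
        k_protein_low=d.k_protein_low, k_ligand_low=d.k_ligand_low,
        seed_index=d.seed_index,
    )
    mdir = outdir / "micro_labels"
    mdir.mkdir(parents=True, exist_ok=True)
    for i, lab in enumerate(assignment.labels):
        synthdata.write_labels(lab, mdir / f"traj_{i:03d}.txt")
    with open(outdir / "micro_provenance.tsv", "w") as fh:
        fh.write("micro\tprotein_cluster\tligand_cluster\tregime\n")
        for k, (p, l, r) in enumerate(assignment.provenance):
            fh.write(f"{k}\t{p}\t{l}\t{r}\n")
    _json_dump({
        "K": assignment.K,
        "n_high": int(sum(1 for p in assignment.provenance if p[2] == discretize.REGIME_HIGH)),
        "n_low": int(sum(1 for p in assignment.provenance if p[2] == discretize.REGIME_LOW)),
        "frame_counts": assignment.frame_counts().tolist(),
    }, outdir / "assignment.json")


def _load_micro_labels(outdir: Path) -> list[np.ndarray]:
    mdir = _require(outdir / "micro_labels", "cluster")
    files = sorted(mdir.glob("traj_*.txt"))
    if not files:
        raise PipelineError("no microstate labels found: run the 'cluster' stage first")
    return [synthdata.read_labels(f) for f in files]


def _load_regimes(outdir: Path) -> np.ndarray:
    path = _require(outdir / "micro_provenance.tsv", "cluster")
    regimes = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            regimes.append(line.rstrip("\n").split("\t")[3])
    return np.asarray(regimes)


def _stage_msm(cfg: PipelineConfig, outdir: Path) -> None:
    labels = _load_micro_labels(outdir)
    a = _json_load(outdir / "assignment.json", "cluster")
    m = cfg.msm
    lag_frames = int(round(m.lag_ns * 1000.0 / m.dt_ps))
    min_res = max(1, int(round(m.min_residence_ps / m.dt_ps)))
    model = msm.TransitionModel.from_labels(
        labels, lag_frames=lag_frames, min_residence_frames=min_res,
        n_states=a["K"], dt_ps=m.dt_ps)
    its = msm.implied_timescales(
        labels, m.lag_scan_ns, n_timescales=m.n_timescales,
        min_residence_frames=min_res, dt_ps=m.dt_ps, n_states=a["K"])
    rows, cols = np.nonzero(model.counts)
    np.savetxt(outdir / "micro_counts.coo.txt",
               np.column_stack([rows, cols, model.counts[rows, cols]]), fmt="%d",
               header="row col count")
    np.savetxt(outdir / "micro_pi.txt", model.pi, fmt="%.12g")
    _json_dump({
        "lag_ns": m.lag_ns, "lag_frames": lag_frames,
        "min_residence_frames": min_res, "dt_ps": m.dt_ps, "K": a["K"],
        "implied_timescales_ns": {
            "lags_ns": its.lags_ns.tolist(),
            "timescales_ns": [[None if not np.isfinite(v) else v for v in row]
                              for row in its.timescales_ns],
        },
    }, outdir / "msm.json")


def _load_counts(outdir: Path, K: int) -> np.ndarray:
    path = _require(outdir / "micro_counts.coo.txt", "msm")
    data = np.loadtxt(path, dtype=np.int64).reshape(-1, 3)
    counts = np.zeros((K, K), dtype=np.int64)
    counts[data[:, 0], data[:, 1]] = data[:, 2]
    return counts


def _stage_lump(cfg: PipelineConfig, outdir: Path) -> None:
    a = _json_load(outdir / "assignment.json", "cluster")
    _json_load(outdir / "msm.json", "msm")
    counts = _load_counts(outdir, a["K"])
    pi = np.loadtxt(outdir / "micro_pi.txt").reshape(-1)
    levels = lump.DensityLevels(tuple(cfg.lump.levels_high), tuple(cfg.lump.levels_low))
    coupling = msm.count_transitions(
        _load_micro_labels(outdir), cfg.lump.coupling_lag_frames, 1, n_states=a["K"])
    mapping = lump.shc_lump(
        coupling, np.asarray(a["frame_counts"]), _load_regimes(outdir),
        levels=levels, pi=pi, max_clusters=cfg.lump.max_clusters, seed=cfg.lump.seed)
    np.savetxt(outdir / "macro_map.txt",
               np.column_stack([np.arange(a["K"]), mapping.micro_to_macro]),
               fmt="%d", header="micro macro")
    macro_counts = lump.aggregate_counts(counts, mapping)
    np.savetxt(outdir / "macro_counts.txt", macro_counts, fmt="%d")
    _json_dump({
        "M": mapping.M,
        "macro_populations": mapping.macro_populations.tolist(),
        "level_of_seed": mapping.level_of_seed.tolist(),
    }, outdir / "lump.json")


def _macro_regimes(outdir: Path, mapping: np.ndarray, M: int) -> np.ndarray:
    micro_regimes = _load_regimes(outdir)
    out = np.empty(M, dtype=object)
    for m in range(M):
        regs = set(micro_regimes[mapping == m])
        out[m] = regs.pop() if len(regs) == 1 else "mixed"
    return out


def _stage_analyze(cfg: PipelineConfig, outdir: Path) -> None:
    a = _json_load(outdir / "assignment.json", "cluster")
    msm_info = _json_load(outdir / "msm.json", "msm")
    lump_info = _json_load(outdir / "lump.json", "lump")
    mapping = np.loadtxt(outdir / "macro_map.txt", dtype=np.int64).reshape(-1, 2)[:, 1]
    M = lump_info["M"]
    macro_counts = np.loadtxt(outdir / "macro_counts.txt", dtype=np.int64).reshape(M, M)
    T_macro = msm.transition_matrix(macro_counts)
    pi_macro = msm.stationary_distribution(T_macro)

    k = cfg.kinetics
    regimes = _macro_regimes(outdir, mapping, M)
    if k.target_macros is not None:
        targets = [int(t) for t in k.target_macros]
    else:
        targets = [int(np.argmax(pi_macro))]
    if k.source_macros is not None:
        sources = [int(s) for s in k.source_macros]
    else:
        sources = [m for m in range(M)
                   if regimes[m] == discretize.REGIME_LOW and m not in targets]
    if not sources:
        raise PipelineError("no diffusing-regime (unbound) macrostates to use as sources; "
                            "set kinetics.source_macros explicitly")

    lag_ns = msm_info["lag_ns"]
    res = kinetics.mfpt(T_macro, lag_ns, sources, targets, pi=pi_macro)

    # bootstrap over trajectories with the frozen state decomposition
    labels = _load_micro_labels(outdir)

    def statistic(trajs):
        c = msm.count_transitions(trajs, msm_info["lag_frames"],
                                  msm_info["min_residence_frames"], n_states=a["K"])
        mc = lump.aggregate_counts(
            c, lump.MacroMapping(mapping, M, np.full(M, 1.0 / M), np.zeros(M)))
        Tm = msm.transition_matrix(mc)
        return kinetics.mfpt(Tm, lag_ns, sources, targets,
                             pi=msm.stationary_distribution(Tm)).value_us

    boot_mean, boot_sd = kinetics.bootstrap_statistic(
        labels, statistic, n_boot=k.n_boot, n_draw=k.n_draw, seed=k.bootstrap_seed)

    alpha_free = float(pi_macro[[m for m in range(M)
                                 if regimes[m] == discretize.REGIME_LOW]].sum())
    if 0.0 < alpha_free < 1.0:
        dG = kinetics.binding_free_energy(alpha_free, k.c0_molar, k.T_K)
    else:
        warnings.warn("free fraction is degenerate (0 or 1); binding free energy undefined")
        dG = None

    q = kinetics.committor(T_macro, sources, targets)
    F, total = kinetics.net_flux(T_macro, pi_macro, q, sources, targets)
    paths = kinetics.top_flux_paths(F, sources, targets, n_paths=k.n_paths,
                                    total_flux=total)
    _json_dump({
        "sources": sources, "targets": targets,
        "macro_regimes": regimes.tolist(),
        "pi_macro": pi_macro.tolist(),
        "mfpt_us": res.value_us,
        "mfpt_per_source_us": {str(s): v for s, v in res.per_source_us.items()},
        "mfpt_bootstrap_mean_us": boot_mean,
        "mfpt_bootstrap_sd_us": boot_sd,
        "alpha_free": alpha_free,
        "alpha_bound": 1.0 - alpha_free,
        "binding_dG_kcal_mol": dG,
        "total_flux_per_lag": total,
        "top_paths": [
            {"path": [int(s) for s in p], "flux": f, "fraction": frac}
            for p, f, frac in paths
        ],
    }, outdir / "analysis.json")


def _stage_report(cfg: PipelineConfig, outdir: Path) -> None:
    report = {
        "config": cfg.to_dict(),
        "scenario": _json_load(outdir / "scenario.json", "simulate"),
        "assignment": {key: val for key, val in
                       _json_load(outdir / "assignment.json", "cluster").items()
                       if key != "frame_counts"},
        "msm": _json_load(outdir / "msm.json", "msm"),
        "lump": _json_load(outdir / "lump.json", "lump"),
        "analysis": _json_load(outdir / "analysis.json", "analyze"),
    }
    _json_dump(report, outdir / "report.json")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "featurize": _stage_featurize,
    "cluster": _stage_cluster,
    "msm": _stage_msm,
    "lump": _stage_lump,
    "analyze": _stage_analyze,
    "report": _stage_report,
}


def run(subcommand: str, config: PipelineConfig | dict | str | Path) -> Path:
    """Run one pipeline stage (or 'all') against a config; returns the output dir."""
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = STAGES if subcommand == "all" else (subcommand,)
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise PipelineError(f"unknown stage '{stage}'; valid: {', '.join(STAGES)}")
        _STAGE_FUNCS[stage](config, outdir)
        _manifest_update(outdir, stage, config)
    return outdir
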