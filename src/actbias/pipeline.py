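"""Study orchestration: train → controls → simulate → geometry → fixed
points → latent circuits → behavior, with seeded stages and CSV outputs.

All stage seeds derive from one master seed through
``numpy.random.SeedSequence(master).spawn``, in a fixed stage order, so a
study is reproducible end to end from (config, master seed).  Stage outputs
are written under the configured output directory together with a JSON
manifest recording every artifact, its seed and the config hash; a re-run
with an existing, hash-matching manifest skips completed stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, fixedpoints, geometry, latent, rnn, tasks

logger = logging.getLogger("actbias")

__all__ = ["ExperimentConfig", "run_study", "export_tables", "load_config"]

#: Scale profiles: network size, iterations, nets per architecture, latent
#: restarts.  "full" is the study-scale profile; "scaled_down" and
#: "smoke" are reduced profiles for desk-scale runs.
PROFILES = {
    "full": dict(n_units=100, n_iter=5000, n_nets=100, n_top=50,
                  latent_restarts=30, latent_iter=3000, icp_tries=60,
                  coherences=tasks.TRAINING_COHERENCES),
    "scaled_down": dict(n_units=50, n_iter=1500, n_nets=3, n_top=3,
                        latent_restarts=10, latent_iter=500, icp_tries=20,
                        coherences=tasks.TRAINING_COHERENCES),
    "smoke": dict(n_units=20, n_iter=200, n_nets=1, n_top=1,
                  latent_restarts=1, latent_iter=150, icp_tries=8,
                  coherences=(-1.0, -0.25, 0.0, 0.25, 1.0)),
}

STAGES = ("train", "controls", "geometry", "fixedpoints", "latent", "behavior")


@dataclass
class ExperimentConfig:
    task: str = "cddm"
    architectures: tuple = rnn.ARCHITECTURES
    profile: str = "scaled_down"
    master_seed: int = 0
    out_dir: str = "study"
    stages: tuple = STAGES
    overrides: dict = field(default_factory=dict)

    def params(self) -> dict:
        p = dict(PROFILES[self.profile])
        p.update(self.overrides)
        return p

    def config_hash(self) -> str:
        blob = json.dumps(
            {**asdict(self), "architectures": [list(a) for a in self.architectures]},
            sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> ExperimentConfig:
    """Read an ExperimentConfig from a YAML file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "architectures" in raw:
        raw["architectures"] = tuple(
            (a[0], bool(a[1])) for a in raw["architectures"])
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return ExperimentConfig(**raw)


def _stage_seeds(master_seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(master_seed).spawn(n)]


def _make_batch(task: str, coherences, seed: int) -> tasks.TrialBatch:
    if task == "cddm":
        return tasks.build_cddm_batch(tasks.enumerate_cddm_conditions(coherences))
    if task == "gonogo":
        return tasks.build_gonogo_batch()
    if task == "memory":
        return tasks.build_memory_batch(seed=seed)
    raise ValueError(f"unknown task {task!r}")


def _task_io(task: str) -> tuple[int, int]:
    return (6, 2) if task == "cddm" else (3, 1)


def run_study(config: ExperimentConfig) -> dict:
    """Execute the configured stages in dependency order; returns manifest."""
    p = config.params()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest_path = out / "manifest.json"
    manifest = {"config_hash": chash, "task": config.task,
                "profile": config.profile, "master_seed": config.master_seed,
                "out_dir": str(out), "stages": {}, "errors": []}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == chash:
            manifest = old
    seeds = _stage_seeds(config.master_seed, len(STAGES))
    seed_of = dict(zip(STAGES, seeds))
    n_in, n_out = _task_io(config.task)
    batch = _make_batch(config.task, p["coherences"], seed_of["train"])

    def done(stage):
        return stage in manifest["stages"]

    def record(stage, artifacts, t0):
        manifest["stages"][stage] = {
            "seed": seed_of[stage], "artifacts": artifacts,
            "wall_clock_s": round(time.time() - t0, 2)}
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
        logger.info("stage %s done in %.1fs", stage,
                    manifest["stages"][stage]["wall_clock_s"])

    net_ids = [f"{act}_{'dale' if d else 'nodale'}_{i}"
               for act, d in config.architectures for i in range(p["n_nets"])]

    try:
        if "train" in config.stages and not done("train"):
            t0 = time.time()
            rng = np.random.default_rng(seed_of["train"])
            artifacts = []
            schedule = None
            if config.task == "memory":
                schedule = [(0.0, p["n_iter"]), (0.3, p["n_iter"])]
            lam_r = 0.5 if config.task in ("cddm", "gonogo") else 0.0
            for act, dale in config.architectures:
                for i in range(p["n_nets"]):
                    net_id = f"{act}_{'dale' if dale else 'nodale'}_{i}"
                    net_seed = int(rng.integers(2 ** 31))
                    params = rnn.initialize_rnn(
                        act, dale, n_units=p["n_units"], n_in=n_in,
                        n_out=n_out, seed=net_seed)
                    trained, trace = rnn.train_rnn(
                        params, batch, schedule=schedule, lam_r=lam_r,
                        n_iter=p["n_iter"], seed=net_seed + 1)
                    mse = behavior.task_performance(trained, batch)
                    path = out / f"net_{net_id}"
                    rnn.save_checkpoint(
                        trained, path, loss_trace=trace,
                        extra={"net_id": net_id, "seed": net_seed,
                               "task": config.task, "masked_mse": mse})
                    artifacts.append(str(path))
            record("train", artifacts, t0)

        if "controls" in config.stages and not done("controls"):
            t0 = time.time()
            rng = np.random.default_rng(seed_of["controls"])
            artifacts = []
            for net_id in net_ids:
                params = rnn.load_checkpoint(out / f"net_{net_id}")
                control = rnn.shuffle_connectivity(
                    params, seed=int(rng.integers(2 ** 31)))
                path = out / f"control_net_{net_id}"
                rnn.save_checkpoint(control, path,
                                    extra={"net_id": net_id, "control": True})
                artifacts.append(str(path))
            record("controls", artifacts, t0)

        sims: dict[str, rnn.ResponseTensor] = {}

        def simulate(prefix, net_id):
            key = f"{prefix}{net_id}"
            if key not in sims:
                params = rnn.load_checkpoint(out / f"{prefix}net_{net_id}")
                sims[key] = rnn.simulate_batch(params, batch, noise=False)
            return sims[key]

        if "geometry" in config.stages and not done("geometry"):
            t0 = time.time()
            artifacts = []
            rows = []
            all_ids = ([("", i) for i in net_ids]
                       + [("control_", i) for i in net_ids])
            traj = [geometry.reduce_trajectories(simulate(p_, i))
                    for p_, i in all_ids]
            sel = [geometry.reduce_selectivity(simulate(p_, i))
                   for p_, i in all_ids]
            ends = [geometry.reduce_endpoints(simulate(p_, i))
                    for p_, i in all_ids]
            for name, summaries in (("trajectory", traj),
                                    ("selectivity", sel),
                                    ("endpoint", ends)):
                d = geometry.distance_matrix(
                    summaries, name, n_tries=p["icp_tries"],
                    seed=seed_of["geometry"])
                coords, stress = geometry.embed_mds(d, seed=seed_of["geometry"])
                df = pd.DataFrame({
                    "net_id": [i for _, i in all_ids],
                    "architecture": ["_".join(i.split("_")[:2])
                                     for _, i in all_ids],
                    "control": [p_ == "control_" for p_, i in all_ids],
                    "mds_x": coords[:, 0], "mds_y": coords[:, 1]})
                path = out / f"embedding_{name}.csv"
                df.to_csv(path, index=False)
                np.savetxt(out / f"distances_{name}.csv", d, delimiter=",")
                artifacts.append(str(path))
                rows.append({"metric": name, "stress1": stress})
            pd.DataFrame(rows).to_csv(out / "mds_stress.csv", index=False)
            record("geometry", artifacts, t0)

        if "fixedpoints" in config.stages and not done("fixedpoints"):
            t0 = time.time()
            artifacts = []
            summaries = []
            keep = []
            all_ids = ([("", i) for i in net_ids]
                       + [("control_", i) for i in net_ids])
            for p_, net_id in all_ids:
                params = rnn.load_checkpoint(out / f"{p_}net_{net_id}")
                pts = fixedpoints.fixed_point_survey(
                    params, simulate(p_, net_id).activity, task=config.task,
                    seed=seed_of["fixedpoints"],
                    max_points=p.get("max_fps", 20),
                    patience=p.get("fp_patience", 20))
                fixedpoints.survey_to_frame(pts).to_csv(
                    out / f"fps_{p_}{net_id}.csv", index=False)
                try:
                    summaries.append(geometry.project_fixed_points(pts))
                    keep.append((p_, net_id))
                except ValueError:
                    manifest["errors"].append(
                        f"too few fixed points for {p_}{net_id}")
            if len(keep) >= 3:
                d = geometry.distance_matrix(
                    summaries, "fixedpoint", n_tries=p["icp_tries"],
                    seed=seed_of["fixedpoints"])
                coords, _ = geometry.embed_mds(d, seed=seed_of["fixedpoints"])
                df = pd.DataFrame({
                    "net_id": [i for _, i in keep],
                    "architecture": ["_".join(i.split("_")[:2])
                                     for _, i in keep],
                    "control": [p_ == "control_" for p_, i in keep],
                    "mds_x": coords[:, 0], "mds_y": coords[:, 1]})
                path = out / "embedding_fixedpoint.csv"
                df.to_csv(path, index=False)
                artifacts.append(str(path))
            record("fixedpoints", artifacts, t0)

        if "latent" in config.stages and not done("latent"):
            t0 = time.time()
            artifacts = []
            rows = []
            rng = np.random.default_rng(seed_of["latent"])
            for net_id in net_ids:
                params = rnn.load_checkpoint(out / f"net_{net_id}")
                z, var = latent.reduce_for_fit(simulate("", net_id))
                fit = latent.fit_latent_circuit(
                    z, batch, params.activation,
                    restarts=p["latent_restarts"], n_iter=p["latent_iter"],
                    seed=int(rng.integers(2 ** 31)))
                np.savez(out / f"latent_{net_id}.npz", w_rec=fit.w_rec,
                         w_inp=fit.w_inp, w_out=fit.w_out, q=fit.q)
                rows.append({"net_id": net_id,
                             "architecture": "_".join(net_id.split("_")[:2]),
                             "variance_captured": var,
                             "r2_dynamics": fit.r2_dynamics,
                             "r2_behaviour": fit.r2_behaviour,
                             "loss": fit.loss, "restart": fit.restart})
            path = out / "latent_fits.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            artifacts.append(str(path))
            record("latent", artifacts, t0)

        if "behavior" in config.stages and not done("behavior"):
            t0 = time.time()
            artifacts = []
            rows = []
            # output epoch: decision period for CDDM, post-cue otherwise
            epoch_start = {"cddm": 200, "gonogo": 30, "memory": 70}[config.task]
            for net_id in net_ids:
                params = rnn.load_checkpoint(out / f"net_{net_id}")
                resp = simulate("", net_id)
                x_out = resp.activity[:, epoch_start:, :]
                rows.append({
                    "net_id": net_id,
                    "architecture": "_".join(net_id.split("_")[:2]),
                    "masked_mse": behavior.task_performance(params, batch),
                    "rho": behavior.output_alignment_rho(params.w_out, x_out)})
            path = out / "behavior.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            artifacts.append(str(path))
            record("behavior", artifacts, t0)
    except Exception as exc:  # record partial progress, then re-raise
        manifest["errors"].append(repr(exc))
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
        raise
    return manifest


def export_tables(manifest: dict, out_dir: str | Path | None = None) -> dict:
    """Summary tables from a completed study: R^2 by architecture, rho.

    The R^2 table has two rows (dynamics, behaviour) and one column per
    architecture, each cell "mean ± s.d." across fitted nets.  Re-export is
    idempotent.
    """
    out = Path(out_dir) if out_dir else Path(manifest.get("out_dir", "study"))
    tables = {}
    latent_path = out / "latent_fits.csv"
    if latent_path.exists():
        df = pd.read_csv(latent_path)
        cells = {"r2_dynamics": {}, "r2_behaviour": {}}
        for arch, grp in df.groupby("architecture"):
            for row in cells:
                cells[row][arch] = (
                    f"{100 * grp[row].mean():.0f}% ± {100 * grp[row].std(ddof=0):.0f}%")
        table = pd.DataFrame(cells).T
        table.to_csv(out / "table_r2.csv")
        tables["r2"] = table
    beh_path = out / "behavior.csv"
    if beh_path.exists():
        df = pd.read_csv(beh_path)
        rho = df.groupby("architecture")["rho"].agg(["mean", "std"])
        rho.to_csv(out / "table_rho.csv")
        tables["rho"] = rho
    return tables
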