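"""Reproducible end-to-end workflow: design -> simulate -> train -> infer ->
evaluate, with per-stage manifests, content hashing, and resumability.

One global seed drives every stochastic component through stable per-stage
child seeds, so a completed pipeline re-run is a no-op and any stage can be
re-executed in isolation after deleting its artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .experiments import (
    build_sim_dataset,
    generate_noisy_observations,
    lhs_design,
    metrics,
)
from .inference import BoxTransform, GaussianLikelihood, sample_posterior
from .inflow import fit_inflow, read_inflow_csv, synthetic_inflow
from .network import (
    BiophysicalParams,
    fixture_network,
    load_network,
    physiological_parameter_space,
)
from .pinn import NetworkEmulator, TrainConfig, make_collocation
from .solver import SolverConfig

log = logging.getLogger(__name__)

STAGES = ("design", "simulate", "train", "infer", "evaluate")


@dataclass
class RunConfig:
    network: str = "single_vessel"  # fixture kind or path to a network file
    theta_names: tuple[str, ...] = ("f2_large", "f3_large[0]")
    inflow_csv: str | None = None
    n_design: int = 48
    n_test: int = 8
    n_t: int = 20
    solver: dict = field(default_factory=dict)
    emulator: dict = field(
        default_factory=lambda: {"width": 32, "depth": 3, "modified": False,
                                 "rwf": True}
    )
    train_steps: int = 1500
    lbfgs_iters: int = 500
    collocation: dict = field(
        default_factory=lambda: {"n_pde": 2048, "n_bif": 256, "n_imp": 8,
                                 "m_imp": 32}
    )
    observed_vessels: tuple[int, ...] | None = None  # default: all terminals
    n_warmup: int = 250
    n_draws: int = 400
    n_chains: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


def _child_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir, until: str = "evaluate") -> Path:
    """Execute (or resume) the workflow up to stage ``until``; returns the
    artifact directory.

    Each stage writes its artifact plus a manifest entry recording the
    config hash and input hashes; stages whose manifest matches are skipped.
    """
    stop_after = STAGES.index(until)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    if manifest.get("config_hash") not in (None, cfg_hash):
        manifest = {}
    manifest["config_hash"] = cfg_hash

    def done(stage, artifact):
        p = out / artifact
        return (
            stage in manifest
            and p.exists()
            and manifest[stage].get("hash") == _hash_file(p)
        )

    def record(stage, artifact, status="ok", **extra):
        manifest[stage] = {
            "artifact": artifact,
            "hash": _hash_file(out / artifact),
            "status": status,
            "time": time.time(),
            **extra,
        }
        manifest_path.write_text(json.dumps(manifest, indent=1))

    # ---- shared objects ----
    if config.network in (
        "single_vessel", "bifurcation3", "nine_vessel", "seventeen_vessel"
    ):
        net = fixture_network(config.network)
    else:
        net = load_network(config.network)
    base = BiophysicalParams()
    space = physiological_parameter_space(
        net.n_groups, include=set(config.theta_names)
    )
    if config.inflow_csv:
        t_in, q_in = read_inflow_csv(config.inflow_csv)
    else:
        t_in, q_in = synthetic_inflow(T=base.period_T, seed=_child_seed(
            config.seed, "inflow"))
    gp = fit_inflow(t_in, q_in, base.period_T)
    scfg = SolverConfig(**config.solver)

    # ---- design ----
    design_file = "design.json"
    if not done("design", design_file):
        design = lhs_design(space, config.n_design,
                            seed=_child_seed(config.seed, "design"))
        (out / design_file).write_text(
            json.dumps({"names": list(space.names),
                        "thetas": design.tolist()})
        )
        record("design", design_file)
    design = np.asarray(
        json.loads((out / design_file).read_text())["thetas"]
    )
    if stop_after < STAGES.index("simulate"):
        return out

    # ---- simulate ----
    ds_file = "dataset.h5"
    from .hdf5io import load_dataset, save_dataset

    if not done("simulate", ds_file):
        ds = build_sim_dataset(
            net, space, base, design, gp.qin, scfg, n_t=config.n_t
        )
        save_dataset(ds, out / ds_file,
                     provenance={"seed": config.seed, "config": cfg_hash})
        record("simulate", ds_file, n_failed=len(ds.failed))
    ds = load_dataset(out / ds_file)
    train_ds, test_ds = ds.split(
        config.n_test, seed=_child_seed(config.seed, "split")
    )
    if stop_after < STAGES.index("train"):
        return out

    # ---- train ----
    ckpt_file = "emulator.npz"
    emu = NetworkEmulator(
        net, space, base, gp, seed=_child_seed(config.seed, "init") % 100000,
        **config.emulator,
    )
    emu.set_normalisation(train_ds.stats())
    if not done("train", ckpt_file):
        coll = make_collocation(
            emu, seed=_child_seed(config.seed, "coll") % 100000,
            **config.collocation,
        )
        emu.train(train_ds, coll,
                  TrainConfig(steps=config.train_steps,
                              seed=_child_seed(config.seed, "train") % 100000))
        if config.lbfgs_iters:
            emu.polish_lbfgs(train_ds, coll, maxiter=config.lbfgs_iters)
        emu.save_checkpoint(out / ckpt_file)
        record("train", ckpt_file)
    emu.load_checkpoint(out / ckpt_file)
    if stop_after < STAGES.index("infer"):
        return out

    # ---- infer (synthetic observations at a held-out truth) ----
    post_file = "posterior.npz"
    obs_vessels = list(config.observed_vessels or net.terminal_ids)
    rng = np.random.default_rng(_child_seed(config.seed, "truth"))
    theta_true = space.denormalise(0.25 + 0.5 * rng.random(space.dim))
    if not done("infer", post_file):
        obs = generate_noisy_observations(
            net, space, base, theta_true, obs_vessels, gp.qin, scfg,
            n_t=config.n_t, seed=_child_seed(config.seed, "noise"),
        )

        def fwd(theta):
            return {
                vid: emu.flow_with_theta_grad(
                    vid, net.vessels[vid].length_L / 2.0, obs.times, theta
                )
                for vid in obs_vessels
            }

        lik = GaussianLikelihood(obs.times, obs.y, fwd, obs.hyper)
        tf = BoxTransform(space.lower, space.upper)
        rng2 = np.random.default_rng(_child_seed(config.seed, "chains"))
        u0s = [
            tf.to_unconstrained(space.denormalise(
                0.2 + 0.6 * rng2.random(space.dim)))
            for _ in range(config.n_chains)
        ]
        post = sample_posterior(
            lik, tf, u0s, space.names, n_warmup=config.n_warmup,
            n_draws=config.n_draws, seed=_child_seed(config.seed, "nuts"),
        )
        np.savez(out / post_file, chains=post.chains,
                 theta_true=theta_true,
                 psrf=np.asarray(post.diagnostics["psrf"]),
                 converged=post.converged)
        record("infer", post_file, converged=bool(post.converged))

    if stop_after < STAGES.index("evaluate"):
        return out

    # ---- evaluate ----
    eval_file = "evaluation.json"
    if not done("evaluate", eval_file):
        report = {"theta_names": list(space.names)}
        per_vessel = {}
        for vid in emu.nets:
            rm = []
            for i in range(test_ds.n):
                qp, _ = emu.predict_midpoint(
                    vid, test_ds.times,
                    np.broadcast_to(test_ds.thetas[i],
                                    (config.n_t, space.dim)),
                )
                rm.append(metrics(qp, test_ds.q[vid][i])["rmse"])
            per_vessel[str(vid)] = float(np.mean(rm))
        report["flow_rmse_per_vessel"] = per_vessel
        report["flow_rmse_total"] = float(sum(per_vessel.values()))
        post = np.load(out / post_file)
        lo, hi = np.percentile(post["chains"].reshape(-1, space.dim),
                               [2.5, 97.5], axis=0)
        report["posterior_ci95"] = {
            n: [float(a), float(b)]
            for n, a, b in zip(space.names, lo, hi)
        }
        report["theta_true"] = post["theta_true"].tolist()
        report["psrf"] = post["psrf"].tolist()
        (out / eval_file).write_text(json.dumps(report, indent=1))
        record("evaluate", eval_file)
    return out
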