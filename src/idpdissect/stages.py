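"""File-based stage runner behind the command-line interface.

Stage graph: simulate -> featurize -> bvae -> msm -> {contacts, dcvae,
entropy} -> report.  Each stage reads the previous stage's arrays from the
run directory, writes its outputs plus a ``manifest.json`` recording the
parameters, seeds and config hash, and is idempotent: re-running with an
unchanged config hash is a no-op.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib

import numpy as np

from . import bvae, featurize, fingerprint, msm, synthetic
from .entropy import TorsionDataset, mist_total_entropy
from .pipeline import RunConfig, correlate_entropy_mfpt

logger = logging.getLogger("idpdissect")

CONDITIONS = ("apo", "ligand")
STATE_COUNTS = {"apo": 3, "ligand": 6}

STAGE_DEPS = {
    "simulate": [],
    "featurize": ["simulate"],
    "bvae": ["featurize"],
    "msm": ["bvae"],
    "contacts": ["simulate", "msm"],
    "dcvae": ["contacts"],
    "entropy": ["simulate", "msm"],
    "report": ["msm", "dcvae", "entropy"],
}

STAGE_ORDER = ["simulate", "featurize", "bvae", "msm", "contacts", "dcvae",
               "entropy", "report"]


def _stage_dir(out_dir, stage):
    p = pathlib.Path(out_dir) / stage
    p.mkdir(parents=True, exist_ok=True)
    return p


def _manifest_path(out_dir, stage):
    return pathlib.Path(out_dir) / stage / "manifest.json"


def _write_manifest(out_dir, stage, config: RunConfig, outputs):
    payload = {"stage": stage, "config_hash": config.hash(),
               "seed": config.seed,
               "params": dataclasses.asdict(config),
               "outputs": sorted(str(o) for o in outputs)}
    _manifest_path(out_dir, stage).write_text(json.dumps(payload, indent=2,
                                                         default=str))


def run_stage(name: str, config: RunConfig, out_dir) -> pathlib.Path:
    """Run one stage (dependencies must have been run first)."""
    if name not in STAGE_DEPS:
        raise ValueError(f"unknown stage {name!r}")
    for dep in STAGE_DEPS[name]:
        mp = _manifest_path(out_dir, dep)
        if not mp.exists():
            raise RuntimeError(
                f"stage '{name}' needs upstream stage '{dep}': run it first")
    mp = _manifest_path(out_dir, name)
    if mp.exists():
        try:
            if json.loads(mp.read_text())["config_hash"] == config.hash():
                logger.info("stage %s up to date (hash %s)", name,
                            config.hash())
                return _stage_dir(out_dir, name)
        except (KeyError, json.JSONDecodeError):
            pass
    logger.info("running stage %s", name)
    outputs = _STAGE_FNS[name](config, out_dir)
    _write_manifest(out_dir, name, config, outputs)
    return _stage_dir(out_dir, name)


def _condition_spec(cond: str, config: RunConfig):
    seed = config.seed if cond == "apo" else config.seed + 1000
    return synthetic.benchmark_spec(STATE_COUNTS[cond], config.n_residues,
                                    seed=seed,
                                    jitter_sigma=config.jitter_sigma)


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out_dir):
    d = _stage_dir(out_dir, "simulate")
    outputs = []
    frames_per = config.n_frames_total // config.n_trajectories
    for cond in CONDITIONS:
        spec = _condition_spec(cond, config)
        rng = np.random.default_rng(spec.seed)
        ens = [synthetic.simulate_markov_ensemble(
            spec, frames_per, seed=int(rng.integers(2**31)),
            with_torsions=True) for _ in range(config.n_trajectories)]
        coords = np.concatenate([e.coordinates for e in ens])
        labels = np.concatenate([e.state_labels for e in ens])
        torsions = np.concatenate([e.torsions for e in ens])
        bounds = np.cumsum([0] + [frames_per] * (config.n_trajectories - 1))
        path = d / f"{cond}.npz"
        np.savez_compressed(path, coordinates=coords.astype(np.float32),
                            state_labels=labels, torsions=torsions,
                            boundaries=bounds,
                            transition_matrix=spec.transition_matrix,
                            kappa=spec.state_torsion_kappa)
        merged = synthetic.SyntheticEnsemble(coordinates=coords,
                                             state_labels=labels)
        synthetic.write_ensemble(merged, str(d / cond))
        outputs += [path, d / f"{cond}.pdb", d / f"{cond}.xtc",
                    d / f"{cond}_states.csv"]
    return outputs


def _stage_featurize(config: RunConfig, out_dir):
    import pandas as pd

    d = _stage_dir(out_dir, "featurize")
    outputs = []
    for cond in CONDITIONS:
        sim = np.load(_stage_dir(out_dir, "simulate") / f"{cond}.npz")
        traj = featurize.EnsembleTrajectory.from_ca_coordinates(
            sim["coordinates"].astype(float))
        feats = featurize.compute_distance_features(traj)
        path = d / f"{cond}_features.npz"
        np.savez_compressed(path, values=feats.values.astype(np.float32),
                            pair_index=feats.pair_index)
        pd.DataFrame(feats.pair_index, columns=["i", "j"]).to_csv(
            d / f"{cond}_pairs.csv", index=False)
        outputs += [path, d / f"{cond}_pairs.csv"]
    return outputs


def _stage_bvae(config: RunConfig, out_dir):
    import pandas as pd

    d = _stage_dir(out_dir, "bvae")
    outputs = []
    for cond in CONDITIONS:
        feats = np.load(_stage_dir(out_dir, "featurize")
                        / f"{cond}_features.npz")["values"].astype(float)
        rng = np.random.default_rng(config.seed)
        sub = rng.choice(feats.shape[0],
                         size=min(config.bvae_train_frames, feats.shape[0]),
                         replace=False)
        train_x, rec = featurize.minmax_scale(feats[sub])
        arch = bvae.BetaVaeArchitecture.scaled(feats.shape[1])
        cfg = bvae.TrainingConfig(beta=config.bvae_beta,
                                  learning_rate=config.bvae_learning_rate,
                                  epochs=config.bvae_epochs, seed=config.seed)
        model, hist = bvae.train(train_x, arch, cfg)
        emb = model.encode(featurize.minmax_apply(feats, rec, clip=True))
        path = d / f"{cond}_embedding.npz"
        np.savez_compressed(path, coordinates=emb.coordinates,
                            mu=emb.mu, sigma=emb.sigma)
        pd.DataFrame(emb.coordinates, columns=["z1", "z2"]).to_csv(
            d / f"{cond}_embedding.csv", index=False)
        pd.DataFrame({"epoch": np.arange(len(hist.total)),
                      "reconstruction": hist.reconstruction,
                      "kl": hist.kl, "total": hist.total,
                      "val_total": hist.val_total}).to_csv(
            d / f"{cond}_loss.csv", index=False)
        outputs += [path, d / f"{cond}_embedding.csv", d / f"{cond}_loss.csv"]
    return outputs


def _stage_msm(config: RunConfig, out_dir):
    import pandas as pd

    d = _stage_dir(out_dir, "msm")
    outputs = []
    for cond in CONDITIONS:
        emb = np.load(_stage_dir(out_dir, "bvae")
                      / f"{cond}_embedding.npz")["coordinates"]
        sim = np.load(_stage_dir(out_dir, "simulate") / f"{cond}.npz")
        bounds = sim["boundaries"]
        assign = msm.cluster_microstates(emb, config.kmeans_k, config.seed,
                                         trajectory_boundaries=bounds)
        its = msm.implied_timescales(assign, config.lag_grid,
                                     n_processes=config.n_its_processes)
        lag = msm.select_lag(its)
        row = int(np.searchsorted(its.lags, lag))
        n_macro = msm.select_n_macrostates(its.timescales[row])
        model = msm.estimate_transition_matrix(assign, lag, mode="reversible")
        boot = msm.bootstrap_populations(assign.split_labels(), assign.k,
                                         lag, n_macro,
                                         n_iter=config.n_bootstrap,
                                         seed=config.seed)
        mfpt_mat = msm.mfpt_matrix(model, boot.crisp_map, n_macro)
        micro_to_macro = np.full(assign.k, -1, dtype=int)
        micro_to_macro[model.active_set] = boot.crisp_map
        path = d / f"{cond}_msm.npz"
        np.savez_compressed(
            path, microstate_labels=assign.labels,
            transition_matrix=model.transition_matrix,
            stationary=model.stationary, active_set=model.active_set,
            memberships=boot.memberships, crisp_map=boot.crisp_map,
            populations=boot.populations,
            population_std=boot.population_std,
            population_se=boot.population_se, mfpt=mfpt_mat,
            macro_of_frame=micro_to_macro[assign.labels],
            its_lags=its.lags, its_timescales=its.timescales)
        pd.DataFrame({"state": np.arange(n_macro),
                      "population": boot.populations,
                      "std": boot.population_std,
                      "se": boot.population_se}).to_csv(
            d / f"{cond}_populations.csv", index=False)
        edges = [(a, b, 1.0 / mfpt_mat[a, b])
                 for a in range(n_macro) for b in range(n_macro)
                 if a != b and np.isfinite(mfpt_mat[a, b])
                 and mfpt_mat[a, b] > 0]
        pd.DataFrame(edges, columns=["state_i", "state_j", "rate"]).to_csv(
            d / f"{cond}_flux_network.csv", index=False)
        (d / f"{cond}_run.json").write_text(json.dumps(
            {"lag": int(lag), "k": int(assign.k),
             "n_macrostates": int(n_macro), "seed": config.seed,
             "connected_set_size": int(model.active_set.size),
             "discarded_frame_fraction": model.discarded_frame_fraction},
            indent=2))
        outputs += [path, d / f"{cond}_populations.csv",
                    d / f"{cond}_flux_network.csv", d / f"{cond}_run.json"]
    return outputs


def _stage_contacts(config: RunConfig, out_dir):
    d = _stage_dir(out_dir, "contacts")
    outputs = []
    for cond in CONDITIONS:
        sim = np.load(_stage_dir(out_dir, "simulate") / f"{cond}.npz")
        m = np.load(_stage_dir(out_dir, "msm") / f"{cond}_msm.npz")
        traj = featurize.EnsembleTrajectory.from_ca_coordinates(
            sim["coordinates"].astype(float))
        macro = m["macro_of_frame"]
        n_macro = int(m["populations"].size)
        maps = []
        for s in range(n_macro):
            sel = np.nonzero(macro == s)[0]
            maps.append(featurize.compute_contact_map(traj, sel).probabilities)
        path = d / f"{cond}_contact_maps.npz"
        np.savez_compressed(path, maps=np.array(maps))
        outputs.append(path)
    return outputs


def _stage_dcvae(config: RunConfig, out_dir):
    import pandas as pd

    d = _stage_dir(out_dir, "dcvae")
    outputs = []
    for cond in CONDITIONS:
        maps = np.load(_stage_dir(out_dir, "contacts")
                       / f"{cond}_contact_maps.npz")["maps"]
        noisy = fingerprint.add_noise(maps, config.dcvae_noise_factor,
                                      config.dcvae_replicas,
                                      seed=config.seed)
        cfg = fingerprint.DcvaeTrainingConfig(
            epochs=config.dcvae_epochs,
            learning_rate=config.dcvae_learning_rate, seed=config.seed)
        model, _, heldout = fingerprint.train_dcvae(noisy, config=cfg)
        rep = fingerprint.fingerprint_report(model, noisy, heldout)
        pd.DataFrame(rep["per_state"]).to_csv(d / f"{cond}_ssim_psnr.csv",
                                              index=False)
        pd.DataFrame(rep["latent"], columns=["z1", "z2"]).assign(
            state=noisy.state_of).to_csv(d / f"{cond}_latent.csv",
                                         index=False)
        (d / f"{cond}_summary.json").write_text(json.dumps(
            {"ssim_gain": rep["ssim_gain"],
             "silhouette": rep["silhouette"]}, indent=2))
        outputs += [d / f"{cond}_ssim_psnr.csv", d / f"{cond}_latent.csv",
                    d / f"{cond}_summary.json"]
    return outputs


def _stage_entropy(config: RunConfig, out_dir):
    import pandas as pd

    d = _stage_dir(out_dir, "entropy")
    outputs = []
    rng = np.random.default_rng(config.seed)
    for cond in CONDITIONS:
        sim = np.load(_stage_dir(out_dir, "simulate") / f"{cond}.npz")
        m = np.load(_stage_dir(out_dir, "msm") / f"{cond}_msm.npz")
        torsions = sim["torsions"]
        macro = m["macro_of_frame"]
        n_macro = int(m["populations"].size)
        labels = [(i + 1, "phi") for i in range(torsions.shape[1])]
        rows = []
        for s in range(n_macro):
            sel = np.nonzero(macro == s)[0]
            if sel.size > config.entropy_max_frames:
                sel = sel[rng.choice(sel.size, config.entropy_max_frames,
                                     replace=False)]
            dec = mist_total_entropy(TorsionDataset(torsions[sel], labels),
                                     order=2,
                                     k_neighbors=config.k_neighbors)
            rows.append({"state": s, "total_J_per_molK": dec.total,
                         "total_nats": dec.total_nats,
                         "marginal_sum_nats": dec.marginal_sum_nats})
        pd.DataFrame(rows).to_csv(d / f"{cond}_entropy.csv", index=False)
        outputs.append(d / f"{cond}_entropy.csv")
    return outputs


def _stage_report(config: RunConfig, out_dir):
    import pandas as pd

    d = _stage_dir(out_dir, "report")
    report = {"config_hash": config.hash()}
    for cond in CONDITIONS:
        m = np.load(_stage_dir(out_dir, "msm") / f"{cond}_msm.npz")
        ent = pd.read_csv(_stage_dir(out_dir, "entropy")
                          / f"{cond}_entropy.csv")
        dc = json.loads((_stage_dir(out_dir, "dcvae")
                         / f"{cond}_summary.json").read_text())
        pops = m["populations"]
        mfpt_mat = m["mfpt"]
        top = int(np.argmax(pops))
        corr = correlate_entropy_mfpt(
            ent["total_J_per_molK"].to_numpy(), mfpt_mat[:, top], top)
        report[cond] = {
            "n_macrostates": int(pops.size),
            "populations": pops.tolist(),
            "population_std": m["population_std"].tolist(),
            "mfpt_frames": mfpt_mat.tolist(),
            "top_state": top,
            "entropies_J_per_molK": ent["total_J_per_molK"].tolist(),
            "entropy_mfpt_spearman": corr["spearman"],
            "ssim_gain": dc["ssim_gain"],
            "latent_silhouette": dc["silhouette"],
        }
    path = d / "report.json"
    path.write_text(json.dumps(report, indent=2))
    return [path]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "featurize": _stage_featurize,
    "bvae": _stage_bvae,
    "msm": _stage_msm,
    "contacts": _stage_contacts,
    "dcvae": _stage_dcvae,
    "entropy": _stage_entropy,
    "report": _stage_report,
}
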