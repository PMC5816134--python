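"""End-to-end orchestration: validated I/O, staged execution, artifacts.

A run is driven by a JSON config that either points at real trial tables
(naming CSV per language, acoustic CSV, triad CSV) or describes a synthetic
study to generate.  Stages (semspace, namestats, acoustic, triad) can be
toggled; each writes its intermediate artifacts (distance matrices as square
CSV with id headers, weights JSON, sweep tables, Newick cladograms) plus a
versioned machine-readable summary JSON.  Identical config and seeds give
identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
import traceback
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import acoustic as ac
from . import namestats as ns
from . import semspace as ss
from . import synthdata as sd
from . import triad as tr
from .datatypes import (
    AcousticFeatureTable,
    DistanceMatrix,
    ValidationError,
    naming_trials_from_frame,
    naming_trials_to_frame,
    triad_trials_from_frame,
    triad_trials_to_frame,
)

log = logging.getLogger("vocalrep")

SCHEMA_VERSION = 1

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "synthetic": {
        "n_stimuli": 132,
        "n_types": 6,
        "dim": 3,
        "spread": 1.0,
        "separation": 4.0,
        "languages": ["english", "swedish", "russian"],
        "n_participants": 20,
        "triad_participants": 150,
        "triads_per_participant": 42,
    },
    "stages": {"semspace": True, "namestats": True, "acoustic": True, "triad": True},
    "semspace": {"q_grid": [0.0, 0.1, 0.2, 0.3, 0.45, 0.5, 0.7, 0.9], "k": 3},
    "namestats": {"n_iter": 1200, "warmup": 400},
    "acoustic": {"n_starts": 4, "cv_folds": 5},
    "triad": {"d_values": [1, 2, 3], "chains": 2, "warmup": 300, "samples": 300},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = json.load(fh)
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


# ---------------------------------------------------------------------------
# Validation / loading
# ---------------------------------------------------------------------------

def validate_and_load(config: dict) -> dict:
    """Build the validated data bundle from real files or a synthetic spec.

    Returns a dict with keys: naming (language -> list of NamingTrial),
    lexicons (language -> (sound_labels, emotion_labels)), acoustics
    (AcousticFeatureTable), triads (list of TriadTrial), world (optional
    SyntheticWorld).  Schema violations raise one aggregated error.
    """
    has_data = "data" in config
    has_synth = "synthetic" in config
    if not has_data and not has_synth:
        raise ValidationError("config needs either 'data' paths or a 'synthetic' spec")

    if has_data:
        return _load_real(config["data"])
    return _generate_synthetic(config)


def _load_real(data_cfg: dict) -> dict:
    errors: list[str] = []
    naming: dict[str, list] = {}
    lexicons: dict[str, tuple] = {}
    for lang, path in data_cfg.get("naming_csv", {}).items():
        df = pd.read_csv(path)
        for i, row in enumerate(df.itertuples(index=False)):
            c = row.certainty_sound
            if not pd.isna(c) and int(c) not in (1, 2, 3):
                errors.append(f"{path} row {i}: bad certainty_sound {c!r}")
        try:
            naming[lang] = naming_trials_from_frame(df)
        except ValidationError as e:
            errors.append(f"{path}: {e}")
        labels = data_cfg.get("labels", {}).get(lang)
        if labels:
            lexicons[lang] = (tuple(labels["sound"]), tuple(labels["emotion"]))
        elif lang in naming:
            lexicons[lang] = (
                tuple(sorted({s for t in naming[lang] for s in t.sound_names})),
                tuple(sorted({e for t in naming[lang] for e in t.emotion_names})),
            )
    acoustics = None
    if "acoustic_csv" in data_cfg:
        acoustics = AcousticFeatureTable.from_csv(data_cfg["acoustic_csv"])
    triads = []
    if "triad_csv" in data_cfg:
        df = pd.read_csv(data_cfg["triad_csv"])
        for i, row in enumerate(df.itertuples(index=False)):
            items = {row.item1, row.item2, row.item3}
            if len(items) != 3:
                errors.append(f"triad row {i}: duplicate items {sorted(items)}")
            elif not {row.chosen1, row.chosen2} <= set(map(str, items)) | items:
                errors.append(f"triad row {i}: chosen pair outside the triad")
        if not errors:
            triads = triad_trials_from_frame(df)
    if errors:
        raise ValidationError("validation failed:\n" + "\n".join(errors))
    return {"naming": naming, "lexicons": lexicons, "acoustics": acoustics,
            "triads": triads, "world": None}


def _generate_synthetic(config: dict) -> dict:
    sc = config["synthetic"]
    seed = int(config.get("seed", 0))
    world = sd.make_world(
        n_stimuli=sc.get("n_stimuli", 132), n_types=sc.get("n_types", 6),
        dim=sc.get("dim", 3), spread=sc.get("spread", 1.0),
        separation=sc.get("separation", 4.0), seed=seed)
    params = sd.GenParams()
    naming, lexicons = {}, {}
    for li, lang in enumerate(sc.get("languages", ["english"])):
        lex = sd.default_lexicon(world, lang, seed=seed + 100 + li)
        naming[lang] = sd.simulate_naming(
            world, lex, sc.get("n_participants", 20), params, seed=seed + 200 + li)
        lexicons[lang] = (lex.sound_labels, lex.emotion_labels)
    acoustics = sd.simulate_acoustics(world, params, seed=seed + 300)
    triads = sd.simulate_triads(
        world.latent_coords, sc.get("triad_participants", 150),
        sc.get("triads_per_participant", 42), params.triad_temperature,
        seed=seed + 400, stimuli=world.stimuli)
    return {"naming": naming, "lexicons": lexicons, "acoustics": acoustics,
            "triads": triads, "world": world}


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_semspace(bundle, cfg, out: Path) -> dict:
    qcfg = cfg["semspace"]
    result: dict[str, Any] = {"languages": {}}
    matrices = []
    for lang, trials in bundle["naming"].items():
        sound_labels, _ = bundle["lexicons"][lang]
        prof = ss.name_profile_matrix(trials, sound_labels, "sound")
        D = ss.cooccurrence_distances(prof)
        D.to_csv(out / f"distances_sound_{lang}.csv")
        modal = ss.modal_clusters(trials, sound_labels, "sound")
        modal.to_csv(out / f"modal_clusters_{lang}.csv")
        ref = pd.Categorical(modal["modal_label"]).codes
        sweep = ss.q_sweep(D, ref, qcfg["q_grid"])
        sweep.to_csv(out / f"q_sweep_{lang}.csv", index=False)
        best = sweep.loc[sweep["ari"].idxmax()]
        emb = ss.embed_space(D, k=qcfg.get("k", 3))
        pd.DataFrame(emb.coords, index=list(emb.stimuli)).to_csv(
            out / f"embedding_{lang}.csv", index_label="stimulus")
        cert = _mean_certainty(trials)
        cert = cert.reindex(list(emb.stimuli)).fillna(cert.mean())
        cents = ss.weighted_centroids(
            emb, modal.loc[list(emb.stimuli), "modal_label"].to_numpy(),
            cert.to_numpy(), modal.loc[list(emb.stimuli), "modal_proportion"].to_numpy())
        cents.to_csv(out / f"centroids_{lang}.csv")
        cd = np.sqrt(((cents.to_numpy()[:, None] - cents.to_numpy()[None]) ** 2).sum(-1))
        newick = ss.cladogram_newick(
            DistanceMatrix(list(cents.index), cd)) if len(cents) >= 2 else ";"
        (out / f"cladogram_{lang}.nwk").write_text(newick + "\n")
        matrices.append(D)
        result["languages"][lang] = {
            "n_stimuli": D.n,
            "explained_variance_3": float(emb.explained_variance[:3].sum()),
            "best_q": float(best["q"]),
            "best_q_ari": float(best["ari"]),
            "best_q_n_clusters": int(best["n_clusters"]),
        }
    avg = ss.average_distance_matrices(matrices)
    avg.to_csv(out / "distances_sound_averaged.csv")
    result["averaged_matrix"] = "distances_sound_averaged.csv"
    return result


def _mean_certainty(trials) -> pd.Series:
    rows = [(t.stimulus, t.certainty_sound) for t in trials
            if t.certainty_sound is not None]
    df = pd.DataFrame(rows, columns=["stimulus", "c"])
    return df.groupby("stimulus")["c"].mean()


def _stage_namestats(bundle, cfg, out: Path, seed: int) -> dict:
    ncfg = cfg["namestats"]
    result: dict[str, Any] = {"languages": {}}
    all_trials = [t for ts in bundle["naming"].values() for t in ts]
    for lang, trials in bundle["naming"].items():
        s_labels, e_labels = bundle["lexicons"][lang]
        ent_s = ns.stimulus_name_entropies(trials, s_labels, "sound")
        ent_e = ns.stimulus_name_entropies(trials, e_labels, "emotion")
        common = ent_s.index.intersection(ent_e.index)
        contrast = ns.entropy_contrast(ent_s[common], ent_e[common], seed=seed)
        tab = ns.sound_emotion_contingency(trials)
        tab.to_frame(clustered=True).to_csv(out / f"contingency_{lang}.csv")
        rf = ns.emotion_from_name_accuracy(trials, seed=seed)
        result["languages"][lang] = {
            "entropy_sound_mean": float(ent_s.mean()),
            "entropy_emotion_mean": float(ent_e.mean()),
            "entropy_difference": contrast.fixed_effects[
                "difference_emotion_minus_sound"],
            "chi2": tab.chi2, "chi2_df": tab.df,
            "emotion_from_name_accuracy": rf["accuracy"],
        }
    rt = ns.fit_rt_model(all_trials, n_iter=ncfg["n_iter"],
                         warmup=ncfg["warmup"], seed=seed)
    order = ns.order_preference(all_trials, seed=seed)
    cert = ns.fit_certainty_model(all_trials, seed=seed)
    result["rt_contrast"] = rt.fixed_effects["kind_emotion_minus_sound"]
    result["rt_ms_difference"] = rt.fixed_effects["ms_difference_emotion_minus_sound"]
    result["order_odds_ratio"] = order.fixed_effects["odds_ratio"]
    result["certainty_contrast"] = cert.fixed_effects["kind_sound_minus_emotion"]
    with open(out / "namestats_posteriors.json", "w") as fh:
        json.dump({"rt": rt.fixed_effects, "order": order.fixed_effects,
                   "certainty": cert.fixed_effects}, fh, indent=2)
    return result


def _stage_acoustic(bundle, cfg, out: Path, seed: int) -> dict:
    acfg = cfg["acoustic"]
    table = ac.standardize_features(bundle["acoustics"])
    ref = DistanceMatrix.from_csv(out / "distances_sound_averaged.csv")
    ref = ref.reorder(table.stimuli)
    learner = ac.optimize_weights(table, ref, n_starts=acfg["n_starts"], seed=seed)
    learner.weight_series().to_json(out / "acoustic_weights.json")
    D = ac.weighted_distance_matrix(table, learner.weights_)
    D.to_csv(out / "distances_acoustic.csv")
    weighted = AcousticFeatureTable(table.stimuli, table.features,
                                    table.values * learner.weights_)
    emb = ac.acoustic_pca(weighted, k=2)
    pd.DataFrame(emb.pc_scores, index=list(emb.stimuli),
                 columns=["PC1", "PC2"]).to_csv(out / "acoustic_pcs.csv",
                                                index_label="stimulus")
    result: dict[str, Any] = {
        "achieved_correlation": learner.achieved_correlation_,
        "pc2_explained_variance": float(emb.explained_variance.sum()),
        "languages": {},
    }
    for lang, trials in bundle["naming"].items():
        s_labels, _ = bundle["lexicons"][lang]
        modal = ss.modal_clusters(trials, s_labels, "sound")
        labels = modal.reindex(list(table.stimuli))["modal_label"].dropna()
        feats = AcousticFeatureTable(
            tuple(labels.index), table.features,
            table.to_frame().loc[labels.index].to_numpy())
        dm = ac.multinomial_decision_map(
            emb.pc_scores[[table.stimuli.index(s) for s in labels.index]],
            labels.to_numpy())
        full = ac.calltype_classifier_accuracy(
            feats, labels.to_numpy(), "full", acfg["cv_folds"], seed)
        pooled = ac.calltype_classifier_accuracy(
            feats, labels.to_numpy(), "major7", acfg["cv_folds"], seed)
        result["languages"][lang] = {
            "decision_map_train_accuracy": dm["train_accuracy"],
            "rf_accuracy_full": full["accuracy"],
            "rf_accuracy_major7": pooled["accuracy"],
            "majority_baseline_major7": pooled["majority_baseline"],
        }
    return result


def _stage_triad(bundle, cfg, out: Path, seed: int) -> dict:
    tcfg = cfg["triad"]
    refs = {}
    avg_path = out / "distances_sound_averaged.csv"
    if avg_path.exists():
        refs["sound_names"] = DistanceMatrix.from_csv(avg_path)
    config = tr.EmbeddingConfig(
        d=3, chains=tcfg["chains"], warmup=tcfg["warmup"],
        samples=tcfg["samples"], seed=seed)
    sweep = tr.dimension_sweep(bundle["triads"], tcfg["d_values"], config,
                               reference_matrices=refs or None)
    sweep.to_csv(out / "triad_dimension_sweep.csv", index=False)
    best_d = int(sweep.loc[sweep["waic"].idxmin(), "d"])
    best_cfg = tr.EmbeddingConfig(**{**config.__dict__, "d": best_d})
    post = tr.fit_embedding(bundle["triads"], best_cfg)
    post.mean_distance_matrix.to_csv(out / "distances_triad.csv")
    result = {"best_d": best_d,
              "waic_by_d": dict(zip(sweep["d"].astype(int).tolist(),
                                    sweep["waic"].tolist())),
              "diagnostics": post.diagnostics}
    if refs:
        from .acoustic import matrix_correlation
        ref = refs["sound_names"].reorder(post.stimuli)
        r, _ = matrix_correlation(post.mean_distance_matrix, ref)
        result["r_vs_sound_names"] = r
    return result


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------

_STAGES = {
    "semspace": _stage_semspace,
    "namestats": _stage_namestats,
    "acoustic": _stage_acoustic,
    "triad": _stage_triad,
}

# acoustic needs the averaged semantic matrix written by semspace
_DEPENDS = {"acoustic": ("semspace",)}


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the enabled stages; a failed stage halts its dependents but
    independent stages still run.  Returns the summary dict (also written to
    ``summary.json``); a 'failed' key lists failed stages."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    t0 = time.time()
    bundle = validate_and_load(config)
    if bundle["world"] is not None:
        (out / "world.json").write_text(bundle["world"].to_json())
        for lang, trials in bundle["naming"].items():
            naming_trials_to_frame(trials).to_csv(
                out / f"naming_trials_{lang}.csv", index=False)
        bundle["acoustics"].to_csv(out / "acoustic_features.csv")
        triad_trials_to_frame(bundle["triads"]).to_csv(
            out / "triad_trials.csv", index=False)

    summary: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "stages": {},
        "timings_s": {},
        "failed": [],
    }
    toggles = config.get("stages", {})
    for name, fn in _STAGES.items():
        if not toggles.get(name, True):
            continue
        if any(dep in summary["failed"] or not toggles.get(dep, True)
               for dep in _DEPENDS.get(name, ())):
            log.warning("skipping stage %s: unmet dependency", name)
            summary["failed"].append(name)
            continue
        ts = time.time()
        log.info("running stage %s (seed %d)", name, seed)
        try:
            if name == "semspace":
                summary["stages"][name] = fn(bundle, config, out)
            else:
                summary["stages"][name] = fn(bundle, config, out, seed)
        except Exception:
            log.error("stage %s failed:\n%s", name, traceback.format_exc())
            summary["failed"].append(name)
        summary["timings_s"][name] = round(time.time() - ts, 3)
    summary["total_s"] = round(time.time() - t0, 3)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
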