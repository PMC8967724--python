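"""End-to-end orchestration of the analysis stages.

A run executes selected stages in dependency order against one output
directory: ``simulate`` writes the synthetic scene, downstream stages read
the files the previous stages wrote, and a manifest records the seed, stage
order and a sha256 digest of every output file so reruns can be verified
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity as act
from . import barcode, bipartite, brainstem, endings, registration, trajectory
from . import io as vio
from . import synthetic

STAGE_ORDER = (
    "simulate",
    "classify",
    "trajectory",
    "activity",
    "register",
    "endings",
    "correlate",
    "brainstem",
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGE_ORDER),
    "thresholds": {
        "upb_threshold": 0.8,
        "min_genes": 500,
        "max_genes": 8000,
        "max_mito": 0.10,
        "response_threshold": 1.0,
        "damage_factor": 5.0,
    },
    "synthetic": {},  # SynthConfig overrides
    "true_assignment": {"J2": "cIMA", "J4": "cIMA", "I7": "cIMA",
                        "I2": "IGLE", "I4": "IGLE", "I5": "IGLE", "I6": "IGLE"},
    "inputs": {},  # optional pre-existing input files, path strings
}

__all__ = ["load_config", "run_pipeline", "DEFAULT_CONFIG", "STAGE_ORDER"]


def load_config(path: str | Path) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    user = yaml.safe_load(Path(path).read_text()) or {}
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k] = {**cfg[k], **v}
        else:
            cfg[k] = v
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_simulate(cfg: dict, out: Path) -> None:
    sc = synthetic.SynthConfig(seed=cfg["seed"], **cfg.get("synthetic", {}))
    cells, truth_cells = synthetic.generate_cell_table(sc)
    vio.write_cell_table(cells, out / "cells")
    vio.write_ground_truth(truth_cells, out / "cells" / "ground_truth.json")
    traces, truth_traces = synthetic.generate_trace_set(sc)
    vio.write_trace_set(traces, out / "traces")
    vio.write_ground_truth(truth_traces, out / "traces" / "ground_truth.json")
    scene, truth_scene = synthetic.generate_landmark_scene(
        ((25.0, 10.0, 5.0), (40.0, -15.0, 8.0)), seed=cfg["seed"]
    )
    vio.write_landmark_scene(scene, out / "landmarks")
    vio.write_ground_truth(truth_scene, out / "landmarks" / "ground_truth.json")
    ending_df, labels, truth_end = synthetic.generate_ending_tables(
        cfg["true_assignment"], seed=cfg["seed"]
    )
    (out / "endings").mkdir(parents=True, exist_ok=True)
    ending_df.to_csv(out / "endings" / "endings.csv", index=False)
    labels.to_csv(out / "endings" / "cluster_labels.csv")
    vio.write_ground_truth(truth_end, out / "endings" / "ground_truth.json")
    innerv = synthetic.generate_innervation_table(seed=cfg["seed"])
    (out / "brainstem").mkdir(parents=True, exist_ok=True)
    innerv.to_csv(out / "brainstem" / "innervation.csv", index=False)


def _stage_classify(cfg: dict, out: Path) -> None:
    th = cfg["thresholds"]
    cells = vio.read_cell_table(out / "cells")
    kept, removed = barcode.qc_filter(
        cells, th["min_genes"], th["max_genes"], th["max_mito"]
    )
    damaged = barcode.flag_damaged(kept, factor=th["damage_factor"])
    kept = kept.loc[~kept["cluster"].map(damaged).fillna(False)]
    labelled = barcode.classify_upb_table(kept, th["upb_threshold"])
    corr = barcode.organ_correlation_matrix(labelled)
    (out / "classify").mkdir(parents=True, exist_ok=True)
    labelled.to_csv(out / "classify" / "labelled_cells.tsv", sep="\t", index=False)
    corr.to_csv(out / "classify" / "organ_correlation.tsv", sep="\t")
    (out / "classify" / "qc_removed.json").write_text(json.dumps(removed, indent=2))


def _stage_trajectory(cfg: dict, out: Path) -> None:
    cells = pd.read_csv(out / "classify" / "labelled_cells.tsv", sep="\t")
    cent = cells.groupby("cluster")[["emb_x", "emb_y"]].mean()
    cent = cent.sort_values("emb_x")  # organ axis runs along x
    path = trajectory.fit_principal_path(cent.to_numpy())
    singles = cells.loc[cells["upb_category"] == "single"].copy()
    organs = sorted(singles["upb_organs"].unique())
    scores = [
        trajectory.trajectory_score(p, path)
        for p in singles[["emb_x", "emb_y"]].to_numpy()
    ]
    singles["trajectory_score"] = scores
    rows = []
    for cluster in cent.index:
        weights = {}
        for organ in organs:
            try:
                weights[organ] = barcode.cluster_upb_percentage(cells, organ, cluster)
            except ValueError:
                continue
        if not weights or sum(weights.values()) == 0:
            continue
        score = trajectory.organ_position_score(weights)
        mean_traj = singles.loc[singles["cluster"] == cluster, "trajectory_score"].mean()
        rows.append({"cluster": cluster, "organ_position_score": score,
                     "mean_trajectory_score": mean_traj})
    table = pd.DataFrame(rows).dropna()
    slope, intercept, r2 = trajectory.score_position_regression(
        table["mean_trajectory_score"], table["organ_position_score"]
    )
    (out / "trajectory").mkdir(parents=True, exist_ok=True)
    singles[["cell_id", "cluster", "upb_organs", "trajectory_score"]].to_csv(
        out / "trajectory" / "cell_scores.tsv", sep="\t", index=False
    )
    table.to_csv(out / "trajectory" / "cluster_scores.tsv", sep="\t", index=False)
    (out / "trajectory" / "regression.json").write_text(
        json.dumps({"slope": slope, "intercept": intercept, "r_squared": r2}, indent=2)
    )


def _stage_activity(cfg: dict, out: Path) -> None:
    th = cfg["thresholds"]
    traces = vio.read_trace_set(out / "traces")
    rows = []
    for i, cid in enumerate(traces.cell_ids):
        row: dict = {"cell_id": cid}
        for w in traces.stimuli:
            dff = act.delta_f_over_f(traces.f[i], w.onset)
            r = act.activation_metrics(dff, w, threshold=th["response_threshold"])
            row[f"{w.name}_responsive"] = r.responsive
            row[f"{w.name}_peak"] = r.peak
            row[f"{w.name}_duration"] = r.activation_duration
        row["archetype"] = act.classify_archetype(traces.f[i], traces.stimuli)
        rows.append(row)
    (out / "activity").mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "activity" / "responses.csv", index=False)


def _stage_register(cfg: dict, out: Path) -> None:
    scene = vio.read_landmark_scene(out / "landmarks")
    iv = scene.invivo
    sec = scene.sections
    iv_lm = iv.loc[iv["landmark"], ["x", "y", "z"]].to_numpy()
    sec_lm = sec.loc[sec["landmark"], ["x", "y", "z"]].to_numpy()
    pairs = registration.match_landmarks(iv_lm, sec_lm, scene.transform)
    src = iv_lm[[i for i, _ in pairs]]
    dst = sec_lm[[j for _, j in pairs]]
    tf, residual = registration.estimate_transform(src, dst)
    outcome = registration.register_nonlandmark(
        iv.loc[~iv["landmark"], ["x", "y", "z"]].to_numpy(),
        sec.loc[~sec["landmark"], ["x", "y", "z"]].to_numpy(),
        tf,
    )
    rate = registration.registration_rate(outcome)
    (out / "register").mkdir(parents=True, exist_ok=True)
    vio.write_transform(tf, out / "register" / "transform.json")
    pd.DataFrame(
        {
            "cell_id": iv.loc[~iv["landmark"], "cell_id"].to_numpy(),
            "status": outcome.status,
            "match_index": outcome.matches,
        }
    ).to_csv(out / "register" / "outcome.csv", index=False)
    (out / "register" / "summary.json").write_text(
        json.dumps({"registration_rate": rate, "landmark_residual": residual}, indent=2)
    )


def _stage_endings(cfg: dict, out: Path) -> None:
    ending_df = vio.read_ending_table(out / "endings" / "endings.csv")
    labels = pd.read_csv(out / "endings" / "cluster_labels.csv", index_col="cluster")
    intensity = endings.innervation_intensity(ending_df)
    af = endings.anatomical_fold_change(intensity)
    free = sorted(cfg["true_assignment"])
    fixed = {c: t for c, t in synthetic.DEFAULT_FIXED_MAP.items() if c in labels.index}
    best, var = endings.best_assignment(af, labels, free, fixed)
    (out / "endings" / "best_assignment.json").write_text(
        json.dumps({"assignment": best, "variance": var}, indent=2)
    )


def _stage_correlate(cfg: dict, out: Path) -> None:
    # link each registered archetype to the subpopulation-free characteristic
    # pair available in the synthetic scene: ending type vs tissue layer
    ending_df = pd.read_csv(out / "endings" / "endings.csv")
    edges = frozenset(
        (str(r["ending_type"]), str(r["layer"])) for _, r in ending_df.iterrows()
    )
    cmap = bipartite.ConnectionMap(
        tuple(sorted(ending_df["ending_type"].unique())),
        tuple(sorted(ending_df["layer"].unique())),
        edges,
    )
    pruned = bipartite.prune_unconnected(cmap)
    result = {
        "C": bipartite.normalized_connections(pruned),
        "v1": bipartite.connection_variance(pruned, 1),
        "v2": bipartite.connection_variance(pruned, 2),
        "index": bipartite.correlation_index(pruned, prune=False),
    }
    (out / "correlate").mkdir(parents=True, exist_ok=True)
    (out / "correlate" / "index.json").write_text(json.dumps(result, indent=2))


def _stage_brainstem(cfg: dict, out: Path) -> None:
    table = pd.read_csv(out / "brainstem" / "innervation.csv")
    pi = brainstem.pi_matrix(table)
    var = brainstem.variance_matrix(pi)
    newick = brainstem.linkage_tree(var)
    pi.to_csv(out / "brainstem" / "pi_matrix.csv")
    var.to_csv(out / "brainstem" / "variance_matrix.csv")
    (out / "brainstem" / "tree.nwk").write_text(newick + "\n")


_STAGES = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "trajectory": _stage_trajectory,
    "activity": _stage_activity,
    "register": _stage_register,
    "endings": _stage_endings,
    "correlate": _stage_correlate,
    "brainstem": _stage_brainstem,
}


def run_pipeline(config: dict | None, out_dir: str | Path) -> dict:
    """Run the selected stages in dependency order; returns the manifest.

    Fails before any stage runs if the config references absent input
    files.  The manifest (also written to ``manifest.json``) lists the
    seed, stage order and sha256 digest of every file produced.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    for key, path in (cfg.get("inputs") or {}).items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input {key!r} references absent file {path}")
    stages = [s for s in STAGE_ORDER if s in cfg["stages"]]
    unknown = set(cfg["stages"]) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for stage in stages:
        _STAGES[stage](cfg, out)
    manifest = {
        "seed": cfg["seed"],
        "stages": stages,
        "outputs": {
            str(p.relative_to(out)): _digest(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
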