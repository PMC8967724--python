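"""Readers and writers for the pipeline's text-based formats.

Cell tables round-trip through a matrix-market triplet file (cells x
features, holding the barcode and marker expression columns) plus a
tab-delimited metadata table; traces, landmarks, ending and innervation
tables are plain delimited text; ground truth and transforms are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .activity import StimulusWindow
from .barcode import GENE_PREFIX, UPB_PREFIX
from .registration import RigidTransform
from .synthetic import GroundTruth, LandmarkScene, TraceSet

__all__ = [
    "write_cell_table",
    "read_cell_table",
    "write_trace_set",
    "read_trace_set",
    "write_landmark_scene",
    "read_landmark_scene",
    "write_ground_truth",
    "read_ground_truth",
    "write_transform",
    "read_transform",
]

_META_COLS = ("cell_id", "cluster", "emb_x", "emb_y", "n_genes", "mito_fraction")


def read_ending_table(path: str | Path) -> pd.DataFrame:
    """Delimited ending table; numeric region labels come back as ints."""
    df = pd.read_csv(path)
    df["region"] = df["region"].map(lambda r: int(r) if str(r).isdigit() else r)
    return df


def write_cell_table(cells: pd.DataFrame, outdir: str | Path) -> None:
    """Write matrix.mtx + features.tsv + metadata.tsv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr_cols = [c for c in cells.columns if c.startswith((UPB_PREFIX, GENE_PREFIX))]
    mat = sparse.csr_matrix(cells[expr_cols].to_numpy())
    spio.mmwrite(outdir / "matrix.mtx", mat)
    pd.Series(expr_cols).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    cells[list(_META_COLS)].to_csv(outdir / "metadata.tsv", sep="\t", index=False)


def read_cell_table(outdir: str | Path) -> pd.DataFrame:
    outdir = Path(outdir)
    mat = spio.mmread(outdir / "matrix.mtx").toarray()
    features = pd.read_csv(outdir / "features.tsv", sep="\t", header=None)[0].tolist()
    meta = pd.read_csv(outdir / "metadata.tsv", sep="\t")
    expr = pd.DataFrame(mat, columns=features, index=meta.index)
    return pd.concat([meta, expr], axis=1)


def write_trace_set(traces: TraceSet, outdir: str | Path) -> None:
    """Write traces.csv (cells x frames) + stimuli.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(traces.f, index=list(traces.cell_ids))
    df.index.name = "cell_id"
    df.to_csv(outdir / "traces.csv")
    meta = {
        "frame_interval": traces.frame_interval,
        "stimuli": [
            {"name": w.name, "onset": w.onset, "start": w.start, "stop": w.stop}
            for w in traces.stimuli
        ],
    }
    (outdir / "stimuli.yaml").write_text(yaml.safe_dump(meta))


def read_trace_set(outdir: str | Path) -> TraceSet:
    outdir = Path(outdir)
    df = pd.read_csv(outdir / "traces.csv", index_col="cell_id")
    meta = yaml.safe_load((outdir / "stimuli.yaml").read_text())
    stimuli = tuple(
        StimulusWindow(s["name"], s["onset"], s["start"], s["stop"])
        for s in meta["stimuli"]
    )
    return TraceSet(
        f=df.to_numpy(),
        stimuli=stimuli,
        cell_ids=tuple(df.index),
        frame_interval=meta["frame_interval"],
    )


def write_landmark_scene(scene: LandmarkScene, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scene.invivo.to_csv(outdir / "invivo.csv", index=False)
    scene.sections.to_csv(outdir / "sections.csv", index=False)
    write_transform(scene.transform, outdir / "true_transform.json")


def read_landmark_scene(outdir: str | Path) -> LandmarkScene:
    outdir = Path(outdir)
    return LandmarkScene(
        invivo=pd.read_csv(outdir / "invivo.csv"),
        sections=pd.read_csv(outdir / "sections.csv"),
        section_thickness=10.0,
        transform=read_transform(outdir / "true_transform.json"),
    )


def write_transform(tf: RigidTransform, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "rotation": tf.rotation.tolist(),
                "translation": tf.translation.tolist(),
                "scale": tf.scale,
            },
            indent=2,
        )
    )


def read_transform(path: str | Path) -> RigidTransform:
    d = json.loads(Path(path).read_text())
    return RigidTransform(np.array(d["rotation"]), np.array(d["translation"]), d["scale"])


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Structured JSON sidecar with every populated ground-truth axis."""
    d = {
        "organ_labels": {k: list(v) for k, v in truth.organ_labels.items()},
        "damage_cells": list(truth.damage_cells),
        "cluster_organ": truth.cluster_organ,
        "cluster_layer": truth.cluster_layer,
        "archetypes": {k: str(v) for k, v in truth.archetypes.items()},
        "correspondence": truth.correspondence,
        "assignment": truth.assignment,
        "transform": None
        if truth.transform is None
        else {
            "rotation": truth.transform.rotation.tolist(),
            "translation": truth.transform.translation.tolist(),
            "scale": truth.transform.scale,
        },
    }
    Path(path).write_text(json.dumps(d, indent=2))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    tf = d.get("transform")
    return GroundTruth(
        organ_labels={k: tuple(v) for k, v in d["organ_labels"].items()},
        damage_cells=tuple(d["damage_cells"]),
        cluster_organ=d["cluster_organ"],
        cluster_layer={k: int(v) for k, v in d["cluster_layer"].items()},
        archetypes=d["archetypes"],
        correspondence=d["correspondence"],
        assignment=d["assignment"],
        transform=None
        if tf is None
        else RigidTransform(np.array(tf["rotation"]), np.array(tf["translation"]), tf["scale"]),
    )
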