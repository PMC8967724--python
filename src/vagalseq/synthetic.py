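"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the structure of a multiplexed projection-barcode
study of vagal sensory neurons: barcode expression that crosses a detection
threshold for a cell's true target organ(s), dual labels concentrated on
physically adjacent organ pairs, a damage-marker-high cluster, cluster
centroids laid out along two orthogonal latent embedding axes (organ
position and tissue layer), archetypal calcium-response kinetics, rigid
landmark scenes and ending/label tables consistent with a chosen
cluster -> ending-type assignment.  All randomness flows from one seed via
spawned generators, so a fixed seed gives bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .activity import StimulusWindow, intestine_stretch_window, stretch_window
from .barcode import GENE_PREFIX, UPB_PREFIX, UPB_THRESHOLD
from .organs import ENDING_TYPES, ORGAN_POSITIONS, STOMACH_REGIONS
from .registration import RigidTransform

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "TraceSet",
    "LandmarkScene",
    "generate_cell_table",
    "generate_trace_set",
    "generate_landmark_scene",
    "generate_ending_tables",
    "DEFAULT_ADJACENCY",
    "DEFAULT_AF_PROFILES",
    "DEFAULT_FIXED_MAP",
]

#: Dual-label propensity for physically adjacent organ pairs (arbitrary
#: weights in [0, 1]; zero for non-adjacent pairs).
DEFAULT_ADJACENCY: dict[frozenset[str], float] = {
    frozenset({"oesophagus", "stomach"}): 0.35,
    frozenset({"stomach", "duodenum"}): 0.35,
    frozenset({"lung", "heart"}): 0.30,
    frozenset({"stomach", "pancreas"}): 0.20,
    frozenset({"duodenum", "pancreas"}): 0.20,
    frozenset({"duodenum", "colon"}): 0.15,
    frozenset({"oesophagus", "heart"}): 0.10,
}

ARCHETYPES = ("sustained", "transient", "polymodal", "non_responder")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic scene.

    Organ positions default to the measured rostro-caudal positions;
    ``dual_rate`` matches the observed share of dual-barcode cells (~16%).
    Barcode expression is generated on the processed (post-normalisation)
    scale that the 0.8 detection threshold applies to.
    """

    n_cells: int = 3000
    n_clusters: int = 12  # includes one damage cluster
    organs: tuple[tuple[str, float], ...] = tuple(ORGAN_POSITIONS.items())
    adjacency: Mapping[frozenset[str], float] = field(
        default_factory=lambda: dict(DEFAULT_ADJACENCY)
    )
    dual_rate: float = 0.16
    upb_noise_sd: float = 0.1
    damage_fraction: float = 0.05
    contaminant_fraction: float = 0.05
    emb_noise_sd: float = 0.3
    n_layers: int = 3
    # calcium-trace scene
    n_trace_cells: int = 200
    n_frames: int = 200
    trace_noise_sd: float = 0.05
    response_amplitude: float = 2.0
    baseline_f: float = 100.0
    archetype_probs: tuple[float, float, float, float] = (0.3, 0.3, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if not self.organs:
            raise ValueError("organ list is empty")
        for name, pos in self.organs:
            if not 0.0 <= pos <= 1.0:
                raise ValueError(f"organ {name!r} position {pos} outside [0, 1]")
        names = {n for n, _ in self.organs}
        for pair, w in self.adjacency.items():
            if len(pair) != 2 or not pair <= names:
                raise ValueError(f"bad adjacency pair {set(pair)}")
            if not 0.0 <= w <= 1.0:
                raise ValueError("adjacency weights must be in [0, 1]")
        for frac in (self.dual_rate, self.damage_fraction, self.contaminant_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if abs(sum(self.archetype_probs) - 1.0) > 1e-9:
            raise ValueError("archetype probabilities must sum to 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one sub-scene, derived from the seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


@dataclass
class GroundTruth:
    """Generator-side truth for downstream recovery checks."""

    organ_labels: dict[str, tuple[str, ...]] = field(default_factory=dict)
    damage_cells: tuple[str, ...] = ()
    cluster_organ: dict[str, str] = field(default_factory=dict)
    cluster_layer: dict[str, int] = field(default_factory=dict)
    archetypes: dict[str, str] = field(default_factory=dict)
    transform: RigidTransform | None = None
    correspondence: dict[str, str] = field(default_factory=dict)
    assignment: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class TraceSet:
    """Raw fluorescence traces with stimulus annotations."""

    f: np.ndarray  # (cells, frames)
    stimuli: tuple[StimulusWindow, ...]
    cell_ids: tuple[str, ...]
    frame_interval: float = 1.72


@dataclass(frozen=True)
class LandmarkScene:
    """Paired in vivo 3-D and sectioned coordinates with known truth."""

    invivo: pd.DataFrame  # cell_id, x, y, z, landmark
    sections: pd.DataFrame  # cell_id, x, y, z, section, landmark
    section_thickness: float
    transform: RigidTransform


# ---------------------------------------------------------------------------
# cell table


def generate_cell_table(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-cell barcode/marker table with embedding, QC fields and truth.

    True-organ barcodes land strictly above the detection threshold
    (threshold + folded normal), all others strictly below it up to noise;
    dual labels are drawn with probability ``dual_rate`` and partner organs
    proportional to adjacency; a ``damage_fraction`` of cells forms a
    distinct injury-marker-high cluster; cluster centroids span an organ
    axis (x, ordered by organ position) and a layer axis (y).
    """
    rng = config.rng(0)
    organs = [n for n, _ in config.organs]
    positions = dict(config.organs)
    order = sorted(organs, key=lambda o: positions[o])

    n_regular = config.n_clusters - 1
    if n_regular < 1:
        raise ValueError("need at least 2 clusters (one damage, one regular)")
    clusters = [f"C{i:02d}" for i in range(n_regular)]
    cluster_organ = {c: order[i % len(order)] for i, c in enumerate(clusters)}
    cluster_layer = {c: (i // len(order)) % config.n_layers for i, c in enumerate(clusters)}

    n = config.n_cells
    cell_ids = [f"cell_{i:05d}" for i in range(n)]
    n_damage = int(round(config.damage_fraction * n))
    damage = np.zeros(n, dtype=bool)
    damage[rng.choice(n, size=n_damage, replace=False)] = True

    cluster_col = np.empty(n, dtype=object)
    cluster_col[damage] = "E1"
    cluster_col[~damage] = rng.choice(clusters, size=n - n_damage)

    truth = GroundTruth(cluster_organ=cluster_organ, cluster_layer=cluster_layer)
    truth.damage_cells = tuple(np.array(cell_ids)[damage])

    # true organ labels (single or adjacency-weighted dual); damage cells none
    labels: list[tuple[str, ...]] = []
    for i in range(n):
        if damage[i]:
            labels.append(())
            continue
        organ = cluster_organ[cluster_col[i]]
        lab = (organ,)
        if rng.random() < config.dual_rate:
            weights = np.array(
                [config.adjacency.get(frozenset({organ, o}), 0.0) for o in organs]
            )
            if weights.sum() > 0:
                partner = rng.choice(organs, p=weights / weights.sum())
                lab = tuple(sorted({organ, partner}))
        labels.append(lab)
    truth.organ_labels = dict(zip(cell_ids, labels))

    # barcode expression: positives strictly above threshold, negatives below
    sd = config.upb_noise_sd
    upb = {}
    for organ in organs:
        pos_mask = np.array([organ in lab for lab in labels])
        vals = np.clip(rng.normal(0.1, sd, size=n), 0.0, None)
        vals[pos_mask] = UPB_THRESHOLD + np.abs(rng.normal(0.7, sd, size=int(pos_mask.sum())))
        upb[UPB_PREFIX + organ] = vals

    # injury markers high only in the damage cluster
    markers = {}
    for m in ("Sprr1a", "Ecel1"):
        vals = np.clip(rng.normal(0.1, 0.05, size=n), 0.0, None)
        vals[damage] = 4.0 + np.abs(rng.normal(0.0, 0.3, size=n_damage))
        markers[GENE_PREFIX + m] = vals

    # embedding: organ axis (x) linear in organ position, layer axis (y)
    cx = {c: positions[cluster_organ[c]] * 10.0 for c in clusters}
    cy = {c: cluster_layer[c] * 2.0 for c in clusters}
    cx["E1"], cy["E1"] = -3.0, -3.0
    emb = np.array([[cx[c], cy[c]] for c in cluster_col])
    emb += rng.normal(0.0, config.emb_noise_sd, size=emb.shape)

    # QC metrics with a configurable contaminant tail
    n_genes = np.round(np.clip(rng.normal(3500, 800, size=n), 600, 7900)).astype(int)
    mito = np.clip(rng.normal(0.04, 0.02, size=n), 0.0, 0.099)
    n_bad = int(round(config.contaminant_fraction * n))
    bad = rng.choice(n, size=n_bad, replace=False)
    for i in bad:
        mode = rng.integers(3)
        if mode == 0:
            n_genes[i] = int(rng.integers(50, 500))
        elif mode == 1:
            n_genes[i] = int(rng.integers(8000, 12000))
        else:
            mito[i] = rng.uniform(0.10, 0.40)

    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "cluster": cluster_col,
            "emb_x": emb[:, 0],
            "emb_y": emb[:, 1],
            "n_genes": n_genes,
            "mito_fraction": mito,
            **upb,
            **markers,
        }
    )
    return cells, truth


# ---------------------------------------------------------------------------
# calcium traces


def _dff_signal(archetype: str, stimuli: Sequence[StimulusWindow],
                n_frames: int, amp: float) -> np.ndarray:
    sig = np.zeros(n_frames)

    def pulse(onset: int, rise: int, hold: int, decay: int) -> None:
        t = onset - rise
        for k in range(rise):
            sig[t + k] = max(sig[t + k], amp * k / rise)
        for k in range(hold + 1):
            sig[onset + k] = amp
        for k in range(1, decay + 1):
            f = onset + hold + k
            if f < n_frames:
                sig[f] = max(sig[f], amp * (1 - k / decay))

    s1, s2 = stimuli[0], stimuli[1]
    if archetype == "sustained":
        pulse(s1.onset, rise=3, hold=s1.stop - 1 - s1.onset, decay=10)
    elif archetype == "transient":
        pulse(s1.onset, rise=2, hold=1, decay=5)
    elif archetype == "polymodal":
        pulse(s1.onset, rise=2, hold=1, decay=5)
        pulse(s2.onset + 2, rise=2, hold=1, decay=5)
    return sig


def generate_trace_set(config: SynthConfig) -> tuple[TraceSet, GroundTruth]:
    """Raw-fluorescence traces drawn from four response archetypes.

    Two stimuli are annotated: a 30-s stretch (window from stretch on to
    off) and an intestinal stretch (40-frame window).  Sustained cells
    plateau for the whole first window, transient cells decay within a few
    frames, polymodal cells respond to both stimuli and non-responders stay
    at baseline.  Peak dF/F equals ``response_amplitude`` at zero noise.
    """
    rng = config.rng(1)
    stimuli = (
        stretch_window("stomach_stretch", onset=40, offset=57),
        intestine_stretch_window("intestine_stretch", onset=120),
    )
    for w in stimuli:
        if w.stop > config.n_frames or w.onset < 20:
            raise ValueError(f"stimulus window {w.name!r} outside trace extent")
    ids = tuple(f"roi_{i:04d}" for i in range(config.n_trace_cells))
    kinds = rng.choice(ARCHETYPES, size=config.n_trace_cells, p=config.archetype_probs)
    f = np.empty((config.n_trace_cells, config.n_frames))
    for i, kind in enumerate(kinds):
        dff = _dff_signal(kind, stimuli, config.n_frames, config.response_amplitude)
        noise = rng.normal(0.0, config.trace_noise_sd * config.baseline_f, config.n_frames)
        f[i] = config.baseline_f * (1.0 + dff) + noise
    truth = GroundTruth(archetypes=dict(zip(ids, kinds)))
    return TraceSet(f=f, stimuli=stimuli, cell_ids=ids), truth


# ---------------------------------------------------------------------------
# landmark scenes


def generate_landmark_scene(
    transform_params: RigidTransform | tuple,
    n_landmarks: int = 8,
    n_cells: int = 40,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_sections: int = 4,
    section_thickness: float = 10.0,
    extent: float = 200.0,
) -> tuple[LandmarkScene, GroundTruth]:
    """Rigid-transform-related in vivo / section point sets.

    ``n_landmarks`` landmark cells are placed in every 10-um section (>= 3
    required) together with ``n_cells`` unlabelled cells spread across
    sections; in vivo coordinates are the exact inverse-transform images of
    the section coordinates, and ``noise_sd`` perturbs the section side.
    """
    if n_landmarks < 3:
        raise ValueError("need at least 3 landmarks per section")
    if isinstance(transform_params, RigidTransform):
        transform = transform_params
    else:
        transform = RigidTransform.from_euler(*transform_params)
    rng = np.random.default_rng(seed)

    rows = []
    for sec in range(n_sections):
        counts = n_landmarks + (n_cells // n_sections) + (sec < n_cells % n_sections)
        for j in range(counts):
            rows.append(
                (
                    sec,
                    j < n_landmarks,
                    rng.uniform(0, extent),
                    rng.uniform(0, extent),
                    rng.uniform(sec * section_thickness, (sec + 1) * section_thickness),
                )
            )
    sec_idx = np.array([r[0] for r in rows])
    landmark = np.array([r[1] for r in rows])
    sec_pts = np.array([r[2:] for r in rows])
    iv_pts = transform.inverse().apply(sec_pts)
    observed = sec_pts + rng.normal(0.0, noise_sd, size=sec_pts.shape)

    iv_ids = [f"iv_{i:04d}" for i in range(len(rows))]
    sec_ids = [f"sec_{i:04d}" for i in range(len(rows))]
    invivo = pd.DataFrame(
        {"cell_id": iv_ids, "x": iv_pts[:, 0], "y": iv_pts[:, 1], "z": iv_pts[:, 2],
         "landmark": landmark}
    )
    # shuffle the section table so correspondence is not positional
    perm = rng.permutation(len(rows))
    sections = pd.DataFrame(
        {
            "cell_id": np.array(sec_ids)[perm],
            "x": observed[perm, 0],
            "y": observed[perm, 1],
            "z": observed[perm, 2],
            "section": sec_idx[perm],
            "landmark": landmark[perm],
        }
    ).reset_index(drop=True)
    truth = GroundTruth(
        transform=transform,
        correspondence=dict(zip(iv_ids, sec_ids)),
    )
    scene = LandmarkScene(
        invivo=invivo,
        sections=sections,
        section_thickness=section_thickness,
        transform=transform,
    )
    return scene, truth


# ---------------------------------------------------------------------------
# ending tables

#: Anatomical fold-change profiles used by the generator, one distinct
#: profile per ending type so the true assignment is the unique optimum.
DEFAULT_AF_PROFILES: dict[str, dict[int, float]] = {
    "ME": {4: 2.0, 6: 0.5, 7: 0.3, 8: 1.2},
    "pIMA": {4: 0.4, 6: 1.8, 7: 0.6, 8: 0.8},
    "cIMA": {4: 1.5, 6: 0.6, 7: 1.9, 8: 0.4},
    "IGLE": {4: 0.3, 6: 1.1, 7: 0.5, 8: 2.1},
}

#: Pre-annotated clusters (every ending type anchored by >= 1 cluster).
DEFAULT_FIXED_MAP: dict[str, str] = {
    "F1": "ME",
    "G1": "ME",
    "H2": "pIMA",
    "J1": "pIMA",
    "I1": "cIMA",
    "C4": "IGLE",
}

#: Whole-stomach innervation intensity per type (area fraction for
#: ME/pIMA/cIMA; terminals per unit area for IGLE).
_WHOLE_INTENSITY = {"ME": 0.12, "pIMA": 0.08, "cIMA": 0.06, "IGLE": 1.5}


def generate_ending_tables(
    true_assignment: Mapping[str, str],
    seed: int = 0,
    noise_sd: float = 0.0,
    fixed_map: Mapping[str, str] | None = None,
    af_profiles: Mapping[str, Mapping[int, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Ending and cluster-label tables consistent with a known assignment.

    Dual-barcode percentages are constructed as AF(type(c), region) x
    single_pct(c) (plus optional Gaussian noise), so that under
    ``true_assignment`` the barcode-derived fold change SF equals AF exactly
    at zero noise and the assignment search recovers the truth with
    variance 0.
    """
    fixed = dict(DEFAULT_FIXED_MAP if fixed_map is None else fixed_map)
    af_profiles = dict(DEFAULT_AF_PROFILES if af_profiles is None else af_profiles)
    full = {**fixed, **true_assignment}
    for c, t in full.items():
        if t not in ENDING_TYPES:
            raise KeyError(f"unknown ending type {t!r} for cluster {c!r}")
    rng = np.random.default_rng(seed)

    records = []
    layer_of = {"ME": "mucosa", "pIMA": "muscle", "cIMA": "muscle", "IGLE": "muscle"}
    for etype in ENDING_TYPES:
        whole = _WHOLE_INTENSITY[etype]
        for region in (*STOMACH_REGIONS, "whole"):
            af = 1.0 if region == "whole" else af_profiles[etype][region]
            records.append(
                {
                    "genotype": "Vglut2",
                    "organ": "stomach",
                    "region": region,
                    "layer": layer_of[etype],
                    "ending_type": etype,
                    "measure": af * whole * 100.0,
                    "sample_total_area": 100.0,
                }
            )
    endings = pd.DataFrame(records)

    rows = {}
    for cluster, etype in full.items():
        single = rng.uniform(5.0, 15.0)
        row = {"single_pct": single}
        for region in STOMACH_REGIONS:
            dual = af_profiles[etype][region] * single
            if noise_sd > 0:
                dual += rng.normal(0.0, noise_sd)
            row[f"dual_pct_{region}"] = max(dual, 0.0)
        rows[cluster] = row
    labels = pd.DataFrame.from_dict(rows, orient="index")
    labels.index.name = "cluster"

    truth = GroundTruth(assignment=dict(true_assignment))
    return endings, labels, truth


# ---------------------------------------------------------------------------
# brainstem innervation tables

DEFAULT_BREGMAS = (-7.2, -7.32, -7.48, -7.56, -7.76, -7.92, -8.0)
DEFAULT_SUBNUCLEI = ("mNTS", "cNTS", "lNTS", "AP", "DMV")


def generate_innervation_table(
    pathways: Sequence[str] = ("stomach", "duodenum", "colon", "lung", "heart"),
    seed: int = 0,
    bregmas: Sequence[float] = DEFAULT_BREGMAS,
    subnuclei: Sequence[str] = DEFAULT_SUBNUCLEI,
    background: float = 20.0,
    noise_sd: float = 2.0,
) -> pd.DataFrame:
    """Fluorescence/area table of brainstem innervation per pathway.

    Each pathway gets a smooth unimodal fluorescence profile over the
    (bregma, subnucleus) grid with a pathway-specific centre, on top of a
    constant background, so related pathways (nearby centres) end up with
    small pairwise correlation variance.
    """
    rng = np.random.default_rng(seed)
    records = []
    for p_i, pathway in enumerate(pathways):
        centre_b = p_i / max(len(pathways) - 1, 1) * (len(bregmas) - 1)
        centre_s = (p_i * 1.3) % len(subnuclei)
        for b_i, bregma in enumerate(bregmas):
            for s_i, sub in enumerate(subnuclei):
                signal = 200.0 * np.exp(
                    -((b_i - centre_b) ** 2) / 8.0 - ((s_i - centre_s) ** 2) / 2.0
                )
                records.append(
                    {
                        "pathway": pathway,
                        "bregma": bregma,
                        "subnucleus": sub,
                        "mean_fluorescence": background
                        + signal
                        + rng.normal(0.0, noise_sd),
                        "background_fluorescence": background,
                        "area": rng.uniform(5e3, 2e4),
                    }
                )
    return pd.DataFrame(records)
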