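"""Desk-scale synthetic analogue of blind docking.

Each *cluster* plays the role of a protein-domain cluster: it owns a layout of
well-separated pocket centers in pose space, a per-pocket chemistry vector,
and a cluster-specific compatibility frame (a rotation) that decides which
pocket a given ligand binds.  A *complex* pairs a ligand feature vector with
its cluster; its ground-truth pose sits inside the compatible pocket.

Clusters are split into ``train`` and ``heldout`` roles.  Held-out clusters
draw their ligand chemistry and compatibility frames from an angular region
disjoint from the training clusters, so a generator fit on training clusters
must extrapolate — this is the synthetic stand-in for docking into unseen
binding domains.  Held-out ground-truth poses exist only for evaluation; the
bootstrapping trainer never reads them.

The context vector ``d`` exposes everything a docking method may legitimately
see: the ligand feature, the pocket centers and chemistries, and the
compatibility frame.  It does *not* contain the true pose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClusterSpec",
    "ToyComplex",
    "TaskConfig",
    "make_task",
    "context_vector",
    "context_dim",
    "save_task",
    "load_task",
]

#: success threshold in pose distance units, mirroring the 2 A convention
TAU = 2.0

#: minimum pairwise separation of pocket centers — wrong-pocket poses are
#: unambiguous failures at the TAU threshold
MIN_POCKET_SEP = 4.0


@dataclass(frozen=True)
class TaskConfig:
    """Shape parameters of the synthetic task (defaults are the study task)."""

    dim: int = 2              # pose space dimension
    n_pockets: int = 3        # pockets per cluster
    box_half: float = 6.0     # pocket centers drawn uniform in [-box_half, box_half]^dim
    pose_noise: float = 0.35  # std of the true pose around its pocket center
    train_arc: tuple = (0.0, math.pi)        # chemistry angles, train clusters
    heldout_arc: tuple = (math.pi, 2 * math.pi)  # disjoint region, held-out clusters


@dataclass(frozen=True)
class ClusterSpec:
    cluster_id: int
    role: str  # "train" | "heldout"
    pocket_layout: np.ndarray        # (n_pockets, dim) centers
    pocket_features: np.ndarray      # (n_pockets, 2) unit chemistry vectors
    compatibility_params: np.ndarray  # (2,) = (cos w, sin w), cluster frame angle w

    def compat_scores(self, ligand_feature: np.ndarray) -> np.ndarray:
        """Affinity of each pocket for a ligand: <u_j, R(w) l>."""
        c, s = self.compatibility_params
        rot = np.array([[c, -s], [s, c]])
        return self.pocket_features @ (rot @ ligand_feature)

    def correct_pocket(self, ligand_feature: np.ndarray) -> int:
        return int(np.argmax(self.compat_scores(ligand_feature)))


@dataclass(frozen=True)
class ToyComplex:
    complex_id: int
    cluster_id: int
    ligand_feature: np.ndarray  # (2,) unit vector
    x_star: np.ndarray          # true pose, (dim,)
    d: np.ndarray               # full context vector
    cluster: ClusterSpec = field(repr=False, compare=False, default=None)


def context_dim(cfg: TaskConfig = TaskConfig()) -> int:
    return 2 + cfg.n_pockets * (cfg.dim + 2) + 2


def context_vector(cluster: ClusterSpec, ligand_feature: np.ndarray) -> np.ndarray:
    """Concatenate ligand feature, pocket (center, chemistry) pairs and frame."""
    parts = [np.asarray(ligand_feature, dtype=float)]
    for j in range(cluster.pocket_layout.shape[0]):
        parts.append(cluster.pocket_layout[j])
        parts.append(cluster.pocket_features[j])
    parts.append(cluster.compatibility_params)
    return np.concatenate(parts)


#: held-out pocket centers keep this margin from every training-cluster
#: center, so held-out true poses (within 1 unit of their center) can never
#: sit within TAU of a training pocket
HELDOUT_MARGIN = 3.0


def _sample_centers(rng, cfg: TaskConfig, avoid: np.ndarray | None = None) -> np.ndarray:
    """Place pocket centers sequentially by rejection: pairwise separation
    >= MIN_POCKET_SEP and (optionally) >= HELDOUT_MARGIN from ``avoid``."""
    for _ in range(200):  # restarts
        placed = []
        for _ in range(cfg.n_pockets):
            for _ in range(2000):
                c = rng.uniform(-cfg.box_half, cfg.box_half, size=cfg.dim)
                if placed and min(np.linalg.norm(c - p) for p in placed) < MIN_POCKET_SEP:
                    continue
                if avoid is not None and avoid.size and \
                        np.linalg.norm(c - avoid, axis=1).min() < HELDOUT_MARGIN:
                    continue
                placed.append(c)
                break
            else:
                break
        if len(placed) == cfg.n_pockets:
            return np.stack(placed)
    raise RuntimeError("could not place pockets; box too small for n_pockets")


def _unit(angle):
    return np.array([math.cos(angle), math.sin(angle)])


def _make_cluster(cluster_id: int, role: str, rng, cfg: TaskConfig,
                  avoid: np.ndarray | None = None) -> ClusterSpec:
    arc = cfg.train_arc if role == "train" else cfg.heldout_arc
    centers = _sample_centers(rng, cfg, avoid)
    # pocket chemistries spread inside the cluster's angular region
    angles = rng.uniform(arc[0], arc[1], size=cfg.n_pockets)
    feats = np.stack([_unit(a) for a in angles])
    w = rng.uniform(arc[0], arc[1])
    return ClusterSpec(cluster_id, role, centers, feats, _unit(w))


def make_task(
    n_train_clusters: int,
    n_heldout_clusters: int,
    complexes_per_cluster: int,
    seed: int = 0,
    cfg: TaskConfig = TaskConfig(),
):
    """Generate a seeded task: disjoint train/held-out clusters plus complexes.

    Held-out clusters always receive at least 6 complexes so that per-cluster
    success rates are meaningful.
    """
    if min(n_train_clusters, n_heldout_clusters, complexes_per_cluster) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    clusters = []
    cid = 0
    for _ in range(n_train_clusters):
        clusters.append(_make_cluster(cid, "train", rng, cfg))
        cid += 1
    train_centers = np.concatenate([c.pocket_layout for c in clusters])
    for _ in range(n_heldout_clusters):
        clusters.append(_make_cluster(cid, "heldout", rng, cfg, avoid=train_centers))
        cid += 1

    complexes = []
    xid = 0
    for cl in clusters:
        arc = cfg.train_arc if cl.role == "train" else cfg.heldout_arc
        n = complexes_per_cluster if cl.role == "train" else max(6, complexes_per_cluster)
        for _ in range(n):
            lig = _unit(rng.uniform(arc[0], arc[1]))
            j = cl.correct_pocket(lig)
            while True:
                off = cfg.pose_noise * rng.standard_normal(cfg.dim)
                if np.linalg.norm(off) < 1.0:  # x_star within 1 unit of its center
                    break
            x_star = cl.pocket_layout[j] + off
            complexes.append(
                ToyComplex(xid, cl.cluster_id, lig, x_star, context_vector(cl, lig), cl)
            )
            xid += 1
    return clusters, complexes


def split_complexes(clusters, complexes):
    """Partition complexes by their cluster's role -> (train, heldout)."""
    role = {c.cluster_id: c.role for c in clusters}
    train = [x for x in complexes if role[x.cluster_id] == "train"]
    heldout = [x for x in complexes if role[x.cluster_id] == "heldout"]
    return train, heldout


# ---------------------------------------------------------------------------
# TSV serialization


def save_task(clusters, complexes, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    crows = []
    for c in clusters:
        row = {"cluster_id": c.cluster_id, "role": c.role,
               "compat_cos": c.compatibility_params[0],
               "compat_sin": c.compatibility_params[1]}
        for j in range(c.pocket_layout.shape[0]):
            for k in range(c.pocket_layout.shape[1]):
                row[f"pocket{j}_x{k}"] = c.pocket_layout[j, k]
            row[f"pocket{j}_u0"] = c.pocket_features[j, 0]
            row[f"pocket{j}_u1"] = c.pocket_features[j, 1]
        crows.append(row)
    pd.DataFrame(crows).to_csv(out / "clusters.tsv", sep="\t", index=False)

    xrows = []
    for x in complexes:
        row = {"complex_id": x.complex_id, "cluster_id": x.cluster_id,
               "lig0": x.ligand_feature[0], "lig1": x.ligand_feature[1]}
        for k, v in enumerate(x.x_star):
            row[f"xstar{k}"] = v
        xrows.append(row)
    pd.DataFrame(xrows).to_csv(out / "complexes.tsv", sep="\t", index=False)


def load_task(task_dir):
    task_dir = Path(task_dir)
    cdf = pd.read_csv(task_dir / "clusters.tsv", sep="\t")
    xdf = pd.read_csv(task_dir / "complexes.tsv", sep="\t")
    n_pockets = len([c for c in cdf.columns if c.endswith("_u0")])
    dim = len([c for c in cdf.columns if c.startswith("pocket0_x")])
    clusters = []
    for _, r in cdf.iterrows():
        layout = np.array([[r[f"pocket{j}_x{k}"] for k in range(dim)] for j in range(n_pockets)])
        feats = np.array([[r[f"pocket{j}_u0"], r[f"pocket{j}_u1"]] for j in range(n_pockets)])
        clusters.append(ClusterSpec(int(r["cluster_id"]), str(r["role"]), layout, feats,
                                    np.array([r["compat_cos"], r["compat_sin"]])))
    by_id = {c.cluster_id: c for c in clusters}
    complexes = []
    for _, r in xdf.iterrows():
        cl = by_id[int(r["cluster_id"])]
        lig = np.array([r["lig0"], r["lig1"]])
        x_star = np.array([r[f"xstar{k}"] for k in range(dim)])
        complexes.append(ToyComplex(int(r["complex_id"]), cl.cluster_id, lig, x_star,
                                    context_vector(cl, lig), cl))
    return clusters, complexes
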