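"""Benchmark curation and pose evaluation in the DockGen style.

Curation acts on a pre-built table of complex records (one row per
protein-ligand complex, already annotated with its binding-domain cluster):
complexes sharing a pocket with another ligand, metals, crystal additives and
ligands over 60 heavy atoms are removed, and at most five complexes per
ligand identity are kept for chemical balance.  Clusters are then split at
the cluster level into validation and test halves, so no binding domain ever
appears on both sides.

Evaluation is the standard holo-frame top-1 protocol: ligand heavy-atom RMSD
without re-superposition, fraction below 2 A, and the median.  The binding-
site similarity audit compares residue compositions of two sites with a
normalized BLOSUM62 best-match score, symmetrized by a harmonic mean, giving
a value in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

__all__ = [
    "ComplexRecord",
    "PosePrediction",
    "BindingSite",
    "filter_records",
    "split_clusters",
    "rmsd",
    "evaluate",
    "site_similarity",
    "records_from_table",
    "records_to_table",
]

SUCCESS_RMSD = 2.0


@dataclass(frozen=True)
class ComplexRecord:
    complex_id: str
    cluster_id: str
    ligand_id: str
    heavy_atoms: int
    is_metal: bool = False
    is_additive: bool = False
    shares_pocket_with_other_ligand: bool = False
    year: int = 0

    def __post_init__(self) -> None:
        if self.heavy_atoms < 1:
            raise ValueError("heavy-atom count must be >= 1")


@dataclass
class PosePrediction:
    complex_id: str
    poses: list  # [(coords (n,3), confidence)], ranked by confidence desc

    def __post_init__(self) -> None:
        confs = [c for _, c in self.poses]
        if confs != sorted(confs, reverse=True):
            self.poses = sorted(self.poses, key=lambda p: -p[1])

    @property
    def top1(self) -> np.ndarray:
        return np.asarray(self.poses[0][0], dtype=float)


@dataclass(frozen=True)
class BindingSite:
    residues: tuple  # ((position, one-letter code), ...)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("binding site must be non-empty")

    @classmethod
    def from_sequence(cls, seq: str, start: int = 1) -> "BindingSite":
        return cls(tuple((start + i, aa) for i, aa in enumerate(seq)))

    @property
    def codes(self) -> tuple:
        return tuple(aa for _, aa in self.residues)


# ---------------------------------------------------------------------------
# curation


def filter_records(
    records: Sequence[ComplexRecord],
    max_heavy: int = 60,
    per_ligand_cap: int = 5,
):
    """Apply the exclusion rules, then cap complexes per ligand identity.

    Drops records that share a pocket with another ligand, metals, crystal
    additives and ligands with more than ``max_heavy`` heavy atoms; within
    each ligand identity keeps the ``per_ligand_cap`` records with the
    smallest complex ids.  Output is sorted by complex id — deterministic and
    idempotent.
    """
    kept = [
        r for r in records
        if not r.shares_pocket_with_other_ligand
        and not r.is_metal
        and not r.is_additive
        and r.heavy_atoms <= max_heavy
    ]
    kept.sort(key=lambda r: r.complex_id)
    seen: dict = {}
    out = []
    for r in kept:
        n = seen.get(r.ligand_id, 0)
        if n < per_ligand_cap:
            out.append(r)
            seen[r.ligand_id] = n + 1
    return out


def split_clusters(cluster_ids: Sequence, seed: int = 0):
    """Randomly divide clusters into two halves (val, test), disjoint and
    exhaustive, sizes differing by at most one."""
    unique = sorted(set(cluster_ids))
    if len(unique) < 2:
        raise ValueError("need at least 2 clusters to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(unique))
    half = (len(unique) + 1) // 2
    val = {unique[i] for i in perm[:half]}
    test = {unique[i] for i in perm[half:]}
    return val, test


# ---------------------------------------------------------------------------
# metrics


def rmsd(coords_a, coords_b) -> float:
    """Heavy-atom RMSD in the receptor frame — no superposition."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def evaluate(
    predictions: Sequence[PosePrediction],
    truths: Mapping,
    clusters: Mapping | None = None,
    threshold: float = SUCCESS_RMSD,
) -> dict:
    """Top-1 report: % of complexes with top-1 RMSD below ``threshold``,
    median top-1 RMSD, and a per-cluster breakdown when ``clusters`` maps
    complex id -> cluster id."""
    missing = [p.complex_id for p in predictions if p.complex_id not in truths]
    if missing:
        raise KeyError(f"missing ground truth for: {', '.join(map(str, missing))}")
    top1 = {p.complex_id: rmsd(p.top1, truths[p.complex_id]) for p in predictions}
    vals = np.array(list(top1.values()))
    report = {
        "pct_below_threshold": float(100.0 * np.mean(vals < threshold)),
        "median_rmsd": float(np.median(vals)),
        "n": len(vals),
        "per_complex": top1,
    }
    if clusters is not None:
        per = {}
        for cid, r in top1.items():
            per.setdefault(clusters[cid], []).append(r)
        report["per_cluster"] = {
            cl: {"pct_below_threshold": float(100.0 * np.mean(np.array(v) < threshold)),
                 "median_rmsd": float(np.median(v)), "n": len(v)}
            for cl, v in per.items()
        }
    return report


# ---------------------------------------------------------------------------
# binding-site similarity


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _pair_sim(a: str, b: str, table) -> float:
    s = table[a, b]
    norm = np.sqrt(table[a, a] * table[b, b])
    return float(np.clip(s / norm, 0.0, 1.0))


def _directed(a: BindingSite, b: BindingSite, table) -> float:
    return float(np.mean([max(_pair_sim(ra, rb, table) for rb in b.codes)
                          for ra in a.codes]))


def site_similarity(a: BindingSite, b: BindingSite, substitution_table=None) -> float:
    """Symmetric site similarity in [0, 1].

    Each residue of one site is matched to its best partner in the other
    under the per-pair normalized substitution score
    ``s(x,y)/sqrt(s(x,x)·s(y,y))`` clipped to [0, 1]; the two directed
    averages are combined by a harmonic mean.  Identical sites score 1.
    """
    table = substitution_table if substitution_table is not None else _BLOSUM62
    ab = _directed(a, b, table)
    ba = _directed(b, a, table)
    if ab + ba == 0.0:
        return 0.0
    return 2.0 * ab * ba / (ab + ba)


# ---------------------------------------------------------------------------
# tabular I/O


_COLUMNS = ["complex_id", "cluster_id", "ligand_id", "heavy_atoms",
            "is_metal", "is_additive", "shares_pocket_with_other_ligand", "year"]


def records_from_table(path_or_df) -> list:
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) \
        else pd.read_csv(path_or_df, sep="\t")
    return [
        ComplexRecord(
            complex_id=str(r.complex_id),
            cluster_id=str(r.cluster_id),
            ligand_id=str(r.ligand_id),
            heavy_atoms=int(r.heavy_atoms),
            is_metal=bool(r.is_metal),
            is_additive=bool(r.is_additive),
            shares_pocket_with_other_ligand=bool(r.shares_pocket_with_other_ligand),
            year=int(getattr(r, "year", 0)),
        )
        for r in df.itertuples()
    ]


def records_to_table(records: Iterable[ComplexRecord], path=None) -> pd.DataFrame:
    df = pd.DataFrame([{c: getattr(r, c) for c in _COLUMNS} for r in records])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
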