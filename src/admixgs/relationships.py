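"""Additive relationship matrices: pedigree A, genomic G, linkage IBD, H.

All matrices are on the additive-relationship scale (twice the kinship):
a non-inbred individual has diagonal 1, a parent-offspring pair 0.5. The
four constructions compared in genomic evaluation are

* ``numerator_relationship`` — pedigree expectation A by the tabular
  method (diagonal 1 + F);
* ``grm_vanraden2`` — identity-by-state genomic relationship matrix with
  each marker standardised by its own variance 2 p (1 - p) before
  averaging (VanRaden's second method);
* ``ibd_relationship`` (in :mod:`admixgs.ibd`, re-exported here) —
  realised identity-by-descent sharing from linkage analysis of mapped
  markers conditioned on the pedigree;
* ``single_step_h`` — the unified matrix H combining genomic
  relationships for genotyped and pedigree relationships for ungenotyped
  individuals.

``adjust_to_pedigree`` rescales a genomic matrix so its mean diagonal and
mean off-diagonal match A (the two-moment "ADJUST" convention), putting G
on the same base as the pedigree before single-step combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream

__all__ = [
    "RelationshipMatrix",
    "MarkerSubset",
    "numerator_relationship",
    "grm_vanraden2",
    "make_marker_subsets",
    "paper_density_scheme",
    "adjust_to_pedigree",
    "single_step_h",
    "topological_order",
]


@dataclass
class RelationshipMatrix:
    """Symmetric additive-relationship matrix keyed by individual ids."""

    ids: np.ndarray
    values: np.ndarray
    method: str = "PED-A"  # PED-A | GRM-VR2 | IBD-GS | H
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids.tolist())) != n:
            raise ValueError("ids must be unique")
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("matrix must be symmetric to 1e-10")
        self.values = 0.5 * (self.values + self.values.T)
        if np.any(np.diag(self.values) < 0):
            raise ValueError("negative diagonal")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = pd.Series(np.arange(self.n), index=self.ids)
        return lookup.loc[np.asarray(ids)].to_numpy()

    def restrict(self, ids) -> "RelationshipMatrix":
        ix = self.index_of(ids)
        return RelationshipMatrix(np.asarray(ids), self.values[np.ix_(ix, ix)],
                                  self.method, dict(self.meta))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, columns=self.ids).to_csv(
            path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, method: str = "PED-A") -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t")
        ids = np.asarray([int(c) if str(c).isdigit() else c for c in df.columns])
        return cls(ids, df.to_numpy(), method)


@dataclass
class MarkerSubset:
    """One random marker panel of a given density; replicates within a
    density family are pairwise disjoint."""

    density: int
    replicate: int
    indices: np.ndarray


def topological_order(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Return the pedigree sorted so parents precede offspring.

    Rejects cycles (an individual its own ancestor). Unknown parents are 0.
    """
    ids = pedigree["id"].tolist()
    parents = {r.id: (r.sire, r.dam) for r in pedigree.itertuples()}
    known = set(ids)
    indeg = {}
    children: dict = {}
    for i in ids:
        s, d = parents[i]
        if s == i or d == i:
            raise ValueError(f"individual {i} is its own parent")
        deg = 0
        for p in (s, d):
            if p != 0 and p in known:
                deg += 1
                children.setdefault(p, []).append(i)
        indeg[i] = deg
    from collections import deque

    queue = deque(i for i in ids if indeg[i] == 0)
    order = []
    while queue:
        i = queue.popleft()   # FIFO keeps an already-sorted pedigree stable
        order.append(i)
        for c in children.get(i, []):
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != len(ids):
        raise ValueError("pedigree contains a cycle")
    return pedigree.set_index("id").loc[order].reset_index()


def numerator_relationship(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Pedigree numerator relationship matrix A by the tabular method.

    a_ii = 1 + F_i with F_i = a(sire, dam)/2; a_ij = (a(j, sire_i) +
    a(j, dam_i))/2 for j preceding i. Parents unknown to the pedigree
    contribute zero.
    """
    ped = topological_order(pedigree)
    ids = ped["id"].to_numpy()
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    sires = ped["sire"].to_numpy()
    dams = ped["dam"].to_numpy()
    for k in range(n):
        s = pos.get(sires[k], -1)
        d = pos.get(dams[k], -1)
        row = np.zeros(k)
        if s >= 0:
            row += 0.5 * A[s, :k]
        if d >= 0:
            row += 0.5 * A[d, :k]
        A[k, :k] = row
        A[:k, k] = row
        A[k, k] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return RelationshipMatrix(ids, A, "PED-A")


def grm_vanraden2(dosages: np.ndarray, ids=None, marker_subset=None,
                  freqs: np.ndarray | None = None) -> RelationshipMatrix:
    """Genomic relationship matrix, VanRaden method 2.

    G = (1/m) sum_j (x_j - 2 p_j)(x_j - 2 p_j)' / (2 p_j (1 - p_j)): each
    marker is centred and standardised by its own expected variance before
    averaging. Allele frequencies default to the observed sample; pass
    ``freqs`` to use base-generation frequencies instead. Monomorphic
    markers are excluded.
    """
    X = np.asarray(dosages, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D dosage matrix with at least 2 individuals")
    if not np.isin(X, (0.0, 1.0, 2.0)).all():
        raise ValueError("dosages must be 0/1/2")
    if marker_subset is not None:
        idx = marker_subset.indices if isinstance(marker_subset, MarkerSubset) else np.asarray(marker_subset)
        X = X[:, idx]
        sub_freqs = freqs[idx] if freqs is not None else None
    else:
        sub_freqs = freqs
    p = X.mean(axis=0) / 2.0 if sub_freqs is None else np.asarray(sub_freqs, dtype=float)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers monomorphic")
    Xp, pp = X[:, poly], p[poly]
    W = (Xp - 2 * pp) / np.sqrt(2 * pp * (1 - pp))
    G = W @ W.T / W.shape[1]
    out_ids = np.arange(X.shape[0]) if ids is None else np.asarray(ids)
    return RelationshipMatrix(out_ids, G, "GRM-VR2",
                              {"n_markers": int(poly.sum())})


def paper_density_scheme(n_markers_total: int) -> dict[int, int]:
    """Marker-density families scaled from the reference 220k design.

    The reference panel uses densities 1100/2200/4400/22000 with 10
    disjoint replicates each, 55000 with 4, and the full panel once; for a
    smaller panel every density is scaled by n/220000 (minimum 10 markers).
    """
    ref = {1100: 10, 2200: 10, 4400: 10, 22000: 10, 55000: 4}
    scale = n_markers_total / 220000
    out = {}
    for dens, reps in ref.items():
        d = max(10, int(round(dens * scale)))
        if d * reps <= n_markers_total:
            out[d] = reps
    out[n_markers_total] = 1
    return out


def make_marker_subsets(n_markers_total: int, densities, replicates,
                        seed: int) -> list[MarkerSubset]:
    """Random disjoint marker panels per density family.

    ``densities`` is a sequence of panel sizes; ``replicates`` an int or a
    per-density sequence. Within one density the replicate panels are
    pairwise disjoint (sampled jointly without replacement); different
    densities are sampled independently.
    """
    if np.isscalar(replicates):
        replicates = [int(replicates)] * len(densities)
    if len(replicates) != len(densities):
        raise ValueError("replicates must match densities")
    rng = stream(seed, "marker-subsets")
    out = []
    for dens, reps in zip(densities, replicates):
        if dens * reps > n_markers_total:
            raise ValueError(
                f"cannot draw {reps} disjoint panels of {dens} from "
                f"{n_markers_total} markers")
        take = rng.choice(n_markers_total, size=dens * reps, replace=False)
        for r in range(reps):
            out.append(MarkerSubset(density=int(dens), replicate=r,
                                    indices=np.sort(take[r * dens:(r + 1) * dens])))
    return out


def adjust_to_pedigree(G: RelationshipMatrix, A: RelationshipMatrix) -> RelationshipMatrix:
    """Affine rescale G* = alpha + beta G matching A's mean diagonal and
    mean off-diagonal (two-moment "ADJUST" convention).

    Solves the 2x2 linear system alpha + beta mean(diag G) = mean(diag A),
    alpha + beta mean(offdiag G) = mean(offdiag A). A constant G (no
    spread between diagonal and off-diagonal) is degenerate and rejected.
    """
    if G.n != A.n or set(G.ids.tolist()) != set(A.ids.tolist()):
        raise ValueError("G and A must cover the same individuals")
    Av = A.restrict(G.ids).values
    n = G.n
    off = ~np.eye(n, dtype=bool)
    md_g, mo_g = np.diag(G.values).mean(), G.values[off].mean()
    md_a, mo_a = np.diag(Av).mean(), Av[off].mean()
    if abs(md_g - mo_g) < 1e-12:
        raise ValueError("degenerate G: no diagonal/off-diagonal contrast")
    beta = (md_a - mo_a) / (md_g - mo_g)
    alpha = md_a - beta * md_g
    return RelationshipMatrix(G.ids, alpha + beta * G.values, G.method,
                              {**G.meta, "adjust_alpha": float(alpha),
                               "adjust_beta": float(beta)})


def single_step_h(A: RelationshipMatrix, G: RelationshipMatrix,
                  genotyped_ids, blend: float = 0.0):
    """Unified single-step relationship matrix H (dense) and its inverse.

    With individuals partitioned into ungenotyped (1) and genotyped (2),

        H = A + [[A12 A22^-1 (G - A22) A22^-1 A21, A12 A22^-1 (G - A22)],
                 [(G - A22) A22^-1 A21,            G - A22          ]]

    and H^-1 = A^-1 + [[0, 0], [0, G^-1 - A22^-1]]. Ids in the returned
    matrix keep A's order. ``blend`` > 0 replaces G by
    (1 - blend) G + blend A22 to guard against a singular marker-derived G
    (off by default). Returns (H, H_inverse) as RelationshipMatrix and
    ndarray aligned with H.ids.
    """
    genotyped_ids = np.asarray(genotyped_ids)
    if not set(genotyped_ids.tolist()) <= set(A.ids.tolist()):
        raise ValueError("genotyped ids must be a subset of the pedigree")
    g_ix = A.index_of(genotyped_ids) if len(genotyped_ids) else np.array([], dtype=int)
    mask = np.zeros(A.n, dtype=bool)
    mask[g_ix] = True
    order = np.concatenate([np.flatnonzero(~mask), np.flatnonzero(mask)])
    ids = A.ids[order]
    Av = A.values[np.ix_(order, order)]
    n1 = int((~mask).sum())

    if len(genotyped_ids) == 0:
        return (RelationshipMatrix(ids, Av, "H", {"n_genotyped": 0}),
                np.linalg.inv(Av))

    Gv = G.restrict(ids[n1:]).values
    A22 = Av[n1:, n1:]
    if blend > 0:
        Gv = (1 - blend) * Gv + blend * A22
    try:
        A22_inv = np.linalg.inv(A22)
        G_inv = np.linalg.inv(Gv)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular genomic block; consider blending G with A22 "
            "(blend > 0)") from err
    D = Gv - A22
    H = Av.copy()
    if n1 > 0:
        A12 = Av[:n1, n1:]
        B = A12 @ A22_inv          # n1 x n2
        H[:n1, :n1] += B @ D @ B.T
        H[:n1, n1:] += B @ D
        H[n1:, :n1] = H[:n1, n1:].T
    H[n1:, n1:] = Gv
    H = 0.5 * (H + H.T)

    H_inv = np.linalg.inv(Av)
    H_inv[n1:, n1:] += G_inv - A22_inv
    return (RelationshipMatrix(ids, H, "H",
                               {"n_genotyped": int(mask.sum()), "blend": blend}),
            H_inv)


# linkage-analysis IBD lives in its own module; re-export for the public API
from .ibd import ibd_relationship  # noqa: E402  (circular-safe: ibd imports nothing from here)

__all__.append("ibd_relationship")
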