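"""Linkage-analysis identity-by-descent relationship estimation.

Full sibs share half their genome *in expectation*, but the realised
fraction varies around 0.5; tracing which parental chromosome segments
each offspring actually inherited turns that variation into usable
relationship information, even from sparse marker panels, because each
meiosis produces on average only one crossover per Morgan.

The estimator conditions on the recorded pedigree (founders assumed
pairwise non-IBD) and works chromosome by chromosome:

1. *Family phasing.* Each parent's two haplotypes are reconstructed from
   the alleles it demonstrably transmitted to its offspring: adjacent
   heterozygous markers are linked by majority vote over offspring (most
   offspring do not recombine between close markers), and the haplotypes
   are oriented against the parent's own sire where the pedigree allows.
2. *Transmission HMM.* For every offspring x parent pair a two-state
   hidden Markov chain over the markers tracks which parental haplotype
   was transmitted; transition probabilities are Haldane recombination
   fractions between adjacent markers and emissions score the observed
   transmitted allele against the phased parental haplotypes (flat when
   the marker is uninformative). Forward-backward gives the posterior
   transmission probability at every locus.
3. *Gametic recursion.* At a grid of marker loci the gametic relationship
   matrix is built down the pedigree: a gamete inherited from parent p is
   p's "sire" gamete with the posterior probability from step 2, so its
   IBD row is the posterior-weighted average of the parent's two gamete
   rows. Locus matrices are averaged within a chromosome and chromosome
   matrices averaged (equal weights by default) into one matrix on the
   additive-relationship scale: non-inbred diagonal 1, parent-offspring
   exactly 0.5.

With no marker information every posterior is 1/2 and the recursion
reproduces the pedigree numerator relationship matrix exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ld_theory import haldane_c

__all__ = ["ibd_relationship", "transmission_posteriors"]

_MISS = 3  # genotype code for missing


def _transmission_lut() -> np.ndarray:
    """t = LUT[g_off, g_parent, g_other]: transmitted allele from the
    parent (0/1), or 2 when ambiguous/unknown."""
    lut = np.full((4, 4, 4), 2, dtype=np.int8)
    opts = {0: (0,), 1: (0, 1), 2: (1,), _MISS: (0, 1)}
    for go in range(3):
        for gp in range(4):
            for gq in range(4):
                a_ok = {a for a in opts[gp] for b in opts[gq] if a + b == go}
                if len(a_ok) == 1:
                    lut[go, gp, gq] = a_ok.pop()
    return lut


_LUT = _transmission_lut()


def _code(dosages: np.ndarray) -> np.ndarray:
    g = np.asarray(dosages, dtype=float)
    out = np.full(g.shape, _MISS, dtype=np.int8)
    ok = np.isfinite(g) & (g >= 0)
    out[ok] = g[ok].astype(np.int8)
    return out


def _phase_parent(gp: np.ndarray, t_off: np.ndarray, t_own: np.ndarray | None):
    """Phase one parent on one chromosome from offspring transmissions.

    gp: (m,) parent genotype codes; t_off: (n_off, m) transmitted-allele
    codes (2 = unknown); t_own: (m,) alleles the parent received from its
    own sire, for orientation (None for founders). Returns (m, 2) phased
    alleles with -1 where unknown, hap column 0 oriented to the parent's
    sire gamete where determinable.
    """
    m = len(gp)
    haps = np.full((m, 2), -1, dtype=np.int8)
    haps[gp == 0] = 0
    haps[gp == 2] = 1
    H = np.flatnonzero(gp == 1)
    if len(H) == 0:
        return haps
    s = t_off[:, H] if t_off.size else np.empty((0, len(H)), dtype=np.int8)
    # relative phase between het markers: each offspring links its
    # consecutive *informative* markers (a vote is wrong only if that
    # offspring recombined in between), so sparse informativeness does not
    # break the chain
    votes: list[list] = [[] for _ in H]
    for o in range(s.shape[0]):
        idx = np.flatnonzero(s[o] != 2)
        if len(idx) < 2:
            continue
        xr = (s[o, idx[:-1]] ^ s[o, idx[1:]]) & 1
        for j, k_, x_ in zip(idx[:-1], idx[1:], xr):
            votes[k_].append((j, x_))
    x = np.zeros(len(H), dtype=np.int8)
    for k_ in range(1, len(H)):
        vs = votes[k_]
        if vs:
            tally = sum(1 if (x[j] ^ x_) else -1 for j, x_ in vs)
            x[k_] = 1 if tally > 0 else 0
        else:
            x[k_] = x[k_ - 1]

    # the alleles the parent itself received from its sire are hard phase
    # anchors: hap 0 *is* the sire gamete there, and a chain flip cannot
    # propagate past an anchor
    anchors = np.array([], dtype=int)
    if t_own is not None:
        to = t_own[H]
        anchors = np.flatnonzero(to != 2)
    if len(anchors) > 0:
        offs = (to[anchors] ^ x[anchors]) & 1
        h0 = np.empty(len(H), dtype=np.int8)
        seg = np.searchsorted(anchors, np.arange(len(H)), side="right") - 1
        seg = np.clip(seg, 0, len(anchors) - 1)
        h0 = (x ^ offs[seg]) & 1
    else:
        h0 = (1 ^ x) & 1  # arbitrary orientation (founder parent)
    haps[H, 0] = h0
    haps[H, 1] = 1 - h0
    return haps


def transmission_posteriors(dosages, gmap, pedigree, epsilon: float = 0.01):
    """Posterior P(sire-side gamete transmitted) per individual x parent x
    marker.

    ``dosages`` rows align with ``pedigree`` rows (already parent-first);
    missing genotypes are NaN or negative. Returns an (n, 2, m) array,
    0.5 wherever uninformative (founders, ungenotyped, monomorphic or
    single-marker chromosomes).
    """
    g = _code(dosages)
    n, m = g.shape
    ped = pedigree.reset_index(drop=True)
    pos_of = {i: k for k, i in enumerate(ped["id"])}
    sire = np.array([pos_of.get(s, -1) for s in ped["sire"]])
    dam = np.array([pos_of.get(d, -1) for d in ped["dam"]])

    b = np.full((n, 2, m), 0.5)
    # transmitted-allele codes for every individual from each parent
    t = np.full((n, 2, m), 2, dtype=np.int8)
    for side, par, oth in ((0, sire, dam), (1, dam, sire)):
        has = par >= 0
        gp = np.where(has[:, None], g[np.maximum(par, 0)], _MISS)
        gq = np.where((oth >= 0)[:, None], g[np.maximum(oth, 0)], _MISS)
        t[has, side] = _LUT[g[has], gp[has], gq[has]]

    children: dict[int, list] = {}
    for k in range(n):
        for side, p in ((0, sire[k]), (1, dam[k])):
            if p >= 0:
                children.setdefault(p, []).append((k, side))

    for _, sl, pos in gmap.chrom_slices():
        mc = sl.stop - sl.start
        if mc < 2:
            continue
        c = haldane_c(np.diff(pos))
        # phase every parent on this chromosome
        hap = np.full((n, mc, 2), -1, dtype=np.int8)
        for p, kids in children.items():
            t_off = np.array([t[k, side, sl] for k, side in kids])
            t_own = t[p, 0, sl] if sire[p] >= 0 else None
            hap[p] = _phase_parent(g[p, sl], t_off, t_own)
        # emissions and forward-backward for all offspring x parent pairs
        pairs = [(k, side, par[k]) for side, par in ((0, sire), (1, dam))
                 for k in range(n) if par[k] >= 0]
        if not pairs:
            continue
        kk = np.array([p[0] for p in pairs])
        ss = np.array([p[1] for p in pairs])
        pp = np.array([p[2] for p in pairs])
        tt = t[kk, ss][:, sl.start:sl.stop]            # (P, mc)
        h0 = hap[pp, :, 0]                             # (P, mc)
        h1 = hap[pp, :, 1]
        inform = (tt != 2) & (h0 >= 0) & (h0 != h1)
        e0 = np.where(inform, np.where(h0 == tt, 1 - epsilon, epsilon), 1.0)
        e1 = np.where(inform, np.where(h1 == tt, 1 - epsilon, epsilon), 1.0)
        E = np.stack([e0, e1], axis=2)                 # (P, mc, 2)

        P = len(pairs)
        alpha = np.empty((P, mc, 2))
        beta = np.empty((P, mc, 2))
        a = 0.5 * E[:, 0]
        a /= a.sum(axis=1, keepdims=True)
        alpha[:, 0] = a
        for j in range(1, mc):
            stay, swap = 1 - c[j - 1], c[j - 1]
            pred = np.empty_like(a)
            pred[:, 0] = stay * a[:, 0] + swap * a[:, 1]
            pred[:, 1] = swap * a[:, 0] + stay * a[:, 1]
            a = pred * E[:, j]
            a /= a.sum(axis=1, keepdims=True)
            alpha[:, j] = a
        bb = np.ones((P, 2))
        beta[:, mc - 1] = bb
        for j in range(mc - 2, -1, -1):
            stay, swap = 1 - c[j], c[j]
            w = bb * E[:, j + 1]
            nxt = np.empty_like(w)
            nxt[:, 0] = stay * w[:, 0] + swap * w[:, 1]
            nxt[:, 1] = swap * w[:, 0] + stay * w[:, 1]
            bb = nxt / nxt.sum(axis=1, keepdims=True)
            beta[:, j] = bb
        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        b[kk, ss, sl.start:sl.stop] = post[:, :, 0]
    return b


def ibd_relationship(dosages, gmap, pedigree, n_eval_points: int = 24,
                     epsilon: float = 0.01, chrom_weights: str = "equal",
                     posteriors=None):
    """Linkage-analysis IBD relationship matrix for a pedigree.

    ``dosages`` is an (n, m) 0/1/2 matrix aligned with ``pedigree`` rows
    (NaN/negative = ungenotyped) over the markers of ``gmap``; the
    pedigree is topologically sorted internally and the result keeps that
    order. The per-chromosome matrices are the average of gametic IBD
    matrices at ``n_eval_points`` marker loci per chromosome, combined
    across chromosomes with equal weights (or ``chrom_weights='length'``).

    Returns a RelationshipMatrix tagged IBD-GS; entries are expected
    realised relationships in [0, 2].
    """
    from .relationships import RelationshipMatrix, topological_order

    dosages = np.asarray(dosages, dtype=float)
    if dosages.shape[1] != gmap.n_markers:
        raise ValueError("dosage columns must match the map (unmapped markers "
                         "are not accepted)")
    ped = topological_order(pedigree)
    order = pd.Series(np.arange(len(pedigree)),
                      index=pedigree["id"]).loc[ped["id"]].to_numpy()
    X = dosages[order]
    n = len(ped)
    if posteriors is None:
        posteriors = transmission_posteriors(X, gmap, ped, epsilon=epsilon)
    else:
        posteriors = np.asarray(posteriors)[order]

    pos_of = {i: k for k, i in enumerate(ped["id"])}
    sire = np.array([pos_of.get(s, -1) for s in ped["sire"]])
    dam = np.array([pos_of.get(d, -1) for d in ped["dam"]])

    chroms = gmap.chrom_slices()
    weights = np.ones(len(chroms))
    if chrom_weights == "length":
        weights = np.array([max(p[-1] - p[0], 1e-9) if len(p) > 1 else 1e-9
                            for _, _, p in chroms])
    elif chrom_weights != "equal":
        raise ValueError("chrom_weights must be 'equal' or 'length'")
    weights = weights / weights.sum()

    A = np.zeros((n, n))
    for (_, sl, pos), w in zip(chroms, weights):
        mc = sl.stop - sl.start
        k_eval = min(n_eval_points, mc)
        grid = np.unique(np.linspace(sl.start, sl.stop - 1, k_eval).astype(int))
        A_chrom = np.zeros((n, n))
        for chunk in np.array_split(grid, max(1, len(grid) // 8)):
            K = len(chunk)
            R = np.zeros((K, 2 * n, 2 * n))
            idx = np.arange(2 * n)
            R[:, idx, idx] = 1.0
            for i in range(n):
                for side, par in ((0, sire[i]), (1, dam[i])):
                    if par < 0:
                        continue
                    gam = 2 * i + side
                    p0 = posteriors[i, side, chunk]           # (K,)
                    row = (p0[:, None] * R[:, 2 * par, :]
                           + (1 - p0)[:, None] * R[:, 2 * par + 1, :])
                    R[:, gam, :] = row
                    R[:, :, gam] = row
                    R[:, gam, gam] = 1.0
            A_chunk = 0.5 * (R[:, 0::2, 0::2] + R[:, 0::2, 1::2]
                             + R[:, 1::2, 0::2] + R[:, 1::2, 1::2])
            A_chrom += A_chunk.sum(axis=0)
        A += w * (A_chrom / len(grid))
    return RelationshipMatrix(ped["id"].to_numpy(), A, "IBD-GS",
                              {"n_eval_points": n_eval_points,
                               "chrom_weights": chrom_weights})
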