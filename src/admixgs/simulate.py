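"""Simulation of admixed, family-structured breeding populations.

The generator emulates the history of a farmed Atlantic salmon nucleus:
several diverged wild founder subpopulations are merged by admixture and
then bred as a closed population for a number of generations with large
full-sib families. It produces

* phased haplotypes over a genetic map, with ground-truth *descent labels*
  (which founder gamete every allele traces to) recorded per marker — the
  gold standard against which linkage-analysis IBD estimation is judged;
* a complete pedigree (id, sire, dam; 0 = unknown);
* true breeding values from randomly placed QTL, rescaled exactly to a
  target base-generation heritability;
* phenotypes: a Gaussian trait (fillet colour) and a skewed count trait
  (lice count) generated on the log-density scale and back-transformed.

Founder divergence follows the Balding–Nichols construction: subpopulation
allele frequencies are Beta((1-F)/F p, (1-F)/F (1-p)) around an ancestral
frequency p, so a single parameter F controls the between-subpopulation
frequency variance 2 F p (1-p) that drives admixture LD. Meiosis is
Haldane: crossover counts are Poisson with mean equal to the chromosome
length in Morgans and breakpoints are uniform on the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream

__all__ = [
    "GeneticMap",
    "FounderModel",
    "BreedingDesign",
    "TraitModel",
    "HaplotypeSet",
    "Founders",
    "Population",
    "TraitValues",
    "FixedEffectDesign",
    "simulate_founders",
    "drop_gamete",
    "breed_population",
    "assign_trait",
    "assign_correlated_traits",
    "generate_phenotypes",
    "select_genotyped",
    "true_ibd_matrix",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GeneticMap:
    """Marker map: per chromosome an id and sorted positions in cM."""

    chromosomes: list  # list of (chrom_id, np.ndarray positions cM)

    def __post_init__(self) -> None:
        chroms = []
        for cid, pos in self.chromosomes:
            pos = np.asarray(pos, dtype=float)
            if np.any(pos < 0):
                raise ValueError(f"chromosome {cid}: negative map position")
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"chromosome {cid}: positions must be non-decreasing")
            chroms.append((cid, pos))
        self.chromosomes = chroms

    @classmethod
    def uniform(cls, n_chrom: int, n_markers: int, length_cm: float) -> "GeneticMap":
        """Evenly spaced markers: ``n_markers`` per chromosome over ``length_cm``."""
        pos = np.linspace(0.0, length_cm, n_markers)
        return cls([(c + 1, pos.copy()) for c in range(n_chrom)])

    @classmethod
    def salmon_like(cls, n_markers_per_chrom: int = 100, length_cm: float = 80.0) -> "GeneticMap":
        """Default 29-chromosome layout (configurable density)."""
        return cls.uniform(29, n_markers_per_chrom, length_cm)

    @property
    def n_markers(self) -> int:
        return sum(len(p) for _, p in self.chromosomes)

    @property
    def total_length_morgans(self) -> float:
        return sum((p[-1] - p[0]) / 100.0 if len(p) > 1 else 0.0
                   for _, p in self.chromosomes)

    def chrom_slices(self) -> list[tuple]:
        """(chrom_id, slice into the concatenated marker axis, positions)."""
        out, start = [], 0
        for cid, pos in self.chromosomes:
            out.append((cid, slice(start, start + len(pos)), pos))
            start += len(pos)
        return out

    def positions_concat(self) -> np.ndarray:
        return np.concatenate([p for _, p in self.chromosomes])

    def chrom_index_per_marker(self) -> np.ndarray:
        return np.concatenate(
            [np.full(len(p), k) for k, (_, p) in enumerate(self.chromosomes)]
        )


@dataclass
class FounderModel:
    """Wild founder structure merged by admixture.

    ``divergence`` is the Balding–Nichols F (in [0, 1)); ``contributions``
    are the admixture proportions of the subpopulations in the synthetic
    base (they must sum to 1).
    """

    n_subpops: int = 2
    divergence: float = 0.15
    ancestral_freq_range: tuple = (0.1, 0.9)
    contributions: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must be within (0, 1)")
        if self.contributions is None:
            self.contributions = tuple([1.0 / self.n_subpops] * self.n_subpops)
        c = np.asarray(self.contributions, dtype=float)
        if len(c) != self.n_subpops or np.any(c < 0) or abs(c.sum() - 1.0) > 1e-12:
            raise ValueError("contributions must be non-negative and sum to 1")


@dataclass
class BreedingDesign:
    """Closed-nucleus breeding design applied each generation.

    Defaults mirror a commercial salmon year-class: 157 full-sib families
    from 99 dams and 97 sires. ``n_generations`` counts generations bred
    after the founders; generation 1 is the admixed F1.
    """

    n_generations: int = 3
    n_sires: int = 97
    n_dams: int = 99
    n_families: int = 157
    offspring_per_family: int = 30
    offspring_per_family_intermediate: int | None = None  # None -> same as final
    mating: str = "partial-factorial"  # or "monogamous"
    selective_genotyping: float | None = None

    def __post_init__(self) -> None:
        if self.n_families > self.n_sires * self.n_dams:
            raise ValueError("more families than available sire x dam pairs")
        if self.mating == "monogamous" and self.n_families > min(self.n_sires, self.n_dams):
            raise ValueError("monogamous mating cannot reuse parents")
        if self.offspring_per_family < 1:
            raise ValueError("offspring_per_family must be >= 1")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")


@dataclass
class TraitModel:
    """Additive polygenic trait architecture.

    ``h2`` is the narrow-sense heritability realised exactly in the base
    generation; ``phen_var`` the phenotypic variance (so genetic variance is
    h2 * phen_var). ``trait_scale`` 'gaussian' emits the trait directly;
    'log-density-count' treats the trait as latent log lice density and
    back-transforms to an integer count via body weight. Defaults for the
    two standard traits: lice resistance h2 = 0.14 on the log-density scale,
    fillet colour h2 = 0.43 Gaussian.
    """

    n_qtl: int = 200
    h2: float = 0.43
    trait_scale: str = "gaussian"  # or "log-density-count"
    qtl_effect_distribution: str = "gaussian"  # or "uniform"
    genetic_correlation: float | None = None
    mean: float = 0.0
    phen_var: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be in (0, 1)")
        if self.trait_scale not in ("gaussian", "log-density-count"):
            raise ValueError(f"unknown trait_scale {self.trait_scale!r}")
        if self.n_qtl < 1:
            raise ValueError("a heritable trait needs n_qtl >= 1")
        if self.genetic_correlation is not None and not -1.0 <= self.genetic_correlation <= 1.0:
            raise ValueError("genetic_correlation must be in [-1, 1]")


@dataclass
class HaplotypeSet:
    """Phased 0/1 haplotypes with ground-truth descent labels.

    ``haps`` and ``descent`` are (n_individuals, 2, n_markers); descent
    holds the founder-gamete identifier each allele was copied from.
    """

    ids: np.ndarray
    haps: np.ndarray
    descent: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        if self.haps.shape != self.descent.shape or self.haps.shape[1] != 2:
            raise ValueError("haps/descent must be (n, 2, m) and congruent")
        if not np.isin(self.haps, (0, 1)).all():
            raise ValueError("alleles must be 0/1")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return self.haps.shape[2]

    def dosages(self) -> np.ndarray:
        return self.haps.sum(axis=1).astype(np.int8)

    def subset(self, index) -> "HaplotypeSet":
        return HaplotypeSet(self.ids[index], self.haps[index], self.descent[index])


@dataclass
class Founders:
    """Founder haplotypes plus their subpopulation labels and model."""

    hapset: HaplotypeSet
    subpops: np.ndarray
    model: FounderModel
    allele_freqs: np.ndarray  # (n_subpops, n_markers)


@dataclass
class Population:
    """A bred population: pedigree + haplotypes for every individual.

    ``pedigree`` has columns id, sire, dam, generation, sex ('M'/'F'),
    with 0 for unknown parents; rows are in id order, parents before
    offspring. ``hapset`` rows align with pedigree rows.
    """

    pedigree: pd.DataFrame
    hapset: HaplotypeSet
    gmap: GeneticMap
    founder_model: FounderModel | None = None

    @property
    def ids(self) -> np.ndarray:
        return self.pedigree["id"].to_numpy()

    def generation_ids(self, gen: int) -> np.ndarray:
        ped = self.pedigree
        return ped.loc[ped["generation"] == gen, "id"].to_numpy()

    @property
    def final_generation(self) -> int:
        return int(self.pedigree["generation"].max())

    def index_of(self, ids) -> np.ndarray:
        lookup = pd.Series(np.arange(len(self.pedigree)), index=self.pedigree["id"])
        return lookup.loc[np.asarray(ids)].to_numpy()


# ---------------------------------------------------------------------------
# founders


def simulate_founders(model: FounderModel, gmap: GeneticMap, n_per_subpop: int,
                      seed: int) -> Founders:
    """Draw founder haplotypes in within-subpopulation linkage equilibrium.

    Subpopulation allele frequencies come from the Balding–Nichols Beta
    construction around a per-marker ancestral frequency; with divergence 0
    all subpopulations share the ancestral frequencies. Every founder
    gamete receives a unique descent label.
    """
    rng = stream(seed, "founders")
    m = gmap.n_markers
    lo, hi = model.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=m)
    F = model.divergence
    if F == 0.0:
        freqs = np.tile(p_anc, (model.n_subpops, 1))
    else:
        a = (1.0 - F) / F
        freqs = rng.beta(a * p_anc, a * (1.0 - p_anc),
                         size=(model.n_subpops, m))
    n = n_per_subpop * model.n_subpops
    subpops = np.repeat(np.arange(model.n_subpops), n_per_subpop)
    u = rng.random(size=(n, 2, m))
    haps = (u < freqs[subpops][:, None, :]).astype(np.uint8)
    descent = np.broadcast_to(
        (np.arange(2 * n, dtype=np.int32).reshape(n, 2))[:, :, None], (n, 2, m)
    ).copy()
    ids = np.arange(1, n + 1)
    return Founders(HaplotypeSet(ids, haps, descent), subpops, model, freqs)


# ---------------------------------------------------------------------------
# meiosis


def drop_gamete(parent_haps: np.ndarray, parent_descent: np.ndarray,
                positions_cm: np.ndarray, rng: np.random.Generator):
    """One meiosis on one chromosome under the Haldane model.

    Crossover count ~ Poisson(length in Morgans), breakpoints uniform on
    the map; the returned haplotype (and its descent labels) is the mosaic
    of the two parental haplotypes. A zero-length chromosome never
    recombines. Returns (haplotype, descent, n_crossovers).
    """
    pos = np.asarray(positions_cm, dtype=float)
    length_m = (pos[-1] - pos[0]) / 100.0 if len(pos) > 1 else 0.0
    n_cross = rng.poisson(length_m) if length_m > 0 else 0
    start = rng.integers(0, 2)
    if n_cross == 0:
        return parent_haps[start].copy(), parent_descent[start].copy(), 0
    breaks = np.sort(rng.uniform(pos[0], pos[-1], size=n_cross))
    # parity of crossovers to the left decides the source haplotype
    n_left = np.searchsorted(breaks, pos, side="right")
    src = (start + n_left) % 2
    take = np.arange(len(pos))
    return parent_haps[src, take].copy(), parent_descent[src, take].copy(), int(n_cross)


def _drop_genome(hapset: HaplotypeSet, parent_row: int, gmap: GeneticMap,
                 rng: np.random.Generator):
    hap = np.empty(gmap.n_markers, dtype=np.uint8)
    desc = np.empty(gmap.n_markers, dtype=np.int32)
    for _, sl, pos in gmap.chrom_slices():
        h, d, _ = drop_gamete(hapset.haps[parent_row][:, sl],
                              hapset.descent[parent_row][:, sl], pos, rng)
        hap[sl], desc[sl] = h, d
    return hap, desc


# ---------------------------------------------------------------------------
# breeding


def _pair_families(sires, dams, n_families, mating, rng):
    if mating == "monogamous":
        s = rng.permutation(sires)[:n_families]
        d = rng.permutation(dams)[:n_families]
        return list(zip(s, d))
    # partial factorial: parents reused as evenly as possible, pairs distinct
    reps_s = int(np.ceil(n_families / len(sires)))
    reps_d = int(np.ceil(n_families / len(dams)))
    for _ in range(100):
        s = np.concatenate([rng.permutation(sires) for _ in range(reps_s)])[:n_families]
        d = np.concatenate([rng.permutation(dams) for _ in range(reps_d)])[:n_families]
        pairs = list(zip(s, d))
        if len(set(pairs)) == n_families:
            return pairs
    raise RuntimeError("could not form distinct sire x dam pairs")


def breed_population(founders: Founders, design: BreedingDesign, gmap: GeneticMap,
                     seed: int) -> Population:
    """Breed an admixed population from the founders.

    Generation 1 (the admixed F1) draws each parent from a subpopulation
    sampled by the founder-model contributions; later generations mate
    within the closed population. Descent labels are propagated through
    every meiosis, so true IBD is known throughout.
    """
    rng = stream(seed, "breeding")
    fh = founders.hapset
    n_markers = gmap.n_markers
    if fh.n_markers != n_markers:
        raise ValueError("founder haplotypes do not match the map")

    ids = list(fh.ids)
    sires = [0] * fh.n
    dams = [0] * fh.n
    gens = [0] * fh.n
    sexes = list(rng.permuted(np.where(np.arange(fh.n) % 2 == 0, "M", "F")))
    haps = [fh.haps]
    descent = [fh.descent]
    row_of = {i: k for k, i in enumerate(ids)}

    for g in range(1, design.n_generations + 1):
        if g == 1:
            # admixture cross: pick each parent's subpop by the contributions
            males = [i for i, s in zip(ids, sexes) if s == "M" and gens[row_of[i]] == 0]
            females = [i for i, s in zip(ids, sexes) if s == "F" and gens[row_of[i]] == 0]
            by_pop_m = {k: [i for i in males if founders.subpops[row_of[i]] == k]
                        for k in range(founders.model.n_subpops)}
            by_pop_f = {k: [i for i in females if founders.subpops[row_of[i]] == k]
                        for k in range(founders.model.n_subpops)}

            def pick(pool_by_pop, n):
                if sum(len(p) for p in pool_by_pop.values()) < n:
                    raise ValueError("not enough founders for the design")
                pops = rng.choice(founders.model.n_subpops, size=n,
                                  p=founders.model.contributions)
                out = []
                for k in pops:
                    pool = pool_by_pop[int(k)]
                    if not pool:
                        # overflow beyond a subpopulation's supply spills to
                        # the largest remaining pool
                        pool = max(pool_by_pop.values(), key=len)
                    out.append(pool.pop(rng.integers(len(pool))))
                return out

            gen_sires = pick(by_pop_m, min(design.n_sires, len(males)))
            gen_dams = pick(by_pop_f, min(design.n_dams, len(females)))
        else:
            prev = [i for i in ids if gens[row_of[i]] == g - 1]
            males = [i for i in prev if sexes[row_of[i]] == "M"]
            females = [i for i in prev if sexes[row_of[i]] == "F"]
            if len(males) < 1 or len(females) < 1:
                raise ValueError("previous generation lacks one sex entirely")
            gen_sires = list(rng.choice(males, size=min(design.n_sires, len(males)),
                                        replace=False))
            gen_dams = list(rng.choice(females, size=min(design.n_dams, len(females)),
                                       replace=False))
        n_fam = min(design.n_families, len(gen_sires) * len(gen_dams))
        pairs = _pair_families(gen_sires, gen_dams, n_fam, design.mating, rng)

        off_n = design.offspring_per_family
        if g < design.n_generations and design.offspring_per_family_intermediate:
            off_n = design.offspring_per_family_intermediate
        n_new = n_fam * off_n
        new_haps = np.empty((n_new, 2, n_markers), dtype=np.uint8)
        new_desc = np.empty((n_new, 2, n_markers), dtype=np.int32)
        k = 0
        next_id = ids[-1] + 1
        for s_id, d_id in pairs:
            for _ in range(off_n):
                hs, ds_ = _drop_from(haps, descent, row_of[s_id], gmap, rng)
                hd, dd = _drop_from(haps, descent, row_of[d_id], gmap, rng)
                new_haps[k, 0], new_desc[k, 0] = hs, ds_
                new_haps[k, 1], new_desc[k, 1] = hd, dd
                ids.append(next_id)
                row_of[next_id] = len(ids) - 1
                sires.append(s_id)
                dams.append(d_id)
                gens.append(g)
                sexes.append("M" if rng.random() < 0.5 else "F")
                next_id += 1
                k += 1
        haps.append(new_haps)
        descent.append(new_desc)

    all_haps = np.concatenate(haps, axis=0)
    all_desc = np.concatenate(descent, axis=0)
    ped = pd.DataFrame({"id": ids, "sire": sires, "dam": dams,
                        "generation": gens, "sex": sexes})
    return Population(ped, HaplotypeSet(np.asarray(ids), all_haps, all_desc),
                      gmap, founders.model)


def _drop_from(haps_blocks, desc_blocks, row, gmap, rng):
    # locate the block holding this row; blocks are stacked in id order
    offset = 0
    for hb, db in zip(haps_blocks, desc_blocks):
        if row < offset + len(hb):
            r = row - offset
            hap = np.empty(gmap.n_markers, dtype=np.uint8)
            desc = np.empty(gmap.n_markers, dtype=np.int32)
            for _, sl, pos in gmap.chrom_slices():
                h, d, _ = drop_gamete(hb[r][:, sl], db[r][:, sl], pos, rng)
                hap[sl], desc[sl] = h, d
            return hap, desc
        offset += len(hb)
    raise IndexError(row)


# ---------------------------------------------------------------------------
# traits and phenotypes


@dataclass
class TraitValues:
    """True breeding values plus the QTL catalogue behind them."""

    name: str
    model: TraitModel
    tbv: np.ndarray          # aligned with Population rows
    qtl_indices: np.ndarray
    effects: np.ndarray
    sigma_g2: float
    sigma_e2: float


def _base_rows(pop: Population, base_generation: int) -> np.ndarray:
    return (pop.pedigree["generation"] == base_generation).to_numpy()


def assign_trait(pop: Population, trait: TraitModel, seed: int,
                 base_generation: int = 0, exclude_markers=None) -> TraitValues:
    """Sample QTL and compute true breeding values.

    QTL are drawn from the mapped markers (optionally excluding indices that
    the analysis panel will use); effects are rescaled so the realised
    genetic variance among base-generation individuals equals exactly
    h2 * phen_var, and the residual variance is set to (1 - h2) * phen_var.
    """
    rng = stream(seed, "trait", trait.trait_scale, trait.n_qtl)
    m = pop.hapset.n_markers
    candidates = np.arange(m)
    if exclude_markers is not None:
        candidates = np.setdiff1d(candidates, np.asarray(exclude_markers))
    if trait.n_qtl > len(candidates):
        raise ValueError("n_qtl exceeds available markers")
    qtl = np.sort(rng.choice(candidates, size=trait.n_qtl, replace=False))
    if trait.qtl_effect_distribution == "gaussian":
        eff = rng.standard_normal(trait.n_qtl)
    elif trait.qtl_effect_distribution == "uniform":
        eff = rng.uniform(-1, 1, trait.n_qtl)
    else:
        raise ValueError(f"unknown effect distribution {trait.qtl_effect_distribution!r}")
    X = pop.hapset.dosages()[:, qtl].astype(float)
    a = X @ eff
    base = _base_rows(pop, base_generation)
    v = a[base].var()
    if v <= 0:
        raise ValueError("QTL effects give zero base-generation variance; cannot rescale")
    target_g = trait.h2 * trait.phen_var
    scale = np.sqrt(target_g / v)
    return TraitValues(name="trait", model=trait, tbv=a * scale,
                       qtl_indices=qtl, effects=eff * scale,
                       sigma_g2=target_g, sigma_e2=(1.0 - trait.h2) * trait.phen_var)


def assign_correlated_traits(pop: Population, trait1: TraitModel, trait2: TraitModel,
                             rho: float, seed: int, base_generation: int = 0):
    """Two traits on a shared QTL set with an exact base-generation genetic
    correlation.

    Effects for trait 2 are re-expressed as a linear combination of the two
    raw effect vectors so that corr(TBV1, TBV2) among base individuals is
    exactly ``rho`` (any linear combination of genic values is itself a
    genic value, so trait 2 remains a proper QTL trait).
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must be in (-1, 1)")
    rng = stream(seed, "trait-pair")
    n_qtl = trait1.n_qtl
    m = pop.hapset.n_markers
    qtl = np.sort(rng.choice(m, size=n_qtl, replace=False))
    e1 = rng.standard_normal(n_qtl)
    e2 = rng.standard_normal(n_qtl)
    X = pop.hapset.dosages()[:, qtl].astype(float)
    base = _base_rows(pop, base_generation)
    a1, a2 = X[base] @ e1, X[base] @ e2
    # orthogonalise a2 against a1, then mix back at angle rho
    beta = np.mean((a1 - a1.mean()) * (a2 - a2.mean())) / a1.var()
    e_res = e2 - beta * e1
    r = X[base] @ e_res
    if a1.std() == 0 or r.std() == 0:
        raise ValueError("degenerate QTL effects; cannot impose correlation")
    u1 = e1 / a1.std()
    u_res = e_res / r.std()
    eff1 = u1 * np.sqrt(trait1.h2 * trait1.phen_var)
    eff2 = (rho * u1 + np.sqrt(1 - rho * rho) * u_res) * np.sqrt(trait2.h2 * trait2.phen_var)
    X_all = pop.hapset.dosages()[:, qtl].astype(float)
    tv1 = TraitValues("trait1", trait1, X_all @ eff1, qtl, eff1,
                      trait1.h2 * trait1.phen_var, (1 - trait1.h2) * trait1.phen_var)
    tv2 = TraitValues("trait2", trait2, X_all @ eff2, qtl, eff2,
                      trait2.h2 * trait2.phen_var, (1 - trait2.h2) * trait2.phen_var)
    return tv1, tv2


@dataclass
class FixedEffectDesign:
    """Nuisance structure of the phenotyping: challenge tests, the person
    counting lice on a given day, and fish gender.

    ``person_day_sd`` is the SD of random person-by-day level effects
    (fitted as fixed in analysis); ``gender_effect`` the male-minus-female
    shift on the Gaussian trait. Body weight is lognormal with the given
    mean/SD in grams.
    """

    n_tests: int = 2
    persons_per_test: int = 4
    person_day_sd: float = 0.25
    gender_effect: float = 0.2
    test_effect_sd: float = 0.3
    bw_mean_g: float = 800.0
    bw_sd_g: float = 290.0


def generate_phenotypes(pop: Population, trait_values, seed: int,
                        design: FixedEffectDesign | None = None,
                        generation: int | None = None) -> pd.DataFrame:
    """Emit a phenotype table for one generation (default: the last).

    ``trait_values`` maps role -> TraitValues with roles 'lice'
    (log-density-count scale) and/or 'color' (Gaussian). For the lice trait
    the latent value mu + fixed + a + e lives on the log-density (LogLD)
    scale; an integer lice count is recovered as
    max(0, round(exp(latent) * BW^(2/3) - 1)), which reproduces the skewed
    count distribution while LogLD recomputed from (LC, BW) stays normal up
    to rounding.

    Columns: id, test, person_day, gender, bw_g, lc, fc (missing trait ->
    NaN column).
    """
    design = design or FixedEffectDesign()
    rng = stream(seed, "phenotypes")
    gen = pop.final_generation if generation is None else generation
    ids = pop.generation_ids(gen)
    rows = pop.index_of(ids)
    n = len(ids)
    if n == 0:
        raise ValueError("no individuals in the requested generation")

    ped = pop.pedigree.iloc[rows]
    gender = ped["sex"].to_numpy()
    test = rng.integers(1, design.n_tests + 1, size=n)
    person = rng.integers(1, design.persons_per_test + 1, size=n)
    person_day = np.array([f"t{t}p{p}" for t, p in zip(test, person)])
    levels = sorted(set(person_day))
    pd_eff = dict(zip(levels, rng.normal(0, design.person_day_sd, len(levels))))
    test_eff = dict(zip(range(1, design.n_tests + 1),
                        rng.normal(0, design.test_effect_sd, design.n_tests)))
    fe = np.array([pd_eff[l] for l in person_day]) + np.array([test_eff[t] for t in test])

    sig2 = np.log(1 + (design.bw_sd_g / design.bw_mean_g) ** 2)
    bw = rng.lognormal(np.log(design.bw_mean_g) - sig2 / 2, np.sqrt(sig2), size=n)

    out = pd.DataFrame({"id": ids, "test": test, "person_day": person_day,
                        "gender": gender, "bw_g": bw,
                        "lc": np.nan, "fc": np.nan})
    for role, tv in trait_values.items():
        a = tv.tbv[rows]
        e = rng.normal(0, np.sqrt(tv.sigma_e2), size=n) if tv.sigma_e2 > 0 else np.zeros(n)
        if role == "lice":
            latent = tv.model.mean + fe + a + e
            lc = np.maximum(0, np.round(np.exp(latent) * bw ** (2.0 / 3.0) - 1.0))
            out["lc"] = lc.astype(int)
            out["logld_latent"] = latent
        elif role == "color":
            g_shift = np.where(gender == "M", design.gender_effect / 2,
                               -design.gender_effect / 2)
            out["fc"] = tv.model.mean + g_shift + a + e
        else:
            raise ValueError(f"unknown trait role {role!r}")
    return out


def select_genotyped(trait_table: pd.DataFrame, pedigree: pd.DataFrame,
                     fraction: float, mode: str = "random", seed: int = 0,
                     on: str = "logld") -> np.ndarray:
    """Choose which phenotyped individuals are genotyped.

    'random' is a simple random sample; 'extreme-families' ranks full-sib
    families by family-mean phenotype (column ``on``) and takes families
    alternately from both tails until the fraction is reached — emulating
    selective genotyping of high/low families.
    """
    if len(trait_table) == 0:
        raise ValueError("empty phenotype table")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = stream(seed, "genotyped", mode)
    ids = trait_table["id"].to_numpy()
    n_take = int(np.ceil(fraction * len(ids)))
    if mode == "random":
        return np.sort(rng.choice(ids, size=n_take, replace=False))
    if mode != "extreme-families":
        raise ValueError(f"unknown mode {mode!r}")
    ped = pedigree.set_index("id")
    fam = [(ped.loc[i, "sire"], ped.loc[i, "dam"]) for i in ids]
    df = trait_table.assign(_fam=pd.Series(fam, index=trait_table.index))
    means = df.groupby("_fam")[on].mean().sort_values()
    order = []
    lo, hi = 0, len(means) - 1
    while lo <= hi:
        order.append(means.index[hi]); hi -= 1
        if lo <= hi:
            order.append(means.index[lo]); lo += 1
    chosen: list = []
    for f in order:
        chosen.extend(df.loc[df["_fam"] == f, "id"].tolist())
        if len(chosen) >= n_take:
            break
    return np.sort(np.asarray(chosen))


# ---------------------------------------------------------------------------
# ground truth


def true_ibd_matrix(hapset: HaplotypeSet, rows=None) -> np.ndarray:
    """Realised additive relationships from descent labels.

    a_ij = 1/2 sum over the four gamete pairs of the genome fraction with
    identical founder-gamete labels (equal marker weights). Diagonal is
    1 + true inbreeding. This is the gold standard for IBD estimation.
    """
    d = hapset.descent if rows is None else hapset.descent[rows]
    n, _, m = d.shape
    g = d.reshape(n * 2, m)
    A = np.zeros((n * 2, n * 2))
    for i in range(n * 2):
        A[i, i:] = (g[i] == g[i:]).mean(axis=1)
        A[i:, i] = A[i, i:]
    return 0.5 * (A[0::2, 0::2] + A[0::2, 1::2] + A[1::2, 0::2] + A[1::2, 1::2])
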