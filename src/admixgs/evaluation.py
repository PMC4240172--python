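"""Model comparison by cross-validated reliability.

Individuals that are both phenotyped and genotyped are split into k random
validation folds. Each fold is predicted in turn with its phenotypes
masked: the model is refit on the remaining records (validation animals
stay in the relationship matrix, so information flows to them only through
relatives) and the squared correlation between predicted breeding values
and the masked phenotypes, pooled over folds, estimates the predictive
ability R^2_EBV,y. Dividing by the heritability turns it into the
reliability of the EBV as a predictor of the true breeding value,

    R^2_EBV,BV = R^2_EBV,y / h^2,

and models are compared as percent gain in reliability over the
pedigree-only model. Variance components are estimated once, from all
data, with the pedigree model, and reused unchanged in every model and
fold (the identical-variance-components convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_seed, stream
from . import simulate as sim
from . import traits as tr
from .config import ScenarioConfig
from .mixed_models import ModelSpec, VarianceComponents, reml, solve_mme
from .relationships import (RelationshipMatrix, adjust_to_pedigree,
                            grm_vanraden2, make_marker_subsets,
                            numerator_relationship, single_step_h)
from .ibd import ibd_relationship

__all__ = [
    "kfold_split",
    "reliability",
    "relative_gain",
    "cross_validate",
    "density_sweep",
    "run_scenario",
    "prune_to_ancestors",
    "CVReport",
]


def kfold_split(ids, k: int, seed: int) -> pd.Series:
    """Random partition of ids into k folds with sizes differing by <= 1.

    Returns a Series fold-number (0..k-1) indexed by id.
    """
    ids = np.asarray(ids)
    n = len(ids)
    if k < 2 or k > n:
        raise ValueError("need 2 <= k <= n")
    perm = stream(seed, "kfold").permutation(n)
    fold = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(np.arange(n), k)):
        fold[perm[chunk]] = f
    return pd.Series(fold, index=ids, name="fold")


def reliability(ebv, y, h2: float) -> float:
    """r(EBV, y)^2 / h2; NaN when the EBVs have no variance.

    Finite-sample values above 1 are possible and returned as-is (with a
    warning) rather than truncated.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    ebv = np.asarray(ebv, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(ebv) < 3:
        raise ValueError("need at least 3 pairs")
    if ebv.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance EBVs or phenotypes; reliability undefined")
        return np.nan
    r = np.corrcoef(ebv, y)[0, 1]
    rel = r * r / h2
    if rel > 1.0:
        warnings.warn(f"reliability {rel:.3f} exceeds 1 (finite-sample)")
    return float(rel)


def relative_gain(model_rel: float, ped_rel: float) -> float:
    """Percent gain in reliability over the pedigree model."""
    if not ped_rel > 0:
        raise ValueError("PED reliability must be positive")
    gain = 100.0 * (model_rel / ped_rel - 1.0)
    if gain < 0:
        warnings.warn(f"model below PED ({gain:.1f}%)")
    return gain


@dataclass
class CVReport:
    """Tidy cross-validation results plus bookkeeping."""

    table: pd.DataFrame                 # model, r2, reliability, ...
    predictions: pd.DataFrame           # id, fold, model, ebv, y
    folds: pd.Series
    h2: float
    masking_verified: bool = True
    meta: dict = field(default_factory=dict)


def cross_validate(models: dict, spec: ModelSpec, table: pd.DataFrame,
                   folds: pd.Series, vc: VarianceComponents) -> CVReport:
    """k-fold masked-phenotype cross-validation of one or more models.

    ``models`` maps a model name to its RelationshipMatrix (each must
    contain every cross-validated id). For each fold the phenotypes of the
    validation ids are removed, the model refit on the rest, and the
    validation EBVs recorded. Reliability is reported pooled over folds
    (default estimand) and as the mean of per-fold values.
    """
    cv_ids = np.asarray(folds.index)
    have_y = set(table.loc[table[spec.response].notna(), "id"])
    if not set(cv_ids) <= have_y:
        raise ValueError("every cross-validated id needs a phenotype")
    h2 = vc.h2
    preds = []
    masking_ok = True
    for f in sorted(folds.unique()):
        val_ids = set(folds.index[folds == f])
        if not val_ids:
            raise ValueError(f"fold {f} empty")
        train = table[~table["id"].isin(val_ids)]
        if train[spec.response].notna().sum() == 0:
            raise ValueError(f"fold {f} leaves no training phenotypes")
        masking_ok &= not (set(train["id"]) & val_ids)
        for name, relmat in models.items():
            fit = solve_mme(spec, train, relmat, vc, model_tag=name)
            ebv = fit.ebv.set_index("id")["ebv"]
            for i in sorted(val_ids):
                preds.append({"id": i, "fold": f, "model": name,
                              "ebv": ebv.loc[i]})
    preds = pd.DataFrame(preds)
    yv = table.set_index("id")[spec.response]
    preds["y"] = yv.loc[preds["id"]].to_numpy()

    rows = []
    for name, g in preds.groupby("model"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rel_pool = reliability(g["ebv"], g["y"], h2)
            by_fold = [reliability(gf["ebv"], gf["y"], h2)
                       for _, gf in g.groupby("fold")]
        r2 = rel_pool * h2 if np.isfinite(rel_pool) else np.nan
        rows.append({"model": name, "n": len(g), "r2_ebv_y": r2,
                     "reliability": rel_pool,
                     "reliability_foldmean": float(np.nanmean(by_fold)),
                     "reliability_foldse": float(np.nanstd(by_fold, ddof=1)
                                                 / np.sqrt(len(by_fold)))})
    out = pd.DataFrame(rows)
    if "PED" in set(out["model"]):
        ped = float(out.loc[out["model"] == "PED", "reliability"].iloc[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["gain_vs_ped_pct"] = [
                relative_gain(r, ped) if ped > 0 and np.isfinite(r) else np.nan
                for r in out["reliability"]]
    return CVReport(out, preds, folds, h2, masking_ok)


def prune_to_ancestors(pedigree: pd.DataFrame, ids) -> pd.DataFrame:
    """Restrict a pedigree to ``ids`` and all their ancestors."""
    parents = {r.id: (r.sire, r.dam) for r in pedigree.itertuples()}
    keep = set()
    stack = list(np.asarray(ids))
    while stack:
        i = stack.pop()
        if i in keep or i == 0 or i not in parents:
            continue
        keep.add(i)
        stack.extend(parents[i])
    return pedigree[pedigree["id"].isin(keep)].reset_index(drop=True)


def _genomic_model_matrix(G_raw: RelationshipMatrix, A: RelationshipMatrix,
                          cv_ids, adjust: bool = True) -> RelationshipMatrix:
    """Adjust a genomic matrix to A's base and, when ungenotyped animals
    carry phenotypes, propagate it through the single-step H matrix."""
    geno_ids = G_raw.ids
    A22 = A.restrict(geno_ids)
    G = adjust_to_pedigree(G_raw, A22) if adjust else G_raw
    if set(np.asarray(cv_ids).tolist()) <= set(geno_ids.tolist()):
        return G
    H, _ = single_step_h(A, G, geno_ids)
    return H


def density_sweep(dosages: np.ndarray, geno_ids, gmap, A: RelationshipMatrix,
                  spec: ModelSpec, table: pd.DataFrame, folds: pd.Series,
                  vc: VarianceComponents, densities, replicates, seed: int,
                  include_ped: bool = True, ibd_matrix=None,
                  adjust: bool = True) -> pd.DataFrame:
    """Cross-validate GBLUP over disjoint random marker panels per density.

    ``dosages`` rows align with ``geno_ids``. Results are averaged over
    the replicate panels of each density; the PED model and an optional
    precomputed IBD-GS matrix are evaluated alongside for reference.
    Returns a tidy table (model, density, replicate, reliability, ...).
    """
    rows = []
    base_models = {}
    if include_ped:
        base_models["PED"] = A
    if ibd_matrix is not None:
        base_models["IBD-GS"] = _genomic_model_matrix(
            ibd_matrix.restrict(geno_ids), A, folds.index, adjust)
    if base_models:
        rep = cross_validate(base_models, spec, table, folds, vc)
        for r in rep.table.to_dict("records"):
            rows.append({**r, "density": None, "replicate": 0})

    subsets = make_marker_subsets(dosages.shape[1], densities, replicates,
                                  child_seed(seed, "subsets"))
    for sub in subsets:
        G_raw = grm_vanraden2(dosages, ids=geno_ids, marker_subset=sub)
        Gm = _genomic_model_matrix(G_raw, A, folds.index, adjust)
        rep = cross_validate({"GBLUP": Gm}, spec, table, folds, vc)
        for r in rep.table.to_dict("records"):
            rows.append({**r, "density": sub.density, "replicate": sub.replicate})
    out = pd.DataFrame(rows)
    ped = out.loc[out["model"] == "PED", "reliability"]
    if len(ped) and float(ped.iloc[0]) > 0:
        p = float(ped.iloc[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["gain_vs_ped_pct"] = [
                relative_gain(r, p) if np.isfinite(r) else np.nan
                for r in out["reliability"]]
    return out


def run_scenario(cfg: ScenarioConfig, seed: int) -> dict:
    """Simulate one admixed scenario and evaluate all models on it.

    Returns a dict with the per-trait sweep tables ('lice', 'color'), the
    PED-estimated variance components, the population and the phenotype
    table. This is the end-to-end driver behind the experiment CLI.
    """
    gmap = sim.GeneticMap.uniform(cfg.n_chrom, cfg.markers_per_chrom,
                                  cfg.chrom_length_cm)
    fmodel = sim.FounderModel(cfg.n_subpops, cfg.divergence,
                              cfg.ancestral_freq_range, cfg.contributions)
    founders = sim.simulate_founders(fmodel, gmap, cfg.n_founders_per_subpop,
                                     child_seed(seed, "founders"))
    design = sim.BreedingDesign(
        n_generations=cfg.n_generations, n_sires=cfg.n_sires,
        n_dams=cfg.n_dams, n_families=cfg.n_families,
        offspring_per_family=cfg.offspring_per_family,
        offspring_per_family_intermediate=cfg.offspring_per_family_intermediate,
        mating=cfg.mating)
    pop = sim.breed_population(founders, design, gmap, child_seed(seed, "breed"))

    tv_lice = sim.assign_trait(
        pop, sim.TraitModel(cfg.lice_n_qtl, cfg.lice_h2, "log-density-count",
                            mean=cfg.lice_mean, phen_var=cfg.lice_phen_var),
        child_seed(seed, "lice"))
    tv_color = sim.assign_trait(
        pop, sim.TraitModel(cfg.color_n_qtl, cfg.color_h2, "gaussian",
                            mean=cfg.color_mean, phen_var=cfg.color_phen_var),
        child_seed(seed, "color"))
    pheno = sim.generate_phenotypes(pop, {"lice": tv_lice, "color": tv_color},
                                    child_seed(seed, "pheno"))
    pheno = tr.derive(pheno)

    geno_ids = sim.select_genotyped(pheno, pop.pedigree, cfg.genotyped_fraction,
                                    cfg.genotyped_mode,
                                    child_seed(seed, "geno"), on="logld")

    ped = prune_to_ancestors(pop.pedigree, pheno["id"])
    A = numerator_relationship(ped)
    ped_ids = ped["id"].to_numpy()
    dos_all = pop.hapset.dosages().astype(float)[pop.index_of(ped_ids)]
    # ancestors of the test generation are genotyped too (they anchor the
    # linkage analysis); among phenotyped fish only the selected subset is
    geno_mask = np.isin(ped_ids, geno_ids) | ~np.isin(ped_ids, pheno["id"])
    dos_masked = dos_all.copy()
    dos_masked[~geno_mask] = np.nan

    ibd = None
    if "IBD-GS" in cfg.models:
        ibd = ibd_relationship(dos_masked, gmap, ped,
                               n_eval_points=cfg.ibd_eval_points)

    m = gmap.n_markers
    densities = cfg.densities or (m // 4, m)
    replicates = [cfg.density_replicates if d * cfg.density_replicates <= m else 1
                  for d in densities]
    lookup = pd.Series(np.arange(len(ped_ids)), index=ped_ids)
    dos_geno = dos_all[lookup.loc[geno_ids].to_numpy()]

    out = {"population": pop, "phenotypes": pheno, "genotyped": geno_ids,
           "A": A, "vc": {}, "true": {"lice": tv_lice, "color": tv_color}}
    for trait, resp, fes in (("lice", "logld", ["person_day"]),
                             ("color", "fc", ["gender"])):
        spec = ModelSpec(resp, fes)
        fit = reml(spec, pheno, A)
        vc = fit.vc
        out["vc"][trait] = fit
        folds = kfold_split(geno_ids, cfg.k_folds, child_seed(seed, "folds", trait))
        sweep = density_sweep(
            dos_geno, geno_ids, gmap, A, spec, pheno, folds, vc,
            densities, replicates, child_seed(seed, "sweep", trait),
            include_ped="PED" in cfg.models,
            ibd_matrix=ibd, adjust=cfg.adjust_g)
        sweep.insert(0, "trait", trait)
        sweep["h2_used"] = vc.h2
        out[trait] = sweep
    return out
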