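"""Plain-text interchange: PLINK .ped/.map, pedigree / phenotype / true-value
CSV dialects and descent-label TSV.

The PLINK dialect is the classic text one: the .map has four columns
(chromosome, marker name, position in cM, bp position — bp written as 0)
and the .ped has the six leading columns (family, id, sire, dam, sex,
phenotype) followed by two allele columns per marker coded 1/2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import GeneticMap, HaplotypeSet, Population

__all__ = [
    "write_plink", "read_plink", "write_pedigree", "read_pedigree",
    "write_phenotypes", "read_phenotypes", "write_true_values",
    "write_descent",
]


def write_plink(prefix: str, pop: Population, ids=None) -> None:
    """Write haplotypes as <prefix>.ped/.map (alleles 1/2, phased order)."""
    gmap = pop.gmap
    with open(f"{prefix}.map", "w") as fh:
        k = 0
        for cid, pos in gmap.chromosomes:
            for p in pos:
                fh.write(f"{cid}\tm{k}\t{p:.6g}\t0\n")
                k += 1
    ped = pop.pedigree.set_index("id")
    use = pop.ids if ids is None else np.asarray(ids)
    rows = pop.index_of(use)
    with open(f"{prefix}.ped", "w") as fh:
        for i, r in zip(use, rows):
            rec = ped.loc[i]
            sex = 1 if rec["sex"] == "M" else 2
            alleles = (pop.hapset.haps[r].T + 1).reshape(-1)  # a1 b1 a2 b2 ...
            fh.write(f"FAM {i} {rec['sire']} {rec['dam']} {sex} -9 "
                     + " ".join(map(str, alleles)) + "\n")


def read_plink(prefix: str):
    """Read <prefix>.ped/.map back into (ids, pedigree, HaplotypeSet, GeneticMap).

    Descent labels are unknown for externally supplied data and are filled
    with -1.
    """
    mp = pd.read_csv(f"{prefix}.map", sep="\t", header=None,
                     names=["chrom", "name", "cm", "bp"])
    chroms = [(c, g["cm"].to_numpy()) for c, g in mp.groupby("chrom", sort=False)]
    gmap = GeneticMap(chroms)
    ids, sires, dams, sexes, haps = [], [], [], [], []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            ids.append(int(parts[1]))
            sires.append(int(parts[2]))
            dams.append(int(parts[3]))
            sexes.append("M" if parts[4] == "1" else "F")
            alleles = np.array(parts[6:], dtype=int) - 1
            haps.append(alleles.reshape(-1, 2).T)
    haps = np.array(haps, dtype=np.uint8)
    hs = HaplotypeSet(np.array(ids), haps,
                      np.full(haps.shape, -1, dtype=np.int32))
    ped = pd.DataFrame({"id": ids, "sire": sires, "dam": dams,
                        "generation": 0, "sex": sexes})
    return ped, hs, gmap


def write_pedigree(path, pedigree: pd.DataFrame) -> None:
    pedigree[["id", "sire", "dam"]].to_csv(path, index=False)


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path)
    need = {"id", "sire", "dam"}
    if not need <= set(ped.columns):
        raise ValueError(f"pedigree CSV needs columns {sorted(need)}")
    return ped


def write_phenotypes(path, table: pd.DataFrame) -> None:
    cols = [c for c in ("id", "test", "person_day", "gender", "bw_g", "lc", "fc")
            if c in table.columns]
    table[cols].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_true_values(path, pop: Population, trait_values: dict) -> None:
    out = pd.DataFrame({"id": pop.ids})
    for name, tv in trait_values.items():
        out[f"tbv_{name}"] = tv.tbv
    out.to_csv(path, index=False)


def write_descent(path, hapset: HaplotypeSet) -> None:
    """Ground-truth descent labels as TSV (id, hap, labels...)."""
    with open(path, "w") as fh:
        for i, ind in enumerate(hapset.ids):
            for h in range(2):
                fh.write(f"{ind}\t{h}\t"
                         + "\t".join(map(str, hapset.descent[i, h])) + "\n")
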