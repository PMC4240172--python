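"""Scenario configuration: one plain-text (YAML) document drives a full
simulation-and-evaluation experiment."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["ScenarioConfig"]


@dataclass
class ScenarioConfig:
    """Parameters of a complete admixed-population prediction experiment.

    Defaults describe a desk-scale version of a salmon breeding nucleus:
    two diverged wild subpopulations admixed into a closed line, bred for
    three generations with large full-sib families in the evaluated
    generation; a lowly heritable log-density lice trait (h2 = 0.14) and a
    highly heritable Gaussian fillet-colour trait (h2 = 0.43).
    """

    # founders
    n_subpops: int = 2
    divergence: float = 0.15
    contributions: tuple | None = None
    ancestral_freq_range: tuple = (0.1, 0.9)
    n_founders_per_subpop: int = 80
    # genome
    n_chrom: int = 5
    markers_per_chrom: int = 240
    chrom_length_cm: float = 80.0
    # breeding
    n_generations: int = 3
    n_sires: int = 40
    n_dams: int = 40
    n_families: int = 80
    offspring_per_family: int = 12
    offspring_per_family_intermediate: int = 5
    mating: str = "partial-factorial"
    # traits
    lice_h2: float = 0.14
    lice_n_qtl: int = 150
    lice_mean: float = -1.7
    lice_phen_var: float = 0.53
    color_h2: float = 0.43
    color_n_qtl: int = 150
    color_mean: float = 6.8
    color_phen_var: float = 0.96
    # genotyping
    genotyped_fraction: float = 1.0
    genotyped_mode: str = "random"  # or "extreme-families"
    # evaluation
    densities: tuple | None = None       # None -> (m // 4, m)
    density_replicates: int = 3
    k_folds: int = 5
    models: tuple = ("PED", "IBD-GS", "GBLUP")
    ibd_eval_points: int = 12
    adjust_g: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("contributions", "ancestral_freq_range", "densities", "models"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)
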