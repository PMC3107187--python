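"""Synthetic replicate-level datasets and the bundled ID11 phage dataset.

The generator realizes the model the fitter assumes: each single mutant
has a latent phenotype, doubles are phenotypically additive
(``z_ij = z_i + z_j``), genotype mean fitness is the gamma curve at the
genotype's phenotype, and assay replicates scatter normally around the
mean.

The bundled dataset comprises the wild-type microvirid phage ID11, nine
single mutants labeled A-I and 18 constructed double mutants, as
mean-level fitness effects (doublings per hour) with replicate counts.
Per-genotype SEs are not part of the bundled data; analyses needing
replicate-level spread must use the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .assay_io import AssayReplicate, EffectTable
from .errors import ConfigurationError
from .gamma_fit import FitInput
from .gamma_map import GammaMapParams, evaluate

#: the 18 constructed double mutants (out of the 36 possible A-I pairs)
DEFAULT_PAIRS = (
    "AB", "AD", "AF", "AG", "AH",
    "BD", "BE", "BG", "BH", "BI",
    "CD", "CE", "CH",
    "DF", "DH", "DI",
    "EH", "EI",
)

# mean fitness effect relative to the wild type, doublings/hour
ID11_SINGLE_EFFECTS = {
    "A": 3.89, "B": 4.15, "C": 4.18, "D": 3.44, "E": 1.65,
    "F": 3.39, "G": 5.84, "H": 3.44, "I": 1.42,
}
ID11_DOUBLE_EFFECTS = {
    "AB": 3.47, "AD": 3.63, "AF": 2.88, "AG": 7.32, "AH": 5.10,
    "BD": 2.59, "BE": 0.40, "BG": 2.12, "BH": 4.29, "BI": 1.34,
    "CD": 2.34, "CE": -3.62, "CH": 4.31, "DF": 4.12, "DH": 3.30,
    "DI": 0.21, "EH": 1.35, "EI": -2.44,
}
# observed double-mutant mean fitness (absolute scale)
ID11_DOUBLE_FITNESS = {
    "AB": 18.66, "AD": 18.82, "AF": 18.07, "AG": 22.50, "AH": 20.29,
    "BD": 17.77, "BE": 15.58, "BG": 17.31, "BH": 19.47, "BI": 16.52,
    "CD": 17.52, "CE": 11.56, "CH": 19.49, "DF": 19.30, "DH": 18.48,
    "DI": 15.40, "EH": 16.54, "EI": 12.74,
}
#: wild-type mean fitness implied by observed double fitness minus effect
ID11_WT_FITNESS = 15.19
ID11_WT_LABEL = "ID11"
ID11_REPLICATE_COUNTS = {
    "ID11": 14,
    "A": 5, "B": 5, "C": 6, "D": 7, "E": 5, "F": 5, "G": 6, "H": 5, "I": 5,
    "AB": 5, "AD": 5, "AF": 5, "AG": 5, "AH": 5, "BD": 5, "BE": 6, "BG": 7,
    "BH": 5, "BI": 7, "CD": 6, "CE": 6, "CH": 5, "DF": 5, "DH": 5, "DI": 5,
    "EH": 5, "EI": 5,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Model-based replicate generator settings.

    ``single_phenotypes`` are absolute latent phenotypes for the singles;
    doubles sit at the sum of their constituents' phenotypes and the wild
    type at ``z_wt``.
    """

    params: GammaMapParams
    z_wt: float
    single_phenotypes: dict[str, float]
    pairs: tuple[str, ...] = DEFAULT_PAIRS
    noise_sd: float = 0.5
    n_replicates: dict[str, int] = field(default_factory=dict)
    default_n: int = 5
    wild_type_label: str = ID11_WT_LABEL
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if any(z < 0 for z in self.single_phenotypes.values()) or self.z_wt < 0:
            raise ConfigurationError("phenotypes must be >= 0")
        for pair in self.pairs:
            if not (pair[0] in self.single_phenotypes and pair[1] in self.single_phenotypes):
                raise ConfigurationError(f"pair {pair} references undefined singles")

    def genotype_means(self) -> dict[str, float]:
        """Deterministic genotype means: the curve at each phenotype."""
        means = {self.wild_type_label: float(evaluate(self.params, self.z_wt))}
        for g, z in self.single_phenotypes.items():
            means[g] = float(evaluate(self.params, z))
        for pair in self.pairs:
            z = self.single_phenotypes[pair[0]] + self.single_phenotypes[pair[1]]
            means[pair] = float(evaluate(self.params, z))
        return means


def default_config(noise_sd: float = 0.5, seed: int = 0, **overrides) -> GeneratorConfig:
    """A 9-single / 18-double configuration shaped like the bundled data.

    The curve and phenotypes are chosen so effects are a few doublings per
    hour with several singles past the optimum, mirroring the empirical
    structure; replicate counts match the bundled dataset.
    """
    params = GammaMapParams(shape=2.5, scale=1.0, height=10.5, shift=11.0)
    # mode at 1.5; z < 1.5 rising limb, z > 1.5 falling limb.  The lowest
    # genotype mean (the EI double) sits in (shift, shift + 1) so the
    # integer-shift rule recovers the generating shift exactly.
    phenotypes = {
        "A": 0.55, "B": 2.05, "C": 2.10, "D": 0.45, "E": 2.95,
        "F": 1.95, "G": 0.95, "H": 0.50, "I": 3.05,
    }
    cfg = GeneratorConfig(
        params=params,
        z_wt=0.30,
        single_phenotypes=phenotypes,
        noise_sd=noise_sd,
        n_replicates=dict(ID11_REPLICATE_COUNTS),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def generate(config: GeneratorConfig) -> list[AssayReplicate]:
    """Draw replicate assays: genotype mean + iid normal noise.

    Deterministic under ``config.seed``; the means themselves do not
    depend on the seed.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    for genotype, mean in sorted(config.genotype_means().items()):
        n = config.n_replicates.get(genotype, config.default_n)
        noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)
        for i in range(n):
            records.append(AssayReplicate(genotype, i + 1, float(mean + noise[i])))
    return records


def generate_from_means(
    means: dict[str, float],
    noise_sd: float,
    n_replicates: dict[str, int] | int = 5,
    seed: int = 0,
) -> list[AssayReplicate]:
    """Replicates scattered around externally supplied genotype means.

    Used to attach replicate-level spread to mean-only datasets (e.g. the
    bundled one, whose SEs are unknown) for tests that need raw data.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for genotype in sorted(means):
        n = n_replicates if isinstance(n_replicates, int) else n_replicates.get(genotype, 5)
        noise = rng.normal(0.0, noise_sd, size=n)
        for i in range(n):
            records.append(AssayReplicate(genotype, i + 1, float(means[genotype] + noise[i])))
    return records


@dataclass(frozen=True)
class Id11Dataset:
    """Mean-level bundled dataset plus its replicate counts."""

    wild_type_label: str
    wt_fitness: float
    single_effects: dict[str, float]
    double_effects: dict[str, float]
    double_fitness: dict[str, float]
    n_replicates: dict[str, int]
    pairs: dict[str, tuple[str, str]]

    def effect_table(self) -> EffectTable:
        effects = {self.wild_type_label: 0.0}
        effects.update(self.single_effects)
        effects.update(self.double_effects)
        mean = {g: self.wt_fitness + s for g, s in effects.items()}
        # observed double fitnesses take precedence over effect-implied ones
        mean.update(self.double_fitness)
        return EffectTable(self.wild_type_label, effects, dict(self.pairs), mean)

    def fit_input(self) -> FitInput:
        return FitInput(
            wild_type_label=self.wild_type_label,
            wt_fitness=self.wt_fitness,
            single_fitness={
                g: self.wt_fitness + s for g, s in self.single_effects.items()
            },
            double_fitness=dict(self.double_fitness),
            pairs=dict(self.pairs),
        )


def id11_dataset() -> Id11Dataset:
    """The bundled ID11 single/double-mutant fitness dataset."""
    return Id11Dataset(
        wild_type_label=ID11_WT_LABEL,
        wt_fitness=ID11_WT_FITNESS,
        single_effects=dict(ID11_SINGLE_EFFECTS),
        double_effects=dict(ID11_DOUBLE_EFFECTS),
        double_fitness=dict(ID11_DOUBLE_FITNESS),
        n_replicates=dict(ID11_REPLICATE_COUNTS),
        pairs={p: (p[0], p[1]) for p in DEFAULT_PAIRS},
    )
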