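"""Exome-like genotype/phenotype simulator with a known causal answer key.

The generator emulates the structure of the GAW17 unrelated-individuals
benchmark: a fixed cohort of unrelated samples typed at gene-grouped SNPs
whose frequency spectrum is dominated by rare variants, with many phenotype
replicates redrawn over the same genotypes.  Genotypes are binomial(2, maf)
under Hardy–Weinberg with no linkage disequilibrium between variants — a
documented simplification that keeps small-sample oracles exact.

Traits follow the benchmark's archetypes:

* Q1-like — causal minor-allele counts plus Age and Smoking effects plus
  Gaussian noise (covariate-influenced, higher residual heritability);
* Q2-like — causal genotype effects plus noise only (no covariate influence);
* Q4-like — Age and Smoking effects plus noise, zero genotype effect, the
  pure-null trait used for type-I-error estimation;
* a binary trait thresholded from a latent liability that mixes the
  quantitative traits (including the Q4-like noise component), so it is
  deliberately harder to detect than the quantitative traits.

``make_confounded_null`` builds the stratified null used to demonstrate
confounding: two subpopulations with Balding–Nichols-divergent allele
frequencies and shifted Age distributions, a trait that depends on Age only —
so genotype and trait are marginally associated although no gene is causal.

Two presets encode the architectures under which the tests trade places:
``q1like_config`` (all causal MAFs < 5%, where a fixed 5% threshold is hard
to beat) and ``q2like_config`` (one rare plus one common ~17%-MAF causal
variant per causal gene, where only a variable threshold captures both).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import field
from typing import Sequence

import numpy as np
import pandas as pd

from . import core
from .core import GeneRegion, GenotypeMatrix, PhenotypeTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MafDistribution:
    """Two-component MAF law: a rare bulk plus a common admixture.

    Rare MAFs are beta(a, b)-distributed scaled to (0, rare_max]; a fraction
    ``common_prop`` of variants instead draws uniformly from
    [common_min, common_max].  Defaults put ~90% of variants below 5%.
    """

    rare_beta_a: float = 0.8
    rare_beta_b: float = 15.0
    rare_max: float = 0.05
    common_prop: float = 0.10
    common_min: float = 0.05
    common_max: float = 0.50

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        maf = rng.beta(self.rare_beta_a, self.rare_beta_b, size) * self.rare_max
        common = rng.random(size) < self.common_prop
        if common.any():
            maf[common] = rng.uniform(self.common_min, self.common_max, int(common.sum()))
        return maf


@dataclasses.dataclass
class CausalGeneSpec:
    """Causal-variant plan for one gene.

    Either ``n_causal_variants`` draws from ``causal_maf_range`` (a point mass
    when both ends coincide) all with ``effect_size`` per minor-allele copy,
    or an explicit per-variant list ``variant_specs`` of
    ``((maf_lo, maf_hi), effect)`` pairs for mixed architectures such as one
    rare plus one common causal variant.
    """

    n_causal_variants: int = 1
    causal_maf_range: tuple[float, float] = (0.005, 0.03)
    effect_size: float = 0.3
    variant_specs: list[tuple[tuple[float, float], float]] | None = None

    def expanded(self) -> list[tuple[tuple[float, float], float]]:
        if self.variant_specs is not None:
            return list(self.variant_specs)
        return [(self.causal_maf_range, self.effect_size)] * self.n_causal_variants


@dataclasses.dataclass
class TraitSpec:
    """One quantitative trait: optional genotype, Age and Smoking effects."""

    name: str
    uses_genotypes: bool
    age_beta: float = 0.0
    smoking_beta: float = 0.0
    noise_sd: float = 1.0


@dataclasses.dataclass
class BinaryTraitSpec:
    """Liability-threshold binary trait.

    liability = sum_k weight_k * trait_k + N(0, noise_sd); affected status is
    liability above its per-replicate (1 - prevalence) quantile.  Mixing in a
    Q4-like component reproduces the benchmark's noisy disease model.
    """

    name: str = "Affected"
    source_traits: tuple[str, ...] = ()
    weights: tuple[float, ...] = ()
    noise_sd: float = 1.0
    prevalence: float = 0.30


@dataclasses.dataclass
class ConfoundingSpec:
    """Two-subpopulation stratification inducing a genotype–trait link via Age.

    Subpopulation allele frequencies diverge from the base draw under a
    Balding–Nichols model with fixation index ``fst`` (0 = panmictic), and the
    two subpopulations have Age means ``age_mean_shift`` years apart.  The
    confounded trait is ``trait_age_beta * Age + noise`` with no direct
    genotype effect.
    """

    prop_pop2: float = 0.5
    fst: float = 0.05
    age_mean_shift: float = 20.0
    trait_age_beta: float = 0.05
    noise_sd: float = 1.0


@dataclasses.dataclass
class SimulationConfig:
    n_samples: int = 697
    n_genes: int = 100
    variants_per_gene: tuple[int, int] = (6, 14)
    maf_distribution: MafDistribution = field(default_factory=MafDistribution)
    causal_genes: list[CausalGeneSpec] = field(default_factory=list)
    trait_specs: list[TraitSpec] = field(default_factory=list)
    binary_spec: BinaryTraitSpec | None = None
    confounding_spec: ConfoundingSpec | None = None
    age_mean: float = 50.0
    age_sd: float = 12.0
    smoking_prev: float = 0.30
    n_replicates: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0 <= self.smoking_prev <= 1):
            raise ValueError("smoking_prev must be in [0, 1]")
        if len(self.causal_genes) > self.n_genes:
            raise ValueError("more causal gene specs than genes")
        lo, hi = self.variants_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("variants_per_gene must satisfy 1 <= min <= max")
        for spec in self.causal_genes:
            for (mlo, mhi), eff in spec.expanded():
                if not (0 < mlo <= mhi <= 0.5):
                    raise ValueError(f"infeasible causal maf range ({mlo}, {mhi})")
                if not np.isfinite(eff):
                    raise ValueError("effect sizes must be finite")
        if self.binary_spec and len(self.binary_spec.source_traits) != len(
            self.binary_spec.weights
        ):
            raise ValueError("binary_spec source_traits and weights differ in length")


@dataclasses.dataclass
class SimulatedDataset:
    """Genotypes fixed once, phenotypes redrawn per replicate, truth attached."""

    genotypes: GenotypeMatrix
    variants: pd.DataFrame
    regions: list[GeneRegion]
    gene_index: dict[str, np.ndarray]
    phenotypes: list[PhenotypeTable]
    truth: dict[str, list[tuple[str, float]]]
    config: SimulationConfig

    @property
    def causal_genes(self) -> set[str]:
        return set(self.truth)

    def phenotype_frame(self) -> PhenotypeTable:
        """All replicates stacked into one table with a replicate_id column."""
        first = self.phenotypes[0]
        return PhenotypeTable(
            pd.concat([t.data for t in self.phenotypes], ignore_index=True),
            traits=first.traits,
            binary_traits=first.binary_traits,
            covariates=first.covariates,
            replicate_col="replicate_id",
        )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

_GENE_STRIDE = 10_000  # base pairs between consecutive gene blocks


def simulate_genotypes(
    config: SimulationConfig, seed: int | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame, list[GeneRegion], dict[str, list[tuple[str, float]]]]:
    """Draw genotypes, variant metadata, gene regions and the causal answer key.

    Genes are disjoint coordinate blocks on one chromosome, so mapping the
    variant table back through the region file reconstructs the planted gene
    membership exactly.  Causal specs occupy the first ``len(causal_genes)``
    genes; their causal variants get MAFs from the spec's range, everything
    else draws from the configured MAF law.  The returned variant table's
    ``maf`` column is the *sample* estimate (used by all tests downstream),
    not the generating frequency.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.variants_per_gene

    gene_names = [f"G{i:04d}" for i in range(config.n_genes)]
    n_vars = rng.integers(lo, hi + 1, size=config.n_genes)
    truth: dict[str, list[tuple[str, float]]] = {}
    maf_list, vid_list, chrom_list, pos_list = [], [], [], []
    regions: list[GeneRegion] = []
    effects_cols: list[int] = []
    effects_vals: list[float] = []
    col = 0
    for g, gene in enumerate(gene_names):
        m = int(n_vars[g])
        causal = config.causal_genes[g].expanded() if g < len(config.causal_genes) else []
        if len(causal) > m:
            m = len(causal)  # gene must hold all its planted variants
        mafs = config.maf_distribution.draw(rng, m)
        slots = rng.choice(m, size=len(causal), replace=False) if causal else []
        gene_truth = []
        for slot, ((mlo, mhi), eff) in zip(slots, causal):
            mafs[slot] = mlo if mlo == mhi else rng.uniform(mlo, mhi)
            vid = f"{gene}_v{slot:03d}"
            gene_truth.append((vid, float(eff)))
            effects_cols.append(col + int(slot))
            effects_vals.append(float(eff))
        if gene_truth:
            truth[gene] = gene_truth
        start = 1 + g * _GENE_STRIDE
        pos = start + np.arange(m)
        regions.append(GeneRegion(gene, "1", int(start), int(start + m - 1)))
        maf_list.append(mafs)
        vid_list.extend(f"{gene}_v{i:03d}" for i in range(m))
        chrom_list.extend(["1"] * m)
        pos_list.extend(pos.tolist())
        col += m

    maf = np.concatenate(maf_list) if maf_list else np.empty(0)
    counts = rng.binomial(2, maf, size=(config.n_samples, maf.size))
    # near-0.5 generating MAFs can drift above 0.5 in sample; keep minor coding
    gm = GenotypeMatrix([f"S{j:04d}" for j in range(config.n_samples)],
                        core._fold_to_minor(counts))
    variants = pd.DataFrame({"variant_id": vid_list, "chrom": chrom_list, "pos": pos_list})
    variants = core.compute_maf(gm, variants)
    # stash the causal column indices for the trait simulator
    variants.attrs["causal_cols"] = np.asarray(effects_cols, dtype=np.int64)
    variants.attrs["causal_effects"] = np.asarray(effects_vals, dtype=float)
    log.info(
        "simulated %d samples × %d variants in %d genes (%d causal)",
        gm.n_samples, gm.n_variants, config.n_genes, len(truth),
    )
    return gm, variants, regions, truth


def _genetic_value(
    gm: GenotypeMatrix, variants: pd.DataFrame, truth: dict
) -> np.ndarray:
    cols = variants.attrs.get("causal_cols")
    if cols is None:  # rebuilt dataset: recover columns from the truth table
        vid_to_col = {v: i for i, v in enumerate(variants["variant_id"])}
        cols, effs = [], []
        for pairs in truth.values():
            for vid, eff in pairs:
                cols.append(vid_to_col[vid])
                effs.append(eff)
        cols = np.asarray(cols, dtype=np.int64)
        effects = np.asarray(effs, dtype=float)
    else:
        effects = variants.attrs["causal_effects"]
    if cols.size == 0:
        return np.zeros(gm.n_samples)
    return gm.counts[:, cols].astype(float) @ effects


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def simulate_traits(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    truth: dict[str, list[tuple[str, float]]],
    config: SimulationConfig,
    seed: int | None = None,
) -> list[PhenotypeTable]:
    """Draw ``n_replicates`` phenotype tables over fixed genotypes.

    Age, Smoking, noise — and hence every trait — are redrawn independently
    per replicate; the genetic value is computed once from the fixed
    genotypes.
    """
    config.validate()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    n = genotypes.n_samples
    gvalue = _genetic_value(genotypes, variants, truth)
    tables = []
    for rep in range(config.n_replicates):
        age = rng.normal(config.age_mean, config.age_sd, n)
        smoking = (rng.random(n) < config.smoking_prev).astype(int)
        cols: dict[str, np.ndarray] = {}
        for spec in config.trait_specs:
            y = rng.normal(0.0, spec.noise_sd, n)
            y += spec.age_beta * age + spec.smoking_beta * smoking
            if spec.uses_genotypes:
                y += gvalue
            cols[spec.name] = y
        binary_names = []
        if config.binary_spec is not None:
            b = config.binary_spec
            liability = rng.normal(0.0, b.noise_sd, n)
            for t, w in zip(b.source_traits, b.weights):
                liability += w * cols[t]
            cut = np.quantile(liability, 1.0 - b.prevalence)
            cols[b.name] = (liability > cut).astype(int)
            binary_names = [b.name]
        df = pd.DataFrame({"sample_id": genotypes.sample_ids, **cols})
        df["Age"] = age
        df["Smoking"] = smoking
        df["replicate_id"] = rep
        tables.append(
            PhenotypeTable(
                df,
                traits=[s.name for s in config.trait_specs],
                binary_traits=binary_names,
                covariates=["Age", "Smoking"],
                replicate_col="replicate_id",
            )
        )
    return tables


def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Genotypes plus replicate phenotypes plus truth, in one call."""
    seed = config.seed if seed is None else seed
    gm, variants, regions, truth = simulate_genotypes(config, seed)
    gene_index = core.map_variants_to_genes(variants, regions)
    phenos = simulate_traits(gm, variants, truth, config, seed)
    return SimulatedDataset(gm, variants, regions, gene_index, phenos, truth, config)


# ---------------------------------------------------------------------------
# confounded null
# ---------------------------------------------------------------------------


def make_confounded_null(config: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Stratified null: genotype–trait association without any causal gene.

    Two subpopulations (membership fixed across replicates) differ both in
    allele frequencies (Balding–Nichols around the base MAF draw) and in mean
    Age; the trait depends on Age only.  With ``fst = 0`` and
    ``age_mean_shift = 0`` this degenerates to an ordinary null dataset.
    The answer key is empty: every rejection is a false positive.
    """
    config.validate()
    if config.confounding_spec is None:
        raise ValueError("config.confounding_spec is required")
    cs = config.confounding_spec
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    lo, hi = config.variants_per_gene

    gene_names = [f"G{i:04d}" for i in range(config.n_genes)]
    n_vars = rng.integers(lo, hi + 1, size=config.n_genes)
    base = config.maf_distribution.draw(rng, int(n_vars.sum()))

    def pop_freqs(p):
        if cs.fst == 0.0:
            return p.copy()
        a = p * (1.0 - cs.fst) / cs.fst
        b = (1.0 - p) * (1.0 - cs.fst) / cs.fst
        return rng.beta(a, b)

    p1, p2 = pop_freqs(base), pop_freqs(base)
    pop2 = rng.random(config.n_samples) < cs.prop_pop2  # fixed across replicates
    freqs = np.where(pop2[:, None], p2[None, :], p1[None, :])
    counts = core._fold_to_minor(rng.binomial(2, freqs))

    vid_list, pos_list, regions = [], [], []
    col = 0
    for g, gene in enumerate(gene_names):
        m = int(n_vars[g])
        start = 1 + g * _GENE_STRIDE
        regions.append(GeneRegion(gene, "1", start, start + m - 1))
        vid_list.extend(f"{gene}_v{i:03d}" for i in range(m))
        pos_list.extend(range(start, start + m))
        col += m
    gm = GenotypeMatrix([f"S{j:04d}" for j in range(config.n_samples)], counts)
    variants = pd.DataFrame({"variant_id": vid_list, "chrom": "1", "pos": pos_list})
    variants = core.compute_maf(gm, variants)
    gene_index = core.map_variants_to_genes(variants, regions)

    tables = []
    age_means = np.where(pop2, config.age_mean + cs.age_mean_shift / 2,
                         config.age_mean - cs.age_mean_shift / 2)
    for rep in range(config.n_replicates):
        age = rng.normal(age_means, config.age_sd)
        smoking = (rng.random(config.n_samples) < config.smoking_prev).astype(int)
        y = cs.trait_age_beta * age + rng.normal(0.0, cs.noise_sd, config.n_samples)
        df = pd.DataFrame(
            {
                "sample_id": gm.sample_ids,
                "Q4": y,
                "Age": age,
                "Smoking": smoking,
                "replicate_id": rep,
            }
        )
        tables.append(
            PhenotypeTable(
                df, traits=["Q4"], covariates=["Age", "Smoking"], replicate_col="replicate_id"
            )
        )
    return SimulatedDataset(gm, variants, regions, gene_index, tables, {}, config)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def q1like_config(
    n_causal_genes: int = 50,
    n_null_genes: int = 200,
    n_samples: int = 697,
    n_replicates: int = 20,
    seed: int = 0,
) -> SimulationConfig:
    """Architecture where every causal variant is rare (MAF < 5%).

    Each causal gene carries four rare causal variants (MAF in 0.1–3.5%,
    +0.25 trait units per copy); the background MAF law still sprinkles
    common non-causal variants into genes, which is what makes higher
    thresholds pure noise here.  The Q1-like trait adds Age and Smoking
    effects; Q4-like is the matching covariate-only null trait; the binary
    trait mixes both.
    """
    causal = [
        CausalGeneSpec(n_causal_variants=4, causal_maf_range=(0.001, 0.035), effect_size=0.25)
        for _ in range(n_causal_genes)
    ]
    return SimulationConfig(
        n_samples=n_samples,
        n_genes=n_causal_genes + n_null_genes,
        causal_genes=causal,
        trait_specs=[
            TraitSpec("Q1", uses_genotypes=True, age_beta=0.05, smoking_beta=0.5, noise_sd=1.0),
            TraitSpec("Q4", uses_genotypes=False, age_beta=0.05, smoking_beta=0.5, noise_sd=1.0),
        ],
        binary_spec=BinaryTraitSpec(
            source_traits=("Q1", "Q4"), weights=(0.6, 0.6), noise_sd=1.0, prevalence=0.30
        ),
        n_replicates=n_replicates,
        seed=seed,
    )


def q2like_config(
    n_causal_genes: int = 50,
    n_null_genes: int = 200,
    n_samples: int = 697,
    n_replicates: int = 20,
    seed: int = 0,
) -> SimulationConfig:
    """Architecture with one rare plus one common (~17% MAF) causal variant.

    Fixed 1%/5% thresholds see only the rare variant and lose most of the
    signal; a variable threshold reaching 17% captures both.  The Q2-like
    trait has no covariate influence at all.
    """
    causal = [
        CausalGeneSpec(
            variant_specs=[(((0.004, 0.010)), 0.5), ((0.17, 0.17), 0.2)]
        )
        for _ in range(n_causal_genes)
    ]
    return SimulationConfig(
        n_samples=n_samples,
        n_genes=n_causal_genes + n_null_genes,
        causal_genes=causal,
        trait_specs=[
            TraitSpec("Q2", uses_genotypes=True, noise_sd=1.0),
            TraitSpec("Q4", uses_genotypes=False, age_beta=0.05, smoking_beta=0.5, noise_sd=1.0),
        ],
        binary_spec=BinaryTraitSpec(
            source_traits=("Q2", "Q4"), weights=(0.6, 0.6), noise_sd=1.0, prevalence=0.30
        ),
        n_replicates=n_replicates,
        seed=seed,
    )


def confounded_config(
    n_genes: int = 100,
    n_samples: int = 697,
    n_replicates: int = 20,
    seed: int = 0,
) -> SimulationConfig:
    """Stratified-null preset for the confounding demonstration."""
    return SimulationConfig(
        n_samples=n_samples,
        n_genes=n_genes,
        confounding_spec=ConfoundingSpec(),
        n_replicates=n_replicates,
        seed=seed,
    )


def null_config(
    n_genes: int = 100,
    n_samples: int = 200,
    n_replicates: int = 20,
    seed: int = 0,
) -> SimulationConfig:
    """Pure-null preset: a Q4-like trait, no causal genes, no stratification."""
    return SimulationConfig(
        n_samples=n_samples,
        n_genes=n_genes,
        trait_specs=[
            TraitSpec("Q4", uses_genotypes=False, age_beta=0.05, smoking_beta=0.5, noise_sd=1.0)
        ],
        n_replicates=n_replicates,
        seed=seed,
    )


PRESETS = {
    "q1like": q1like_config,
    "q2like": q2like_config,
    "confounded": confounded_config,
    "null": null_config,
}
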