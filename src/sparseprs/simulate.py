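"""Synthetic multi-population genotype/phenotype generator with known truth.

Generates diploid dosage matrices under a Balding–Nichols allele-frequency
drift model with blockwise equicorrelated-Gaussian-copula LD, annotation
categories, covariates, and quantitative or liability-threshold binary
phenotypes with a specified SNP heritability. Every generator is a pure
function of its arguments and a seed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, write_json, write_plink_bed, write_tsv

logger = logging.getLogger(__name__)

CONSEQUENCE_GROUPS = ("PTV", "PAV", "PCV", "Intronic", "UTR", "Others")
CLINVAR_CLASSES = ("pathogenic", "likely_pathogenic", "none")

COVARIATE_COLUMNS = ("age", "sex", "array", *[f"PC{i}" for i in range(1, 11)])


class ConfigurationError(ValueError):
    """Invalid simulation parameters."""


@dataclasses.dataclass
class SimulationConfig:
    """Parameters for one synthetic dataset."""

    n_per_population: dict[str, int]
    m_variants: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    fst_per_population: dict[str, float] | None = None
    ld_block_size: int = 10
    ld_rho: float = 0.0
    n_causal: int = 10
    h2_true: float = 0.3
    prevalence_K: float = 0.1
    causal_enrichment: float = 1.0
    family: str = "gaussian"
    consequence_proportions: dict[str, float] | None = None
    clinvar_proportions: dict[str, float] | None = None
    allelotype_proportion: float = 0.0
    covariate_betas: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        low, high = self.maf_range
        if not (0 < low <= high <= 0.5):
            raise ConfigurationError(f"invalid maf_range {self.maf_range}")
        if self.fst_per_population is None:
            self.fst_per_population = {p: 0.0 for p in self.n_per_population}
        for pop, fst in self.fst_per_population.items():
            if not (0 <= fst < 1):
                raise ConfigurationError(f"Fst for {pop} must be in [0,1), got {fst}")
        if not (0 <= self.h2_true <= 1):
            raise ConfigurationError(f"h2_true must be in [0,1], got {self.h2_true}")
        if self.n_causal > self.m_variants:
            raise ConfigurationError("n_causal exceeds m_variants")
        if not (0 <= self.ld_rho < 1):
            raise ConfigurationError(f"ld_rho must be in [0,1), got {self.ld_rho}")
        if self.family not in ("gaussian", "binomial"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.family == "binomial" and not (0 < self.prevalence_K < 1):
            raise ConfigurationError("prevalence_K must be in (0,1)")
        if self.covariate_betas is None:
            # nonzero age/sex effects by default so covariate-only models
            # have known, nontrivial performance
            self.covariate_betas = {"age": 0.1, "sex": 0.1}


@dataclasses.dataclass
class TruthSet:
    """Ground-truth effects behind a simulated phenotype."""

    beta_true: np.ndarray  # per-variant effect on standardized-genotype scale
    causal_mask: np.ndarray
    base_freq: np.ndarray
    pop_freq: dict[str, np.ndarray]

    def __post_init__(self):
        if np.any(self.beta_true[~self.causal_mask] != 0):
            raise ValueError("non-causal variants must have zero beta_true")


def draw_base_frequencies(m: int, maf_range: tuple[float, float], seed: int) -> np.ndarray:
    """Ancestral allele frequencies, uniform on ``maf_range``."""
    low, high = maf_range
    if not (0 < low <= high <= 0.5):
        raise ConfigurationError(f"invalid maf_range {maf_range}")
    rng = np.random.default_rng(seed)
    return rng.uniform(low, high, size=m)


def drift_frequencies(
    base_freq: np.ndarray, fst: float, seed: int, n_clamp: int = 1000
) -> np.ndarray:
    """Population frequencies under the Balding–Nichols Beta model.

    At drift ``fst`` the population frequency for ancestral frequency p is
    Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance F·p(1-p).
    Frequencies are clamped to [1/(4n), 1 - 1/(4n)] to avoid monomorphism.
    """
    if not (0 <= fst < 1):
        raise ConfigurationError(f"fst must be in [0,1), got {fst}")
    base_freq = np.asarray(base_freq, dtype=float)
    if fst == 0:
        return base_freq.copy()
    rng = np.random.default_rng(seed)
    scale = (1 - fst) / fst
    freq = rng.beta(base_freq * scale, (1 - base_freq) * scale)
    eps = 1.0 / (4 * n_clamp)
    return np.clip(freq, eps, 1 - eps)


def simulate_genotypes(
    pop_freq: np.ndarray,
    n: int,
    ld_block_size: int,
    ld_rho: float,
    seed: int,
    population: str = "pop",
) -> GenotypeMatrix:
    """Diploid dosages as the sum of two copula haplotypes.

    Within a block of ``ld_block_size`` adjacent variants, haplotype alleles
    are derived from an equicorrelated latent Gaussian (correlation
    ``ld_rho``) thresholded at each variant's frequency quantile; blocks are
    independent. Variant j carries allele A1 with frequency ``pop_freq[j]``.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    pop_freq = np.asarray(pop_freq, dtype=float)
    m = pop_freq.size
    rng = np.random.default_rng(seed)
    thresholds = stats.norm.ppf(pop_freq)
    X = np.empty((n, m), dtype=np.int8)
    sqrt_rho = np.sqrt(ld_rho)
    sqrt_comp = np.sqrt(1 - ld_rho)
    for start in range(0, m, ld_block_size):
        stop = min(start + ld_block_size, m)
        width = stop - start
        dos = np.zeros((n, width), dtype=np.int8)
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            latent = sqrt_rho * shared + sqrt_comp * rng.standard_normal((n, width))
            dos += (latent < thresholds[start:stop]).astype(np.int8)
        X[:, start:stop] = dos

    mono = (X == X[0]).all(axis=0)
    if mono.any():
        logger.warning("%d monomorphic simulated variant(s)", int(mono.sum()))
    variants = pd.DataFrame(
        {
            "id": [f"var{j+1}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 1000,
            "a1": "A",
            "a2": "G",
        }
    )
    samples = pd.DataFrame(
        {
            "fid": [f"{population}_{i+1}" for i in range(n)],
            "iid": [f"{population}_{i+1}" for i in range(n)],
            "population": population,
        }
    )
    return GenotypeMatrix(X=X, variants=variants, samples=samples)


def simulate_annotations(
    m: int,
    seed: int,
    consequence_proportions: dict[str, float] | None = None,
    clinvar_proportions: dict[str, float] | None = None,
    allelotype_proportion: float = 0.0,
    variant_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Multinomial draw of consequence group, ClinVar class, allelotype flag.

    Unspecified consequence mass defaults to "Others" and unspecified ClinVar
    mass to "none".
    """
    cons = dict(consequence_proportions or {})
    clin = dict(clinvar_proportions or {})
    for key in cons:
        if key not in CONSEQUENCE_GROUPS:
            raise ConfigurationError(f"unknown consequence group {key!r}")
    for key in clin:
        if key not in CLINVAR_CLASSES:
            raise ConfigurationError(f"unknown ClinVar class {key!r}")
    for name, props in (("consequence", cons), ("clinvar", clin)):
        total = sum(props.values())
        if any(p < 0 for p in props.values()) or total > 1 + 1e-12:
            raise ConfigurationError(f"invalid {name} proportions (sum {total})")
    if not (0 <= allelotype_proportion <= 1):
        raise ConfigurationError("allelotype_proportion must be in [0,1]")

    cons.setdefault("Others", 0.0)
    cons["Others"] += 1.0 - sum(cons.values())
    clin.setdefault("none", 0.0)
    clin["none"] += 1.0 - sum(clin.values())

    rng = np.random.default_rng(seed)
    groups = rng.choice(CONSEQUENCE_GROUPS, size=m,
                        p=[cons.get(g, 0.0) for g in CONSEQUENCE_GROUPS])
    classes = rng.choice(CLINVAR_CLASSES, size=m,
                         p=[clin.get(c, 0.0) for c in CLINVAR_CLASSES])
    allelo = rng.random(m) < allelotype_proportion
    ids = variant_ids if variant_ids is not None else [f"var{j+1}" for j in range(m)]
    return pd.DataFrame(
        {
            "id": ids,
            "consequence_group": groups,
            "clinvar_class": classes,
            "is_allelotype": allelo,
        }
    )


def simulate_effects(
    annotation: pd.DataFrame,
    n_causal: int,
    causal_enrichment: float,
    h2_true: float,
    seed: int,
    base_freq: np.ndarray | None = None,
    pop_freq: dict[str, np.ndarray] | None = None,
) -> TruthSet:
    """Sample causal variants and standardized-scale effect sizes.

    Causal indices are drawn without replacement with probability weights of
    ``causal_enrichment`` for medically relevant variants and 1 otherwise.
    Effects are i.i.d. Normal rescaled so that the variance of the
    standardized-genotype linear predictor (under independence) is
    ``h2_true``.
    """
    from .annotate_qc import medically_relevant_mask

    m = len(annotation)
    if n_causal < 1:
        raise ConfigurationError("n_causal must be >= 1")
    if n_causal > m:
        raise ConfigurationError("n_causal exceeds number of variants")
    rng = np.random.default_rng(seed)
    relevant = medically_relevant_mask(annotation).to_numpy()
    weights = np.where(relevant, float(causal_enrichment), 1.0)
    weights = weights / weights.sum()
    causal_idx = rng.choice(m, size=n_causal, replace=False, p=weights)
    causal_mask = np.zeros(m, dtype=bool)
    causal_mask[causal_idx] = True

    beta = np.zeros(m)
    if h2_true > 0:
        raw = rng.standard_normal(n_causal)
        beta[causal_idx] = raw * np.sqrt(h2_true / np.sum(raw**2))
    if base_freq is None:
        base_freq = np.full(m, 0.5)
    if pop_freq is None:
        pop_freq = {}
    return TruthSet(beta_true=beta, causal_mask=causal_mask,
                    base_freq=np.asarray(base_freq), pop_freq=pop_freq)


def simulate_covariates(n: int, seed: int) -> pd.DataFrame:
    """Covariate table: age, sex, genotyping-array indicator, PC1..PC10.

    The array indicator has a 10% positive rate, mirroring the share of a
    cohort genotyped on a secondary array.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    data = {
        "age": rng.normal(55.0, 8.0, size=n),
        "sex": rng.binomial(1, 0.5, size=n).astype(float),
        "array": rng.binomial(1, 0.1, size=n).astype(float),
    }
    for i in range(1, 11):
        data[f"PC{i}"] = rng.standard_normal(n)
    return pd.DataFrame(data, columns=list(COVARIATE_COLUMNS))


def _genetic_score(G: GenotypeMatrix, beta_true: np.ndarray) -> np.ndarray:
    """Linear predictor on the standardized-genotype scale."""
    D = G.dosages(impute_freq=G.allele_frequencies())
    mean = D.mean(axis=0)
    sd = D.std(axis=0)
    sd[sd == 0] = 1.0
    nz = beta_true != 0
    Z = (D[:, nz] - mean[nz]) / sd[nz]
    return Z @ beta_true[nz]


def _covariate_score(covariates: pd.DataFrame, covariate_betas: dict[str, float]) -> np.ndarray:
    score = np.zeros(len(covariates))
    for name, b in covariate_betas.items():
        if b == 0:
            continue
        col = covariates[name].to_numpy(dtype=float)
        sd = col.std()
        score += b * (col - col.mean()) / (sd if sd > 0 else 1.0)
    return score


def simulate_phenotype(
    G: GenotypeMatrix,
    truth: TruthSet,
    covariates: pd.DataFrame,
    covariate_betas: dict[str, float],
    family: str,
    h2_true: float,
    prevalence_K: float,
    seed: int,
) -> np.ndarray:
    """Phenotype with genetic variance fraction ``h2_true``.

    gaussian: y = g + c + e with Var(e) chosen so Var(g)/Var(y) = h2_true.
    binomial: liability l = a·g + c + e with e ~ N(0,1) and a chosen so the
    genetic share of the liability variance is h2_true; cases are samples
    whose liability exceeds the (1 - K) quantile of the liability's Normal
    approximation.
    """
    if family not in ("gaussian", "binomial"):
        raise ConfigurationError(f"unknown family {family!r}")
    rng = np.random.default_rng(seed)
    n = G.n_samples
    g = _genetic_score(G, truth.beta_true)
    c = _covariate_score(covariates, covariate_betas)
    var_g = float(np.var(g))
    var_c = float(np.var(c))

    if family == "gaussian":
        if h2_true == 0 or var_g == 0:
            return c + rng.standard_normal(n)
        var_e = var_g * (1 - h2_true) / h2_true - var_c
        if var_e < 0:
            raise ConfigurationError(
                "covariate variance too large for requested h2_true"
            )
        return g + c + rng.normal(0.0, np.sqrt(var_e), size=n)

    if not (0 < prevalence_K < 1):
        raise ConfigurationError("prevalence_K must be in (0,1)")
    # liability: unit Normal noise; genetic term rescaled to the target share
    if h2_true == 0 or var_g == 0:
        alpha = 0.0
    else:
        alpha = np.sqrt(h2_true * (var_c + 1.0) / ((1 - h2_true) * var_g))
    liability = alpha * g + c + rng.standard_normal(n)
    total_var = alpha**2 * var_g + var_c + 1.0
    threshold = stats.norm.ppf(1 - prevalence_K) * np.sqrt(total_var)
    return (liability > threshold).astype(float)


def split_samples(
    n: int, fractions: tuple[float, float, float] = (0.7, 0.1, 0.2), seed: int = 0
) -> pd.Series:
    """Random disjoint train/validation/test assignment.

    Train and validation sizes are floored; the remainder goes to test, so
    counts are reproducible. Returns a Series of labels indexed 0..n-1.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    labels = np.empty(n, dtype=object)
    labels[order[:n_train]] = "train"
    labels[order[n_train : n_train + n_val]] = "validation"
    labels[order[n_train + n_val :]] = "test"
    return pd.Series(labels, name="split")


@dataclasses.dataclass
class SimulatedDataset:
    """Everything downstream stages need, with ground truth attached."""

    config: SimulationConfig
    genotypes: GenotypeMatrix  # all populations stacked
    annotation: pd.DataFrame
    covariates: pd.DataFrame
    phenotype: np.ndarray
    truth: TruthSet
    split: pd.Series  # for the first (score-development) population only

    @property
    def populations(self) -> list[str]:
        return list(self.config.n_per_population)

    def population_index(self, population: str) -> np.ndarray:
        return np.flatnonzero(
            self.genotypes.samples["population"].to_numpy() == population
        )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """End-to-end generation for all configured populations.

    The first population in ``n_per_population`` is the score-development
    cohort and receives the train/validation/test split; later populations
    are evaluation-only. Phenotypes in every population share the same
    causal effects on the standardized scale.
    """
    seed = config.seed
    base = draw_base_frequencies(config.m_variants, config.maf_range, seed)
    annotation = simulate_annotations(
        config.m_variants,
        seed=seed + 1,
        consequence_proportions=config.consequence_proportions,
        clinvar_proportions=config.clinvar_proportions,
        allelotype_proportion=config.allelotype_proportion,
    )
    pop_freqs: dict[str, np.ndarray] = {}
    blocks = []
    covs = []
    phenos = []
    for k, (pop, n_pop) in enumerate(config.n_per_population.items()):
        fst = config.fst_per_population[pop]
        pop_freqs[pop] = drift_frequencies(base, fst, seed + 100 + k, n_clamp=n_pop)

    truth = simulate_effects(
        annotation,
        config.n_causal,
        config.causal_enrichment,
        config.h2_true,
        seed + 2,
        base_freq=base,
        pop_freq=pop_freqs,
    )
    for k, (pop, n_pop) in enumerate(config.n_per_population.items()):
        Gp = simulate_genotypes(
            pop_freqs[pop], n_pop, config.ld_block_size, config.ld_rho,
            seed + 200 + k, population=pop,
        )
        cov = simulate_covariates(n_pop, seed + 300 + k)
        y = simulate_phenotype(
            Gp, truth, cov, config.covariate_betas, config.family,
            config.h2_true, config.prevalence_K, seed + 400 + k,
        )
        blocks.append(Gp)
        covs.append(cov)
        phenos.append(y)

    X = np.vstack([b.X for b in blocks])
    samples = pd.concat([b.samples for b in blocks], ignore_index=True)
    G = GenotypeMatrix(X=X, variants=blocks[0].variants, samples=samples)
    covariates = pd.concat(covs, ignore_index=True)
    phenotype = np.concatenate(phenos)
    first_pop_n = next(iter(config.n_per_population.values()))
    split = split_samples(first_pop_n, seed=seed + 5)
    return SimulatedDataset(
        config=config,
        genotypes=G,
        annotation=annotation,
        covariates=covariates,
        phenotype=phenotype,
        truth=truth,
        split=split,
    )


def write_dataset(data: SimulatedDataset, outdir: str | Path) -> None:
    """Write PLINK genotypes, TSV tables, and a JSON config sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_plink_bed(data.genotypes, outdir / "genotypes")
    write_tsv(data.annotation, outdir / "annotation.tsv")
    cov = data.covariates.copy()
    cov.insert(0, "IID", data.genotypes.samples["iid"].to_numpy())
    cov.insert(0, "FID", data.genotypes.samples["fid"].to_numpy())
    write_tsv(cov, outdir / "covariates.tsv")
    phe = pd.DataFrame(
        {
            "FID": data.genotypes.samples["fid"],
            "IID": data.genotypes.samples["iid"],
            "population": data.genotypes.samples["population"],
            "phenotype": data.phenotype,
        }
    )
    write_tsv(phe, outdir / "phenotype.tsv")
    truth_df = pd.DataFrame(
        {
            "id": data.genotypes.variants["id"],
            "beta_true": data.truth.beta_true,
            "causal_mask": data.truth.causal_mask,
            "base_freq": data.truth.base_freq,
        }
    )
    write_tsv(truth_df, outdir / "truth.tsv")
    split_df = pd.DataFrame(
        {
            "FID": data.genotypes.samples["fid"][: len(data.split)],
            "IID": data.genotypes.samples["iid"][: len(data.split)],
            "split": data.split.to_numpy(),
        }
    )
    write_tsv(split_df, outdir / "split.tsv")
    write_json(dataclasses.asdict(data.config), outdir / "simulation_config.json")
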