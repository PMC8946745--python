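"""Variant QC filters, penalty-factor assignment, and HLA dosage rounding.

Variants are kept when they have low missingness, non-trivial minor allele
frequency, no extreme Hardy–Weinberg departure, and lie outside the MHC
region. Penalty factors encode prioritization of medically relevant alleles
(pathogenic/protein-truncating: 0.5; likely-pathogenic/protein-altering/
allelotype: 0.75; everything else: 1.0).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MISSING, GenotypeMatrix
from .simulate import CLINVAR_CLASSES, CONSEQUENCE_GROUPS


@dataclasses.dataclass
class QCThresholds:
    """Filter thresholds; coordinates are 1-based inclusive (hg19)."""

    max_missingness: float = 0.01
    min_maf: float = 0.0001
    hwe_p_cutoff: float = 1e-7
    mhc_chrom: str = "6"
    mhc_start: int = 25_477_797
    mhc_end: int = 36_448_354

    def __post_init__(self):
        if not (0 <= self.max_missingness <= 1):
            raise ValueError("max_missingness must be in [0,1]")
        if not (0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must be in [0,0.5]")
        if not (0 < self.hwe_p_cutoff <= 1):
            raise ValueError("hwe_p_cutoff must be in (0,1]")


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy–Weinberg test (no mid-p correction).

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one, under the conditional distribution given allele counts.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotype observation required")
    n_a = 2 * n_hom_alt + n_het  # minor-allele copies (either allele works)
    n_b = 2 * n_hom_ref + n_het
    rare = min(n_a, n_b)

    # het count shares the parity of the rare-allele count
    het_values = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - het_values) // 2
    hom_common = n - het_values - hom_rare
    # P(het | allele counts) ∝ n! / (hom_rare! het! hom_common!) * 2^het
    logp = (
        het_values * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(het_values + 1)
        - gammaln(hom_common + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[het_values == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def assign_penalty_factor(
    consequence_group: str, clinvar_class: str, is_allelotype: bool
) -> float:
    """Penalty factor in {0.5, 0.75, 1.0} from variant annotation."""
    if consequence_group not in CONSEQUENCE_GROUPS:
        raise ValueError(f"unknown consequence group {consequence_group!r}")
    if clinvar_class not in CLINVAR_CLASSES:
        raise ValueError(f"unknown ClinVar class {clinvar_class!r}")
    if clinvar_class == "pathogenic" or consequence_group == "PTV":
        return 0.5
    if (
        clinvar_class == "likely_pathogenic"
        or consequence_group == "PAV"
        or is_allelotype
    ):
        return 0.75
    return 1.0


def assign_penalty_factors(annotation: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`assign_penalty_factor` over an annotation table."""
    pf = pd.Series(1.0, index=annotation.index, name="penalty_factor")
    mid = (
        (annotation["clinvar_class"] == "likely_pathogenic")
        | (annotation["consequence_group"] == "PAV")
        | annotation["is_allelotype"].astype(bool)
    )
    pf[mid] = 0.75
    top = (annotation["clinvar_class"] == "pathogenic") | (
        annotation["consequence_group"] == "PTV"
    )
    pf[top] = 0.5
    return pf


def medically_relevant_mask(annotation: pd.DataFrame) -> pd.Series:
    """True for PTV/PAV, allelotypes, and (likely-)pathogenic ClinVar variants."""
    return (
        annotation["consequence_group"].isin(["PTV", "PAV"])
        | annotation["is_allelotype"].astype(bool)
        | annotation["clinvar_class"].isin(["pathogenic", "likely_pathogenic"])
    ).rename("medically_relevant")


def round_hla_dosage(dosage) -> np.ndarray:
    """Round imputed allele dosages to hard calls.

    Dosages within ±0.1 of 0, 1, or 2 are rounded to that integer; all other
    values become NaN (excluded).
    """
    d = np.asarray(dosage, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("dosages must be finite")
    nearest = np.clip(np.round(d), 0, 2)
    out = np.where(np.abs(d - nearest) <= 0.1 + 1e-12, nearest, np.nan)
    return out if out.shape else float(out)


def variant_qc(
    G: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    blocklist: set[str] | None = None,
    sample_index: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply the variant filters; returns (keep mask, per-variant report).

    ``sample_index`` restricts frequency/missingness/HWE computation to the
    score-development population. A variant is kept iff missingness <
    max_missingness, MAF > min_maf, HWE p >= cutoff, it lies outside the MHC
    region, and it is not blocklisted.
    """
    thresholds = thresholds or QCThresholds()
    blocklist = blocklist or set()
    X = G.X if sample_index is None else G.X[sample_index]
    pos = G.variants["pos"].to_numpy()
    if np.any(pos < 1):
        raise ValueError(
            "0-based or negative positions found; coordinates must be 1-based"
        )

    miss = (X == MISSING).mean(axis=0)
    called = np.maximum((X != MISSING).sum(axis=0), 1)
    Xz = np.where(X == MISSING, 0, X)
    freq = Xz.sum(axis=0) / (2.0 * called)
    maf = np.minimum(freq, 1 - freq)
    n0 = (X == 0).sum(axis=0)
    n1 = (X == 1).sum(axis=0)
    n2 = (X == 2).sum(axis=0)
    hwe_p = np.array(
        [
            hwe_exact_test(int(n0[j]), int(n1[j]), int(n2[j]))
            if n0[j] + n1[j] + n2[j] > 0
            else 1.0
            for j in range(G.n_variants)
        ]
    )
    chrom = G.variants["chrom"].astype(str).to_numpy()
    in_mhc = (
        (chrom == thresholds.mhc_chrom)
        & (pos >= thresholds.mhc_start)
        & (pos <= thresholds.mhc_end)
    )
    blocked = G.variants["id"].isin(blocklist).to_numpy()

    pass_miss = miss < thresholds.max_missingness
    pass_maf = maf > thresholds.min_maf
    pass_hwe = hwe_p >= thresholds.hwe_p_cutoff
    keep = pass_miss & pass_maf & pass_hwe & ~in_mhc & ~blocked
    report = pd.DataFrame(
        {
            "id": G.variants["id"],
            "missingness": miss,
            "maf": maf,
            "hwe_p": hwe_p,
            "in_mhc": in_mhc,
            "blocklisted": blocked,
            "pass_missingness": pass_miss,
            "pass_maf": pass_maf,
            "pass_hwe": pass_hwe,
            "kept": keep,
        }
    )
    return keep, report
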