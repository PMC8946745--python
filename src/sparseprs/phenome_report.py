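"""Phenome-level aggregation of per-trait PRS results.

Significance tallies, model-size vs incremental-performance rank
correlation, enrichment of medically relevant alleles among selected
variants, percentile-bin odds ratios, and cross-population transferability
slopes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .score_eval import EvaluationResult, incremental_performance, is_significant

#: percentile bin edges: fine tails, decile steps in the middle
DEFAULT_BIN_EDGES = (
    0.0, 0.5, 1.0, 5.0, 10.0, 20.0, 30.0, 40.0, 60.0,
    70.0, 80.0, 90.0, 95.0, 99.0, 99.5, 100.0,
)
REFERENCE_BIN = (40.0, 60.0)


def spearman_size_effect(
    sizes: np.ndarray, incremental_values: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    sizes = np.asarray(sizes, float)
    incremental_values = np.asarray(incremental_values, float)
    if sizes.size != incremental_values.size:
        raise ValueError("length mismatch")
    rho, p = stats.spearmanr(sizes, incremental_values)
    return float(rho), float(p)


def enrichment_fold(
    selected_relevant_pf: int,
    selected_total_pf: int,
    selected_relevant_nopf: int,
    selected_total_nopf: int,
) -> float:
    """Fold enrichment (a/b)/(c/d) of medically relevant selected variants.

    Compares the penalty-factor model's fraction against the
    no-penalty-factor model's fraction, rounded to two decimals for
    reporting. Returns NaN when a denominator is zero.
    """
    if selected_total_pf == 0 or selected_total_nopf == 0 or selected_relevant_nopf == 0:
        return float("nan")
    fold = (selected_relevant_pf / selected_total_pf) / (
        selected_relevant_nopf / selected_total_nopf
    )
    return round(fold, 2)


def percentile_bin_or(
    scores: np.ndarray,
    labels: np.ndarray,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    reference: tuple[float, float] = REFERENCE_BIN,
) -> pd.DataFrame:
    """Odds ratio of case status per PRS percentile bin vs the reference bin.

    SE of log OR is sqrt(Σ 1/cell); zero cells get the Haldane–Anscombe 0.5
    correction and are flagged.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pct = 100.0 * (stats.rankdata(scores) - 0.5) / len(scores)
    edges = np.asarray(bin_edges, float)
    if reference[0] not in edges or reference[1] not in edges:
        raise ValueError("reference bin bounds must be bin edges")

    bin_idx = np.clip(np.searchsorted(edges, pct, side="right") - 1, 0, len(edges) - 2)
    ref_mask = (pct >= reference[0]) & (pct < reference[1])
    ref_case = int(labels[ref_mask].sum())
    ref_ctrl = int((ref_mask & (labels == 0)).sum())

    rows = []
    for b in range(len(edges) - 1):
        lo, hi = edges[b], edges[b + 1]
        in_bin = bin_idx == b
        case = int(labels[in_bin].sum())
        ctrl = int((in_bin & (labels == 0)).sum())
        if (lo, hi) == tuple(reference):
            rows.append(
                dict(bin_low=lo, bin_high=hi, n_case=case, n_control=ctrl,
                     odds_ratio=1.0, log_or_se=0.0, corrected=False)
            )
            continue
        cells = np.array([case, ctrl, ref_case, ref_ctrl], float)
        corrected = bool((cells == 0).any())
        if corrected:
            cells = cells + 0.5
        a, b_, c, d = cells
        or_ = (a / b_) / (c / d)
        se = float(np.sqrt((1 / cells).sum()))
        rows.append(
            dict(bin_low=lo, bin_high=hi, n_case=case, n_control=ctrl,
                 odds_ratio=float(or_), log_or_se=se, corrected=corrected)
        )
    return pd.DataFrame(rows)


def transfer_slope(
    incremental_target: np.ndarray, incremental_source: np.ndarray
) -> tuple[float, float]:
    """Through-origin regression slope of target on source, with SE.

    b = Σxy / Σx²; SE = sqrt(Σ(y − bx)² / (n − 1) / Σx²).
    """
    y = np.asarray(incremental_target, float)
    x = np.asarray(incremental_source, float)
    if x.size != y.size or x.size == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("source values are all zero")
    b = float(x @ y) / sxx
    if x.size > 1:
        se = float(np.sqrt(np.sum((y - b * x) ** 2) / (x.size - 1) / sxx))
    else:
        se = np.nan
    return b, se


@dataclasses.dataclass
class PhenomeSummary:
    """Per-trait table plus phenome-level statistics."""

    table: pd.DataFrame
    n_significant: int
    spearman: dict[str, tuple[float, float]]  # family -> (rho, p)
    transfer_slopes: dict[str, tuple[float, float]]  # population -> (slope, se)


def build_phenome_table(
    results: list[EvaluationResult],
    model_sizes: dict[str, int],
    families: dict[str, str],
    source_population: str = "test",
) -> PhenomeSummary:
    """Aggregate evaluation rows into the per-trait phenome summary.

    The primary metric is R² (gaussian) or Nagelkerke pseudo-R² (binomial);
    the incremental value is full minus covariate-only on that metric,
    evaluated in the source population; transfer slopes relate each other
    population's incremental values to the source's.
    """
    by_key: dict[tuple, EvaluationResult] = {
        (r.trait, r.population, r.model_type, r.metric): r for r in results
    }
    traits = sorted({r.trait for r in results})
    populations = sorted({r.population for r in results})
    rows = []
    incr: dict[tuple[str, str], float] = {}
    for trait in traits:
        family = families.get(trait, "gaussian")
        metric = "R2" if family == "gaussian" else "NagelkerkeR2"
        for pop in populations:
            full = by_key.get((trait, pop, "full", metric))
            cov = by_key.get((trait, pop, "covariate_only", metric))
            geno = by_key.get((trait, pop, "genotype_only", metric))
            if full is None or cov is None:
                continue
            delta = incremental_performance(full, cov)
            incr[(trait, pop)] = delta
            rows.append(
                {
                    "trait": trait,
                    "population": pop,
                    "family": family,
                    "metric": metric,
                    "n_variants_selected": model_sizes.get(trait, 0),
                    "genotype_only": np.nan if geno is None else geno.value,
                    "covariate_only": cov.value,
                    "full": full.value,
                    "incremental": delta,
                    "p_value": full.p_value,
                    "significant": is_significant(full.p_value)
                    if np.isfinite(full.p_value)
                    else False,
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        src = table[table["population"] == source_population]
        n_sig = int(src["significant"].sum())
    else:
        n_sig = 0

    spearman = {}
    if len(table):
        src = table[table["population"] == source_population]
        for family in sorted(src["family"].unique()):
            sub = src[src["family"] == family]
            if len(sub) >= 3:
                spearman[family] = spearman_size_effect(
                    sub["n_variants_selected"].to_numpy(),
                    sub["incremental"].to_numpy(),
                )

    slopes = {}
    for pop in populations:
        if pop == source_population:
            continue
        pairs = [
            (incr[(t, pop)], incr[(t, source_population)])
            for t in traits
            if (t, pop) in incr and (t, source_population) in incr
        ]
        if len(pairs) >= 2:
            tgt, src_vals = zip(*pairs)
            slopes[pop] = transfer_slope(np.array(tgt), np.array(src_vals))
    return PhenomeSummary(
        table=table, n_significant=n_sig, spearman=spearman, transfer_slopes=slopes
    )
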