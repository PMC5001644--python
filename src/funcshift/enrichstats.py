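"""Empirical-null thresholds and enrichment testing.

The score distribution of putatively neutral variants serves as an
empirical null.  The decision threshold at a false positive rate (FPR) q
is the ceil((1-q)*n)-th order statistic of the n null scores; exceedance
is the strictly-greater fraction, so the null's own exceedance never
exceeds q and equals it exactly when n*q is an integer and scores are
tie-free.  Disease-versus-neutral enrichment of exceedance is assessed by
a one-tailed Fisher's exact test with Bonferroni correction: the default
family sizes are (number of functions) x {loss, gain} for single-type
tests (58 with the full 29-function registry) and 4 for the combined
independence/max models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import fisher_exact


class EnrichmentError(ValueError):
    pass


@dataclass
class NullDistribution:
    """Sorted neutral-cohort scores for one (function, score column)."""

    function: str
    column: str
    scores: np.ndarray

    def __post_init__(self):
        s = np.sort(np.asarray(self.scores, dtype=float))
        if s.size == 0:
            raise EnrichmentError("null distribution must be nonempty")
        if np.any(s < 0) or np.any(s > 1):
            raise EnrichmentError("null scores must lie in [0, 1]")
        self.scores = s


@dataclass
class EnrichmentResult:
    function: str
    column: str
    threshold: float
    disease_exceedance: float  # percent
    neutral_exceedance: float  # percent
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    p_value: float
    family_size: int
    corrected_alpha: float
    significant: bool


def fpr_threshold(null, fpr: float = 0.01) -> float:
    """Decision threshold at a given false positive rate.

    The ceil((1-fpr)*n)-th order statistic of the null scores; exceedance
    is evaluated with strict inequality downstream.
    """
    if not (0.0 < fpr < 1.0):
        raise EnrichmentError("fpr must lie strictly between 0 and 1")
    scores = null.scores if isinstance(null, NullDistribution) else np.sort(
        np.asarray(null, dtype=float)
    )
    n = scores.size
    if n == 0:
        raise EnrichmentError("empty null distribution")
    k = math.ceil((1.0 - fpr) * n)
    return float(scores[k - 1])


def exceedance(scores, threshold: float) -> float:
    """Percentage of scores strictly greater than the threshold."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise EnrichmentError("empty score set")
    return float(100.0 * (s > threshold).mean())


def fisher_one_tailed(table) -> float:
    """One-tailed (enrichment) Fisher's exact test on a 2x2 count table
    ``[[disease_exceed, disease_rest], [neutral_exceed, neutral_rest]]``."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise EnrichmentError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise EnrichmentError("table entries must be nonnegative integers")
    _, p = fisher_exact(np.round(t).astype(int), alternative="greater")
    return float(p)


def bonferroni(alpha: float, k: int) -> float:
    """Bonferroni-corrected per-test cutoff alpha / k."""
    if k < 1:
        raise EnrichmentError("family size must be >= 1")
    if not (0.0 < alpha <= 1.0):
        raise EnrichmentError("alpha must lie in (0, 1]")
    return alpha / k


def empirical_pvalue(score: float, null) -> float:
    """Add-one empirical p-value of a single score against the null:
    (1 + #{null >= score}) / (1 + n)."""
    scores = null.scores if isinstance(null, NullDistribution) else np.asarray(
        null, dtype=float
    )
    if scores.size == 0:
        raise EnrichmentError("empty null distribution")
    return float((1 + int((scores >= score).sum())) / (1 + scores.size))


COMBINED_KEYS = ("independence", "max", "Independence", "Max")


def enrichment_table(
    disease_scores: Dict[tuple, Sequence],
    neutral_scores: Dict[tuple, Sequence],
    fpr: float = 0.01,
    alpha: float = 0.05,
    family_sizes: Optional[dict] = None,
) -> dict:
    """Full enrichment analysis over (function, column) score cohorts.

    Thresholds come from the neutral cohort only.  Keys are
    ``(function, column)`` pairs; functions named ``independence``/``max``
    belong to the combined-model family.  Returns the per-cell results
    plus metadata with the family sizes and corrected cutoffs.
    """
    if set(disease_scores) != set(neutral_scores):
        raise EnrichmentError(
            "disease and neutral cohorts must cover identical (function, "
            "column) pairs"
        )
    single_funcs = sorted({
        f for f, _ in disease_scores if f not in COMBINED_KEYS
    })
    combined_funcs = sorted({
        f for f, _ in disease_scores if f in COMBINED_KEYS
    })
    if family_sizes is None:
        family_sizes = {}
    fam_single = family_sizes.get("single", 2 * len(single_funcs))
    fam_combined = family_sizes.get("combined", 2 * len(combined_funcs))

    results = []
    for (f, col) in sorted(disease_scores):
        d = np.asarray(disease_scores[(f, col)], dtype=float)
        n = np.asarray(neutral_scores[(f, col)], dtype=float)
        t = fpr_threshold(n, fpr)
        d_exc = int((d > t).sum())
        n_exc = int((n > t).sum())
        table = ((d_exc, d.size - d_exc), (n_exc, n.size - n_exc))
        p = fisher_one_tailed(table)
        fam = fam_combined if f in COMBINED_KEYS else fam_single
        fam = max(fam, 1)
        cutoff = bonferroni(alpha, fam)
        results.append(EnrichmentResult(
            function=f, column=col, threshold=t,
            disease_exceedance=100.0 * d_exc / d.size,
            neutral_exceedance=100.0 * n_exc / n.size,
            table=table, p_value=p, family_size=fam,
            corrected_alpha=cutoff, significant=p < cutoff,
        ))
    return {
        "results": results,
        "metadata": {
            "fpr": fpr,
            "alpha": alpha,
            "family_size_single": fam_single,
            "family_size_combined": fam_combined,
            "corrected_alpha_single": bonferroni(alpha, max(fam_single, 1)),
            "corrected_alpha_combined": bonferroni(alpha, max(fam_combined, 1)),
            "n_single_functions": len(single_funcs),
            "n_combined_models": len(combined_funcs),
        },
    }


def neutral_set(unlabeled_ids: Sequence, disease_ids: Sequence) -> list:
    """Putatively neutral cohort: unlabeled minus known-disease overlap."""
    disease = set(disease_ids)
    return [i for i in unlabeled_ids if i not in disease]
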