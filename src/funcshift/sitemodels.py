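"""Training-set assembly, cross-validation and evaluation of site models.

Cross-validation is per protein chain: every residue of a chain shares a
fold, so structural near-duplicates never straddle the train/test split.
Evaluation reports AUC together with sensitivity and the Matthews
correlation coefficient at the score threshold where specificity over the
unlabeled-as-negative side reaches 99% (pooled across folds).  The
model-selection grid spans alphabet size |Sigma| in {20, 40}, edit budget
m in {0, 1}, maximum graphlet size N in {4, 5} and the three edit-
operation modes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from . import graphlets, pulearn
from .graphlets import KernelSpec
from .pulearn import PUDataset
from .registry import REGISTRY, FunctionType

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass
class EvalMetrics:
    auc: float
    mcc: float
    sensitivity: float
    specificity: float
    threshold: float


@dataclass
class CVPlan:
    """Assignment of protein chains to folds 1..k."""

    folds: dict  # chain -> fold index
    k: int
    seed: int

    def fold_of(self, chain) -> int:
        return self.folds[chain]


def make_cv_plan(chains: Sequence, k: int = 10, seed: int = 0) -> CVPlan:
    """Partition chains into k folds with sizes differing by at most one;
    deterministic per seed."""
    chains = list(dict.fromkeys(chains))
    if len(chains) < k:
        raise EvaluationError(f"need at least {k} chains, got {len(chains)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(chains)))
    folds = {chains[idx]: (pos % k) + 1 for pos, idx in enumerate(order)}
    return CVPlan(folds=folds, k=k, seed=seed)


def auc_score(scores, labels) -> float:
    """Rank-statistic AUC with tie averaging (Mann-Whitney)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC requires both classes")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(scores, labels, specificity: float = 0.99) -> EvalMetrics:
    """AUC plus sensitivity/MCC at the sp >= ``specificity`` threshold.

    The threshold is the smallest observed score for which the fraction of
    negatives scoring below it is at least ``specificity`` (prediction is
    positive when score >= threshold).  A degenerate MCC denominator is
    guarded to 0.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    auc = auc_score(s, y)
    neg = s[y == 0]
    pos = s[y == 1]
    threshold = None
    for t in np.unique(s):
        if (neg < t).mean() >= specificity:
            threshold = float(t)
            break
    if threshold is None:
        threshold = float(np.max(s)) + 1.0  # nothing predicted positive
    tp = int((pos >= threshold).sum())
    fn = len(pos) - tp
    fp = int((neg >= threshold).sum())
    tn = len(neg) - fp
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom > 0 else 0.0
    return EvalMetrics(
        auc=auc, mcc=float(mcc), sensitivity=float(sn),
        specificity=float(sp), threshold=threshold,
    )


def assemble_training_set(
    f: FunctionType | str,
    positives: Sequence,
    unlabeled_pool: Sequence,
    size: int = 10000,
    seed: int = 0,
) -> PUDataset:
    """Draw the unlabeled sample for a function type.

    ``positives`` and ``unlabeled_pool`` are sequences of ``(item_id, aa)``
    pairs.  The unlabeled draw respects the function's residue restriction
    (e.g. Ser/Thr/Tyr for phosphorylation), excludes known positives, and
    is deterministic per seed.
    """
    ftype = REGISTRY[f] if isinstance(f, str) else f
    pos_ids = [p[0] for p in positives]
    pos_set = set(pos_ids)
    eligible = [
        (item_id, aa) for item_id, aa in unlabeled_pool
        if item_id not in pos_set and ftype.allows(aa)
    ]
    if not eligible:
        raise EvaluationError(
            f"residue restriction {sorted(ftype.restriction)} for {ftype.id} "
            "leaves no eligible unlabeled residues"
        )
    rng = np.random.default_rng(seed)
    if len(eligible) <= size:
        if len(eligible) < size:
            logger.warning(
                "unlabeled pool for %s has only %d eligible residues "
                "(requested %d); using all", ftype.id, len(eligible), size,
            )
        sample = list(eligible)
    else:
        idx = rng.choice(len(eligible), size=size, replace=False)
        sample = [eligible[i] for i in sorted(idx)]
    return PUDataset(labeled=pos_ids, unlabeled=[s[0] for s in sample])


# ---------------------------------------------------------------------------
# Cross-validated training and the model-selection grid


def cross_validate(
    envs: Sequence,
    labels: Sequence[int],
    groups: Sequence,
    spec: KernelSpec,
    k: int = 10,
    seed: int = 0,
    capacity: float = 1.0,
    plan: Optional[CVPlan] = None,
) -> dict:
    """Per-chain k-fold cross-validation of a graphlet-kernel PU predictor.

    ``labels`` are 1 for labeled positives, 0 for unlabeled; ``groups``
    assigns each item to a protein chain.  Test-fold items contribute no
    rows or columns to training-fold kernel fitting.  Scores are pooled
    across folds before computing AUC and the sp = 99% operating point.
    """
    y = np.asarray(labels).astype(int)
    groups = list(groups)
    if plan is None:
        plan = make_cv_plan(groups, k=k, seed=seed)
    profiles = [graphlets.compute_profile(e, spec) for e in envs]
    pooled_scores = np.full(len(envs), np.nan)
    for fold in range(1, plan.k + 1):
        test_idx = [i for i, g in enumerate(groups) if plan.fold_of(g) == fold]
        train_idx = [i for i, g in enumerate(groups) if plan.fold_of(g) != fold]
        if not test_idx:
            continue
        tr_pos = [i for i in train_idx if y[i] == 1]
        tr_unl = [i for i in train_idx if y[i] == 0]
        if not tr_pos or not tr_unl:
            continue
        ordered = tr_pos + tr_unl
        K_train = graphlets.kernel_matrix(
            [profiles[i] for i in ordered]
        ).entries
        svc, _ = pulearn.train_nontraditional(K_train, len(tr_pos), capacity)
        K_test = graphlets.cross_kernel(
            [profiles[i] for i in test_idx], [profiles[i] for i in ordered]
        )
        pooled_scores[test_idx] = svc.decision_function(K_test)
    mask = ~np.isnan(pooled_scores)
    metrics = evaluate(pooled_scores[mask], y[mask])
    return {"spec": spec, "metrics": metrics, "scores": pooled_scores, "plan": plan}


def default_grid(
    alphabet20: tuple,
    alphabet40: tuple,
    N_values=(4, 5),
    m_values=(0, 1),
    modes=("full", "label_sub", "edge_indel"),
) -> list:
    """The model-selection grid over (|Sigma|, m, N, mode)."""
    grid = []
    for sigma, alphabet in ((20, alphabet20), (40, alphabet40)):
        for N, m, mode in itertools.product(N_values, m_values, modes):
            grid.append((sigma, KernelSpec(N=N, m=m, mode=mode, alphabet=alphabet)))
    return grid


def grid_search(
    data_by_sigma: dict,
    grid: Sequence,
    k: int = 10,
    seed: int = 0,
    capacity: float = 1.0,
) -> dict:
    """Select the kernel spec maximizing cross-validated AUC.

    ``data_by_sigma`` maps alphabet size (20 or 40) to an
    ``(envs, labels, groups)`` triple whose environments carry labels from
    the matching alphabet.  Ties in AUC are broken toward smaller
    (N, m, |Sigma|) for parsimony.
    """
    if not grid:
        raise EvaluationError("empty model-selection grid")
    results = []
    for sigma, spec in grid:
        envs, labels, groups = data_by_sigma[sigma]
        res = cross_validate(
            envs, labels, groups, spec, k=k, seed=seed, capacity=capacity
        )
        results.append((sigma, spec, res["metrics"]))
    mode_order = {m: i for i, m in enumerate(graphlets.MODES)}
    best = min(
        results,
        key=lambda r: (-round(r[2].auc, 12), r[1].N, r[1].m, r[0],
                       mode_order[r[1].mode]),
    )
    return {
        "best_sigma": best[0],
        "best_spec": best[1],
        "best_metrics": best[2],
        "all_results": results,
    }


def train_site_predictor(
    pos_envs: Sequence,
    unl_envs: Sequence,
    spec: KernelSpec,
    capacity: float = 1.0,
    alpha: Optional[float] = None,
    prior_method: str = "elkan_noto_e1",
) -> pulearn.PUModel:
    """Convenience wrapper: profile the environments and fit a PU model."""
    pos = [graphlets.compute_profile(e, spec) for e in pos_envs]
    unl = [graphlets.compute_profile(e, spec) for e in unl_envs]
    return pulearn.fit_pu_model(
        pos, unl, spec, capacity=capacity, alpha=alpha, prior_method=prior_method
    )
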