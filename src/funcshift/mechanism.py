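"""Loss- and gain-of-function probability calculus for missense variants.

For a variant x, let p_wt = P(f|x'_wt) and p_mt = P(f|x'_mt) be the
posterior probabilities that the residue is functional for f in the
wild-type and mutant microenvironments (same structure, same locus, only
the root's amino acid replaced), and let p_S = P(S|x) be the probability
that the substitution significantly disrupts stability.  The calculus
assumes a dichotomized stability impact with two approximations: a large
stability change abolishes residue function, so P(loss|S,x) ~ p_wt; and
stability disruption essentially never creates function, so
P(gain|S,x) ~ 0.  Then

    P(loss|S-bar,x) = p_wt (1 - p_mt)          (function held, then lost)
    P(gain|S-bar,x) = (1 - p_wt) p_mt          (function absent, then found)
    P(loss|x)       = p_wt p_S + p_wt (1 - p_mt)(1 - p_S)
    P(gain|x)       = (1 - p_wt) p_mt (1 - p_S)

Joint columns condition on the stable stratum: P(loss, S-bar|x) =
P(loss|S-bar,x)(1 - p_S), likewise for gain (which equals the gain
marginal).  Multi-function events over a set F use either an independence
model, 1 - prod_f (1 - v_f), or the more conservative max model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

from . import structgraph
from .registry import CATEGORIES, REGISTRY, FunctionType

COMBINED_MODELS = ("independence", "max")
EVENTS = ("loss", "gain")
STRATA = ("stable", "joint", "marginal")


class MechanismError(ValueError):
    pass


def _check01(name: str, *values) -> None:
    for v in values:
        if not (isinstance(v, (int, float)) and math.isfinite(v) and 0.0 <= v <= 1.0):
            raise MechanismError(f"{name} must lie in [0, 1], got {v!r}")


def _complement_product(values: Iterable[float]) -> float:
    """1 - prod(1 - v); computed in log1p space when any factor is extreme
    to avoid cancellation."""
    vals = list(values)
    if any(v > 0.999 for v in vals):
        if any(v >= 1.0 for v in vals):
            return 1.0
        log_surv = sum(math.log1p(-v) for v in vals)
        return -math.expm1(log_surv)
    prod = 1.0
    for v in vals:
        prod *= 1.0 - v
    return 1.0 - prod


def loss_given_stable(p_wt: float, p_mt: float) -> float:
    """P(loss of f | S-bar, x) = p_wt * (1 - p_mt)."""
    _check01("posterior", p_wt, p_mt)
    return p_wt * (1.0 - p_mt)


def gain_given_stable(p_wt: float, p_mt: float) -> float:
    """P(gain of f | S-bar, x) = (1 - p_wt) * p_mt."""
    _check01("posterior", p_wt, p_mt)
    return (1.0 - p_wt) * p_mt


def loss_marginal(p_wt: float, p_mt: float, p_s: float) -> float:
    """P(loss of f | x), mixing the two stability strata."""
    _check01("posterior", p_wt, p_mt, p_s)
    return p_wt * p_s + loss_given_stable(p_wt, p_mt) * (1.0 - p_s)


def gain_marginal(p_wt: float, p_mt: float, p_s: float) -> float:
    """P(gain of f | x); the disrupted stratum contributes nothing."""
    _check01("posterior", p_wt, p_mt, p_s)
    return gain_given_stable(p_wt, p_mt) * (1.0 - p_s)


def combine_independence(values: Sequence[float]) -> float:
    """P(at least one of F altered) assuming independent functions."""
    vals = list(values)
    if not vals:
        raise MechanismError("function set F must be nonempty")
    _check01("combined value", *vals)
    return _complement_product(vals)


def combine_max(values: Sequence[float]) -> float:
    """Conservative multi-function model: the single largest probability."""
    vals = list(values)
    if not vals:
        raise MechanismError("function set F must be nonempty")
    _check01("combined value", *vals)
    return max(vals)


@dataclass
class FunctionScores:
    """The six probability columns for one function type."""

    function: str
    p_wt: float
    p_mt: float
    loss_stable: float
    loss_joint: float
    loss_marginal: float
    gain_stable: float
    gain_joint: float
    gain_marginal: float
    reason: str = ""

    def column(self, event: str, stratum: str) -> float:
        return getattr(self, f"{event}_{stratum}")


@dataclass
class MechanismScores:
    """All per-function and combined alteration probabilities of a variant."""

    variant: object
    p_s: float
    per_function: Dict[str, FunctionScores]
    combined: Dict[tuple, float] = field(default_factory=dict)
    # keys: (scope, model, event, stratum); scope is "all" or a category


def function_scores(
    function: str, p_wt: float, p_mt: float, p_s: float, reason: str = ""
) -> FunctionScores:
    ls = loss_given_stable(p_wt, p_mt)
    gs = gain_given_stable(p_wt, p_mt)
    return FunctionScores(
        function=function,
        p_wt=p_wt,
        p_mt=p_mt,
        loss_stable=ls,
        loss_joint=ls * (1.0 - p_s),
        loss_marginal=loss_marginal(p_wt, p_mt, p_s),
        gain_stable=gs,
        gain_joint=gs * (1.0 - p_s),
        gain_marginal=gain_marginal(p_wt, p_mt, p_s),
        reason=reason,
    )


def _combined_columns(scores: Sequence[FunctionScores], p_s: float) -> dict:
    """Combined loss/gain columns under both multi-function models.

    The disrupted-stratum loss probability of a single f is ~ p_wt, so the
    combined marginal mixes the combined stable-stratum value with the
    combined p_wt under the same model.
    """
    out = {}
    for model, combine in (("independence", combine_independence), ("max", combine_max)):
        loss_stable_c = combine([s.loss_stable for s in scores])
        loss_S_c = combine([s.p_wt for s in scores])
        gain_stable_c = combine([s.gain_stable for s in scores])
        out[(model, "loss", "stable")] = loss_stable_c
        out[(model, "loss", "joint")] = loss_stable_c * (1.0 - p_s)
        out[(model, "loss", "marginal")] = (
            loss_S_c * p_s + loss_stable_c * (1.0 - p_s)
        )
        out[(model, "gain", "stable")] = gain_stable_c
        out[(model, "gain", "joint")] = gain_stable_c * (1.0 - p_s)
        out[(model, "gain", "marginal")] = gain_stable_c * (1.0 - p_s)
    return out


def mutate_environment(env, mt_aa: str):
    """The mutant microenvironment: identical graph, only the root's label
    replaced.  The mutant root inherits the wild-type conservation class
    (lowercase stays lowercase under the 40-symbol alphabet)."""
    g = env.graph.copy()
    old = g.nodes[env.root]["label"]
    new = mt_aa.lower() if old.islower() else mt_aa.upper()
    g.nodes[env.root]["label"] = new
    g.nodes[env.root]["aa"] = mt_aa.upper()
    return structgraph.RootedEnvironment(graph=g, root=env.root, level=env.level)


def score_variant(
    variant,
    env_wt,
    models: dict,
    p_s: float,
    functions: Optional[Sequence[str]] = None,
    categories: bool = True,
) -> MechanismScores:
    """Score a mapped variant against a set of per-function site models.

    ``models`` maps function id to a predictor exposing
    ``posterior_env(env) -> float``.  PTM residue restrictions make the
    corresponding posterior an exact 0: a wild-type residue that cannot
    carry the modification has p_wt = 0 (no loss possible); a mutant
    residue that cannot carry it has p_mt = 0 (no gain possible).
    Combined models are computed over the full set and per category.
    """
    if variant.mapped is None:
        raise MechanismError(f"variant {variant.protein}:{variant.position} is unmapped")
    _check01("p_S", p_s)
    wt_aa = env_wt.graph.nodes[env_wt.root].get("aa", variant.wt_aa)
    if wt_aa.upper() != variant.wt_aa.upper():
        raise MechanismError(
            f"environment root is {wt_aa}, variant wild-type is {variant.wt_aa}"
        )
    env_mt = mutate_environment(env_wt, variant.mt_aa)
    fids = list(functions) if functions is not None else list(models)
    per_function: Dict[str, FunctionScores] = {}
    for fid in fids:
        ftype = REGISTRY.get(fid, FunctionType(fid, "ligand"))
        model = models[fid]
        reasons = []
        if ftype.allows(variant.wt_aa):
            p_wt = float(model.posterior_env(env_wt))
        else:
            p_wt, r = 0.0, f"wild-type {variant.wt_aa} cannot carry {fid}"
            reasons.append(r)
        if ftype.allows(variant.mt_aa):
            p_mt = float(model.posterior_env(env_mt))
        else:
            p_mt = 0.0
            reasons.append(f"mutant {variant.mt_aa} cannot carry {fid}")
        per_function[fid] = function_scores(
            fid, p_wt, p_mt, p_s, reason="; ".join(reasons)
        )

    combined: Dict[tuple, float] = {}
    all_scores = list(per_function.values())
    for key, val in _combined_columns(all_scores, p_s).items():
        combined[("all",) + key] = val
    if categories:
        for cat in CATEGORIES:
            cat_scores = [
                s for s in all_scores
                if REGISTRY.get(s.function) and REGISTRY[s.function].category == cat
            ]
            if cat_scores:
                for key, val in _combined_columns(cat_scores, p_s).items():
                    combined[(cat,) + key] = val
    return MechanismScores(
        variant=variant, p_s=p_s, per_function=per_function, combined=combined
    )


def scores_table(ms: MechanismScores) -> list:
    """Flatten MechanismScores into (variant, function, six columns) rows."""
    v = ms.variant
    vid = f"{v.protein}:{v.wt_aa}{v.position}{v.mt_aa}"
    rows = []
    for fid, s in ms.per_function.items():
        rows.append({
            "variant": vid, "function": fid,
            "loss_stable": s.loss_stable, "loss_joint": s.loss_joint,
            "loss_marginal": s.loss_marginal, "gain_stable": s.gain_stable,
            "gain_joint": s.gain_joint, "gain_marginal": s.gain_marginal,
            "p_wt": s.p_wt, "p_mt": s.p_mt, "reason": s.reason,
        })
    for (scope, model, event, stratum), val in sorted(ms.combined.items()):
        rows.append({
            "variant": vid, "function": f"{scope}:{model}:{event}:{stratum}",
            "value": val,
        })
    return rows
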