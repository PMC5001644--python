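"""Positive-unlabeled (PU) learning over precomputed kernels.

All predictors are trained from a set of known positives plus an unlabeled
mixture.  A "non-traditional" large-margin classifier first separates
labeled from unlabeled items; its decision values are mapped to (0, 1) by
Platt's sigmoid correction, giving P(l=+1|x), the probability that an item
is labeled.  The traditional posterior follows from the class prior
alpha = P(y=+1) (the fraction of true positives inside the unlabeled set):

    P(y=+1|x) = alpha * (n/m) * P(l=+1|x) / (1 - P(l=+1|x)),

with m and n the labeled and unlabeled sample sizes; outputs are clipped
into [0, 1] because downstream probability calculus requires proper
probabilities.  The prior itself is either supplied by the user or
estimated from calibrated scores with a mean-posterior baseline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.svm import SVC

from . import graphlets
from .graphlets import GraphletProfile, KernelSpec

AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")


class PUError(ValueError):
    pass


@dataclass
class PUDataset:
    """Labeled positives plus an unlabeled mixture, with disjoint ids."""

    labeled: list  # item ids (all positive)
    unlabeled: list
    payload: dict = field(default_factory=dict)  # id -> features/profile

    def __post_init__(self):
        if len(self.labeled) < 1 or len(self.unlabeled) < 1:
            raise PUError("both labeled and unlabeled sets must be nonempty")
        overlap = set(self.labeled) & set(self.unlabeled)
        if overlap:
            raise PUError(f"item ids shared between sets: {sorted(overlap)[:5]}")

    @property
    def m(self) -> int:
        return len(self.labeled)

    @property
    def n(self) -> int:
        return len(self.unlabeled)


@dataclass(frozen=True)
class StabilityRecord:
    """A single-site mutation with its measured stability change."""

    protein: str
    position: int
    wt_aa: str
    mt_aa: str
    ddg: float  # kcal/mol
    solvent_accessibility: Optional[float] = None
    ph: Optional[float] = None
    temperature: Optional[float] = None

    def __post_init__(self):
        if not math.isfinite(self.ddg):
            raise PUError("ddG must be finite")


def check_psd(K: np.ndarray, tol: float = 1e-8) -> None:
    """Raise if a kernel matrix is visibly not positive semidefinite."""
    K = np.asarray(K, dtype=float)
    if K.shape[0] != K.shape[1] or not np.allclose(K, K.T, atol=1e-10):
        raise PUError("kernel matrix must be square and symmetric")
    w = np.linalg.eigvalsh(K)
    scale = max(1.0, float(np.abs(w).max()))
    if w.min() < -tol * scale:
        raise PUError(
            f"kernel matrix is not positive semidefinite (min eigenvalue "
            f"{w.min():.3e}); consider adding diagonal jitter"
        )


def train_nontraditional(K: np.ndarray, n_labeled: int, capacity: float = 1.0):
    """Fit the labeled-vs-unlabeled SVM on a precomputed kernel.

    Rows/columns of ``K`` must be ordered labeled first.  Returns the
    fitted classifier and its decision values on the training items.
    Deterministic given the data and capacity.
    """
    K = np.asarray(K, dtype=float)
    m = int(n_labeled)
    n = K.shape[0] - m
    if m < 1 or n < 1:
        raise PUError("both labeled and unlabeled items are required")
    check_psd(K)
    y = np.concatenate([np.ones(m), -np.ones(n)])
    svc = SVC(C=capacity, kernel="precomputed")
    svc.fit(K, y)
    return svc, svc.decision_function(K)


@dataclass
class PlattSigmoid:
    """Platt's sigmoid: P(l=+1|s) = 1 / (1 + exp(A*s + B))."""

    A: float
    B: float

    def __call__(self, scores):
        s = np.asarray(scores, dtype=float)
        z = self.A * s + self.B
        out = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))
        return out if out.ndim else float(out)


def platt_calibrate(scores, labels) -> PlattSigmoid:
    """Fit Platt's correction by regularized maximum likelihood.

    Uses the standard smoothed targets t+ = (N+ + 1)/(N+ + 2) and
    t- = 1/(N- + 2) and the robust Newton iteration of Lin, Lin & Weng.
    Requires both classes to be present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise PUError("Platt calibration requires scores from both classes")
    t = np.where(pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    A, B = 0.0, math.log((n_neg + 1.0) / (n_pos + 1.0))
    def objective(A, B):
        z = A * s + B
        return float(np.sum(np.where(
            z >= 0, t * z + np.log1p(np.exp(-z)), (t - 1.0) * z + np.log1p(np.exp(z))
        )))

    fval = objective(A, B)
    sigma = 1e-12
    for _ in range(100):
        z = A * s + B
        p = np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))
        d1 = t - p  # gradient pieces dF/df
        d2 = p * (1.0 - p)
        g1 = float(np.sum(s * d1))
        g2 = float(np.sum(d1))
        if abs(g1) < 1e-10 and abs(g2) < 1e-10:
            break
        h11 = float(np.sum(s * s * d2)) + sigma
        h22 = float(np.sum(d2)) + sigma
        h21 = float(np.sum(s * d2))
        det = h11 * h22 - h21 * h21
        dA = -(h22 * g1 - h21 * g2) / det
        dB = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * dA + g2 * dB
        step = 1.0
        while step >= 1e-10:
            A2, B2 = A + step * dA, B + step * dB
            f2 = objective(A2, B2)
            if f2 < fval + 1e-4 * step * gd:
                A, B, fval = A2, B2, f2
                break
            step /= 2.0
        else:
            break
    return PlattSigmoid(A=A, B=B)


def pu_convert(p_l, alpha: float, m: int, n: int):
    """Convert the labeled-posterior P(l=+1|x) to P(y=+1|x).

    alpha * (n/m) * p_l / (1 - p_l), clipped into [0, 1]; p_l -> 1 maps
    to 1.  Vectorized over ``p_l``.
    """
    if not (0.0 <= alpha <= 1.0):
        raise PUError("class prior alpha must lie in [0, 1]")
    if m < 1 or n < 1:
        raise PUError("labeled and unlabeled sizes must be >= 1")
    p = np.asarray(p_l, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise PUError("p_l must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = alpha * (n / m) * p / (1.0 - p)
    raw = np.where(p >= 1.0, np.inf, raw)
    out = np.clip(raw, 0.0, 1.0)
    return out if out.ndim else float(out)


def estimate_class_prior(
    labeled_scores,
    unlabeled_scores,
    method: str = "elkan_noto_e1",
    value: Optional[float] = None,
) -> float:
    """Estimate the class prior alpha = P(y=+1) of the unlabeled set.

    ``given`` passes through a user-supplied value (priors estimated
    externally, e.g. by mixture-proportion algorithms, enter here).
    ``elkan_noto_e1`` is the mean labeled-posterior baseline
    alpha = mean_unlabeled(p_l) / mean_labeled(p_l), clipped to [0, 1];
    it assumes ``p_l`` scores are calibrated labeled-vs-unlabeled
    posteriors.
    """
    if method == "given":
        if value is None:
            raise PUError("method 'given' requires a value")
        if not (0.0 <= value <= 1.0):
            raise PUError("class prior must lie in [0, 1]")
        return float(value)
    if method != "elkan_noto_e1":
        raise PUError(f"unknown prior estimation method {method!r}")
    ls = np.asarray(labeled_scores, dtype=float)
    us = np.asarray(unlabeled_scores, dtype=float)
    if ls.size == 0 or us.size == 0:
        raise PUError("score sets must be nonempty")
    denom = ls.mean()
    if denom <= 0:
        raise PUError("labeled scores have zero mean; prior not identifiable")
    return float(np.clip(us.mean() / denom, 0.0, 1.0))


def empirical_frequency(posteriors) -> float:
    """Arithmetic mean of converted posteriors P(y=+1|x) over a data set."""
    p = np.asarray(posteriors, dtype=float)
    if p.size == 0:
        raise PUError("empirical frequency of an empty set is undefined")
    return float(p.mean())


# ---------------------------------------------------------------------------
# Stability training labels and mutation features


def stability_positive(ddg: float, cutoff: float = 0.5) -> bool:
    """Stability-training positive: |ddG| strictly greater than the cutoff
    (0.5 kcal/mol), covering both stabilizing and destabilizing changes."""
    if not math.isfinite(ddg):
        raise PUError("ddG must be finite")
    return abs(ddg) > cutoff


# Reconstructed per-residue physicochemical property table (13 scalars per
# amino acid): Kyte-Doolittle hydropathy, van der Waals volume (A^3),
# Grantham polarity, net charge at pH 7, isoelectric point, average
# flexibility, accessible surface area (A^2), molecular weight (Da),
# alpha-helix and beta-sheet propensities (Chou-Fasman), H-bond donor and
# acceptor counts of the side chain, and aromaticity.  The table is a
# documented reconstruction and is user-replaceable.
PROPERTY_NAMES = (
    "hydropathy", "volume", "polarity", "charge", "isoelectric_point",
    "flexibility", "surface_area", "molecular_weight", "helix_propensity",
    "sheet_propensity", "hbond_donors", "hbond_acceptors", "aromaticity",
)

DEFAULT_PROPERTY_TABLE = {
    #        hyd    vol   pol  chg    pI   flex   asa     mw   helx  shet  don acc  aro
    "A": ( 1.80,  67.0,  8.1,  0.0,  6.00, 0.357, 115.0,  89.1, 1.42, 0.83, 0.0, 0.0, 0.0),
    "C": ( 2.50,  86.0,  5.5,  0.0,  5.07, 0.346, 135.0, 121.2, 0.70, 1.19, 1.0, 0.0, 0.0),
    "D": (-3.50,  91.0, 13.0, -1.0,  2.77, 0.511, 150.0, 133.1, 1.01, 0.54, 1.0, 4.0, 0.0),
    "E": (-3.50, 109.0, 12.3, -1.0,  3.22, 0.497, 190.0, 147.1, 1.51, 0.37, 1.0, 4.0, 0.0),
    "F": ( 2.80, 135.0,  5.2,  0.0,  5.48, 0.314, 210.0, 165.2, 1.13, 1.38, 0.0, 0.0, 1.0),
    "G": (-0.40,  48.0,  9.0,  0.0,  5.97, 0.544,  75.0,  75.1, 0.57, 0.75, 0.0, 0.0, 0.0),
    "H": (-3.20, 118.0, 10.4,  0.1,  7.59, 0.323, 195.0, 155.2, 1.00, 0.87, 1.0, 1.0, 1.0),
    "I": ( 4.50, 124.0,  5.2,  0.0,  6.02, 0.462, 175.0, 131.2, 1.08, 1.60, 0.0, 0.0, 0.0),
    "K": (-3.90, 135.0, 11.3,  1.0,  9.74, 0.466, 200.0, 146.2, 1.16, 0.74, 2.0, 0.0, 0.0),
    "L": ( 3.80, 124.0,  4.9,  0.0,  5.98, 0.365, 170.0, 131.2, 1.21, 1.30, 0.0, 0.0, 0.0),
    "M": ( 1.90, 124.0,  5.7,  0.0,  5.74, 0.295, 185.0, 149.2, 1.45, 1.05, 0.0, 0.0, 0.0),
    "N": (-3.50,  96.0, 11.6,  0.0,  5.41, 0.463, 160.0, 132.1, 0.67, 0.89, 2.0, 2.0, 0.0),
    "P": (-1.60,  90.0,  8.0,  0.0,  6.30, 0.509, 145.0, 115.1, 0.57, 0.55, 0.0, 0.0, 0.0),
    "Q": (-3.50, 114.0, 10.5,  0.0,  5.65, 0.493, 180.0, 146.2, 1.11, 1.10, 2.0, 2.0, 0.0),
    "R": (-4.50, 148.0, 10.5,  1.0, 10.76, 0.529, 225.0, 174.2, 0.98, 0.93, 4.0, 0.0, 0.0),
    "S": (-0.80,  73.0,  9.2,  0.0,  5.68, 0.507, 115.0, 105.1, 0.77, 0.75, 1.0, 1.0, 0.0),
    "T": (-0.70,  93.0,  8.6,  0.0,  5.60, 0.444, 140.0, 119.1, 0.83, 1.19, 1.0, 1.0, 0.0),
    "V": ( 4.20, 105.0,  5.9,  0.0,  5.96, 0.386, 155.0, 117.1, 1.06, 1.70, 0.0, 0.0, 0.0),
    "W": (-0.90, 163.0,  5.4,  0.0,  5.89, 0.305, 255.0, 204.2, 1.08, 1.37, 1.0, 0.0, 1.0),
    "Y": (-1.30, 141.0,  6.2,  0.0,  5.66, 0.420, 230.0, 181.2, 0.69, 1.47, 2.0, 1.0, 1.0),
}


def stability_features(
    wt_aa: str, mt_aa: str, property_table: Optional[dict] = None
) -> np.ndarray:
    """33-dimensional mutation feature vector for stability prediction.

    The first 20 entries indicate the substitution (-1 at the wild-type
    amino acid, +1 at the mutant, 0 elsewhere); the remaining 13 entries
    are property differences mutant - wild-type.
    """
    table = property_table if property_table is not None else DEFAULT_PROPERTY_TABLE
    wt, mt = wt_aa.upper(), mt_aa.upper()
    if wt == mt:
        raise PUError("wild-type and mutant amino acids must differ")
    for aa in (wt, mt):
        if aa not in AA_ORDER or aa not in table:
            raise PUError(f"unknown amino acid {aa!r}")
    vec = np.zeros(33)
    vec[AA_ORDER.index(wt)] = -1.0
    vec[AA_ORDER.index(mt)] = 1.0
    wt_props = np.asarray(table[wt], dtype=float)
    mt_props = np.asarray(table[mt], dtype=float)
    if wt_props.shape != (13,) or mt_props.shape != (13,):
        raise PUError("property table must provide 13 scalars per amino acid")
    vec[20:] = mt_props - wt_props
    return vec


# ---------------------------------------------------------------------------
# The trained PU model


@dataclass
class PUModel:
    """A calibrated PU predictor over graphlet profiles.

    Stores the support profiles and dual coefficients of the underlying
    SVM so that decision values on new environments are reproducible
    without the original training matrix.
    """

    spec: KernelSpec
    support_profiles: list
    dual_coef: np.ndarray
    intercept: float
    platt: PlattSigmoid
    alpha: float
    m: int
    n: int
    normalized: bool = True

    def decision(self, profiles: Sequence[GraphletProfile]) -> np.ndarray:
        K = graphlets.cross_kernel(
            list(profiles), self.support_profiles, normalized=self.normalized
        )
        return K @ self.dual_coef + self.intercept

    def posterior_labeled(self, profiles) -> np.ndarray:
        return np.asarray(self.platt(self.decision(profiles)))

    def posterior(self, profiles) -> np.ndarray:
        return pu_convert(self.posterior_labeled(profiles), self.alpha, self.m, self.n)

    def posterior_env(self, env) -> float:
        """Posterior P(y=+1|x') for a single rooted environment."""
        profile = graphlets.compute_profile(env, self.spec)
        return float(np.atleast_1d(self.posterior([profile]))[0])

    # -- serialization (text-only bundle directory) --

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "kernel_spec.json").write_text(json.dumps({
            "N": self.spec.N, "m": self.spec.m, "mode": self.spec.mode,
            "alphabet": list(self.spec.alphabet), "normalized": self.normalized,
        }))
        (d / "platt.json").write_text(json.dumps({"A": self.platt.A, "B": self.platt.B}))
        (d / "prior.json").write_text(json.dumps({
            "alpha": self.alpha, "m": self.m, "n": self.n,
        }))
        with open(d / "support.tsv", "w") as fh:
            fh.write("dual_coef\tprofile_psi\n")
            for coef, prof in zip(self.dual_coef, self.support_profiles):
                psi = json.dumps({g.id: c for g, c in sorted(
                    prof.psi.items(), key=lambda kv: kv[0].id)})
                fh.write(f"{float(coef)!r}\t{psi}\n")
        (d / "intercept.json").write_text(json.dumps({"intercept": self.intercept}))

    @classmethod
    def load(cls, directory) -> "PUModel":
        d = Path(directory)
        ks = json.loads((d / "kernel_spec.json").read_text())
        spec = KernelSpec(
            N=ks["N"], m=ks["m"], mode=ks["mode"], alphabet=tuple(ks["alphabet"])
        )
        platt = PlattSigmoid(**json.loads((d / "platt.json").read_text()))
        prior = json.loads((d / "prior.json").read_text())
        intercept = json.loads((d / "intercept.json").read_text())["intercept"]
        coefs, profiles = [], []
        with open(d / "support.tsv") as fh:
            next(fh)
            for line in fh:
                coef_str, psi_str = line.rstrip("\n").split("\t")
                coefs.append(float(coef_str))
                psi = {
                    graphlets.Graphlet.from_id(k): v
                    for k, v in json.loads(psi_str).items()
                }
                profiles.append(GraphletProfile(
                    phi={}, N=spec.N, spec=spec, psi=psi
                ))
        return cls(
            spec=spec, support_profiles=profiles,
            dual_coef=np.asarray(coefs), intercept=float(intercept),
            platt=platt, alpha=prior["alpha"], m=prior["m"], n=prior["n"],
            normalized=ks.get("normalized", True),
        )


def fit_pu_model(
    pos_profiles: Sequence[GraphletProfile],
    unl_profiles: Sequence[GraphletProfile],
    spec: KernelSpec,
    capacity: float = 1.0,
    alpha: Optional[float] = None,
    prior_method: str = "elkan_noto_e1",
    normalized: bool = True,
) -> PUModel:
    """Train the non-traditional SVM, calibrate with Platt's sigmoid, and
    attach a class prior (given, or estimated from the calibrated training
    scores)."""
    items = list(pos_profiles) + list(unl_profiles)
    m, n = len(pos_profiles), len(unl_profiles)
    K = graphlets.kernel_matrix(items, normalized=normalized).entries
    svc, scores = train_nontraditional(K, m, capacity=capacity)
    y = np.concatenate([np.ones(m), np.zeros(n)])
    platt = platt_calibrate(scores, y)
    p_l = platt(scores)
    if alpha is not None:
        a = estimate_class_prior(None, None, method="given", value=alpha)
    else:
        a = estimate_class_prior(p_l[:m], p_l[m:], method=prior_method)
    support_idx = svc.support_
    dual = svc.dual_coef_.ravel()
    return PUModel(
        spec=spec,
        support_profiles=[items[i] for i in support_idx],
        dual_coef=dual,
        intercept=float(svc.intercept_[0]),
        platt=platt,
        alpha=a,
        m=m,
        n=n,
        normalized=normalized,
    )
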