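"""Genetic-value estimation, variance components, folds and accuracy.

Estimated breeding values and dominance deviations use the same
allele-substitution decomposition as the trait simulator, evaluated at the
posterior-mean marker effects:

    EBV_j = sum_i [I(x=1) 2q_i + I(x=0)(q_i - p_i) - I(x=-1) 2p_i] alpha_i + u_j
    EDD_j = sum_i [-I(x=1) 2q_i^2 + I(x=0) 2 p_i q_i - I(x=-1) 2p_i^2] d_i + delta_j

with alpha_i = a_i + d_i (q_i - p_i).  Marker-derived variance components
assume linkage and Hardy-Weinberg equilibrium:

    V_A = 2 sum_i p_i q_i [sigma_ai^2 + (q_i - p_i)^2 sigma_di^2] + sigma_u^2
    V_D = 4 sum_i (p_i q_i)^2 sigma_di^2 + sigma_delta^2

RKHS fits only expose the whole genotypic variance, so only broad-sense
heritability is reported for them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from forestgs.models import PosteriorSummary
from forestgs.traitsim import breeding_value_design, dominance_design

__all__ = [
    "VarianceComponents", "FoldAssignment", "EvaluationResult",
    "estimate_breeding_values", "estimate_dominance_deviations",
    "variance_components", "make_folds", "evaluate", "evaluate_folds",
]

SCHEMES = ("across_family", "within_family", "random")


class UnsupportedModelError(TypeError):
    """Raised when a fit cannot provide the requested genetic partition."""


def _require_markers(fit: PosteriorSummary) -> None:
    if fit.model.startswith("rkhs"):
        raise UnsupportedModelError(
            "RKHS fits predict whole genotypic values only; breeding "
            "values and dominance deviations cannot be separated")


def estimate_breeding_values(fit: PosteriorSummary, X: np.ndarray,
                             p: np.ndarray, q: np.ndarray,
                             polygenic: np.ndarray | None = None,
                             ) -> np.ndarray:
    """EBV from posterior-mean marker effects (+ additive polygenic term).

    ``polygenic`` supplies u for the rows of ``X``; when omitted the fit's
    own training-set u (if any) is used, which requires ``X`` to cover the
    training individuals.
    """
    _require_markers(fit)
    ebv = np.zeros(X.shape[0])
    if fit.a is not None:
        alpha = fit.a.copy()
        if fit.d is not None:
            alpha = alpha + fit.d * (q - p)
        ebv = breeding_value_design(X, p, q) @ alpha
    if polygenic is None and "u" in fit.effects:
        polygenic = fit.effects["u"]
    if polygenic is not None:
        if len(polygenic) != len(ebv):
            raise ValueError("polygenic term does not align with X rows")
        ebv = ebv + polygenic
    return ebv


def estimate_dominance_deviations(fit: PosteriorSummary, X: np.ndarray,
                                  p: np.ndarray, q: np.ndarray,
                                  polygenic: np.ndarray | None = None,
                                  ) -> np.ndarray:
    """EDD from posterior-mean dominance effects (+ dominance polygenic term).

    An additive-only fit carries no marker dominance, so the estimate
    reduces to the delta polygenic term (zero without a D matrix); a
    warning flags that case.
    """
    _require_markers(fit)
    edd = np.zeros(X.shape[0])
    if fit.d is not None:
        edd = dominance_design(X, p, q) @ fit.d
    else:
        warnings.warn("additive-only fit: dominance deviation estimate is "
                      "the polygenic delta term only", stacklevel=2)
    if polygenic is None and "delta" in fit.effects:
        polygenic = fit.effects["delta"]
    if polygenic is not None:
        if len(polygenic) != len(edd):
            raise ValueError("polygenic term does not align with X rows")
        edd = edd + polygenic
    return edd


@dataclass
class VarianceComponents:
    """Additive/dominance variance partition and heritability ratios."""

    V_A: float
    V_D: float
    sigma_e2: float
    V_G: float
    h2: float
    d2: float
    H2: float


def variance_components(fit: PosteriorSummary,
                        p: np.ndarray | None = None,
                        q: np.ndarray | None = None) -> VarianceComponents:
    """Variance components and h2 / d2 / H2 from one model fit.

    For marker models ``p`` and ``q`` are the allele frequencies of the
    fitted loci.  RKHS fits report only total genotypic variance and H2
    (h2 and d2 are NaN).
    """
    sigma_u2 = fit.variances.get("sigma2:u", 0.0)
    sigma_d2 = fit.variances.get("sigma2:delta", 0.0)
    if fit.model.startswith("rkhs"):
        vg_markers = sum(v for k, v in fit.variances.items()
                         if k.startswith("sigma2:g:"))
        vg = vg_markers + sigma_u2 + sigma_d2
        vp = vg + fit.sigma_e2
        return VarianceComponents(V_A=np.nan, V_D=np.nan,
                                  sigma_e2=fit.sigma_e2, V_G=vg,
                                  h2=np.nan, d2=np.nan, H2=vg / vp)
    va = sigma_u2
    vd = sigma_d2
    if fit.a is not None:
        if p is None or q is None:
            raise ValueError("allele frequencies are required for marker "
                             "variance components")
        pq = p * q
        sig_ai = fit.sigma_a2
        sig_di = fit.sigma_d2 if fit.sigma_d2 is not None \
            else np.zeros_like(sig_ai)
        va = va + 2.0 * float(np.sum(pq * (sig_ai + (q - p) ** 2 * sig_di)))
        vd = vd + 4.0 * float(np.sum(pq ** 2 * sig_di))
    vg = va + vd
    vp = vg + fit.sigma_e2
    return VarianceComponents(V_A=va, V_D=vd, sigma_e2=fit.sigma_e2, V_G=vg,
                              h2=va / vp, d2=vd / vp, H2=vg / vp)


# ---------------------------------------------------------------------------
# Cross-validation folds
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """Fold ids (0..k-1) per individual under one validation scheme."""

    scheme: str
    k: int
    fold: np.ndarray

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        present = np.unique(self.fold)
        if not np.all((present >= 0) & (present < self.k)):
            raise ValueError("fold ids out of range")


def make_folds(family_ids: np.ndarray, scheme: str, k: int = 10,
               rng: np.random.Generator | None = None) -> FoldAssignment:
    """Partition individuals into k folds under one of three schemes.

    ``across_family``: whole families go to one fold (validation families
    are absent from training).  ``within_family``: each family's members
    are dealt round-robin over folds, so every sufficiently large family
    appears in training and validation alike.  ``random``: individuals are
    dealt regardless of family.
    """
    rng = rng or np.random.default_rng()
    family_ids = np.asarray(family_ids)
    n = len(family_ids)
    fold = np.empty(n, dtype=np.int64)
    if scheme == "random":
        fold[:] = (np.arange(n) % k)[rng.permutation(n)]
    elif scheme == "across_family":
        fams = np.unique(family_ids)
        if len(fams) < k:
            raise ValueError(f"across-family folds need >= {k} families, "
                             f"got {len(fams)}")
        sizes = {f: int(np.sum(family_ids == f)) for f in fams}
        order = sorted(rng.permutation(fams), key=lambda f: -sizes[f])
        load = np.zeros(k)
        for f in order:  # greedy balance: largest family to lightest fold
            target = int(np.argmin(load + rng.uniform(0, 1e-9, k)))
            fold[family_ids == f] = target
            load[target] += sizes[f]
    elif scheme == "within_family":
        for f in np.unique(family_ids):
            members = np.flatnonzero(family_ids == f)
            members = members[rng.permutation(len(members))]
            start = rng.integers(k)
            fold[members] = (start + np.arange(len(members))) % k
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return FoldAssignment(scheme=scheme, k=k, fold=fold)


# ---------------------------------------------------------------------------
# Accuracy and bias
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Per-fold accuracy (Pearson r) and bias slope, with their means."""

    target: str
    fold_accuracy: np.ndarray
    fold_slope: np.ndarray
    accuracy: float = field(init=False)
    slope: float = field(init=False)

    def __post_init__(self) -> None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.accuracy = float(np.nanmean(self.fold_accuracy))
            self.slope = float(np.nanmean(self.fold_slope))


def evaluate(predicted: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Pearson correlation and regression slope of truth on prediction.

    A slope of one indicates unbiased prediction.  Zero-variance
    predictions leave both undefined (NaN, recorded as missing).
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if len(predicted) != len(truth) or len(truth) < 3:
        raise ValueError("need aligned vectors of length >= 3")
    vp = np.var(predicted)
    if vp == 0 or np.var(truth) == 0:
        return np.nan, np.nan
    cov = float(np.cov(truth, predicted)[0, 1])
    r = cov / np.sqrt(np.var(truth, ddof=1) * np.var(predicted, ddof=1))
    slope = cov / float(np.var(predicted, ddof=1))
    return float(r), slope


def evaluate_folds(predicted: np.ndarray, truth: np.ndarray,
                   folds: FoldAssignment, target: str = "") -> EvaluationResult:
    """Score a prediction vector fold by fold against its truth."""
    accs, slopes = [], []
    for f in range(folds.k):
        rows = np.flatnonzero(folds.fold == f)
        r, s = evaluate(predicted[rows], truth[rows])
        accs.append(r)
        slopes.append(s)
    return EvaluationResult(target=target, fold_accuracy=np.asarray(accs),
                            fold_slope=np.asarray(slopes))
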