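"""Gibbs samplers for whole-genome regression, RKHS and pedigree models.

All models share one base structure for individual j:

    y*_j = mu + g_j + u_j + delta_j + e_j

where ``g`` is the marker-driven genetic term, ``u | A sigma_u^2`` and
``delta | D sigma_delta^2`` are optional pedigree-based additive and
dominance polygenic effects, and ``e ~ N(0, sigma_e^2)``.

* **BayesA** writes g_j = sum_i (x_ij a_i + w_ij d_i) with a per-marker
  variance sigma_ai^2 ~ scaled-inv-chi2(nu_a, S_a) and a gamma hyperprior
  on the scale S_a (likewise for dominance effects d_i), so the scale is
  learned from the data rather than fixed.
* **RKHS kernel averaging** writes g = sum_r g_r with
  g_r ~ N(0, K_r sigma_gr^2) over Gaussian kernels of genotype distances
  at three fixed bandwidths (local / intermediate / global); the
  additive-dominance variant uses six kernels (three on the additive
  coding X, three on the heterozygosity coding W).
* **Pedigree** drops g entirely; u and delta are the breeding values and
  dominance deviations.

Multivariate-normal blocks are sampled through a one-off eigendecomposition
of each covariance matrix, after which every draw costs two matrix-vector
products.  Per-marker updates run through numba loops in
:mod:`forestgs._samplers`.

Hyperparameter defaults reconstruct the conventions of standard Bayesian
genomic-prediction software: degrees of freedom 5 for every
scaled-inverse-chi-square prior, prior scales solved so the prior modes
jointly account for half of Var(y) split equally across genetic terms,
and a gamma(1.1, rate) hyperprior on S_a / S_d whose mode sits at that
same solved scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from forestgs import _samplers

__all__ = [
    "KernelSet", "ModelConfig", "PosteriorSummary",
    "build_kernels", "gaussian_cross_kernels",
    "fit_bayesa", "fit_rkhs", "fit_pedigree", "batch_means_se",
]

DEFAULT_BANDWIDTH_MULTIPLIERS = (5.0, 1.0, 0.2)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def _squared_distances(M: np.ndarray) -> np.ndarray:
    G = M @ M.T
    sq = np.diag(G)
    D2 = sq[:, None] + sq[None, :] - 2.0 * G
    np.maximum(D2, 0.0, out=D2)
    return D2


@dataclass
class KernelSet:
    """Gaussian kernels over genotype distances at fixed bandwidths.

    ``h`` (and ``h_d``) are the 5th percentiles of the off-diagonal
    squared-Euclidean distances on X (and W); bandwidths are
    multiplier / h for multipliers (5, 1, 0.2), giving local,
    intermediate and global kernels.
    """

    kernels: dict[str, np.ndarray]
    h: float
    h_d: float | None
    multipliers: tuple[float, ...]
    X: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    W: np.ndarray | None = field(repr=False, default=None)

    @property
    def names(self) -> list[str]:
        return list(self.kernels)


def _percentile_bandwidth(D2: np.ndarray, label: str) -> float:
    off = D2[np.triu_indices_from(D2, k=1)]
    h = float(np.percentile(off, 5))
    if h <= 0:
        raise ValueError(f"5th percentile of off-diagonal {label} distances "
                         "is zero (constant or duplicated genotypes)")
    return h


def build_kernels(X: np.ndarray, W: np.ndarray | None = None,
                  multipliers: tuple[float, ...] = DEFAULT_BANDWIDTH_MULTIPLIERS,
                  ) -> KernelSet:
    """Build the additive (and optionally dominance) kernel-averaging set.

    K_ar = exp(-phi_ar * Da2) with phi_ar = multiplier / h; Da2 is the
    squared Euclidean distance on the -1/0/1 additive coding.  When ``W``
    is given, three further kernels are built the same way on the 0/1
    heterozygosity coding.
    """
    X = np.asarray(X, dtype=np.float64)
    Da2 = _squared_distances(X)
    h = _percentile_bandwidth(Da2, "additive")
    kernels = {f"Ka_{m:g}": np.exp(-(m / h) * Da2) for m in multipliers}
    h_d = None
    if W is not None:
        Dd2 = _squared_distances(np.asarray(W, dtype=np.float64))
        h_d = _percentile_bandwidth(Dd2, "dominance")
        kernels.update(
            {f"Kd_{m:g}": np.exp(-(m / h_d) * Dd2) for m in multipliers})
    return KernelSet(kernels=kernels, h=h, h_d=h_d,
                     multipliers=tuple(multipliers), X=X, W=W)


def gaussian_cross_kernels(kset: KernelSet, X_new: np.ndarray,
                           W_new: np.ndarray | None = None,
                           ) -> dict[str, np.ndarray]:
    """Kernels between new individuals (rows) and the training set.

    Uses the bandwidths fixed on the training distances, so fold-held-out
    individuals are related to the training set without re-estimating h.
    """
    out: dict[str, np.ndarray] = {}
    X_new = np.asarray(X_new, dtype=np.float64)
    d2 = (np.square(X_new).sum(1)[:, None] + np.square(kset.X).sum(1)[None, :]
          - 2.0 * X_new @ kset.X.T)
    np.maximum(d2, 0.0, out=d2)
    for m in kset.multipliers:
        out[f"Ka_{m:g}"] = np.exp(-(m / kset.h) * d2)
    if kset.W is not None and W_new is not None:
        W_new = np.asarray(W_new, dtype=np.float64)
        d2 = (np.square(W_new).sum(1)[:, None]
              + np.square(kset.W).sum(1)[None, :] - 2.0 * W_new @ kset.W.T)
        np.maximum(d2, 0.0, out=d2)
        for m in kset.multipliers:
            out[f"Kd_{m:g}"] = np.exp(-(m / kset.h_d) * d2)
    return out


# ---------------------------------------------------------------------------
# Configuration and results
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """MCMC chain settings and prior hyperparameters.

    ``fixed_*`` entries pin the corresponding variances instead of
    sampling them, which turns the samplers into their fixed-variance
    (ridge / BLUP) special cases — used for closed-form cross-checks.
    """

    n_iter: int = 100_000
    burn_in: int = 20_000
    thin: int = 3
    nu_a: float = 5.0
    nu_d: float = 5.0
    nu_g: float = 5.0
    nu_gd: float = 5.0
    nu_u: float = 5.0
    nu_delta: float = 5.0
    nu_e: float = 5.0
    r2: float = 0.5
    scale_shape: float = 1.1
    jitter: float = 1e-8
    seed: int = 0
    fixed_marker_variance: float | None = None
    fixed_residual_variance: float | None = None
    fixed_gp_variance: dict[str, float] | None = None
    store_effect_samples: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        for name in ("nu_a", "nu_d", "nu_g", "nu_gd", "nu_u", "nu_delta",
                     "nu_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSummary:
    """Posterior means (and retained variance samples) from one chain.

    ``effects`` holds the posterior-mean random-effect vectors on the
    training individuals keyed by block name ("u", "delta", "g:<kernel>");
    ``gp_alpha`` holds K^{-1} * effect per block, so a cross-covariance
    times alpha predicts the effect for new individuals.
    """

    model: str
    mu: float
    n_retained: int
    a: np.ndarray | None = None
    sigma_a2: np.ndarray | None = None
    scale_a: float | None = None
    d: np.ndarray | None = None
    sigma_d2: np.ndarray | None = None
    scale_d: float | None = None
    effects: dict[str, np.ndarray] = field(default_factory=dict)
    gp_alpha: dict[str, np.ndarray] = field(default_factory=dict)
    variances: dict[str, float] = field(default_factory=dict)
    variance_samples: dict[str, np.ndarray] = field(default_factory=dict,
                                                    repr=False)
    effect_samples: dict[str, np.ndarray] = field(default_factory=dict,
                                                  repr=False)

    @property
    def sigma_e2(self) -> float:
        return self.variances["sigma_e2"]

    @property
    def g_hat(self) -> np.ndarray:
        """Summed kernel genetic values (RKHS models)."""
        keys = [k for k in self.effects if k.startswith("g:")]
        if not keys:
            raise ValueError("no kernel effects in this fit")
        return np.sum([self.effects[k] for k in keys], axis=0)

    def has_pedigree(self) -> bool:
        return "u" in self.effects


# ---------------------------------------------------------------------------
# Core Gibbs engine
# ---------------------------------------------------------------------------

class _MarkerBlock:
    """State for one set of regression coefficients with BayesA priors."""

    def __init__(self, name: str, M: np.ndarray, nu: float, share: float,
                 vy: float, config: ModelConfig):
        self.name = name
        self.Xt = np.ascontiguousarray(np.asarray(M, dtype=np.float64).T)
        self.n, self.p = M.shape[0], M.shape[1]
        self.xtx = np.square(self.Xt).sum(axis=1)
        self.nu = nu
        msx = float(np.sum(np.var(M, axis=0)))
        if msx <= 0:
            msx = 1.0
        mode = share * vy / msx
        self.pinned = config.fixed_marker_variance is not None
        if self.pinned:
            init = config.fixed_marker_variance
            self.scale = init
        else:
            init = mode
            self.scale = mode * (nu + 2.0) / nu
        # gamma hyperprior on the scale, mode at the solved prior scale
        self.hyper_shape = config.scale_shape
        self.hyper_rate = (config.scale_shape - 1.0) / self.scale \
            if config.scale_shape > 1 else 1.0 / self.scale
        self.beta = np.zeros(self.p)
        self.var = np.full(self.p, init)
        # accumulators
        self.sum_beta = np.zeros(self.p)
        self.sum_var = np.zeros(self.p)
        self.sum_scale = 0.0

    def update(self, e: np.ndarray, sigma_e2: float,
               rng: np.random.Generator) -> None:
        order = rng.permutation(self.p)
        _samplers.update_marker_effects(self.Xt, self.xtx, self.beta,
                                        self.var, e, sigma_e2, order)
        if not self.pinned:
            _samplers.update_marker_variances(self.beta, self.var, self.nu,
                                              self.scale)
            shape = self.hyper_shape + 0.5 * self.p * self.nu
            rate = self.hyper_rate + 0.5 * self.nu * np.sum(1.0 / self.var)
            self.scale = rng.gamma(shape, 1.0 / rate)


class _GPBlock:
    """State for one multivariate-normal effect u ~ N(0, K sigma^2)."""

    def __init__(self, name: str, K: np.ndarray, nu: float, share: float,
                 vy: float, config: ModelConfig):
        self.name = name
        self.nu = nu
        n = K.shape[0]
        lam, V = np.linalg.eigh(K + config.jitter * np.eye(n))
        if lam.min() < -1e-8 * max(lam.max(), 1.0):
            raise ValueError(f"covariance for block {name!r} is not "
                             "positive semidefinite after jitter")
        keep = lam > 1e-8 * lam.max()
        self.lam, self.V = lam[keep], V[:, keep]
        self.rank = int(keep.sum())
        init = share * vy / float(np.mean(np.diag(K)))
        self.pinned = (config.fixed_gp_variance is not None
                       and name in config.fixed_gp_variance)
        if self.pinned:
            self.sigma2 = config.fixed_gp_variance[name]
            self.scale = self.sigma2
        else:
            self.sigma2 = init
            self.scale = init * (nu + 2.0) / nu
        self.b = np.zeros(self.rank)
        self.u = np.zeros(n)
        self.sum_u = np.zeros(n)
        self.sum_sigma2 = 0.0

    def update(self, e: np.ndarray, sigma_e2: float,
               rng: np.random.Generator) -> None:
        r = e + self.u
        z = self.V.T @ r
        prec = 1.0 / sigma_e2 + 1.0 / (self.lam * self.sigma2)
        self.b = (z / sigma_e2) / prec \
            + rng.standard_normal(self.rank) / np.sqrt(prec)
        self.u = self.V @ self.b
        e[:] = r - self.u
        if not self.pinned:
            ss = float(np.sum(self.b ** 2 / self.lam))
            chi2 = 2.0 * rng.gamma(0.5 * (self.nu + self.rank))
            self.sigma2 = (self.nu * self.scale + ss) / chi2

    def alpha(self, u_hat: np.ndarray) -> np.ndarray:
        """K^{-1} u_hat on the retained eigenspace, for cross-prediction."""
        return self.V @ ((self.V.T @ u_hat) / self.lam)


def _fit_core(y: np.ndarray, model: str,
              marker_specs: list[tuple[str, np.ndarray, float]],
              gp_specs: list[tuple[str, np.ndarray, float]],
              config: ModelConfig) -> PosteriorSummary:
    y = np.asarray(y, dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes must be finite")
    n = len(y)
    vy = float(np.var(y))
    if vy == 0:
        raise ValueError("phenotype variance is zero")

    rng = np.random.default_rng(config.seed)
    _samplers.seed_numba(int(rng.integers(1, 2**31)))

    n_genetic = len(marker_specs) + len(gp_specs)
    share = config.r2 / max(n_genetic, 1)
    markers = [_MarkerBlock(nm, M, nu, share, vy, config)
               for nm, M, nu in marker_specs]
    gps = [_GPBlock(nm, K, nu, share, vy, config)
           for nm, K, nu in gp_specs]

    e_pinned = config.fixed_residual_variance is not None
    sigma_e2 = (config.fixed_residual_variance if e_pinned
                else vy * (1.0 - config.r2))
    scale_e = vy * (1.0 - config.r2) * (config.nu_e + 2.0) / config.nu_e

    mu = float(np.mean(y))
    e = y - mu

    n_ret = config.n_retained
    sum_mu = 0.0
    sum_sigma_e2 = 0.0
    var_samples: dict[str, list[float]] = {"sigma_e2": []}
    for g in gps:
        var_samples[f"sigma2:{g.name}"] = []
    eff_samples: dict[str, list[np.ndarray]] = {}

    for it in range(config.n_iter):
        # intercept (flat prior)
        e += mu
        mu = float(np.mean(e)) + rng.standard_normal() * np.sqrt(sigma_e2 / n)
        e -= mu
        for blk in markers:
            blk.update(e, sigma_e2, rng)
        for g in gps:
            g.update(e, sigma_e2, rng)
        if not e_pinned:
            chi2 = 2.0 * rng.gamma(0.5 * (config.nu_e + n))
            sigma_e2 = (config.nu_e * scale_e + float(e @ e)) / chi2

        if it >= config.burn_in and (it - config.burn_in + 1) % config.thin == 0:
            sum_mu += mu
            sum_sigma_e2 += sigma_e2
            var_samples["sigma_e2"].append(sigma_e2)
            for blk in markers:
                blk.sum_beta += blk.beta
                blk.sum_var += blk.var
                blk.sum_scale += blk.scale
                if config.store_effect_samples:
                    eff_samples.setdefault(blk.name, []).append(
                        blk.beta.copy())
            for g in gps:
                g.sum_u += g.u
                g.sum_sigma2 += g.sigma2
                var_samples[f"sigma2:{g.name}"].append(g.sigma2)
                if config.store_effect_samples:
                    eff_samples.setdefault(g.name, []).append(g.u.copy())

    out = PosteriorSummary(model=model, mu=sum_mu / n_ret, n_retained=n_ret)
    out.variances["sigma_e2"] = sum_sigma_e2 / n_ret
    for blk in markers:
        beta = blk.sum_beta / n_ret
        var = blk.sum_var / n_ret
        if blk.name == "a":
            out.a, out.sigma_a2 = beta, var
            out.scale_a = blk.sum_scale / n_ret
        else:
            out.d, out.sigma_d2 = beta, var
            out.scale_d = blk.sum_scale / n_ret
    for g in gps:
        u_hat = g.sum_u / n_ret
        out.effects[g.name] = u_hat
        out.gp_alpha[g.name] = g.alpha(u_hat)
        out.variances[f"sigma2:{g.name}"] = g.sum_sigma2 / n_ret
    out.variance_samples = {k: np.asarray(v) for k, v in var_samples.items()}
    out.effect_samples = {k: np.asarray(v) for k, v in eff_samples.items()}
    return out


# ---------------------------------------------------------------------------
# Public model fits
# ---------------------------------------------------------------------------

def _pedigree_specs(A, D, config) -> list[tuple[str, np.ndarray, float]]:
    specs = []
    if A is not None:
        specs.append(("u", np.asarray(A, dtype=np.float64), config.nu_u))
    if D is not None:
        specs.append(("delta", np.asarray(D, dtype=np.float64),
                      config.nu_delta))
    return specs


def fit_bayesa(y: np.ndarray, X: np.ndarray, W: np.ndarray | None = None,
               A: np.ndarray | None = None, D: np.ndarray | None = None,
               config: ModelConfig | None = None) -> PosteriorSummary:
    """BayesA whole-genome regression, additive or additive-dominance.

    Supply ``W`` for the additive-dominance variant and ``A`` / ``D`` to
    add pedigree polygenic terms.
    """
    config = config or ModelConfig()
    markers = [("a", np.asarray(X, dtype=np.float64), config.nu_a)]
    if W is not None:
        markers.append(("d", np.asarray(W, dtype=np.float64), config.nu_d))
    name = "bayesa-ad" if W is not None else "bayesa-a"
    return _fit_core(y, name, markers, _pedigree_specs(A, D, config), config)


def fit_rkhs(y: np.ndarray, kernels: KernelSet,
             A: np.ndarray | None = None, D: np.ndarray | None = None,
             config: ModelConfig | None = None) -> PosteriorSummary:
    """RKHS kernel averaging: one genetic term per kernel, summed.

    Ka model uses the three additive-coding kernels; when the kernel set
    was built with ``W`` the six-kernel Ka-Kd variant is fitted.
    """
    config = config or ModelConfig()
    gp = [(f"g:{name}", K,
           config.nu_gd if name.startswith("Kd") else config.nu_g)
          for name, K in kernels.kernels.items()]
    if not gp:
        raise ValueError("kernel set is empty")
    name = "rkhs-kakd" if any(k.startswith("Kd") for k in kernels.kernels) \
        else "rkhs-ka"
    return _fit_core(y, name, [], gp + _pedigree_specs(A, D, config), config)


def fit_pedigree(y: np.ndarray, A: np.ndarray, D: np.ndarray | None = None,
                 config: ModelConfig | None = None) -> PosteriorSummary:
    """Pedigree-only model: y = mu + u + delta + e with u|A, delta|D."""
    config = config or ModelConfig()
    specs = _pedigree_specs(A, D, config)
    if not specs:
        raise ValueError("A is required")
    name = "ped-ad" if D is not None else "ped-a"
    return _fit_core(y, name, [], specs, config)


def batch_means_se(samples: np.ndarray, n_batches: int = 20) -> float:
    """Monte-Carlo standard error of a chain mean by batch means."""
    samples = np.asarray(samples)
    m = len(samples) // n_batches
    if m < 1:
        raise ValueError("too few samples for the requested batches")
    means = samples[:m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(np.std(means, ddof=1) / np.sqrt(n_batches))
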