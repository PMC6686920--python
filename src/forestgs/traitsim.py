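"""Quantitative trait architectures over simulated QTL genotypes.

Six architectures are studied: {oligogenic, polygenic} x dominance ratio
d2 in {0, 0.1, 0.2}.  Additive effects are gamma-distributed with random
sign (oligogenic, 30 QTL) or standard normal (polygenic, 1,000 QTL).
Dominance effects are d_i = a_i * tau_i with tau_i ~ N(0, sd) where sd is
1 (medium) or 2 (high dominance); whole tau vectors are rejection-sampled
until the realized dominance ratio lands in [0.09, 0.11] (medium) or
[0.19, 0.21] (high).

Parametric breeding values and dominance deviations use the classical
allele-substitution decomposition at the allele frequencies of the
genotyped generation; environmental variance is solved so that the
narrow-sense heritability Var(BV)/Var(phenotype) equals its 0.25 target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from forestgs.popsim import MarkerCodings

#: tau standard deviation and accepted d2 interval per dominance level
DOMINANCE_LEVELS: dict[str, tuple[float, tuple[float, float]]] = {
    "none": (0.0, (0.0, 0.0)),
    "medium": (1.0, (0.09, 0.11)),
    "high": (2.0, (0.19, 0.21)),
}

#: QTL count per inheritance mode
QTL_COUNTS = {"oligogenic": 30, "polygenic": 1_000}

GAMMA_SHAPE = 0.4
GAMMA_RATE = 1.66


@dataclass
class TraitArchitecture:
    """A sampled trait: QTL effects plus the targets they were drawn under."""

    label: str
    dominance_level: str
    qtl_loci: np.ndarray
    a: np.ndarray
    tau: np.ndarray
    d: np.ndarray
    realized_d2: float
    h2_target: float = 0.25
    d2_bounds: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not np.allclose(self.d, self.a * self.tau):
            raise ValueError("dominance effects must equal a * tau")


@dataclass
class TrueGeneticValues:
    """Parametric genetic values and phenotypes for one trait replicate."""

    bv: np.ndarray
    dd: np.ndarray
    g: np.ndarray
    phenotype: np.ndarray
    sigma_e2: float
    realized_h2: float
    realized_d2: float


def breeding_value_design(X: np.ndarray, p: np.ndarray,
                          q: np.ndarray) -> np.ndarray:
    """Per-locus breeding-value multipliers: 2q / (q-p) / -2p for AA/Aa/aa.

    The breeding value is this matrix times the average substitution
    effects alpha_i = a_i + d_i (q_i - p_i).
    """
    return ((X == 1) * (2.0 * q) + (X == 0) * (q - p)
            - (X == -1) * (2.0 * p))


def dominance_design(X: np.ndarray, p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Per-locus dominance-deviation multipliers: -2q^2 / 2pq / -2p^2."""
    return ((X == 1) * (-2.0 * q ** 2) + (X == 0) * (2.0 * p * q)
            - (X == -1) * (2.0 * p ** 2))


def sample_additive_effects(n_qtl: int, architecture: str,
                            rng: np.random.Generator) -> np.ndarray:
    """Draw additive QTL effects (half the homozygote difference).

    Oligogenic: |a| ~ gamma(shape 0.4, rate 1.66) with equiprobable sign.
    Polygenic: a ~ N(0, 1).
    """
    if architecture == "oligogenic":
        mag = rng.gamma(GAMMA_SHAPE, 1.0 / GAMMA_RATE, size=n_qtl)
        return mag * rng.choice([-1.0, 1.0], size=n_qtl)
    if architecture == "polygenic":
        return rng.normal(0.0, 1.0, size=n_qtl)
    raise ValueError(f"unknown architecture: {architecture!r}")


def _variance_ratios(a: np.ndarray, d: np.ndarray, qtl: MarkerCodings,
                     h2_target: float) -> tuple[float, float]:
    """Realized (Var(BV), d2) on the genotyped individuals at the h2 target."""
    alpha = a + d * (qtl.q - qtl.p)
    bv = breeding_value_design(qtl.X, qtl.p, qtl.q) @ alpha
    dd = dominance_design(qtl.X, qtl.p, qtl.q) @ d
    var_bv = float(np.var(bv))
    if var_bv == 0.0:
        raise ValueError("breeding-value variance is zero")
    # Vp = Var(G) + sigma_e2 is pinned to Var(BV) / h2 by the h2 constraint
    return var_bv, float(np.var(dd)) * h2_target / var_bv


def sample_dominance_effects(a: np.ndarray, level: str, qtl: MarkerCodings,
                             rng: np.random.Generator,
                             d2_bounds: tuple[float, float] | None = None,
                             max_tries: int = 10_000,
                             h2_target: float = 0.25,
                             ) -> tuple[np.ndarray, np.ndarray, float]:
    """Rejection-sample the tau vector until the realized d2 is in bounds.

    The whole tau vector is redrawn on each failure.  Returns
    (tau, d, realized d2).  Level ``'none'`` short-circuits to d = 0.
    """
    if level not in DOMINANCE_LEVELS:
        raise ValueError(f"unknown dominance level: {level!r}")
    tau_sd, default_bounds = DOMINANCE_LEVELS[level]
    bounds = default_bounds if d2_bounds is None else d2_bounds
    if level == "none":
        zero = np.zeros_like(a)
        return zero, zero, 0.0
    last = np.nan
    for _ in range(max_tries):
        tau = rng.normal(0.0, tau_sd, size=len(a))
        d = a * tau
        _, last = _variance_ratios(a, d, qtl, h2_target)
        if bounds[0] <= last <= bounds[1]:
            return tau, d, last
    raise RuntimeError(
        f"dominance rejection sampling failed after {max_tries} tries "
        f"(last realized d2 = {last:.4f}, bounds {bounds})")


def sample_architecture(qtl: MarkerCodings, inheritance: str, level: str,
                        rng: np.random.Generator,
                        h2_target: float = 0.25) -> TraitArchitecture:
    """Draw one full trait architecture on the given QTL genotypes."""
    a = sample_additive_effects(qtl.n_loci, inheritance, rng)
    tau, d, d2 = sample_dominance_effects(a, level, qtl, rng,
                                          h2_target=h2_target)
    return TraitArchitecture(
        label=f"{inheritance}_{level}",
        dominance_level=level,
        qtl_loci=qtl.kept_loci,
        a=a, tau=tau, d=d, realized_d2=d2,
        h2_target=h2_target,
        d2_bounds=DOMINANCE_LEVELS[level][1],
    )


def build_trait(qtl: MarkerCodings, arch: TraitArchitecture,
                rng: np.random.Generator) -> TrueGeneticValues:
    """Compute parametric BV, DD, genotypic values and phenotypes.

    BV_j = sum_i [I(x=1) 2q + I(x=0)(q-p) - I(x=-1) 2p] alpha_i with
    alpha_i = a_i + d_i (q_i - p_i);
    DD_j = sum_i [-I(x=1) 2q^2 + I(x=0) 2pq - I(x=-1) 2p^2] d_i;
    G = BV + DD.  The environmental variance solves
    Var(BV) / (Var(G) + sigma_e2) = h2_target and phenotypes are
    y* = G + N(0, sigma_e2).
    """
    alpha = arch.a + arch.d * (qtl.q - qtl.p)
    bv = breeding_value_design(qtl.X, qtl.p, qtl.q) @ alpha
    dd = dominance_design(qtl.X, qtl.p, qtl.q) @ arch.d
    g = bv + dd
    var_bv, var_g = float(np.var(bv)), float(np.var(g))
    if var_bv == 0.0:
        raise ValueError("breeding-value variance is zero; "
                         "cannot scale environmental variance")
    sigma_e2 = var_bv / arch.h2_target - var_g
    if sigma_e2 < 0:
        raise ValueError(
            f"h2 target {arch.h2_target} unattainable: genetic variance "
            f"{var_g:.3f} exceeds Var(BV)/h2 = {var_bv / arch.h2_target:.3f}")
    phenotype = g + rng.normal(0.0, np.sqrt(sigma_e2), size=len(g))
    vp = var_g + sigma_e2
    return TrueGeneticValues(
        bv=bv, dd=dd, g=g, phenotype=phenotype, sigma_e2=sigma_e2,
        realized_h2=var_bv / vp, realized_d2=float(np.var(dd)) / vp,
    )
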