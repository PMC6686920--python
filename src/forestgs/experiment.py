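"""End-to-end drivers: simulate a study replicate, cross-validate models.

One replicate follows the study design: coalescent base population of
1,000 individuals, truncation selection of 100 and random mating to 1,000
(first breeding cycle), then phenotypic selection of 42 founders crossed
into 71 full-sib families (~923 genotyped offspring).  Selection acts on
the trait's additive genetic value plus environmental noise at the 0.25
heritability target; dominance effects are rejection-sampled on the
genotyped generation, where accuracy is ultimately assessed.

Cross-validation fits every model on training folds only.  Marker allele
frequencies, kernel bandwidths and relationship sub-matrices are all taken
from the training set; random effects for validation individuals come
from the conditional (BLUP-style) extension
u_test = C[test, train] C[train, train]^{-1} u_train of each covariance C.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from forestgs import popsim, traitsim
from forestgs.kinship import additive_relationship, dominance_relationship
from forestgs.models import (
    ModelConfig, build_kernels, gaussian_cross_kernels,
    fit_bayesa, fit_pedigree, fit_rkhs,
)
from forestgs.evaluation import (
    EvaluationResult, estimate_breeding_values,
    estimate_dominance_deviations, evaluate_folds, make_folds,
)

logger = logging.getLogger(__name__)

TARGETS = ("breeding_value", "dominance_deviation", "genotypic_value",
           "phenotype")

#: base model ids; append "+ped" for the combined marker + pedigree variants
BASE_MODELS = ("ped-a", "ped-ad", "bayesa-a", "bayesa-ad",
               "rkhs-ka", "rkhs-kakd")


@dataclass
class SimulatedReplicate:
    """Everything one model-comparison replicate needs, on the genotyped set."""

    pop: popsim.Population
    markers: popsim.MarkerCodings
    qtl: popsim.MarkerCodings
    arch: traitsim.TraitArchitecture
    truth: traitsim.TrueGeneticValues
    A: np.ndarray
    D: np.ndarray
    family: np.ndarray

    @property
    def truth_by_target(self) -> dict[str, np.ndarray]:
        return {
            "breeding_value": self.truth.bv,
            "dominance_deviation": self.truth.dd,
            "genotypic_value": self.truth.g,
            "phenotype": self.truth.phenotype,
        }


def _additive_values(pop: popsim.Population, rows: np.ndarray,
                     a: np.ndarray) -> np.ndarray:
    """Raw additive genetic values sum_i a_i x_i on the -1/0/1 coding."""
    X = pop.genotypes(rows)[:, pop.qtl_loci].astype(np.float64) - 1.0
    return X @ a


def _selection_phenotype(pop: popsim.Population, a: np.ndarray,
                         h2: float, rng: np.random.Generator) -> np.ndarray:
    gv = _additive_values(pop, pop.generation_index(), a)
    var_g = np.var(gv)
    if var_g == 0:
        return rng.normal(size=len(gv))
    sigma_e = np.sqrt(var_g * (1.0 - h2) / h2)
    return gv + rng.normal(0.0, sigma_e, size=len(gv))


def simulate_replicate(spec: popsim.GenomeSpec, inheritance: str, level: str,
                       seed: int, *, n_base: int = 1000, n_select: int = 100,
                       n_cycle: int = 1000, method: str = "coalescent",
                       h2_target: float = 0.25,
                       cclones_kwargs: dict | None = None,
                       ) -> SimulatedReplicate:
    """Simulate one full study replicate for one trait architecture."""
    rng = np.random.default_rng(seed)
    pop = popsim.simulate_base_population(spec, n_base, seed, method=method)
    a_full = traitsim.sample_additive_effects(spec.n_qtl, inheritance, rng)

    pheno = _selection_phenotype(pop, a_full, h2_target, rng)
    pop = popsim.breed_generation(pop, pheno, n_select, n_cycle, rng)
    pheno = _selection_phenotype(pop, a_full, h2_target, rng)
    pop = popsim.cclones_design(pop, pheno, rng, **(cclones_kwargs or {}))

    qtl = popsim.encode_markers(pop, pop.qtl_loci)
    a = a_full[np.searchsorted(pop.qtl_loci, qtl.kept_loci)]
    tau, d, d2 = traitsim.sample_dominance_effects(a, level, qtl, rng,
                                                   h2_target=h2_target)
    arch = traitsim.TraitArchitecture(
        label=f"{inheritance}_{level}", dominance_level=level,
        qtl_loci=qtl.kept_loci, a=a, tau=tau, d=d, realized_d2=d2,
        h2_target=h2_target, d2_bounds=traitsim.DOMINANCE_LEVELS[level][1])
    truth = traitsim.build_trait(qtl, arch, rng)

    markers = popsim.encode_markers(pop, pop.marker_loci)
    ped = pop.pedigree_frame()
    A_full = additive_relationship(ped)
    D_full = dominance_relationship(ped, A_full)
    rows = pop.generation_index()
    A = A_full[np.ix_(rows, rows)]
    D = D_full[np.ix_(rows, rows)]
    return SimulatedReplicate(pop=pop, markers=markers, qtl=qtl, arch=arch,
                              truth=truth, A=A, D=D,
                              family=pop.family[rows])


# ---------------------------------------------------------------------------
# Model dispatch within one training fold
# ---------------------------------------------------------------------------

def _train_frequencies(X_tr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = (X_tr.mean(axis=0) + 1.0) / 2.0
    return p, 1.0 - p


def _fit_and_predict(model: str, use_pedigree: bool, rep: SimulatedReplicate,
                     y: np.ndarray, tr: np.ndarray, te: np.ndarray,
                     config: ModelConfig) -> dict[str, np.ndarray]:
    """Fit one model on the training rows, predict the validation rows.

    Returns one prediction vector per target quantity.  RKHS models
    predict whole genotypic values only; that prediction is scored
    against every target, as the partition into breeding value and
    dominance deviation is not available.
    """
    X_tr, X_te = rep.markers.X[tr].astype(np.float64), rep.markers.X[te]
    W_tr, W_te = rep.markers.W[tr].astype(np.float64), rep.markers.W[te]
    is_ped = model.startswith("ped")
    with_ped = is_ped or use_pedigree
    with_dom = model.endswith(("-ad", "kakd"))
    A_tr = rep.A[np.ix_(tr, tr)] if with_ped else None
    D_tr = rep.D[np.ix_(tr, tr)] if (with_ped and with_dom) else None

    n_te = len(te)
    zeros = np.zeros(n_te)

    if model.startswith("bayesa"):
        fit = fit_bayesa(y[tr], X_tr, W_tr if with_dom else None,
                         A=A_tr, D=D_tr, config=config)
    elif model.startswith("rkhs"):
        kset = build_kernels(X_tr, W_tr if with_dom else None)
        fit = fit_rkhs(y[tr], kset, A=A_tr, D=D_tr, config=config)
    elif model.startswith("ped"):
        fit = fit_pedigree(y[tr], rep.A[np.ix_(tr, tr)],
                           D=rep.D[np.ix_(tr, tr)] if with_dom else None,
                           config=config)
    else:
        raise ValueError(f"unknown model {model!r}")

    u_te = (rep.A[np.ix_(te, tr)] @ fit.gp_alpha["u"]
            if "u" in fit.gp_alpha else zeros)
    delta_te = (rep.D[np.ix_(te, tr)] @ fit.gp_alpha["delta"]
                if "delta" in fit.gp_alpha else zeros)

    if model.startswith("rkhs"):
        cross = gaussian_cross_kernels(kset, X_te,
                                       W_te if with_dom else None)
        g_te = sum(cross[name] @ fit.gp_alpha[f"g:{name}"]
                   for name in cross) + u_te + delta_te
        return {"breeding_value": g_te, "dominance_deviation": g_te,
                "genotypic_value": g_te, "phenotype": fit.mu + g_te}

    if is_ped:
        ebv, edd = u_te, delta_te
    else:
        p_tr, q_tr = _train_frequencies(X_tr)
        ebv = estimate_breeding_values(fit, X_te, p_tr, q_tr, polygenic=u_te)
        if with_dom:
            edd = estimate_dominance_deviations(fit, X_te, p_tr, q_tr,
                                                polygenic=delta_te)
        else:
            edd = delta_te
    g = ebv + edd
    return {"breeding_value": ebv, "dominance_deviation": edd,
            "genotypic_value": g, "phenotype": fit.mu + g}


def run_cross_validation(rep: SimulatedReplicate, model: str, scheme: str,
                         config: ModelConfig, rng: np.random.Generator,
                         k: int = 10, use_pedigree: bool = False,
                         ) -> dict[str, EvaluationResult]:
    """One 10-fold cross-validation of one model under one fold scheme."""
    folds = make_folds(rep.family, scheme, k=k, rng=rng)
    y = rep.truth.phenotype
    n = len(y)
    preds = {t: np.full(n, np.nan) for t in TARGETS}
    for f in range(k):
        te = np.flatnonzero(folds.fold == f)
        tr = np.flatnonzero(folds.fold != f)
        cfg = dataclasses.replace(config, seed=int(rng.integers(2**31)))
        fold_pred = _fit_and_predict(model, use_pedigree, rep, y, tr, te, cfg)
        for t in TARGETS:
            preds[t][te] = fold_pred[t]
    truth = rep.truth_by_target
    return {t: evaluate_folds(preds[t], truth[t], folds, target=t)
            for t in TARGETS}


def results_frame(cell_results: dict[str, EvaluationResult],
                  **labels) -> pd.DataFrame:
    """Tidy per-fold rows (one per fold x target) for one CV cell."""
    rows = []
    for target, res in cell_results.items():
        for f, (acc, slope) in enumerate(zip(res.fold_accuracy,
                                             res.fold_slope)):
            rows.append({**labels, "target": target, "fold": f,
                         "accuracy": acc, "slope": slope})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Experiment plan
# ---------------------------------------------------------------------------

@dataclass
class ExperimentPlan:
    """Full factorial plan: architectures x replicates x schemes x models."""

    spec: popsim.GenomeSpec = field(default_factory=popsim.GenomeSpec)
    architectures: tuple[tuple[str, str], ...] = (
        ("oligogenic", "none"), ("oligogenic", "medium"),
        ("oligogenic", "high"), ("polygenic", "none"),
        ("polygenic", "medium"), ("polygenic", "high"))
    n_replicates: int = 10
    schemes: tuple[str, ...] = ("across_family", "within_family", "random")
    models: tuple[str, ...] = BASE_MODELS
    k: int = 10
    config: ModelConfig = field(default_factory=ModelConfig)
    base_seed: int = 1
    n_base: int = 1000
    n_select: int = 100
    n_cycle: int = 1000
    method: str = "coalescent"

    def cells(self):
        for inheritance, level in self.architectures:
            for r in range(self.n_replicates):
                for scheme in self.schemes:
                    for model in self.models:
                        yield inheritance, level, r, scheme, model


def plan_from_yaml(path) -> ExperimentPlan:
    """Build an ExperimentPlan from a YAML config.

    Top-level keys map to ExperimentPlan fields; the nested ``spec`` and
    ``config`` mappings populate GenomeSpec and ModelConfig.  Absent keys
    keep their defaults, so a config file only states what it changes.
    """
    import yaml

    raw = yaml.safe_load(open(path)) or {}
    spec = popsim.GenomeSpec(**raw.pop("spec", {}))
    config = ModelConfig(**raw.pop("config", {}))
    if "architectures" in raw:
        raw["architectures"] = tuple(tuple(a) for a in raw["architectures"])
    for key in ("schemes", "models"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return ExperimentPlan(spec=spec, config=config, **raw)


def run_experiment(plan: ExperimentPlan, out_dir) -> pd.DataFrame:
    """Run every plan cell, resumably, and write tidy results.

    Each (architecture, replicate) shares one simulated population; each
    (scheme, model) cell is written to its own CSV under ``out_dir/cells``
    and skipped when already present, so interrupted runs resume.  Failed
    cells are logged and skipped; the summary only contains completed
    cells.
    """
    from pathlib import Path

    out = Path(out_dir)
    (out / "cells").mkdir(parents=True, exist_ok=True)
    frames = []
    qtl_for = {"oligogenic": 30, "polygenic": 1000}
    current_rep: tuple | None = None
    rep = None
    for inheritance, level, r, scheme, model in plan.cells():
        cell_id = f"{inheritance}_{level}_r{r}_{scheme}_{model}"
        cell_path = out / "cells" / f"{cell_id}.csv"
        if cell_path.exists():
            frames.append(pd.read_csv(cell_path))
            continue
        try:
            if current_rep != (inheritance, level, r):
                spec = dataclasses.replace(plan.spec,
                                           n_qtl=qtl_for[inheritance])
                rep = simulate_replicate(
                    spec, inheritance, level, seed=plan.base_seed + r,
                    n_base=plan.n_base, n_select=plan.n_select,
                    n_cycle=plan.n_cycle, method=plan.method)
                current_rep = (inheritance, level, r)
            digest = hashlib.sha256(
                f"{plan.base_seed}|{cell_id}".encode()).digest()
            rng = np.random.default_rng(
                int.from_bytes(digest[:4], "little") % 2**31)
            use_ped = model.endswith("+ped")
            res = run_cross_validation(rep, model.removesuffix("+ped"),
                                       scheme, plan.config, rng, k=plan.k,
                                       use_pedigree=use_ped)
            frame = results_frame(res, architecture=inheritance,
                                  dominance=level, replicate=r,
                                  scheme=scheme, model=model)
            frame.to_csv(cell_path, index=False)
            frames.append(frame)
            logger.info("cell %s done", cell_id)
        except Exception:
            logger.exception("cell %s failed; skipping", cell_id)
    result = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame())
    if len(result):
        from forestgs import io as fgs_io

        fgs_io.write_results(out / "results.csv", result,
                             {"plan_hash": fgs_io.plan_hash(plan),
                              "base_seed": plan.base_seed})
    return result


def summarize_table2(results: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy by target and model group, mirroring the study's
    pedigree / markers / markers+pedigree summary layout."""
    def group(model: str) -> str:
        if model.endswith("+ped"):
            return "markers+pedigree"
        return "pedigree" if model.startswith("ped") else "markers"

    df = results.copy()
    df["group"] = df["model"].map(group)
    per_model = (df.groupby(["architecture", "dominance", "target",
                             "group", "model"])["accuracy"]
                 .mean().reset_index())
    return (per_model.groupby(["architecture", "dominance", "target",
                               "group"])["accuracy"]
            .mean().unstack(["architecture", "dominance"]).round(3))
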