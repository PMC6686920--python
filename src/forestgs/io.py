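"""Plain-text exchange formats and binary population snapshots.

Genotypes travel as a tab-delimited individuals x loci matrix of -1/0/1
additive codes (0/1/2 dosage files are detected and recoded), with a
companion locus map (chromosome, position in cM).  Pedigrees are CSV with
columns id,sire,dam,generation and 0 for unknown parents.  Population
snapshots (haplotypes keyed by generation plus pedigree and locus map)
use a compressed npz container.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from forestgs.popsim import MarkerCodings, Population

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def write_genotypes(path, X: np.ndarray, ids: np.ndarray,
                    locus_map: pd.DataFrame | None = None) -> None:
    """Write an individuals x loci matrix of -1/0/1 codes, ids in column 1.

    ``locus_map`` (columns chrom, pos_cm) goes to ``<path>.map`` when given.
    """
    frame = pd.DataFrame(np.asarray(X),
                         columns=[f"L{i}" for i in range(X.shape[1])])
    frame.insert(0, "id", ids)
    frame.to_csv(path, sep="\t", index=False)
    if locus_map is not None:
        locus_map.to_csv(f"{path}.map", sep="\t", index=False)


def read_genotypes(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a genotype matrix; returns (ids, X in -1/0/1 codes).

    Accepts -1/0/1 additive codes or 0/1/2 dosages (recoded automatically);
    anything else is rejected.
    """
    frame = pd.read_csv(path, sep="\t")
    ids = frame.iloc[:, 0].to_numpy()
    X = frame.iloc[:, 1:].to_numpy()
    values = set(np.unique(X))
    if values <= {-1, 0, 1}:
        pass
    elif values <= {0, 1, 2}:
        logger.info("recoding 0/1/2 dosages to -1/0/1")
        X = X - 1
    else:
        raise ValueError(f"non-biallelic genotype codes found: "
                         f"{sorted(values - {-1, 0, 1, 2})}")
    return ids, X.astype(np.int8)


def codings_from_matrix(X: np.ndarray) -> MarkerCodings:
    """Build MarkerCodings from a -1/0/1 matrix, dropping monomorphic loci."""
    X = np.asarray(X, dtype=np.int8)
    p = (X + 1).mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    dropped = int((~poly).sum())
    if dropped:
        logger.info("dropped %d monomorphic loci (%d polymorphic retained)",
                    dropped, int(poly.sum()))
    X = X[:, poly]
    return MarkerCodings(X=X, W=(X == 0).astype(np.int8),
                         p=p[poly], q=1.0 - p[poly],
                         kept_loci=np.flatnonzero(poly))


# ---------------------------------------------------------------------------
# Pedigree and phenotypes
# ---------------------------------------------------------------------------

def write_pedigree(path, pedigree: pd.DataFrame) -> None:
    pedigree[["id", "sire", "dam", "generation"]].to_csv(path, index=False)


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path)
    required = {"id", "sire", "dam", "generation"}
    if not required <= set(ped.columns):
        raise ValueError(f"pedigree file must have columns {sorted(required)}")
    return ped


def write_phenotypes(path, ids: np.ndarray, y: np.ndarray,
                     name: str = "phenotype") -> None:
    pd.DataFrame({"id": ids, name: y}).to_csv(path, index=False)


def read_inputs(genotype_file, pedigree_file, phenotype_file,
                ) -> tuple[MarkerCodings, pd.DataFrame, np.ndarray]:
    """Load and cross-validate the three tabular inputs.

    Ids must be consistent: genotyped ids appear in the pedigree and every
    genotyped id has a phenotype.  Monomorphic loci are dropped (logged).
    """
    ids, X = read_genotypes(genotype_file)
    ped = read_pedigree(pedigree_file)
    missing = set(ids) - set(ped["id"])
    if missing:
        raise ValueError(f"genotyped ids missing from pedigree: "
                         f"{sorted(missing)[:5]}")
    pheno = pd.read_csv(phenotype_file).set_index("id").iloc[:, 0]
    missing = [i for i in ids if i not in pheno.index]
    if missing:
        raise ValueError(f"phenotype missing for id {missing[0]}")
    y = pheno.loc[ids].to_numpy(dtype=np.float64)
    return codings_from_matrix(X), ped, y


# ---------------------------------------------------------------------------
# Traits, results, snapshots
# ---------------------------------------------------------------------------

def write_trait_values(path, ids, truth, arch=None) -> None:
    """Trait CSV (id, BV, DD, G, phenotype) plus a YAML manifest."""
    pd.DataFrame({"id": ids, "BV": truth.bv, "DD": truth.dd, "G": truth.g,
                  "phenotype": truth.phenotype}).to_csv(path, index=False)
    if arch is not None:
        manifest = {
            "label": arch.label, "n_qtl": int(len(arch.a)),
            "h2_target": float(arch.h2_target),
            "realized_d2": float(arch.realized_d2),
            "d2_bounds": [float(b) for b in arch.d2_bounds],
        }
        Path(f"{path}.manifest.yaml").write_text(yaml.safe_dump(manifest))


def plan_hash(plan) -> str:
    """Stable short hash of an experiment plan's printable form."""
    return hashlib.sha256(repr(plan).encode()).hexdigest()[:12]


def write_results(path, results: pd.DataFrame, header: dict) -> None:
    """Tidy results CSV with a provenance header comment (plan hash, seed)."""
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}={value}\n")
        results.to_csv(fh, index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def save_population(path, pop: Population) -> None:
    np.savez_compressed(
        path, haplotypes=pop.haplotypes, sire=pop.sire, dam=pop.dam,
        generation=pop.generation, chrom=pop.chrom, pos_cm=pop.pos_cm,
        marker_loci=pop.marker_loci, qtl_loci=pop.qtl_loci,
        family=pop.family)


def load_population(path) -> Population:
    with np.load(path) as z:
        return Population(**{k: z[k] for k in z.files})
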