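"""Pedigree-expected additive (A) and dominance (D) relationship matrices.

A is built with the tabular (recursive) method; D from parental additive
relationships under the non-inbred approximation
D_jk = 1/4 (A_{s_j s_k} A_{d_j d_k} + A_{s_j d_k} A_{d_j s_k}).
Unknown parents are treated as unique, unrelated, non-inbred founders.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _parent_arrays(pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Extract 0-based parent indices (-1 = unknown) from a pedigree.

    Accepts a DataFrame with id/sire/dam columns (ids 1..n in record
    order, 0 = unknown) or a pair of such arrays.
    """
    if isinstance(pedigree, pd.DataFrame):
        ids = pedigree["id"].to_numpy()
        if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValueError("pedigree ids must be 1..n in record order")
        sire = pedigree["sire"].to_numpy()
        dam = pedigree["dam"].to_numpy()
    else:
        sire, dam = (np.asarray(p) for p in pedigree)
    n = len(sire)
    own = np.arange(1, n + 1)
    if np.any(sire >= own) or np.any(dam >= own):
        raise ValueError("every individual must be listed after its parents")
    return sire.astype(np.int64) - 1, dam.astype(np.int64) - 1


def additive_relationship(pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    A_jj = 1 + (1/2) A_{s_j d_j};  A_jk = (1/2)(A_{k s_j} + A_{k d_j}).
    Founders are mutually unrelated and non-inbred.
    """
    sire, dam = _parent_arrays(pedigree)
    n = len(sire)
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sire[j], dam[j]
        if s < 0:  # founder (validated: both parents known or neither)
            A[j, j] = 1.0
            continue
        row = 0.5 * (A[s, :j] + A[d, :j])
        A[j, :j] = row
        A[:j, j] = row
        A[j, j] = 1.0 + 0.5 * A[s, d]
    return A


def dominance_relationship(pedigree, A: np.ndarray) -> np.ndarray:
    """Dominance relationship matrix from parental additive relationships.

    Uses the non-inbred formula; a warning is emitted when the pedigree is
    inbred (diagonal of A above 1), where this construction is only
    approximate.  Entries involving a founder are zero off-diagonal.
    """
    sire, dam = _parent_arrays(pedigree)
    n = len(sire)
    if A.shape != (n, n):
        raise ValueError("A must be computed on the same pedigree")
    if np.any(np.diag(A) > 1.0 + 1e-12):
        warnings.warn("pedigree is inbred; non-inbred dominance formula "
                      "is approximate", stacklevel=2)
    D = np.zeros((n, n))
    nf = np.flatnonzero(sire >= 0)
    if len(nf):
        s, d = sire[nf], dam[nf]
        block = 0.25 * (A[np.ix_(s, s)] * A[np.ix_(d, d)]
                        + A[np.ix_(s, d)] * A[np.ix_(d, s)])
        D[np.ix_(nf, nf)] = block
    np.fill_diagonal(D, 1.0)
    return D


def add_jitter(M: np.ndarray, jitter: float = 1e-8) -> np.ndarray:
    """Return M + jitter * I; D is often singular for sparse designs."""
    logger.debug("adding ridge %g for positive-definiteness", jitter)
    return M + jitter * np.eye(M.shape[0])


def relationship_to_long(M: np.ndarray, ids: np.ndarray | None = None,
                         drop_zeros: bool = True) -> pd.DataFrame:
    """Long-format export (id1, id2, value) of the upper triangle."""
    n = M.shape[0]
    ids = np.arange(1, n + 1) if ids is None else np.asarray(ids)
    i, j = np.triu_indices(n)
    frame = pd.DataFrame({"id1": ids[i], "id2": ids[j], "value": M[i, j]})
    if drop_zeros:
        frame = frame[frame["value"] != 0.0].reset_index(drop=True)
    return frame
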