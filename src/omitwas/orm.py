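"""Omics relationship matrix (ORM) construction and leave-one-gene-out downdates.

The ORM plays the role a kinship matrix plays in a genetic mixed model: the
similarity between samples j and k is the average over genes of the product
of their standardized expression values,

    O_jk = (1/m) * sum_i (x_ij - mu_i)(x_ik - mu_i) / sigma_i^2 ,

i.e. O = Z'Z/m for the m x n standardized matrix Z. Because O is a mean of
per-gene rank-one contributions z_i z_i', removing one gene is an exact
rank-one downdate, which is what target-gene-excluded association needs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ORM", "compute_orm", "downdate"]


@dataclass
class ORM:
    sample_ids: np.ndarray
    O: np.ndarray
    m: int
    gene_ids: np.ndarray
    Z: np.ndarray  # per-gene contribution cache: standardized vectors, m x n

    def gene_index(self, gene) -> int:
        if isinstance(gene, (int, np.integer)):
            return int(gene)
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} is not in the ORM")
        return int(idx[0])


def compute_orm(
    Z: np.ndarray,
    gene_ids=None,
    sample_ids=None,
    mean_tol: float = 1e-6,
    psd_tol: float = -1e-8,
    check_psd: bool = True,
) -> ORM:
    """O = Z'Z/m from an m x n standardized expression matrix.

    Rows of ``Z`` must already be standardized (mean 0, population variance 1);
    a row mean beyond ``mean_tol`` is rejected rather than silently centered.
    Positive semi-definiteness is asserted (min eigenvalue >= ``psd_tol``) and
    violation raises instead of bending eigenvalues.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 1:
        raise ValueError("Z must be a non-empty m x n matrix")
    m, n = Z.shape
    row_means = Z.mean(axis=1)
    if np.max(np.abs(row_means)) > mean_tol:
        raise ValueError(
            f"input rows are not standardized: max |row mean| = {np.max(np.abs(row_means)):.3g}"
        )
    if gene_ids is None:
        gene_ids = np.array([f"G{i}" for i in range(m)], dtype=object)
    if sample_ids is None:
        sample_ids = np.array([f"S{j}" for j in range(n)], dtype=object)
    O = Z.T @ Z / m
    O = (O + O.T) / 2.0
    if check_psd:
        w_min = float(np.linalg.eigvalsh(O)[0])
        if w_min < psd_tol:
            raise ValueError(f"ORM is not positive semi-definite: min eigenvalue {w_min:.3g}")
    return ORM(
        sample_ids=np.asarray(sample_ids, dtype=object),
        O=O,
        m=m,
        gene_ids=np.asarray(gene_ids, dtype=object),
        Z=Z,
    )


def downdate(orm: ORM, gene) -> ORM:
    """Exact ORM over the remaining m-1 genes after removing one gene.

    O_minus_i = (m*O - z_i z_i') / (m - 1), identical to recomputing the ORM
    without gene i.
    """
    if orm.m <= 1:
        raise ValueError("cannot downdate an ORM with a single gene")
    i = orm.gene_index(gene)
    z = orm.Z[i]
    O_new = (orm.m * orm.O - np.outer(z, z)) / (orm.m - 1)
    keep = np.ones(orm.m, dtype=bool)
    keep[i] = False
    return ORM(
        sample_ids=orm.sample_ids,
        O=(O_new + O_new.T) / 2.0,
        m=orm.m - 1,
        gene_ids=orm.gene_ids[keep],
        Z=orm.Z[keep],
    )
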