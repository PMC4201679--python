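"""Pedigree (A) and genomic (G) relationship matrices.

A is built by the tabular method; G by VanRaden's first method,
``G = Z Z' / (2 * sum_j p_j (1 - p_j))`` with Z the dosage matrix whose
column j is centered by twice the reference-allele frequency p_j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popsim import Pedigree, GenotypeMatrix

__all__ = ["RelationshipMatrix", "pedigree_a_matrix", "genomic_g_matrix"]


@dataclass
class RelationshipMatrix:
    ids: np.ndarray
    values: np.ndarray
    kind: str  # 'A' or 'G'
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match id list")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-12:
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        pos = {iid: i for i, iid in enumerate(self.ids)}
        try:
            return np.array([pos[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} absent from relationship matrix") from None

    def submatrix(self, row_ids, col_ids=None) -> np.ndarray:
        r = self.index_of(row_ids)
        c = r if col_ids is None else self.index_of(col_ids)
        return self.values[np.ix_(r, c)]


def pedigree_a_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    For individual i with parents s, d (in topological order):
    ``A[i, j] = (A[s, j] + A[d, j]) / 2`` for earlier j, and
    ``A[i, i] = 1 + A[s, d] / 2``; an unknown parent contributes 0.
    """
    sire, dam = pedigree.parent_indices()
    n = pedigree.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(ids=pedigree.ids, values=A, kind="A")


def genomic_g_matrix(
    genotypes: GenotypeMatrix,
    allele_freqs: np.ndarray | str = "observed",
    ridge: float = 1e-6,
) -> RelationshipMatrix:
    """Genomic relationship matrix (VanRaden method 1).

    ``allele_freqs`` is either the string 'observed' (frequencies
    computed from the supplied matrix) or an explicit per-SNP array,
    e.g. base-population frequencies.  A small ridge (default 1e-6) is
    added to the diagonal so that downstream factorizations of G are
    well posed; it is recorded in the metadata.  Monomorphic SNPs
    contribute nothing to either numerator or denominator; a wholly
    monomorphic panel is an error.
    """
    d = genotypes.dosages
    if np.isnan(d).any():
        raise ValueError("G requires an imputed (fully called) genotype matrix")
    if isinstance(allele_freqs, str):
        if allele_freqs != "observed":
            raise ValueError(f"unknown allele frequency source {allele_freqs!r}")
        p = d.mean(axis=0) / 2.0
        freq_source = "observed"
    else:
        p = np.asarray(allele_freqs, dtype=float)
        if p.shape != (genotypes.n_snps,):
            raise ValueError("allele frequency vector length does not match SNP count")
        if ((p <= 0) | (p >= 1)).any():
            raise ValueError("external allele frequencies must lie strictly in (0, 1)")
        freq_source = "external"
    poly = (p > 0) & (p < 1)
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: G denominator is zero")
    Z = d[:, poly] - 2.0 * p[poly]
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0
    if ridge:
        G = G + ridge * np.eye(G.shape[0])
    return RelationshipMatrix(
        ids=genotypes.ids,
        values=G,
        kind="G",
        metadata={"allele_freq_source": freq_source, "ridge": float(ridge),
                  "denominator": float(denom), "n_snps_used": int(poly.sum())},
    )
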