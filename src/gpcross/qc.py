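"""SNP quality control and genotype-matrix preparation.

Markers are removed when their call rate or minor allele frequency falls
strictly below the configured thresholds (defaults 0.95 and 0.01).  A
GenTrain-style score filter cannot be computed from dosage data; an
externally supplied boolean keep-mask can be passed instead.  Remaining
missing dosages are mean-imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .popsim import GenotypeMatrix

__all__ = ["QCReport", "filter_snps", "impute_missing"]


@dataclass
class QCReport:
    n_input: int
    n_fail_call_rate: int
    n_fail_maf: int
    n_fail_both: int
    n_fail_external: int
    n_retained: int
    min_call_rate: float
    min_maf: float

    def __post_init__(self) -> None:
        removed = (
            self.n_fail_call_rate + self.n_fail_maf - self.n_fail_both + self.n_fail_external
        )
        if self.n_retained + removed != self.n_input:
            raise ValueError("QC counts do not partition the input SNP set")

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"QC: {self.n_input} SNPs in; removed {self.n_fail_call_rate} below call rate "
            f"{self.min_call_rate}, {self.n_fail_maf} below MAF {self.min_maf} "
            f"({self.n_fail_both} failed both), {self.n_fail_external} by external mask; "
            f"{self.n_retained} retained"
        )


def filter_snps(
    genotypes: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_maf: float = 0.01,
    external_keep: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs with call rate < min_call_rate or MAF < min_maf (strict).

    MAF is computed on non-missing dosages over all genotyped
    individuals.  ``external_keep`` applies an additional user-supplied
    per-SNP mask (e.g. a chip-quality score filter computed elsewhere);
    SNPs dropped by it alone are counted separately.
    """
    if not (0.0 <= min_call_rate <= 1.0 and 0.0 <= min_maf <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    d = genotypes.dosages
    if d.size == 0:
        raise ValueError("empty genotype matrix")
    called = ~np.isnan(d)
    call_rate = called.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
    maf = np.fmin(p, 1.0 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)

    fail_cr = call_rate < min_call_rate
    fail_maf = maf < min_maf
    keep = ~(fail_cr | fail_maf)
    fail_ext = np.zeros_like(keep)
    if external_keep is not None:
        external_keep = np.asarray(external_keep, dtype=bool)
        if external_keep.shape != (genotypes.n_snps,):
            raise ValueError("external keep-mask length does not match SNP count")
        fail_ext = keep & ~external_keep
        keep = keep & external_keep
    if not keep.any():
        raise ValueError("quality control removed every SNP")

    report = QCReport(
        n_input=genotypes.n_snps,
        n_fail_call_rate=int(fail_cr.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_fail_both=int((fail_cr & fail_maf).sum()),
        n_fail_external=int(fail_ext.sum()),
        n_retained=int(keep.sum()),
        min_call_rate=min_call_rate,
        min_maf=min_maf,
    )
    filtered = GenotypeMatrix(
        ids=genotypes.ids.copy(),
        snp_ids=genotypes.snp_ids[keep].copy(),
        dosages=d[:, keep].copy(),
        snp_map=genotypes.snp_map[keep].reset_index(drop=True),
        metadata=dict(genotypes.metadata),
    )
    filtered.snp_map.attrs.update(genotypes.snp_map.attrs)
    return filtered, report


def impute_missing(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the per-SNP mean of called dosages.

    The imputed-entry mask is stored under metadata['imputed_mask'];
    matrices with no missing entries are returned unchanged apart from
    the flag.
    """
    d = genotypes.dosages
    missing = np.isnan(d)
    if missing.all(axis=0).any():
        raise ValueError("SNP with zero called genotypes; run filter_snps first")
    out = d.copy()
    if missing.any():
        means = np.nanmean(d, axis=0)
        out[missing] = np.broadcast_to(means, d.shape)[missing]
    meta = dict(genotypes.metadata)
    meta["imputed"] = True
    meta["imputed_mask"] = missing
    result = GenotypeMatrix(
        ids=genotypes.ids.copy(),
        snp_ids=genotypes.snp_ids.copy(),
        dosages=out,
        snp_map=genotypes.snp_map.copy(),
        metadata=meta,
    )
    result.snp_map.attrs.update(genotypes.snp_map.attrs)
    return result
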