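"""Readers and writers for the tabular file formats.

Pedigrees and phenotypes travel as CSV, genotypes as either a
tab-separated dosage matrix (header row of SNP ids, first column of
individual ids, missing = "NA") or a PLINK-style .ped/.map pair whose
map carries a fifth reference-allele column; dosages count copies of
that reference allele and a "0 0" genotype is missing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .popsim import UNKNOWN_PARENT, GenotypeMatrix, Pedigree, PhenotypeTable
from .relmat import RelationshipMatrix

__all__ = [
    "write_pedigree", "read_pedigree",
    "write_phenotypes", "read_phenotypes",
    "write_genotypes_tsv", "write_plink", "read_genotypes",
    "write_relationship_matrix", "read_relationship_matrix",
]

_ALLELES = {"A", "C", "G", "T", "0"}


# -- pedigree ---------------------------------------------------------------


def write_pedigree(pedigree: Pedigree, path) -> None:
    cols = ["id", "sire", "dam", "sex", "generation", "hatch"]
    pedigree.table[cols].to_csv(path, index=False)


def _toposort(df: pd.DataFrame) -> pd.DataFrame:
    """Reorder pedigree rows parents-first; raise on cycles/unknown parents."""
    ids = set(df["id"])
    children: dict[str, list[str]] = {}
    indeg = {i: 0 for i in df["id"]}
    for _, row in df.iterrows():
        for parent in (row["sire"], row["dam"]):
            if parent == UNKNOWN_PARENT:
                continue
            if parent not in ids:
                raise ValueError(f"unknown parent id {parent!r} for {row['id']!r}")
            children.setdefault(parent, []).append(row["id"])
            indeg[row["id"]] += 1
    order = []
    ready = sorted(i for i, d in indeg.items() if d == 0)
    while ready:
        cur = ready.pop(0)
        order.append(cur)
        for ch in children.get(cur, []):
            indeg[ch] -= 1
            if indeg[ch] == 0:
                ready.append(ch)
        ready.sort()
    if len(order) != len(df):
        raise ValueError("pedigree contains a cycle")
    return df.set_index("id").loc[order].reset_index()


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str, "hatch": int})
    missing = {"id", "sire", "dam", "sex", "generation", "hatch"} - set(df.columns)
    if missing:
        raise ValueError(f"pedigree file lacks column(s) {sorted(missing)}")
    return Pedigree(_toposort(df))


# -- phenotypes -------------------------------------------------------------


def write_phenotypes(phenos: PhenotypeTable, path) -> None:
    phenos.table.to_csv(path, index=False)


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, dtype={"id": str})
    if "tbv" not in df.columns:
        df["tbv"] = np.nan
    return PhenotypeTable(df)


# -- genotypes --------------------------------------------------------------


def write_genotypes_tsv(geno: GenotypeMatrix, path, map_path=None) -> None:
    df = pd.DataFrame(geno.dosages, index=geno.ids, columns=geno.snp_ids)
    df.index.name = "id"
    # integral dosages print as integers, missing as NA
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")
    if map_path is not None:
        geno.snp_map.to_csv(map_path, index=False)


def _read_genotypes_tsv(path, map_path=None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.duplicated().any():
        raise ValueError("duplicate individual ids in genotype file")
    if map_path is not None and Path(map_path).exists():
        snp_map = pd.read_csv(map_path)
    else:
        snp_map = pd.DataFrame(
            {"snp_id": df.columns, "chrom": 1, "pos_cm": np.arange(len(df.columns), dtype=float)}
        )
    dosages = df.to_numpy(dtype=float)
    called = dosages[~np.isnan(dosages)]
    fractional = bool(called.size) and not np.isin(called, (0.0, 1.0, 2.0)).all()
    return GenotypeMatrix(
        ids=df.index.to_numpy(dtype=object),
        snp_ids=df.columns.to_numpy(dtype=object),
        dosages=dosages,
        snp_map=snp_map,
        metadata={"imputed": True} if fractional else {},
    )


def write_plink(geno: GenotypeMatrix, prefix) -> None:
    """Write a .ped/.map pair; reference allele 'A', alternate 'C'.

    The .map gains a fifth column with the reference allele so dosages
    round-trip without external metadata.
    """
    prefix = Path(prefix)
    ref, alt = "A", "C"
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in geno.snp_map.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp_id']}\t{row['pos_cm']}\t0\t{ref}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, iid in enumerate(geno.ids):
            fields = ["FAM", str(iid), "0", "0", "0", "-9"]
            for d in geno.dosages[i]:
                if np.isnan(d):
                    fields += ["0", "0"]
                else:
                    nref = int(round(d))
                    fields += [ref] * nref + [alt] * (2 - nref)
            fh.write(" ".join(fields) + "\n")


def _read_plink(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    map_rows = []
    with open(prefix.with_suffix(".map")) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(".map file lacks the reference-allele column")
            map_rows.append((parts[1], int(parts[0]), float(parts[2]), parts[4]))
    snp_map = pd.DataFrame(map_rows, columns=["snp_id", "chrom", "pos_cm", "ref_allele"])
    refs = snp_map["ref_allele"].to_numpy()
    k = len(snp_map)

    ids, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * k:
                raise ValueError(f"ragged .ped row ({len(parts)} fields, expected {6 + 2 * k})")
            ids.append(parts[1])
            alleles = parts[6:]
            dos = np.empty(k)
            for j in range(k):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                for a in (a1, a2):
                    if a not in _ALLELES:
                        raise ValueError(f"invalid allele code {a!r}")
                if a1 == "0" or a2 == "0":
                    dos[j] = np.nan
                else:
                    dos[j] = (a1 == refs[j]) + (a2 == refs[j])
            rows.append(dos)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids in .ped file")
    return GenotypeMatrix(
        ids=np.array(ids, dtype=object),
        snp_ids=snp_map["snp_id"].to_numpy(dtype=object),
        dosages=np.array(rows),
        snp_map=snp_map[["snp_id", "chrom", "pos_cm"]].assign(ref_allele=refs),
    )


def read_genotypes(path, format: str | None = None, map_path=None) -> GenotypeMatrix:
    """Load genotypes; format {'tsv-dosage', 'ped-map'} or by extension."""
    path = Path(path)
    if format is None:
        format = "ped-map" if path.suffix in (".ped", ".map") else "tsv-dosage"
    if format == "tsv-dosage":
        return _read_genotypes_tsv(path, map_path)
    if format == "ped-map":
        return _read_plink(path.with_suffix(""))
    raise ValueError(f"unknown genotype format {format!r}")


# -- relationship matrices --------------------------------------------------


def write_relationship_matrix(rm: RelationshipMatrix, path) -> None:
    df = pd.DataFrame(rm.values, index=rm.ids, columns=rm.ids)
    df.index.name = f"kind={rm.kind}"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_relationship_matrix(path) -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    kind = (df.index.name or "kind=A").split("=", 1)[-1]
    values = df.to_numpy(dtype=float)
    if np.abs(values - values.T).max(initial=0.0) > 1e-8:
        raise ValueError("relationship matrix file is not symmetric")
    values = (values + values.T) / 2.0
    return RelationshipMatrix(
        ids=df.index.to_numpy(dtype=object), values=values, kind=kind
    )
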