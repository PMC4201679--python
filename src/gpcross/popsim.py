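"""Simulation of an F2 intercross population.

The generator emulates a three-generation cross between two divergent
founder lines: a small F0 cohort drawn from each line, F1 produced by
between-line matings, and a large F2 generation organised in paternal
half-sib families.  Founder line allele frequencies follow a
Balding-Nichols-style construction around a shared ancestral frequency;
meiosis uses a Haldane (no-interference) crossover model.  True breeding
values are purely additive sums over QTL that are themselves members of
the marker panel, and phenotypes add fixed sex and hatch effects plus
normal residuals calibrated to a target narrow-sense heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

UNKNOWN_PARENT = "0"

__all__ = [
    "Pedigree",
    "GenotypeMatrix",
    "TraitArchitecture",
    "PhenotypeTable",
    "FounderSet",
    "SimulatedPopulation",
    "simulate_founders",
    "make_cross_design",
    "drop_gamete",
    "drop_gametes",
    "drop_pedigree_genotypes",
    "simulate_phenotypes",
    "simulate_population",
    "default_architectures",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Pedigree:
    """Three-generation pedigree table.

    ``table`` columns: id, sire, dam, sex ('M'/'F'), generation
    ('F0'/'F1'/'F2'), hatch (small int batch label).  Unknown parents are
    encoded as :data:`UNKNOWN_PARENT`.  Rows are kept in topological order
    (parents before offspring).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        t = self.table
        ids = t["id"].to_numpy()
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in pedigree")
        seen: set[str] = set()
        for _, row in t.iterrows():
            for parent in (row["sire"], row["dam"]):
                if parent != UNKNOWN_PARENT and parent not in seen:
                    raise ValueError(
                        f"parent {parent!r} of {row['id']!r} does not precede it "
                        "(pedigree not topologically ordered, or unknown id)"
                    )
            if row["id"] in (row["sire"], row["dam"]):
                raise ValueError(f"individual {row['id']!r} is its own parent")
            seen.add(row["id"])
        f2 = t[t["generation"] == "F2"]
        if ((f2["sire"] == UNKNOWN_PARENT) | (f2["dam"] == UNKNOWN_PARENT)).any():
            raise ValueError("every F2 individual must have both parents recorded")

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def n(self) -> int:
        return len(self.table)

    def subset_generation(self, generation: str) -> pd.DataFrame:
        return self.table[self.table["generation"] == generation]

    @property
    def f2_ids(self) -> np.ndarray:
        return self.subset_generation("F2")["id"].to_numpy()

    def half_sib_families(self) -> dict[str, list[str]]:
        """F2 individuals grouped by sire (paternal half-sib families)."""
        fam: dict[str, list[str]] = {}
        for _, row in self.subset_generation("F2").iterrows():
            fam.setdefault(row["sire"], []).append(row["id"])
        return fam

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based sire/dam row indices; -1 for unknown parents."""
        pos = {iid: i for i, iid in enumerate(self.ids)}
        sire = np.array([pos.get(s, -1) for s in self.table["sire"]], dtype=np.int64)
        dam = np.array([pos.get(d, -1) for d in self.table["dam"]], dtype=np.int64)
        return sire, dam


@dataclass
class GenotypeMatrix:
    """Individual x SNP allele-dosage matrix with map metadata.

    Dosages count copies of the reference allele (0/1/2); missing entries
    are NaN.  ``snp_map`` has one row per SNP: snp_id, chrom (1-based
    index), pos_cm, and optionally ancestral_freq / line frequency columns
    written by the simulator.
    """

    ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray  # float, shape (n_individuals, n_snps), NaN = missing
    snp_map: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError("dosage matrix shape does not match id/SNP lists")
        called = self.dosages[~np.isnan(self.dosages)]
        if called.size and not np.isin(called, (0.0, 1.0, 2.0)).all():
            # imputed matrices carry fractional dosages and set this flag
            if not self.metadata.get("imputed", False):
                raise ValueError("dosages must be in {0, 1, 2} or missing")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids in genotype matrix")
        for _, sub in self.snp_map.groupby("chrom", sort=False):
            if (np.diff(sub["pos_cm"].to_numpy()) < 0).any():
                raise ValueError("map positions must be non-decreasing within a chromosome")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset_individuals(self, keep_ids) -> "GenotypeMatrix":
        pos = {iid: i for i, iid in enumerate(self.ids)}
        idx = np.array([pos[i] for i in keep_ids], dtype=int)
        return GenotypeMatrix(
            ids=np.asarray(list(keep_ids), dtype=object),
            snp_ids=self.snp_ids.copy(),
            dosages=self.dosages[idx].copy(),
            snp_map=self.snp_map.copy(),
            metadata=dict(self.metadata),
        )

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP reference-allele frequency over called genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass
class TraitArchitecture:
    """Additive genetic architecture of one trait.

    ``qtl_indices`` select SNP columns that act as causal loci; effects
    are allele-substitution effects in trait units per dosage unit.  The
    pair (mean, phenotypic_sd) sets the scale of the trait; sex_effects /
    hatch_effects are level-indexed fixed effects in trait units.
    """

    name: str
    h2: float
    n_qtl: int = 200
    mean: float = 0.0
    phenotypic_sd: float = 1.0
    sex_effects: dict = field(default_factory=lambda: {"M": 0.0, "F": 0.0})
    hatch_effects: tuple = (0.0, 0.0, 0.0, 0.0)
    qtl_indices: np.ndarray | None = None
    qtl_effects: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"heritability must be in [0, 1], got {self.h2}")
        if self.h2 > 0 and self.n_qtl < 1 and self.qtl_indices is None:
            raise ValueError("a trait with h2 > 0 needs at least one QTL")


@dataclass
class PhenotypeTable:
    """One record per individual per trait; simulation carries the TBV.

    Columns: id, trait, y, sex, hatch, tbv (NaN for real data).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.table.duplicated(subset=["id", "trait"])
        if dup.any():
            raise ValueError("duplicate (id, trait) phenotype records")

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.table[self.table["trait"] == trait]
        if sub.empty:
            raise KeyError(f"no phenotype records for trait {trait!r}")
        return sub.reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.table["trait"]))


@dataclass
class FounderSet:
    """Two labelled founder lines with phased haplotypes."""

    pedigree: Pedigree
    haplotypes: np.ndarray  # int8, shape (n_founders, 2, n_snps)
    snp_map: pd.DataFrame
    lines: np.ndarray  # per-founder line label 'A'/'B'

    @property
    def genotypes(self) -> GenotypeMatrix:
        return GenotypeMatrix(
            ids=self.pedigree.ids,
            snp_ids=self.snp_map["snp_id"].to_numpy(),
            dosages=self.haplotypes.sum(axis=1).astype(float),
            snp_map=self.snp_map,
        )


@dataclass
class SimulatedPopulation:
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    haplotypes: np.ndarray | None = None
    architectures: dict = field(default_factory=dict)
    seed: int = 0


# Trait defaults: heritabilities and phenotypic scales of the five recorded
# traits (6- and 12-week body weight, eviscerating / breast muscle / leg
# muscle percentage) in the F2 reference data.  Sex effects are a moderate
# dimorphism on the weights; hatch effects are small batch shifts.
_TRAIT_DEFAULTS = {
    # name: (h2, mean, sd)
    "BW6": (0.26, 802.33, 133.58),
    "BW12": (0.13, 2027.06, 360.27),
    "EP": (0.44, 66.57, 1.82),
    "BMP": (0.39, 17.40, 1.43),
    "LMP": (0.39, 23.73, 2.57),
}


def default_architectures(n_qtl: int = 200, n_hatches: int = 4) -> dict[str, TraitArchitecture]:
    """Default architectures for the five study traits."""
    archs = {}
    for name, (h2, mean, sd) in _TRAIT_DEFAULTS.items():
        hatch = tuple(((i - (n_hatches - 1) / 2) * 0.1) * sd for i in range(n_hatches))
        archs[name] = TraitArchitecture(
            name=name,
            h2=h2,
            n_qtl=n_qtl,
            mean=mean,
            phenotypic_sd=sd,
            sex_effects={"M": 0.25 * sd, "F": -0.25 * sd},
            hatch_effects=hatch,
        )
    return archs


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------


def _make_snp_map(n_snps: int, n_chromosomes: int, map_length_cm: float) -> pd.DataFrame:
    """Markers spread uniformly at random along equal-length chromosomes."""
    per = np.full(n_chromosomes, n_snps // n_chromosomes, dtype=int)
    per[: n_snps % n_chromosomes] += 1
    rows = []
    k = 0
    for c, m in enumerate(per, start=1):
        # deterministic uniform grid keeps the map independent of the seed
        pos = np.linspace(0.0, map_length_cm, m + 2)[1:-1]
        for p in pos:
            rows.append((f"snp{k + 1:06d}", c, float(p)))
            k += 1
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_cm"])
    df.attrs["chrom_length_cm"] = float(map_length_cm)
    return df


def simulate_founders(
    n_per_line: int,
    n_snps: int,
    n_chromosomes: int = 10,
    map_length_cm: float = 100.0,
    divergence: float = 0.3,
    seed: int = 0,
) -> FounderSet:
    """Sample two divergent founder lines.

    Each SNP has a shared ancestral frequency p0 ~ U(0.05, 0.95); line
    frequencies are drawn Beta(p0 (1-F)/F, (1-p0)(1-F)/F) where F is the
    ``divergence`` parameter (F = 0 collapses both lines onto p0).
    Founder haplotypes are independent Bernoulli draws at the line
    frequency; dosage = haplotype sum.
    """
    if n_per_line < 1 or n_snps < 1 or n_chromosomes < 1:
        raise ValueError("counts must be positive")
    if not 0.0 <= divergence < 1.0:
        raise ValueError(f"divergence must be in [0, 1), got {divergence}")
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.05, 0.95, size=n_snps)
    if divergence == 0.0:
        pa, pb = p0.copy(), p0.copy()
    else:
        conc = (1.0 - divergence) / divergence
        pa = rng.beta(p0 * conc, (1.0 - p0) * conc)
        pb = rng.beta(p0 * conc, (1.0 - p0) * conc)
        eps = 1e-6
        pa = np.clip(pa, eps, 1 - eps)
        pb = np.clip(pb, eps, 1 - eps)

    snp_map = _make_snp_map(n_snps, n_chromosomes, map_length_cm)
    snp_map["ancestral_freq"] = p0
    snp_map["freq_line_a"] = pa
    snp_map["freq_line_b"] = pb

    haps = np.empty((2 * n_per_line, 2, n_snps), dtype=np.int8)
    haps[:n_per_line] = rng.random((n_per_line, 2, n_snps)) < pa
    haps[n_per_line:] = rng.random((n_per_line, 2, n_snps)) < pb

    rows = []
    lines = []
    for j, line in enumerate("AB"):
        for i in range(n_per_line):
            sex = "M" if i % 2 == 0 else "F"
            rows.append((f"F0_{line}{i + 1:03d}", UNKNOWN_PARENT, UNKNOWN_PARENT, sex, "F0", 0))
            lines.append(line)
    ped = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation", "hatch"])
    return FounderSet(
        pedigree=Pedigree(ped),
        haplotypes=haps,
        snp_map=snp_map,
        lines=np.array(lines, dtype=object),
    )


# ---------------------------------------------------------------------------
# cross design
# ---------------------------------------------------------------------------


def _balanced_sizes(total: int, groups: int) -> np.ndarray:
    """Integer split of ``total`` into ``groups`` parts differing by <= 1."""
    base = np.full(groups, total // groups, dtype=int)
    base[: total % groups] += 1
    return base


def make_cross_design(
    founders: FounderSet,
    n_f1: int = 51,
    n_sires_f1: int = 8,
    n_f2: int = 511,
    n_hatches: int = 4,
    seed: int = 0,
) -> Pedigree:
    """Build the F0 -> F1 -> F2 mating pedigree.

    F1 arise from between-line F0 matings (A male x B female and B male x
    A female pairs, offspring assigned round-robin).  A fixed number of
    F1 males are chosen as F2 sires, each mated to its own contiguous
    block of F1 dams, producing paternal half-sib families whose sizes
    differ by at most 1.  Hatch labels cycle round-robin within family.
    """
    t = founders.pedigree.table
    lines = founders.lines
    males_a = t[(t["sex"] == "M") & (lines == "A")]["id"].tolist()
    fem_a = t[(t["sex"] == "F") & (lines == "A")]["id"].tolist()
    males_b = t[(t["sex"] == "M") & (lines == "B")]["id"].tolist()
    fem_b = t[(t["sex"] == "F") & (lines == "B")]["id"].tolist()
    pairs = list(zip(males_a, fem_b)) + list(zip(males_b, fem_a))
    if not pairs:
        raise ValueError("infeasible cross: no between-line male/female pair available")

    rows = [tuple(r) for r in t[["id", "sire", "dam", "sex", "generation", "hatch"]].to_numpy()]
    f1_ids, f1_sex = [], {}
    for i in range(n_f1):
        sire, dam = pairs[i % len(pairs)]
        iid = f"F1_{i + 1:03d}"
        sex = "M" if i % 2 == 0 else "F"
        rows.append((iid, sire, dam, sex, "F1", 0))
        f1_ids.append(iid)
        f1_sex[iid] = sex

    f1_males = [i for i in f1_ids if f1_sex[i] == "M"]
    f1_females = [i for i in f1_ids if f1_sex[i] == "F"]
    if n_sires_f1 > len(f1_males):
        raise ValueError(
            f"infeasible design: {n_sires_f1} F2 sires requested but only "
            f"{len(f1_males)} F1 males available"
        )
    if not f1_females:
        raise ValueError("infeasible design: no F1 females to serve as dams")
    sires = f1_males[:n_sires_f1]

    # dams are nested within sire: contiguous balanced blocks of F1 females
    dam_sizes = _balanced_sizes(len(f1_females), n_sires_f1)
    dam_blocks, start = [], 0
    for s in dam_sizes:
        block = f1_females[start : start + s]
        dam_blocks.append(block if block else [f1_females[-1]])
        start += s

    fam_sizes = _balanced_sizes(n_f2, n_sires_f1)
    rng = np.random.default_rng(seed)
    k = 0
    for fam, (sire, size) in enumerate(zip(sires, fam_sizes)):
        dams = dam_blocks[fam]
        for j in range(size):
            iid = f"F2_{k + 1:04d}"
            dam = dams[j % len(dams)]
            sex = "M" if rng.random() < 0.5 else "F"
            hatch = j % n_hatches + 1
            rows.append((iid, sire, dam, sex, "F2", hatch))
            k += 1

    ped = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation", "hatch"])
    return Pedigree(ped)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def _chrom_slices(snp_map: pd.DataFrame):
    out = []
    chrom = snp_map["chrom"].to_numpy()
    pos = snp_map["pos_cm"].to_numpy(dtype=float)
    length = float(snp_map.attrs.get("chrom_length_cm", 0.0))
    for c in pd.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        lo, hi = idx[0], idx[-1] + 1
        p = pos[lo:hi]
        out.append((lo, hi, p, max(length, p[-1] if len(p) else 0.0)))
    return out


def drop_gametes(hap_pair: np.ndarray, snp_map: pd.DataFrame, n: int, rng) -> np.ndarray:
    """Sample ``n`` gametes from one parent's haplotype pair.

    Crossover counts per chromosome are Poisson(length_cM / 100) with
    positions uniform along the chromosome (Haldane model, no
    interference); chromosomes assort independently.
    """
    if snp_map.empty:
        raise ValueError("empty SNP map")
    k = hap_pair.shape[1]
    out = np.empty((n, k), dtype=np.int8)
    for lo, hi, pos, length in _chrom_slices(snp_map):
        start = rng.integers(0, 2, size=n)
        if length <= 0:
            phase = np.broadcast_to(start[:, None], (n, hi - lo))
        else:
            counts = rng.poisson(length / 100.0, size=n)
            total = int(counts.sum())
            xpos = rng.uniform(0.0, length, size=total)
            owner = np.repeat(np.arange(n), counts)
            # switches below each marker position, per gamete
            below = np.zeros((n, hi - lo), dtype=np.int64)
            if total:
                cols = np.searchsorted(pos, xpos)  # first marker index at/after the crossover
                valid = cols < (hi - lo)
                np.add.at(below, (owner[valid], cols[valid]), 1)
                # crossing over before marker j affects markers j..end
                below = np.cumsum(below, axis=1)
            phase = (start[:, None] + below) % 2
        rows = np.arange(hi - lo)
        out[:, lo:hi] = hap_pair[:, lo:hi][phase, rows]
    return out


def drop_gamete(hap_pair: np.ndarray, snp_map: pd.DataFrame, rng) -> np.ndarray:
    """Single meiosis; see :func:`drop_gametes`."""
    return drop_gametes(hap_pair, snp_map, 1, rng)[0]


def drop_pedigree_genotypes(
    pedigree: Pedigree, founders: FounderSet, seed: int = 0
) -> tuple[np.ndarray, GenotypeMatrix]:
    """Gene-drop founder haplotypes through the pedigree.

    Returns phased haplotypes for every pedigree member (founders copied
    verbatim) and the corresponding dosage matrix.
    """
    rng = np.random.default_rng(seed)
    snp_map = founders.snp_map
    n_snps = founders.haplotypes.shape[2]
    ids = pedigree.ids
    pos = {iid: i for i, iid in enumerate(ids)}
    haps = np.zeros((len(ids), 2, n_snps), dtype=np.int8)
    founder_pos = {iid: i for i, iid in enumerate(founders.pedigree.ids)}
    sire_idx, dam_idx = pedigree.parent_indices()
    for i, iid in enumerate(ids):
        if sire_idx[i] < 0 and dam_idx[i] < 0:
            haps[i] = founders.haplotypes[founder_pos[iid]]
        else:
            haps[i, 0] = drop_gamete(haps[sire_idx[i]], snp_map, rng)
            haps[i, 1] = drop_gamete(haps[dam_idx[i]], snp_map, rng)
    geno = GenotypeMatrix(
        ids=ids,
        snp_ids=snp_map["snp_id"].to_numpy(),
        dosages=haps.sum(axis=1).astype(float),
        snp_map=snp_map,
    )
    return haps, geno


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    architecture: TraitArchitecture,
    pedigree: Pedigree,
    seed: int = 0,
) -> PhenotypeTable:
    """Generate phenotypes (F2 only) and true breeding values (everyone).

    QTL effects are drawn N(0,1) then rescaled so the realised additive
    variance among F2 equals h2 * phenotypic_sd**2; the residual variance
    is (1 - h2) * phenotypic_sd**2, making the realised heritability hit
    the target up to residual sampling noise.
    """
    arch = architecture
    rng = np.random.default_rng(seed)
    n_snps = genotypes.n_snps
    ped = pedigree.table.set_index("id")
    f2_mask = np.array([ped.loc[i, "generation"] == "F2" for i in genotypes.ids])

    sigma_p2 = arch.phenotypic_sd**2
    if arch.h2 == 0.0:
        tbv = np.zeros(genotypes.n_individuals)
        qtl_idx = np.array([], dtype=int)
        effects = np.array([])
    else:
        if arch.qtl_indices is not None:
            qtl_idx = np.asarray(arch.qtl_indices, dtype=int)
            if (qtl_idx < 0).any() or (qtl_idx >= n_snps).any():
                raise ValueError("QTL indices outside the SNP panel")
        else:
            qtl_idx = rng.choice(n_snps, size=min(arch.n_qtl, n_snps), replace=False)
        effects = (
            np.asarray(arch.qtl_effects, dtype=float)
            if arch.qtl_effects is not None
            else rng.standard_normal(len(qtl_idx))
        )
        raw = genotypes.dosages[:, qtl_idx] @ effects
        v = np.var(raw[f2_mask])
        if not np.isfinite(v) or v <= 0:
            raise ValueError("QTL effects generate no additive variance in the F2")
        scale = np.sqrt(arch.h2 * sigma_p2 / v)
        effects = effects * scale
        tbv = raw * scale
    sigma_e2 = (1.0 - arch.h2) * sigma_p2

    rows = []
    for i, iid in enumerate(genotypes.ids):
        sex = ped.loc[iid, "sex"]
        hatch = int(ped.loc[iid, "hatch"])
        if not f2_mask[i]:
            continue
        mu = arch.mean + arch.sex_effects.get(sex, 0.0)
        mu += arch.hatch_effects[(hatch - 1) % len(arch.hatch_effects)]
        y = mu + tbv[i] + rng.normal(0.0, np.sqrt(sigma_e2))
        rows.append((iid, arch.name, y, sex, hatch, tbv[i]))
    table = pd.DataFrame(rows, columns=["id", "trait", "y", "sex", "hatch", "tbv"])
    table.attrs["qtl_indices"] = qtl_idx
    table.attrs["qtl_effects"] = effects
    table.attrs["sigma_e2"] = sigma_e2
    return PhenotypeTable(table)


# ---------------------------------------------------------------------------
# one-call population simulator
# ---------------------------------------------------------------------------


def simulate_population(
    n_f0: int = 20,
    n_f1: int = 51,
    n_sires_f1: int = 8,
    n_f2: int = 511,
    n_snps: int = 5000,
    n_chromosomes: int = 10,
    map_length_cm: float = 100.0,
    divergence: float = 0.3,
    architectures: dict[str, TraitArchitecture] | None = None,
    n_hatches: int = 4,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> SimulatedPopulation:
    """Simulate a complete study population (default: the reference study design).

    ``missing_rate`` masks a random fraction of dosages to exercise the
    QC path; the default produces a fully called matrix.
    """
    if n_f0 % 2:
        raise ValueError("n_f0 must be even (two equal founder lines)")
    rng = np.random.default_rng(seed)
    s_found, s_cross, s_drop, s_phen, s_miss = rng.integers(0, 2**31 - 1, size=5)
    founders = simulate_founders(
        n_per_line=n_f0 // 2,
        n_snps=n_snps,
        n_chromosomes=n_chromosomes,
        map_length_cm=map_length_cm,
        divergence=divergence,
        seed=int(s_found),
    )
    pedigree = make_cross_design(
        founders, n_f1=n_f1, n_sires_f1=n_sires_f1, n_f2=n_f2,
        n_hatches=n_hatches, seed=int(s_cross),
    )
    haps, geno = drop_pedigree_genotypes(pedigree, founders, seed=int(s_drop))

    if architectures is None:
        architectures = default_architectures(n_hatches=n_hatches)
    tables = []
    prng = np.random.default_rng(int(s_phen))
    for arch in architectures.values():
        t = simulate_phenotypes(geno, arch, pedigree, seed=int(prng.integers(0, 2**31 - 1))).table
        t.attrs = {}  # per-trait QTL metadata does not survive concatenation
        tables.append(t)
    phenos = PhenotypeTable(pd.concat(tables, ignore_index=True))

    if missing_rate > 0:
        mrng = np.random.default_rng(int(s_miss))
        mask = mrng.random(geno.dosages.shape) < missing_rate
        dos = geno.dosages.copy()
        dos[mask] = np.nan
        geno = replace(geno, dosages=dos)

    return SimulatedPopulation(
        pedigree=pedigree,
        genotypes=geno,
        phenotypes=phenos,
        haplotypes=haps,
        architectures=architectures,
        seed=seed,
    )
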