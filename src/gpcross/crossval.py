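"""Cross-validation design and evaluation statistics.

Two 4-fold designs are supported: a family sample, where whole paternal
half-sib families are held out so test individuals have no half or full
sibs in training, and a random sample, where phenotyped individuals are
shuffled into near-equal folds.  Accuracy is the Pearson correlation
between predictions and corrected phenotypes ``y_c = y - sex - hatch``
(fixed effects from the full-data pedigree BLUP), pooled over the
concatenated test sets; bias is the OLS slope of ``y_c`` on the
prediction; models are compared fold-wise by a paired t-test, and each
pooled correlation gets a Fisher-z power against rho = 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import MMESolution, ai_reml, design_from_phenotypes, solve_mme
from .popsim import Pedigree, SimulatedPopulation
from .qc import filter_snps, impute_missing
from .relmat import genomic_g_matrix, pedigree_a_matrix
from .wgr import DEFAULT_PI, MCMCConfig, gebv_from_markers, marker_spec, run_bayes_lasso, run_bayes_mix4

__all__ = [
    "FoldPlan",
    "EvaluationReport",
    "make_family_folds",
    "make_random_folds",
    "corrected_phenotypes",
    "accuracy",
    "bias_regression",
    "paired_t_test",
    "power_correlation",
    "run_study",
]


@dataclass
class FoldPlan:
    scenario: str  # 'family' | 'random'
    k: int
    assignment: pd.Series  # individual id -> fold index (0-based)

    def __post_init__(self) -> None:
        folds = set(self.assignment.to_numpy())
        if folds != set(range(self.k)):
            raise ValueError("fold assignment does not cover exactly k folds")
        if self.assignment.index.duplicated().any():
            raise ValueError("individual assigned to more than one fold")

    def test_ids(self, fold: int) -> list:
        return list(self.assignment.index[self.assignment == fold])

    def train_ids(self, fold: int) -> list:
        return list(self.assignment.index[self.assignment != fold])

    @property
    def fold_sizes(self) -> list[int]:
        return [int((self.assignment == f).sum()) for f in range(self.k)]

    @property
    def train_sizes(self) -> list[int]:
        n = len(self.assignment)
        return [n - s for s in self.fold_sizes]


def make_family_folds(pedigree: Pedigree, k: int = 4) -> FoldPlan:
    """Assign whole half-sib families to folds by greedy bin-packing.

    Families (sorted largest first, ties by sire id) go one at a time
    into the currently smallest fold that still has capacity
    ceil(n_families / k), keeping both family counts and fold sizes as
    even as the family sizes allow.
    """
    families = pedigree.half_sib_families()
    if len(families) < k:
        raise ValueError(f"{len(families)} half-sib families cannot fill {k} folds")
    cap = -(-len(families) // k)
    order = sorted(families.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    sizes = [0] * k
    counts = [0] * k
    assign: dict[str, int] = {}
    for sire, members in order:
        open_folds = [f for f in range(k) if counts[f] < cap]
        fold = min(open_folds, key=lambda f: (sizes[f], f))
        sizes[fold] += len(members)
        counts[fold] += 1
        for iid in members:
            assign[iid] = fold
    ser = pd.Series(assign, name="fold")
    return FoldPlan(scenario="family", k=k, assignment=ser.loc[pedigree.f2_ids])


def make_random_folds(ids, k: int = 4, seed: int = 0) -> FoldPlan:
    """Seeded uniform shuffle into folds whose sizes differ by at most 1."""
    ids = list(ids)
    if not ids:
        raise ValueError("empty id list")
    if len(ids) < k:
        raise ValueError("fewer individuals than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n, base, extra = len(ids), len(ids) // k, len(ids) % k
    folds = np.empty(n, dtype=int)
    start = 0
    for f in range(k):
        size = base + (1 if f < extra else 0)
        folds[perm[start : start + size]] = f
        start += size
    return FoldPlan(scenario="random", k=k, assignment=pd.Series(folds, index=ids, name="fold"))


def corrected_phenotypes(pheno: pd.DataFrame, full_data_blup: MMESolution) -> pd.Series:
    """y_c = y - estimated sex effect - estimated hatch effect.

    Fixed-effect estimates come from the conventional pedigree BLUP
    fitted on the full dataset; the intercept is retained in y_c (a
    constant shift that leaves correlations and slopes unchanged).
    """
    design = full_data_blup.design
    for factor, levels in design.factor_levels.items():
        unseen = set(pheno[factor]) - set(levels)
        if unseen:
            raise ValueError(f"factor {factor!r} level(s) {unseen} absent from the full-data fit")
    sub = design_from_phenotypes(pheno, factors=tuple(design.factor_levels))
    contrib = sub.factor_contribution(full_data_blup.b)
    return pd.Series(pheno["y"].to_numpy(dtype=float) - contrib, index=pheno["id"], name="y_c")


def _check_pairs(a, b, min_n: int = 3):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d arrays")
    if len(a) < min_n:
        raise ValueError(f"need at least {min_n} paired values")
    return a, b


def accuracy(predictions, y_c) -> float:
    """Pearson correlation between predictions and corrected phenotypes."""
    a, b = _check_pairs(predictions, y_c)
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("correlation undefined: zero variance input")
    return float(np.corrcoef(a, b)[0, 1])


def bias_regression(y_c, predictions) -> float:
    """OLS slope of y_c on the prediction; 1 indicates unbiased predictions."""
    yc, pred = _check_pairs(y_c, predictions)
    if np.var(pred) == 0:
        raise ValueError("regression undefined: zero variance predictions")
    return float(np.cov(yc, pred, ddof=1)[0, 1] / np.var(pred, ddof=1))


@dataclass
class PairedTResult:
    d_bar: float
    s_d: float
    t: float
    df: int
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def paired_t_test(corr_a, corr_b) -> PairedTResult:
    """Paired t-test over folds: t = d_bar / (S_D / sqrt(n)), df = n - 1."""
    a, b = _check_pairs(corr_a, corr_b, min_n=2)
    d = a - b
    n = len(d)
    d_bar = float(np.mean(d))
    s_d = float(np.std(d, ddof=1))
    if s_d == 0.0:
        if d_bar == 0.0:
            return PairedTResult(0.0, 0.0, 0.0, n - 1, 1.0)
        raise ValueError("degenerate paired t-test: zero spread with nonzero mean difference")
    t = d_bar / (s_d / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTResult(d_bar, s_d, float(t), n - 1, float(p))


def power_correlation(r: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided test of rho = 0 (Fisher z approximation)."""
    if not -1.0 < r < 1.0:
        raise ValueError("correlation must lie strictly in (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    nc = abs(np.arctanh(r)) * np.sqrt(n - 3)
    return float(stats.norm.cdf(-z_a + nc) + stats.norm.cdf(-z_a - nc))


# ---------------------------------------------------------------------------
# study driver
# ---------------------------------------------------------------------------

MODELS = ("blup", "gblup", "lasso", "mix4")


@dataclass
class EvaluationReport:
    """Tidy per-fold and pooled evaluation results.

    ``records`` columns: scenario, fold ('pooled' for pooled rows, 'full'
    for full-data rows), trait, model, statistic, value.
    """

    records: pd.DataFrame
    paired_tests: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def value(self, scenario: str, trait: str, model: str, statistic: str, fold="pooled") -> float:
        r = self.records
        m = (
            (r["scenario"] == scenario)
            & (r["trait"] == trait)
            & (r["model"] == model)
            & (r["statistic"] == statistic)
            & (r["fold"] == str(fold))
        )
        if m.sum() != 1:
            raise KeyError(f"no unique record for {(scenario, trait, model, statistic, fold)}")
        return float(r.loc[m, "value"].iloc[0])

    def pooled_accuracy(self, scenario: str, trait: str, model: str) -> float:
        return self.value(scenario, trait, model, "accuracy")

    def fold_accuracies(self, scenario: str, trait: str, model: str) -> np.ndarray:
        r = self.records
        m = (
            (r["scenario"] == scenario)
            & (r["trait"] == trait)
            & (r["model"] == model)
            & (r["statistic"] == "accuracy")
            & r["fold"].str.isdigit()
        )
        sub = r.loc[m].sort_values("fold")
        return sub["value"].to_numpy(dtype=float)

    def slope(self, scenario: str, trait: str, model: str) -> float:
        return self.value(scenario, trait, model, "slope")

    def summary_table(self, statistic: str = "accuracy") -> pd.DataFrame:
        r = self.records
        sub = r[(r["statistic"] == statistic) & (r["fold"] == "pooled")]
        return sub.pivot_table(index=["scenario", "trait"], columns="model", values="value")

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _fit_seed(root: int, *key: int) -> int:
    return int(np.random.default_rng([root, *key]).integers(0, 2**31 - 1))


def _fit_predict(
    model: str,
    train: pd.DataFrame,
    test_ids: list,
    A,
    G,
    geno,
    mcmc: MCMCConfig,
    chain_seed: int,
    pi=DEFAULT_PI,
) -> np.ndarray:
    """Fit one model on training records and predict the test individuals."""
    if model in ("blup", "gblup"):
        K = A if model == "blup" else G
        design = design_from_phenotypes(train)
        vc = ai_reml(design, K)
        sol = solve_mme(design, K, vc)
        return sol.predict(test_ids)
    kind = model
    spec = marker_spec(train, geno, kind=kind, pi=pi)
    cfg = MCMCConfig(mcmc.n_cycles, mcmc.burn_in, mcmc.thin, seed=chain_seed)
    summary = run_bayes_lasso(spec, cfg) if kind == "lasso" else run_bayes_mix4(spec, cfg)
    m_test = spec.design_target(geno.subset_individuals(test_ids).dosages)
    return gebv_from_markers(m_test, summary.q_hat)


def run_study(
    population: SimulatedPopulation,
    traits: list[str] | None = None,
    models: tuple[str, ...] = MODELS,
    scenarios: tuple[str, ...] = ("family", "random"),
    k: int = 4,
    qc_thresholds: tuple[float, float] = (0.95, 0.01),
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
    include_full_data: bool = False,
    g_ridge: float = 1e-6,
    pi=DEFAULT_PI,
) -> EvaluationReport:
    """Run the full cross-validation study on one population.

    For every scenario x fold x trait x model the model is fitted on the
    training records only (test phenotypes are masked by exclusion) and
    the held-out individuals are predicted; accuracies are pooled over
    the concatenated test sets.  ``include_full_data`` adds an analysis
    where each model is fitted on all records and evaluated on the same
    individuals (the own-record analogue).
    """
    unknown = set(models) - set(MODELS)
    if unknown:
        raise ValueError(f"unknown model(s) {unknown}")
    if mcmc is None:
        mcmc = MCMCConfig.desk()

    geno_f, qc_report = filter_snps(population.genotypes, *qc_thresholds)
    geno = impute_missing(geno_f)
    A = pedigree_a_matrix(population.pedigree)
    G = genomic_g_matrix(geno, ridge=g_ridge)
    phenos = population.phenotypes
    if traits is None:
        traits = phenos.traits

    rows = []
    t_rows = []
    for ti, trait in enumerate(traits):
        pheno_t = phenos.for_trait(trait)
        full_design = design_from_phenotypes(pheno_t)
        vc_full = ai_reml(full_design, A)
        sol_full = solve_mme(full_design, A, vc_full)
        y_c = corrected_phenotypes(pheno_t, sol_full)

        plans = {}
        if "family" in scenarios:
            plans["family"] = make_family_folds(population.pedigree, k=k)
        if "random" in scenarios:
            plans["random"] = make_random_folds(
                pheno_t["id"].tolist(), k=k, seed=_fit_seed(seed, 1, ti)
            )

        for si, (scen, plan) in enumerate(plans.items()):
            fold_corr: dict[str, list[float]] = {m: [] for m in models}
            pooled_pred: dict[str, list[np.ndarray]] = {m: [] for m in models}
            pooled_yc: list[np.ndarray] = []
            for f in range(k):
                test_ids = plan.test_ids(f)
                train = pheno_t[~pheno_t["id"].isin(test_ids)].reset_index(drop=True)
                yc_test = y_c.loc[test_ids].to_numpy()
                pooled_yc.append(yc_test)
                for mi, model in enumerate(models):
                    pred = _fit_predict(
                        model, train, test_ids, A, G, geno, mcmc,
                        chain_seed=_fit_seed(seed, 2, ti, si, f, mi), pi=pi,
                    )
                    fold_corr[model].append(accuracy(pred, yc_test))
                    pooled_pred[model].append(pred)
                    rows.append((scen, str(f), trait, model, "accuracy", fold_corr[model][-1]))
            yc_all = np.concatenate(pooled_yc)
            for model in models:
                pred_all = np.concatenate(pooled_pred[model])
                acc = accuracy(pred_all, yc_all)
                rows.append((scen, "pooled", trait, model, "accuracy", acc))
                rows.append((scen, "pooled", trait, model, "slope", bias_regression(yc_all, pred_all)))
                rows.append(
                    (scen, "pooled", trait, model, "power", power_correlation(acc, len(yc_all)))
                )
            for ma, mb in itertools.combinations(models, 2):
                res = paired_t_test(fold_corr[ma], fold_corr[mb])
                t_rows.append(
                    (scen, trait, ma, mb, res.d_bar, res.s_d, res.t, res.df, res.p, res.significant)
                )

        if include_full_data:
            all_ids = pheno_t["id"].tolist()
            yc_all = y_c.loc[all_ids].to_numpy()
            for mi, model in enumerate(models):
                pred = _fit_predict(
                    model, pheno_t, all_ids, A, G, geno, mcmc,
                    chain_seed=_fit_seed(seed, 3, ti, mi), pi=pi,
                )
                rows.append(("full_data", "full", trait, model, "accuracy", accuracy(pred, yc_all)))
                rows.append(
                    ("full_data", "full", trait, model, "slope", bias_regression(yc_all, pred))
                )

    records = pd.DataFrame(
        rows, columns=["scenario", "fold", "trait", "model", "statistic", "value"]
    )
    paired = pd.DataFrame(
        t_rows,
        columns=["scenario", "trait", "model_a", "model_b", "d_bar", "s_d", "t", "df", "p", "significant"],
    )
    return EvaluationReport(
        records=records,
        paired_tests=paired,
        metadata={
            "seed": seed,
            "k": k,
            "models": models,
            "scenarios": scenarios,
            "qc": qc_report.to_dict(),
            "mcmc": mcmc,
            "pi": tuple(pi),
        },
    )
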