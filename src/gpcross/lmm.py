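"""Linear mixed models: AI-REML variance components and (G)BLUP.

The model is ``y = X b + Z a + e`` with ``a ~ N(0, K sigma_a^2)`` for a
pedigree (A) or genomic (G) relationship matrix K and
``e ~ N(0, I sigma_e^2)``.  Variance components are estimated by
average-information REML with an EM fallback; breeding values are the
BLUP ``a_hat = sigma_a^2 K Z' V^{-1} (y - X b_hat)``, which extends
naturally to individuals without records through their rows of K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .relmat import RelationshipMatrix

__all__ = [
    "DesignSpec",
    "VarianceComponents",
    "MMESolution",
    "design_from_phenotypes",
    "solve_mme",
    "ai_reml",
    "predict_unobserved",
]


@dataclass
class DesignSpec:
    """Response, fixed-effect incidence and individual mapping.

    Fixed factors use full-rank treatment coding: an intercept plus
    dummies for all but the first (sorted) level of each factor, so the
    reference level of every factor is absorbed into the intercept.
    """

    y: np.ndarray
    X: np.ndarray
    obs_ids: np.ndarray
    column_names: list[str]
    factor_levels: dict = field(default_factory=dict)  # factor -> sorted level list
    factor_values: dict = field(default_factory=dict)  # factor -> per-obs level array

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.y)
        if self.X.shape[0] != n or len(self.obs_ids) != n:
            raise ValueError("y, X and obs_ids must have matching length")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient under treatment coding")

    @property
    def n(self) -> int:
        return len(self.y)

    def factor_contribution(self, b: pd.Series) -> np.ndarray:
        """Per-observation sum of the estimated non-intercept factor effects."""
        out = np.zeros(self.n)
        for factor, levels in self.factor_levels.items():
            values = self.factor_values[factor]
            for level in levels[1:]:
                name = f"{factor}[{level}]"
                out += np.where(np.asarray(values) == level, float(b[name]), 0.0)
        return out


def design_from_phenotypes(pheno: pd.DataFrame, factors: tuple[str, ...] = ("sex", "hatch")) -> DesignSpec:
    """Build a DesignSpec from a single-trait phenotype frame (id, y, factors)."""
    y = pheno["y"].to_numpy(dtype=float)
    cols = [np.ones(len(pheno))]
    names = ["intercept"]
    factor_levels, factor_values = {}, {}
    for factor in factors:
        values = pheno[factor].to_numpy()
        levels = sorted(set(values), key=str)
        factor_levels[factor] = levels
        factor_values[factor] = values
        for level in levels[1:]:
            cols.append((values == level).astype(float))
            names.append(f"{factor}[{level}]")
    return DesignSpec(
        y=y,
        X=np.column_stack(cols),
        obs_ids=pheno["id"].to_numpy(),
        column_names=names,
        factor_levels=factor_levels,
        factor_values=factor_values,
    )


@dataclass
class VarianceComponents:
    """Additive and residual variances with approximate standard errors."""

    sigma_a2: float
    sigma_e2: float
    se_a2: float = np.nan
    se_e2: float = np.nan
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def h2(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)

    @property
    def se_h2(self) -> float:
        # delta method; needs the sampling covariance stored by ai_reml
        cov = getattr(self, "_cov", None)
        if cov is None:
            return np.nan
        s = self.sigma_a2 + self.sigma_e2
        g = np.array([self.sigma_e2, -self.sigma_a2]) / s**2
        return float(np.sqrt(max(g @ cov @ g, 0.0)))


@dataclass
class MMESolution:
    """Joint fixed-effect estimates and random-effect predictions."""

    b: pd.Series
    u: pd.Series  # indexed by individual id, covers every id in K
    vc: VarianceComponents
    design: DesignSpec
    diagnostics: dict = field(default_factory=dict)

    def predict(self, ids) -> np.ndarray:
        return self.u.reindex(ids).to_numpy(dtype=float)


def _obs_kernel(design: DesignSpec, K: RelationshipMatrix) -> tuple[np.ndarray, np.ndarray]:
    idx = K.index_of(design.obs_ids)
    return idx, K.values[np.ix_(idx, idx)]


def solve_mme(design: DesignSpec, K: RelationshipMatrix, vc: VarianceComponents) -> MMESolution:
    """Solve the mixed-model equations for b_hat and a_hat.

    Implemented through the phenotypic covariance
    ``V = sigma_a^2 Z K Z' + sigma_e^2 I`` so that a singular K (e.g. a
    centered G) is handled without forming its inverse; the solution is
    identical to the classical Henderson system whenever that system
    exists.  All individuals carried by K receive predictions.
    """
    if vc.sigma_e2 <= 0:
        raise ValueError("residual variance must be strictly positive")
    idx, H = _obs_kernel(design, K)
    n = design.n
    V = vc.sigma_a2 * H + vc.sigma_e2 * np.eye(n)
    cf = linalg.cho_factor(V, lower=True)
    ViX = linalg.cho_solve(cf, design.X)
    Viy = linalg.cho_solve(cf, design.y)
    XtViX = design.X.T @ ViX
    b = np.linalg.solve(XtViX, design.X.T @ Viy)
    w = linalg.cho_solve(cf, design.y - design.X @ b)
    u = vc.sigma_a2 * (K.values[:, idx] @ w)
    cond = float(np.linalg.cond(XtViX))
    return MMESolution(
        b=pd.Series(b, index=design.column_names),
        u=pd.Series(u, index=K.ids),
        vc=vc,
        design=design,
        diagnostics={"condition_XtViX": cond, "n_obs": n, "kind": K.kind},
    )


def predict_unobserved(solution: MMESolution, K: RelationshipMatrix, target_ids) -> np.ndarray:
    """Breeding-value predictions for individuals without records.

    Since :func:`solve_mme` propagates information through K to every
    individual, this is a lookup; absent ids raise.
    """
    K.index_of(target_ids)  # raises on unknown ids
    return solution.predict(target_ids)


def ai_reml(
    design: DesignSpec,
    K: RelationshipMatrix,
    init: VarianceComponents | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> VarianceComponents:
    """Average-information REML for the two-component model (K, I).

    The observed kernel ``Z K Z'`` is eigendecomposed once, after which
    every iteration works with diagonal matrices.  When an AI update
    would leave the parameter space, an EM step is taken instead; the
    returned standard errors come from the inverse AI matrix at
    convergence and the heritability SE from the delta method.
    """
    n, p = design.n, design.X.shape[1]
    if n < p + 2:
        raise ValueError("too few observations for REML")
    _, H = _obs_kernel(design, K)
    D, U = linalg.eigh(H)
    D = np.maximum(D, 0.0)  # K is PSD up to round-off
    yt = U.T @ design.y
    Xt = U.T @ design.X

    vary = float(np.var(design.y))
    floor = 1e-8 * max(vary, 1e-12)
    if init is None:
        theta = np.array([vary / 2, vary / 2])
    else:
        theta = np.array([max(init.sigma_a2, floor), max(init.sigma_e2, floor)])

    AI = np.eye(2)
    converged = False
    for it in range(1, max_iter + 1):
        sa, se = theta
        d = sa * D + se
        w = 1.0 / d
        wX = Xt * w[:, None]
        Amat = Xt.T @ wX
        Ainv_Xtwy = np.linalg.solve(Amat, Xt.T @ (w * yt))
        Py = w * yt - wX @ Ainv_Xtwy

        def P_dot(f: np.ndarray) -> np.ndarray:
            return w * f - wX @ np.linalg.solve(Amat, Xt.T @ (w * f))

        # traces of P*Vi for Vi in {diag(D), I} in the rotated basis
        tr1 = float(np.sum(w * D) - np.trace(np.linalg.solve(Amat, Xt.T @ (wX * (D * w)[:, None]))))
        tr2 = float(np.sum(w) - np.trace(np.linalg.solve(Amat, Xt.T @ (wX * w[:, None]))))
        q1 = float(np.sum(D * Py * Py))
        q2 = float(np.sum(Py * Py))
        score = -0.5 * np.array([tr1 - q1, tr2 - q2])

        f1, f2 = D * Py, Py
        Pf1, Pf2 = P_dot(f1), P_dot(f2)
        AI = 0.5 * np.array([[f1 @ Pf1, f1 @ Pf2], [f2 @ Pf1, f2 @ Pf2]])

        try:
            step = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            step = None
        new = theta + step if step is not None else None
        if new is None or (new <= 0).any() or not np.isfinite(new).all():
            # EM fallback keeps the iterate inside the parameter space
            new = np.array(
                [
                    sa + sa**2 * (q1 - tr1) / n,
                    se + se**2 * (q2 - tr2) / n,
                ]
            )
            new = np.maximum(new, floor)
        rel = np.max(np.abs(new - theta) / np.maximum(np.abs(theta), floor))
        theta = new
        if rel < tol:
            converged = True
            break

    try:
        cov = np.linalg.inv(AI)
        se_a2, se_e2 = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate AI
        cov = None
        se_a2 = se_e2 = np.nan
    vc = VarianceComponents(
        sigma_a2=float(max(theta[0], 0.0)),
        sigma_e2=float(max(theta[1], floor)),
        se_a2=float(se_a2),
        se_e2=float(se_e2),
        converged=converged,
        n_iter=it,
    )
    vc._cov = cov
    return vc
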