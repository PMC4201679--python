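"""Numba kernels for the whole-genome regression Gibbs samplers.

Both chains keep a running residual vector and update one coordinate at
a time; marker matrices are passed transposed (markers x individuals,
C-contiguous) so the inner loops stream over contiguous memory.  The
numba RNG is seeded once per chain, making runs bit-reproducible.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _rinvgauss(mu, lam):
    """One draw from InverseGaussian(mu, lam) (Michael-Schucany-Haas)."""
    v = np.random.standard_normal()
    w = v * v
    x = mu + mu * mu * w / (2.0 * lam) - mu / (2.0 * lam) * np.sqrt(
        4.0 * mu * lam * w + mu * mu * w * w
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _chi2(df):
    return 2.0 * np.random.gamma(df / 2.0, 1.0)


@njit(cache=True)
def _update_fixed(Xt, xtx, b, e, sige2):
    p, n = Xt.shape
    for l in range(p):
        old = b[l]
        rhs = xtx[l] * old
        for i in range(n):
            rhs += Xt[l, i] * e[i]
        mean = rhs / xtx[l]
        new = mean + np.sqrt(sige2 / xtx[l]) * np.random.standard_normal()
        diff = old - new
        if diff != 0.0:
            for i in range(n):
                e[i] += Xt[l, i] * diff
        b[l] = new


@njit(cache=True)
def lasso_chain(y, Xt, Mt, n_cycles, burn, thin, seed,
                lam0, fix_lam, sige20, fix_sige2, lam_max):
    """Bayesian LASSO Gibbs chain.

    Marker-effect prior: Laplace via the exponential scale mixture
    q_j | tau_j^2 ~ N(0, tau_j^2), tau_j^2 ~ Exp(lam^2 / 2); the rate
    lam has a flat prior on (0, lam_max] with a truncated
    Gamma(k + 1, sum|q|) full conditional.
    """
    np.random.seed(seed)
    n = y.shape[0]
    p = Xt.shape[0]
    k = Mt.shape[0]
    xtx = np.empty(p)
    for l in range(p):
        s = 0.0
        for i in range(n):
            s += Xt[l, i] * Xt[l, i]
        xtx[l] = s
    mtm = np.empty(k)
    for j in range(k):
        s = 0.0
        for i in range(n):
            s += Mt[j, i] * Mt[j, i]
        mtm[j] = s

    b = np.zeros(p)
    q = np.zeros(k)
    tau2 = np.ones(k)
    lam = lam0
    sige2 = sige20
    e = y.copy()

    n_saved = (n_cycles - burn) // thin
    q_sum = np.zeros(k)
    b_sum = np.zeros(p)
    lam_trace = np.zeros(n_saved)
    sige2_trace = np.zeros(n_saved)
    isave = 0

    for c in range(1, n_cycles + 1):
        _update_fixed(Xt, xtx, b, e, sige2)
        for j in range(k):
            if mtm[j] <= 0.0:
                q[j] = 0.0
                continue
            old = q[j]
            rhs = mtm[j] * old
            for i in range(n):
                rhs += Mt[j, i] * e[i]
            v = mtm[j] + sige2 / tau2[j]
            new = rhs / v + np.sqrt(sige2 / v) * np.random.standard_normal()
            diff = old - new
            if diff != 0.0:
                for i in range(n):
                    e[i] += Mt[j, i] * diff
            q[j] = new
            aq = abs(new)
            if aq < 1e-10:
                aq = 1e-10
            tau2[j] = 1.0 / _rinvgauss(lam / aq, lam * lam)
        if fix_lam == 0:
            sq = 0.0
            for j in range(k):
                sq += abs(q[j])
            if sq < 1e-12:
                sq = 1e-12
            accepted = False
            for _ in range(100):
                cand = np.random.gamma(k + 1.0, 1.0 / sq)
                if cand <= lam_max:
                    lam = cand
                    accepted = True
                    break
            if not accepted:
                lam = lam_max
        if fix_sige2 == 0:
            ete = 0.0
            for i in range(n):
                ete += e[i] * e[i]
            sige2 = ete / _chi2(n - 2.0)
        if c > burn and (c - burn) % thin == 0:
            q_sum += q
            b_sum += b
            lam_trace[isave] = lam
            sige2_trace[isave] = sige2
            isave += 1

    return q_sum / n_saved, b_sum / n_saved, lam_trace, sige2_trace


@njit(cache=True)
def mix4_chain(y, Xt, Mt, n_cycles, burn, thin, seed,
               pi, scales, nu, fix_compvar, sige20, fix_sige2):
    """Four-component normal-mixture Gibbs chain (BayesR-style).

    Component indicators are drawn from their multinomial conditional
    with the marker effect integrated out; effects then come from the
    normal conditional given the assigned component variance; component
    variances from scaled-inverse-chi-square conditionals with fixed
    degrees of freedom nu and slot scales, re-sorted ascending each
    cycle so slot 1 remains the smallest-variance component.
    """
    np.random.seed(seed)
    n = y.shape[0]
    p = Xt.shape[0]
    k = Mt.shape[0]
    nc = pi.shape[0]
    xtx = np.empty(p)
    for l in range(p):
        s = 0.0
        for i in range(n):
            s += Xt[l, i] * Xt[l, i]
        xtx[l] = s
    mtm = np.empty(k)
    for j in range(k):
        s = 0.0
        for i in range(n):
            s += Mt[j, i] * Mt[j, i]
        mtm[j] = s

    b = np.zeros(p)
    q = np.zeros(k)
    comp = np.zeros(k, dtype=np.int64)
    sigc2 = scales.copy()
    sige2 = sige20
    e = y.copy()
    logpi = np.log(pi)

    n_saved = (n_cycles - burn) // thin
    q_sum = np.zeros(k)
    b_sum = np.zeros(p)
    comp_count = np.zeros((k, nc))
    sigc2_trace = np.zeros((n_saved, nc))
    sige2_trace = np.zeros(n_saved)
    isave = 0
    logw = np.empty(nc)

    for c in range(1, n_cycles + 1):
        _update_fixed(Xt, xtx, b, e, sige2)
        for j in range(k):
            if mtm[j] <= 0.0:
                q[j] = 0.0
                comp[j] = 0
                continue
            old = q[j]
            rhs = mtm[j] * old
            for i in range(n):
                rhs += Mt[j, i] * e[i]
            best = -1e300
            for t in range(nc):
                v = mtm[j] + sige2 / sigc2[t]
                logw[t] = (
                    logpi[t]
                    + 0.5 * (np.log(sige2) - np.log(sigc2[t]) - np.log(v))
                    + 0.5 * rhs * rhs / (sige2 * v)
                )
                if logw[t] > best:
                    best = logw[t]
            tot = 0.0
            for t in range(nc):
                logw[t] = np.exp(logw[t] - best)
                tot += logw[t]
            u = np.random.random() * tot
            cj = nc - 1
            acc = 0.0
            for t in range(nc):
                acc += logw[t]
                if u <= acc:
                    cj = t
                    break
            comp[j] = cj
            v = mtm[j] + sige2 / sigc2[cj]
            new = rhs / v + np.sqrt(sige2 / v) * np.random.standard_normal()
            diff = old - new
            if diff != 0.0:
                for i in range(n):
                    e[i] += Mt[j, i] * diff
            q[j] = new
        if fix_compvar == 0:
            for t in range(nc):
                ssq = 0.0
                kt = 0
                for j in range(k):
                    if comp[j] == t:
                        ssq += q[j] * q[j]
                        kt += 1
                sigc2[t] = (ssq + nu * scales[t]) / _chi2(nu + kt)
            sigc2 = np.sort(sigc2)
        if fix_sige2 == 0:
            ete = 0.0
            for i in range(n):
                ete += e[i] * e[i]
            sige2 = ete / _chi2(n - 2.0)
        if c > burn and (c - burn) % thin == 0:
            q_sum += q
            b_sum += b
            for j in range(k):
                comp_count[j, comp[j]] += 1.0
            for t in range(nc):
                sigc2_trace[isave, t] = sigc2[t]
            sige2_trace[isave] = sige2
            isave += 1

    return (
        q_sum / n_saved,
        b_sum / n_saved,
        comp_count / n_saved,
        sigc2_trace,
        sige2_trace,
    )
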