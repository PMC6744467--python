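"""Finite beta-mixture fitting by expectation-maximization.

Components are parametrized by mean mu in (0,1) and precision phi > 0
(shape parameters a = mu*phi, b = (1-mu)*phi). The M-step maximizes the
weighted beta log-likelihood exactly through its sufficient statistics
(sum of responsibilities, weighted mean log x and log(1-x)), which keeps
the per-iteration cost independent of sample size and guarantees a
monotone log-likelihood. Model order is chosen by BIC with
p = 3K - 1 free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "MixtureFit",
    "fit_beta_mixture",
    "select_k_bic",
    "classify_groups",
    "sample_beta_mixture",
    "GROUP_NAMES_K4",
]

GROUP_NAMES_K4 = ("straight", "semi-straight", "semi-curvy", "curvy")

_CLAMP = 1e-4


@dataclass
class MixtureFit:
    """A fitted K-component beta mixture."""

    k: int
    weights: np.ndarray  # (K,) mixing proportions, sum to 1
    means: np.ndarray  # (K,) in (0,1)
    precisions: np.ndarray  # (K,) > 0
    log_likelihood: float
    bic: float
    n: int
    responsibilities: np.ndarray  # (n, K)
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def alphas(self) -> np.ndarray:
        return self.means * self.precisions

    @property
    def betas(self) -> np.ndarray:
        return (1.0 - self.means) * self.precisions


def _clamp(values: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(values, dtype=float), _CLAMP, 1.0 - _CLAMP)


def _weighted_beta_mle(
    w_sum: float, t_logx: float, t_log1mx: float, a0: float, b0: float
) -> tuple[float, float]:
    """Maximize sum_i w_i log Beta(x_i; a, b) given sufficient statistics.

    t_logx and t_log1mx are responsibility-weighted means of log x and
    log(1-x). The objective (a-1) t_logx + (b-1) t_log1mx - betaln(a, b) is
    concave in (a, b) (exponential family), so a safeguarded Newton
    iteration with the digamma gradient and trigamma Hessian converges in a
    handful of steps; L-BFGS over (log a, log b) is the fallback.
    """

    def loglik(a: float, b: float) -> float:
        return (a - 1.0) * t_logx + (b - 1.0) * t_log1mx - special.betaln(a, b)

    lo, hi = 1e-3, 1e6
    a, b = min(max(a0, lo), hi), min(max(b0, lo), hi)
    f_cur = loglik(a, b)
    for _ in range(60):
        psi_ab = special.digamma(a + b)
        ga = t_logx - special.digamma(a) + psi_ab
        gb = t_log1mx - special.digamma(b) + psi_ab
        if max(abs(ga), abs(gb)) < 1e-11:
            return float(a), float(b)
        tri_ab = special.polygamma(1, a + b)
        haa = -special.polygamma(1, a) + tri_ab
        hbb = -special.polygamma(1, b) + tri_ab
        det = haa * hbb - tri_ab * tri_ab
        if det <= 0 or not np.isfinite(det):
            break
        da = -(hbb * ga - tri_ab * gb) / det
        db = -(haa * gb - tri_ab * ga) / det
        step = 1.0
        improved = False
        for _ in range(30):  # backtrack into the feasible, improving region
            an, bn = a + step * da, b + step * db
            if lo <= an <= hi and lo <= bn <= hi:
                f_new = loglik(an, bn)
                if f_new >= f_cur:
                    a, b, f_cur = an, bn, f_new
                    improved = True
                    break
            step *= 0.5
        if not improved:
            break
    else:
        return float(a), float(b)

    def negloglik(theta):
        aa, bb = np.exp(theta)
        psi_ab = special.digamma(aa + bb)
        ga = (t_logx - special.digamma(aa) + psi_ab) * aa
        gb = (t_log1mx - special.digamma(bb) + psi_ab) * bb
        return -loglik(aa, bb), -np.array([ga, gb])

    res = optimize.minimize(
        negloglik,
        x0=np.log([a, b]),
        jac=True,
        method="L-BFGS-B",
        bounds=[(np.log(lo), np.log(hi))] * 2,
        options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-10},
    )
    a, b = np.exp(res.x)
    return float(a), float(b)


def _moment_init(block: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(block))
    v = float(np.var(block))
    m = min(max(m, _CLAMP), 1.0 - _CLAMP)
    v = max(v, 1e-8)
    phi = max(m * (1.0 - m) / v - 1.0, 2.0)
    return m, phi


def _init_params(
    x_sorted: np.ndarray, k: int, rng: np.random.Generator, perturb: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(x_sorted)
    if perturb:
        props = rng.dirichlet(np.full(k, 5.0))
    else:
        props = np.full(k, 1.0 / k)
    bounds = np.concatenate([[0], np.cumsum(props)]) * n
    idx = np.round(bounds).astype(int)
    idx[-1] = n
    means, phis, weights = [], [], []
    for j in range(k):
        lo, hi = idx[j], max(idx[j + 1], idx[j] + 2)
        hi = min(hi, n)
        lo = min(lo, hi - 2) if hi >= 2 else 0
        block = x_sorted[lo:hi]
        m, phi = _moment_init(block)
        means.append(m)
        phis.append(phi)
        weights.append(max(hi - lo, 1))
    w = np.asarray(weights, dtype=float)
    return w / w.sum(), np.asarray(means), np.asarray(phis)


class DegenerateComponentError(RuntimeError):
    pass


def _em(
    x: np.ndarray,
    weights: np.ndarray,
    means: np.ndarray,
    phis: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray, list[float], bool]:
    n, k = len(x), len(weights)
    logx = np.log(x)
    log1mx = np.log1p(-x)
    trace: list[float] = []
    prev = -np.inf
    converged = False
    resp = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        a = means * phis
        b = (1.0 - means) * phis
        # beta log-density from precomputed log x / log(1-x)
        logdens = (
            np.log(weights)[None, :]
            + logx[:, None] * (a - 1.0)[None, :]
            + log1mx[:, None] * (b - 1.0)[None, :]
            - special.betaln(a, b)[None, :]
        )
        lse = special.logsumexp(logdens, axis=1)
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(logdens - lse[:, None])
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
        # M-step
        w_sums = resp.sum(axis=0)
        if np.any(w_sums / n < 1e-6):
            raise DegenerateComponentError("a component collapsed to zero weight")
        weights = w_sums / n
        for j in range(k):
            t1 = float(resp[:, j] @ logx) / w_sums[j]
            t2 = float(resp[:, j] @ log1mx) / w_sums[j]
            a_j, b_j = _weighted_beta_mle(w_sums[j], t1, t2, a[j], b[j])
            phis[j] = a_j + b_j
            means[j] = a_j / (a_j + b_j)
    return weights, means, phis, trace[-1], resp, trace, converged


def fit_beta_mixture(
    values: np.ndarray,
    k: int,
    seed: int | None = None,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureFit:
    """Fit a K-component beta mixture by EM with seeded restarts.

    Values are clamped into [1e-4, 1 - 1e-4] first (straightness can equal
    exactly 1). Initialization partitions the sorted sample into K blocks
    (equal blocks for the first restart, randomized proportions after) with
    method-of-moments estimates per block; the best log-likelihood over
    ``n_restarts`` successful runs is kept.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = _clamp(values)
    n = len(x)
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} observations for k={k}, got {n}")
    x_sorted = np.sort(x)
    rng = np.random.default_rng(seed)

    best: tuple | None = None
    attempts = 0
    successes = 0
    while successes < n_restarts and attempts < 3 * n_restarts:
        perturb = attempts > 0
        w0, m0, p0 = _init_params(x_sorted, k, rng, perturb)
        attempts += 1
        try:
            out = _em(x, w0.copy(), m0.copy(), p0.copy(), max_iter, tol)
        except DegenerateComponentError:
            continue
        successes += 1
        if best is None or out[3] > best[3]:
            best = out
        if k == 1:
            break  # single component: restarts are identical
    if best is None:
        raise RuntimeError(f"all EM restarts degenerated for k={k}")
    weights, means, phis, ll, resp, trace, converged = best
    p = 3 * k - 1
    bic = -2.0 * ll + p * np.log(n)
    return MixtureFit(
        k=k,
        weights=weights,
        means=means,
        precisions=phis,
        log_likelihood=ll,
        bic=bic,
        n=n,
        responsibilities=resp,
        loglik_trace=trace,
        converged=converged,
    )


def select_k_bic(
    values: np.ndarray,
    k_max: int = 6,
    seed: int | None = None,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> tuple[int, dict[int, MixtureFit]]:
    """Fit K = 1..k_max and return (argmin-BIC K, all fits)."""
    fits: dict[int, MixtureFit] = {}
    rng = np.random.default_rng(seed)
    for k in range(1, k_max + 1):
        fits[k] = fit_beta_mixture(
            values,
            k,
            seed=int(rng.integers(2**31)),
            n_restarts=n_restarts,
            max_iter=max_iter,
            tol=tol,
        )
    k_best = min(fits, key=lambda k: fits[k].bic)
    return k_best, fits


def classify_groups(fit: MixtureFit) -> tuple[np.ndarray, list[dict]]:
    """Hard-assign each observation to its maximum-responsibility component.

    Components are reported in order of decreasing mean; when K = 4 they are
    named straight / semi-straight / semi-curvy / curvy. Returns (labels,
    summary) where labels[i] indexes the ordered components and each summary
    row carries name, proportion, n, member mean, and minimum member value.
    """
    order = np.argsort(-fit.means)
    rank_of = np.empty(fit.k, dtype=int)
    rank_of[order] = np.arange(fit.k)
    raw = np.argmax(fit.responsibilities, axis=1)
    labels = rank_of[raw]

    summary = []
    n = len(labels)
    for rank, comp in enumerate(order):
        members = labels == rank
        name = GROUP_NAMES_K4[rank] if fit.k == 4 else f"group{rank + 1}"
        summary.append(
            {
                "name": name,
                "component": int(comp),
                "proportion": float(members.sum() / n),
                "n": int(members.sum()),
                "fitted_mean": float(fit.means[comp]),
                "fitted_precision": float(fit.precisions[comp]),
                "weight": float(fit.weights[comp]),
            }
        )
    return labels, summary


def group_value_summary(
    values: np.ndarray, labels: np.ndarray, summary: list[dict]
) -> list[dict]:
    """Augment a classify_groups summary with member-value statistics."""
    x = np.asarray(values, dtype=float)
    out = []
    for rank, row in enumerate(summary):
        members = x[labels == rank]
        row = dict(row)
        row["member_mean"] = float(members.mean()) if len(members) else float("nan")
        row["member_min"] = float(members.min()) if len(members) else float("nan")
        out.append(row)
    return out


def sample_beta_mixture(
    weights,
    means,
    precisions,
    n: int,
    seed: int | None = None,
) -> np.ndarray:
    """Draw n values from a beta mixture (used to seed recovery tests)."""
    rng = np.random.default_rng(seed)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    means = np.asarray(means, dtype=float)
    precisions = np.asarray(precisions, dtype=float)
    comp = rng.choice(len(weights), size=n, p=weights)
    a = means * precisions
    b = (1.0 - means) * precisions
    return rng.beta(a[comp], b[comp])
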