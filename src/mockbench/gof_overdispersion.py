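"""Overdispersion-aware goodness of fit for count compositions.

Replicate counts from a mock community are noisier than multinomial sampling
alone predicts.  We model each replicate as Dirichlet-multinomial: replicate
proportions are Dirichlet(theta * pi) around a mean composition pi, and the
counts are multinomial given those proportions.  The concentration theta
controls overdispersion — as theta grows the model collapses onto the pure
multinomial.

The fit of observed counts to an expected composition is scored with a
likelihood-ratio statistic (free composition vs fixed composition, theta
estimated in both), whose null distribution is obtained by parametric
bootstrap from the fitted null model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import digamma, gammaln

from .community_model import ProportionVector
from .count_processing import CountTable

__all__ = [
    "THETA_MIN",
    "THETA_MAX",
    "OverdispersedModel",
    "GofResult",
    "FitError",
    "dm_log_likelihood",
    "fit_null",
    "fit_alternative",
    "lrt_gof",
    "simulate_dm_counts",
]

# theta search window (log scale); the ceiling is "effectively multinomial".
THETA_MIN = 1e-2
THETA_MAX = 1e8
_LRT_CLIP = 1e-6


class FitError(RuntimeError):
    """Raised when an optimizer fails to converge; carries the best fit found."""

    def __init__(self, message: str, best: "OverdispersedModel | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class OverdispersedModel:
    """A mean composition plus a Dirichlet-multinomial concentration."""

    proportions: ProportionVector
    concentration: float
    fit_info: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (self.concentration > 0):
            raise ValueError(f"concentration must be > 0, got {self.concentration}")


@dataclass
class GofResult:
    """Outcome of the bootstrapped likelihood-ratio goodness-of-fit test."""

    lrt_stat: float
    p_value: float
    theta_null: float
    theta_alt: float
    pi_alt: ProportionVector
    n_bootstrap: int
    seed: int
    bootstrap_stats: np.ndarray
    loglik_null: float
    loglik_alt: float

    def to_dict(self) -> dict:
        return {
            "lrt_stat": self.lrt_stat,
            "p_value": self.p_value,
            "theta_null": self.theta_null,
            "theta_alt": self.theta_alt,
            "pi_alt": {t: v for t, v in zip(self.pi_alt.taxa, self.pi_alt.values)},
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "bootstrap_stats": [float(s) for s in self.bootstrap_stats],
            "loglik_null": self.loglik_null,
            "loglik_alt": self.loglik_alt,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _dm_loglik(counts: np.ndarray, pi: np.ndarray, theta: float) -> float:
    """Dirichlet-multinomial log-likelihood, summed over replicate columns.

    Counts on taxa with pi == 0 have zero probability: returns -inf (by
    contract, not an exception).  Taxa with pi == 0 and zero counts simply
    drop out of the product.
    """
    counts = np.asarray(counts, dtype=float)
    depths = counts.sum(axis=0)
    n_rep = counts.shape[1]
    support = pi > 0
    if np.any(counts[~support] > 0):
        return -np.inf
    alpha = theta * pi[support]
    x = counts[support]
    ll = float(gammaln(depths + 1).sum() - gammaln(counts + 1).sum())
    ll += n_rep * gammaln(theta) - float(gammaln(depths + theta).sum())
    ll += float((gammaln(x + alpha[:, None]) - gammaln(alpha[:, None])).sum())
    return ll


def dm_log_likelihood(table: CountTable, model: OverdispersedModel) -> float:
    """Log-likelihood of a count table under an overdispersed model."""
    model.proportions.check_taxa(table.taxa)
    return _dm_loglik(table.counts, model.proportions.values, model.concentration)


def _optimize_theta(
    counts: np.ndarray, pi: np.ndarray, xatol: float = 1e-8
) -> tuple[float, float]:
    """Maximize the DM log-likelihood over theta on a bounded log scale."""
    lo, hi = np.log(THETA_MIN), np.log(THETA_MAX)
    res = minimize_scalar(
        lambda t: -_dm_loglik(counts, pi, float(np.exp(t))),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": xatol},
    )
    theta = float(np.exp(res.x))
    best_ll = -float(res.fun)
    # bounded Brent can stop short of a boundary optimum; check the endpoints
    for t_edge in (THETA_MIN, THETA_MAX):
        ll_edge = _dm_loglik(counts, pi, t_edge)
        if ll_edge > best_ll:
            theta, best_ll = t_edge, ll_edge
    return theta, best_ll


def fit_null(
    table: CountTable, expected: ProportionVector, xatol: float = 1e-8
) -> OverdispersedModel:
    """Fix the composition at ``expected`` and estimate theta by ML."""
    expected.check_taxa(table.taxa)
    theta, ll = _optimize_theta(table.counts, expected.values, xatol=xatol)
    if not np.isfinite(ll):
        raise FitError(
            "null likelihood is -inf: counts observed on taxa with expected "
            "proportion zero",
            OverdispersedModel(expected, theta),
        )
    return OverdispersedModel(
        expected,
        theta,
        fit_info={
            "loglik": ll,
            "bounds": (THETA_MIN, THETA_MAX),
            "xatol": xatol,
        },
    )


def _fit_alt_alternating(
    counts: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, float, float, bool]:
    """Joint (pi, theta) MLE by alternating optimization.

    theta step: exact bounded 1-D maximization given pi (as in the null fit);
    pi step: a few multiplicative fixed-point updates

        pi_i <- pi_i * s_i / sum_k pi_k s_k,
        s_i = sum_j [psi(x_ij + theta pi_i) - psi(theta pi_i)]

    given theta.  Taxa with all-zero counts have MLE proportion 0 and are
    held out of the updates.  Stops when the log-likelihood moves by less
    than ``tol`` between outer iterations.
    """
    depths = counts.sum(axis=0)
    support = counts.sum(axis=1) > 0
    x = counts[support].astype(float)
    pi_s = x.sum(axis=1) / x.sum()
    theta = 10.0
    ll_prev = _dm_loglik_supported(x, depths, theta * pi_s)
    converged = False
    ll = ll_prev
    for _ in range(max_iter):
        theta, _ = _optimize_theta(x, pi_s, xatol=1e-8)
        for _inner in range(3):
            a = theta * pi_s[:, None]
            s = (digamma(x + a) - digamma(a)).sum(axis=1)
            w = pi_s * s
            total = w.sum()
            if total <= 0 or np.any(~np.isfinite(w)):
                break
            pi_s = w / total
        ll = _dm_loglik_supported(x, depths, theta * pi_s)
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
    pi = np.zeros(counts.shape[0])
    pi[support] = pi_s
    return pi, float(np.clip(theta, THETA_MIN, THETA_MAX)), ll, converged


def _dm_loglik_supported(x: np.ndarray, depths: np.ndarray, alpha: np.ndarray) -> float:
    """DM log-likelihood for supported taxa given raw alpha (theta folded in)."""
    a_tot = alpha.sum()
    n_rep = x.shape[1]
    ll = float(gammaln(depths + 1).sum() - gammaln(x + 1).sum())
    ll += n_rep * gammaln(a_tot) - float(gammaln(depths + a_tot).sum())
    ll += float((gammaln(x + alpha[:, None]) - gammaln(alpha[:, None])).sum())
    return ll


def _fit_alt_lbfgs(
    counts: np.ndarray, pi0: np.ndarray, theta0: float
) -> tuple[np.ndarray, float, float, bool]:
    """Polish the alternative fit with L-BFGS on (logits, log theta)."""
    support = counts.sum(axis=1) > 0
    x = counts[support].astype(float)
    k = x.shape[0]
    p0 = np.clip(pi0[support], 1e-9, None)
    p0 = p0 / p0.sum()
    z0 = np.log(p0[1:] / p0[0]) if k > 1 else np.array([])
    params0 = np.concatenate([z0, [np.log(np.clip(theta0, THETA_MIN, THETA_MAX))]])

    def unpack(params: np.ndarray) -> tuple[np.ndarray, float]:
        z = np.concatenate([[0.0], params[:-1]])
        z = z - z.max()
        p = np.exp(z)
        p /= p.sum()
        return p, float(np.exp(params[-1]))

    def neg_ll(params: np.ndarray) -> float:
        p, theta = unpack(params)
        full_p = np.zeros(counts.shape[0])
        full_p[support] = p
        return -_dm_loglik(counts, full_p, theta)

    bounds = [(-30.0, 30.0)] * (k - 1) + [(np.log(THETA_MIN), np.log(THETA_MAX))]
    res = minimize(neg_ll, params0, method="L-BFGS-B", bounds=bounds)
    p, theta = unpack(res.x)
    pi = np.zeros(counts.shape[0])
    pi[support] = p
    return pi, theta, -float(res.fun), bool(res.success)


def fit_alternative(
    table: CountTable,
    fix_theta: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> OverdispersedModel:
    """Joint MLE of composition and concentration (or composition alone).

    A fast fixed-point pass does most of the work; a gradient polish runs
    whenever the fixed point stalls before meeting the tolerance.
    """
    counts = table.counts
    if fix_theta is not None:
        pi, theta, ll, ok = _fit_alt_lbfgs_fixed_theta(counts, fix_theta)
        info = {"loglik": ll, "converged": ok, "theta_fixed": True}
        return OverdispersedModel(ProportionVector(table.taxa, pi), theta, info)
    pi, theta, ll, converged = _fit_alt_alternating(counts, tol, max_iter)
    used_polish = False
    if not converged:
        pi2, theta2, ll2, ok = _fit_alt_lbfgs(counts, pi, theta)
        if ll2 >= ll:
            pi, theta, ll, converged = pi2, theta2, ll2, ok
            used_polish = True
    info = {
        "loglik": ll,
        "converged": bool(converged),
        "polished": used_polish,
        "tol": tol,
        "max_iter": max_iter,
    }
    model = OverdispersedModel(ProportionVector(table.taxa, pi), float(theta), info)
    if not converged:
        raise FitError("alternative fit did not converge", model)
    return model


def _fit_alt_lbfgs_fixed_theta(
    counts: np.ndarray, theta: float
) -> tuple[np.ndarray, float, float, bool]:
    support = counts.sum(axis=1) > 0
    x = counts[support].astype(float)
    k = x.shape[0]
    p0 = x.sum(axis=1) / x.sum()
    if k == 1:
        pi = np.zeros(counts.shape[0])
        pi[support] = 1.0
        return pi, theta, _dm_loglik(counts, pi, theta), True
    z0 = np.log(p0[1:] / p0[0])

    def neg_ll(z_free: np.ndarray) -> float:
        z = np.concatenate([[0.0], z_free])
        z = z - z.max()
        p = np.exp(z)
        p /= p.sum()
        full_p = np.zeros(counts.shape[0])
        full_p[support] = p
        return -_dm_loglik(counts, full_p, theta)

    res = minimize(neg_ll, z0, method="L-BFGS-B", bounds=[(-30.0, 30.0)] * (k - 1))
    z = np.concatenate([[0.0], res.x])
    z = z - z.max()
    p = np.exp(z)
    p /= p.sum()
    pi = np.zeros(counts.shape[0])
    pi[support] = p
    return pi, theta, -float(res.fun), bool(res.success)


def simulate_dm_counts(
    rng: np.random.Generator,
    proportions: np.ndarray,
    theta: float,
    depths: np.ndarray,
) -> np.ndarray:
    """Draw a taxa x replicates matrix of Dirichlet-multinomial counts."""
    proportions = np.asarray(proportions, dtype=float)
    depths = np.asarray(depths, dtype=int)
    support = proportions > 0
    alpha = theta * proportions[support]
    out = np.zeros((proportions.shape[0], depths.shape[0]), dtype=np.int64)
    for j, depth in enumerate(depths):
        p = rng.dirichlet(alpha)
        # numerical underflow can leave tiny negatives after dirichlet
        p = np.clip(p, 0, None)
        s = p.sum()
        p = p / s if s > 0 else np.full(alpha.shape, 1 / alpha.shape[0])
        out[support, j] = rng.multinomial(int(depth), p)
    return out


def _lrt_statistic(
    counts: np.ndarray,
    taxa: tuple[str, ...],
    expected: ProportionVector,
    meta=None,
) -> tuple[float, OverdispersedModel, OverdispersedModel]:
    table = CountTable(taxa, counts, meta or ())
    null = fit_null(table, expected)
    try:
        alt = fit_alternative(table)
    except FitError as err:  # non-converged alternative: use best found
        if err.best is None:
            raise
        alt = err.best
    ll_null = null.fit_info["loglik"]
    ll_alt = max(alt.fit_info["loglik"], ll_null)  # alt nests the null
    lam = 2.0 * (ll_alt - ll_null)
    if lam < 0:
        lam = 0.0 if lam > -_LRT_CLIP else lam
    return lam, null, alt


def lrt_gof(
    table: CountTable,
    expected: ProportionVector,
    n_bootstrap: int = 999,
    seed: int = 0,
) -> GofResult:
    """Bootstrapped likelihood-ratio goodness of fit against ``expected``.

    The statistic is 2 * (loglik_alt - loglik_null), clipped at zero.  Its
    null distribution comes from ``n_bootstrap`` datasets simulated from the
    fitted null (same depths, composition = expected, theta = theta_null),
    each re-fit from scratch.  The p-value uses the never-zero estimator
    (1 + exceedances) / (B + 1).  One parent seed spawns an independent
    substream per bootstrap dataset, so results do not depend on execution
    order.
    """
    expected.check_taxa(table.taxa)
    if np.any((expected.values == 0) & (table.counts.sum(axis=1) > 0)):
        raise ValueError(
            "counts observed for taxa with zero expected proportion; "
            "the community and count table do not describe the same mixture"
        )
    lam, null, alt = _lrt_statistic(table.counts, table.taxa, expected, table.meta)
    depths = table.depths
    parent = np.random.SeedSequence(seed)
    children = parent.spawn(n_bootstrap)
    boot = np.empty(n_bootstrap)
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        sim = simulate_dm_counts(rng, expected.values, null.concentration, depths)
        boot[b], _, _ = _lrt_statistic(sim, table.taxa, expected)
    p_value = (1.0 + float(np.sum(boot >= lam))) / (n_bootstrap + 1.0)
    return GofResult(
        lrt_stat=float(lam),
        p_value=p_value,
        theta_null=null.concentration,
        theta_alt=alt.concentration,
        pi_alt=alt.proportions,
        n_bootstrap=n_bootstrap,
        seed=seed,
        bootstrap_stats=boot,
        loglik_null=float(null.fit_info["loglik"]),
        loglik_alt=float(max(alt.fit_info["loglik"], null.fit_info["loglik"])),
    )
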