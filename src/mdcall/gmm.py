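"""Per-SNP three-component bivariate Gaussian mixture fitted by EM.

This is the workhorse model for common SNPs: within one SNP, the raw
intensity pairs of all samples fall into up to three genotype clusters
(AA, AB, BB).  The mixture

    x_i ~ sum_k pi_k N(mu_k, Sigma_k),    k = AA, AB, BB

is fitted by expectation-maximisation, and each sample's Posterior Rate
(PR) — the converged responsibility of its assigned component — acts as
the per-call quality score.  Calls with PR below the no-call threshold
(default 0.85) are withheld as NC; this is how abnormal ("null")
intensities are rejected rather than by an explicit fourth component.
The per-SNP Average Posterior Rate (APR) is the mean PR over assigned
samples.

Genotype labels attach to components by mean contrast: the component
whose mean has the highest contrast y = (r-g)/(r+g) is AA (r is the
A-channel), the lowest is BB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core import GENOTYPES, NO_CALL, DegenerateDataError, GenotypeCall, contrast_array

_LOG2PI = float(np.log(2.0 * np.pi))
PI_FLOOR = 1e-10  # mixing-weight floor for frozen empty components


def _regularization(X: np.ndarray) -> float:
    """Covariance ridge scaled to the data: 1e-6 x mean variance, floored."""
    v = float(np.mean(np.var(X, axis=0)))
    return max(1e-6 * v, 1e-12)


def _log_gauss2(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Log bivariate normal density at each row of X."""
    d = X - mu
    a, b, c = sigma[0, 0], sigma[0, 1], sigma[1, 1]
    det = a * c - b * b
    if det <= 0:
        raise np.linalg.LinAlgError("covariance not positive-definite")
    # closed-form 2x2 inverse
    quad = (c * d[:, 0] ** 2 - 2 * b * d[:, 0] * d[:, 1] + a * d[:, 1] ** 2) / det
    return -_LOG2PI - 0.5 * np.log(det) - 0.5 * quad


@dataclass(frozen=True)
class MixtureComponent:
    """One genotype cluster: weight, mean intensity pair, covariance, label."""

    pi: float
    mu: np.ndarray
    sigma: np.ndarray
    genotype_label: str


@dataclass
class SnpMixtureFit:
    """Converged (or truncated) EM fit for one SNP."""

    components: list[MixtureComponent]
    responsibilities: np.ndarray  # (n_s, 3), rows sum to 1
    loglik_trace: np.ndarray
    converged: bool
    assignments: np.ndarray = field(default=None)  # argmax responsibility

    def __post_init__(self):
        if self.assignments is None:
            self.assignments = np.argmax(self.responsibilities, axis=1)

    @property
    def labels(self) -> list[str]:
        return [c.genotype_label for c in self.components]


def init_gmm(X: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic initial (pi, mu, sigma) for the 3-component EM.

    Points are split by the contrast cutoffs y = +/-0.5 (the rough
    genotype boundaries).  A component whose contrast region holds no
    point is anchored at the centre of its empty region (at the mean
    total intensity), so EM leaves it empty rather than splitting an
    occupied cluster — exactly what a rare SNP with one or two genotype
    clusters needs for an honest MAF estimate.  When all three regions
    are occupied a short Lloyd (k-means) refinement sharpens the means.
    Components are ordered by descending mean contrast (AA, AB, BB);
    pi starts uniform and sigma at the pooled within-group covariance
    plus a ridge.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise DegenerateDataError(f"need >= 3 points to initialise, got {n}")
    if np.allclose(X, X[0], atol=1e-12):
        raise DegenerateDataError("all points identical")
    y = contrast_array(X)
    y = np.where(np.isnan(y), 0.0, y)

    groups = [y >= 0.5, (y > -0.5) & (y < 0.5), y <= -0.5]
    region_y = (0.75, 0.0, -0.75)  # centres of the three contrast regions
    tbar = float(X.sum(axis=1).mean())
    centers = np.array(
        [
            X[m].mean(axis=0)
            if m.any()
            else [tbar * (1 + yc) / 2.0, tbar * (1 - yc) / 2.0]
            for m, yc in zip(groups, region_y)
        ]
    )

    # Lloyd refinement only when every region is occupied; deterministic
    # (ties to lowest index), seed kept for API stability only — no
    # randomness is actually consumed.
    rng = np.random.default_rng(seed)
    del rng
    if all(m.any() for m in groups):
        for _ in range(25):
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            lab = np.argmin(d2, axis=1)
            new = centers.copy()
            for k in range(3):
                if np.any(lab == k):
                    new[k] = X[lab == k].mean(axis=0)
            if np.allclose(new, centers, atol=1e-10):
                centers = new
                break
            centers = new

    # order components by descending mean contrast -> AA, AB, BB
    cy = contrast_array(centers)
    cy = np.where(np.isnan(cy), 0.0, cy)
    order = np.argsort(-cy, kind="stable")
    centers = centers[order]
    lab = np.argmin(((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1)

    eps = _regularization(X)
    pooled = np.zeros((2, 2))
    for k in range(3):
        if np.sum(lab == k) >= 2:
            pooled += np.cov(X[lab == k].T) * (np.sum(lab == k) - 1)
    denom = max(n - 3, 1)
    pooled = pooled / denom + eps * np.eye(2)
    pi = np.full(3, 1.0 / 3.0)
    sigma = np.array([pooled.copy() for _ in range(3)])
    return pi, centers, sigma


def e_step(
    X: np.ndarray, pi: np.ndarray, mu: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """Responsibilities f_k(x_i) = pi_k N(x_i|mu_k,Sigma_k) / sum_u pi_u N(x_i|mu_u,Sigma_u).

    Computed in log space; rows sum to one exactly even when all
    densities underflow.
    """
    logr, _ = _e_step_log(X, pi, mu, sigma)
    return np.exp(logr)


def _e_step_log(X, pi, mu, sigma):
    K = len(pi)
    logp = np.empty((X.shape[0], K))
    for k in range(K):
        if pi[k] <= 0.0:
            logp[:, k] = -np.inf  # a zero-weight component never claims a point
        else:
            logp[:, k] = np.log(pi[k]) + _log_gauss2(X, mu[k], sigma[k])
    norm = logsumexp(logp, axis=1)
    return logp - norm[:, None], float(norm.sum())


def m_step(
    X: np.ndarray,
    resp: np.ndarray,
    prev: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weighted-moment updates of (pi, mu, sigma).

    mu_k is the responsibility-weighted mean; Sigma_k the weighted
    scatter about the *new* mean plus a ridge; pi_k the mean
    responsibility.  A component whose responsibility mass vanishes is
    frozen at its previous parameters with pi at a floor (flagged in the
    returned empty mask); with no previous parameters this is an error.
    """
    X = np.asarray(X, dtype=float)
    resp = np.asarray(resp, dtype=float)
    n, K = resp.shape
    eps = _regularization(X)
    nk = resp.sum(axis=0)
    empty = nk <= n * 1e-12
    if empty.any() and prev is None:
        raise DegenerateDataError("empty mixture component with no previous parameters")
    pi = nk / n
    mu = np.zeros((K, 2))
    sigma = np.zeros((K, 2, 2))
    for k in range(K):
        if empty[k]:
            pi[k] = PI_FLOOR
            mu[k] = prev[1][k]
            sigma[k] = prev[2][k]
            continue
        mu[k] = resp[:, k] @ X / nk[k]
        d = X - mu[k]
        sigma[k] = (resp[:, k, None] * d).T @ d / nk[k] + eps * np.eye(2)
    pi = pi / pi.sum()
    return pi, mu, sigma, empty


def fit_gmm(
    X: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> SnpMixtureFit:
    """Fit the three-component mixture by EM on one SNP's intensity rows.

    Alternates E and M steps until the relative log-likelihood change
    drops below ``tol`` or ``max_iter`` is reached; the log-likelihood
    trace is non-decreasing.  At convergence components are relabelled
    by descending mean contrast (AA, AB, BB).
    """
    X = np.asarray(X, dtype=float)
    pi, mu, sigma = init_gmm(X, seed)
    trace = []
    converged = False
    resp = None
    for _ in range(max_iter):
        logr, ll = _e_step_log(X, pi, mu, sigma)
        resp = np.exp(logr)
        trace.append(ll)
        if len(trace) >= 2:
            prev_ll = trace[-2]
            if abs(ll - prev_ll) < tol * max(abs(ll), 1.0):
                converged = True
                break
        pi, mu, sigma, _ = m_step(X, resp, prev=(pi, mu, sigma))

    # relabel by descending mean contrast
    cy = contrast_array(mu)
    cy = np.where(np.isnan(cy), 0.0, cy)
    order = np.argsort(-cy, kind="stable")
    pi, mu, sigma, resp = pi[order], mu[order], sigma[order], resp[:, order]
    comps = [
        MixtureComponent(float(pi[k]), mu[k].copy(), sigma[k].copy(), GENOTYPES[k])
        for k in range(3)
    ]
    return SnpMixtureFit(comps, resp, np.asarray(trace), converged)


def posterior_rate(fit: SnpMixtureFit) -> np.ndarray:
    """Per-sample PR: the responsibility of each sample's assigned component."""
    return fit.responsibilities[np.arange(fit.responsibilities.shape[0]), fit.assignments]


def average_posterior_rate(pr_values: np.ndarray, assigned: np.ndarray | None = None) -> float:
    """APR: mean PR over assigned (non-NC) samples; NaN when none are assigned.

    ``assigned`` is a boolean mask of samples counted in the per-cluster
    sizes n_ks; by default every sample is assigned.
    """
    pr_values = np.asarray(pr_values, dtype=float)
    if assigned is None:
        assigned = np.ones(pr_values.shape[0], dtype=bool)
    assigned = np.asarray(assigned, dtype=bool)
    if not assigned.any():
        return float("nan")
    return float(pr_values[assigned].mean())


def call_genotypes(fit: SnpMixtureFit, pr_threshold: float = 0.85) -> list[GenotypeCall]:
    """Threshold calls: argmax component's label if PR >= threshold, else NC.

    The threshold is inclusive (a posterior of exactly 0.85 is called).
    """
    pr = posterior_rate(fit)
    labels = fit.labels
    calls = []
    for i in range(pr.shape[0]):
        if pr[i] >= pr_threshold:
            calls.append(GenotypeCall(labels[fit.assignments[i]], float(pr[i]), "GMM"))
        else:
            calls.append(GenotypeCall(NO_CALL, float(pr[i]), "GMM"))
    return calls
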