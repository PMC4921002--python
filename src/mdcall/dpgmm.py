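"""Dirichlet-process Gaussian mixture for rare-SNP genotype calling.

For rare SNPs the number of genotype clusters present is uncertain (one
or two clusters may be empty or hold a handful of points), so a fixed
three-component mixture is the wrong model.  Here cluster indicators are
resampled from the collapsed (Chinese-restaurant-process) conditional

    p(z_i = k | ...) ∝ n_{-i,k} / (n - 1 + alpha) * N(x_i | mu_k, R_k)   (existing k)
    p(z_i = new | ...) ∝ alpha / (n - 1 + alpha) * ∫ N(x|mu,R) p(mu,R) dmu dR

with a conjugate Normal–Wishart component prior

    R_k ~ Wishart(nu, S^{-1}),   mu_k | R_k ~ N(m, (r R_k)^{-1}),

so the new-cluster prior predictive is a closed-form bivariate Student-t.
R_k is a precision matrix and r a relative precision; this reading makes
the prior conjugate.  The concentration alpha has the prior
1/alpha ~ Gamma(1, 1) (unit shape and mean) and is resampled with a
log-scale random-walk Metropolis step.

A Gibbs sweep resamples every indicator, then every occupied cluster's
(mu, R) from its Normal–Wishart full conditional, then alpha.  The
reported partition is the post-burn-in sample that agrees best, in mean
pairwise co-assignment, with the whole post-burn-in set — a consensus
that sidesteps label switching entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .core import NO_CALL, GenotypeCall, ValidationError, contrast_array

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# hyperparameters
# ---------------------------------------------------------------------------


@dataclass
class DPHyperparams:
    """Normal–Wishart + concentration hyperparameters (fixed within a fit).

    m : prior mean of the component means (intensity units)
    r : relative precision of mu (small r = vague mean prior)
    nu : Wishart degrees of freedom (>= 2 for 2x2)
    S : Wishart scale base; the component precision prior is W(nu, S^-1),
        so the prior-expected precision is nu * S^-1
    alpha_shape, alpha_scale : parameters of the prior on 1/alpha
        (Gamma with unit shape and mean by default)
    """

    m: np.ndarray
    r: float
    nu: float
    S: np.ndarray
    alpha_shape: float = 1.0
    alpha_scale: float = 1.0

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float).reshape(2)
        self.S = np.asarray(self.S, dtype=float).reshape(2, 2)
        if self.r <= 0:
            raise ValidationError("r must be positive")
        if self.nu < 2:
            raise ValidationError("nu must be >= 2 for bivariate data")
        if not np.allclose(self.S, self.S.T):
            raise ValidationError("S must be symmetric")
        if np.linalg.eigvalsh(self.S).min() <= 0:
            raise ValidationError("S must be positive-definite")
        # precompute Student-t predictive constants (see new_cluster_predictive)
        df = self.nu - 1.0  # nu - d + 1, d = 2
        scale = (1.0 + self.r) / (self.r * df) * self.S
        inv = np.linalg.inv(scale)
        self._t_df = df
        self._t_inv = (float(inv[0, 0]), float(inv[0, 1]), float(inv[1, 1]))
        # bivariate t: Gamma((df+2)/2) / (Gamma(df/2) (df pi) |scale|^1/2)
        self._t_lognorm = float(
            gammaln((df + 2.0) / 2.0)
            - gammaln(df / 2.0)
            - math.log(df)
            - math.log(math.pi)
            - 0.5 * np.linalg.slogdet(scale)[1]
        )

    @classmethod
    def from_data(cls, X: np.ndarray, r: float = 0.01, nu: float = 4.0) -> "DPHyperparams":
        """Empirical defaults: m at the data mean, S = nu x within-cluster covariance.

        The covariance scale is pooled over the rough contrast-cutoff
        clusters (the same +/-0.5 partition used for reference
        screening), so the prior expects genotype-cluster-sized
        components rather than components as broad as the whole SNP.
        This is what lets a lone far-away point open a new cluster:
        the Student-t prior predictive is diffuse on the cluster scale,
        not on the panel scale.  Falls back to the total covariance
        when no rough cluster has two members.
        """
        X = np.asarray(X, dtype=float)
        m = X.mean(axis=0)
        from .reference import rough_cluster_by_contrast

        rc = rough_cluster_by_contrast(X)
        pooled = np.zeros((2, 2))
        dof = 0
        for rows in rc.members:
            if rows.shape[0] >= 2:
                pooled += np.cov(rows.T) * (rows.shape[0] - 1)
                dof += rows.shape[0] - 1
        if dof > 0:
            cov = pooled / dof
        elif X.shape[0] > 1:
            cov = np.atleast_2d(np.cov(X.T))
        else:
            cov = np.eye(2)
        tr = max(np.trace(cov) / 2.0, 1e-8)
        cov = cov + 1e-6 * tr * np.eye(2)
        return cls(m=m, r=r, nu=nu, S=nu * cov)


# ---------------------------------------------------------------------------
# sampler state
# ---------------------------------------------------------------------------


class _Cluster:
    """Occupied-cluster parameters with cached 2x2 precision terms."""

    __slots__ = ("mu0", "mu1", "p00", "p01", "p11", "logdet", "count")

    def __init__(self, mu: np.ndarray, prec: np.ndarray, count: int) -> None:
        self.count = count
        self.set_params(mu, prec)

    def set_params(self, mu: np.ndarray, prec: np.ndarray) -> None:
        self.mu0 = float(mu[0])
        self.mu1 = float(mu[1])
        self.p00 = float(prec[0, 0])
        self.p01 = float(prec[0, 1])
        self.p11 = float(prec[1, 1])
        det = self.p00 * self.p11 - self.p01 * self.p01
        if det <= 0:
            raise ValidationError("cluster precision not positive-definite")
        self.logdet = math.log(det)

    @property
    def mu(self) -> np.ndarray:
        return np.array([self.mu0, self.mu1])

    @property
    def precision(self) -> np.ndarray:
        return np.array([[self.p00, self.p01], [self.p01, self.p11]])

    def log_density(self, x0: float, x1: float) -> float:
        d0 = x0 - self.mu0
        d1 = x1 - self.mu1
        quad = self.p00 * d0 * d0 + 2.0 * self.p01 * d0 * d1 + self.p11 * d1 * d1
        return -_LOG2PI + 0.5 * self.logdet - 0.5 * quad


@dataclass
class DPState:
    """Gibbs state for one SNP: indicators, occupied clusters, alpha."""

    z: np.ndarray
    clusters: dict[int, _Cluster]
    alpha: float
    iteration: int = 0
    _next_id: int = 0

    @property
    def n_occupied(self) -> int:
        return len(self.clusters)

    def check_counts(self) -> None:
        counts = {k: int(np.sum(self.z == k)) for k in self.clusters}
        for k, c in self.clusters.items():
            if c.count != counts[k] or c.count < 1:
                raise ValidationError("cluster counts inconsistent with indicators")


def _nw_posterior(X: np.ndarray, hyper: DPHyperparams):
    """Normal–Wishart posterior (m_n, r_n, nu_n, S_n) given cluster members."""
    n = X.shape[0]
    xbar = X.mean(axis=0)
    r_n = hyper.r + n
    m_n = (hyper.r * hyper.m + n * xbar) / r_n
    nu_n = hyper.nu + n
    d = X - xbar
    scatter = d.T @ d
    dm = (xbar - hyper.m).reshape(2, 1)
    S_n = hyper.S + scatter + (hyper.r * n / r_n) * (dm @ dm.T)
    return m_n, r_n, nu_n, S_n


def _chol2(a: float, b: float, c: float) -> tuple[float, float, float]:
    """Cholesky factor entries (l11, l21, l22) of [[a, b], [b, c]]."""
    l11 = math.sqrt(a)
    l21 = b / l11
    l22 = math.sqrt(max(c - l21 * l21, 1e-300))
    return l11, l21, l22


def _draw_cluster_params(X: np.ndarray, hyper: DPHyperparams, rng: np.random.Generator):
    """Draw (mu, R) from the Normal–Wishart full conditional given members X.

    The 2x2 Wishart draw uses the Bartlett decomposition of
    W(nu_n, S_n^-1) and mu is drawn from N(m_n, (r_n R)^-1) by
    triangular solve — closed 2x2 forms, no linear-algebra library
    calls in the sampling hot path.
    """
    m_n, r_n, nu_n, S_n = _nw_posterior(X, hyper)
    # chol of S_n^{-1} via inverse of the 2x2
    a, b, c = float(S_n[0, 0]), float(S_n[0, 1]), float(S_n[1, 1])
    det = a * c - b * b
    l11, l21, l22 = _chol2(c / det, -b / det, a / det)
    # Bartlett: R = (L A)(L A)^T with A lower-tri, chi-square diagonal
    a11 = math.sqrt(rng.chisquare(nu_n))
    a22 = math.sqrt(rng.chisquare(nu_n - 1.0))
    a21 = rng.standard_normal()
    b11 = l11 * a11
    b21 = l21 * a11 + l22 * a21
    b22 = l22 * a22
    R = np.array([[b11 * b11, b11 * b21], [b11 * b21, b21 * b21 + b22 * b22]])
    # mu = m_n + B^{-T} z / sqrt(r_n), B = chol(R)
    z1, z2 = rng.standard_normal(2)
    w2 = z2 / b22
    w1 = (z1 - b21 * w2) / b11
    s = math.sqrt(r_n)
    mu = np.array([m_n[0] + w1 / s, m_n[1] + w2 / s])
    return mu, R


def init_dp_state(X: np.ndarray, hyper: DPHyperparams, seed: int | np.random.Generator) -> DPState:
    """All samples start in a single cluster; alpha starts at 1.

    The single cluster's parameters are drawn from their Normal–Wishart
    full conditional given all the data (i.e. the prior conditioned on
    the data), so the chain starts in a supported region.
    """
    X = np.asarray(X, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = X.shape[0]
    if n < 1:
        raise ValidationError("need at least one sample")
    mu, R = _draw_cluster_params(X, hyper, rng)
    state = DPState(
        z=np.zeros(n, dtype=np.int64),
        clusters={0: _Cluster(mu, R, n)},
        alpha=1.0,
        _next_id=1,
    )
    return state


# ---------------------------------------------------------------------------
# conditional distributions
# ---------------------------------------------------------------------------


def new_cluster_predictive(x, hyper: DPHyperparams) -> float:
    """Prior-predictive density ∫ N(x|mu,R) p(mu,R|m,r,nu,S) dmu dR.

    Under the Normal–Wishart prior this integral is a bivariate
    Student-t with nu - 1 degrees of freedom, location m and scale
    (1+r) / (r (nu-1)) S.
    """
    x0 = float(x[0]) - hyper.m[0]
    x1 = float(x[1]) - hyper.m[1]
    i00, i01, i11 = hyper._t_inv
    quad = i00 * x0 * x0 + 2.0 * i01 * x0 * x1 + i11 * x1 * x1
    df = hyper._t_df
    return math.exp(hyper._t_lognorm - (df + 2.0) / 2.0 * math.log1p(quad / df))


def _crp_logw(
    state: DPState, zi: int, x0: float, x1: float, log_pred: float
) -> tuple[list[int], list[float]]:
    """Unnormalised log CRP weights: existing clusters then the new-cluster slot.

    ``zi`` is the cluster whose count must be reduced by one (the
    sample's current membership); pass a sentinel (e.g. -2) when the
    sample has already been removed from the state.
    """
    ids: list[int] = []
    logw: list[float] = []
    for k, cl in state.clusters.items():
        n_minus = cl.count - 1 if k == zi else cl.count
        if n_minus <= 0:
            continue
        ids.append(k)
        logw.append(math.log(n_minus) + cl.log_density(x0, x1))
    ids.append(-1)
    logw.append(math.log(state.alpha) + log_pred)
    return ids, logw


def crp_indicator_conditional(
    i: int, state: DPState, X: np.ndarray, hyper: DPHyperparams
) -> tuple[list[int], np.ndarray]:
    """Normalised reassignment probabilities for sample i.

    Returns the list of existing cluster ids plus a trailing ``-1`` slot
    for "open a new cluster", and the matching probability vector.
    Sample i's own membership is excluded from the counts; if i is the
    sole member of its cluster that cluster is removed from the menu
    (it is identical to the new-cluster option up to its parameters
    being integrated out).
    """
    X = np.asarray(X, dtype=float)
    x0, x1 = float(X[i, 0]), float(X[i, 1])
    pred = new_cluster_predictive((x0, x1), hyper)
    ids, logw = _crp_logw(state, int(state.z[i]), x0, x1, math.log(max(pred, 1e-300)))
    logw_arr = np.asarray(logw)
    logw_arr -= logw_arr.max()
    w = np.exp(logw_arr)
    w /= w.sum()
    return ids, w


def sample_cluster_params(
    state: DPState, X: np.ndarray, hyper: DPHyperparams, rng: np.random.Generator
) -> None:
    """Resample every occupied cluster's (mu, R) from its full conditional."""
    X = np.asarray(X, dtype=float)
    for k in sorted(state.clusters):
        members = X[state.z == k]
        mu, R = _draw_cluster_params(members, hyper, rng)
        state.clusters[k].set_params(mu, R)


def _log_alpha_posterior(alpha: float, n_occupied: int, n: int, hyper: DPHyperparams) -> float:
    """log p(alpha | K, n) up to a constant.

    Prior: 1/alpha ~ Gamma(shape, scale) => log p(alpha) =
    -(shape+1) log alpha - 1/(scale * alpha) + const.  Likelihood of the
    partition: alpha^K Gamma(alpha) / Gamma(alpha + n).  With K = n = 0
    this reduces to the bare prior.
    """
    lp = -(hyper.alpha_shape + 1.0) * math.log(alpha) - 1.0 / (hyper.alpha_scale * alpha)
    if n > 0:
        lp += n_occupied * math.log(alpha) + gammaln(alpha) - gammaln(alpha + n)
    return lp


def sample_alpha(
    state: DPState, hyper: DPHyperparams, rng: np.random.Generator, step: float = 0.7
) -> float:
    """One log-scale random-walk Metropolis update of alpha (in place)."""
    n = state.z.shape[0]
    cur = state.alpha
    prop = cur * math.exp(step * rng.standard_normal())
    # Jacobian of the log-scale walk contributes log(prop) - log(cur)
    log_acc = (
        _log_alpha_posterior(prop, state.n_occupied, n, hyper)
        - _log_alpha_posterior(cur, state.n_occupied, n, hyper)
        + math.log(prop)
        - math.log(cur)
    )
    if math.log(rng.random()) < log_acc:
        state.alpha = prop
    return state.alpha


# ---------------------------------------------------------------------------
# full Gibbs fit
# ---------------------------------------------------------------------------


@dataclass
class DPFit:
    """Consensus partition and conditional component estimates for one SNP."""

    consensus_z: np.ndarray  # per-sample cluster index, 0..K-1 by descending contrast
    pis: np.ndarray  # (K,)
    mus: np.ndarray  # (K, 2)
    sigmas: np.ndarray  # (K, 2, 2)
    n_occupied: int
    responsibilities: np.ndarray  # (n, K) under the component estimates
    pr: np.ndarray  # responsibility of the consensus-assigned component
    apr: float
    cluster_contrast: np.ndarray  # (K,) mean-contrast of each component


def _coassign(z: np.ndarray) -> np.ndarray:
    return z[:, None] == z[None, :]


def fit_dp_gmm(
    X: np.ndarray,
    hyper: DPHyperparams | None = None,
    n_iter: int = 2000,
    burn_in: int = 500,
    seed: int | np.random.Generator = 0,
    thin: int = 5,
) -> DPFit:
    """Collapsed Gibbs sampling of the DP mixture on one SNP's intensities.

    Each sweep resamples all indicators, all occupied-cluster parameters
    and alpha.  Post-burn-in partitions (every ``thin``-th sweep) form
    the consensus pool; the reported partition is the pooled sample with
    the highest mean pairwise co-assignment agreement.  Component
    estimates are the Normal–Wishart conditional posterior means given
    the consensus partition; PR/APR are then computed exactly as in the
    EM model.
    """
    X = np.asarray(X, dtype=float)
    if n_iter <= 0 or burn_in < 0 or n_iter <= burn_in:
        raise ValidationError("need n_iter > burn_in >= 0")
    n = X.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if hyper is None:
        hyper = DPHyperparams.from_data(X)
    state = init_dp_state(X, hyper, rng)

    # the new-cluster predictive depends only on x_i: precompute its log once
    log_pred = [
        math.log(max(new_cluster_predictive(X[i], hyper), 1e-300)) for i in range(n)
    ]

    saved: list[np.ndarray] = []
    for it in range(n_iter):
        _gibbs_sweep(state, X, hyper, rng, log_pred)
        sample_cluster_params(state, X, hyper, rng)
        sample_alpha(state, hyper, rng)
        state.iteration = it + 1
        if it >= burn_in and (it - burn_in) % thin == 0:
            saved.append(state.z.copy())

    consensus = _consensus_partition(saved)
    return _fit_from_partition(X, consensus, hyper)


def _gibbs_sweep(
    state: DPState,
    X: np.ndarray,
    hyper: DPHyperparams,
    rng,
    log_pred: list[float] | None = None,
) -> None:
    """One full sweep of indicator resampling (in place)."""
    n = X.shape[0]
    if log_pred is None:
        log_pred = [
            math.log(max(new_cluster_predictive(X[i], hyper), 1e-300)) for i in range(n)
        ]
    x0s = X[:, 0].tolist()
    x1s = X[:, 1].tolist()
    z = state.z.tolist()
    clusters = state.clusters
    us = rng.random(n).tolist()
    for i in range(n):
        zi = z[i]
        cl = clusters[zi]
        cl.count -= 1
        if cl.count == 0:
            del clusters[zi]
        ids, logw = _crp_logw(state, -2, x0s[i], x1s[i], log_pred[i])
        mx = max(logw)
        ws = [math.exp(lw - mx) for lw in logw]
        u = us[i] * math.fsum(ws)
        acc = 0.0
        j = len(ws) - 1
        for jj, w in enumerate(ws):
            acc += w
            if u <= acc:
                j = jj
                break
        choice = ids[j]
        if choice == -1:
            mu, R = _draw_cluster_params(X[i : i + 1], hyper, rng)
            choice = state._next_id
            state._next_id += 1
            clusters[choice] = _Cluster(mu, R, 1)
        else:
            clusters[choice].count += 1
        z[i] = choice
    state.z = np.asarray(z, dtype=np.int64)


def _consensus_partition(saved: list[np.ndarray]) -> np.ndarray:
    """Pick the saved partition maximising mean pairwise co-assignment agreement."""
    if len(saved) == 1:
        return saved[0]
    n = saved[0].shape[0]
    mean_co = np.zeros((n, n))
    for z in saved:
        mean_co += _coassign(z)
    mean_co /= len(saved)
    best, best_score = None, -np.inf
    for z in saved:
        A = _coassign(z)
        score = float(np.where(A, mean_co, 1.0 - mean_co).sum())
        if score > best_score:
            best, best_score = z, score
    return best


def _fit_from_partition(X: np.ndarray, z: np.ndarray, hyper: DPHyperparams) -> DPFit:
    """Conditional component estimates and PR/APR given a fixed partition."""
    ids = [k for k in np.unique(z)]
    K = len(ids)
    n = X.shape[0]
    mus = np.zeros((K, 2))
    sigmas = np.zeros((K, 2, 2))
    pis = np.zeros(K)
    for j, k in enumerate(ids):
        members = X[z == k]
        m_n, r_n, nu_n, S_n = _nw_posterior(members, hyper)
        mus[j] = m_n
        # posterior mean of the covariance R^-1 under W(nu_n, S_n^-1)
        sigmas[j] = S_n / (nu_n - 2.0 - 1.0)
        pis[j] = members.shape[0] / n

    # relabel by descending mean contrast
    cy = contrast_array(mus)
    cy = np.where(np.isnan(cy), 0.0, cy)
    order = np.argsort(-cy, kind="stable")
    mus, sigmas, pis, cy = mus[order], sigmas[order], pis[order], cy[order]
    remap = {ids[old]: new for new, old in enumerate(order)}
    z_rel = np.array([remap[int(k)] for k in z], dtype=np.int64)

    from .gmm import _e_step_log  # shared responsibility computation

    logr, _ = _e_step_log(X, pis, mus, sigmas)
    resp = np.exp(logr)
    pr = resp[np.arange(n), z_rel]
    apr = float(pr.mean()) if n else float("nan")
    return DPFit(z_rel, pis, mus, sigmas, K, resp, pr, apr, cy)


# ---------------------------------------------------------------------------
# genotype mapping
# ---------------------------------------------------------------------------


def _side_label(y: float) -> str:
    if y >= 0.5:
        return "AA"
    if y < -0.5:
        return "BB"
    return "AB"


def _labels_for_clusters(contrasts: np.ndarray, sizes: np.ndarray) -> list[str]:
    """Genotype labels for consensus clusters, by contrast-cutoff side.

    Each cluster is labelled by which side of the rough genotype
    boundaries (y = +/-0.5) its mean contrast falls on: y >= 0.5 -> AA,
    y < -0.5 -> BB, else AB.  Several clusters may share a genotype —
    a split major cluster or an outlier micro-cluster sitting inside a
    genotype region is still that genotype.  A positional map
    (descending contrast -> AA, AB, BB) was rejected because a single
    spurious high-contrast cluster would shift every other cluster's
    label by one, miscalling the whole SNP.
    """
    del sizes  # labelling depends on geometry only
    return [_side_label(float(y)) for y in contrasts]


def dp_calls_to_genotypes(fit: DPFit, pr_threshold: float = 0.85) -> list[GenotypeCall]:
    """Map consensus clusters to genotypes and apply the PR no-call filter."""
    n = fit.consensus_z.shape[0]
    sizes = np.array([np.sum(fit.consensus_z == j) for j in range(fit.n_occupied)])
    labels = _labels_for_clusters(fit.cluster_contrast, sizes)
    calls = []
    for i in range(n):
        lab = labels[int(fit.consensus_z[i])]
        pr = float(fit.pr[i])
        if lab == NO_CALL or pr < pr_threshold:
            calls.append(GenotypeCall(NO_CALL, pr, "DP-GMM"))
        else:
            calls.append(GenotypeCall(lab, pr, "DP-GMM"))
    return calls
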