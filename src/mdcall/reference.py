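"""Reference-SNP selection and reference-assisted DP calling.

Extremely rare SNPs (zero to two observations in a minor genotype
cluster) defeat even the DP mixture: the rich-gets-richer behaviour of
the Chinese restaurant process lets the large major cluster swallow a
lone minor-cluster point.  The remedy is to borrow cluster geometry
from a good-quality *reference* SNP:

Step I   — candidate R1 SNPs: MAF > 0.15, located before the target
           (T-) SNP in array order (capped at the nearest few hundred).
Step II  — R2 SNPs: R1 candidates whose rough contrast clustering shows
           all three genotype clusters, each holding at least 10 % of
           the observations.
Step III — the R-SNP: the R2 candidate with the smallest cluster
           distance to the T-SNP,

    D_t = min_d sum_k trace{ (x_kt - mu_kd) ((S_kt + S_kd)/2)^-1 (x_kt - mu_kd)^T },

where x_kt are the T-SNP's member rows in rough cluster k and
(mu_kd, S_kd) the candidate's rough-cluster moments.  The rough
clustering uses the fixed contrast cutoffs y = +/-0.5.

The T-SNP's intensity rows are then stacked with the R-SNP's rows and
the DP mixture is fitted to the augmented vector; the reference rows
populate all three clusters so the T-SNP's few minor points co-cluster
correctly.  Only the T rows' calls are returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    NO_CALL,
    GenotypeCall,
    ReferenceUnavailableError,
    ValidationError,
    contrast_array,
)
from .dpgmm import DPHyperparams, dp_calls_to_genotypes, fit_dp_gmm

_CUTOFF_HI = 0.5
_CUTOFF_LO = -0.5


def _reg_eps(X: np.ndarray) -> float:
    v = float(np.mean(np.var(X, axis=0))) if X.shape[0] > 1 else 0.0
    return max(1e-6 * v, 1e-8)


@dataclass
class RoughClustering:
    """Contrast-cutoff clustering of one SNP: labels and per-cluster moments.

    ``labels[i]`` in {0,1,2} for (AA, AB, BB); -1 marks degenerate
    (r+g=0) points which are excluded from all statistics.
    """

    labels: np.ndarray
    members: list[np.ndarray]  # per-cluster (m_k, 2) rows
    mu: np.ndarray  # (3, 2); NaN rows for empty clusters
    sigma: np.ndarray  # (3, 2, 2); eps*I for singletons
    counts: np.ndarray  # (3,)

    @property
    def proportions(self) -> np.ndarray:
        tot = self.counts.sum()
        return self.counts / tot if tot else np.zeros(3)


@dataclass
class ReferenceCandidate:
    """An R1/R2 candidate with its rough-cluster statistics."""

    snp_id: str
    position: int
    maf: float
    clustering: RoughClustering


def rough_cluster_by_contrast(X: np.ndarray) -> RoughClustering:
    """Assign AA / AB / BB by the fixed contrast cutoffs y = +/-0.5.

    y >= 0.5 -> AA; -0.5 <= y < 0.5 -> AB; y < -0.5 -> BB (boundary
    conventions follow the printed inequalities).
    """
    X = np.asarray(X, dtype=float)
    y = contrast_array(X)
    labels = np.full(X.shape[0], -1, dtype=np.int64)
    labels[y >= _CUTOFF_HI] = 0
    labels[(y >= _CUTOFF_LO) & (y < _CUTOFF_HI)] = 1
    labels[y < _CUTOFF_LO] = 2
    members, mus, sigmas, counts = [], [], [], []
    eps = _reg_eps(X)
    for k in range(3):
        rows = X[labels == k]
        members.append(rows)
        counts.append(rows.shape[0])
        if rows.shape[0] == 0:
            mus.append(np.array([np.nan, np.nan]))
            sigmas.append(eps * np.eye(2))
        elif rows.shape[0] == 1:
            mus.append(rows[0].copy())
            sigmas.append(eps * np.eye(2))
        else:
            mus.append(rows.mean(axis=0))
            sigmas.append(np.cov(rows.T) + eps * np.eye(2))
    return RoughClustering(
        labels, members, np.array(mus), np.array(sigmas), np.array(counts)
    )


def select_r1(
    t_index: int,
    maf_table: dict[str, float] | "list[float]",
    snp_ids: list[str],
    ref_maf: float = 0.15,
    max_candidates: int = 200,
) -> list[int]:
    """Step I: indices of SNPs before the T-SNP with MAF > ref_maf.

    Nearest-first order, capped at ``max_candidates``.  Raises
    :class:`ReferenceUnavailableError` when no predecessor qualifies.
    """
    out = []
    for j in range(t_index - 1, -1, -1):
        maf = maf_table[snp_ids[j]] if isinstance(maf_table, dict) else maf_table[j]
        if maf is not None and not np.isnan(maf) and maf > ref_maf:
            out.append(j)
            if len(out) >= max_candidates:
                break
    if not out:
        raise ReferenceUnavailableError(f"no R1 candidate before SNP index {t_index}")
    return out


def select_r2(
    candidate_indices: list[int],
    dataset,
    maf_table,
    min_prop: float = 0.10,
) -> list[ReferenceCandidate]:
    """Step II: keep candidates whose three rough clusters each hold >= min_prop.

    The boundary is inclusive (exactly 10 % qualifies).
    """
    if not candidate_indices:
        raise ReferenceUnavailableError("empty R1 candidate list")
    kept = []
    for j in candidate_indices:
        X, _ = dataset.snp_data(j)
        if X.shape[0] == 0:
            continue
        rc = rough_cluster_by_contrast(X)
        props = rc.proportions
        if np.all(props >= min_prop):
            snp_id = dataset.snp_ids[j]
            maf = maf_table[snp_id] if isinstance(maf_table, dict) else maf_table[j]
            kept.append(ReferenceCandidate(snp_id, j, float(maf), rc))
    if not kept:
        raise ReferenceUnavailableError("no R1 candidate passed the cluster-proportion screen")
    return kept


def cluster_distance(t_clustering: RoughClustering, cand: ReferenceCandidate) -> float:
    """Cluster measure between a T-SNP and one candidate.

    For each genotype cluster k, every T member row is centred at the
    candidate's cluster mean and the quadratic form under the pooled
    covariance (S_kt + S_kd)/2 is accumulated (the trace of the centred
    Gram matrix).  Clusters empty in the T-SNP contribute zero.
    """
    total = 0.0
    for k in range(3):
        rows = t_clustering.members[k]
        if rows.shape[0] == 0:
            continue
        mu_d = cand.clustering.mu[k]
        if np.any(np.isnan(mu_d)):
            raise ValidationError("candidate lacks a cluster required for the distance")
        pooled = (t_clustering.sigma[k] + cand.clustering.sigma[k]) / 2.0
        d = rows - mu_d
        sol = np.linalg.solve(pooled, d.T)
        total += float(np.einsum("ij,ji->", d, sol))
    return total


def select_reference(
    t_clustering: RoughClustering,
    t_index: int,
    r2_candidates: list[ReferenceCandidate],
) -> ReferenceCandidate:
    """Step III: the candidate minimising the cluster distance.

    Ties break to the candidate nearest in array position, then to the
    lexicographically smallest id.
    """
    if not r2_candidates:
        raise ReferenceUnavailableError("empty R2 candidate list")
    scored = [
        (cluster_distance(t_clustering, c), abs(c.position - t_index), c.snp_id, c)
        for c in r2_candidates
    ]
    scored.sort(key=lambda t: t[:3])
    return scored[0][3]


def call_with_reference(
    t_data: np.ndarray,
    r_data: np.ndarray,
    hyper: DPHyperparams | None = None,
    pr_threshold: float = 0.85,
    n_iter: int = 2000,
    burn_in: int = 500,
    seed: int | np.random.Generator = 0,
) -> list[GenotypeCall]:
    """Fit the DP mixture on the augmented vector m_t = (x_t; x_d).

    The T-SNP's rows are stacked on the reference SNP's rows, the DP
    mixture is fitted to the combined intensities, cluster labels map to
    genotypes as usual, and only the T rows' calls are returned.  A
    failed DP fit yields all-NC for the T-SNP.
    """
    t_data = np.asarray(t_data, dtype=float)
    r_data = np.asarray(r_data, dtype=float)
    n_t = t_data.shape[0]
    stacked = np.vstack([t_data, r_data])
    try:
        fit = fit_dp_gmm(stacked, hyper=hyper, n_iter=n_iter, burn_in=burn_in, seed=seed)
        calls = dp_calls_to_genotypes(fit, pr_threshold)
    except Exception as exc:  # contained per SNP: a bad fit must not abort a run
        warnings.warn(f"DP fit on augmented vector failed ({exc}); T-SNP set to all-NC")
        return [GenotypeCall(NO_CALL, float("nan"), "DP-Ref") for _ in range(n_t)]
    return [GenotypeCall(c.genotype, c.pr, "DP-Ref") for c in calls[:n_t]]
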