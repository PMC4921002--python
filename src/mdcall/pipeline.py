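"""The M-D orchestrator: partition SNPs by MAF/cluster size, route models.

Pass 1 fits the three-component EM mixture to every SNP, estimates the
minor-allele frequency by allele counting over its calls and records
the per-genotype cluster sizes n_ks.  Each SNP is then routed:

    g1  if MAF >= 0.05                          -> keep the EM (GMM) calls
    g2  if MAF < 0.05 and some cluster has
        b1 <= n_ks < b2 (b1=3, b2=10)           -> refit with the DP mixture
    g3  otherwise                               -> reference-assisted DP

Pass 2 refits g2 and g3 SNPs.  Reference candidates for a g3 SNP are
drawn from the SNPs before it in array order using the pass-1 MAF
estimates; when none qualifies the search falls back to the SNPs after
it, and failing that the SNP is called with the plain DP mixture.
All randomness is driven by per-SNP seeds spawned from the config seed,
so a rerun with the same config reproduces the call set exactly.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .config import MDConfig
from .core import (
    GENOTYPES,
    NO_CALL,
    DegenerateDataError,
    GenotypeCall,
    GenotypeCallSet,
    IntensityDataset,
    SnpSummary,
)
from .dpgmm import dp_calls_to_genotypes, fit_dp_gmm
from .gmm import average_posterior_rate, call_genotypes, fit_gmm, posterior_rate
from .reference import (
    ReferenceUnavailableError,
    call_with_reference,
    rough_cluster_by_contrast,
    select_r1,
    select_r2,
    select_reference,
)

logger = logging.getLogger("mdcall")


@dataclass
class PartitionRecord:
    """Routing decision for one SNP from the pass-1 estimates."""

    snp_id: str
    maf: float  # NaN when no sample was called
    n_ks: tuple[int, int, int]
    group: str


def estimate_maf(genotypes: "list[str] | np.ndarray") -> float:
    """Allele-counting MAF estimate from called genotypes; NC excluded.

    (2 * minor-homozygote count + heterozygote count) / (2 * called),
    with the minor allele chosen so the result is at most 0.5.  NaN
    when nothing is called.
    """
    counts = Counter(genotypes)
    n_called = sum(counts[g] for g in GENOTYPES)
    if n_called == 0:
        return float("nan")
    q = (2 * counts["BB"] + counts["AB"]) / (2.0 * n_called)
    return min(q, 1.0 - q)


def genotype_counts(genotypes) -> tuple[int, int, int]:
    counts = Counter(genotypes)
    return tuple(counts[g] for g in GENOTYPES)


def partition_snp(
    maf: float,
    n_ks: tuple[int, int, int],
    b1: int = 3,
    b2: int = 10,
    maf_threshold: float = 0.05,
) -> str:
    """Route one SNP to g1 / g2 / g3.

    g1 when MAF >= threshold (inclusive); else g2 when at least one
    *non-empty* cluster count lies in [b1, b2); else g3.  A missing MAF
    (nothing called) routes to g3.
    """
    if not np.isnan(maf) and maf >= maf_threshold:
        return "g1"
    if any(n > 0 and b1 <= n < b2 for n in n_ks):
        return "g2"
    return "g3"


def partition_snps(
    records: "list[tuple[str, float, tuple[int, int, int]]]",
    b1: int = 3,
    b2: int = 10,
    maf_threshold: float = 0.05,
) -> list[PartitionRecord]:
    """Vector form of :func:`partition_snp` over (snp_id, maf, n_ks) triples."""
    return [
        PartitionRecord(sid, maf, tuple(n_ks), partition_snp(maf, n_ks, b1, b2, maf_threshold))
        for sid, maf, n_ks in records
    ]


def _snp_seed(base_seed: int, snp_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=base_seed, spawn_key=(snp_index,))


def _summarise(snp_id, calls, group, model, maf, pr, assigned_mask) -> SnpSummary:
    genos = [c.genotype for c in calls]
    n_ks = genotype_counts(genos)
    n_nc = genos.count(NO_CALL)
    apr = average_posterior_rate(pr, assigned_mask) if pr is not None else float("nan")
    return SnpSummary(snp_id, apr, maf, group, model, n_ks, n_nc)


def _all_nc(n: int, model: str) -> list[GenotypeCall]:
    return [GenotypeCall(NO_CALL, float("nan"), model) for _ in range(n)]


def run_md(dataset: IntensityDataset, config: MDConfig | None = None) -> GenotypeCallSet:
    """Run the full two-pass calling procedure on a dataset.

    Per-SNP failures are contained: the SNP is reported all-NC and the
    run continues.  Returns a call set whose summary records the MAF,
    routing group and model used for every SNP.
    """
    config = config or MDConfig()
    callset = GenotypeCallSet()

    # ---- pass 1: EM on every SNP -> calls, MAF, cluster sizes ----------
    pass1: dict[int, dict] = {}
    for idx, snp_id in enumerate(dataset.snp_ids):
        X, sample_idx = dataset.snp_data(idx)
        entry = {"X": X, "sample_idx": sample_idx, "fit": None,
                 "calls": None, "maf": float("nan"), "n_ks": (0, 0, 0)}
        if X.shape[0] >= 3:
            try:
                seed = int(_snp_seed(config.seed, idx).generate_state(1)[0] % (2**31))
                fit = fit_gmm(X, tol=config.em_tol, max_iter=config.em_max_iter, seed=seed)
                calls = call_genotypes(fit, config.pr_threshold)
                entry.update(
                    fit=fit,
                    calls=calls,
                    maf=estimate_maf([c.genotype for c in calls]),
                    n_ks=genotype_counts([c.genotype for c in calls]),
                )
            except DegenerateDataError as exc:
                logger.warning("SNP %s: pass-1 EM failed (%s)", snp_id, exc)
        pass1[idx] = entry

    maf_table = [pass1[i]["maf"] for i in range(dataset.S)]
    partition = {
        i: partition_snp(pass1[i]["maf"], pass1[i]["n_ks"], config.b1, config.b2, config.maf_threshold)
        for i in range(dataset.S)
    }

    # ---- pass 2: route ---------------------------------------------------
    for idx, snp_id in enumerate(dataset.snp_ids):
        entry = pass1[idx]
        X = entry["X"]
        group = partition[idx]
        sample_ids = [dataset.sample_ids[j] for j in entry["sample_idx"]]
        if X.shape[0] == 0:
            callset.add_snp(snp_id, [], [], _summarise(snp_id, [], group, "GMM", entry["maf"], None, None))
            continue
        seed_seq = _snp_seed(config.seed, idx)
        rng = np.random.default_rng(seed_seq.spawn(1)[0])
        try:
            if group == "g1" and entry["calls"] is not None:
                calls = entry["calls"]
                pr = posterior_rate(entry["fit"])
                assigned = np.array([c.genotype != NO_CALL for c in calls])
                summary = _summarise(snp_id, calls, group, "GMM", entry["maf"], pr, assigned)
            elif group == "g2":
                fit = fit_dp_gmm(
                    X,
                    n_iter=config.dp_n_iter,
                    burn_in=config.dp_burn_in,
                    thin=config.dp_thin,
                    seed=rng,
                )
                calls = dp_calls_to_genotypes(fit, config.pr_threshold)
                assigned = np.array([c.genotype != NO_CALL for c in calls])
                summary = _summarise(snp_id, calls, group, "DP-GMM", entry["maf"], fit.pr, assigned)
            else:  # g3 (and g1 SNPs whose EM failed fall through here)
                calls, model = _call_g3(dataset, idx, maf_table, config, rng)
                pr = np.array([c.pr for c in calls])
                assigned = np.array([c.genotype != NO_CALL for c in calls])
                summary = _summarise(snp_id, calls, group, model, entry["maf"], pr, assigned)
        except Exception as exc:  # containment: never abort the panel
            logger.warning("SNP %s: calling failed (%s); all-NC", snp_id, exc)
            model = {"g1": "GMM", "g2": "DP-GMM", "g3": "DP-Ref"}[group]
            calls = _all_nc(X.shape[0], model)
            summary = _summarise(snp_id, calls, group, model, entry["maf"], None, None)
        callset.add_snp(snp_id, sample_ids, calls, summary)
    return callset


def _find_reference(dataset, t_index, maf_table, config, direction: str):
    """R1 + R2 screens in one direction ('before' or 'after' the T-SNP)."""
    if direction == "before":
        r1 = select_r1(t_index, maf_table, dataset.snp_ids, config.ref_maf, config.max_candidates)
    else:
        # mirrored search: successors in nearest-first order
        r1 = []
        for j in range(t_index + 1, dataset.S):
            maf = maf_table[j]
            if maf is not None and not np.isnan(maf) and maf > config.ref_maf:
                r1.append(j)
                if len(r1) >= config.max_candidates:
                    break
        if not r1:
            raise ReferenceUnavailableError("no R1 candidate after the T-SNP")
    return select_r2(r1, dataset, maf_table, config.ref_min_prop)


def _call_g3(dataset, t_index, maf_table, config, rng):
    """Reference-assisted call of one g3 SNP, with the configured fallbacks."""
    X, _ = dataset.snp_data(t_index)
    t_rough = rough_cluster_by_contrast(X)
    cand = None
    try:
        r2 = _find_reference(dataset, t_index, maf_table, config, "before")
        cand = select_reference(t_rough, t_index, r2)
    except ReferenceUnavailableError:
        if config.fallback_policy == "search-after":
            try:
                r2 = _find_reference(dataset, t_index, maf_table, config, "after")
                cand = select_reference(t_rough, t_index, r2)
            except ReferenceUnavailableError:
                cand = None
    if cand is None:
        logger.warning(
            "SNP %s: no reference candidate; falling back to plain DP-GMM",
            dataset.snp_ids[t_index],
        )
        fit = fit_dp_gmm(
            X, n_iter=config.dp_n_iter, burn_in=config.dp_burn_in,
            thin=config.dp_thin, seed=rng,
        )
        return dp_calls_to_genotypes(fit, config.pr_threshold), "DP-GMM"
    r_data, _ = dataset.snp_data(cand.position)
    calls = call_with_reference(
        X,
        r_data,
        pr_threshold=config.pr_threshold,
        n_iter=config.dp_n_iter,
        burn_in=config.dp_burn_in,
        seed=rng,
    )
    return calls, "DP-Ref"
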