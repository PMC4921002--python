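"""Evaluation metrics: call rate, concordance, accuracy, HWE testing.

Call rate is the fraction of observed cells that received a genotype;
concordance compares two call sets over cells both called; accuracy is
concordance against a truth table.  The Hardy–Weinberg test is the
1-df chi-square goodness of fit of genotype counts against the
expectations (1-q)^2, 2q(1-q), q^2 from the estimated allele frequency,
run separately per population; a SNP fails at p below alpha (default
1e-4).  Monomorphic SNPs fit HWE exactly and pass with statistic 0.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import chi2

from .core import GENOTYPES, NO_CALL, GenotypeCallSet, ValidationError


def call_rate(callset: GenotypeCallSet | dict) -> float:
    """Percentage of observed cells with a non-NC genotype."""
    calls = callset.calls if isinstance(callset, GenotypeCallSet) else callset
    if not calls:
        raise ValidationError("empty callset")
    n = len(calls)
    called = sum(1 for c in calls.values() if c.genotype != NO_CALL)
    return 100.0 * called / n


def concordance(calls_a, calls_b) -> float:
    """Percentage agreement over cells called (non-NC) by both sets.

    NaN when no cell is jointly called.  Symmetric in its arguments.
    """
    a = calls_a.calls if isinstance(calls_a, GenotypeCallSet) else calls_a
    b = calls_b.calls if isinstance(calls_b, GenotypeCallSet) else calls_b
    joint = agree = 0
    for key, ca in a.items():
        cb = b.get(key)
        if cb is None or ca.genotype == NO_CALL or cb.genotype == NO_CALL:
            continue
        joint += 1
        agree += ca.genotype == cb.genotype
    if joint == 0:
        return float("nan")
    return 100.0 * agree / joint


def accuracy(callset, truth: dict[tuple[str, str], str]) -> float:
    """Percentage of non-NC calls matching the truth genotype.

    ``truth`` maps (SNP, Sample) to a genotype string; cells without
    truth are ignored.  NaN when no called cell is truth-covered.
    """
    calls = callset.calls if isinstance(callset, GenotypeCallSet) else callset
    joint = agree = 0
    for key, c in calls.items():
        t = truth.get(key)
        if t is None or c.genotype == NO_CALL:
            continue
        joint += 1
        agree += c.genotype == t
    if joint == 0:
        return float("nan")
    return 100.0 * agree / joint


def hwe_chi_square(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """1-df chi-square HWE statistic and p-value from genotype counts.

    Allele frequency is estimated by counting; expected counts follow
    (1-q)^2 / 2q(1-q) / q^2.  Monomorphic counts give statistic 0 and
    p = 1 by definition.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 0.0, 1.0
    q = (2 * n_bb + n_ab) / (2.0 * n)  # B-allele frequency
    if q == 0.0 or q == 1.0:
        return 0.0, 1.0
    exp = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * n
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return stat, float(chi2.sf(stat, df=1))


def hwe_test(
    genotypes: dict[str, str],
    populations: dict[str, str] | None,
    alpha: float = 1e-4,
    min_samples: int = 5,
) -> dict[str, dict]:
    """Per-population HWE test for one SNP's calls.

    ``genotypes`` maps sample id to a call; NC calls are excluded.
    Populations with fewer than ``min_samples`` called samples are
    skipped with a warning.  Returns, per population, the genotype
    counts, statistic, p-value and the fail flag (p < alpha).
    """
    if populations is None:
        warnings.warn("no population labels; HWE test skipped")
        return {}
    by_pop: dict[str, list[str]] = {}
    for samp, g in genotypes.items():
        if g == NO_CALL:
            continue
        pop = populations.get(samp)
        if pop is not None:
            by_pop.setdefault(pop, []).append(g)
    out = {}
    for pop, gs in sorted(by_pop.items()):
        if len(gs) < min_samples:
            warnings.warn(f"population {pop!r} has {len(gs)} called samples; HWE skipped")
            continue
        counts = [gs.count(g) for g in GENOTYPES]
        stat, p = hwe_chi_square(*counts)
        out[pop] = {
            "counts": tuple(counts),
            "statistic": stat,
            "p_value": p,
            "fail": p < alpha,
        }
    return out


def hwe_failure_counts(
    callset: GenotypeCallSet,
    populations: dict[str, str] | None,
    alpha: float = 1e-4,
) -> dict[str, int]:
    """Number of SNPs failing HWE in each population across a call set."""
    if populations is None:
        warnings.warn("no population labels; HWE test skipped")
        return {}
    per_snp: dict[str, dict[str, str]] = {}
    for (snp, samp), c in callset.calls.items():
        per_snp.setdefault(snp, {})[samp] = c.genotype
    fails: dict[str, int] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for snp, genos in per_snp.items():
            for pop, res in hwe_test(genos, populations, alpha).items():
                fails.setdefault(pop, 0)
                fails[pop] += int(res["fail"])
    return fails
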