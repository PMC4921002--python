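"""Synthetic two-channel SNP-array intensity generator with ground truth.

Each simulated SNP draws genotypes from Hardy–Weinberg proportions
((1-q)^2, 2q(1-q), q^2) at its minor-allele frequency q, places the
three genotype clusters by (contrast, total intensity) geometry —
AA at contrast +0.8, AB at 0, BB at -0.8, total intensity 2000 by
default — and adds independent per-channel Gaussian noise.  A
configurable fraction of samples is replaced by uniform draws over the
intensity bounding box to mimic abnormal ("null") measurements; those
rows are flagged in the truth table.  Intensities are truncated at
zero after noise, since raw intensities are non-negative.

The generator is what the calling models assume and nothing more: it
produces no probe-level replicates, batch effects, or allele-specific
cross-talk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GENOTYPES, IntensityDataset, ValidationError

DEFAULT_CONTRAST = (0.8, 0.0, -0.8)  # AA, AB, BB
DEFAULT_TOTAL = 2000.0


@dataclass(frozen=True)
class SnpSimSpec:
    """Generating parameters for one simulated SNP.

    ``maf`` is the B-allele frequency in [0, 0.5] (BB is the minor
    homozygote); ``cluster_contrast`` and ``total_intensity`` fix the
    cluster means via r = T(1+y)/2, g = T(1-y)/2; ``noise_sd`` is the
    per-channel Gaussian standard deviation (adjacent clusters are
    separated by |Delta y| * T / sqrt(2) / noise_sd noise units);
    ``outlier_frac`` of samples are replaced by box-uniform outliers.
    """

    snp_id: str
    maf: float
    n: int
    cluster_contrast: tuple[float, float, float] = DEFAULT_CONTRAST
    total_intensity: float = DEFAULT_TOTAL
    noise_sd: float = 100.0
    outlier_frac: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 0.5):
            raise ValidationError("maf must be in [0, 0.5]")
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not (0.0 <= self.outlier_frac < 1.0):
            raise ValidationError("outlier_frac must be in [0, 1)")
        if self.total_intensity <= 0:
            raise ValidationError("total_intensity must be positive")

    def cluster_means(self) -> np.ndarray:
        """(3, 2) array of (r, g) cluster means for AA, AB, BB."""
        T = self.total_intensity
        return np.array(
            [[T * (1 + y) / 2.0, T * (1 - y) / 2.0] for y in self.cluster_contrast]
        )


def hwe_frequencies(maf: float) -> np.ndarray:
    """Genotype frequencies (AA, AB, BB) under HWE at B-allele frequency maf."""
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def simulate_snp(
    spec: SnpSimSpec, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate one SNP: (n, 2) intensities plus per-sample truth rows.

    Genotype counts are multinomial draws from the HWE frequencies;
    each sample's intensity is its genotype-cluster mean plus isotropic
    Gaussian channel noise, truncated at zero.  Outlier rows are
    overwritten with uniform draws on [0, 1.5 * total_intensity]^2.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = hwe_frequencies(spec.maf)
    geno_idx = rng.choice(3, size=spec.n, p=freqs)
    means = spec.cluster_means()
    X = means[geno_idx] + rng.normal(scale=spec.noise_sd, size=(spec.n, 2))
    outliers = rng.random(spec.n) < spec.outlier_frac
    n_out = int(outliers.sum())
    if n_out:
        X[outliers] = rng.uniform(0.0, 1.5 * spec.total_intensity, size=(n_out, 2))
    np.clip(X, 0.0, None, out=X)
    truth = pd.DataFrame(
        {
            "SNP": spec.snp_id,
            "Sample": [f"S{i:04d}" for i in range(spec.n)],
            "Genotype": [GENOTYPES[k] for k in geno_idx],
            "Outlier": outliers,
        }
    )
    return X, truth


def simulate_panel(
    specs: list[SnpSimSpec],
    populations: dict[str, str] | list[str] | None = None,
    seed: int = 0,
) -> tuple[IntensityDataset, pd.DataFrame]:
    """Simulate a panel of SNPs sharing one sample set.

    All specs must share ``n``; SNP order follows spec order, which
    defines the "before the T-SNP" structure for reference search (put
    common SNPs first so rare SNPs have reference candidates).
    ``populations`` may be a per-sample list cycled over sample ids.
    Per-SNP randomness comes from independent spawned seeds, so the
    panel is reproducible as a whole.
    """
    if not specs:
        raise ValidationError("no SNP specs")
    n = specs[0].n
    if any(s.n != n for s in specs):
        raise ValidationError("all specs must share the same sample count")
    ids = [s.snp_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate SNP ids in specs")
    sample_ids = [f"S{i:04d}" for i in range(n)]
    child_seeds = np.random.SeedSequence(seed).spawn(len(specs))
    r = np.empty((len(specs), n))
    g = np.empty((len(specs), n))
    truth_parts = []
    for i, (spec, ss) in enumerate(zip(specs, child_seeds)):
        X, truth = simulate_snp(spec, np.random.default_rng(ss))
        r[i], g[i] = X[:, 0], X[:, 1]
        truth_parts.append(truth)
    pops = None
    if populations is not None:
        if isinstance(populations, dict):
            pops = populations
        else:
            pops = {s: populations[i % len(populations)] for i, s in enumerate(sample_ids)}
    dataset = IntensityDataset(ids, sample_ids, r, g, pops)
    return dataset, pd.concat(truth_parts, ignore_index=True)


def make_rare_snp_fixture(
    kind: str,
    seed: int = 0,
    n: int = 300,
    noise_sd: float = 100.0,
    minor_size: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """A single rare SNP with an exact minor-cluster size.

    ``g2-like`` places 3-9 samples in the heterozygote cluster,
    ``g3-like`` 0-2, and ``monomorphic`` none — the three regimes where
    clusters disappear or hold very few observations.  The realised
    minor count is drawn (or forced via ``minor_size``) and encoded
    exactly in the truth table.
    """
    rng = np.random.default_rng(seed)
    if kind == "g2-like":
        m = int(rng.integers(3, 10)) if minor_size is None else int(minor_size)
        if not 3 <= m < 10:
            raise ValidationError("g2-like minor size must be in [3, 10)")
    elif kind == "g3-like":
        m = int(rng.integers(0, 3)) if minor_size is None else int(minor_size)
        if not 0 <= m < 3:
            raise ValidationError("g3-like minor size must be in [0, 3)")
    elif kind == "monomorphic":
        m = 0
    else:
        raise ValidationError(f"unknown fixture kind {kind!r}")
    geno_idx = np.zeros(n, dtype=int)
    if m:
        geno_idx[rng.choice(n, size=m, replace=False)] = 1  # heterozygotes
    spec = SnpSimSpec(
        snp_id=f"sim_{kind}", maf=0.0, n=n, noise_sd=noise_sd, outlier_frac=0.0
    )
    means = spec.cluster_means()
    X = means[geno_idx] + rng.normal(scale=noise_sd, size=(n, 2))
    np.clip(X, 0.0, None, out=X)
    truth = pd.DataFrame(
        {
            "SNP": spec.snp_id,
            "Sample": [f"S{i:04d}" for i in range(n)],
            "Genotype": [GENOTYPES[k] for k in geno_idx],
            "Outlier": False,
        }
    )
    return X, truth


def default_panel_specs(
    n_samples: int = 300,
    n_common: int = 70,
    n_low: int = 20,
    n_rare: int = 10,
    common_maf: float = 0.3,
    low_maf: float = 0.03,
    rare_maf: float = 0.005,
    noise_sd: float = 100.0,
    outlier_frac: float = 0.01,
) -> list[SnpSimSpec]:
    """The standard desk-scale mixed panel: common SNPs first, then rare.

    MAF spectrum 0.3 x 70, 0.03 x 20, 0.005 x 10 over 300 samples with
    1 % outlier contamination — small enough to run in minutes while
    exercising all three routing groups.
    """
    specs = []
    for i in range(n_common):
        specs.append(
            SnpSimSpec(f"common{i:03d}", common_maf, n_samples, noise_sd=noise_sd, outlier_frac=outlier_frac)
        )
    for i in range(n_low):
        specs.append(
            SnpSimSpec(f"low{i:03d}", low_maf, n_samples, noise_sd=noise_sd, outlier_frac=outlier_frac)
        )
    for i in range(n_rare):
        specs.append(
            SnpSimSpec(f"rare{i:03d}", rare_maf, n_samples, noise_sd=noise_sd, outlier_frac=outlier_frac)
        )
    return specs


def truth_mapping(truth: pd.DataFrame) -> dict[tuple[str, str], str]:
    """Truth table rows as a (SNP, Sample) -> genotype mapping."""
    return {
        (row.SNP, row.Sample): row.Genotype for row in truth.itertuples(index=False)
    }
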