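"""Core domain types and text I/O for two-channel SNP-array intensity data.

The basic measurement is a pair of raw fluorescence intensities
``(r, g)`` per sample per SNP — ``r`` for the A-allele channel and ``g``
for the B-allele channel.  Datasets arrive as long-form TSV
(``SNP  Sample  r  g  [Population]``), which mirrors Illumina final-report
exports and represents missing cells naturally (an absent row).

SNP order is significant: it is the array order used when searching for
reference SNPs "before" a hard-to-call SNP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("AA", "AB", "BB")
NO_CALL = "NC"
MODELS = ("GMM", "DP-GMM", "DP-Ref")


class MDCallError(Exception):
    """Base class for errors raised by this package."""


class ParseError(MDCallError):
    """A malformed input file row."""


class ValidationError(MDCallError):
    """Input violates a domain invariant (negative intensity, duplicates...)."""


class DegenerateDataError(MDCallError):
    """Data too degenerate for the requested fit (e.g. all points identical)."""


class ReferenceUnavailableError(MDCallError):
    """No eligible reference SNP exists for a target SNP."""


@dataclass(frozen=True)
class IntensityPair:
    """One two-channel raw intensity measurement.

    Both channels are non-negative and finite; units are arbitrary
    fluorescence units and are used raw (no normalisation step).
    """

    r: float
    g: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.r) and math.isfinite(self.g)):
            raise ValidationError(f"non-finite intensity pair ({self.r}, {self.g})")
        if self.r < 0 or self.g < 0:
            raise ValidationError(f"negative intensity pair ({self.r}, {self.g})")


def compute_contrast(x: "IntensityPair | tuple[float, float]") -> float:
    """Contrast projection ``y = (r - g) / (r + g)`` in ``[-1, 1]``.

    The contrast separates the three genotype clusters along one axis:
    AA sits at high ``y``, BB at low ``y``, AB near zero.  Antisymmetric
    under swapping the two channels.

    Raises
    ------
    DegenerateDataError
        If ``r + g == 0`` (the point carries no signal; callers must
        treat it as missing / no-call).
    """
    r, g = (x.r, x.g) if isinstance(x, IntensityPair) else (float(x[0]), float(x[1]))
    tot = r + g
    if tot == 0:
        raise DegenerateDataError("contrast undefined for r + g = 0")
    return (r - g) / tot


def contrast_array(xy: np.ndarray) -> np.ndarray:
    """Vectorised contrast for an ``(n, 2)`` array; ``r + g = 0`` rows yield NaN."""
    xy = np.asarray(xy, dtype=float)
    tot = xy[:, 0] + xy[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        y = (xy[:, 0] - xy[:, 1]) / tot
    y[tot == 0] = np.nan
    return y


class IntensityDataset:
    """Samples x SNPs grid of two-channel intensities with stable SNP order.

    Internally stores two ``(S, N)`` float arrays (``r`` and ``g``) with
    NaN marking missing cells, plus optional per-sample population labels.
    """

    def __init__(
        self,
        snp_ids: Sequence[str],
        sample_ids: Sequence[str],
        r: np.ndarray,
        g: np.ndarray,
        populations: Mapping[str, str] | None = None,
    ) -> None:
        snp_ids = list(snp_ids)
        sample_ids = list(sample_ids)
        if len(set(snp_ids)) != len(snp_ids):
            raise ValidationError("duplicate SNP ids")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample ids")
        r = np.asarray(r, dtype=float)
        g = np.asarray(g, dtype=float)
        if r.shape != (len(snp_ids), len(sample_ids)) or g.shape != r.shape:
            raise ValidationError("intensity array shape mismatch")
        if np.any(r[np.isfinite(r)] < 0) or np.any(g[np.isfinite(g)] < 0):
            raise ValidationError("negative intensities")
        if np.any(np.isinf(r)) or np.any(np.isinf(g)):
            raise ValidationError("infinite intensities")
        if not np.array_equal(np.isnan(r), np.isnan(g)):
            raise ValidationError("r/g missingness masks disagree")
        self.snp_ids = snp_ids
        self.sample_ids = sample_ids
        self.r = r
        self.g = g
        self.populations = dict(populations) if populations is not None else None
        self._snp_index = {s: i for i, s in enumerate(snp_ids)}
        self._sample_index = {s: i for i, s in enumerate(sample_ids)}

    # -- basic shape ------------------------------------------------------
    @property
    def S(self) -> int:
        """Total number of SNPs."""
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def observed(self) -> np.ndarray:
        """Boolean ``(S, N)`` mask of observed cells."""
        return ~np.isnan(self.r)

    def n_obs(self, snp: str | int) -> int:
        """Number of samples observed at one SNP (``n_s``)."""
        i = snp if isinstance(snp, int) else self._snp_index[snp]
        return int(self.observed[i].sum())

    def snp_index(self, snp_id: str) -> int:
        return self._snp_index[snp_id]

    def snp_data(self, snp: str | int) -> tuple[np.ndarray, np.ndarray]:
        """Observed ``(n_s, 2)`` intensity rows and their sample indices."""
        i = snp if isinstance(snp, int) else self._snp_index[snp]
        mask = self.observed[i]
        idx = np.flatnonzero(mask)
        xy = np.column_stack([self.r[i, idx], self.g[i, idx]])
        return xy, idx

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, snp in enumerate(self.snp_ids):
            mask = self.observed[i]
            for j in np.flatnonzero(mask):
                rows.append((snp, self.sample_ids[j], self.r[i, j], self.g[i, j]))
        df = pd.DataFrame(rows, columns=["SNP", "Sample", "r", "g"])
        if self.populations is not None:
            df["Population"] = df["Sample"].map(self.populations)
        return df


def read_intensities(path, fmt: str = "tsv") -> IntensityDataset:
    """Read a long-form intensity TSV into an :class:`IntensityDataset`.

    Required header columns: ``SNP``, ``Sample``, ``r``, ``g``; optional
    ``Population``.  SNP and sample order follow first appearance in the
    file.  Duplicate ``(SNP, Sample)`` rows and negative or non-finite
    intensities are rejected with the offending line number.
    """
    if fmt != "tsv":
        raise ValidationError(f"unknown intensity format {fmt!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"SNP", "Sample", "r", "g"}
    if not required.issubset(df.columns):
        raise ParseError(f"missing required columns {sorted(required - set(df.columns))}")
    # line number = dataframe index + 2 (1-based, after the header)
    for col in ("r", "g"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise ParseError(f"line {bad[0] + 2}: non-numeric {col!r} value {df.loc[bad[0], col]!r}")
        if np.any(np.isinf(vals.to_numpy())):
            line = vals.index[np.isinf(vals.to_numpy())][0]
            raise ParseError(f"line {line + 2}: non-finite {col!r} value")
        neg = vals.index[vals < 0]
        if len(neg):
            raise ValidationError(f"line {neg[0] + 2}: negative {col!r} value {vals[neg[0]]}")
        df[col] = vals
    dup = df.duplicated(subset=["SNP", "Sample"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValidationError(f"line {line}: duplicate (SNP, Sample) cell")

    snp_ids = list(dict.fromkeys(df["SNP"]))
    sample_ids = list(dict.fromkeys(df["Sample"]))
    S, N = len(snp_ids), len(sample_ids)
    r = np.full((S, N), np.nan)
    g = np.full((S, N), np.nan)
    si = {s: i for i, s in enumerate(snp_ids)}
    pi = {s: i for i, s in enumerate(sample_ids)}
    r[[si[s] for s in df["SNP"]], [pi[s] for s in df["Sample"]]] = df["r"].to_numpy()
    g[[si[s] for s in df["SNP"]], [pi[s] for s in df["Sample"]]] = df["g"].to_numpy()

    populations = None
    if "Population" in df.columns:
        pop = df.drop_duplicates(subset="Sample").set_index("Sample")["Population"]
        if (pop != "").any():
            populations = pop.to_dict()
    return IntensityDataset(snp_ids, sample_ids, r, g, populations)


def write_intensities(dataset: IntensityDataset, path) -> None:
    """Write the long-form intensity TSV (inverse of :func:`read_intensities`)."""
    dataset.to_long().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass(frozen=True)
class GenotypeCall:
    """One genotype call with its Posterior Rate quality score.

    ``genotype`` is NC when the posterior falls below the no-call
    threshold or the cell is missing; ``pr`` is the posterior probability
    of the assigned cluster.
    """

    genotype: str
    pr: float
    model_used: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES + (NO_CALL,):
            raise ValidationError(f"unknown genotype {self.genotype!r}")
        if not (np.isnan(self.pr) or 0.0 <= self.pr <= 1.0):
            raise ValidationError(f"PR out of [0,1]: {self.pr}")


@dataclass
class SnpSummary:
    """Per-SNP record: quality, estimated MAF, routing group, cluster sizes."""

    snp_id: str
    apr: float  # NaN when no sample was assigned
    maf: float  # NaN when no sample was called
    group: str  # g1 / g2 / g3
    model: str
    n_ks: tuple[int, int, int]  # called cluster sizes for AA, AB, BB
    n_nc: int


class GenotypeCallSet:
    """Per-(SNP, sample) calls plus per-SNP summary records."""

    def __init__(self) -> None:
        self.calls: dict[tuple[str, str], GenotypeCall] = {}
        self.snp_summary: dict[str, SnpSummary] = {}

    def add_snp(
        self,
        snp_id: str,
        sample_ids: Iterable[str],
        calls: Iterable[GenotypeCall],
        summary: SnpSummary,
    ) -> None:
        for samp, call in zip(sample_ids, calls, strict=True):
            self.calls[(snp_id, samp)] = call
        self.snp_summary[snp_id] = summary

    def __len__(self) -> int:
        return len(self.calls)

    def calls_frame(self) -> pd.DataFrame:
        rows = [
            (snp, samp, c.genotype, c.pr, c.model_used)
            for (snp, samp), c in self.calls.items()
        ]
        return pd.DataFrame(rows, columns=["SNP", "Sample", "Genotype", "PR", "Model"])

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            (s.snp_id, s.apr, s.maf, s.group, s.model, *s.n_ks, s.n_nc)
            for s in self.snp_summary.values()
        ]
        return pd.DataFrame(
            rows,
            columns=["SNP", "APR", "MAF", "Group", "Model", "n_AA", "n_AB", "n_BB", "n_NC"],
        )


def write_calls(callset: GenotypeCallSet, path) -> None:
    """Write calls as TSV (SNP, Sample, Genotype, PR, Model); PR at 8 sig. digits."""
    if not len(callset):
        raise ValidationError("empty callset")
    callset.calls_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_calls(path) -> GenotypeCallSet:
    """Read a calls TSV written by :func:`write_calls` (summary not restored)."""
    df = pd.read_csv(path, sep="\t")
    cs = GenotypeCallSet()
    for row in df.itertuples(index=False):
        cs.calls[(str(row.SNP), str(row.Sample))] = GenotypeCall(
            row.Genotype, float(row.PR), row.Model
        )
    return cs


def write_snp_summary(callset: GenotypeCallSet, path) -> None:
    """Write the per-SNP summary TSV; NaN MAF/APR serialised as ``NA``."""
    df = callset.summary_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.8g", na_rep="NA")


def read_snp_summary(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
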