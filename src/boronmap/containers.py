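"""Shared in-memory containers for genotypes, depth profiles and junctions.

Tabular data (phenotypes, BLUEs, association results, window tables) travel
as pandas DataFrames with documented column contracts; the structured objects
below carry the non-tabular state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # integer sentinel for a missing haploid call

#: column contract for ionome phenotype tables
IONOME_COLUMNS = ["sample_id", "accession", "block", "replicate", "B", "Cr", "Ti"]


@dataclass
class GenotypeMatrix:
    """Samples x variants haploid call matrix with per-call DP/GQ.

    Inbred lines are represented by a single haplotype each, so calls are
    coded 0 (reference) / 1 (alternate) / ``MISSING``.

    Attributes
    ----------
    samples : list of str
        Sample identifiers, one per inbred accession.
    variants : pandas.DataFrame
        One row per variant with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt`` and a string ``id`` (``chrom:pos``).
    calls : ndarray of int8, shape (n_samples, n_variants)
        Haploid calls in {0, 1, MISSING}.
    dp : ndarray of int32, shape (n_samples, n_variants)
        Per-call read depth.
    gq : ndarray of int32, shape (n_samples, n_variants)
        Per-call phred-scaled genotype quality.
    """

    samples: list
    variants: pd.DataFrame
    calls: np.ndarray
    dp: np.ndarray
    gq: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.dp = np.asarray(self.dp, dtype=np.int32)
        self.gq = np.asarray(self.gq, dtype=np.int32)
        n, p = self.calls.shape
        if n != len(self.samples):
            raise ValueError("calls rows must match number of samples")
        if p != len(self.variants):
            raise ValueError("calls columns must match number of variants")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise ValueError("calls must be 0, 1 or MISSING")
        # positions strictly increasing within each chromosome
        for _, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("variant positions must be strictly "
                                 "increasing within a chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> np.ndarray:
        return self.variants["id"].to_numpy()

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing calls."""
        obs = self.calls != MISSING
        alt = np.where(self.calls == 1, 1, 0)
        with np.errstate(invalid="ignore"):
            return alt.sum(axis=0) / obs.sum(axis=0)

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def dosage(self, impute: bool = True) -> np.ndarray:
        """Float call matrix with missing entries NaN or mean-imputed."""
        x = self.calls.astype(float)
        x[self.calls == MISSING] = np.nan
        if impute:
            col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(x))
            x[idx] = col_mean[idx[1]]
        return x

    def subset_samples(self, keep_samples) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in keep_samples]
        return GenotypeMatrix(
            samples=list(keep_samples),
            variants=self.variants.copy(),
            calls=self.calls[idx, :],
            dp=self.dp[idx, :],
            gq=self.gq[idx, :],
        )

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[keep].reset_index(drop=True),
            calls=self.calls[:, keep],
            dp=self.dp[:, keep],
            gq=self.gq[:, keep],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.variants.reset_index(drop=True).equals(
                other.variants.reset_index(drop=True))
            and np.array_equal(self.calls, other.calls)
            and np.array_equal(self.dp, other.dp)
            and np.array_equal(self.gq, other.gq)
        )


@dataclass
class DepthProfile:
    """Per-base read depth over a genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    depth: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if self.end - self.start != len(self.depth):
            raise ValueError("depth length must equal end - start")
        if np.any(self.depth < 0):
            raise ValueError("depths must be non-negative")

    def __len__(self) -> int:
        return len(self.depth)


@dataclass(frozen=True)
class JunctionCall:
    """Classification of a tandem-duplication breakpoint junction.

    ``blunt`` junctions join the two copies directly; ``microhomology``
    junctions share an identical motif at both breakpoint ends (a signature
    of microhomology-mediated repair); ``insertion`` junctions carry novel
    untemplated sequence between the copies.
    """

    type: str
    length: int
    sequence: str

    def __post_init__(self):
        if self.type not in ("blunt", "microhomology", "insertion"):
            raise ValueError(f"unknown junction type {self.type!r}")
        if self.type == "blunt":
            if self.length != 0 or self.sequence != "":
                raise ValueError("blunt junction must have length 0 and "
                                 "empty sequence")
        else:
            if self.length != len(self.sequence) or self.length < 1:
                raise ValueError("junction length must equal sequence length "
                                 "and be >= 1")


@dataclass
class CnCall:
    """Copy-number call for a candidate duplication region."""

    region: tuple
    window_ratios: list
    median_ratio: float
    cn: int


@dataclass
class TruthRecord:
    """Ground truth attached to a synthetic dataset.

    causal_snps maps variant id -> per-allele effect (µg/g DW);
    causal_td is (start, end, carrier sample ids, per-extra-copy effect).
    """

    seed: int
    subpop_labels: dict
    causal_snps: dict = field(default_factory=dict)
    causal_td: tuple | None = None
    true_h2: float = 0.0
    junction_truth: JunctionCall | None = None

    def __post_init__(self):
        if not (0.0 <= self.true_h2 <= 1.0):
            raise ValueError("true_h2 must lie in [0, 1]")
        if self.causal_td is not None:
            start, end, carriers, _ = self.causal_td
            if not start < end:
                raise ValueError("causal TD region start must precede end")
            unknown = set(carriers) - set(self.subpop_labels)
            if unknown:
                raise ValueError(f"TD carriers not among samples: {unknown}")
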