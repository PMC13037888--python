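"""Synthetic island-population generator with full ground truth.

Emulates the statistical structure of a low-diversity, recently bottlenecked
selfing population split across island subpopulations: homozygous (haploid-
coded) genotypes with allele-frequency differentiation between subpopulations,
a replicated randomized-block ionome trait with causal SNP and tandem-
duplication effects, read-depth profiles over a duplicated segment, and
breakpoint junction sequences.  Every generator is a pure function of
(config, seed) and returns the ground truth needed for parameter-recovery
tests downstream.

The population model is a finite-island Balding-Nichols construction: an
island-wide allele frequency is drawn from a neutral site-frequency spectrum
(probability proportional to 1/i for derived count i), then each
subpopulation's frequency is drawn from a Beta distribution centred on it
with spread set by the differentiation parameter F_ST.  When a per-site
Watterson's theta target is supplied, the number of segregating sites is
drawn as Poisson(theta * a_n * L) and every emitted site is guaranteed
polymorphic, so the realized Watterson estimator is unbiased for the target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    DepthProfile,
    GenotypeMatrix,
    JunctionCall,
    TruthRecord,
)

__all__ = [
    "SimulationConfig",
    "JunctionConstruction",
    "simulate_island_population",
    "simulate_trait",
    "simulate_depth_profile",
    "make_junction_sequence",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic island population.

    Parameters
    ----------
    n_samples : int
        Number of inbred accessions (one haplotype each).
    n_variants : int
        Number of variant sites when no diversity target is given.
    n_subpops : int
        Number of island subpopulations; must not exceed n_samples.
    bottleneck_diversity : float or None
        Per-site Watterson's theta target.  When set, the site count is
        Poisson(theta * a_n * region_length); 0 produces only monomorphic
        sites.  None keeps n_variants fixed.
    region_length : int
        Length in bp of the simulated region.
    fst : float
        Balding-Nichols differentiation between subpopulations.
    maf_floor : float
        Minimum realized minor-allele frequency per emitted variant.
    n_blocks, n_reps : int
        Randomized-block trait design: every accession is grown in each
        block with n_reps replicates (default four plants per accession).
    depth_mean : float
        Mean per-call sequencing depth (reads).
    depth_dispersion : float
        Negative-binomial overdispersion of depth; 0 degenerates to Poisson.
    contamination_rate : float
        Fraction of plants carrying a joint Cr/Ti soil-contamination outlier.
    missing_rate : float
        Per-call probability of a missing genotype.
    true_h2 : float
        Target broad-sense heritability of the simulated trait.
    n_causal_snps : int
        Number of causal SNPs to designate (among common variants).
    causal_effect : float
        Per-allele effect of each causal SNP, µg/g dry weight.
    causal_maf_min : float
        Minimum MAF required of a designated causal variant.
    td_effect : float
        Per-extra-copy effect of a causal tandem duplication (0 disables it).
    td_carrier_frac : float
        Fraction of samples carrying the duplication; carriers are private
        to a single subpopulation, mirroring island TD haplotypes.
    td_region : (int, int)
        Duplicated span in bp within the region.
    trait_intercept : float
        Baseline leaf B in µg/g dry weight.
    block_var_share : float
        Share of the non-genetic variance attributable to block effects.
    baseline_env_sd : float
        Residual SD (µg/g) used when true_h2 = 0 leaves the ratio undefined.
    chrom : str
        Chromosome label for emitted variants.
    """

    n_samples: int = 150
    n_variants: int = 500
    n_subpops: int = 2
    bottleneck_diversity: float | None = None
    region_length: int = 100_000
    fst: float = 0.3
    maf_floor: float = 0.0
    n_blocks: int = 4
    n_reps: int = 1
    depth_mean: float = 30.0
    depth_dispersion: float = 0.0
    contamination_rate: float = 0.02
    missing_rate: float = 0.02
    true_h2: float = 0.75
    n_causal_snps: int = 1
    causal_effect: float = 11.4
    causal_maf_min: float = 0.2
    td_effect: float = 0.0
    td_carrier_frac: float = 0.1
    td_region: tuple = (40_000, 78_000)
    trait_intercept: float = 40.0
    block_var_share: float = 0.3
    baseline_env_sd: float = 2.0
    chrom: str = "chr2"

    def __post_init__(self):
        for name in ("n_samples", "n_variants", "n_subpops", "n_blocks",
                     "n_reps", "region_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("maf_floor", "fst", "contamination_rate", "missing_rate",
                     "true_h2", "td_carrier_frac", "block_var_share"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_subpops > self.n_samples:
            raise ValueError("n_subpops may not exceed n_samples")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be non-negative")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be non-negative")
        if self.bottleneck_diversity is not None and self.bottleneck_diversity < 0:
            raise ValueError("bottleneck_diversity must be non-negative")


def _child_rngs(seed: int, n: int) -> list:
    """Deterministic child generators derived from one integer seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def _draw_site(rng, n: int, subpop_of: np.ndarray, n_subpops: int,
               fst: float, sfs_probs: np.ndarray, maf_floor: float) -> np.ndarray:
    """One guaranteed-segregating haploid site under the island model."""
    for _ in range(10_000):
        i = rng.choice(np.arange(1, n), p=sfs_probs)
        p0 = i / n
        if fst > 0 and n_subpops > 1:
            a = p0 * (1.0 - fst) / fst
            b = (1.0 - p0) * (1.0 - fst) / fst
            p_sub = rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9),
                             size=n_subpops)
        else:
            p_sub = np.full(n_subpops, p0)
        calls = (rng.random(n) < p_sub[subpop_of]).astype(np.int8)
        count = int(calls.sum())
        if 0 < count < n:
            maf = min(count, n - count) / n
            if maf >= maf_floor:
                return calls
    raise RuntimeError("could not draw a segregating site satisfying the "
                       "MAF floor; lower maf_floor")


def simulate_island_population(config: SimulationConfig, seed: int):
    """Generate structured inbred genotypes plus ground truth.

    Returns
    -------
    (GenotypeMatrix, TruthRecord)
    """
    rng_sites, rng_meta, rng_qual, rng_causal = _child_rngs(seed, 4)
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    subpop_of = np.sort(np.arange(n) % config.n_subpops)
    labels = {s: f"pop{p}" for s, p in zip(samples, subpop_of)}

    # site count: fixed, or Poisson around the Watterson expectation
    if config.bottleneck_diversity is None:
        n_sites = config.n_variants
        monomorphic = False
    elif config.bottleneck_diversity == 0:
        n_sites = config.n_variants
        monomorphic = True
    else:
        expected_s = (config.bottleneck_diversity * _harmonic(n)
                      * config.region_length)
        n_sites = int(rng_sites.poisson(expected_s))
        monomorphic = False

    n_sites = max(n_sites, 0)
    positions = np.sort(rng_meta.choice(
        np.arange(1, config.region_length + 1),
        size=min(n_sites, config.region_length), replace=False))
    n_sites = len(positions)

    if monomorphic or n_sites == 0:
        calls = np.zeros((n, n_sites), dtype=np.int8)
    else:
        i_probs = 1.0 / np.arange(1, n)
        i_probs /= i_probs.sum()
        cols = [
            _draw_site(rng_sites, n, subpop_of, config.n_subpops, config.fst,
                       i_probs, config.maf_floor)
            for _ in range(n_sites)
        ]
        calls = np.column_stack(cols) if cols else np.zeros((n, 0), np.int8)

    ref = rng_meta.choice(_BASES, size=n_sites)
    alt = np.array([rng_meta.choice(_BASES[_BASES != r]) for r in ref]) \
        if n_sites else np.array([], dtype=str)
    variants = pd.DataFrame({
        "chrom": config.chrom,
        "pos": positions.astype(int),
        "ref": ref,
        "alt": alt,
    })
    variants["id"] = [f"{config.chrom}:{p}" for p in variants["pos"]]

    dp = rng_qual.poisson(config.depth_mean, size=calls.shape).astype(np.int32)
    gq = np.where(rng_qual.random(calls.shape) < 0.97, 99,
                  rng_qual.integers(5, 41, size=calls.shape)).astype(np.int32)
    if config.missing_rate > 0 and calls.size:
        miss = rng_qual.random(calls.shape) < config.missing_rate
        calls = calls.copy()
        calls[miss] = MISSING
        dp[miss] = 0
        gq[miss] = 0

    g = GenotypeMatrix(samples=samples, variants=variants,
                       calls=calls, dp=dp, gq=gq)

    # designate causal variants among sufficiently common sites
    causal_snps: dict = {}
    if not monomorphic and config.n_causal_snps > 0 and n_sites > 0:
        maf = g.maf()
        eligible = np.flatnonzero(maf >= config.causal_maf_min)
        if len(eligible) == 0:
            eligible = np.array([int(np.argmax(maf))])
        pick = rng_causal.choice(
            eligible, size=min(config.n_causal_snps, len(eligible)),
            replace=False)
        for j in pick:
            causal_snps[variants["id"].iloc[int(j)]] = config.causal_effect

    causal_td = None
    if config.td_effect != 0:
        home = int(rng_causal.integers(config.n_subpops))
        pool = [s for s, p in zip(samples, subpop_of) if p == home]
        k = max(1, round(config.td_carrier_frac * n))
        k = min(k, len(pool))
        carriers = sorted(str(s) for s in
                          rng_causal.choice(pool, size=k, replace=False))
        causal_td = (config.td_region[0], config.td_region[1],
                     list(carriers), config.td_effect)

    truth = TruthRecord(seed=seed, subpop_labels=labels,
                        causal_snps=causal_snps, causal_td=causal_td,
                        true_h2=config.true_h2)
    return g, truth


def _genetic_values(g: GenotypeMatrix, truth: TruthRecord) -> np.ndarray:
    ids = list(g.variant_ids())
    values = np.zeros(g.n_samples)
    for vid, effect in truth.causal_snps.items():
        if vid not in ids:
            raise KeyError(f"causal variant {vid!r} absent from genotypes")
        j = ids.index(vid)
        dose = np.where(g.calls[:, j] == 1, 1.0, 0.0)
        values += effect * dose
    if truth.causal_td is not None:
        _, _, carriers, effect = truth.causal_td
        carrier_set = set(carriers)
        values += effect * np.array(
            [1.0 if s in carrier_set else 0.0 for s in g.samples])
    return values


def simulate_trait(g: GenotypeMatrix, truth: TruthRecord,
                   config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Replicated, blocked ionome phenotypes with contamination outliers.

    One row per (accession, block, replicate).  Leaf B is
    intercept + genetic value + block effect + residual; the residual scale
    is set from truth.true_h2 so the realized broad-sense heritability
    matches the target.  Cr and Ti carry joint soil-contamination outliers
    at config.contamination_rate (contaminated plants also show inflated B).
    """
    rng_env, rng_contam = _child_rngs(seed, 2)
    gvals = _genetic_values(g, truth)
    h2 = truth.true_h2
    var_g = float(np.var(gvals))

    if h2 == 0.0:
        gvals = np.zeros_like(gvals)
        env_var = config.baseline_env_sd ** 2
    elif h2 == 1.0:
        env_var = 0.0
    elif var_g == 0.0:
        warnings.warn("no genetic variance; trait is noiseless intercept")
        env_var = 0.0
    else:
        env_var = var_g * (1.0 - h2) / h2

    sd_block = np.sqrt(config.block_var_share * env_var)
    sd_e = np.sqrt((1.0 - config.block_var_share) * env_var)
    block_effects = rng_env.normal(0.0, sd_block, size=config.n_blocks) \
        if sd_block > 0 else np.zeros(config.n_blocks)

    rows = []
    for i, acc in enumerate(g.samples):
        for b in range(config.n_blocks):
            for r in range(config.n_reps):
                resid = rng_env.normal(0.0, sd_e) if sd_e > 0 else 0.0
                bval = (config.trait_intercept + gvals[i]
                        + block_effects[b] + resid)
                cr = abs(rng_env.normal(0.5, 0.1))
                ti = abs(rng_env.normal(2.0, 0.4))
                rows.append([f"{acc}_b{b + 1}_r{r + 1}", acc,
                             f"block{b + 1}", r + 1, bval, cr, ti])
    table = pd.DataFrame(
        rows, columns=["sample_id", "accession", "block", "replicate",
                       "B", "Cr", "Ti"])

    if config.contamination_rate > 0:
        hit = rng_contam.random(len(table)) < config.contamination_rate
        # joint multiplicative Cr/Ti shift far beyond the z=3 filter,
        # plus a soil-borne B inflation so QC matters for the trait
        table.loc[hit, "Cr"] *= 8.0
        table.loc[hit, "Ti"] *= 8.0
        table.loc[hit, "B"] += rng_contam.normal(6.0, 1.0, size=int(hit.sum()))
    table["B"] = table["B"].clip(lower=0.0)
    return table


def simulate_depth_profile(region_length: int, duplication: tuple,
                           depth_mean: float, dispersion: float,
                           seed: int, chrom: str = "chr2") -> DepthProfile:
    """Per-base depth over a region containing a tandem duplication.

    Expected depth is depth_mean * copies inside [start, end) and depth_mean
    outside; counts are negative-binomial with the given overdispersion
    (Poisson when dispersion = 0).
    """
    if depth_mean < 0:
        raise ValueError("depth_mean must be non-negative")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    start, end, copies = duplication
    if not (0 <= start < end <= region_length):
        raise ValueError("duplication must satisfy 0 <= start < end <= "
                         "region_length")
    rng = np.random.default_rng(seed)
    mu = np.full(region_length, float(depth_mean))
    mu[start:end] *= copies
    if dispersion == 0:
        depth = rng.poisson(mu)
    else:
        size = 1.0 / dispersion
        p = size / (size + mu)
        depth = rng.negative_binomial(size, p)
    return DepthProfile(chrom=chrom, start=0, end=region_length,
                        depth=depth.astype(float))


@dataclass
class JunctionConstruction:
    """A constructed duplication junction with its ground truth.

    ``reference`` is the (possibly edited) reference the junction was built
    from; ``edits`` records every (position, old_base, new_base) applied to
    enforce the requested homology structure.
    """

    sequence: str
    truth: JunctionCall
    reference: str
    dup_start: int
    dup_end: int
    flank_len: int
    edits: list = field(default_factory=list)


def _max_homology(ref: list, dup_start: int, dup_end: int, cap: int) -> int:
    """Maximal m with ref[dup_end-m:dup_end] == ref[dup_start:dup_start+m].

    'N' never matches.
    """
    best = 0
    for m in range(1, cap + 1):
        left = ref[dup_end - m:dup_end]
        right = ref[dup_start:dup_start + m]
        if "N" in left or "N" in right:
            continue
        if left == right:
            best = m
    return best


def make_junction_sequence(reference: str, dup_start: int, dup_end: int,
                           junction_type: str, flank_len: int = 150,
                           *, motif=None, insert=None, seed: int = 0):
    """Build a junction-spanning sequence for a tandem duplication.

    Parameters
    ----------
    junction_type : {"blunt", "microhomology", "insertion"}
    motif : str or int, for microhomology
        The shared breakpoint motif, or its length (a random motif is drawn).
        The constructor edits the reference so the motif occupies both
        breakpoint ends and the maximal homology equals exactly len(motif).
    insert : str or int, for insertion
        Novel sequence placed between the copies, or its length.
    flank_len : int
        Reference context kept on each side of the junction.

    Returns
    -------
    JunctionConstruction
    """
    ref = list(reference.upper())
    L = len(ref)
    dup_len = dup_end - dup_start
    if not (0 <= dup_start < dup_end <= L):
        raise ValueError("duplication must lie within the reference")
    if flank_len < 1 or flank_len > dup_len or dup_end - flank_len < 0:
        raise ValueError("flank_len must be >= 1 and fit inside the "
                         "duplicated span")
    rng = np.random.default_rng(seed)

    edits: list = []

    def edit(pos: int, base: str):
        if ref[pos] != base:
            edits.append((pos, ref[pos], base))
            ref[pos] = base

    if junction_type == "microhomology":
        if motif is None:
            raise ValueError("microhomology requires a motif or its length")
        if isinstance(motif, (int, np.integer)):
            motif = "".join(rng.choice(_BASES, size=int(motif)))
        motif = motif.upper()
        k = len(motif)
        if k < 1:
            raise ValueError("microhomology length must be >= 1")
        if 2 * k > dup_len:
            raise ValueError("homology length must not exceed half the "
                             "duplication length")
        for i, base in enumerate(motif):
            edit(dup_start + i, base)
            edit(dup_end - k + i, base)
        target = k
    elif junction_type == "blunt":
        target = 0
    elif junction_type == "insertion":
        if insert is None:
            raise ValueError("insertion requires a sequence or its length")
        if isinstance(insert, (int, np.integer)):
            insert = "".join(rng.choice(_BASES, size=int(insert)))
        insert = insert.upper()
        if len(insert) < 1:
            raise ValueError("insert length must be >= 1")
        target = 0
    else:
        raise ValueError(f"unknown junction type {junction_type!r}")

    # break accidental homology beyond the requested length so the truth is
    # exactly what the classifier should recover
    cap = min(flank_len, dup_len // 2 if junction_type == "microhomology"
              else flank_len)
    cap = min(cap, dup_len)
    for _ in range(200):
        m = _max_homology(ref, dup_start, dup_end, cap)
        if m <= target:
            break
        pos = dup_end - m
        bad = {ref[pos], ref[dup_start]}
        choices = [b for b in "ACGT" if b not in bad]
        edit(pos, choices[int(rng.integers(len(choices)))])
    else:  # pragma: no cover - pathological references only
        raise RuntimeError("could not normalize accidental homology")

    left = "".join(ref[dup_end - flank_len:dup_end])
    if junction_type == "microhomology":
        k = target
        right = "".join(ref[dup_start + k:dup_start + flank_len])
        seq = left + right
        truth = JunctionCall("microhomology", k,
                             "".join(ref[dup_start:dup_start + k]))
    elif junction_type == "blunt":
        seq = left + "".join(ref[dup_start:dup_start + flank_len])
        truth = JunctionCall("blunt", 0, "")
    else:
        seq = left + insert + "".join(ref[dup_start:dup_start + flank_len])
        truth = JunctionCall("insertion", len(insert), insert)

    return JunctionConstruction(sequence=seq, truth=truth,
                                reference="".join(ref), dup_start=dup_start,
                                dup_end=dup_end, flank_len=flank_len,
                                edits=edits)
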