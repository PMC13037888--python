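"""Population-genetic summaries and genealogy-input preprocessing.

Watterson's θ from segregating-site counts, missingness-corrected mutation
rates in sliding windows, outcrossing-scaled recombination maps,
subpopulation haplotype frequencies, and export of haps/sample/map bundles
(SHAPEIT-style, haploid: one haplotype per inbred line) with tandem-
duplication breakpoints inserted as pseudo-variants — the verified input
files for downstream genealogy inference, which itself is out of scope.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

__all__ = [
    "watterson_theta",
    "corrected_mutation_rate",
    "scale_recombination_map",
    "haplotype_frequency_by_subpop",
    "export_genealogy_inputs",
    "read_haps_bundle",
]


def watterson_theta(g: GenotypeMatrix, region_length: int) -> float:
    """Per-site Watterson's θ = S / (a_n · L).

    S counts sites segregating among the sampled haplotypes (both alleles
    observed among non-missing calls); a_n = Σ_{i=1}^{n-1} 1/i with n the
    number of haploid sequences — one per inbred accession.
    """
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    n = g.n_samples
    if n < 2:
        raise ValueError("need at least two haploid sequences")
    obs = g.calls != MISSING
    alt = ((g.calls == 1) & obs).sum(axis=0)
    tot = obs.sum(axis=0)
    segregating = int(np.sum((alt > 0) & (alt < tot)))
    a_n = np.sum(1.0 / np.arange(1, n))
    return float(segregating / (a_n * region_length))


def corrected_mutation_rate(g: GenotypeMatrix, window: int = 10_000_000,
                            step: int = 50_000, mu0: float = 7e-9,
                            miss_max: float = 0.10,
                            dp_min_exclusive: int = 3,
                            gq_min_exclusive: int = 25) -> pd.DataFrame:
    """Missingness-corrected mutation rate μ0·(1 − missing/total) per window.

    Per sliding window, ``total`` counts biallelic SNPs with at most
    ``miss_max`` genotype missingness; ``missing`` counts those among them
    where some called genotype fails the completeness rule (DP > 3 and
    GQ > 25), i.e. sites a missing-data-intolerant genealogy method must
    drop.  Windows are truncated at chromosome ends; a window with no
    eligible site reports NaN.

    Returns columns chrom, start, end, total_variants, missing_variants,
    mu_corrected.
    """
    eligible = g.missing_fraction() <= miss_max
    called = g.calls != MISSING
    ok_call = (g.dp > dp_min_exclusive) & (g.gq > gq_min_exclusive)
    complete = np.all(~called | ok_call, axis=0)

    rows = []
    for chrom, grp in g.variants.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        idx = grp.index.to_numpy()
        chrom_end = int(pos.max())
        start = 1
        while start <= chrom_end:
            end = min(start + window, chrom_end + 1)
            in_win = (pos >= start) & (pos < end)
            sel = idx[in_win]
            total = int(eligible[sel].sum())
            miss = int((eligible[sel] & ~complete[sel]).sum())
            mu = mu0 * (1.0 - miss / total) if total > 0 else np.nan
            rows.append([chrom, start, end, total, miss, mu])
            if end >= chrom_end + 1:
                break
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "total_variants", "missing_variants",
                                       "mu_corrected"])


def scale_recombination_map(map_df: pd.DataFrame,
                            outcrossing_rate: float = 0.05) -> pd.DataFrame:
    """Scale genetic distances by the outcrossing fraction.

    A selfing population recombines effectively only in outcrossed
    generations, so cumulative cM are multiplied by the outcrossing rate
    (5% ⇒ division by twenty).  Expects columns pos (bp, strictly
    increasing) and cm (non-decreasing cumulative cM).
    """
    if not (0 < outcrossing_rate <= 1):
        raise ValueError("outcrossing_rate must lie in (0, 1]")
    pos = map_df["pos"].to_numpy()
    cm = map_df["cm"].to_numpy(dtype=float)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("map positions must be strictly increasing")
    if np.any(np.diff(cm) < 0):
        raise ValueError("genetic distances must be non-decreasing")
    out = map_df.copy()
    out["cm"] = cm * outcrossing_rate
    return out


def haplotype_frequency_by_subpop(carriers, labels) -> pd.DataFrame:
    """Carrier counts and frequencies per subpopulation.

    ``carriers`` is a {0,1} vector (or a collection of carrier sample ids)
    and ``labels`` maps sample id -> subpopulation.  The ``private`` column
    flags haplotypes whose carriers all fall in a single subpopulation.
    """
    samples = list(labels)
    items = list(carriers)
    if not items:
        carrier_set: set = set()
    elif isinstance(items[0], str):
        carrier_set = set(items)
        unknown = carrier_set - set(samples)
        if unknown:
            raise KeyError(f"carriers not among labelled samples: {unknown}")
    else:
        vec = np.asarray(items, dtype=int)
        if len(vec) != len(samples):
            raise ValueError("carrier vector must cover all labelled samples")
        carrier_set = {s for s, c in zip(samples, vec) if c}
    pops = pd.Series({s: labels[s] for s in samples})
    rows = []
    pops_with_carriers = {labels[s] for s in carrier_set}
    private = len(pops_with_carriers) == 1
    for pop in pd.unique(pops):
        members = pops.index[pops == pop]
        k = sum(1 for s in members if s in carrier_set)
        rows.append([pop, k, len(members), k / len(members), private])
    return pd.DataFrame(rows, columns=["subpopulation", "carriers", "size",
                                       "frequency", "private"])


def _complete_sites(g: GenotypeMatrix, dp_min_exclusive: int = 3,
                    gq_min_exclusive: int = 25) -> np.ndarray:
    """Sites every sample passes: called, DP > 3, GQ > 25 (no missing data)."""
    called = g.calls != MISSING
    ok = called & (g.dp > dp_min_exclusive) & (g.gq > gq_min_exclusive)
    return np.all(ok, axis=0)


def export_genealogy_inputs(g: GenotypeMatrix, map_df: pd.DataFrame,
                            breakpoint_pseudovariants=(),
                            outgroup_samples=(),
                            out_prefix: str = "genealogy") -> dict:
    """Write a haps/sample/map bundle for haploid genealogy inference.

    Sites failing the completeness rule (every sample called with DP > 3
    and GQ > 25) are excluded, since the downstream method tolerates no
    missing data.  Tandem-duplication breakpoints are inserted as biallelic
    pseudo-variants coded 1 for carriers, in position order; a pseudo-
    variant colliding with an existing site position raises an error naming
    the position.

    Returns {"haps": path, "sample": path, "map": path}.
    """
    outgroup = list(outgroup_samples)
    unknown = set(outgroup) - set(g.samples)
    if unknown:
        raise KeyError(f"outgroup samples not in genotypes: {unknown}")

    keep = _complete_sites(g)
    sub = g.subset_variants(keep)
    existing = set(zip(sub.variants["chrom"], sub.variants["pos"]))
    all_pos = set(zip(g.variants["chrom"], g.variants["pos"]))

    records = []
    for j in range(sub.n_variants):
        v = sub.variants.iloc[j]
        records.append((v["chrom"], int(v["pos"]), v["id"], v["ref"],
                        v["alt"], sub.calls[:, j].astype(int)))

    chrom_default = g.variants["chrom"].iloc[0] if g.n_variants else "chr2"
    seen_pseudo = set()
    for pos, carriers in breakpoint_pseudovariants:
        pos = int(pos)
        if (chrom_default, pos) in all_pos or (chrom_default, pos) in seen_pseudo:
            raise ValueError(f"pseudo-variant collides with an existing "
                             f"site at position {pos}")
        seen_pseudo.add((chrom_default, pos))
        carrier_set = set(carriers)
        unknown = carrier_set - set(g.samples)
        if unknown:
            raise KeyError(f"pseudo-variant carriers unknown: {unknown}")
        calls = np.array([1 if s in carrier_set else 0 for s in g.samples])
        records.append((chrom_default, pos, f"{chrom_default}:{pos}_TD",
                        "A", "T", calls))
    records.sort(key=lambda r: (r[0], r[1]))

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    haps_path = prefix.with_suffix(".haps")
    sample_path = prefix.with_suffix(".sample")
    map_path = prefix.with_suffix(".map")

    with open(haps_path, "w") as fh:
        for chrom, pos, vid, ref, alt, calls in records:
            fh.write(" ".join([str(chrom), vid, str(pos), ref, alt]
                              + [str(int(c)) for c in calls]) + "\n")
    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for s in g.samples:
            fh.write(f"{s} {s} 0\n")
    pos = map_df["pos"].to_numpy(dtype=float)
    cm = map_df["cm"].to_numpy(dtype=float)
    rate = np.zeros_like(cm)
    if len(pos) > 1:
        seg = np.diff(cm) / (np.diff(pos) / 1e6)  # cM/Mb
        rate[:-1] = seg
        rate[-1] = seg[-1]
    with open(map_path, "w") as fh:
        fh.write("pos COMBINED_rate Genetic_Map\n")
        for p, r, c in zip(pos, rate, cm):
            fh.write(f"{int(p)} {r:.8g} {c:.8g}\n")
    if outgroup:
        with open(prefix.with_suffix(".outgroup.txt"), "w") as fh:
            fh.write("\n".join(outgroup) + "\n")
    return {"haps": str(haps_path), "sample": str(sample_path),
            "map": str(map_path)}


def read_haps_bundle(haps_path: str, sample_path: str):
    """Parse a haps/sample pair back into (samples, sites DataFrame, calls).

    The calls matrix is samples x sites with {0,1} entries, mirroring the
    writer's orientation.
    """
    samples = []
    with open(sample_path) as fh:
        lines = [ln.split() for ln in fh.read().splitlines() if ln.strip()]
    for row in lines[2:]:
        samples.append(row[0])
    chroms, poss, ids, refs, alts, cols = [], [], [], [], [], []
    with open(haps_path) as fh:
        for ln in fh:
            parts = ln.split()
            chroms.append(parts[0])
            ids.append(parts[1])
            poss.append(int(parts[2]))
            refs.append(parts[3])
            alts.append(parts[4])
            cols.append([int(x) for x in parts[5:]])
    sites = pd.DataFrame({"chrom": chroms, "id": ids, "pos": poss,
                          "ref": refs, "alt": alts})
    calls = np.array(cols, dtype=int).T if cols else np.zeros((len(samples), 0), int)
    return samples, sites, calls
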