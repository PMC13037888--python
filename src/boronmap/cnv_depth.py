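"""Read-depth tandem-duplication genotyping and junction classification.

Copy number over a candidate duplication is estimated from mean depth in
sliding windows (800 bp every 400 bp), normalized to the pooled per-base
depth of the 3 kb flanks outside the breakpoints; the median window ratio,
rounded half-up, is the copy-number call per haplotype.  Breakpoint
junctions are classified from junction-spanning sequence into blunt joins,
microhomology (an identical motif shared by both breakpoint ends) or novel
insertions — the signatures of end-joining and microhomology-mediated
repair.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CnCall, DepthProfile, JunctionCall

__all__ = [
    "window_depth",
    "flank_normalize",
    "estimate_cn",
    "detect_depth_changepoints",
    "classify_junction",
    "sv_snp_ld",
]


def window_depth(profile: DepthProfile, window: int = 800,
                 step: int = 400) -> pd.DataFrame:
    """Mean depth in sliding windows over the profile.

    Windows start every ``step`` bp while a full window fits; an uncovered
    tail shorter than window/2 extends the last window, a longer one becomes
    its own truncated window.  A profile shorter than one window yields a
    single whole-profile window with a warning.

    Returns a DataFrame with columns start, end, mean (absolute bp).
    """
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    depth = profile.depth
    L = len(depth)
    csum = np.concatenate([[0.0], np.cumsum(depth)])

    if L < window:
        warnings.warn("profile shorter than one window; using the whole "
                      "profile as a single window")
        bounds = [(0, L)]
    else:
        starts = list(range(0, L - window + 1, step))
        bounds = [(s, s + window) for s in starts]
        tail = L - bounds[-1][1]
        if tail > 0:
            if tail < window / 2:
                bounds[-1] = (bounds[-1][0], L)
            else:
                bounds.append((bounds[-1][0] + step, L))
    rows = [(profile.start + s, profile.start + e,
             (csum[e] - csum[s]) / (e - s)) for s, e in bounds]
    return pd.DataFrame(rows, columns=["start", "end", "mean"])


def flank_normalize(windows: pd.DataFrame, profile: DepthProfile,
                    breakpoints: tuple, flank: int = 3000,
                    stat: str = "mean") -> np.ndarray:
    """Window means divided by the pooled per-base depth of the two flanks.

    The flanks are the ``flank`` bp immediately outside [bp1, bp2), clipped
    (with a warning) where they run past the profile.
    """
    bp1, bp2 = breakpoints
    lo = bp1 - flank
    hi = bp2 + flank
    if lo < profile.start or hi > profile.end:
        warnings.warn("flank extends past the profile; clipping")
        lo = max(lo, profile.start)
        hi = min(hi, profile.end)
    left = profile.depth[lo - profile.start:bp1 - profile.start]
    right = profile.depth[bp2 - profile.start:hi - profile.start]
    pooled = np.concatenate([left, right])
    if pooled.size == 0 or (stat == "mean" and pooled.mean() == 0) or \
            (stat == "median" and np.median(pooled) == 0):
        raise ValueError("zero pooled flank depth; cannot normalize")
    denom = pooled.mean() if stat == "mean" else float(np.median(pooled))
    return windows["mean"].to_numpy() / denom


def estimate_cn(profile: DepthProfile, breakpoints: tuple,
                window: int = 800, step: int = 400,
                flank: int = 3000, stat: str = "mean") -> CnCall:
    """Copy number per haplotype from the median flank-normalized ratio.

    Only windows lying fully inside [bp1, bp2) enter the median; the
    integer call rounds half-up, so ratios in [1.5, 2.5) give CN 2.
    """
    bp1, bp2 = breakpoints
    if not (profile.start <= bp1 < bp2 <= profile.end):
        raise ValueError("breakpoints must lie within the profile")
    win = window_depth(profile, window=window, step=step)
    ratios = flank_normalize(win, profile, breakpoints, flank=flank,
                             stat=stat)
    inside = (win["start"] >= bp1) & (win["end"] <= bp2)
    if not inside.any():
        raise ValueError("no complete window inside the region; "
                         "try a smaller window")
    sel = ratios[inside.to_numpy()]
    median_ratio = float(np.median(sel))
    cn = int(np.floor(median_ratio + 0.5))
    return CnCall(region=(bp1, bp2), window_ratios=list(sel),
                  median_ratio=median_ratio, cn=cn)


def detect_depth_changepoints(profile: DepthProfile, window: int = 800,
                              step: int = 400, ratio_threshold: float = 1.5,
                              min_run: int = 3) -> list:
    """Candidate duplication spans from runs of elevated window depth.

    Windows whose mean exceeds ratio_threshold times the global median
    window depth, in maximal runs of at least min_run consecutive windows,
    are reported as (start, end) spans.  A lightweight stand-in for a
    dedicated SV caller, sufficient to seed breakpoint refinement.
    """
    win = window_depth(profile, window=window, step=step)
    med = float(np.median(win["mean"]))
    if med == 0:
        return []
    hot = (win["mean"].to_numpy() / med) > ratio_threshold
    spans = []
    i = 0
    while i < len(hot):
        if hot[i]:
            j = i
            while j + 1 < len(hot) and hot[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                spans.append((int(win["start"].iloc[i]),
                              int(win["end"].iloc[j])))
            i = j + 1
        else:
            i += 1
    return spans


def _max_ref_homology(ref: str, dup_start: int, dup_end: int,
                      cap: int) -> int:
    """Maximal m with ref[dup_end-m:dup_end] == ref[dup_start:dup_start+m].

    Case-insensitive ('ref' must already be uppercased); 'N' never matches.
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


def classify_junction(junction_seq: str, reference: str, dup_start: int,
                      dup_end: int, flank_probe: int = 50) -> JunctionCall:
    """Classify a duplication junction as blunt / microhomology / insertion.

    Anchors of ``flank_probe`` bp — the reference sequence ending at the
    duplication end (copy-1 terminus) and starting at the duplication start
    (copy-2 head) — are located in the junction by exact match.  Overlapping
    anchors share the microhomology motif; a gap between them is a novel
    insertion; direct adjacency is blunt unless the reference itself carries
    identical sequence at both breakpoint ends, in which case the longest
    zero-insert microhomology explanation is preferred.
    """
    jseq = junction_seq.upper()
    ref = reference.upper()
    if dup_end - dup_start < flank_probe:
        raise ValueError("flank_probe larger than the duplicated span")
    left_anchor = ref[dup_end - flank_probe:dup_end]
    right_anchor = ref[dup_start:dup_start + flank_probe]
    i1 = jseq.find(left_anchor)
    i2 = jseq.find(right_anchor)
    if i1 < 0 or i2 < 0 or "N" in left_anchor or "N" in right_anchor:
        raise ValueError("junction context does not match reference")
    e1 = i1 + flank_probe  # where copy-1 context ends
    s2 = i2                # where copy-2 context starts
    gap = s2 - e1
    if gap > 0:
        ins = jseq[e1:s2]
        return JunctionCall("insertion", len(ins), ins)
    overlap = -gap
    # the physical overlap is reference homology; extend to the maximal
    # homology so ties prefer the longest zero-insert explanation
    m = _max_ref_homology(ref, dup_start, dup_end,
                          cap=min(flank_probe, dup_end - dup_start))
    k = max(overlap, m)
    if k >= 1:
        return JunctionCall("microhomology", k, ref[dup_start:dup_start + k])
    return JunctionCall("blunt", 0, "")


def sv_snp_ld(sv_carrier, snp_calls) -> float:
    """r² between a 0/1 carrier vector and a 0/1 SNP call vector.

    Pairs with a missing entry (NaN or negative sentinel) are dropped;
    a monomorphic vector leaves r² undefined (NaN).
    """
    a = np.asarray(sv_carrier, dtype=float)
    b = np.asarray(snp_calls, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must cover the same samples")
    ok = ~(np.isnan(a) | np.isnan(b) | (a < 0) | (b < 0))
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r ** 2)
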