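"""Independent brute-force oracles used to cross-check the implementation.

Each oracle takes a deliberately different route from the library code:
string scanning instead of run-length encoding for segmentation,
group-mean sums of squares instead of probability-based regression for the
LOD score, and exhaustive enumeration of gamete crossover configurations
instead of forward-backward for the genotype HMM.
"""

from __future__ import annotations

import itertools

import numpy as np


def segment_bars_oracle(values, min_run: int = 5):
    """Bar calling by literal string search over the below/above sequence.

    Returns (threshold, bars) with bars as half-open intervals.  A bar
    starts at the first of >= min_run consecutive 'b' (below average),
    ends at the last 'b' before the first run of >= min_run consecutive
    'a' (at or above average), and runs to the end of the profile if no
    such closing run follows.
    """
    values = np.asarray(values, dtype=float)
    thr = float(values.mean())
    s = "".join("b" if v < thr else "a" for v in values)
    n = len(s)
    opening, closing = "b" * min_run, "a" * min_run
    bars = []
    i = 0
    while True:
        start = s.find(opening, i)
        if start == -1:
            break
        close = s.find(closing, start)
        if close == -1:
            bars.append((start, n))
            break
        bars.append((start, s.rfind("b", start, close) + 1))
        i = close
    return thr, bars


def marker_lod_oracle(genotypes, phenotype):
    """Two-degree-of-freedom single-marker LOD from group sums of squares.

    With the genotype observed at the marker, the Haley-Knott full model is
    the three-group-means model, so LOD = (n/2) log10(TSS / within-SS).
    Returns (lod, r_squared).
    """
    g = np.asarray(genotypes)
    y = np.asarray(phenotype, dtype=float)
    ok = np.isfinite(y) & (g >= 0)
    g, y = g[ok], y[ok]
    n = y.size
    tss = float(((y - y.mean()) ** 2).sum())
    wss = 0.0
    for code in (0, 1, 2):
        sub = y[g == code]
        if sub.size:
            wss += float(((sub - sub.mean()) ** 2).sum())
    lod = n / 2.0 * np.log10(tss / wss)
    return lod, 1.0 - wss / tss


def f2_midpoint_oracle(r_left: float, r_right: float, left_geno: int, right_geno: int):
    """Posterior genotype at a middle locus by enumerating gamete paths.

    Two independent gametes each take states in {0, 1} at (left, mid,
    right); each path's probability is 1/2 times the product of the switch
    / no-switch probabilities.  Conditioning on the observed flanking
    genotypes (counts of allele 1) yields the exact posterior at the
    midpoint.  Returns (p_AA, p_AB, p_BB).
    """

    def path_prob(states, r12, r23):
        p = 0.5
        p *= r12 if states[0] != states[1] else 1 - r12
        p *= r23 if states[1] != states[2] else 1 - r23
        return p

    post = np.zeros(3)
    for gam1 in itertools.product((0, 1), repeat=3):
        for gam2 in itertools.product((0, 1), repeat=3):
            if gam1[0] + gam2[0] != left_geno or gam1[2] + gam2[2] != right_geno:
                continue
            p = path_prob(gam1, r_left, r_right) * path_prob(gam2, r_left, r_right)
            post[gam1[1] + gam2[1]] += p
    return post / post.sum()
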