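"""Haley-Knott genome scans and multiple-QTL model building.

At every grid position the phenotype is regressed on the expected additive
dosage (p_BB - p_AA) and the dominance indicator (p_AB) derived from the
genotype probabilities, optionally alongside cofactor QTL.  The LOD score is
(n/2) log10(RSS_null / RSS_full).  Genome-wide significance comes from
permutation of the phenotype vector; multiple-QTL models are built by
admitting suggestive peaks as cofactors, iterating the conditional scan and
pruning by backward elimination; QTL location uncertainty is summarized by
a Bayes credible interval of the normalized 10^LOD mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cross import AA, AB, BB, CrossData, GenotypeProbabilities

DEFAULT_ALPHAS = (0.05, 0.10)
#: cM window around a cofactor within which that cofactor is dropped from
#: the model while scanning (avoids the cofactor absorbing its own signal).
DEFAULT_WINDOW_CM = 10.0
#: minimum cM separation between same-group cofactors.
DEFAULT_MIN_SEP_CM = 30.0


@dataclass(frozen=True)
class Cofactor:
    """A putative QTL used as a regression covariate during a scan."""

    linkage_group: str
    position_cM: float


@dataclass
class ScanGroup:
    name: str
    positions: np.ndarray
    lod: np.ndarray
    marker_names: list


@dataclass
class ScanResult:
    """LOD curves for one trait over the whole genome grid."""

    trait: str
    groups: list[ScanGroup]
    cofactors: list[Cofactor] = field(default_factory=list)

    def group(self, name: str) -> ScanGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def max_lod(self) -> float:
        return max(float(g.lod.max()) for g in self.groups)

    def peak(self) -> tuple[str, float, float]:
        """(linkage group, position cM, LOD) of the genome-wide maximum."""
        best = None
        for g in self.groups:
            k = int(np.argmax(g.lod))
            if best is None or g.lod[k] > best[2]:
                best = (g.name, float(g.positions[k]), float(g.lod[k]))
        return best

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for pos, lod, name in zip(g.positions, g.lod, g.marker_names):
                rows.append((self.trait, g.name, pos, name or "", lod))
        return pd.DataFrame(
            rows, columns=["trait", "linkage_group", "position_cM", "nearest_marker", "LOD"]
        )


def _aligned_phenotype(phenotype, probs: GenotypeProbabilities) -> np.ndarray:
    if isinstance(phenotype, pd.Series):
        return phenotype.reindex(probs.individuals).to_numpy(dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if y.shape != (probs.n_individuals,):
        raise ValueError("phenotype length must match the individuals in probs")
    return y


def _design_at(probs: GenotypeProbabilities, cof: Cofactor) -> np.ndarray:
    """Additive/dominance columns (n, 2) at the grid point nearest a cofactor."""
    g = probs.group(cof.linkage_group)
    k = int(np.argmin(np.abs(g.positions - cof.position_cM)))
    p = g.probs[:, k, :]
    return np.column_stack([p[:, BB] - p[:, AA], p[:, AB]])


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def _prune_collinear(
    probs: GenotypeProbabilities, cofactors: list[Cofactor], mask: np.ndarray
) -> list[Cofactor]:
    """Drop cofactors whose columns add no rank to the design (with a warning)."""
    kept: list[Cofactor] = []
    X = np.ones((int(mask.sum()), 1))
    for cof in cofactors:
        cols = _design_at(probs, cof)[mask]
        cand = np.column_stack([X, cols])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(X):
            kept.append(cof)
            X = cand
        else:
            warnings.warn(f"dropping collinear cofactor {cof}")
    return kept


def scan_hk(
    probs: GenotypeProbabilities,
    phenotype,
    cofactors: list[Cofactor] | None = None,
    *,
    trait: str = "trait",
    window_cM: float = DEFAULT_WINDOW_CM,
) -> ScanResult:
    """Haley-Knott LOD curve at every grid position.

    The null model holds the intercept and all active cofactors; the full
    model adds the additive and dominance regressors of the scanned
    position.  A cofactor within ``window_cM`` of the scanned position on
    the same linkage group is dropped from both models there.  Only
    individuals with a non-missing phenotype enter (n in the LOD formula).
    """
    y_all = _aligned_phenotype(phenotype, probs)
    mask = np.isfinite(y_all)
    y = y_all[mask]
    n = y.size
    if n < 10:
        raise ValueError("need >= 10 non-missing phenotype values")
    if np.ptp(y) == 0:
        raise ValueError("phenotype has zero variance")
    cofactors = list(cofactors or [])
    if cofactors:
        cofactors = _prune_collinear(probs, cofactors, mask)
    cof_cols = [_design_at(probs, c)[mask] for c in cofactors]

    ones = np.ones((n, 1))
    null_cache: dict[tuple[int, ...], float] = {}

    def null_rss(active: tuple[int, ...]) -> float:
        if active not in null_cache:
            X0 = np.column_stack([ones] + [cof_cols[i] for i in active]) if active else ones
            null_cache[active] = _rss(X0, y)
        return null_cache[active]

    out_groups: list[ScanGroup] = []
    for g in probs.groups:
        lods = np.empty(g.positions.size)
        for k, pos in enumerate(g.positions):
            active = tuple(
                i
                for i, c in enumerate(cofactors)
                if not (
                    c.linkage_group == g.name and abs(c.position_cM - pos) < window_cM
                )
            )
            p = g.probs[mask, k, :]
            Xq = np.column_stack([p[:, BB] - p[:, AA], p[:, AB]])
            X1 = np.column_stack([ones] + [cof_cols[i] for i in active] + [Xq])
            rss1 = _rss(X1, y)
            rss0 = null_rss(active)
            lods[k] = 0.0 if rss1 <= 0 else max(0.0, n / 2.0 * np.log10(rss0 / rss1))
        out_groups.append(ScanGroup(g.name, g.positions.copy(), lods, list(g.marker_names)))
    return ScanResult(trait=trait, groups=out_groups, cofactors=cofactors)


def permutation_thresholds(
    probs: GenotypeProbabilities,
    phenotype,
    n_perm: int = 1000,
    alphas=DEFAULT_ALPHAS,
    seed: int = 0,
) -> dict[float, float]:
    """Genome-wide LOD significance cutoffs by phenotype permutation.

    The phenotype is shuffled across individuals (genotypes fixed), the
    cofactor-free genome-wide maximum LOD recorded per permutation, and the
    cutoff for level alpha is the empirical (1 - alpha) quantile (linear
    interpolation).  Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y_all = _aligned_phenotype(phenotype, probs)
    mask = np.isfinite(y_all)
    y = y_all[mask]
    n = y.size
    if n < 10:
        raise ValueError("need >= 10 non-missing phenotype values")
    if np.ptp(y) == 0:
        raise ValueError("phenotype has zero variance")

    rng = np.random.default_rng(seed)
    Y = np.empty((n, n_perm))
    for j in range(n_perm):
        Y[:, j] = y[rng.permutation(n)]
    yc = Y - Y.mean(axis=0, keepdims=True)
    rss0 = (yc**2).sum(axis=0)  # identical across perms up to fp noise

    max_lod = np.zeros(n_perm)
    for g in probs.groups:
        for k in range(g.positions.size):
            p = g.probs[mask, k, :]
            X = np.column_stack(
                [np.ones(n), p[:, BB] - p[:, AA], p[:, AB]]
            )
            Q, _ = np.linalg.qr(X)
            proj = Q.T @ Y
            rss1 = (Y**2).sum(axis=0) - (proj**2).sum(axis=0)
            with np.errstate(divide="ignore"):
                lod = n / 2.0 * np.log10(rss0 / np.maximum(rss1, 1e-300))
            np.maximum(max_lod, lod, out=max_lod)
    return {
        float(a): float(np.quantile(max_lod, 1.0 - a)) for a in sorted(alphas)
    }


@dataclass
class CredibleInterval:
    lo_cM: float
    hi_cM: float
    lo_marker: str | None = None
    hi_marker: str | None = None


def bayes_interval(
    scan: ScanResult, linkage_group: str, coverage: float = 0.95
) -> CredibleInterval:
    """Bayes credible interval for QTL location on one linkage group.

    Grid weights are proportional to 10^LOD, normalized over the linkage
    group; the interval is the smallest contiguous grid span containing the
    peak whose summed weight reaches ``coverage``.  The nearest true markers
    at or outside the endpoints are reported alongside.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    g = scan.group(linkage_group)
    if g.positions.size < 2:
        raise ValueError("need >= 2 grid positions on the linkage group")
    lod = g.lod
    w = 10.0 ** (lod - lod.max())
    w = w / w.sum()
    pk = int(np.argmax(lod))
    G = w.size
    best = (0, G - 1)
    found = False
    for width in range(G):
        for i in range(max(0, pk - width), min(pk, G - 1 - width) + 1):
            j = i + width
            if w[i : j + 1].sum() >= coverage - 1e-12:
                best = (i, j)
                found = True
                break
        if found:
            break
    i, j = best
    lo, hi = float(g.positions[i]), float(g.positions[j])

    def _flank(idx: int, direction: int) -> str | None:
        k = idx
        while 0 <= k < G:
            if g.marker_names[k] is not None:
                return g.marker_names[k]
            k += direction
        return None

    return CredibleInterval(lo, hi, _flank(i, -1), _flank(j, +1))


def qtl_effects(genotypes_at_marker, phenotype):
    """Genotype-class means and additive/dominance effects at a marker.

    a = (mean_BB - mean_AA) / 2 and d = mean_AB - (mean_AA + mean_BB) / 2.
    A class with no individuals leaves the dependent effects NaN with a
    warning.
    """
    g = np.asarray(genotypes_at_marker)
    y = np.asarray(phenotype, dtype=float)
    ok = np.isfinite(y) & (g >= 0)
    means = {}
    for code, lab in ((AA, "AA"), (AB, "AB"), (BB, "BB")):
        sel = ok & (g == code)
        means[lab] = float(y[sel].mean()) if sel.any() else float("nan")
    if not np.isfinite(means["AA"]) or not np.isfinite(means["BB"]):
        warnings.warn("empty homozygote class: additive/dominance effects undefined")
    a = (means["BB"] - means["AA"]) / 2.0
    d = means["AB"] - (means["AA"] + means["BB"]) / 2.0
    if not np.isfinite(means["AB"]):
        warnings.warn("empty heterozygote class: dominance effect undefined")
    return means, a, d


def pve(lod: float, n: int) -> float:
    """Percent phenotypic variance explained implied by a LOD score."""
    if lod < 0 or n < 2:
        raise ValueError("need LOD >= 0 and n >= 2")
    return 100.0 * (1.0 - 10.0 ** (-2.0 * lod / n))


@dataclass
class QTL:
    """One mapped locus in a final multiple-QTL model."""

    linkage_group: str
    peak_cM: float
    peak_marker: str | None
    lod: float
    pve_pct: float
    interval: CredibleInterval
    means: dict[str, float]
    additive: float
    dominance: float
    significance: str  # 'significant' (5%) or 'suggestive' (10%)


@dataclass
class QTLModel:
    """Final multiple-QTL model for one trait."""

    trait: str
    qtl: list[QTL]
    thresholds: dict[float, float]
    cofactors: list[Cofactor]
    cumulative_pve_pct: float = float("nan")
    n: int = 0

    def to_frame(self) -> pd.DataFrame:
        thr5 = self.thresholds.get(0.05, float("nan"))
        thr10 = self.thresholds.get(0.10, float("nan"))
        cof_str = ";".join(
            f"{c.linkage_group}@{c.position_cM:g}" for c in self.cofactors
        )
        rows = []
        for q in self.qtl:
            rows.append(
                {
                    "trait": self.trait,
                    "cofactors": cof_str,
                    "linkage_group": q.linkage_group,
                    "peak_cM": q.peak_cM,
                    "peak_marker": q.peak_marker or "",
                    "LOD": q.lod,
                    "PVE_pct": q.pve_pct,
                    "CI_lo_cM": q.interval.lo_cM,
                    "CI_hi_cM": q.interval.hi_cM,
                    "mean_AA": q.means["AA"],
                    "mean_AB": q.means["AB"],
                    "mean_BB": q.means["BB"],
                    "additive": q.additive,
                    "dominance": q.dominance,
                    "threshold_5": thr5,
                    "threshold_10": thr10,
                    "class": q.significance,
                }
            )
        cols = ["trait", "cofactors", "linkage_group", "peak_cM", "peak_marker",
                "LOD", "PVE_pct", "CI_lo_cM", "CI_hi_cM", "mean_AA", "mean_AB",
                "mean_BB", "additive", "dominance", "threshold_5", "threshold_10",
                "class"]
        return pd.DataFrame(rows, columns=cols)


def _pick_peaks(
    scan: ScanResult, threshold: float, min_sep_cM: float
) -> list[Cofactor]:
    """Greedy peak selection: grid points above threshold, strongest first,
    at least ``min_sep_cM`` apart within a linkage group."""
    cands = []
    for g in scan.groups:
        for k in np.flatnonzero(g.lod >= threshold):
            cands.append((float(g.lod[k]), g.name, float(g.positions[k])))
    cands.sort(reverse=True)
    picked: list[Cofactor] = []
    for lod, lg, pos in cands:
        if any(
            c.linkage_group == lg and abs(c.position_cM - pos) < min_sep_cM
            for c in picked
        ):
            continue
        picked.append(Cofactor(lg, pos))
    return picked


def _conditional_peak(
    probs: GenotypeProbabilities,
    phenotype,
    target: Cofactor,
    others: list[Cofactor],
    *,
    trait: str,
    window_cM: float,
    search_cM: float = 15.0,
):
    """Scan with the other cofactors and return (scan, peak_pos, peak_lod)
    for the target's own neighbourhood (within ``search_cM`` of it)."""
    scan = scan_hk(probs, phenotype, others, trait=trait, window_cM=window_cM)
    g = scan.group(target.linkage_group)
    near = np.abs(g.positions - target.position_cM) <= search_cM
    idx = np.flatnonzero(near)
    k = idx[np.argmax(g.lod[idx])]
    return scan, float(g.positions[k]), float(g.lod[k])


def mqm_fit(
    probs: GenotypeProbabilities,
    phenotype,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    trait: str = "trait",
    cross: CrossData | None = None,
    thresholds: dict[float, float] | None = None,
    admit_alpha: float = 0.10,
    window_cM: float = DEFAULT_WINDOW_CM,
    min_sep_cM: float = DEFAULT_MIN_SEP_CM,
    max_iter: int = 10,
    coverage: float = 0.95,
    initial_cofactors: list[Cofactor] | None = None,
) -> QTLModel:
    """Build a multiple-QTL model for one trait.

    Procedure: (1) cofactor-free scan; suggestive peaks (>= the
    ``admit_alpha`` permutation cutoff) on distinct linkage groups, or >=
    ``min_sep_cM`` apart within one, become candidate cofactors; (2) the
    scan is repeated with the cofactors in the model, refreshing the peak
    set, until stable or ``max_iter`` rounds; (3) backward elimination drops
    any cofactor whose conditional LOD (scanned with all the others) falls
    below the suggestive cutoff, weakest first; (4) survivors are classified
    significant (5% cutoff) or suggestive (10%), and each gets a Bayes
    credible interval, its PVE, and allelic effects at the nearest genotyped
    marker (when ``cross`` is supplied).
    """
    if thresholds is None:
        thresholds = permutation_thresholds(
            probs, phenotype, n_perm=n_perm, alphas=DEFAULT_ALPHAS, seed=seed
        )
    thr_admit = thresholds[admit_alpha]
    thr_sig = thresholds[min(thresholds)]

    scan0 = scan_hk(probs, phenotype, trait=trait, window_cM=window_cM)
    cofs = _pick_peaks(scan0, thr_admit, min_sep_cM)
    for extra in initial_cofactors or []:
        if not any(
            c.linkage_group == extra.linkage_group
            and abs(c.position_cM - extra.position_cM) < min_sep_cM
            for c in cofs
        ):
            cofs.append(extra)
    for _ in range(max_iter):
        if not cofs:
            break
        scan_c = scan_hk(probs, phenotype, cofs, trait=trait, window_cM=window_cM)
        new = _pick_peaks(scan_c, thr_admit, min_sep_cM)
        if {(c.linkage_group, round(c.position_cM, 6)) for c in new} == {
            (c.linkage_group, round(c.position_cM, 6)) for c in cofs
        }:
            cofs = new
            break
        cofs = new

    # Backward elimination, weakest conditional cofactor first.
    while cofs:
        cond = []
        for c in cofs:
            others = [o for o in cofs if o is not c]
            _, pos, lod = _conditional_peak(
                probs, phenotype, c, others, trait=trait, window_cM=window_cM
            )
            cond.append((lod, pos, c))
        worst = min(cond, key=lambda t: t[0])
        if worst[0] >= thr_admit:
            cofs = [replace(c, position_cM=pos) for lod, pos, c in cond]
            break
        cofs = [c for c in cofs if c is not worst[2]]

    y = _aligned_phenotype(phenotype, probs)
    n = int(np.isfinite(y).sum())

    qtls: list[QTL] = []
    for c in cofs:
        others = [o for o in cofs if o is not c]
        scan_c, pos, lod = _conditional_peak(
            probs, phenotype, c, others, trait=trait, window_cM=window_cM
        )
        ci = bayes_interval(scan_c, c.linkage_group, coverage=coverage)
        g = probs.group(c.linkage_group)
        marker_idx = np.flatnonzero(g.is_marker)
        mk = marker_idx[np.argmin(np.abs(g.positions[marker_idx] - pos))]
        marker = g.marker_names[mk]
        if cross is not None and marker is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                means, a, d = qtl_effects(
                    cross.genotypes[marker].to_numpy(), y
                )
        else:
            nanv = float("nan")
            means, a, d = {"AA": nanv, "AB": nanv, "BB": nanv}, nanv, nanv
        qtls.append(
            QTL(
                linkage_group=c.linkage_group,
                peak_cM=pos,
                peak_marker=marker,
                lod=lod,
                pve_pct=pve(lod, n),
                interval=ci,
                means=means,
                additive=a,
                dominance=d,
                significance="significant" if lod >= thr_sig else "suggestive",
            )
        )

    # Cumulative PVE from the joint multi-QTL regression R^2.
    cum = float("nan")
    if qtls:
        mask = np.isfinite(y)
        yv = y[mask]
        X = np.column_stack(
            [np.ones(mask.sum())]
            + [_design_at(probs, Cofactor(q.linkage_group, q.peak_cM))[mask] for q in qtls]
        )
        rss = _rss(X, yv)
        tss = float(((yv - yv.mean()) ** 2).sum())
        cum = 100.0 * (1.0 - rss / tss)

    qtls.sort(key=lambda q: (q.linkage_group, q.peak_cM))
    return QTLModel(
        trait=trait,
        qtl=qtls,
        thresholds=thresholds,
        cofactors=cofs,
        cumulative_pve_pct=cum,
        n=n,
    )
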