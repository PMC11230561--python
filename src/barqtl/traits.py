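"""Pigment-level and patterning measures derived from a segmented profile.

Seven measures describe the level of eumelanin (darkest, lightest and range
of intensity, covariance of intensity with anterior-posterior position,
average bar and interbar intensities and their differential) and four
describe the pattern (number of bars, percent barring, average bar and
interbar widths in cm).  Traits are residualized against standard length to
remove allometric size effects before group comparisons, correlations and
QTL mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import IntensityProfile
from .segmentation import BarSegmentation, segment_bars

#: Trait column order used throughout tables and reports.
TRAIT_NAMES = (
    "darkest_intensity",
    "lightest_intensity",
    "range_intensity",
    "covariance",
    "avg_bar_intensity",
    "avg_interbar_intensity",
    "differential_intensity",
    "n_bars",
    "percent_barring",
    "avg_bar_width_cm",
    "avg_interbar_width_cm",
)

PIGMENT_TRAITS = TRAIT_NAMES[:7]
PATTERN_TRAITS = TRAIT_NAMES[7:]


@dataclass
class TraitVector:
    """The eleven per-individual pigmentation measures.

    Intensities are on the raw 0-255 gray scale (larger = lighter);
    ``covariance`` is the sample covariance (n-1 denominator) of gray value
    with 0-based pixel position, in gray*px units; widths are in cm.
    Bar-dependent values are NaN when the profile has no bars.
    """

    darkest_intensity: float
    lightest_intensity: float
    range_intensity: float
    covariance: float
    avg_bar_intensity: float
    avg_interbar_intensity: float
    differential_intensity: float
    n_bars: int
    percent_barring: float
    avg_bar_width_cm: float
    avg_interbar_width_cm: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_traits(
    profile: IntensityProfile,
    seg: BarSegmentation | None = None,
    *,
    positional_variance: bool = False,
) -> TraitVector:
    """Compute the eleven measures for one individual.

    ``seg`` must have been produced from ``profile`` (it is recomputed when
    omitted).  ``positional_variance=True`` replaces the literal
    cov(position, intensity) definition of the covariance trait with the
    variance of intensity along the profile; the literal definition is the
    default.
    """
    values = profile.values
    if seg is None:
        seg = segment_bars(profile)
    if seg.length_px != profile.length_px:
        raise ValueError(
            f"segmentation length {seg.length_px} != profile length {profile.length_px}"
        )
    n = values.size
    darkest = float(values.min())
    lightest = float(values.max())
    if positional_variance:
        cov = float(np.var(values, ddof=1)) if n > 1 else float("nan")
    else:
        pos = np.arange(n, dtype=float)
        cov = float(np.cov(pos, values, ddof=1)[0, 1]) if n > 1 else float("nan")

    mask = seg.bar_mask()
    if seg.n_bars > 0:
        bar_mean = float(values[mask].mean())
        bar_widths = np.array([e - s for s, e in seg.bars], dtype=float)
        avg_bar_width = float(bar_widths.mean()) * profile.scale_cm_per_px
    else:
        bar_mean = float("nan")
        avg_bar_width = float("nan")
    if seg.interbars:
        interbar_mean = float(values[~mask].mean())
        inter_widths = np.array([e - s for s, e in seg.interbars], dtype=float)
        avg_interbar_width = float(inter_widths.mean()) * profile.scale_cm_per_px
    else:
        interbar_mean = float("nan")
        avg_interbar_width = float("nan")

    return TraitVector(
        darkest_intensity=darkest,
        lightest_intensity=lightest,
        range_intensity=lightest - darkest,
        covariance=cov,
        avg_bar_intensity=bar_mean,
        avg_interbar_intensity=interbar_mean,
        differential_intensity=interbar_mean - bar_mean,
        n_bars=seg.n_bars,
        percent_barring=float(mask.sum()) / n,
        avg_bar_width_cm=avg_bar_width,
        avg_interbar_width_cm=avg_interbar_width,
    )


def build_trait_table(
    profiles: Iterable[IntensityProfile],
    min_run: int = 5,
    **trait_kwargs,
) -> pd.DataFrame:
    """Segment each profile and assemble the per-individual trait table.

    Returns one row per individual with metadata columns (``individual_id``,
    ``group``, ``sex``, ``standard_length_cm``) followed by the eleven traits.
    """
    rows = []
    for p in profiles:
        tv = compute_traits(p, segment_bars(p, min_run=min_run), **trait_kwargs)
        rows.append(
            {
                "individual_id": p.individual_id,
                "group": p.group,
                "sex": p.sex,
                "standard_length_cm": (
                    np.nan if p.standard_length_cm is None else p.standard_length_cm
                ),
                **tv.as_dict(),
            }
        )
    if not rows:
        raise ValueError("no profiles supplied")
    return pd.DataFrame(rows)


def residualize(
    table: pd.DataFrame,
    traits: Sequence[str] = TRAIT_NAMES,
    fit_population: pd.Series | np.ndarray | None = None,
    length_col: str = "standard_length_cm",
) -> pd.DataFrame:
    """Regress each trait on standard length; append ``<trait>_resid`` columns.

    The ordinary-least-squares line is fitted over ``fit_population`` (a
    boolean row filter; default all rows — parentals and hybrids together)
    and residuals observed - predicted are computed for every row with data.
    Idempotent: residualizing residual columns returns them unchanged.
    """
    out = table.copy()
    sl = pd.to_numeric(out[length_col], errors="coerce").to_numpy(dtype=float)
    fit_mask = (
        np.ones(len(out), dtype=bool)
        if fit_population is None
        else np.asarray(fit_population, dtype=bool)
    )
    for trait in traits:
        y = pd.to_numeric(out[trait], errors="coerce").to_numpy(dtype=float)
        use = fit_mask & np.isfinite(y) & np.isfinite(sl)
        if use.sum() < 3:
            raise ValueError(f"{trait}: need >= 3 complete rows to fit allometry")
        if np.ptp(sl[use]) == 0:
            raise ValueError("standard length has zero variance in the fit population")
        slope, intercept = np.polyfit(sl[use], y[use], 1)
        resid = y - (intercept + slope * sl)
        resid[~np.isfinite(y) | ~np.isfinite(sl)] = np.nan
        out[f"{trait}_resid"] = resid
    return out


@dataclass
class GroupComparison:
    """One-way ANOVA with Tukey HSD post-hoc pairwise comparisons."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    group_means: dict[str, float]
    tukey: pd.DataFrame  # columns: group1, group2, diff, p_adj


def group_compare(values, groups) -> GroupComparison:
    """Compare a trait across groups: fixed-effects ANOVA + Tukey HSD.

    Degenerate data with zero between-group variance yields F = 0, p = 1
    (including the all-constant case where the within-group variance is also
    zero).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    labels = [str(g) for g in pd.unique(groups)]
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    for lab, s in zip(labels, samples):
        if s.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 observations")

    n = values.size
    k = len(samples)
    grand = values.mean()
    ssb = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    dfb, dfw = k - 1, n - k
    if ssb <= 0:
        f_stat, p = 0.0, 1.0
    elif ssw == 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ssb / dfb) / (ssw / dfw)
        p = float(stats.f.sf(f_stat, dfb, dfw))

    pairs = []
    if ssw == 0:
        # Tukey undefined without within-group variance; p is 0/1 by mean equality.
        for i in range(k):
            for j in range(i + 1, k):
                diff = samples[j].mean() - samples[i].mean()
                pairs.append((labels[i], labels[j], diff, 1.0 if diff == 0 else 0.0))
    else:
        res = stats.tukey_hsd(*samples)
        for i in range(k):
            for j in range(i + 1, k):
                pairs.append(
                    (
                        labels[i],
                        labels[j],
                        float(samples[j].mean() - samples[i].mean()),
                        float(res.pvalue[i, j]),
                    )
                )
    tukey = pd.DataFrame(pairs, columns=["group1", "group2", "diff", "p_adj"])
    return GroupComparison(
        f_statistic=float(f_stat),
        p_value=float(p),
        df_between=dfb,
        df_within=dfw,
        group_means={lab: float(s.mean()) for lab, s in zip(labels, samples)},
        tukey=tukey,
    )


def trait_correlations(
    table: pd.DataFrame,
    traits: Sequence[str] = TRAIT_NAMES,
    population: pd.Series | np.ndarray | None = None,
    use_residuals: bool = True,
    length_col: str = "standard_length_cm",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations among traits and standard length.

    Size-corrected (residual) trait values are used when available, except
    for standard length itself which enters raw.  Returns (r, p) matrices.
    Zero-variance traits yield NaN cells with a warning.
    """
    sub = table if population is None else table.loc[np.asarray(population, dtype=bool)]
    cols: dict[str, np.ndarray] = {}
    for t in traits:
        col = f"{t}_resid" if use_residuals and f"{t}_resid" in sub.columns else t
        cols[t] = pd.to_numeric(sub[col], errors="coerce").to_numpy(dtype=float)
    if length_col in sub.columns:
        cols[length_col] = pd.to_numeric(sub[length_col], errors="coerce").to_numpy(float)

    names = list(cols)
    m = len(names)
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i, m):
            x, y = cols[names[i]], cols[names[j]]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                continue
            if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                warnings.warn(
                    f"zero variance in {names[i]} or {names[j]}; correlation undefined"
                )
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
            else:
                res = stats.pearsonr(x[ok], y[ok])
                r[i, j] = r[j, i] = float(res.statistic)
                p[i, j] = p[j, i] = float(res.pvalue)
    return (
        pd.DataFrame(r, index=names, columns=names),
        pd.DataFrame(p, index=names, columns=names),
    )
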