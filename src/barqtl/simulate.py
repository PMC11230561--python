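"""Synthetic barred-flank profiles and F2 intercrosses with known truth.

Two generators make every downstream stage testable without raw data: a
profile painter that lays down rectangular dark bars on a lighter background
(with optional width jitter, a linear anterior-posterior trend, Gaussian
noise and edge smoothing) while recording the exact painted intervals, and
a meiosis simulator that drops gametes down each linkage group as a Markov
chain with Haldane recombination probabilities (no interference), plants
additive/dominant QTL, and adds an allometric standard-length effect plus
Gaussian residual noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .cross import AA, BB, MISSING, CrossData, LinkageMap, haldane_r
from .profiles import GROUPS, IntensityProfile

Interval = tuple[int, int]


@dataclass
class ProfileSpec:
    """Recipe for one synthetic flank profile.

    Widths are means in pixels; ``width_jitter`` draws each segment width
    uniformly within +/- that fraction of its mean.  ``background_slope``
    adds a linear anterior->posterior trend in gray units per pixel.
    ``edge_sigma`` > 0 smooths bar edges with a Gaussian kernel (default
    off so painted intervals are unambiguous ground truth).
    """

    length_px: int = 200
    n_bars: int = 6
    bar_width_px: int = 11
    interbar_width_px: int = 15
    width_jitter: float = 0.0
    bar_level: float = 70.0
    interbar_level: float = 170.0
    background_slope: float = 0.0
    noise_sd: float = 0.0
    edge_sigma: float = 0.0
    scale_cm_per_px: float = 0.0072
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_px < 1 or self.n_bars < 0:
            raise ValueError("length_px must be >= 1 and n_bars >= 0")
        if self.bar_width_px < 1 or self.interbar_width_px < 1:
            raise ValueError("segment widths must be positive")
        if not 0 <= self.width_jitter < 1:
            raise ValueError("width_jitter must be in [0, 1)")
        for lv in (self.bar_level, self.interbar_level):
            if not 0 <= lv <= 255:
                raise ValueError("gray levels must be in [0, 255]")
        if self.n_bars >= 1 and not self.bar_level < self.interbar_level:
            raise ValueError("bar_level must be darker (smaller) than interbar_level")
        if self.noise_sd < 0 or self.edge_sigma < 0:
            raise ValueError("noise_sd and edge_sigma must be >= 0")


def generate_profile(
    spec: ProfileSpec,
    *,
    individual_id: str = "sim",
    group: str = "F2",
    sex: str = "unknown",
    standard_length_cm: float | None = None,
) -> tuple[IntensityProfile, list[Interval]]:
    """Paint a profile from ``spec``; return it with the true bar intervals.

    The layout alternates interbar / bar / interbar ... starting and ending
    with an interbar; any pixels left over after the jittered widths extend
    the trailing interbar.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)

    def draw_width(mean: int) -> int:
        if spec.width_jitter == 0:
            return int(mean)
        lo = mean * (1 - spec.width_jitter)
        hi = mean * (1 + spec.width_jitter)
        return max(1, int(round(rng.uniform(lo, hi))))

    bar_w = [draw_width(spec.bar_width_px) for _ in range(spec.n_bars)]
    gap_w = [draw_width(spec.interbar_width_px) for _ in range(spec.n_bars)]
    used = sum(bar_w) + sum(gap_w)
    if used > spec.length_px:
        raise ValueError(
            f"requested segments ({used} px) exceed profile length {spec.length_px}"
        )

    bars: list[Interval] = []
    cursor = 0
    for g, b in zip(gap_w, bar_w):
        cursor += g
        bars.append((cursor, cursor + b))
        cursor += b

    values = np.full(spec.length_px, float(spec.interbar_level))
    for s, e in bars:
        values[s:e] = spec.bar_level
    if spec.edge_sigma > 0:
        values = gaussian_filter1d(values, spec.edge_sigma, mode="nearest")
    values = values + spec.background_slope * np.arange(spec.length_px)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, spec.length_px)
    profile = IntensityProfile(
        values=np.clip(values, 0.0, 255.0),
        scale_cm_per_px=spec.scale_cm_per_px,
        individual_id=individual_id,
        group=group,
        sex=sex,
        standard_length_cm=standard_length_cm,
    )
    return profile, bars


@dataclass
class CohortSpec:
    """A cohort of profiles sharing one recipe (parental line or F2)."""

    group: str
    n: int
    profile: ProfileSpec = field(default_factory=ProfileSpec)
    level_sd: float = 8.0  # per-individual shift of both gray levels
    standard_length_mean_cm: float = 4.1
    standard_length_sd_cm: float = 0.5

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.n < 1:
            raise ValueError(f"cohort {self.group!r} is empty")

    @property
    def contrast(self) -> float:
        return self.profile.interbar_level - self.profile.bar_level


def default_cohorts(
    n_parental_A: int = 10, n_parental_M: int = 6, n_f2: int = 322
) -> list[CohortSpec]:
    """Cohort recipes emulating the study populations.

    The Aulonocara-like parental line carries strong high-contrast bars, the
    Metriaclima-like line weak low-contrast bars with noisier profiles, and
    the F2 hybrids are intermediate and variable.
    """
    return [
        CohortSpec(
            "parental_A",
            n_parental_A,
            ProfileSpec(bar_level=45, interbar_level=190, noise_sd=8, width_jitter=0.2),
        ),
        CohortSpec(
            "parental_M",
            n_parental_M,
            ProfileSpec(bar_level=115, interbar_level=155, noise_sd=14, width_jitter=0.25),
        ),
        CohortSpec(
            "F2",
            n_f2,
            ProfileSpec(bar_level=75, interbar_level=175, noise_sd=10, width_jitter=0.25),
        ),
    ]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def generate_population_profiles(
    cohorts: list[CohortSpec], seed: int = 0
) -> list[IntensityProfile]:
    """Generate all cohorts' profiles with group/sex/standard-length metadata.

    Sex is assigned 50/50 and carried as metadata only; standard length is
    drawn lognormal per cohort.  Deterministic given ``seed``.
    """
    if not cohorts:
        raise ValueError("no cohorts requested")
    rng = np.random.default_rng(seed)
    out: list[IntensityProfile] = []
    for cohort in cohorts:
        mu, sigma = _lognormal_params(
            cohort.standard_length_mean_cm, cohort.standard_length_sd_cm
        )
        for i in range(cohort.n):
            shift = rng.normal(0.0, cohort.level_sd) if cohort.level_sd > 0 else 0.0
            spec = ProfileSpec(
                **{
                    **cohort.profile.__dict__,
                    "bar_level": float(np.clip(cohort.profile.bar_level + shift, 0, 254)),
                    "interbar_level": float(
                        np.clip(cohort.profile.interbar_level + shift, 1, 255)
                    ),
                    "seed": int(rng.integers(2**31)),
                }
            )
            sex = "F" if rng.random() < 0.5 else "M"
            sl = float(rng.lognormal(mu, sigma))
            profile, _ = generate_profile(
                spec,
                individual_id=f"{cohort.group}_{i + 1:03d}",
                group=cohort.group,
                sex=sex,
                standard_length_cm=sl,
            )
            out.append(profile)
    return out


@dataclass
class PlantedQTL:
    """A known causal locus: genotype effects (-a, d, +a) for (AA, AB, BB)."""

    linkage_group: str
    position_cM: float
    trait: str
    a: float = 0.0
    d: float = 0.0


@dataclass
class CrossSimSpec:
    """Recipe for a simulated F2 intercross.

    ``residual_sd`` is either one value for every trait or a per-trait
    mapping; ``allometry`` maps trait -> (slope, intercept) against standard
    length in cm.  Standard length is drawn lognormal.
    """

    lmap: LinkageMap
    n_individuals: int
    qtl: list[PlantedQTL] = field(default_factory=list)
    traits: list[str] = field(default_factory=list)
    residual_sd: float | dict[str, float] = 1.0
    allometry: dict[str, tuple[float, float]] = field(default_factory=dict)
    standard_length_mean_cm: float = 4.1
    standard_length_sd_cm: float = 0.5
    missing_genotype_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if not 0 <= self.missing_genotype_rate < 1:
            raise ValueError("missing_genotype_rate must be in [0, 1)")
        for q in self.qtl:
            if q.linkage_group not in self.lmap.groups:
                raise ValueError(f"QTL on unknown linkage group {q.linkage_group!r}")
            pos = self.lmap.positions(q.linkage_group)
            if not pos[0] <= q.position_cM <= pos[-1]:
                raise ValueError(
                    f"QTL at {q.position_cM} cM outside {q.linkage_group} "
                    f"[{pos[0]}, {pos[-1]}]"
                )

    def trait_names(self) -> list[str]:
        names = list(self.traits)
        for source in (
            [q.trait for q in self.qtl],
            list(self.residual_sd) if isinstance(self.residual_sd, dict) else [],
            list(self.allometry),
        ):
            for t in source:
                if t not in names:
                    names.append(t)
        return names or ["pheno"]

    def sd_for(self, trait: str) -> float:
        sd = (
            self.residual_sd.get(trait, 1.0)
            if isinstance(self.residual_sd, dict)
            else self.residual_sd
        )
        if not sd > 0:
            raise ValueError(f"residual_sd for {trait!r} must be positive")
        return float(sd)


def simulate_gametes(
    positions_cM: np.ndarray, n_gametes: int, rng: np.random.Generator
) -> np.ndarray:
    """Parental origin (0/1) of ``n_gametes`` gametes at each locus.

    A Markov chain along the linkage group: origin at the first locus is
    Bernoulli(1/2), and switches between adjacent loci with the Haldane
    recombination probability of their distance (no interference).
    """
    pos = np.asarray(positions_cM, dtype=float)
    g = np.empty((n_gametes, pos.size), dtype=np.int8)
    g[:, 0] = rng.random(n_gametes) < 0.5
    r = haldane_r(np.diff(pos)) if pos.size > 1 else np.empty(0)
    for k in range(1, pos.size):
        flip = rng.random(n_gametes) < r[k - 1]
        g[:, k] = g[:, k - 1] ^ flip
    return g


def simulate_f2_cross(spec: CrossSimSpec) -> CrossData:
    """Simulate an F2 intercross with planted QTL.

    Each individual receives two independent gametes from everywhere-
    heterozygous F1 parents; the genotype is the count of B alleles (0=AA,
    1=AB, 2=BB).  Phenotypes sum the planted per-QTL effects, the allometric
    standard-length term and Gaussian residual noise; genotypes are then
    masked to missing at ``missing_genotype_rate``.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    mu, sigma = _lognormal_params(
        spec.standard_length_mean_cm, spec.standard_length_sd_cm
    )
    sl = rng.lognormal(mu, sigma, n)

    marker_cols: dict[str, np.ndarray] = {}
    qtl_geno: dict[int, np.ndarray] = {}
    for lg, markers in spec.lmap.groups.items():
        qtl_here = [(i, q) for i, q in enumerate(spec.qtl) if q.linkage_group == lg]
        loci = sorted({pos for _, pos in markers} | {q.position_cM for _, q in qtl_here})
        loci_arr = np.array(loci)
        g1 = simulate_gametes(loci_arr, n, rng)
        g2 = simulate_gametes(loci_arr, n, rng)
        geno = (g1 + g2).astype(np.int8)  # 0=AA, 1=AB, 2=BB
        col_of = {pos: k for k, pos in enumerate(loci)}
        for name, pos in markers:
            marker_cols[name] = geno[:, col_of[pos]]
        for i, q in qtl_here:
            qtl_geno[i] = geno[:, col_of[q.position_cM]]

    traits = spec.trait_names()
    phen = pd.DataFrame(index=pd.Index([f"F2_{i + 1:04d}" for i in range(n)], name="id"))
    phen["standard_length_cm"] = sl
    for t in traits:
        y = np.zeros(n)
        for i, q in enumerate(spec.qtl):
            if q.trait != t:
                continue
            g = qtl_geno[i]
            y += np.where(g == AA, -q.a, np.where(g == BB, q.a, q.d))
        if t in spec.allometry:
            slope, intercept = spec.allometry[t]
            y += slope * sl + intercept
        y += rng.normal(0.0, spec.sd_for(t), n)
        phen[t] = y

    geno_mat = np.column_stack([marker_cols[m] for m in spec.lmap.marker_names])
    if spec.missing_genotype_rate > 0:
        drop = rng.random(geno_mat.shape) < spec.missing_genotype_rate
        geno_mat = np.where(drop, MISSING, geno_mat).astype(np.int8)
    genotypes = pd.DataFrame(
        geno_mat, index=phen.index, columns=spec.lmap.marker_names
    )
    return CrossData(lmap=spec.lmap, genotypes=genotypes, phenotypes=phen)
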