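"""F2 intercross data model: linkage map, genotypes, QC and the genotype HMM.

An F2 cross of two inbred-like grandparents segregates AA : AB : BB close to
1 : 2 : 1 at every marker (A = allele from the Metriaclima granddam, B =
allele from the Aulonocara grandsire).  Marker positions live on a linkage
map in centiMorgans; the Haldane map function (no crossover interference)
converts map distance to recombination fraction.  A hidden Markov model
over the three genotype states fills in genotype probabilities at markers
and at pseudomarkers on a regular cM grid, which is what the scan engine
regresses phenotypes on.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

# Integer genotype codes used internally; strings 'A','H','B','-' on disk.
AA, AB, BB, MISSING = 0, 1, 2, -1
CODE_TO_INT = {"A": AA, "H": AB, "B": BB, "-": MISSING, "": MISSING}
INT_TO_CODE = {AA: "A", AB: "H", BB: "B", MISSING: "-"}


@dataclass
class LinkageMap:
    """Ordered markers per linkage group with positions in cM.

    ``groups`` maps linkage-group name -> list of (marker_name, position_cM),
    positions non-decreasing within a group.
    """

    groups: dict[str, list[tuple[str, float]]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for lg, markers in self.groups.items():
            if not markers:
                raise ValueError(f"linkage group {lg!r} has no markers")
            prev = -math.inf
            for name, pos in markers:
                if name in seen:
                    raise ValueError(f"duplicate marker name {name!r}")
                seen.add(name)
                if pos < 0:
                    raise ValueError(f"marker {name!r}: negative position {pos}")
                if pos < prev:
                    raise ValueError(f"marker {name!r}: positions must be non-decreasing")
                prev = pos

    @property
    def marker_names(self) -> list[str]:
        return [name for markers in self.groups.values() for name, _ in markers]

    def positions(self, lg: str) -> np.ndarray:
        return np.array([pos for _, pos in self.groups[lg]], dtype=float)

    def length_cM(self, lg: str) -> float:
        pos = self.positions(lg)
        return float(pos[-1] - pos[0])

    @property
    def total_length_cM(self) -> float:
        return sum(self.length_cM(lg) for lg in self.groups)


def make_grid_map(
    n_groups: int = 3, markers_per_group: int = 30, spacing_cM: float = 10.0
) -> LinkageMap:
    """Convenience builder: evenly spaced markers on numbered linkage groups."""
    groups = {
        f"LG{g + 1}": [
            (f"LG{g + 1}_m{i + 1}", i * spacing_cM) for i in range(markers_per_group)
        ]
        for g in range(n_groups)
    }
    return LinkageMap(groups)


@dataclass
class CrossData:
    """One F2 cross: map + genotype matrix + phenotype table.

    ``genotypes`` is individuals x markers with integer codes
    (0=AA, 1=AB, 2=BB, -1=missing); columns follow the map's marker order.
    ``phenotypes`` is individuals x traits (float, NaN = missing) and shares
    the genotype index.
    """

    lmap: LinkageMap
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        expected = self.lmap.marker_names
        if list(self.genotypes.columns) != expected:
            raise ValueError("genotype columns must match the map's marker order")
        vals = self.genotypes.to_numpy()
        if not np.isin(vals, [AA, AB, BB, MISSING]).all():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        if not self.genotypes.index.equals(self.phenotypes.index):
            raise ValueError("genotype and phenotype tables must share the same index")

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes)


def haldane_r(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for a map distance under the Haldane function.

    r = (1 - exp(-2 d)) / 2 with d in Morgans; no crossover interference.
    """
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cM) else r


def f2_transition_matrix(r: float) -> np.ndarray:
    """F2 genotype transition matrix from two independent gametes.

    Each gamete switches parental origin with probability ``r`` between the
    two loci; the genotype chain is the product of the two gamete chains.
    """
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


F2_PRIOR = np.array([0.25, 0.5, 0.25])


def segregation_qc(cross_or_genotypes, alpha: float = 0.05) -> pd.DataFrame:
    """Chi-square each marker's genotype counts against the F2 1:2:1 ratio.

    Returns a per-marker frame with observed counts, the chi-square
    statistic, raw and Bonferroni-adjusted p-values (raw p x number of
    testable markers, capped at 1) and a ``keep`` flag that is False when
    the adjusted p-value falls below ``alpha``.  Markers with no non-missing
    genotypes are flagged untestable and kept with a warning.
    """
    geno = (
        cross_or_genotypes.genotypes
        if isinstance(cross_or_genotypes, CrossData)
        else cross_or_genotypes
    )
    records = []
    for marker in geno.columns:
        col = geno[marker].to_numpy()
        n_aa = int((col == AA).sum())
        n_ab = int((col == AB).sum())
        n_bb = int((col == BB).sum())
        n = n_aa + n_ab + n_bb
        if n == 0:
            records.append((marker, 0, 0, 0, np.nan, np.nan, np.nan, True, False))
            continue
        expected = np.array([n / 4, n / 2, n / 4])
        chi2, p = stats.chisquare([n_aa, n_ab, n_bb], expected)
        records.append((marker, n_aa, n_ab, n_bb, float(chi2), float(p), np.nan, True, True))
    out = pd.DataFrame(
        records,
        columns=["marker", "n_AA", "n_AB", "n_BB", "chi2", "p_raw", "p_bonferroni",
                 "keep", "testable"],
    ).set_index("marker")
    n_tests = int(out["testable"].sum())
    if n_tests < len(out):
        warnings.warn("markers with no genotype calls are untestable and kept")
    if n_tests:
        out.loc[out["testable"], "p_bonferroni"] = np.minimum(
            out.loc[out["testable"], "p_raw"] * n_tests, 1.0
        )
        out.loc[out["testable"], "keep"] = out.loc[out["testable"], "p_bonferroni"] >= alpha
    return out


@dataclass
class GroupGrid:
    """Genotype probabilities for one linkage group on a cM grid."""

    name: str
    positions: np.ndarray  # (G,) cM
    is_marker: np.ndarray  # (G,) bool
    marker_names: list[str | None]  # None at pseudomarkers
    probs: np.ndarray  # (n_individuals, G, 3): p_AA, p_AB, p_BB


@dataclass
class GenotypeProbabilities:
    """Per-individual genotype probabilities at markers and pseudomarkers."""

    groups: list[GroupGrid]
    individuals: pd.Index

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def group(self, name: str) -> GroupGrid:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)


def _build_grid(positions: np.ndarray, step_cM: float):
    """Marker positions plus pseudomarkers so adjacent spacing <= step_cM."""
    grid: list[float] = [float(positions[0])]
    is_marker: list[bool] = [True]
    for p0, p1 in zip(positions[:-1], positions[1:]):
        gap = float(p1 - p0)
        if gap > step_cM * (1 + 1e-9):
            n_sub = math.ceil(gap / step_cM - 1e-9)
            for k in range(1, n_sub):
                grid.append(float(p0 + gap * k / n_sub))
                is_marker.append(False)
        grid.append(float(p1))
        is_marker.append(True)
    return np.array(grid), np.array(is_marker, dtype=bool)


def genotype_probabilities(
    cross: CrossData, step_cM: float = 1.0, error_rate: float = 1e-4
) -> GenotypeProbabilities:
    """Forward-backward genotype probabilities on a pseudomarker grid.

    Hidden states {AA, AB, BB} start from the F2 prior (1/4, 1/2, 1/4) and
    evolve with Haldane transition matrices between adjacent grid points.
    An observed genotype emits its own code with probability
    ``1 - error_rate`` (the error mass split evenly over the other two
    codes); missing genotypes and pseudomarkers are uninformative.
    """
    if step_cM <= 0:
        raise ValueError("step_cM must be positive")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    n = cross.n_individuals
    out: list[GroupGrid] = []
    for lg, markers in cross.lmap.groups.items():
        mpos = cross.lmap.positions(lg)
        grid, is_marker = _build_grid(mpos, step_cM)
        G = grid.size
        names: list[str | None] = [None] * G
        obs = np.full((n, G), MISSING, dtype=np.int8)
        m_iter = iter(markers)
        for gi in np.flatnonzero(is_marker):
            name, _ = next(m_iter)
            names[gi] = name
            obs[:, gi] = cross.genotypes[name].to_numpy()

        # Emission table: rows indexed by observed code (-1 -> uniform).
        emis = np.full((4, 3), 1.0)  # row 3 = missing
        for c in (AA, AB, BB):
            emis[c] = error_rate / 2.0
            emis[c, c] = 1.0 - error_rate
        E = emis[np.where(obs >= 0, obs, 3)]  # (n, G, 3)

        T = [f2_transition_matrix(haldane_r(float(d))) for d in np.diff(grid)]

        alpha = np.empty((n, G, 3))
        a = F2_PRIOR * E[:, 0]
        a /= a.sum(axis=1, keepdims=True)
        alpha[:, 0] = a
        for k in range(1, G):
            a = (a @ T[k - 1]) * E[:, k]
            a /= a.sum(axis=1, keepdims=True)
            alpha[:, k] = a

        beta = np.empty((n, G, 3))
        b = np.ones((n, 3))
        beta[:, -1] = b
        for k in range(G - 2, -1, -1):
            b = (E[:, k + 1] * b) @ T[k].T
            b /= b.sum(axis=1, keepdims=True)
            beta[:, k] = b

        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        out.append(GroupGrid(lg, grid, is_marker, names, post))
    return GenotypeProbabilities(groups=out, individuals=cross.genotypes.index)


# ---------------------------------------------------------------------------
# Cross CSV dialect
# ---------------------------------------------------------------------------
# Row 1: "id", trait names..., marker names...
# Row 2: blanks under id/traits, linkage-group label under each marker
# Row 3: blanks, then cM position under each marker
# Rows 4+: individual id, trait values (empty = missing), codes A/H/B/-


def write_cross_csv(cross: CrossData, path: str | Path) -> None:
    traits = list(cross.phenotypes.columns)
    markers = cross.lmap.marker_names
    lg_of = {name: lg for lg, ms in cross.lmap.groups.items() for name, _ in ms}
    pos_of = {name: pos for ms in cross.lmap.groups.values() for name, pos in ms}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id"] + traits + markers)
        w.writerow([""] + [""] * len(traits) + [lg_of[m] for m in markers])
        w.writerow([""] + [""] * len(traits) + [repr(float(pos_of[m])) for m in markers])
        geno = cross.genotypes.to_numpy()
        phen = cross.phenotypes.to_numpy()
        for i, ind in enumerate(cross.genotypes.index):
            row = [str(ind)]
            row += ["" if not np.isfinite(v) else repr(float(v)) for v in phen[i]]
            row += [INT_TO_CODE[int(g)] for g in geno[i]]
            w.writerow(row)


def read_cross_csv(path: str | Path) -> CrossData:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise ValueError(f"{path}: cross CSV needs 3 header rows plus data")
    header, lg_row, pos_row = rows[0], rows[1], rows[2]
    if header[0] != "id":
        raise ValueError(f"{path}: first column must be 'id'")
    # Traits are the leading columns whose linkage-group cell is blank.
    n_cols = len(header)
    first_marker = next(
        (j for j in range(1, n_cols) if lg_row[j].strip() != ""), n_cols
    )
    traits = header[1:first_marker]
    markers = header[first_marker:]
    if not markers:
        raise ValueError(f"{path}: no marker columns found")

    groups: dict[str, list[tuple[str, float]]] = {}
    for j, m in enumerate(markers, start=first_marker):
        lg = lg_row[j].strip()
        try:
            pos = float(pos_row[j])
        except ValueError as exc:
            raise ValueError(f"{path}: bad cM position for marker {m!r}") from exc
        groups.setdefault(lg, []).append((m, pos))
    lmap = LinkageMap(groups)

    ids, phen_rows, geno_rows = [], [], []
    for r, row in enumerate(rows[3:], start=4):
        if not row or all(c == "" for c in row):
            continue
        ids.append(row[0])
        phen_rows.append(
            [float(c) if c.strip() != "" else np.nan for c in row[1:first_marker]]
        )
        try:
            geno_rows.append([CODE_TO_INT[c.strip()] for c in row[first_marker:]])
        except KeyError as exc:
            raise ValueError(f"{path}:{r}: unknown genotype code {exc}") from exc
    index = pd.Index(ids, name="id")
    genotypes = pd.DataFrame(
        np.array(geno_rows, dtype=np.int8), index=index, columns=markers
    )
    # read order == map order because groups dict preserves insertion order
    phenotypes = pd.DataFrame(np.array(phen_rows, dtype=float), index=index, columns=traits)
    return CrossData(lmap=lmap, genotypes=genotypes[lmap.marker_names], phenotypes=phenotypes)
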