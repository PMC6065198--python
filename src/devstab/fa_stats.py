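"""Fluctuating asymmetry via the FA10 index.

Fluctuating asymmetry (FA) — small random left-right deviations of a
bilaterally symmetric trait — estimates developmental noise, but a naive
left-right variance confounds it with digitization error.  The FA10 index
(Palmer & Strobeck's index 10) removes that confound with a balanced
two-way mixed ANOVA on repeated measurements:

    trait ~ side (fixed) + individual (random) + side x individual,
    M replicate digitizations per wing.

The side x individual interaction mean square captures FA plus measurement
error; the within-cell error mean square captures measurement error alone.
The FA10 estimate is the interaction variance component

    FA10 = (MS_interaction - MS_error) / M,

floored at zero (the raw value is kept for diagnostics).  Two F-tests
accompany it: interaction vs error (is FA real, i.e. larger than
measurement error?) and side vs interaction (directional asymmetry).
Genotypes are compared by the ratio of their FA10 estimates against an F
distribution on the two interaction degrees of freedom.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, ParameterError
from .morphometry import LEFT, RIGHT


@dataclass(frozen=True)
class AnovaDecomposition:
    """Mean squares and degrees of freedom of the sides ANOVA."""

    n: int                  # individuals
    s: int                  # sides (2)
    M: int                  # replicate sessions
    ms_side: float
    ms_individual: float
    ms_interaction: float
    ms_error: float
    df_side: int
    df_individual: int
    df_interaction: int
    df_error: int

    @property
    def total_ss(self) -> float:
        return (
            self.ms_side * self.df_side
            + self.ms_individual * self.df_individual
            + self.ms_interaction * self.df_interaction
            + self.ms_error * self.df_error
        )


@dataclass(frozen=True)
class FAEstimate:
    """FA10 estimate with its ANOVA provenance."""

    genotype: str
    fa10: float                 # floored at 0
    fa10_raw: float             # may be negative by sampling
    interaction_F: float
    interaction_p: float
    da_F: float
    da_p: float
    n: int
    M: int
    df_interaction: int
    df_error: int
    ms_side: float
    ms_individual: float
    ms_interaction: float
    ms_error: float


@dataclass(frozen=True)
class FAComparison:
    genotype_a: str
    genotype_b: str
    F: float
    df1: int
    df2: int
    p: float
    stars: str


def significance_stars(p: float) -> str:
    """Star coding at 0.05 / 0.01 / 0.001, as in the study's figures."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Two-way mixed ANOVA (sides ANOVA)
# ---------------------------------------------------------------------------

def _as_cell_array(measures: pd.DataFrame) -> np.ndarray:
    """Pivot a tidy SizeMeasure table into a (n, 2, M) value array.

    Requires a balanced design: both sides and all sessions for every
    individual; session replicates within a wing keep session order.
    """
    required = {"individual", "side", "session", "value"}
    missing = required - set(measures.columns)
    if missing:
        raise ParameterError(f"measures table missing columns {sorted(missing)}")
    if "trait" in measures.columns and measures["trait"].nunique() > 1:
        raise ParameterError(
            f"measures mix traits {sorted(measures['trait'].unique())}; "
            "filter to one trait first"
        )
    individuals = sorted(measures["individual"].astype(str).unique())
    sessions = sorted(measures["session"].unique())
    n, m = len(individuals), len(sessions)
    arr = np.full((n, 2, m), np.nan)
    idx = {ind: i for i, ind in enumerate(individuals)}
    sidx = {LEFT: 0, RIGHT: 1}
    sess_idx = {sess: j for j, sess in enumerate(sessions)}
    for row in measures.itertuples(index=False):
        side = str(row.side)
        if side not in sidx:
            raise ParameterError(f"unnormalized side label {side!r}")
        arr[idx[str(row.individual)], sidx[side], sess_idx[row.session]] = row.value
    bad = np.argwhere(np.isnan(arr).any(axis=(1, 2))).ravel()
    if bad.size:
        names = [individuals[i] for i in bad]
        raise DesignError(
            f"unbalanced design; individuals missing cells: {names}"
        )
    return arr


def sides_anova_array(values: np.ndarray) -> AnovaDecomposition:
    """Balanced two-way mixed ANOVA on a (n, 2, M) value array.

    Individuals random, side fixed, M replicate measurements per cell.
    M >= 2 is required so measurement error is separable from FA.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3 or values.shape[1] != 2:
        raise ParameterError("expected array of shape (n, 2, M)")
    n, s, m = values.shape
    if n < 2:
        raise ParameterError("need at least 2 individuals")
    if m < 2:
        raise ParameterError(
            "M = 1: measurement error cannot be separated from FA; "
            "digitize each wing at least twice"
        )
    grand = values.mean()
    ind_means = values.mean(axis=(1, 2))
    side_means = values.mean(axis=(0, 2))
    cell_means = values.mean(axis=2)

    ss_side = n * m * float(((side_means - grand) ** 2).sum())
    ss_ind = s * m * float(((ind_means - grand) ** 2).sum())
    interaction_dev = (
        cell_means - ind_means[:, None] - side_means[None, :] + grand
    )
    ss_int = m * float((interaction_dev ** 2).sum())
    ss_err = float(((values - cell_means[:, :, None]) ** 2).sum())

    df_side = s - 1
    df_ind = n - 1
    df_int = (n - 1) * (s - 1)
    df_err = n * s * (m - 1)
    return AnovaDecomposition(
        n=n, s=s, M=m,
        ms_side=ss_side / df_side,
        ms_individual=ss_ind / df_ind,
        ms_interaction=ss_int / df_int,
        ms_error=ss_err / df_err,
        df_side=df_side, df_individual=df_ind,
        df_interaction=df_int, df_error=df_err,
    )


def sides_anova(measures: pd.DataFrame) -> AnovaDecomposition:
    """Sides ANOVA from a tidy SizeMeasure table (one genotype, one trait)."""
    return sides_anova_array(_as_cell_array(measures))


# ---------------------------------------------------------------------------
# FA10 and genotype comparison
# ---------------------------------------------------------------------------

def fa10(
    decomp: AnovaDecomposition,
    genotype: str = "",
    convention: str = "component",
) -> FAEstimate:
    """FA10 estimate from a sides-ANOVA decomposition.

    ``convention="component"`` (default) reports the interaction variance
    component (MS_interaction - MS_error)/M; ``"difference-variance"``
    doubles it, matching the expected variance of the left-right difference.
    """
    if convention not in ("component", "difference-variance"):
        raise ParameterError(f"unknown convention {convention!r}")
    if decomp.M < 2:
        raise ParameterError("FA10 requires M >= 2 replicate measurements")
    raw = (decomp.ms_interaction - decomp.ms_error) / decomp.M
    if convention == "difference-variance":
        raw *= 2.0
    interaction_F = (
        decomp.ms_interaction / decomp.ms_error
        if decomp.ms_error > 0 else math.inf
    )
    interaction_p = float(
        stats.f.sf(interaction_F, decomp.df_interaction, decomp.df_error)
    ) if math.isfinite(interaction_F) else 0.0
    da_F = (
        decomp.ms_side / decomp.ms_interaction
        if decomp.ms_interaction > 0 else math.inf
    )
    da_p = float(
        stats.f.sf(da_F, decomp.df_side, decomp.df_interaction)
    ) if math.isfinite(da_F) else 0.0
    return FAEstimate(
        genotype=genotype,
        fa10=max(raw, 0.0),
        fa10_raw=raw,
        interaction_F=interaction_F,
        interaction_p=interaction_p,
        da_F=da_F,
        da_p=da_p,
        n=decomp.n,
        M=decomp.M,
        df_interaction=decomp.df_interaction,
        df_error=decomp.df_error,
        ms_side=decomp.ms_side,
        ms_individual=decomp.ms_individual,
        ms_interaction=decomp.ms_interaction,
        ms_error=decomp.ms_error,
    )


def compare_fa(
    a: FAEstimate, b: FAEstimate, two_tailed: bool = True
) -> FAComparison:
    """F-test comparing two genotypes' FA10 estimates.

    F = fa10_a / fa10_b on (df_interaction_a, df_interaction_b); the
    two-tailed p doubles the smaller tail (capped at 1).  The test treats
    each FA10 as a variance on its interaction degrees of freedom, which is
    approximate when measurement error is non-negligible.
    """
    if b.fa10 <= 0:
        raise ParameterError(
            f"genotype {b.genotype!r} has FA10 = {b.fa10} (raw "
            f"{b.fa10_raw:.3g}); F ratio undefined"
        )
    F = a.fa10 / b.fa10
    df1, df2 = a.df_interaction, b.df_interaction
    upper = float(stats.f.sf(F, df1, df2))
    lower = float(stats.f.cdf(F, df1, df2))
    p = min(1.0, 2.0 * min(upper, lower)) if two_tailed else upper
    return FAComparison(
        genotype_a=a.genotype, genotype_b=b.genotype,
        F=F, df1=df1, df2=df2, p=p, stars=significance_stars(p),
    )


def fa_table(
    datasets: dict[str, pd.DataFrame],
    control: str,
    convention: str = "component",
    two_tailed: bool = True,
    bonferroni: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FA10 per genotype plus each genotype's F-test against the control.

    Returns (estimates table, comparisons table).  No multiplicity
    correction by default; ``bonferroni=True`` multiplies comparison
    p-values by the number of comparisons.
    """
    if len(datasets) < 2:
        raise ParameterError("need at least 2 genotypes")
    if control not in datasets:
        raise ParameterError(
            f"control {control!r} not among genotypes {sorted(datasets)}"
        )
    estimates = {
        g: fa10(sides_anova(df), genotype=g, convention=convention)
        for g, df in datasets.items()
    }
    est_rows = [
        {
            "genotype": e.genotype, "n": e.n, "M": e.M,
            "MS_side": e.ms_side, "MS_individual": e.ms_individual,
            "MS_interaction": e.ms_interaction, "MS_error": e.ms_error,
            "FA10": e.fa10, "FA10_raw": e.fa10_raw,
            "interaction_F": e.interaction_F, "interaction_p": e.interaction_p,
            "DA_F": e.da_F, "DA_p": e.da_p,
        }
        for e in estimates.values()
    ]
    others = [g for g in datasets if g != control]
    comp_rows = []
    for g in others:
        comp = compare_fa(estimates[g], estimates[control], two_tailed)
        p = comp.p
        if bonferroni:
            p = min(1.0, p * len(others))
        comp_rows.append(
            {
                "genotype": g, "control": control, "F": comp.F,
                "df1": comp.df1, "df2": comp.df2, "p": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(est_rows), pd.DataFrame(comp_rows)


# ---------------------------------------------------------------------------
# Brute-force oracle (kept here so external suites can cross-check)
# ---------------------------------------------------------------------------

def sides_anova_bruteforce(values: np.ndarray) -> AnovaDecomposition:
    """Direct sums-of-squares ANOVA via explicit loops over cells.

    Independent of :func:`sides_anova_array`'s vectorized path; intended
    for exhaustive small-design verification.
    """
    values = np.asarray(values, dtype=float)
    n, s, m = values.shape
    if m < 2 or n < 2:
        raise ParameterError("oracle needs n >= 2, M >= 2")
    total = [values[i, j, k] for i, j, k in
             itertools.product(range(n), range(s), range(m))]
    grand = sum(total) / len(total)
    ss_side = ss_ind = ss_int = ss_err = 0.0
    for j in range(s):
        mean_j = sum(values[i, j, k] for i in range(n) for k in range(m)) / (n * m)
        ss_side += n * m * (mean_j - grand) ** 2
    for i in range(n):
        mean_i = sum(values[i, j, k] for j in range(s) for k in range(m)) / (s * m)
        ss_ind += s * m * (mean_i - grand) ** 2
    for i in range(n):
        mean_i = sum(values[i, j, k] for j in range(s) for k in range(m)) / (s * m)
        for j in range(s):
            mean_j = sum(values[p, j, k] for p in range(n) for k in range(m)) / (n * m)
            cell = sum(values[i, j, k] for k in range(m)) / m
            ss_int += m * (cell - mean_i - mean_j + grand) ** 2
            for k in range(m):
                ss_err += (values[i, j, k] - cell) ** 2
    return AnovaDecomposition(
        n=n, s=s, M=m,
        ms_side=ss_side / (s - 1),
        ms_individual=ss_ind / (n - 1),
        ms_interaction=ss_int / ((n - 1) * (s - 1)),
        ms_error=ss_err / (n * s * (m - 1)),
        df_side=s - 1, df_individual=n - 1,
        df_interaction=(n - 1) * (s - 1), df_error=n * s * (m - 1),
    )
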