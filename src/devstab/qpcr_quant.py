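"""Efficiency-corrected relative RT-qPCR quantification (Pfaffl method).

The Pfaffl ratio compares a target gene's expression between a treated and
a control condition while correcting for per-primer amplification
efficiency and normalizing on reference genes:

    ratio = E_target ** dCq_target / geomean_r(E_r ** dCq_r)

where dCq = mean Cq(control) - mean Cq(treated), E is the amplification
factor per cycle (2.0 = perfect doubling), and the geometric mean runs over
the reference genes (the study normalized on the geometric mean of Lam and
rin).  Technical replicates are averaged within biological replicates
before any Cq difference is formed; biological replicates are the unit of
dispersion for the accompanying t-test on log-ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, ParameterError

CONTROL = "control"
TREATED = "treated"

E_MIN, E_MAX = 1.0, 2.2  # amplification factor sanity bounds (exclusive min)


def parse_efficiency(value) -> float:
    """Normalize an efficiency entry to an amplification factor in (1, 2.2].

    Accepts the factor convention directly (e.g. ``1.95``), a percent
    string (``"95%"`` -> 1.95) or a bare percent number in [50, 120]
    (``95`` -> 1.95).  Anything else is rejected rather than silently
    misread — the two conventions differ by a factor of ~2 in log space.
    """
    if isinstance(value, str):
        text = value.strip()
        if text.endswith("%"):
            return parse_efficiency(float(text[:-1]))
        value = float(text)
    e = float(value)
    if 50.0 <= e <= 120.0:
        e = 1.0 + e / 100.0
    if not E_MIN < e <= E_MAX:
        raise ParameterError(
            f"amplification efficiency {value!r} outside ({E_MIN}, {E_MAX}] "
            "after conversion; supply a factor (1 < E <= 2.2) or a percent"
        )
    return e


@dataclass(frozen=True)
class RelativeExpression:
    target: str
    ratio: float
    references: tuple[str, ...]
    per_replicate: pd.DataFrame  # bio_rep, ratio, log2_ratio
    t_statistic: float | None
    p_value: float | None


def _mean_cq_by_bio(cq: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Technical replicates averaged within biological replicates."""
    sub = cq[cq["gene"] == gene]
    if sub.empty:
        raise DesignError(f"no Cq rows for gene {gene!r}")
    for cond in (CONTROL, TREATED):
        if not (sub["condition"] == cond).any():
            raise DesignError(f"gene {gene!r}: missing condition {cond!r}")
    if (sub["Cq"] <= 0).any():
        raise ParameterError(f"gene {gene!r}: non-positive Cq value")
    return (
        sub.groupby(["condition", "bio_rep"], as_index=False)["Cq"].mean()
    )


def pfaffl_ratio(
    cq: pd.DataFrame,
    target: str,
    references: list[str] | tuple[str, ...],
    efficiencies: dict[str, float] | pd.DataFrame,
) -> RelativeExpression:
    """Treated-vs-control expression ratio of ``target`` by the Pfaffl method.

    ``cq`` columns: gene, condition (control/treated), bio_rep, tech_rep,
    Cq.  ``efficiencies`` maps gene -> amplification factor (percent inputs
    accepted, see :func:`parse_efficiency`).  The overall ratio uses
    condition-mean Cq values; per-biological-replicate ratios (treated bio
    reps vs the control condition mean) feed a one-sample t-test of
    log2-ratio = 0.
    """
    if not references:
        raise ParameterError("at least one reference gene is required")
    if isinstance(efficiencies, pd.DataFrame):
        efficiencies = dict(zip(efficiencies["gene"], efficiencies["E"]))
    genes = [target, *references]
    eff = {}
    for gene in genes:
        if gene not in efficiencies:
            raise ParameterError(f"no efficiency supplied for gene {gene!r}")
        eff[gene] = parse_efficiency(efficiencies[gene])

    bio_means = {g: _mean_cq_by_bio(cq, g) for g in genes}

    def delta_cq(gene: str, treated_cq: float | None = None) -> float:
        tbl = bio_means[gene]
        control_mean = tbl.loc[tbl["condition"] == CONTROL, "Cq"].mean()
        if treated_cq is None:
            treated_cq = tbl.loc[tbl["condition"] == TREATED, "Cq"].mean()
        return float(control_mean - treated_cq)

    def ratio_from(treated_target_cq: float | None) -> float:
        numer = eff[target] ** delta_cq(target, treated_target_cq)
        ref_factors = [eff[r] ** delta_cq(r) for r in references]
        geomean = math.exp(np.mean([math.log(f) for f in ref_factors]))
        return numer / geomean

    overall = ratio_from(None)

    # per-biological-replicate ratios (references at their condition means)
    ttbl = bio_means[target]
    treated_rows = ttbl[ttbl["condition"] == TREATED]
    per_rep = pd.DataFrame(
        {
            "bio_rep": treated_rows["bio_rep"].to_numpy(),
            "ratio": [ratio_from(v) for v in treated_rows["Cq"]],
        }
    )
    per_rep["log2_ratio"] = np.log2(per_rep["ratio"])
    t_stat = p_val = None
    if len(per_rep) >= 2 and per_rep["log2_ratio"].std(ddof=1) > 0:
        t_stat, p_val = stats.ttest_1samp(per_rep["log2_ratio"], 0.0)
        t_stat, p_val = float(t_stat), float(p_val)
    return RelativeExpression(
        target=target,
        ratio=float(overall),
        references=tuple(references),
        per_replicate=per_rep,
        t_statistic=t_stat,
        p_value=p_val,
    )


def quantify_all(
    cq: pd.DataFrame,
    references: list[str] | tuple[str, ...],
    efficiencies: dict[str, float] | pd.DataFrame,
) -> pd.DataFrame:
    """Pfaffl ratios for every non-reference gene in the Cq table."""
    targets = [
        g for g in pd.unique(cq["gene"]) if g not in set(references)
    ]
    if not targets:
        raise ParameterError("no target genes besides the references")
    rows = []
    for target in targets:
        res = pfaffl_ratio(cq, target, references, efficiencies)
        rows.append(
            {
                "gene": target,
                "ratio": res.ratio,
                "log2_ratio": math.log2(res.ratio),
                "n_bio_reps": len(res.per_replicate),
                "t": res.t_statistic,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows)
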