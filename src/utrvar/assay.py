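"""Dual-reporter assay statistics.

Reproduces the analysis of a secreted-luciferase translation assay in which
Gaussia luciferase (GLuc) is translated downstream of a candidate 5'UTR and
secreted alkaline phosphatase (SeAP), expressed from the same construct,
normalises transfection efficiency.  Per transfection replicate, technical
duplicates are averaged, the GLuc/SeAP ratio is taken, and each ratio is
divided by the mean wildtype ratio of the same experiment, so the wildtype
experiment mean is 1 by construction and batch effects cancel.  Group
comparison is a one-way ANOVA followed by Tukey's HSD test on the linear
relative-activity scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ASSAY_COLUMNS = ["construct", "experiment", "replicate", "duplicate", "gluc", "seap"]

ALPHA = 0.05


class AssayError(ValueError):
    pass


def validate_assay_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the five-column per-well table (construct, experiment,
    replicate, duplicate, gluc, seap): positive signals, every construct in
    every experiment."""
    missing = set(ASSAY_COLUMNS) - set(table.columns)
    if missing:
        raise AssayError(f"assay table missing columns: {sorted(missing)}")
    if (table["gluc"] <= 0).any() or (table["seap"] <= 0).any():
        raise AssayError("luminescence signals must be positive")
    per_exp = table.groupby("experiment")["construct"].unique()
    all_constructs = set(table["construct"])
    for exp, cs in per_exp.items():
        absent = all_constructs - set(cs)
        if absent:
            raise AssayError(f"experiment {exp!r} missing constructs {sorted(absent)}")
    return table


def normalize(table: pd.DataFrame, wildtype: str = "wildtype") -> pd.DataFrame:
    """Per-replicate relative activities.

    Technical duplicates are averaged first (so n per construct equals the
    number of transfections, avoiding pseudo-replication); the GLuc/SeAP
    ratio is then referenced to the mean wildtype ratio of the same
    experiment.  Returns columns construct, experiment, replicate,
    relative_activity.
    """
    validate_assay_table(table)
    if wildtype not in set(table["construct"]):
        raise AssayError(f"no wildtype construct {wildtype!r} in assay table")
    per_rep = (
        table.groupby(["construct", "experiment", "replicate"], sort=False)[["gluc", "seap"]]
        .mean()
        .reset_index()
    )
    per_rep["ratio"] = per_rep["gluc"] / per_rep["seap"]
    wt_mean = (
        per_rep[per_rep["construct"] == wildtype]
        .groupby("experiment")["ratio"]
        .mean()
        .rename("wt_ratio")
    )
    if wt_mean.isna().any():
        raise AssayError("wildtype missing from an experiment")
    per_rep = per_rep.join(wt_mean, on="experiment")
    per_rep["relative_activity"] = per_rep["ratio"] / per_rep["wt_ratio"]
    return per_rep[["construct", "experiment", "replicate", "relative_activity"]]


@dataclass
class TukeyResult:
    """Pairwise Tukey HSD comparisons on the relative-activity scale.

    ``pairs`` maps the ordered pair (A, B) to (mean difference A - B,
    adjusted p, significant at alpha).  The paper-style convention reports
    (wildtype, variant), positive when the variant reduces activity.
    """

    pairs: dict[tuple[str, str], tuple[float, float, bool]]
    alpha: float = ALPHA

    def mean_difference(self, a: str, b: str) -> float:
        return self.pairs[(a, b)][0]

    def adjusted_p(self, a: str, b: str) -> float:
        return self.pairs[(a, b)][1]

    def significant(self, a: str, b: str) -> bool:
        return self.pairs[(a, b)][2]


@dataclass
class AnovaTukey:
    f_statistic: float
    p_value: float
    tukey: TukeyResult


def anova_tukey(
    normalized: pd.DataFrame, alpha: float = ALPHA
) -> AnovaTukey:
    """One-way ANOVA plus Tukey HSD over constructs.

    Adjusted p-values come from the studentized-range distribution with the
    pooled within-group variance (statsmodels).  Requires >=2 groups with
    >=2 observations each and non-degenerate within-group variance.
    """
    groups = {
        name: g["relative_activity"].to_numpy()
        for name, g in normalized.groupby("construct", sort=False)
    }
    if len(groups) < 2:
        raise AssayError("need at least two constructs")
    if any(len(v) < 2 for v in groups.values()):
        raise AssayError("need at least two observations per construct")
    values = list(groups.values())
    if all(np.allclose(v, v[0]) for v in values):
        raise AssayError("degenerate input: zero within-group variance in every group")
    f_stat, p = stats.f_oneway(*values)

    endog = normalized["relative_activity"].to_numpy()
    labels = normalized["construct"].to_numpy()
    res = pairwise_tukeyhsd(endog, labels, alpha=alpha)
    # statsmodels orders comparisons as combinations of the sorted groups
    from itertools import combinations

    pair_order = [(str(a), str(b)) for a, b in combinations(res.groupsunique, 2)]
    pairs: dict[tuple[str, str], tuple[float, float, bool]] = {}
    for (g1, g2), p_adj in zip(pair_order, res.pvalues):
        diff = float(np.mean(groups[g2]) - np.mean(groups[g1]))
        sig = bool(p_adj < alpha)
        pairs[(g2, g1)] = (diff, float(p_adj), sig)
        pairs[(g1, g2)] = (-diff, float(p_adj), sig)
    return AnovaTukey(float(f_stat), float(p), TukeyResult(pairs, alpha))


def percent_change(mean_difference: float) -> float:
    """Signed percent change of a variant versus wildtype.

    ``mean_difference`` follows the wildtype-minus-variant convention on the
    relative scale (wildtype mean = 1): a reduction (positive difference)
    maps to a negative percent, an increase to a positive percent.
    """
    return -100.0 * mean_difference


def format_p(p: float) -> str:
    """Report p-values below 1e-4 as '<0.0001'."""
    return "<0.0001" if p < 1e-4 else f"{p:.4g}"
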