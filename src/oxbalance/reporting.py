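"""Publication-style outputs: baseline tables, association tables, forest data.

Formatting follows the conventions of epidemiological baseline tables:
categorical cells as "count (percent%)" with two decimals, continuous cells
as "mean ± dispersion", p-values printed as "<0.0001" below 1e-4.  All
formatting is locale-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationResult, SubgroupResult

#: default variables summarised in a baseline table, by type
DEFAULT_CONTINUOUS = ("age", "sua_umol_l", "pir", "obs_total")
DEFAULT_CATEGORICAL = (
    "sex",
    "race",
    "bmi_category",
    "education",
    "hypertension",
    "hyperlipidemia",
    "diabetes",
    "smoking_binary",
    "drinking_binary",
)


def fmt_count_pct(count: int, total: int) -> str:
    """'319 (10.96%)' — percentage of the stratum total at two decimals."""
    return f"{count} ({count / total * 100:.2f}%)"


def fmt_mean_disp(mean: float, disp: float) -> str:
    return f"{mean:.2f} ± {disp:.2f}"


def fmt_p(p: float) -> str:
    """p-values at 4 decimals, '<0.0001' below 1e-4."""
    if np.isnan(p):
        return ""
    return "<0.0001" if p < 1e-4 else f"{p:.4f}"


@dataclass
class BaselineTable:
    """A formatted baseline-characteristics table plus per-variable p-values."""

    frame: pd.DataFrame
    p_values: dict[str, float]
    stratum_sizes: dict[str, int]


def _continuous_p(groups: list[np.ndarray]) -> float:
    groups = [g for g in groups if len(g) > 1]
    if len(groups) < 2:
        return np.nan
    if len(groups) == 2:
        return float(stats.ttest_ind(groups[0], groups[1], equal_var=False).pvalue)
    return float(stats.f_oneway(*groups).pvalue)


def baseline_table(
    records: pd.DataFrame,
    stratifier: str,
    continuous: Sequence[str] = DEFAULT_CONTINUOUS,
    categorical: Sequence[str] = DEFAULT_CATEGORICAL,
    dispersion: str = "sd",
) -> BaselineTable:
    """Baseline characteristics stratified by e.g. hyperuricemia or OBS quartile.

    Continuous variables are summarised as mean ± SD by default
    (``dispersion='se'`` switches to the standard error); categorical
    variables as count (percent of stratum).  p-values: Welch t-test for two
    strata / one-way ANOVA for more (continuous), chi-square test of
    independence (categorical).  Empty strata raise.
    """
    if dispersion not in ("sd", "se"):
        raise ValueError("dispersion must be 'sd' or 'se'")
    strata = records.groupby(stratifier, observed=False, sort=True)
    sizes = strata.size().to_dict()
    if any(n == 0 for n in sizes.values()) or len(sizes) == 0:
        raise ValueError(f"empty stratum for {stratifier!r}")
    level_names = list(sizes.keys())

    rows = []
    p_values: dict[str, float] = {}
    for var in continuous:
        if var not in records.columns:
            continue
        groups = [records.loc[records[stratifier] == lv, var].dropna().to_numpy()
                  for lv in level_names]
        p_values[var] = _continuous_p(groups)
        cells = {}
        for lv, g in zip(level_names, groups):
            disp = g.std(ddof=1) if dispersion == "sd" else g.std(ddof=1) / np.sqrt(len(g))
            cells[str(lv)] = fmt_mean_disp(g.mean(), disp)
        rows.append({"variable": var, "level": "", **cells, "p": fmt_p(p_values[var])})
    for var in categorical:
        if var not in records.columns:
            continue
        ct = pd.crosstab(records[var], records[stratifier])
        ct = ct.reindex(columns=level_names, fill_value=0)
        if ct.shape[0] > 1 and (ct.to_numpy().sum(axis=1) > 0).all():
            p_values[var] = float(stats.chi2_contingency(ct.to_numpy()).pvalue)
        else:
            p_values[var] = np.nan
        first = True
        for level in ct.index:
            cells = {
                str(lv): fmt_count_pct(int(ct.loc[level, lv]), int(sizes[lv]))
                for lv in level_names
            }
            rows.append(
                {
                    "variable": var,
                    "level": str(level),
                    **cells,
                    "p": fmt_p(p_values[var]) if first else "",
                }
            )
            first = False

    frame = pd.DataFrame(rows, columns=["variable", "level"] + [str(lv) for lv in level_names] + ["p"])
    return BaselineTable(frame=frame, p_values=p_values,
                         stratum_sizes={str(k): int(v) for k, v in sizes.items()})


def association_table(results: Iterable[AssociationResult]) -> pd.DataFrame:
    """Rows 'estimate (ci_low, ci_high) p'; the reference level prints
    '1.0(ref)' on the OR scale and '0' on the β scale."""
    results = list(results)
    if not results:
        raise ValueError("no association results to format")
    rows = []
    for r in results:
        if r.is_reference:
            cell = "1.0(ref)" if r.measure == "or" else "0"
        else:
            cell = f"{r.estimate:.2f} ({r.ci_low:.2f}, {r.ci_high:.2f}) {fmt_p(r.p_value)}"
        rows.append({"term": r.term, "summary": cell, "estimate": r.estimate,
                     "ci_low": r.ci_low, "ci_high": r.ci_high, "p_value": r.p_value,
                     "n_used": r.n_used})
    return pd.DataFrame(rows, columns=["term", "summary", "estimate", "ci_low",
                                       "ci_high", "p_value", "n_used"])


#: stable column order for forest-plot exports (golden-file contract)
FOREST_COLUMNS = (
    "stratifier",
    "stratum",
    "term",
    "estimate",
    "ci_low",
    "ci_high",
    "p_value",
    "n_used",
    "p_interaction",
)


def forest_data(subgroup_result: SubgroupResult) -> pd.DataFrame:
    """Serialise subgroup results to one row per stratum x exposure term,
    with the shared interaction p-value repeated; column order is stable."""
    rows = []
    for stratum, results in subgroup_result.strata.items():
        for r in results:
            if r.is_reference:
                continue
            rows.append(
                {
                    "stratifier": subgroup_result.stratifier,
                    "stratum": stratum,
                    "term": r.term,
                    "estimate": r.estimate,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p_value": r.p_value,
                    "n_used": r.n_used,
                    "p_interaction": subgroup_result.p_interaction,
                }
            )
    frame = pd.DataFrame(rows, columns=list(FOREST_COLUMNS))
    frame.attrs["skipped"] = list(subgroup_result.skipped)
    return frame
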