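"""Univariate layer: t-tests with Bonferroni correction, Pearson correlation
matrices of combination abundances, per-cell analyte normalization with a
responder cutoff, and simple linear regressions of analytes on the TIGIT+
fraction.

The Welch (unequal-variance) t-test is the default two-sample comparison;
Student's pooled-variance variant is available by flag. Thresholds are applied
with strict inequality throughout, and the Bonferroni-adjusted alpha for the
six pairwise four-group comparisons is displayed truncated (not rounded) to
three decimals — 0.05/6 = 0.008333... shown as 0.008 — while decisions use the
untruncated value.
"""
from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import AnalytePanel

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


@dataclasses.dataclass
class TestResult:
    comparison: str
    statistic: float
    df: float
    p: float
    adjusted_alpha: float
    displayed_alpha: float
    significant: bool


def _truncate(x: float, decimals: int = 3) -> float:
    factor = 10 ** decimals
    return math.floor(x * factor) / factor


def _group_series(design: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping == "hiv_only":
        return design["hiv"].map({0: "uninfected", 1: "hiv"})
    if grouping == "four_group":
        return (design["hiv"].map({0: "uninfected", 1: "hiv"})
                + "_" + design["age_group"].astype(str))
    raise StatsError(f"unknown grouping {grouping!r}")


def t_test_pairs(
    values: pd.Series,
    design: pd.DataFrame,
    grouping: str = "hiv_only",
    family_alpha: float = 0.05,
    welch: bool = True,
) -> list[TestResult]:
    """Two-tailed two-sample t-tests over all group pairs.

    ``four_group`` runs the six pairwise comparisons with Bonferroni-adjusted
    alpha ``family_alpha / 6``; ``hiv_only`` is the single unadjusted
    comparison. Groups with fewer than two subjects are skipped with a warning.
    """
    groups = _group_series(design, grouping)
    vals = values.reindex(design["subject_id"]).to_numpy(dtype=float)
    names = sorted(groups.unique())
    pairs = list(itertools.combinations(names, 2))
    adj_alpha = family_alpha / len(pairs)
    out = []
    for a, b in pairs:
        xa = vals[(groups == a).to_numpy()]
        xb = vals[(groups == b).to_numpy()]
        xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
        if len(xa) < 2 or len(xb) < 2:
            logger.warning("t_test_pairs: skipping %s vs %s (group < 2 subjects)", a, b)
            continue
        res = stats.ttest_ind(xa, xb, equal_var=not welch)
        df = float(getattr(res, "df", len(xa) + len(xb) - 2))
        p = float(res.pvalue)
        out.append(TestResult(
            comparison=f"{a} vs {b}",
            statistic=float(res.statistic),
            df=df,
            p=p,
            adjusted_alpha=adj_alpha,
            displayed_alpha=_truncate(adj_alpha),
            significant=p < adj_alpha,
        ))
    return out


def combo_correlation_matrix(
    signatures: pd.DataFrame,
    subjects: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations (with p-values) of the combo columns.

    Intended to be run separately per cohort stratum (uninfected vs HIV+, both
    age groups pooled within each). p-values are uncorrected. Constant columns
    yield NaN entries off the diagonal.
    """
    combo_cols = [c for c in signatures.columns if c.startswith("combo_")]
    table = signatures.loc[list(subjects), combo_cols] if subjects is not None \
        else signatures[combo_cols]
    table = table.dropna()
    if len(table) < 3:
        raise StatsError("need >= 3 subjects with non-missing abundances")
    k = len(combo_cols)
    r = pd.DataFrame(np.eye(k), index=combo_cols, columns=combo_cols)
    p = pd.DataFrame(np.ones((k, k)), index=combo_cols, columns=combo_cols)
    for i, a in enumerate(combo_cols):
        for b in combo_cols[i + 1:]:
            xa, xb = table[a].to_numpy(), table[b].to_numpy()
            if np.std(xa) == 0 or np.std(xb) == 0:
                logger.warning("correlation undefined for constant column pair (%s, %s)", a, b)
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = stats.pearsonr(xa, xb)
            r.loc[a, b] = r.loc[b, a] = float(res.statistic)
            p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return r, p


def normalize_per_cell(panel: AnalytePanel) -> AnalytePanel:
    """Divide each well concentration by the subject's cultured cell count."""
    if panel.per_cell_normalized:
        raise StatsError("panel is already per-cell normalized")
    if panel.cells_per_well is None:
        raise StatsError("cells_per_well is required for per-cell normalization")
    cells = panel.cells_per_well.reindex(panel.values.index)
    keep = cells.notna() & (cells > 0)
    if not keep.all():
        logger.warning("normalize_per_cell: dropping %d subjects without cell counts",
                       int((~keep).sum()))
    values = panel.values.loc[keep].div(cells[keep], axis=0)
    return AnalytePanel(
        values=values,
        units=panel.units.replace("/well", "/cell"),
        detection_mask=panel.detection_mask.loc[keep],
        cells_per_well=cells[keep],
        per_cell_normalized=True,
    )


def responder_filter(panel: AnalytePanel, min_fraction: float = 0.45) -> list[str]:
    """Analytes detected in at least ``min_fraction`` of subjects.

    The default 45% cutoff separates analytes the cohort substantially
    responds with from sporadically detected ones.
    """
    detected = panel.detection_mask.mean(axis=0)
    if min_fraction == 0:
        return [a for a in panel.analytes if panel.detection_mask[a].any()]
    return [a for a in panel.analytes if detected[a] >= min_fraction]


@dataclasses.dataclass
class RegressionResult:
    analyte: str
    stratum: str
    slope: float
    intercept: float
    r: float
    p: float
    n: int


def analyte_regressions(
    x: pd.Series,
    panel: AnalytePanel,
    design: pd.DataFrame,
    analytes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """OLS of each analyte on x (TIGIT+ fraction), per cohort stratum.

    Strata are uninfected and HIV+ (both age groups pooled within each).
    Returns one row per (analyte, stratum) with slope, Pearson r and two-sided
    slope p-value; zero x-variance strata are flagged as NaN.
    """
    analytes = list(analytes) if analytes is not None else panel.analytes
    rows = []
    for stratum, hiv_flag in (("uninfected", 0), ("hiv", 1)):
        subj = design.loc[design["hiv"] == hiv_flag, "subject_id"]
        subj = [s for s in subj if s in panel.values.index and s in x.index]
        if len(subj) < 3:
            raise StatsError(f"need >= 3 subjects in stratum {stratum}")
        xs = x.reindex(subj).to_numpy(dtype=float)
        for a in analytes:
            ys = panel.values.loc[subj, a].to_numpy(dtype=float)
            if np.std(xs) == 0:
                logger.warning("zero x-variance in stratum %s; regression undefined", stratum)
                rows.append(RegressionResult(a, stratum, np.nan, np.nan, np.nan, np.nan, len(subj)))
                continue
            res = stats.linregress(xs, ys)
            rows.append(RegressionResult(
                a, stratum, float(res.slope), float(res.intercept),
                float(res.rvalue), float(res.pvalue), len(subj),
            ))
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])
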