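"""Drug-response categorization and response-linked expression selection.

Cell lines are called resistant when the fitted IC50/EC50 lies above the
assay's maximum tested dose and sensitive when below the minimum dose (the
PRISM screen tested eight doses from 0.0006 to 10 µM).  In-window activities
are trichotomized by log10-scale tertiles of the dose window — an explicit,
configurable convention recorded in output metadata.  Genes differentially
expressed between sensitive and resistant lines are selected by a Welch
t-test (p < 0.05) combined with a linear-scale fold-change filter
(< 0.5 or > 2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .errors import InsufficientSamples, InvalidActivity

DEFAULT_DOSE_WINDOW = (0.0006, 10.0)  # µM
FOLD_CHANGE_BOUNDS = (0.5, 2.0)


@dataclass(frozen=True)
class DrugActivityRecord:
    """One fitted activity value for a (cell line, drug) pair, in µM."""

    cell_line: str
    drug: str
    metric: str  # "IC50" or "EC50"
    value: float
    min_dose: float = DEFAULT_DOSE_WINDOW[0]
    max_dose: float = DEFAULT_DOSE_WINDOW[1]
    category: str | None = None

    def __post_init__(self):
        if self.metric not in ("IC50", "EC50"):
            raise ValueError(f"metric must be IC50 or EC50, got {self.metric!r}")
        if not self.min_dose < self.max_dose:
            raise InvalidActivity("min_dose must be below max_dose")


def categorize_response(record: DrugActivityRecord) -> str:
    """Assign sensitive / partial / resistant against the dose window.

    Out-of-window values are categorical by definition: above the maximum
    dose ⇒ resistant, below the minimum ⇒ sensitive.  In-window values
    (boundaries inclusive) fall into log10-scale tertiles of the window, so
    an IC50 exactly at the maximum dose is resistant.
    """
    if not np.isfinite(record.value) or record.value <= 0:
        raise InvalidActivity(f"activity must be positive and finite, got {record.value}")
    if record.value > record.max_dose:
        return "resistant"
    if record.value < record.min_dose:
        return "sensitive"
    lo, hi = np.log10(record.min_dose), np.log10(record.max_dose)
    u = (np.log10(record.value) - lo) / (hi - lo)
    if u < 1 / 3:
        return "sensitive"
    if u < 2 / 3:
        return "partial"
    return "resistant"


def categorize_records(records: list[DrugActivityRecord]) -> list[DrugActivityRecord]:
    """Return copies of the records with their category filled in."""
    return [replace(r, category=categorize_response(r)) for r in records]


def de_by_response(
    matrix: pd.DataFrame,
    categories: pd.Series,
    *,
    alpha: float = 0.05,
    fc_bounds: tuple[float, float] = FOLD_CHANGE_BOUNDS,
    log_base: float | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Select genes differentially expressed in sensitive vs resistant lines.

    ``matrix`` is genes × cell lines on a linear scale (set ``log_base`` to
    de-log first — fold changes are ratios of linear-scale means).  Partial
    responders are ignored: the contrast is strict sensitive vs resistant.
    A gene is ``selected`` when p < alpha and its fold change
    mean(sensitive)/mean(resistant) is outside ``fc_bounds``; the direction
    column labels it higher-in-sensitive or higher-in-resistant.
    """
    if log_base is not None:
        matrix = np.power(float(log_base), matrix)
    cats = categories.reindex(matrix.columns)
    sens = matrix.loc[:, (cats == "sensitive").to_numpy()]
    res = matrix.loc[:, (cats == "resistant").to_numpy()]
    if sens.shape[1] < 3 or res.shape[1] < 3:
        raise InsufficientSamples(
            f"need ≥ 3 lines per group, got sensitive={sens.shape[1]}, resistant={res.shape[1]}"
        )
    t, p = stats.ttest_ind(sens.to_numpy(dtype=float), res.to_numpy(dtype=float),
                           axis=1, equal_var=equal_var)
    mean_s = sens.mean(axis=1)
    mean_r = res.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_s / mean_r
    lo, hi = fc_bounds
    selected = (p < alpha) & ((fc < lo) | (fc > hi))
    return pd.DataFrame({
        "t": t,
        "p": p,
        "mean_sensitive": mean_s,
        "mean_resistant": mean_r,
        "fold_change": fc,
        "direction": np.where(fc > 1, "higher-in-sensitive", "higher-in-resistant"),
        "selected": selected,
    }, index=matrix.index)


def mrna_protein_correlation(
    mrna: pd.DataFrame,
    protein: pd.DataFrame,
    pairs: list[tuple[str, str]],
    *,
    alpha: float = 0.05,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Pearson correlation per (mRNA gene, protein quantification) pair.

    One output row per pair, so a gene with two protein quantifications
    yields two rows.  Pairs with fewer than ``min_pairs`` shared cell lines
    or a constant vector are emitted with NaN statistics and flagged.
    """
    rows = []
    for gene, prot in pairs:
        row: dict = {"gene": gene, "protein_id": prot, "r": np.nan, "p": np.nan,
                     "n": 0, "significant": False, "flag": ""}
        if gene not in mrna.index or prot not in protein.index:
            row["flag"] = "missing"
            rows.append(row)
            continue
        shared = mrna.columns.intersection(protein.columns)
        x = mrna.loc[gene, shared].astype(float)
        y = protein.loc[prot, shared].astype(float)
        keep = x.notna() & y.notna()
        x, y = x[keep], y[keep]
        row["n"] = int(keep.sum())
        if row["n"] < min_pairs:
            row["flag"] = "too-few-pairs"
        elif x.nunique() <= 1 or y.nunique() <= 1:
            row["flag"] = "constant"
        else:
            r, p = stats.pearsonr(x, y)
            row.update(r=float(r), p=float(p), significant=bool(p < alpha))
        rows.append(row)
    return pd.DataFrame(rows)


def proportion_test(
    k1: int, n1: int, k2: int, n2: int, tails: str = "two"
) -> tuple[float, float]:
    """Pooled two-proportion z-test.

    ``tails="two"`` for a two-sided p, ``"one"`` for the one-sided
    alternative that the first proportion is larger.  Returns (z, p).
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2 and n1 > 0 and n2 > 0):
        raise ValueError("require 0 ≤ k ≤ n and n > 0 for both groups")
    alternative = {"two": "two-sided", "one": "larger"}[tails]
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative=alternative)
    return float(z), float(p)
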