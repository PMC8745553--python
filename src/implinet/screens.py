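"""CRISPR/RNAi dependency-score standardization and proliferation-gene calls.

Screens arrive as genes × cell-lines score matrices (NaN = not tested) with
designated essential (positive) and non-essential (negative) control gene
sets.  Standardization is the two-point affine map anchoring the control-set
medians at −1 (essential) and 0 (non-essential): per cell line for CRISPR
knockout scores, and on the across-line gene averages for RNAi (the
DEMETER2 output convention).  A score below −0.5 marks a significant
dependency; proliferation genes are called either by a ≥50%-of-tested-lines
majority or by a more-than-``min_lines`` count, in either assay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DegenerateControls

log = logging.getLogger(__name__)

SIGNIFICANT_THRESHOLD = -0.5
MIN_CONTROLS = 3


@dataclass
class DependencyScreen:
    """Genes × cell-lines dependency scores with control gene sets."""

    scores: pd.DataFrame
    essential_controls: frozenset[str]
    nonessential_controls: frozenset[str]
    assay: str = "CRISPR"

    def __post_init__(self) -> None:
        self.essential_controls = frozenset(self.essential_controls)
        self.nonessential_controls = frozenset(self.nonessential_controls)
        if not self.essential_controls or not self.nonessential_controls:
            raise ValueError("control sets must be nonempty")
        if self.essential_controls & self.nonessential_controls:
            raise ValueError("control sets must be disjoint")
        if self.assay not in ("CRISPR", "RNAi"):
            raise ValueError(f"assay must be CRISPR or RNAi, got {self.assay!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.scores.columns)

    def control_rows(self, which: str) -> pd.DataFrame:
        genes = self.essential_controls if which == "essential" else self.nonessential_controls
        return self.scores.loc[self.scores.index.intersection(sorted(genes))]


def normalize_crispr(screen: DependencyScreen) -> DependencyScreen:
    """Per-cell-line two-point standardization of knockout effects.

    After the map ``x' = (x − med_ne) / (med_ne − med_e)`` the median over
    non-essential controls is exactly 0 and over essential controls exactly
    −1 in every cell line.  Lines with < 3 measured controls in either set or
    coincident control medians raise :class:`DegenerateControls`.
    """
    ess = screen.control_rows("essential")
    ne = screen.control_rows("nonessential")
    out = screen.scores.copy()
    for line in screen.scores.columns:
        e_vals = ess[line].dropna()
        n_vals = ne[line].dropna()
        if len(e_vals) < MIN_CONTROLS or len(n_vals) < MIN_CONTROLS:
            raise DegenerateControls(f"line {line!r}: fewer than {MIN_CONTROLS} measured controls")
        med_e, med_ne = float(e_vals.median()), float(n_vals.median())
        if med_e == med_ne:
            raise DegenerateControls(f"line {line!r}: control medians coincide at {med_e}")
        out[line] = (screen.scores[line] - med_ne) / (med_ne - med_e)
    return replace(screen, scores=out)


def normalize_rnai(screen: DependencyScreen) -> tuple[DependencyScreen, pd.Series]:
    """Standardize an RNAi screen at the across-line-average level.

    Each gene is first averaged across its tested cell lines; the two-point
    map is then anchored so that the median averaged score of the essential
    (positive) controls is −1 and of the non-essential (negative) controls is
    0.  The same affine map rescales the per-line matrix so the −0.5
    significance threshold applies downstream.  Returns the rescaled screen
    and the standardized gene averages.
    """
    averages = screen.scores.mean(axis=1, skipna=True)
    e_avg = averages.loc[averages.index.intersection(sorted(screen.essential_controls))].dropna()
    n_avg = averages.loc[averages.index.intersection(sorted(screen.nonessential_controls))].dropna()
    if len(e_avg) < MIN_CONTROLS or len(n_avg) < MIN_CONTROLS:
        raise DegenerateControls(f"fewer than {MIN_CONTROLS} measured control averages")
    med_e, med_ne = float(e_avg.median()), float(n_avg.median())
    if med_e == med_ne:
        raise DegenerateControls(f"control average medians coincide at {med_e}")
    scale = med_ne - med_e
    out = (screen.scores - med_ne) / scale
    return replace(screen, scores=out), (averages - med_ne) / scale


def significant_dependency(
    scores: DependencyScreen | pd.DataFrame,
    threshold: float = SIGNIFICANT_THRESHOLD,
) -> pd.DataFrame:
    """Boolean mask of significant dependencies: score strictly below the
    threshold and measured (missing cells are False)."""
    df = scores.scores if isinstance(scores, DependencyScreen) else scores
    return (df < threshold) & df.notna()


def _per_gene_counts(screen: DependencyScreen, threshold: float) -> pd.DataFrame:
    sig = significant_dependency(screen, threshold)
    return pd.DataFrame({
        "tested": screen.scores.notna().sum(axis=1),
        "significant": sig.sum(axis=1),
    })


def proliferation_genes_majority(
    crispr: DependencyScreen | None,
    rnai: DependencyScreen | None,
    *,
    fraction: float = 0.5,
    threshold: float = SIGNIFICANT_THRESHOLD,
) -> set[str]:
    """Genes significant in ≥ ``fraction`` of their tested lines, either assay.

    Denominators are per-gene tested (non-missing) line counts.  Genes tested
    in zero lines are excluded and logged.
    """
    hits: set[str] = set()
    for screen in (crispr, rnai):
        if screen is None:
            continue
        counts = _per_gene_counts(screen, threshold)
        untested = counts.index[counts["tested"] == 0]
        if len(untested):
            log.info("%s: %d genes tested in 0 lines excluded", screen.assay, len(untested))
        tested = counts[counts["tested"] > 0]
        hits |= set(tested.index[tested["significant"] >= fraction * tested["tested"]])
    return hits


def proliferation_genes_count(
    crispr: DependencyScreen | None,
    rnai: DependencyScreen | None,
    min_lines: int = 10,
    *,
    threshold: float = SIGNIFICANT_THRESHOLD,
) -> set[str]:
    """Genes significant in strictly more than ``min_lines`` lines, either assay."""
    hits: set[str] = set()
    for screen in (crispr, rnai):
        if screen is None:
            continue
        counts = _per_gene_counts(screen, threshold)
        hits |= set(counts.index[counts["significant"] > min_lines])
    return hits
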