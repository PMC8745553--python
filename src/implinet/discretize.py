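"""Three-level discretization of expression and copy-number matrices.

Continuous expression is converted to calls in {-1, 0, 1} (under-, normal,
over-expressed) using per-gene thresholds ``mean ± n·std``.  The multiplier
``n`` is calibrated on a panel of stably expressed housekeeping genes so that
a fixed fraction of samples (30% by default) falls outside the band, and the
averaged housekeeping ``n`` is then applied uniformly to every gene in the
cohort.  Copy-number input is categorized to amplification (+1), normal (0)
and deletion (-1) against explicit gain/loss thresholds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInput, InsufficientSamples, MissingGene

log = logging.getLogger(__name__)

#: The 27 housekeeping genes used to calibrate expression-call thresholds.
HOUSEKEEPING_GENES: tuple[str, ...] = (
    "ACTB", "B2M", "CDKN1B", "ESD", "FLOT2", "GAPDH", "GRB2", "GUSB",
    "HMBS", "HPRT1", "HSP90AB1", "IPO8", "LDHA", "NONO", "PGK1", "POLR2A",
    "PPIA", "PPIH", "PPP1CA", "RHOA", "RPL13A", "SDCBP", "TBP", "TFRC",
    "UBC", "YAP1", "YWHAZ",
)

MIN_SAMPLES = 10


@dataclass
class ExpressionMatrix:
    """Genes × samples continuous expression with a housekeeping subset.

    ``values`` is a DataFrame indexed by gene symbol with sample ids as
    columns.  ``housekeeping_ids`` must be a subset of the index.
    """

    values: pd.DataFrame
    housekeeping_ids: tuple[str, ...] = HOUSEKEEPING_GENES

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        self.housekeeping_ids = tuple(self.housekeeping_ids)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DiscretizedMatrix:
    """Genes × samples calls in {-1, 0, 1} with provenance.

    ``layer`` records the source omics layer ("GE" or "CNV"); ``n_used`` is
    the threshold multiplier for expression-derived calls.  ``missing`` marks
    cells whose source value was non-finite (calls there are 0).
    """

    calls: pd.DataFrame
    layer: str
    n_used: float | None = None
    missing: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.layer not in ("GE", "CNV"):
            raise ValueError(f"layer must be GE or CNV, got {self.layer!r}")
        bad = ~self.calls.isin([-1, 0, 1]).to_numpy()
        if bad.any():
            raise ValueError("calls must be in {-1, 0, 1}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)


def solve_threshold_n(values, target_fraction: float) -> float:
    """Solve for the smallest multiplier ``n`` flagging the target fraction.

    A sample is flagged when its value is strictly above ``mean + n·std`` or
    strictly below ``mean − n·std``.  The flagged count is a step function of
    ``n`` that only changes at the breakpoints ``|x − mean| / std``, so the
    search is exact, not iterative: every interval between consecutive
    breakpoints is evaluated and the lowest interval whose count equals
    ``round(target_fraction·N)`` is chosen.  When no interval attains that
    count (ties in the data), the closest count wins, preferring the smaller
    count on ties.  The returned ``n`` is the midpoint of the chosen interval
    rather than its left edge, so re-evaluating the thresholds downstream
    reproduces the same flagged count exactly despite floating-point
    rounding.

    Parameters
    ----------
    values : array-like of float
        Expression values of one gene across samples (N ≥ 10, finite).
    target_fraction : float in (0, 1)
        Fraction of samples to flag as over- or under-expressed.

    Returns
    -------
    float
        The threshold multiplier ``n ≥ 0``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    n_samples = x.size
    if n_samples < MIN_SAMPLES:
        raise InsufficientSamples(f"need ≥ {MIN_SAMPLES} samples, got {n_samples}")
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie in (0, 1)")
    std = x.std(ddof=0)
    if std == 0.0:
        raise DegenerateInput("zero variance")

    target = int(round(target_fraction * n_samples))
    dev = np.abs(x - x.mean()) / std
    # count(n) = #{dev > n} is constant on [u_j, u_{j+1}); evaluate each
    # interval at an interior representative
    edges = np.unique(np.concatenate(([0.0], dev)))
    candidates = np.concatenate((
        0.5 * (edges[:-1] + edges[1:]),  # interval midpoints
        [edges[-1] + 1.0],               # everything-unflagged interval
    ))
    if edges[0] > 0.0:
        candidates = np.concatenate(([0.5 * edges[0]], candidates))
    counts = np.array([(dev > n).sum() for n in candidates])

    exact = candidates[counts == target]
    if exact.size:
        return float(exact.min())
    gap = np.abs(counts - target)
    tied = gap == gap.min()
    # prefer the smaller count, then the smaller n
    smallest_count = counts[tied].min()
    chosen = candidates[tied & (counts == smallest_count)]
    return float(chosen.min())


def average_housekeeping_n(matrix: ExpressionMatrix, target_fraction: float = 0.30) -> float:
    """Mean threshold multiplier over the housekeeping genes of a cohort.

    Raises :class:`MissingGene` listing any housekeeping gene absent from the
    matrix, and propagates :class:`DegenerateInput` for zero-variance rows.
    """
    missing = [g for g in matrix.housekeeping_ids if g not in matrix.values.index]
    if missing:
        raise MissingGene(missing)
    ns = [
        solve_threshold_n(matrix.values.loc[g].to_numpy(), target_fraction)
        for g in matrix.housekeeping_ids
    ]
    return float(np.mean(ns))


def discretize_expression(matrix: ExpressionMatrix, n: float) -> DiscretizedMatrix:
    """Call each gene's samples against its own ``mean ± n·std`` band.

    Strict inequalities: a sample is +1 only if strictly above the upper
    threshold, -1 only if strictly below the lower one.  Zero-variance rows
    yield all-zero calls with a logged warning.
    """
    if n < 0:
        raise ValueError("n must be ≥ 0")
    vals = matrix.values.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=1, keepdims=True)
    std = np.nanstd(vals, axis=1, ddof=0, keepdims=True)
    flat = (std == 0.0).ravel()
    if flat.any():
        names = [matrix.gene_ids[i] for i in np.where(flat)[0][:20]]
        log.warning("zero-variance rows set to 0: %s%s", names, "..." if flat.sum() > 20 else "")
        warnings.warn(f"{int(flat.sum())} zero-variance rows discretized to 0", stacklevel=2)
    with np.errstate(invalid="ignore"):
        calls = np.where(vals > mean + n * std, 1, np.where(vals < mean - n * std, -1, 0))
    calls[flat, :] = 0
    calls[~np.isfinite(vals)] = 0
    return DiscretizedMatrix(
        calls=pd.DataFrame(calls, index=matrix.values.index, columns=matrix.values.columns),
        layer="GE",
        n_used=float(n),
        missing=pd.DataFrame(~np.isfinite(vals), index=matrix.values.index,
                             columns=matrix.values.columns),
    )


def categorize_cnv(
    cnv: pd.DataFrame,
    gain_threshold: float = 0.3,
    loss_threshold: float = -0.3,
) -> DiscretizedMatrix:
    """Categorize copy-number values to amplification/normal/deletion.

    Inclusive thresholds: +1 when ``value ≥ gain_threshold``, -1 when
    ``value ≤ loss_threshold``, else 0.  With thresholds ``(0.5, -0.5)`` an
    already 3-level integer matrix passes through unchanged.  Non-finite
    entries become 0 and are flagged in the per-cell missing mask.
    """
    if not gain_threshold > loss_threshold:
        raise ValueError("gain_threshold must exceed loss_threshold")
    vals = cnv.to_numpy(dtype=float)
    missing = ~np.isfinite(vals)
    with np.errstate(invalid="ignore"):
        calls = np.where(vals >= gain_threshold, 1, np.where(vals <= loss_threshold, -1, 0))
    calls[missing] = 0
    return DiscretizedMatrix(
        calls=pd.DataFrame(calls, index=cnv.index, columns=cnv.columns),
        layer="CNV",
        missing=pd.DataFrame(missing, index=cnv.index, columns=cnv.columns),
    )
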