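"""Seven-gene proportional-hazards risk score and Kaplan–Meier comparisons.

The risk score is the uncentered linear predictor Σ β_g·x_g of a multivariate
Cox model over the signature genes; patients are stratified low/high at a
fixed cutoff (−0.74 by default, the value used with the seven-gene NSCLC
signature).  Model fitting and log-rank testing delegate to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test

from .errors import ModelError, StratumError

log = logging.getLogger(__name__)

#: The seven signature genes, in assay order.
SEVEN_GENES: tuple[str, ...] = (
    "ABCC4", "CCL19", "SLC39A8", "CD27", "FUT7", "DAG1", "ZNF71",
)

DEFAULT_RISK_CUTOFF = -0.74


@dataclass
class SurvivalTable:
    """Per-patient survival data with covariates.

    ``data`` is indexed by patient id and must contain ``time`` (months, > 0)
    and ``event`` (0/1) columns; covariate columns are named by gene.  Optional
    clinical columns: ``stage`` (e.g. "I".."IV") and ``radiotherapy`` (0/1).
    Derived columns ``risk_score`` and ``stratum`` are added by
    :func:`score_and_stratify`.
    """

    data: pd.DataFrame
    covariates: tuple[str, ...] = field(default=SEVEN_GENES)

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"missing required column {col!r}")
        t = self.data["time"]
        if not (np.isfinite(t) & (t > 0)).all():
            raise ValueError("time must be finite and positive")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")
        self.covariates = tuple(self.covariates)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class RiskModel:
    """Fitted Cox coefficients (log hazard ratios) and fit log-likelihood."""

    betas: pd.Series
    log_likelihood: float


def random_partition(
    table: SurvivalTable, fraction: float, seed: int
) -> tuple[SurvivalTable, SurvivalTable]:
    """Seeded disjoint exhaustive split; training size is round(fraction·N)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    idx = table.data.index.to_numpy().copy()  # never shuffle the live index
    rng.shuffle(idx)
    n_train = int(round(fraction * len(idx)))
    train = table.data.loc[idx[:n_train]]
    test = table.data.loc[idx[n_train:]]
    return (
        SurvivalTable(train, covariates=table.covariates),
        SurvivalTable(test, covariates=table.covariates),
    )


def fit_risk_model(
    training: SurvivalTable, covariate_names: tuple[str, ...] | None = None
) -> RiskModel:
    """Fit the multivariate Cox model on the training set.

    Requires ≥ 10 events and no constant covariate; non-convergence raises
    :class:`ModelError` with lifelines' diagnostics.
    """
    names = tuple(covariate_names or training.covariates)
    df = training.data[["time", "event", *names]].dropna()
    if int(df["event"].sum()) < 10:
        raise ModelError(f"need ≥ 10 events, got {int(df['event'].sum())}")
    constant = [c for c in names if df[c].nunique() <= 1]
    if constant:
        raise ModelError(f"constant covariates: {constant}")
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises several convergence errors
        raise ModelError(f"Cox fit failed: {exc}") from exc
    return RiskModel(
        betas=fitter.params_.reindex(list(names)),
        log_likelihood=float(fitter.log_likelihood_),
    )


def score_and_stratify(
    table: SurvivalTable,
    model: RiskModel | pd.Series,
    cutoff: float = DEFAULT_RISK_CUTOFF,
) -> SurvivalTable:
    """Attach risk scores and the low/high stratum at the cutoff.

    The score is the raw linear predictor (no centering, no baseline term);
    the boundary is assigned to the high-risk stratum (score < cutoff ⇒ low,
    otherwise high).  Patients missing any modeled covariate are excluded and
    logged.
    """
    betas = model.betas if isinstance(model, RiskModel) else model
    names = list(betas.index)
    df = table.data.copy()
    complete = df[names].notna().all(axis=1)
    if (~complete).any():
        log.warning("excluding %d patients with missing covariates", int((~complete).sum()))
        df = df[complete]
    df["risk_score"] = df[names].to_numpy() @ betas.to_numpy()
    df["stratum"] = np.where(df["risk_score"] < cutoff, "low", "high")
    return SurvivalTable(df, covariates=table.covariates)


def km_logrank(table: SurvivalTable, *, max_display_months: float | None = 120.0) -> dict:
    """Two-sided log-rank test between strata plus the stratum hazard ratio.

    The HR and its 95% CI come from a one-covariate Cox fit on the high-risk
    indicator.  ``max_display_months`` only truncates the exported survival
    curves, never the test.  Raises :class:`StratumError` when a stratum is
    empty or event-free.
    """
    if "stratum" not in table.data.columns:
        raise StratumError("table has no stratum column; run score_and_stratify first")
    df = table.data
    low = df[df["stratum"] == "low"]
    high = df[df["stratum"] == "high"]
    for name, grp in (("low", low), ("high", high)):
        if grp.empty:
            raise StratumError(f"stratum {name!r} is empty")
        if int(grp["event"].sum()) == 0:
            raise StratumError(f"stratum {name!r} has no events")

    lr = logrank_test(low["time"], high["time"], low["event"], high["event"])

    cox_df = pd.DataFrame({
        "time": df["time"],
        "event": df["event"],
        "high_risk": (df["stratum"] == "high").astype(int),
    })
    fitter = CoxPHFitter()
    try:
        fitter.fit(cox_df, duration_col="time", event_col="event")
    except Exception as exc:
        raise ModelError(f"stratum Cox fit failed: {exc}") from exc
    beta = float(fitter.params_.loc["high_risk"])
    lo, hi = fitter.confidence_intervals_.loc["high_risk"]
    curves = _km_curves(low, high, max_display_months)
    return {
        "p_logrank": float(lr.p_value),
        "hr": float(np.exp(beta)),
        "hr_ci": (float(np.exp(lo)), float(np.exp(hi))),
        "n_low": len(low),
        "n_high": len(high),
        "curves": curves,
    }


def _km_curves(low: pd.DataFrame, high: pd.DataFrame, max_months: float | None) -> pd.DataFrame:
    from lifelines import KaplanMeierFitter

    frames = []
    for name, grp in (("low", low), ("high", high)):
        km = KaplanMeierFitter()
        km.fit(grp["time"], grp["event"], label=name)
        sf = km.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf["stratum"] = name
        if max_months is not None:
            sf = sf[sf["time"] <= max_months]
        frames.append(sf)
    return pd.concat(frames, ignore_index=True)
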