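"""Panel-level statistics: regressions, activity classification, PCA, time-kill.

A formulation panel is a table of records, one per mouthwash formulation,
carrying the CPC dose, the qNMR/diffusion-derived free concentration
[CPC]_f, observed diffusion coefficients with and without HEC, the disk
retention assay (DRA) value and the measured log10 kill.  This module
provides the downstream analytics: pairwise ordinary-least-squares fits
with r^2, a >5-log activity classifier with an HEC-binding veto, z-scored
PCA, and conversion of serial-dilution plate counts to log10 reductions.

Diffusion enters regressions and PCA as log10(D): the raw coefficients span
decades and their physical interpretation (micelle size) is logarithmic.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "FormulationRecord",
    "PanelModel",
    "ActivityThresholds",
    "ActivityPredictor",
    "ClassificationResult",
    "LogKillResult",
    "linear_fit",
    "fit_activity_predictor",
    "classify_activity",
    "pca_panel",
    "log_kill_from_counts",
    "records_to_frame",
    "DEFAULT_PCA_VARIABLES",
]

DEFAULT_PCA_VARIABLES = [
    "cpc_dose_pct",
    "cpc_free_conc",
    "log10_D_obs",
    "log10_D_obs_with_hec",
    "dra_value",
    "log_kill",
]


@dataclass
class FormulationRecord:
    """One formulation: composition descriptors and measured responses."""

    id: str
    cpc_dose_pct: float
    cpc_free_conc: float | None = None  # M
    D_obs: float | None = None  # m^2/s
    D_obs_with_hec: float | None = None  # m^2/s
    dra_value: float | None = None
    log_kill: float | None = None
    bound_percent: float | None = None
    excipient_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.cpc_dose_pct < 0:
            raise ValueError("CPC dose must be non-negative")
        for name in ("D_obs", "D_obs_with_hec"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present")
        self.excipient_flags = frozenset(self.excipient_flags)


@dataclass
class PanelModel:
    """PCA decomposition of a panel plus any attached regressions."""

    variables: list[str]
    loadings: np.ndarray  # variables x components, columns orthonormal
    scores: np.ndarray  # records x components
    explained_variance_fraction: np.ndarray
    n_records_used: int
    n_records_dropped: int
    dropped_variables: list[str]
    regression_results: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ActivityThresholds:
    """Decision thresholds for the activity region.

    ``log_kill``: minimum predicted log10 kill to call a formulation
    acceptable (>5 by default).  ``bound_percent_veto``: HEC-bound CPC at or
    above this percentage vetoes the call regardless of the predictor
    (binding below 50% leaves high activity possible; above it, not).
    """

    log_kill: float = 5.0
    bound_percent_veto: float = 50.0


@dataclass(frozen=True)
class ActivityPredictor:
    """Linear predictor of log10 kill on ([CPC]_f, log10 D_obs)."""

    intercept: float
    coef_cpc_free: float  # per M
    coef_log10_D: float  # per decade

    def predict(self, cpc_free_conc: float, D_obs: float) -> float:
        return (
            self.intercept
            + self.coef_cpc_free * cpc_free_conc
            + self.coef_log10_D * math.log10(D_obs)
        )


@dataclass(frozen=True)
class ClassificationResult:
    record_id: str
    acceptable: bool
    predicted_log_kill: float | None
    reasons: tuple[str, ...]


@dataclass(frozen=True)
class LogKillResult:
    """Log10 reduction; ``censored`` marks an at-least value (all plates 0)."""

    log_kill: float
    survivors_per_ml: float
    n_countable_plates: int
    censored: bool = False


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

def linear_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, r^2).

    r^2 is the squared Pearson correlation.  Constant x is rejected;
    constant y returns slope 0 and r^2 = 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    if np.ptp(y) == 0:
        warnings.warn("y is constant: r^2 defined as 0", stacklevel=2)
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def records_to_frame(records: list[FormulationRecord]) -> pd.DataFrame:
    """Tabulate records, adding log10 diffusion columns for analytics."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "cpc_dose_pct": r.cpc_dose_pct,
                "cpc_free_conc": r.cpc_free_conc,
                "D_obs": r.D_obs,
                "D_obs_with_hec": r.D_obs_with_hec,
                "log10_D_obs": math.log10(r.D_obs) if r.D_obs else np.nan,
                "log10_D_obs_with_hec": (
                    math.log10(r.D_obs_with_hec) if r.D_obs_with_hec else np.nan
                ),
                "dra_value": r.dra_value,
                "log_kill": r.log_kill,
                "bound_percent": r.bound_percent,
                "excipient_flags": ";".join(sorted(r.excipient_flags)),
            }
        )
    return pd.DataFrame(rows)


def fit_activity_predictor(records: list[FormulationRecord]) -> ActivityPredictor:
    """Fit the linear activity predictor on records with complete fields."""
    df = records_to_frame(records)
    df = df.dropna(subset=["cpc_free_conc", "log10_D_obs", "log_kill"])
    if len(df) < 3:
        raise ValueError("need >= 3 complete records to fit the activity predictor")
    X = np.column_stack([np.ones(len(df)), df["cpc_free_conc"], df["log10_D_obs"]])
    beta, *_ = np.linalg.lstsq(X, df["log_kill"].to_numpy(), rcond=None)
    return ActivityPredictor(
        intercept=float(beta[0]), coef_cpc_free=float(beta[1]), coef_log10_D=float(beta[2])
    )


def classify_activity(
    record: FormulationRecord,
    predictor: ActivityPredictor,
    thresholds: ActivityThresholds = ActivityThresholds(),
) -> ClassificationResult:
    """Predict whether a formulation falls in the acceptable-activity region.

    Acceptable iff the predicted log10 kill exceeds ``thresholds.log_kill``
    on the ([CPC]_f, log10 D_obs) predictor, vetoed whenever the HEC-bound
    percentage reaches ``thresholds.bound_percent_veto``.
    """
    missing = [f for f in ("cpc_free_conc", "D_obs") if getattr(record, f) is None]
    if missing:
        raise ValueError(f"record {record.id!r} missing required fields: {missing}")
    reasons: list[str] = []
    predicted = predictor.predict(record.cpc_free_conc, record.D_obs)
    if record.bound_percent is not None and record.bound_percent >= thresholds.bound_percent_veto:
        reasons.append(
            f"HEC-bound {record.bound_percent:.0f}% >= veto {thresholds.bound_percent_veto:.0f}%"
        )
        return ClassificationResult(record.id, False, predicted, tuple(reasons))
    ok = predicted > thresholds.log_kill
    reasons.append(
        f"predicted log kill {predicted:.2f} {'>' if ok else '<='} threshold {thresholds.log_kill:g}"
    )
    return ClassificationResult(record.id, ok, predicted, tuple(reasons))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_panel(
    records: list[FormulationRecord],
    variables: list[str] | None = None,
    n_components: int | None = None,
) -> PanelModel:
    """Z-score-normalised PCA over the panel.

    Each variable is standardised to zero mean and unit variance before the
    decomposition (mixed units demand scale invariance).  Records with a
    missing value in any selected variable are dropped (counted in the
    result); zero-variance variables are dropped with a warning.  Component
    signs are fixed by making each loading's largest-magnitude entry
    positive, so results are fully deterministic.
    """
    if len(records) < 2:
        raise ValueError("PCA needs at least 2 records")
    variables = list(variables) if variables is not None else list(DEFAULT_PCA_VARIABLES)
    if len(variables) < 2:
        raise ValueError("PCA needs at least 2 variables")
    df = records_to_frame(records)
    missing_cols = [v for v in variables if v not in df.columns]
    if missing_cols:
        raise ValueError(f"unknown panel variables: {missing_cols}")

    sub = df[variables].astype(float)
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    if n_dropped:
        logger.info("PCA dropped %d records with missing values", n_dropped)
    if len(complete) < 2:
        raise ValueError("fewer than 2 complete records for PCA")

    sd = complete.std(ddof=0)
    dead = [v for v in variables if sd[v] == 0 or not np.isfinite(sd[v])]
    if dead:
        warnings.warn(f"dropping zero-variance variables: {dead}", stacklevel=2)
    kept = [v for v in variables if v not in dead]
    if len(kept) < 2:
        raise ValueError("fewer than 2 variables with non-zero variance")

    Z = ((complete[kept] - complete[kept].mean()) / sd[kept]).to_numpy()
    k_max = min(Z.shape)
    k = k_max if n_components is None else min(n_components, k_max)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T  # variables x components

    # deterministic sign: largest-|entry| of each loading made positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0

    total_var = Z.var(axis=0, ddof=0).sum()
    evf = pca.explained_variance_ * (len(Z) - 1) / len(Z) / total_var

    return PanelModel(
        variables=kept,
        loadings=loadings,
        scores=scores,
        explained_variance_fraction=np.asarray(evf, dtype=float),
        n_records_used=len(complete),
        n_records_dropped=n_dropped,
        dropped_variables=dead,
    )


# ---------------------------------------------------------------------------
# Time-kill arithmetic
# ---------------------------------------------------------------------------

def log_kill_from_counts(
    colony_counts,
    dilution_exponents,
    initial_cfu_per_ml: float,
    plated_volume_ml: float = 1.0,
    countable_range: tuple[int, int] = (30, 300),
) -> LogKillResult:
    """Log10 reduction from serial-dilution plate counts.

    Each plate at dilution exponent e (e.g. −3) plating ``plated_volume_ml``
    estimates survivors as count / (volume × 10^e) CFU/mL.  Plates within
    the countable window (30–300 colonies by default) are averaged; the
    result is log10(initial) − log10(survivors).  When every plate is zero
    the kill is censored at the detection limit (one colony on the most
    concentrated plate).
    """
    counts = np.asarray(colony_counts, dtype=float)
    exps = np.asarray(dilution_exponents, dtype=float)
    if counts.size == 0 or counts.size != exps.size:
        raise ValueError("need paired counts and dilution exponents")
    if initial_cfu_per_ml <= 0 or plated_volume_ml <= 0:
        raise ValueError("initial CFU and plated volume must be positive")
    lo, hi = countable_range
    countable = (counts >= lo) & (counts <= hi)
    if np.all(counts == 0):
        detection = 1.0 / (plated_volume_ml * 10.0 ** float(np.max(exps)))
        return LogKillResult(
            log_kill=math.log10(initial_cfu_per_ml) - math.log10(detection),
            survivors_per_ml=detection,
            n_countable_plates=0,
            censored=True,
        )
    if not np.any(countable):
        raise ValueError(
            f"no plate in the countable window {countable_range}; counts={counts.tolist()}"
        )
    survivors = counts[countable] / (plated_volume_ml * 10.0 ** exps[countable])
    mean_survivors = float(np.mean(survivors))
    return LogKillResult(
        log_kill=math.log10(initial_cfu_per_ml) - math.log10(mean_survivors),
        survivors_per_ml=mean_survivors,
        n_countable_plates=int(countable.sum()),
        censored=False,
    )
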