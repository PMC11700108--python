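"""Evaluation harness: error metrics, splits, k-fold, model comparison.

RMSE and the coefficient of determination are computed between measured and
estimated weights; cohorts are split 70/30 (half-up rounding of the train
count), machine-learning hyperparameters are selected by 10-fold validation,
and frozen models can be transfer-validated on other cohorts. The 1:1-line
diagnostic regresses measured on estimated weight and t-tests slope = 1 and
intercept = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from fruitmass._rng import substream
from fruitmass.errors import FitError
from fruitmass.models.forms import records_to_arrays


def rmse(measured, estimated) -> float:
    """Root mean squared error between two equal-length weight series."""
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if m.shape != e.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {e.shape}")
    if m.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((m - e) ** 2)))


def r_squared(measured, estimated) -> float:
    """1 - SS_res/SS_tot; may be negative for estimators worse than the mean."""
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if m.shape != e.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {e.shape}")
    if m.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant measured series: R^2 undefined")
    ss_res = float(np.sum((m - e) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def train_size(n: int, train_fraction: float = 0.7) -> int:
    """Half-up rounding of train_fraction * n."""
    return int(math.floor(train_fraction * n + 0.5))


def split_dataset(records: pd.DataFrame, spec: SplitSpec) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded uniform random train/test partition of a cohort.

    The train count is the half-up rounding of train_fraction * n; the two
    parts are disjoint and exhaustive, and the draw is deterministic per seed.
    """
    n = len(records)
    if n < 2:
        raise ValueError("cohort must have at least 2 records")
    n_train = train_size(n, spec.train_fraction)
    if n_train in (0, n):
        raise ValueError(f"degenerate split: {n_train}/{n - n_train}")
    rng = substream(spec.seed, "split")
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return records.iloc[train_idx], records.iloc[test_idx]


def kfold_indices(n: int, k: int = 10, seed: int = 0) -> List[np.ndarray]:
    """Shuffled k-fold validation index sets partitioning range(n)."""
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    rng = substream(seed, "kfold")
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


@dataclass
class EvalReport:
    """Train/test RMSE and R^2 plus 1:1-line diagnostics for one model."""

    label: str
    rmse_train: float
    rmse_test: float
    r2_train: float
    r2_test: float
    n_train: int
    n_test: int
    identity_slope: float
    identity_intercept: float
    identity_slope_p: float = float("nan")
    identity_intercept_p: float = float("nan")
    model: object = field(default=None, repr=False)


def _identity_line(measured: np.ndarray, estimated: np.ndarray):
    """Regress measured on estimated; t-test slope=1 and intercept=0."""
    res = stats.linregress(estimated, measured)
    df = measured.size - 2
    if df > 0 and res.stderr > 0:
        t_slope = (res.slope - 1.0) / res.stderr
        p_slope = 2.0 * stats.t.sf(abs(t_slope), df)
    else:
        p_slope = float("nan")
    if df > 0 and res.intercept_stderr > 0:
        t_int = res.intercept / res.intercept_stderr
        p_int = 2.0 * stats.t.sf(abs(t_int), df)
    else:
        p_int = float("nan")
    return res.slope, res.intercept, p_slope, p_int


def evaluate_model(
    fit: Callable[[pd.DataFrame], object],
    records: pd.DataFrame,
    spec: SplitSpec,
    label: str = "",
) -> EvalReport:
    """Fit on the train partition and report metrics on both partitions."""
    if len(records) < 10:
        raise ValueError("need at least 10 records")
    train, test = split_dataset(records, spec)
    model = fit(train)
    Ltr, Dtr, FWtr = records_to_arrays(train)
    Lte, Dte, FWte = records_to_arrays(test)
    est_tr = np.atleast_1d(model.predict(Ltr, Dtr))
    est_te = np.atleast_1d(model.predict(Lte, Dte))
    slope, intercept, p_slope, p_int = _identity_line(
        np.concatenate([FWtr, FWte]), np.concatenate([est_tr, est_te])
    )
    return EvalReport(
        label=label or getattr(model, "label", type(model).__name__),
        rmse_train=rmse(FWtr, est_tr),
        rmse_test=rmse(FWte, est_te),
        r2_train=r_squared(FWtr, est_tr),
        r2_test=r_squared(FWte, est_te),
        n_train=len(train),
        n_test=len(test),
        identity_slope=float(slope),
        identity_intercept=float(intercept),
        identity_slope_p=float(p_slope),
        identity_intercept_p=float(p_int),
        model=model,
    )


def select_best(reports: Sequence[EvalReport]) -> EvalReport:
    """Lowest training RMSE wins; ties go to higher training R^2, then to
    the earlier declaration in the input sequence."""
    if not reports:
        raise ValueError("empty report collection")
    order = sorted(
        range(len(reports)),
        key=lambda i: (reports[i].rmse_train, -reports[i].r2_train, i),
    )
    return reports[order[0]]


def reports_to_frame(reports: Sequence[EvalReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": r.label,
                "rmse_train": r.rmse_train,
                "rmse_test": r.rmse_test,
                "r2_train": r.r2_train,
                "r2_test": r.r2_test,
                "n_train": r.n_train,
                "n_test": r.n_test,
                "identity_slope": r.identity_slope,
                "identity_intercept": r.identity_intercept,
            }
            for r in reports
        ]
    )


def descriptive_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Per-variable mean, SD, SE of the mean, min, max and skewness."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    rows = {}
    for col in records.columns:
        x = np.asarray(records[col], dtype=float)
        sd = float(np.std(x, ddof=1))
        rows[col] = {
            "mean": float(np.mean(x)),
            "sd": sd,
            "se": sd / math.sqrt(x.size),
            "min": float(np.min(x)),
            "max": float(np.max(x)),
            "skewness": float(stats.skew(x, bias=False)) if sd > 0 else 0.0,
        }
    return pd.DataFrame(rows).T


@dataclass
class CorrelationReport:
    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # p < alpha off-diagonal
    alpha: float


def correlation_matrix(records: pd.DataFrame, alpha: float = 0.01) -> CorrelationReport:
    """Pairwise Pearson correlations with two-sided t-distribution p-values."""
    cols = list(records.columns)
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    n = len(cols)
    r = np.eye(n)
    p = np.zeros((n, n))
    for i in range(n):
        xi = np.asarray(records[cols[i]], dtype=float)
        if np.std(xi) == 0:
            raise ValueError(f"constant variable {cols[i]!r}")
        for j in range(i + 1, n):
            xj = np.asarray(records[cols[j]], dtype=float)
            res = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    sig = (pdf < alpha) & ~np.eye(n, dtype=bool)
    return CorrelationReport(r=rdf, p=pdf, significant=sig, alpha=alpha)


def transfer_validate(model, cohorts: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Apply a frozen model to each cohort (no refitting); RMSE and R^2 rows."""
    if not hasattr(model, "predict"):
        raise FitError("model is not fitted")
    rows = []
    for name, records in cohorts.items():
        if len(records) == 0:
            raise ValueError(f"cohort {name!r} is empty")
        L, D, FW = records_to_arrays(records)
        est = np.atleast_1d(model.predict(L, D))
        rows.append(
            {
                "cohort": name,
                "n": len(records),
                "rmse": rmse(FW, est),
                "r2": r_squared(FW, est),
            }
        )
    return pd.DataFrame(rows)
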