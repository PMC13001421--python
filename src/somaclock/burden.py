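"""Genome-wide burden extrapolation and age-rate regression.

Each cell's somatic-variant calls cover only the callable fraction of its
genome, so the genome-wide burden is ``n_calls / callable_fraction``.  Burdens
increase linearly with donor age ("clock-like" accumulation); the annual rate
is estimated by regressing burden on age.  When each subject contributes a
single age — the typical cross-sectional design — per-cell errors are
confounded with subject effects, so inference runs on subject-mean burdens
(valid under either error model); a random-intercept mixed model on per-cell
burdens is used when subjects outnumber distinct ages.  Pairwise rate
differences between cell types are tested with Tukey studentized-range
adjusted contrasts on a pooled celltype-by-age interaction model over
subject means.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CellProfile:
    """Per-cell metadata plus call counts and extrapolated burdens."""

    cell_id: str
    subject_id: str
    age: float
    celltype: str = "GN"
    region: str = "other"
    depth_class: str = "30X"
    callable_fraction: float = 1.0
    n_calls_snv: int = 0
    n_calls_indel: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.callable_fraction <= 1):
            raise ValueError(
                f"callable_fraction must be in (0, 1], got {self.callable_fraction}"
            )

    @property
    def burden_snv(self) -> float:
        return extrapolate_burden(self.n_calls_snv, self.callable_fraction)

    @property
    def burden_indel(self) -> float:
        return extrapolate_burden(self.n_calls_indel, self.callable_fraction)

    def burden(self, response: str = "snv") -> float:
        return self.burden_snv if response == "snv" else self.burden_indel


@dataclass
class RateFit:
    """Fitted age-rate line for one cell type."""

    slope: float
    intercept: float
    ci95_slope: tuple[float, float]
    ci95_intercept: tuple[float, float]
    se_slope: float
    se_intercept: float
    residual_sd: float
    n_cells: int
    n_subjects: int
    method: str = "subject-ols"
    subject_effects: dict[str, float] = field(default_factory=dict)
    response: str = "snv"
    celltype: str = ""

    def predict(self, age: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(age)


def extrapolate_burden(n_calls: float, callable_fraction: float) -> float:
    """Genome-wide burden from calls restricted to the callable genome."""
    if not (0 < callable_fraction <= 1):
        raise ValueError(
            f"callable_fraction must be in (0, 1], got {callable_fraction}"
        )
    return n_calls / callable_fraction


def _profiles_frame(profiles: list[CellProfile], response: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [p.cell_id for p in profiles],
            "subject": [p.subject_id for p in profiles],
            "age": [p.age for p in profiles],
            "celltype": [p.celltype for p in profiles],
            "burden": [p.burden(response) for p in profiles],
        }
    )


def fit_rate(profiles: list[CellProfile], response: str = "snv") -> RateFit:
    """Fit burden ~ age for one cell type.

    Uses a random-intercept-per-subject model when subjects outnumber
    distinct ages; otherwise (one subject per age, the usual design) falls
    back to OLS on subject-mean burdens with a logged notice, since subject
    effects and residuals are then perfectly confounded.
    """
    df = _profiles_frame(profiles, response)
    if df["celltype"].nunique() > 1:
        warnings.warn(
            "fit_rate called with multiple cell types pooled; "
            "use compare_rates for cross-type contrasts"
        )
    ages = df["age"].nunique()
    if ages < 2:
        raise ValueError("rate fit requires at least 2 distinct ages")
    n_subjects = df["subject"].nunique()
    X = sm.add_constant(df["age"].to_numpy())
    y = df["burden"].to_numpy()

    if n_subjects > ages:
        model = sm.MixedLM(y, X, groups=df["subject"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=True)
        params, bse = np.asarray(res.fe_params), np.asarray(res.bse_fe)
        crit = stats.norm.ppf(0.975)
        method = "mixedlm"
        resid = y - X @ params
        ranef = {g: float(v.iloc[0]) for g, v in res.random_effects.items()}
    else:
        # one subject per age: subject effects and residuals are confounded,
        # so inference runs on subject means (valid under either error model)
        logger.info(
            "subjects (%d) do not exceed distinct ages (%d); "
            "fitting OLS on subject means", n_subjects, ages,
        )
        means = df.groupby("subject").agg(age=("age", "mean"), burden=("burden", "mean"))
        Xm = sm.add_constant(means["age"].to_numpy())
        res = sm.OLS(means["burden"].to_numpy(), Xm).fit()
        params, bse = res.params, res.bse
        crit = stats.t.ppf(0.975, max(n_subjects - 2, 1))
        if n_subjects == 2:
            bse = np.array([0.0, 0.0])  # saturated: no residual df
        method = "subject-ols"
        resid = y - X @ params
        ranef = {
            g: float(np.mean(resid[df["subject"].to_numpy() == g]))
            for g in df["subject"].unique()
        }
    if not np.isfinite(bse[1]):
        bse = np.array([0.0, 0.0])
    return RateFit(
        slope=float(params[1]),
        intercept=float(params[0]),
        ci95_slope=(float(params[1] - crit * bse[1]), float(params[1] + crit * bse[1])),
        ci95_intercept=(
            float(params[0] - crit * bse[0]),
            float(params[0] + crit * bse[0]),
        ),
        se_slope=float(bse[1]),
        se_intercept=float(bse[0]),
        residual_sd=float(np.std(resid, ddof=2)) if len(resid) > 2 else 0.0,
        n_cells=len(df),
        n_subjects=n_subjects,
        method=method,
        subject_effects=ranef,
        response=response,
        celltype=df["celltype"].iloc[0],
    )


def compare_rates(
    profiles: list[CellProfile], response: str = "snv"
) -> pd.DataFrame:
    """Pairwise slope contrasts between cell types, Tukey-adjusted.

    Fits a pooled celltype-by-age interaction model on subject-mean burdens
    and reports every pairwise slope difference with its t statistic and
    studentized-range (Tukey) adjusted p-value.  Cell types observed at
    fewer than 2 distinct ages are excluded with a warning.
    """
    df = _profiles_frame(profiles, response)
    keep = []
    for ct, sub in df.groupby("celltype"):
        if sub["age"].nunique() >= 2:
            keep.append(ct)
        else:
            warnings.warn(f"cell type {ct!r} has <2 distinct ages; excluded")
    df = df[df["celltype"].isin(keep)]
    types = sorted(keep)
    if len(types) < 2:
        raise ValueError("compare_rates needs >=2 cell types with >=2 ages each")

    # subject-level means per type (subject effects confound per-cell errors),
    # then per-type intercept and slope via cell-means coding
    agg = (
        df.groupby(["celltype", "subject"])
        .agg(age=("age", "mean"), burden=("burden", "mean"))
        .reset_index()
    )
    cols = {}
    for ct in types:
        ind = (agg["celltype"] == ct).astype(float).to_numpy()
        cols[f"i_{ct}"] = ind
        cols[f"s_{ct}"] = ind * agg["age"].to_numpy()
    X = pd.DataFrame(cols)
    res = sm.OLS(agg["burden"].to_numpy(), X.to_numpy()).fit()
    names = list(X.columns)
    cov = res.cov_params()
    k = len(types)
    dof = max(len(agg) - 2 * k, 1)

    rows = []
    for a, b in itertools.combinations(types, 2):
        L = np.zeros(len(names))
        L[names.index(f"s_{a}")] = 1.0
        L[names.index(f"s_{b}")] = -1.0
        diff = float(L @ res.params)
        se = float(np.sqrt(L @ cov @ L))
        t = diff / se if se > 0 else 0.0
        p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2), k, dof))
        rows.append(
            {
                "type_a": a,
                "type_b": b,
                "slope_a": float(res.params[names.index(f"s_{a}")]),
                "slope_b": float(res.params[names.index(f"s_{b}")]),
                "slope_diff": diff,
                "se": se,
                "t": t,
                "p_tukey": min(p, 1.0),
            }
        )
    return pd.DataFrame(rows)
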