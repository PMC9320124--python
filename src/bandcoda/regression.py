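"""Compositional regression of BMI z-score on pivot ILR coordinates.

The model regresses the outcome on the eight pivot ILR coordinates of the
nine-band time-use composition plus covariates (sex, school-mean-centred age,
EIMD decile, accelerometer model, sampling frequency) by ordinary least
squares.  The nine-rotation *pivot scan* refits the model once per band with
that band leading the basis and extracts the first-pivot-coordinate
coefficient beta_ILR1 — the association of that band relative to the
geometric mean of all the remaining bands.  All nine rotations span the same
column space, so their fitted values coincide and the nine beta_ILR1 values
sum to zero; both identities are exploited as correctness oracles in the test
suite.

Model-level inference is the omnibus F-test of the eight ILR coordinates
against the covariates-only model; diagnostics are variance inflation factors
and the one-way school ICC.  Where sex is itself associated with the outcome,
the scan is repeated within each sex with sex dropped from the covariates.

OLS fits are delegated to statsmodels; this module owns the compositional
design construction and the rotation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .bands import BAND_LABELS
from .composition import PivotBasis, pivot_ilr, replace_zeros

__all__ = [
    "DEFAULT_COVARIATES",
    "CompositionalRegression",
    "fit_model",
    "omnibus_ilr_test",
    "PivotScanResult",
    "pivot_scan",
    "StratifiedScan",
    "stratify_by_sex",
    "vif",
    "icc_oneway",
]

#: Covariate set of the adjusted models.
DEFAULT_COVARIATES = (
    "sex",
    "age_centred",
    "eimd_decile",
    "accel_model",
    "sampling_freq",
)

# Fixed dummy coding keeps designs full-rank and reproducible across strata.
_CATEGORICAL = {
    "sex": ("boy", "girl"),  # indicator for girl
    "school_type": ("primary", "secondary"),
    "accel_model": ("GT9X", "GENEActiv", "AX3"),  # two indicators
    "sampling_freq": (100, 30),  # indicator for 30 Hz
}


def build_covariate_matrix(records: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric covariate design (no intercept) with fixed reference levels."""
    cols = {}
    for cov in covariates:
        if cov in _CATEGORICAL:
            levels = _CATEGORICAL[cov]
            vals = records[cov]
            bad = ~vals.isin(levels)
            if bad.any():
                raise ValueError(
                    f"unknown {cov} level(s): {sorted(vals[bad].unique())}"
                )
            for lev in levels[1:]:
                cols[f"{cov}[{lev}]"] = (vals == lev).astype(float).to_numpy()
        else:
            cols[cov] = records[cov].astype(float).to_numpy()
    return pd.DataFrame(cols, index=records.index)


def _check_full_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy()
    _, R, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    bad = diag <= tol
    if bad.any():
        names = [X.columns[piv[i]] for i in np.nonzero(bad)[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {names}")


class CompositionalRegression(RegressorMixin, BaseEstimator):
    """OLS of an outcome on pivot ILR coordinates plus covariates.

    Parameters
    ----------
    lead_band : str
        Band label isolated by the first pivot coordinate (beta_ILR1 is its
        coefficient).
    band_labels : tuple of str
        Composition columns, in band order.
    covariates : tuple of str
        Covariate columns; categorical ones use fixed dummy coding.
        ``include_composition=False`` drops the ILR block (the reduced model
        of the omnibus test).
    zero_pseudo : float
        Pseudo-duration substituted for zero band times before the log-ratio
        transform.

    Attributes (after fit)
    ----------------------
    params_ : pandas.Series            coefficient estimates
    cov_params_ : pandas.DataFrame     coefficient covariance
    df_resid_ : int                    residual degrees of freedom
    rss_, resid_var_, n_ : float/int   residual sum of squares, variance, rows
    basis_ : PivotBasis                the rotation used
    ilr_names_ : list of str           names of the ILR coefficient block
    """

    def __init__(
        self,
        lead_band: str = BAND_LABELS[-1],
        band_labels: tuple = BAND_LABELS,
        covariates: tuple = DEFAULT_COVARIATES,
        include_composition: bool = True,
        zero_pseudo: float = 1.0 / 120.0,
    ):
        self.lead_band = lead_band
        self.band_labels = band_labels
        self.covariates = covariates
        self.include_composition = include_composition
        self.zero_pseudo = zero_pseudo

    # -- design ------------------------------------------------------------
    def _basis(self) -> PivotBasis:
        labels = list(self.band_labels)
        if self.lead_band not in labels:
            raise ValueError(f"unknown lead band {self.lead_band!r}")
        return PivotBasis(len(labels), labels.index(self.lead_band))

    def _design(self, X: pd.DataFrame) -> pd.DataFrame:
        parts = []
        if self.include_composition:
            comp = replace_zeros(X[list(self.band_labels)].to_numpy(float),
                                 self.zero_pseudo)
            Z = pivot_ilr(comp, self._basis())
            names = [f"ilr_{k + 1}" for k in range(Z.shape[1])]
            parts.append(pd.DataFrame(Z, columns=names, index=X.index))
        if self.covariates:
            parts.append(build_covariate_matrix(X, self.covariates))
        design = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=X.index)
        design.insert(0, "const", 1.0)
        return design

    # -- estimator API -----------------------------------------------------
    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        design = self._design(X)
        if len(design) <= design.shape[1]:
            raise ValueError(
                f"n = {len(design)} rows cannot identify {design.shape[1]} coefficients"
            )
        _check_full_rank(design)
        res = sm.OLS(y, design).fit()
        self.basis_ = self._basis() if self.include_composition else None
        self.feature_names_ = list(design.columns)
        self.ilr_names_ = [c for c in design.columns if c.startswith("ilr_")]
        self.params_ = res.params
        self.cov_params_ = res.cov_params()
        self.df_resid_ = int(res.df_resid)
        self.n_ = int(res.nobs)
        self.rss_ = float(res.ssr)
        self.resid_var_ = float(res.ssr / res.df_resid)
        self.results_ = res
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "params_")
        return self._design(X).to_numpy() @ self.params_.to_numpy()

    # -- reporting ---------------------------------------------------------
    def ilr1_summary(self, alpha: float = 0.05) -> dict:
        """Estimate, t-based CI and p-value of the first pivot coordinate."""
        check_is_fitted(self, "params_")
        if not self.include_composition:
            raise ValueError("covariates-only model has no ILR coefficients")
        name = self.ilr_names_[0]
        beta = float(self.params_[name])
        se = float(np.sqrt(self.cov_params_.loc[name, name]))
        tq = stats.t.ppf(1 - alpha / 2, self.df_resid_)
        p = 2 * stats.t.sf(abs(beta / se), self.df_resid_)
        return {
            "band": self.lead_band,
            "beta_ilr1": beta,
            "se": se,
            "ci_lo": beta - tq * se,
            "ci_hi": beta + tq * se,
            "p": float(p),
        }

    def term_test(self, name: str) -> tuple[float, float]:
        """t statistic and p-value for a single coefficient."""
        check_is_fitted(self, "params_")
        beta = float(self.params_[name])
        se = float(np.sqrt(self.cov_params_.loc[name, name]))
        t = beta / se
        return t, float(2 * stats.t.sf(abs(t), self.df_resid_))


def fit_model(
    records: pd.DataFrame,
    outcome: str = "bmi_z",
    covariates=DEFAULT_COVARIATES,
    lead_band: str = BAND_LABELS[-1],
    **kwargs,
) -> CompositionalRegression:
    """Fit one rotation of the compositional model on a cohort frame."""
    model = CompositionalRegression(lead_band=lead_band, covariates=covariates, **kwargs)
    return model.fit(records, records[outcome])


def omnibus_ilr_test(full: CompositionalRegression, reduced: CompositionalRegression):
    """F-test of the ILR coordinate block: full vs covariates-only model.

    F = ((RSS_r - RSS_f)/df1) / (RSS_f/df2) with df1 the number of ILR
    coordinates and df2 the full model's residual df.  Invariant to which
    rotation's coordinates the full model uses.
    """
    check_is_fitted(full, "params_")
    check_is_fitted(reduced, "params_")
    if full.n_ != reduced.n_:
        raise ValueError("full and reduced models must be fit on the same rows")
    df1 = reduced.df_resid_ - full.df_resid_
    if df1 <= 0:
        raise ValueError("reduced model is not nested in the full model")
    extra = set(full.feature_names_) - set(reduced.feature_names_)
    if set(reduced.feature_names_) - set(full.feature_names_) or not extra:
        raise ValueError("reduced model terms must be a strict subset of the full's")
    df2 = full.df_resid_
    F = ((reduced.rss_ - full.rss_) / df1) / (full.rss_ / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), int(df1), int(df2), p


@dataclass
class PivotScanResult:
    """Nine-rotation scan: beta_ILR1 per band plus the shared omnibus test."""

    table: pd.DataFrame
    omnibus: dict
    models: dict = field(repr=False, default_factory=dict)

    def fitted_values(self) -> np.ndarray:
        """(n_bands, n) fitted values of each rotation (identical in theory)."""
        return np.vstack([m.results_.fittedvalues for m in self.models.values()])


def pivot_scan(
    records: pd.DataFrame,
    outcome: str = "bmi_z",
    covariates=DEFAULT_COVARIATES,
    band_labels=BAND_LABELS,
    alpha: float = 0.05,
    **kwargs,
) -> PivotScanResult:
    """Refit the model once per band (that band leading) and collect beta_ILR1.

    All rotations share one column space, so the omnibus F (computed from the
    first rotation) applies to every one of them.
    """
    y = records[outcome]
    reduced = CompositionalRegression(
        covariates=covariates, include_composition=False, band_labels=band_labels,
        **kwargs,
    ).fit(records, y)
    models, rows = {}, []
    omnibus = None
    for band in band_labels:
        m = CompositionalRegression(
            lead_band=band, covariates=covariates, band_labels=band_labels, **kwargs
        ).fit(records, y)
        if omnibus is None:
            F, df1, df2, p = omnibus_ilr_test(m, reduced)
            omnibus = {"F": F, "df1": df1, "df2": df2, "p": p}
        models[band] = m
        rows.append(m.ilr1_summary(alpha))
    table = pd.DataFrame(rows)
    table["significant"] = table["p"] < alpha
    return PivotScanResult(table=table, omnibus=omnibus, models=models)


@dataclass
class StratifiedScan:
    """Pooled scan plus per-sex scans when sex predicts the outcome."""

    pooled: PivotScanResult
    sex_p: float
    stratified: dict | None  # sex -> PivotScanResult, or None


def stratify_by_sex(
    records: pd.DataFrame,
    outcome: str = "bmi_z",
    covariates=DEFAULT_COVARIATES,
    alpha: float = 0.05,
    **kwargs,
) -> StratifiedScan:
    """Pooled scan; if sex is associated with the outcome (p < alpha), rerun
    the scan within each sex with sex removed from the covariates."""
    if "sex" not in covariates:
        raise ValueError("pooled covariates must include sex")
    sexes = records["sex"].unique()
    if len(sexes) < 2:
        # degenerate single-sex input: fit without the sex term, no strata
        cov = tuple(c for c in covariates if c != "sex")
        pooled = pivot_scan(records, outcome, cov, alpha=alpha, **kwargs)
        return StratifiedScan(pooled=pooled, sex_p=float("nan"), stratified=None)

    pooled = pivot_scan(records, outcome, covariates, alpha=alpha, **kwargs)
    first = next(iter(pooled.models.values()))
    sex_name = next(n for n in first.feature_names_ if n.startswith("sex["))
    _, sex_p = first.term_test(sex_name)
    if sex_p >= alpha:
        return StratifiedScan(pooled=pooled, sex_p=sex_p, stratified=None)

    cov = tuple(c for c in covariates if c != "sex")
    strata = {}
    for sex, sub in records.groupby("sex"):
        strata[sex] = pivot_scan(sub.reset_index(drop=True), outcome, cov,
                                 alpha=alpha, **kwargs)
    return StratifiedScan(pooled=pooled, sex_p=sex_p, stratified=strata)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: 1/(1 - R^2) of each column on the others.

    The intercept (a ``const`` column, if present) participates in the
    auxiliary regressions but is not itself scored.  Perfectly collinear
    columns report ``inf``.
    """
    cols = [c for c in design.columns if c != "const"]
    X = design[cols].to_numpy(float)
    n = X.shape[0]
    out = {}
    ones = np.ones((n, 1))
    for j, name in enumerate(cols):
        yj = X[:, j]
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        resid = yj - others @ np.linalg.lstsq(others, yj, rcond=None)[0]
        tss = np.sum((yj - yj.mean()) ** 2)
        rss = np.sum(resid**2)
        if tss == 0:
            out[name] = np.inf
            continue
        r2 = 1 - rss / tss
        out[name] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def icc_oneway(y, groups) -> float:
    """One-way random-effects ICC of ``y`` within ``groups`` (schools).

    ICC = (MSB - MSW) / (MSB + (n0 - 1) MSW) with n0 the ANOVA-harmonised
    mean group size; negative estimates are truncated to zero.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    a = len(labels)
    if a < 2 or np.any(counts < 2):
        raise ValueError("ICC needs >= 2 groups with >= 2 members each")
    N = y.size
    grand = y.mean()
    ssb = ssw = 0.0
    for lab, n_i in zip(labels, counts):
        yi = y[groups == lab]
        ssb += n_i * (yi.mean() - grand) ** 2
        ssw += np.sum((yi - yi.mean()) ** 2)
    msb = ssb / (a - 1)
    msw = ssw / (N - a)
    n0 = (N - np.sum(counts**2) / N) / (a - 1)
    icc = (msb - msw) / (msb + (n0 - 1) * msw)
    return float(max(icc, 0.0))
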