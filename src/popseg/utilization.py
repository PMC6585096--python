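"""Follow-up utilization summaries, bivariate tests and adjusted negative
binomial regression with survival-time exposure.

The count model is NB2 (variance mu + alpha*mu^2) with a log link and
log(exposure-days) offset; exponentiated segment coefficients are incidence
rate ratios (IRRs) versus the Mostly Healthy reference segment, adjusted for
age, gender, ethnicity and baseline-year utilization.  Overdispersion alpha
is estimated by maximum likelihood jointly with the coefficients (or can be
fixed, in which case the model degenerates to Poisson at alpha=0).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import EstimationError, ModelError
from .segments import ENCOUNTER_KINDS, SEGMENT_ORDER

FOLLOWUP_WINDOW = (pd.Timestamp("2013-01-01"), pd.Timestamp("2015-12-31"))

#: Left-closed age bands used when age is modeled categorically and in
#: demographic tables.
AGE_BANDS = [(21, 30), (31, 40), (41, 50), (51, 60), (61, 70), (71, 80), (81, 90), (91, 200)]
AGE_BAND_LABELS = ["21-30", "31-40", "41-50", "51-60", "61-70", "71-80", "81-90", ">90"]


def aggregate_counts(encounters: pd.DataFrame,
                     window: tuple = FOLLOWUP_WINDOW,
                     patient_ids=None) -> pd.DataFrame:
    """Per-patient encounter counts of each kind within the closed window.

    ``patient_ids`` (optional) fixes the output universe so patients with no
    encounters appear with zero counts — the typical case in this cohort.
    """
    lo, hi = window
    dates = pd.to_datetime(encounters["date"])
    sel = encounters.loc[(dates >= lo) & (dates <= hi)]
    wide = (sel.groupby(["patient_id", "kind"], observed=True).size()
            .unstack(fill_value=0))
    for kind in ENCOUNTER_KINDS:
        if kind not in wide.columns:
            wide[kind] = 0
    wide = wide[ENCOUNTER_KINDS]
    if patient_ids is not None:
        wide = wide.reindex(pd.Index(patient_ids, name="patient_id"), fill_value=0)
    return wide.astype(np.int64)


def rate_per_1000_days(total_count: float, patient_days: float) -> float:
    """Utilization rate per 1000 patient-days."""
    if patient_days <= 0:
        raise EstimationError("rate undefined: zero patient-days")
    return total_count * 1000.0 / patient_days


def summarize_utilization(counts: pd.DataFrame, survival: pd.DataFrame,
                          segments: pd.Series) -> pd.DataFrame:
    """Per-segment (plus overall) utilization summary for each encounter kind.

    Returns a tidy frame with one row per (segment, kind): total_count,
    patient_days, rate_per_1000_days, mean, sd, pct_any.  Segment totals and
    patient-days sum exactly to the overall ("All") rows.
    """
    surv = survival.set_index("patient_id")["time_days"]
    seg = segments.reindex(counts.index)
    if seg.isna().any() or surv.reindex(counts.index).isna().any():
        raise EstimationError("every patient needs a segment and a survival time")
    days = surv.reindex(counts.index)

    rows = []
    segment_groups = [(s, counts.index[seg == s]) for s in SEGMENT_ORDER]
    segment_groups.append(("All", counts.index))
    for name, idx in segment_groups:
        pdays = int(days.loc[idx].sum())
        for kind in ENCOUNTER_KINDS:
            c = counts.loc[idx, kind]
            rows.append({
                "segment": name, "kind": kind,
                "n_patients": len(idx),
                "total_count": int(c.sum()),
                "patient_days": pdays,
                "rate_per_1000_days": rate_per_1000_days(c.sum(), pdays) if pdays else np.nan,
                "mean": float(c.mean()) if len(idx) else np.nan,
                "sd": float(c.std(ddof=1)) if len(idx) > 1 else np.nan,
                "pct_any": float((c >= 1).mean() * 100.0) if len(idx) else np.nan,
            })
    return pd.DataFrame(rows)


# --- bivariate tests --------------------------------------------------------

def chi_square_test(table: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a contingency table (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise EstimationError("degenerate contingency table: a margin is zero")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def anova_test(values: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """One-way ANOVA F test of equal group means."""
    samples = [values[groups == g].to_numpy() for g in pd.unique(groups)]
    if len(samples) < 2:
        raise EstimationError("ANOVA needs at least two groups")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


# --- negative binomial regression ------------------------------------------

@dataclasses.dataclass
class NBFitResult:
    """Fitted adjusted count model for one outcome."""

    outcome: str
    reference: str
    coefficients: pd.Series       # log-rate scale, all model terms
    bse: pd.Series
    cov_params: pd.DataFrame
    irr: pd.Series                # per segment, reference == 1
    ci95: pd.DataFrame            # columns low/high, per segment
    pvalues: pd.Series            # per segment
    dispersion_alpha: float
    converged: bool
    loglik: float


def _segment_param(segment: str) -> str:
    return f"segment[{segment}]"


def _moment_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB2 alpha from Poisson fitted means (auxiliary
    regression of ((y-mu)^2 - mu)/mu on mu through the origin)."""
    num = float((((y - mu) ** 2 - mu)).sum())
    den = float((mu ** 2).sum())
    return max(num / den, 1e-4) if den > 0 else 1.0


def _fit_nb_mle(y: np.ndarray, X: pd.DataFrame, offset: np.ndarray):
    """NB2 MLE with Poisson warm start and optimizer fallbacks.

    Returns (results, converged), or None when no attempt yields finite
    parameters and covariance — which in practice means the dispersion MLE
    is at the Poisson boundary (alpha -> 0) where the NB2 Hessian is
    singular; the caller then falls back to the Poisson MLE.
    """
    poisson = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    alpha0 = _moment_alpha(y, np.asarray(poisson.mu))
    start = np.append(np.asarray(poisson.params), alpha0)
    model = sm.NegativeBinomial(y, X, offset=offset, loglike_method="nb2")
    last = None
    for method, kwargs in (("newton", {"tol": 1e-8, "maxiter": 500}),
                           ("bfgs", {"gtol": 1e-6, "maxiter": 500}),
                           ("nm", {"maxiter": 5000, "xtol": 1e-6, "ftol": 1e-6})):
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(start_params=start, disp=0, method=method, **kwargs)
            cov = np.asarray(res.cov_params())  # raises if the Hessian failed
            if not (np.all(np.isfinite(res.params)) and np.all(np.isfinite(cov))):
                continue
            if bool(res.mle_retvals.get("converged", False)):
                return res, True
            last = res
            start = np.asarray(res.params)  # warm-start the next attempt
        except (np.linalg.LinAlgError, ValueError):
            continue
    return (last, False) if last is not None else None


class NegativeBinomialIRR(BaseEstimator):
    """NB2 regression of follow-up encounter counts with exposure offset.

    scikit-learn style estimator.  ``fit`` expects a model frame with
    columns ``count``, ``exposure_days``, ``segment`` and (depending on the
    adjustment switches) ``age``, ``gender``, ``ethnicity`` and
    ``past_ED`` / ``past_SOC`` / ``past_INPATIENT``.

    Parameters
    ----------
    outcome : name carried through to the result (informational).
    reference : segment absorbed into the intercept; IRRs are relative to it.
    adjust_demographics : include age (continuous years or bands), gender
        and ethnicity.
    adjust_past_utilization : include the three baseline-year counts.
    age_bands : model age as the standard bands instead of a linear term.
    alpha : None to estimate overdispersion by MLE; a float >= 0 to fix it
        (0 fits a Poisson GLM).
    exposure_floor : minimum exposure days (immediate deaths contribute one
        day rather than a -inf offset).
    """

    def __init__(self, outcome: str = "ED", reference: str = "MOSTLY_HEALTHY",
                 adjust_demographics: bool = True,
                 adjust_past_utilization: bool = True,
                 age_bands: bool = False, alpha: float | None = None,
                 exposure_floor: int = 1):
        self.outcome = outcome
        self.reference = reference
        self.adjust_demographics = adjust_demographics
        self.adjust_past_utilization = adjust_past_utilization
        self.age_bands = age_bands
        self.alpha = alpha
        self.exposure_floor = exposure_floor

    # design matrix -------------------------------------------------------

    def _design(self, data: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(index=data.index)
        X["Intercept"] = 1.0
        present = set(data["segment"])
        unknown = present - set(SEGMENT_ORDER)
        if unknown:
            raise ModelError(f"unknown segment labels in model frame: {sorted(unknown)}")
        if self.reference not in present:
            raise ModelError(f"reference segment {self.reference} absent from data")
        self.segments_ = [self.reference] + [s for s in SEGMENT_ORDER
                                             if s != self.reference and s in present]
        for s in self.segments_[1:]:
            X[_segment_param(s)] = (data["segment"] == s).astype(float)
        if self.adjust_demographics:
            if self.age_bands:
                band = pd.cut(data["age"],
                              bins=[b[0] for b in AGE_BANDS] + [AGE_BANDS[-1][1]],
                              labels=AGE_BAND_LABELS, right=False, include_lowest=True)
                for lab in AGE_BAND_LABELS[1:]:
                    X[f"age_band[{lab}]"] = (band == lab).astype(float)
            else:
                X["age"] = data["age"].astype(float)
            X["gender[male]"] = (data["gender"] == "male").astype(float)
            for eth in ("Malay", "Indian", "Others"):
                X[f"ethnicity[{eth}]"] = (data["ethnicity"] == eth).astype(float)
        if self.adjust_past_utilization:
            for kind in ENCOUNTER_KINDS:
                X[f"past_{kind}"] = data[f"past_{kind}"].astype(float)
        return X

    def fit(self, data: pd.DataFrame, y=None) -> "NegativeBinomialIRR":
        """Fit by maximum likelihood; raises :class:`ModelError` on a
        degenerate design, flags (never hides) non-convergence."""
        y_ = data["count"].to_numpy(dtype=float)
        exposure = np.maximum(data["exposure_days"].to_numpy(dtype=float),
                              self.exposure_floor)
        if (exposure <= 0).any():
            raise ModelError("exposure must be positive after flooring")
        X = self._design(data)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            raise ModelError(
                f"design matrix is rank deficient ({rank} < {X.shape[1]})")
        offset = np.log(exposure)

        if self.alpha is None:
            fitted = _fit_nb_mle(y_, X, offset)
            if fitted is not None:
                res, converged = fitted
                raw = np.asarray(res.params)
                alpha_hat = float(raw[-1])
                params = pd.Series(raw[:-1], index=X.columns)
                cov = pd.DataFrame(np.asarray(res.cov_params())[:-1, :-1],
                                   index=X.columns, columns=X.columns)
            else:
                # dispersion at the Poisson boundary: report the Poisson MLE
                res = sm.GLM(y_, X, family=sm.families.Poisson(), offset=offset).fit()
                converged = bool(res.converged)
                alpha_hat = 0.0
                params = pd.Series(np.asarray(res.params), index=X.columns)
                cov = pd.DataFrame(np.asarray(res.cov_params()),
                                   index=X.columns, columns=X.columns)
        else:
            family = (sm.families.Poisson() if self.alpha == 0
                      else sm.families.NegativeBinomial(alpha=self.alpha))
            res = sm.GLM(y_, X, family=family, offset=offset).fit()
            converged = bool(res.converged)
            alpha_hat = float(self.alpha)
            params = pd.Series(np.asarray(res.params), index=X.columns)
            cov = pd.DataFrame(np.asarray(res.cov_params()),
                               index=X.columns, columns=X.columns)

        bse = pd.Series(np.sqrt(np.diag(cov)), index=X.columns)
        seg_rows, irr, low, high, pvals = [], [], [], [], []
        for s in [x for x in SEGMENT_ORDER if x in self.segments_]:
            seg_rows.append(s)
            if s == self.reference:
                irr.append(1.0); low.append(1.0); high.append(1.0); pvals.append(np.nan)
                continue
            name = _segment_param(s)
            b, se = params[name], bse[name]
            irr.append(np.exp(b))
            low.append(np.exp(b - 1.959963984540054 * se))
            high.append(np.exp(b + 1.959963984540054 * se))
            pvals.append(2 * stats.norm.sf(abs(b / se)))

        self.result_ = NBFitResult(
            outcome=self.outcome, reference=self.reference,
            coefficients=params, bse=bse, cov_params=cov,
            irr=pd.Series(irr, index=seg_rows, name="irr"),
            ci95=pd.DataFrame({"low": low, "high": high}, index=seg_rows),
            pvalues=pd.Series(pvals, index=seg_rows, name="p"),
            dispersion_alpha=alpha_hat, converged=converged,
            loglik=float(res.llf))
        self.irr_ = self.result_.irr
        self.converged_ = converged
        self.alpha_ = alpha_hat
        return self


def build_model_frame(counts: pd.DataFrame, survival: pd.DataFrame,
                      segments: pd.Series, patients: pd.DataFrame,
                      baseline_counts: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Assemble the regression frame for one outcome from pipeline pieces."""
    pat = patients.set_index("patient_id")
    surv = survival.set_index("patient_id")
    idx = counts.index
    frame = pd.DataFrame({
        "count": counts[outcome],
        "exposure_days": surv["time_days"].reindex(idx),
        "segment": segments.reindex(idx),
        "age": pat["age_2012"].reindex(idx),
        "gender": pat["gender"].reindex(idx),
        "ethnicity": pat["ethnicity"].reindex(idx),
    })
    for kind in ENCOUNTER_KINDS:
        frame[f"past_{kind}"] = baseline_counts[kind].reindex(idx).fillna(0)
    if frame[["exposure_days", "segment", "age"]].isna().any().any():
        raise ModelError("model frame has patients missing survival, segment or age")
    return frame


def fit_nb_regression(data: pd.DataFrame, outcome: str = "ED",
                      **params) -> NBFitResult:
    """Functional wrapper over :class:`NegativeBinomialIRR`."""
    est = NegativeBinomialIRR(outcome=outcome, **params)
    return est.fit(data).result_


# --- pairwise segment contrasts ---------------------------------------------

def pairwise_segment_test(fit: NBFitResult, seg_a: str, seg_b: str,
                          method: str = "wald-1df") -> tuple[float, float]:
    """Chi-square test of utilization difference between two segments.

    ``wald-1df`` (default) tests equality of the two segment coefficients
    (one constraint); ``joint-2df`` tests the two coefficients jointly
    against zero (two constraints, both segments at the reference rate).
    """
    for seg in (seg_a, seg_b):
        if seg not in fit.irr.index:
            raise ModelError(f"segment {seg} is not in the fitted model")
    if seg_a == seg_b:
        return 0.0, 1.0
    names = list(fit.coefficients.index)
    k = len(names)

    def unit(seg: str) -> np.ndarray:
        v = np.zeros(k)
        if seg != fit.reference:
            v[names.index(_segment_param(seg))] = 1.0
        return v

    beta = fit.coefficients.to_numpy()
    V = fit.cov_params.to_numpy()
    if method == "wald-1df":
        c = unit(seg_a) - unit(seg_b)
        var = float(c @ V @ c)
        if var <= 0:
            return 0.0, 1.0
        stat = float((c @ beta) ** 2 / var)
        df = 1
    elif method == "joint-2df":
        C = np.vstack([unit(seg_a), unit(seg_b)])
        keep = ~np.all(C == 0, axis=1)  # reference rows carry no constraint
        C = C[keep]
        if C.shape[0] == 0:
            return 0.0, 1.0
        cb = C @ beta
        stat = float(cb @ np.linalg.solve(C @ V @ C.T, cb))
        df = C.shape[0]
    else:
        raise ValueError(f"unknown method {method!r}")
    return stat, float(stats.chi2.sf(stat, df))


def pairwise_all(fit: NBFitResult, method: str = "wald-1df",
                 bonferroni: bool = False) -> pd.DataFrame:
    """All pairwise segment tests (15 with all six segments fitted)."""
    rows = []
    fitted_segments = [s for s in SEGMENT_ORDER if s in fit.irr.index]
    pairs = list(itertools.combinations(fitted_segments, 2))
    for a, b in pairs:
        stat, p = pairwise_segment_test(fit, a, b, method=method)
        rows.append({"segment_a": a, "segment_b": b, "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    if bonferroni:
        out["p_adjusted"] = np.minimum(out["p"] * len(pairs), 1.0)
    return out
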