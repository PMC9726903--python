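"""Probit psychometric fitting and subject-level derived measures.

The response model is a binomial GLM with probit link,

    Phi^{-1}[ P(Y = 1) ] = beta0 + beta1 * c,

with ``c`` the comparison duration in ms and ``Y = 1`` the response
"comparison longer than standard".  From a fit we derive

* PSE  = -beta0 / beta1, the comparison duration judged equal to the
  standard;
* slope/JND = 1 / beta1, the SD of the underlying probit curve in ms
  (temporal precision: smaller is more precise);
* constant error CE = PSE - phi_s for group SC and phi_s - PSE for group
  CS, with phi_s the physical standard duration — signed so that a
  positive CE means the trial's *first* interval was relatively
  overestimated.

Fitting goes through statsmodels IRLS; (quasi-)separated data fall back
to a ridge-penalized maximum likelihood (penalty 1e-4 on both
coefficients) and are flagged as non-converged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr

from .design import Group

#: Ridge strength used for separated / non-converged probit fits.
RIDGE_PENALTY = 1e-4
#: Convergence tolerance on the IRLS deviance.
FIT_TOL = 1e-8
FIT_MAXITER = 100


@dataclass(frozen=True)
class PsychometricFit:
    """Per-subject probit fit and derived quantities for one ISI (or pooled)."""

    subject_id: int | str
    group: Group
    isi: float | str
    beta0: float
    beta1: float
    pse: float
    jnd: float
    ce: float
    converged: bool
    n_trials: int
    loglik: float
    pse_se: float = math.nan


def pse(beta0: float, beta1: float) -> float:
    """Point of subjective equality, -beta0/beta1."""
    if beta1 == 0:
        raise ZeroDivisionError("PSE undefined for zero slope")
    return -beta0 / beta1


def constant_error(pse_ms: float, phi_s: float, group: Group) -> float:
    """Signed constant error under the group-specific sign convention."""
    if group == "SC":
        return pse_ms - phi_s
    if group == "CS":
        return phi_s - pse_ms
    raise ValueError(f"unknown group {group!r}")


def _penalized_probit(c: np.ndarray, y: np.ndarray, ridge: float) -> tuple[np.ndarray, float]:
    """Ridge-penalized probit MLE via BFGS on the (scaled) design."""
    scale = np.std(c) or 1.0
    cz = (c - c.mean()) / scale

    def nll(beta):
        eta = beta[0] + beta[1] * cz
        ll = np.where(y == 1, log_ndtr(eta), log_ndtr(-eta)).sum()
        return -ll + ridge * float(beta @ beta)

    res = minimize(nll, x0=np.zeros(2), method="BFGS")
    b0z, b1z = res.x
    beta1 = b1z / scale
    beta0 = b0z - b1z * c.mean() / scale
    eta = beta0 + beta1 * c
    loglik = float(np.where(y == 1, log_ndtr(eta), log_ndtr(-eta)).sum())
    return np.array([beta0, beta1]), loglik


def fit_probit(
    c_durations: Sequence[float],
    responses: Sequence[int],
    *,
    subject_id: int | str = 0,
    group: Group = "SC",
    isi: float | str = "pooled",
    phi_s: float = 120.0,
) -> PsychometricFit:
    """Maximum-likelihood probit fit of P("C longer") against C duration.

    Requires at least two distinct comparison durations and binary
    responses.  Separated or otherwise non-converging data are refit with
    a small ridge penalty and flagged ``converged=False`` instead of
    raising.
    """
    c = np.asarray(c_durations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise ValueError("c_durations and responses must be equal-length 1-D")
    if np.unique(c).size < 2:
        raise ValueError("need responses at >= 2 distinct comparison durations")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("responses must be binary")

    X = sm.add_constant(c)
    params = None
    converged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.Binomial(sm.families.links.Probit()))
            res = model.fit(maxiter=FIT_MAXITER, tol=FIT_TOL)
        params = np.asarray(res.params, dtype=float)
        converged = bool(res.converged) and np.isfinite(params).all()
    except Exception:
        converged = False

    # (quasi-)separation shows up as an absurdly steep curve (probit SD
    # below one tenth of a ms), diverged coefficients, or an essentially
    # perfect likelihood
    if params is not None and converged:
        if (
            abs(params[1]) > 10.0
            or not np.isfinite(params).all()
            or res.llf > -1e-6
        ):
            converged = False
    pse_se = math.nan
    if params is None or not converged:
        params, loglik = _penalized_probit(c, y, RIDGE_PENALTY)
        converged = False
    else:
        loglik = float(res.llf)
        # delta-method SE of PSE = -b0/b1: grad = (-1/b1, b0/b1^2)
        b0, b1 = params
        if b1 != 0:
            grad = np.array([-1.0 / b1, b0 / b1**2])
            cov = np.asarray(res.cov_params())
            var = float(grad @ cov @ grad)
            pse_se = math.sqrt(var) if var >= 0 else math.nan

    beta0, beta1 = float(params[0]), float(params[1])
    pse_ms = pse(beta0, beta1) if beta1 != 0 else math.nan
    jnd = 1.0 / beta1 if beta1 != 0 else math.inf
    ce = constant_error(pse_ms, phi_s, group) if beta1 != 0 else math.nan
    return PsychometricFit(
        subject_id=subject_id,
        group=group,
        isi=isi,
        beta0=beta0,
        beta1=beta1,
        pse=pse_ms,
        jnd=jnd,
        ce=ce,
        converged=converged,
        n_trials=int(c.size),
        loglik=loglik,
        pse_se=pse_se,
    )


def fits_to_frame(fits: Iterable[PsychometricFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [f.subject_id for f in fits],
            "group": [f.group for f in fits],
            "isi": [f.isi for f in fits],
            "beta0": [f.beta0 for f in fits],
            "beta1": [f.beta1 for f in fits],
            "pse_ms": [f.pse for f in fits],
            "jnd_ms": [f.jnd for f in fits],
            "ce_ms": [f.ce for f in fits],
            "pse_se_ms": [f.pse_se for f in fits],
            "converged": [f.converged for f in fits],
            "n_trials": [f.n_trials for f in fits],
            "loglik": [f.loglik for f in fits],
        }
        # rebuilt each call: fits may be a one-shot iterable
    )


def fit_subjects(
    records: pd.DataFrame, *, per_isi: bool = True, phi_s: float = 120.0
) -> pd.DataFrame:
    """Fit one probit per subject (and per ISI by default) from a tidy
    response table with columns subject_id, group, isi_ms, c_ms, response."""
    fits: list[PsychometricFit] = []
    keys = ["subject_id", "group"] + (["isi_ms"] if per_isi else [])
    for key, sub in records.groupby(keys, sort=True):
        sid, group = key[0], key[1]
        isi = key[2] if per_isi else "pooled"
        fits.append(
            fit_probit(
                sub["c_ms"].to_numpy(),
                sub["response"].to_numpy(),
                subject_id=sid,
                group=group,
                isi=isi,
                phi_s=phi_s,
            )
        )
    return fits_to_frame(fits)


def subject_accuracy(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject overall proportion correct (one row per subject)."""
    acc = (
        records.groupby(["subject_id", "group"], sort=True)["correct"]
        .mean()
        .rename("accuracy")
        .reset_index()
    )
    return acc


def exclude_chance(
    subjects: pd.DataFrame, threshold: float = 0.55
) -> pd.DataFrame:
    """Flag subjects whose overall accuracy is at chance (strictly below
    ``threshold``); returns a copy with ``excluded``/``exclusion_reason``."""
    if not subjects["accuracy"].between(0, 1).all():
        raise ValueError("accuracies must lie in [0, 1]")
    out = subjects.copy()
    at_chance = out["accuracy"] < threshold
    out["excluded"] = at_chance
    out["exclusion_reason"] = np.where(at_chance, "chance_level", "none")
    return out


def exclude_outliers_3sd(
    fits: pd.DataFrame,
    variables: Sequence[str] = ("ce_ms", "jnd_ms"),
    *,
    n_sd: float = 3.0,
    groupwise: bool = True,
) -> pd.DataFrame:
    """Single-pass outlier exclusion on fitted dependent variables.

    A subject is excluded when any of its fits has a value of any listed
    variable outside mean ± ``n_sd``·SD, moments computed within group
    (or pooled with ``groupwise=False``) on the incoming table only — no
    re-iteration after removal.  Degenerate zero-SD cells exclude nobody.
    """
    if len(fits) < 3:
        raise ValueError("need at least 3 fits for an SD-based criterion")
    out = fits.copy()
    flagged = pd.Series(False, index=out.index)
    grouper = out.groupby("group") if groupwise else [(None, out)]
    for _, sub in grouper:
        for var in variables:
            vals = sub[var]
            mu, sd = vals.mean(), vals.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                continue
            flagged.loc[sub.index] |= (vals - mu).abs() > n_sd * sd
    bad_subjects = set(out.loc[flagged, "subject_id"])
    excluded = out["subject_id"].isin(bad_subjects)
    out["excluded"] = excluded
    out["exclusion_reason"] = np.where(excluded, "outlier_3sd", "none")
    return out


def aic(k: int, loglik: float) -> float:
    """Akaike information criterion, 2k - 2·loglik."""
    return 2.0 * k - 2.0 * loglik


def aic_compare(models: Mapping[str, object]) -> str:
    """Pick the candidate with the lowest AIC; ties go to fewer parameters.

    ``models`` maps an identifier to a fitted statsmodels results object
    (anything exposing ``llf``, ``df_model`` and ``nobs``).  All
    candidates must be fitted on the same number of observations.
    """
    if not models:
        raise ValueError("no candidate models")
    rows = []
    nobs = None
    for name, res in models.items():
        n = int(res.nobs)
        if nobs is None:
            nobs = n
        elif n != nobs:
            raise ValueError("candidate models fitted on different data")
        k = int(res.df_model) + 1  # + intercept
        rows.append((name, aic(k, float(res.llf)), k))
    rows.sort(key=lambda t: (t[1], t[2]))
    return rows[0][0]


def fit_response_models(
    records: pd.DataFrame, formulas: Mapping[str, str], *, link: Literal["probit", "logit"] = "probit"
) -> dict[str, object]:
    """Fit fixed-effects binomial GLMs for AIC comparison.

    Formulas use the statsmodels/patsy syntax against the tidy response
    table (e.g. ``"response ~ c_ms * isi_ms * group"``).
    """
    import statsmodels.formula.api as smf

    link_obj = (
        sm.families.links.Probit() if link == "probit" else sm.families.links.Logit()
    )
    out = {}
    for name, formula in formulas.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[name] = smf.glm(
                formula, data=records, family=sm.families.Binomial(link_obj)
            ).fit(maxiter=FIT_MAXITER, tol=FIT_TOL)
    return out
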