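"""Comparison of proportional- and non-proportional-odds growth model fits.

Provides the likelihood-ratio test of the proportional-odds assumption
(the PO model is nested in the NPO model: equality of the K-1
category-specific coefficients of every npo covariate, i.e. K-2 freed
coefficients per covariate), DIC comparison of two posterior fits, and an
odds-ratio report table in the field's usual layout (one exponentiated
coefficient with 95% interval per covariate per cumulative logit, random
components, ICC and model-diagnosis block appended).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .model import FitResult, PosteriorFit

__all__ = ["TestResult", "DICReport", "lr_proportionality_test", "compare_dic", "odds_ratio_table"]

_NEG_TOL = 1e-4


@dataclass
class TestResult:
    """Likelihood-ratio chi-square test result."""

    statistic: float
    df: int
    p_value: float
    alpha: float
    reject: bool

    def __str__(self) -> str:
        verdict = "rejected" if self.reject else "not rejected"
        return (
            f"LR chi2 = {self.statistic:.2f} on {self.df} df, p = {self.p_value:.4g}; "
            f"proportional odds {verdict} at alpha = {self.alpha}"
        )


@dataclass
class DICReport:
    """Per-model DIC decomposition and preference by lower DIC."""

    models: pd.DataFrame  # model, dbar, pD, dic
    delta_dic: float
    preferred: str | None
    warnings: list


def _check_nested(fit_po: FitResult, fit_npo: FitResult) -> int:
    spo, snpo = fit_po.spec, fit_npo.spec
    if spo.K != snpo.K:
        raise ValueError("fits have different numbers of outcome categories")
    if spo.npo:
        raise ValueError("the restricted fit must have an empty npo set")
    if not snpo.npo:
        raise ValueError("the general fit has no npo covariates; models are identical")
    if set(spo.shared) != set(snpo.shared) | set(snpo.npo):
        raise ValueError(
            "models are not nested: the PO shared set must equal the NPO shared+npo sets"
        )
    if set(spo.time_interactions) != set(snpo.time_interactions):
        raise ValueError("models are not nested: different time interactions")
    # freed coefficients: (K-1) - 1 per npo design column
    n_npo_cols = len([n for n in fit_npo.table["name"] if "|logit1" in n])
    return n_npo_cols * (spo.K - 2)


def lr_proportionality_test(fit_po: FitResult, fit_npo: FitResult, alpha: float = 0.05) -> TestResult:
    """Likelihood-ratio test of the proportional-odds assumption.

    statistic = (-2logL restricted) - (-2logL general), referred to a
    chi-square with (K-2) x (number of npo design columns) degrees of
    freedom.  A statistic below -1e-4 indicates the general fit did not
    reach the restricted fit's likelihood and asks for a refit.
    """
    df = _check_nested(fit_po, fit_npo)
    stat = fit_po.minus2loglik - fit_npo.minus2loglik
    if stat < -_NEG_TOL:
        raise ValueError(
            f"negative LR statistic {stat:.6g}: the NPO fit is worse than the nested PO fit; "
            "refit the NPO model (e.g. initialized from the PO solution)"
        )
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    return TestResult(statistic=float(stat), df=df, p_value=p, alpha=alpha, reject=p < alpha)


def compare_dic(po: PosteriorFit, npo: PosteriorFit) -> DICReport:
    """DIC comparison of two posterior fits; lower DIC preferred.

    If either chain carries convergence warnings the report declines to
    declare a preference.
    """
    rows = [
        {"model": "proportional_odds", "dbar": po.dbar, "pD": po.p_d, "dic": po.dic},
        {"model": "non_proportional_odds", "dbar": npo.dbar, "pD": npo.p_d, "dic": npo.dic},
    ]
    warns = [f"proportional_odds: {w}" for w in po.warnings]
    warns += [f"non_proportional_odds: {w}" for w in npo.warnings]
    delta = float(po.dic - npo.dic)
    if po.converged and npo.converged:
        preferred = "non_proportional_odds" if npo.dic < po.dic else "proportional_odds"
    else:
        preferred = None
        warns.append("no preference declared: at least one chain did not converge")
    return DICReport(models=pd.DataFrame(rows), delta_dic=delta, preferred=preferred, warnings=warns)


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def odds_ratio_table(fit: FitResult | PosteriorFit) -> pd.DataFrame:
    """Exponentiated report table: OR (95% CI) per covariate per logit.

    Thresholds are reported as exp(delta); shared (proportional-odds)
    covariates repeat the same odds ratio across the K-1 logit columns;
    random components, ICC and -2logL/DIC are appended on their own scale.
    """
    is_mle = isinstance(fit, FitResult)
    tab = fit.table
    K = fit.spec.K
    logit_cols = [f"logit{k}" for k in range(1, K)]
    rows = []

    def fmt(est, lo, hi, p):
        return f"{np.exp(est):.2f} ({np.exp(lo):.2f}, {np.exp(hi):.2f}){_stars(p)}"

    for _, r in tab[tab["kind"] == "threshold"].iterrows():
        row = {"effect": r["name"], **{c: "" for c in logit_cols}}
        row[f"logit{int(r['logit'])}"] = fmt(r["estimate"], r["ci_low"], r["ci_high"], r["p_value"])
        rows.append(row)
    for _, r in tab[tab["kind"] == "shared"].iterrows():
        cell = fmt(r["estimate"], r["ci_low"], r["ci_high"], r["p_value"])
        rows.append({"effect": r["name"], **{c: cell for c in logit_cols}})
    npo_tab = tab[tab["kind"] == "npo"]
    for base in dict.fromkeys(n.split("|logit")[0] for n in npo_tab["name"]):
        row = {"effect": base}
        for k in range(1, K):
            r = npo_tab[npo_tab["name"] == f"{base}|logit{k}"].iloc[0]
            row[f"logit{k}"] = fmt(r["estimate"], r["ci_low"], r["ci_high"], r["p_value"])
        rows.append(row)
    for _, r in tab[tab["kind"] == "random"].iterrows():
        cell = f"{r['estimate']:.2f}"
        if np.isfinite(r.get("ci_low", np.nan)):
            cell += f" ({r['ci_low']:.2f}, {r['ci_high']:.2f})"
        rows.append({"effect": r["name"], "logit1": cell, **{c: "" for c in logit_cols[1:]}})
    if fit.icc is not None:
        rows.append({"effect": "ICC", "logit1": f"{fit.icc:.4f}", **{c: "" for c in logit_cols[1:]}})
    if is_mle:
        rows.append({"effect": "-2 log L", "logit1": f"{fit.minus2loglik:.2f}", **{c: "" for c in logit_cols[1:]}})
    else:
        rows.append({"effect": "Deviance (dbar)", "logit1": f"{fit.dbar:.2f}", **{c: "" for c in logit_cols[1:]}})
        rows.append({"effect": "Bayesian DIC", "logit1": f"{fit.dic:.2f}", **{c: "" for c in logit_cols[1:]}})
    return pd.DataFrame(rows, columns=["effect", *logit_cols])
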