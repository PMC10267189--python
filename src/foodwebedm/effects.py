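"""Temperature/biodiversity effect estimation with linear mixed models.

Point-wise responses (structural stability and the trophic-group
contributions) are modelled with crossed random intercepts for site, year
and season, to factor out shared seasonal and between-system variation.
Window-based responses (log CV, synchrony) use a site random intercept
only, since the moving window already averages over year and season.
Within-web trends are ordinary least squares per site.  Inference is Wald:
z-based two-sided p-values and 95% confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["EffectEstimate", "fit_mixed_model", "fit_per_web_models",
           "mediation_chain"]

CROSSED = "site+year+season"
SITE_ONLY = "site"


@dataclass
class EffectEstimate:
    response: str
    predictor: str
    slope: float
    ci_low: float
    ci_high: float
    p_value: float
    random_spec: str
    n_obs: int
    metadata: dict = field(default_factory=dict)
    per_web: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError("confidence interval must bracket the slope")


def _clean(data: pd.DataFrame, cols) -> pd.DataFrame:
    sub = data[list(cols)].replace([np.inf, -np.inf], np.nan).dropna()
    if sub.empty:
        raise ValueError("no complete observations")
    return sub


def fit_mixed_model(data: pd.DataFrame, response: str, predictor: str,
                    random_spec: str = CROSSED) -> EffectEstimate:
    """Random-intercept mixed model of ``response ~ predictor``.

    ``random_spec`` is ``"site+year+season"`` (crossed intercepts, used for
    point-wise responses) or ``"site"`` (window-based responses).  The
    predictor must already be on its analysis scale (ln °F temperature,
    ln richness, ...).  Variance components that collapse to zero trigger a
    refit without them (down to OLS if all vanish), recorded in metadata.
    """
    factors = random_spec.split("+")
    cols = [response, predictor] + factors
    sub = _clean(data, dict.fromkeys(cols))  # dedupe, keep order
    if np.ptp(sub[predictor].to_numpy()) == 0:
        raise ValueError(f"predictor {predictor!r} has no variance")
    sub = sub.rename(columns={response: "_y", predictor: "_x"})

    dropped = []
    remaining = list(factors)
    while True:
        result = _fit_once(sub, remaining)
        vcomp = _variance_components(result, remaining)
        zero = [f for f, v in vcomp.items() if v < 1e-8]
        if not zero or not remaining:
            break
        for f in zero:
            remaining.remove(f)
            dropped.append(f)
        warnings.warn(
            f"variance component(s) {zero} estimated at 0; refitting "
            f"without them")
    params = result.params
    conf = result.conf_int()
    return EffectEstimate(
        response=response, predictor=predictor,
        slope=float(params["_x"]),
        ci_low=float(conf.loc["_x", 0]), ci_high=float(conf.loc["_x", 1]),
        p_value=float(result.pvalues["_x"]),
        random_spec="+".join(remaining) if remaining else "none (OLS)",
        n_obs=len(sub),
        metadata={"dropped_components": dropped,
                  "inference": "Wald z",
                  "variance_components": _variance_components(
                      result, remaining)},
    )


def _fit_once(sub: pd.DataFrame, factors: list):
    if not factors:
        X = sm.add_constant(sub["_x"])
        return sm.OLS(sub["_y"], X).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if factors == ["site"]:
            model = smf.mixedlm("_y ~ _x", sub, groups=sub["site"])
        else:
            vc = {f: f"0 + C({f})" for f in factors}
            model = smf.mixedlm("_y ~ _x", sub,
                                groups=np.ones(len(sub)),
                                vc_formula=vc, re_formula="0")
        return model.fit(reml=True, method="lbfgs")


def _variance_components(result, factors: list) -> dict:
    if not factors:
        return {}
    out = {}
    if factors == ["site"]:
        out["site"] = float(np.asarray(result.cov_re)[0, 0])
    else:
        vc = getattr(result, "vcomp", np.array([]))
        for f, v in zip(sorted(factors), vc):
            out[f] = float(v)
    return out


def fit_per_web_models(data: pd.DataFrame, response: str, predictor: str,
                       min_obs: int = 10):
    """OLS of response on predictor within each site (food web).

    Sites with fewer than ``min_obs`` complete observations are skipped.
    Returns a DataFrame of per-web slopes/p-values plus sign counts:
    ``n_negative``/``n_positive`` (slope sign) and the counts significant
    at p < 0.05.
    """
    rows = []
    skipped = []
    for site, chunk in data.groupby("site"):
        try:
            sub = _clean(chunk, [response, predictor])
        except ValueError:
            skipped.append(site)
            continue
        if len(sub) < min_obs or np.ptp(sub[predictor].to_numpy()) == 0:
            skipped.append(site)
            continue
        X = sm.add_constant(sub[predictor])
        fit = sm.OLS(sub[response], X).fit()
        rows.append({"site": site, "slope": float(fit.params[predictor]),
                     "p_value": float(fit.pvalues[predictor]),
                     "n_obs": len(sub)})
    table = pd.DataFrame(rows)
    summary = {
        "n_webs": len(table),
        "n_negative": int((table["slope"] < 0).sum()) if len(table) else 0,
        "n_positive": int((table["slope"] > 0).sum()) if len(table) else 0,
        "n_negative_significant": int(((table["slope"] < 0)
                                       & (table["p_value"] < 0.05)).sum())
        if len(table) else 0,
        "n_positive_significant": int(((table["slope"] > 0)
                                       & (table["p_value"] < 0.05)).sum())
        if len(table) else 0,
        "skipped": skipped,
    }
    return table, summary


def mediation_chain(data: pd.DataFrame, x: str, m: str, y: str,
                    random_spec_xm: str = CROSSED,
                    random_spec_my: str = SITE_ONLY):
    """Two-step indirect-effect report: x→m and m→y mixed models.

    Mirrors two-stage reasoning such as temperature → link density →
    temporal stability.  No product-of-coefficients inference is attempted;
    the two slope estimates are returned as a pair.
    """
    first = fit_mixed_model(data, response=m, predictor=x,
                            random_spec=random_spec_xm)
    second = fit_mixed_model(data, response=y, predictor=m,
                             random_spec=random_spec_my)
    return first, second
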