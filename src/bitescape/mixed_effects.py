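"""Repeated-measures linear mixed models for kinematics and bite size.

Multiple strikes are filmed per fish (up to sixteen), so species and
strike-type comparisons use a linear mixed model with independent fixed
effects for species and strike type plus a random intercept per
individual, fit by REML.  Candidate structures (added interactions,
random slopes) are compared by AIC after refitting with full maximum
likelihood, since REML likelihoods are not comparable across different
fixed-effect sets.

Reference levels are generalist (species) and edge (strike type).
Per-coefficient tests are large-sample Wald z tests; exact small-sample
denominator degrees of freedom (Satterthwaite-style) are intentionally
not implemented, so p-values are mildly anti-conservative in small
samples and should be read directionally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from .errors import FitError, ValidationError
from .gam import REFERENCE_LEVELS

RESPONSES = ("g", "jp", "ja", "ttpg", "rs", "length_mm", "width_mm", "depth_mm")


@dataclass(frozen=True)
class LMMSpec:
    """One mixed-model structure for a single response variable."""

    response: str
    fixed: tuple = ("species", "strike_type")
    interactions: tuple = ()  # pairs of fixed-effect names
    random_slopes: tuple = ()  # numeric columns with per-individual slopes
    group: str = "individual_id"

    @property
    def label(self) -> str:
        terms = list(self.fixed) + [f"{a}:{b}" for a, b in self.interactions]
        if self.random_slopes:
            terms.append(f"(1+{'+'.join(self.random_slopes)}|{self.group})")
        else:
            terms.append(f"(1|{self.group})")
        return f"{self.response} ~ " + " + ".join(terms)


@dataclass
class LMMResult:
    spec: LMMSpec
    fixed_effects: pd.DataFrame  # estimate, se, z, p per coefficient
    random_intercept_variance: float
    residual_variance: float
    log_likelihood: float
    aic: float
    n_obs: int
    n_groups: int
    converged: bool
    method: str = "reml"
    extra: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.fixed_effects["estimate"].to_numpy()


def _design(spec: LMMSpec, table: pd.DataFrame):
    """Treatment-coded fixed-effect design matrix with named columns."""
    needed = [spec.response, spec.group, *spec.fixed, *spec.random_slopes]
    needed += [v for pair in spec.interactions for v in pair]
    missing = [c for c in dict.fromkeys(needed) if c not in table.columns]
    if missing:
        raise ValidationError(f"table lacks columns {missing}")
    data = table.dropna(subset=list(dict.fromkeys(needed))).reset_index(drop=True)
    cols = {"(Intercept)": np.ones(len(data))}
    level_cols = {}
    for f in spec.fixed:
        if data[f].dtype.kind in "fiu":
            cols[f] = data[f].to_numpy(dtype=float)
            level_cols[f] = {f: cols[f]}
            continue
        vals = data[f].astype(str)
        levels = sorted(vals.unique())
        ref = REFERENCE_LEVELS.get(f)
        if ref in levels:
            levels = [ref] + [l for l in levels if l != ref]
        level_cols[f] = {}
        for lev in levels[1:]:
            name = f"{f}[{lev}]"
            cols[name] = (vals == lev).to_numpy(float)
            level_cols[f][name] = cols[name]
    def _cols_for(name):
        if name in level_cols:
            return level_cols[name]
        return {name: data[name].to_numpy(dtype=float)}

    for a, b in spec.interactions:
        for na, ca in _cols_for(a).items():
            for nb, cb in _cols_for(b).items():
                cols[f"{na}:{nb}"] = ca * cb
    X = np.column_stack(list(cols.values()))
    return data, X, list(cols.keys())


def fit_lmm(
    spec: LMMSpec,
    table: pd.DataFrame,
    reml: bool = True,
    re_variance_ratio: float | None = None,
) -> LMMResult:
    """Fit the mixed model (REML by default).

    ``re_variance_ratio`` fixes the random-intercept-to-residual
    variance ratio instead of estimating it; the fit is then closed-form
    generalized least squares (ratio 0 collapses to ordinary least
    squares exactly).  Random slopes are not supported on that path.
    """
    data, X, names = _design(spec, table)
    y = data[spec.response].to_numpy(dtype=float)
    groups = data[spec.group].astype(str).to_numpy()
    n_groups = len(np.unique(groups))
    if re_variance_ratio is None and n_groups < 2:
        raise ValidationError("random intercept needs at least 2 individuals")

    if re_variance_ratio is not None:
        if spec.random_slopes:
            raise ValidationError("fixed-ratio GLS path has no random slopes")
        return _fit_gls_fixed_ratio(spec, X, y, names, groups, re_variance_ratio)

    exog_re = np.ones((len(data), 1))
    re_names = ["intercept"]
    for v in spec.random_slopes:
        exog_re = np.column_stack([exog_re, data[v].to_numpy(dtype=float)])
        re_names.append(v)
    model = MixedLM(y, X, groups=groups, exog_re=exog_re)
    fit = None
    last_exc = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (None, "powell", "cg"):
            try:
                kwargs = {} if method is None else {"method": method}
                cand = model.fit(reml=reml, maxiter=500, **kwargs)
            except Exception as exc:  # noqa: BLE001
                last_exc = exc
                continue
            if cand.converged and np.all(np.isfinite(cand.fe_params)):
                fit = cand
                break
    if fit is None:
        raise FitError(
            f"mixed-model fit did not converge for {spec.label}"
            + (f": {last_exc}" if last_exc else "")
        )
    k_fe = X.shape[1]
    fe = pd.DataFrame(
        {
            "estimate": fit.fe_params,
            "se": fit.bse_fe,
            "z": fit.fe_params / fit.bse_fe,
        },
        index=names,
    )
    from scipy.stats import norm

    fe["p"] = 2 * norm.sf(np.abs(fe["z"]))
    n_vc = fit.cov_re.shape[0] * (fit.cov_re.shape[0] + 1) // 2
    aic = -2 * fit.llf + 2 * (k_fe + n_vc + 1)
    return LMMResult(
        spec=spec,
        fixed_effects=fe,
        random_intercept_variance=float(np.asarray(fit.cov_re)[0, 0]),
        residual_variance=float(fit.scale),
        log_likelihood=float(fit.llf),
        aic=float(aic),
        n_obs=len(y),
        n_groups=n_groups,
        converged=bool(fit.converged),
        method="reml" if reml else "ml",
        extra={"cov_re": np.asarray(fit.cov_re), "re_names": re_names},
    )


def _fit_gls_fixed_ratio(spec, X, y, names, groups, ratio):
    """Closed-form GLS with the intercept-variance ratio held fixed.

    V = I + ratio * Z Z' blockwise by individual; ratio = 0 is OLS.
    Written directly in numpy so the zero-variance limit can be checked
    against an independent OLS implementation.
    """
    if ratio < 0:
        raise ValidationError("variance ratio must be nonnegative")
    n, p = X.shape
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    yWy = 0.0
    for gkey in np.unique(groups):
        idx = groups == gkey
        Xg, yg = X[idx], y[idx]
        m = idx.sum()
        # (I + ratio J)^-1 = I - ratio/(1+m*ratio) J   (J = ones)
        a = ratio / (1.0 + m * ratio)
        Xs = Xg.sum(axis=0)
        ys = yg.sum()
        XtWX += Xg.T @ Xg - a * np.outer(Xs, Xs)
        XtWy += Xg.T @ yg - a * Xs * ys
        yWy += yg @ yg - a * ys * ys
    beta = np.linalg.solve(XtWX, XtWy)
    rss_w = yWy - 2 * beta @ XtWy + beta @ XtWX @ beta
    sigma2 = rss_w / (n - p)
    cov = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    from scipy.stats import norm

    z = beta / se
    fe = pd.DataFrame(
        {"estimate": beta, "se": se, "z": z, "p": 2 * norm.sf(np.abs(z))}, index=names
    )
    # Gaussian log likelihood at the GLS solution
    logdet_V = 0.0
    for gkey in np.unique(groups):
        m = int((groups == gkey).sum())
        logdet_V += np.log1p(m * ratio)
    sigma2_ml = rss_w / n
    llf = -0.5 * (n * (np.log(2 * np.pi * sigma2_ml) + 1) + logdet_V)
    aic = -2 * llf + 2 * (p + 2)
    return LMMResult(
        spec=spec,
        fixed_effects=fe,
        random_intercept_variance=float(ratio * sigma2),
        residual_variance=float(sigma2),
        log_likelihood=float(llf),
        aic=float(aic),
        n_obs=n,
        n_groups=len(np.unique(groups)),
        converged=True,
        method=f"gls(ratio={ratio})",
    )


def compare_lmm(specs, table: pd.DataFrame) -> pd.DataFrame:
    """ML-based AIC comparison table across candidate structures.

    All candidates are refit on the rows complete for the union of
    their variables; per-candidate failures are flagged, not fatal.
    """
    specs = list(specs)
    responses = {s.response for s in specs}
    if len(responses) != 1:
        raise ValidationError("all candidate specs must share the response")
    needed = set()
    for s in specs:
        needed |= {s.response, s.group, *s.fixed, *s.random_slopes}
        needed |= {v for pair in s.interactions for v in pair}
    shared = table.dropna(subset=[c for c in needed if c in table.columns])
    rows = []
    for s in specs:
        try:
            r = fit_lmm(s, shared, reml=False)
            rows.append(
                {"model": s.label, "aic": r.aic, "loglik": r.log_likelihood, "error": ""}
            )
        except Exception as exc:  # noqa: BLE001 - isolate failures per spec
            rows.append(
                {"model": s.label, "aic": np.nan, "loglik": np.nan, "error": str(exc)}
            )
    out = pd.DataFrame(rows)
    out["delta_aic"] = out["aic"] - out["aic"].min()
    return out.sort_values("aic", kind="stable").reset_index(drop=True)


def ols_oracle(spec: LMMSpec, table: pd.DataFrame):
    """Independent OLS fit of the same fixed-effect design (statsmodels)."""
    data, X, names = _design(spec, table)
    y = data[spec.response].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    return pd.Series(res.params, index=names), res
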