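"""Gaussian GAMs with thin-plate regression splines and REML smoothing.

The model is penalized least squares

    y = X beta + eps,   minimize ||y - X beta||^2 + sum_j lambda_j beta' S_j beta

where X holds an intercept, treatment-coded factors, linear covariates,
and low-rank thin-plate spline bases (univariate s(x) or the bivariate
interaction surface s(g, jp)); each smooth contributes a positive
semi-definite penalty S_j whose null space is exactly the polynomial
(affine) part of the smooth.  Smoothing parameters are chosen by
restricted maximum likelihood (REML), optimized over log(lambda) by
derivative-free Nelder-Mead from a lambda = 1 start.

Thin-plate regression splines follow the standard low-rank construction:
the full-rank radial-kernel matrix (r^2 log r in 2-D, r^3 in 1-D) is
truncated to its k largest-magnitude eigenpairs and the affine null
space is separated via the usual orthogonality constraint, leaving k - M
"wiggly" columns with a full-rank penalty plus M - 1 unpenalized linear
columns (the constant is absorbed by the model intercept).  Smooth
columns are centered over the training data for identifiability.

Optional shrinkage per smooth adds a second, separately-REML-weighted
identity penalty on the smooth's null-space columns so the whole term
can be shrunk out of the model (double-penalty selection).

AIC uses the conditional convention: AIC = -2 logLik + 2 (total edf + 1),
with the Gaussian log likelihood evaluated at the ML variance RSS/n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .errors import FitError, ValidationError

REFERENCE_LEVELS = {"species": "generalist", "strike_type": "edge"}


# ---------------------------------------------------------------------------
# thin-plate spline basis


def _tps_kernel(r: np.ndarray, d: int) -> np.ndarray:
    if d == 1:
        return r**3 / 12.0
    if d == 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            k = r**2 * np.log(r) / (8.0 * np.pi)
        return np.where(r > 0, k, 0.0)
    raise ValidationError("thin-plate kernels implemented for 1-D and 2-D only")


def tps_basis(points: np.ndarray, k: int):
    """Low-rank thin-plate spline basis and penalty at the given points.

    Returns ``(B, S)``: ``B`` is n x k with the last ``M`` columns the
    polynomial null space (constant then linear coordinates) and the
    first ``k - M`` columns the penalized wiggly basis; ``S`` is the
    k x k positive semi-definite penalty, zero on the null-space block.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.ndim != 2:
        raise ValidationError("points must be n x d")
    n, d = points.shape
    M = d + 1
    if k < M + 2:
        raise ValidationError(f"k must be at least {M + 2} (null space + 2)")
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of points n={n}")
    T = np.column_stack([np.ones(n), points])
    if np.linalg.matrix_rank(T) < M:
        raise ValidationError("degenerate points: collinear/constant configuration")
    wiggly, S_w, _ = _tps_wiggly(points, k)
    B = np.column_stack([wiggly, T])
    S = np.zeros((k, k))
    S[: k - M, : k - M] = S_w
    return B, S


def _tps_wiggly(points: np.ndarray, k: int):
    """Wiggly design, its penalty, and the prediction map delta = UZ w."""
    n, d = points.shape
    M = d + 1
    E = _tps_kernel(cdist(points, points), d)
    eigval, eigvec = np.linalg.eigh(E)
    order = np.argsort(np.abs(eigval))[::-1][:k]
    U = eigvec[:, order]
    D = eigval[order]
    T = np.column_stack([np.ones(n), points])
    # constraint T' delta = 0 with delta = U z  ->  z in null(T'U)
    _, _, vt = np.linalg.svd(T.T @ U)
    Z = vt[M:].T  # k x (k - M)
    X_w = (U * D) @ Z
    S_w = (Z.T * D) @ Z  # Z' D Z, PSD on the constrained space
    UZ = U @ Z  # maps wiggly coefs to kernel weights at the knots
    return X_w, S_w, UZ


@dataclass(frozen=True)
class SmoothSpec:
    """One smooth term: s(x) or s(x, y)."""

    variables: tuple
    k: int | None = None
    shrinkage: bool = False

    @property
    def label(self) -> str:
        return f"s({','.join(self.variables)})"

    def default_k(self) -> int:
        return self.k if self.k is not None else (30 if len(self.variables) == 2 else 10)


@dataclass
class GAMSpec:
    """Model formula for one bite-dimension response."""

    response: str
    factors: tuple = ("species", "strike_type")
    linear: tuple = ()
    smooths: tuple = ()

    def __post_init__(self):
        self.smooths = tuple(
            s if isinstance(s, SmoothSpec) else SmoothSpec(tuple(s)) for s in self.smooths
        )
        smooth_vars = {v for s in self.smooths for v in s.variables}
        overlap = smooth_vars & set(self.linear)
        if overlap:
            raise ValidationError(
                f"variables cannot be both linear and smooth: {sorted(overlap)}"
            )

    @property
    def label(self) -> str:
        rhs = list(self.factors) + list(self.linear) + [s.label for s in self.smooths]
        return f"{self.response} ~ " + " + ".join(rhs) if rhs else f"{self.response} ~ 1"


class _SmoothBlock:
    """A fitted smooth term's basis, penalty blocks, and prediction state."""

    def __init__(self, spec: SmoothSpec, data: pd.DataFrame):
        self.spec = spec
        self.variables = spec.variables
        pts = data[list(spec.variables)].to_numpy(dtype=float)
        d = pts.shape[1]
        k = min(spec.default_k(), pts.shape[0])
        if k < d + 3:
            raise ValidationError(f"{spec.label}: too few rows for k={k}")
        X_w, S_w, UZ = _tps_wiggly(pts, k)
        self.knots = pts
        self.UZ = UZ
        # rescale for conditioning: penalty transforms as S / c^2
        c = np.sqrt(np.mean(X_w**2))
        if c <= 0 or not np.isfinite(c):
            raise ValidationError(f"{spec.label}: degenerate basis")
        self.scale = c
        X_w = X_w / c
        self.S_w = S_w / c**2
        self.wiggly_means = X_w.mean(axis=0)
        self.X_wiggly = X_w - self.wiggly_means
        null = pts.copy()  # linear columns; constant absorbed by intercept
        self.null_means = null.mean(axis=0)
        self.X_null = null - self.null_means
        ev = np.linalg.eigvalsh(self.S_w)
        ev = np.clip(ev, 1e-12 * max(ev.max(), 1.0), None)
        self.logdet_S = float(np.log(ev).sum())
        self.rank = self.S_w.shape[0]

    def design(self, data: pd.DataFrame):
        pts = data[list(self.variables)].to_numpy(dtype=float)
        E = _tps_kernel(cdist(pts, self.knots), self.knots.shape[1])
        Xw = (E @ self.UZ) / self.scale - self.wiggly_means
        Xn = pts - self.null_means
        return Xw, Xn


@dataclass
class FittedGAM:
    spec: GAMSpec
    coefficients: np.ndarray
    column_names: list
    smoothing_parameters: dict
    edf_by_term: dict
    edf_total: float
    aic: float
    log_likelihood: float
    deviance_explained: float
    fitted_values: np.ndarray
    residual_variance: float
    reml_score: float
    # internal prediction state
    _blocks: dict = field(repr=False, default_factory=dict)
    _factor_levels: dict = field(repr=False, default_factory=dict)
    _linear_vars: tuple = field(repr=False, default=())
    _train_means: dict = field(repr=False, default_factory=dict)
    _train_ranges: dict = field(repr=False, default_factory=dict)

    def predict(self, newdata: pd.DataFrame) -> np.ndarray:
        X = _assemble_design(
            newdata, self.spec, self._factor_levels, self._blocks, self.column_names
        )
        return X @ self.coefficients

    @property
    def bivariate_smooth(self) -> SmoothSpec | None:
        for s in self.spec.smooths:
            if len(s.variables) == 2:
                return s
        return None


def _factor_columns(data: pd.DataFrame, factor: str, levels: list) -> np.ndarray:
    vals = data[factor].astype(str)
    unknown = set(vals) - set(levels)
    if unknown:
        raise ValidationError(f"unseen {factor} levels: {sorted(unknown)}")
    return np.column_stack([(vals == lev).to_numpy(float) for lev in levels[1:]])


def _assemble_design(data, spec, factor_levels, blocks, column_names):
    cols = [np.ones((len(data), 1))]
    for f in spec.factors:
        cols.append(_factor_columns(data, f, factor_levels[f]))
    for v in spec.linear:
        cols.append(data[v].to_numpy(dtype=float)[:, None])
    for s in spec.smooths:
        blk = blocks.get(s.label)
        if blk is None:  # fully removed via lambda = inf overrides
            continue
        Xw, Xn = blk.design(data)
        cols.append(Xn)
        if not getattr(blk, "null_only", False):
            cols.append(Xw)
    X = np.hstack(cols)
    if X.shape[1] != len(column_names):
        raise FitError("design assembly mismatch")
    return X


def fit_gam(
    spec: GAMSpec,
    data: pd.DataFrame,
    lambda_overrides: dict | None = None,
    maxiter: int = 400,
) -> FittedGAM:
    """Fit a Gaussian GAM by penalized least squares + REML.

    ``lambda_overrides`` maps a smooth label (e.g. ``"s(g,jp)"``) to a
    fixed smoothing parameter; ``numpy.inf`` removes the penalized part
    entirely (the lambda -> infinity limit, leaving the smooth's linear
    null space), which reproduces the parametric OLS fit exactly.  A
    shrinkage smooth has a second override key ``label + ".null"``.
    """
    lambda_overrides = dict(lambda_overrides or {})
    needed = (
        [spec.response]
        + list(spec.factors)
        + list(spec.linear)
        + [v for s in spec.smooths for v in s.variables]
    )
    data = data.dropna(subset=[c for c in needed if c in data.columns]).reset_index(
        drop=True
    )
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValidationError(f"data lacks columns {missing}")
    n = len(data)
    y = data[spec.response].to_numpy(dtype=float)

    factor_levels = {}
    for f in spec.factors:
        levels = sorted(data[f].astype(str).unique())
        ref = REFERENCE_LEVELS.get(f)
        if ref in levels:
            levels = [ref] + [l for l in levels if l != ref]
        factor_levels[f] = levels

    # build blocks, honoring inf overrides by dropping the wiggly part
    blocks = {}
    penalties = []  # (name, col_slice, S, rank, logdet, fixed_lambda or None)
    cols = [np.ones((n, 1))]
    names = ["(Intercept)"]
    for f in spec.factors:
        cols.append(_factor_columns(data, f, factor_levels[f]))
        names += [f"{f}[{lev}]" for lev in factor_levels[f][1:]]
    for v in spec.linear:
        cols.append(data[v].to_numpy(dtype=float)[:, None])
        names.append(v)
    term_slices = {}
    pos = sum(c.shape[1] for c in cols)
    for s in spec.smooths:
        lam_fix = lambda_overrides.get(s.label)
        if lam_fix is not None and np.isinf(lam_fix):
            if s.shrinkage and np.isinf(
                lambda_overrides.get(s.label + ".null", np.inf)
            ):
                continue  # fully removed
            blk = _SmoothBlock(s, data)
            blk.null_only = True
            blocks[s.label] = blk
            # keep only the null space (linear) columns
            cols.append(blk.X_null)
            names += [f"{s.label}.null{i}" for i in range(blk.X_null.shape[1])]
            term_slices[s.label] = slice(pos, pos + blk.X_null.shape[1])
            pos += blk.X_null.shape[1]
            continue
        blk = _SmoothBlock(s, data)
        blk.null_only = False
        blocks[s.label] = blk
        d_null = blk.X_null.shape[1]
        d_wig = blk.X_wiggly.shape[1]
        cols.append(blk.X_null)
        names += [f"{s.label}.null{i}" for i in range(d_null)]
        null_slice = slice(pos, pos + d_null)
        pos += d_null
        cols.append(blk.X_wiggly)
        names += [f"{s.label}.w{i}" for i in range(d_wig)]
        wig_slice = slice(pos, pos + d_wig)
        pos += d_wig
        term_slices[s.label] = slice(null_slice.start, wig_slice.stop)
        penalties.append(
            (s.label, wig_slice, blk.S_w, blk.rank, blk.logdet_S, lam_fix)
        )
        if s.shrinkage:
            penalties.append(
                (
                    s.label + ".null",
                    null_slice,
                    np.eye(d_null),
                    d_null,
                    0.0,
                    lambda_overrides.get(s.label + ".null"),
                )
            )
    X = np.hstack(cols)
    p = X.shape[1]
    if n <= p - sum(pen[3] for pen in penalties):
        raise ValidationError(
            f"too few complete rows (n={n}) for the unpenalized dimension"
        )
    XtX = X.T @ X
    Xty = X.T @ y

    free = [i for i, pen in enumerate(penalties) if pen[5] is None]
    M_p = p - sum(pen[3] for pen in penalties)

    def _penalty_total(lams):
        S = np.zeros((p, p))
        for (name, sl, Sj, rank, ld, fix), lam in zip(penalties, lams):
            S[sl, sl] += lam * Sj
        return S

    def _solve(lams):
        S = _penalty_total(lams)
        H = XtX + S
        try:
            L = np.linalg.cholesky(H)
        except np.linalg.LinAlgError:
            H = H + 1e-10 * np.trace(XtX) / p * np.eye(p)
            L = np.linalg.cholesky(H)
        beta = np.linalg.solve(L.T, np.linalg.solve(L, Xty))
        logdet_H = 2.0 * float(np.log(np.diag(L)).sum())
        return beta, S, logdet_H

    def reml(rho_free):
        lams = []
        j = 0
        for i, pen in enumerate(penalties):
            if pen[5] is not None:
                lams.append(pen[5])
            else:
                lams.append(float(np.exp(np.clip(rho_free[j], -18, 18))))
                j += 1
        beta, S, logdet_H = _solve(lams)
        r = y - X @ beta
        rss = float(r @ r)
        pen_val = float(beta @ S @ beta)
        sigma2 = (rss + pen_val) / (n - M_p)
        if sigma2 <= 0:
            return np.inf
        val = (n - M_p) * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_H
        for (name, sl, Sj, rank, ld, fix), lam in zip(penalties, lams):
            val -= rank * np.log(lam) + ld
        return 0.5 * val

    if free:
        x0 = np.zeros(len(free))  # lambda = 1 start
        res = minimize(
            reml,
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter * max(1, len(free)), "xatol": 1e-6, "fatol": 1e-9},
        )
        if not np.all(np.isfinite(res.x)):
            raise FitError(f"REML optimization failed: {res.message}")
        rho_opt = res.x
        reml_score = float(res.fun)
    else:
        rho_opt = np.zeros(0)
        reml_score = float(reml(rho_opt)) if penalties else np.nan

    lams = []
    j = 0
    for pen in penalties:
        if pen[5] is not None:
            lams.append(pen[5])
        else:
            lams.append(float(np.exp(np.clip(rho_opt[j], -18, 18))))
            j += 1
    beta, S, _ = _solve(lams)
    H = XtX + S
    F = np.linalg.solve(H, XtX)
    edf_i = np.diag(F)
    edf_total = float(edf_i.sum())
    fitted = X @ beta
    rss = float(((y - fitted) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    # guard against a numerically-constant response (tss at rounding level)
    tss_floor = n * (1e-12 * max(1.0, float(np.abs(y).max()))) ** 2
    dev_expl = 0.0 if tss <= tss_floor else max(0.0, 1.0 - rss / tss)
    sigma2_ml = rss / n
    if sigma2_ml <= 0:
        sigma2_ml = np.finfo(float).tiny
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0)
    aic = -2.0 * loglik + 2.0 * (edf_total + 1.0)

    edf_by_term = {}
    for label, sl in term_slices.items():
        edf_by_term[label] = float(edf_i[sl].sum())
    smoothing = {pen[0]: lam for pen, lam in zip(penalties, lams)}
    if not penalties and reml_score is np.nan:
        reml_score = np.nan

    return FittedGAM(
        spec=spec,
        coefficients=beta,
        column_names=names,
        smoothing_parameters=smoothing,
        edf_by_term=edf_by_term,
        edf_total=edf_total,
        aic=float(aic),
        log_likelihood=float(loglik),
        deviance_explained=float(dev_expl),
        fitted_values=fitted,
        residual_variance=rss / max(n - edf_total, 1.0),
        reml_score=reml_score,
        _blocks=blocks,
        _factor_levels=factor_levels,
        _linear_vars=spec.linear,
        _train_means={
            v: float(data[v].mean())
            for v in set(spec.linear)
            | {v for s in spec.smooths for v in s.variables}
        },
        _train_ranges={
            v: (float(data[v].min()), float(data[v].max()))
            for v in {v for s in spec.smooths for v in s.variables}
        },
    )


# ---------------------------------------------------------------------------
# model selection


def candidate_models(response: str, shrinkage: bool = False) -> list[GAMSpec]:
    """The standard candidate set for one bite-dimension response.

    Seven shapes: the full model with the bivariate (g, jp) surface,
    the same without TTPG, separate univariate smooths for g and jp,
    all-smooth, all-linear, and the surface model dropping strike type
    or species.
    """
    s_gjp = SmoothSpec(("g", "jp"), shrinkage=shrinkage)
    return [
        GAMSpec(response, ("species", "strike_type"), ("ja", "rs", "ttpg"), (s_gjp,)),
        GAMSpec(response, ("species", "strike_type"), ("ja", "rs"), (s_gjp,)),
        GAMSpec(
            response,
            ("species", "strike_type"),
            ("ja", "ttpg", "rs"),
            (SmoothSpec(("g",)), SmoothSpec(("jp",))),
        ),
        GAMSpec(
            response,
            ("species", "strike_type"),
            (),
            tuple(SmoothSpec((v,)) for v in ("g", "jp", "ja", "ttpg", "rs")),
        ),
        GAMSpec(response, ("species", "strike_type"), ("g", "jp", "ja", "ttpg", "rs"), ()),
        GAMSpec(response, ("species",), ("ja", "ttpg", "rs"), (s_gjp,)),
        GAMSpec(response, ("strike_type",), ("ja", "ttpg", "rs"), (s_gjp,)),
    ]


def select_models(candidates: list[GAMSpec], data: pd.DataFrame) -> pd.DataFrame:
    """Fit candidates on shared rows; AIC comparison table.

    Rows are restricted to cases complete for the union of all candidate
    variables so AICs are comparable.  Per-candidate failures are
    flagged, not fatal.
    """
    all_vars = set()
    for c in candidates:
        all_vars |= {c.response, *c.factors, *c.linear}
        all_vars |= {v for s in c.smooths for v in s.variables}
    shared = data.dropna(subset=[v for v in all_vars if v in data.columns]).reset_index(
        drop=True
    )
    rows = []
    fits = []
    for c in candidates:
        try:
            f = fit_gam(c, shared)
            rows.append(
                {
                    "model": c.label,
                    "deviance_explained": f.deviance_explained,
                    "edf": f.edf_total,
                    "aic": f.aic,
                    "error": "",
                }
            )
            fits.append(f)
        except Exception as exc:  # noqa: BLE001 - per-candidate isolation
            rows.append(
                {
                    "model": c.label,
                    "deviance_explained": np.nan,
                    "edf": np.nan,
                    "aic": np.nan,
                    "error": str(exc),
                }
            )
            fits.append(None)
    table = pd.DataFrame(rows)
    best = table["aic"].min()
    table["delta_aic"] = table["aic"] - best
    table = table.sort_values("aic", kind="stable").reset_index(drop=True)
    table.attrs["fits"] = fits
    return table
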