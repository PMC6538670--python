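"""Mixed binomial / beta regression with spline smooths.

This module is the numerical engine behind the response sub-models.  It fits
generalized linear mixed models of two families:

* ``binomial`` — logit link, response either binary or (successes, trials);
* ``beta`` — logit link on the mean with a common precision ``phi``, for
  proportions in (0, 1).

Random intercepts for a single grouping factor (site or colony) are
integrated out with Gauss–Hermite quadrature, which yields the marginal
log-likelihood needed for AICc-based model comparison.  Crossed random
intercepts (e.g. site × fortnight) are handled with a joint Laplace
approximation.

Smooth terms are natural cubic regression splines with a small basis
dimension (default k = 5, i.e. five knots at quantiles of the training data,
four free columns after identifiability centring) — deliberately low-rank so
fitted effects stay close to monotone and ecologically interpretable.
Parameter uncertainty is propagated by multivariate-normal draws around the
maximum-likelihood estimate (covariance from the numerical Hessian of the
marginal log-likelihood).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator
from statsmodels.tools import numdiff

__all__ = ["SplineBasis", "DesignBuilder", "MixedGLM", "aicc"]


def aicc(loglik: float, n_params: int, n_obs: int) -> float:
    """Small-sample Akaike information criterion.

    ``AICc = -2 loglik + 2k + 2k(k+1)/(n - k - 1)``; undefined when
    ``n <= k + 1``.
    """
    k, n = n_params, n_obs
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


class SplineBasis:
    """Natural cubic regression spline basis with knots at training quantiles.

    Basis column ``j`` is the natural cubic spline interpolating the ``j``-th
    unit vector at the knots.  The columns form a partition of unity; for use
    alongside an intercept the first column is dropped and the remaining
    columns are centred on their training means.
    """

    def __init__(self, k: int = 5):
        if k < 3:
            raise ValueError("spline basis needs k >= 3 knots")
        self.k = k

    def fit(self, x):
        x = np.asarray(x, dtype=float)
        qs = np.linspace(0, 1, self.k)
        knots = np.quantile(x[~np.isnan(x)], qs)
        knots = np.unique(knots)
        if len(knots) < 3:
            raise ValueError("covariate has too few distinct values for a smooth")
        self.knots_ = knots
        self._splines = [
            CubicSpline(knots, np.eye(len(knots))[j], bc_type="natural")
            for j in range(len(knots))
        ]
        raw = self._raw(x)
        self.center_ = raw.mean(axis=0)
        return self

    def _raw(self, x):
        x = np.asarray(x, dtype=float)
        # linear extrapolation beyond the boundary knots
        lo, hi = self.knots_[0], self.knots_[-1]
        xc = np.clip(x, lo, hi)
        cols = []
        for sp in self._splines[1:]:
            v = sp(xc)
            d_lo, d_hi = sp(lo, 1), sp(hi, 1)
            v = v + np.where(x < lo, (x - lo) * d_lo, 0.0)
            v = v + np.where(x > hi, (x - hi) * d_hi, 0.0)
            cols.append(v)
        return np.column_stack(cols)

    def transform(self, x):
        return self._raw(x) - self.center_

    @property
    def n_cols(self) -> int:
        return len(self.knots_) - 1


# ---------------------------------------------------------------------------
# formula mini-language
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"^\s*(.*?)\s*$")


@dataclass
class _Term:
    kind: str  # "linear" | "spline" | "factor" | "tensor" | "interaction"
    vars: tuple
    k: int = 5
    parts: tuple = ()
    label: str = ""


def _parse_atom(tok: str) -> _Term:
    tok = tok.strip()
    m = re.fullmatch(r"s\(\s*(\w+)\s*(?:,\s*k\s*=\s*(\d+)\s*)?\)", tok)
    if m:
        k = int(m.group(2)) if m.group(2) else 5
        return _Term("spline", (m.group(1),), k=k, label=tok)
    m = re.fullmatch(r"te\(\s*(\w+)\s*,\s*(\w+)\s*(?:,\s*k\s*=\s*(\d+)\s*)?\)", tok)
    if m:
        k = int(m.group(3)) if m.group(3) else 3
        return _Term("tensor", (m.group(1), m.group(2)), k=k, label=tok)
    m = re.fullmatch(r"C\(\s*(\w+)\s*\)", tok)
    if m:
        return _Term("factor", (m.group(1),), label=tok)
    if re.fullmatch(r"\w+", tok):
        return _Term("linear", (tok,), label=tok)
    raise ValueError(f"cannot parse formula term {tok!r}")


def _parse_term(tok: str) -> _Term:
    tok = tok.strip()
    # split on ':' not inside parentheses
    depth, parts, cur = 0, [], ""
    for ch in tok:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == ":" and depth == 0:
            parts.append(cur)
            cur = ""
        else:
            cur += ch
    parts.append(cur)
    atoms = [_parse_atom(p) for p in parts]
    if len(atoms) == 1:
        return atoms[0]
    if len(atoms) > 2:
        raise ValueError(f"only two-way interactions supported: {tok!r}")
    allvars = tuple(v for a in atoms for v in a.vars)
    return _Term("interaction", allvars, parts=tuple(atoms), label=tok)


def parse_formula(formula: str):
    """Parse ``"response ~ term + term + ..."`` into (lhs, [terms]).

    Terms: bare names (linear), ``s(x)`` / ``s(x, k=5)`` smooths, ``C(f)``
    factors, ``te(x, z)`` tensor-product smooths and ``a:b`` interactions.
    ``response ~ 1`` is the intercept-only model.
    """
    lhs, _, rhs = formula.partition("~")
    if not rhs:
        raise ValueError("formula must contain '~'")
    tokens = [t.strip() for t in rhs.split("+") if t.strip()]
    terms = [_parse_term(t) for t in tokens if t != "1"]
    return lhs.strip(), terms


class DesignBuilder:
    """Build (and rebuild, for prediction) a fixed-effect design matrix."""

    def __init__(self, terms):
        self.terms = terms

    def fit(self, df: pd.DataFrame):
        self._bases = {}
        self._levels = {}
        for term in self._atoms():
            if term.kind == "spline":
                self._bases[term.label] = SplineBasis(term.k).fit(df[term.vars[0]])
            elif term.kind == "tensor":
                self._bases[term.label] = (
                    SplineBasis(term.k).fit(df[term.vars[0]]),
                    SplineBasis(term.k).fit(df[term.vars[1]]),
                )
            elif term.kind == "factor":
                self._levels[term.vars[0]] = sorted(pd.unique(df[term.vars[0]]))
        X, names, slices = self._build(df)
        self.columns_ = names
        self.term_slices_ = slices
        return X

    def transform(self, df: pd.DataFrame):
        X, _, _ = self._build(df)
        return X

    def _atoms(self):
        for term in self.terms:
            if term.kind == "interaction":
                yield from term.parts
            else:
                yield term

    def _atom_cols(self, term: _Term, df):
        if term.kind == "linear":
            return df[term.vars[0]].to_numpy(dtype=float)[:, None], [term.vars[0]]
        if term.kind == "spline":
            B = self._bases[term.label].transform(df[term.vars[0]])
            return B, [f"{term.label}.{j}" for j in range(B.shape[1])]
        if term.kind == "tensor":
            bx, bz = self._bases[term.label]
            Bx, Bz = bx.transform(df[term.vars[0]]), bz.transform(df[term.vars[1]])
            cols = [Bx[:, i] * Bz[:, j] for i in range(Bx.shape[1]) for j in range(Bz.shape[1])]
            return np.column_stack(cols), [
                f"{term.label}.{i}{j}" for i in range(Bx.shape[1]) for j in range(Bz.shape[1])
            ]
        if term.kind == "factor":
            levels = self._levels[term.vars[0]]
            vals = df[term.vars[0]]
            cols = [(vals == lv).to_numpy(dtype=float) for lv in levels[1:]]
            if not cols:
                return np.zeros((len(df), 0)), []
            return np.column_stack(cols), [f"{term.vars[0]}[{lv}]" for lv in levels[1:]]
        raise AssertionError(term.kind)

    def _build(self, df):
        blocks = [np.ones((len(df), 1))]
        names = ["intercept"]
        slices = {}
        for term in self.terms:
            if term.kind == "interaction":
                a, b = term.parts
                Xa, na = self._atom_cols(a, df)
                Xb, nb = self._atom_cols(b, df)
                cols = [Xa[:, i] * Xb[:, j] for i in range(Xa.shape[1]) for j in range(Xb.shape[1])]
                X = np.column_stack(cols) if cols else np.zeros((len(df), 0))
                n = [f"{ni}:{nj}" for ni in na for nj in nb]
            else:
                X, n = self._atom_cols(term, df)
            start = sum(b.shape[1] for b in blocks)
            slices[term.label] = slice(start, start + X.shape[1])
            blocks.append(X)
            names.extend(n)
        return np.column_stack(blocks), names, slices


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return special.expit(x)


class _Binomial:
    n_extra = 0

    def __init__(self, y, trials):
        self.y = y
        self.m = trials
        self.const = special.gammaln(trials + 1) - special.gammaln(y + 1) - special.gammaln(
            trials - y + 1
        )

    def ll(self, eta, extra=None):
        return (
            self.y[:, None] * eta - self.m[:, None] * _softplus(eta) + self.const[:, None]
        )

    def dll_deta(self, eta, extra=None):
        return self.y[:, None] - self.m[:, None] * _sigmoid(eta)

    def d2ll_deta2(self, eta, extra=None):
        p = _sigmoid(eta)
        return -self.m[:, None] * p * (1 - p)

    def dll_dextra(self, eta, extra=None):
        return np.zeros_like(eta)[..., None][..., :0]

    @staticmethod
    def mean(eta, extra=None):
        return _sigmoid(eta)


class _Beta:
    n_extra = 1  # log precision

    def __init__(self, y, trials=None, eps=1e-4):
        y = np.clip(np.asarray(y, dtype=float), eps, 1 - eps)
        self.y = y
        self.logy = np.log(y)
        self.log1my = np.log1p(-y)

    def ll(self, eta, extra):
        phi = np.exp(extra[0])
        mu = _sigmoid(eta)
        a, b = mu * phi, (1 - mu) * phi
        return (
            special.gammaln(phi)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1) * self.logy[:, None]
            + (b - 1) * self.log1my[:, None]
        )

    def dll_deta(self, eta, extra):
        phi = np.exp(extra[0])
        mu = _sigmoid(eta)
        dmu = phi * (
            -special.digamma(mu * phi)
            + special.digamma((1 - mu) * phi)
            + self.logy[:, None]
            - self.log1my[:, None]
        )
        return dmu * mu * (1 - mu)

    def dll_dextra(self, eta, extra):
        phi = np.exp(extra[0])
        mu = _sigmoid(eta)
        d_phi = (
            special.digamma(phi)
            - mu * special.digamma(mu * phi)
            - (1 - mu) * special.digamma((1 - mu) * phi)
            + mu * self.logy[:, None]
            + (1 - mu) * self.log1my[:, None]
        )
        return (d_phi * phi)[..., None]

    @staticmethod
    def mean(eta, extra=None):
        return _sigmoid(eta)


_FAMILIES = {"binomial": _Binomial, "beta": _Beta}


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class MixedGLM(BaseEstimator):
    """Binomial / beta regression with random intercepts and spline smooths.

    Parameters
    ----------
    formula : str
        ``"response ~ terms"``; for site-level binomial data pass
        ``trials_col`` and let the response column hold success counts.
    family : {"binomial", "beta"}
    groups : str | list[str] | None
        Random-intercept factor(s).  One factor uses Gauss–Hermite
        quadrature (marginal likelihood, AICc-valid); two or more use a
        joint Laplace approximation.
    trials_col : str | None
        Column of binomial trials; omit for binary data.
    n_quad : int
        Gauss–Hermite nodes per group.
    ridge : float
        L2 penalty applied to non-intercept coefficients only as a fallback
        when the unpenalized fit diverges (complete separation).

    Fitted attributes (trailing underscore): ``coef_``, ``coef_names_``,
    ``re_sd_``, ``phi_`` (beta family), ``loglik_``, ``n_obs_``, ``aicc_``,
    ``cov_params_``, ``converged_``, ``regularized_``.
    """

    def __init__(
        self,
        formula: str = "y ~ 1",
        family: str = "binomial",
        groups=None,
        trials_col: str | None = None,
        n_quad: int = 13,
        ridge: float = 0.0,
        re_sd_start: float = 0.5,
    ):
        self.formula = formula
        self.family = family
        self.groups = groups
        self.trials_col = trials_col
        self.n_quad = n_quad
        self.ridge = ridge
        self.re_sd_start = re_sd_start

    # -- fitting ----------------------------------------------------------

    def fit(self, data: pd.DataFrame, y=None):
        lhs, terms = parse_formula(self.formula)
        self._design = DesignBuilder(terms)
        X = self._design.fit(data)
        yv = data[lhs].to_numpy(dtype=float)
        trials = (
            data[self.trials_col].to_numpy(dtype=float)
            if self.trials_col
            else np.ones_like(yv)
        )
        fam_cls = _FAMILIES[self.family]
        fam = fam_cls(yv, trials)

        group_cols = (
            [self.groups] if isinstance(self.groups, str) else list(self.groups or [])
        )
        codes, sizes = [], []
        for col in group_cols:
            c, levels = pd.factorize(data[col])
            codes.append(c)
            sizes.append(len(levels))
        self._group_cols = group_cols

        p = X.shape[1]
        n_re = len(group_cols)
        n_extra = fam.n_extra
        x0 = np.zeros(p + n_re + n_extra)
        mean_y = np.clip(np.mean(yv / np.maximum(trials, 1)), 1e-3, 1 - 1e-3)
        x0[0] = special.logit(mean_y)
        x0[p : p + n_re] = np.log(self.re_sd_start)
        if n_extra:
            x0[p + n_re] = np.log(5.0)

        # keep variance parameters in a numerically safe range
        bounds = (
            [(None, None)] * p + [(-10.0, 5.0)] * n_re + [(-5.0, 12.0)] * n_extra
        )
        obj = self._make_objective(X, fam, codes, sizes, p, n_re, n_extra, self.ridge)
        res = optimize.minimize(
            obj, x0, jac=True if n_re <= 1 else None, method="L-BFGS-B", bounds=bounds
        )
        self.regularized_ = False
        if (not res.success and not np.isfinite(res.fun)) or np.abs(res.x[:p]).max() > 15:
            warnings.warn(
                "unstable fit (possible complete separation); refitting with ridge penalty",
                stacklevel=2,
            )
            obj = self._make_objective(X, fam, codes, sizes, p, n_re, n_extra, max(self.ridge, 1.0))
            res = optimize.minimize(
                obj, x0, jac=True if n_re <= 1 else None, method="L-BFGS-B", bounds=bounds
            )
            self.regularized_ = True

        xhat = res.x
        self.converged_ = bool(res.success)
        self.coef_ = xhat[:p]
        self.coef_names_ = list(self._design.columns_)
        self.re_sd_ = {
            col: float(np.exp(xhat[p + j])) for j, col in enumerate(group_cols)
        }
        self.phi_ = float(np.exp(xhat[p + n_re])) if n_extra else None
        self.params_ = xhat
        # unpenalized marginal loglik at the optimum
        obj0 = self._make_objective(X, fam, codes, sizes, p, n_re, n_extra, 0.0)
        val = obj0(xhat)
        self.loglik_ = -float(val[0] if isinstance(val, tuple) else val)
        self.n_obs_ = len(yv)
        self.n_params_ = p + n_re + n_extra
        self.aicc_ = aicc(self.loglik_, self.n_params_, self.n_obs_)

        hess = numdiff.approx_hess(xhat, lambda v: _scalar(obj0(v)))
        self.cov_params_ = _safe_inv(hess)
        self._fam_cls = fam_cls
        return self

    def _make_objective(self, X, fam, codes, sizes, p, n_re, n_extra, ridge):
        if n_re == 0:
            return lambda v: _nll_fixed(v, X, fam, p, n_extra, ridge)
        if n_re == 1:
            zq, wq = np.polynomial.hermite.hermgauss(self.n_quad)
            return lambda v: _nll_gh(v, X, fam, codes[0], sizes[0], zq, wq, p, n_extra, ridge)
        return lambda v: _nll_laplace(v, X, fam, codes, sizes, p, n_extra, ridge)

    # -- prediction -------------------------------------------------------

    def predict_eta(self, data: pd.DataFrame, params=None):
        """Linear predictor at random effects = 0."""
        X = self._design.transform(data)
        beta = self.coef_ if params is None else np.asarray(params)[: X.shape[1]]
        return X @ beta

    def predict(self, data: pd.DataFrame, params=None):
        """Mean response (probability / proportion) at random effects = 0."""
        return self._fam_cls.mean(self.predict_eta(data, params=params))

    def predict_many(self, data: pd.DataFrame, params_matrix) -> np.ndarray:
        """Mean response for a whole draw matrix at once: (n_rows, n_draws)."""
        X = self._design.transform(data)
        B = np.asarray(params_matrix)[:, : X.shape[1]]
        return self._fam_cls.mean(X @ B.T)

    # -- uncertainty ------------------------------------------------------

    def draws(self, n_draws: int, seed: int, scale: float = 1.0) -> np.ndarray:
        """Seeded multivariate-normal parameter draws around the MLE.

        Rows are parameter vectors ordered like ``params_`` (fixed effects,
        then log random-effect SDs, then log precision for the beta family).
        ``scale`` multiplies the covariance Cholesky factor; ``scale=0`` is
        the zero-variance engine (every draw is the point estimate).
        """
        rng = np.random.default_rng(seed)
        cov = self.cov_params_
        if not np.all(np.isfinite(cov)):
            warnings.warn("non-finite covariance; using ridge-stabilized identity", stacklevel=2)
            cov = np.eye(len(self.params_)) * 1e-6
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            warnings.warn("singular covariance; ridge-stabilizing", stacklevel=2)
            w, v = np.linalg.eigh((cov + cov.T) / 2)
            chol = v * np.sqrt(np.clip(w, 1e-10, None))
        z = rng.standard_normal((n_draws, len(self.params_)))
        return self.params_ + scale * (z @ chol.T)


def _scalar(v):
    return v[0] if isinstance(v, tuple) else v


def _safe_inv(h):
    try:
        cov = np.linalg.inv(h)
    except np.linalg.LinAlgError:
        cov = np.linalg.inv(h + 1e-6 * np.eye(len(h)))
    # symmetrize and clip eigenvalues: numerical Hessians of Laplace/quadrature
    # objectives can carry small negative curvature
    cov = (cov + cov.T) / 2
    w, v = np.linalg.eigh(cov)
    if (w <= 0).any():
        warnings.warn("non-PSD parameter covariance; clipping eigenvalues", stacklevel=2)
        w = np.clip(w, 1e-10, None)
        cov = (v * w) @ v.T
    return cov


def _nll_fixed(v, X, fam, p, n_extra, ridge):
    beta = v[:p]
    extra = v[p:]
    eta = (X @ beta)[:, None]
    ll = fam.ll(eta, extra).sum()
    g_eta = fam.dll_deta(eta, extra)
    grad_beta = X.T @ g_eta[:, 0]
    grad = np.concatenate(
        [grad_beta, fam.dll_dextra(eta, extra).sum(axis=(0, 1)) if n_extra else []]
    )
    pen = 0.5 * ridge * np.sum(beta[1:] ** 2)
    grad_pen = np.concatenate([[0.0], ridge * beta[1:], np.zeros(n_extra)])
    return -(ll - pen), -(grad - grad_pen)


def _nll_gh(v, X, fam, code, n_groups, zq, wq, p, n_extra, ridge):
    beta, log_sig = v[:p], v[p]
    extra = v[p + 1 :]
    sigma = np.exp(log_sig)
    nodes = np.sqrt(2.0) * sigma * zq  # (Q,)
    logw = np.log(wq) - 0.5 * np.log(np.pi)
    eta = (X @ beta)[:, None] + nodes[None, :]  # (n, Q)
    ll = fam.ll(eta, extra)  # (n, Q)
    # per-group sums
    G, Q = n_groups, len(zq)
    ll_g = np.zeros((G, Q))
    np.add.at(ll_g, code, ll)
    a = ll_g + logw[None, :]
    amax = a.max(axis=1, keepdims=True)
    lse = amax[:, 0] + np.log(np.exp(a - amax).sum(axis=1))
    total = lse.sum()
    # posterior weights per group/node
    pw = np.exp(a - lse[:, None])  # (G, Q)
    w_obs = pw[code]  # (n, Q)
    g_eta = fam.dll_deta(eta, extra)  # (n, Q)
    s = (w_obs * g_eta).sum(axis=1)  # (n,)
    grad_beta = X.T @ s
    grad_logsig = float(((w_obs * g_eta) @ nodes).sum())
    if n_extra:
        g_extra = (w_obs[..., None] * fam.dll_dextra(eta, extra)).sum(axis=(0, 1))
    else:
        g_extra = np.zeros(0)
    pen = 0.5 * ridge * np.sum(beta[1:] ** 2)
    grad = np.concatenate([grad_beta, [grad_logsig], g_extra])
    grad_pen = np.concatenate([[0.0], ridge * beta[1:], np.zeros(1 + n_extra)])
    return -(total - pen), -(grad - grad_pen)


def _nll_laplace(v, X, fam, codes, sizes, p, n_extra, ridge):
    """Joint Laplace approximation for crossed random intercepts (binomial)."""
    beta = v[:p]
    log_sigs = v[p : p + len(codes)]
    extra = v[p + len(codes) :]
    sig2 = np.exp(2 * log_sigs)
    m = int(np.sum(sizes))
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    n = X.shape[0]
    # dense indicator Z (n, m); sizes are small for site/interval factors
    Z = np.zeros((n, m))
    for c, off in zip(codes, offsets):
        Z[np.arange(n), off + c] = 1.0
    d_inv = np.concatenate([np.full(s, 1.0 / s2) for s, s2 in zip(sizes, sig2)])
    eta_fix = X @ beta
    u = np.zeros(m)
    for _ in range(50):
        eta = (eta_fix + Z @ u)[:, None]
        g = fam.dll_deta(eta, extra)[:, 0]
        w = -fam.d2ll_deta2(eta, extra)[:, 0]
        grad = Z.T @ g - d_inv * u
        H = (Z.T * w) @ Z + np.diag(d_inv)
        step = np.linalg.solve(H, grad)
        u_new = u + step
        if np.max(np.abs(step)) < 1e-9:
            u = u_new
            break
        u = u_new
    eta = (eta_fix + Z @ u)[:, None]
    ll = fam.ll(eta, extra).sum()
    w = -fam.d2ll_deta2(eta, extra)[:, 0]
    H = (Z.T * w) @ Z + np.diag(d_inv)
    sign, logdet_h = np.linalg.slogdet(H)
    logdet_d = np.sum([s * np.log(s2) for s, s2 in zip(sizes, sig2)])
    lap = ll - 0.5 * np.sum(d_inv * u**2) - 0.5 * logdet_d - 0.5 * logdet_h
    pen = 0.5 * ridge * np.sum(beta[1:] ** 2)
    return -(lap - pen)
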