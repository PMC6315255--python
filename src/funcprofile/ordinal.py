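"""Weighted ordered-categorical additive model (cumulative-logit GAM).

The response takes ordered categories 1 < 2 < ... < C (here C = 3:
lowest quartile, interquartile range, highest quartile of a capacity
measure).  The model is proportional odds on a latent additive
predictor:

    P(Y <= c | X) = logistic(theta_c - eta(X)),
    eta(X) = sum_p f_p(X_p),

with estimated thresholds theta_1 < ... < theta_{C-1}.  Continuous
predictors enter through penalized cubic B-spline smooths (second-order
curvature penalty, so a fully penalized smooth shrinks to a line);
categorical predictors enter as unpenalized level offsets.  The
intercept is absorbed into the thresholds and every smooth basis is
column-centered over the training data for identifiability.

Observations may carry prevalence weights (see :func:`class_weights`).
Smoothing parameters are shared within term groups (by default one
group, hence one parameter) and chosen by a coordinate sweep over a
log-spaced grid minimizing an information criterion — BIC-style
(2*NLL + log(n)*edf) by default, with edf the trace of the
penalized-Hessian influence matrix.  The heavier BIC penalty matters
when many candidate smooths are pure noise: it lets the fit shrink
them to zero instead of keeping spurious structure, which AIC tends
to retain when the predictor count approaches the sample size.
Optimization is damped Newton on the concave log-likelihood with the
analytic Hessian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from statsmodels.gam.smooth_basis import BSplines

_PCLIP = 1e-10


class ConvergenceError(RuntimeError):
    """Optimizer failed; carries the scipy result for diagnosis."""

    def __init__(self, message, result=None):
        super().__init__(message)
        self.result = result


def class_weights(categories) -> np.ndarray:
    """Inverse-prevalence observation weights, mean 1.

    w_i = N / (C * n_c(i)) with C the number of *observed* categories;
    balances the quartile design's 1:2:1 imbalance so each category
    contributes equally to the fit.
    """
    cats = np.asarray(categories)
    if cats.size == 0:
        raise ValueError("need at least one observation")
    levels, counts = np.unique(cats, return_counts=True)
    n, c = cats.size, levels.size
    lookup = dict(zip(levels.tolist(), (n / (c * counts)).tolist()))
    return np.array([lookup[v] for v in cats.tolist()])


@dataclass
class _Term:
    name: str
    kind: str                    # "spline" | "linear" | "categorical"
    sl: slice                    # columns in the design matrix
    penalty: np.ndarray | None = None
    basis: object = None         # BSplines for spline terms
    center: np.ndarray | None = None
    xmin: float = 0.0
    xmax: float = 0.0
    mean: float = 0.0            # standardization, linear terms
    scale: float = 1.0
    levels: tuple = ()


@dataclass
class PartialEffect:
    """A centered smooth evaluated on a grid with a pointwise SE band."""

    predictor: str
    points: np.ndarray
    effect: np.ndarray
    se: np.ndarray
    extrapolated: np.ndarray


class OrdinalGAM:
    """Cumulative-logit additive model with penalized smooths.

    Parameters
    ----------
    smooth_df : int
        Basis dimension per continuous predictor (df of the B-spline
        basis before the intercept column is dropped).
    smooth : {"spline", "linear"}
        "linear" forces every continuous predictor to enter linearly
        (the model then reduces to proportional-odds logistic
        regression when ``penalized`` is off).
    penalized : bool
        Turn the curvature penalty off entirely (linear-reduction and
        oracle-comparison use).
    lambda_grid : sequence of float
        Candidate smoothing parameters.
    criterion : {"bic", "aic"}
        Information criterion scoring each candidate.
    term_groups : mapping name -> int, optional
        Smooth terms sharing a group share one smoothing parameter;
        groups are tuned separately by a coordinate sweep over the
        grid (unnamed terms fall in group 0).  One group — the
        default — means a single shared parameter.
    tol : float
        Convergence tolerance on the penalized log-likelihood.
    seed : int
        Accepted for interface uniformity; the fit is deterministic,
        so the seed has no effect.
    """

    def __init__(
        self,
        smooth_df: int = 6,
        degree: int = 3,
        smooth: str = "spline",
        penalized: bool = True,
        lambda_grid=(1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3, 1e4, 1e6),
        criterion: str = "bic",
        term_groups: dict | None = None,
        tol: float = 1e-8,
        max_iter: int = 1000,
        seed: int | None = None,
    ):
        if smooth not in ("spline", "linear"):
            raise ValueError("smooth must be 'spline' or 'linear'")
        self.smooth_df = smooth_df
        self.degree = degree
        self.smooth = smooth
        self.penalized = penalized
        self.lambda_grid = tuple(lambda_grid)
        if criterion not in ("aic", "bic"):
            raise ValueError("criterion must be 'aic' or 'bic'")
        self.criterion = criterion
        self.term_groups = dict(term_groups or {})
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed

    # ------------------------------------------------------------ design

    def _build_terms(self, X: pd.DataFrame):
        terms: list[_Term] = []
        blocks: list[np.ndarray] = []
        col = 0
        for name in X.columns:
            x = X[name]
            if isinstance(x.dtype, pd.CategoricalDtype) or x.dtype == object:
                if isinstance(x.dtype, pd.CategoricalDtype):
                    levels = tuple(str(lv) for lv in x.cat.categories)
                else:
                    levels = tuple(sorted(pd.unique(x.astype(str))))
                dummies = np.column_stack(
                    [(x.astype(str) == lv).to_numpy(float) for lv in levels[1:]]
                ) if len(levels) > 1 else np.zeros((len(x), 0))
                k = dummies.shape[1]
                terms.append(
                    _Term(name, "categorical", slice(col, col + k), levels=levels)
                )
                blocks.append(dummies)
                col += k
                continue
            xv = x.to_numpy(dtype=float)
            if np.isnan(xv).any():
                raise ValueError(f"missing values in predictor {name!r}")
            distinct = np.unique(xv).size
            if self.smooth == "spline" and distinct >= self.smooth_df + 2:
                bs = BSplines(
                    xv[:, None],
                    df=[self.smooth_df],
                    degree=[self.degree],
                    include_intercept=False,
                )
                basis = np.asarray(bs.basis, dtype=float)
                center = basis.mean(axis=0)
                basis = basis - center
                k = basis.shape[1]
                terms.append(
                    _Term(
                        name,
                        "spline",
                        slice(col, col + k),
                        penalty=np.asarray(bs.penalty_matrices[0], dtype=float),
                        basis=bs,
                        center=center,
                        xmin=float(xv.min()),
                        xmax=float(xv.max()),
                    )
                )
                blocks.append(basis)
                col += k
            else:
                m = float(xv.mean())
                s = float(xv.std()) or 1.0
                terms.append(
                    _Term(
                        name, "linear", slice(col, col + 1),
                        xmin=float(xv.min()), xmax=float(xv.max()),
                        mean=m, scale=s,
                    )
                )
                blocks.append(((xv - m) / s)[:, None])
                col += 1
        D = np.hstack(blocks) if blocks else np.zeros((len(X), 0))
        return terms, D

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        blocks = []
        for t in self.terms_:
            if t.name not in X.columns:
                raise ValueError(f"predictor {t.name!r} missing from input")
            x = X[t.name]
            if t.kind == "categorical":
                xs = x.astype(str)
                unknown = set(pd.unique(xs)) - set(t.levels)
                if unknown:
                    raise ValueError(
                        f"unknown level(s) {sorted(unknown)} for {t.name!r}"
                    )
                blocks.append(
                    np.column_stack(
                        [(xs == lv).to_numpy(float) for lv in t.levels[1:]]
                    ) if len(t.levels) > 1 else np.zeros((len(x), 0))
                )
            elif t.kind == "spline":
                xv = np.clip(x.to_numpy(dtype=float), t.xmin, t.xmax)
                b = np.asarray(t.basis.transform(xv[:, None]), dtype=float)
                blocks.append(b - t.center)
            else:
                xv = x.to_numpy(dtype=float)
                blocks.append(((xv - t.mean) / t.scale)[:, None])
        return np.hstack(blocks) if blocks else np.zeros((len(X), 0))

    # --------------------------------------------------------- likelihood

    def _nll_grad(self, xi, D, yidx, w, S, n_thresh):
        """Penalized NLL and gradient in natural (theta, beta) coordinates."""
        n, p = D.shape
        theta = xi[:n_thresh]
        beta = xi[n_thresh:]
        eta = D @ beta
        up = yidx < n_thresh          # has an upper threshold
        lo = yidx > 0                 # has a lower threshold
        f_up = np.zeros(n)
        f_lo = np.zeros(n)
        F_up = np.ones(n)
        F_lo = np.zeros(n)
        F_up[up] = expit(theta[yidx[up]] - eta[up])
        F_lo[lo] = expit(theta[yidx[lo] - 1] - eta[lo])
        f_up[up] = F_up[up] * (1.0 - F_up[up])
        f_lo[lo] = F_lo[lo] * (1.0 - F_lo[lo])
        P = np.clip(F_up - F_lo, _PCLIP, None)
        nll = -np.sum(w * np.log(P))
        # gradient wrt natural thresholds and eta
        dl_dtheta = np.zeros((n, n_thresh))
        idx = np.arange(n)
        dl_dtheta[idx[up], yidx[up]] = f_up[up] / P[up]
        dl_dtheta[idx[lo], yidx[lo] - 1] -= f_lo[lo] / P[lo]
        dl_deta = (f_lo - f_up) / P
        g_theta = -(w[:, None] * dl_dtheta).sum(axis=0)
        g_beta = -(D.T @ (w * dl_deta))
        if S is not None:
            nll += 0.5 * beta @ S @ beta
            g_beta += S @ beta
        return nll, np.concatenate([g_theta, g_beta])

    def _natural_hessian(self, xi, D, yidx, w, n_thresh):
        """Hessian of the unpenalized NLL in (theta, beta) coordinates."""
        n, p = D.shape
        theta = xi[:n_thresh]
        beta = xi[n_thresh:]
        eta = D @ beta
        up = yidx < n_thresh
        lo = yidx > 0
        F_up = np.ones(n)
        F_lo = np.zeros(n)
        F_up[up] = expit(theta[yidx[up]] - eta[up])
        F_lo[lo] = expit(theta[yidx[lo] - 1] - eta[lo])
        b = F_up * (1.0 - F_up) * up
        a = F_lo * (1.0 - F_lo) * lo
        bp = b * (1.0 - 2.0 * F_up)
        ap = a * (1.0 - 2.0 * F_lo)
        P = np.clip(F_up - F_lo, _PCLIP, None)
        # per-observation second derivatives of -loglik
        h_vv = w * (b**2 / P**2 - bp / P)                    # d2/dtheta_up^2
        h_uu = w * (ap / P + a**2 / P**2)                    # d2/dtheta_lo^2
        h_uv = -w * (a * b / P**2)                           # cross thresholds
        h_veta = w * (bp / P + b * (a - b) / P**2)
        h_ueta = -w * (ap / P + a * (a - b) / P**2)
        h_ee = w * ((ap - bp) / P + (a - b) ** 2 / P**2)
        m = n_thresh + p
        H = np.zeros((m, m))
        idx = np.arange(n)
        # threshold block
        for c in range(n_thresh):
            sel_up = up & (yidx == c)
            sel_lo = lo & (yidx - 1 == c)
            H[c, c] += h_vv[sel_up].sum() + h_uu[sel_lo].sum()
        for c in range(n_thresh - 1):
            sel = (yidx == c + 1) & up & lo   # upper=c+1, lower=c
            v = h_uv[sel].sum()
            H[c, c + 1] += v
            H[c + 1, c] += v
        # threshold x beta
        for c in range(n_thresh):
            sel_up = up & (yidx == c)
            sel_lo = lo & (yidx - 1 == c)
            row = np.zeros(n)
            row[sel_up] += h_veta[sel_up]
            row[sel_lo] += h_ueta[sel_lo]
            Hcb = D.T @ row
            H[c, n_thresh:] += Hcb
            H[n_thresh:, c] += Hcb
        # beta block
        H[n_thresh:, n_thresh:] = D.T @ (D * h_ee[:, None])
        return H

    def _newton(self, xi0, D, yidx, w, S, n_thresh):
        """Damped Newton on the penalized NLL (concave log-likelihood).

        Steps that would disorder the thresholds or fail to decrease
        the objective are halved; convergence when the objective change
        falls below ``tol`` relative and the gradient is small.
        """
        p = D.shape[1]
        xi = xi0.copy()
        nll, g = self._nll_grad(xi, D, yidx, w, S, n_thresh)
        for _ in range(self.max_iter):
            H = self._natural_hessian(xi, D, yidx, w, n_thresh)
            if S is not None:
                H[n_thresh:, n_thresh:] += S
            ridge = 1e-9 * max(1.0, float(np.trace(H)) / H.shape[0])
            try:
                d = np.linalg.solve(H + ridge * np.eye(H.shape[0]), -g)
            except np.linalg.LinAlgError:
                d = np.linalg.lstsq(H, -g, rcond=None)[0]
            if g @ d > 0:  # not a descent direction; fall back to gradient
                d = -g
            step = 1.0
            accepted = False
            while step > 1e-12:
                xi_new = xi + step * d
                theta_new = xi_new[:n_thresh]
                if np.all(np.diff(theta_new) > 0) or n_thresh == 1:
                    nll_new, g_new = self._nll_grad(
                        xi_new, D, yidx, w, S, n_thresh
                    )
                    if nll_new <= nll + 1e-4 * step * (g @ d):
                        accepted = True
                        break
                step *= 0.5
            if not accepted:
                break
            drop = nll - nll_new
            xi, nll, g = xi_new, nll_new, g_new
            if drop <= self.tol * (1.0 + abs(nll)) and np.max(np.abs(g)) < 1e-5 * (
                1.0 + abs(nll)
            ):
                return xi
        gnorm = float(np.max(np.abs(g)))
        if gnorm > 1e-3 * (1.0 + abs(nll)):
            raise ConvergenceError(
                f"ordinal fit did not converge (|g|={gnorm:.2e}, nll={nll:.4g})"
            )
        return xi

    # ---------------------------------------------------------------- fit

    def fit(self, X: pd.DataFrame, y, weights=None) -> "OrdinalGAM":
        y = np.asarray(y)
        self.categories_ = np.unique(y)
        if self.categories_.size < 2:
            raise ValueError("need at least two observed categories")
        yidx = np.searchsorted(self.categories_, y)
        w = np.ones(len(y)) if weights is None else np.asarray(weights, float)
        if w.shape != (len(y),) or (w < 0).any():
            raise ValueError("weights must be nonnegative, one per observation")
        self.terms_, D = self._build_terms(X)
        n, p = D.shape
        n_thresh = self.categories_.size - 1
        self._n_thresh = n_thresh
        # Per-group (lambda = 1) block-diagonal penalties over spline
        # terms.  Each block carries a double penalty: the curvature
        # penalty plus its null-space projector scaled to the mean
        # curvature eigenvalue, so that a sufficiently large lambda can
        # shrink a pure-noise smooth to zero (linear leftover included).
        group_bases: dict[int, np.ndarray] = {}
        for t in self.terms_:
            if t.kind == "spline" and self.penalized:
                evals, evecs = np.linalg.eigh(t.penalty)
                null = evals < 1e-8 * max(evals.max(), 1e-300)
                block = t.penalty.copy()
                if null.any() and (~null).any():
                    proj = evecs[:, null] @ evecs[:, null].T
                    block = block + float(evals[~null].mean()) * proj
                g = int(self.term_groups.get(t.name, 0))
                group_bases.setdefault(g, np.zeros((p, p)))
                group_bases[g][t.sl, t.sl] = block
        # starting values: thresholds at weighted cumulative logits
        cum = np.cumsum(
            [w[yidx == c].sum() for c in range(n_thresh + 1)]
        ) / w.sum()
        theta0 = np.log(cum[:-1] / (1.0 - cum[:-1]))
        for j in range(1, n_thresh):
            theta0[j] = max(theta0[j], theta0[j - 1] + 1e-3)
        xi0 = np.concatenate([theta0, np.zeros(p)])

        def evaluate(lams: dict, xi_start):
            S = None
            if group_bases:
                S = sum(lams[g] * B for g, B in group_bases.items())
            xi = self._newton(xi_start, D, yidx, w, S, n_thresh)
            H = self._natural_hessian(xi, D, yidx, w, n_thresh)
            S_full = np.zeros_like(H)
            if S is not None:
                S_full[n_thresh:, n_thresh:] = S
            A = H + S_full
            A_reg = A + 1e-8 * np.eye(A.shape[0]) * max(1.0, np.trace(A) / A.shape[0])
            try:
                Finf = np.linalg.solve(A_reg, H)
            except np.linalg.LinAlgError:
                Finf = np.linalg.lstsq(A_reg, H, rcond=None)[0]
            edf = float(np.trace(Finf))
            nll_unpen, _ = self._nll_grad(xi, D, yidx, w, None, n_thresh)
            df_pen = 2.0 if self.criterion == "aic" else float(np.log(n))
            return {
                "aic": 2.0 * nll_unpen + df_pen * edf, "lams": dict(lams),
                "xi": xi, "H": H, "A_reg": A_reg, "Finf": Finf,
                "edf": edf, "nll": nll_unpen,
            }

        grid = sorted(self.lambda_grid, reverse=True)
        if not group_bases:
            best = evaluate({}, xi0)
        else:
            groups = sorted(group_bases)
            lams = {g: grid[0] for g in groups}  # start fully shrunk
            best = None
            xi_start = xi0
            # coordinate sweep: tune one group's lambda at a time by AIC
            for g in groups:
                group_best = None
                for lam in grid:
                    cand = evaluate({**lams, g: lam}, xi_start)
                    xi_start = cand["xi"]
                    if group_best is None or cand["aic"] < group_best["aic"]:
                        group_best = cand
                lams[g] = group_best["lams"][g]
                xi_start = group_best["xi"]
                if best is None or group_best["aic"] < best["aic"]:
                    best = group_best
        self.lambda_ = (
            best["lams"].get(0, 0.0) if len(best["lams"]) == 1
            else dict(best["lams"])
        ) if best["lams"] else 0.0
        self.lambdas_ = dict(best["lams"])
        self.thresholds_ = best["xi"][:n_thresh]
        self.coef_ = best["xi"][n_thresh:]
        self.edf_total_ = best["edf"]
        self.aic_ = best["aic"]
        self.nll_ = best["nll"]
        self.converged_ = True
        try:
            self.cov_ = np.linalg.inv(best["A_reg"])
        except np.linalg.LinAlgError:
            self.cov_ = np.linalg.pinv(best["A_reg"])
        diagF = np.diag(best["Finf"])
        self.edf_ = {}
        for t in self.terms_:
            lo = n_thresh + t.sl.start
            hi = n_thresh + t.sl.stop
            self.edf_[t.name] = float(diagF[lo:hi].sum())
        self._train_eta_ = self._design(X) @ self.coef_
        return self

    # ----------------------------------------------------------- predict

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")

    def latent(self, X: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        return self._design(X) @ self.coef_

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Category probabilities, rows on the simplex."""
        eta = self.latent(X)
        cum = expit(self.thresholds_[None, :] - eta[:, None])
        cum = np.hstack([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))])
        return np.diff(cum, axis=1)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Most probable category for each row."""
        proba = self.predict_proba(X)
        return self.categories_[np.argmax(proba, axis=1)]

    # ------------------------------------------------------------ effects

    def linear_coefficients(self) -> dict[str, float]:
        """Raw-scale slopes of the linear terms (standardization undone)."""
        self._check_fitted()
        out = {}
        for t in self.terms_:
            if t.kind == "linear":
                out[t.name] = float(self.coef_[t.sl.start] / t.scale)
        return out

    def thresholds_natural(self) -> np.ndarray:
        """Thresholds on the raw-predictor scale for all-linear models:
        theta_nat = theta + sum_p beta_raw_p * mean_p."""
        self._check_fitted()
        shift = 0.0
        for t in self.terms_:
            if t.kind == "linear":
                shift += self.coef_[t.sl.start] / t.scale * t.mean
        return self.thresholds_ + shift

    def partial_effect(self, name: str, points=None, n_points: int = 100
                       ) -> PartialEffect:
        """Centered smooth f_p on a grid with a pointwise SE band.

        Points beyond the training range are flagged as extrapolation;
        the smooth is extended at its boundary value and the band is
        widened in proportion to the distance outside the range.
        """
        self._check_fitted()
        term = next((t for t in self.terms_ if t.name == name), None)
        if term is None or term.kind == "categorical":
            raise ValueError(f"no continuous predictor named {name!r}")
        if points is None:
            points = np.linspace(term.xmin, term.xmax, n_points)
        points = np.asarray(points, dtype=float)
        clipped = np.clip(points, term.xmin, term.xmax)
        extrap = (points < term.xmin) | (points > term.xmax)
        if term.kind == "spline":
            B = np.asarray(term.basis.transform(clipped[:, None]), float)
            B = B - term.center
        else:
            B = ((clipped - term.mean) / term.scale)[:, None]
        beta_p = self.coef_[term.sl]
        effect = B @ beta_p
        lo = self._n_thresh + term.sl.start
        hi = self._n_thresh + term.sl.stop
        V = self.cov_[lo:hi, lo:hi]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, V, B), 0.0))
        span = max(term.xmax - term.xmin, 1e-12)
        infl = 1.0 + np.abs(points - clipped) / span
        return PartialEffect(name, points, effect, se * infl, extrap)
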