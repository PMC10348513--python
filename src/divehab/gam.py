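"""Penalized-spline binomial additive models (GAMs).

The habitat models are logistic additive models: presence/pseudo-absence
(1/0) regressed on smooth functions of environmental covariates plus a
categorical year effect.  Each 1-D smooth is a cubic B-spline basis
(default 10 basis functions) with a second-order difference penalty
(P-spline); the spatial term is a tensor-product surface of two marginal
bases with an additive row/column penalty.  Every smooth carries a
sum-to-zero constraint absorbed by an orthonormal reparameterisation, so
the intercept stays identifiable.

Fitting is penalized iteratively reweighted least squares (PIRLS).
Smoothing parameters are chosen by generalized cross-validation (GCV) of
the working penalized least-squares problem, updated by coordinate
descent over a log-spaced grid and alternated with refitting
("performance iteration").  The effective degrees of freedom are the
trace of the influence matrix at convergence, and model comparison uses
the small-sample Akaike criterion

    AICc = -2 l + 2 k + 2 k (k + 1) / (n - k - 1),   k = effective df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SmoothTerm", "TensorTerm", "BinomialGam", "GamFit", "LAMBDA_GRID"]

#: log-spaced smoothing-parameter search grid (coarse but logged; the GCV
#: profile in these models is flat near its optimum)
LAMBDA_GRID = np.logspace(-2.0, 6.0, 9)
RIDGE = 1e-6  # separation safeguard on the unpenalized subspace
ETA_CAP = 30.0


def _bspline_basis(x: np.ndarray, lo: float, hi: float, k: int, degree: int = 3) -> np.ndarray:
    """Clamped, equally-spaced cubic B-spline design matrix with k columns.

    x is clamped to [lo, hi]: outside the training range the basis (and
    hence any prediction) extends flat to the boundary value.
    """
    from scipy.interpolate import BSpline

    if k < degree + 2:
        raise ValueError(f"need at least {degree + 2} basis functions")
    if hi <= lo:
        hi = lo + 1.0  # degenerate covariate: constant column, penalized away
    # uniform knots extended past the range (P-spline convention): the
    # difference penalty's null space is then exactly the linear functions
    inner = np.linspace(lo, hi, k - degree + 1)
    d = inner[1] - inner[0]
    knots = np.r_[lo - d * np.arange(degree, 0, -1), inner, hi + d * np.arange(1, degree + 1)]
    xc = np.clip(np.asarray(x, dtype=float), lo, hi)
    return BSpline.design_matrix(xc, knots, degree).toarray()


def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def _constraint_null(colsum: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of the null space of the sum-to-zero constraint."""
    c = colsum.reshape(-1, 1) / np.linalg.norm(colsum)
    q, _ = np.linalg.qr(c, mode="complete")
    return q[:, 1:]


@dataclass
class SmoothTerm:
    """1-D penalized smooth of one covariate."""

    name: str
    k: int = 10
    degree: int = 3
    lo: float = field(default=np.nan)
    hi: float = field(default=np.nan)
    Z: np.ndarray | None = None
    S: np.ndarray | None = None

    @property
    def covariates(self) -> tuple[str, ...]:
        return (self.name,)

    def prepare(self, df: pd.DataFrame) -> np.ndarray:
        x = df[self.name].to_numpy(dtype=float)
        self.lo, self.hi = float(np.min(x)), float(np.max(x))
        B = _bspline_basis(x, self.lo, self.hi, self.k, self.degree)
        self.Z = _constraint_null(B.sum(axis=0))
        self.S = self.Z.T @ _difference_penalty(self.k) @ self.Z
        return B @ self.Z

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        B = _bspline_basis(df[self.name].to_numpy(dtype=float), self.lo, self.hi, self.k, self.degree)
        return B @ self.Z

    def partial(self, x: np.ndarray, beta: np.ndarray) -> np.ndarray:
        """Centred partial response f(x) on the linear-predictor scale."""
        B = _bspline_basis(np.asarray(x, dtype=float), self.lo, self.hi, self.k, self.degree)
        return B @ self.Z @ beta


@dataclass
class TensorTerm:
    """2-D tensor-product smooth (e.g. a longitude x latitude surface)."""

    names: tuple[str, str]
    k: tuple[int, int] = (5, 5)
    degree: int = 3
    lo: tuple[float, float] = (np.nan, np.nan)
    hi: tuple[float, float] = (np.nan, np.nan)
    Z: np.ndarray | None = None
    S: np.ndarray | None = None

    @property
    def name(self) -> str:
        return ":".join(self.names)

    @property
    def covariates(self) -> tuple[str, ...]:
        return self.names

    def _marginals(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        bs = []
        for d, nm in enumerate(self.names):
            x = df[nm].to_numpy(dtype=float)
            bs.append(_bspline_basis(x, self.lo[d], self.hi[d], self.k[d], self.degree))
        return bs[0], bs[1]

    def prepare(self, df: pd.DataFrame) -> np.ndarray:
        self.lo = tuple(float(df[nm].min()) for nm in self.names)
        self.hi = tuple(float(df[nm].max()) for nm in self.names)
        Bx, By = self._marginals(df)
        B = np.einsum("ni,nj->nij", Bx, By).reshape(len(df), -1)
        kx, ky = self.k
        S_raw = np.kron(_difference_penalty(kx), np.eye(ky)) + np.kron(np.eye(kx), _difference_penalty(ky))
        self.Z = _constraint_null(B.sum(axis=0))
        self.S = self.Z.T @ S_raw @ self.Z
        return B @ self.Z

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        Bx, By = self._marginals(df)
        return np.einsum("ni,nj->nij", Bx, By).reshape(len(df), -1) @ self.Z


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


@dataclass
class GamFit:
    """A fitted binomial additive model."""

    terms: list
    factor: str | None
    factor_levels: list
    beta: np.ndarray
    slices: dict[str, slice]
    lambdas: dict[str, float]
    edf: float
    edf_by_term: dict[str, float]
    deviance: float
    null_deviance: float
    n: int
    converged: bool

    # -- information criteria ------------------------------------------------
    @property
    def loglik(self) -> float:
        return -0.5 * self.deviance

    @property
    def aicc(self) -> float:
        k = self.edf
        n = self.n
        if n - k - 1 <= 0:
            return np.inf
        return self.deviance + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)

    @property
    def deviance_explained(self) -> float:
        return 1.0 - self.deviance / self.null_deviance

    @property
    def adj_r2(self) -> float:
        n, k = self.n, self.edf
        return 1.0 - (self.deviance / max(n - k, 1.0)) / (self.null_deviance / (n - 1.0))

    # -- prediction ----------------------------------------------------------
    def _design(self, df: pd.DataFrame, year=None) -> np.ndarray:
        X = np.zeros((len(df), self.beta.size))
        X[:, 0] = 1.0
        if self.factor is not None:
            sl = self.slices["_factor"]
            if year == "mean" or year is None:
                # pooled prediction: average the factor effect over levels
                X[:, sl] = 1.0 / len(self.factor_levels)
            else:
                levels = list(self.factor_levels)
                if year not in levels:
                    raise KeyError(f"unknown {self.factor} level {year!r}")
                idx = levels.index(year)
                if idx > 0:  # level 0 is the reference
                    X[:, sl.start + idx - 1] = 1.0
        for term in self.terms:
            X[:, self.slices[term.name]] = term.transform(df)
        return X

    def predict(self, df: pd.DataFrame, year=None) -> np.ndarray:
        """Probability of presence; covariates clamped to training range."""
        eta = np.clip(self._design(df, year) @ self.beta, -ETA_CAP, ETA_CAP)
        return 1.0 / (1.0 + np.exp(-eta))

    def partial_response(self, name: str, x: np.ndarray) -> np.ndarray:
        """Centred smooth f(x) on the log-odds scale for a 1-D term."""
        for term in self.terms:
            if term.name == name and isinstance(term, SmoothTerm):
                return term.partial(x, self.beta[self.slices[name]])
        raise KeyError(f"no 1-D smooth named {name!r}")


class BinomialGam:
    """Penalized additive logistic regression with GCV smoothing selection.

    Parameters
    ----------
    terms : list of SmoothTerm / TensorTerm
    factor : optional name of a categorical column added as a fixed effect
        (reference coding, first level dropped).
    """

    def __init__(self, terms, factor: str | None = None,
                 lambda_grid: np.ndarray = LAMBDA_GRID, max_outer: int = 4,
                 max_pirls: int = 100, tol: float = 1e-8):
        self.terms = list(terms)
        self.factor = factor
        self.lambda_grid = np.asarray(lambda_grid, dtype=float)
        self.max_outer = max_outer
        self.max_pirls = max_pirls
        self.tol = tol

    # -- design assembly -----------------------------------------------------
    def _assemble(self, df: pd.DataFrame):
        n = len(df)
        blocks = [np.ones((n, 1))]
        slices: dict[str, slice] = {}
        levels: list = []
        p = 1
        if self.factor is not None:
            levels = sorted(pd.unique(df[self.factor]))
            F = np.zeros((n, max(len(levels) - 1, 0)))
            for i, lv in enumerate(levels[1:]):
                F[:, i] = (df[self.factor] == lv).to_numpy(dtype=float)
            slices["_factor"] = slice(p, p + F.shape[1])
            blocks.append(F)
            p += F.shape[1]
        for term in self.terms:
            Xt = term.prepare(df)
            slices[term.name] = slice(p, p + Xt.shape[1])
            blocks.append(Xt)
            p += Xt.shape[1]
        return np.hstack(blocks), slices, levels

    @staticmethod
    def _penalty(slices, terms, lambdas, p) -> np.ndarray:
        S = np.zeros((p, p))
        for term in terms:
            sl = slices[term.name]
            S[sl, sl] += lambdas[term.name] * term.S
        return S

    # -- core solvers --------------------------------------------------------
    @staticmethod
    def _solve(A, S, b):
        p = A.shape[0]
        H = A + S + RIDGE * np.eye(p)
        beta = np.linalg.solve(H, b)
        return beta, H

    def _pirls(self, X, y, S):
        n, p = X.shape
        beta = np.zeros(p)
        beta[0] = np.log(np.clip(y.mean(), 1e-6, 1 - 1e-6) / np.clip(1 - y.mean(), 1e-6, 1))
        dev = np.inf
        for _ in range(self.max_pirls):
            eta = np.clip(X @ beta, -ETA_CAP, ETA_CAP)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.maximum(mu * (1.0 - mu), 1e-10)
            z = eta + (y - mu) / w
            Xw = X * w[:, None]
            A = X.T @ Xw
            b = Xw.T @ z
            beta_new, _ = self._solve(A, S, b)
            dev_new = _binomial_deviance(y, 1.0 / (1.0 + np.exp(-np.clip(X @ beta_new, -ETA_CAP, ETA_CAP))))
            step = beta_new - beta
            # step-halving if the deviance increased
            for _ in range(8):
                if dev_new <= dev + 1e-10:
                    break
                step *= 0.5
                cand = beta + step
                dev_new = _binomial_deviance(y, 1.0 / (1.0 + np.exp(-np.clip(X @ cand, -ETA_CAP, ETA_CAP))))
                beta_new = cand
            converged = abs(dev - dev_new) < self.tol * (abs(dev_new) + 0.1)
            beta, dev = beta_new, dev_new
            if converged:
                return beta, dev, True
        return beta, dev, False

    def _gcv_lambda_update(self, X, y, beta, lambdas, slices):
        """One round of coordinate descent on GCV of the working model."""
        n, p = X.shape
        eta = np.clip(X @ beta, -ETA_CAP, ETA_CAP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        A = X.T @ Xw
        b = Xw.T @ z
        zwz = float(z @ (w * z))

        def gcv(lam):
            S = self._penalty(slices, self.terms, lam, p)
            bb, H = self._solve(A, S, b)
            edf = float(np.trace(np.linalg.solve(H, A)))
            rss = max(zwz - 2.0 * bb @ b + bb @ A @ bb, 1e-12)
            denom = max(n - edf, 1.0)
            return n * rss / denom ** 2

        lam = dict(lambdas)
        for _ in range(2):
            for term in self.terms:
                scores = []
                for cand in self.lambda_grid:
                    trial = dict(lam)
                    trial[term.name] = cand
                    scores.append(gcv(trial))
                lam[term.name] = float(self.lambda_grid[int(np.argmin(scores))])
        return lam

    # -- public fit ----------------------------------------------------------
    def fit(self, df: pd.DataFrame, y) -> GamFit:
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("response must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("response has a single label; cannot fit")
        X, slices, levels = self._assemble(df)
        n, p = X.shape
        if n <= p:
            raise ValueError(f"need n > total basis size ({n} <= {p})")

        lambdas = {t.name: 1.0 for t in self.terms}
        beta = dev = None
        converged = False
        for _ in range(self.max_outer):
            S = self._penalty(slices, self.terms, lambdas, p)
            beta, dev, converged = self._pirls(X, y, S)
            if not self.terms:
                break
            new_lam = self._gcv_lambda_update(X, y, beta, lambdas, slices)
            if new_lam == lambdas:
                break
            lambdas = new_lam
        S = self._penalty(slices, self.terms, lambdas, p)
        beta, dev, converged = self._pirls(X, y, S)

        eta = np.clip(X @ beta, -ETA_CAP, ETA_CAP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        if np.mean(mu * (1.0 - mu) < 1e-10) > 0.01:
            warnings.warn("possible complete separation; ridge-stabilised fit returned")
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        A = X.T @ (X * w[:, None])
        H = A + S + RIDGE * np.eye(p)
        F = np.linalg.solve(H, A)
        edf_all = np.diag(F)
        edf_by_term = {t.name: float(edf_all[slices[t.name]].sum()) for t in self.terms}
        n_par = 1 + (len(levels) - 1 if self.factor else 0)
        edf_by_term["_parametric"] = float(edf_all[:n_par].sum())

        ybar = y.mean()
        null_dev = _binomial_deviance(y, np.full_like(y, ybar))
        return GamFit(
            terms=self.terms, factor=self.factor, factor_levels=levels,
            beta=beta, slices=slices, lambdas=dict(lambdas),
            edf=float(edf_all.sum()), edf_by_term=edf_by_term,
            deviance=dev, null_deviance=null_dev, n=n, converged=converged,
        )
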