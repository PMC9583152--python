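"""Single-feature proportional-odds ordinal regression for three-level
torsadogenic risk (low < intermediate < high).

Model: with cumulative logits P(Y <= j | x) = sigma(zeta_j - beta * x),
j in {low, intermediate}, a common slope beta and ordered cutpoints
zeta_1 < zeta_2.  The two feature-unit decision thresholds are

    TH1 = zeta_1 / beta   (low  vs intermediate/high boundary)
    TH2 = zeta_2 / beta   (high vs low/intermediate boundary)

i.e. the feature values where the cumulative probability of the lower class
group is exactly one half.  When the feature decreases with risk (beta < 0)
TH1 > TH2 — the orientation of the comparison flips with the sign of beta,
which the cumulative-probability classification rule handles automatically.

Fitting is maximum likelihood with an analytic gradient; cutpoint ordering is
structural via zeta_2 = zeta_1 + exp(delta); the input feature is
standardised internally (so fits are invariant to affine rescaling of x) and
a quasi-Newton optimisation with restarts is polished by Newton steps on the
3-parameter problem.  Each of the 12 features gets its OWN single-feature
model; non-convergence (e.g. complete separation) is reported as a structured
unfit result, not an exception, so report tables can print a dash.
"""
from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .invitro import RISK_LEVELS

__all__ = [
    "OrdinalRiskClassifier",
    "fit_olr",
    "thresholds",
    "class_probabilities",
    "predict_class",
]

_SEPARATION_BETA = 30.0  # |beta| on the standardised scale treated as separation


def _nll_and_grad(theta, x, y_codes):
    """Mean negative log-likelihood and gradient wrt (beta, zeta1, delta)."""
    beta, zeta1, delta = theta
    zeta2 = zeta1 + math.exp(delta)
    eta1 = zeta1 - beta * x
    eta2 = zeta2 - beta * x
    p1 = expit(eta1)
    p2 = expit(eta2)

    n = x.size
    ll = np.empty(n)
    dl_d1 = np.zeros(n)  # d loglik / d eta1
    dl_d2 = np.zeros(n)  # d loglik / d eta2

    m0 = y_codes == 0
    m1 = y_codes == 1
    m2 = y_codes == 2

    tiny = 1e-300
    ll[m0] = np.log(np.maximum(p1[m0], tiny))
    dl_d1[m0] = 1.0 - p1[m0]

    pm = np.maximum(p2[m1] - p1[m1], tiny)
    ll[m1] = np.log(pm)
    dl_d1[m1] = -p1[m1] * (1.0 - p1[m1]) / pm
    dl_d2[m1] = p2[m1] * (1.0 - p2[m1]) / pm

    ll[m2] = np.log(np.maximum(1.0 - p2[m2], tiny))
    dl_d2[m2] = -p2[m2]

    # eta1 = zeta1 - beta x ; eta2 = zeta1 + e^delta - beta x
    g_beta = -(dl_d1 * x + dl_d2 * x).mean()
    g_zeta1 = (dl_d1 + dl_d2).mean()
    g_delta = math.exp(delta) * dl_d2.mean()
    return -ll.mean(), -np.array([g_beta, g_zeta1, g_delta])


def _fd_hessian(theta, x, y):
    """Central finite-difference Hessian of the mean NLL (3x3) from the
    analytic gradient."""
    h = 1e-5
    H = np.empty((3, 3))
    for k in range(3):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        _, gp = _nll_and_grad(tp, x, y)
        _, gm = _nll_and_grad(tm, x, y)
        H[:, k] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


class OrdinalRiskClassifier(BaseEstimator, ClassifierMixin):
    """Proportional-odds logistic classifier on a single feature.

    Parameters
    ----------
    class_order : tuple of str
        Labels in increasing risk order (default low < intermediate < high).
    n_restarts : int
        Extra perturbed optimisation starts (best likelihood wins).
    gtol : float
        Gradient-norm threshold (mean log-likelihood scale) below which the
        fit is flagged converged.
    random_state : int
        Seed for the restart perturbations.

    Fitted attributes
    -----------------
    beta_ : float            slope on the original feature scale
    cutpoints_ : (2,) array  zeta_1 < zeta_2 on the original scale
    th1_, th2_ : float       zeta / beta thresholds (None when not converged)
    converged_ : bool
    diagnostic_ : str        reason when not converged
    fit_log_ : list          negative log-likelihood trace (non-increasing)
    se_beta_ : float         large-sample standard error of beta_
    n_dropped_ : int         rows removed for non-finite feature values
    """

    def __init__(self, class_order: Sequence[str] = RISK_LEVELS,
                 n_restarts: int = 3, gtol: float = 1e-8,
                 max_iter: int = 500, random_state: int = 0):
        self.class_order = tuple(class_order)
        self.n_restarts = n_restarts
        self.gtol = gtol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------
    def _encode(self, y):
        lookup = {c: i for i, c in enumerate(self.class_order)}
        try:
            return np.asarray([lookup[v] for v in y], dtype=int)
        except KeyError as e:
            raise ValueError(f"unknown class label {e.args[0]!r}") from None

    @staticmethod
    def _as_1d(X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("exactly one feature column expected")
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("x must be 1-d (or a single-column 2-d array)")
        return X

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y):
        x = self._as_1d(X)
        y = np.asarray(y)
        if x.shape[0] != y.shape[0]:
            raise ValueError("x and y length mismatch")
        keep = np.isfinite(x)
        self.n_dropped_ = int((~keep).sum())
        x, y = x[keep], y[keep]
        codes = self._encode(y)
        present = np.unique(codes)
        if present.size < 3:
            missing = [self.class_order[i] for i in range(3) if i not in present]
            raise ValueError(f"all three classes required; absent: {', '.join(missing)}")

        mu, sd = float(x.mean()), float(x.std())
        if sd == 0:
            raise ValueError("feature is constant")
        z = (x - mu) / sd

        # starting cutpoints from the empirical cumulative class proportions
        p_low = (codes == 0).mean()
        p_le_int = (codes <= 1).mean()
        z1_0 = float(np.clip(math.log(p_low / (1 - p_low)), -3, 3))
        z2_0 = max(float(np.clip(math.log(p_le_int / (1 - p_le_int)), -3, 3)), z1_0 + 1e-2)
        base = np.array([0.0, z1_0, math.log(z2_0 - z1_0)])

        rng = np.random.default_rng(self.random_state)
        starts = [base] + [base + rng.normal(0.0, 0.5, 3) for _ in range(self.n_restarts)]

        best = None
        best_log = None
        for x0 in starts:
            log: list = []

            def cb(xk, log=log):
                log.append(float(_nll_and_grad(xk, z, codes)[0]))

            sol = minimize(
                _nll_and_grad, x0, args=(z, codes), jac=True, method="L-BFGS-B",
                callback=cb, options={"maxiter": self.max_iter, "ftol": 1e-15,
                                      "gtol": 1e-12},
            )
            if best is None or sol.fun < best.fun:
                best, best_log = sol, [float(_nll_and_grad(x0, z, codes)[0])] + log

        theta = np.asarray(best.x, dtype=float)
        # Newton polish on the 3-parameter problem
        for _ in range(25):
            f, g = _nll_and_grad(theta, z, codes)
            if np.linalg.norm(g) < 0.1 * self.gtol:
                break
            H = _fd_hessian(theta, z, codes)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            new = theta - step
            f_new, _ = _nll_and_grad(new, z, codes)
            if not np.isfinite(f_new) or f_new > f + 1e-12:
                break
            theta = new
            best_log.append(float(f_new))

        f, g = _nll_and_grad(theta, z, codes)
        gnorm = float(np.linalg.norm(g))
        beta_z, zeta1_z, delta = theta
        zeta2_z = zeta1_z + math.exp(delta)

        self.classes_ = np.asarray(self.class_order, dtype=object)
        self.fit_log_ = best_log
        self.x_mean_, self.x_scale_ = mu, sd
        self.beta_ = beta_z / sd
        self.cutpoints_ = np.array([zeta1_z + beta_z * mu / sd,
                                    zeta2_z + beta_z * mu / sd])

        self.converged_ = bool(gnorm < self.gtol and abs(beta_z) < _SEPARATION_BETA)
        if abs(beta_z) >= _SEPARATION_BETA:
            self.diagnostic_ = ("complete separation suspected: |beta| diverges "
                                f"(standardised beta = {beta_z:.2f})")
        elif gnorm >= self.gtol:
            self.diagnostic_ = f"gradient norm {gnorm:.2e} above tolerance {self.gtol:.0e}"
        else:
            self.diagnostic_ = ""

        if self.converged_ and self.beta_ != 0:
            self.th1_ = float(self.cutpoints_[0] / self.beta_)
            self.th2_ = float(self.cutpoints_[1] / self.beta_)
        else:
            self.th1_ = self.th2_ = None

        # large-sample SE of beta from the observed information (total NLL)
        try:
            H = _fd_hessian(theta, z, codes) * z.size
            cov = np.linalg.inv(H)
            self.se_beta_ = float(np.sqrt(max(cov[0, 0], 0.0))) / sd
        except np.linalg.LinAlgError:
            self.se_beta_ = math.nan
        return self

    def _check_converged(self):
        if not getattr(self, "converged_", False):
            raise ValueError(f"model not converged: {getattr(self, 'diagnostic_', 'unfit')}")

    def predict_proba(self, X):
        """(n, 3) class probabilities in class_order; rows sum to 1."""
        self._check_converged()
        x = self._as_1d(X)
        c1 = expit(self.cutpoints_[0] - self.beta_ * x)
        c2 = expit(self.cutpoints_[1] - self.beta_ * x)
        return np.column_stack([c1, c2 - c1, 1.0 - c2])

    def predict(self, X):
        """Cumulative-probability rule: low if P(Y<=low) >= 1/2, high if
        P(Y<=intermediate) < 1/2, else intermediate.  Equivalent to comparing
        x against (TH1, TH2) oriented by the sign of beta."""
        self._check_converged()
        x = self._as_1d(X)
        c1 = expit(self.cutpoints_[0] - self.beta_ * x)
        c2 = expit(self.cutpoints_[1] - self.beta_ * x)
        out = np.full(x.shape, self.class_order[1], dtype=object)
        out[c1 >= 0.5] = self.class_order[0]
        out[c2 < 0.5] = self.class_order[2]
        return out

    def thresholds(self) -> tuple:
        """(TH1, TH2) = cutpoints / beta in feature units."""
        self._check_converged()
        if self.beta_ == 0:
            raise ValueError("uninformative feature: beta = 0")
        return (float(self.cutpoints_[0] / self.beta_),
                float(self.cutpoints_[1] / self.beta_))

    def to_dict(self) -> dict:
        """Flat key-value serialisation (feature-agnostic part)."""
        return {
            "beta": self.beta_,
            "zeta1": float(self.cutpoints_[0]),
            "zeta2": float(self.cutpoints_[1]),
            "th1": self.th1_ if self.th1_ is not None else math.nan,
            "th2": self.th2_ if self.th2_ is not None else math.nan,
            "converged": self.converged_,
            "n_dropped": self.n_dropped_,
        }


def fit_olr(x, y, **kwargs) -> OrdinalRiskClassifier:
    """Fit the proportional-odds model; returns the fitted classifier."""
    return OrdinalRiskClassifier(**kwargs).fit(x, y)


def thresholds(model: OrdinalRiskClassifier) -> tuple:
    """(TH1, TH2); TH1 > TH2 when the feature decreases with risk."""
    return model.thresholds()


def class_probabilities(model: OrdinalRiskClassifier, x) -> tuple:
    """(p_low, p_intermediate, p_high) at feature value(s) x."""
    p = model.predict_proba(np.atleast_1d(np.asarray(x, dtype=float)))
    if np.isscalar(x) or np.asarray(x).ndim == 0:
        return tuple(p[0])
    return p[:, 0], p[:, 1], p[:, 2]


def predict_class(model: OrdinalRiskClassifier, x):
    """Risk label(s) at feature value(s) x."""
    out = model.predict(np.atleast_1d(np.asarray(x, dtype=float)))
    if np.isscalar(x) or np.asarray(x).ndim == 0:
        return out[0]
    return out
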