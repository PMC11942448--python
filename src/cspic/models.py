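"""Genomic prediction models: RRBLUP, BayesB, and RKHS regression.

All three fit the linear model

    y = 1 mu + Z alpha + eps

and differ in the prior on the marker effects alpha:

* RRBLUP — alpha ~ N(0, I sigma_a^2), variances by REML on the equivalent
  random-effect model through an eigendecomposition of the marker Gram
  matrix; equivalent to ridge regression at lambda = sigma_e^2/sigma_a^2
  and to GBLUP with genomic relationship ZZ'.
* BayesB — a mixture of a point mass at zero (probability pi) and a
  scaled-t effect distribution, realized as marker-specific variances with
  a scaled inverse-chi-square prior; fitted by Gibbs sampling.
* RKHS — semi-parametric regression on a Gaussian kernel
  K_ij = exp(-h * D_ij), D_ij the mean squared dosage difference; a
  Bayesian linear model on the kernel eigenbasis, fitted by Gibbs sampling
  (or in closed form when the variance ratio is fixed).

Dosages are centered (not standardized) per marker before fitting; the
centering vector is stored so new individuals are centered identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy import optimize

from .genodata import MISSING, GenotypeMatrix


@dataclass
class MarkerDesign:
    """Centered dosage matrix with the centering vector kept for reuse."""

    Z: np.ndarray  # (n, m) centered
    center: np.ndarray  # per-marker means on the training scale
    individual_ids: list[str]
    marker_ids: list[str]

    @classmethod
    def from_genotypes(
        cls, g: GenotypeMatrix, standardize: bool = False
    ) -> "MarkerDesign":
        Z = g.dosage.astype(float)
        Z[Z == MISSING] = np.nan
        col_mean = np.nanmean(Z, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        inds = np.where(np.isnan(Z))
        Z[inds] = col_mean[inds[1]]
        Z = Z - col_mean
        scale = np.ones(Z.shape[1])
        if standardize:
            sd = Z.std(axis=0)
            scale = np.where(sd > 0, sd, 1.0)
            Z = Z / scale
        d = cls(Z, col_mean, list(g.ids), list(g.loci["id"]))
        d._scale = scale
        return d

    def transform(self, g: GenotypeMatrix) -> np.ndarray:
        """Center new genotypes with the training centering vector."""
        aligned = g.align_loci(self.marker_ids)
        Z = aligned.dosage.astype(float)
        Z[Z == MISSING] = np.nan
        inds = np.where(np.isnan(Z))
        Z[inds] = self.center[inds[1]]
        Z = Z - self.center
        scale = getattr(self, "_scale", None)
        if scale is not None:
            Z = Z / scale
        return Z


@dataclass
class GSModelFit:
    """Fitted model state with a uniform predict contract."""

    kind: str  # rrblup | bayesb | rkhs
    mu: float
    alpha: np.ndarray | None  # marker effects (marker models)
    design: MarkerDesign
    var_params: dict = field(default_factory=dict)
    train_ids: list[str] = field(default_factory=list)
    fitted: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def predict(self, new: GenotypeMatrix | np.ndarray) -> np.ndarray:
        return predict(self, new)


# ---------------------------------------------------------------------- #
# RRBLUP


def fit_rrblup(
    y: np.ndarray, design: MarkerDesign, lam: float | None = None
) -> GSModelFit:
    """Ridge-regression BLUP with REML variance estimation.

    ``lam`` fixes the ridge parameter sigma_e^2 / sigma_a^2 instead of
    estimating it (useful for oracle comparisons).
    """
    y = np.asarray(y, dtype=float)
    Z = design.Z
    n, m = Z.shape
    if n < 3:
        raise ValueError("need at least three training individuals")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes must be finite")
    vy = float(np.var(y))
    if vy < 1e-14:
        warnings.warn("zero phenotypic variance: degenerate RRBLUP fit")
        fit = GSModelFit(
            "rrblup",
            float(y.mean()),
            np.zeros(m),
            design,
            {"sigma_a2": 0.0, "sigma_e2": 0.0, "lambda": np.inf},
            list(design.individual_ids),
        )
        fit.fitted = np.full(n, fit.mu)
        return fit
    K = Z @ Z.T
    # orthonormal basis of the complement of the intercept
    Q, _ = np.linalg.qr(
        np.hstack([np.ones((n, 1)) / np.sqrt(n), np.eye(n)[:, : n - 1]])
    )
    T = Q[:, 1:]
    M = T.T @ K @ T
    M = (M + M.T) / 2.0
    d, V = np.linalg.eigh(M)
    d = np.maximum(d, 0.0)
    yt = V.T @ (T.T @ y)

    if lam is None:

        def neg2ll(log_lam: float) -> float:
            lv = np.exp(np.clip(log_lam, -25, 25))
            w = d + lv
            return float(np.sum(np.log(w)) + (n - 1) * np.log(np.sum(yt**2 / w)))

        res = optimize.minimize_scalar(
            neg2ll, bounds=(-20.0, 20.0), method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(np.exp(res.x))
    sigma_a2 = float(np.sum(yt**2 / (d + lam)) / (n - 1))
    sigma_e2 = lam * sigma_a2
    Hinv = np.linalg.inv(K + lam * np.eye(n))
    ones = np.ones(n)
    mu = float(ones @ Hinv @ y / (ones @ Hinv @ ones))
    r = y - mu
    alpha = Z.T @ (Hinv @ r)
    fit = GSModelFit(
        "rrblup",
        mu,
        alpha,
        design,
        {"sigma_a2": sigma_a2, "sigma_e2": sigma_e2, "lambda": lam},
        list(design.individual_ids),
    )
    fit.fitted = mu + Z @ alpha
    return fit


# ---------------------------------------------------------------------- #
# BayesB


@njit(cache=True)
def _bayesb_gibbs(Z, y, pi, nu, S2, nu_e, n_iter, burn, thin, seed):
    np.random.seed(seed)
    n, m = Z.shape
    c = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        c[j] = s
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    vy = 0.0
    for i in range(n):
        vy += (y[i] - mu) ** 2
    vy /= n
    S2_e = 0.5 * vy if vy > 0 else 1.0
    alpha = np.zeros(m)
    incl = np.zeros(m)
    sigma_j2 = np.full(m, S2 * nu / max(nu - 2.0, 0.5))
    sigma_e2 = S2_e if S2_e > 0 else 1.0
    e = np.empty(n)
    for i in range(n):
        e[i] = y[i] - mu
    sum_alpha = np.zeros(m)
    sum_incl = np.zeros(m)
    sum_mu = 0.0
    sum_se = 0.0
    n_keep = 0
    log_prior_odds = np.log(1.0 - pi) - np.log(max(pi, 1e-300))
    for it in range(n_iter):
        for j in range(m):
            if incl[j] == 1.0:
                aj = alpha[j]
                for i in range(n):
                    e[i] += Z[i, j] * aj
            rhs = 0.0
            for i in range(n):
                rhs += Z[i, j] * e[i]
            v1 = c[j] * sigma_j2[j] + sigma_e2
            log_bf = -0.5 * np.log(v1 / sigma_e2) + 0.5 * rhs * rhs * sigma_j2[
                j
            ] / (sigma_e2 * v1)
            logit = log_prior_odds + log_bf
            if logit > 35.0:
                p1 = 1.0
            elif logit < -35.0:
                p1 = 0.0
            else:
                p1 = 1.0 / (1.0 + np.exp(-logit))
            if np.random.random() < p1:
                incl[j] = 1.0
                prec = c[j] + sigma_e2 / sigma_j2[j]
                mean_post = rhs / prec
                sd_post = np.sqrt(sigma_e2 / prec)
                aj = mean_post + sd_post * np.random.standard_normal()
                alpha[j] = aj
                for i in range(n):
                    e[i] -= Z[i, j] * aj
                sigma_j2[j] = (nu * S2 + aj * aj) / np.random.chisquare(nu + 1.0)
            else:
                incl[j] = 0.0
                alpha[j] = 0.0
                sigma_j2[j] = nu * S2 / np.random.chisquare(nu)
        # intercept
        for i in range(n):
            e[i] += mu
        ebar = 0.0
        for i in range(n):
            ebar += e[i]
        ebar /= n
        mu = ebar + np.sqrt(sigma_e2 / n) * np.random.standard_normal()
        for i in range(n):
            e[i] -= mu
        # residual variance
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sigma_e2 = (sse + nu_e * S2_e) / np.random.chisquare(n + nu_e)
        if it >= burn and (it - burn) % thin == 0:
            n_keep += 1
            sum_mu += mu
            sum_se += sigma_e2
            for j in range(m):
                sum_alpha[j] += alpha[j] * incl[j]
                sum_incl[j] += incl[j]
    return (
        sum_mu / n_keep,
        sum_alpha / n_keep,
        sum_incl / n_keep,
        sum_se / n_keep,
    )


def fit_bayesb(
    y: np.ndarray,
    design: MarkerDesign,
    pi: float = 0.95,
    nu: float = 4.0,
    S2: float | None = None,
    n_iter: int = 10_000,
    burn_in: int = 2_000,
    thin: int = 5,
    seed: int = 0,
    r2: float = 0.5,
) -> GSModelFit:
    """BayesB by Gibbs sampling with per-marker inclusion indicators.

    Marker variances carry a scaled inverse-chi-square(nu, S2) prior
    (marginally scaled-t effects). When ``S2`` is not given it is solved
    so that the prior genetic variance matches a share ``r2`` of the
    phenotypic variance given ``pi``. ``pi = 1`` returns the exact null
    model (all effects zero, mu = mean(y)).
    """
    y = np.asarray(y, dtype=float)
    if not 0 <= pi <= 1:
        raise ValueError("pi must be in [0, 1]")
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    Z = np.ascontiguousarray(design.Z)
    n, m = Z.shape
    if pi == 1.0:
        fit = GSModelFit(
            "bayesb",
            float(y.mean()),
            np.zeros(m),
            design,
            {"pi": pi, "nu": nu, "S2": 0.0},
            list(design.individual_ids),
            extras={"inclusion_prob": np.zeros(m)},
        )
        fit.fitted = np.full(n, fit.mu)
        return fit
    vy = float(np.var(y))
    mean_c = float(np.mean((Z**2).sum(axis=0))) / n  # mean marker variance
    if S2 is None:
        S2 = (
            r2 * vy * max(nu - 2.0, 0.5) / (nu * max(1.0 - pi, 1e-12) * m * max(mean_c, 1e-12))
        )
    mu, alpha, incl, sigma_e2 = _bayesb_gibbs(
        Z, y, float(pi), float(nu), float(S2), 4.0,
        int(n_iter), int(burn_in), int(thin), int(seed) % (2**31 - 1),
    )
    if not (np.all(np.isfinite(alpha)) and np.isfinite(mu)):
        raise RuntimeError("non-finite posterior draws in BayesB chain")
    fit = GSModelFit(
        "bayesb",
        float(mu),
        alpha,
        design,
        {"pi": pi, "nu": nu, "S2": float(S2), "sigma_e2": float(sigma_e2)},
        list(design.individual_ids),
        extras={
            "inclusion_prob": incl,
            "chain": {"n_iter": n_iter, "burn_in": burn_in, "thin": thin, "seed": seed},
        },
    )
    fit.fitted = mu + Z @ alpha
    return fit


# ---------------------------------------------------------------------- #
# RKHS


def _sq_dist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Mean squared dosage difference between rows of A and rows of B."""
    m = A.shape[1]
    aa = (A**2).sum(axis=1)[:, None]
    bb = (B**2).sum(axis=1)[None, :]
    D = (aa + bb - 2.0 * A @ B.T) / m
    return np.maximum(D, 0.0)


def build_kernel(design: MarkerDesign, bandwidth: float) -> np.ndarray:
    """Gaussian kernel K_ij = exp(-h * D_ij) on the mean squared dosage
    difference D; symmetric PSD with unit diagonal."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    D = _sq_dist(design.Z, design.Z)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite marker distances")
    K = np.exp(-bandwidth * D)
    return (K + K.T) / 2.0


def _rkhs_closed_form(y, K, lam):
    n = len(y)
    Hinv = np.linalg.inv(K + lam * np.eye(n))
    ones = np.ones(n)
    mu = float(ones @ Hinv @ y / (ones @ Hinv @ ones))
    coef = Hinv @ (y - mu)
    return mu, coef


def _rkhs_gibbs(y, K, n_iter, burn_in, thin, rng, nu=4.0):
    n = len(y)
    s, V = np.linalg.eigh((K + K.T) / 2.0)
    keep = s > 1e-10 * s.max()
    s, V = s[keep], V[:, keep]
    yt_basis = V.T @ y
    vy = float(np.var(y))
    S2_u = 0.5 * vy
    S2_e = 0.5 * vy
    sigma_u2 = max(S2_u, 1e-8)
    sigma_e2 = max(S2_e, 1e-8)
    mu = float(y.mean())
    w = np.zeros(len(s))
    sums = {"u": np.zeros(n), "mu": 0.0, "su": 0.0, "se": 0.0, "n": 0}
    for it in range(n_iter):
        # w | rest: independent Gaussians on the eigenbasis
        prior_var = sigma_u2 * s
        post_var = sigma_e2 * prior_var / (prior_var + sigma_e2)
        resid_t = yt_basis - (V.T @ np.full(n, mu))
        post_mean = resid_t * prior_var / (prior_var + sigma_e2)
        w = post_mean + np.sqrt(post_var) * rng.standard_normal(len(s))
        u = V @ w
        # mu
        r = y - u
        mu = float(r.mean() + np.sqrt(sigma_e2 / n) * rng.standard_normal())
        # variances: scaled inverse chi-square updates
        quad_u = float(np.sum(w**2 / s))
        sigma_u2 = (quad_u + nu * S2_u) / rng.chisquare(len(s) + nu)
        e = y - mu - u
        sigma_e2 = (float(e @ e) + nu * S2_e) / rng.chisquare(n + nu)
        if it >= burn_in and (it - burn_in) % thin == 0:
            sums["u"] += u
            sums["mu"] += mu
            sums["su"] += sigma_u2
            sums["se"] += sigma_e2
            sums["n"] += 1
    k = sums["n"]
    u_bar = sums["u"] / k
    mu_bar = sums["mu"] / k
    # kernel-space coefficients so new individuals predict via K_cross @ coef
    coef = V @ ((V.T @ u_bar) / s)
    return mu_bar, coef, sums["su"] / k, sums["se"] / k


def fit_rkhs(
    y: np.ndarray,
    design: MarkerDesign,
    bandwidth: float | Sequence[float] = 1.0,
    lam: float | None = None,
    n_iter: int = 6_000,
    burn_in: int = 1_000,
    thin: int = 5,
    seed: int = 0,
) -> GSModelFit:
    """Gaussian-kernel RKHS regression.

    With ``lam`` fixed the posterior mean is computed in closed form,
    u = K (K + lam I)^{-1} (y - mu); otherwise variance components are
    sampled by Gibbs on the kernel eigenbasis. A sequence of bandwidths
    fits one kernel per value and averages predictions (kernel averaging).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    bandwidths = (
        [float(bandwidth)] if np.isscalar(bandwidth) else [float(b) for b in bandwidth]
    )
    kernels = []
    rng = np.random.default_rng(seed)
    for h in bandwidths:
        K = build_kernel(design, h)
        if lam is not None:
            mu_h, coef, su, se = *(_rkhs_closed_form(y, K, lam)), np.nan, np.nan
        else:
            mu_h, coef, su, se = _rkhs_gibbs(y, K, n_iter, burn_in, thin, rng)
        kernels.append(
            {"h": h, "mu": mu_h, "coef": coef, "sigma_u2": su, "sigma_e2": se}
        )
    fitted = np.mean(
        [k["mu"] + build_kernel(design, k["h"]) @ k["coef"] for k in kernels],
        axis=0,
    )
    fit = GSModelFit(
        "rkhs",
        float(np.mean([k["mu"] for k in kernels])),
        None,
        design,
        {"lambda": lam, "bandwidths": bandwidths},
        list(design.individual_ids),
        extras={"kernels": kernels, "chain": {"n_iter": n_iter, "burn_in": burn_in, "thin": thin, "seed": seed}},
    )
    fit.fitted = fitted
    return fit


# ---------------------------------------------------------------------- #
# prediction


def predict(fit: GSModelFit, new: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """GEBVs for new individuals on the fit's marker panel.

    New genotypes are centered with the training centering vector;
    deterministic given the fit.
    """
    if isinstance(new, GenotypeMatrix):
        Z_new = fit.design.transform(new)
    else:
        Z_new = np.asarray(new, dtype=float)
        miss = Z_new < 0  # -1 sentinel: impute at the training mean
        if miss.any():
            Z_new = Z_new.copy()
            Z_new[miss] = fit.design.center[np.where(miss)[1]]
        Z_new = Z_new - fit.design.center
    if fit.kind in ("rrblup", "bayesb"):
        return fit.mu + Z_new @ fit.alpha
    if fit.kind == "rkhs":
        preds = []
        for k in fit.extras["kernels"]:
            Kx = np.exp(-k["h"] * _sq_dist(Z_new, fit.design.Z))
            preds.append(k["mu"] + Kx @ k["coef"])
        return np.mean(preds, axis=0)
    raise ValueError(f"unknown model kind: {fit.kind}")


MODEL_FITTERS = {
    "rrblup": fit_rrblup,
    "bayesb": fit_bayesb,
    "rkhs": fit_rkhs,
}


def fit_model(kind: str, y: np.ndarray, design: MarkerDesign, **kwargs) -> GSModelFit:
    try:
        fitter = MODEL_FITTERS[kind]
    except KeyError:
        raise ValueError(
            f"unknown model {kind!r}; choose from {sorted(MODEL_FITTERS)}"
        ) from None
    return fitter(y, design, **kwargs)
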