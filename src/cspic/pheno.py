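"""Plot-level mixed-model analysis: BLUEs and plot-mean heritability.

The model for a plot observation is

    y_ijk = mu + g_i + e_j + b_k(e_j) + eps_ijk

with genotype g_i fixed, environment e_j and block-within-environment
b_k(e_j) random, and eps residual. BLUEs are the generalized-least-squares
genotype estimates (reported as mu + g_i) under REML variance components.

Plot-mean heritability is H2 = Vg / (Vg + Ve / l) with l the number of
environments. Because the BLUE model declares genotype fixed, Vg comes
from a companion fit of the same model with genotype random — the only
model under which a genotypic variance component exists.

REML is computed by profiling the residual variance out analytically and
optimizing the remaining variance *ratios* (gamma_k = V_k / Ve) on the log
scale with derivative-free Nelder-Mead; the covariance inverse uses the
Woodbury identity, so each evaluation costs only small-matrix algebra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

LOG_GAMMA_BOUND = 15.0


@dataclass
class VarianceComponents:
    Vg: float | None
    Venv: float
    Vblock: float
    Ve: float
    l: int
    n_blocks: int = 1
    converged: bool = True
    loglik: float = np.nan

    def __post_init__(self) -> None:
        for name in ("Venv", "Vblock", "Ve"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.Vg is not None and self.Vg < 0:
            raise ValueError("Vg must be non-negative")
        if self.l < 1:
            raise ValueError("need at least one environment")


def _indicator(labels: pd.Series) -> tuple[np.ndarray, list]:
    levels, inv = np.unique(labels.to_numpy(), return_inverse=True)
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), inv] = 1.0
    return Z, list(levels)


@dataclass
class REMLResult:
    gamma: np.ndarray  # variance ratios V_k / Ve per random term
    sigma2: float  # residual variance Ve
    beta: np.ndarray  # GLS fixed effects
    loglik: float  # REML log-likelihood at the optimum
    converged: bool


def profiled_reml(
    y: np.ndarray,
    X: np.ndarray,
    Z_terms: list[np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 400,
) -> REMLResult:
    """REML for y = X beta + sum_k Z_k u_k + eps, u_k ~ N(0, gamma_k Ve I).

    Deterministic initialization at an equal variance split
    (gamma_k = 1 for every term).
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("more fixed-effect levels than observations")
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    k = len(Z_terms)
    if k == 0:
        beta = np.linalg.solve(XtX, Xty)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / (n - p)
        ll = -0.5 * (
            (n - p) * (1 + np.log(2 * np.pi * sigma2))
            + np.linalg.slogdet(XtX / sigma2)[1]
        )
        return REMLResult(np.zeros(0), sigma2, beta, ll, True)

    Z = np.hstack(Z_terms)
    q = Z.shape[1]
    term_of_col = np.concatenate(
        [np.full(Zk.shape[1], i) for i, Zk in enumerate(Z_terms)]
    )
    ZtZ = Z.T @ Z
    ZtX = Z.T @ X
    Zty = Z.T @ y

    def neg2_restricted_ll(log_gamma: np.ndarray) -> tuple[float, dict]:
        lg = np.clip(log_gamma, -LOG_GAMMA_BOUND, LOG_GAMMA_BOUND)
        d = np.sqrt(np.exp(lg)[term_of_col])
        A = np.eye(q) + (d[:, None] * ZtZ) * d[None, :]
        cA = np.linalg.cholesky(A)
        logdetH = 2.0 * np.log(np.diag(cA)).sum()
        # H^-1 M = M - Z D A^-1 D Z' M for any M, via the precomputed blocks
        DZtX = d[:, None] * ZtX
        DZty = d * Zty
        W_X = np.linalg.solve(A, DZtX)
        W_y = np.linalg.solve(A, DZty)
        XtHiX = XtX - DZtX.T @ W_X
        XtHiy = Xty - DZtX.T @ W_y
        ytHiy = yty - DZty @ W_y
        cXX = np.linalg.cholesky(XtHiX)
        logdetXtHiX = 2.0 * np.log(np.diag(cXX)).sum()
        beta = np.linalg.solve(XtHiX, XtHiy)
        yPy = max(ytHiy - XtHiy @ beta, 1e-300)
        sigma2 = yPy / (n - p)
        crit = (n - p) * np.log(sigma2) + logdetH + logdetXtHiX
        return crit, {"beta": beta, "sigma2": sigma2, "lg": lg}

    def objective(log_gamma: np.ndarray) -> float:
        try:
            return neg2_restricted_ll(log_gamma)[0]
        except np.linalg.LinAlgError:
            return np.inf

    x0 = np.zeros(k)
    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": tol, "maxiter": max_iter * k, "maxfev": max_iter * k},
    )
    crit, aux = neg2_restricted_ll(res.x)
    gamma = np.exp(aux["lg"])
    # a ratio pinned to the lower clip bound is effectively a zero component
    gamma[gamma <= np.exp(-LOG_GAMMA_BOUND) * 1.01] = 0.0
    ll = -0.5 * (crit + (n - p) * (1 + np.log(2 * np.pi)))
    if not res.success:
        warnings.warn("REML did not converge; returning last iterate")
    return REMLResult(gamma, aux["sigma2"], aux["beta"], ll, bool(res.success))


def _prepare(records: pd.DataFrame, trait: str | None) -> pd.DataFrame:
    df = records.copy()
    if trait is not None:
        df = df[df["trait"] == trait]
    elif df["trait"].nunique() > 1:
        raise ValueError("records contain several traits; pass trait=...")
    if df.empty:
        raise ValueError("no records for the requested trait")
    df = df.sort_values(["genotype_id", "env", "block"]).reset_index(drop=True)
    return df


def _random_terms(df: pd.DataFrame) -> tuple[list[np.ndarray], int, int]:
    """Environment and block-within-environment indicator blocks.

    Environments with a single level (or single-block environments) carry
    no estimable variance and are dropped from the random part.
    """
    terms: list[np.ndarray] = []
    envs = df["env"].nunique()
    if envs > 1:
        Ze, _ = _indicator(df["env"])
        terms.append(Ze)
    blk = df["env"].astype(str) + ":" + df["block"].astype(str)
    if blk.nunique() > envs:
        Zb, _ = _indicator(blk)
        terms.append(Zb)
    return terms, envs, df["block"].nunique()


def fit_lmm_blue(
    records: pd.DataFrame, trait: str | None = None
) -> tuple[pd.Series, VarianceComponents]:
    """Genotype BLUEs (mu + g_i) and REML variance components.

    Genotype enters fixed, so the returned components carry ``Vg=None``;
    use :func:`fit_variance_components` for the genotypic variance.
    Accepts unbalanced data (e.g. augmented designs).
    """
    df = _prepare(records, trait)
    X, genotypes = _indicator(df["genotype_id"])
    if X.shape[1] < 2:
        raise ValueError("need at least two genotypes")
    counts = X.sum(axis=0)
    if (counts == 0).any():
        raise ValueError("genotype level without records (singular design)")
    terms, n_env, n_blk = _random_terms(df)
    y = df["value"].to_numpy(dtype=float)
    fit = profiled_reml(y, X, terms)
    gamma = list(fit.gamma)
    venv = gamma.pop(0) * fit.sigma2 if n_env > 1 else 0.0
    vblock = gamma.pop(0) * fit.sigma2 if gamma else 0.0
    vc = VarianceComponents(
        Vg=None,
        Venv=venv,
        Vblock=vblock,
        Ve=fit.sigma2,
        l=n_env,
        n_blocks=n_blk,
        converged=fit.converged,
        loglik=fit.loglik,
    )
    blues = pd.Series(fit.beta, index=genotypes, name=trait or "BLUE")
    return blues, vc


def fit_variance_components(
    records: pd.DataFrame, trait: str | None = None
) -> VarianceComponents:
    """Companion fit with genotype random: the source of Vg for
    heritability (the same plot model, genotype moved to the random part)."""
    df = _prepare(records, trait)
    Zg, _ = _indicator(df["genotype_id"])
    terms, n_env, n_blk = _random_terms(df)
    X = np.ones((len(df), 1))
    y = df["value"].to_numpy(dtype=float)
    fit = profiled_reml(y, X, [Zg] + terms)
    gamma = list(fit.gamma)
    vg = gamma.pop(0) * fit.sigma2
    venv = gamma.pop(0) * fit.sigma2 if n_env > 1 else 0.0
    vblock = gamma.pop(0) * fit.sigma2 if gamma else 0.0
    return VarianceComponents(
        Vg=vg,
        Venv=venv,
        Vblock=vblock,
        Ve=fit.sigma2,
        l=n_env,
        n_blocks=n_blk,
        converged=fit.converged,
        loglik=fit.loglik,
    )


def heritability(
    vc: VarianceComponents, include_design_variance: bool = False
) -> float:
    """Plot-mean heritability H2 = Vg / (Vg + Ve / l).

    With ``include_design_variance=True`` the denominator also carries the
    design variances (Venv / l and Vblock / (l * b)); the plain form is the
    default and the convention reported throughout.
    """
    if vc.Vg is None:
        raise ValueError(
            "Vg unavailable: fit with fit_variance_components (genotype random)"
        )
    denom = vc.Vg + vc.Ve / vc.l
    if include_design_variance:
        denom += vc.Venv / vc.l + vc.Vblock / (vc.l * max(vc.n_blocks, 1))
    if denom == 0:
        raise ValueError("zero total variance: heritability undefined")
    return vc.Vg / denom


def heritability_from_records(
    records: pd.DataFrame, trait: str | None = None
) -> float:
    return heritability(fit_variance_components(records, trait))
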