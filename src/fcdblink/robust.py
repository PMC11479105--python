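"""Robust MM regression: fast-S scale stage plus a high-efficiency M-step.

The estimator is the classic two-stage MM:

1. an S-estimate of regression and scale with 50% breakdown, computed by
   the fast-S subsampling algorithm (Tukey bisquare rho, c0 = 1.5476 for
   consistency at the normal, candidate fits from p-point elemental sets,
   a few IRLS refinement steps each, full refinement of the best few);
2. an M-step: IRLS with the bisquare psi at c1 = 4.685 (95% asymptotic
   efficiency), holding the S scale fixed, started at the S coefficients.

Standard asymptotic covariance: s^2 * E[psi^2] / E[psi']^2 * (X'X)^-1
with a small-sample n/(n-p) correction; confidence intervals are the
symmetric normal form (estimate ± 1.96 robust SE).  Multi-coefficient
tests are quadratic-form Wald tests against chi-square (default) and an
F reference (statistic/df1 on df1, n-p), both reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MMConfig",
    "MMFit",
    "WaldResult",
    "RobustModelError",
    "rho_bisquare",
    "psi_bisquare",
    "psi_prime_bisquare",
    "weight_bisquare",
    "mscale",
    "fit_mm",
    "robust_wald",
    "build_model_frame",
    "anova_table",
    "DESIGN_COLUMNS",
]

#: design columns in model-frame order (intercept added by the fitter)
DESIGN_COLUMNS = [
    "mass_25", "n_ingredients",
    "rawcooked_one", "rawcooked_more",
    "recreated_yes",
    "rawcooked_one:recreated_yes", "rawcooked_more:recreated_yes",
]


class RobustModelError(ValueError):
    pass


@dataclass(frozen=True)
class MMConfig:
    """Tuning for the two stages; defaults follow lmrob-style conventions."""

    n_subsamples: int = 500
    c0: float = 1.5476          # S-stage bisquare: 50% breakdown, Gaussian-consistent
    c1: float = 4.685           # M-step bisquare: 95% efficiency
    breakdown: float = 0.5
    k_refine: int = 2           # IRLS steps per elemental candidate
    n_best: int = 5             # candidates kept for full refinement
    refine_tol: float = 1e-7
    tol: float = 1e-8           # M-step convergence on max coefficient change
    max_iter: int = 200
    seed: int = 20240101        # fast-S subsampling seed (required)

    @property
    def b(self) -> float:
        """Consistency constant: E_N(0,1)[rho] = breakdown * rho(inf)."""
        return self.breakdown * self.c0 ** 2 / 6.0


# --------------------------------------------------------------------------
# bisquare family

def rho_bisquare(u: np.ndarray, c: float) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    t = np.clip(np.abs(u) / c, None, 1.0)
    return (c ** 2 / 6.0) * (1.0 - (1.0 - t ** 2) ** 3)


def psi_bisquare(u: np.ndarray, c: float) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    t = u / c
    out = u * (1.0 - t ** 2) ** 2
    out[np.abs(u) > c] = 0.0
    return out


def psi_prime_bisquare(u: np.ndarray, c: float) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    t = (u / c) ** 2
    out = (1.0 - t) * (1.0 - 5.0 * t)
    out[np.abs(u) > c] = 0.0
    return out


def weight_bisquare(u: np.ndarray, c: float) -> np.ndarray:
    """psi(u)/u, continuous at 0: (1 - (u/c)^2)^2 inside, 0 outside."""
    u = np.asarray(u, dtype=float)
    t = (u / c) ** 2
    out = (1.0 - t) ** 2
    out[t > 1.0] = 0.0
    return out


def mscale(r: np.ndarray, c0: float, b: float,
           tol: float = 1e-10, max_iter: int = 200) -> float:
    """M-estimate of scale: the s solving mean(rho(r/s; c0)) = b."""
    r = np.asarray(r, dtype=float)
    s = np.median(np.abs(r)) / 0.6744897501960817
    if s <= 0:
        nz = np.abs(r[r != 0])
        if nz.size == 0:
            return 0.0
        s = np.median(nz) / 0.6744897501960817
    for _ in range(max_iter):
        m = float(np.mean(rho_bisquare(r / s, c0)))
        if m <= 0:
            return 0.0
        s_new = s * np.sqrt(m / b)
        if abs(s_new - s) <= tol * s:
            return float(s_new)
        s = s_new
    return float(s)


# --------------------------------------------------------------------------
# fitting

def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta


def _s_refine(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
              cfg: MMConfig, steps: int) -> tuple[np.ndarray, float]:
    """IRLS improvement of an S-candidate, rescaling each step."""
    s = 0.0
    for _ in range(steps):
        r = y - X @ beta
        s = mscale(r, cfg.c0, cfg.b)
        if s <= 0:
            return beta, 0.0
        w = weight_bisquare(r / s, cfg.c0)
        if not np.any(w > 0):
            break
        beta_new = _wls(X, y, w)
        if np.max(np.abs(beta_new - beta)) <= cfg.refine_tol * (1 + np.max(np.abs(beta))):
            beta = beta_new
            break
        beta = beta_new
    r = y - X @ beta
    return beta, mscale(r, cfg.c0, cfg.b)


def _fast_s(X: np.ndarray, y: np.ndarray, cfg: MMConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, float]:
    n, p = X.shape
    candidates: list[tuple[float, np.ndarray]] = []
    for _ in range(cfg.n_subsamples):
        idx = rng.choice(n, size=p, replace=False)
        Xi, yi = X[idx], y[idx]
        if np.linalg.matrix_rank(Xi) < p:
            continue
        beta0 = np.linalg.solve(Xi, yi)
        beta, s = _s_refine(X, y, beta0, cfg, cfg.k_refine)
        if s > 0:
            candidates.append((s, beta))
    if not candidates:
        # fall back to the LS fit (e.g. exact-fit data where scale is 0)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta, mscale(y - X @ beta, cfg.c0, cfg.b)
    candidates.sort(key=lambda t: t[0])
    best_s, best_beta = np.inf, candidates[0][1]
    for s0, beta0 in candidates[: cfg.n_best]:
        beta, s = _s_refine(X, y, beta0, cfg, steps=50)
        if 0 < s < best_s:
            best_s, best_beta = s, beta
    if not np.isfinite(best_s):
        best_s, best_beta = candidates[0]
    return best_beta, float(best_s)


@dataclass
class MMFit:
    """MM regression result with robust covariance and diagnostics."""

    params: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    scale: float
    weights: np.ndarray
    converged: bool
    n_iter: int
    cov: pd.DataFrame
    n: int
    p: int
    s_params: pd.Series | None = None

    @property
    def names(self) -> list[str]:
        return list(self.params.index)

    def summary_frame(self) -> pd.DataFrame:
        z = self.params / self.se
        pvals = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({
            "beta": self.params, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "z": z, "p": pvals,
        })


def fit_mm(
    frame: pd.DataFrame,
    response: str,
    design_columns: Sequence[str] | None = None,
    config: MMConfig | None = None,
    add_intercept: bool = True,
) -> MMFit:
    """Fit the MM estimator of ``response ~ design_columns`` on ``frame``."""
    cfg = config or MMConfig()
    cols = list(design_columns) if design_columns is not None else [
        c for c in frame.columns if c != response]
    X = frame[cols].to_numpy(dtype=float)
    y = frame[response].to_numpy(dtype=float)
    names = list(cols)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept"] + names
    n, p = X.shape
    if n <= p:
        raise RobustModelError(f"n={n} must exceed the number of columns p={p}")
    if np.linalg.matrix_rank(X) < p:
        raise RobustModelError("design matrix is rank deficient")

    rng = np.random.default_rng(cfg.seed)
    beta_s, s = _fast_s(X, y, cfg, rng)

    if s <= 0:
        # exact fit: zero residual scale, coefficients are the LS solution
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        zero = pd.Series(np.zeros(p), index=names)
        params = pd.Series(beta, index=names)
        return MMFit(params, zero, params.copy(), params.copy(), 0.0,
                     np.ones(n), True, 0,
                     pd.DataFrame(np.zeros((p, p)), index=names, columns=names),
                     n, p, s_params=params.copy())

    # M-step IRLS at fixed scale
    beta = beta_s.copy()
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        r = y - X @ beta
        w = weight_bisquare(r / s, cfg.c1)
        if not np.any(w > 0):
            break
        beta_new = _wls(X, y, w)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < cfg.tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break

    r = y - X @ beta
    u = r / s
    w = weight_bisquare(u, cfg.c1)
    psi = psi_bisquare(u, cfg.c1)
    psi_p = psi_prime_bisquare(u, cfg.c1)
    num = float(np.mean(psi ** 2)) * n / (n - p)  # small-sample correction
    den = float(np.mean(psi_p)) ** 2
    if den <= 0:
        raise RobustModelError("degenerate psi'; covariance unavailable")
    xtx_inv = np.linalg.inv(X.T @ X)
    cov = s ** 2 * (num / den) * xtx_inv
    se = np.sqrt(np.diag(cov))

    params = pd.Series(beta, index=names)
    se_s = pd.Series(se, index=names)
    return MMFit(
        params=params, se=se_s,
        ci_low=params - 1.96 * se_s, ci_high=params + 1.96 * se_s,
        scale=float(s), weights=w, converged=converged, n_iter=it,
        cov=pd.DataFrame(cov, index=names, columns=names),
        n=n, p=p, s_params=pd.Series(beta_s, index=names),
    )


@dataclass(frozen=True)
class WaldResult:
    statistic: float
    df: int
    p: float
    f_statistic: float
    df2: int
    f_p: float


def robust_wald(fit: MMFit, coefficients: Sequence[str] | Sequence[int]) -> WaldResult:
    """Joint Wald test that the selected coefficients are all zero.

    Chi-square reference by default; the F version (statistic/df1 on
    df1, n-p) is reported alongside.
    """
    if len(coefficients) == 0:
        raise RobustModelError("empty coefficient set")
    if all(isinstance(c, str) for c in coefficients):
        idx = [fit.names.index(c) for c in coefficients]
    else:
        idx = [int(c) for c in coefficients]
    beta = fit.params.to_numpy()[idx]
    V = fit.cov.to_numpy()[np.ix_(idx, idx)]
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        raise RobustModelError("singular sub-covariance for the Wald test") from None
    stat = float(beta @ Vinv @ beta)
    df = len(idx)
    p = float(stats.chi2.sf(stat, df))
    df2 = fit.n - fit.p
    fstat = stat / df
    fp = float(stats.f.sf(fstat, df, df2))
    return WaldResult(stat, df, p, fstat, df2, fp)


def anova_table(fit: MMFit, groups: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Per-variable robust ANOVA: joint Wald on each variable's dummies."""
    rows = []
    for name, cols in groups.items():
        w = robust_wald(fit, list(cols))
        rows.append({"variable": name, "statistic": w.statistic, "df": w.df,
                     "p_chi2": w.p, "f": w.f_statistic, "p_f": w.f_p})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# model frame

def build_model_frame(
    deltas: pd.DataFrame,
    mass: Mapping[str, float],
    n_ingredients: Mapping[str, int],
    discrepancy_counts: Mapping[str, int],
    recreated: Mapping[str, bool],
    response: str,
) -> pd.DataFrame:
    """Assemble the difference-determinants design, one row per dish.

    ``deltas`` holds dish_id plus per-nutrient differences.  The raw/cooked
    factor is none/one/more by the count of uses flagged with a
    discrepancy; ``recreated`` is yes iff any use resolved via the recipe
    strategy.  Reference levels (none, no) yield all-zero dummies.  Mass
    enters as total mass / 25 g.
    """
    rows = []
    for r in deltas.itertuples():
        did = r.dish_id
        for src, label in ((mass, "mass"), (n_ingredients, "n_ingredients"),
                           (discrepancy_counts, "raw/cooked flags"),
                           (recreated, "recipe flags")):
            if did not in src:
                raise RobustModelError(f"dish {did!r}: missing {label}")
        k = discrepancy_counts[did]
        one = 1.0 if k == 1 else 0.0
        more = 1.0 if k > 1 else 0.0
        rec = 1.0 if recreated[did] else 0.0
        rows.append({
            "dish_id": did,
            "delta": getattr(r, response),
            "mass_25": mass[did] / 25.0,
            "n_ingredients": float(n_ingredients[did]),
            "rawcooked_one": one,
            "rawcooked_more": more,
            "recreated_yes": rec,
            "rawcooked_one:recreated_yes": one * rec,
            "rawcooked_more:recreated_yes": more * rec,
        })
    return pd.DataFrame(rows)
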