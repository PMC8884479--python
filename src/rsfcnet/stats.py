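"""Covariate-adjusted group contrasts with permutation-based FDR control.

The group comparison at every level is one general linear model per feature,

    feature ~ intercept + group + age + sex + education,

whose group-coefficient t statistic reduces exactly to the pooled two-sample
t when no covariates are supplied.  Multiple-comparison control combines
Benjamini-Hochberg FDR with a Freedman-Lane permutation scheme: nuisance
covariates are regressed out once, the residual rows are permuted B times,
and the group t is recomputed on each permuted outcome, giving per-feature
permutation p values (and a max-T family-wise p as a stricter companion).
Clinical regressions of symptom scales on altered features are exploratory
(uncorrected, as flagged in the output metadata).

All per-feature OLS quantities are computed via Frisch-Waugh partialling so
that 4005 edge features x thousands of permutations stay vectorised; the
equivalence with an ordinary OLS fit is covered by tests against
statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatsError", "glm_group_contrast", "bh_fdr", "permutation_correction",
    "clinical_regression", "ttest_from_summary", "group_tstats",
]

COVARIATES_DEFAULT = ("age", "sex", "education")


class StatsError(ValueError):
    pass


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    """Nuisance design: intercept plus covariate columns."""
    if covariates is None or covariates.size == 0:
        return np.ones((n, 1))
    Z = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise StatsError(
            "covariate design is rank deficient (collinear covariates)")
    return Z


def _residualize(M: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residual of X against the column space of M (via QR)."""
    Q, _ = np.linalg.qr(M)
    return X - Q @ (Q.T @ X)


def group_tstats(Y: np.ndarray, group: np.ndarray,
                 covariates: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray, int]:
    """Group-coefficient t statistics for many features at once.

    Parameters
    ----------
    Y
        n_subjects x n_features outcome matrix.
    group
        Binary indicator (1 = case group).
    covariates
        Optional n_subjects x C nuisance matrix.

    Returns
    -------
    t, beta, df
        Per-feature t statistic and group coefficient, plus the residual
        degrees of freedom ``n - (C + 2)``.  Identical (by the
        Frisch-Waugh-Lovell theorem) to the group coefficient t from a full
        OLS fit per feature.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    g = np.asarray(group, dtype=float)
    if g.shape[0] != n:
        raise StatsError("group length does not match feature rows")
    if len(np.unique(g)) != 2:
        raise StatsError("group must take exactly two values")
    Z = _design(n, covariates)
    g_res = _residualize(Z, g[:, None])[:, 0]
    gg = g_res @ g_res
    if gg < 1e-12:
        raise StatsError(
            "group indicator is collinear with the covariates; the contrast "
            "is not identifiable")
    Y_res = _residualize(Z, Y)
    beta = (g_res @ Y_res) / gg
    rss = np.einsum("ij,ij->j", Y_res, Y_res) - beta ** 2 * gg
    df = n - Z.shape[1] - 1
    if df <= 0:
        raise StatsError(f"not enough subjects: residual df = {df}")
    sigma2 = np.maximum(rss, 0.0) / df
    zero_var = sigma2 <= 1e-24 * np.maximum(
        1.0, np.einsum("ij,ij->j", Y_res, Y_res))
    if zero_var.any():
        raise StatsError(
            f"zero residual variance for feature indices "
            f"{np.flatnonzero(zero_var).tolist()}; feature is constant "
            "given the design")
    t = beta / np.sqrt(sigma2 / gg)
    return t, beta, df


def glm_group_contrast(y: np.ndarray, group: np.ndarray,
                       covariates: np.ndarray | None = None,
                       labels: tuple[str, str] = ("HC", "PD"),
                       ) -> dict:
    """Covariate-adjusted two-group contrast for a single feature.

    ``group`` is binary with 1 = second label.  Returns the group t, the
    two-sided parametric p from the t distribution, and the effect direction
    (e.g. ``"PD<HC"``).
    """
    g = np.asarray(group, dtype=float)
    for lab in np.unique(g):
        if np.sum(g == lab) < 3:
            raise StatsError("need >= 3 subjects per group")
    t, beta, df = group_tstats(np.asarray(y, float)[:, None], g, covariates)
    t, beta = float(t[0]), float(beta[0])
    p = 2.0 * sps.t.sf(abs(t), df)
    direction = (f"{labels[1]}>{labels[0]}" if beta > 0
                 else f"{labels[1]}<{labels[0]}")
    return {"t": t, "p": p, "df": df, "beta": beta, "direction": direction}


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q values and rejection flags at level q."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise StatsError("p values must lie in [0, 1]")
    reject, qvals, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def permutation_correction(features: pd.DataFrame, group: np.ndarray,
                           covariates: np.ndarray | None = None,
                           B: int = 5000, seed: int | None = None,
                           q: float = 0.05,
                           scheme: str = "freedman-lane",
                           labels: tuple[str, str] = ("HC", "PD"),
                           ) -> pd.DataFrame:
    """Permutation p values (Freedman-Lane) with BH-FDR across features.

    For each feature the observed group t is compared with B recomputations
    under permuted residuals: covariates are regressed out of the outcomes,
    the residual rows are permuted, and the full-model group t is recomputed.
    ``p_perm = (1 + #{|t_b| >= |t_obs|}) / (B + 1)``, so the attainable
    minimum is 1/(B+1).  ``scheme="labels"`` permutes raw group labels
    instead (valid only when covariates are balanced).

    Returns a DataFrame indexed by feature with columns ``t``, ``p_param``,
    ``p_perm``, ``q_param``, ``q_perm``, ``p_fwe_maxt``, ``direction`` and
    ``significant`` (BH on permutation p at level ``q``).  Features that are
    entirely missing (NaN) are dropped with a note in ``attrs``.
    """
    if B < 100:
        raise StatsError("B must be >= 100")
    if seed is None:
        raise StatsError("a seed is mandatory for permutation inference")
    if scheme not in ("freedman-lane", "labels"):
        raise StatsError(f"unknown permutation scheme '{scheme}'")

    keep = features.columns[features.notna().all(axis=0)]
    dropped = [c for c in features.columns if c not in set(keep)]
    Y = features[keep].to_numpy(dtype=float)
    g = np.asarray(group, dtype=float)
    n = Y.shape[0]
    rng = np.random.default_rng(seed)

    t_obs, beta, df = group_tstats(Y, g, covariates)
    p_param = 2.0 * sps.t.sf(np.abs(t_obs), df)

    Z = _design(n, covariates)
    Qz, _ = np.linalg.qr(Z)
    g_res = g - Qz @ (Qz.T @ g)
    gg = g_res @ g_res
    E = Y - Qz @ (Qz.T @ Y)  # reduced-model residuals (Freedman-Lane)
    EE = np.einsum("ij,ij->j", E, E)

    count = np.zeros(Y.shape[1])
    maxt_count = np.zeros(Y.shape[1])
    abs_t = np.abs(t_obs)
    for _ in range(B):
        perm = rng.permutation(n)
        if scheme == "freedman-lane":
            # full-model refit on Y* = permuted reduced-model residuals:
            # partial Z back out of the permuted rows before the group fit
            Ep = E[perm]
            Ep -= Qz @ (Qz.T @ Ep)
            b = (g_res @ Ep) / gg
            rss = np.einsum("ij,ij->j", Ep, Ep) - b ** 2 * gg
            ggp = gg
        else:
            gp = g[perm]
            gp = gp - Qz @ (Qz.T @ gp)
            ggp = gp @ gp
            b = (gp @ E) / ggp
            rss = EE - b ** 2 * ggp
        with np.errstate(divide="ignore", invalid="ignore"):
            t_b = np.abs(b) / np.sqrt(np.maximum(rss, 1e-300) / df / ggp)
        count += t_b >= abs_t
        maxt_count += t_b.max() >= abs_t
    p_perm = (1.0 + count) / (B + 1.0)
    p_fwe = (1.0 + maxt_count) / (B + 1.0)

    q_param, _ = bh_fdr(p_param, q)
    q_perm, reject = bh_fdr(p_perm, q)
    direction = np.where(beta > 0, f"{labels[1]}>{labels[0]}",
                         f"{labels[1]}<{labels[0]}")
    out = pd.DataFrame({
        "t": t_obs, "p_param": p_param, "p_perm": p_perm,
        "q_param": q_param, "q_perm": q_perm, "p_fwe_maxt": p_fwe,
        "direction": direction, "significant": reject,
    }, index=keep)
    out.attrs.update({"B": B, "seed": seed, "q": q, "scheme": scheme,
                      "dropped_features": dropped})
    return out


def clinical_regression(features: pd.DataFrame, scales: pd.DataFrame,
                        covariates: np.ndarray | None = None,
                        min_n: int = 10) -> pd.DataFrame:
    """Exploratory OLS of each clinical scale on each altered feature.

    One model per (feature, scale): ``scale ~ feature + covariates``.  Run on
    case-group subjects only, on features already flagged in the group
    contrast; no multiplicity correction is applied and the output metadata
    says so.  Pairs with fewer than ``min_n`` complete observations are
    flagged ``low_n``.
    """
    rows = []
    Zfull = covariates if covariates is not None else np.empty((len(features), 0))
    for scale in scales.columns:
        s = scales[scale].to_numpy(dtype=float)
        for feat in features.columns:
            x = features[feat].to_numpy(dtype=float)
            ok = np.isfinite(s) & np.isfinite(x)
            if Zfull.size:
                ok &= np.isfinite(Zfull).all(axis=1)
            n_used = int(ok.sum())
            if n_used < 3 + (Zfull.shape[1] if Zfull.size else 0):
                rows.append({"feature": feat, "scale": scale, "slope": np.nan,
                             "t": np.nan, "p": np.nan, "n": n_used,
                             "low_n": True})
                continue
            if np.ptp(s[ok]) == 0:
                raise StatsError(f"scale '{scale}' is constant")
            X = np.column_stack([np.ones(n_used), x[ok]] +
                                ([Zfull[ok]] if Zfull.size else []))
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise StatsError(
                    f"design rank deficient for feature '{feat}' / scale "
                    f"'{scale}'")
            beta, *_ = np.linalg.lstsq(X, s[ok], rcond=None)
            resid = s[ok] - X @ beta
            df = n_used - X.shape[1]
            sigma2 = resid @ resid / df
            XtX_inv = np.linalg.inv(X.T @ X)
            se = np.sqrt(sigma2 * XtX_inv[1, 1])
            t = beta[1] / se if se > 0 else np.nan
            p = 2.0 * sps.t.sf(abs(t), df) if np.isfinite(t) else np.nan
            rows.append({"feature": feat, "scale": scale,
                         "slope": float(beta[1]), "t": float(t),
                         "p": float(p), "n": n_used,
                         "low_n": n_used < min_n})
    out = pd.DataFrame(rows)
    out.attrs["correction"] = "none (exploratory)"
    return out


def ttest_from_summary(mean1: float, sd1: float, n1: int,
                       mean2: float, sd2: float, n2: int,
                       variant: str = "welch") -> dict:
    """Two-sample t test from printed summary statistics.

    ``variant="welch"`` (default, unequal variances) or ``"pooled"``.
    Used to reproduce cohort-description tables from their mean (SD) rows.
    """
    if n1 < 2 or n2 < 2:
        raise StatsError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise StatsError("standard deviations must be positive")
    if variant not in ("welch", "pooled"):
        raise StatsError(f"unknown variant '{variant}'")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=(variant == "pooled"))
    if variant == "welch":
        v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
    return {"t": float(res.statistic), "df": float(df),
            "p": float(res.pvalue)}
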