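"""Negative-binomial differential accessibility versus the sedentary baseline.

Per peak, each exercised condition is tested against sedentary with a
two-group NB model (mean mu, variance mu + alpha*mu^2) on a log link:
counts y_ij ~ NB(s_j * q_g, alpha_i) with known per-sample size factors s_j
and per-peak dispersion alpha_i.  Group abundances q_g are per-group maximum
likelihood estimates (Newton on the profile score, vectorized over peaks);
the Wald statistic uses the observed Fisher information of log q.  Benjamini-
Hochberg FDR is controlled within each contrast and directions are called at
a strict FDR cutoff.

An all-zero group receives the half-count stabilizer q = 0.5 / sum(s_j) so
fold changes stay finite; peaks that are all-zero in both groups are flagged
and reported with log2fc = 0, p = 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import CONDITIONS, SEDENTARY, CountMatrix, condition_label

LN2 = float(np.log(2.0))


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For sample j: the median over zero-free peaks of
    ``counts[i, j] / geometric_mean_i`` where the geometric mean runs across
    samples of peak i.  Requires >= 2 samples and at least one peak with all
    counts positive.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if df.shape[1] < 2:
        raise ValueError("size factors need >= 2 samples")
    mat = df.to_numpy(dtype=float)
    zero_free = (mat > 0).all(axis=1)
    if not zero_free.any():
        raise ValueError(
            "no peak has positive counts in every sample; consider a "
            "pseudo-reference fallback"
        )
    logs = np.log(mat[zero_free])
    log_geo = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo, axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def estimate_dispersion(
    counts: CountMatrix,
    sf: pd.Series,
    *,
    shrinkage: float = 0.5,
) -> pd.Series:
    """Per-peak NB dispersion, method-of-moments shrunk toward a mean trend.

    On size-factor-normalized counts, the raw per-peak estimate pools the
    within-group moments:
    ``alpha_hat = sum_g (n_g-1)(s2_g - mu_g) / sum_g (n_g-1) mu_g^2``
    (clipped at 0).  A trend ``alpha(mu) = a0 + a1/mu`` is fitted across all
    peaks by least squares and each estimate is shrunk toward it with weight
    ``shrinkage``.  Requires >= 2 replicates in at least one group per peak.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    df = counts.counts
    norm = df.to_numpy(dtype=float) / sf.loc[df.columns].to_numpy()[None, :]
    design = counts.design.loc[list(df.columns)]
    groups = [
        list(np.flatnonzero((design["state"] == st).to_numpy() & (design["time"] == tm).to_numpy()))
        for st, tm in design[["state", "time"]].drop_duplicates().itertuples(index=False)
    ]
    if max(len(g) for g in groups) < 2:
        raise ValueError("dispersion estimation needs >= 2 replicates per group")
    num = np.zeros(df.shape[0])
    den = np.zeros(df.shape[0])
    mu_overall = norm.mean(axis=1)
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = norm[:, idx]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        w = len(idx) - 1
        num += w * (s2 - mu)
        den += w * mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / den, 0.0)
    alpha_hat = np.clip(raw, 0.0, None)

    # mean-dispersion trend a0 + a1/mu, fitted on the raw (unclipped) values
    ok = mu_overall > 0
    a0, a1 = 0.0, 0.0
    if ok.sum() >= 2:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mu_overall[ok]])
        coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    with np.errstate(divide="ignore"):
        trend = np.clip(a0 + np.where(ok, a1 / np.where(ok, mu_overall, 1.0), 0.0), 0.0, None)
    final = np.clip((1.0 - shrinkage) * alpha_hat + shrinkage * trend, 0.0, None)
    return pd.Series(final, index=df.index, name="dispersion")


def _group_mle(
    y: np.ndarray, s: np.ndarray, alpha: np.ndarray, max_iter: int = 60, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-peak NB MLE of the group abundance q (mean mu_j = s_j q).

    Returns (q, fisher_information_of_log_q, all_zero_mask).  All-zero groups
    get the half-count stabilizer q = 0.5 / sum(s).
    """
    total = y.sum(axis=1)
    all_zero = total == 0
    q = y.sum(axis=1) / s.sum()
    q = np.where(all_zero, 0.5 / s.sum(), q)
    a = alpha[:, None]
    for _ in range(max_iter):
        mu = s[None, :] * q[:, None]
        denom = 1.0 + a * mu
        f = ((y - mu) / denom).sum(axis=1)
        fp = -(s[None, :] * (1.0 + a * y) / denom**2).sum(axis=1)
        step = np.where(all_zero, 0.0, f / fp)
        q_new = q - step
        q_new = np.where(q_new <= 0, q / 10.0, q_new)
        moved = np.abs(q_new - q) > tol * np.maximum(q, 1e-300)
        q = q_new
        if not moved.any():
            break
    mu = s[None, :] * q[:, None]
    info = (mu / (1.0 + a * mu)).sum(axis=1)
    return q, info, all_zero


def nb_wald_test(
    counts: CountMatrix,
    sf: pd.Series,
    dispersions: pd.Series,
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Wald test of one exercised condition against sedentary, per peak.

    Returns a DataFrame (indexed by peak_id) with the contrast label,
    ``log2fc`` = log2(q_cond / q_sed), its standard error, the two-sided
    normal p-value and an ``all_zero`` flag for peaks empty in both groups
    (reported as log2fc 0, p 1).
    """
    state, time = contrast
    cond_samples = counts.samples_of(state, time)
    sed_samples = counts.samples_of(SEDENTARY)
    if len(cond_samples) < 2 or len(sed_samples) < 2:
        raise ValueError("both groups of a contrast need >= 2 samples")
    df = counts.counts
    alpha = dispersions.loc[df.index].to_numpy(dtype=float)
    y1 = df[cond_samples].to_numpy(dtype=float)
    y0 = df[sed_samples].to_numpy(dtype=float)
    s1 = sf.loc[cond_samples].to_numpy(dtype=float)
    s0 = sf.loc[sed_samples].to_numpy(dtype=float)

    q1, i1, z1 = _group_mle(y1, s1, alpha)
    q0, i0, z0 = _group_mle(y0, s0, alpha)
    both_zero = z1 & z0

    log2fc = np.log2(q1 / q0)
    se = np.sqrt(1.0 / i1 + 1.0 / i0) / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    log2fc = np.where(both_zero, 0.0, log2fc)
    p = np.where(both_zero, 1.0, p)
    return pd.DataFrame(
        {
            "contrast": f"{condition_label(state, time)}_vs_{SEDENTARY}",
            "log2fc": log2fc,
            "se": se,
            "p_value": np.clip(p, 0.0, 1.0),
            "all_zero": both_zero,
        },
        index=df.index.rename("peak_id"),
    )


def bh_adjust(p_values: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_directions(results: pd.DataFrame, fdr_cutoff: float = 0.05) -> pd.DataFrame:
    """Fill ``fdr`` (if absent) and ``direction`` in a Wald-test table.

    direction = gain if fdr < cutoff and log2fc > 0, loss if fdr < cutoff and
    log2fc < 0, else none (strict inequality at the cutoff).
    """
    out = results.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    sig = out["fdr"].to_numpy() < fdr_cutoff
    lfc = out["log2fc"].to_numpy()
    direction = np.where(sig & (lfc > 0), "gain", np.where(sig & (lfc < 0), "loss", "none"))
    out["direction"] = direction
    return out


def run_all_contrasts(
    counts: CountMatrix,
    *,
    fdr_cutoff: float = 0.05,
    shrinkage: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """Full differential run: normalization, dispersion, all six contrasts.

    FDR is controlled within each contrast separately.  Returns a mapping
    condition label -> result table with directions called.
    """
    sf = size_factors(counts)
    disp = estimate_dispersion(counts, sf, shrinkage=shrinkage)
    out: dict[str, pd.DataFrame] = {}
    for state, time in CONDITIONS:
        res = nb_wald_test(counts, sf, disp, (state, time))
        out[condition_label(state, time)] = call_directions(res, fdr_cutoff)
    return out
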