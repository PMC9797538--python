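"""Feature ranking by one-way ANOVA F with eta-squared effect sizes.

The ranking is descriptive, mirroring filter-style feature selection: each
feature is scored by the one-way fixed-effects ANOVA F statistic across
the phase classes, effect size is eta² = SS_between / SS_total with a 95 %
bias-corrected bootstrap confidence interval, and features are sorted by
descending F with a deterministic lexicographic tie-break on the name.
No multiple-testing correction is applied — the F values order features,
they are not used for inference.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def _group_sums(values: np.ndarray, group_idx: np.ndarray, k: int):
    """Per-group count, sum and sum of squares along axis 0.

    ``values`` is (n,) or (n, p); returns arrays with leading dimension k.
    """
    v = values if values.ndim == 2 else values[:, None]
    counts = np.bincount(group_idx, minlength=k).astype(float)
    sums = np.zeros((k, v.shape[1]))
    sqsums = np.zeros((k, v.shape[1]))
    np.add.at(sums, group_idx, v)
    np.add.at(sqsums, group_idx, v ** 2)
    return counts, sums, sqsums


def _anova_core(values: np.ndarray, group_idx: np.ndarray, k: int):
    """Vectorized SS decomposition → (F, p, eta_sq), each shaped like features."""
    n = values.shape[0]
    counts, sums, sqsums = _group_sums(values, group_idx, k)
    grand_sum = sums.sum(axis=0)
    ss_total = sqsums.sum(axis=0) - grand_sum ** 2 / n
    ss_between = (sums ** 2 / counts[:, None]).sum(axis=0) - grand_sum ** 2 / n
    ss_within = ss_total - ss_between
    df_b, df_w = k - 1, n - k

    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
        eta = np.where(ss_total > 0, ss_between / ss_total, 0.0)
    # Degenerate cases: no variation at all → F = 0 (p = 1); zero within-class
    # variance with unequal means → F = +inf, p = 0.
    f = np.where(ss_total <= 0, 0.0, f)
    f = np.where((ss_within <= 0) & (ss_between > 0), np.inf, f)
    f = np.where((ss_within > 0) & (ss_between <= 0), 0.0, f)
    p = np.where(np.isinf(f), 0.0, stats.f.sf(np.where(np.isinf(f), 1.0, f),
                                              df_b, df_w))
    p = np.where(f == 0.0, 1.0, p)
    eta = np.clip(eta, 0.0, 1.0)
    return f, p, eta


def _check_groups(labels: np.ndarray):
    classes, group_idx = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("ANOVA requires at least 2 classes")
    counts = np.bincount(group_idx)
    small = classes[counts < 2]
    if small.size:
        raise ValueError(f"class(es) {list(small)} have fewer than 2 samples")
    return classes, group_idx


def anova_f(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """One-way fixed-effects ANOVA: F = (SS_b/df_b)/(SS_w/df_w), p from F."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes, group_idx = _check_groups(labels)
    f, p, _ = _anova_core(values[:, None], group_idx, classes.size)
    return float(f[0]), float(p[0])


def eta_squared(values: np.ndarray, labels: np.ndarray,
                n_boot: int = 2000, seed: int = 0,
                ci_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """eta² = SS_between / SS_total with a bias-corrected bootstrap CI."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes, group_idx = _check_groups(labels)
    _, _, eta = _anova_core(values[:, None], group_idx, classes.size)
    est = float(eta[0])
    if n_boot <= 0:
        return est, (float("nan"), float("nan"))
    lo, hi = _bootstrap_eta_ci(values[:, None], group_idx, classes.size,
                               np.array([est]), n_boot, seed, ci_level)
    return est, (float(lo[0]), float(hi[0]))


def _bootstrap_eta_ci(values: np.ndarray, group_idx: np.ndarray, k: int,
                      estimates: np.ndarray, n_boot: int, seed: int,
                      ci_level: float):
    """Bias-corrected percentile bootstrap over samples (resampled with labels)."""
    rng = np.random.default_rng(seed)
    n, p = values.shape
    boots = np.empty((n_boot, p))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        gi = group_idx[idx]
        if np.unique(gi).size < k or np.bincount(gi, minlength=k).min() < 2:
            boots[b] = estimates  # degenerate resample: keep the point estimate
            continue
        _, _, eta = _anova_core(values[idx], gi, k)
        boots[b] = eta
    alpha = 1.0 - ci_level
    prop = np.clip((boots < estimates[None, :]).mean(axis=0), 1e-6, 1 - 1e-6)
    z0 = stats.norm.ppf(prop)
    z_lo, z_hi = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
    q_lo = stats.norm.cdf(2 * z0 + z_lo)
    q_hi = stats.norm.cdf(2 * z0 + z_hi)
    lo = np.array([np.quantile(boots[:, j], q_lo[j]) for j in range(p)])
    hi = np.array([np.quantile(boots[:, j], q_hi[j]) for j in range(p)])
    return lo, hi


def rank_features(table: pd.DataFrame, label_col: str = "label",
                  n_boot: int = 0, seed: int = 0) -> pd.DataFrame:
    """Rank every feature column of a (samples × features) table.

    ``table`` must carry the class in ``label_col``; non-feature bookkeeping
    columns (``subject_id``) are ignored.  Returns a DataFrame indexed by
    feature with columns F, p, eta_sq, ci_lo, ci_hi, rank, sorted by
    descending F (ties broken by feature name).  Constant features get
    F = 0 with a warning.  Set ``n_boot`` > 0 to bootstrap eta² CIs.
    """
    feat_cols = [c for c in table.columns if c not in (label_col, "subject_id")]
    if not feat_cols:
        raise ValueError("table has no feature columns")
    labels = table[label_col].to_numpy()
    classes, group_idx = _check_groups(labels)
    values = table[feat_cols].to_numpy(dtype=float)

    constant = values.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) assigned F = 0: "
            f"{[feat_cols[i] for i in np.flatnonzero(constant)][:5]}",
            stacklevel=2,
        )
    f, p, eta = _anova_core(values, group_idx, classes.size)

    if n_boot > 0:
        ci_lo, ci_hi = _bootstrap_eta_ci(values, group_idx, classes.size, eta,
                                         n_boot, seed, 0.95)
    else:
        ci_lo = np.full_like(eta, np.nan)
        ci_hi = np.full_like(eta, np.nan)

    out = pd.DataFrame(
        {"F": f, "p": p, "eta_sq": eta, "ci_lo": ci_lo, "ci_hi": ci_hi},
        index=pd.Index(feat_cols, name="feature"),
    )
    out = out.sort_values(["F", "feature"], ascending=[False, True])
    out["rank"] = np.arange(1, len(out) + 1)
    return out
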