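"""Negative-binomial two-group testing for window/gene count matrices.

The model: counts for window *w* in sample *i* of group *g* are
NB(mean mu_wg * N_i, dispersion phi_w), with N_i the effective library size.
Dispersion is estimated by conditional maximum likelihood on library-size
equalized pseudo-counts, first as a single common value, then per window with
empirical-Bayes shrinkage toward the common value (weighted likelihood with a
prior weight expressed in windows' worth of shared information).  Differences
between two groups are assessed with the conditional exact test on group
sums, and p-values are Benjamini-Hochberg adjusted.

Numerics: the conditional log-likelihood is evaluated on a fixed log-spaced
dispersion grid over [1e-6, 10]; maximizers are refined by quadratic
interpolation in log-dispersion.  Pseudo-counts are kept continuous (the
gamma-function form of the NB likelihood is valid at non-integer counts);
only the exact-test group sums are rounded to integers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .windows import CountMatrix

__all__ = [
    "norm_factors",
    "tmm_norm_factors",
    "pseudo_counts",
    "estimate_common_dispersion",
    "estimate_tagwise_dispersion",
    "nb_exact_pvalue",
    "bh_adjust",
    "run_differential",
]

PHI_MIN = 1e-6
PHI_MAX = 10.0
_N_GRID = 121
_LOG_PHI_GRID = np.linspace(np.log(PHI_MIN), np.log(PHI_MAX), _N_GRID)
_PHI_GRID = np.exp(_LOG_PHI_GRID)


# ---------------------------------------------------------------------------
# normalization


def tmm_norm_factors(
    counts: np.ndarray,
    lib_sizes: np.ndarray,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed mean of M-values normalization factors.

    The reference sample is the one whose upper-quartile relative abundance is
    closest to the mean upper quartile.  Per sample, log ratios (M) against
    the reference are trimmed (30% by M, 5% by absolute abundance A) and
    averaged with inverse-variance (delta-method) weights.  Factors are scaled
    to geometric mean 1.
    """
    counts = np.asarray(counts, dtype=float)
    lib = np.asarray(lib_sizes, dtype=float)
    if (counts.sum(axis=0) == 0).any():
        bad = int(np.where(counts.sum(axis=0) == 0)[0][0])
        raise ValueError(f"sample at column {bad} has all-zero counts")
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    p = counts / lib[None, :]
    uq = np.array([np.quantile(p[:, j][counts[:, j] > 0], 0.75) for j in range(p.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log2f = np.zeros(p.shape[1])
    for j in range(p.shape[1]):
        if j == ref:
            continue
        ok = (counts[:, j] > 0) & (counts[:, ref] > 0)
        if ok.sum() == 0:
            continue
        ps, pr = p[ok, j], p[ok, ref]
        M = np.log2(ps / pr)
        A = 0.5 * np.log2(ps * pr)
        var = (lib[j] - counts[ok, j]) / (lib[j] * counts[ok, j]) + (
            lib[ref] - counts[ok, ref]
        ) / (lib[ref] * counts[ok, ref])
        lo_m, hi_m = np.quantile(M, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(A, [trim_a, 1 - trim_a])
        keep = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a) & (var > 0)
        if keep.sum() == 0:
            continue
        w = 1.0 / var[keep]
        log2f[j] = np.sum(w * M[keep]) / np.sum(w)
    f = 2.0 ** log2f
    return f / np.exp(np.mean(np.log(f)))


def norm_factors(cm: CountMatrix, method: str = "libsize") -> np.ndarray:
    """Per-sample scaling factors: ``libsize`` (all 1) or ``tmm``."""
    if (cm.lib_sizes <= 0).any():
        bad = [s for s, n in zip(cm.samples, cm.lib_sizes) if n <= 0]
        raise ValueError(f"zero library size for sample(s) {bad}")
    if method == "libsize":
        return np.ones(len(cm.samples))
    if method == "tmm":
        return tmm_norm_factors(cm.counts, cm.lib_sizes)
    raise ValueError(f"unknown normalization method {method!r}")


def pseudo_counts(counts: np.ndarray, eff_lib_sizes: np.ndarray) -> tuple:
    """Scale counts to a common (geometric-mean) library size.

    Returns (pseudo, common_size).  Pseudo-counts are continuous.
    """
    eff = np.asarray(eff_lib_sizes, dtype=float)
    if (eff <= 0).any():
        raise ValueError("effective library sizes must be positive")
    common = float(np.exp(np.mean(np.log(eff))))
    return np.asarray(counts, dtype=float) * (common / eff)[None, :], common


# ---------------------------------------------------------------------------
# dispersion estimation (conditional likelihood on equalized counts)


def _group_indices(groups) -> list:
    labels = pd.unique(np.asarray(groups))
    return [np.where(np.asarray(groups) == g)[0] for g in labels]


def _cond_ll_grid(pseudo: np.ndarray, group_idx: list, phis: np.ndarray) -> np.ndarray:
    """Per-window NB conditional log-likelihood on a dispersion grid.

    Returns an (n_windows, len(phis)) matrix; terms constant in phi are
    dropped.  Groups with fewer than two samples carry no information about
    dispersion and are ignored.
    """
    W = pseudo.shape[0]
    L = np.zeros((W, len(phis)))
    for idx in group_idx:
        n = len(idx)
        if n < 2:
            continue
        y = pseudo[:, idx]
        z = y.sum(axis=1)
        for k, phi in enumerate(phis):
            r = 1.0 / phi
            L[:, k] += (
                gammaln(y + r).sum(axis=1)
                - n * gammaln(r)
                + gammaln(n * r)
                - gammaln(z + n * r)
            )
    return L


def _refine_argmax(F: np.ndarray) -> np.ndarray:
    """Quadratic-interpolated maximizer of rows of F over the phi grid."""
    F = np.atleast_2d(F)
    i = np.argmax(F, axis=1)
    h = _LOG_PHI_GRID[1] - _LOG_PHI_GRID[0]
    interior = (i > 0) & (i < _N_GRID - 1)
    delta = np.zeros(len(i))
    ii = np.where(interior)[0]
    if len(ii):
        y0 = F[ii, i[ii] - 1]
        y1 = F[ii, i[ii]]
        y2 = F[ii, i[ii] + 1]
        denom = y0 - 2 * y1 + y2
        good = denom < 0
        d = np.zeros(len(ii))
        d[good] = 0.5 * (y0[good] - y2[good]) / denom[good]
        delta[ii] = np.clip(d, -0.5, 0.5)
    phi = np.exp(_LOG_PHI_GRID[i] + delta * h)
    return np.clip(phi, PHI_MIN, PHI_MAX)


def _check_replication(group_idx):
    if not any(len(idx) >= 2 for idx in group_idx):
        raise ValueError(
            "no group has replicates; dispersion cannot be estimated -- "
            "run with a fixed dispersion instead"
        )


def estimate_common_dispersion(cm: CountMatrix, groups) -> float:
    """Single dispersion maximizing the summed conditional log-likelihood."""
    group_idx = _group_indices(groups)
    _check_replication(group_idx)
    pseudo, _ = pseudo_counts(cm.counts, cm.effective_lib_sizes)
    L = _cond_ll_grid(pseudo, group_idx, _PHI_GRID)
    S = L.sum(axis=0)
    return float(_refine_argmax(S[None, :])[0])


def estimate_tagwise_dispersion(
    cm: CountMatrix, groups, phi_common: float = None, prior_df: float = 10.0
) -> np.ndarray:
    """Per-window dispersions shrunk toward the common value.

    Maximizes, per window, its own conditional log-likelihood plus
    ``prior_df`` times the average per-window log-likelihood across all
    windows (the common-likelihood contribution).  Large ``prior_df``
    collapses every window onto the common estimate.
    """
    if prior_df <= 0:
        raise ValueError("prior_df must be positive")
    group_idx = _group_indices(groups)
    _check_replication(group_idx)
    pseudo, _ = pseudo_counts(cm.counts, cm.effective_lib_sizes)
    L = _cond_ll_grid(pseudo, group_idx, _PHI_GRID)
    S = L.sum(axis=0)
    F = L + (prior_df / L.shape[0]) * S[None, :]
    return _refine_argmax(F)


# ---------------------------------------------------------------------------
# exact test


def nb_exact_pvalue(
    sum_a: int,
    sum_b: int,
    n_a: int,
    n_b: int,
    phi: float,
    rule: str = "doubling",
) -> float:
    """Two-sided conditional exact test on equalized group sums.

    With equalized library sizes the group sums are NB with sizes
    ``n_a/phi`` and ``n_b/phi`` and a shared mean per sample; conditional on
    the total, the probability of each split is free of the mean.  ``phi=0``
    reduces to the binomial split.  ``rule`` picks the two-sided construction:
    ``doubling`` (twice the smaller tail, capped at 1) or ``smallp`` (sum of
    outcomes no more probable than the observed one).
    """
    if sum_a < 0 or sum_b < 0:
        raise ValueError("group sums must be non-negative")
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    sum_a, sum_b = int(round(sum_a)), int(round(sum_b))
    t = sum_a + sum_b
    if t == 0:
        return 1.0
    a = np.arange(t + 1)
    if phi == 0:
        # Poisson counts -> binomial conditional split
        from scipy.stats import binom

        lp = binom.logpmf(a, t, n_a / (n_a + n_b))
    else:
        r_a, r_b = n_a / phi, n_b / phi
        lp = (
            gammaln(a + r_a)
            - gammaln(a + 1)
            + gammaln(t - a + r_b)
            - gammaln(t - a + 1)
        )
        lp -= logsumexp(lp)
    pmf = np.exp(lp)
    if rule == "doubling":
        lower = pmf[: sum_a + 1].sum()
        upper = pmf[sum_a:].sum()
        return float(min(1.0, 2.0 * min(lower, upper)))
    if rule == "smallp":
        return float(min(1.0, pmf[pmf <= pmf[sum_a] * (1 + 1e-12)].sum()))
    raise ValueError(f"unknown two-sided rule {rule!r}")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# orchestration


def run_differential(
    cm: CountMatrix,
    groups,
    pair: tuple,
    config: PipelineConfig = None,
    phi: float | np.ndarray | None = None,
) -> pd.DataFrame:
    """Two-group differential test for every window of ``cm``.

    Parameters
    ----------
    groups : per-sample labels aligned with ``cm.samples``.
    pair : (label_A, label_B) with B the higher-dose group; log2FC and the
        hyper/hypo direction refer to B relative to A.
    phi : optional fixed dispersion (scalar or per-window) bypassing
        estimation, e.g. for designs without replication.

    Returns a DataFrame with chrom/start/end, log2FC, p, q, direction, phi.
    """
    config = config or PipelineConfig()
    groups = np.asarray(groups)
    label_a, label_b = pair
    sel = np.isin(groups, [label_a, label_b])
    sub = cm.subset_samples([s for s, ok in zip(cm.samples, sel) if ok])
    sub_groups = groups[sel]
    idx_a = np.where(sub_groups == label_a)[0]
    idx_b = np.where(sub_groups == label_b)[0]
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError(f"empty group in pair {pair}")

    sub.norm_factors = norm_factors(sub, config.normalization)
    pseudo, _ = pseudo_counts(sub.counts, sub.effective_lib_sizes)

    if phi is None:
        phi_common = estimate_common_dispersion(sub, sub_groups)
        if config.tagwise:
            phi_w = estimate_tagwise_dispersion(
                sub, sub_groups, phi_common, prior_df=config.prior_df
            )
        else:
            phi_w = np.full(sub.n_windows, phi_common)
    else:
        phi_w = np.broadcast_to(np.asarray(phi, dtype=float), (sub.n_windows,)).copy()

    sums_a = pseudo[:, idx_a].sum(axis=1)
    sums_b = pseudo[:, idx_b].sum(axis=1)
    n_a, n_b = len(idx_a), len(idx_b)
    p = np.empty(sub.n_windows)
    for w in range(sub.n_windows):
        p[w] = nb_exact_pvalue(
            sums_a[w], sums_b[w], n_a, n_b, float(phi_w[w]), rule=config.two_sided_rule
        )
    q = bh_adjust(p)

    prior = config.fc_prior
    log2fc = np.log2((sums_b / n_b + prior) / (sums_a / n_a + prior))
    out = sub.windows.copy()
    out["log2FC"] = log2fc
    out["p"] = p
    out["q"] = q
    out["direction"] = np.where(log2fc > 0, "hyper", "hypo")
    out["phi"] = phi_w
    return out
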