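"""Concordance and differential-expression statistics for mask validation.

Covers the quantities used to judge whether residual host tissue skews a
human expression profile: sample-pair Pearson correlation matrices with
per-group summary statistics, MvA records (per-cluster log ratio M against
average log intensity A) with a 2-fold outlier count, mean squared distance
(MSD) between paired group mean profiles, per-group signal histograms, and
an empirical-Bayes moderated t-test with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix


@dataclass
class ConcordanceReport:
    """Pearson correlation matrix plus per-group-pair summary statistics."""

    correlations: pd.DataFrame  # sample x sample
    summaries: pd.DataFrame  # pair, n, min, max, mean, sd, se
    groups: Mapping[str, str] = field(default_factory=dict)


@dataclass
class MvAResult:
    """Per-cluster M (log2 difference) and A (average log2 signal)."""

    records: pd.DataFrame  # index cluster, columns M, A
    outlier_count: int  # |M| >= fold_threshold
    fold_threshold: float


@dataclass
class DEResult:
    """Moderated-t differential expression with BH-adjusted p values."""

    table: pd.DataFrame  # index cluster, columns logFC, t, p, adj_p
    prior_df: float  # d0
    prior_var: float  # s0^2
    residual_df: int


def _group_samples(samples: Sequence[str],
                   groups: Mapping[str, str]) -> dict[str, list[str]]:
    missing = [s for s in samples if s not in groups]
    if missing:
        raise ValueError(f"samples without group label: {missing}")
    out: dict[str, list[str]] = {}
    for s in samples:
        out.setdefault(groups[s], []).append(s)
    return out


def pearson_summary(m: ExpressionMatrix,
                    groups: Mapping[str, str]) -> ConcordanceReport:
    """All-pairs Pearson r over clusters with per-group-pair summaries.

    Within-group comparisons are the unordered distinct sample pairs
    (k choose 2 for k samples); cross-group comparisons are the full
    k1 x k2 cartesian product.
    """
    X = m.values.to_numpy(dtype=float)
    sds = X.std(axis=0)
    flat = [s for s, sd in zip(m.samples, sds) if sd == 0]
    if flat:
        raise ValueError(f"zero-variance samples: {flat}")
    corr = pd.DataFrame(np.corrcoef(X.T), index=m.samples, columns=m.samples)
    by_group = _group_samples(m.samples, groups)
    labels = list(by_group)
    rows = []
    pairs: list[tuple[str, list[tuple[str, str]]]] = []
    for g in labels:
        pairs.append((f"{g}-{g}", list(combinations(by_group[g], 2))))
    for g, h in combinations(labels, 2):
        pairs.append((f"{g}-{h}", list(product(by_group[g], by_group[h]))))
    for label, sample_pairs in pairs:
        if not sample_pairs:
            continue
        r = np.array([corr.loc[a, b] for a, b in sample_pairs])
        n = len(r)
        sd = float(r.std(ddof=1)) if n > 1 else float("nan")
        rows.append({
            "pair": label, "n": n,
            "min": float(r.min()), "max": float(r.max()),
            "mean": float(r.mean()), "sd": sd,
            "se": sd / np.sqrt(n) if n > 1 else float("nan"),
        })
    return ConcordanceReport(corr, pd.DataFrame(rows), dict(groups))


def group_means(m: ExpressionMatrix, groups: Mapping[str, str],
                group: str) -> pd.Series:
    """Per-cluster mean log2 signal over the samples of one group."""
    cols = [s for s in m.samples if groups.get(s) == group]
    if not cols:
        raise ValueError(f"no samples labelled {group!r}")
    return m.values.loc[:, cols].mean(axis=1)


def mva(mean_a: pd.Series, mean_b: pd.Series,
        fold_threshold: float = 1.0) -> MvAResult:
    """MvA records for two mean profiles over the same cluster universe.

    M = mean_a - mean_b, A = (mean_a + mean_b) / 2 per cluster; the
    outlier count is #{|M| >= fold_threshold}, with the default threshold
    of 1 on the log2 scale marking a 2-fold difference (inclusive).
    """
    if set(mean_a.index) != set(mean_b.index):
        raise ValueError("MvA requires identical cluster universes")
    b = mean_b.reindex(mean_a.index)
    records = pd.DataFrame({"M": mean_a - b, "A": (mean_a + b) / 2.0})
    outliers = int((records["M"].abs() >= fold_threshold).sum())
    return MvAResult(records, outliers, fold_threshold)


def msd_ranked(reference: pd.Series, comparison: pd.Series) -> float:
    """Mean squared distance between two paired mean profiles.

    Pairing is by cluster identity; clusters are conventionally reported
    ranked by descending reference mean (see :func:`ranked_profile`), but
    the ordering does not change the value.
    """
    if set(reference.index) != set(comparison.index):
        raise ValueError("MSD requires identical cluster universes")
    diff = reference - comparison.reindex(reference.index)
    return float((diff ** 2).mean())


def ranked_profile(reference: pd.Series, comparison: pd.Series) -> pd.DataFrame:
    """Both profiles ordered by descending reference mean (for ranked plots)."""
    if set(reference.index) != set(comparison.index):
        raise ValueError("ranked profile requires identical cluster universes")
    order = reference.sort_values(ascending=False).index
    return pd.DataFrame({
        "reference": reference.loc[order],
        "comparison": comparison.reindex(order),
    })


def signal_histogram(m: ExpressionMatrix, groups: Mapping[str, str],
                     bins: int = 50) -> tuple[pd.DataFrame, np.ndarray]:
    """Binned frequencies of per-cluster group mean signals.

    Returns (frequencies, bin_edges): one row of counts per group over a
    common set of bin edges; each row sums to the cluster count.
    """
    if m.values.shape[0] == 0:
        raise ValueError("empty expression matrix")
    by_group = _group_samples(m.samples, groups)
    means = {g: m.values.loc[:, cols].mean(axis=1).to_numpy()
             for g, cols in by_group.items()}
    lo = min(v.min() for v in means.values())
    hi = max(v.max() for v in means.values())
    edges = np.histogram_bin_edges(np.array([lo, hi]), bins=bins)
    freqs = pd.DataFrame(
        {g: np.histogram(v, bins=edges)[0] for g, v in means.items()}
    ).T
    return freqs, edges


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive target")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return y


def _estimate_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments empirical-Bayes hyperparameters (d0, s0^2).

    Fits a scaled inverse chi-square prior to the per-cluster residual
    variances via the moments of log s^2; zero variances are excluded.
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("too few positive residual variances to estimate the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess dispersion beyond sampling noise: variances are
        # effectively common, summarised by their mean
        d0 = float("inf")
        s0_sq = float(s2.mean())
    return d0, s0_sq


def moderated_t_test(m: ExpressionMatrix, groups: Mapping[str, str],
                     group_a: str | None = None, group_b: str | None = None,
                     prior_df: float | None = None) -> DEResult:
    """Two-group empirical-Bayes moderated t-test per transcript cluster.

    Per-cluster pooled variances s_g^2 (df d = n1 + n2 - 2) are shrunk
    towards a prior variance s0^2 with prior df d0, both estimated by
    method of moments on log s_g^2 unless ``prior_df`` overrides d0
    (0 recovers the ordinary pooled t; inf gives every cluster the common
    variance s0^2).  Moderated t is Delta-mean / (s~ * sqrt(1/n1 + 1/n2))
    on d0 + d degrees of freedom; p values are two-sided and BH-adjusted.
    """
    by_group = _group_samples(m.samples, groups)
    if group_a is None or group_b is None:
        if len(by_group) != 2:
            raise ValueError("specify group_a and group_b when more than two groups")
        group_a, group_b = list(by_group)
    for g in (group_a, group_b):
        if g not in by_group:
            raise ValueError(f"unknown group {g!r}")
        if len(by_group[g]) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    Xa = m.values.loc[:, by_group[group_a]].to_numpy(dtype=float)
    Xb = m.values.loc[:, by_group[group_b]].to_numpy(dtype=float)
    n1, n2 = Xa.shape[1], Xb.shape[1]
    d = n1 + n2 - 2
    diff = Xa.mean(axis=1) - Xb.mean(axis=1)
    ss = ((Xa - Xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((Xb - Xb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / d
    d0_est, s0_sq = _estimate_prior(s2, d)
    d0 = d0_est if prior_df is None else float(prior_df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(d)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    # total df cannot exceed the pooled residual df over all clusters
    df_total = min(df_total, float(d * len(s2)))
    scale = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(scale > 0, diff / scale,
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    table = pd.DataFrame(
        {"logFC": diff, "t": t, "p": p, "adj_p": bh_adjust(p)},
        index=m.values.index,
    )
    return DEResult(table, float(d0), float(s0_sq), d)
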