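"""The four inferential procedures the pipeline reports.

Each statistic is computed from its closed form here (so the arithmetic is
auditable and testable against independent oracles); tail probabilities come
from scipy's t/chi2/F distributions.  No multiple-testing correction is
applied anywhere — reports carry raw p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    method: str

    def as_dict(self) -> dict:
        df = list(self.df) if isinstance(self.df, tuple) else self.df
        return {
            "statistic": self.statistic,
            "df": df,
            "p_value": self.p_value,
            "method": self.method,
        }


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int

    def as_dict(self) -> dict:
        return {"r": self.r, "p_value": self.p_value, "n": self.n}


def welch_t(
    x: Sequence[float],
    y: Sequence[float],
    two_sided: bool = True,
    pooled: bool = False,
) -> TestResult:
    """Unpaired t-test; Welch (unequal variances) by default.

    t = (x̄ − ȳ) / sqrt(s²ₓ/nₓ + s²ᵧ/nᵧ), with Welch–Satterthwaite degrees of
    freedom.  ``pooled=True`` switches to the classical equal-variance test.
    Zero variance in both samples with equal means gives t = 0, p = 1; with
    unequal means the limit t = ±inf, p = 0 is reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t needs at least 2 observations per sample")
    nx, ny = x.size, y.size
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if pooled:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se2 = sp2 * (1 / nx + 1 / ny)
        df = float(nx + ny - 2)
        method = "student_t"
    else:
        se2 = vx / nx + vy / ny
        if se2 > 0:
            df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        else:
            df = float(nx + ny - 2)
        method = "welch_t"
    if se2 == 0:
        if mx == my:
            return TestResult(0.0, df, 1.0, method)
        t = math.inf if mx > my else -math.inf
        return TestResult(t, df, 0.0, method)
    t = (mx - my) / math.sqrt(se2)
    tail = sps.t.sf(abs(t), df)
    p = 2 * min(tail, 0.5) if two_sided else tail
    return TestResult(float(t), float(df), float(p), method)


def chi_square_2x2(table: Sequence[Sequence[float]], yates: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table, df = 1.

    Statistic Σ(O−E)²/E with expectations from the margins; optional Yates
    continuity correction subtracts 0.5 from each |O−E|.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("chi_square_2x2 expects a 2x2 table")
    if (obs < 0).any():
        raise ValueError("negative counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal in 2x2 table")
    expected = np.outer(row, col) / total
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(stat, 1.0, p, "chi_square_yates" if yates else "chi_square")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation; p via t = r·sqrt((n−2)/(1−r²)), two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs equal-length samples with n >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = math.sqrt(float((dx**2).sum()) * float((dy**2).sum()))
    if denom == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float((dx * dy).sum() / denom)
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = float(2 * min(sps.t.sf(abs(t), n - 2), 0.5))
    return CorrelationResult(r, p, int(n))


def two_way_anova_lengths(data: pd.DataFrame, response: str = "value") -> TestResult:
    """Two-way fixed-effects ANOVA (no interaction) for the group main effect.

    ``data`` holds one row per (sample, bin) with columns ``group``, ``bin``
    and the response (a per-sample binned length proportion).  The design is
    additive: SS are taken around factor-level means, residual df is
    N − a − b + 1.  Intended for balanced designs (equal replicates per
    group); an empty group×bin cell is an error.
    """
    for col in ("group", "bin", response):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    groups = sorted(data["group"].unique())
    bins = sorted(data["bin"].unique())
    if len(groups) < 2 or len(bins) < 2:
        raise ValueError("need >= 2 groups and >= 2 bins")
    for g in groups:
        for b in bins:
            cell = data[(data["group"] == g) & (data["bin"] == b)]
            if cell.empty:
                raise ValueError(f"empty cell group={g!r} bin={b!r}")
    y = data[response].to_numpy(dtype=float)
    grand = y.mean()
    n_total = y.size

    def factor_ss(col: str, levels) -> float:
        ss = 0.0
        for level in levels:
            vals = data.loc[data[col] == level, response].to_numpy(dtype=float)
            ss += vals.size * (vals.mean() - grand) ** 2
        return ss

    ss_group = factor_ss("group", groups)
    ss_bin = factor_ss("bin", bins)
    ss_total = float(((y - grand) ** 2).sum())
    ss_resid = max(ss_total - ss_group - ss_bin, 0.0)
    df_group = len(groups) - 1
    df_bin = len(bins) - 1
    df_resid = n_total - df_group - df_bin - 1
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom; need replicates per group")
    ms_resid = ss_resid / df_resid
    if ms_resid == 0:
        f_stat = 0.0 if ss_group == 0 else math.inf
        p = 1.0 if ss_group == 0 else 0.0
    else:
        f_stat = (ss_group / df_group) / ms_resid
        p = float(sps.f.sf(f_stat, df_group, df_resid))
    return TestResult(float(f_stat), (float(df_group), float(df_resid)), p, "two_way_anova")


def bin_lengths(
    lengths: Sequence[int], bin_width: int = 200, overflow_at: int = 2000
) -> pd.Series:
    """Per-sample read-length proportions in fixed bins.

    Bins are ``[0,200), [200,400), ..., [1800,2000)`` plus a ``>=2000``
    overflow; values sum to 1 for a non-empty sample.
    """
    edges = list(range(0, overflow_at + bin_width, bin_width))
    labels = [f"[{lo},{lo + bin_width})" for lo in edges[:-1]] + [f">={overflow_at}"]
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("no reads")
    counts = np.zeros(len(labels))
    idx = np.minimum(arr // bin_width, len(labels) - 1).astype(int)
    for i in idx:
        counts[i] += 1
    return pd.Series(counts / counts.sum(), index=labels, name="proportion")
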