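"""Repeatability and comparison statistics.

Coefficient of repeatability (1.96 x SD of signed intra-subject test-retest
differences), coefficient of variation (SD across all scans over the mean),
an exact two-tailed Wilcoxon signed-rank test (zero differences dropped,
average ranks for ties), Welch's t-test from summary statistics, and
two-sample sample-size calculations.

Sample SD (n-1 denominator) is used throughout.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import PairingError, ParameterError, UndefinedStatisticError

COHORT_COLUMNS = [
    "subject", "session", "gated", "method",
    "pcr_atp", "snr", "crlb_pct", "fwhm_hz",
]


def coefficient_of_repeatability(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
) -> float:
    """1.96 x sample SD of the signed session-2 minus session-1 differences.

    ``pairs`` is an (n, 2) array-like of (session 1, session 2) values per
    subject; every subject must have both sessions.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise PairingError("pairs must be (n, 2): one row per subject")
    if arr.shape[0] < 2:
        raise PairingError("need at least two subjects with both sessions")
    if not np.all(np.isfinite(arr)):
        raise PairingError("a subject is missing a session value")
    diffs = arr[:, 1] - arr[:, 0]
    return 1.96 * float(np.std(diffs, ddof=1))


def coefficient_of_variation(
    mean: float | None = None,
    sd: float | None = None,
    values: Iterable[float] | None = None,
) -> float:
    """SD over mean, either from a printed (mean, sd) summary or raw values."""
    if values is not None:
        v = np.asarray(list(values), dtype=float)
        mean = float(np.mean(v))
        sd = float(np.std(v, ddof=1))
    if mean is None or sd is None:
        raise ParameterError("give either values or both mean and sd")
    if mean == 0:
        raise UndefinedStatisticError("CoV undefined for zero mean")
    return sd / mean


def _exact_wilcoxon_sf_cdf(ranks2: np.ndarray, w2: int) -> tuple[float, float]:
    """P(W <= w) and P(W >= w) for W = sum of + ranks, via integer DP.

    ``ranks2`` are the (tie-averaged) ranks doubled so they are integers;
    signs are i.i.d. +/- under the null, so the distribution of the doubled
    statistic is an exact convolution.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    dist /= dist.sum()
    cdf = float(dist[: w2 + 1].sum())
    sf = float(dist[w2:].sum())
    return cdf, sf


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-tailed signed-rank p-value for paired samples.

    Zero differences are dropped; tied absolute differences get average
    ranks.  Exact null distribution by dynamic programming for n <= 25,
    normal approximation with continuity correction beyond.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("x and y must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise UndefinedStatisticError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= 25:
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w_pos))
        cdf, sf = _exact_wilcoxon_sf_cdf(ranks2, w2)
        return min(1.0, 2.0 * min(cdf, sf))
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction
    _, counts = np.unique(ranks, return_counts=True)
    var -= np.sum(counts**3 - counts) / 48.0
    z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / math.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def welch_t(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> tuple[float, float, float]:
    """Welch's two-sample t-test from summary statistics.

    Returns (t, Welch-Satterthwaite df, two-tailed p).
    """
    if n_a < 2 or n_b < 2:
        raise ParameterError("need n >= 2 in each group")
    if sd_a < 0 or sd_b < 0 or (sd_a == 0 and sd_b == 0):
        raise ParameterError("degenerate variances")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    se = math.sqrt(va + vb)
    t = (mean_a - mean_b) / se
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(t), float(df), p


def sample_size_two_sample(
    mean_a: float, sd_a: float, mean_b: float, sd_b: float,
    power: float = 0.8, alpha: float = 0.05,
    convention: str = "normal_approx", sd_choice: str = "a",
) -> tuple[int, int]:
    """Participants needed per group (and total) for a two-sample t-test.

    ``normal_approx``: n = 2 sigma^2 (z_{1-a/2} + z_{1-b})^2 / delta^2,
    ceiled; ``noncentral_t``: smallest n whose exact two-sided noncentral-t
    power reaches the target.  ``sd_choice`` selects which SD plays sigma:
    group a, group b, or the RMS-pooled value.
    """
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ParameterError("power and alpha must be in (0, 1)")
    delta = abs(mean_a - mean_b)
    if delta == 0:
        raise ParameterError("zero effect size")
    sigma = {"a": sd_a, "b": sd_b,
             "pooled": math.sqrt((sd_a**2 + sd_b**2) / 2.0)}.get(sd_choice)
    if sigma is None:
        raise ParameterError("sd_choice must be 'a', 'b' or 'pooled'")
    if sigma <= 0:
        raise ParameterError("sigma must be positive")

    if convention == "normal_approx":
        z = sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)
        n = math.ceil(2.0 * sigma**2 * z**2 / delta**2)
        n = max(n, 2)
        return n, 2 * n
    if convention == "noncentral_t":
        for n in range(2, 10_000):
            df = 2 * n - 2
            nc = delta / (sigma * math.sqrt(2.0 / n))
            tcrit = sps.t.ppf(1 - alpha / 2, df)
            pw = sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
            if pw >= power:
                return n, 2 * n
        raise ParameterError("sample size search did not converge")
    raise ParameterError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# cohort-table summaries


@dataclass
class RepeatabilitySummary:
    """Per (method, gated) summary of a cohort table."""

    table: pd.DataFrame  # one row per (method, gated) x metric summary

    def row(self, method: str, gated: bool) -> pd.Series:
        sel = self.table[(self.table["method"] == method)
                         & (self.table["gated"] == gated)]
        if sel.empty:
            raise KeyError((method, gated))
        return sel.iloc[0]


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ParameterError(f"cohort table missing columns: {missing}")
    keys = table[["subject", "session", "gated", "method"]]
    if keys.duplicated().any():
        raise ParameterError("duplicate (subject, session, gated, method) rows")
    return table


def paired_sessions(table: pd.DataFrame, method: str, gated: bool,
                    metric: str = "pcr_atp") -> np.ndarray:
    """(n_subjects, 2) array of session-1/session-2 values for one method."""
    sel = table[(table["method"] == method) & (table["gated"] == gated)]
    piv = sel.pivot(index="subject", columns="session", values=metric)
    if piv.isna().any().any() or piv.shape[1] != 2:
        raise PairingError(
            f"incomplete test-retest pairs for method={method} gated={gated}")
    return piv.to_numpy()


def repeatability_summary(
    table: pd.DataFrame,
    reference: tuple[str, bool] = ("ft", False),
    metrics: Sequence[str] = ("pcr_atp", "snr", "crlb_pct", "fwhm_hz"),
) -> RepeatabilitySummary:
    """Mean/SD, CoR and CoV per method, plus Wilcoxon p against a reference.

    CoR and CoV are computed for the PCr/ATP ratio; Wilcoxon compares each
    metric scan-by-scan against the reference (method, gated) arm.
    """
    validate_cohort_table(table)
    ref_method, ref_gated = reference
    rows = []
    arms = table[["method", "gated"]].drop_duplicates().itertuples(index=False)
    for method, gated in arms:
        sel = table[(table["method"] == method) & (table["gated"] == gated)]
        sel = sel.sort_values(["subject", "session"])
        row: dict = {"method": method, "gated": gated, "n_scans": len(sel)}
        for m in metrics:
            row[f"{m}_mean"] = float(sel[m].mean())
            row[f"{m}_sd"] = float(sel[m].std(ddof=1))
        try:
            pairs = paired_sessions(table, method, gated)
            row["cor"] = coefficient_of_repeatability(pairs)
        except PairingError:
            row["cor"] = float("nan")
        row["cov"] = coefficient_of_variation(values=sel["pcr_atp"])
        is_ref = method == ref_method and gated == ref_gated
        ref_sel = table[(table["method"] == ref_method)
                        & (table["gated"] == ref_gated)]
        ref_sel = ref_sel.sort_values(["subject", "session"])
        for m in metrics:
            if is_ref or len(ref_sel) != len(sel):
                row[f"{m}_p_vs_ref"] = float("nan")
                continue
            try:
                row[f"{m}_p_vs_ref"] = wilcoxon_signed_rank(
                    sel[m].to_numpy(), ref_sel[m].to_numpy())
            except UndefinedStatisticError:
                row[f"{m}_p_vs_ref"] = float("nan")
        rows.append(row)
    return RepeatabilitySummary(pd.DataFrame(rows))
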