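"""Rank-based comparison of menu sources.

Implements the comparison stage: Kruskal-Wallis across the three menu
sources per (target group, meal type, metric) stratum, pairwise
Mann-Whitney U tests gated on Kruskal-Wallis significance (a protected
Fisher-style procedure, with no further multiplicity correction), and
Spearman correlation between profile scores.

The U statistic counts, over all cross pairs, wins of the first sample with
half credit for ties.  For combined sample sizes up to
:data:`EXACT_THRESHOLD` the p-value is computed by exact enumeration of all
label assignments (a permutation test on U, valid under ties); larger
samples use the normal approximation with tie correction.  Kruskal-Wallis
uses the tie-corrected H statistic against chi-square; Spearman is the
Pearson correlation of mid-ranks with a t-approximation p-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EXACT_THRESHOLD",
    "TestResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "spearman_rho",
    "ComparisonTable",
    "compare_sources",
    "assign_letters",
]

#: Largest combined n for which the Mann-Whitney p-value is enumerated exactly.
EXACT_THRESHOLD = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float

    def __iter__(self):
        return iter((self.statistic, self.pvalue))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample ``a``: wins over ``b`` plus half credit for ties."""
    ranks = sps.rankdata(np.concatenate([a, b]))
    r_a = ranks[: len(a)].sum()
    return r_a - len(a) * (len(a) + 1) / 2.0


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration over all ``C(n_a+n_b, n_a)`` assignments when the
    combined size is at most :data:`EXACT_THRESHOLD`; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    u = _u_statistic(a, b)
    mu = n_a * n_b / 2.0

    if n_a + n_b <= EXACT_THRESHOLD:
        pooled = np.concatenate([a, b])
        idx = range(n_a + n_b)
        observed_dev = abs(u - mu)
        hits = 0
        total = 0
        for comb in combinations(idx, n_a):
            mask = np.zeros(n_a + n_b, dtype=bool)
            mask[list(comb)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            # tolerance guards half-integer U values under ties
            if abs(u_perm - mu) >= observed_dev - 1e-9:
                hits += 1
            total += 1
        return TestResult(statistic=u, pvalue=hits / total)

    pooled = np.concatenate([a, b])
    n = n_a + n_b
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # all observations identical
        return TestResult(statistic=u, pvalue=1.0)
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(max(z, 0.0))
    return TestResult(statistic=u, pvalue=min(p, 1.0))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test against chi-square (g-1 df).

    All observations identical is a degenerate, not an error: H = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(g.size == 0 for g in arrays):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    grand_mean = (n + 1) / 2.0
    h = 0.0
    start = 0
    for g in arrays:
        r = ranks[start : start + g.size]
        h += g.size * (r.mean() - grand_mean) ** 2
        start += g.size
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if correction <= 0.0:  # every observation tied
        return TestResult(statistic=0.0, pvalue=1.0)
    h /= correction
    p = sps.chi2.sf(h, df=len(arrays) - 1)
    return TestResult(statistic=h, pvalue=p)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with two-sided t-approximation p-value.

    Constant input leaves the coefficient undefined: returns NaN/NaN with a
    warning rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return TestResult(statistic=float("nan"), pvalue=float("nan"))
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(rho) >= 1.0:
        return TestResult(statistic=float(np.sign(rho)), pvalue=0.0)
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return TestResult(statistic=rho, pvalue=min(p, 1.0))


def assign_letters(
    sources: Sequence[str], significant_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Compact letter display: sources sharing a letter are not significantly
    different.

    Insert-and-absorb: start with one column holding every source; for each
    significant pair split any column containing both; drop columns that are
    subsets of others; letter the columns in source order.
    """
    columns: list[set[str]] = [set(sources)]
    for pair in sorted(significant_pairs):
        i, j = pair
        for col in list(columns):
            if i in col and j in col:
                columns.remove(col)
                columns.extend([col - {i}, col - {j}])
        columns = [
            c
            for c in columns
            if c and not any(c < other for other in columns if other is not c)
        ]
    # deduplicate while preserving deterministic order
    uniq: list[set[str]] = []
    for c in columns:
        if c not in uniq:
            uniq.append(c)
    order = {s: k for k, s in enumerate(sources)}
    uniq.sort(key=lambda c: min(order[s] for s in c))
    letters = {s: "" for s in sources}
    for idx, col in enumerate(uniq):
        ch = chr(ord("a") + idx)
        for s in col:
            letters[s] += ch
    return letters


@dataclass
class ComparisonTable:
    """Stratified source comparison.

    ``table``: one row per (target_group, meal_type, metric) with per-source
    mean/SD/letter plus Kruskal-Wallis H and p.  ``pairwise``: one row per
    source pair actually tested (only in strata where KW p < alpha).
    """

    table: pd.DataFrame
    pairwise: pd.DataFrame
    alpha: float


STRATUM_KEYS = ["target_group", "meal_type", "metric"]


def compare_sources(reports: pd.DataFrame, alpha: float = 0.05) -> ComparisonTable:
    """Compare menu sources stratum by stratum on long-form score rows.

    ``reports`` columns: source, target_group, meal_type, metric, value (one
    row per scored meal).  Within each stratum a Kruskal-Wallis test runs
    across sources; when it rejects at ``alpha``, pairwise Mann-Whitney U
    tests are run and homogeneity letters assigned (sources sharing a letter
    do not differ significantly).  Strata with fewer than two sources are
    skipped with a warning.
    """
    required = {"source", "value", *STRATUM_KEYS}
    missing = required - set(reports.columns)
    if missing:
        raise ValueError(f"reports missing columns {sorted(missing)}")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")

    rows = []
    pair_rows = []
    for key, chunk in reports.groupby(STRATUM_KEYS, sort=True):
        sources = sorted(chunk["source"].unique())
        if len(sources) < 2:
            warnings.warn(
                f"stratum {key}: only {len(sources)} source(s); skipped",
                stacklevel=2,
            )
            continue
        samples = {s: chunk.loc[chunk["source"] == s, "value"].to_numpy() for s in sources}
        kw = kruskal_wallis([samples[s] for s in sources])
        sig_pairs: set[tuple[str, str]] = set()
        if kw.pvalue < alpha:
            for s1, s2 in combinations(sources, 2):
                mw = mann_whitney_u(samples[s1], samples[s2])
                pair_rows.append(
                    dict(
                        zip(STRATUM_KEYS, key),
                        source_a=s1,
                        source_b=s2,
                        u=mw.statistic,
                        p=mw.pvalue,
                    )
                )
                if mw.pvalue < alpha:
                    sig_pairs.add((s1, s2))
            letters = assign_letters(sources, sig_pairs)
        else:
            letters = {s: "" for s in sources}
        row = dict(zip(STRATUM_KEYS, key))
        row["kw_h"] = kw.statistic
        row["kw_p"] = kw.pvalue
        for s in sources:
            row[f"mean_{s}"] = samples[s].mean()
            row[f"sd_{s}"] = samples[s].std(ddof=1) if samples[s].size > 1 else float("nan")
            row[f"letter_{s}"] = letters[s]
        rows.append(row)

    table = pd.DataFrame(rows)
    pairwise = pd.DataFrame(
        pair_rows, columns=STRATUM_KEYS + ["source_a", "source_b", "u", "p"]
    )
    if not rows:
        warnings.warn("no comparable strata; empty table", stacklevel=2)
        table = pd.DataFrame(columns=STRATUM_KEYS + ["kw_h", "kw_p"])
    return ComparisonTable(table=table, pairwise=pairwise, alpha=alpha)
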