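"""Per-sample summaries and group comparisons.

Implements the two-sample Wilcoxon rank-sum test (exact by tail counting
on the rank-sum distribution for small untied samples, otherwise a normal
approximation with tie and continuity corrections) and an ordinary
least-squares fit reporting r^2 and the F statistic, plus sample-level
report assembly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence

from scipy import stats as sps

from .classify import FateCounts
from .pmd import PmdResult, median_read_length, pmd_ratio

EXACT_THRESHOLD = 10  # exact p when n1 + n2 <= this and no ties


@dataclass
class WilcoxonResult:
    """W is the Mann-Whitney U of the first sample; ``rank_sum`` is the
    R-convention statistic W + n1(n1+1)/2 printed alongside for parity
    with conventional reports."""

    W: float
    rank_sum: float
    p_value: float
    method: str  # "exact" | "normal_approx"


def _midranks(pooled: Sequence[float]) -> List[float]:
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


@lru_cache(maxsize=None)
def _count_u(n1: int, n2: int, u: int) -> int:
    """Number of orderings of n1 vs n2 untied observations with Mann-Whitney
    statistic exactly u (standard recursion)."""
    if u < 0 or u > n1 * n2:
        return 0
    if n1 == 0 or n2 == 0:
        return 1 if u == 0 else 0
    return _count_u(n1 - 1, n2, u - n2) + _count_u(n1, n2 - 1, u)


def _exact_p(n1: int, n2: int, u: float, alternative: str) -> float:
    total = math.comb(n1 + n2, n1)
    u = int(round(u))
    cdf = sum(_count_u(n1, n2, k) for k in range(0, u + 1)) / total
    sf = sum(_count_u(n1, n2, k) for k in range(u, n1 * n2 + 1)) / total
    if alternative == "less":
        return cdf
    if alternative == "greater":
        return sf
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
    continuity: bool = True,
) -> WilcoxonResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    W is the rank-sum of ``x`` minus n1(n1+1)/2 with midranks for ties.
    The p-value is exact (distribution enumeration) when n1 + n2 <= 10 and
    the pooled data are untied, else a normal approximation with tie
    correction and (optionally) continuity correction.
    """
    if alternative not in ("two_sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = list(x) + list(y)
    ranks = _midranks(pooled)
    rank_sum_x = sum(ranks[:n1])
    u = rank_sum_x - n1 * (n1 + 1) / 2.0

    has_ties = len(set(pooled)) < len(pooled)
    if n1 + n2 <= EXACT_THRESHOLD and not has_ties:
        p = _exact_p(n1, n2, u, alternative)
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        tie_counts: Dict[float, int] = {}
        for v in pooled:
            tie_counts[v] = tie_counts.get(v, 0) + 1
        tie_term = sum(t**3 - t for t in tie_counts.values())
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var == 0:
            p = 1.0
        else:
            diff = u - mu
            if continuity:
                diff -= math.copysign(0.5, diff) if diff != 0 else 0.0
            z = diff / math.sqrt(var)
            if alternative == "less":
                p = sps.norm.cdf(z)
            elif alternative == "greater":
                p = sps.norm.sf(z)
            else:
                p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        method = "normal_approx"
    return WilcoxonResult(W=u, rank_sum=rank_sum_x, p_value=float(p), method=method)


@dataclass
class FitResult:
    r2: float
    F: float
    p_value: float
    slope: float
    intercept: float


def linear_fit_r2_f(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """OLS fit y = a + b x with r^2 and the slope F statistic (1, n-2 df).

    With a single predictor, F equals the square of the slope t statistic
    and r^2 equals the squared Pearson correlation.
    """
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if len(set(x)) == 1:
        raise ValueError("x is constant; fit undefined")
    res = sps.linregress(x, y)
    r2 = res.rvalue**2
    if res.stderr == 0:
        f = math.inf
        p = 0.0
    else:
        t = res.slope / res.stderr
        f = t * t
        p = float(res.pvalue)
    return FitResult(r2=float(r2), F=float(f), p_value=p,
                     slope=float(res.slope), intercept=float(res.intercept))


SAMPLE_STATS_COLUMNS = (
    "sample_id", "n_reads", "mRL", "PMDR",
    "frac_target", "frac_contaminant", "frac_ambiguous",
    "frac_unmapped", "frac_too_short",
)


@dataclass
class SampleStats:
    sample_id: str
    n_reads: int
    mRL: Optional[float]
    PMDR: Optional[float]
    frac_target: float
    frac_contaminant: float
    frac_ambiguous: float
    frac_unmapped: float
    frac_too_short: float

    def as_dict(self) -> Dict:
        return {c: getattr(self, c) for c in SAMPLE_STATS_COLUMNS}


def summarize_sample(
    sample_id: str,
    fate_counts: FateCounts,
    pmd_results: Iterable[PmdResult],
    reads,
    pmd_threshold: float = 5.0,
) -> SampleStats:
    """Compose per-sample fractions, median read length and PMD ratio."""
    fate_counts.validate()
    n = fate_counts.n_total
    if n == 0:
        raise ValueError(f"sample {sample_id!r}: no reads")
    return SampleStats(
        sample_id=sample_id,
        n_reads=n,
        mRL=median_read_length(reads),
        PMDR=pmd_ratio(pmd_results, threshold=pmd_threshold),
        frac_target=fate_counts.n_target / n,
        frac_contaminant=fate_counts.n_contaminant / n,
        frac_ambiguous=fate_counts.n_ambiguous / n,
        frac_unmapped=fate_counts.n_unmapped / n,
        frac_too_short=fate_counts.n_too_short / n,
    )


def write_report(rows: Sequence[SampleStats], path) -> None:
    """TSV with fixed column order plus a JSON twin at <path>.json."""
    if not rows:
        raise ValueError("no rows to write")
    path = str(path)
    try:
        with open(path, "w") as fh:
            fh.write("\t".join(SAMPLE_STATS_COLUMNS) + "\n")
            for row in rows:
                d = row.as_dict()
                cells = []
                for col in SAMPLE_STATS_COLUMNS:
                    v = d[col]
                    if isinstance(v, float):
                        cells.append(f"{v:.6f}")
                    elif v is None:
                        cells.append("NA")
                    else:
                        cells.append(str(v))
                fh.write("\t".join(cells) + "\n")
        with open(path + ".json", "w") as fh:
            json.dump([r.as_dict() for r in rows], fh, indent=2)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"failed writing report to {path}: {exc}") from exc


def load_report(path) -> List[SampleStats]:
    rows: List[SampleStats] = []
    with open(path) as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != SAMPLE_STATS_COLUMNS:
            raise ValueError(f"unexpected report header in {path}: {header}")
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            d = dict(zip(SAMPLE_STATS_COLUMNS, cells))
            rows.append(
                SampleStats(
                    sample_id=d["sample_id"],
                    n_reads=int(d["n_reads"]),
                    mRL=None if d["mRL"] == "NA" else float(d["mRL"]),
                    PMDR=None if d["PMDR"] == "NA" else float(d["PMDR"]),
                    frac_target=float(d["frac_target"]),
                    frac_contaminant=float(d["frac_contaminant"]),
                    frac_ambiguous=float(d["frac_ambiguous"]),
                    frac_unmapped=float(d["frac_unmapped"]),
                    frac_too_short=float(d["frac_too_short"]),
                )
            )
    return rows
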