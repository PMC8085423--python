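"""Genomic-control and plotting-ready diagnostics for genome-wide scans.

The genomic inflation factor lambda is the median observed chi-square
statistic divided by the median of the null chi-square distribution with
the test's degrees of freedom (0.4549... for 1 df, 2 ln 2 for 2 df); a
well-calibrated test gives lambda near 1.  QQ and Manhattan tables are
emitted as plain data; rendering is optional glue over matplotlib.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

logger = logging.getLogger(__name__)

GENOMEWIDE_P = 5e-8
SUGGESTIVE_P = 1e-6


@dataclass
class LambdaEstimate:
    lambda_gc: float
    df: int
    n_tests: int
    n_dropped: int = 0


def lambda_gc(chisq_values: np.ndarray, df: int) -> LambdaEstimate:
    """Median-based genomic inflation factor; NA statistics are dropped."""
    if df not in (1, 2):
        raise ValueError("df must be 1 or 2")
    values = np.asarray(chisq_values, dtype=float)
    finite = values[np.isfinite(values)]
    n_dropped = values.size - finite.size
    if n_dropped:
        logger.info("lambda_gc: dropped %d non-finite statistics", n_dropped)
    if finite.size == 0:
        raise ValueError("no finite chi-square statistics for lambda")
    lam = float(np.median(finite) / chi2.ppf(0.5, df))
    return LambdaEstimate(lambda_gc=lam, df=df, n_tests=int(finite.size), n_dropped=n_dropped)


def qq_table(p_values: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p under the uniform null.

    Expected quantile for rank k of n is (k - 0.5)/n; duplicated p-values
    are preserved.  Output is sorted by the expected coordinate.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    observed = -np.log10(np.sort(p)[::-1])  # ascending -log10 p
    n = p.size
    expected = -np.log10((np.arange(n, 0, -1) - 0.5) / n)
    return pd.DataFrame({"expected_neglog10_p": expected, "observed_neglog10_p": observed})


_CHROM_ORDER = {str(i): i for i in range(1, 23)}


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (_CHROM_ORDER.get(c, 99), c)


def manhattan_table(
    results: pd.DataFrame,
    p_column: str = "P_1DF",
    genomewide_p: float = GENOMEWIDE_P,
    suggestive_p: float = SUGGESTIVE_P,
) -> pd.DataFrame:
    """Cumulative-coordinate table for a Manhattan plot.

    Cumulative position adds the observed maximum position of every
    preceding chromosome; flags are strict (p exactly at a threshold is
    not flagged).
    """
    frame = results[["CHR", "POS", p_column]].copy()
    frame["CHR"] = frame["CHR"].astype(str)
    frame = frame.sort_values(
        by=["CHR", "POS"], key=lambda s: s.map(_chrom_sort_key) if s.name == "CHR" else s
    ).reset_index(drop=True)
    offsets: dict[str, float] = {}
    running = 0.0
    for chrom in frame["CHR"].unique():
        offsets[chrom] = running
        running += float(frame.loc[frame["CHR"] == chrom, "POS"].max())
    p = frame[p_column].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(p)
    return pd.DataFrame(
        {
            "CHR": frame["CHR"],
            "POS": frame["POS"],
            "CUM_POS": frame["POS"] + frame["CHR"].map(offsets),
            "NEGLOG10_P": neglog,
            "FLAG_GENOMEWIDE": (p < genomewide_p).astype(int),
            "FLAG_SUGGESTIVE": (p < suggestive_p).astype(int),
        }
    )


def qq_plot(p_values: np.ndarray, path: str, title: str = "") -> None:
    """Render a QQ plot PNG (optional glue; the tested artifact is the table)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = qq_table(p_values)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(table["expected_neglog10_p"], table["observed_neglog10_p"], ".", ms=3)
    lim = max(table["expected_neglog10_p"].max(), table["observed_neglog10_p"].max())
    ax.plot([0, lim], [0, lim], "r--", lw=1)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def manhattan_plot(results: pd.DataFrame, path: str, p_column: str = "P_1DF", title: str = "") -> None:
    """Render a Manhattan plot PNG from a summary-statistics frame."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = manhattan_table(results, p_column=p_column)
    fig, ax = plt.subplots(figsize=(9, 3.5))
    for i, (_, grp) in enumerate(table.groupby("CHR", sort=False)):
        ax.plot(grp["CUM_POS"], grp["NEGLOG10_P"], ".", ms=2, color="C0" if i % 2 else "C1")
    ax.axhline(-math.log10(GENOMEWIDE_P), color="red", ls="--", lw=1)
    ax.axhline(-math.log10(SUGGESTIVE_P), color="blue", ls=":", lw=1)
    ax.set_xlabel("cumulative position")
    ax.set_ylabel("$-\\log_{10} p$")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
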