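"""False-positive/negative essential-call estimation from representation bias.

The accounting compares, below every candidate pDNA threshold (and within
every equal-count pDNA bin), the observed number of essential calls with the
number expected if essentiality were independent of representation
(fraction x subset size). The elbow of the essential-ratio curve locates a
data-driven pDNA cut-off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from screenbias.bias_diagnostics import BinPartition

DEFAULT_MIN_GENES_BELOW = 100


@dataclass(frozen=True)
class ThresholdCurve:
    """Essential-ratio and predicted-FP curves over ascending pDNA thresholds.

    ``n_below``/``ess_below`` count genes with pDNA <= threshold; ``ratio``
    is ess_below/n_below (NaN where n_below is 0); ``predicted_fp`` is
    ess_below - fraction * n_below.
    """

    thresholds: np.ndarray
    n_below: np.ndarray
    ess_below: np.ndarray
    fraction: float

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.ess_below / self.n_below
        return np.where(self.n_below > 0, r, np.nan)

    @property
    def expected(self) -> np.ndarray:
        return self.fraction * self.n_below

    @property
    def predicted_fp(self) -> np.ndarray:
        return self.ess_below - self.expected

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "n_below": self.n_below,
            "ess_below": self.ess_below,
            "ratio": self.ratio,
            "expected": self.expected,
            "predicted_fp": self.predicted_fp,
        })

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def threshold_curve(pdna: pd.Series, essential: pd.Series, fraction: float = 0.15) -> ThresholdCurve:
    """Build the essential-ratio curve over all observed pDNA thresholds.

    ``essential`` holds boolean flags from a rank-based call at the same
    fraction; thresholds are the sorted unique pDNA values (inclusive below).
    """
    ess = essential.reindex(pdna.index)
    if ess.isna().any():
        raise ValueError("essential flags missing for some genes")
    ess = ess.astype(bool)
    if not ess.any():
        raise ValueError("no essential genes flagged")
    order = np.argsort(pdna.to_numpy(), kind="mergesort")
    vals = pdna.to_numpy()[order]
    flags = ess.to_numpy()[order]
    thresholds, last_idx = np.unique(vals, return_index=True)
    # cumulative counts at the last occurrence of each unique value
    cum_n = np.arange(1, len(vals) + 1)
    cum_e = np.cumsum(flags)
    # index of final occurrence per unique threshold
    end = np.append(last_idx[1:], len(vals)) - 1
    return ThresholdCurve(
        thresholds=thresholds,
        n_below=cum_n[end],
        ess_below=cum_e[end],
        fraction=fraction,
    )


@dataclass(frozen=True)
class ElbowResult:
    threshold: float
    index: int
    distances: np.ndarray = field(repr=False)
    degenerate: bool = False


def detect_elbow(curve: ThresholdCurve,
                 min_genes_below: int = DEFAULT_MIN_GENES_BELOW) -> ElbowResult:
    """Locate the elbow of the essential-ratio curve.

    After excluding thresholds with fewer than ``min_genes_below`` genes
    beneath them, the elbow is the threshold maximizing the perpendicular
    distance between the (threshold, ratio) point and the chord joining the
    first and last restricted points. Ties resolve to the smallest
    threshold; exactly collinear curves return the smallest threshold with
    the degenerate flag set.
    """
    keep = curve.n_below >= min_genes_below
    x = curve.thresholds[keep]
    y = curve.ratio[keep]
    ok = ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(
            f"need at least 3 curve points with n_below >= {min_genes_below}, got {len(x)}"
        )
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    chord = float(np.hypot(dx, dy))
    if chord == 0:
        raise ValueError("zero-length chord: first and last curve points coincide")
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / chord
    if np.allclose(dist, 0):
        return ElbowResult(threshold=float(x[0]), index=0, distances=dist, degenerate=True)
    best = int(np.argmax(dist))  # argmax returns the first (smallest threshold) maximum
    return ElbowResult(threshold=float(x[best]), index=best, distances=dist)


@dataclass(frozen=True)
class FpFnEstimate:
    """Per-bin expected-vs-observed essential accounting plus summary stats."""

    bins: pd.DataFrame  # columns: bin, mean_pdna, n, observed, expected, fp, fn
    fraction: float
    total_fp: float
    total_fn: float
    elbow_threshold: float | None = None
    ks_stat: float | None = None
    ks_p: float | None = None

    @property
    def total_misclassified(self) -> float:
        return self.total_fp + self.total_fn

    def to_dict(self) -> dict:
        return {
            "fraction": self.fraction,
            "total_fp": self.total_fp,
            "total_fn": self.total_fn,
            "total_misclassified": self.total_misclassified,
            "elbow_threshold": self.elbow_threshold,
            "ks": {"D": self.ks_stat, "p": self.ks_p},
            "bins": self.bins.to_dict(orient="records"),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def per_bin_fp_fn(
    pdna: pd.Series,
    essential: pd.Series,
    partition: BinPartition,
    fraction: float = 0.15,
    integerize: bool = False,
) -> FpFnEstimate:
    """Estimate FP/FN essential calls per equal-count pDNA bin.

    Per bin: expected = fraction x bin size, fp = max(observed - expected, 0),
    fn = max(expected - observed, 0); each bin contributes to exactly one of
    FP or FN. Counts stay fractional unless ``integerize``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    ess = essential.reindex(partition.genes)
    if ess.isna().any():
        raise ValueError("partition contains genes without essential flags")
    ess = ess.astype(bool)
    grouped = ess.groupby(partition.assignment)
    observed = grouped.sum().astype(float)
    n = grouped.size().astype(float)
    expected = fraction * n
    if integerize:
        expected = expected.round()
    fp = (observed - expected).clip(lower=0.0)
    fn = (expected - observed).clip(lower=0.0)
    mean_pdna = partition.mean_key_per_bin()
    bins = pd.DataFrame({
        "bin": observed.index,
        "mean_pdna": mean_pdna.reindex(observed.index).to_numpy(),
        "n": n.to_numpy(),
        "observed": observed.to_numpy(),
        "expected": expected.to_numpy(),
        "fp": fp.to_numpy(),
        "fn": fn.to_numpy(),
    }).reset_index(drop=True)
    return FpFnEstimate(bins=bins, fraction=fraction,
                        total_fp=float(fp.sum()), total_fn=float(fn.sum()))


def ecdf_ks(pdna: pd.Series, essential: pd.Series) -> dict:
    """Two-sample KS comparison of essential vs non-essential pDNA distributions.

    Returns the KS statistic D, its asymptotic two-sided p-value, and both
    empirical CDFs.
    """
    ess = essential.reindex(pdna.index).astype(bool)
    a = pdna[ess].to_numpy(dtype=float)
    b = pdna[~ess].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both essential and non-essential groups must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return {
        "ks_stat": float(res.statistic),
        "ks_p": float(res.pvalue),
        "ecdf_essential": stats.ecdf(a).cdf,
        "ecdf_nonessential": stats.ecdf(b).cdf,
    }


def ks_uniform(pdna_ranks: pd.Series, essential: pd.Series) -> dict:
    """One-sample KS of essential genes' pDNA rank quantiles against uniform."""
    ess = essential.reindex(pdna_ranks.index).astype(bool)
    quantiles = pdna_ranks.rank(pct=True)[ess].to_numpy(dtype=float)
    if quantiles.size == 0:
        raise ValueError("no essential genes flagged")
    res = stats.kstest(quantiles, "uniform")
    return {"ks_stat": float(res.statistic), "ks_p": float(res.pvalue)}


def estimate(
    pdna: pd.Series,
    essential: pd.Series,
    partition: BinPartition,
    fraction: float = 0.15,
    min_genes_below: int = DEFAULT_MIN_GENES_BELOW,
) -> FpFnEstimate:
    """Full estimate: per-bin FP/FN plus elbow threshold and KS comparison."""
    base = per_bin_fp_fn(pdna, essential, partition, fraction=fraction)
    curve = threshold_curve(pdna, essential, fraction=fraction)
    elbow = detect_elbow(curve, min_genes_below=min_genes_below)
    ks = ecdf_ks(pdna, essential)
    return FpFnEstimate(
        bins=base.bins,
        fraction=fraction,
        total_fp=base.total_fp,
        total_fn=base.total_fn,
        elbow_threshold=elbow.threshold,
        ks_stat=ks["ks_stat"],
        ks_p=ks["ks_p"],
    )
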