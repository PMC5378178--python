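"""Peak-to-trough ratio (PTR) estimation and growth-rate statistics.

In a replicating bacterial population, sequencing coverage decays from the
replication origin to the terminus because a fraction of cells carry
partially replicated chromosomes.  The ratio of coverage at the origin to
coverage at the terminus (the peak-to-trough ratio) is therefore an in-situ
proxy for population replication rate: 1.0 means no detectable replication,
2.0 means on average one active replication fork pair per cell.

PTR is computed on an ordered, oriented (core) genome from a smoothed,
outlier-trimmed coverage profile, either at an externally supplied ori/ter
(from GC skew) or at the global coverage extrema subject to the constraint
that peak and trough sit roughly half a genome apart (bidirectional
replication places the terminus opposite the origin, and the constraint
stops prophage or repeat coverage spikes from masquerading as origins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .containers import CoverageTrack
from .skew import OriTerCall

__all__ = ["PTREstimate", "estimate_ptr", "compare_growth", "growth_trend",
           "validate_growth_table"]

BODY_SITES = ("gut", "mouth", "skin")


@dataclass
class PTREstimate:
    """A PTR measurement, or an explicit no-call with QC flags."""

    ptr: float | None
    peak_position: int | None = None
    trough_position: int | None = None
    median_coverage: float = 0.0
    method: str = "gc_skew"
    qc_flags: list[str] = field(default_factory=list)

    @property
    def called(self) -> bool:
        return self.ptr is not None


def _sliding_window_means(depths: np.ndarray, window: int, slide: int) -> tuple[np.ndarray, np.ndarray]:
    """Circular sliding-window means; returns (bin_centers, means).

    Bin i covers ``[i*slide, i*slide + window)`` circularly and is reported
    at its center, so a coverage peak sits inside the bin reported at the
    peak's coordinate rather than at the bin downstream of it.
    """
    L = len(depths)
    ext = np.concatenate([depths, depths[:window]])
    cum = np.concatenate([[0.0], np.cumsum(ext)])
    starts = np.arange(0, L, slide)
    means = (cum[starts + window] - cum[starts]) / window
    centers = (starts + window // 2) % L
    return centers, means


def estimate_ptr(core_coverage: CoverageTrack, ori_ter: OriTerCall | None = None,
                 window: int = 10_000, slide: int = 100, method: str = "gc_skew",
                 min_median_coverage: float = 5.0, median_filter_bins: int | None = None,
                 tail_fraction: float = 0.01,
                 separation: tuple[float, float] = (0.4, 0.6)) -> PTREstimate:
    """Estimate the peak-to-trough coverage ratio on a circular core genome.

    Coverage is binned in circular sliding windows, median-filtered, and bins
    in the top/bottom ``tail_fraction`` (plus zero-coverage bins) are
    excluded.  With ``method='gc_skew'`` the peak and trough are read off the
    filtered profile at the supplied ori/ter call; with ``method='coverage'``
    they are the global extrema subject to a circular separation of
    ``separation`` (fractions of the genome).  PTR is reported as max/min so
    it is always >= 1; a flipped skew convention therefore cannot silently
    invert it.  Tracks whose raw median coverage is below
    ``min_median_coverage`` (default 5x) produce an explicit no-call.
    """
    depths = core_coverage.depths
    L = len(depths)
    if window < 1_000:
        raise ValueError("window must be >= 1 kb")
    if window > L:
        raise ValueError("window exceeds genome length")
    if method not in ("gc_skew", "coverage"):
        raise ValueError("method must be 'gc_skew' or 'coverage'")
    if method == "gc_skew" and ori_ter is None:
        raise ValueError("method='gc_skew' requires an ori/ter call")
    med = float(np.median(depths))
    if med < min_median_coverage:
        return PTREstimate(None, median_coverage=med, method=method,
                           qc_flags=[f"coverage<{min_median_coverage:g}x"])
    centers, means = _sliding_window_means(depths, window, slide)
    if median_filter_bins is None:
        median_filter_bins = max(3, window // slide) | 1  # odd
    filt = ndimage.median_filter(means, size=median_filter_bins, mode="wrap")
    n = len(filt)
    excluded = filt <= 0
    k = int(np.floor(tail_fraction * n))
    if k > 0:
        order = np.argsort(filt)
        excluded[order[:k]] = True
        excluded[order[-k:]] = True
    if excluded.all():
        return PTREstimate(None, median_coverage=med, method=method,
                           qc_flags=["no usable coverage bins"])

    def nearest_valid_bin(pos: int) -> int:
        # bin whose center is nearest pos, skipping excluded bins
        b = int(round((pos - window // 2) / slide)) % n
        if not excluded[b]:
            return b
        valid = np.flatnonzero(~excluded)
        fwd = (valid - b) % n
        circ = np.minimum(fwd, n - fwd)
        return int(valid[np.argmin(circ)])

    if method == "gc_skew":
        b_ori = nearest_valid_bin(ori_ter.ori_position)
        b_ter = nearest_valid_bin(ori_ter.ter_position)
        v_ori, v_ter = filt[b_ori], filt[b_ter]
        flags = []
        if v_ori >= v_ter:
            peak_b, trough_b = b_ori, b_ter
        else:
            peak_b, trough_b = b_ter, b_ori
            flags.append("coverage peak at supplied terminus")
        ptr = float(filt[peak_b] / filt[trough_b])
        return PTREstimate(ptr, int(centers[peak_b]), int(centers[trough_b]),
                           med, method, flags)

    # method == 'coverage': extrema constrained to lie ~half a genome apart
    valid = np.flatnonzero(~excluded)
    lo, hi = separation

    def circ_sep(a: np.ndarray, b: int) -> np.ndarray:
        fwd = (a - b) % n
        return np.minimum(fwd, n - fwd) / n

    best = None
    for pivot_is_peak in (True, False):
        pivot = int(valid[np.argmax(filt[valid])]) if pivot_is_peak else int(valid[np.argmin(filt[valid])])
        sep = circ_sep(valid, pivot)
        band = valid[(sep >= lo) & (sep <= hi)]
        if band.size == 0:
            continue
        if pivot_is_peak:
            other = int(band[np.argmin(filt[band])])
            pair = (pivot, other)
        else:
            other = int(band[np.argmax(filt[band])])
            pair = (other, pivot)
        ratio = float(filt[pair[0]] / filt[pair[1]])
        if best is None or ratio > best[0]:
            best = (ratio, pair)
    if best is None:
        return PTREstimate(None, median_coverage=med, method=method,
                           qc_flags=["no peak/trough pair satisfies the separation constraint"])
    ratio, (peak_b, trough_b) = best
    return PTREstimate(ratio, int(centers[peak_b]), int(centers[trough_b]), med, method, [])


# ---------------------------------------------------------------------------
# growth tables & statistics
# ---------------------------------------------------------------------------

def validate_growth_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a (genome_id, sample_id, body_site, day_of_life, ptr) table."""
    required = {"genome_id", "sample_id", "body_site", "day_of_life", "ptr"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    t = table.dropna(subset=["ptr"])
    if (t["ptr"] < 1).any():
        raise ValueError("ptr values must be >= 1")
    if (t["day_of_life"] < 0).any():
        raise ValueError("day_of_life must be >= 0")
    return t


def compare_growth(table: pd.DataFrame, site_a: str, site_b: str) -> tuple[float, float]:
    """Mann-Whitney U test of PTR between two body sites.

    Uses the exact null distribution for small samples without ties and the
    tie-corrected normal approximation otherwise (scipy's automatic policy).
    Returns ``(U, two_sided_p)`` with U computed for ``site_a``.
    """
    t = validate_growth_table(table)
    a = t.loc[t.body_site == site_a, "ptr"].to_numpy()
    b = t.loc[t.body_site == site_b, "ptr"].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("each body site needs at least one observation")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def growth_trend(table: pd.DataFrame, site: str) -> tuple[float, float, int]:
    """Spearman rank correlation of PTR against day of life within one site.

    Ties are mid-ranked.  Returns ``(rho, p, n)``.
    """
    t = validate_growth_table(table)
    t = t[t.body_site == site]
    n = len(t)
    if n < 3:
        raise ValueError("growth_trend needs at least 3 observations")
    rho, p = stats.spearmanr(t["day_of_life"].to_numpy(), t["ptr"].to_numpy())
    return float(rho), float(p), n
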