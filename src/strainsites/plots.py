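"""Diagnostic plots: cumulative GC skew with coverage overlay.

The standard visual check for an ordered, oriented genome is a single panel
with the cumulative GC skew (sawtooth, extrema at ori/ter) and the smoothed
coverage gradient (peak at ori).  Disagreement between the two flags either
a misassembly or a wrong ori/ter convention.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .containers import CoverageTrack
from .skew import OriTerCall, SkewProfile


def plot_skew_coverage(profile: SkewProfile, coverage: CoverageTrack | None = None,
                       ori_ter: OriTerCall | None = None,
                       path: str | Path | None = None):
    """Plot cumulative GC skew, optionally with coverage and ori/ter marks."""
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.plot(profile.window_starts, profile.cumulative_skew, color="green",
            label="cumulative GC skew")
    ax.set_xlabel("genome position (bp)")
    ax.set_ylabel("cumulative GC skew", color="green")
    if coverage is not None:
        ax2 = ax.twinx()
        # light smoothing for display only
        d = coverage.depths
        w = max(len(d) // 500, 1)
        sm = np.convolve(d, np.ones(w) / w, mode="same")
        ax2.plot(np.arange(len(d)), sm, color="black", alpha=0.7, label="coverage")
        ax2.set_ylabel("coverage (x)", color="black")
    if ori_ter is not None:
        ax.axvline(ori_ter.ori_position, color="red", ls="--", label="ori")
        ax.axvline(ori_ter.ter_position, color="blue", ls="--", label="ter")
    ax.legend(loc="upper right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
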