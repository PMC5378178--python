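"""GC skew profiles, replication origin/terminus calls, and skew QC.

On most bacterial chromosomes the leading strand is G-rich, so the windowed
skew ``(G - C) / (G + C)`` is positive on one replichore and negative on the
other, and the *cumulative* skew is a circular sawtooth with its minimum at
the replication origin and its maximum at the terminus.  This module computes
the profile, calls ori/ter from the sawtooth extrema, and scores how well a
genome's cumulative skew actually matches that expected two-segment shape —
genomes that fail the score (misassemblies, non-chromosomal elements) should
not be used for replication-rate estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import CoverageTrack

logger = logging.getLogger(__name__)

__all__ = ["SkewProfile", "OriTerCall", "gc_skew_profile", "locate_ori_ter", "skew_qc"]


@dataclass
class SkewProfile:
    """Windowed GC skew over a genome.

    ``window_skew[i]`` is ``(G - C)/(G + C)`` over the window starting at
    ``window_starts[i]``; ``cumulative_skew`` is its running sum.
    """

    window_size: int
    step: int
    window_starts: np.ndarray
    window_skew: np.ndarray
    genome_length: int

    @property
    def cumulative_skew(self) -> np.ndarray:
        return np.cumsum(self.window_skew)

    def detrended_cumulative(self) -> np.ndarray:
        """Cumulative skew minus its linear closure trend.

        Subtracting ``(i+1) * total / n`` makes the track exactly circular
        (value 0 at both ends), so extremum positions are equivariant under
        rotation of the genome.
        """
        cum = self.cumulative_skew
        n = len(cum)
        if n == 0:
            return cum
        return cum - np.arange(1, n + 1) * (cum[-1] / n)

    def __len__(self) -> int:
        return len(self.window_skew)


@dataclass
class OriTerCall:
    """Called replication origin and terminus with QC annotations."""

    ori_position: int
    ter_position: int
    qc_pass: bool = False
    qc_score: float = 0.0
    convention_flipped: bool = False
    notes: list[str] = field(default_factory=list)


def gc_skew_profile(sequence: str, window_size: int = 1_000, step: int | None = None) -> SkewProfile:
    """Windowed GC skew of a sequence.

    Windows with no G or C get skew 0.  ``step`` defaults to ``window_size``
    (non-overlapping windows).  Trailing bases that do not fill a window are
    ignored.
    """
    if step is None:
        step = window_size
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    if step > window_size:
        raise ValueError("step must be <= window_size")
    if len(sequence) < window_size:
        raise ValueError("sequence shorter than one window")
    arr = np.frombuffer(sequence.upper().encode(), dtype="S1")
    is_g = (arr == b"G").astype(np.int64)
    is_c = (arr == b"C").astype(np.int64)
    cg = np.concatenate([[0], np.cumsum(is_g)])
    cc = np.concatenate([[0], np.cumsum(is_c)])
    starts = np.arange(0, len(sequence) - window_size + 1, step)
    g = cg[starts + window_size] - cg[starts]
    c = cc[starts + window_size] - cc[starts]
    denom = g + c
    skew = np.zeros(len(starts), dtype=float)
    nz = denom > 0
    skew[nz] = (g[nz] - c[nz]) / denom[nz]
    return SkewProfile(window_size, step, starts, skew, len(sequence))


def locate_ori_ter(profile: SkewProfile, genome_length: int | None = None,
                   coverage: CoverageTrack | np.ndarray | None = None) -> OriTerCall | None:
    """Call ori/ter from the extrema of the detrended cumulative skew.

    Convention: leading strand G-rich, so the cumulative-skew minimum marks
    the origin and the maximum the terminus.  If a coverage track is
    supplied, the convention is checked against the coverage peak (which must
    sit at the origin in a replicating population); when the peak lies nearer
    the skew maximum the assignment is flipped with a logged warning.

    Returns ``None`` (an explicit no-call) when the cumulative skew is
    constant and has no extremum.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    L = genome_length if genome_length is not None else profile.genome_length
    d = profile.detrended_cumulative()
    if np.allclose(d, d[0]):
        return None
    i_min = int(np.argmin(d))
    i_max = int(np.argmax(d))
    ori = int(profile.window_starts[i_min])
    ter = int(profile.window_starts[i_max])
    call = OriTerCall(ori_position=ori, ter_position=ter)
    if coverage is not None:
        depths = coverage.depths if isinstance(coverage, CoverageTrack) else np.asarray(coverage)
        peak = int(np.argmax(depths))
        def circdist(a: int, b: int) -> int:
            fwd = (a - b) % L
            return min(fwd, L - fwd)
        if circdist(peak, ter) < circdist(peak, ori):
            logger.warning("coverage peak at %d is nearer the skew maximum; "
                           "flipping ori/ter convention", peak)
            call.ori_position, call.ter_position = ter, ori
            call.convention_flipped = True
            call.notes.append("ori/ter convention flipped to match coverage peak")
    return call


def _segment_indices(a: int, b: int, n: int) -> np.ndarray:
    """Circular index range a..b inclusive."""
    m = (b - a) % n
    return (a + np.arange(m + 1)) % n


def skew_qc(profile: SkewProfile, ori_ter: OriTerCall, threshold: float = 0.8) -> tuple[bool, float]:
    """Score how sawtooth-like the cumulative skew is, given the ori/ter call.

    The detrended cumulative skew of a correctly assembled chromosome rises
    linearly from ori to ter and falls linearly back.  The score is the
    minimum over the two replichore segments of the coefficient of
    determination of the anchored linear fit (the continuous circular
    sawtooth through the ori/ter extrema), clamped to [0, 1].  Aberrant
    genomes — misassemblies, random-walk-like skew — score low on at least
    one segment.

    Returns ``(qc_pass, qc_score)`` with ``qc_pass = score >= threshold``.
    """
    d = profile.detrended_cumulative()
    n = len(d)
    starts = profile.window_starts
    # map called positions back to window indices
    i_ori = int(np.argmin(np.abs(starts - ori_ter.ori_position)))
    i_ter = int(np.argmin(np.abs(starts - ori_ter.ter_position)))
    if i_ori == i_ter:
        return False, 0.0
    scores = []
    for a, b in ((i_ori, i_ter), (i_ter, i_ori)):
        idx = _segment_indices(a, b, n)
        y = d[idx]
        pred = np.linspace(d[a], d[b], len(idx))
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            return False, 0.0
        r2 = 1.0 - float(np.sum((y - pred) ** 2)) / sst
        scores.append(min(1.0, max(0.0, r2)))
    score = float(min(scores))
    return score >= threshold, score
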