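"""CRISPR array comparison, protospacer search, and variant-array tracking.

CRISPR arrays record a population's phage-exposure history as an ordered
series of spacers between near-identical repeats; because spacers are
acquired unidirectionally at the leader end, shared spacer blocks identify
common ancestry and array differences separate coexisting subpopulations.
This module compares arrays by exact (strand-agnostic) spacer identity with
an order-preserving alignment, searches sequence sets for protospacers
(full-length spacer matches at <= 1 mismatch by default, with hits inside
CRISPR arrays themselves filtered out via repeat proximity), quantifies the
per-sample mixture of two coexisting array variants from reads on their
variant-unique regions, and links genome SNVs to array-variant frequencies
by Pearson correlation with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import reverse_complement
from scipy import stats

from .microdiversity import VariantTrajectory

__all__ = ["CrisprArray", "ProtospacerMatch", "ArrayComparison", "compare_arrays",
           "find_protospacers", "unique_regions", "variant_array_ratio",
           "correlate_snvs"]


def canonical(seq: str) -> str:
    """Strand-agnostic canonical form of a sequence."""
    seq = seq.upper()
    return min(seq, reverse_complement(seq))


@dataclass
class CrisprArray:
    """An ordered repeat/spacer structure.

    ``spacers`` is an ordered list of (spacer_id, sequence); duplicate spacer
    sequences are allowed and tracked by their position in the array.
    """

    array_id: str
    repeat: str
    spacers: list[tuple[str, str]]
    source_genome: str = ""

    def __post_init__(self) -> None:
        if not self.spacers:
            raise ValueError("array must contain at least one spacer")
        if len(self.repeat) < 20:
            raise ValueError("repeat length must be >= 20 bp")

    def __len__(self) -> int:
        return len(self.spacers)

    def spacer_sequences(self) -> list[str]:
        return [s for _, s in self.spacers]

    def locus_sequence(self) -> str:
        """The array as genomic sequence: repeat-spacer-...-spacer-repeat."""
        parts = [self.repeat]
        for _, s in self.spacers:
            parts.append(s)
            parts.append(self.repeat)
        return "".join(parts)


@dataclass(frozen=True)
class ProtospacerMatch:
    """A full-length spacer occurrence in a target sequence."""

    spacer_id: str
    target_id: str
    position: int
    strand: str
    mismatches: int


@dataclass
class ArrayComparison:
    """Shared/unique spacer census plus an order-preserving alignment."""

    shared: list[tuple[int, int]]          # aligned (index_in_a, index_in_b) pairs
    unique_a: list[int]                    # spacer positions unique to array a
    unique_b: list[int]
    duplicates_a: dict[str, list[int]] = field(default_factory=dict)
    duplicates_b: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def _duplicate_positions(seqs: list[str]) -> dict[str, list[int]]:
    by_seq: dict[str, list[int]] = {}
    for i, s in enumerate(seqs):
        by_seq.setdefault(canonical(s), []).append(i)
    return {s: pos for s, pos in by_seq.items() if len(pos) > 1}


def compare_arrays(a: CrisprArray, b: CrisprArray) -> ArrayComparison:
    """Compare two arrays by strand-agnostic exact spacer identity.

    The alignment is the longest common subsequence of spacer identities, so
    it preserves array order; spacers outside the alignment are listed as
    unique per array, and duplicated spacers are reported at every position
    they occupy.
    """
    sa = [canonical(s) for s in a.spacer_sequences()]
    sb = [canonical(s) for s in b.spacer_sequences()]
    n, m = len(sa), len(sb)
    # longest common subsequence
    dp = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            dp[i, j] = (dp[i + 1, j + 1] + 1 if sa[i] == sb[j]
                        else max(dp[i + 1, j], dp[i, j + 1]))
    pairs = []
    i = j = 0
    while i < n and j < m:
        if sa[i] == sb[j]:
            pairs.append((i, j))
            i += 1
            j += 1
        elif dp[i + 1, j] >= dp[i, j + 1]:
            i += 1
        else:
            j += 1
    in_a = {p for p, _ in pairs}
    in_b = {q for _, q in pairs}
    return ArrayComparison(
        shared=pairs,
        unique_a=[i for i in range(n) if i not in in_a],
        unique_b=[j for j in range(m) if j not in in_b],
        duplicates_a=_duplicate_positions(a.spacer_sequences()),
        duplicates_b=_duplicate_positions(b.spacer_sequences()),
    )


# ---------------------------------------------------------------------------
# protospacer search
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def scan_mismatch(pattern: str, text: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All full-length occurrences of ``pattern`` in ``text`` with at most
    ``max_mismatch`` mismatches, as (position, mismatches).

    Pigeonhole-seeded: the pattern is split into ``max_mismatch + 1`` chunks,
    at least one of which must match exactly; each exact chunk hit nominates
    a candidate window that is then verified by Hamming distance.
    """
    m, n = len(pattern), len(text)
    if m == 0 or m > n:
        return []
    k = max_mismatch + 1
    bounds = np.linspace(0, m, k + 1).astype(int)
    candidates: set[int] = set()
    for c in range(k):
        chunk = pattern[bounds[c]:bounds[c + 1]]
        start = text.find(chunk)
        while start != -1:
            pos = start - bounds[c]
            if 0 <= pos <= n - m:
                candidates.add(pos)
            start = text.find(chunk, start + 1)
    out = []
    for pos in sorted(candidates):
        d = _hamming(pattern, text[pos:pos + m])
        if d <= max_mismatch:
            out.append((pos, d))
    return out


def _strand_hits(pattern: str, text: str, max_mismatch: int) -> list[tuple[int, str, int]]:
    """(position, strand, mismatches) hits of pattern on both strands."""
    hits = [(p, "+", d) for p, d in scan_mismatch(pattern, text, max_mismatch)]
    rc = reverse_complement(pattern)
    if rc != pattern:
        hits += [(p, "-", d) for p, d in scan_mismatch(rc, text, max_mismatch)]
    return hits


def find_protospacers(spacers: Sequence[tuple[str, str]],
                      targets: Sequence[tuple[str, str]],
                      repeats: Sequence[str] = (),
                      max_mismatch: int = 1,
                      exclude_targets: Iterable[str] = (),
                      repeat_exclusion_margin: int | None = None) -> list[ProtospacerMatch]:
    """Search target sequences for full-length spacer matches.

    Every occurrence of each spacer (either strand) with at most
    ``max_mismatch`` mismatches is reported, except hits that sit within
    ``repeat_exclusion_margin`` bp of a full-length match to a supplied
    CRISPR repeat — such hits are the CRISPR array itself, not a protospacer.
    The margin defaults to repeat length + spacer length, which covers a
    spacer flanked by its repeats.  Targets listed in ``exclude_targets``
    (e.g. flagged as CRISPR-containing) are skipped wholesale.
    """
    for _, s in spacers:
        if len(s) < 20:
            raise ValueError("spacer lengths must be >= 20 bp")
    excluded = set(exclude_targets)
    matches: list[ProtospacerMatch] = []
    for tid, tseq in targets:
        if tid in excluded:
            continue
        tseq = tseq.upper()
        repeat_positions: list[tuple[int, int]] = []  # (start, end) of repeat hits
        for rep in repeats:
            for p, _, _ in _strand_hits(rep.upper(), tseq, max_mismatch):
                repeat_positions.append((p, p + len(rep)))
        for sid, sseq in spacers:
            sseq = sseq.upper()
            margin = (repeat_exclusion_margin if repeat_exclusion_margin is not None
                      else len(sseq) + (max(len(r) for r in repeats) if repeats else 0))
            for pos, strand, mm in _strand_hits(sseq, tseq, max_mismatch):
                lo, hi = pos - margin, pos + len(sseq) + margin
                if any(rs < hi and re > lo for rs, re in repeat_positions):
                    continue
                matches.append(ProtospacerMatch(sid, tid, pos, strand, mm))
    return matches


# ---------------------------------------------------------------------------
# variant arrays
# ---------------------------------------------------------------------------

def unique_regions(locus_a: str, locus_b: str, min_length: int = 30) -> list[tuple[int, int]]:
    """Maximal intervals of ``locus_a`` absent from ``locus_b``.

    A position belongs to a unique region when the ``min_length`` window
    starting there does not occur in ``locus_b`` on either strand;
    consecutive such positions merge into intervals.  These are the regions
    reads can map to unambiguously when two array variants coexist.
    """
    a = locus_a.upper()
    b = locus_b.upper()
    rc_b = reverse_complement(b)
    n = len(a)
    if n < min_length:
        return []
    flags = np.zeros(n - min_length + 1, dtype=bool)
    for i in range(n - min_length + 1):
        w = a[i:i + min_length]
        flags[i] = w not in b and w not in rc_b
    out = []
    i = 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j + 1 < len(flags) and flags[j + 1]:
                j += 1
            out.append((i, j + min_length))
            i = j + 1
        else:
            i += 1
    return out


def variant_array_ratio(reads_a: np.ndarray | Sequence[float],
                        reads_b: np.ndarray | Sequence[float],
                        length_a: float | None = None,
                        length_b: float | None = None,
                        normalize: bool = True) -> np.ndarray:
    """Per-sample frequency of array variant A from unique-region read counts.

    ``freq(A) = rate_A / (rate_A + rate_B)`` where rates are raw counts, or
    counts per unique-region base when ``normalize`` is set and lengths are
    supplied (unbiased when the two variants' unique regions differ in
    length).  Samples with zero reads on both regions get NaN (no-call).
    """
    ra = np.asarray(reads_a, dtype=float)
    rb = np.asarray(reads_b, dtype=float)
    if ra.shape != rb.shape:
        raise ValueError("read-count vectors must align")
    if np.any(ra < 0) or np.any(rb < 0):
        raise ValueError("read counts must be >= 0")
    if normalize and length_a and length_b:
        if length_a <= 0 or length_b <= 0:
            raise ValueError("unique-region lengths must be positive")
        ra = ra / length_a
        rb = rb / length_b
    total = ra + rb
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, ra / np.maximum(total, 1e-300), np.nan)
    return freq


def correlate_snvs(snv_trajectories: Sequence[VariantTrajectory],
                   variant_series: Mapping[str, np.ndarray | Sequence[float]],
                   alpha: float = 0.01) -> list[tuple[int, str, float, float]]:
    """Link genome SNVs to CRISPR array-variant frequency series.

    Computes the Pearson correlation of every SNV trajectory against every
    array-variant frequency series over shared samples, and reports
    ``(position, variant_name, r, p)`` for pairs significant after
    Bonferroni correction over all SNV x variant tests.  Pairs where either
    series is constant (correlation undefined) are skipped as no-calls.
    """
    series = {k: np.asarray(v, dtype=float) for k, v in variant_series.items()}
    n_tests = len(snv_trajectories) * len(series)
    if n_tests == 0:
        return []
    links = []
    for traj in snv_trajectories:
        f = np.asarray(traj.freqs, dtype=float)
        for name, v in series.items():
            if len(v) != len(f):
                raise ValueError("series and trajectory sample counts differ")
            ok = ~np.isnan(f) & ~np.isnan(v)
            if ok.sum() < 3:
                continue
            if np.std(f[ok]) == 0 or np.std(v[ok]) == 0:
                continue  # correlation undefined: no-call
            r, p = stats.pearsonr(f[ok], v[ok])
            if p < alpha / n_tests:
                links.append((traj.position, name, float(r), float(p)))
    return links
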