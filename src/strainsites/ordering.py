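"""Reference-guided ordering and orienting of draft-genome contigs.

Draft assemblies of bacterial chromosomes arrive as unordered, arbitrarily
stranded contigs.  To compute replication-linked statistics (GC skew, the
origin-to-terminus coverage gradient) the contigs must first be placed on the
coordinate system of a closely related complete reference.  This module does
that with exact-match seeding: maximal exact matches of length >= k between
contig and (doubled, to handle the circular wrap) reference are chained into
the highest-weight collinear chain per contig and strand; contigs whose chain
covers less than 20% of their length are discarded; the rest are oriented by
their best strand, sorted by their median chained reference position, and
concatenated into an ordered, oriented "core genome" used purely as a
coordinate scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import reverse_complement

from .containers import CoverageTrack

__all__ = ["Anchor", "ContigAnchoring", "OrientedAssembly",
           "anchor_contigs", "order_and_orient", "liftover_coverage"]

#: contigs below this fraction of chained anchor coverage are discarded
MIN_ALIGNMENT_COVERAGE = 0.20


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match between a contig and the reference.

    Coordinates are 0-based half-open.  ``contig_start/end`` are on the
    forward strand of the contig as supplied; for strand '-', the *reverse
    complement* of that contig interval matches the reference interval.
    ``ref_start`` may exceed the reference length when the match wraps the
    circular origin (coordinates on the doubled reference).
    """

    contig_id: str
    contig_start: int
    contig_end: int
    ref_start: int
    ref_end: int
    strand: str

    @property
    def length(self) -> int:
        return self.contig_end - self.contig_start

    def __post_init__(self) -> None:
        if self.contig_end <= self.contig_start or self.ref_end <= self.ref_start:
            raise ValueError("anchor intervals must be non-empty")
        if (self.contig_end - self.contig_start) != (self.ref_end - self.ref_start):
            raise ValueError("anchor intervals must have equal length")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class ContigAnchoring:
    """Best collinear chain for one contig against the reference."""

    contig_id: str
    contig_length: int
    strand: str
    chain: list[Anchor]
    coverage: float          # chained anchor bases / contig length
    placement: float         # median reference position of the chain, mod L


@dataclass
class OrientedAssembly:
    """Contigs placed, oriented and concatenated into a core genome."""

    placements: list[tuple[str, str, int]]   # (contig_id, orientation, core_offset)
    contig_lengths: dict[str, int]
    core_length: int
    discarded_contigs: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    def offset_of(self, contig_id: str) -> int:
        for cid, _, off in self.placements:
            if cid == contig_id:
                return off
        raise KeyError(contig_id)


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

def _kmer_index(reference: str, k: int) -> dict[bytes, list[int]]:
    """Index of k-mer start positions in the doubled reference, keyed on the
    first copy only (start < L) so each circular locus appears once."""
    L = len(reference)
    doubled = (reference + reference).encode()
    index: dict[bytes, list[int]] = {}
    for i in range(L):
        index.setdefault(doubled[i:i + k], []).append(i)
    return index


def _maximal_matches(query: bytes, doubled_ref: bytes, index: dict[bytes, list[int]],
                     k: int, ref_len: int) -> list[tuple[int, int, int]]:
    """Maximal exact matches >= k as (query_start, ref_start, length).

    Hits are grouped by diagonal; consecutive k-mer hits on one diagonal merge
    into a single maximal match.
    """
    by_diag: dict[int, list[int]] = {}
    n = len(query)
    for i in range(n - k + 1):
        for p in index.get(query[i:i + k], ()):  # p < ref_len by construction
            by_diag.setdefault(p - i, []).append(i)
    out = []
    for diag, starts in by_diag.items():
        starts.sort()
        run_start = starts[0]
        prev = starts[0]
        for s in starts[1:] + [None]:
            if s is not None and s == prev + 1:
                prev = s
                continue
            length = prev - run_start + k
            out.append((run_start, run_start + diag, length))
            if s is not None:
                run_start = prev = s
    return out


def _best_chain(matches: list[tuple[int, int, int]]) -> tuple[list[tuple[int, int, int]], int]:
    """Highest-weight collinear chain (weight = summed non-overlapping bases).

    Matches must advance in both query and reference coordinate; overlapping
    anchors (e.g. the k-1 bases shared where a match crosses the circular
    origin) are allowed and their overlap subtracted from the chain weight.
    Classic O(n^2) weighted longest-increasing-subsequence chaining.
    """
    if not matches:
        return [], 0
    ms = sorted(matches, key=lambda m: (m[0], m[1]))
    n = len(ms)
    best = [m[2] for m in ms]
    prev = [-1] * n
    for j in range(n):
        qj, rj, lj = ms[j]
        for i in range(j):
            qi, ri, li = ms[i]
            if qj > qi and rj > ri and qj + lj > qi + li and rj + lj > ri + li:
                overlap = max(0, qi + li - qj, ri + li - rj)
                if overlap >= lj:
                    continue
                cand = best[i] + lj - overlap
                if cand > best[j]:
                    best[j] = cand
                    prev[j] = i
    j = int(np.argmax(best))
    weight = best[j]
    chain = []
    while j >= 0:
        chain.append(ms[j])
        j = prev[j]
    chain.reverse()
    return chain, weight


def anchor_contigs(contigs: list[tuple[str, str]], reference: str,
                   k: int = 31) -> dict[str, ContigAnchoring]:
    """Anchor each contig to a circular reference by maximal exact matches.

    Both strands are tried; the reported chain is the higher-weight of the
    two.  Alignment coverage is chained anchor bases over contig length.
    Returns a mapping contig_id -> :class:`ContigAnchoring` (contigs with no
    match get coverage 0 and an empty chain).
    """
    if k < 15:
        raise ValueError("k must be >= 15")
    L = len(reference)
    if L < k:
        raise ValueError("reference shorter than k")
    reference = reference.upper()
    index = _kmer_index(reference, k)
    doubled = (reference + reference).encode()
    results: dict[str, ContigAnchoring] = {}
    for cid, seq in contigs:
        seq = seq.upper()
        best_strand, best_chain_raw, best_weight = "+", [], -1
        for strand in "+-":
            q = seq if strand == "+" else reverse_complement(seq)
            matches = _maximal_matches(q.encode(), doubled, index, k, L) if len(q) >= k else []
            # each circular locus also exists one wrap later; adding the +L
            # copies lets chains cross the reference origin
            matches = matches + [(qs, rs + L, ln) for qs, rs, ln in matches]
            chain, weight = _best_chain(matches)
            if weight > best_weight:
                best_strand, best_chain_raw, best_weight = strand, chain, weight
        anchors = []
        n = len(seq)
        for qs, rs, ln in best_chain_raw:
            if best_strand == "+":
                a = Anchor(cid, qs, qs + ln, rs, rs + ln, "+")
            else:  # map reverse-complement coordinates back to the forward contig
                a = Anchor(cid, n - (qs + ln), n - qs, rs, rs + ln, "-")
            anchors.append(a)
        weight = max(best_weight, 0)
        coverage = weight / n if n else 0.0
        if anchors:
            mids = np.concatenate([np.array([(a.ref_start + a.ref_end) / 2.0]).repeat(a.length)
                                   for a in anchors])
            placement = float(np.median(mids)) % L
        else:
            placement = float("nan")
        results[cid] = ContigAnchoring(cid, n, best_strand, anchors, coverage, placement)
    return results


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------

def order_and_orient(anchorings: dict[str, ContigAnchoring],
                     contigs: list[tuple[str, str]],
                     reference: str,
                     min_coverage: float = MIN_ALIGNMENT_COVERAGE) -> OrientedAssembly:
    """Order and orient contigs by their chained reference placements.

    Contigs with alignment coverage below ``min_coverage`` (default 20%) are
    discarded with a reason.  Retained contigs are oriented by the strand of
    their best chain, sorted by placement coordinate (ties broken by length,
    longer first, then contig id) and concatenated without gap padding into a
    core-genome coordinate scaffold.
    """
    lengths = {cid: len(seq) for cid, seq in contigs}
    discarded: list[tuple[str, str]] = []
    retained: list[ContigAnchoring] = []
    for cid, _ in contigs:
        if cid not in anchorings:
            discarded.append((cid, "no anchors"))
            continue
        anc = anchorings[cid]
        if anc.coverage < min_coverage:
            discarded.append((cid, f"alignment coverage < {min_coverage:.0%}"))
        else:
            retained.append(anc)
    if not retained:
        raise ValueError("zero contigs retained after alignment-coverage filtering")
    retained.sort(key=lambda a: (a.placement, -a.contig_length, a.contig_id))
    placements = []
    offset = 0
    for anc in retained:
        placements.append((anc.contig_id, anc.strand, offset))
        offset += anc.contig_length
    return OrientedAssembly(placements, lengths, offset, discarded)


def core_genome_sequence(assembly: OrientedAssembly, contigs: list[tuple[str, str]]) -> str:
    """Concatenated oriented sequence of the retained contigs."""
    seqs = dict(contigs)
    parts = []
    for cid, strand, _ in assembly.placements:
        s = seqs[cid]
        parts.append(reverse_complement(s) if strand == "-" else s)
    return "".join(parts)


def liftover_coverage(tracks: dict[str, CoverageTrack | np.ndarray],
                      assembly: OrientedAssembly) -> CoverageTrack:
    """Lift per-contig coverage tracks onto the core-genome coordinates.

    Tracks of '-'-strand contigs are reversed.  Positions of discarded
    contigs are simply absent from the core track (the core genome only
    contains retained contigs).
    """
    core = np.zeros(assembly.core_length, dtype=float)
    for cid, strand, off in assembly.placements:
        t = tracks.get(cid)
        if t is None:
            raise ValueError(f"missing coverage track for retained contig {cid}")
        depths = t.depths if isinstance(t, CoverageTrack) else np.asarray(t, dtype=float)
        n = assembly.contig_lengths[cid]
        if len(depths) != n:
            raise ValueError(f"track length {len(depths)} != contig length {n} for {cid}")
        core[off:off + n] = depths[::-1] if strand == "-" else depths
    return CoverageTrack(core, genome_id="core", circular=True)
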