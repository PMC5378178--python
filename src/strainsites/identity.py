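"""Consensus-ANI strain identity, colonist calls and shared populations.

Whether the "same" bacterial strain occupies two body sites is decided here
without re-assembly: reads from each sample are summarised as a pileup
against a reference genome, positions near scaffold ends, in conserved
regions (rRNA/tRNA) or of insufficient coverage are masked, and the
consensus average nucleotide identity is

    consensus ANI = 1 - (# variant positions) / (unmasked genome length)

where a variant position is an unmasked position at which at least 80% of
reads conflict with the reference.  Populations with consensus ANI above
99.9% are treated as identical; combining those identity calls with simple
abundance rules (>= 1% of a sample's non-human reads defines a body-site
colonist; 99% breadth defines phage/plasmid carriage) yields the census of
populations shared across body sites and infants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import PileupMatrix

__all__ = ["MaskedRegions", "ConsensusANIResult", "mask_genome", "consensus_ani",
           "same_population", "call_colonists", "detection_threshold", "carriage",
           "shared_populations", "PopulationCensus"]


@dataclass
class MaskedRegions:
    """Masked intervals (0-based half-open) on a concatenated genome.

    ``intervals`` carry a reason per interval; the effective mask is their
    union.  ``total_length`` is the length of the coordinate system.
    """

    total_length: int
    intervals: list[tuple[int, int, str]] = field(default_factory=list)

    def add(self, start: int, end: int, reason: str) -> None:
        if start < 0 or end > self.total_length:
            raise ValueError("interval outside genome bounds")
        if end > start:
            self.intervals.append((int(start), int(end), reason))

    def mask_array(self) -> np.ndarray:
        """Boolean array, True where masked."""
        m = np.zeros(self.total_length, dtype=bool)
        for s, e, _ in self.intervals:
            m[s:e] = True
        return m

    @property
    def unmasked_length(self) -> int:
        return int(self.total_length - self.mask_array().sum())

    def reasons_at(self, position: int) -> set[str]:
        return {r for s, e, r in self.intervals if s <= position < e}


@dataclass
class ConsensusANIResult:
    """Consensus ANI of one sample's read population against a reference."""

    variant_position_count: int
    unmasked_length: int
    consensus_ani: float
    breadth: float
    mean_depth: float


def mask_genome(scaffold_lengths: Sequence[int],
                conserved: pd.DataFrame | Iterable[tuple[int, int]] | None = None,
                pileup: PileupMatrix | None = None,
                end_buffer: int = 100,
                min_depth: int = 5) -> MaskedRegions:
    """Build the mask for consensus-ANI calculation.

    Masks the first and last ``end_buffer`` bp of every scaffold (scaffolds
    are given as an ordered list of lengths on a concatenated coordinate
    system), every conserved interval (a BED-like frame with ``start``/``end``
    columns, or raw (start, end) pairs, in concatenated coordinates), and —
    when a single-sample pileup is supplied — every position with depth below
    ``min_depth``.  Overlapping intervals simply union.
    """
    if end_buffer < 0:
        raise ValueError("end_buffer must be >= 0")
    total = int(sum(scaffold_lengths))
    masked = MaskedRegions(total)
    offset = 0
    for ln in scaffold_lengths:
        b = min(end_buffer, ln)
        masked.add(offset, offset + b, "scaffold_end")
        masked.add(offset + max(ln - b, b), offset + ln, "scaffold_end")
        offset += ln
    if conserved is not None:
        rows = (conserved[["start", "end"]].itertuples(index=False)
                if isinstance(conserved, pd.DataFrame) else conserved)
        for start, end in rows:
            if start < 0 or end > total:
                raise ValueError("conserved region outside scaffold bounds")
            masked.add(int(start), int(end), "conserved")
    if pileup is not None:
        if pileup.n_samples != 1:
            raise ValueError("depth masking expects a single-sample pileup")
        depth = pileup.depth()[0]
        low = depth < min_depth
        # turn the boolean run-length segments into intervals
        edges = np.flatnonzero(np.diff(np.concatenate([[0], low.view(np.int8), [0]])))
        for s, e in edges.reshape(-1, 2):
            masked.add(int(s), int(e), "low_coverage")
    return masked


def consensus_ani(pileup: PileupMatrix, masked: MaskedRegions,
                  conflict_threshold: float = 0.80) -> ConsensusANIResult:
    """Consensus ANI of a single-sample pileup against its reference.

    A variant position is an unmasked position where the fraction of reads
    conflicting with the reference — ``(depth - ref_count) / depth`` over the
    *total* depth — is at least ``conflict_threshold``.  Breadth is the
    fraction of all genome positions with depth >= 1.
    """
    if pileup.n_samples != 1:
        raise ValueError("consensus_ani expects a single-sample pileup")
    if pileup.length != masked.total_length:
        raise ValueError("pileup and mask lengths differ")
    unmasked = ~masked.mask_array()
    n_unmasked = int(unmasked.sum())
    if n_unmasked == 0:
        raise ValueError("unmasked genome length is zero")
    depth = pileup.depth()[0]
    refc = pileup.ref_counts()[0]
    covered = depth > 0
    conflict = np.zeros(pileup.length)
    conflict[covered] = (depth[covered] - refc[covered]) / depth[covered]
    variants = int(np.count_nonzero(unmasked & covered & (conflict >= conflict_threshold)))
    ani = 1.0 - variants / n_unmasked
    return ConsensusANIResult(
        variant_position_count=variants,
        unmasked_length=n_unmasked,
        consensus_ani=ani,
        breadth=float(covered.mean()),
        mean_depth=float(depth.mean()),
    )


def same_population(ani_result: ConsensusANIResult | float, threshold: float = 0.999) -> bool:
    """True iff consensus ANI strictly exceeds the identity threshold (99.9%)."""
    ani = ani_result.consensus_ani if isinstance(ani_result, ConsensusANIResult) else float(ani_result)
    return ani > threshold


def call_colonists(table: pd.DataFrame, threshold_percent: float = 1.0) -> pd.DataFrame:
    """Flag each (genome, body site) pair as colonised or not.

    A genome is a colonist of a body site if it accounts for at least
    ``threshold_percent`` of the non-human reads in *any* sample from that
    site.  ``table`` needs columns ``genome_id``, ``body_site``,
    ``percent_of_nonhuman_reads``.  Returns a frame indexed by (genome_id,
    body_site) with a boolean ``colonist`` column.
    """
    if table.empty:
        raise ValueError("empty abundance table")
    flags = (table.groupby(["genome_id", "body_site"])["percent_of_nonhuman_reads"]
             .max() >= threshold_percent)
    return flags.rename("colonist").to_frame()


def detection_threshold(table: pd.DataFrame, genome_length: int) -> tuple[float, pd.DataFrame]:
    """Depth-normalised presence cutoff and per-sample presence calls.

    The cutoff is the read percentage corresponding to 0.1x coverage of the
    genome in the most shallowly sequenced sample:

        cutoff% = 100 * (0.1 * genome_length / read_length) / min(total_sample_reads)

    All samples share this single cutoff, so presence calls are comparable
    across sequencing depths.  Presence is inclusive (percent >= cutoff).
    Returns ``(cutoff_percent, calls)`` where calls adds a boolean
    ``present`` column to the table.
    """
    for col in ("total_sample_reads", "read_length"):
        if col not in table.columns or table[col].isna().any():
            raise ValueError(f"{col} must be known for every sample")
    read_length = float(table["read_length"].iloc[0])
    shallowest = float(table["total_sample_reads"].min())
    reads_needed = 0.1 * genome_length / read_length
    cutoff = 100.0 * reads_needed / shallowest
    calls = table.copy()
    calls["present"] = calls["percent_of_nonhuman_reads"] >= cutoff
    return cutoff, calls


def carriage(breadth: float, threshold: float = 0.99) -> bool:
    """Phage/plasmid carriage: at least 99% of positions covered by a read."""
    if not 0.0 <= breadth <= 1.0:
        raise ValueError("breadth must be in [0, 1]")
    return breadth >= threshold


@dataclass
class PopulationCensus:
    """Populations grouped by identity, with multi-site and cross-infant counts."""

    populations: list[set[str]]
    multi_site: list[set[str]]
    cross_infant: list[set[str]]

    @property
    def n_multi_site(self) -> int:
        return len(self.multi_site)

    @property
    def n_cross_infant(self) -> int:
        return len(self.cross_infant)


def shared_populations(colonists: pd.DataFrame,
                       identical_pairs: Iterable[tuple[str, str]],
                       infant_of: Mapping[str, str]) -> PopulationCensus:
    """Group genomes into populations and census their habitat range.

    Populations are connected components of the "same population" relation
    (>99.9% consensus ANI calls).  A population is *multi-site* if it is
    flagged colonist of at least two body sites of the same infant;
    populations spanning more than one infant are reported separately.

    ``colonists`` is the output of :func:`call_colonists`; ``infant_of`` maps
    genome_id to infant id.
    """
    g = nx.Graph()
    g.add_nodes_from(infant_of.keys())
    g.add_nodes_from(colonists.index.get_level_values("genome_id"))
    g.add_edges_from(identical_pairs)
    populations = [set(c) for c in nx.connected_components(g)]
    flags = colonists["colonist"]
    multi, cross = [], []
    for pop in populations:
        sites_by_infant: dict[str, set[str]] = {}
        for gid in pop:
            infant = infant_of.get(gid, "?")
            for (g_id, site), flag in flags.items():
                if g_id == gid and flag:
                    sites_by_infant.setdefault(infant, set()).add(site)
        if any(len(sites) >= 2 for sites in sites_by_infant.values()):
            multi.append(pop)
        if len({infant_of.get(gid, "?") for gid in pop}) > 1:
            cross.append(pop)
    return PopulationCensus(populations, multi, cross)
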