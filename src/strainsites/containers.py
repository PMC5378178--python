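"""Core in-memory containers shared across the pipeline.

Two abstractions stand in for raw read mapping throughout the package: a
per-position depth vector over a (usually circular) genome coordinate system
(:class:`CoverageTrack`), and a per-position, per-sample tally of A/C/G/T read
counts against a reference (:class:`PileupMatrix`).  Both are thin wrappers
over numpy arrays; all heavy computation happens on the arrays directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed base order used for all pileup count matrices.
BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}


def base_indices(bases: str | np.ndarray) -> np.ndarray:
    """Map a sequence of A/C/G/T characters to indices into :data:`BASE_ORDER`.

    Non-ACGT characters (e.g. N) map to -1.
    """
    arr = np.frombuffer(str(bases).upper().encode(), dtype="S1") if isinstance(bases, str) else np.asarray(bases, dtype="S1")
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[arr.view(np.uint8)].astype(np.int64)


@dataclass
class CoverageTrack:
    """Per-position read depth over one genome or contig.

    Parameters
    ----------
    depths
        1-D array of non-negative depths, one entry per genome position.
    genome_id
        Identifier of the coordinate system the track lives on.
    circular
        Whether position 0 follows the last position (true for complete
        bacterial chromosomes and for oriented core genomes).
    """

    depths: np.ndarray
    genome_id: str = "genome"
    circular: bool = True

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.ndim != 1:
            raise ValueError("coverage track must be one-dimensional")
        if self.depths.size == 0:
            raise ValueError("empty coverage track")
        if np.any(self.depths < 0):
            raise ValueError("negative depth")

    def __len__(self) -> int:
        return int(self.depths.size)

    @property
    def median(self) -> float:
        return float(np.median(self.depths))


@dataclass
class PileupMatrix:
    """Per-position A/C/G/T read counts for one or more samples.

    ``counts`` has shape ``(n_samples, genome_length, 4)`` with the last axis
    ordered as :data:`BASE_ORDER`.  ``ref`` holds the reference base index per
    position (-1 for ambiguous bases, which never count as matches).
    """

    counts: np.ndarray
    ref: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    genome_id: str = "genome"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim == 2:  # single sample convenience
            self.counts = self.counts[None, :, :]
        if self.counts.ndim != 3 or self.counts.shape[2] != 4:
            raise ValueError("counts must have shape (n_samples, length, 4)")
        if isinstance(self.ref, str):
            self.ref = base_indices(self.ref)
        self.ref = np.asarray(self.ref, dtype=np.int64)
        if self.ref.shape[0] != self.counts.shape[1]:
            raise ValueError("reference length does not match pileup length")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(self.counts.shape[0])]
        if len(self.sample_ids) != self.counts.shape[0]:
            raise ValueError("sample_ids do not match number of samples")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def depth(self) -> np.ndarray:
        """Total read depth per sample and position, shape (n_samples, length)."""
        return self.counts.sum(axis=2)

    def ref_counts(self) -> np.ndarray:
        """Reads agreeing with the reference, shape (n_samples, length)."""
        idx = np.clip(self.ref, 0, 3)
        out = np.take_along_axis(self.counts, idx[None, :, None], axis=2)[:, :, 0]
        out = out.copy()
        out[:, self.ref < 0] = 0
        return out

    def sample(self, sample_id: str) -> "PileupMatrix":
        """Extract a single-sample pileup."""
        i = self.sample_ids.index(sample_id)
        return PileupMatrix(self.counts[i], self.ref, [sample_id], self.genome_id)
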