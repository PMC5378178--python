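"""SNV frequency trajectories, filtering, cohort clustering and site tests.

Within a single bacterial population, low-frequency single-nucleotide
variants that rise and fall *together* across a longitudinal sample series
mark subpopulations descending from distinct founding cells.  The pipeline
here is: call candidate variant sites from multi-sample pileups, assemble
each site's alternate-allele frequency trajectory, filter trajectories by
coverage / frequency / conserved-region / autocorrelation rules, cluster the
survivors into cohorts by hierarchical clustering of their frequency
vectors, and test individual sites for body-site differentiation with
Fisher's exact test under Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .containers import BASE_ORDER, PileupMatrix
from .identity import MaskedRegions

__all__ = ["VariantTrajectory", "Cohort", "call_variant_trajectories",
           "filter_variants", "cluster_cohorts", "site_differential"]


@dataclass
class VariantTrajectory:
    """One polymorphic site's alt-allele frequency across ordered samples.

    Frequencies are defined only where depth > 0 (NaN elsewhere).  Samples
    are assumed chronologically ordered.
    """

    position: int
    ref_base: str
    alt_base: str
    freqs: np.ndarray
    depths: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.depths = np.asarray(self.depths)
        if self.freqs.shape != self.depths.shape:
            raise ValueError("freqs and depths must align")

    def alt_counts(self) -> np.ndarray:
        """Recover integer alt read counts (freq * depth)."""
        counts = np.where(self.depths > 0, np.nan_to_num(self.freqs) * self.depths, 0)
        return np.rint(counts).astype(np.int64)


@dataclass
class Cohort:
    """A set of variants with a common frequency trajectory."""

    cohort_id: int
    members: list[VariantTrajectory]

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1

    @property
    def positions(self) -> list[int]:
        return [t.position for t in self.members]

    def mean_trajectory(self) -> np.ndarray:
        return np.vstack([t.freqs for t in self.members]).mean(axis=0)


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_variant_trajectories(pileup: PileupMatrix,
                              min_call_depth: int = 3,
                              min_call_freq: float = 0.2) -> list[VariantTrajectory]:
    """Call candidate polymorphic sites and assemble their trajectories.

    A position is a candidate if, in at least one sample with depth >=
    ``min_call_depth``, the most abundant non-reference allele reaches
    frequency >= ``min_call_freq``.  For each candidate the alternate allele
    is fixed to the globally most abundant non-reference base (summed over
    samples), and its frequency/depth trajectory is reported for all samples
    in pileup order.
    """
    if pileup.n_samples == 0:
        raise ValueError("no samples in pileup")
    depth = pileup.depth()                      # (S, L)
    counts = pileup.counts
    ref = pileup.ref
    L = pileup.length
    nonref = counts.copy()
    np.put_along_axis(nonref, np.clip(ref, 0, 3)[None, :, None].repeat(pileup.n_samples, 0), 0, axis=2)
    top_alt = nonref.max(axis=2)                # (S, L) most abundant non-ref allele count
    with np.errstate(invalid="ignore", divide="ignore"):
        top_freq = np.where(depth > 0, top_alt / depth, 0.0)
    candidate = ((depth >= min_call_depth) & (top_freq >= min_call_freq)).any(axis=0)
    positions = np.flatnonzero(candidate)
    out: list[VariantTrajectory] = []
    global_alt = nonref.sum(axis=0).argmax(axis=1)   # (L,)
    for pos in positions:
        alt_i = int(global_alt[pos])
        d = depth[:, pos]
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(d > 0, counts[:, pos, alt_i] / np.maximum(d, 1), np.nan)
        ref_i = int(ref[pos])
        out.append(VariantTrajectory(
            position=int(pos),
            ref_base=BASE_ORDER[ref_i] if 0 <= ref_i < 4 else "N",
            alt_base=BASE_ORDER[alt_i],
            freqs=f,
            depths=d,
            sample_ids=list(pileup.sample_ids)))
    return out


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def lag1_autocorrelation(freqs: np.ndarray) -> float:
    """Lag-1 autocorrelation of a frequency vector.

    A constant vector has no noise to de-correlate and is scored 1.0 (a
    perfectly self-consistent trajectory) rather than NaN.
    """
    f = np.asarray(freqs, dtype=float)
    if len(f) < 2:
        return 1.0
    a, b = f[:-1], f[1:]
    if np.std(a) == 0 or np.std(b) == 0:
        return 1.0 if np.std(f) == 0 else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def filter_variants(trajectories: list[VariantTrajectory],
                    conserved: MaskedRegions | None = None,
                    min_depth_all: int = 10,
                    min_freq: float = 0.2,
                    min_samples_at_freq: int = 2,
                    autocorr_min: float = 0.0) -> list[VariantTrajectory]:
    """Apply the four retention rules to candidate trajectories.

    A trajectory is retained iff (1) depth >= ``min_depth_all`` in *every*
    sample, (2) frequency exceeds ``min_freq`` in at least
    ``min_samples_at_freq`` samples, (3) its position is not inside a
    conserved region, and (4) its lag-1 autocorrelation over the
    chronologically ordered samples is >= ``autocorr_min``.
    """
    mask = conserved.mask_array() if conserved is not None else None
    kept = []
    for t in trajectories:
        if np.any(t.depths < min_depth_all):
            continue
        if np.count_nonzero(np.nan_to_num(t.freqs) > min_freq) < min_samples_at_freq:
            continue
        if mask is not None and t.position < len(mask) and mask[t.position]:
            continue
        if lag1_autocorrelation(t.freqs) < autocorr_min:
            continue
        kept.append(t)
    return kept


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_cohorts(trajectories: list[VariantTrajectory],
                    linkage_method: str = "average",
                    distance_metric: str = "correlation",
                    cutoff: float = 0.275) -> list[Cohort]:
    """Group trajectories into cohorts by hierarchical clustering.

    Frequency vectors are clustered agglomeratively (default: average
    linkage on correlation distance, 1 - Pearson r) and the dendrogram is
    cut at ``cutoff``; each flat cluster is a cohort, one-member cohorts are
    singletons.  All trajectories must share the same sample set with no
    undefined frequencies.
    """
    if not trajectories:
        raise ValueError("no trajectories to cluster")
    sample_sets = {tuple(t.sample_ids) for t in trajectories}
    if len(sample_sets) != 1:
        raise ValueError("trajectories are defined over mismatched sample sets")
    X = np.vstack([t.freqs for t in trajectories])
    if np.isnan(X).any():
        raise ValueError("trajectories contain undefined frequencies; filter first")
    if len(trajectories) == 1:
        return [Cohort(1, list(trajectories))]
    d = pdist(X, metric=distance_metric)
    # correlation distance is undefined for constant vectors; treat a
    # constant trajectory as uncorrelated with everything (distance 1)
    d = np.nan_to_num(d, nan=1.0)
    Z = linkage(d, method=linkage_method)
    labels = fcluster(Z, t=cutoff, criterion="distance")
    cohorts: dict[int, list[VariantTrajectory]] = {}
    for lab, traj in zip(labels, trajectories):
        cohorts.setdefault(int(lab), []).append(traj)
    return [Cohort(lab, members) for lab, members in sorted(cohorts.items())]


# ---------------------------------------------------------------------------
# between-site tests
# ---------------------------------------------------------------------------

def site_differential(trajectory: VariantTrajectory, sample_a: str, sample_b: str,
                      alpha: float = 0.01, n_tests: int = 1) -> tuple[bool, float]:
    """Fisher's exact test of allele counts between two samples/body sites.

    Builds the 2x2 table of (alt, non-alt) read counts in the two samples
    and reports the two-sided exact p-value; significance is Bonferroni
    corrected: ``p < alpha / n_tests`` with ``n_tests`` the number of
    retained variant positions in the comparison.
    """
    ia = trajectory.sample_ids.index(sample_a)
    ib = trajectory.sample_ids.index(sample_b)
    alt = trajectory.alt_counts()
    d = np.asarray(trajectory.depths)
    if d[ia] == 0 or d[ib] == 0:
        raise ValueError("zero depth in one of the compared samples")
    table = [[int(alt[ia]), int(d[ia] - alt[ia])],
             [int(alt[ib]), int(d[ib] - alt[ib])]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return bool(p < alpha / max(n_tests, 1)), float(p)
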