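"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; tables (pileups, coverage, BED masks, CRISPR
array dialect, placements, growth tables) are TSV via pandas.  The pileup
TSV is long-form with columns ``genome_id, position_0based, ref_base,
count_A, count_C, count_G, count_T, sample_id``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import BASE_ORDER, CoverageTrack, PileupMatrix
from .crispr import CrisprArray
from .ordering import OrientedAssembly

PILEUP_COLUMNS = ["genome_id", "position_0based", "ref_base",
                  "count_A", "count_C", "count_G", "count_T", "sample_id"]


# -- FASTA ------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write((SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
                str(path), "fasta")


# -- pileups ----------------------------------------------------------------

def write_pileup(pileup: PileupMatrix, path: str | Path) -> None:
    frames = []
    pos = np.arange(pileup.length)
    ref_chars = np.array(list(BASE_ORDER) + ["N"])[np.where(pileup.ref >= 0, pileup.ref, 4)]
    for i, sid in enumerate(pileup.sample_ids):
        frames.append(pd.DataFrame({
            "genome_id": pileup.genome_id,
            "position_0based": pos,
            "ref_base": ref_chars,
            "count_A": pileup.counts[i, :, 0],
            "count_C": pileup.counts[i, :, 1],
            "count_G": pileup.counts[i, :, 2],
            "count_T": pileup.counts[i, :, 3],
            "sample_id": sid,
        }))
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_pileup(path: str | Path) -> PileupMatrix:
    df = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup TSV missing columns: {sorted(missing)}")
    genome_id = str(df["genome_id"].iloc[0])
    length = int(df["position_0based"].max()) + 1
    sample_ids = list(dict.fromkeys(df["sample_id"].astype(str)))
    counts = np.zeros((len(sample_ids), length, 4), dtype=np.int64)
    ref = np.full(length, -1, dtype=np.int64)
    base_idx = {b: i for i, b in enumerate(BASE_ORDER)}
    ref_rows = df.drop_duplicates("position_0based")
    ref[ref_rows["position_0based"].to_numpy()] = [
        base_idx.get(b, -1) for b in ref_rows["ref_base"].astype(str).str.upper()]
    for s, sid in enumerate(sample_ids):
        sub = df[df["sample_id"].astype(str) == sid]
        p = sub["position_0based"].to_numpy()
        for j, b in enumerate(BASE_ORDER):
            counts[s, p, j] = sub[f"count_{b}"].to_numpy()
    return PileupMatrix(counts, ref, sample_ids, genome_id)


# -- coverage ---------------------------------------------------------------

def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    pd.DataFrame({"genome_id": track.genome_id,
                  "position_0based": np.arange(len(track)),
                  "depth": track.depths}).to_csv(path, sep="\t", index=False)


def read_coverage(path: str | Path) -> CoverageTrack:
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("position_0based")
    return CoverageTrack(df["depth"].to_numpy(dtype=float),
                         genome_id=str(df["genome_id"].iloc[0]))


# -- BED --------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name"][:df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    return df


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals.to_csv(path, sep="\t", header=False, index=False)


# -- CRISPR array dialect ---------------------------------------------------

def write_crispr_arrays(arrays: list[CrisprArray], path: str | Path) -> None:
    """TSV dialect: array_id, element_index, type (repeat|spacer), sequence."""
    rows = []
    for arr in arrays:
        idx = 0
        rows.append((arr.array_id, idx, "repeat", arr.repeat))
        for _, seq in arr.spacers:
            idx += 1
            rows.append((arr.array_id, idx, "spacer", seq))
            idx += 1
            rows.append((arr.array_id, idx, "repeat", arr.repeat))
    pd.DataFrame(rows, columns=["array_id", "element_index", "type", "sequence"]) \
        .to_csv(path, sep="\t", index=False)


def read_crispr_arrays(path: str | Path) -> list[CrisprArray]:
    df = pd.read_csv(path, sep="\t")
    arrays = []
    for aid, sub in df.groupby("array_id", sort=False):
        sub = sub.sort_values("element_index")
        repeats = sub[sub["type"] == "repeat"]["sequence"]
        spacer_rows = sub[sub["type"] == "spacer"]["sequence"]
        spacers = [(f"{aid}_s{i}", s) for i, s in enumerate(spacer_rows)]
        arrays.append(CrisprArray(str(aid), str(repeats.iloc[0]), spacers))
    return arrays


# -- placements & truth -----------------------------------------------------

def write_placements(assembly: OrientedAssembly, path: str | Path) -> None:
    """AGP-like placement TSV: contig_id, core_start, core_end, orientation."""
    rows = [(cid, off, off + assembly.contig_lengths[cid], strand)
            for cid, strand, off in assembly.placements]
    pd.DataFrame(rows, columns=["contig_id", "core_start", "core_end", "orientation"]) \
        .to_csv(path, sep="\t", index=False)


def write_truth_json(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
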