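"""Small-RNA sequencing side: trimming, <=1-difference precursor mapping,
read-count quantification, single-base alteration flagging, and Phred QC.

Reads are truncated to their leading bases (mature miRNAs are ~21-22 nt and
the 3' end of a longer sequencing read runs into adaptor), then aligned
against every substring of every precursor allowing at most one base
difference in four classes: exact match, one substitution, one base deleted
in the read, one base inserted in the read.  Exact mappings suppress
1-difference mappings for the same read.  A miRNA whose supported read
counts are all 1-difference (zero exact) across every sample and replicate,
with at least ``min_reads`` support everywhere, is flagged as a potential
single-base alteration.  Without a genome-wide exclusion step these flags
remain "potential" alterations only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PrecursorSet, ReadSet, SequenceRead, write_table

logger = logging.getLogger(__name__)

EXACT = "exact"
SUBSTITUTION = "substitution"
DELETION_IN_READ = "deletion_in_read"
INSERTION_IN_READ = "insertion_in_read"


@dataclass(frozen=True)
class ReadMapping:
    """One read-to-precursor assignment at edit distance 0 or 1."""

    read_id: str
    mirna_id: str
    difference_class: str
    offset: int  # start of the aligned substring within the precursor


def trim_reads(reads: ReadSet, keep_length: int = 21) -> ReadSet:
    """Truncate every read (and its quality string) to its leading
    ``keep_length`` bases; shorter reads pass through, counted in a log
    warning."""
    if keep_length < 1:
        raise ValueError("keep_length must be >= 1")
    short = 0
    out = []
    for r in reads:
        if len(r.sequence) <= keep_length:
            short += len(r.sequence) < keep_length
            out.append(r)
        else:
            out.append(SequenceRead(r.read_id, r.sequence[:keep_length],
                                    r.quality[:keep_length]))
    if short:
        logger.warning("%d read(s) shorter than keep_length=%d passed "
                       "through untrimmed", short, keep_length)
    return ReadSet(out)


def _hamming1_offsets(read: str, ref: str) -> list[int]:
    """Offsets where ``read`` matches a same-length substring of ``ref``
    with exactly one mismatch."""
    out = []
    L = len(read)
    for off in range(len(ref) - L + 1):
        window = ref[off:off + L]
        mismatches = sum(a != b for a, b in zip(read, window))
        if mismatches == 1:
            out.append(off)
    return out


def _exact_offsets(read: str, ref: str) -> list[int]:
    out = []
    start = ref.find(read)
    while start != -1:
        out.append(start)
        start = ref.find(read, start + 1)
    return out


def _deletion_offsets(read: str, ref: str) -> list[int]:
    """Offsets of length len(read)+1 reference substrings from which deleting
    one base yields ``read`` (a base missing from the read)."""
    out = []
    L = len(read) + 1
    for off in range(len(ref) - L + 1):
        window = ref[off:off + L]
        # window with one base removed equals read <=> prefix match up to the
        # first mismatch, suffix match after skipping one reference base
        i = 0
        while i < len(read) and read[i] == window[i]:
            i += 1
        if read[i:] == window[i + 1:]:
            out.append(off)
    return out


def _insertion_offsets(read: str, ref: str) -> list[int]:
    """Offsets of length len(read)-1 reference substrings obtained by
    deleting one base from ``read`` (an extra base in the read)."""
    out = []
    L = len(read) - 1
    if L < 1:
        return out
    for off in range(len(ref) - L + 1):
        window = ref[off:off + L]
        i = 0
        while i < L and read[i] == window[i]:
            i += 1
        if read[i + 1:] == window[i:]:
            out.append(off)
    return out


def map_read(read_sequence: str, precursors: PrecursorSet,
             read_id: str = "", min_length: int = 10) -> list[ReadMapping]:
    """All best mappings of one read against a precursor set.

    Exact mappings beat 1-difference mappings globally: if the read matches
    any precursor exactly anywhere, only exact mappings are returned;
    otherwise every substitution / deletion-in-read / insertion-in-read
    mapping is returned.  An unmappable read yields an empty list.
    """
    read = read_sequence.upper().replace("U", "T")
    if len(read) < min_length:
        raise ValueError(
            f"read shorter than the {min_length}-base mapping floor"
        )
    exact: list[ReadMapping] = []
    near: list[ReadMapping] = []
    for mid in precursors:
        ref = precursors[mid]
        for off in _exact_offsets(read, ref):
            exact.append(ReadMapping(read_id, mid, EXACT, off))
        if exact:
            continue  # cheap short-circuit; exact suppresses 1-diff anyway
        for off in _hamming1_offsets(read, ref):
            near.append(ReadMapping(read_id, mid, SUBSTITUTION, off))
        for off in _deletion_offsets(read, ref):
            near.append(ReadMapping(read_id, mid, DELETION_IN_READ, off))
        for off in _insertion_offsets(read, ref):
            near.append(ReadMapping(read_id, mid, INSERTION_IN_READ, off))
    return exact if exact else near


def map_reads(reads: ReadSet, precursors: PrecursorSet,
              min_length: int = 10) -> dict[str, list[ReadMapping]]:
    """Best mappings for every read, keyed by read id."""
    return {
        r.read_id: map_read(r.sequence, precursors, r.read_id, min_length)
        for r in reads
    }


def quantify(mappings_by_read: Mapping[str, Sequence[ReadMapping]],
             precursors: PrecursorSet) -> pd.DataFrame:
    """Per-miRNA read counts: total at <=1 difference and exact-only.

    A read contributes one count to every miRNA it best-maps to
    (multi-mapping is counted per miRNA); ``count_exact`` increments only
    when the read has an exact-class mapping to that miRNA.
    """
    le1 = {mid: 0 for mid in precursors}
    exact = {mid: 0 for mid in precursors}
    for maps in mappings_by_read.values():
        mirnas = {m.mirna_id for m in maps}
        exact_mirnas = {m.mirna_id for m in maps if m.difference_class == EXACT}
        for mid in mirnas:
            le1[mid] += 1
        for mid in exact_mirnas:
            exact[mid] += 1
    return pd.DataFrame(
        {"count_le1": pd.Series(le1), "count_exact": pd.Series(exact)}
    ).rename_axis("mirna_id")


@dataclass(frozen=True)
class AlterationCall:
    """Potential single-base alteration for one miRNA across samples."""

    mirna_id: str
    counts: tuple[tuple[str, int, int], ...]  # (sample, count_le1, count_exact)
    flagged: bool


def flag_alterations(counts_by_sample: Mapping[str, pd.DataFrame],
                     min_reads: int = 10) -> list[AlterationCall]:
    """Flag miRNAs supported only by 1-difference reads in every sample.

    ``counts_by_sample`` maps sample/replicate name to a ``quantify`` output.
    A miRNA is flagged iff in every sample count_le1 >= min_reads and
    count_exact == 0.
    """
    if not counts_by_sample:
        raise ValueError("need at least one sample")
    samples = list(counts_by_sample)
    mirnas = sorted(
        set().union(*(set(df.index) for df in counts_by_sample.values()))
    )
    calls = []
    for mid in mirnas:
        per_sample = []
        flagged = True
        for s in samples:
            df = counts_by_sample[s]
            c1 = int(df.at[mid, "count_le1"]) if mid in df.index else 0
            c0 = int(df.at[mid, "count_exact"]) if mid in df.index else 0
            per_sample.append((s, c1, c0))
            if c1 < min_reads or c0 != 0:
                flagged = False
        calls.append(AlterationCall(mid, tuple(per_sample), flagged))
    return calls


def phred_mean_accuracy(mean_q: float) -> float:
    """Implied percent base-call accuracy for a mean Phred score:
    100 * (1 - 10^(-Q/10)).  Q30 -> 99.9%."""
    if mean_q < 0:
        raise ValueError("Phred score must be non-negative")
    return 100.0 * (1.0 - 10.0 ** (-mean_q / 10.0))


def qc_summary(readsets: Mapping[str, ReadSet]) -> pd.DataFrame:
    """Per-sample mean Phred quality and implied base-call accuracy."""
    rows = {}
    for sample, rs in readsets.items():
        q = rs.mean_phred()
        rows[sample] = {
            "n_reads": len(rs),
            "mean_phred": q,
            "implied_accuracy_pct": phred_mean_accuracy(q),
        }
    return pd.DataFrame(rows).T.rename_axis("sample")


def write_alteration_report(calls: Sequence[AlterationCall],
                            path: str | Path,
                            comments: Iterable[str] = ()) -> None:
    rows = [
        {"mirna_id": c.mirna_id, "sample": s, "count_le1": c1,
         "count_exact": c0, "flagged": c.flagged}
        for c in calls for (s, c1, c0) in c.counts
    ]
    df = pd.DataFrame(rows, columns=["mirna_id", "sample", "count_le1",
                                     "count_exact", "flagged"])
    notes = list(comments) + [
        "flags are potential alterations only: genome-wide exclusion of "
        "other loci was not performed"
    ]
    write_table(df, path, notes, index=False)
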