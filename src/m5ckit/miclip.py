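"""Truncation-site inference from crosslink-and-immunoprecipitation reads.

Pipeline: demultiplex + PCR-deduplicate by the split random barcode, align
inserts, assign each truncation to the closest strand-matched cytosine
within +/-2 nt, normalize to reads-per-million (RPM), and keep sites above
50 RPM in at least 2 of 3 replicates.

Conventions (configurable): the truncation position is the base immediately
5' of the insert's 5'-most aligned base; equidistant cytosines in the
assignment window tie-break to the upstream (5') one.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._align import SeqIndex
from .core_io import AlignedRead, SiteRecord, TranscriptModel

_BARCODE_LEN = 10  # 3 random + 4 experimental + 3 random


@dataclass
class UniqueInsert:
    """One deduplicated insert with its cDNA count (distinct random barcodes)."""

    insert: str
    cdna_count: int


@dataclass
class DedupResult:
    by_sample: Dict[str, List[UniqueInsert]]
    n_input: int
    n_too_short: int
    n_undetermined: int

    def library_size(self, sample: str) -> int:
        """Unique cDNA count of a sample (post-dedup), used for RPM."""
        return sum(u.cdna_count for u in self.by_sample.get(sample, []))


def demultiplex_dedup(
    reads: Iterable[Tuple[str, str]],
    experimental_barcodes: Mapping[str, str],
) -> DedupResult:
    """Split reads by experimental barcode and collapse PCR duplicates.

    Read layout: positions 1-3 random barcode, 4-7 experimental barcode,
    8-10 random barcode, then insert. Reads with identical (random barcode,
    insert) are PCR products and collapse to one; the cDNA count of an
    insert is the number of distinct random barcodes observed for it.
    Barcodes are trimmed from the returned inserts. Reads shorter than the
    10-nt header are discarded (counted); unknown experimental barcodes are
    routed to the "undetermined" sample.
    """
    bc_to_sample = {bc: sample for sample, bc in experimental_barcodes.items()}
    keys: Dict[str, set] = defaultdict(set)  # sample -> {(random_bc, insert)}
    n_input = n_too_short = n_undetermined = 0
    for _, seq in reads:
        n_input += 1
        if len(seq) <= _BARCODE_LEN:
            n_too_short += 1
            continue
        random_bc = seq[0:3] + seq[7:10]
        sample = bc_to_sample.get(seq[3:7])
        if sample is None:
            sample = "undetermined"
            n_undetermined += 1
        keys[sample].add((random_bc, seq[10:]))

    by_sample: Dict[str, List[UniqueInsert]] = {}
    for sample, pairs in keys.items():
        counts = Counter(insert for _, insert in pairs)
        by_sample[sample] = [
            UniqueInsert(insert, n) for insert, n in sorted(counts.items())
        ]
    return DedupResult(by_sample, n_input, n_too_short, n_undetermined)


def trim_adapter(seq: str, adapter: str, min_overlap: int = 4, min_len: int = 18) -> Optional[str]:
    """Trim an exact 3'-adapter prefix match; None if the trimmed read is short."""
    for i in range(len(seq)):
        tail = seq[i:]
        if len(tail) >= min_overlap and adapter.startswith(tail):
            seq = seq[:i]
            break
    else:
        if adapter in seq:
            seq = seq[: seq.index(adapter)]
    return seq if len(seq) >= min_len else None


def align_inserts(
    inserts: Sequence[UniqueInsert],
    reference: Dict[str, str],
    max_mismatches: int = 1,
    index: Optional[SeqIndex] = None,
) -> Tuple[List[Tuple[AlignedRead, int]], int]:
    """Unique-best alignment of inserts (at most ``max_mismatches``).

    Mirrors unique-mapping semantics: an insert whose best mismatch stratum
    holds more than one alignment is discarded. Returns
    ([(alignment, cdna_count)], n_unaligned_or_ambiguous).
    """
    idx = index or SeqIndex(reference)
    out: List[Tuple[AlignedRead, int]] = []
    n_dropped = 0
    for k, u in enumerate(inserts):
        hit = idx.align(u.insert, max_mismatches=max_mismatches)
        if hit is None:
            n_dropped += 1
            continue
        out.append(
            (
                AlignedRead(
                    read_id=f"insert{k}",
                    contig=hit.contig,
                    pos=hit.pos,
                    strand="+",
                    length=len(u.insert),
                    mismatches=hit.mismatches,
                    query=u.insert,
                ),
                u.cdna_count,
            )
        )
    return out, n_dropped


@dataclass
class SiteCallResult:
    counts: Dict[Tuple[str, int, str], int]  # (contig, pos, strand) -> cDNA count
    n_assigned: int
    n_no_cytosine: int
    n_no_upstream: int

    @property
    def n_discarded(self) -> int:
        return self.n_no_cytosine + self.n_no_upstream


def call_truncation_sites(
    aligned_inserts: Iterable[Tuple[AlignedRead, int]],
    reference: Dict[str, str],
    window: int = 2,
) -> SiteCallResult:
    """Assign each insert's truncation to the closest cytosine within the window.

    The truncation position is the base immediately 5' of the read's
    5'-most aligned base (strand-aware). Search order is distance 0, 1, ..,
    ``window``, upstream before downstream at each distance; the first
    strand-matched C wins. Inserts with no C in the window, or aligned at
    the contig edge (no upstream base), are discarded and counted.
    """
    counts: Dict[Tuple[str, int, str], int] = defaultdict(int)
    n_assigned = n_no_c = n_edge = 0
    for read, cdna in aligned_inserts:
        seq = reference[read.contig]
        if read.strand == "+":
            trunc = read.pos - 1
            upstream_step = -1
            target = "C"
        else:
            trunc = read.end
            upstream_step = +1
            target = "G"  # C on the minus strand
        if trunc < 0 or trunc >= len(seq):
            n_edge += 1
            continue
        assigned = None
        for d in range(window + 1):
            for step in ((upstream_step, -upstream_step) if d else (1,)):
                p = trunc + d * step if d else trunc
                if 0 <= p < len(seq) and seq[p] == target:
                    assigned = p
                    break
            if assigned is not None:
                break
        if assigned is None:
            n_no_c += 1
            continue
        counts[(read.contig, assigned, read.strand)] += cdna
        n_assigned += 1
    return SiteCallResult(dict(counts), n_assigned, n_no_c, n_edge)


def normalize_rpm(
    site_counts: Mapping[Tuple[str, int, str], int], library_unique_reads: int
) -> Dict[Tuple[str, int, str], float]:
    """Reads-per-million: count * 1e6 / unique library size."""
    if library_unique_reads <= 0:
        raise ValueError("library_unique_reads must be > 0")
    return {k: c * 1e6 / library_unique_reads for k, c in site_counts.items()}


def filter_high_confidence(
    rpm_by_replicate: pd.DataFrame,
    rpm_threshold: float = 50.0,
    min_replicates: int = 2,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Keep sites with RPM strictly above threshold in >= min_replicates.

    ``rpm_by_replicate`` is sites x replicates; the replicate count must
    match ``n_replicates``.
    """
    if rpm_by_replicate.shape[1] != n_replicates:
        raise ValueError(
            f"expected {n_replicates} replicate columns, got {rpm_by_replicate.shape[1]}"
        )
    mask = (rpm_by_replicate > rpm_threshold).sum(axis=1) >= min_replicates
    return rpm_by_replicate.loc[mask]


def rpm_table(
    per_replicate_counts: Sequence[Mapping[Tuple[str, int, str], int]],
    library_sizes: Sequence[int],
) -> pd.DataFrame:
    """Assemble a sites x replicates RPM matrix (absent sites get 0)."""
    if len(per_replicate_counts) != len(library_sizes):
        raise ValueError("one library size per replicate required")
    all_sites = sorted({k for c in per_replicate_counts for k in c})
    data = {}
    for i, (counts, lib) in enumerate(zip(per_replicate_counts, library_sizes)):
        rpm = normalize_rpm(counts, lib)
        data[f"rep{i + 1}"] = [rpm.get(s, 0.0) for s in all_sites]
    return pd.DataFrame(data, index=pd.MultiIndex.from_tuples(all_sites, names=["contig", "pos", "strand"]))


@dataclass
class SiteAnnotation:
    labels: Dict[Tuple[str, int, str], str]
    window_counts: Dict[Tuple[str, int], int]  # (transcript, window index) -> n sites
    singleton_fraction: float


def annotate_sites(
    sites: Iterable[SiteRecord],
    transcript_models: Sequence[TranscriptModel],
    window_size: int = 50,
) -> SiteAnnotation:
    """Label sites 5UTR/CDS/3UTR/noncoding and count them per 50-nt window.

    Windows tile each transcript from position 0; the singleton fraction is
    the share of occupied windows holding exactly one site. Sites on a
    contig with no model are labeled intergenic.
    """
    by_contig = {m.contig: m for m in transcript_models}
    labels: Dict[Tuple[str, int, str], str] = {}
    window_counts: Dict[Tuple[str, int], int] = defaultdict(int)
    for s in sites:
        model = by_contig.get(s.contig)
        if model is None:
            labels[(s.contig, s.pos, s.strand)] = "intergenic"
            continue
        labels[(s.contig, s.pos, s.strand)] = model.region_of(s.pos)
        window_counts[(s.contig, s.pos // window_size)] += 1
    occupied = list(window_counts.values())
    singleton = sum(1 for n in occupied if n == 1) / len(occupied) if occupied else 0.0
    return SiteAnnotation(labels, dict(window_counts), singleton)


def assert_sites_are_cytosines(
    sites: Iterable[Tuple[str, int, str]], reference: Dict[str, str]
) -> None:
    """Hard assertion: every reported site is a C on its strand."""
    for contig, pos, strand in sites:
        base = reference[contig][pos]
        expected = "C" if strand == "+" else "G"
        if base != expected:
            raise AssertionError(f"site {contig}:{pos}({strand}) is {base}, not a cytosine")


def sites_to_bed(rpm: pd.DataFrame) -> List[SiteRecord]:
    """BED export with score = mean RPM across replicates."""
    records = []
    means = rpm.mean(axis=1)
    for (contig, pos, strand), score in means.items():
        records.append(SiteRecord(contig, int(pos), strand, name=f"{contig}:{pos}", score=float(score)))
    return records
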