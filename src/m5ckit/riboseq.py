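"""Ribosome-footprint analyses: periodicity/frame filtering, nine-codon
position profiles (-5..+3, 0 = A-site), codon enrichment between
conditions, single-nucleotide P-site tracks, and motif positioning within
footprints.

Register: the P-site nucleotide is read offset 12 (0-based), so the nine
codons occupy read positions 1-27 (1-based) with the P-site as codon -1
(read offsets 12-14) and the A-site as codon 0 (offsets 15-17).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import AlignedRead, Track, TranscriptModel

ALL_CODONS = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")
CODON_POSITIONS = tuple(range(-5, 4))  # 0 = A-site
N_PROFILE_NT = 27


# ---------------------------------------------------------------------------
# Frame / periodicity filtering


@dataclass
class FilterStats:
    n_input: int = 0
    n_bad_length: int = 0
    n_low_cds_overlap: int = 0
    n_bad_frame: int = 0
    n_no_cds: int = 0
    n_kept: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_bad_length + self.n_low_cds_overlap + self.n_bad_frame + self.n_no_cds


def _frame(read: AlignedRead, model: TranscriptModel) -> int:
    return (read.five_prime - model.cds_start) % 3


def _cds_overlap(read: AlignedRead, model: TranscriptModel) -> int:
    return max(0, min(read.end, model.cds_end) - max(read.pos, model.cds_start))


def learn_expected_frames(
    alignments: Sequence[AlignedRead],
    models_by_contig: Mapping[str, TranscriptModel],
    lengths: Iterable[int],
    min_cds_overlap: float = 0.5,
) -> Dict[int, int]:
    """Modal 5'-end frame per read length among CDS-overlapping reads."""
    tallies: Dict[int, Counter] = defaultdict(Counter)
    for read in alignments:
        model = models_by_contig.get(read.contig)
        if model is None or not model.has_cds:
            continue
        if _cds_overlap(read, model) < min_cds_overlap * read.length:
            continue
        tallies[read.length][_frame(read, model)] += 1
    out = {}
    for length in lengths:
        counter = tallies.get(length)
        out[length] = counter.most_common(1)[0][0] if counter else 0
    return out


def select_periodic_reads(
    alignments: Sequence[AlignedRead],
    transcript_models: Sequence[TranscriptModel],
    lengths: Iterable[int] = (27, 28, 29),
    min_cds_overlap: float = 0.5,
    expected_frames: Optional[Mapping[int, int]] = None,
) -> Tuple[List[AlignedRead], FilterStats]:
    """Keep footprints of the periodic lengths, with >=50% CDS overlap, and
    whose 5'-end frame matches the expected frame for their length.

    The expected frame is learned from the data (modal frame per length)
    unless supplied. Reads on transcripts without a CDS are dropped.
    """
    lengths = set(lengths)
    by_contig = {m.contig: m for m in transcript_models}
    if expected_frames is None:
        expected_frames = learn_expected_frames(alignments, by_contig, lengths, min_cds_overlap)
    stats_ = FilterStats(n_input=len(alignments))
    kept: List[AlignedRead] = []
    for read in alignments:
        model = by_contig.get(read.contig)
        if model is None or not model.has_cds:
            stats_.n_no_cds += 1
            continue
        if read.length not in lengths:
            stats_.n_bad_length += 1
            continue
        if _cds_overlap(read, model) < min_cds_overlap * read.length:
            stats_.n_low_cds_overlap += 1
            continue
        if _frame(read, model) != expected_frames.get(read.length, 0):
            stats_.n_bad_frame += 1
            continue
        kept.append(read)
    stats_.n_kept = len(kept)
    assert stats_.n_kept + stats_.n_dropped == stats_.n_input
    return kept, stats_


def periodicity_report(
    alignments: Sequence[AlignedRead],
    transcript_models: Sequence[TranscriptModel],
    min_cds_overlap: float = 0.5,
) -> pd.DataFrame:
    """Per-length 5'-end frame distribution of CDS-overlapping reads.

    Columns: length, frame0..frame2 counts, dominant_frame,
    dominant_fraction.
    """
    by_contig = {m.contig: m for m in transcript_models}
    tallies: Dict[int, Counter] = defaultdict(Counter)
    for read in alignments:
        model = by_contig.get(read.contig)
        if model is None or not model.has_cds:
            continue
        if _cds_overlap(read, model) < min_cds_overlap * read.length:
            continue
        tallies[read.length][_frame(read, model)] += 1
    rows = []
    for length in sorted(tallies):
        c = tallies[length]
        total = sum(c.values())
        dom_frame, dom_n = c.most_common(1)[0]
        rows.append((length, c[0], c[1], c[2], dom_frame, dom_n / total))
    return pd.DataFrame(
        rows, columns=["length", "frame0", "frame1", "frame2", "dominant_frame", "dominant_fraction"]
    )


# ---------------------------------------------------------------------------
# Codon profiles


@dataclass
class CodonProfile:
    """64 codons x 9 positions count matrix from footprints."""

    counts: pd.DataFrame  # index ALL_CODONS, columns -5..3
    n_reads: int = 0
    n_skipped_short: int = 0

    @classmethod
    def empty(cls) -> "CodonProfile":
        return cls(
            counts=pd.DataFrame(
                0.0, index=list(ALL_CODONS), columns=list(CODON_POSITIONS)
            )
        )

    def fractions(self) -> pd.DataFrame:
        """Per position, codon counts normalized to sum to 1."""
        sums = self.counts.sum(axis=0)
        return self.counts / sums.replace(0, np.nan)

    def normalized(self) -> pd.DataFrame:
        """Fraction divided by the codon's mean fraction across the 9
        positions (so each codon's row averages 1)."""
        frac = self.fractions()
        return frac.div(frac.mean(axis=1), axis=0)


def extract_codon_profile(
    filtered_reads: Sequence[AlignedRead],
    transcript_models: Sequence[TranscriptModel],
) -> CodonProfile:
    """Split read positions 1-27 into nine codons at positions -5..+3.

    Codon identity is taken from the transcript sequence under the read.
    Reads shorter than 27 nt cannot host nine codons and are skipped
    (counted).
    """
    by_contig = {m.contig: m for m in transcript_models}
    profile = CodonProfile.empty()
    counts = profile.counts
    for read in filtered_reads:
        if read.length < N_PROFILE_NT:
            profile.n_skipped_short += 1
            continue
        model = by_contig.get(read.contig)
        if model is None:
            continue
        window = model.sequence[read.pos : read.pos + N_PROFILE_NT]
        for i, position in enumerate(CODON_POSITIONS):
            codon = window[3 * i : 3 * i + 3]
            counts.at[codon, position] += 1
        profile.n_reads += 1
    return profile


def codon_enrichment(
    profile_ko: CodonProfile, profile_ctrl: CodonProfile, pseudocount: float = 0.5
) -> pd.DataFrame:
    """log2 ratio of normalized codon usage, knockout over control.

    A pseudocount is added to the raw counts before computing fractions.
    Codons with zero raw counts in both profiles at a position are NA.
    """
    def norm(profile: CodonProfile) -> pd.DataFrame:
        pseudo = CodonProfile(counts=profile.counts + pseudocount)
        return pseudo.normalized()

    enr = np.log2(norm(profile_ko) / norm(profile_ctrl))
    both_zero = (profile_ko.counts == 0) & (profile_ctrl.counts == 0)
    return enr.mask(both_zero)


# ---------------------------------------------------------------------------
# P-site coverage track


def psite_coverage_track(
    alignments: Sequence[AlignedRead], offset: int = 12
) -> Dict[str, Track]:
    """Single-nucleotide P-site track: each read contributes 1 at its
    5' end + offset (strand-aware); strands are kept separate.

    Reads shorter than the offset are skipped. Returns
    {strand: {contig: {pos: count}}}.
    """
    tracks: Dict[str, Track] = {"+": {}, "-": {}}
    for read in alignments:
        if offset >= read.length:
            continue
        if read.strand == "+":
            pos = read.pos + offset
        else:
            pos = read.end - 1 - offset
        per = tracks[read.strand].setdefault(read.contig, {})
        per[pos] = per.get(pos, 0) + 1
    return tracks


# ---------------------------------------------------------------------------
# Motif position within footprints


def motif_position_counts(
    filtered_reads: Sequence[AlignedRead],
    transcript_models: Sequence[TranscriptModel],
    motif: str = "CTCCA",
) -> pd.DataFrame:
    """Where the motif starts within footprints (read positions 1..27).

    Counts the motif start position (1-based within the read) over all
    reads, plus the fraction normalized by the total read count.
    """
    by_contig = {m.contig: m for m in transcript_models}
    counts = np.zeros(N_PROFILE_NT, dtype=float)
    n_reads = 0
    for read in filtered_reads:
        model = by_contig.get(read.contig)
        if model is None:
            continue
        n_reads += 1
        window = model.sequence[read.pos : read.pos + min(read.length, N_PROFILE_NT)]
        for i in range(len(window) - len(motif) + 1):
            if window[i : i + len(motif)] == motif:
                counts[i] += 1
    frac = counts / n_reads if n_reads else counts
    return pd.DataFrame(
        {"read_position": np.arange(1, N_PROFILE_NT + 1), "count": counts, "fraction": frac, "n_reads": n_reads}
    )


def compare_motif_positions(wt: pd.DataFrame, ko: pd.DataFrame) -> pd.DataFrame:
    """Two-proportion z-test per read position, BH-corrected.

    Inputs are ``motif_position_counts`` outputs for the two conditions.
    """
    n_wt = int(wt["n_reads"].iloc[0]) if len(wt) else 0
    n_ko = int(ko["n_reads"].iloc[0]) if len(ko) else 0
    rows = []
    pvals = []
    for pos in wt["read_position"]:
        a = float(wt.loc[wt["read_position"] == pos, "count"].iloc[0])
        b = float(ko.loc[ko["read_position"] == pos, "count"].iloc[0])
        if n_wt == 0 or n_ko == 0 or (a + b) == 0:
            p = 1.0
        else:
            pool = (a + b) / (n_wt + n_ko)
            se = np.sqrt(pool * (1 - pool) * (1 / n_wt + 1 / n_ko))
            z = ((a / n_wt) - (b / n_ko)) / se if se > 0 else 0.0
            p = float(2 * stats.norm.sf(abs(z)))
        rows.append((int(pos), a / n_wt if n_wt else np.nan, b / n_ko if n_ko else np.nan, p))
        pvals.append(p)
    qvals = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    df = pd.DataFrame(rows, columns=["read_position", "fraction_wt", "fraction_ko", "p"])
    df["q"] = qvals
    return df
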