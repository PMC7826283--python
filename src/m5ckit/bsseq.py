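"""Bisulfite-sequencing stage: conversion-aware alignment, artifact
filtering, per-cytosine methylation extraction, tRNA reference handling,
and capped site-level quantification around the target motif.

Alignment happens in three-letter space (C and T collapsed in both read
and reference) so that conversion state never costs a mismatch; the
original read is kept for the methylation calls. Quantification caps each
site's contribution at 5 reads using exact rational rescaling, so capping
changes a site's aggregation weight but never its methylated fraction.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._align import Hit, SeqIndex, collapse_ct
from .core_io import AlignedRead, SiteRecord


@dataclass
class CytosineCounts:
    contig: str
    pos: int
    strand: str
    n_meth: int = 0
    n_unmeth: int = 0

    @property
    def total(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def level(self) -> float:
        return self.n_meth / self.total if self.total else float("nan")


# ---------------------------------------------------------------------------
# Alignment


def make_bs_index(reference: Dict[str, str]) -> SeqIndex:
    return SeqIndex(reference, transform=collapse_ct)


def align_bs_reads(
    reads: Iterable[Tuple[str, str]],
    reference: Dict[str, str],
    max_mismatches: int = 2,
    index: Optional[SeqIndex] = None,
) -> Tuple[List[AlignedRead], List[Tuple[str, str]]]:
    """Align reads in collapsed C/T space; unique best alignment required.

    Returns (aligned, unaligned). Mismatches are counted in collapsed
    space, so an unconverted C never costs a mismatch. Ambiguous-best reads
    are reported as unaligned (they go to the retry pass).
    """
    idx = index or make_bs_index(reference)
    aligned: List[AlignedRead] = []
    unaligned: List[Tuple[str, str]] = []
    for read_id, seq in reads:
        hit = idx.align(seq, max_mismatches=max_mismatches)
        if hit is None:
            unaligned.append((read_id, seq))
            continue
        aligned.append(
            AlignedRead(
                read_id=read_id,
                contig=hit.contig,
                pos=hit.pos,
                strand="+",
                length=len(seq),
                mismatches=hit.mismatches,
                query=seq,
            )
        )
    return aligned, unaligned


def retry_cca_trim(
    unaligned: Iterable[Tuple[str, str]],
    reference: Dict[str, str],
    max_mismatches: int = 2,
    min_len: int = 18,
    index: Optional[SeqIndex] = None,
) -> Tuple[List[AlignedRead], List[Tuple[str, str]]]:
    """Second pass: drop the last 3 bases (potential tRNA CCA tail), realign.

    Alignments gained here carry a ``:ccatrim`` suffix on the read id as a
    provenance flag. Trimmed reads shorter than ``min_len`` are discarded.
    """
    idx = index or make_bs_index(reference)
    aligned: List[AlignedRead] = []
    still_unaligned: List[Tuple[str, str]] = []
    for read_id, seq in unaligned:
        trimmed = seq[:-3]
        if len(trimmed) < min_len:
            continue
        hit = idx.align(trimmed, max_mismatches=max_mismatches)
        if hit is None:
            still_unaligned.append((read_id, seq))
            continue
        aligned.append(
            AlignedRead(
                read_id=f"{read_id}:ccatrim",
                contig=hit.contig,
                pos=hit.pos,
                strand="+",
                length=len(trimmed),
                mismatches=hit.mismatches,
                query=trimmed,
            )
        )
    return aligned, still_unaligned


# ---------------------------------------------------------------------------
# Read-level artifact filter


def read_methylation_fraction(read: AlignedRead, reference: Dict[str, str]) -> Tuple[int, int]:
    """(unconverted C count, total reference Cs covered) for one read."""
    ref = reference[read.contig]
    n_c = n_meth = 0
    for i in range(read.length):
        if ref[read.pos + i] == "C":
            n_c += 1
            if read.query[i] == "C":
                n_meth += 1
    return n_meth, n_c


def filter_conversion_artifacts(
    aligned_reads: Iterable[AlignedRead],
    reference: Dict[str, str],
    max_meth_fraction: float = 1 / 3,
) -> Tuple[List[AlignedRead], List[AlignedRead]]:
    """Discard reads with strictly more than ``max_meth_fraction`` of their
    covered cytosines unconverted (conversion-resistant artifacts).

    Reads covering zero cytosines are kept. Returns (kept, discarded).
    The boundary is exact: with the default 1/3 the test is 3*n_meth > n_c.
    """
    kept: List[AlignedRead] = []
    discarded: List[AlignedRead] = []
    frac = Fraction(max_meth_fraction).limit_denominator(10**6)
    for read in aligned_reads:
        n_meth, n_c = read_methylation_fraction(read, reference)
        if n_c > 0 and Fraction(n_meth, n_c) > frac:
            discarded.append(read)
        else:
            kept.append(read)
    return kept, discarded


# ---------------------------------------------------------------------------
# Methylation extraction


def extract_methylation(
    kept_reads: Iterable[AlignedRead], reference: Dict[str, str]
) -> Dict[Tuple[str, int], CytosineCounts]:
    """Per-position methylation evidence at reference cytosines.

    A read base of C at a reference C counts as methylated, T as
    unmethylated; anything else (a true mismatch) is ignored as evidence.
    Positions never covered are absent from the output.
    """
    counts: Dict[Tuple[str, int], CytosineCounts] = {}
    for read in kept_reads:
        ref = reference[read.contig]
        for i in range(read.length):
            pos = read.pos + i
            if ref[pos] != "C":
                continue
            base = read.query[i]
            if base not in "CT":
                continue
            key = (read.contig, pos)
            if key not in counts:
                counts[key] = CytosineCounts(read.contig, pos, "+")
            if base == "C":
                counts[key].n_meth += 1
            else:
                counts[key].n_unmeth += 1
    return counts


def cytosine_report(counts: Mapping[Tuple[str, int], CytosineCounts]) -> pd.DataFrame:
    rows = [
        (c.contig, c.pos, c.strand, c.n_meth, c.n_unmeth, c.level)
        for c in sorted(counts.values(), key=lambda c: (c.contig, c.pos))
    ]
    return pd.DataFrame(rows, columns=["contig", "pos", "strand", "n_meth", "n_unmeth", "level"])


# ---------------------------------------------------------------------------
# tRNA reference


@dataclass
class TrnaGene:
    """A tRNA gene: body sequence plus intron intervals in gene coordinates."""

    name: str  # GtRNAdb style, e.g. tRNA-Ala-AGC-9-1
    sequence: str
    introns: List[Tuple[int, int]] = field(default_factory=list)


def build_trna_reference(trna_models: Sequence[TrnaGene]) -> Dict[str, str]:
    """Per-tRNA contigs: first gene copies only, introns spliced, CCA tail
    appended, and two flanking Ns on each side.

    The copy filter keeps genes whose fifth dash-separated name field is
    '1'; malformed names warn and are kept.
    """
    out: Dict[str, str] = {}
    for gene in trna_models:
        fields = gene.name.split("-")
        if len(fields) < 5:
            warnings.warn(f"malformed tRNA name {gene.name!r}; keeping", stacklevel=2)
        elif fields[4] != "1":
            continue
        body = gene.sequence
        for s, e in sorted(gene.introns, reverse=True):
            body = body[:s] + body[e:]
        out[gene.name] = "NN" + body + "CCA" + "NN"
    return out


def resolve_trna_multimappers(
    read_alignments: Mapping[str, Sequence[Hit]], seed: int = 0
) -> Dict[str, Hit]:
    """One alignment per read: restrict to the fewest-mismatch stratum and
    pick uniformly at random (seeded) so no read is counted twice."""
    rng = np.random.default_rng(seed)
    chosen: Dict[str, Hit] = {}
    for read_id in sorted(read_alignments):
        hits = read_alignments[read_id]
        if not hits:
            continue
        best_mm = min(h.mismatches for h in hits)
        best = [h for h in hits if h.mismatches == best_mm]
        chosen[read_id] = best[int(rng.integers(len(best)))]
    return chosen


# ---------------------------------------------------------------------------
# Site-level quantification


@dataclass
class SiteMethylationProfile:
    """Per-offset capped methylation evidence around one site."""

    contig: str
    pos: int
    motif: bool
    # offset -> (capped methylated, capped total), exact rationals
    by_offset: Dict[int, Tuple[Fraction, Fraction]] = field(default_factory=dict)
    no_coverage: bool = False

    def level(self) -> float:
        """Capped methylation level at the site cytosine (offset 0)."""
        m, t = self.by_offset.get(0, (Fraction(0), Fraction(0)))
        return float(m / t) if t else float("nan")


@dataclass
class SiteQuantification:
    profiles: List[SiteMethylationProfile]
    context: int

    def aggregate(self) -> pd.DataFrame:
        """Per-offset aggregated level: sum(capped meth) / sum(capped total)."""
        offs = range(-self.context, self.context + 1)
        rows = []
        for off in offs:
            m = sum((p.by_offset.get(off, (Fraction(0), Fraction(0)))[0] for p in self.profiles), Fraction(0))
            t = sum((p.by_offset.get(off, (Fraction(0), Fraction(0)))[1] for p in self.profiles), Fraction(0))
            rows.append((off, float(m / t) if t else float("nan"), float(t)))
        return pd.DataFrame(rows, columns=["offset", "level", "capped_total"])

    def aggregate_site_level(self) -> float:
        """Aggregated level at offset 0 across sites."""
        m = sum((p.by_offset.get(0, (Fraction(0), Fraction(0)))[0] for p in self.profiles), Fraction(0))
        t = sum((p.by_offset.get(0, (Fraction(0), Fraction(0)))[1] for p in self.profiles), Fraction(0))
        return float(m / t) if t else float("nan")

    def matrix(self) -> pd.DataFrame:
        """Heatmap-ready site x offset matrix of per-offset levels."""
        offs = list(range(-self.context, self.context + 1))
        data = []
        idx = []
        for p in self.profiles:
            row = []
            for off in offs:
                m, t = p.by_offset.get(off, (Fraction(0), Fraction(0)))
                row.append(float(m / t) if t else np.nan)
            data.append(row)
            idx.append(f"{p.contig}:{p.pos}")
        return pd.DataFrame(data, index=idx, columns=offs)


def shift_sites_to_motif(
    sites: Sequence[SiteRecord],
    reference: Dict[str, str],
    motif: str = "CTC[CT]A",
    shift_window: int = 2,
) -> List[SiteRecord]:
    """Move sites within ``shift_window`` nt of a motif's methylated C onto
    it, then drop duplicates (keeping the first occurrence)."""
    motif_starts: Dict[str, List[int]] = {}
    pat = re.compile(motif)
    shifted: List[SiteRecord] = []
    seen = set()
    for s in sites:
        seq = reference[s.contig]
        if s.contig not in motif_starts:
            motif_starts[s.contig] = [m.start() for m in pat.finditer(seq)]
        pos = s.pos
        best = None
        for start in motif_starts[s.contig]:
            d = abs(start - pos)
            if d <= shift_window and (best is None or d < best[0]):
                best = (d, start)
        if best is not None:
            pos = best[1]
        key = (s.contig, pos, s.strand)
        if key in seen:
            continue
        seen.add(key)
        shifted.append(SiteRecord(s.contig, pos, s.strand, s.name, s.score))
    return shifted


def quantify_site_methylation(
    sites: Sequence[SiteRecord],
    cytosine_counts: Mapping[Tuple[str, int], CytosineCounts],
    reference: Dict[str, str],
    motif: str = "CTC[CT]A",
    context: int = 10,
    cap: int = 5,
    shift_window: int = 2,
) -> Tuple[SiteQuantification, SiteQuantification]:
    """Capped methylation profiles around sites, split by motif presence.

    Sites next to a motif are shifted onto its methylated C and
    deduplicated. For each offset in [-context, context] restricted to
    reference Cs, a site contributing more than ``cap`` reads is rescaled
    to exactly ``cap`` total reads with its methylated fraction preserved
    (exact rational arithmetic). Returns (motif subset, non-motif subset);
    together they partition the deduplicated input.
    """
    pat = re.compile(motif)
    shifted = shift_sites_to_motif(sites, reference, motif, shift_window)
    motif_profiles: List[SiteMethylationProfile] = []
    other_profiles: List[SiteMethylationProfile] = []
    for s in shifted:
        seq = reference[s.contig]
        has_motif = bool(pat.match(seq, s.pos))
        prof = SiteMethylationProfile(s.contig, s.pos, has_motif)
        covered = False
        for off in range(-context, context + 1):
            p = s.pos + off
            if not (0 <= p < len(seq)) or seq[p] != "C":
                continue
            cc = cytosine_counts.get((s.contig, p))
            if cc is None or cc.total == 0:
                continue
            covered = True
            m, t = Fraction(cc.n_meth), Fraction(cc.total)
            if cc.total > cap:
                m = Fraction(cc.n_meth * cap, cc.total)
                t = Fraction(cap)
            prof.by_offset[off] = (m, t)
        prof.no_coverage = not covered
        (motif_profiles if has_motif else other_profiles).append(prof)
    return (
        SiteQuantification(motif_profiles, context),
        SiteQuantification(other_profiles, context),
    )
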