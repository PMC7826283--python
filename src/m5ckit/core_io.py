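"""Readers/writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open. GTF on disk is 1-based
closed; BED and bedGraph are 0-based half-open. Minus-strand features are
reverse-complemented into transcript orientation when building
:class:`TranscriptModel` objects, so downstream stages only ever see
transcript-oriented sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from Bio import SeqIO

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """One transcript's coordinate frame, in transcript orientation.

    ``cds_start``/``cds_end`` are 0-based half-open offsets in transcript
    coordinates. ``stop_codons`` lists ``(offset, codon)`` pairs for every
    annotated stop of the gene, also in transcript coordinates.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    sequence: str
    cds_start: int
    cds_end: int
    stop_codons: List[Tuple[int, str]] = field(default_factory=list)
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.cds_start <= self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start},{self.cds_end}) "
                f"outside transcript of length {len(self.sequence)}"
            )
        for off, codon in self.stop_codons:
            if codon not in STOP_CODONS:
                raise ValueError(f"{self.transcript_id}: invalid stop codon {codon!r}")

    @property
    def has_cds(self) -> bool:
        return self.cds_end > self.cds_start

    def region_of(self, pos: int) -> str:
        """Classify a transcript position as 5UTR / CDS / 3UTR / noncoding."""
        if not self.has_cds:
            return "noncoding"
        if pos < self.cds_start:
            return "5UTR"
        if pos < self.cds_end:
            return "CDS"
        return "3UTR"


@dataclass
class AlignedRead:
    """Uniform alignment record consumed by the miclip/bsseq/riboseq stages."""

    read_id: str
    contig: str
    pos: int
    strand: str
    length: int
    mismatches: int = 0
    query: str = ""

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"{self.read_id}: negative position")

    @property
    def end(self) -> int:
        return self.pos + self.length

    @property
    def five_prime(self) -> int:
        """Position of the 5'-most aligned base in reference coordinates."""
        return self.pos if self.strand == "+" else self.end - 1


@dataclass
class SiteRecord:
    """Single-nucleotide site; serializes as a BED6 interval [pos, pos+1)."""

    contig: str
    pos: int
    strand: str
    name: str = "."
    score: float = 0.0


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> Dict[str, str]:
    """Read FASTA into contig -> uppercase sequence; U is normalized to T.

    Raises ``ValueError`` on duplicate contig names.
    """
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate contig name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper().replace("U", "T")
    return seqs


def write_fasta(seqs: Dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> List[Tuple[str, str]]:
    """Read FASTQ into a list of (read_id, sequence); qualities are dropped."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[Tuple[str, str]], path, qual_char: str = "I") -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# GTF annotation


def _gtf_attributes(raw: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_annotation(path, contig_seqs: Dict[str, str]) -> List[TranscriptModel]:
    """Parse a GTF (exon/CDS/stop_codon features) into transcript models.

    On-disk coordinates are 1-based closed; models are built in transcript
    orientation with 0-based half-open offsets. A CDS whose length is not
    divisible by 3 produces a warning and a flagged model.
    """
    per_tx: Dict[str, Dict[str, list]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GTF line: {line!r}")
            contig, _, feature, start, end, _, strand, _, raw_attrs = fields[:9]
            if feature not in ("exon", "CDS", "stop_codon"):
                continue
            attrs = _gtf_attributes(raw_attrs)
            tx_id = attrs.get("transcript_id", "")
            gene_id = attrs.get("gene_id", tx_id)
            iv = (int(start) - 1, int(end))  # to 0-based half-open
            per_tx.setdefault(tx_id, {"exon": [], "CDS": [], "stop_codon": []})
            per_tx[tx_id][feature].append(iv)
            meta[tx_id] = (gene_id, contig, strand)

    models: List[TranscriptModel] = []
    for tx_id, feats in per_tx.items():
        gene_id, contig, strand = meta[tx_id]
        if contig not in contig_seqs:
            raise ValueError(f"{tx_id}: contig {contig!r} not in reference")
        genome = contig_seqs[contig]
        exons = sorted(feats["exon"]) or [
            (min(s for s, _ in feats["CDS"]), max(e for _, e in feats["CDS"]))
        ]
        seq = "".join(genome[s:e] for s, e in exons)
        if strand == "-":
            seq = revcomp(seq)

        def to_tx(gpos: int) -> int:
            """Map genomic position to transcript offset (position must be exonic)."""
            acc = 0
            for s, e in exons:
                if s <= gpos < e:
                    off = acc + (gpos - s)
                    break
                acc += e - s
            else:
                raise ValueError(f"{tx_id}: position {gpos} not exonic")
            if strand == "-":
                off = len(seq) - 1 - off
            return off

        cds_start = cds_end = 0
        flagged = False
        if feats["CDS"]:
            gs = min(s for s, _ in feats["CDS"])
            ge = max(e for _, e in feats["CDS"])
            a, b = to_tx(gs), to_tx(ge - 1)
            cds_start, cds_end = min(a, b), max(a, b) + 1
            cds_len = sum(e - s for s, e in feats["CDS"])
            if cds_len % 3 != 0:
                warnings.warn(
                    f"{tx_id}: CDS length {cds_len} not divisible by 3", stacklevel=2
                )
                flagged = True
        stops: List[Tuple[int, str]] = []
        for gs, ge in sorted(feats["stop_codon"]):
            a, b = to_tx(gs), to_tx(ge - 1)
            off = min(a, b)
            stops.append((off, seq[off : off + 3]))
        models.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_id=gene_id,
                contig=contig,
                strand=strand,
                sequence=seq,
                cds_start=cds_start,
                cds_end=cds_end,
                stop_codons=stops,
                flagged=flagged,
            )
        )
    return models


def write_annotation(models: List[TranscriptModel], path) -> None:
    """Write transcript-space models as GTF (each transcript on its own contig).

    Only valid for models where ``contig == transcript_id`` and strand ``+``
    (the synthetic-transcriptome convention); 0-based half-open offsets are
    converted back to 1-based closed coordinates.
    """
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            rows = [("exon", 0, len(m.sequence))]
            if m.has_cds:
                rows.append(("CDS", m.cds_start, m.cds_end))
            for off, _ in m.stop_codons:
                rows.append(("stop_codon", off, off + 3))
            for feature, s, e in rows:
                fh.write(
                    f"{m.contig}\tm5ckit\t{feature}\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED6


def read_bed(path) -> List[SiteRecord]:
    sites: List[SiteRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            contig, start = f[0], int(f[1])
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "+"
            sites.append(SiteRecord(contig, start, strand, name, score))
    return sites


def write_bed(sites: Iterable[SiteRecord], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.contig}\t{s.pos}\t{s.pos + 1}\t{s.name}\t{s.score:g}\t{s.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph tracks

Track = Dict[str, Dict[int, float]]  # contig -> position -> value


def write_bedgraph(track: Track, path) -> None:
    """Write a per-position track, merging runs of adjacent equal values."""
    with open(path, "w") as fh:
        for contig in sorted(track):
            values = track[contig]
            run_start: Optional[int] = None
            prev_pos = prev_val = None
            for pos in sorted(values):
                val = values[pos]
                if run_start is not None and pos == prev_pos + 1 and val == prev_val:
                    prev_pos = pos
                    continue
                if run_start is not None:
                    fh.write(f"{contig}\t{run_start}\t{prev_pos + 1}\t{prev_val:g}\n")
                run_start, prev_pos, prev_val = pos, pos, val
            if run_start is not None:
                fh.write(f"{contig}\t{run_start}\t{prev_pos + 1}\t{prev_val:g}\n")


def read_bedgraph(path) -> Track:
    """Read a bedGraph into a per-position track; overlapping intervals error."""
    track: Track = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, start, end, value = line.rstrip("\n").split("\t")[:4]
            per = track.setdefault(contig, {})
            for pos in range(int(start), int(end)):
                if pos in per:
                    raise ValueError(f"overlapping bedGraph intervals at {contig}:{pos}")
                per[pos] = float(value)
    return track


# ---------------------------------------------------------------------------
# SAM subset

_SAM_FLAG_REVERSE = 16


def read_sam(path) -> List[AlignedRead]:
    """Read the minimal SAM subset: QNAME, FLAG (strand bit), RNAME, POS, SEQ, NM.

    Header lines starting '@' are ignored; alignments are assumed full-length
    matches (no CIGAR interpretation beyond read length).
    """
    reads: List[AlignedRead] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            qname, flag, rname, pos, seq = f[0], int(f[1]), f[2], int(f[3]) - 1, f[9]
            nm = 0
            for tag in f[11:]:
                if tag.startswith("NM:i:"):
                    nm = int(tag[5:])
            strand = "-" if flag & _SAM_FLAG_REVERSE else "+"
            reads.append(
                AlignedRead(
                    read_id=qname,
                    contig=rname,
                    pos=pos,
                    strand=strand,
                    length=len(seq),
                    mismatches=nm,
                    query=seq,
                )
            )
    return reads


def write_sam(reads: Iterable[AlignedRead], path, contig_lengths: Optional[Dict[str, int]] = None) -> None:
    with open(path, "w") as fh:
        if contig_lengths:
            for contig, length in contig_lengths.items():
                fh.write(f"@SQ\tSN:{contig}\tLN:{length}\n")
        for r in reads:
            flag = _SAM_FLAG_REVERSE if r.strand == "-" else 0
            seq = r.query or "*"
            fh.write(
                f"{r.read_id}\t{flag}\t{r.contig}\t{r.pos + 1}\t255\t{r.length}M\t*\t0\t0\t{seq}\t*\tNM:i:{r.mismatches}\n"
            )


# ---------------------------------------------------------------------------
# TSV count matrices


def read_counts(path):
    """Read a TSV count matrix (gene_id index, one column per sample)."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(df, path) -> None:
    df.to_csv(path, sep="\t")
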