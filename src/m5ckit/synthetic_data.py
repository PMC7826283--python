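"""Synthetic transcriptomes, read sets and count matrices with planted truth.

Every generator is deterministic under its seed, and the truth object it
returns is sufficient to compute the expected output of the downstream
stage by brute force. The planted methylation motif is CTCCA with the
methylated cytosine as the FIRST base (so the following CCA sits one codon
downstream in the reading frame continued from the CDS).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core_io import AlignedRead, TranscriptModel

MOTIF = "CTCCA"
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


@dataclass
class PlantedSite:
    transcript_id: str
    pos: int  # 0-based transcript offset of the methylated C
    stoichiometry: float
    motif_present: bool
    in_hairpin: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.stoichiometry <= 1.0:
            raise ValueError("stoichiometry must be in [0, 1]")


@dataclass
class SimTruth:
    """Planted ground truth shared across the simulators."""

    seed: int
    planted_sites: List[PlantedSite] = field(default_factory=list)
    true_log2fc_rna: Dict[str, float] = field(default_factory=dict)
    true_log2fc_ribo: Dict[str, float] = field(default_factory=dict)
    readthrough_fraction: Dict[str, float] = field(default_factory=dict)
    incidental_motifs: List[Tuple[str, int]] = field(default_factory=list)

    def sites_on(self, transcript_id: str) -> List[PlantedSite]:
        return [s for s in self.planted_sites if s.transcript_id == transcript_id]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["planted_sites"] = [PlantedSite(**s) for s in d["planted_sites"]]
        d["incidental_motifs"] = [tuple(x) for x in d["incidental_motifs"]]
        return cls(**d)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _find_incidental(seq: str, planted_pos: Optional[int]) -> List[int]:
    out = []
    for i in range(len(seq) - 4):
        if seq[i] == "C" and seq[i + 1] == "T" and seq[i + 2] == "C" and seq[i + 3] in "CT" and seq[i + 4] == "A":
            if i != planted_pos:
                out.append(i)
    return out


def make_transcriptome(
    n_genes: int,
    length_range: Tuple[int, int] = (400, 700),
    motif_fraction: float = 1.0,
    hairpin_fraction: float = 0.0,
    seed: int = 0,
    stoichiometry: float | Sequence[float] = 0.8,
    utr5_range: Tuple[int, int] = (20, 40),
    stem_len: int = 8,
    plant_sites: bool = True,
) -> Tuple[Dict[str, str], List[TranscriptModel], SimTruth]:
    """Build a transcript-space reference with one planted site per gene.

    Each transcript has a 5'UTR, an ATG...stop CDS, and a 3'UTR. A
    ``motif_fraction`` subset of genes carries one planted CTCCA in the
    3'UTR (methylated C = motif start); a ``hairpin_fraction`` subset of
    those embeds the motif inside the loop of an explicit GC stem-loop.
    The remaining genes get a planted plain-C site without the motif.
    ``stoichiometry`` may be a scalar or a sequence cycled across genes.
    Returns (contig sequences, transcript models, truth).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not (0 <= motif_fraction <= 1 and 0 <= hairpin_fraction <= 1):
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = SimTruth(seed=seed)
    seqs: Dict[str, str] = {}
    models: List[TranscriptModel] = []
    n_motif = round(motif_fraction * n_genes)
    n_hairpin = round(hairpin_fraction * n_motif)
    stoichs = [stoichiometry] if np.isscalar(stoichiometry) else list(stoichiometry)

    for g in range(n_genes):
        tx_id = f"tx{g:04d}"
        total = int(rng.integers(length_range[0], length_range[1] + 1))
        utr5 = int(rng.integers(utr5_range[0], utr5_range[1] + 1))
        n_codons = int(rng.integers(40, 61))  # incl. start + stop
        cds_len = 3 * n_codons
        utr3 = total - utr5 - cds_len
        if utr3 < 100:
            raise ValueError(
                f"{tx_id}: transcript of length {total} too short to host UTRs + CDS"
            )
        cds = "ATG" + "".join(rng.choice(_SENSE_CODONS, size=n_codons - 2)) + str(
            rng.choice(_STOPS)
        )
        seq = list(_random_seq(rng, utr5) + cds + _random_seq(rng, utr3))
        cds_start, cds_end = utr5, utr5 + cds_len

        site_pos: Optional[int] = None
        in_hairpin = False
        motif_present = g < n_motif
        if plant_sites:
            lo = cds_end + 30
            hi = total - 40 - (stem_len if motif_present else 0)
            if hi <= lo:
                raise ValueError(f"{tx_id}: 3'UTR too short to host a site window")
            if motif_present and g < n_hairpin:
                in_hairpin = True
                region_start = int(rng.integers(lo, hi + 1)) - stem_len
                left = "".join(rng.choice(list("GC"), size=stem_len))
                right = _revcomp(left)
                plant = left + MOTIF + right
                seq[region_start : region_start + len(plant)] = list(plant)
                site_pos = region_start + stem_len
            elif motif_present:
                site_pos = int(rng.integers(lo, hi + 1))
                seq[site_pos : site_pos + 5] = list(MOTIF)
            else:
                site_pos = int(rng.integers(lo, hi + 1))
                # plain C site, deliberately NOT a motif: C followed by A
                seq[site_pos : site_pos + 2] = list("CA")

        seq_s = "".join(seq)
        seqs[tx_id] = seq_s
        models.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_id=f"gene{g:04d}",
                contig=tx_id,
                strand="+",
                sequence=seq_s,
                cds_start=cds_start,
                cds_end=cds_end,
                stop_codons=[(cds_end - 3, seq_s[cds_end - 3 : cds_end])],
            )
        )
        if site_pos is not None:
            truth.planted_sites.append(
                PlantedSite(tx_id, site_pos, float(stoichs[g % len(stoichs)]), motif_present, in_hairpin)
            )
            for i in _find_incidental(seq_s, site_pos if motif_present else None):
                truth.incidental_motifs.append((tx_id, i))
    return seqs, models, truth


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# miCLIP reads


def simulate_miclip_reads(
    truth: SimTruth,
    seqs: Dict[str, str],
    depth: int = 100,
    pcr_dup_rate: float = 0.0,
    noise_rate: float = 0.0,
    seed: int = 0,
    insert_len: int = 35,
    experimental_barcode: str = "TCGA",
) -> List[Tuple[str, str]]:
    """Simulate truncation-style reads with the 10-nt barcode header.

    Layout: positions 1-3 random barcode, 4-7 experimental barcode, 8-10
    random barcode, then the insert. Each site read's insert begins at the
    base immediately 3' of the planted cytosine. A ``pcr_dup_rate``
    fraction of emitted reads are exact copies of earlier reads; a
    ``noise_rate`` fraction of unique reads start at random non-site
    positions.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= pcr_dup_rate < 1:
        raise ValueError("pcr_dup_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    all_bc = ["".join(p) for p in __import__("itertools").product("ACGT", repeat=6)]
    if depth > len(all_bc):
        raise ValueError("depth exceeds the 4^6 random-barcode space")

    unique: List[str] = []
    for site in truth.planted_sites:
        seq = seqs[site.transcript_id]
        insert = seq[site.pos + 1 : site.pos + 1 + insert_len]
        if len(insert) < insert_len:
            raise ValueError(f"site at {site.transcript_id}:{site.pos} too close to 3' end")
        for bc in rng.choice(all_bc, size=depth, replace=False):
            unique.append(bc[:3] + experimental_barcode + bc[3:] + insert)

    n_noise = round(noise_rate * len(unique))
    tx_ids = sorted(seqs)
    site_starts = {(s.transcript_id, s.pos + 1) for s in truth.planted_sites}
    made = 0
    while made < n_noise:
        tx = tx_ids[int(rng.integers(len(tx_ids)))]
        start = int(rng.integers(0, len(seqs[tx]) - insert_len + 1))
        if (tx, start) in site_starts:
            continue
        bc = "".join(rng.choice(bases, size=6))
        unique.append(bc[:3] + experimental_barcode + bc[3:] + seqs[tx][start : start + insert_len])
        made += 1

    n_dups = round(len(unique) * pcr_dup_rate / (1 - pcr_dup_rate))
    dups = [unique[int(i)] for i in rng.integers(0, len(unique), size=n_dups)]
    reads = unique + dups
    rng.shuffle(reads)
    return [(f"read{i:07d}", s) for i, s in enumerate(reads)]


# ---------------------------------------------------------------------------
# Bisulfite reads


def simulate_bs_reads(
    truth: SimTruth,
    seqs: Dict[str, str],
    coverage: int = 50,
    conversion_rate: float = 0.99,
    artifact_fraction: float = 0.0,
    seed: int = 0,
    read_len: int = 60,
    stoichiometry_override: Optional[float] = None,
) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Bisulfite-converted reads drawn uniformly along each transcript.

    Non-site cytosines read T with probability ``conversion_rate``; planted
    cytosines read C with probability of the site stoichiometry (override
    with ``stoichiometry_override`` to emulate a knockout). An
    ``artifact_fraction`` of reads keep ALL their cytosines unconverted.
    Returns (reads, per-read truth table).
    """
    if not 0.9 < conversion_rate <= 1.0:
        raise ValueError("conversion_rate must be in (0.9, 1]")
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    rng = np.random.default_rng(seed)
    site_stoich = {
        (s.transcript_id, s.pos): (
            s.stoichiometry if stoichiometry_override is None else stoichiometry_override
        )
        for s in truth.planted_sites
    }
    reads: List[Tuple[str, str]] = []
    rows = []
    i = 0
    for tx in sorted(seqs):
        seq = seqs[tx]
        n_reads = math.ceil(coverage * len(seq) / read_len)
        starts = rng.integers(0, len(seq) - read_len + 1, size=n_reads)
        artifacts = rng.random(n_reads) < artifact_fraction
        for start, is_artifact in zip(starts, artifacts):
            start = int(start)
            frag = list(seq[start : start + read_len])
            n_c = 0
            for j, base in enumerate(frag):
                if base != "C":
                    continue
                n_c += 1
                if is_artifact:
                    continue  # conversion-resistant: stays C
                stoich = site_stoich.get((tx, start + j))
                if stoich is not None:
                    if rng.random() >= stoich:
                        frag[j] = "T"
                else:
                    if rng.random() < conversion_rate:
                        frag[j] = "T"
            read_id = f"bs{i:07d}"
            reads.append((read_id, "".join(frag)))
            rows.append((read_id, tx, start, bool(is_artifact), n_c))
            i += 1
    read_truth = pd.DataFrame(
        rows, columns=["read_id", "transcript_id", "start", "is_artifact", "n_cytosines"]
    )
    return reads, read_truth


# ---------------------------------------------------------------------------
# Ribosome footprints


def simulate_ribo_footprints(
    truth: SimTruth,
    models: Sequence[TranscriptModel],
    expression: int = 5,
    lengths: Sequence[int] = (27, 28, 29),
    psite_offset: int = 12,
    readthrough_fraction: float = 0.0,
    readthrough_depth: Optional[int] = None,
    stop_psite_dwell: int = 0,
    seed: int = 0,
) -> List[AlignedRead]:
    """Triplet-periodic footprints whose P-site walks the CDS codon starts.

    The P-site nucleotide sits at read offset ``psite_offset`` (0-based), so
    the A-site codon of the terminal footprint (P-site on the last sense
    codon) is the annotated stop. ``stop_psite_dwell`` adds reads with the
    STOP codon in the P-site (a post-termination stall), used to emulate a
    knockout with increased terminal dwell. A ``readthrough_fraction`` of
    motif-carrying transcripts additionally gets in-frame footprints from
    the stop up to (but not past) the planted 3'UTR motif; the transcripts
    chosen are recorded in ``truth.readthrough_fraction``.
    """
    if psite_offset < 0:
        raise ValueError("psite_offset must be >= 0")
    if any(l < 26 or l > 31 for l in lengths):
        raise ValueError("footprint lengths must be within [26, 31]")
    rng = np.random.default_rng(seed)
    lengths = list(lengths)
    motif_tx = sorted(
        {s.transcript_id for s in truth.planted_sites if s.motif_present}
    )
    n_rt = round(readthrough_fraction * len(motif_tx))
    rt_tx = set(rng.choice(motif_tx, size=n_rt, replace=False)) if n_rt else set()
    for tx in rt_tx:
        truth.readthrough_fraction[tx] = 1.0
    rt_depth = expression if readthrough_depth is None else readthrough_depth
    site_by_tx = {s.transcript_id: s.pos for s in truth.planted_sites}

    reads: List[AlignedRead] = []
    i = 0

    def emit(model: TranscriptModel, psite: int, n: int) -> None:
        nonlocal i
        for _ in range(n):
            length = int(lengths[int(rng.integers(len(lengths)))])
            start = psite - psite_offset
            if start < 0 or start + length > len(model.sequence):
                continue
            reads.append(
                AlignedRead(
                    read_id=f"fp{i:07d}",
                    contig=model.contig,
                    pos=start,
                    strand="+",
                    length=length,
                    mismatches=0,
                    query=model.sequence[start : start + length],
                )
            )
            i += 1

    for model in models:
        if not model.has_cds:
            continue
        for psite in range(model.cds_start, model.cds_end - 3, 3):
            emit(model, psite, expression)
        if stop_psite_dwell:
            emit(model, model.cds_end - 3, stop_psite_dwell)
        if model.transcript_id in rt_tx:
            site_pos = site_by_tx[model.transcript_id]
            psite = model.cds_end
            while psite + 3 <= site_pos:
                emit(model, psite, rt_depth)
                psite += 3
    return reads


# ---------------------------------------------------------------------------
# Count matrices


def simulate_counts(
    n_genes: int,
    n_reps: int = 4,
    dispersion: float = 0.05,
    de_fraction: float = 0.0,
    lfc_sd: float = 1.0,
    seed: int = 0,
    mean_range: Tuple[float, float] = (50.0, 2000.0),
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial RNA and Ribo count matrices with planted delta-TE.

    A ``de_fraction`` of genes receives a nonzero true
    ``delta_te = log2FC_ribo - log2FC_rna`` (drawn N(0, lfc_sd), applied to
    the Ribo assay only). Returns (rna, ribo, truth) data frames; count
    columns are ctrl_1..n then ko_1..n.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    base = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), size=n_genes))
    is_de = rng.random(n_genes) < de_fraction
    delta = np.where(is_de, rng.normal(0.0, lfc_sd, size=n_genes), 0.0)
    lfc_rna = np.zeros(n_genes)
    lfc_ribo = lfc_rna + delta

    def sample(mean_ctrl: np.ndarray, lfc: np.ndarray) -> pd.DataFrame:
        cols = {}
        for r in range(n_reps):
            cols[f"ctrl_{r + 1}"] = _nb(rng, mean_ctrl, dispersion)
        mean_ko = mean_ctrl * np.exp2(lfc)
        for r in range(n_reps):
            cols[f"ko_{r + 1}"] = _nb(rng, mean_ko, dispersion)
        return pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))

    rna = sample(base, lfc_rna)
    ribo = sample(base, lfc_ribo)
    truth = pd.DataFrame(
        {
            "log2fc_rna": lfc_rna,
            "log2fc_ribo": lfc_ribo,
            "delta_te": delta,
            "is_de": is_de,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return rna, ribo, truth


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, mean * dispersion))
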