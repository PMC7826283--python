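"""Motif scanning, hairpin free-energy screening, transcriptome-wide site
prediction, and the readthrough / stop-codon-context sequence analyses.

The hairpin model is a deliberately simplified nearest-neighbour score
(per-pair energies for Watson-Crick and GT/GU wobble pairs, a linear loop
penalty and a bulge penalty), calibrated so that a 6-bp GC stem closed by
a short loop scores at or below the -5 kcal/mol stem-loop threshold. An
external folding engine can be plugged in for real-data use via
``energy_fn``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core_io import STOP_CODONS, SiteRecord, TranscriptModel

DEFAULT_MOTIF = "CTC[CT]A"


@dataclass
class MotifHit:
    contig: str
    start: int  # 0-based position of the methylated C (first motif base)
    strand: str
    pattern_matched: str


def _parse_pattern(pattern: str) -> List[FrozenSet[str]]:
    """Parse a simple character-class pattern ("CTC[CT]A") into base sets."""
    sets: List[FrozenSet[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            sets.append(frozenset(pattern[i + 1 : j]))
            i = j + 1
        else:
            sets.append(frozenset(ch))
            i += 1
    return sets


def scan_motif(
    sequence: str, pattern: str = DEFAULT_MOTIF, contig: str = ".", strand: str = "+"
) -> List[MotifHit]:
    """All (possibly overlapping) motif matches; the methylated C is the
    match start. Implemented as a direct sliding-window scan (no regex)."""
    sets = _parse_pattern(pattern)
    k = len(sets)
    seq = sequence.upper().replace("U", "T")
    hits: List[MotifHit] = []
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in sets[j] for j in range(k)):
            hits.append(MotifHit(contig, i, strand, seq[i : i + k]))
    return hits


# ---------------------------------------------------------------------------
# Hairpin energy model

#: unordered pair type -> stacking energy (kcal/mol); symmetric by design
PAIR_ENERGY: Dict[FrozenSet[str], float] = {
    frozenset("GC"): -3.0,
    frozenset("AT"): -2.0,
    frozenset("GT"): -1.0,
}

MIN_STEM_PAIRS = 3
LOOP_BASE_PENALTY = 3.0
LOOP_LENGTH_PENALTY = 0.4  # per nt beyond the 3-nt minimum
BULGE_PENALTY = 3.0
MIN_LOOP = 3
MAX_LOOP = 10
STEM_LOOP_THRESHOLD = -5.0


@dataclass
class HairpinCall:
    window: str
    energy: float
    is_stem_loop: bool
    motif_in_loop: bool
    loop: Optional[Tuple[int, int]] = None  # best-register loop interval
    n_pairs: int = 0


def _pair_energy(a: str, b: str) -> Optional[float]:
    return PAIR_ENERGY.get(frozenset((a, b)))


def hairpin_energy(
    window: str,
    threshold: float = STEM_LOOP_THRESHOLD,
    min_loop: int = MIN_LOOP,
    max_loop: int = MAX_LOOP,
    energy_fn: Optional[Callable[[str], float]] = None,
) -> HairpinCall:
    """Minimum hairpin energy over all loop registers of the window.

    For each candidate loop, base pairs are extended outward from the loop
    boundary; one single-nucleotide bulge per arm is allowed at a penalty.
    Registers with fewer than 3 consecutive pairs score 0 (no nucleation),
    so a negative energy requires at least 3 pairs. ``is_stem_loop`` is
    true iff the minimum energy is at or below the threshold;
    ``motif_in_loop`` is true iff the central base of the window falls in
    the unpaired loop of the best register. ``energy_fn`` (sequence ->
    kcal/mol) overrides the internal model for the energy value.
    """
    seq = window.upper().replace("U", "T")
    n = len(seq)
    center = n // 2
    best = HairpinCall(window=seq, energy=0.0, is_stem_loop=False, motif_in_loop=False)
    if n < MIN_STEM_PAIRS * 2 + min_loop:
        return best
    for loop_len in range(min_loop, max_loop + 1):
        for loop_start in range(1, n - loop_len):
            energy = LOOP_BASE_PENALTY + LOOP_LENGTH_PENALTY * (loop_len - min_loop)
            n_pairs = 0
            bulges = 0
            l, r = loop_start - 1, loop_start + loop_len
            while l >= 0 and r < n:
                e = _pair_energy(seq[l], seq[r])
                if e is not None:
                    energy += e
                    n_pairs += 1
                    l -= 1
                    r += 1
                    continue
                if n_pairs >= 1 and bulges < 2:
                    if l - 1 >= 0 and _pair_energy(seq[l - 1], seq[r]) is not None:
                        energy += BULGE_PENALTY
                        bulges += 1
                        l -= 1
                        continue
                    if r + 1 < n and _pair_energy(seq[l], seq[r + 1]) is not None:
                        energy += BULGE_PENALTY
                        bulges += 1
                        r += 1
                        continue
                break
            if n_pairs < MIN_STEM_PAIRS:
                continue
            if energy < best.energy:
                best = HairpinCall(
                    window=seq,
                    energy=energy,
                    is_stem_loop=False,
                    motif_in_loop=loop_start <= center < loop_start + loop_len,
                    loop=(loop_start, loop_start + loop_len),
                    n_pairs=n_pairs,
                )
    if energy_fn is not None:
        best.energy = float(energy_fn(seq))
    best.is_stem_loop = best.energy <= threshold
    return best


# ---------------------------------------------------------------------------
# Transcriptome-wide prediction


@dataclass
class PredictionResult:
    predicted: List[MotifHit]
    n_predicted: int
    n_observed: int
    n_overlap: int
    fraction_observed_of_predicted: float
    calls: List[HairpinCall] = field(default_factory=list)


def predict_transcriptome_sites(
    transcripts: Sequence[TranscriptModel],
    observed_sites: Sequence[SiteRecord] = (),
    motif: str = DEFAULT_MOTIF,
    energy_threshold: float = STEM_LOOP_THRESHOLD,
    flank: int = 25,
    energy_fn: Optional[Callable[[str], float]] = None,
) -> PredictionResult:
    """Predicted sequence-structure elements: motif hits whose centred
    window passes the stem-loop energy screen; reports overlap with the
    observed site set."""
    predicted: List[MotifHit] = []
    calls: List[HairpinCall] = []
    for model in transcripts:
        seq = model.sequence
        for hit in scan_motif(seq, motif, contig=model.contig):
            lo = max(0, hit.start - flank)
            window = seq[lo : hit.start + flank + 1]
            call = hairpin_energy(window, threshold=energy_threshold, energy_fn=energy_fn)
            if call.is_stem_loop or energy_threshold == float("inf"):
                predicted.append(hit)
                calls.append(call)
    pred_keys = {(h.contig, h.start) for h in predicted}
    obs_keys = {(s.contig, s.pos) for s in observed_sites}
    overlap = pred_keys & obs_keys
    return PredictionResult(
        predicted=predicted,
        n_predicted=len(pred_keys),
        n_observed=len(obs_keys),
        n_overlap=len(overlap),
        fraction_observed_of_predicted=(len(overlap) / len(pred_keys)) if pred_keys else 0.0,
        calls=calls,
    )


# ---------------------------------------------------------------------------
# Readthrough analyses


def inframe_stop_frequency(
    transcript: TranscriptModel,
    annotated_stop_offset: int,
    site_offset: int,
) -> Tuple[int, int, bool]:
    """In-frame stop codons between the annotated stop and a 3'UTR site,
    versus an equal-size control region immediately downstream of the site.

    The reading frame continues from the annotated stop codon. Codons
    counted lie entirely within (stop codon end, site] and, for the
    control, within the next region of equal codon count. Returns
    (n_between, n_control, control_truncated). The site must be downstream
    of the stop.
    """
    if site_offset <= annotated_stop_offset:
        raise ValueError("site must be downstream of the annotated stop")
    seq = transcript.sequence
    first = annotated_stop_offset + 3  # first codon start after the stop
    # codons entirely within (stop codon end, site]: start <= site - 2
    starts_between = [s for s in range(first, site_offset - 1, 3)]
    n_between = sum(1 for s in starts_between if seq[s : s + 3] in STOP_CODONS)

    n_codons = len(starts_between)
    control_first = first + 3 * n_codons
    truncated = False
    n_control = 0
    for k in range(n_codons):
        s = control_first + 3 * k
        if s + 3 > len(seq):
            truncated = True
            break
        if seq[s : s + 3] in STOP_CODONS:
            n_control += 1
    return n_between, n_control, truncated


@dataclass
class StopContext:
    stop_codon: str
    next_base: str  # A/C/G/T or "end"
    weight: float


def stop_codon_context(
    transcript_models: Sequence[TranscriptModel],
    target_genes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Distribution over (stop codon, downstream base) pairs.

    Each gene's annotated stops contribute weight 1/k (k stops per gene),
    so per-gene weights sum to 1 and total weight equals the gene count.
    Returns a tidy frame with columns stop_codon, next_base, weight_all,
    weight_targets (targets only populated when ``target_genes`` given).
    """
    target_set = set(target_genes) if target_genes is not None else None
    weights_all: Dict[Tuple[str, str], float] = defaultdict(float)
    weights_tgt: Dict[Tuple[str, str], float] = defaultdict(float)
    by_gene: Dict[str, List[Tuple[TranscriptModel, int, str]]] = defaultdict(list)
    for m in transcript_models:
        for off, codon in m.stop_codons:
            by_gene[m.gene_id].append((m, off, codon))
    for gene, stops in by_gene.items():
        w = 1.0 / len(stops)
        for model, off, codon in stops:
            nxt = model.sequence[off + 3] if off + 3 < len(model.sequence) else "end"
            weights_all[(codon, nxt)] += w
            if target_set is not None and gene in target_set:
                weights_tgt[(codon, nxt)] += w
    keys = sorted(set(weights_all) | set(weights_tgt))
    return pd.DataFrame(
        {
            "stop_codon": [k[0] for k in keys],
            "next_base": [k[1] for k in keys],
            "weight_all": [weights_all.get(k, 0.0) for k in keys],
            "weight_targets": [weights_tgt.get(k, 0.0) for k in keys],
        }
    )
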