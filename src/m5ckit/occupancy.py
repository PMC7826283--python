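"""Coverage matrices around sites, upstream/downstream signal
classification, and coding-annotation profiles with a randomized motif
control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .core_io import SiteRecord, Track, TranscriptModel


def matrix_around_sites(
    track: Track, sites: Sequence[SiteRecord], flank: int = 1500
) -> np.ndarray:
    """Sites x positions coverage matrix, columns -flank..flank-1.

    Each row is the track slice [pos - flank, pos + flank) in the 5'->3'
    orientation of the site's strand (minus-strand rows are reversed), with
    missing data and out-of-contig positions as 0. Column ``flank`` (label
    0) aligns to the site nucleotide.
    """
    out = np.zeros((len(sites), 2 * flank))
    for i, s in enumerate(sites):
        per = track.get(s.contig, {})
        row = [float(per.get(p, 0.0)) for p in range(s.pos - flank, s.pos + flank)]
        if s.strand == "-":
            row = row[::-1]
        out[i, :] = row
    return out


def column_labels(flank: int) -> np.ndarray:
    return np.arange(-flank, flank)


@dataclass
class Classification:
    classes: List[str]  # per site: lower / unchanged / higher
    d: np.ndarray  # upstream-minus-downstream covered-base difference
    se: float

    def group_sizes(self) -> Dict[str, int]:
        out = {"lower": 0, "unchanged": 0, "higher": 0}
        for c in self.classes:
            out[c] += 1
        return out


def classify_sites(matrix: np.ndarray, z: float = 1.96, use_depth: bool = False) -> Classification:
    """Classify each site by upstream vs downstream footprint signal.

    d = (# upstream positions with coverage > 0) - (# downstream covered),
    or the depth sums when ``use_depth``. The standard error of d is
    computed over all sites (population SD / sqrt(n)); a site is "higher"
    if d > +z*SE, "lower" if d < -z*SE, else "unchanged". Requires at
    least 2 sites.
    """
    n_sites, width = matrix.shape
    if n_sites < 2:
        raise ValueError("classification needs at least 2 sites")
    half = width // 2
    up, down = matrix[:, :half], matrix[:, half:]
    if use_depth:
        d = up.sum(axis=1) - down.sum(axis=1)
    else:
        d = (up > 0).sum(axis=1) - (down > 0).sum(axis=1)
    d = d.astype(float)
    se = float(d.std(ddof=0) / np.sqrt(n_sites))
    classes = [
        "higher" if di > z * se else "lower" if di < -z * se else "unchanged"
        for di in d
    ]
    return Classification(classes, d, se)


def cds_profile_around_sites(
    transcript_models: Sequence[TranscriptModel],
    sites: Sequence[SiteRecord],
    flank: int = 1500,
) -> np.ndarray:
    """Per column, the fraction of sites whose aligned position falls inside
    a (merged) annotated CDS. Positions off the transcript count as
    non-coding."""
    cds_by_contig: Dict[str, List[Tuple[int, int]]] = {}
    for m in transcript_models:
        if m.has_cds:
            cds_by_contig.setdefault(m.contig, []).append((m.cds_start, m.cds_end))
    merged: Dict[str, List[Tuple[int, int]]] = {}
    for contig, ivs in cds_by_contig.items():
        ivs.sort()
        acc: List[Tuple[int, int]] = []
        for s, e in ivs:
            if acc and s <= acc[-1][1]:
                acc[-1] = (acc[-1][0], max(acc[-1][1], e))
            else:
                acc.append((s, e))
        merged[contig] = acc

    out = np.zeros(2 * flank)
    if not sites:
        return out
    for s in sites:
        ivs = merged.get(s.contig, [])
        positions = np.arange(s.pos - flank, s.pos + flank)
        if s.strand == "-":
            positions = positions[::-1]
        inside = np.zeros(2 * flank, dtype=bool)
        for a, b in ivs:
            inside |= (positions >= a) & (positions < b)
        out += inside
    return out / len(sites)


@dataclass
class ControlEnvelope:
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray


def random_motif_control(
    sites: Sequence[SiteRecord],
    candidate_positions: Sequence[SiteRecord],
    profile_fn: Callable[[Sequence[SiteRecord]], np.ndarray],
    n_draws: int = 1000,
    seed: int = 0,
    ci: float = 95.0,
) -> ControlEnvelope:
    """Randomized control: resample |sites| candidates without replacement
    ``n_draws`` times, evaluate ``profile_fn`` on each draw, and return the
    mean with a percentile envelope (default 2.5-97.5)."""
    if len(candidate_positions) < len(sites):
        raise ValueError("candidate pool smaller than the site set")
    rng = np.random.default_rng(seed)
    draws = []
    pool = list(candidate_positions)
    for _ in range(n_draws):
        idx = rng.choice(len(pool), size=len(sites), replace=False)
        draws.append(profile_fn([pool[i] for i in idx]))
    arr = np.asarray(draws)
    alpha = (100.0 - ci) / 2.0
    return ControlEnvelope(
        mean=arr.mean(axis=0),
        lo=np.percentile(arr, alpha, axis=0),
        hi=np.percentile(arr, 100.0 - alpha, axis=0),
    )


def profile_table(profile: np.ndarray, flank: int, envelope: ControlEnvelope = None) -> pd.DataFrame:
    df = pd.DataFrame({"position": column_labels(flank), "observed": profile})
    if envelope is not None:
        df["control_mean"] = envelope.mean
        df["control_lo"] = envelope.lo
        df["control_hi"] = envelope.hi
    return df
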