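"""Minimal seed-and-verify aligner for transcriptome-scale references.

Supports an optional alphabet collapse (C->T) so the bisulfite stage can
align in three-letter space while the miCLIP stage aligns in full space.
Unique-best semantics: a read is reported only when exactly one alignment
achieves the minimal mismatch count at or below the allowed maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Tuple

_K = 16  # seed length


def collapse_ct(seq: str) -> str:
    return seq.replace("C", "T")


@dataclass
class Hit:
    contig: str
    pos: int
    mismatches: int


class SeqIndex:
    """Exact k-mer index over a (possibly collapsed) reference."""

    def __init__(self, reference: Dict[str, str], transform: Optional[Callable[[str], str]] = None):
        self.transform = transform or (lambda s: s)
        self.ref = {name: self.transform(seq.upper()) for name, seq in reference.items()}
        self.kmers: Dict[str, List[Tuple[str, int]]] = {}
        for name, seq in self.ref.items():
            for i in range(len(seq) - _K + 1):
                self.kmers.setdefault(seq[i : i + _K], []).append((name, i))

    def _candidates(self, query: str, max_mismatches: int) -> List[Tuple[str, int]]:
        """Diagonal candidates via pigeonhole seeding: with m mismatches at
        least one of m+1 non-overlapping seeds matches exactly."""
        n = len(query)
        n_seeds = max_mismatches + 1
        seen = set()
        out: List[Tuple[str, int]] = []
        for j in range(n_seeds):
            off = min(j * (n // n_seeds), n - _K)
            if off < 0:
                break
            for contig, pos in self.kmers.get(query[off : off + _K], ()):
                start = pos - off
                if start < 0:
                    continue
                key = (contig, start)
                if key not in seen:
                    seen.add(key)
                    out.append(key)
        return out

    def align(self, query: str, max_mismatches: int = 0) -> Optional[Hit]:
        """Return the unique best hit, or None (no hit / ambiguous best)."""
        q = self.transform(query.upper())
        if len(q) < _K:
            return None
        best: List[Hit] = []
        best_mm = max_mismatches + 1
        for contig, start in self._candidates(q, max_mismatches):
            ref = self.ref[contig]
            if start + len(q) > len(ref):
                continue
            mm = 0
            for a, b in zip(q, ref[start : start + len(q)]):
                if a != b:
                    mm += 1
                    if mm > max_mismatches:
                        break
            if mm > max_mismatches:
                continue
            if mm < best_mm:
                best_mm = mm
                best = [Hit(contig, start, mm)]
            elif mm == best_mm:
                best.append(Hit(contig, start, mm))
        if len(best) == 1:
            return best[0]
        return None

    def align_all(self, query: str, max_mismatches: int = 0) -> List[Hit]:
        """All valid hits at or below the mismatch cap (for multi-mapper logic)."""
        q = self.transform(query.upper())
        if len(q) < _K:
            return []
        hits: List[Hit] = []
        for contig, start in self._candidates(q, max_mismatches):
            ref = self.ref[contig]
            if start + len(q) > len(ref):
                continue
            mm = sum(1 for a, b in zip(q, ref[start : start + len(q)]) if a != b)
            if mm <= max_mismatches:
                hits.append(Hit(contig, start, mm))
        return hits
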