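"""5'UTR regulatory motif scanning: IRE stem-loops, Musashi binding
elements, a motif census over inclusion vs exclusion first-exon sequences,
and a base-pair-maximization hairpin support score.

The IRE detector looks for the apical loop consensus C-A-G-N-G-N flanked by
a 5-bp upper stem (Watson-Crick or G.U pairs, antiparallel) with the single
unpaired C bulge immediately 5' of the stem.  The loop is deliberately more
degenerate than the canonical CAGUGH so that naturally occurring IRE-like
elements with non-canonical loops are admitted; a strict mode restores the
canonical consensus.  Scanning is sense-strand only: 5'UTRs arrive in mRNA
sense.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ValidationError

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}
_VALID = set("ACGUTN")

STEM_LEN = 5
LOOP_LEN = 6


@dataclass(frozen=True)
class IreHit:
    sequence_id: str
    loop_start: int
    loop_seq: str
    stem_pairs: int
    bulge_c_offset: int
    span: tuple[int, int]

    @property
    def mismatches(self) -> int:
        return STEM_LEN - self.stem_pairs


def _norm(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - _VALID
    if bad:
        raise ValidationError(f"illegal characters in sequence: {sorted(bad)}")
    return s


def _paired(a: str, b: str) -> bool:
    return (a, b) in _WC or (a, b) in _GU


def _loop_ok(loop: str, strict: bool) -> bool:
    if "N" in loop:
        return False
    if strict:
        # canonical CAGUGH (H = not G)
        return loop[:5] == "CAGUG" and loop[5] != "G"
    return loop[0] == "C" and loop[1] == "A" and loop[2] == "G" and loop[4] == "G"


def scan_ire(seq: str, sequence_id: str = "", min_pairs: int = 4, strict_loop: bool = False) -> list[IreHit]:
    """Find IRE-like stem-loops on the sense strand.

    For every loop-consensus hexamer the 5 nt on either side form the upper
    stem (antiparallel pairing, WC or G.U); a hit needs >= ``min_pairs``
    paired positions of 5 and a C immediately 5' of the stem (the unpaired
    bulge).  Overlapping hits are all reported.  Sequences shorter than the
    full element yield no hits.
    """
    s = _norm(seq)
    hits: list[IreHit] = []
    # element layout: [bulge C][5' arm x5][loop x6][3' arm x5]
    for i in range(STEM_LEN + 1, len(s) - (LOOP_LEN + STEM_LEN) + 1):
        loop = s[i : i + LOOP_LEN]
        if not _loop_ok(loop, strict_loop):
            continue
        arm5 = s[i - STEM_LEN : i]
        arm3 = s[i + LOOP_LEN : i + LOOP_LEN + STEM_LEN]
        if "N" in arm5 or "N" in arm3:
            continue
        pairs = sum(_paired(arm5[k], arm3[STEM_LEN - 1 - k]) for k in range(STEM_LEN))
        if pairs >= min_pairs and s[i - STEM_LEN - 1] == "C":
            hits.append(
                IreHit(
                    sequence_id=sequence_id,
                    loop_start=i,
                    loop_seq=loop,
                    stem_pairs=pairs,
                    bulge_c_offset=i - STEM_LEN - 1,
                    span=(i - STEM_LEN - 1, i + LOOP_LEN + STEM_LEN),
                )
            )
    return hits


_MBE_RE = re.compile(r"(?=([GA]U{1,3}AGU))")


def scan_mbe(seq: str, sequence_id: str = "") -> list[tuple[int, str]]:
    """All (possibly overlapping) Musashi binding elements (G/A)U(1-3)AGU."""
    s = _norm(seq)
    return [(m.start(), m.group(1)) for m in _MBE_RE.finditer(s)]


DEFAULT_SCANNERS: Mapping[str, Callable] = {
    "IRE": lambda seq, sid: scan_ire(seq, sid),
    "MBE": lambda seq, sid: scan_mbe(seq, sid),
}


def motif_census(
    inclusion_seqs: Sequence[tuple[str, str]],
    exclusion_seqs: Sequence[tuple[str, str]],
    scanners: Mapping[str, Callable] = DEFAULT_SCANNERS,
) -> pd.DataFrame:
    """Count motif hits in inclusion-exon vs exclusion-exon sequence sets.

    Returns one row per motif class with totals per set, the
    inclusion:exclusion ratio, and per-sequence hit counts in the row's
    ``per_sequence`` columns.
    """
    rows = []
    for name, fn in scanners.items():
        per_inc = {sid: len(fn(seq, sid)) for sid, seq in inclusion_seqs}
        per_exc = {sid: len(fn(seq, sid)) for sid, seq in exclusion_seqs}
        inc_total = sum(per_inc.values())
        exc_total = sum(per_exc.values())
        rows.append(
            {
                "motif": name,
                "inclusion_total": inc_total,
                "exclusion_total": exc_total,
                "ratio": (inc_total / exc_total) if exc_total else np.inf if inc_total else np.nan,
                "per_sequence_inclusion": per_inc,
                "per_sequence_exclusion": per_exc,
            }
        )
    return pd.DataFrame(rows).set_index("motif")


def hairpin_support(seq: str, min_loop: int = 3) -> int:
    """Maximum number of non-crossing base pairs (WC + G.U) by dynamic
    programming, with a minimum hairpin loop of ``min_loop`` unpaired bases.

    A coarse stand-in for thermodynamic folding: it scores how much pairing
    a window can support, not a free energy.
    """
    s = _norm(seq)
    n = len(s)
    if n > 200:
        raise ValidationError("hairpin_support window must be <= 200 nt")
    dp = np.zeros((n + 1, n + 1), dtype=int)  # dp[i][j]: max pairs in s[i:j]
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            best = dp[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j):  # pair i with k
                if _paired(s[i], s[k]):
                    cand = 1 + dp[i + 1][k] + dp[k + 1][j]
                    if cand > best:
                        best = cand
            dp[i][j] = best
    return int(dp[0][n])


def hits_table(hits: Sequence[IreHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sequence_id": h.sequence_id,
                "motif": "IRE",
                "start": h.span[0],
                "end": h.span[1],
                "loop_seq": h.loop_seq,
                "stem_pairs": h.stem_pairs,
            }
            for h in hits
        ],
        columns=["sequence_id", "motif", "start", "end", "loop_seq", "stem_pairs"],
    )
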