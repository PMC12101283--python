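"""Spacer-gene suitability scoring for ribosome display.

The spacer gene tethers the nascent nanobody inside the ribosome exit
tunnel.  Its mRNA must be traversed by the ribosome, and the reconstituted
translation system contains no helicases, so GC-rich spacers that fold into
stable secondary structure stall translation and depress display
efficiency.  Two cheap sequence-level proxies are computed here: windowed
GC content and the maximum number of nested base pairs the sequence can
form (a Nussinov dynamic program over Watson-Crick plus GU wobble pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "SpacerProfile",
    "gc_profile",
    "max_pairing",
    "pairing_density",
    "profile_spacer",
    "compare_spacers",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _normalize(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    return s


def _can_pair(a: str, b: str, wobble: bool) -> bool:
    pair = a + b
    if pair in ("AT", "TA", "GC", "CG"):
        return True
    return wobble and pair in ("GT", "TG")


@dataclass(frozen=True)
class SpacerProfile:
    """GC and base-pairing summary of one spacer sequence."""

    name: str
    length: int
    gc_overall: float
    gc_windows: tuple[tuple[int, int, float], ...]  # (start, end) half-open, 0-based
    pairing_score: int | None = None
    pairing_density: float | None = None


def gc_profile(
    seq: str,
    window: int,
    step: int | None = None,
    name: str = "",
) -> SpacerProfile:
    """Windowed GC content; the final partial window is included.

    Windows are half-open and 0-based internally.  With ``step`` omitted
    the windows tile the sequence.
    """
    s = _normalize(seq)
    if not s:
        raise ValueError("empty sequence")
    if window < 1:
        raise ValueError("window must be >= 1")
    step = window if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")

    def gc(frag: str) -> float:
        return (frag.count("G") + frag.count("C")) / len(frag)

    windows = []
    for start in range(0, len(s), step):
        end = min(start + window, len(s))
        windows.append((start, end, gc(s[start:end])))
        if end == len(s):
            break
    return SpacerProfile(
        name=name or "spacer",
        length=len(s),
        gc_overall=gc(s),
        gc_windows=tuple(windows),
    )


def max_pairing(seq: str, min_loop: int = 3, wobble: bool = True) -> int:
    """Maximum number of nested base pairs (Nussinov dynamic program).

    Counts Watson-Crick pairs plus, by default, GU wobble pairs, requiring
    at least ``min_loop`` unpaired bases inside every hairpin loop.  This is
    a combinatorial stand-in for thermodynamic folding: a high score means
    the sequence *can* form extensive secondary structure.
    """
    s = _normalize(seq) if seq else ""
    if min_loop < 0:
        raise ValueError("min_loop must be >= 0")
    n = len(s)
    if n == 0:
        return 0
    # dp[i][j] = max pairs in s[i..j] inclusive
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - min_loop):
                if _can_pair(s[k], s[j], wobble):
                    left = dp[i][k - 1] if k > i else 0
                    inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    cand = left + 1 + inner
                    if cand > best:
                        best = cand
            dp[i][j] = best
    return dp[0][n - 1]


def pairing_density(score: int, length: int) -> float:
    """Pairs per maximum possible pair count (length / 2)."""
    if length <= 0:
        raise ValueError("length must be positive")
    return score / (length / 2)


def profile_spacer(
    name: str,
    seq: str,
    window: int = 50,
    step: int | None = None,
    min_loop: int = 3,
    wobble: bool = True,
) -> SpacerProfile:
    """Full spacer profile: GC windows plus base-pairing score and density."""
    prof = gc_profile(seq, window=window, step=step, name=name)
    score = max_pairing(seq, min_loop=min_loop, wobble=wobble)
    return SpacerProfile(
        name=prof.name,
        length=prof.length,
        gc_overall=prof.gc_overall,
        gc_windows=prof.gc_windows,
        pairing_score=score,
        pairing_density=pairing_density(score, prof.length),
    )


def compare_spacers(profiles: list[SpacerProfile]) -> pd.DataFrame:
    """Rank spacers for display suitability: least structure-prone first.

    Sorted ascending by (pairing_density, gc_overall); stable, so identical
    profiles keep their input order.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two spacer profiles to compare")
    if any(p.pairing_density is None for p in profiles):
        raise ValueError("profiles must carry pairing scores (use profile_spacer)")
    frame = pd.DataFrame(
        {
            "name": [p.name for p in profiles],
            "length": [p.length for p in profiles],
            "gc_overall": [p.gc_overall for p in profiles],
            "pairing_score": [p.pairing_score for p in profiles],
            "pairing_density": [p.pairing_density for p in profiles],
        }
    )
    frame = frame.sort_values(
        ["pairing_density", "gc_overall"], kind="mergesort"
    ).reset_index(drop=True)
    frame.insert(0, "rank", range(1, len(frame) + 1))
    return frame
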