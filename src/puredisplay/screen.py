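"""Single-clone ELISA hit calling.

After the final biopanning round individual clones are expressed and
assayed in target-coated versus BSA-coated wells; the A450 ratio between
the two wells separates binders from background.  A clone is a hit when
its ratio strictly exceeds the threshold (default 1.9).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ElisaTable", "HitResult", "call_hits"]

REQUIRED_COLUMNS = ("clone", "a450_target", "a450_control")


@dataclass(frozen=True)
class ElisaTable:
    """Validated plate table with per-clone target/control absorbances."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"ELISA table missing columns {missing}")
        for col in ("a450_target", "a450_control"):
            vals = pd.to_numeric(self.frame[col], errors="raise")
            if (vals < 0).any():
                raise ValueError(f"negative absorbance in column {col!r}")

    @classmethod
    def from_csv(cls, path) -> "ElisaTable":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class HitResult:
    hits: pd.DataFrame  # sorted by descending ratio
    flagged: pd.DataFrame  # rows excluded for unreliable control wells
    threshold: float

    @property
    def n_hits(self) -> int:
        return len(self.hits)


def call_hits(
    table: ElisaTable | pd.DataFrame,
    ratio_threshold: float = 1.9,
    control_floor: float = 0.01,
) -> HitResult:
    """Call binder hits at a strict A450 target/control ratio threshold.

    Rows whose control absorbance falls below ``control_floor`` are
    excluded and flagged rather than allowed to produce unbounded ratios.
    Hits are ordered by descending ratio (ties keep input order).
    """
    if ratio_threshold <= 0:
        raise ValueError("ratio threshold must be positive")
    if isinstance(table, pd.DataFrame):
        table = ElisaTable(table)
    frame = table.frame.copy().reset_index(drop=True)

    unreliable = frame["a450_control"] < control_floor
    flagged = frame[unreliable].copy()
    usable = frame[~unreliable].copy()
    usable["ratio"] = usable["a450_target"] / usable["a450_control"]

    hits = usable[usable["ratio"] > ratio_threshold].copy()
    hits = hits.sort_values("ratio", ascending=False, kind="mergesort").reset_index(drop=True)
    return HitResult(hits=hits, flagged=flagged.reset_index(drop=True), threshold=ratio_threshold)
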