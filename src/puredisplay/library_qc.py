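"""Synthesis-error modelling and clone quality control.

Oligo-assembled libraries accumulate single-nucleotide deletions during
primer synthesis; a deletion shifts the reading frame and destroys the
clone.  This module injects such errors at a calibratable per-base rate and
classifies sequenced clones as full-length / in-frame / framework-correct,
reproducing the kind of pass fraction obtained by Sanger-sequencing a
random sample of transformants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import beta

from .library_design import Clone, LibraryScheme

__all__ = [
    "ErrorModel",
    "QcVerdict",
    "QcSummary",
    "apply_synthesis_errors",
    "qc_classify",
    "in_frame_fraction",
    "calibrate_deletion_rate",
    "translate_dna",
]

_CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
_CODON_TO_AA.update({codon: "*" for codon in standard_dna_table.stop_codons})

_NUCLEOTIDES = "ACGT"


@dataclass(frozen=True)
class ErrorModel:
    """Independent per-nucleotide synthesis errors.

    ``del_rate`` is the probability that any given nucleotide is deleted;
    ``sub_rate`` the probability it is substituted by a different base.
    Deletions dominate in practice (frameshifts), so substitutions default
    to zero.
    """

    del_rate: float
    sub_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name, rate in (("del_rate", self.del_rate), ("sub_rate", self.sub_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")


@dataclass(frozen=True)
class QcVerdict:
    clone_id: str
    in_frame: bool
    full_length: bool
    framework_match: bool
    fail_reason: str | None = None

    @property
    def passed(self) -> bool:
        return self.in_frame and self.full_length and self.framework_match


@dataclass(frozen=True)
class QcSummary:
    n: int
    n_pass: int
    fraction: float
    ci_low: float
    ci_high: float


def apply_synthesis_errors(
    clones: Sequence[Clone],
    model: ErrorModel,
    rng: np.random.Generator | None = None,
) -> list[Clone]:
    """Apply the error model independently to every nucleotide of every clone.

    Returns new clone records with mutated DNA (protein field left as the
    designed protein; the DNA is what gets sequenced).  Reproducible via
    ``model.seed`` or an explicit generator.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    if model.del_rate == 0.0 and model.sub_rate == 0.0:
        return list(clones)

    out: list[Clone] = []
    nt = np.frombuffer(_NUCLEOTIDES.encode(), dtype=np.uint8)
    for clone in clones:
        arr = np.frombuffer(clone.dna.encode(), dtype=np.uint8).copy()
        n = arr.size
        if model.sub_rate > 0.0 and n:
            sub_mask = rng.random(n) < model.sub_rate
            n_sub = int(sub_mask.sum())
            if n_sub:
                # substitute with a uniformly chosen *different* base
                offsets = rng.integers(1, 4, size=n_sub)
                current = np.searchsorted(nt, arr[sub_mask])
                arr[sub_mask] = nt[(current + offsets) % 4]
        if model.del_rate > 0.0 and n:
            keep = rng.random(n) >= model.del_rate
            arr = arr[keep]
        out.append(Clone(clone.clone_id, clone.protein, arr.tobytes().decode()))
    return out


def translate_dna(dna: str) -> str:
    """Translate complete codons; stop codons appear as '*'."""
    n = len(dna) // 3
    try:
        return "".join(_CODON_TO_AA[dna[3 * i : 3 * i + 3]] for i in range(n))
    except KeyError as exc:
        raise ValueError(f"invalid codon {exc.args[0]!r}") from None


def qc_classify(dna: str, scheme: LibraryScheme, clone_id: str = "") -> QcVerdict:
    """Classify a sequenced clone against the library scheme.

    ``in_frame``: length divisible by three and no internal stop codon.
    ``full_length``: the translated product has exactly the designed length
    (an in-frame 3-nt deletion is in frame but not full length).
    ``framework_match``: every framework position carries the designed
    residue (checked once the product is full length).
    """
    bad = set(dna) - set(_NUCLEOTIDES)
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")

    aa = translate_dna(dna)
    has_stop = "*" in aa
    if has_stop:
        aa = aa[: aa.index("*")]
    in_frame = (len(dna) % 3 == 0) and not has_stop
    full_length = (not has_stop) and len(aa) == scheme.protein_length and len(dna) % 3 == 0

    framework_match = False
    if full_length:
        fw = scheme.framework_positions()
        designed = scheme.assemble(["X" * c.length for c in scheme.cdrs])
        framework_match = all(aa[i] == designed[i] for i in fw)
        # fixed CDR residues are part of the design too
        if framework_match:
            offset = len(scheme.framework[0])
            for k, cdr in enumerate(scheme.cdrs):
                for pos, res in cdr.fixed.items():
                    if aa[offset + pos - 1] != res:
                        framework_match = False
                        break
                offset += cdr.length + len(scheme.framework[k + 1])

    if in_frame and full_length and framework_match:
        reason = None
    elif len(dna) % 3 != 0:
        reason = "frameshift"
    elif has_stop:
        reason = "internal_stop"
    elif not full_length:
        reason = "length_mismatch"
    else:
        reason = "framework_mismatch"
    return QcVerdict(clone_id, in_frame, full_length, framework_match, reason)


def in_frame_fraction(verdicts: Iterable[QcVerdict], conf: float = 0.95) -> QcSummary:
    """Pass fraction with an exact Clopper-Pearson confidence interval.

    Exactness matters at the small sample sizes typical of colony sequencing
    (tens of clones).
    """
    verdicts = list(verdicts)
    n = len(verdicts)
    if n == 0:
        raise ValueError("no verdicts supplied")
    k = sum(v.passed for v in verdicts)
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return QcSummary(n=n, n_pass=k, fraction=k / n, ci_low=lo, ci_high=hi)


def calibrate_deletion_rate(target_pass_prob: float, length_nt: int) -> float:
    """Per-base deletion rate giving a target zero-deletion (pass) probability.

    Under pure independent deletions a clone of length L passes iff it has no
    deletion, so the pass probability is (1 - d)**L; solve for d.
    """
    if not 0.0 < target_pass_prob <= 1.0:
        raise ValueError("target pass probability must lie in (0, 1]")
    if length_nt <= 0:
        raise ValueError("length must be positive")
    return 1.0 - target_pass_prob ** (1.0 / length_nt)
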