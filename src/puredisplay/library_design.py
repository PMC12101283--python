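"""Synthetic nanobody library definition and sampling.

A synthetic nanobody library is defined by a consensus framework scaffold
(FR1-FR4) derived from an alignment of published library frameworks, plus
three CDR randomization schemes.  Each CDR scheme fixes a few boundary
positions to their modal residue (when that residue's observed frequency in
structurally characterized nanobodies exceeds a threshold) and fully
randomizes the rest over the 19 amino acids excluding cysteine.  Sequences
sampled from the scheme are reverse-translated with a host-preferred codon
table, mirroring a trimer-phosphoramidite synthesis that avoids rare codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "CDR_ALPHABET",
    "ECOLI_PREFERRED_CODONS",
    "FrameworkAlignment",
    "CdrFrequencyTable",
    "CdrScheme",
    "LibraryScheme",
    "Clone",
    "consensus_framework",
    "design_cdr_scheme",
    "theoretical_diversity",
    "sample_clones",
    "reverse_translate",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: Default randomization alphabet: all 20 residues minus cysteine, which is
#: excluded to avoid unpaired thiols and aberrant disulfide cross-links.
CDR_ALPHABET = "".join(a for a in AMINO_ACIDS if a != "C")

#: Most frequent codon per amino acid in highly expressed E. coli genes;
#: used so designed genes avoid rare codons in the expression host.
ECOLI_PREFERRED_CODONS: dict[str, str] = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}


@dataclass(frozen=True)
class FrameworkAlignment:
    """Aligned amino-acid framework sequences (gaps allowed)."""

    names: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows must have equal length")
        if not self.rows:
            raise ValueError("alignment is empty")
        length = len(self.rows[0])
        allowed = set(AMINO_ACIDS) | {GAP}
        for name, row in zip(self.names, self.rows):
            if len(row) != length:
                raise ValueError(f"row {name!r} has length {len(row)}, expected {length}")
            bad = set(row) - allowed
            if bad:
                raise ValueError(f"row {name!r} contains invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class CdrFrequencyTable:
    """Per-position amino-acid frequency table for one CDR.

    ``freqs[i]`` maps residue -> frequency at 1-based position ``i + 1``;
    each position's frequencies must sum to 1 within 1e-9.
    """

    cdr_id: str
    freqs: tuple[Mapping[str, float], ...]

    def __post_init__(self) -> None:
        if not self.freqs:
            raise ValueError("frequency table must cover at least one position")
        for i, dist in enumerate(self.freqs):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.cdr_id} position {i + 1}: frequencies sum to {total}, not 1"
                )
            if any(f < 0 for f in dist.values()):
                raise ValueError(f"{self.cdr_id} position {i + 1}: negative frequency")

    @property
    def length(self) -> int:
        return len(self.freqs)

    def modal_residue(self, position: int) -> tuple[str, float]:
        """Most frequent residue at a 1-based position (alphabetical tie-break)."""
        dist = self.freqs[position - 1]
        top = max(dist.values())
        winners = sorted(res for res, f in dist.items() if f == top)
        return winners[0], top


@dataclass(frozen=True)
class CdrScheme:
    """Randomization scheme for one CDR: fixed positions + free alphabet."""

    cdr_id: str
    length: int
    fixed: Mapping[int, str] = field(default_factory=dict)
    alphabet: str = CDR_ALPHABET

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("CDR length must be positive")
        for pos, res in self.fixed.items():
            if not 1 <= pos <= self.length:
                raise ValueError(f"fixed position {pos} outside [1, {self.length}]")
            if res not in AMINO_ACIDS:
                raise ValueError(f"fixed residue {res!r} is not an amino acid")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet contains duplicate residues")

    @property
    def n_randomized(self) -> int:
        return self.length - len(self.fixed)

    @property
    def randomized_positions(self) -> tuple[int, ...]:
        return tuple(p for p in range(1, self.length + 1) if p not in self.fixed)


@dataclass(frozen=True)
class LibraryScheme:
    """Full generative definition of a synthetic nanobody library.

    The assembled protein is FR1 + CDR1 + FR2 + CDR2 + FR3 + CDR3 + FR4.
    """

    framework: tuple[str, str, str, str]
    cdrs: tuple[CdrScheme, CdrScheme, CdrScheme]
    codon_table: Mapping[str, str] = field(default_factory=lambda: dict(ECOLI_PREFERRED_CODONS))

    def __post_init__(self) -> None:
        if len(self.framework) != 4:
            raise ValueError("framework must have four segments FR1-FR4")
        if len(self.cdrs) != 3:
            raise ValueError("scheme must define exactly three CDRs")
        needed = set("".join(self.framework))
        for cdr in self.cdrs:
            needed |= set(cdr.fixed.values())
            needed |= set(cdr.alphabet)
        missing = needed - set(self.codon_table)
        if missing:
            raise ValueError(f"codon table lacks residues {sorted(missing)}")

    @property
    def protein_length(self) -> int:
        return sum(len(s) for s in self.framework) + sum(c.length for c in self.cdrs)

    @property
    def dna_length(self) -> int:
        return 3 * self.protein_length

    def assemble(self, cdr_seqs: Sequence[str]) -> str:
        """Interleave framework segments with concrete CDR sequences."""
        c1, c2, c3 = cdr_seqs
        f1, f2, f3, f4 = self.framework
        return f1 + c1 + f2 + c2 + f3 + c3 + f4

    def framework_positions(self) -> np.ndarray:
        """0-based indices of framework residues in the assembled protein."""
        idx = []
        offset = 0
        parts = [self.framework[0], self.cdrs[0].length, self.framework[1],
                 self.cdrs[1].length, self.framework[2], self.cdrs[2].length,
                 self.framework[3]]
        for part in parts:
            if isinstance(part, str):
                idx.extend(range(offset, offset + len(part)))
                offset += len(part)
            else:
                offset += part
        return np.asarray(idx, dtype=np.intp)


@dataclass(frozen=True)
class Clone:
    """One sampled library member: protein and its designed coding DNA."""

    clone_id: str
    protein: str
    dna: str


def consensus_framework(aln: FrameworkAlignment) -> str:
    """Column-wise consensus of a framework alignment.

    Per column the most frequent non-gap residue is taken, with alphabetical
    tie-break.  Columns that are gaps in a strict majority of rows are
    dropped from the consensus; a column consisting only of gaps is an
    error (it carries no residue information and signals a corrupt input).
    """
    n = aln.n_rows
    out: list[str] = []
    for col in range(aln.length):
        residues = [row[col] for row in aln.rows]
        n_gap = residues.count(GAP)
        if n_gap == n:
            if n == 1:  # single-row alignment: gaps are simply removed
                continue
            raise ValueError(f"alignment column {col + 1} contains only gaps")
        if n_gap * 2 > n:
            continue
        counts: dict[str, int] = {}
        for r in residues:
            if r != GAP:
                counts[r] = counts.get(r, 0) + 1
        top = max(counts.values())
        out.append(sorted(r for r, c in counts.items() if c == top)[0])
    return "".join(out)


def design_cdr_scheme(
    freqs: CdrFrequencyTable,
    candidate_fixed: Iterable[int],
    threshold: float,
    alphabet: str = CDR_ALPHABET,
) -> CdrScheme:
    """Fix candidate positions whose modal residue exceeds a frequency threshold.

    A candidate position is fixed to its modal residue iff that residue's
    frequency is strictly greater than ``threshold``; every other position is
    randomized over ``alphabet``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    candidates = sorted(set(candidate_fixed))
    if any(p < 1 or p > freqs.length for p in candidates):
        raise ValueError("candidate positions outside table range")
    fixed: dict[int, str] = {}
    for pos in candidates:
        residue, f = freqs.modal_residue(pos)
        if f > threshold:
            fixed[pos] = residue
    return CdrScheme(cdr_id=freqs.cdr_id, length=freqs.length, fixed=fixed, alphabet=alphabet)


def theoretical_diversity(scheme: LibraryScheme) -> int:
    """Exact number of distinct proteins the scheme can produce.

    Multiplicative over CDRs: |alphabet| ** (randomized positions), computed
    with arbitrary-precision integers (the default design yields 19**23).
    """
    total = 1
    for cdr in scheme.cdrs:
        total *= len(cdr.alphabet) ** cdr.n_randomized
    return total


def reverse_translate(protein: str, codon_table: Mapping[str, str]) -> str:
    """Reverse-translate a protein with one codon per residue."""
    try:
        return "".join(codon_table[aa] for aa in protein)
    except KeyError as exc:
        raise ValueError(f"no codon for residue {exc.args[0]!r}") from None


def sample_clones(
    scheme: LibraryScheme,
    n: int,
    seed: int | np.random.Generator | None = None,
    id_prefix: str = "clone",
) -> list[Clone]:
    """Draw ``n`` clones from the library scheme.

    Framework and fixed-CDR residues are deterministic; randomized positions
    are i.i.d. uniform over the CDR alphabet.  Reproducible for a given seed.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return []

    # Draw all randomized residues for all clones in one vectorized call per CDR.
    cdr_draws: list[np.ndarray] = []
    for cdr in scheme.cdrs:
        letters = np.frombuffer(cdr.alphabet.encode(), dtype="S1")
        draws = rng.integers(0, len(letters), size=(n, cdr.n_randomized))
        cdr_draws.append(letters[draws])

    clones: list[Clone] = []
    for i in range(n):
        cdr_seqs = []
        for cdr, draws in zip(scheme.cdrs, cdr_draws):
            chars = list(b"".join(draws[i]).decode())
            seq = []
            it = iter(chars)
            for pos in range(1, cdr.length + 1):
                seq.append(cdr.fixed.get(pos) or next(it))
            cdr_seqs.append("".join(seq))
        protein = scheme.assemble(cdr_seqs)
        dna = reverse_translate(protein, scheme.codon_table)
        clones.append(Clone(clone_id=f"{id_prefix}_{i:06d}", protein=protein, dna=dna))
    return clones
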