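"""Core peptide types, BLOSUM62 scoring with anchor masking, and
tumor/normal epitope-pair enumeration from missense variants.

Conventions: protein and epitope positions are 1-based; windows are closed
intervals. Similarity scores are self-normalized percentages, with the
denominator masked identically to the numerator so each scale is
internally consistent and bounded by 100.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity letters carried by the bundled BLOSUM62 (blastp's alphabet).
AMBIGUOUS_AA = "BZX"
VALID_AA = frozenset(STANDARD_AA + AMBIGUOUS_AA)


class PeptideError(ValueError):
    """Invalid peptide sequence (empty or non-alphabet letters)."""


class AlignmentLengthError(ValueError):
    """Operands of a fixed-length alignment operation differ in length."""


class AlphabetError(KeyError):
    """A letter is absent from the scoring matrix."""


class NormalizationError(ValueError):
    """Self-similarity score is non-positive; percent scale undefined."""


@dataclass(frozen=True)
class Peptide:
    """An immutable amino-acid string over the BLOSUM62 alphabet."""

    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PeptideError("peptide sequence must be non-empty")
        bad = set(self.sequence) - VALID_AA
        if bad:
            raise PeptideError(
                f"invalid amino-acid letter(s) {sorted(bad)} in {self.sequence!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def __getitem__(self, i):
        return self.sequence[i]

    def __iter__(self):
        return iter(self.sequence)

    def __str__(self) -> str:
        return self.sequence


def as_peptide(p: "Peptide | str") -> Peptide:
    return p if isinstance(p, Peptide) else Peptide(p)


class ScoringMatrix:
    """A symmetric integer substitution matrix keyed by letter pairs."""

    def __init__(self, entries: dict[tuple[str, str], int], name: str = "BLOSUM62"):
        self.name = name
        self.entries = dict(entries)
        self.letters = sorted({a for a, _ in self.entries})
        self._index = {c: i for i, c in enumerate(self.letters)}
        n = len(self.letters)
        self._array = np.zeros((n, n), dtype=np.int64)
        for (a, b), s in self.entries.items():
            self._array[self._index[a], self._index[b]] = s

    def __call__(self, a: str, b: str) -> int:
        try:
            return self.entries[(a, b)]
        except KeyError:
            raise AlphabetError(f"letter pair ({a!r}, {b!r}) not in matrix {self.name}")

    def encode(self, sequence: str) -> np.ndarray:
        """Map a sequence to matrix row indices (vectorized scoring)."""
        try:
            return np.fromiter(
                (self._index[c] for c in sequence), dtype=np.intp, count=len(sequence)
            )
        except KeyError as exc:
            raise AlphabetError(f"letter {exc.args[0]!r} not in matrix {self.name}")

    @property
    def array(self) -> np.ndarray:
        return self._array

    def is_symmetric(self) -> bool:
        return bool(np.array_equal(self._array, self._array.T))

    def is_diagonally_dominant(self, letters: str = STANDARD_AA) -> bool:
        """entry(a, a) >= entry(a, b) over the given letters. Holds for the
        20 standard letters of BLOSUM62; the ambiguity rows (e.g. X) do not
        satisfy it, which is why percent-similarity bounds are stated for
        the standard alphabet only."""
        idx = np.array([self._index[c] for c in letters])
        sub = self._array[np.ix_(idx, idx)]
        diag = np.diag(sub)
        return bool(np.all(sub <= diag[:, None]))


def _load_blosum62() -> ScoringMatrix:
    text = (
        importlib.resources.files("neonovelty")
        .joinpath("data/blosum62.txt")
        .read_text()
    )
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    cols = lines[0].split()
    entries: dict[tuple[str, str], int] = {}
    for ln in lines[1:]:
        parts = ln.split()
        row = parts[0]
        for col, val in zip(cols, parts[1:]):
            entries[(row, col)] = int(val)
    matrix = ScoringMatrix(entries, name="BLOSUM62")
    # guard against a corrupted data file
    if not matrix.is_symmetric():
        raise RuntimeError("bundled BLOSUM62 failed symmetry check")
    return matrix


BLOSUM62 = _load_blosum62()


@dataclass(frozen=True)
class AnchorMask:
    """1-based epitope positions excluded from similarity scoring."""

    masked_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "masked_positions", frozenset(self.masked_positions))
        if any(p < 1 for p in self.masked_positions):
            raise ValueError("masked positions are 1-based and must be >= 1")

    def validate_for_length(self, length: int) -> None:
        out = [p for p in self.masked_positions if p > length]
        if out:
            raise ValueError(f"masked positions {out} exceed epitope length {length}")

    def __contains__(self, position: int) -> bool:
        return position in self.masked_positions


EMPTY_MASK = AnchorMask(frozenset())


def anchor_positions(epitope_length: int) -> AnchorMask:
    """MHC anchor residues of an epitope: position 2 and the last position.

    Stated for 9mers; generalized to any length >= 3 (see package docs).
    """
    if epitope_length < 3:
        raise ValueError(f"epitope length must be >= 3, got {epitope_length}")
    return AnchorMask(frozenset({2, epitope_length}))


def blosum_score(
    a: Peptide | str,
    b: Peptide | str,
    mask: AnchorMask = EMPTY_MASK,
    matrix: ScoringMatrix = BLOSUM62,
) -> int:
    """Sum of substitution-matrix entries at every unmasked position."""
    a, b = as_peptide(a), as_peptide(b)
    if len(a) != len(b):
        raise AlignmentLengthError(f"length mismatch: {len(a)} vs {len(b)}")
    mask.validate_for_length(len(a))
    return sum(
        matrix(x, y)
        for pos, (x, y) in enumerate(zip(a.sequence, b.sequence), start=1)
        if pos not in mask
    )


def percent_similarity(
    query: Peptide | str,
    subject: Peptide | str,
    mask: AnchorMask = EMPTY_MASK,
    matrix: ScoringMatrix = BLOSUM62,
) -> float:
    """Self-normalized similarity: 100 * score(q, s) / score(q, q).

    The denominator uses the same mask as the numerator. Bounded above by
    100 for a diagonally dominant matrix; may be negative.
    """
    query, subject = as_peptide(query), as_peptide(subject)
    self_score = blosum_score(query, query, mask, matrix)
    if self_score <= 0:
        raise NormalizationError(
            f"non-positive self-score {self_score} for {query.sequence!r}"
        )
    return 100.0 * blosum_score(query, subject, mask, matrix) / self_score


def mismatch_count(a: Peptide | str, b: Peptide | str) -> int:
    """Hamming distance over all positions (no anchor masking)."""
    a, b = as_peptide(a), as_peptide(b)
    if len(a) != len(b):
        raise AlignmentLengthError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a.sequence, b.sequence))


class ReferenceMismatchError(ValueError):
    """Protein sequence disagrees with the stated reference residue."""


class NotMissenseError(ValueError):
    """Reference and alternate residues are identical."""


@dataclass(frozen=True)
class EpitopePair:
    """A tumor epitope window and its paired normal (wild-type) window.

    The two sequences differ at exactly one position, ``window_position``
    (1-based within the window), where the normal carries ``ref_aa`` and
    the tumor carries ``alt_aa``.
    """

    tumor: Peptide
    normal: Peptide
    gene: str
    protein_position: int
    window_position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self):
        if len(self.tumor) != len(self.normal):
            raise AlignmentLengthError("tumor and normal epitopes differ in length")
        diffs = [
            i + 1
            for i, (t, n) in enumerate(zip(self.tumor, self.normal))
            if t != n
        ]
        if diffs != [self.window_position]:
            raise ValueError(
                f"tumor/normal must differ exactly at window position "
                f"{self.window_position}, found differences at {diffs}"
            )
        wp = self.window_position - 1
        if self.normal[wp] != self.ref_aa or self.tumor[wp] != self.alt_aa:
            raise ValueError("window_position residues disagree with ref/alt letters")

    @property
    def length(self) -> int:
        return len(self.tumor)


def enumerate_epitope_pairs(
    protein: Peptide | str,
    protein_position: int,
    ref_aa: str,
    alt_aa: str,
    lengths: Iterable[int] = (9,),
    gene: str = "",
) -> list[EpitopePair]:
    """All tumor/normal window pairs containing a missense substitution.

    For each length ``k`` in ``lengths``, emits one pair per length-``k``
    window that contains ``protein_position`` and lies fully inside the
    protein. An interior 9mer mutation yields the 9 windows of the 17-mer
    flanking construction. Pairs are ordered by (length, window start).
    """
    protein = as_peptide(protein)
    if ref_aa == alt_aa:
        raise NotMissenseError(f"ref and alt are both {ref_aa!r}; not a missense change")
    if not 1 <= protein_position <= len(protein):
        raise ValueError(
            f"protein_position {protein_position} outside protein of length {len(protein)}"
        )
    if protein[protein_position - 1] != ref_aa:
        raise ReferenceMismatchError(
            f"protein has {protein[protein_position - 1]!r} at position "
            f"{protein_position}, expected ref {ref_aa!r}"
        )
    pairs: list[EpitopePair] = []
    for k in sorted(set(lengths)):
        if k > len(protein):
            continue
        lo = max(1, protein_position - k + 1)
        hi = min(protein_position, len(protein) - k + 1)
        for start in range(lo, hi + 1):
            normal_seq = protein.sequence[start - 1 : start - 1 + k]
            wp = protein_position - start + 1
            tumor_seq = normal_seq[: wp - 1] + alt_aa + normal_seq[wp:]
            pairs.append(
                EpitopePair(
                    tumor=Peptide(tumor_seq),
                    normal=Peptide(normal_seq),
                    gene=gene,
                    protein_position=protein_position,
                    window_position=wp,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                )
            )
    return pairs
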