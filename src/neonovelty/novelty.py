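"""Binding-affinity records, the tumor-vs-normal affinity difference, and
the putatively-novel-binding-change classifier.

A novel binding change: the tumor epitope binds strongly (affinity below
the strong-binding threshold, default 500 nM) while its paired normal
epitope binds at or above that threshold and at least fold_change_threshold
times more weakly. Boundary reading: tumor strictly <, normal >=, ratio >=.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .peptides import EpitopePair, Peptide, as_peptide


class AffinityDomainError(ValueError):
    """Affinity values must be strictly positive (nM)."""


class AffinityLookupError(KeyError):
    """A required (peptide, allele) affinity is absent from the table."""

    def __init__(self, peptide: str, allele: str):
        self.peptide, self.allele = peptide, allele
        super().__init__(f"no affinity for peptide {peptide!r} / allele {allele!r}")


@dataclass(frozen=True)
class BindingRecord:
    peptide: Peptide
    allele: str
    affinity: float  # nM; lower = tighter binding

    def __post_init__(self):
        object.__setattr__(self, "peptide", as_peptide(self.peptide))
        if not self.affinity > 0:
            raise AffinityDomainError(f"affinity must be > 0 nM, got {self.affinity}")


@dataclass(frozen=True)
class NoveltyConfig:
    strong_binding_threshold: float = 500.0  # nM
    fold_change_threshold: float = 5.0

    def __post_init__(self):
        if self.strong_binding_threshold <= 0 or self.fold_change_threshold <= 0:
            raise ValueError("thresholds must be > 0")


DEFAULT_NOVELTY = NoveltyConfig()


class AffinityTable:
    """(peptide sequence, allele) -> affinity nM, with strict lookups."""

    def __init__(self, records=()):
        self._table: dict[tuple[str, str], float] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: BindingRecord) -> None:
        self._table[(record.peptide.sequence, record.allele)] = record.affinity

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AffinityTable":
        """Build from a frame with columns peptide, allele, affinity_nm."""
        table = cls()
        for row in frame.itertuples(index=False):
            table.add(BindingRecord(Peptide(row.peptide), row.allele, float(row.affinity_nm)))
        return table

    def lookup(self, peptide: Peptide | str, allele: str) -> float:
        seq = as_peptide(peptide).sequence
        try:
            return self._table[(seq, allele)]
        except KeyError:
            raise AffinityLookupError(seq, allele)

    def get(self, peptide: Peptide | str, allele: str) -> float | None:
        return self._table.get((as_peptide(peptide).sequence, allele))

    def peptides(self) -> list[str]:
        return sorted({seq for seq, _ in self._table})

    def __len__(self) -> int:
        return len(self._table)


def _check_positive(*affinities: float) -> None:
    for a in affinities:
        if not a > 0:
            raise AffinityDomainError(f"affinity must be > 0 nM, got {a}")


def affinity_difference(normal_affinity: float, tumor_affinity: float) -> float:
    """Normal minus tumor affinity; positive when the tumor binds tighter."""
    _check_positive(normal_affinity, tumor_affinity)
    return normal_affinity - tumor_affinity


def is_novel_binding(
    tumor_affinity: float,
    normal_affinity: float,
    config: NoveltyConfig = DEFAULT_NOVELTY,
) -> bool:
    _check_positive(tumor_affinity, normal_affinity)
    return (
        tumor_affinity < config.strong_binding_threshold
        and normal_affinity >= config.strong_binding_threshold
        and normal_affinity / tumor_affinity >= config.fold_change_threshold
    )


def classify_pairs(
    pairs: list[EpitopePair],
    affinities: AffinityTable,
    alleles: list[str],
    config: NoveltyConfig = DEFAULT_NOVELTY,
) -> pd.DataFrame:
    """One row per pair x allele with affinities, difference, novel flag.

    Raises AffinityLookupError on any missing (peptide, allele) entry —
    missing affinities are never imputed.
    """
    rows = []
    for pair in pairs:
        for allele in alleles:
            t = affinities.lookup(pair.tumor, allele)
            n = affinities.lookup(pair.normal, allele)
            rows.append(
                {
                    "gene": pair.gene,
                    "protein_position": pair.protein_position,
                    "length": pair.length,
                    "window_position": pair.window_position,
                    "tumor_peptide": pair.tumor.sequence,
                    "normal_peptide": pair.normal.sequence,
                    "allele": allele,
                    "tumor_affinity_nm": t,
                    "normal_affinity_nm": n,
                    "difference_nm": affinity_difference(n, t),
                    "novel_binding": int(is_novel_binding(t, n, config)),
                }
            )
    columns = [
        "gene", "protein_position", "length", "window_position",
        "tumor_peptide", "normal_peptide", "allele",
        "tumor_affinity_nm", "normal_affinity_nm", "difference_nm", "novel_binding",
    ]
    return pd.DataFrame(rows, columns=columns)
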