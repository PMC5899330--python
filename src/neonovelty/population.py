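"""Cross-patient neoepitope recurrence accounting and random six-allele
HLA-set overlap spectra."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .novelty import AffinityTable


class SamplingError(ValueError):
    pass


@dataclass(frozen=True)
class AlleleSet:
    """Two HLA-A, two HLA-B, and two HLA-C alleles."""

    a: tuple[str, str]
    b: tuple[str, str]
    c: tuple[str, str]

    def __post_init__(self):
        for gene, pair in (("A", self.a), ("B", self.b), ("C", self.c)):
            if len(pair) != 2 or pair[0] == pair[1]:
                raise ValueError(f"HLA-{gene} pair must be two distinct alleles: {pair}")

    @property
    def alleles(self) -> tuple[str, ...]:
        return self.a + self.b + self.c


def recurrence_counts(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sequence occurrence counts and per-patient repeated fractions.

    Input columns: patient, disease, peptide. (patient, peptide) rows are
    deduplicated before counting, so counts are numbers of distinct
    patients carrying each sequence — overall and within each disease.
    Each patient's repeated fraction is the share of their distinct
    sequences seen in at least one other patient.

    Returns (sequence_counts, patient_fractions). sequence_counts columns:
    peptide, disease, n_patients_disease, n_patients_overall (one row per
    peptide x disease in which it occurs). patient_fractions columns:
    patient, disease, n_peptides, repeated_fraction_disease,
    repeated_fraction_overall.
    """
    if table.empty:
        raise ValueError("patient epitope table is empty")
    dedup = table[["patient", "disease", "peptide"]].drop_duplicates(
        subset=["patient", "peptide"]
    )

    overall = dedup.groupby("peptide")["patient"].nunique()
    within = dedup.groupby(["disease", "peptide"])["patient"].nunique()

    seq_rows = [
        {
            "peptide": pep,
            "disease": dis,
            "n_patients_disease": int(n),
            "n_patients_overall": int(overall[pep]),
        }
        for (dis, pep), n in within.items()
    ]
    sequence_counts = pd.DataFrame(
        seq_rows, columns=["peptide", "disease", "n_patients_disease", "n_patients_overall"]
    ).sort_values(["disease", "peptide"], ignore_index=True)

    pat_rows = []
    for (patient, disease), grp in dedup.groupby(["patient", "disease"]):
        peptides = grp["peptide"]
        n = len(peptides)
        rep_overall = sum(overall[p] > 1 for p in peptides)
        rep_disease = sum(within[(disease, p)] > 1 for p in peptides)
        pat_rows.append(
            {
                "patient": patient,
                "disease": disease,
                "n_peptides": n,
                "repeated_fraction_disease": rep_disease / n,
                "repeated_fraction_overall": rep_overall / n,
            }
        )
    patient_fractions = pd.DataFrame(
        pat_rows,
        columns=[
            "patient", "disease", "n_peptides",
            "repeated_fraction_disease", "repeated_fraction_overall",
        ],
    ).sort_values(["patient"], ignore_index=True)
    return sequence_counts, patient_fractions


def sample_allele_sets(
    a_alleles: list[str],
    b_alleles: list[str],
    c_alleles: list[str],
    n_sets: int,
    seed: int,
) -> list[AlleleSet]:
    """n_sets random six-allele sets: two per gene, without replacement.

    A single top-level seed spawns one substream per set, so set i is
    identical regardless of n_sets.
    """
    for name, lst in (("A", a_alleles), ("B", b_alleles), ("C", c_alleles)):
        if len(set(lst)) < 2:
            raise SamplingError(f"need >= 2 distinct HLA-{name} alleles, got {lst}")
    if n_sets < 1:
        raise SamplingError("n_sets must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_sets)
    sets = []
    for child in children:
        rng = np.random.default_rng(child)
        pick = lambda lst: tuple(rng.choice(sorted(set(lst)), size=2, replace=False))
        sets.append(AlleleSet(a=pick(a_alleles), b=pick(b_alleles), c=pick(c_alleles)))
    return sets


def overlap_spectrum(
    affinities: AffinityTable,
    allele_set: AlleleSet,
    strong_threshold: float = 500.0,
    peptides: list[str] | None = None,
) -> dict:
    """Counts of unique epitopes binding exactly 1..6 alleles of the set.

    An epitope "binds" an allele iff its affinity is strictly below
    strong_threshold. Evaluates every unique peptide in the table unless
    an explicit peptide list is given; a missing (peptide, allele) entry
    raises. The exact-k counts partition the total binding >= 1.
    """
    if peptides is None:
        peptides = affinities.peptides()
    counts = {k: 0 for k in range(1, 7)}
    total = 0
    for pep in peptides:
        n_bound = sum(
            affinities.lookup(pep, allele) < strong_threshold
            for allele in allele_set.alleles
        )
        if n_bound >= 1:
            counts[n_bound] += 1
            total += 1
    return {"counts": counts, "total": total}
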