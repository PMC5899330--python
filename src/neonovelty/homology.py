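"""Fixed-length, ungapped closest-peptide search against human, bacterial,
and viral peptide window databases.

The search is exact and exhaustive: every length-k window of every database
protein is scored against the query with the all-residue BLOSUM62 sum, and
every window attaining the maximum score is retained as a tie. For a fixed
query length, alignment length, and database, a blastp E-value is a monotone
decreasing function of this raw score, so "lowest E-value" and "highest raw
score" select the same matches; no E-values are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .novelty import AffinityTable, NoveltyConfig, DEFAULT_NOVELTY, affinity_difference, is_novel_binding
from .peptides import (
    BLOSUM62,
    AlignmentLengthError,
    AnchorMask,
    EpitopePair,
    Peptide,
    ScoringMatrix,
    anchor_positions,
    as_peptide,
    mismatch_count,
    percent_similarity,
)


class EmptyDatabaseError(ValueError):
    pass


class NoHitError(LookupError):
    """Raised by gene_match_status on an empty match list."""


@dataclass(frozen=True)
class ScoredMatch:
    """A database window tied for the maximal raw score against a query."""

    subject: Peptide
    protein_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    raw_score: int
    similarity_nonanchor: float
    similarity_all_residue: float
    mismatches: int


@dataclass(frozen=True)
class MatchStatus:
    status: str  # "matching" | "nonmatching"

    def __post_init__(self):
        if self.status not in ("matching", "nonmatching"):
            raise ValueError(f"invalid match status {self.status!r}")


MATCHING = MatchStatus("matching")
NONMATCHING = MatchStatus("nonmatching")


class PeptideDB:
    """Every length-k window of a protein database, ready for scoring.

    Windows are deduplicated by sequence; each unique window keeps the
    sorted set of (protein id, gene id) back-references.
    """

    def __init__(self, k: int, source: str, matrix: ScoringMatrix = BLOSUM62):
        if k < 1:
            raise ValueError(f"window length k must be >= 1, got {k}")
        self.k = k
        self.source = source
        self.matrix = matrix
        self._origin: dict[str, set[tuple[str, str]]] = {}
        self._sequences: list[str] = []
        self._encoded: np.ndarray | None = None

    def add_protein(self, protein_id: str, gene_id: str, sequence: str) -> None:
        seq = as_peptide(sequence).sequence
        for i in range(len(seq) - self.k + 1):
            window = seq[i : i + self.k]
            if window not in self._origin:
                self._origin[window] = set()
                self._sequences.append(window)
                self._encoded = None
            self._origin[window].add((protein_id, gene_id))

    def __len__(self) -> int:
        return len(self._sequences)

    @property
    def window_sequences(self) -> list[str]:
        return list(self._sequences)

    def origins(self, window: str) -> list[tuple[str, str]]:
        return sorted(self._origin[window])

    def _encode(self) -> np.ndarray:
        if self._encoded is None:
            flat = "".join(self._sequences)
            self._encoded = self.matrix.encode(flat).reshape(len(self._sequences), self.k)
        return self._encoded


def build_peptide_db(
    records,
    k: int = 9,
    source: str = "human",
    matrix: ScoringMatrix = BLOSUM62,
) -> PeptideDB:
    """Index every length-k window of a (protein_id, gene_id, sequence)
    record stream. Proteins shorter than k contribute nothing."""
    db = PeptideDB(k=k, source=source, matrix=matrix)
    n_records = 0
    for protein_id, gene_id, sequence in records:
        db.add_protein(protein_id, gene_id, sequence)
        n_records += 1
    if n_records == 0:
        raise EmptyDatabaseError(f"no records supplied for {source} database")
    return db


def search_closest(
    query: Peptide | str,
    db: PeptideDB,
    mask: AnchorMask | None = None,
) -> list[ScoredMatch]:
    """All database windows attaining the maximum all-residue raw score.

    Ranking always uses all k residues (as blastp does); the returned
    matches carry percent similarities on both the non-anchor and
    all-residue scales. `mask` defaults to the anchor mask for db.k.
    Deterministic: ties are ordered by subject sequence.
    """
    query = as_peptide(query)
    if len(query) != db.k:
        raise AlignmentLengthError(f"query length {len(query)} != db window length {db.k}")
    if len(db) == 0:
        raise EmptyDatabaseError(f"{db.source} database has no windows")
    if mask is None:
        mask = anchor_positions(db.k)

    encoded = db._encode()
    q_idx = db.matrix.encode(query.sequence)
    scores = db.matrix.array[encoded, q_idx[None, :]].sum(axis=1)
    top = int(scores.max())
    tied = sorted(np.flatnonzero(scores == top), key=lambda i: db.window_sequences[i])

    matches = []
    for i in tied:
        subject = db.window_sequences[i]
        origins = db.origins(subject)
        matches.append(
            ScoredMatch(
                subject=Peptide(subject),
                protein_ids=tuple(p for p, _ in origins),
                gene_ids=tuple(g for _, g in origins),
                raw_score=top,
                similarity_nonanchor=percent_similarity(query, subject, mask, db.matrix),
                similarity_all_residue=percent_similarity(query, subject, matrix=db.matrix),
                mismatches=mismatch_count(query, subject),
            )
        )
    return matches


def gene_match_status(matches: list[ScoredMatch], gene_of_origin: str) -> MatchStatus:
    """"matching" iff any retained tie originates from the query's gene."""
    if not matches:
        raise NoHitError("cannot assign match status without any retained match")
    for m in matches:
        if gene_of_origin in m.gene_ids:
            return MATCHING
    return NONMATCHING


@dataclass(frozen=True)
class MatchSummary:
    """Flattened best-match fields for one database; None when no hit."""

    subject: str | None = None
    protein_ids: tuple[str, ...] = ()
    gene_ids: tuple[str, ...] = ()
    raw_score: int | None = None
    similarity_nonanchor: float | None = None
    similarity_all_residue: float | None = None
    mismatches: int | None = None

    @property
    def has_hit(self) -> bool:
        return self.subject is not None


def _summarize(matches: list[ScoredMatch]) -> MatchSummary:
    if not matches:
        return MatchSummary()
    # ties collapse to one row: first subject lexicographically, all ids kept
    best = matches[0]
    protein_ids = tuple(sorted({p for m in matches for p in m.protein_ids}))
    gene_ids = tuple(sorted({g for m in matches for g in m.gene_ids}))
    return MatchSummary(
        subject=best.subject.sequence,
        protein_ids=protein_ids,
        gene_ids=gene_ids,
        raw_score=best.raw_score,
        similarity_nonanchor=best.similarity_nonanchor,
        similarity_all_residue=best.similarity_all_residue,
        mismatches=best.mismatches,
    )


@dataclass(frozen=True)
class NoveltyProfile:
    """All four novelty metrics for one (neoepitope, allele)."""

    tumor: str
    normal: str
    gene: str
    allele: str
    tumor_affinity_nm: float
    normal_affinity_nm: float
    paired_difference_nm: float
    novel_binding: bool
    paired_similarity_nonanchor: float
    paired_similarity_all_residue: float
    paired_mismatches: int
    human: MatchSummary = field(default_factory=MatchSummary)
    human_match_status: str | None = None  # "matching"/"nonmatching"/None
    human_match_difference_nm: float | None = None
    bacterial: MatchSummary = field(default_factory=MatchSummary)
    viral: MatchSummary = field(default_factory=MatchSummary)
    bacterial_closer_nonanchor: bool | None = None
    bacterial_closer_all_residue: bool | None = None
    viral_closer_nonanchor: bool | None = None
    viral_closer_all_residue: bool | None = None


def _closer_than_human(
    microbial: MatchSummary,
    paired_sim: float,
    human_sim: float | None,
    scale: str,
) -> bool | None:
    """Microbial match strictly more similar than both human comparators
    (the paired normal epitope and the closest human proteome match)."""
    if not microbial.has_hit:
        return None
    m = getattr(microbial, f"similarity_{scale}")
    comparators = [paired_sim]
    if human_sim is not None:
        comparators.append(human_sim)
    return all(m > c for c in comparators)


def profile_neoepitope(
    pair: EpitopePair,
    human_db: PeptideDB | None,
    bacterial_db: PeptideDB | None,
    viral_db: PeptideDB | None,
    affinities: AffinityTable,
    allele: str,
    config: NoveltyConfig = DEFAULT_NOVELTY,
    mask: AnchorMask | None = None,
) -> NoveltyProfile:
    """Aggregate all four metrics for one epitope pair under one allele.

    A None or empty database yields no-hit markers for that source rather
    than an error. The human-match affinity difference is reported only
    when the matched human peptide's affinity for the allele is present in
    the input table.
    """
    k = pair.length
    if mask is None:
        mask = anchor_positions(k)

    tumor_aff = affinities.lookup(pair.tumor, allele)
    normal_aff = affinities.lookup(pair.normal, allele)

    def _search(db: PeptideDB | None) -> MatchSummary:
        if db is None or len(db) == 0:
            return MatchSummary()
        return _summarize(search_closest(pair.tumor, db, mask))

    human = _search(human_db)
    bacterial = _search(bacterial_db)
    viral = _search(viral_db)

    human_status = None
    human_diff = None
    if human.has_hit:
        human_status = (
            MATCHING.status if pair.gene in human.gene_ids else NONMATCHING.status
        )
        match_aff = affinities.get(human.subject, allele)
        if match_aff is not None:
            human_diff = affinity_difference(match_aff, tumor_aff)

    paired_sim_na = percent_similarity(pair.tumor, pair.normal, mask)
    paired_sim_all = percent_similarity(pair.tumor, pair.normal)

    return NoveltyProfile(
        tumor=pair.tumor.sequence,
        normal=pair.normal.sequence,
        gene=pair.gene,
        allele=allele,
        tumor_affinity_nm=tumor_aff,
        normal_affinity_nm=normal_aff,
        paired_difference_nm=affinity_difference(normal_aff, tumor_aff),
        novel_binding=is_novel_binding(tumor_aff, normal_aff, config),
        paired_similarity_nonanchor=paired_sim_na,
        paired_similarity_all_residue=paired_sim_all,
        paired_mismatches=mismatch_count(pair.tumor, pair.normal),
        human=human,
        human_match_status=human_status,
        human_match_difference_nm=human_diff,
        bacterial=bacterial,
        viral=viral,
        bacterial_closer_nonanchor=_closer_than_human(
            bacterial, paired_sim_na, human.similarity_nonanchor, "nonanchor"
        ),
        bacterial_closer_all_residue=_closer_than_human(
            bacterial, paired_sim_all, human.similarity_all_residue, "all_residue"
        ),
        viral_closer_nonanchor=_closer_than_human(
            viral, paired_sim_na, human.similarity_nonanchor, "nonanchor"
        ),
        viral_closer_all_residue=_closer_than_human(
            viral, paired_sim_all, human.similarity_all_residue, "all_residue"
        ),
    )
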