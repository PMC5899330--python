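import numpy as np
import pytest

from neonovelty.homology import (
    EmptyDatabaseError,
    MatchStatus,
    NoHitError,
    build_peptide_db,
    gene_match_status,
    profile_neoepitope,
    search_closest,
)
from neonovelty.novelty import AffinityTable, BindingRecord
from neonovelty.peptides import (
    AlignmentLengthError,
    Peptide,
    anchor_positions,
    enumerate_epitope_pairs,
    mismatch_count,
    percent_similarity,
    STANDARD_AA,
)
from neonovelty.synthetic import FixtureConfig, generate_proteome, pseudo_affinity

from oracles import naive_percent, naive_score, naive_search


def random_proteins(rng, n, length):
    letters = list(STANDARD_AA)
    return [
        (f"P{i}", f"G{i}", "".join(rng.choice(letters, size=length)))
        for i in range(n)
    ]


class TestBuildPeptideDB:
    def test_window_counts(self):
        db = build_peptide_db([("P1", "G1", "A" * 15)], k=9)
        assert len(db) == 1  # all 7 windows are the same sequence "A"*9
        db2 = build_peptide_db([("P1", "G1", "ACDEFGHIKLMNPQR")], k=9)
        assert len(db2) == 7

    def test_short_protein_contributes_nothing(self):
        db = build_peptide_db([("P1", "G1", "ACDEFGHI"), ("P2", "G2", "ACDEFGHIK")], k=9)
        assert len(db) == 1

    def test_empty_input_raises(self):
        with pytest.raises(EmptyDatabaseError):
            build_peptide_db([], k=9)

    def test_random_window_count_matches_naive(self, rng):
        proteins = random_proteins(rng, 10, 100)
        db = build_peptide_db(proteins, k=9)
        naive = {seq[i : i + 9] for _, _, seq in proteins for i in range(92)}
        assert len(db) == len(naive)
        assert set(db.window_sequences) == naive

    def test_dedup_keeps_multi_source_backrefs(self):
        db = build_peptide_db(
            [("P1", "G1", "ACDEFGHIK"), ("P2", "G2", "ACDEFGHIK")], k=9
        )
        assert db.origins("ACDEFGHIK") == [("P1", "G1"), ("P2", "G2")]


class TestSearchClosest:
    def test_identity_window_is_top(self, rng):
        proteins = random_proteins(rng, 5, 60)
        query = proteins[0][2][10:19]
        db = build_peptide_db(proteins, k=9)
        matches = search_closest(query, db)
        subjects = {m.subject.sequence for m in matches}
        assert query in subjects
        top = [m for m in matches if m.subject.sequence == query][0]
        assert top.similarity_all_residue == pytest.approx(100.0)
        assert top.raw_score == naive_score(query, query)

    def test_verbatim_in_two_proteins_both_retained(self):
        db = build_peptide_db(
            [("P1", "G1", "WWWACDEFGHIK"), ("P2", "G2", "ACDEFGHIKWWW")], k=9
        )
        matches = search_closest("ACDEFGHIK", db)
        assert len(matches) == 1  # deduplicated window, both origins kept
        assert matches[0].protein_ids == ("P1", "P2")
        assert matches[0].gene_ids == ("G1", "G2")

    def test_query_length_mismatch(self):
        db = build_peptide_db([("P1", "G1", "ACDEFGHIKL")], k=9)
        with pytest.raises(AlignmentLengthError):
            search_closest("ACDEFGH", db)

    def test_matches_naive_double_loop(self, rng):
        proteins = random_proteins(rng, 20, 60)
        db = build_peptide_db(proteins, k=9)
        for _ in range(30):
            query = "".join(rng.choice(list(STANDARD_AA), size=9))
            matches = search_closest(query, db)
            top, ties = naive_search(query, proteins)
            assert matches[0].raw_score == top
            assert {m.subject.sequence for m in matches} == set(ties)
            for m in matches:
                assert set(zip(m.protein_ids, m.gene_ids)) == ties[m.subject.sequence]
                assert m.similarity_all_residue == pytest.approx(naive_percent(query, m.subject.sequence))
                assert m.similarity_nonanchor == pytest.approx(
                    naive_percent(query, m.subject.sequence, {2, 9})
                )
                assert m.mismatches == mismatch_count(query, m.subject.sequence)

    def test_permutation_invariance(self, rng):
        proteins = random_proteins(rng, 15, 50)
        query = "".join(rng.choice(list(STANDARD_AA), size=9))
        db1 = build_peptide_db(proteins, k=9)
        db2 = build_peptide_db(list(reversed(proteins)), k=9)
        assert search_closest(query, db1) == search_closest(query, db2)


class TestGeneMatchStatus:
    def _match(self, genes):
        db = build_peptide_db(
            [(f"P{i}", g, "ACDEFGHIK") for i, g in enumerate(genes)], k=9
        )
        return search_closest("ACDEFGHIK", db)

    def test_own_gene_matching(self):
        assert gene_match_status(self._match(["G1"]), "G1") == MatchStatus("matching")

    def test_foreign_genes_nonmatching(self):
        assert gene_match_status(self._match(["G2", "G3"]), "G1") == MatchStatus("nonmatching")

    def test_any_tie_rule(self):
        assert gene_match_status(self._match(["G2", "G1"]), "G1") == MatchStatus("matching")

    def test_empty_raises(self):
        with pytest.raises(NoHitError):
            gene_match_status([], "G1")


def _affinity_table_for(pairs, alleles, config):
    table = AffinityTable()
    for p in pairs:
        for a in alleles:
            table.add(BindingRecord(p.tumor, a, pseudo_affinity(p.tumor, a, config)))
            table.add(BindingRecord(p.normal, a, pseudo_affinity(p.normal, a, config)))
    return table


class TestProfileNeoepitope:
    def test_bacterial_identity_beats_human(self):
        protein = "ACDEFGHIKLMNPQRSTVWY"
        pairs = enumerate_epitope_pairs(protein, 10, "L", "W", lengths={9}, gene="G0")
        # non-anchor mutation, so the paired non-anchor similarity is < 100
        pair = next(p for p in pairs if p.window_position not in (2, 9))
        tumor = pair.tumor.sequence
        # bacterial DB contains the tumor peptide verbatim; human DB windows
        # all differ from it
        human = build_peptide_db([("HP1", "HG1", protein)], k=9, source="human")
        bact = build_peptide_db([("BP1", "BG1", "WWW" + tumor + "WWW")], k=9, source="bacterial")
        cfg = FixtureConfig()
        table = _affinity_table_for([pair], ["X"], cfg)
        prof = profile_neoepitope(pair, human, bact, None, table, "X")
        assert prof.bacterial.similarity_all_residue == pytest.approx(100.0)
        assert prof.bacterial_closer_nonanchor is True
        assert prof.bacterial_closer_all_residue is True
        assert prof.viral.subject is None
        assert prof.viral_closer_nonanchor is None

    def test_anchor_mutation_gives_100_paired_similarity(self):
        protein = "ACDEFGHIKLMNPQRSTVWY"
        # mutation at window_position 2 of some window: choose position 11,
        # window starting at 10 puts it at in-window position 2
        pairs = enumerate_epitope_pairs(protein, 11, "M", "W", lengths={9})
        pair = next(p for p in pairs if p.window_position == 2)
        cfg = FixtureConfig()
        table = _affinity_table_for([pair], ["X"], cfg)
        prof = profile_neoepitope(pair, None, None, None, table, "X")
        assert prof.paired_similarity_nonanchor == pytest.approx(100.0)
        assert prof.paired_similarity_all_residue < 100.0

    def test_human_match_status_and_diff(self, small_proteome):
        pid, gid, seq = small_proteome[0]
        pair = enumerate_epitope_pairs(seq, 20, seq[19],
                                       "W" if seq[19] != "W" else "Y",
                                       lengths={9}, gene=gid)[0]
        human = build_peptide_db(small_proteome, k=9, source="human")
        cfg = FixtureConfig()
        table = _affinity_table_for([pair], ["X"], cfg)
        prof0 = profile_neoepitope(pair, human, None, None, table, "X")
        assert prof0.human_match_status in ("matching", "nonmatching")
        # diff is reported only when the matched peptide's affinity is known
        known = table.get(prof0.human.subject, "X")
        if known is None:
            assert prof0.human_match_difference_nm is None
        # after adding the matched peptide's affinity, the diff must appear
        table.add(BindingRecord(Peptide(prof0.human.subject), "X",
                                pseudo_affinity(prof0.human.subject, "X", cfg)))
        prof1 = profile_neoepitope(pair, human, None, None, table, "X")
        expected = pseudo_affinity(prof0.human.subject, "X", cfg) - prof1.tumor_affinity_nm
        assert prof1.human_match_difference_nm == pytest.approx(expected)

    def test_profiles_match_naive_pipeline(self, rng, small_proteome):
        """End-to-end oracle: every profile field recomputed naively."""
        human = build_peptide_db(small_proteome, k=9, source="human")
        bact_recs = random_proteins(rng, 6, 40)
        viral_recs = random_proteins(rng, 4, 40)
        bact = build_peptide_db(bact_recs, k=9, source="bacterial")
        viral = build_peptide_db(viral_recs, k=9, source="viral")
        cfg = FixtureConfig()

        pairs = []
        for pid, gid, seq in small_proteome[:6]:
            pos = int(rng.integers(1, len(seq) + 1))
            ref = seq[pos - 1]
            alt = rng.choice([c for c in STANDARD_AA if c != ref])
            pairs.extend(
                enumerate_epitope_pairs(seq, pos, ref, str(alt), lengths={9}, gene=gid)[:2]
            )
        table = _affinity_table_for(pairs, ["X"], cfg)

        for pair in pairs:
            prof = profile_neoepitope(pair, human, bact, viral, table, "X")
            t = pair.tumor.sequence
            t_aff = pseudo_affinity(t, "X", cfg)
            n_aff = pseudo_affinity(pair.normal.sequence, "X", cfg)
            assert prof.paired_difference_nm == pytest.approx(n_aff - t_aff)
            assert prof.paired_similarity_nonanchor == pytest.approx(naive_percent(t, pair.normal.sequence, {2, 9}))
            for summary, recs in ((prof.human, small_proteome), (prof.bacterial, bact_recs), (prof.viral, viral_recs)):
                top, ties = naive_search(t, recs)
                assert summary.raw_score == top
                assert summary.subject == min(ties)
                assert summary.similarity_all_residue == pytest.approx(naive_percent(t, summary.subject))
            # gene status from the naive tie set
            _, hties = naive_search(t, small_proteome)
            genes = {g for origins in hties.values() for _, g in origins}
            expected_status = "matching" if pair.gene in genes else "nonmatching"
            assert prof.human_match_status == expected_status
            # closer-than-human flags from naive percents
            paired_na = naive_percent(t, pair.normal.sequence, {2, 9})
            human_na = prof.human.similarity_nonanchor
            bact_na = prof.bacterial.similarity_nonanchor
            assert prof.bacterial_closer_nonanchor == (bact_na > paired_na and bact_na > human_na)


class TestDatabaseSizeEffect:
    def test_bacterial_closer_fraction_grows_with_db_size(self, rng):
        """Bigger microbial DBs find closer matches (statistical trend)."""
        human = build_peptide_db(random_proteins(rng, 10, 80), k=9, source="human")
        queries = ["".join(rng.choice(list(STANDARD_AA), size=9)) for _ in range(40)]

        def closer_fraction(n_bact):
            bact = build_peptide_db(random_proteins(rng, n_bact, 80), k=9, source="bacterial")
            wins = 0
            for q in queries:
                b = search_closest(q, bact)[0].similarity_all_residue
                h = search_closest(q, human)[0].similarity_all_residue
                wins += b > h
            return wins / len(queries)

        assert closer_fraction(100) >= closer_fraction(2)
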