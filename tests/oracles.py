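"""Independent naive implementations used as oracles by the test suite.

Everything here is deliberately written as plainly as possible (double
loops, direct table lookups, no numpy vectorization) and stays independent
of the code paths it checks.
"""

from __future__ import annotations

from neonovelty.peptides import BLOSUM62

# direct dict lookups into the bundled matrix entries (not via the scoring
# helpers under test)
_ENTRIES = BLOSUM62.entries


def naive_score(a: str, b: str, masked_positions=()) -> int:
    total = 0
    for pos in range(1, len(a) + 1):
        if pos in masked_positions:
            continue
        total += _ENTRIES[(a[pos - 1], b[pos - 1])]
    return total


def naive_percent(a: str, b: str, masked_positions=()) -> float:
    return 100.0 * naive_score(a, b, masked_positions) / naive_score(a, a, masked_positions)


def naive_windows(protein: str, position: int, k: int) -> list[tuple[int, str]]:
    """All (start, substring) of length k containing 1-based `position`."""
    out = []
    for start in range(1, len(protein) - k + 2):
        if start <= position <= start + k - 1:
            out.append((start, protein[start - 1 : start - 1 + k]))
    return out


def naive_novel(tumor_nm: float, normal_nm: float, strong=500.0, fold=5.0) -> bool:
    if tumor_nm >= strong:
        return False
    if normal_nm < strong:
        return False
    if normal_nm / tumor_nm < fold:
        return False
    return True


def naive_search(query: str, proteins: list[tuple[str, str, str]], k: int = 9):
    """Double-loop closest-window search. Returns (top_score, tie_dict)
    where tie_dict maps window sequence -> set of (protein_id, gene_id)."""
    best = None
    ties: dict[str, set] = {}
    for pid, gid, seq in proteins:
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            score = naive_score(query, window)
            if best is None or score > best:
                best = score
                ties = {window: {(pid, gid)}}
            elif score == best:
                ties.setdefault(window, set()).add((pid, gid))
    return best, ties


def naive_auroc(scores, labels) -> float:
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def normal_equations_fit(X, y):
    """Hand-rolled OLS via the normal equations (numpy only for linalg)."""
    import numpy as np

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta


def naive_recurrence(rows):
    """rows: list of (patient, disease, peptide). Nested-loop tally.
    Returns (overall_counts, within_counts, per_patient) where
    per_patient[patient] = (disease, n, frac_disease, frac_overall)."""
    dedup = sorted({(p, d, s) for p, d, s in rows})
    overall = {}
    within = {}
    for p, d, s in dedup:
        overall.setdefault(s, set()).add(p)
        within.setdefault((d, s), set()).add(p)
    per_patient = {}
    patients = sorted({(p, d) for p, d, _ in dedup})
    for patient, disease in patients:
        seqs = sorted({s for p, d, s in dedup if p == patient})
        rep_o = sum(1 for s in seqs if len(overall[s]) > 1)
        rep_d = sum(1 for s in seqs if len(within[(disease, s)]) > 1)
        per_patient[patient] = (disease, len(seqs), rep_d / len(seqs), rep_o / len(seqs))
    overall_counts = {s: len(ps) for s, ps in overall.items()}
    within_counts = {k: len(ps) for k, ps in within.items()}
    return overall_counts, within_counts, per_patient


def naive_spectrum(affinity: dict, peptides, alleles, threshold=500.0):
    """affinity: {(peptide, allele): nM}. Per-epitope allele count tally."""
    counts = {k: 0 for k in range(1, 7)}
    total = 0
    for pep in peptides:
        n = sum(1 for a in alleles if affinity[(pep, a)] < threshold)
        if n >= 1:
            counts[n] += 1
            total += 1
    return counts, total
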