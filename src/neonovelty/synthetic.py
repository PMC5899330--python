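"""Deterministic generators that make the pipeline testable offline:
random proteomes, random single-substitution neoepitopes, a pseudo-affinity
predictor, and immune-response cohorts with known generative structure.

Every generator is a pure function of (config, seed). Per-item substreams
are spawned from the top-level seed, so increasing n extends — never
reorders — the earlier items.

The pseudo-affinity function is a fixed positional-weight hash. It is NOT
a biological binding model; it exists so that pipelines run end to end
with no external predictor, while weighting anchor positions more heavily
so that novel-binding cases arise naturally in fixtures.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peptides import STANDARD_AA, Peptide, as_peptide, mismatch_count


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureConfig:
    n_proteins: int = 20
    length_min: int = 50
    length_max: int = 150
    alphabet_weights: tuple[float, ...] | None = None  # None = uniform over 20
    seed: int = 0
    # pseudo-affinity model
    affinity_min_nm: float = 1.0
    affinity_max_nm: float = 50000.0
    anchor_weight: float = 4.0
    # cohort generative model (latent linear-probability scale)
    cohort_coefficients: dict = field(
        default_factory=lambda: {
            "intercept": 0.45,
            "neo_affinity": -6e-6,
            "sim_viral": 0.004,
            "human_match_diff": 2e-5,
            "mismatches_paired": 0.05,
        }
    )
    cohort_noise_sigma: float = 0.1
    cohort_prevalence: float = 0.3


@dataclass(frozen=True)
class SimulatedNeoepitope:
    source_window: Peptide
    source_protein: str
    source_gene: str
    mutated_position: int  # 1-based within the window
    original_aa: str
    substituted_aa: str
    sequence: Peptide

    def __post_init__(self):
        if self.substituted_aa == self.original_aa:
            raise ValueError("substitution must change the residue")
        if mismatch_count(self.source_window, self.sequence) != 1:
            raise ValueError("simulated neoepitope must be Hamming-1 from its source")


def generate_proteome(config: FixtureConfig) -> list[tuple[str, str, str]]:
    """Random (protein_id, gene_id, sequence) records, deterministic
    under config.seed. One gene per protein: PROT0001 <-> GENE0001."""
    if config.n_proteins < 1:
        raise FixtureError("n_proteins must be >= 1")
    if config.length_max < 9:
        raise FixtureError("degenerate length distribution: max protein length < 9")
    if config.length_min > config.length_max or config.length_min < 1:
        raise FixtureError("invalid protein length bounds")
    weights = config.alphabet_weights
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if len(weights) != 20 or weights.sum() <= 0:
            raise FixtureError("alphabet_weights must be 20 non-negative values")
        weights = weights / weights.sum()
    letters = np.array(list(STANDARD_AA))
    children = np.random.SeedSequence(config.seed).spawn(config.n_proteins)
    records = []
    for i, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        length = int(rng.integers(config.length_min, config.length_max + 1))
        seq = "".join(rng.choice(letters, size=length, p=weights))
        records.append((f"PROT{i:04d}", f"GENE{i:04d}", seq))
    return records


def simulate_neoepitopes(
    proteome: list[tuple[str, str, str]],
    n: int,
    k: int = 9,
    seed: int = 0,
) -> list[SimulatedNeoepitope]:
    """n random k-mers drawn uniformly over all windows of the proteome,
    each with one random substitution at a random position. The
    substituted letter is uniform over the 19 letters other than the
    original; the source gene is retained for match-status analysis."""
    windows = [
        (seq[i : i + k], pid, gid)
        for pid, gid, seq in proteome
        for i in range(len(seq) - k + 1)
    ]
    if not windows:
        raise FixtureError(f"proteome contains no window of length {k}")
    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        window, pid, gid = windows[int(rng.integers(len(windows)))]
        pos = int(rng.integers(1, k + 1))
        original = window[pos - 1]
        alternatives = [c for c in STANDARD_AA if c != original]
        substituted = alternatives[int(rng.integers(len(alternatives)))]
        mutated = window[: pos - 1] + substituted + window[pos:]
        out.append(
            SimulatedNeoepitope(
                source_window=Peptide(window),
                source_protein=pid,
                source_gene=gid,
                mutated_position=pos,
                original_aa=original,
                substituted_aa=substituted,
                sequence=Peptide(mutated),
            )
        )
    return out


_AA_INDEX = {c: i for i, c in enumerate(STANDARD_AA)}


def _allele_weights(allele: str, length: int, config: FixtureConfig) -> np.ndarray:
    """Fixed per-allele positional weight table, (length x 20). Seeded from
    a stable hash of the allele name (never Python's randomized hash)."""
    digest = hashlib.blake2b(
        f"{allele}|{length}".encode(), digest_size=8
    ).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "big"))
    weights = rng.normal(size=(length, 20))
    weights[1, :] *= config.anchor_weight  # position 2
    weights[length - 1, :] *= config.anchor_weight  # last position
    return weights


def pseudo_affinity(
    peptide: Peptide | str,
    allele: str,
    config: FixtureConfig = FixtureConfig(),
) -> float:
    """Deterministic pseudo nM affinity of a peptide for an allele.

    Pure function of (peptide, allele, config); output strictly inside
    [affinity_min_nm, affinity_max_nm], log-scaled via a logistic squash
    of the positional-weight sum.
    """
    seq = as_peptide(peptide).sequence
    weights = _allele_weights(allele, len(seq), config)
    score = sum(weights[i, _AA_INDEX[c]] for i, c in enumerate(seq))
    # squash: anchor-weighted sums have sd ~ sqrt(L + 2*(w^2-1)) — scale down
    scale = np.sqrt(len(seq) + 2 * (config.anchor_weight**2 - 1))
    u = 1.0 / (1.0 + np.exp(-score / scale * 2.5))
    log_lo, log_hi = np.log(config.affinity_min_nm), np.log(config.affinity_max_nm)
    return float(np.exp(log_lo + u * (log_hi - log_lo)))


def generate_cohort(
    config: FixtureConfig,
    n: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Synthetic immune-response cohort with known generative structure.

    Predictors are drawn independently; the latent score is the configured
    linear combination of {neo_affinity, sim_viral, human_match_diff,
    mismatches_paired} plus Gaussian noise (cohort_noise_sigma). The
    binary response thresholds the noisy latent at the quantile hitting
    cohort_prevalence.

    Returns (frame, truth). frame carries every ImmunogenicityRecord
    predictor column plus `latent` (noiseless), `response_continuous`
    (latent + noise, the OLS recovery target) and boolean `response`.
    truth records the generating coefficients, noise sigma and threshold.
    """
    coeffs = dict(config.cohort_coefficients)
    n_terms = len(coeffs)
    if n <= n_terms:
        raise FixtureError(f"need n > {n_terms} records")
    if not 0 < config.cohort_prevalence < 1:
        raise FixtureError("infeasible prevalence; must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lo, hi = np.log(config.affinity_min_nm), np.log(config.affinity_max_nm)
    neo_affinity = np.exp(rng.uniform(lo, hi, size=n))
    normal_affinity = np.exp(rng.uniform(lo, hi, size=n))
    frame = pd.DataFrame(
        {
            "neo_affinity": neo_affinity,
            "normal_affinity": normal_affinity,
            "paired_diff": normal_affinity - neo_affinity,
            "human_match_diff": rng.normal(0.0, 2000.0, size=n),
            "mismatches_paired": rng.integers(1, 5, size=n),
            "sim_paired": rng.uniform(50.0, 100.0, size=n),
            "sim_human": rng.uniform(50.0, 100.0, size=n),
            "sim_bacterial": rng.uniform(60.0, 100.0, size=n),
            "sim_viral": rng.uniform(40.0, 100.0, size=n),
            "novel_flag": rng.random(size=n) < 0.2,
        }
    )
    latent = np.full(n, coeffs.get("intercept", 0.0))
    for name, beta in coeffs.items():
        if name == "intercept":
            continue
        latent = latent + beta * frame[name].to_numpy(dtype=float)
    noise = rng.normal(0.0, config.cohort_noise_sigma, size=n)
    noisy = latent + noise
    threshold = float(np.quantile(noisy, 1.0 - config.cohort_prevalence))
    frame["latent"] = latent
    frame["response_continuous"] = noisy
    frame["response"] = noisy > threshold
    if frame["response"].nunique() < 2:
        raise FixtureError("infeasible prevalence: single-class cohort generated")
    truth = {
        "coefficients": coeffs,
        "noise_sigma": config.cohort_noise_sigma,
        "threshold": threshold,
    }
    return frame, truth
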