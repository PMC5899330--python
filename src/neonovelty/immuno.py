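"""Immune-response binarization, linear-probability immunogenicity models,
and rank-based AUROC.

The binary response is fit by ordinary least squares (a linear probability
model), mirroring the original analysis choice of R's lm on a 0/1 outcome;
logistic regression is available as a clearly-labeled alternative. The
reduced "multiplicative" model is the full factorial interaction expansion
of four predictors (all main effects plus every product term), with the
term set overridable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

FULL_MODEL_TERMS = [
    "neo_affinity",
    "novel_flag",
    "paired_diff",
    "human_match_diff",
    "mismatches_paired",
    "sim_paired",
    "sim_human",
    "sim_bacterial",
    "sim_viral",
]

#: The four predictors of the reduced multiplicative model.
REDUCED_MODEL_FIELDS = [
    "neo_affinity",
    "sim_viral",
    "human_match_diff",
    "mismatches_paired",
]


class IncompleteRecordError(ValueError):
    """A record is missing the field its binarization rule requires."""


class SingularFitError(ValueError):
    pass


class UndefinedAUROCError(ValueError):
    pass


@dataclass(frozen=True)
class ImmunogenicityRecord:
    """Predictor vector for one peptide plus its binary response label."""

    neo_affinity: float
    normal_affinity: float
    paired_diff: float
    human_match_diff: float
    mismatches_paired: int
    sim_paired: float
    sim_human: float
    sim_bacterial: float
    sim_viral: float
    novel_flag: bool
    response: bool

    def __post_init__(self):
        if self.neo_affinity <= 0 or self.normal_affinity <= 0:
            raise ValueError("affinities must be > 0 nM")
        for name in ("sim_paired", "sim_human", "sim_bacterial", "sim_viral"):
            if getattr(self, name) > 100.0 + 1e-9:
                raise ValueError(f"{name} exceeds 100%")


@dataclass(frozen=True)
class ResponseBinarizationRule:
    """Maps one cohort row to a boolean response, per source study.

    kinds: "threshold" (continuous field strictly greater than threshold),
    "boolean" (pass-through), "categorical" (field value in responder set).
    """

    study: str
    kind: str
    field: str
    threshold: float | None = None
    responder_values: frozenset = frozenset()


STUDY_RULES: dict[str, ResponseBinarizationRule] = {
    # percent neoantigen-specific T cells in lymph+/CD8+ gated cells, > 10%
    "carreno": ResponseBinarizationRule(
        "carreno", "threshold", "tcell_fraction_pct", threshold=10.0
    ),
    "ott": ResponseBinarizationRule("ott", "boolean", "response"),
    "bjerregaard": ResponseBinarizationRule("bjerregaard", "boolean", "response"),
    # clonal T-cell expansion = responder; ELISpot-only reactivity is not
    "le": ResponseBinarizationRule(
        "le", "categorical", "assay_result",
        responder_values=frozenset({"clonal_expansion"}),
    ),
    "tran": ResponseBinarizationRule(
        "tran", "categorical", "assay_result",
        responder_values=frozenset({"tcell_reactive"}),
    ),
    "gros": ResponseBinarizationRule(
        "gros", "categorical", "assay_result",
        responder_values=frozenset({"tcell_reactive"}),
    ),
}


def binarize_response(raw_record: dict, rule: ResponseBinarizationRule) -> bool:
    value = raw_record.get(rule.field)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise IncompleteRecordError(
            f"record lacks field {rule.field!r} required by rule {rule.study!r}"
        )
    if rule.kind == "threshold":
        return float(value) > rule.threshold
    if rule.kind == "boolean":
        if isinstance(value, str):
            return value.strip().lower() in ("1", "true", "yes")
        return bool(value)
    if rule.kind == "categorical":
        return str(value) in rule.responder_values
    raise ValueError(f"unknown rule kind {rule.kind!r}")


def factorial_terms(fields: list[str]) -> list[str]:
    """All main effects and every interaction product, R's a*b*... expansion."""
    terms = []
    for r in range(1, len(fields) + 1):
        for combo in itertools.combinations(fields, r):
            terms.append(":".join(combo))
    return terms


REDUCED_MODEL_TERMS = factorial_terms(REDUCED_MODEL_FIELDS)


@dataclass(frozen=True)
class ModelFit:
    terms: tuple[str, ...]  # includes "intercept" first
    coefficients: tuple[float, ...]
    standard_errors: tuple[float, ...]
    p_values: tuple[float, ...]
    adjusted_r_squared: float
    model_p_value: float
    n_observations: int
    family: str = "ols"

    def to_dict(self) -> dict:
        return asdict(self)


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([asdict(r) for r in records])


def design_matrix(frame: pd.DataFrame, terms: list[str]) -> np.ndarray:
    """Intercept column followed by one column per term; a term of the
    form "a:b:c" is the elementwise product of those fields."""
    cols = [np.ones(len(frame))]
    for term in terms:
        parts = term.split(":")
        missing = [p for p in parts if p not in frame.columns]
        if missing:
            raise KeyError(f"term {term!r} references missing column(s) {missing}")
        col = np.ones(len(frame))
        for p in parts:
            col = col * frame[p].to_numpy(dtype=float)
        cols.append(col)
    return np.column_stack(cols)


def fit_linear_model(
    records,
    terms: list[str] | None = None,
    family: str = "ols",
) -> ModelFit:
    """OLS fit of the 0/1 response on the requested terms.

    `terms` defaults to the full nine-predictor additive model. Pass
    REDUCED_MODEL_TERMS for the four-predictor full-factorial
    multiplicative model, or any single term for per-metric fits.
    family="logit" fits logistic regression instead (optional alternative;
    model_p_value is then the likelihood-ratio test, and
    adjusted_r_squared is McFadden's pseudo-R2).
    """
    frame = _records_to_frame(records)
    if terms is None:
        terms = FULL_MODEL_TERMS
    y = frame["response"].to_numpy(dtype=float)
    X = design_matrix(frame, terms)
    n, p = X.shape
    if n <= p:
        raise SingularFitError(f"underdetermined fit: {n} records, {p} columns")
    if np.linalg.matrix_rank(X) < p:
        raise SingularFitError("design matrix is rank-deficient")

    if family == "ols":
        res = sm.OLS(y, X).fit()
        adj_r2 = float(res.rsquared_adj)
        model_p = float(res.f_pvalue)
    elif family == "logit":
        res = sm.Logit(y, X).fit(disp=0)
        adj_r2 = float(res.prsquared)
        model_p = float(res.llr_pvalue)
    else:
        raise ValueError(f"unknown family {family!r}")

    return ModelFit(
        terms=("intercept", *terms),
        coefficients=tuple(float(c) for c in res.params),
        standard_errors=tuple(float(s) for s in res.bse),
        p_values=tuple(float(pv) for pv in res.pvalues),
        adjusted_r_squared=adj_r2,
        model_p_value=model_p,
        n_observations=n,
        family=family,
    )


def predict(fit: ModelFit, records) -> np.ndarray:
    """Unclipped linear scores from a fit's coefficients."""
    frame = _records_to_frame(records)
    X = design_matrix(frame, list(fit.terms[1:]))
    eta = X @ np.asarray(fit.coefficients)
    if fit.family == "logit":
        return 1.0 / (1.0 + np.exp(-eta))
    return eta


def auroc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUROC; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUROCError("AUROC requires at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks: ties contribute 1/2
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
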