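"""Evaluation of predicted CRMs against a curated database of known CRMs.

Five interval-overlap performance measures, all percentages of a documented
denominator (NA when the denominator is empty), every overlap qualified by
a minimum fraction of the *prediction's* length (default 10%):

- database recovery: predictions overlapping known CRMs / all predictions
  (a precision-like measure over predictions);
- database recall: distinct known CRMs hit / all known CRMs;
- training set sensitivity: distinct training CRMs hit / training set size;
- expression pattern precision: among predictions overlapping any
  expression-annotated CRM, the fraction whose hits include the target
  term;
- expression pattern recall: distinct target-term CRMs hit / all CRMs
  carrying the target term.

Random expectation comes from a permutation null: predictions are shuffled
over the non-excluded genome and each measure recomputed, yielding an
empirical mean/sd and a z score for the observed value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    CrmRecord,
    GenomicInterval,
    GenomeSpace,
    intersect_fraction,
    shuffle_intervals,
    sort_merge,
)

__all__ = [
    "EvaluationInput",
    "MeasureSet",
    "NullSummary",
    "prepare_reference",
    "redfly_recovery",
    "redfly_recall",
    "training_set_sensitivity",
    "expression_pattern_precision",
    "expression_pattern_recall",
    "evaluate_fixed",
    "evaluate_continuous",
    "permutation_null",
    "write_summary",
    "MEASURES",
]

NA = math.nan


def _is_na(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


@dataclass
class EvaluationInput:
    """Everything one evaluation needs.

    ``predictions`` are ranked, best first. ``reference_crms`` is the
    known-CRM database (records may carry expression terms);
    ``training_crms`` and ``target_term`` are optional and enable the
    training-sensitivity and expression measures.
    """

    predictions: list[GenomicInterval]
    reference_crms: list[CrmRecord]
    space: GenomeSpace
    training_crms: list[GenomicInterval] | None = None
    target_term: str | None = None
    min_frac: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.min_frac <= 1):
            raise ValueError("min_frac must be in (0, 1]")
        coords = [(p.chrom, p.start, p.end) for p in self.predictions]
        if len(set(coords)) != len(coords):
            raise ValueError("duplicate prediction coordinates")


@dataclass
class MeasureSet:
    redfly_recovery: float
    redfly_recall: float
    training_set_sensitivity: float
    expression_pattern_precision: float
    expression_pattern_recall: float
    n_predictions: int

    def as_dict(self) -> dict[str, float]:
        return {
            "redfly_recovery": self.redfly_recovery,
            "redfly_recall": self.redfly_recall,
            "training_set_sensitivity": self.training_set_sensitivity,
            "expression_pattern_precision": self.expression_pattern_precision,
            "expression_pattern_recall": self.expression_pattern_recall,
            "n_predictions": self.n_predictions,
        }


@dataclass
class NullSummary:
    n_permutations: int
    null_mean: float
    null_sd: float
    z: float
    seed: int
    observed: float = NA

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


def prepare_reference(
    reference_crms: list[CrmRecord],
    training_crms: list[GenomicInterval] | None = None,
    max_len: int = 2000,
) -> tuple[list[GenomicInterval], list[CrmRecord]]:
    """Length-filter and training-filter the reference database.

    CRMs of length >= ``max_len`` are dropped (the database convention is a
    strict "< 2 kb" inclusion rule). Any reference CRM sharing at least 50%
    of its own length with a training CRM is removed (training sequences
    must not count as discoveries). Survivors are returned twice: sorted
    and merged for the recovery track, and un-merged with their terms for
    the expression track.
    """
    survivors = [r for r in reference_crms if r.interval.length < max_len]
    if training_crms:
        ivs = [r.interval for r in survivors]
        hit = intersect_fraction(ivs, training_crms, 0.50).a_hit_indices
        survivors = [r for i, r in enumerate(survivors) if i not in hit]
    merged_ref = sort_merge([r.interval for r in survivors])
    return merged_ref, survivors


def redfly_recovery(
    predictions: list[GenomicInterval],
    merged_ref: list[GenomicInterval],
    min_frac: float = 0.10,
) -> float:
    """Percent of predictions overlapping a known CRM (NA if no predictions)."""
    if not predictions:
        return NA
    res = intersect_fraction(predictions, merged_ref, min_frac)
    return 100.0 * len(res.a_hit_indices) / len(predictions)


def redfly_recall(
    predictions: list[GenomicInterval],
    merged_ref: list[GenomicInterval],
    min_frac: float = 0.10,
) -> float:
    """Percent of known CRMs hit by at least one qualifying prediction."""
    if not merged_ref:
        return NA
    res = intersect_fraction(predictions, merged_ref, min_frac)
    return 100.0 * len(res.b_hit_indices) / len(merged_ref)


def training_set_sensitivity(
    predictions: list[GenomicInterval],
    training_crms: list[GenomicInterval],
    min_frac: float = 0.10,
) -> float:
    """Percent of distinct training CRMs recovered by the predictions.

    Counting distinct training CRMs (rather than qualifying predictions)
    caps the measure at 100% when several predictions tile one training
    CRM.
    """
    if not training_crms:
        return NA
    res = intersect_fraction(predictions, training_crms, min_frac)
    return 100.0 * len(res.b_hit_indices) / len(training_crms)


def _annotated_hits(
    predictions: list[GenomicInterval],
    expr_ref: list[CrmRecord],
    min_frac: float,
) -> dict[int, set[int]]:
    """prediction index -> indices of term-carrying reference records hit."""
    annotated = [(j, r) for j, r in enumerate(expr_ref) if r.terms]
    res = intersect_fraction(predictions, [r.interval for _, r in annotated], min_frac)
    out: dict[int, set[int]] = {}
    for i, jj in res.pairs:
        out.setdefault(i, set()).add(annotated[jj][0])
    return out


def expression_pattern_precision(
    predictions: list[GenomicInterval],
    expr_ref: list[CrmRecord],
    target_term: str,
    min_frac: float = 0.10,
) -> float:
    """Among predictions hitting any annotated CRM, percent hitting the term.

    A prediction with several annotated hits counts once in the denominator
    and is correct if any of its hits carries the target term.
    """
    if not target_term:
        raise ValueError("target_term must be non-empty")
    hits = _annotated_hits(predictions, expr_ref, min_frac)
    if not hits:
        return NA
    correct = sum(
        1
        for js in hits.values()
        if any(target_term in expr_ref[j].terms for j in js)
    )
    return 100.0 * correct / len(hits)


def expression_pattern_recall(
    predictions: list[GenomicInterval],
    expr_ref: list[CrmRecord],
    target_term: str,
    min_frac: float = 0.10,
) -> float:
    """Percent of target-term reference CRMs hit by at least one prediction."""
    if not target_term:
        raise ValueError("target_term must be non-empty")
    targets = [r for r in expr_ref if target_term in r.terms]
    if not targets:
        return NA
    res = intersect_fraction(predictions, [r.interval for r in targets], min_frac)
    return 100.0 * len(res.b_hit_indices) / len(targets)


MEASURES = (
    "redfly_recovery",
    "redfly_recall",
    "training_set_sensitivity",
    "expression_pattern_precision",
    "expression_pattern_recall",
)


def _measures_on(
    predictions: list[GenomicInterval],
    merged_ref: list[GenomicInterval],
    expr_ref: list[CrmRecord],
    inp: EvaluationInput,
) -> MeasureSet:
    has_term = inp.target_term is not None
    return MeasureSet(
        redfly_recovery=redfly_recovery(predictions, merged_ref, inp.min_frac),
        redfly_recall=redfly_recall(predictions, merged_ref, inp.min_frac),
        training_set_sensitivity=(
            training_set_sensitivity(predictions, inp.training_crms, inp.min_frac)
            if inp.training_crms
            else NA
        ),
        expression_pattern_precision=(
            expression_pattern_precision(predictions, expr_ref, inp.target_term, inp.min_frac)
            if has_term
            else NA
        ),
        expression_pattern_recall=(
            expression_pattern_recall(predictions, expr_ref, inp.target_term, inp.min_frac)
            if has_term
            else NA
        ),
        n_predictions=len(predictions),
    )


def evaluate_fixed(inp: EvaluationInput) -> MeasureSet:
    """All five measures on the full prediction list as given."""
    merged_ref, expr_ref = prepare_reference(inp.reference_crms, inp.training_crms)
    return _measures_on(inp.predictions, merged_ref, expr_ref, inp)


def evaluate_continuous(
    inp: EvaluationInput, step: int = 250, max_n: int = 7000
) -> list[tuple[int, MeasureSet]]:
    """Measures every ``step`` predictions over the ranked top ``max_n``.

    One row per n in {step, 2*step, ...} up to min(max_n, #predictions),
    with a final partial bucket when the list does not divide evenly.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    merged_ref, expr_ref = prepare_reference(inp.reference_crms, inp.training_crms)
    limit = min(max_n, len(inp.predictions))
    ns = list(range(step, limit + 1, step))
    if not ns or ns[-1] < limit:
        ns.append(limit)
    return [(n, _measures_on(inp.predictions[:n], merged_ref, expr_ref, inp)) for n in ns]


def permutation_null(
    inp: EvaluationInput,
    measure_name: str,
    n_perm: int = 100,
    seed: int = 0,
) -> NullSummary:
    """Empirical random expectation of one measure by interval shuffling.

    Each permutation relocates every prediction uniformly over the
    non-excluded genome and recomputes the measure; NA replicate values
    (empty denominator under shuffling) count as 0. The z score uses the
    population standard deviation and is NA when the null is degenerate
    (sd == 0).
    """
    if measure_name not in MEASURES:
        raise ValueError(f"unknown measure {measure_name!r}")
    merged_ref, expr_ref = prepare_reference(inp.reference_crms, inp.training_crms)

    def compute(predictions: list[GenomicInterval]) -> float:
        ms = _measures_on(predictions, merged_ref, expr_ref, inp)
        return getattr(ms, measure_name)

    observed = compute(inp.predictions)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = shuffle_intervals(inp.predictions, inp.space, rng)
        v = compute(shuffled)
        vals[i] = 0.0 if _is_na(v) else v
    mean, sd = float(vals.mean()), float(vals.std())  # population sd
    z = NA if sd == 0 or _is_na(observed) else (observed - mean) / sd
    return NullSummary(
        n_permutations=n_perm, null_mean=mean, null_sd=sd, z=z, seed=seed, observed=observed
    )


def write_summary(
    rows: list[dict[str, object]], path: str, header: list[str] | None = None
) -> None:
    """Write evaluation rows as a tab-delimited table; NA rendered as 'NA'."""
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        for h in header or []:
            fh.write(f"# {h}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")
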