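"""Synthetic oxaliplatin-report cohorts with planted drug-event odds effects.

The generator stands in for a spontaneous-report database extract: every
report carries the anchor drug (oxaliplatin), each co-medication is an
independent Bernoulli exposure at its configured prevalence, and the target
event is drawn from an odds model,

    P(event | drugs present) = m * b / (1 - b + m * b),

where ``b`` is the baseline event probability of an unexposed report and
``m`` is the product of the odds multipliers of the exposure drugs present.
Under this model the population reporting odds ratio of a single planted drug
equals its multiplier exactly, which makes the multiplier the recovery target
for the downstream disproportionality analysis.

Filler drugs and filler reaction terms (multiplier 1) are sprinkled in to make
term matching non-trivial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .reports import ANCHOR_DRUG, OIPN_TERMS, Role, SpontaneousReport, fold_term, normalize_drug_name

__all__ = ["CohortConfig", "generate_cohort", "expected_table"]

#: Default filler reaction vocabulary (common, neuropathy-unrelated PTs).
DEFAULT_EVENT_VOCAB = (
    "Nausea",
    "Diarrhoea",
    "Vomiting",
    "Fatigue",
    "Neutropenia",
    "Thrombocytopenia",
    "Anaemia",
    "Pyrexia",
    "Decreased appetite",
    "Alopecia",
)

#: Default filler co-medication vocabulary.
DEFAULT_DRUG_VOCAB = (
    "FLUOROURACIL",
    "LEUCOVORIN",
    "CAPECITABINE",
    "IRINOTECAN",
    "BEVACIZUMAB",
    "DEXAMETHASONE",
    "ONDANSETRON",
    "APREPITANT",
    "FILGRASTIM",
    "HEPARIN",
)


@dataclass
class CohortConfig:
    """Generative specification for one synthetic report cohort.

    Parameters
    ----------
    n_reports
        Number of oxaliplatin reports to draw.
    baseline_event_prob
        Probability in (0, 1) that a report with no multiplier-carrying drug
        lists the target event.
    exposures
        Drug name -> per-report exposure prevalence in [0, 1].
    odds_multipliers
        Drug name -> positive odds multiplier on the event; keys must be a
        subset of ``exposures``.  Drugs absent from this map act as multiplier 1.
    event_terms
        Preferred terms the planted event may be reported under; one is chosen
        uniformly per event report.
    extra_event_vocab, extra_drug_vocab
        Filler vocabularies; 0-3 fillers of each kind are added per report.
    concomitant_fraction
        Probability that a listed co-medication carries the CONCOMITANT role
        (otherwise SUSPECT); the anchor drug is always SUSPECT.
    seed
        Seed of the cohort's single RNG stream.
    """

    n_reports: int
    baseline_event_prob: float
    exposures: Mapping[str, float] = field(default_factory=dict)
    odds_multipliers: Mapping[str, float] = field(default_factory=dict)
    event_terms: tuple[str, ...] = OIPN_TERMS
    extra_event_vocab: tuple[str, ...] = DEFAULT_EVENT_VOCAB
    extra_drug_vocab: tuple[str, ...] = DEFAULT_DRUG_VOCAB
    concomitant_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_reports, (int, np.integer)) or self.n_reports < 0:
            raise ConfigurationError(f"n_reports must be a non-negative integer, got {self.n_reports!r}")
        if not (0.0 < self.baseline_event_prob < 1.0):
            raise ConfigurationError(
                f"baseline_event_prob must lie in (0, 1), got {self.baseline_event_prob!r}"
            )
        self.exposures = {normalize_drug_name(k): float(v) for k, v in self.exposures.items()}
        self.odds_multipliers = {
            normalize_drug_name(k): float(v) for k, v in self.odds_multipliers.items()
        }
        for key, p in self.exposures.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"exposure prevalence for {key!r} must lie in [0, 1], got {p!r}")
        for key, m in self.odds_multipliers.items():
            if key not in self.exposures:
                raise ConfigurationError(f"odds multiplier for {key!r} has no matching exposure entry")
            if not (m > 0.0) or not math.isfinite(m):
                raise ConfigurationError(f"odds multiplier for {key!r} must be a positive real, got {m!r}")
        if not self.event_terms:
            raise ConfigurationError("event_terms must be non-empty")
        if not (0.0 <= self.concomitant_fraction <= 1.0):
            raise ConfigurationError("concomitant_fraction must lie in [0, 1]")
        self.event_terms = tuple(str(t) for t in self.event_terms)
        self.extra_event_vocab = tuple(str(t) for t in self.extra_event_vocab)
        self.extra_drug_vocab = tuple(normalize_drug_name(d) for d in self.extra_drug_vocab)
        event_folds = {fold_term(t) for t in self.event_terms}
        if any(fold_term(t) in event_folds for t in self.extra_event_vocab):
            raise ConfigurationError("extra_event_vocab must not overlap event_terms")
        reserved = set(self.exposures) | {ANCHOR_DRUG}
        if any(d in reserved for d in self.extra_drug_vocab):
            raise ConfigurationError("extra_drug_vocab must not overlap exposures or the anchor drug")

    def event_probability(self, drugs_present: Sequence[str] = ()) -> float:
        """Event probability of a report listing exactly ``drugs_present``."""
        m = 1.0
        for d in drugs_present:
            m *= self.odds_multipliers.get(normalize_drug_name(d), 1.0)
        odds = m * self.baseline_event_prob / (1.0 - self.baseline_event_prob)
        return odds / (1.0 + odds)


def generate_cohort(config: CohortConfig) -> list[SpontaneousReport]:
    """Draw a cohort of spontaneous reports from ``config``.

    All randomness comes from a single ``numpy`` Generator seeded with
    ``config.seed``; identical configs reproduce identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    n = int(config.n_reports)
    if n == 0:
        return []

    drug_names = sorted(config.exposures)
    k = len(drug_names)
    anchor = (ANCHOR_DRUG, Role.SUSPECT)

    if k:
        prev = np.array([config.exposures[d] for d in drug_names])
        logm = np.array([math.log(config.odds_multipliers.get(d, 1.0)) for d in drug_names])
        exposed = rng.random((n, k)) < prev
        log_mult = exposed @ logm
        conc = rng.random((n, k)) < config.concomitant_fraction
    else:
        exposed = np.zeros((n, 0), dtype=bool)
        log_mult = np.zeros(n)
        conc = np.zeros((n, 0), dtype=bool)

    base_odds = config.baseline_event_prob / (1.0 - config.baseline_event_prob)
    odds = np.exp(log_mult) * base_odds
    event = rng.random(n) < odds / (1.0 + odds)
    term_idx = rng.integers(0, len(config.event_terms), size=n)

    if config.extra_event_vocab:
        n_fill_r = rng.integers(0, 4, size=n)
        fill_r = rng.integers(0, len(config.extra_event_vocab), size=int(n_fill_r.sum()))
    else:
        n_fill_r = np.zeros(n, dtype=np.int64)
        fill_r = np.empty(0, dtype=np.int64)
    if config.extra_drug_vocab:
        n_fill_d = rng.integers(0, 4, size=n)
        total_d = int(n_fill_d.sum())
        fill_d = rng.integers(0, len(config.extra_drug_vocab), size=total_d)
        fill_d_conc = rng.random(total_d) < config.concomitant_fraction
    else:
        n_fill_d = np.zeros(n, dtype=np.int64)
        fill_d = np.empty(0, dtype=np.int64)
        fill_d_conc = np.empty(0, dtype=bool)

    # per-report exposure index lists, via one global nonzero scan
    rows, cols = np.nonzero(exposed)

    reports: list[SpontaneousReport] = []
    width = max(6, len(str(n)))
    rpos = dpos = epos = 0
    empty_reactions = frozenset()
    anchor_only = frozenset((anchor,))
    event_terms = config.event_terms
    rvocab = config.extra_event_vocab
    dvocab = config.extra_drug_vocab
    for i in range(n):
        drugs = None
        while epos < len(rows) and rows[epos] == i:
            j = int(cols[epos])
            if drugs is None:
                drugs = {anchor}
            drugs.add((drug_names[j], Role.CONCOMITANT if conc[i, j] else Role.SUSPECT))
            epos += 1
        nd = int(n_fill_d[i])
        if nd:
            if drugs is None:
                drugs = {anchor}
            for _ in range(nd):
                drugs.add(
                    (dvocab[int(fill_d[dpos])], Role.CONCOMITANT if fill_d_conc[dpos] else Role.SUSPECT)
                )
                dpos += 1
        reactions = set()
        if event[i]:
            reactions.add(event_terms[int(term_idx[i])])
        nr = int(n_fill_r[i])
        for _ in range(nr):
            reactions.add(rvocab[int(fill_r[rpos])])
            rpos += 1
        reports.append(
            SpontaneousReport(
                report_id=f"R{i:0{width}d}",
                drugs=anchor_only if drugs is None else frozenset(drugs),
                reactions=empty_reactions if not reactions else frozenset(reactions),
            )
        )
    return reports


def _multiplier_distribution(config: CohortConfig, exclude: str) -> list[tuple[float, float]]:
    """Distribution of the odds-multiplier product over all drugs except ``exclude``.

    Exposures are independent, so the product distribution is built drug by
    drug; drugs with multiplier 1 never change the product and are skipped.
    """
    dist: dict[float, float] = {1.0: 1.0}
    for d, m in config.odds_multipliers.items():
        if d == exclude or m == 1.0:
            continue
        p = config.exposures[d]
        new: dict[float, float] = {}
        for value, prob in dist.items():
            new[value] = new.get(value, 0.0) + prob * (1.0 - p)
            mv = value * m
            new[mv] = new.get(mv, 0.0) + prob * p
        dist = new
    return list(dist.items())


def expected_table(
    config: CohortConfig, drug: str, event_terms: Sequence[str]
) -> tuple[float, float, float, float]:
    """Exact expected 2x2 cell counts (n11, n12, n21, n22) under the model.

    ``event_terms`` is the case definition applied downstream; only the
    fraction of planted terms it covers contributes to case counts (filler
    vocabulary never matches, by construction).  Cells sum to ``n_reports``.
    """
    drug = normalize_drug_name(drug)
    if drug not in config.exposures:
        raise KeyError(f"drug {drug!r} is not an exposure of this cohort config")
    covered = {fold_term(t) for t in event_terms}
    filler_folds = {fold_term(t) for t in config.extra_event_vocab}
    if covered & filler_folds:
        raise ConfigurationError(
            "expected_table requires case terms disjoint from the filler reaction vocabulary"
        )
    frac = sum(1 for t in config.event_terms if fold_term(t) in covered) / len(config.event_terms)

    b = config.baseline_event_prob
    base_odds = b / (1.0 - b)
    m_drug = config.odds_multipliers.get(drug, 1.0)
    p_drug = config.exposures[drug]
    others = _multiplier_distribution(config, exclude=drug)

    def p_case(extra_mult: float) -> float:
        total = 0.0
        for value, prob in others:
            o = value * extra_mult * base_odds
            total += prob * o / (1.0 + o)
        return total * frac

    n = float(config.n_reports)
    pe_case = p_case(m_drug)
    pu_case = p_case(1.0)
    n11 = n * p_drug * pe_case
    n12 = n * p_drug * (1.0 - pe_case)
    n21 = n * (1.0 - p_drug) * pu_case
    n22 = n * (1.0 - p_drug) * (1.0 - pu_case)
    return (n11, n12, n21, n22)
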