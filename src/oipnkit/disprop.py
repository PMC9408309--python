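"""Disproportionality analysis of spontaneous-report cohorts.

Within a cohort of oxaliplatin reports, each exposure (a drug or a drug
class) is contrasted against all other reports in a 2x2 table

    =============  ======  ==========
    .              case    non-case
    =============  ======  ==========
    exposed        n11     n12
    unexposed      n21     n22
    =============  ======  ==========

from which the reporting odds ratio

    ROR = (n11 / n21) / (n12 / n22) = (n11 * n22) / (n12 * n21)

and its 95% Wald confidence interval

    exp( ln ROR +/- 1.96 * sqrt(1/n11 + 1/n12 + 1/n21 + 1/n22) )

are computed, together with a Pearson chi-square test of independence that
switches to the Yates continuity correction at small cell counts.  A solver
is included that reconstructs the integer 2x2 table behind a published
summary that prints only the cohort size, the case count, and the two group
rates rounded to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateTableError, InfeasibleMarginalsError
from .reports import OIPN_TERMS, PPI_CORE, PPI_EXTRA, Role, SpontaneousReport, fold_term, normalize_drug_name

__all__ = [
    "CaseDefinition",
    "ExposureDefinition",
    "ContingencyTable",
    "DisproportionalityResult",
    "MarginalSummary",
    "ReconstructionResult",
    "DEFAULT_CASE",
    "default_ppi_panel",
    "match_case",
    "classify_exposure",
    "build_table",
    "compute_ror",
    "compute_wald_ci",
    "chi_square_test",
    "analyze_table",
    "analyze_panel",
    "reconstruct_from_marginals",
]

YatesRule = Literal["observed", "expected", "always", "never"]


@dataclass(frozen=True)
class CaseDefinition:
    """A named set of reaction preferred terms defining the case."""

    name: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("case definition needs at least one term")
        folded = [fold_term(t) for t in self.terms]
        if len(set(folded)) != len(folded):
            raise ValueError("case terms must be unique after case-folding and trimming")
        object.__setattr__(self, "_folded", frozenset(folded))

    @property
    def folded_terms(self) -> frozenset[str]:
        return self._folded  # type: ignore[attr-defined]


#: Peripheral-neuropathy case: the three preferred terms of the source analysis.
DEFAULT_CASE = CaseDefinition(name="OIPN", terms=OIPN_TERMS)


@dataclass(frozen=True)
class ExposureDefinition:
    """A drug or drug class: member drug names plus the roles that count."""

    name: str
    members: tuple[str, ...]
    roles_counted: frozenset[Role] = frozenset(Role)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("exposure definition needs at least one member drug")
        if not self.roles_counted:
            raise ValueError("roles_counted must be non-empty")
        normalized = tuple(dict.fromkeys(normalize_drug_name(m) for m in self.members))
        object.__setattr__(self, "members", normalized)


def default_ppi_panel(include_extra: bool = True) -> list[ExposureDefinition]:
    """Per-drug PPI exposures plus an "any PPI" class row.

    The three PPIs analysed individually in the source cohort are always
    present; ``include_extra`` adds the remaining marketed PPIs to the class.
    """
    members = PPI_CORE + (PPI_EXTRA if include_extra else ())
    panel = [ExposureDefinition(name=d.capitalize(), members=(d,)) for d in PPI_CORE]
    panel.append(ExposureDefinition(name="any PPI", members=members))
    return panel


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts of the exposure-by-case 2x2 table."""

    n11: int  # exposed cases
    n12: int  # exposed non-cases
    n21: int  # unexposed cases
    n22: int  # unexposed non-cases

    def __post_init__(self) -> None:
        for name in ("n11", "n12", "n21", "n22"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.n11, self.n12, self.n21, self.n22)

    @property
    def exposed_case_rate_pct(self) -> float:
        return 100.0 * self.n11 / (self.n11 + self.n12)

    @property
    def unexposed_case_rate_pct(self) -> float:
        return 100.0 * self.n21 / (self.n21 + self.n22)


@dataclass
class DisproportionalityResult:
    """ROR, CI, chi-square and rates for one exposure row of a panel."""

    exposure: str
    table: ContingencyTable
    ror: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    ci_level: float = 0.95
    chi2: float | None = None
    p_value: float | None = None
    yates_applied: bool | None = None
    exposed_case_rate: float | None = None
    unexposed_case_rate: float | None = None
    haldane_applied: bool = False
    error: str | None = None


@dataclass(frozen=True)
class MarginalSummary:
    """Printed cohort marginals: totals plus two group rates at 2 decimals."""

    total_reports: int
    total_cases: int
    exposed_case_rate_pct: float
    unexposed_case_rate_pct: float

    def __post_init__(self) -> None:
        if self.total_reports <= 0:
            raise ValueError("total_reports must be positive")
        if not (0 <= self.total_cases <= self.total_reports):
            raise ValueError("total_cases must lie in [0, total_reports]")
        for name in ("exposed_case_rate_pct", "unexposed_case_rate_pct"):
            v = getattr(self, name)
            if not (0.0 < v < 100.0):
                raise ValueError(f"{name} must lie in (0, 100), got {v!r}")


# ---------------------------------------------------------------------------
# classification

def match_case(report: SpontaneousReport, case_def: CaseDefinition = DEFAULT_CASE) -> bool:
    """True iff any reaction term matches any case term (case/space-insensitive)."""
    folded = case_def.folded_terms
    return any(fold_term(r) in folded for r in report.reactions)


def classify_exposure(report: SpontaneousReport, exposure: ExposureDefinition) -> bool:
    """True iff the report lists any member drug in a counted role."""
    drugs = report.drugs
    return any((m, role) in drugs for m in exposure.members for role in exposure.roles_counted)


def build_table(
    reports: Sequence[SpontaneousReport],
    case_def: CaseDefinition,
    exposure: ExposureDefinition,
) -> ContingencyTable:
    """Count each report into exactly one cell of the 2x2 table."""
    if not reports:
        raise ValueError("cannot build a contingency table from an empty cohort")
    n11 = n12 = n21 = n22 = 0
    folded = case_def.folded_terms
    members = exposure.members
    roles = tuple(exposure.roles_counted)
    for rep in reports:
        drugs = rep.drugs
        exposed = any((m, role) in drugs for m in members for role in roles)
        case = any(fold_term(r) in folded for r in rep.reactions)
        if exposed:
            if case:
                n11 += 1
            else:
                n12 += 1
        elif case:
            n21 += 1
        else:
            n22 += 1
    return ContingencyTable(n11, n12, n21, n22)


# ---------------------------------------------------------------------------
# statistics

def _effective_cells(table: ContingencyTable, haldane: bool) -> tuple[float, float, float, float]:
    cells = table.cells
    if haldane:
        return tuple(c + 0.5 for c in cells)  # type: ignore[return-value]
    if any(c == 0 for c in cells):
        raise DegenerateTableError(
            f"table {cells} has a zero cell; pass haldane=True to apply the +0.5 correction"
        )
    return tuple(float(c) for c in cells)  # type: ignore[return-value]


def compute_ror(table: ContingencyTable, haldane: bool = False) -> float:
    """Reporting odds ratio (n11*n22)/(n12*n21) of the table.

    With ``haldane=True`` the Haldane-Anscombe +0.5 correction is applied to
    every cell first, which makes zero-cell tables estimable.
    """
    a, b, c, d = _effective_cells(table, haldane)
    return (a * d) / (b * c)


def compute_wald_ci(
    table: ContingencyTable, level: float = 0.95, haldane: bool = False
) -> tuple[float, float]:
    """Wald confidence interval on the log odds scale.

    At ``level=0.95`` the critical value is 1.96 exactly (as conventionally
    printed); other levels use the exact normal quantile.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    a, b, c, d = _effective_cells(table, haldane)
    z = 1.96 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2.0))
    log_ror = math.log((a * d) / (b * c))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return (math.exp(log_ror - z * se), math.exp(log_ror + z * se))


def chi_square_test(
    table: ContingencyTable, yates: YatesRule = "observed"
) -> tuple[float, float, bool]:
    """Pearson chi-square (1 df) on the 2x2, with an automatic Yates rule.

    ``yates`` selects when the continuity correction triggers:

    - ``"observed"`` (default): any observed cell < 5,
    - ``"expected"``: any expected cell < 5,
    - ``"always"`` / ``"never"``: force the choice.

    Returns ``(statistic, p_value, yates_applied)``.
    """
    a, b, c, d = table.cells
    n = table.total
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    if 0 in (row1, row2, col1, col2):
        raise DegenerateTableError(f"table {table.cells} has a zero marginal")
    if yates == "observed":
        apply = min(table.cells) < 5
    elif yates == "expected":
        apply = min(r * c_ / n for r in (row1, row2) for c_ in (col1, col2)) < 5
    elif yates == "always":
        apply = True
    elif yates == "never":
        apply = False
    else:
        raise ValueError(f"unknown yates rule {yates!r}")
    stat, p, _, _ = stats.chi2_contingency(
        np.array([[a, b], [c, d]]), correction=apply
    )
    return float(stat), float(p), apply


def analyze_table(
    table: ContingencyTable,
    exposure_name: str = "exposure",
    *,
    ci_level: float = 0.95,
    haldane: bool = False,
    yates: YatesRule = "observed",
) -> DisproportionalityResult:
    """Full disproportionality summary of one table."""
    result = DisproportionalityResult(
        exposure=exposure_name,
        table=table,
        ci_level=ci_level,
        haldane_applied=haldane,
        exposed_case_rate=table.exposed_case_rate_pct if table.n11 + table.n12 else None,
        unexposed_case_rate=table.unexposed_case_rate_pct if table.n21 + table.n22 else None,
    )
    try:
        result.ror = compute_ror(table, haldane=haldane)
        result.ci_low, result.ci_high = compute_wald_ci(table, level=ci_level, haldane=haldane)
        result.chi2, result.p_value, result.yates_applied = chi_square_test(table, yates=yates)
    except DegenerateTableError as exc:
        result.error = str(exc)
    return result


def analyze_panel(
    reports: Sequence[SpontaneousReport],
    case_def: CaseDefinition,
    exposures: Iterable[ExposureDefinition],
    *,
    ci_level: float = 0.95,
    haldane: bool = False,
    yates: YatesRule = "observed",
) -> list[DisproportionalityResult]:
    """One disproportionality result per exposure, each against the full cohort.

    Every row contrasts reports listing the exposure against *all other*
    reports of the cohort; a class row counts a report once however many
    member drugs it lists.  Degenerate tables mark their row via ``error``
    rather than aborting the panel.
    """
    results = []
    for exposure in exposures:
        table = build_table(reports, case_def, exposure)
        results.append(
            analyze_table(
                table, exposure.name, ci_level=ci_level, haldane=haldane, yates=yates
            )
        )
    return results


# ---------------------------------------------------------------------------
# marginal reconstruction

def _round2(x: np.ndarray | float) -> np.ndarray | float:
    """Round half away from zero at 2 decimals (print convention)."""
    return np.floor(np.asarray(x) * 100.0 + 0.5) / 100.0


@dataclass
class ReconstructionResult:
    """Primary table, its discrepancy, and the full minimal-discrepancy tie set."""

    table: ContingencyTable
    discrepancy: float
    ties: list[ContingencyTable] = field(default_factory=list)


def reconstruct_from_marginals(
    m: MarginalSummary, tie_break: Literal["central", "smallest"] = "central"
) -> ReconstructionResult:
    """Recover integer 2x2 tables consistent with printed cohort marginals.

    Exhaustive integer search over the exposed-group size ``Ne`` in
    ``[1, total-1]`` and ``n11`` in its feasible range, scoring each candidate
    by the sum of squared differences between its two group rates (rounded to
    2 decimals, half away from zero) and the printed rates.  All tables
    achieving the minimal score are returned, ordered by (Ne, n11).

    ``tie_break`` picks the primary table among them: ``"central"`` (default)
    takes the middle of the tie set — the printed rates are interval-censored
    by rounding, so the central consistent table is the least extreme choice —
    while ``"smallest"`` takes the smallest exposed group.
    """
    total, cases = m.total_reports, m.total_cases
    r1, r0 = m.exposed_case_rate_pct, m.unexposed_case_rate_pct
    overall = 100.0 * cases / total
    if not (min(r1, r0) <= overall <= max(r1, r0)):
        raise InfeasibleMarginalsError(
            f"group rates ({r1}, {r0}) do not straddle the overall rate {overall:.4f}"
        )

    best = math.inf
    ties: list[tuple[int, int]] = []
    for ne in range(1, total):
        nu = total - ne
        lo = max(0, cases - nu)
        hi = min(ne, cases)
        if lo > hi:
            continue
        n11 = np.arange(lo, hi + 1)
        rate_e = _round2(100.0 * n11 / ne)
        rate_u = _round2(100.0 * (cases - n11) / nu)
        d = (rate_e - r1) ** 2 + (rate_u - r0) ** 2
        dmin = float(d.min())
        if dmin < best - 1e-12:
            best = dmin
            ties = [(ne, int(v)) for v in n11[np.nonzero(d <= dmin + 1e-12)]]
        elif dmin <= best + 1e-12:
            ties.extend((ne, int(v)) for v in n11[np.nonzero(d <= dmin + 1e-12)])

    tables = [
        ContingencyTable(a, ne - a, cases - a, (total - ne) - (cases - a)) for ne, a in ties
    ]
    if tie_break == "smallest":
        primary = tables[0]
    elif tie_break == "central":
        primary = tables[len(tables) // 2]
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    return ReconstructionResult(table=primary, discrepancy=best, ties=tables)
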