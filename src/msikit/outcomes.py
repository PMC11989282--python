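"""Exact response-rate inference and the composite non-responder score.

ORR (CR+PR) and DCR (CR+PR+SD) are reported over the intention-to-treat
denominator, with Clopper-Pearson exact binomial confidence intervals.
Between-group response comparisons use Barnard's unconditional exact test
(score statistic, nuisance success probability maximized over a fixed grid)
alongside Fisher's conditional exact test.

The composite score flags a likely non-responder when at least two of four
predictors are present — IHC/genomic discordance, MSS liquid biopsy, FFPE
clonality <= 15%, LB clonality >= 7% — or when LB clonality alone is
extremely high (>= 10%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .concordance import discordance_flag
from .panel_io import PatientRecord

BARNARD_GRID_SIZE = 1001  # nuisance grid: equally spaced interior points of (0, 1)
EXTREME_LB_CLONALITY = 10.0  # percent; flags a non-responder on its own
FFPE_LOW_CLONALITY_PREDICTOR = 15.0  # percent; composite-score cutoff for tissue


@dataclass(frozen=True)
class Table2x2:
    """2x2 contingency table: rows are groups, columns are success/failure."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def row_totals(self) -> tuple[int, int]:
        return self.a + self.b, self.c + self.d


@dataclass
class ResponseSummary:
    n: int
    n_cr: int
    n_pr: int
    n_sd: int
    n_pd: int
    n_ne: int
    orr: float
    orr_ci: tuple[float, float]
    dcr: float
    dcr_ci: tuple[float, float]


@dataclass
class CompositeScore:
    patient_id: str
    predictors: dict[str, Optional[bool]] = field(default_factory=dict)
    n_present: int = 0
    extreme_lb_clonality: bool = False
    flagged_nonresponder: bool = False


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI for x/n, returned as percents.

    lo = Beta(alpha/2; x, n-x+1) quantile (0 when x = 0);
    hi = Beta(1-alpha/2; x+1, n-x) quantile (100 when x = n).
    """
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"invalid (x, n) = ({x}, {n})")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    lo = 0.0 if x == 0 else 100.0 * float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    hi = 100.0 if x == n else 100.0 * float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return (lo, hi)


def response_summary(
    records: Sequence[PatientRecord],
    subset_filter: Optional[Callable[[PatientRecord], bool]] = None,
    alpha: float = 0.05,
) -> ResponseSummary:
    """Response counts, ORR and DCR with Clopper-Pearson CIs over the ITT subset.

    Non-evaluable (NE/censored) patients stay in the denominator but never in
    a numerator, as in intention-to-treat reporting.
    """
    subset = [r for r in records if subset_filter is None or subset_filter(r)]
    if not subset:
        raise ValueError("empty patient subset")
    counts = {k: sum(1 for r in subset if r.response == k) for k in ("CR", "PR", "SD", "PD", "NE")}
    n = len(subset)
    responders = counts["CR"] + counts["PR"]
    controlled = responders + counts["SD"]
    return ResponseSummary(
        n=n,
        n_cr=counts["CR"],
        n_pr=counts["PR"],
        n_sd=counts["SD"],
        n_pd=counts["PD"],
        n_ne=counts["NE"],
        orr=100.0 * responders / n,
        orr_ci=clopper_pearson(responders, n, alpha),
        dcr=100.0 * controlled / n,
        dcr_ci=clopper_pearson(controlled, n, alpha),
    )


def _score_statistic(x1: np.ndarray, n1: int, x2: np.ndarray, n2: int) -> np.ndarray:
    """Pooled-variance score statistic for a difference of two proportions.

    Zero (by convention) when the pooled estimate is 0 or 1, where the
    variance vanishes.
    """
    p1 = x1 / n1
    p2 = x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0.0, (p1 - p2) / np.sqrt(np.where(var > 0.0, var, 1.0)), 0.0)
    return z


def barnard_test(table: Table2x2, grid_size: int = BARNARD_GRID_SIZE) -> float:
    """Two-sided unconditional exact p-value for a 2x2 table.

    Enumerates all outcomes with the observed group sizes, orders them by the
    absolute pooled score statistic, and maximizes the tail probability over a
    grid of ``grid_size`` equally spaced nuisance success probabilities in the
    open interval (0, 1).
    """
    n1, n2 = table.row_totals
    if n1 == 0 or n2 == 0:
        return 1.0
    x1 = np.arange(n1 + 1)
    x2 = np.arange(n2 + 1)
    X1, X2 = np.meshgrid(x1, x2, indexing="ij")
    z = _score_statistic(X1.astype(float), n1, X2.astype(float), n2)
    z_obs = _score_statistic(np.array([float(table.a)]), n1, np.array([float(table.c)]), n2)[0]
    extreme = np.abs(z) >= np.abs(z_obs) - 1e-12

    pi = np.linspace(0.0, 1.0, grid_size + 2)[1:-1]
    log_b1 = stats.binom.logpmf(x1[:, None], n1, pi[None, :])
    log_b2 = stats.binom.logpmf(x2[:, None], n2, pi[None, :])
    # P(x1, x2 | pi) over the extreme region, for every grid point at once
    tail = np.zeros(len(pi))
    idx1, idx2 = np.nonzero(extreme)
    probs = np.exp(log_b1[idx1, :] + log_b2[idx2, :])
    tail = probs.sum(axis=0)
    return float(min(1.0, tail.max()))


def fisher_exact(table: Table2x2) -> float:
    """Two-sided Fisher exact p-value (hypergeometric tail sum)."""
    _, p = stats.fisher_exact([[table.a, table.b], [table.c, table.d]], alternative="two-sided")
    return float(p)


def composite_score(
    record: PatientRecord,
    extreme_lb_threshold: float = EXTREME_LB_CLONALITY,
    ffpe_low_threshold: float = FFPE_LOW_CLONALITY_PREDICTOR,
) -> Optional[CompositeScore]:
    """Composite non-responder score for one patient.

    Predictors (each True/False/None-for-unevaluable):
    ``discordance`` — IHC vs genomic methods; ``lb_mss`` — negative NGS call in
    liquid biopsy; ``ffpe_clonality_le15`` — tissue clonality at or below 15%;
    ``lb_clonality_ge7`` — LB clonality at or above 7%. Flagged when >= 2
    present predictors are True, or when LB clonality is >= 10% alone.
    Returns None when no predictor is evaluable.
    """
    predictors: dict[str, Optional[bool]] = {
        "discordance": discordance_flag(record),
        "lb_mss": (
            None if record.calls.get("NGS_LB") is None else record.calls["NGS_LB"] == "negative"
        ),
        "ffpe_clonality_le15": (
            None
            if record.clonality_ffpe is None
            else record.clonality_ffpe <= ffpe_low_threshold
        ),
        "lb_clonality_ge7": (
            None if record.clonality_lb is None else record.clonality_lb >= 7.0
        ),
    }
    if all(v is None for v in predictors.values()):
        return None
    n_present = sum(1 for v in predictors.values() if v is True)
    extreme = record.clonality_lb is not None and record.clonality_lb >= extreme_lb_threshold
    return CompositeScore(
        patient_id=record.patient_id,
        predictors=predictors,
        n_present=n_present,
        extreme_lb_clonality=extreme,
        flagged_nonresponder=(n_present >= 2) or extreme,
    )
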