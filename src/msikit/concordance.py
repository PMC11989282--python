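"""Agreement among MSI/dMMR determination methods.

dMMR by IHC and MSI by PCR/NGS are treated as the same binary phenotype, so
the four methods form a ratings matrix (patients x methods) with values
positive / negative / missing. Pairwise statistics use pairwise deletion of
missing cells; Fleiss's kappa and the all-method agreement rate use listwise
deletion — this mirrors how cohorts with method-specific dropout are usually
summarized (each statistic has its own denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .panel_io import METHODS, PatientRecord

CATEGORIES = ("positive", "negative")


@dataclass
class PairwiseConcordance:
    method_a: str
    method_b: str
    rate: float
    n_pairs: int
    cohen_kappa: Optional[float]  # None when chance agreement is 1 (degenerate)


def ratings_matrix(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Patients x methods matrix of calls; missing calls become NaN."""
    data = {
        m: [r.calls.get(m) for r in records] for m in METHODS
    }
    df = pd.DataFrame(data, index=[r.patient_id for r in records])
    return df.astype(object).where(df.notna(), other=np.nan)


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.shape[1] < 2:
        raise ValueError("ratings matrix needs at least 2 methods")
    values = set(matrix.stack().dropna().unique())
    unknown = values - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown rating values {sorted(unknown)}")


def pairwise_concordance(
    matrix: pd.DataFrame, method_a: str, method_b: str
) -> PairwiseConcordance:
    """Concordance rate and Cohen's kappa for one method pair.

    Kappa uses the marginal-product chance agreement; when both marginals are
    degenerate (chance agreement 1, e.g. everything positive in both methods)
    kappa is undefined and reported as None.
    """
    _check_matrix(matrix)
    sub = matrix[[method_a, method_b]].dropna()
    n = len(sub)
    if n == 0:
        raise ValueError(f"no complete pairs for {method_a} vs {method_b}")
    a = sub[method_a].to_numpy()
    b = sub[method_b].to_numpy()
    p_o = float(np.mean(a == b))
    p_e = sum(
        float(np.mean(a == cat)) * float(np.mean(b == cat)) for cat in CATEGORIES
    )
    if p_e >= 1.0 - 1e-12:
        kappa = None
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return PairwiseConcordance(
        method_a=method_a,
        method_b=method_b,
        rate=p_o,
        n_pairs=n,
        cohen_kappa=kappa,
    )


def pairwise_concordance_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """All method pairs as a tidy table (rate, kappa, n)."""
    rows = []
    methods = list(matrix.columns)
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            sub = matrix[[a, b]].dropna()
            if sub.empty:
                continue
            pc = pairwise_concordance(matrix, a, b)
            rows.append(
                {
                    "method_a": a,
                    "method_b": b,
                    "concordance_rate": pc.rate,
                    "cohen_kappa": pc.cohen_kappa,
                    "n_pairs": pc.n_pairs,
                }
            )
    return pd.DataFrame(rows)


def fleiss_kappa(matrix: pd.DataFrame) -> float:
    """Fleiss's kappa over rows complete for all methods (two categories)."""
    _check_matrix(matrix)
    complete = matrix.dropna()
    if len(complete) < 2:
        raise ValueError("need at least 2 complete rows for Fleiss's kappa")
    codes = complete.apply(lambda col: col.map({"positive": 0, "negative": 1})).to_numpy(dtype=int)
    table, _ = aggregate_raters(codes, n_cat=2)
    return float(_sm_fleiss_kappa(table, method="fleiss"))


def overall_agreement(matrix: pd.DataFrame) -> tuple[float, int]:
    """Fraction of complete rows on which all methods agree, and that row count."""
    _check_matrix(matrix)
    complete = matrix.dropna()
    n = len(complete)
    if n == 0:
        raise ValueError("no complete rows")
    agree = int((complete.nunique(axis=1) == 1).sum())
    return agree / n, n


GENOMIC_METHODS = ("PCR", "NGS_FFPE", "NGS_LB")


def discordance_from_calls(
    ihc: Optional[str],
    genomic_calls: Sequence[Optional[str]],
    mode: str = "any",
) -> Optional[bool]:
    """Discrepancy between the IHC (dMMR) call and the genomic (MSI) calls.

    ``mode="any"`` (default): discordant when IHC differs from at least one
    available genomic call; ``mode="all"``: when it differs from every one.
    Returns None when IHC or all genomic calls are missing.
    """
    if mode not in ("any", "all"):
        raise ValueError(f"unknown discordance mode {mode!r}")
    available = [c for c in genomic_calls if c is not None]
    if ihc is None or not available:
        return None
    differs = [c != ihc for c in available]
    return any(differs) if mode == "any" else all(differs)


def discordance_flag(record: PatientRecord, mode: str = "any") -> Optional[bool]:
    """Per-patient IHC-vs-genomic discordance predictor (None = not evaluable)."""
    return discordance_from_calls(
        record.calls.get("IHC"),
        [record.calls.get(m) for m in GENOMIC_METHODS],
        mode=mode,
    )
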