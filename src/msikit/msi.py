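"""MSI scoring from STR length histograms.

A locus is *altered* in a read when the observed STR tract length is shortened
by at least 2 bp relative to the panel reference length, or lengthened by any
amount. One-bp shortenings are excluded because PCR stutter at mononucleotide
repeats produces them in stable samples; requiring >= 2 bp of shortening keeps
the detector sensitive to true somatic deletions (which remove whole repeat
units, typically two or more bases) while suppressing that noise. The per-locus
alteration prevalence is the altered-read fraction of the locus depth, and the
sample's MSI score is the cumulative (summed) prevalence across all evaluable
panel loci. The positivity threshold is calibrated on a set of stable reference
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .panel_io import LengthHistogram, STRLocus, SampleProfile

DEFAULT_MIN_LOCI = 10
DEFAULT_MIN_REFERENCES = 20


class MSIStatus(str, Enum):
    MSI_POSITIVE = "MSI_positive"
    MSS = "MSS"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class AlterationRule:
    """Which observed lengths count as altered relative to the reference length.

    ``min_shortening_bp`` — minimum bp of shortening counted (2 by default;
    set ``exact_shortening`` to count only exactly that shortening).
    ``count_lengthening`` — whether any lengthening counts as altered.
    """

    min_shortening_bp: int = 2
    exact_shortening: bool = False
    count_lengthening: bool = True

    def is_altered(self, length_bp: int, ref_length_bp: int) -> bool:
        if length_bp > ref_length_bp:
            return self.count_lengthening
        shortening = ref_length_bp - length_bp
        if self.exact_shortening:
            return shortening == self.min_shortening_bp
        return shortening >= self.min_shortening_bp


DEFAULT_RULE = AlterationRule()


@dataclass
class MSIResult:
    sample_id: str
    per_locus_prevalence: dict[str, float] = field(default_factory=dict)
    msi_score: float = 0.0
    threshold: Optional[float] = None
    status: MSIStatus = MSIStatus.INDETERMINATE
    n_loci_evaluated: int = 0

    @property
    def normalized_score(self) -> float:
        """Score divided by the number of evaluated loci (comparable across panels)."""
        if self.n_loci_evaluated == 0:
            return float("nan")
        return self.msi_score / self.n_loci_evaluated


def locus_alteration_prevalence(
    hist: LengthHistogram, locus: STRLocus, rule: AlterationRule = DEFAULT_RULE
) -> Optional[float]:
    """Altered-read fraction at one locus, or None when the locus has no reads."""
    depth = hist.depth
    if depth == 0:
        return None
    altered = sum(
        count
        for length, count in hist.counts.items()
        if rule.is_altered(length, locus.ref_length_bp)
    )
    return altered / depth


def msi_score(
    profile: SampleProfile,
    panel: Sequence[STRLocus],
    rule: AlterationRule = DEFAULT_RULE,
) -> MSIResult:
    """Cumulative alteration prevalence across evaluable panel loci (score only).

    Loci absent from the profile or with zero depth are excluded and do not
    count toward ``n_loci_evaluated``.
    """
    prevalences: dict[str, float] = {}
    for locus in panel:
        hist = profile.histograms.get(locus.locus_id)
        if hist is None:
            continue
        prevalence = locus_alteration_prevalence(hist, locus, rule)
        if prevalence is not None:
            prevalences[locus.locus_id] = prevalence
    return MSIResult(
        sample_id=profile.sample_id,
        per_locus_prevalence=prevalences,
        msi_score=float(sum(prevalences.values())),
        n_loci_evaluated=len(prevalences),
    )


def calibrate_threshold(
    reference_profiles: Sequence[SampleProfile],
    panel: Sequence[STRLocus],
    rule: AlterationRule = DEFAULT_RULE,
    threshold_rule: str = "mean_3sd",
    percentile: float = 99.0,
    min_references: int = DEFAULT_MIN_REFERENCES,
) -> float:
    """Positivity threshold from the MSI-score distribution of stable references.

    ``threshold_rule`` is ``"mean_3sd"`` (mean + 3 SD, the default) or
    ``"percentile"`` (the given percentile of reference scores).
    """
    if len(reference_profiles) < min_references:
        raise ValueError(
            f"need at least {min_references} reference profiles, got {len(reference_profiles)}"
        )
    scores = np.array([msi_score(p, panel, rule).msi_score for p in reference_profiles])
    if threshold_rule == "mean_3sd":
        return float(scores.mean() + 3.0 * scores.std(ddof=1))
    if threshold_rule == "percentile":
        return float(np.percentile(scores, percentile))
    raise ValueError(f"unknown threshold rule {threshold_rule!r}")


def call_msi(
    profile: SampleProfile,
    panel: Sequence[STRLocus],
    threshold: float,
    rule: AlterationRule = DEFAULT_RULE,
    min_loci: int = DEFAULT_MIN_LOCI,
) -> MSIResult:
    """MSI call for one sample: positive iff score strictly exceeds the threshold.

    A score exactly at the threshold is called MSS (conservative tie rule).
    Samples with fewer than ``min_loci`` evaluable loci are indeterminate.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    result = msi_score(profile, panel, rule)
    result.threshold = threshold
    if result.n_loci_evaluated < min_loci:
        result.status = MSIStatus.INDETERMINATE
    elif result.msi_score > threshold:
        result.status = MSIStatus.MSI_POSITIVE
    else:
        result.status = MSIStatus.MSS
    return result
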