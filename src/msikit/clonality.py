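"""Quantitative MSI clonality from STR length distributions.

Clonality — the fraction of MSI-bearing cells (FFPE) or ctDNA (plasma) — is
estimated by comparing a sample's per-locus length distributions to an envelope
built from stable reference samples. For each locus the *area above the
reference* is the total probability mass the sample places beyond what the
reference envelope allows at each length bin; ``s`` is the mean of that area
over evaluable loci. Percent clonality is the fitted linear transform

    clonality% = clamp(88.81 * s - 11.42, 0, 100)

with sample-type-specific dichotomization: FFPE samples are high-clonality at
>= 18%, liquid-biopsy samples at >= 7%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .msi import MSIResult, MSIStatus
from .panel_io import LengthHistogram, STRLocus, SampleProfile, SampleType

# Coefficients of the clonality calibration line (percent = SLOPE * s - OFFSET).
CLONALITY_SLOPE = 88.81
CLONALITY_OFFSET = 11.42

# Dichotomization thresholds (percent): high clonality at or above these values.
FFPE_HIGH_THRESHOLD = 18.0
LB_HIGH_THRESHOLD = 7.0

DEFAULT_MIN_REFERENCES = 20


class ClonalityClass(str, Enum):
    LOW = "low"
    HIGH = "high"
    NOT_APPLICABLE = "not_applicable"


@dataclass
class ReferenceEnvelope:
    """Per-locus, per-length prevalence bound over the stable reference set."""

    bounds: dict[str, dict[int, float]]
    n_reference_samples: int
    rule: str = "max"

    def locus_bound(self, locus_id: str) -> Mapping[int, float]:
        return self.bounds[locus_id]


@dataclass
class ClonalityResult:
    sample_id: str
    s: float
    clonality_pct: float
    sample_type: SampleType
    threshold_used: Optional[float]
    clonality_class: ClonalityClass
    n_loci_evaluated: int = 0


def build_envelope(
    reference_profiles: Sequence[SampleProfile],
    panel: Sequence[STRLocus],
    rule: str = "max",
    min_references: int = DEFAULT_MIN_REFERENCES,
) -> ReferenceEnvelope:
    """Reference prevalence envelope per locus and length bin.

    ``rule`` — ``"max"`` (default): per-bin maximum prevalence ever observed in
    a reference; ``"mean"``: per-bin mean; ``"mean_2sd"``: mean + 2 SD.
    The maximum rule reads "excess over what stable samples ever show".
    """
    if len(reference_profiles) < min_references:
        raise ValueError(
            f"need at least {min_references} reference profiles, got {len(reference_profiles)}"
        )
    if rule not in ("max", "mean", "mean_2sd"):
        raise ValueError(f"unknown envelope rule {rule!r}")

    bounds: dict[str, dict[int, float]] = {}
    for locus in panel:
        per_sample: list[dict[int, float]] = []
        for profile in reference_profiles:
            hist = profile.histograms.get(locus.locus_id)
            if hist is not None and hist.depth > 0:
                per_sample.append(hist.prevalences())
        if not per_sample:
            raise ValueError(
                f"locus {locus.locus_id!r} missing from all reference profiles"
            )
        lengths = sorted({l for prev in per_sample for l in prev})
        mat = np.array([[prev.get(l, 0.0) for l in lengths] for prev in per_sample])
        if rule == "max":
            bound = mat.max(axis=0)
        elif rule == "mean":
            bound = mat.mean(axis=0)
        else:  # mean_2sd
            bound = mat.mean(axis=0) + 2.0 * mat.std(axis=0, ddof=1 if len(per_sample) > 1 else 0)
        bounds[locus.locus_id] = {
            int(l): float(min(b, 1.0)) for l, b in zip(lengths, bound)
        }
    return ReferenceEnvelope(
        bounds=bounds, n_reference_samples=len(reference_profiles), rule=rule
    )


def area_above_reference(
    hist: LengthHistogram, envelope_locus: Mapping[int, float]
) -> Optional[float]:
    """Probability mass of the sample exceeding the envelope, summed over bins.

    Returns None when the locus has no reads (excluded from the mean).
    """
    if hist.depth == 0:
        return None
    area = 0.0
    for length, prevalence in hist.prevalences().items():
        area += max(0.0, prevalence - envelope_locus.get(length, 0.0))
    return min(area, 1.0)


def clonality_s(profile: SampleProfile, envelope: ReferenceEnvelope) -> tuple[float, int]:
    """Mean area above the reference over evaluable loci; returns (s, n_loci)."""
    areas = []
    for locus_id, hist in profile.histograms.items():
        if locus_id not in envelope.bounds:
            continue
        area = area_above_reference(hist, envelope.bounds[locus_id])
        if area is not None:
            areas.append(area)
    if not areas:
        raise ValueError(f"sample {profile.sample_id!r}: no evaluable loci")
    return float(np.mean(areas)), len(areas)


def clonality_percent(s: float) -> float:
    """Percent clonality from the mean area above reference, clamped to [0, 100]."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s must be in [0, 1], got {s}")
    return float(np.clip(CLONALITY_SLOPE * s - CLONALITY_OFFSET, 0.0, 100.0))


def classify_clonality(clonality_pct: float, sample_type: SampleType) -> ClonalityClass:
    """Low/high dichotomization: FFPE high at >= 18%, LB high at >= 7%."""
    if not 0.0 <= clonality_pct <= 100.0:
        raise ValueError(f"clonality_pct must be in [0, 100], got {clonality_pct}")
    if sample_type == SampleType.REFERENCE:
        return ClonalityClass.NOT_APPLICABLE
    threshold = FFPE_HIGH_THRESHOLD if sample_type == SampleType.FFPE else LB_HIGH_THRESHOLD
    return ClonalityClass.HIGH if clonality_pct >= threshold else ClonalityClass.LOW


def estimate_clonality(
    profile: SampleProfile,
    envelope: ReferenceEnvelope,
    msi_result: Optional[MSIResult] = None,
) -> ClonalityResult:
    """Full clonality chain for one sample.

    When an MSI result is supplied and the sample is not MSI-positive, the
    class is ``not_applicable`` (clonality is only meaningful in MSI+ samples),
    though s and the percent value are still reported for inspection.
    """
    s, n_loci = clonality_s(profile, envelope)
    pct = clonality_percent(s)
    if msi_result is not None and msi_result.status != MSIStatus.MSI_POSITIVE:
        cls = ClonalityClass.NOT_APPLICABLE
    else:
        cls = classify_clonality(pct, profile.sample_type)
    threshold = {
        SampleType.FFPE: FFPE_HIGH_THRESHOLD,
        SampleType.LB: LB_HIGH_THRESHOLD,
        SampleType.REFERENCE: None,
    }[profile.sample_type]
    return ClonalityResult(
        sample_id=profile.sample_id,
        s=s,
        clonality_pct=pct,
        sample_type=profile.sample_type,
        threshold_used=threshold,
        clonality_class=cls,
        n_loci_evaluated=n_loci,
    )
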