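"""Synthetic STR profiles and patient cohorts with the structure the pipeline assumes.

The generator emulates an amplicon MSI panel run end to end:

* a 39-locus STR panel dominated by mononucleotide repeats, read at an average
  depth of 5000x per locus;
* stable reference samples whose histograms sit at the reference tract length
  apart from symmetric PCR stutter (whole-repeat-unit shifts, geometric step
  count);
* tumor (FFPE) and plasma (LB) samples as binomial mixtures of the stable
  background and an MSI clone carrying a deletion of >= 2 repeat units per
  locus, with plasma clone fractions additionally shrunk by a lognormal ctDNA
  fraction factor;
* patient cohorts in which IHC/PCR calls derive from the true MSI status
  through per-method error and missingness rates, NGS calls come from actually
  running the MSI caller on generated profiles, response follows a logistic
  model on the non-response predictors, and PFS is Weibull.

Every draw flows from a single seed through spawned child streams, so adding a
downstream stage never perturbs earlier draws and the same seed reproduces the
same cohort byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import clonality as clonality_mod
from . import msi as msi_mod
from .concordance import discordance_from_calls
from .panel_io import (
    LengthHistogram,
    PatientRecord,
    STRLocus,
    SampleProfile,
    SampleType,
)

_STUTTER_MAX_STEPS = 8  # geometric tail beyond this is renormalized away


def _default_method_error() -> dict[str, dict[str, float]]:
    # False-negative / false-positive probabilities for the assay-based calls.
    return {
        "IHC": {"fn": 0.15, "fp": 0.02},
        "PCR": {"fn": 0.05, "fp": 0.01},
    }


def _default_method_missing() -> dict[str, float]:
    # Per-method probability that a result is unavailable (failed assay,
    # insufficient material); mirrors real cohorts' varying denominators.
    return {"IHC": 0.25, "PCR": 0.03, "NGS_FFPE": 0.2, "NGS_LB": 0.07}


def _default_aft_coefficients() -> dict[str, float]:
    # Log-time coefficients for the Weibull PFS model on the binary
    # non-response predictors; negative = shorter time = higher hazard.
    return {
        "ffpe_clonality_high": 0.36,
        "lb_clonality_high": -0.86,
        "discordance": -0.59,
    }


@dataclass
class SimulationConfig:
    """All generator parameters; defaults define the emulated study conditions."""

    n_loci: int = 39
    n_reference: int = 400
    depth_per_locus: int = 5000
    stutter_rate: float = 0.02
    stutter_geometric_p: float = 0.8
    deletion_mean_units: float = 3.0
    ctdna_factor_log_mean: float = math.log(0.05)
    ctdna_factor_log_sd: float = 1.5
    method_error: dict[str, dict[str, float]] = field(default_factory=_default_method_error)
    method_missing: dict[str, float] = field(default_factory=_default_method_missing)
    response_intercept: float = 0.7
    response_weight: float = -1.5
    aft_intercept: float = math.log(250.0)
    aft_shape: float = 1.3
    aft_coefficients: dict[str, float] = field(default_factory=_default_aft_coefficients)
    censor_rate: float = 0.2
    min_loci: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stutter_rate", "stutter_geometric_p", "censor_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.depth_per_locus <= 0:
            raise ValueError("depth_per_locus must be > 0")
        if self.n_loci <= 0 or self.n_reference <= 0:
            raise ValueError("n_loci and n_reference must be > 0")
        if self.deletion_mean_units < 2.0:
            raise ValueError("deletion_mean_units must be >= 2 (detectable deletions)")
        if self.aft_shape <= 0:
            raise ValueError("aft_shape must be > 0")

    def rng_streams(self, n: int) -> list[np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(n)
        return [np.random.default_rng(c) for c in children]


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------


def generate_panel(config: SimulationConfig) -> list[STRLocus]:
    """Deterministic synthetic STR panel: ~80% mononucleotide loci, rest dinucleotide."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    loci = []
    pos = 1_000_000
    for i in range(config.n_loci):
        if i % 5 == 4:
            unit = "AC" if i % 2 else "AT"
            n_units = int(rng.integers(7, 13))
        else:
            unit = "A" if i % 2 else "T"
            n_units = int(rng.integers(12, 28))
        length = n_units * len(unit)
        loci.append(
            STRLocus(
                locus_id=f"STR{i + 1:03d}",
                chrom=f"chr{(i % 22) + 1}",
                start=pos,
                end=pos + length,
                repeat_unit=unit,
            )
        )
        pos += 10_000
    return loci


# ---------------------------------------------------------------------------
# Read-length distributions
# ---------------------------------------------------------------------------


def _stutter_offsets(unit_length: int, stutter_rate: float, geom_p: float) -> dict[int, float]:
    """Probability of each bp offset under the stutter model (0 offset included)."""
    if stutter_rate == 0.0:
        return {0: 1.0}
    pmf = np.array(
        [geom_p * (1.0 - geom_p) ** (k - 1) for k in range(1, _STUTTER_MAX_STEPS + 1)]
    )
    pmf /= pmf.sum()  # renormalize the truncated geometric
    offsets = {0: 1.0 - stutter_rate}
    for k, p in enumerate(pmf, start=1):
        for sign in (-1, 1):
            offset = sign * k * unit_length
            offsets[offset] = offsets.get(offset, 0.0) + stutter_rate / 2.0 * float(p)
    return offsets


def _length_distribution(
    true_length: int, unit_length: int, stutter_rate: float, geom_p: float
) -> dict[int, float]:
    """Distribution of observed tract lengths for reads from one true allele."""
    dist: dict[int, float] = {}
    for offset, p in _stutter_offsets(unit_length, stutter_rate, geom_p).items():
        length = max(1, true_length + offset)  # tract cannot vanish entirely
        dist[length] = dist.get(length, 0.0) + p
    return dist


def _draw_histogram(
    rng: np.random.Generator, locus: STRLocus, dist: dict[int, float], depth: int
) -> LengthHistogram:
    lengths = sorted(dist)
    probs = np.array([dist[l] for l in lengths])
    probs = probs / probs.sum()
    counts = rng.multinomial(depth, probs)
    return LengthHistogram(
        locus_id=locus.locus_id,
        counts={l: int(c) for l, c in zip(lengths, counts) if c > 0},
    )


def _deletion_units(rng: np.random.Generator, config: SimulationConfig) -> int:
    """Repeat units deleted in the MSI clone allele: 2 + shifted geometric."""
    if config.deletion_mean_units == 2.0:
        return 2
    p = 1.0 / (config.deletion_mean_units - 1.0)
    return 2 + int(rng.geometric(p)) - 1


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------


def generate_reference_profiles(
    config: SimulationConfig,
    panel: Sequence[STRLocus],
    rng: Optional[np.random.Generator] = None,
    prefix: str = "REF",
) -> list[SampleProfile]:
    """Stable reference profiles: reference-length alleles plus stutter only."""
    if rng is None:
        rng = config.rng_streams(2)[1]
    profiles = []
    dists = {
        locus.locus_id: _length_distribution(
            locus.ref_length_bp, locus.unit_length, config.stutter_rate, config.stutter_geometric_p
        )
        for locus in panel
    }
    for i in range(config.n_reference):
        hists = {
            locus.locus_id: _draw_histogram(
                rng, locus, dists[locus.locus_id], config.depth_per_locus
            )
            for locus in panel
        }
        profiles.append(
            SampleProfile(
                sample_id=f"{prefix}{i + 1:04d}",
                sample_type=SampleType.REFERENCE,
                histograms=hists,
            )
        )
    return profiles


def generate_sample_profile(
    config: SimulationConfig,
    panel: Sequence[STRLocus],
    clone_fraction: float,
    sample_type: SampleType,
    rng: np.random.Generator,
    sample_id: str = "SAMPLE",
) -> tuple[SampleProfile, dict]:
    """One FFPE/LB profile as a stable-background / MSI-clone mixture.

    Each read is drawn from the MSI clone allele with probability
    ``clone_fraction`` (the clone allele is the reference shortened by >= 2
    repeat units, drawn once per locus per sample), otherwise from the stable
    allele; stutter applies to every read. Returns the profile and its truth row.
    """
    if not 0.0 <= clone_fraction <= 1.0:
        raise ValueError(f"clone_fraction must be in [0, 1], got {clone_fraction}")
    hists = {}
    for locus in panel:
        stable = _length_distribution(
            locus.ref_length_bp, locus.unit_length, config.stutter_rate, config.stutter_geometric_p
        )
        if clone_fraction > 0.0:
            d_units = _deletion_units(rng, config)
            clone_length = max(1, locus.ref_length_bp - d_units * locus.unit_length)
            clone = _length_distribution(
                clone_length, locus.unit_length, config.stutter_rate, config.stutter_geometric_p
            )
            mix: dict[int, float] = {}
            for l, p in stable.items():
                mix[l] = mix.get(l, 0.0) + (1.0 - clone_fraction) * p
            for l, p in clone.items():
                mix[l] = mix.get(l, 0.0) + clone_fraction * p
        else:
            mix = stable
        hists[locus.locus_id] = _draw_histogram(rng, locus, mix, config.depth_per_locus)
    profile = SampleProfile(sample_id=sample_id, sample_type=sample_type, histograms=hists)
    truth = {
        "sample_id": sample_id,
        "sample_type": sample_type.value,
        "true_clone_fraction": clone_fraction,
        "true_msi_positive": clone_fraction > 0.0,
    }
    return profile, truth


# ---------------------------------------------------------------------------
# Survival draws
# ---------------------------------------------------------------------------


def simulate_survival_times(
    rng: np.random.Generator,
    linear_predictor: np.ndarray,
    shape: float,
    censor_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Weibull event times with log-scale lambda = exp(linear predictor).

    S(t | x) = exp(-(t / lambda(x))^k). With probability ``censor_rate`` a
    subject is administratively censored at a uniform fraction of its event
    time. Returns (times, events).
    """
    n = len(linear_predictor)
    u = rng.uniform(size=n)
    times = np.exp(linear_predictor) * (-np.log(u)) ** (1.0 / shape)
    events = rng.uniform(size=n) >= censor_rate
    censor_frac = rng.uniform(size=n)
    times = np.where(events, times, times * censor_frac)
    times = np.maximum(times, 1e-6)
    return times, events


def simulate_single_covariate_cohort(
    n: int,
    hr_true: float,
    shape: float = 1.3,
    censor_rate: float = 0.2,
    intercept: float = math.log(250.0),
    binary: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Survival data with one covariate at a configured true hazard ratio.

    Under the Weibull AFT<->PH equivalence HR = exp(-k*beta), the log-time
    coefficient is beta = -log(hr_true)/k. Used for parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    beta = -math.log(hr_true) / shape
    if binary:
        x = rng.integers(0, 2, size=n).astype(float)
    else:
        x = rng.normal(size=n)
    lp = intercept + beta * x
    times, events = simulate_survival_times(rng, lp, shape, censor_rate)
    return pd.DataFrame({"time": times, "event": events, "x": x})


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortSimulation:
    """Everything one simulated study produces, truth included."""

    records: list[PatientRecord]
    profiles: dict[str, SampleProfile]
    panel: list[STRLocus]
    reference_profiles: list[SampleProfile]
    msi_threshold: float
    truth: pd.DataFrame


def _assay_call(rng: np.random.Generator, truth_positive: bool, error: dict[str, float]) -> str:
    if truth_positive:
        return "negative" if rng.uniform() < error.get("fn", 0.0) else "positive"
    return "positive" if rng.uniform() < error.get("fp", 0.0) else "negative"


def generate_cohort(
    config: SimulationConfig, n_patients: int = 30
) -> CohortSimulation:
    """Full synthetic study: profiles, reference set, method calls, outcomes.

    All patients are truly MSI-positive (the inclusion criterion of the
    emulated study); heterogeneity enters through clone fractions, ctDNA
    shedding, assay error and missingness. NGS calls are produced by running
    the MSI caller on the generated profiles against a calibrated threshold,
    and NGS clonality values by the clonality chain against the reference
    envelope — the generator does not shortcut the measurement model.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be > 0")
    rng_panel, rng_ref, rng_samples, rng_cohort = config.rng_streams(4)

    panel = generate_panel(config)
    references = generate_reference_profiles(config, panel, rng_ref)
    threshold = msi_mod.calibrate_threshold(references, panel)
    envelope = clonality_mod.build_envelope(references, panel)

    records: list[PatientRecord] = []
    profiles: dict[str, SampleProfile] = {}
    truth_rows = []

    for i in range(n_patients):
        pid = f"PT{i + 1:03d}"
        age = float(np.clip(rng_cohort.normal(60.0, 12.0), 25.0, 90.0))
        sex = "F" if rng_cohort.uniform() < 0.5 else "M"
        stage = rng_cohort.choice(["II", "III", "IV"], p=[0.2, 0.55, 0.25])
        setting = rng_cohort.choice(
            ["preoperative", "advanced_1L", "advanced_2L3L"], p=[0.5, 0.3, 0.2]
        )
        braf = "positive" if rng_cohort.uniform() < 0.4 else "negative"
        ras = "positive" if rng_cohort.uniform() < 0.25 else "negative"

        f_ffpe = float(0.05 + 0.9 * rng_cohort.beta(2.0, 2.0))
        ctdna_factor = float(
            np.exp(rng_cohort.normal(config.ctdna_factor_log_mean, config.ctdna_factor_log_sd))
        )
        f_lb = float(min(1.0, f_ffpe * ctdna_factor))

        missing = {
            m: rng_cohort.uniform() < config.method_missing.get(m, 0.0)
            for m in ("IHC", "PCR", "NGS_FFPE", "NGS_LB")
        }

        calls: dict[str, Optional[str]] = {}
        calls["IHC"] = (
            None if missing["IHC"] else _assay_call(rng_cohort, True, config.method_error["IHC"])
        )
        calls["PCR"] = (
            None if missing["PCR"] else _assay_call(rng_cohort, True, config.method_error["PCR"])
        )

        clon_ffpe = clon_lb = None
        for method, stype, frac in (
            ("NGS_FFPE", SampleType.FFPE, f_ffpe),
            ("NGS_LB", SampleType.LB, f_lb),
        ):
            if missing[method]:
                calls[method] = None
                continue
            sample_id = f"{pid}_{stype.value}"
            profile, _ = generate_sample_profile(
                config, panel, frac, stype, rng_samples, sample_id
            )
            profiles[sample_id] = profile
            result = msi_mod.call_msi(profile, panel, threshold, min_loci=config.min_loci)
            if result.status == msi_mod.MSIStatus.MSI_POSITIVE:
                calls[method] = "positive"
                clon = clonality_mod.estimate_clonality(profile, envelope, result)
                if stype == SampleType.FFPE:
                    clon_ffpe = clon.clonality_pct
                else:
                    clon_lb = clon.clonality_pct
            elif result.status == msi_mod.MSIStatus.MSS:
                calls[method] = "negative"
            else:
                calls[method] = None

        # Non-response predictors, from measured values as a clinician would see them.
        lb_mss = calls["NGS_LB"] == "negative"
        ffpe_low = clon_ffpe is not None and clon_ffpe <= 15.0
        lb_high = clon_lb is not None and clon_lb >= clonality_mod.LB_HIGH_THRESHOLD
        disc = bool(
            discordance_from_calls(
                calls["IHC"], [calls["PCR"], calls["NGS_FFPE"], calls["NGS_LB"]]
            )
            or False
        )
        predictors = {
            "discordance": disc,
            "lb_mss": lb_mss,
            "ffpe_clonality_le15": ffpe_low,
            "lb_clonality_ge7": lb_high,
        }

        logit = config.response_intercept + config.response_weight * sum(
            predictors.values()
        )
        p_resp = 1.0 / (1.0 + math.exp(-logit))
        if rng_cohort.uniform() < 0.05:
            response = "NE"
        elif rng_cohort.uniform() < p_resp:
            response = "CR" if rng_cohort.uniform() < 0.25 else "PR"
        else:
            response = "SD" if rng_cohort.uniform() < 0.5 else "PD"

        aft_x = {
            "ffpe_clonality_high": float(100.0 * f_ffpe >= clonality_mod.FFPE_HIGH_THRESHOLD),
            "lb_clonality_high": float(100.0 * f_lb >= clonality_mod.LB_HIGH_THRESHOLD),
            "discordance": float(disc),
        }
        lp = config.aft_intercept + sum(
            config.aft_coefficients.get(k, 0.0) * v for k, v in aft_x.items()
        )
        times, events = simulate_survival_times(
            rng_cohort, np.array([lp]), config.aft_shape, config.censor_rate
        )
        pfs_days = float(max(times[0], 1.0))
        event = bool(events[0])

        records.append(
            PatientRecord(
                patient_id=pid,
                age=age,
                sex=sex,
                stage=str(stage),
                setting=str(setting),
                calls=calls,
                clonality_ffpe=clon_ffpe,
                clonality_lb=clon_lb,
                response=response,
                pfs_days=pfs_days,
                event=event,
                braf_v600=braf,
                ras=ras,
            )
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "true_clone_fraction_ffpe": f_ffpe,
                "true_clone_fraction_lb": f_lb,
                "true_discordance": disc,
                "true_linear_predictor": lp,
                **{f"true_{k}": v for k, v in aft_x.items()},
            }
        )

    return CohortSimulation(
        records=records,
        profiles=profiles,
        panel=panel,
        reference_profiles=references,
        msi_threshold=threshold,
        truth=pd.DataFrame(truth_rows),
    )
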