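"""Domain types and file I/O for STR panels, length histograms and patient cohorts.

The on-disk formats are deliberately plain:

* **Panel** — TSV with columns ``locus_id, chrom, start, end, repeat_unit``.
  Coordinates are 0-based half-open (BED convention); the reference STR tract
  length in bp is ``end - start``.
* **Histograms** — long-format TSV with columns
  ``sample_id, sample_type, locus_id, length_bp, count``. Allele lengths are
  total tract lengths in base pairs, not repeat-unit counts.
* **Cohort** — CSV, one row per patient, with method calls, clonality values,
  response, PFS time and covariates. Missing values are empty cells.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("msikit")

VALID_BASES = set("ACGT")

METHODS = ("IHC", "PCR", "NGS_FFPE", "NGS_LB")
RESPONSES = ("CR", "PR", "SD", "PD", "NE")
STAGES = ("II", "III", "IV")
SETTINGS = ("preoperative", "advanced_1L", "advanced_2L3L")


class SampleType(str, Enum):
    FFPE = "FFPE"
    LB = "LB"
    REFERENCE = "REFERENCE"


@dataclass(frozen=True)
class STRLocus:
    """One microsatellite locus of the panel.

    ``start``/``end`` follow the BED convention (0-based, half-open), so the
    reference tract length in bp is ``end - start``.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    repeat_unit: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"locus {self.locus_id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if not self.repeat_unit or not set(self.repeat_unit) <= VALID_BASES:
            raise ValueError(
                f"locus {self.locus_id!r}: repeat unit must be a non-empty DNA string, "
                f"got {self.repeat_unit!r}"
            )
        if not 1 <= len(self.repeat_unit) <= 6:
            raise ValueError(
                f"locus {self.locus_id!r}: repeat unit length must be 1-6 bp"
            )

    @property
    def ref_length_bp(self) -> int:
        """Total reference tract length in bp."""
        return self.end - self.start

    @property
    def unit_length(self) -> int:
        return len(self.repeat_unit)


@dataclass
class LengthHistogram:
    """Read counts per observed allele length (total tract length, bp) at one locus."""

    locus_id: str
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for length, count in self.counts.items():
            if length < 0:
                raise ValueError(f"locus {self.locus_id!r}: negative allele length {length}")
            if count < 0:
                raise ValueError(f"locus {self.locus_id!r}: negative count {count}")

    @property
    def depth(self) -> int:
        return int(sum(self.counts.values()))

    def prevalences(self) -> dict[int, float]:
        """Fraction of reads per allele length; empty when depth is 0."""
        d = self.depth
        if d == 0:
            return {}
        return {length: count / d for length, count in sorted(self.counts.items()) if count > 0}


@dataclass
class SampleProfile:
    """Per-locus length histograms for one FFPE, plasma or stable-reference sample."""

    sample_id: str
    sample_type: SampleType
    histograms: dict[str, LengthHistogram] = field(default_factory=dict)

    def validate_against_panel(self, panel: Sequence[STRLocus]) -> None:
        panel_ids = {locus.locus_id for locus in panel}
        unknown = set(self.histograms) - panel_ids
        if unknown:
            raise ValueError(
                f"sample {self.sample_id!r}: histogram loci not in panel: {sorted(unknown)}"
            )


@dataclass
class PatientRecord:
    """One enrolled patient: method calls, clonality estimates, response and PFS."""

    patient_id: str
    age: float
    sex: str
    stage: str
    setting: str
    calls: dict[str, Optional[str]]
    clonality_ffpe: Optional[float]
    clonality_lb: Optional[float]
    response: str
    pfs_days: float
    event: bool
    braf_v600: str = "unknown"
    ras: str = "unknown"

    def __post_init__(self) -> None:
        if self.pfs_days <= 0:
            raise ValueError(f"patient {self.patient_id!r}: pfs_days must be > 0")
        if self.response not in RESPONSES:
            raise ValueError(
                f"patient {self.patient_id!r}: unknown response {self.response!r}"
            )
        if self.stage not in STAGES:
            raise ValueError(f"patient {self.patient_id!r}: unknown stage {self.stage!r}")
        if self.setting not in SETTINGS:
            raise ValueError(
                f"patient {self.patient_id!r}: unknown setting {self.setting!r}"
            )
        for method in METHODS:
            call = self.calls.get(method)
            if call not in ("positive", "negative", None):
                raise ValueError(
                    f"patient {self.patient_id!r}: invalid {method} call {call!r}"
                )
        # Clonality is quantified only in samples called MSI-positive by NGS.
        if self.clonality_ffpe is not None and self.calls.get("NGS_FFPE") != "positive":
            raise ValueError(
                f"patient {self.patient_id!r}: FFPE clonality present without a "
                "positive NGS_FFPE call"
            )
        if self.clonality_lb is not None and self.calls.get("NGS_LB") != "positive":
            raise ValueError(
                f"patient {self.patient_id!r}: LB clonality present without a "
                "positive NGS_LB call"
            )


# ---------------------------------------------------------------------------
# Panel I/O
# ---------------------------------------------------------------------------

PANEL_COLUMNS = ["locus_id", "chrom", "start", "end", "repeat_unit"]


def read_panel(path: str | Path) -> list[STRLocus]:
    """Read an STR panel TSV into validated :class:`STRLocus` records.

    Rejects duplicate locus ids and rows violating locus invariants.
    """
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "chrom": str, "repeat_unit": str})
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel file {path}: missing columns {sorted(missing)}")
    dup = df["locus_id"][df["locus_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"panel file {path}: duplicate locus ids {sorted(dup.unique())}")
    loci = [
        STRLocus(
            locus_id=row.locus_id,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            repeat_unit=row.repeat_unit,
        )
        for row in df.itertuples()
    ]
    logger.debug("read %d loci from %s", len(loci), path)
    return loci


def write_panel(loci: Sequence[STRLocus], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "locus_id": l.locus_id,
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "repeat_unit": l.repeat_unit,
            }
            for l in loci
        ],
        columns=PANEL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Histogram I/O
# ---------------------------------------------------------------------------

HISTOGRAM_COLUMNS = ["sample_id", "sample_type", "locus_id", "length_bp", "count"]


def read_histograms(
    path: str | Path, panel: Optional[Sequence[STRLocus]] = None
) -> dict[str, SampleProfile]:
    """Read a long-format histogram TSV into one :class:`SampleProfile` per sample.

    Duplicate ``(sample, locus, length)`` rows are summed with a warning;
    negative counts and (when a panel is given) unknown loci are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus_id": str, "sample_type": str})
    missing = set(HISTOGRAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"histogram file {path}: missing columns {sorted(missing)}")
    if (df["count"] < 0).any():
        raise ValueError(f"histogram file {path}: negative counts present")
    if (df["length_bp"] < 0).any():
        raise ValueError(f"histogram file {path}: negative allele lengths present")
    if df.duplicated(subset=["sample_id", "locus_id", "length_bp"]).any():
        logger.warning("histogram file %s: duplicate (sample, locus, length) rows summed", path)

    profiles: dict[str, SampleProfile] = {}
    grouped = df.groupby(["sample_id", "sample_type"], sort=True)
    for (sample_id, sample_type), sub in grouped:
        if sample_id in profiles:
            raise ValueError(
                f"histogram file {path}: sample {sample_id!r} has multiple sample types"
            )
        hists: dict[str, LengthHistogram] = {}
        for locus_id, locus_sub in sub.groupby("locus_id", sort=True):
            counts = (
                locus_sub.groupby("length_bp")["count"].sum().astype(int).to_dict()
            )
            hists[locus_id] = LengthHistogram(
                locus_id=locus_id, counts={int(k): int(v) for k, v in counts.items()}
            )
        profile = SampleProfile(
            sample_id=sample_id, sample_type=SampleType(sample_type), histograms=hists
        )
        if panel is not None:
            profile.validate_against_panel(panel)
        profiles[sample_id] = profile
    return profiles


def write_histograms(profiles: Iterable[SampleProfile], path: str | Path) -> None:
    rows = []
    for profile in profiles:
        for locus_id in sorted(profile.histograms):
            hist = profile.histograms[locus_id]
            for length in sorted(hist.counts):
                count = hist.counts[length]
                if count == 0:
                    continue
                rows.append(
                    {
                        "sample_id": profile.sample_id,
                        "sample_type": profile.sample_type.value,
                        "locus_id": locus_id,
                        "length_bp": length,
                        "count": count,
                    }
                )
    pd.DataFrame(rows, columns=HISTOGRAM_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "stage",
    "setting",
    "ihc",
    "pcr",
    "ngs_ffpe",
    "ngs_lb",
    "clonality_ffpe",
    "clonality_lb",
    "response",
    "pfs_days",
    "event",
    "braf_v600",
    "ras",
]

_CALL_COLUMNS = {"IHC": "ihc", "PCR": "pcr", "NGS_FFPE": "ngs_ffpe", "NGS_LB": "ngs_lb"}


def _parse_event(value) -> bool:
    if isinstance(value, str):
        lowered = value.strip().lower()
        if lowered in ("true", "1", "yes"):
            return True
        if lowered in ("false", "0", "no"):
            return False
        raise ValueError(f"invalid event flag {value!r}")
    return bool(value)


def _parse_call(value) -> Optional[str]:
    if pd.isna(value) or value == "":
        return None
    value = str(value)
    if value not in ("positive", "negative"):
        raise ValueError(f"invalid method call {value!r}")
    return value


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` rows.

    A missing event flag is treated as censored (event=False) with a warning.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file {path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples():
        if pd.isna(row.event):
            logger.warning(
                "cohort file %s: patient %s has no event flag; treated as censored",
                path,
                row.patient_id,
            )
            event = False
        else:
            event = _parse_event(row.event)
        calls = {m: _parse_call(getattr(row, col)) for m, col in _CALL_COLUMNS.items()}
        records.append(
            PatientRecord(
                patient_id=row.patient_id,
                age=float(row.age),
                sex=str(row.sex),
                stage=str(row.stage),
                setting=str(row.setting),
                calls=calls,
                clonality_ffpe=None if pd.isna(row.clonality_ffpe) else float(row.clonality_ffpe),
                clonality_lb=None if pd.isna(row.clonality_lb) else float(row.clonality_lb),
                response=str(row.response),
                pfs_days=float(row.pfs_days),
                event=event,
                braf_v600=str(row.braf_v600),
                ras=str(row.ras),
            )
        )
    return records


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "age": r.age,
                "sex": r.sex,
                "stage": r.stage,
                "setting": r.setting,
                "ihc": r.calls.get("IHC"),
                "pcr": r.calls.get("PCR"),
                "ngs_ffpe": r.calls.get("NGS_FFPE"),
                "ngs_lb": r.calls.get("NGS_LB"),
                "clonality_ffpe": r.clonality_ffpe,
                "clonality_lb": r.clonality_lb,
                "response": r.response,
                "pfs_days": r.pfs_days,
                "event": r.event,
                "braf_v600": r.braf_v600,
                "ras": r.ras,
            }
        )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame (method calls as columns named after the methods)."""
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "age": r.age,
            "sex": r.sex,
            "stage": r.stage,
            "setting": r.setting,
            "clonality_ffpe": r.clonality_ffpe,
            "clonality_lb": r.clonality_lb,
            "response": r.response,
            "pfs_days": r.pfs_days,
            "event": r.event,
            "braf_v600": r.braf_v600,
            "ras": r.ras,
        }
        for m in METHODS:
            row[m] = r.calls.get(m)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Config and run report
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path}: expected a mapping at the top level")
    return cfg


def save_config(config: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def write_run_report(path: str | Path, **fields) -> None:
    """Write a JSON run report (inputs, seed, thresholds, versions)."""
    import msikit

    report = {"msikit_version": msikit.__version__}
    report.update(fields)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
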