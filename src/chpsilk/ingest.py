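"""Transition-report ingestion and tracer-enrichment bookkeeping.

A targeted (MRM) proteomics run exports one peak area per peptide channel
(labelled ``13C6``-leucine vs unlabelled) per sample.  This module reads and
writes those tables, converts paired peak areas into tracer-to-tracee ratios
(TTR) and mole fractions labelled, assembles per-subject enrichment time
courses, and classifies peptide sequences as human- or bovine-unique by
in-silico tryptic digestion of reference proteins.

Conventions
-----------
TTR is the molar labelled/unlabelled peak-area ratio.  The mole fraction
labelled is ``f = TTR / (1 + TTR)``; it is bounded in ``[0, 1)`` and is the
quantity all kinetic fits operate on (TTR is retained for reporting).
Time is in hours elapsed since infusion start (in vivo) or label-media
introduction (in vitro).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import parser as _pep_parser

from .errors import FormatError, IntegrityError, UndefinedRatioError, ValidationError

__all__ = [
    "Group",
    "Compartment",
    "Channel",
    "TransitionRecord",
    "EnrichmentPoint",
    "EnrichmentSeries",
    "SeriesBundle",
    "SpeciesCall",
    "DEFAULT_DIALECT",
    "read_transition_report",
    "write_transition_report",
    "ttr_from_areas",
    "mole_fraction_from_ttr",
    "ttr_from_mole_fraction",
    "build_series",
    "series_to_frame",
    "tryptic_peptides",
    "classify_peptide_species",
]


class Group(str, Enum):
    NPH = "NPH"
    CONTROL_VENTRICULAR = "control_ventricular"
    CONTROL_LUMBAR = "control_lumbar"
    ORGANOID_CSF = "organoid_csf"
    ORGANOID_LYSATE = "organoid_lysate"
    PLASMA = "plasma"


class Compartment(str, Enum):
    LUMBAR = "lumbar"
    VENTRICULAR = "ventricular"
    ICSF = "iCSF"
    LYSATE = "lysate"
    PLASMA = "plasma"


class Channel(str, Enum):
    LABELED = "labeled"
    UNLABELED = "unlabeled"


@dataclass(frozen=True)
class TransitionRecord:
    """One measured peak area for one peptide channel in one sample."""

    sample_id: str
    subject_id: str
    group: str
    compartment: str
    time_h: float
    protein: str
    peptide_id: str
    channel: str
    peak_area: float

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValidationError(f"time_h must be >= 0, got {self.time_h}")
        if not math.isfinite(self.peak_area) or self.peak_area < 0:
            raise ValidationError(
                f"peak_area must be finite and >= 0, got {self.peak_area}"
            )
        Group(self.group)
        Compartment(self.compartment)
        Channel(self.channel)


@dataclass(frozen=True)
class EnrichmentPoint:
    """Enrichment at one timepoint: TTR and the mole fraction labelled."""

    time_h: float
    ttr: float
    mole_fraction: float

    @classmethod
    def from_ttr(cls, time_h: float, ttr: float) -> "EnrichmentPoint":
        return cls(time_h=time_h, ttr=ttr, mole_fraction=mole_fraction_from_ttr(ttr))


@dataclass
class EnrichmentSeries:
    """Time course of enrichment for one (subject, compartment, peptide)."""

    subject_id: str
    group: str
    compartment: str
    peptide_id: str
    points: list[EnrichmentPoint]

    def __post_init__(self) -> None:
        if not self.points:
            raise ValidationError("EnrichmentSeries requires at least one point")
        times = [p.time_h for p in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("EnrichmentSeries times must be strictly increasing")

    @property
    def times(self) -> list[float]:
        return [p.time_h for p in self.points]

    @property
    def mole_fractions(self) -> list[float]:
        return [p.mole_fraction for p in self.points]


@dataclass
class SeriesBundle:
    """Output of :func:`build_series`: the series plus exclusion diagnostics."""

    series: list[EnrichmentSeries]
    n_dropped_nonpositive: int = 0
    omitted_empty: list[tuple[str, str, str]] = field(default_factory=list)


class SpeciesCallKind(str, Enum):
    HUMAN_UNIQUE = "human_unique"
    BOVINE_UNIQUE = "bovine_unique"
    SHARED = "shared"
    ABSENT = "absent"


@dataclass(frozen=True)
class SpeciesCall:
    peptide_sequence: str
    call: SpeciesCallKind


#: Canonical field -> CSV column name.  Override entries to ingest exports
#: whose headers differ (e.g. Skyline-style column names) without code changes.
DEFAULT_DIALECT: dict[str, str] = {
    "sample_id": "sample_id",
    "subject_id": "subject_id",
    "group": "group",
    "compartment": "compartment",
    "time_h": "time_h",
    "protein": "protein",
    "peptide_id": "peptide_id",
    "channel": "channel",
    "peak_area": "peak_area",
}


def read_transition_report(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[TransitionRecord]:
    """Read a transition-report CSV into validated records.

    Raises
    ------
    FormatError
        if a mandatory column (after dialect mapping) is missing.
    IntegrityError
        if any (sample_id, peptide_id, channel) triple occurs twice.
    ValidationError
        if a row carries a negative peak area or an unknown enum label.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path)
    missing = [col for col in dialect.values() if col not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s): {', '.join(sorted(missing))}"
        )
    inverse = {v: k for k, v in dialect.items()}
    df = df.rename(columns=inverse)[list(DEFAULT_DIALECT)]

    dup_mask = df.duplicated(subset=["sample_id", "peptide_id", "channel"], keep=False)
    if dup_mask.any():
        dups = (
            df.loc[dup_mask, ["sample_id", "peptide_id", "channel"]]
            .drop_duplicates()
            .itertuples(index=False)
        )
        listing = "; ".join(f"({d.sample_id}, {d.peptide_id}, {d.channel})" for d in dups)
        raise IntegrityError(f"{path}: duplicate (sample, peptide, channel): {listing}")

    records: list[TransitionRecord] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                TransitionRecord(
                    sample_id=str(row.sample_id),
                    subject_id=str(row.subject_id),
                    group=str(row.group),
                    compartment=str(row.compartment),
                    time_h=float(row.time_h),
                    protein=str(row.protein),
                    peptide_id=str(row.peptide_id),
                    channel=str(row.channel),
                    peak_area=float(row.peak_area),
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
    if problems:
        raise ValidationError(f"{path}: {len(problems)} invalid row(s): " + "; ".join(problems))
    return records


_COLUMN_ORDER = list(DEFAULT_DIALECT)


def write_transition_report(records: Iterable[TransitionRecord], path: str | Path) -> None:
    """Write records as a transition-report CSV (fixed column order, 9 sig figs)."""
    rows = []
    for r in records:
        d = {k: getattr(r, k) for k in _COLUMN_ORDER}
        d["time_h"] = f"{r.time_h:.9g}"
        d["peak_area"] = f"{r.peak_area:.9g}"
        rows.append(d)
    pd.DataFrame(rows, columns=_COLUMN_ORDER).to_csv(path, index=False)


def ttr_from_areas(labeled_area: float, unlabeled_area: float) -> float:
    """Tracer-to-tracee ratio from labelled/unlabelled peak areas.

    Raises :class:`UndefinedRatioError` when the unlabelled area is
    nonpositive — such points carry no enrichment information and must be
    flagged by the caller rather than silently dropped.
    """
    if unlabeled_area <= 0:
        raise UndefinedRatioError(
            f"TTR undefined: unlabeled_area={unlabeled_area} (must be > 0)"
        )
    if labeled_area < 0:
        raise ValidationError(f"labeled_area must be >= 0, got {labeled_area}")
    return labeled_area / unlabeled_area


def mole_fraction_from_ttr(ttr: float) -> float:
    """Mole fraction labelled ``f = TTR / (1 + TTR)``; TTR 1.0 -> 0.5 (50% mol)."""
    if ttr < 0:
        raise ValidationError(f"ttr must be >= 0, got {ttr}")
    return ttr / (1.0 + ttr)


def ttr_from_mole_fraction(f: float) -> float:
    """Inverse conversion ``TTR = f / (1 - f)`` for ``f`` in ``[0, 1)``."""
    if not 0 <= f < 1:
        raise ValidationError(f"mole fraction must be in [0, 1), got {f}")
    return f / (1.0 - f)


def build_series(records: Sequence[TransitionRecord]) -> SeriesBundle:
    """Pair channels and assemble one enrichment series per (subject, compartment, peptide).

    Points whose unlabelled area is nonpositive are excluded and counted in
    the bundle diagnostics; a series left with zero valid points is omitted
    (listed in ``omitted_empty``), never fabricated.
    """
    by_key: dict[tuple[str, str, str], dict] = {}
    for r in records:
        key = (r.subject_id, r.compartment, r.peptide_id)
        entry = by_key.setdefault(key, {"group": r.group, "times": {}})
        slot = entry["times"].setdefault(r.time_h, {})
        slot[r.channel] = r.peak_area

    series: list[EnrichmentSeries] = []
    dropped = 0
    omitted: list[tuple[str, str, str]] = []
    for (subject, compartment, peptide), entry in by_key.items():
        points: list[EnrichmentPoint] = []
        for t in sorted(entry["times"]):
            areas = entry["times"][t]
            lab, unlab = Channel.LABELED.value, Channel.UNLABELED.value
            if lab not in areas or unlab not in areas:
                dropped += 1
                continue
            try:
                ttr = ttr_from_areas(areas[lab], areas[unlab])
            except UndefinedRatioError:
                dropped += 1
                continue
            points.append(EnrichmentPoint.from_ttr(t, ttr))
        if not points:
            omitted.append((subject, compartment, peptide))
            continue
        series.append(
            EnrichmentSeries(
                subject_id=subject,
                group=entry["group"],
                compartment=compartment,
                peptide_id=peptide,
                points=points,
            )
        )
    return SeriesBundle(series=series, n_dropped_nonpositive=dropped, omitted_empty=omitted)


def series_to_frame(series: Iterable[EnrichmentSeries]) -> pd.DataFrame:
    """Tidy enrichment table: one row per (subject, compartment, peptide, time)."""
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "compartment": s.compartment,
            "peptide_id": s.peptide_id,
            "time_h": p.time_h,
            "ttr": p.ttr,
            "mole_fraction": p.mole_fraction,
        }
        for s in series
        for p in s.points
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "group",
            "compartment",
            "peptide_id",
            "time_h",
            "ttr",
            "mole_fraction",
        ],
    )


_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


def _check_sequence(seq: str, what: str) -> str:
    seq = seq.upper()
    if not _AA_RE.match(seq):
        raise ValidationError(f"{what} contains non-amino-acid characters: {seq!r}")
    return seq


#: Tryptic cleavage: C-terminal to K/R unless followed by proline.
_TRYPSIN_RULE = r"[KR](?!P)"


def tryptic_peptides(sequence: str, missed_cleavages: int = 0) -> set[str]:
    """In-silico tryptic digest: cleave C-terminal to K/R, not before P."""
    sequence = _check_sequence(sequence, "reference sequence")
    return set(_pep_parser.cleave(sequence, _TRYPSIN_RULE, missed_cleavages=missed_cleavages))


def classify_peptide_species(
    peptide: str,
    human_ref: str,
    bovine_ref: str,
    missed_cleavages: int = 0,
) -> SpeciesCall:
    """Call a peptide human-unique, bovine-unique, shared, or absent.

    A peptide is species-unique iff it occurs verbatim among the tryptic
    digest products of one reference protein and not the other; this is the
    basis for disambiguating human (organoid-synthesized) from bovine
    (media-derived) protein in targeted MS.
    """
    pep = _check_sequence(peptide, "peptide")
    in_human = pep in tryptic_peptides(human_ref, missed_cleavages)
    in_bovine = pep in tryptic_peptides(bovine_ref, missed_cleavages)
    if in_human and in_bovine:
        kind = SpeciesCallKind.SHARED
    elif in_human:
        kind = SpeciesCallKind.HUMAN_UNIQUE
    elif in_bovine:
        kind = SpeciesCallKind.BOVINE_UNIQUE
    else:
        kind = SpeciesCallKind.ABSENT
    return SpeciesCall(peptide_sequence=pep, call=kind)
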