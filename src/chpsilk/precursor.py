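"""Plasma precursor (13C6-leucine) enrichment profiles and plateau estimation.

The fractional synthesis rate normalizes the CSF upslope by the plasma free
leucine enrichment at plateau during the infusion.  This module estimates
that plateau (mean mole fraction inside a window, by default the second half
of the infusion period) and implements the surrogate-plateau rule used when
a subject's own infusion never reached a steady plateau: another subject's
steady profile stands in, and the substitution is recorded in provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .ingest import EnrichmentPoint

__all__ = ["PrecursorProfile", "plateau_enrichment", "surrogate_plateau"]

logger = logging.getLogger(__name__)

#: Coefficient of variation above which a plateau is not considered steady.
DEFAULT_STEADINESS_CV = 0.15


@dataclass
class PrecursorProfile:
    """Plasma leucine enrichment time course and its plateau estimate."""

    subject_id: str
    points: list[EnrichmentPoint]
    plateau_mole_fraction: float
    plateau_window_h: tuple[float, float]
    plateau_cv: float
    surrogate_of: str | None = None  #: set when this profile stands in for another subject
    warnings: list[str] = field(default_factory=list)

    def is_steady(self, cv_threshold: float = DEFAULT_STEADINESS_CV) -> bool:
        return self.plateau_cv <= cv_threshold


def plateau_enrichment(
    points: Sequence[EnrichmentPoint],
    window: tuple[float, float] | str = "auto",
    infusion_end_h: float | None = None,
    subject_id: str = "",
    cv_warn: float = DEFAULT_STEADINESS_CV,
) -> PrecursorProfile:
    """Estimate the plateau mole fraction as the mean over a late-infusion window.

    ``window="auto"`` uses the second half of the infusion period, which
    requires ``infusion_end_h``.  The estimator is the arithmetic mean of
    in-window mole fractions (robust to single-sample MS noise); its
    coefficient of variation is reported, with a logged warning above
    ``cv_warn``.

    Raises
    ------
    InsufficientDataError
        with fewer than 2 points inside the window.
    ValidationError
        if the estimated plateau is nonpositive (FSR would be undefined).
    """
    pts = sorted(points, key=lambda p: p.time_h)
    if window == "auto":
        if infusion_end_h is None:
            raise ValidationError("auto plateau window requires infusion_end_h")
        window = (infusion_end_h / 2.0, infusion_end_h)
    start, end = float(window[0]), float(window[1])
    if not start < end:
        raise ValidationError(f"plateau window start must precede end, got ({start}, {end})")

    inside = [p.mole_fraction for p in pts if start <= p.time_h <= end]
    if len(inside) < 2:
        raise InsufficientDataError(
            f"plateau window [{start}, {end}] h holds {len(inside)} plasma point(s); >= 2 required"
        )
    arr = np.asarray(inside, dtype=float)
    plateau = float(arr.mean())
    if plateau <= 0:
        raise ValidationError(f"plateau mole fraction must be > 0, got {plateau}")
    cv = float(arr.std(ddof=1) / plateau)

    warns: list[str] = []
    if cv > cv_warn:
        msg = (
            f"subject {subject_id or '?'}: plateau CV {cv:.3f} exceeds {cv_warn:.2f}; "
            "infusion may not have reached a steady plateau"
        )
        warns.append(msg)
        logger.warning(msg)
    return PrecursorProfile(
        subject_id=subject_id,
        points=list(pts),
        plateau_mole_fraction=plateau,
        plateau_window_h=(start, end),
        plateau_cv=cv,
        warnings=warns,
    )


def surrogate_plateau(
    profiles: Iterable[PrecursorProfile],
    strategy: str = "best_cv",
    designated_subject: str | None = None,
    cv_threshold: float = DEFAULT_STEADINESS_CV,
) -> PrecursorProfile:
    """Choose one steady profile to normalize a whole cohort's synthesis rates.

    Used when infusion duration varied with clinical circumstances and not
    every subject reached a plateau.  ``best_cv`` picks the profile with the
    smallest plateau CV among those below ``cv_threshold``; ``named`` picks a
    designated subject.  The choice is recorded downstream via
    ``surrogate_of`` provenance on the fitted rates.
    """
    profiles = list(profiles)
    if not profiles:
        raise InsufficientDataError("no precursor profiles supplied")
    if strategy == "named":
        if designated_subject is None:
            raise ValidationError("strategy 'named' requires designated_subject")
        for p in profiles:
            if p.subject_id == designated_subject:
                return p
        raise ValidationError(f"no precursor profile for subject {designated_subject!r}")
    if strategy != "best_cv":
        raise ValidationError(f"unknown surrogate strategy {strategy!r}")
    steady = [p for p in profiles if p.is_steady(cv_threshold)]
    if not steady:
        raise InsufficientDataError(
            f"no profile has plateau CV <= {cv_threshold}; designate a surrogate subject explicitly"
        )
    return min(steady, key=lambda p: p.plateau_cv)
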