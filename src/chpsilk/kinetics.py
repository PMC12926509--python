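"""Protein turnover estimation from pulse-chase enrichment time courses.

The estimators mirror the standard SILK analysis:

* **FSR** (fractional synthesis rate, %/h): ordinary least-squares slope of
  the mole fraction labelled over the upslope window (first timepoint
  through the peak of labelling, inclusive), divided by the plasma precursor
  plateau enrichment and expressed per 100 units of pool:
  ``FSR = 100 * slope / plateau``.
* **FCR** (fractional clearance rate, /h): negative OLS slope of
  ``ln(mole fraction)`` over the clearance window (peak of labelling onward
  in vivo; all chase timepoints in vitro).
* **Half-life** (h): ``t_half = ln(2) / k`` with ``k`` from a nonlinear
  exponential regression ``E(t) = A * exp(-k * (t - t_peak))`` over the same
  window, initialized from the log-linear fit.

The public surface is a statsmodels-style pair: :class:`TurnoverModel` built
from one :class:`~chpsilk.ingest.EnrichmentSeries` (plus a precursor
plateau), whose :meth:`~TurnoverModel.fit` returns a
:class:`TurnoverResults` carrying estimates, diagnostics, quality flags and
a ``summary()`` table.  The underlying single-purpose fitters
(:func:`detect_peak`, :func:`fit_fsr`, :func:`fit_fcr`,
:func:`fit_half_life`) are exposed for direct use; all of them are
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ValidationError
from .ingest import EnrichmentSeries
from .precursor import PrecursorProfile

__all__ = [
    "KineticFitConfig",
    "TurnoverModel",
    "TurnoverResults",
    "detect_peak",
    "fit_fsr",
    "fit_fcr",
    "fit_half_life",
    "fit_subject",
    "results_to_frame",
]


@dataclass(frozen=True)
class KineticFitConfig:
    """Windowing and minimum-data rules for the three turnover fits.

    ``chase_rule="from_peak"`` is the in vivo convention (clearance window
    starts at the peak of labelling); ``"all_chase_timepoints"`` is the in
    vitro convention and requires ``chase_start_h`` (the time label media
    was removed).  ``precursor_convention="plateau"`` normalizes FSR by the
    measured plasma plateau; ``"unity"`` divides by 1, the in vitro
    convention for media in which labelled and unlabelled leucine are
    equimolar.
    """

    min_points_fsr: int = 3
    min_points_fcr: int = 3
    peak_rule: str = "global_max_earliest"
    chase_rule: str = "from_peak"
    chase_start_h: float | None = None
    fsr_upslope_rule: str = "first_to_peak"
    precursor_convention: str = "plateau"

    def __post_init__(self) -> None:
        if self.min_points_fsr < 2 or self.min_points_fcr < 2:
            raise ValidationError("minimum points per fit must be >= 2")
        if self.chase_rule not in ("from_peak", "all_chase_timepoints"):
            raise ValidationError(f"unknown chase_rule {self.chase_rule!r}")
        if self.chase_rule == "all_chase_timepoints" and self.chase_start_h is None:
            raise ValidationError("chase_rule 'all_chase_timepoints' requires chase_start_h")
        if self.precursor_convention not in ("plateau", "unity"):
            raise ValidationError(f"unknown precursor_convention {self.precursor_convention!r}")


@dataclass
class TurnoverResults:
    """Estimated turnover rates and diagnostics for one peptide in one subject.

    Undefined quantities are ``nan`` with an explanatory entry in ``flags``.
    Invariants: ``fsr_pct_per_h = 100 * fsr_slope_per_h / precursor_plateau``
    (under the plateau convention) and ``half_life_h = ln(2) / k_exp_per_h``.
    """

    subject_id: str
    peptide_id: str
    fsr_pct_per_h: float = math.nan
    fsr_slope_per_h: float = math.nan
    precursor_plateau: float = math.nan
    fcr_per_h: float = math.nan
    half_life_h: float = math.nan
    k_exp_per_h: float = math.nan
    n_points_fsr: int = 0
    n_points_fcr: int = 0
    r2_fsr: float = math.nan
    r2_fcr: float = math.nan
    flags: set[str] = field(default_factory=set)
    provenance: str = ""

    def summary(self) -> str:
        """Human-readable one-peptide summary table."""
        lines = [
            f"Turnover fit: subject {self.subject_id}, peptide {self.peptide_id}",
            "-" * 56,
            f"{'FSR':<22}{self.fsr_pct_per_h:>12.4g} %/h   (n={self.n_points_fsr}, r2={self.r2_fsr:.3f})"
            if self.n_points_fsr
            else f"{'FSR':<22}{'undefined':>12}",
            f"{'raw upslope':<22}{self.fsr_slope_per_h:>12.4g} /h",
            f"{'precursor plateau':<22}{self.precursor_plateau:>12.4g}",
            f"{'FCR':<22}{self.fcr_per_h:>12.4g} /h    (n={self.n_points_fcr}, r2={self.r2_fcr:.3f})"
            if self.n_points_fcr
            else f"{'FCR':<22}{'undefined':>12}",
            f"{'half-life':<22}{self.half_life_h:>12.4g} h",
            f"{'exp rate k':<22}{self.k_exp_per_h:>12.4g} /h",
            f"{'flags':<22}{', '.join(sorted(self.flags)) or 'none':>12}",
            f"provenance: {self.provenance}",
        ]
        return "\n".join(lines)

    def plot(self, series: EnrichmentSeries | None = None, ax=None):
        """Plot the enrichment curve with the fitted upslope and decay overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if series is not None:
            t = np.asarray(series.times)
            e = np.asarray(series.mole_fractions)
            ax.plot(t, e, "o-", color="0.4", label="mole fraction labelled")
            if np.isfinite(self.k_exp_per_h):
                peak = int(np.argmax(e))
                tt = np.linspace(t[peak], t[-1], 100)
                a0 = e[peak]
                ax.plot(tt, a0 * np.exp(-self.k_exp_per_h * (tt - t[peak])), "--",
                        label=f"exp decay, t1/2={self.half_life_h:.3g} h")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("mole fraction labelled")
        ax.set_title(f"{self.subject_id} / {self.peptide_id}")
        ax.legend()
        return ax


def detect_peak(series: EnrichmentSeries) -> int:
    """Index of the peak of labelling: maximum mole fraction, earliest on ties."""
    frac = series.mole_fractions
    best = 0
    for i, v in enumerate(frac):
        if v > frac[best]:
            best = i
    return best


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Unweighted least squares of y on t; returns (slope, intercept, r2)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    tbar, ybar = t.mean(), y.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    sxy = float(np.sum((t - tbar) * (y - ybar)))
    syy = float(np.sum((y - ybar) ** 2))
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    r2 = 1.0 if syy == 0 else min(1.0, max(0.0, sxy * sxy / (sxx * syy)))
    return slope, intercept, r2


def fit_fsr(
    series: EnrichmentSeries,
    plateau: PrecursorProfile | float,
    cfg: KineticFitConfig = KineticFitConfig(),
) -> TurnoverResults:
    """Fractional synthesis rate from the labelling upslope.

    The window runs from the first timepoint through the detected peak,
    inclusive.  A negative slope is permitted (observed for proteins
    transported rather than synthesized) and flagged ``negative_fsr``.
    """
    res = TurnoverResults(subject_id=series.subject_id, peptide_id=series.peptide_id)
    if cfg.precursor_convention == "unity":
        plateau_value = 1.0
        precursor_src = "unity (in vitro convention)"
        res.flags.add("precursor_unity")
    elif isinstance(plateau, PrecursorProfile):
        plateau_value = plateau.plateau_mole_fraction
        precursor_src = plateau.subject_id
        if plateau.surrogate_of:
            precursor_src += f" (surrogate for {plateau.surrogate_of})"
            res.flags.add("surrogate_plateau")
    else:
        plateau_value = float(plateau)
        precursor_src = "scalar plateau"
    if plateau_value <= 0:
        raise ValidationError(f"precursor plateau must be > 0, got {plateau_value}")

    peak = detect_peak(series)
    t = np.asarray(series.times[: peak + 1])
    e = np.asarray(series.mole_fractions[: peak + 1])
    res.precursor_plateau = plateau_value
    res.provenance = f"precursor={precursor_src}; fsr_window=[{series.times[0]:g},{series.times[peak]:g}]h"
    if len(t) < cfg.min_points_fsr:
        res.flags.add("too_few_points_fsr")
        return res
    slope, _, r2 = _ols(t, e)
    res.fsr_slope_per_h = slope
    res.fsr_pct_per_h = 100.0 * slope / plateau_value
    res.r2_fsr = r2
    res.n_points_fsr = len(t)
    if slope < 0:
        res.flags.add("negative_fsr")
    return res


def _clearance_window(series: EnrichmentSeries, cfg: KineticFitConfig) -> list[int]:
    if cfg.chase_rule == "all_chase_timepoints":
        return [i for i, t in enumerate(series.times) if t >= cfg.chase_start_h]
    peak = detect_peak(series)
    return list(range(peak, len(series.points)))


def fit_fcr(
    series: EnrichmentSeries, cfg: KineticFitConfig = KineticFitConfig()
) -> TurnoverResults:
    """Fractional clearance rate: negative log-linear slope over the chase.

    Nonpositive mole fractions cannot enter the log fit; they are excluded
    with flag ``dropped_nonpositive`` rather than offset, because an additive
    offset biases small-enrichment decay estimates.
    """
    res = TurnoverResults(subject_id=series.subject_id, peptide_id=series.peptide_id)
    idx = _clearance_window(series, cfg)
    t_all = [series.times[i] for i in idx]
    e_all = [series.mole_fractions[i] for i in idx]
    keep = [(t, e) for t, e in zip(t_all, e_all) if e > 0]
    if len(keep) < len(t_all):
        res.flags.add("dropped_nonpositive")
    if idx:
        res.provenance = f"fcr_window=[{series.times[idx[0]]:g},{series.times[idx[-1]]:g}]h"
    if len(keep) < cfg.min_points_fcr:
        res.flags.add("too_few_points_fcr")
        return res
    t = np.array([p[0] for p in keep])
    loge = np.log([p[1] for p in keep])
    slope, _, r2 = _ols(t, loge)
    res.fcr_per_h = -slope
    res.r2_fcr = r2
    res.n_points_fcr = len(keep)
    if res.fcr_per_h < 0:
        res.flags.add("negative_fcr")
    return res


def fit_half_life(
    series: EnrichmentSeries, cfg: KineticFitConfig = KineticFitConfig()
) -> TurnoverResults:
    """Half-life from a nonlinear exponential regression of the clearance portion.

    Fits ``E(t) = A * exp(-k * (t - t_peak))`` by least squares, initialized
    from the log-linear fit; ``t_half = ln(2) / k``.  Convergence: relative
    parameter change below 1e-8 or 200 iterations; failures are flagged
    ``exp_fit_failed``, a nonpositive optimal ``k`` is flagged
    ``nondecaying`` (half-life undefined in both cases).
    """
    res = fit_fcr(series, cfg)
    if res.n_points_fcr < cfg.min_points_fcr:
        return res
    idx = _clearance_window(series, cfg)
    t0 = series.times[idx[0]]
    pts = [
        (series.times[i] - t0, series.mole_fractions[i])
        for i in idx
        if series.mole_fractions[i] > 0
    ]
    t = np.array([p[0] for p in pts])
    e = np.array([p[1] for p in pts])
    # log-linear initialisation: A from the intercept, k from the FCR
    slope, intercept, _ = _ols(t, np.log(e))
    x0 = np.array([math.exp(intercept), -slope])

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, k = theta
        return a * np.exp(-k * t) - e

    try:
        sol = optimize.least_squares(residuals, x0, method="lm", xtol=1e-8, max_nfev=200 * 4)
    except Exception:
        res.flags.add("exp_fit_failed")
        return res
    if not sol.success:
        res.flags.add("exp_fit_failed")
        return res
    _, k = sol.x
    if k <= 0:
        res.flags.add("nondecaying")
        return res
    res.k_exp_per_h = float(k)
    res.half_life_h = math.log(2) / float(k)
    return res


class TurnoverModel:
    """Turnover model for one enrichment time course.

    Parameters
    ----------
    series
        Enrichment time course for one (subject, compartment, peptide).
    precursor
        Plasma precursor profile (or a plateau mole fraction as a scalar);
        may be omitted when ``config.precursor_convention == "unity"``.
    config
        Windowing rules; defaults follow the in vivo convention.

    Examples
    --------
    >>> model = TurnoverModel(series, precursor=profile)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        series: EnrichmentSeries,
        precursor: PrecursorProfile | float | None = None,
        config: KineticFitConfig = KineticFitConfig(),
    ) -> None:
        if precursor is None and config.precursor_convention != "unity":
            raise ValidationError(
                "a precursor plateau is required unless precursor_convention='unity'"
            )
        self.series = series
        self.precursor = precursor if precursor is not None else 1.0
        self.config = config

    def fit(self) -> TurnoverResults:
        """Run the FSR, FCR and half-life fits and merge their outputs."""
        fsr = fit_fsr(self.series, self.precursor, self.config)
        decay = fit_half_life(self.series, self.config)
        merged = replace(
            fsr,
            fcr_per_h=decay.fcr_per_h,
            half_life_h=decay.half_life_h,
            k_exp_per_h=decay.k_exp_per_h,
            n_points_fcr=decay.n_points_fcr,
            r2_fcr=decay.r2_fcr,
        )
        merged.flags = fsr.flags | decay.flags
        merged.provenance = "; ".join(p for p in (fsr.provenance, decay.provenance) if p)
        return merged


def fit_subject(
    series_set: Iterable[EnrichmentSeries],
    precursor: PrecursorProfile | float | None,
    cfg: KineticFitConfig = KineticFitConfig(),
) -> list[TurnoverResults]:
    """Fit every peptide series of one subject; failures never abort the subject."""
    out: list[TurnoverResults] = []
    for series in series_set:
        try:
            out.append(TurnoverModel(series, precursor, cfg).fit())
        except Exception as exc:  # propagate per peptide as a flagged row
            row = TurnoverResults(subject_id=series.subject_id, peptide_id=series.peptide_id)
            row.flags.add(f"fit_error:{type(exc).__name__}")
            row.provenance = str(exc)
            out.append(row)
    return out


_RATE_COLUMNS = [
    "subject_id",
    "peptide_id",
    "fsr_pct_per_h",
    "fsr_slope_per_h",
    "precursor_plateau",
    "fcr_per_h",
    "half_life_h",
    "k_exp_per_h",
    "n_points_fsr",
    "n_points_fcr",
    "r2_fsr",
    "r2_fcr",
    "flags",
    "provenance",
]


def results_to_frame(results: Sequence[TurnoverResults], group: dict[str, str] | None = None) -> pd.DataFrame:
    """Rates table, one row per (subject, peptide); optional subject->group map."""
    rows = []
    for r in results:
        d = {c: getattr(r, c) for c in _RATE_COLUMNS}
        d["flags"] = "|".join(sorted(r.flags))
        rows.append(d)
    df = pd.DataFrame(rows, columns=_RATE_COLUMNS)
    if group is not None:
        df.insert(1, "group", df["subject_id"].map(group))
    return df
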