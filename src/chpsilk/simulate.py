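"""Compartmental pulse-chase SILK simulator with known ground truth.

Emulates a complete in vivo labelling experiment: an intravenous
``13C6``-leucine bolus + constant infusion drives plasma precursor
enrichment up to a plateau; each protein pool incorporates label in
proportion to its synthesis rate and loses it at its clearance rate; MS
peak areas are corrupted with multiplicative lognormal noise and exported
in the transition-report schema the ingest module reads, together with a
ground-truth manifest.  Because the true fractional synthesis and
clearance rates of every simulated pool are known, the whole
ingest -> precursor -> kinetics -> statistics pipeline can be validated by
parameter recovery at desk scale.

Model
-----
Plasma precursor (phenomenological; the clinical protocol measures rather
than models it)::

    p(t) = P_max * (1 - exp(-t / tau_r))                      t <= T_end
    p(t) = p(T_end) * exp(-(t - T_end) / tau_d)               t >  T_end

Protein pool (labelled and unlabelled amounts, fixed-step RK4)::

    dA_L/dt = S * p(t - delta) - k_c * A_L          A_L(0) = 0
    dA_U/dt = S * (1 - p(t - delta)) - k_c * A_U    A_U(0) = A0

with enrichment ``E(t) = A_L / (A_L + A_U)``.  Mass balance follows
``d(A_L + A_U)/dt = S - k_c * (A_L + A_U)``, so a pool initialized at its
steady state ``A0 = S / k_c`` (the default) keeps a constant total and the
chase log-slope of E identifies ``k_c`` exactly; with an explicit
non-steady ``A0`` the total pool drifts toward ``S / k_c`` during the
experiment, which biases the empirical slope estimators (quantified in the
test suite).

The optional two-compartment mode feeds a lumbar pool from the ventricular
one by first-order transfer at rate ``r`` (inflow ``r * V``, washout
``r + k_c``), so lumbar enrichment lags ventricular and converges to it as
``r`` grows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .ingest import (
    Channel,
    EnrichmentPoint,
    EnrichmentSeries,
    TransitionRecord,
    write_transition_report,
)

__all__ = [
    "InfusionSchedule",
    "PrecursorModel",
    "ProteinPool",
    "SimConfig",
    "precursor_curve",
    "make_precursor_fn",
    "simulate_pool",
    "simulate_two_compartment",
    "corrupt_series",
    "corrupt_and_export",
    "make_cohort",
    "CohortBundle",
    "nph_vs_control_configs",
]

DEFAULT_STEP_H = 0.01
#: CSF sampling grid: hourly through the 9-h infusion, then a 72-h chase.
DEFAULT_CSF_TIMES = tuple(float(t) for t in list(range(10)) + [24, 32, 40, 48, 56, 64, 72])
#: Extended grid for slow-clearing (NPH-like) subjects on prolonged lumbar
#: drainage: 12-hourly chase sampling out to 5 days.  A pool with half-life
#: of weeks barely decays inside 72 h, so resolving its clearance needs the
#: longer window; chase duration differing between cohorts is a feature of
#: the clinical protocol being emulated.
EXTENDED_CSF_TIMES = tuple(float(t) for t in list(range(10)) + list(range(24, 121, 12)))
#: Plasma leucine sampled hourly during the infusion.
DEFAULT_PLASMA_TIMES = tuple(float(t) for t in range(1, 10))


@dataclass(frozen=True)
class InfusionSchedule:
    """Primed infusion: 3 mg/kg/h bolus for 10 min, then 2 mg/kg/h to 9 h."""

    bolus_rate: float = 3.0  # mg/kg/h
    bolus_duration_h: float = 1.0 / 6.0
    infusion_rate: float = 2.0  # mg/kg/h
    infusion_end_h: float = 9.0

    def __post_init__(self) -> None:
        if min(self.bolus_rate, self.bolus_duration_h, self.infusion_rate, self.infusion_end_h) <= 0:
            raise ConfigError("all infusion schedule fields must be positive")
        if self.bolus_duration_h >= self.infusion_end_h:
            raise ConfigError(
                f"bolus_duration_h ({self.bolus_duration_h}) must be < infusion_end_h "
                f"({self.infusion_end_h})"
            )


@dataclass(frozen=True)
class PrecursorModel:
    """Phenomenological plasma enrichment: exponential rise to plateau, then decay."""

    plateau_mole_fraction: float = 0.10
    rise_time_const_h: float = 0.5
    decay_time_const_h: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.plateau_mole_fraction < 1:
            raise ConfigError("plateau_mole_fraction must be in (0,1)")
        if self.rise_time_const_h <= 0 or self.decay_time_const_h <= 0:
            raise ConfigError("time constants must be positive")


def precursor_curve(model: PrecursorModel, schedule: InfusionSchedule, t) -> np.ndarray | float:
    """Plasma precursor mole fraction at time(s) ``t`` (continuous at infusion end)."""
    t = np.asarray(t, dtype=float)
    t_end = schedule.infusion_end_h
    rise = model.plateau_mole_fraction * (1.0 - np.exp(-np.clip(t, 0.0, None) / model.rise_time_const_h))
    boundary = model.plateau_mole_fraction * (1.0 - np.exp(-t_end / model.rise_time_const_h))
    decay = boundary * np.exp(-(t - t_end) / model.decay_time_const_h)
    out = np.where(t <= t_end, rise, decay)
    out = np.where(t < 0, 0.0, out)
    return out if out.ndim else float(out)


def make_precursor_fn(model: PrecursorModel, schedule: InfusionSchedule) -> Callable:
    """Bind a (model, schedule) pair into a vectorized ``p(t)`` callable."""
    return lambda t: precursor_curve(model, schedule, t)


@dataclass(frozen=True)
class ProteinPool:
    """One protein pool: synthesis rate S, clearance k_c, initial amount A0.

    ``initial_pool=None`` (default) uses the tracee steady state
    ``A0 = S / k_c``, under which the total pool stays constant.  A transit
    delay ``delta`` makes the pool see the precursor ``delta`` hours late
    (ventricular-to-lumbar transit); ``origin`` distinguishes locally
    synthesized from blood-CSF-barrier-transported proteins (bookkeeping
    only).
    """

    protein: str
    synthesis_rate: float  # amount/h
    clearance_rate: float  # /h
    initial_pool: float | None = None
    transit_delay_h: float = 0.0
    origin: str = "chp"  # chp | plasma_transported
    peptide_id: str | None = None

    def __post_init__(self) -> None:
        if self.synthesis_rate <= 0:
            raise ConfigError("synthesis_rate must be > 0")
        if self.clearance_rate < 0:
            raise ConfigError("clearance_rate must be >= 0")
        if self.transit_delay_h < 0:
            raise ConfigError("transit_delay_h must be >= 0")
        if self.initial_pool is None and self.clearance_rate == 0:
            raise ConfigError("a pool with zero clearance needs an explicit initial_pool")
        if self.initial_pool is not None and self.initial_pool <= 0:
            raise ConfigError("initial_pool must be > 0")

    @property
    def a0(self) -> float:
        if self.initial_pool is not None:
            return self.initial_pool
        return self.synthesis_rate / self.clearance_rate

    @property
    def true_fsr_pct_per_h(self) -> float:
        """Ground-truth fractional synthesis rate, % of pool per hour."""
        return 100.0 * self.synthesis_rate / self.a0

    @property
    def label(self) -> str:
        return self.peptide_id or f"{self.protein}_SIM"


def _sample_indices(times: Sequence[float], step: float) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ConfigError("at least one sample time required")
    if np.any(np.diff(times) <= 0):
        raise ConfigError("sample times must be strictly increasing")
    if times.size > 1 and step > np.min(np.diff(times)) + 1e-12:
        raise ConfigError(f"integrator step {step} exceeds minimum sample spacing")
    idx = np.rint(times / step).astype(int)
    if np.max(np.abs(idx * step - times)) > 1e-6:
        raise ConfigError(f"sample times must lie on the {step} h integration grid")
    return idx


def _integrate_enrichment(
    S: np.ndarray,
    kc: np.ndarray,
    A0: np.ndarray,
    delay: np.ndarray,
    p: Callable,
    times: Sequence[float],
    step: float = DEFAULT_STEP_H,
    return_amounts: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched RK4 integration of the pool ODEs; returns E of shape (n_pools, n_times).

    With ``return_amounts=True`` also returns the labelled and unlabelled
    amounts at the sample times (used to verify mass balance).
    """
    S, kc, A0, delay = np.broadcast_arrays(
        np.atleast_1d(np.asarray(S, float)),
        np.atleast_1d(np.asarray(kc, float)),
        np.atleast_1d(np.asarray(A0, float)),
        np.atleast_1d(np.asarray(delay, float)),
    )
    idx = _sample_indices(times, step)
    n_steps = int(idx[-1])
    AL = np.zeros_like(S)
    AU = A0.copy()
    out = np.empty((S.shape[0], len(idx)))
    out_al = np.empty_like(out)
    out_au = np.empty_like(out)
    targets = {int(i): j for j, i in enumerate(idx)}

    def deriv(t: float, al: np.ndarray, au: np.ndarray):
        pt = np.asarray(p(t - delay), dtype=float)
        pt = np.where(t - delay < 0, 0.0, pt)
        return S * pt - kc * al, S * (1.0 - pt) - kc * au

    def record(j: int) -> None:
        out[:, j] = AL / (AL + AU)
        out_al[:, j] = AL
        out_au[:, j] = AU

    if 0 in targets:
        record(targets[0])
    for i in range(n_steps):
        t = i * step
        k1l, k1u = deriv(t, AL, AU)
        k2l, k2u = deriv(t + step / 2, AL + step / 2 * k1l, AU + step / 2 * k1u)
        k3l, k3u = deriv(t + step / 2, AL + step / 2 * k2l, AU + step / 2 * k2u)
        k4l, k4u = deriv(t + step, AL + step * k3l, AU + step * k3u)
        AL = AL + step / 6 * (k1l + 2 * k2l + 2 * k3l + k4l)
        AU = AU + step / 6 * (k1u + 2 * k2u + 2 * k3u + k4u)
        if (i + 1) in targets:
            record(targets[i + 1])
    if return_amounts:
        return out, out_al, out_au
    return out


def _series_from_e(
    times: Sequence[float],
    e: np.ndarray,
    subject_id: str,
    group: str,
    compartment: str,
    peptide_id: str,
) -> EnrichmentSeries:
    pts = [
        EnrichmentPoint(time_h=float(t), ttr=float(v / (1.0 - v)), mole_fraction=float(v))
        for t, v in zip(times, e)
    ]
    return EnrichmentSeries(
        subject_id=subject_id, group=group, compartment=compartment, peptide_id=peptide_id, points=pts
    )


def simulate_pool(
    pool: ProteinPool,
    precursor: Callable,
    times: Sequence[float],
    step: float = DEFAULT_STEP_H,
    subject_id: str = "sim",
    group: str = "NPH",
    compartment: str = "ventricular",
) -> EnrichmentSeries:
    """Noise-free enrichment time course of one pool at the sample times."""
    e = _integrate_enrichment(
        pool.synthesis_rate, pool.clearance_rate, pool.a0, pool.transit_delay_h, precursor, times, step
    )[0]
    return _series_from_e(times, e, subject_id, group, compartment, pool.label)


def simulate_two_compartment(
    pool: ProteinPool,
    precursor: Callable,
    times: Sequence[float],
    intercompartment_rate: float,
    step: float = DEFAULT_STEP_H,
    subject_id: str = "sim",
    group: str = "NPH",
) -> tuple[EnrichmentSeries, EnrichmentSeries]:
    """Ventricular pool plus a downstream lumbar compartment fed at rate ``r``.

    Lumbar amounts obey ``dL_x/dt = r * V_x - (r + k_c) * L_x``; lumbar
    enrichment lags the ventricular curve and approaches it as ``r`` grows.
    """
    if intercompartment_rate <= 0:
        raise ConfigError("intercompartment_rate must be > 0")
    r = float(intercompartment_rate)
    S, kc, A0, delay = pool.synthesis_rate, pool.clearance_rate, pool.a0, pool.transit_delay_h
    idx = _sample_indices(times, step)
    n_steps = int(idx[-1])
    targets = {int(i): j for j, i in enumerate(idx)}
    # state: ventricular labelled/unlabelled, lumbar labelled/unlabelled
    y = np.array([0.0, A0, 0.0, A0 * r / (r + kc)])

    def deriv(t: float, y: np.ndarray) -> np.ndarray:
        pt = float(precursor(t - delay)) if t - delay >= 0 else 0.0
        vl, vu, ll, lu = y
        return np.array(
            [
                S * pt - kc * vl,
                S * (1.0 - pt) - kc * vu,
                r * vl - (r + kc) * ll,
                r * vu - (r + kc) * lu,
            ]
        )

    out = np.empty((len(idx), 4))
    if 0 in targets:
        out[targets[0]] = y
    for i in range(n_steps):
        t = i * step
        k1 = deriv(t, y)
        k2 = deriv(t + step / 2, y + step / 2 * k1)
        k3 = deriv(t + step / 2, y + step / 2 * k2)
        k4 = deriv(t + step, y + step * k3)
        y = y + step / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if (i + 1) in targets:
            out[targets[i + 1]] = y
    e_vent = out[:, 0] / (out[:, 0] + out[:, 1])
    e_lum = out[:, 2] / (out[:, 2] + out[:, 3])
    vent = _series_from_e(times, e_vent, subject_id, group, "ventricular", pool.label)
    lum = _series_from_e(times, e_lum, subject_id, group, "lumbar", pool.label)
    return vent, lum


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def corrupt_series(
    series: EnrichmentSeries,
    rng: np.random.Generator,
    noise_cv: float,
    mean_total_area: float = 1.0e6,
    protein: str | None = None,
) -> list[TransitionRecord]:
    """Convert a true enrichment series to noisy labelled/unlabelled peak areas.

    Each channel's expected area (``total * E`` and ``total * (1 - E)``) is
    scaled by an independent unit-mean lognormal factor with CV =
    ``noise_cv``, so the measured ratio — and hence the ingested enrichment
    — is stochastic while remaining unbiased on the area scale.
    """
    if noise_cv < 0:
        raise ConfigError("noise_cv must be >= 0")
    protein = protein or series.peptide_id.split("_")[0]
    records = []
    for pt in series.points:
        factors = _lognormal_factors(rng, noise_cv, 2)
        lab = mean_total_area * pt.mole_fraction * factors[0]
        unlab = mean_total_area * (1.0 - pt.mole_fraction) * factors[1]
        sample_id = f"{series.subject_id}_{series.compartment}_{pt.time_h:g}h"
        for channel, area in ((Channel.LABELED.value, lab), (Channel.UNLABELED.value, unlab)):
            records.append(
                TransitionRecord(
                    sample_id=sample_id,
                    subject_id=series.subject_id,
                    group=series.group,
                    compartment=series.compartment,
                    time_h=pt.time_h,
                    protein=protein,
                    peptide_id=series.peptide_id,
                    channel=channel,
                    peak_area=float(area),
                )
            )
    return records


def corrupt_and_export(
    truth: Sequence[EnrichmentSeries],
    noise_cv: float,
    seed: int,
    path: str | Path,
    mean_total_area: float = 1.0e6,
) -> list[TransitionRecord]:
    """Corrupt noise-free series and write them as a transition-report CSV."""
    rng = np.random.default_rng(seed)
    records: list[TransitionRecord] = []
    for s in truth:
        records.extend(corrupt_series(s, rng, noise_cv, mean_total_area))
    write_transition_report(records, path)
    return records


@dataclass
class SimConfig:
    """Full parameterization of one simulated cohort (one study arm)."""

    group: str = "NPH"
    compartment: str = "lumbar"
    n_subjects: int = 8
    pools: list[ProteinPool] = field(
        default_factory=lambda: [ProteinPool("TTHY", synthesis_rate=0.002, clearance_rate=0.002)]
    )
    schedule: InfusionSchedule = field(default_factory=InfusionSchedule)
    precursor: PrecursorModel = field(default_factory=PrecursorModel)
    compartments: str = "one"  # one | two
    intercompartment_rate: float = 1.0  # /h, two-compartment mode only
    sample_times_h: tuple[float, ...] = DEFAULT_CSF_TIMES
    plasma_times_h: tuple[float, ...] = DEFAULT_PLASMA_TIMES
    noise_cv: float = 0.05
    mean_total_area: float = 1.0e6
    between_subject_cv: float = 0.15
    step_h: float = DEFAULT_STEP_H
    seed: int = 0
    subject_prefix: str = "SUBJ"
    production_coef_ml_per_amount: float | None = None  # enables the production table
    production_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.compartments not in ("one", "two"):
            raise ConfigError(f"unknown compartments mode {self.compartments!r}")
        if self.noise_cv > 0 or self.between_subject_cv > 0:
            if self.seed is None:
                raise ConfigError("seed is mandatory when any randomness is enabled")
        times = np.asarray(self.sample_times_h, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ConfigError("sample_times_h must be strictly increasing")


@dataclass
class CohortBundle:
    """In-memory study bundle: noisy records, truth tables, optional files."""

    config: SimConfig
    csf_records: list[TransitionRecord]
    plasma_records: list[TransitionRecord]
    truth: dict
    production: pd.DataFrame | None = None
    files: dict[str, str] = field(default_factory=dict)


def make_cohort(config: SimConfig, out_dir: str | Path | None = None) -> CohortBundle:
    """Simulate a cohort and (optionally) export it in the ingest formats.

    Per subject, synthesis and clearance rates are drawn lognormally around
    the pool values with CV ``between_subject_cv`` (steady-state pools keep
    ``A0 = S / k_c`` per subject).  Writes, when ``out_dir`` is given:
    ``transitions.csv`` (CSF), ``plasma.csv``, ``truth.json`` and, if
    enabled, ``production.csv``.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    p_fn = make_precursor_fn(config.precursor, config.schedule)
    subjects = [f"{config.subject_prefix}{i + 1:02d}" for i in range(config.n_subjects)]

    truth: dict = {"group": config.group, "subjects": {}}
    csf_records: list[TransitionRecord] = []
    plasma_records: list[TransitionRecord] = []
    mean_synthesis: dict[str, float] = {}

    # draw all between-subject parameters first, then integrate every
    # one-compartment pool in a single batched RK4 pass
    subj_pools: dict[str, list[ProteinPool]] = {}
    for subj in subjects:
        truth["subjects"][subj] = {}
        pools_i = []
        for pool in config.pools:
            f_s, f_k = _lognormal_factors(rng, config.between_subject_cv, 2)
            pool_i = ProteinPool(
                protein=pool.protein,
                synthesis_rate=pool.synthesis_rate * f_s,
                clearance_rate=pool.clearance_rate * f_k,
                initial_pool=pool.initial_pool,
                transit_delay_h=pool.transit_delay_h,
                origin=pool.origin,
                peptide_id=pool.peptide_id,
            )
            pools_i.append(pool_i)
            truth["subjects"][subj][pool_i.label] = {
                "synthesis_rate": pool_i.synthesis_rate,
                "clearance_rate": pool_i.clearance_rate,
                "initial_pool": pool_i.a0,
                "true_fsr_pct_per_h": pool_i.true_fsr_pct_per_h,
                "true_fcr_per_h": pool_i.clearance_rate,
                "origin": pool_i.origin,
            }
        subj_pools[subj] = pools_i
        mean_synthesis[subj] = float(np.mean([p.synthesis_rate for p in pools_i]))

    e_rows: dict[tuple[str, int], np.ndarray] = {}
    if config.compartments == "one":
        flat = [(subj, j, p) for subj in subjects for j, p in enumerate(subj_pools[subj])]
        e_all = _integrate_enrichment(
            [p.synthesis_rate for _, _, p in flat],
            [p.clearance_rate for _, _, p in flat],
            [p.a0 for _, _, p in flat],
            [p.transit_delay_h for _, _, p in flat],
            p_fn,
            config.sample_times_h,
            config.step_h,
        )
        for row, (subj, j, _) in zip(e_all, flat):
            e_rows[(subj, j)] = row

    for subj in subjects:
        for j, pool_i in enumerate(subj_pools[subj]):
            if config.compartments == "two":
                vent, lum = simulate_two_compartment(
                    pool_i, p_fn, config.sample_times_h, config.intercompartment_rate,
                    config.step_h, subject_id=subj, group=config.group,
                )
                series_list = [vent, lum]
            else:
                series_list = [
                    _series_from_e(
                        config.sample_times_h, e_rows[(subj, j)], subj, config.group,
                        config.compartment, pool_i.label,
                    )
                ]
            for s in series_list:
                csf_records.extend(
                    corrupt_series(s, rng, config.noise_cv, config.mean_total_area,
                                   protein=pool_i.protein)
                )

        # plasma leucine: the precursor curve itself, measured with the same noise
        plasma_e = np.asarray(p_fn(np.asarray(config.plasma_times_h)))
        plasma = _series_from_e(
            config.plasma_times_h, plasma_e, subj, Group_PLASMA, Compartment_PLASMA, "LEU"
        )
        plasma_records.extend(
            corrupt_series(plasma, rng, config.noise_cv, config.mean_total_area, protein="LEU")
        )

    production = None
    if config.production_coef_ml_per_amount is not None:
        rows = []
        for subj in subjects:
            noise = rng.normal(0.0, config.production_noise_sd) if config.production_noise_sd > 0 else 0.0
            rows.append(
                {
                    "subject_id": subj,
                    "production_ml_per_h": config.production_coef_ml_per_amount * mean_synthesis[subj]
                    + noise,
                }
            )
        production = pd.DataFrame(rows)

    files: dict[str, str] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_transition_report(csf_records, out / "transitions.csv")
        write_transition_report(plasma_records, out / "plasma.csv")
        truth_out = dict(truth)
        truth_out["config"] = _config_dict(config)
        with open(out / "truth.json", "w") as fh:
            json.dump(truth_out, fh, indent=2, sort_keys=True)
        files = {
            "transitions": str(out / "transitions.csv"),
            "plasma": str(out / "plasma.csv"),
            "truth": str(out / "truth.json"),
        }
        if production is not None:
            production.to_csv(out / "production.csv", index=False, float_format="%.9g")
            files["production"] = str(out / "production.csv")
    return CohortBundle(
        config=config,
        csf_records=csf_records,
        plasma_records=plasma_records,
        truth=truth,
        production=production,
        files=files,
    )


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["sample_times_h"] = list(config.sample_times_h)
    d["plasma_times_h"] = list(config.plasma_times_h)
    return d


# string constants used for plasma bookkeeping (values of the ingest enums)
Group_PLASMA = "plasma"
Compartment_PLASMA = "plasma"


def nph_vs_control_configs(
    seed: int = 0,
    n_nph: int = 8,
    n_control_v: int = 4,
    n_control_l: int = 5,
    nph_clearance: float = 0.002,
    control_clearance: float = 0.02,
    noise_cv: float = 0.05,
    between_subject_cv: float = 0.15,
    include_lumbar_controls: bool = True,
    production_coef: float | None = 1000.0,
) -> list[SimConfig]:
    """Study-like scenario: slow-clearing NPH arm vs ten-fold faster controls.

    Pools are steady-state transthyretin stand-ins (peptide ``TTHY_TSE``),
    so each arm's true FSR equals its clearance rate; the ten-fold clearance
    contrast is the mechanism under test.  Sub-seeds are derived from
    ``seed`` so arms are independent but jointly reproducible.
    """
    def pool(kc: float) -> ProteinPool:
        return ProteinPool("TTHY", synthesis_rate=kc, clearance_rate=kc, peptide_id="TTHY_TSE")

    configs = [
        SimConfig(
            group="NPH",
            compartment="lumbar",
            n_subjects=n_nph,
            pools=[pool(nph_clearance)],
            sample_times_h=EXTENDED_CSF_TIMES,
            noise_cv=noise_cv,
            between_subject_cv=between_subject_cv,
            seed=seed * 3 + 1,
            subject_prefix="NPH",
            production_coef_ml_per_amount=production_coef,
        ),
        SimConfig(
            group="control_ventricular",
            compartment="ventricular",
            n_subjects=n_control_v,
            pools=[pool(control_clearance)],
            noise_cv=noise_cv,
            between_subject_cv=between_subject_cv,
            seed=seed * 3 + 2,
            subject_prefix="CTV",
        ),
    ]
    if include_lumbar_controls:
        configs.append(
            SimConfig(
                group="control_lumbar",
                compartment="lumbar",
                n_subjects=n_control_l,
                pools=[pool(control_clearance)],
                noise_cv=noise_cv,
                between_subject_cv=between_subject_cv,
                seed=seed * 3 + 3,
                subject_prefix="CTL",
            )
        )
    return configs
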