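"""End-to-end orchestration: simulate -> fit -> compare, with run manifests.

These functions back the command-line interface but are equally usable from
Python.  Every stage writes diff-able CSVs (fixed column order, 9
significant digits) plus a JSON manifest recording the configuration
digest, input/output file digests, software version, timestamps and
per-stage record/exclusion counts.  All CSV outputs are deterministic given
the inputs and seed; only manifest timestamps vary between identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ChpSilkError, ValidationError
from .ingest import build_series, read_transition_report, series_to_frame
from .kinetics import KineticFitConfig, fit_subject, results_to_frame
from .precursor import PrecursorProfile, plateau_enrichment, surrogate_plateau
from .simulate import SimConfig, make_cohort
from .stats import compare_groups

__all__ = ["run_simulate", "run_fit", "run_compare", "write_manifest", "file_digest"]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.9g"


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Path, stage: str, config: dict, inputs: list[str],
                   outputs: list[str], counts: dict) -> Path:
    manifest = {
        "stage": stage,
        "software": {"package": "chpsilk", "version": __version__},
        "timestamp_unix": time.time(),
        "config": config,
        "config_digest": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {str(p): file_digest(p) for p in inputs},
        "outputs": {str(p): file_digest(p) for p in outputs},
        "counts": counts,
    }
    path = out_dir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path


def run_simulate(configs: list[SimConfig], out_dir: str | Path) -> dict:
    """Simulate one or more cohorts into ``out_dir`` (one subdirectory per group)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    counts: dict = {}
    for cfg in configs:
        t0 = time.perf_counter()
        bundle = make_cohort(cfg, out / cfg.group)
        outputs.extend(bundle.files.values())
        counts[cfg.group] = {
            "n_subjects": cfg.n_subjects,
            "csf_records": len(bundle.csf_records),
            "plasma_records": len(bundle.plasma_records),
        }
        logger.info("simulated %s (%d subjects) in %.2f s", cfg.group, cfg.n_subjects,
                    time.perf_counter() - t0)
    from .simulate import _config_dict

    write_manifest(out, "simulate", {"cohorts": [_config_dict(c) for c in configs]}, [], outputs, counts)
    return counts


def _plasma_profiles(plasma_records, infusion_end_h: float) -> dict[str, PrecursorProfile]:
    bundle = build_series(plasma_records)
    profiles: dict[str, PrecursorProfile] = {}
    for s in bundle.series:
        if s.compartment != "plasma":
            continue
        try:
            profiles[s.subject_id] = plateau_enrichment(
                s.points, "auto", infusion_end_h=infusion_end_h, subject_id=s.subject_id
            )
        except ChpSilkError as exc:
            logger.warning("plateau estimation failed for %s: %s", s.subject_id, exc)
    return profiles


def run_fit(
    transitions_path: str | Path,
    plasma_path: str | Path | None,
    out_dir: str | Path,
    infusion_end_h: float = 9.0,
    fit_config: KineticFitConfig = KineticFitConfig(),
    surrogate: str = "off",  # off | missing_only | all
) -> pd.DataFrame:
    """Ingest transition reports, estimate plateaus, fit turnover rates.

    ``surrogate`` controls the plateau used when a subject lacks a steady
    plasma plateau: ``off`` drops the subject's FSR, ``missing_only``
    substitutes the best steady profile only where needed, ``all`` applies
    one surrogate plateau to the whole cohort (the convention used when
    infusion durations vary too much for per-subject plateaus).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    records = read_transition_report(transitions_path)
    bundle = build_series([r for r in records if r.compartment != "plasma"])

    profiles: dict[str, PrecursorProfile] = {}
    surrogate_profile: PrecursorProfile | None = None
    inputs = [transitions_path]
    if plasma_path is not None:
        plasma_records = read_transition_report(plasma_path)
        profiles = _plasma_profiles(plasma_records, infusion_end_h)
        inputs.append(plasma_path)
        if surrogate in ("missing_only", "all") and profiles:
            surrogate_profile = surrogate_plateau(profiles.values())
    elif surrogate != "off" or fit_config.precursor_convention == "plateau":
        raise ValidationError(
            "no plasma file given: supply one, or use precursor_convention='unity'"
        )

    results = []
    skipped: list[str] = []
    by_subject: dict[str, list] = {}
    for s in bundle.series:
        by_subject.setdefault(s.subject_id, []).append(s)
    for subject in sorted(by_subject):
        if fit_config.precursor_convention == "unity":
            plateau = 1.0
        elif surrogate == "all" and surrogate_profile is not None:
            plateau = _as_surrogate(surrogate_profile, subject)
        elif subject in profiles:
            plateau = profiles[subject]
        elif surrogate == "missing_only" and surrogate_profile is not None:
            plateau = _as_surrogate(surrogate_profile, subject)
        else:
            skipped.append(subject)
            logger.warning("subject %s has no plasma plateau and surrogate is off; skipped", subject)
            continue
        results.extend(fit_subject(by_subject[subject], plateau, fit_config))

    group_map = {s.subject_id: s.group for s in bundle.series}
    rates = results_to_frame(results, group=group_map)
    rates_path = out / "rates.csv"
    rates.to_csv(rates_path, index=False, float_format=FLOAT_FMT)
    series_path = out / "series.csv"
    series_to_frame(bundle.series).to_csv(series_path, index=False, float_format=FLOAT_FMT)

    if profiles:
        plateau_rows = [
            {
                "subject_id": p.subject_id,
                "plateau_mole_fraction": p.plateau_mole_fraction,
                "window_start_h": p.plateau_window_h[0],
                "window_end_h": p.plateau_window_h[1],
                "plateau_cv": p.plateau_cv,
                "surrogate_of": p.surrogate_of or "",
            }
            for p in profiles.values()
        ]
        pd.DataFrame(plateau_rows).to_csv(out / "plateaus.csv", index=False, float_format=FLOAT_FMT)

    counts = {
        "transition_records": len(records),
        "series": len(bundle.series),
        "points_dropped_nonpositive": bundle.n_dropped_nonpositive,
        "series_omitted_empty": len(bundle.omitted_empty),
        "subjects_skipped_no_plateau": skipped,
        "rates_rows": len(rates),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    cfg_dict = {
        "infusion_end_h": infusion_end_h,
        "surrogate": surrogate,
        "fit_config": vars(fit_config).copy(),
    }
    outputs = [rates_path, series_path] + ([out / "plateaus.csv"] if profiles else [])
    write_manifest(out, "fit", cfg_dict, [str(p) for p in inputs], [str(p) for p in outputs], counts)
    return rates


def _as_surrogate(profile: PrecursorProfile, subject: str) -> PrecursorProfile:
    if profile.subject_id == subject:
        return profile
    clone = PrecursorProfile(
        subject_id=profile.subject_id,
        points=profile.points,
        plateau_mole_fraction=profile.plateau_mole_fraction,
        plateau_window_h=profile.plateau_window_h,
        plateau_cv=profile.plateau_cv,
        surrogate_of=subject,
    )
    return clone


def format_comparison_report(comparisons: pd.DataFrame, correlations: pd.DataFrame) -> str:
    """Figure-legend-style text summary: ``U = ..., P = ...`` per peptide/quantity."""
    lines = ["Group comparisons (Mann-Whitney U)", "=" * 40]
    for _, row in comparisons.iterrows():
        if row["method"] == "skipped_empty_group":
            lines.append(
                f"{row['peptide_id']} {row['quantity']}: {row['group_a']} vs {row['group_b']} "
                "skipped (empty group after exclusions)"
            )
            continue
        lines.append(
            f"{row['peptide_id']} {row['quantity']}: {row['group_a']} (n={row['n_a']}) vs "
            f"{row['group_b']} (n={row['n_b']}): U = {row['statistic']:g}, P = {row['p']:.3f} "
            f"[{row['method']}]"
        )
    if len(correlations):
        lines += ["", "Spearman correlations (FSR vs CSF production)", "=" * 40]
        for _, row in correlations.iterrows():
            lines.append(
                f"{row['peptide_id']}: n = {row['n']}, rho = {row['rho']:.3f}, "
                f"P = {row['p']:.3f} [{row['method']}]"
            )
    return "\n".join(lines) + "\n"


def run_compare(
    rates_paths: list[str | Path],
    out_dir: str | Path,
    production_path: str | Path | None = None,
    quantities: tuple[str, ...] = ("fsr_pct_per_h", "fcr_per_h"),
    seed: int = 0,
    holm: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenate rates tables and run the group comparison report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rates = pd.concat([pd.read_csv(p) for p in rates_paths], ignore_index=True)
    production = pd.read_csv(production_path) if production_path is not None else None
    comparisons, correlations = compare_groups(
        rates, quantities=quantities, production=production, seed=seed, holm=holm
    )
    comp_path = out / "comparisons.csv"
    comparisons.to_csv(comp_path, index=False, float_format=FLOAT_FMT)
    corr_path = out / "correlations.csv"
    correlations.to_csv(corr_path, index=False, float_format=FLOAT_FMT)
    report = format_comparison_report(comparisons, correlations)
    report_path = out / "summary.txt"
    report_path.write_text(report)
    inputs = [str(p) for p in rates_paths] + ([str(production_path)] if production_path else [])
    write_manifest(
        out,
        "compare",
        {"quantities": list(quantities), "seed": seed, "holm": holm},
        inputs,
        [str(comp_path), str(corr_path), str(report_path)],
        {"comparisons": len(comparisons), "correlations": len(correlations)},
    )
    return comparisons, correlations
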