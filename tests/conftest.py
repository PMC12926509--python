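import numpy as np
import pytest

from chpsilk.ingest import EnrichmentPoint, EnrichmentSeries, TransitionRecord
from chpsilk.simulate import InfusionSchedule, PrecursorModel, make_precursor_fn


def make_series(times, fractions, subject="S1", group="NPH", compartment="lumbar",
                peptide="TTHY_TSE"):
    pts = [
        EnrichmentPoint(time_h=float(t), ttr=float(f / (1 - f)), mole_fraction=float(f))
        for t, f in zip(times, fractions)
    ]
    return EnrichmentSeries(subject, group, compartment, peptide, pts)


def make_record(**kw):
    defaults = dict(
        sample_id="s1", subject_id="S1", group="NPH", compartment="lumbar",
        time_h=0.0, protein="TTHY", peptide_id="TTHY_TSE", channel="labeled",
        peak_area=1000.0,
    )
    defaults.update(kw)
    return TransitionRecord(**defaults)


@pytest.fixture
def default_precursor_fn():
    return make_precursor_fn(PrecursorModel(), InfusionSchedule())


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
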