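"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from nirscreen.decision_eval import loso_cross_validate
from nirscreen.spectral_core import (
    CocaineForm,
    SampleMeta,
    Spectrum,
    WavelengthGrid,
    build_library,
)
from nirscreen.synthetic_data import (
    LibraryDesign,
    MeasurementModel,
    SampleDesign,
    benchmark_design,
    generate_library,
    make_component_signature,
)


@pytest.fixture(scope="session")
def grid() -> WavelengthGrid:
    return WavelengthGrid()


@pytest.fixture(scope="session")
def benchmark_generated():
    """The frozen benchmark library (generated once per session)."""
    return generate_library(benchmark_design())


@pytest.fixture(scope="session")
def benchmark_library(benchmark_generated):
    return benchmark_generated.to_library()


@pytest.fixture(scope="session")
def benchmark_cv(benchmark_library):
    """One full leave-one-sample-out evaluation of the frozen benchmark."""
    return loso_cross_validate(benchmark_library, seed=1)


@pytest.fixture(scope="session")
def tiny_design() -> LibraryDesign:
    """A fast 8-sample design with two random components for smoke tests."""
    comps = {
        "alpha": make_component_signature("alpha", seed=11),
        "beta": make_component_signature("beta", seed=23),
        "cocaine_hcl": make_component_signature("cocaine_hcl", seed=5),
        "cocaine_base": make_component_signature("cocaine_base", seed=17),
    }
    samples = []
    for wt in (80, 60, 40, 0):
        frac = wt / 100.0
        comp = {"cocaine_hcl": frac, "alpha": 1 - frac} if frac else {"alpha": 1.0}
        samples.append(SampleDesign(f"hcl-{wt}", comp, "REF"))
    for wt in (90, 50):
        frac = wt / 100.0
        samples.append(
            SampleDesign(f"base-{wt}", {"cocaine_base": frac, "beta": 1 - frac}, "A")
        )
    samples.append(SampleDesign("beta-pure", {"beta": 1.0}, "B"))
    samples.append(SampleDesign("mix", {"alpha": 0.5, "beta": 0.5}, "B"))
    return LibraryDesign(
        components=comps,
        samples=tuple(samples),
        n_scanners=2,
        replicates_per_scanner=3,
        measurement=MeasurementModel(),
        seed=99,
    )


@pytest.fixture()
def toy_library():
    """Four hand-built scans over two samples on the standard grid."""
    g = WavelengthGrid()
    lam = g.wavelengths
    base = 1.0 + 0.5 * np.exp(-((lam - 900.0) ** 2) / (2 * 30.0**2))
    other = 1.0 + 0.8 * np.exp(-((lam - 800.0) ** 2) / (2 * 20.0**2))
    scans = [
        Spectrum("s1.a", "S1", "sc1", 1, base),
        Spectrum("s1.b", "S1", "sc1", 2, 2.0 * base + 0.3),
        Spectrum("s2.a", "S2", "sc1", 1, other),
        Spectrum("s2.b", "S2", "sc2", 1, 1.5 * other - 0.1),
    ]
    meta = [
        SampleMeta("S1", "cocaine HCl", CocaineForm.HCL, 86.6, "A"),
        SampleMeta("S2", "levamisole", CocaineForm.NONE, 0.0, "B"),
    ]
    return build_library(scans, meta)
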