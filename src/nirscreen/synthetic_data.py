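"""Seeded simulator of handheld NIR powder spectra.

The original 10,059-scan casework dataset is not public, so every model
in this package is exercised on synthetic spectra that emulate its
*measurement physics* rather than its chemistry:

* each pure component is a smooth, strictly positive **signature** on the
  740-1070 nm grid — a gentle sloping baseline plus a few Gaussian
  absorption-like bands (overtone features in this window are broad and
  weak);
* a powder mixture reflects the **linear (Beer-Lambert-like) combination**
  of its components' signatures, weighted by mass fraction;
* each recorded scan is distorted by a per-scan **multiplicative scatter
  factor** (log-normal; particle-size effects), a per-scanner plus
  per-scan **additive baseline offset** (vial positioning, electronics),
  and i.i.d. per-wavelength noise — exactly the artifact family that SNV
  preprocessing is meant to cancel;
* optionally a small fraction of scans is **spike-corrupted** (a large
  offset over a random 20-point window) to exercise replicate-outlier
  flagging; the generator records which scans it corrupted.

Every draw flows from a single integer seed, so identical designs yield
byte-identical scan tables.  The frozen :func:`benchmark_design` mirrors
the study's sample plan at desk scale: cocaine-HCl and cocaine-base
dilution ladders in common cutting agents (including the published
42/34/30/25/20/19/10/5/0 wt% caffeine series), pure negative components,
and equal-weight binary negative mixtures, scanned on 5 scanners with 5
replicates each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .spectral_core import (
    CocaineForm,
    LabeledLibrary,
    SampleMeta,
    Spectrum,
    WavelengthGrid,
    build_library,
)

__all__ = [
    "ComponentSignature",
    "MeasurementModel",
    "SampleDesign",
    "LibraryDesign",
    "GeneratedLibrary",
    "make_component_signature",
    "simulate_scan",
    "generate_library",
    "benchmark_components",
    "benchmark_design",
    "novel_component_signature",
]

COCAINE_COMPONENTS = {"cocaine_hcl": CocaineForm.HCL, "cocaine_base": CocaineForm.BASE}


@dataclass(frozen=True)
class ComponentSignature:
    """Synthetic pure-compound reflectance signature.

    ``baseline_offset + baseline_slope * (lambda - 740) +
    sum_i amp_i * exp(-(lambda - center_i)^2 / (2 width_i^2))``,
    required to be strictly positive over the grid.
    """

    name: str
    band_centers: tuple[float, ...]
    band_widths: tuple[float, ...]
    band_amplitudes: tuple[float, ...]
    baseline_slope: float = 0.0
    baseline_offset: float = 1.0

    def __post_init__(self) -> None:
        if not (
            len(self.band_centers)
            == len(self.band_widths)
            == len(self.band_amplitudes)
        ):
            raise ValueError("band parameter tuples must have equal length")

    def evaluate(self, grid: WavelengthGrid | None = None) -> np.ndarray:
        if grid is None:
            grid = WavelengthGrid()
        lam = grid.wavelengths
        for c in self.band_centers:
            if not grid.start_nm <= c <= grid.end_nm:
                raise ValueError(
                    f"signature {self.name!r}: band centre {c} nm outside grid"
                )
        y = self.baseline_offset + self.baseline_slope * (lam - grid.start_nm)
        for c, w, a in zip(
            self.band_centers, self.band_widths, self.band_amplitudes
        ):
            y = y + a * np.exp(-((lam - c) ** 2) / (2.0 * w**2))
        if np.any(y <= 0):
            raise ValueError(f"signature {self.name!r} not strictly positive")
        return y


def make_component_signature(
    name: str,
    seed: int | None = None,
    n_bands: int | None = None,
    grid: WavelengthGrid | None = None,
) -> ComponentSignature:
    """Draw a random smooth positive signature (3-8 bands, 10-60 nm wide).

    Deterministic for a given seed; the bands are kept inside the grid
    with a margin so the full feature is observed.
    """
    if grid is None:
        grid = WavelengthGrid()
    rng = np.random.default_rng(seed)
    if n_bands is None:
        n_bands = int(rng.integers(3, 9))
    if not 3 <= n_bands <= 8:
        raise ValueError("n_bands must be within 3..8")
    centers = tuple(
        float(c)
        for c in np.sort(
            rng.uniform(grid.start_nm + 25.0, grid.end_nm - 25.0, size=n_bands)
        )
    )
    widths = tuple(float(w) for w in rng.uniform(10.0, 60.0, size=n_bands))
    amps = tuple(float(a) for a in rng.uniform(0.25, 1.0, size=n_bands))
    slope = float(rng.uniform(-4e-4, 4e-4))
    sig = ComponentSignature(
        name=name,
        band_centers=centers,
        band_widths=widths,
        band_amplitudes=amps,
        baseline_slope=slope,
        baseline_offset=1.0,
    )
    sig.evaluate(grid)  # validates positivity and band placement
    return sig


@dataclass(frozen=True)
class MeasurementModel:
    """Per-scan distortion parameters of the simulated instrument.

    ``scatter_sd`` is the log-SD of the multiplicative factor ``a``
    (always positive), ``offset_sd`` the SD of the per-scan additive
    offset, ``scanner_offset_sd`` the SD of a systematic per-scanner
    offset component, and ``noise_sd`` the SD of i.i.d. per-wavelength
    noise, all in raw reflectance units relative to signatures of order 1.
    """

    scatter_sd: float = 0.15
    offset_sd: float = 0.10
    scanner_offset_sd: float = 0.15
    noise_sd: float = 0.002

    def __post_init__(self) -> None:
        for name in ("scatter_sd", "offset_sd", "scanner_offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_scan(
    composition: Mapping[str, float],
    signatures: Mapping[str, ComponentSignature],
    model: MeasurementModel,
    rng: np.random.Generator,
    scanner_offset: float = 0.0,
    grid: WavelengthGrid | None = None,
) -> np.ndarray:
    """One simulated raw spectrum of a powder mixture.

    ``values = a * sum_c fraction_c * signature_c + b_scanner + b_scan +
    noise`` with ``a`` log-normal and ``b_scan``/noise Gaussian, all drawn
    from ``rng``.  With a zero-spread model the output is the exact convex
    combination of the signatures.
    """
    if grid is None:
        grid = WavelengthGrid()
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-12:
        raise ValueError(f"composition fractions sum to {total}, not 1")
    mix = np.zeros(grid.n_points)
    for comp, frac in composition.items():
        if frac < 0:
            raise ValueError("negative mixing fraction")
        if frac:
            mix += frac * signatures[comp].evaluate(grid)
    a = float(np.exp(rng.normal(0.0, model.scatter_sd))) if model.scatter_sd else 1.0
    b = float(rng.normal(0.0, model.offset_sd)) if model.offset_sd else 0.0
    noise = (
        rng.normal(0.0, model.noise_sd, size=grid.n_points)
        if model.noise_sd
        else 0.0
    )
    return a * mix + scanner_offset + b + noise


@dataclass(frozen=True)
class SampleDesign:
    """One planned sample: mass fractions over the design's components."""

    sample_id: str
    composition: Mapping[str, float]
    set_tag: str = "A"

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(
                f"sample {self.sample_id}: fractions sum to {total}, not 1"
            )
        cocaine = [c for c in self.composition if c in COCAINE_COMPONENTS]
        if len(cocaine) > 1:
            raise ValueError(
                f"sample {self.sample_id}: more than one cocaine component"
            )

    @property
    def cocaine_component(self) -> str | None:
        for c, f in self.composition.items():
            if c in COCAINE_COMPONENTS and f > 0:
                return c
        return None

    @property
    def cocaine_wt_pct(self) -> float:
        c = self.cocaine_component
        return 100.0 * self.composition[c] if c else 0.0

    @property
    def cocaine_form(self) -> CocaineForm:
        c = self.cocaine_component
        return COCAINE_COMPONENTS[c] if c else CocaineForm.NONE

    @property
    def identity(self) -> str:
        """Composition label: components by descending mass fraction."""
        parts = sorted(
            ((f, c) for c, f in self.composition.items() if f > 0),
            key=lambda t: (-t[0], t[1]),
        )
        return ":".join(c for _, c in parts)

    def to_meta(self) -> SampleMeta:
        return SampleMeta(
            sample_id=self.sample_id,
            identity=self.identity,
            cocaine_form=self.cocaine_form,
            cocaine_wt_pct=self.cocaine_wt_pct,
            set_tag=self.set_tag,
        )


@dataclass(frozen=True)
class LibraryDesign:
    """Full replicate-scan experiment plan, reproducible from its seed."""

    components: Mapping[str, ComponentSignature]
    samples: tuple[SampleDesign, ...]
    n_scanners: int = 5
    replicates_per_scanner: int = 5
    measurement: MeasurementModel = field(default_factory=MeasurementModel)
    outlier_rate: float = 0.0
    spike_window: int = 20
    spike_magnitude: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scanners < 1 or self.replicates_per_scanner < 1:
            raise ValueError("need >= 1 scanner and >= 1 replicate")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must be in [0, 1)")
        for s in self.samples:
            for comp in s.composition:
                if comp not in self.components:
                    raise KeyError(
                        f"sample {s.sample_id} uses unknown component {comp!r}"
                    )


@dataclass
class GeneratedLibrary:
    """Generator output: scans, metadata, and injected-corruption truth."""

    scans: list[Spectrum]
    meta: list[SampleMeta]
    corrupted_scan_ids: list[str]
    design: LibraryDesign

    def to_library(self) -> LabeledLibrary:
        return build_library(self.scans, self.meta)


def generate_library(design: LibraryDesign) -> GeneratedLibrary:
    """Simulate every planned scan; deterministic for a given design.

    Scanner offsets are drawn once per scanner (systematic inter-device
    baseline shift); each scan then receives its own scatter factor,
    offset and noise.  When ``outlier_rate > 0``, each scan is
    independently spike-corrupted with that probability — a random
    ``spike_window``-point stretch is displaced by a large offset — and
    the corrupted scan ids are recorded as ground truth.
    """
    rng = np.random.default_rng(design.seed)
    grid = WavelengthGrid()
    scanner_ids = [f"scanner{k + 1:02d}" for k in range(design.n_scanners)]
    scanner_offsets = {
        sid: (
            float(rng.normal(0.0, design.measurement.scanner_offset_sd))
            if design.measurement.scanner_offset_sd
            else 0.0
        )
        for sid in scanner_ids
    }
    scans: list[Spectrum] = []
    corrupted: list[str] = []
    for sample in design.samples:
        for sid in scanner_ids:
            for rep in range(1, design.replicates_per_scanner + 1):
                values = simulate_scan(
                    sample.composition,
                    design.components,
                    design.measurement,
                    rng,
                    scanner_offset=scanner_offsets[sid],
                    grid=grid,
                )
                scan_id = f"{sample.sample_id}.{sid}.r{rep}"
                if design.outlier_rate and rng.random() < design.outlier_rate:
                    start = int(
                        rng.integers(0, grid.n_points - design.spike_window)
                    )
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    values = values.copy()
                    values[start : start + design.spike_window] += (
                        sign
                        * design.spike_magnitude
                        * float(rng.uniform(0.8, 1.2))
                    )
                    corrupted.append(scan_id)
                scans.append(
                    Spectrum(
                        scan_id=scan_id,
                        sample_id=sample.sample_id,
                        scanner_id=sid,
                        replicate_index=rep,
                        values=values,
                    )
                )
    meta = [s.to_meta() for s in design.samples]
    return GeneratedLibrary(
        scans=scans, meta=meta, corrupted_scan_ids=corrupted, design=design
    )


# ---------------------------------------------------------------------------
# Frozen benchmark: signatures and sample plan
# ---------------------------------------------------------------------------

# Hand-laid band layouts.  Amplitudes and centre layouts were chosen once so
# that (a) all pairwise SNV + first-derivative distances between pure
# signatures clearly exceed the 0.1 matching threshold, (b) the two cocaine
# forms differ inside the 839-939 nm region of interest, and (c) mixture
# spectra move smoothly with composition so dilution ladders form usable
# nearest-neighbour chains.
_BENCHMARK_BANDS: dict[str, tuple[tuple[float, float, float], ...]] = {
    # (centre nm, width nm, amplitude)
    "cocaine_hcl": ((790, 18, 0.55), (862, 14, 0.95), (905, 16, 0.70), (1015, 30, 0.45)),
    "cocaine_base": ((775, 20, 0.50), (848, 13, 0.85), (926, 15, 0.90), (990, 25, 0.40)),
    "caffeine": ((805, 24, 0.70), (885, 22, 0.55), (968, 20, 0.75)),
    "lactose": ((768, 16, 0.60), (844, 28, 0.45), (952, 18, 0.85), (1040, 22, 0.50)),
    "levamisole": ((782, 14, 0.80), (876, 18, 0.95), (1002, 26, 0.60)),
    "phenacetin": ((798, 22, 0.45), (858, 12, 0.70), (935, 24, 0.65), (1028, 18, 0.80)),
    "lidocaine": ((815, 18, 0.85), (898, 26, 0.50), (978, 14, 0.70)),
    "inositol": ((772, 26, 0.55), (852, 20, 0.60), (916, 12, 0.85), (1048, 16, 0.45)),
    "mannitol": ((788, 12, 0.65), (870, 24, 0.75), (944, 16, 0.55), (1010, 20, 0.70)),
    "paracetamol": ((808, 16, 0.90), (890, 14, 0.60), (960, 28, 0.45), (1035, 14, 0.65)),
}

_BENCHMARK_SLOPES: dict[str, float] = {
    "cocaine_hcl": 2.0e-4,
    "cocaine_base": -1.5e-4,
    "caffeine": 1.0e-4,
    "lactose": -2.0e-4,
    "levamisole": 3.0e-4,
    "phenacetin": -1.0e-4,
    "lidocaine": 1.5e-4,
    "inositol": -2.5e-4,
    "mannitol": 0.5e-4,
    "paracetamol": 2.5e-4,
}


# Broad overtone-like bands shared by every powder (common O-H/C-H matrix
# structure).  The shared part raises the shape similarity of all spectra,
# so composition changes move spectra gently: a ~5-8 wt% dilution step stays
# inside the 0.1 distance threshold while distinct pure compounds stay far
# outside it.
_COMMON_BANDS: tuple[tuple[float, float, float], ...] = (
    (858.0, 48.0, 2.2),
    (978.0, 55.0, 1.8),
)


def _signature_from_bands(name: str) -> ComponentSignature:
    bands = _COMMON_BANDS + _BENCHMARK_BANDS[name]
    return ComponentSignature(
        name=name,
        band_centers=tuple(b[0] for b in bands),
        band_widths=tuple(b[1] for b in bands),
        band_amplitudes=tuple(b[2] for b in bands),
        baseline_slope=_BENCHMARK_SLOPES[name],
        baseline_offset=1.0,
    )


def benchmark_components() -> dict[str, ComponentSignature]:
    """The frozen pure-component signatures of the benchmark library."""
    return {name: _signature_from_bands(name) for name in _BENCHMARK_BANDS}


def novel_component_signature() -> ComponentSignature:
    """A frozen signature deliberately absent from the benchmark library.

    Used to probe abstention: it shares the common powder-matrix bands
    (as any new cutting agent would) but its specific band layout matches
    no benchmark component, so the nearest-neighbour stage finds nothing
    within its thresholds for these scans.
    """
    bands = _COMMON_BANDS + ((825.0, 14.0, 0.8), (942.0, 18.0, 0.75), (1055.0, 16.0, 0.5))
    return ComponentSignature(
        name="novel_cutting_agent",
        band_centers=tuple(b[0] for b in bands),
        band_widths=tuple(b[1] for b in bands),
        band_amplitudes=tuple(b[2] for b in bands),
        baseline_slope=1.0e-4,
        baseline_offset=1.0,
    )


# Dilution ladders: (cocaine component, diluent, wt% levels).  The caffeine
# ladder reproduces the published reference series levels.
_LADDERS: tuple[tuple[str, str, tuple[float, ...]], ...] = (
    ("cocaine_hcl", "caffeine", (42, 34, 30, 25, 20, 19, 10, 5, 0)),
    ("cocaine_hcl", "lactose", (81, 76, 44, 33, 17, 9, 0)),
    ("cocaine_hcl", "phenacetin", (73, 50, 35, 21, 13, 5, 0)),
    ("cocaine_base", "levamisole", (99, 90, 75, 60, 45, 31, 0)),
    ("cocaine_base", "lidocaine", (95, 80, 65, 50, 40, 31, 0)),
)

# Pure negative components; repeated entries are independent preparations
# of the same material (real negative sets routinely contain duplicates).
_PURE_NEGATIVES: tuple[tuple[str, int], ...] = (
    ("caffeine", 1),
    ("lactose", 1),
    ("levamisole", 1),
    ("phenacetin", 1),
    ("lidocaine", 1),
    ("inositol", 2),
    ("mannitol", 2),
    ("paracetamol", 2),
)

# Equal-weight binary negative mixtures, two preparations each.
_NEGATIVE_MIXTURES: tuple[tuple[str, str], ...] = (
    ("levamisole", "phenacetin"),
    ("phenacetin", "lidocaine"),
    ("paracetamol", "caffeine"),
    ("lactose", "mannitol"),
    ("inositol", "caffeine"),
    ("levamisole", "lidocaine"),
)

#: Frozen generator seed of the benchmark (study-conditions constant).
BENCHMARK_SEED = 20200727


def benchmark_samples() -> tuple[SampleDesign, ...]:
    """The frozen 60-sample plan of the synthetic benchmark."""
    samples: list[SampleDesign] = []
    for cocaine, diluent, levels in _LADDERS:
        tag = "REF" if diluent == "caffeine" else "A"
        for wt in levels:
            frac = wt / 100.0
            comp = {cocaine: frac, diluent: 1.0 - frac} if frac else {diluent: 1.0}
            samples.append(
                SampleDesign(
                    sample_id=f"{cocaine}-{diluent}-{wt:g}",
                    composition=comp,
                    set_tag=tag,
                )
            )
    samples.append(
        SampleDesign(
            sample_id="cocaine_hcl-pure-100",
            composition={"cocaine_hcl": 1.0},
            set_tag="REF",
        )
    )
    for comp_name, n_prep in _PURE_NEGATIVES:
        for p in range(1, n_prep + 1):
            samples.append(
                SampleDesign(
                    sample_id=f"{comp_name}-pure-{p}",
                    composition={comp_name: 1.0},
                    set_tag="B",
                )
            )
    for a, b in _NEGATIVE_MIXTURES:
        for p in (1, 2):
            samples.append(
                SampleDesign(
                    sample_id=f"{a}-{b}-mix-{p}",
                    composition={a: 0.5, b: 0.5},
                    set_tag="B",
                )
            )
    return tuple(samples)


def benchmark_design(
    seed: int = BENCHMARK_SEED,
    outlier_rate: float = 0.0,
    measurement: MeasurementModel | None = None,
) -> LibraryDesign:
    """The frozen desk-scale benchmark: 60 samples x 5 scanners x 5 scans.

    ``seed`` only re-randomises the measurement noise; the sample plan and
    signatures are fixed.  ``outlier_rate`` enables spike corruption for
    outlier-flagging studies.
    """
    return LibraryDesign(
        components=benchmark_components(),
        samples=benchmark_samples(),
        n_scanners=5,
        replicates_per_scanner=5,
        measurement=measurement or MeasurementModel(),
        outlier_rate=outlier_rate,
        seed=seed,
    )
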