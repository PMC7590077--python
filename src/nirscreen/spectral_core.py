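"""Data model and tabular I/O for handheld NIR powder scans.

A *scan* is a single diffuse-reflectance spectrum recorded on the fixed
740-1070 nm, 1 nm grid (331 points).  Scans carry identifiers linking them
to a physical *sample* (the vial of powder) and to the scanner that
recorded them; sample-level ground truth (composition identity, cocaine
form, cocaine weight percent) lives in a separate metadata table.  A
:class:`LabeledLibrary` joins the two into the aligned matrix + metadata
container that every downstream model operates on.

File formats are plain CSV: scan tables are wide (one row per scan,
reflectance columns named ``w740`` .. ``w1070``), metadata tables are one
row per sample.  Round-trips are value-preserving.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "CocaineForm",
    "SampleMeta",
    "LabeledLibrary",
    "GridMismatchError",
    "read_scans",
    "write_scans",
    "read_sample_metadata",
    "write_sample_metadata",
    "build_library",
]

_WAVELENGTH_COL = re.compile(r"^w(\d+(?:\.\d+)?)$")


class GridMismatchError(ValueError):
    """Raised when a scan table's wavelength columns do not form a valid grid."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nm.

    The default is the 740-1070 nm range at 1 nm spacing (331 points) of the
    handheld sensor.  The grid is carried explicitly through preprocessing
    (derivative filters shrink it, region-of-interest selection crops it) so
    that no resampling ever happens silently.
    """

    start_nm: float = 740.0
    end_nm: float = 1070.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError("grid step must be positive")
        if self.end_nm <= self.start_nm:
            raise ValueError("grid must be strictly increasing")
        n = (self.end_nm - self.start_nm) / self.step_nm + 1.0
        if abs(n - round(n)) > 1e-9:
            raise GridMismatchError(
                f"grid {self.start_nm}-{self.end_nm} nm is not an integer "
                f"number of {self.step_nm} nm steps"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    def column_names(self) -> list[str]:
        return [_format_wavelength_col(w) for w in self.wavelengths]

    @classmethod
    def from_columns(cls, names: Sequence[str]) -> "WavelengthGrid":
        """Infer and validate a grid from ``w<nm>`` column headers."""
        waves = []
        for name in names:
            m = _WAVELENGTH_COL.match(name)
            if not m:
                raise GridMismatchError(f"column {name!r} is not a wavelength column")
            waves.append(float(m.group(1)))
        if len(waves) < 2:
            raise GridMismatchError("need at least two wavelength columns")
        arr = np.asarray(waves)
        steps = np.diff(arr)
        if np.any(steps <= 0):
            raise GridMismatchError("wavelength columns must be strictly increasing")
        if not np.allclose(steps, steps[0], atol=1e-9):
            raise GridMismatchError("wavelength columns are not uniformly spaced")
        grid = cls(start_nm=arr[0], end_nm=arr[-1], step_nm=float(steps[0]))
        if grid.n_points != len(waves):
            raise GridMismatchError(
                f"{len(waves)} wavelength columns inconsistent with grid "
                f"{grid.start_nm}-{grid.end_nm}/{grid.step_nm} nm "
                f"({grid.n_points} points expected)"
            )
        return grid


def _format_wavelength_col(w: float) -> str:
    return f"w{w:g}"


@dataclass
class Spectrum:
    """One scan: identifiers plus the reflectance vector on a grid."""

    scan_id: str
    sample_id: str
    scanner_id: str
    replicate_index: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError(f"scan {self.scan_id}: values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"scan {self.scan_id}: non-finite reflectance values")


class CocaineForm(str, Enum):
    """Salt form of cocaine in a sample; spectrally distinct classes."""

    HCL = "hcl"
    BASE = "base"
    NONE = "none"


@dataclass(frozen=True)
class SampleMeta:
    """Ground truth for one physical sample.

    ``identity`` is the composition label used for nearest-neighbour
    identity voting (e.g. ``"cocaine HCl:caffeine"`` or ``"levamisole"``);
    ``cocaine_wt_pct`` is the cocaine mass fraction in weight percent.
    """

    sample_id: str
    identity: str
    cocaine_form: CocaineForm
    cocaine_wt_pct: float
    set_tag: str = "A"

    def __post_init__(self) -> None:
        if not 0.0 <= self.cocaine_wt_pct <= 100.0:
            raise ValueError(
                f"sample {self.sample_id}: cocaine_wt_pct "
                f"{self.cocaine_wt_pct} outside [0, 100]"
            )
        if (self.cocaine_form is CocaineForm.NONE) != (self.cocaine_wt_pct == 0.0):
            raise ValueError(
                f"sample {self.sample_id}: cocaine_form={self.cocaine_form.value} "
                f"inconsistent with cocaine_wt_pct={self.cocaine_wt_pct} "
                "(form 'none' iff 0 wt%)"
            )


@dataclass
class LabeledLibrary:
    """Aligned scan matrix joined to sample metadata.

    ``matrix`` rows align with ``scan_meta`` rows (columns ``scan_id``,
    ``sample_id``, ``scanner_id``, ``replicate_index``); ``sample_meta``
    maps every referenced ``sample_id`` to its :class:`SampleMeta`.
    ``preprocess_tag`` records what has been applied to the matrix
    (``"raw"`` for untouched reflectance).
    """

    grid: WavelengthGrid
    matrix: np.ndarray
    scan_meta: pd.DataFrame
    sample_meta: dict[str, SampleMeta]
    preprocess_tag: str = "raw"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("library matrix must be 2-D")
        if self.matrix.shape[0] != len(self.scan_meta):
            raise ValueError("matrix rows and scan_meta rows misaligned")
        if self.matrix.shape[1] != self.grid.n_points:
            raise GridMismatchError(
                f"matrix width {self.matrix.shape[1]} != grid "
                f"n_points {self.grid.n_points}"
            )
        missing = set(self.scan_meta["sample_id"]) - set(self.sample_meta)
        if missing:
            raise KeyError(
                "scans reference samples without metadata: "
                + ", ".join(sorted(missing))
            )

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def scan_ids(self) -> np.ndarray:
        return self.scan_meta["scan_id"].to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        """Per-row sample id, aligned with matrix rows."""
        return self.scan_meta["sample_id"].to_numpy()

    def meta_for_row(self, row: int) -> SampleMeta:
        return self.sample_meta[self.scan_meta["sample_id"].iat[row]]

    def with_matrix(
        self, matrix: np.ndarray, grid: WavelengthGrid, preprocess_tag: str
    ) -> "LabeledLibrary":
        """New library with a transformed matrix but the same scan rows."""
        return LabeledLibrary(
            grid=grid,
            matrix=matrix,
            scan_meta=self.scan_meta.reset_index(drop=True),
            sample_meta=dict(self.sample_meta),
            preprocess_tag=preprocess_tag,
        )


_ID_COLUMNS = ["scan_id", "sample_id", "scanner_id", "replicate_index"]


def read_scans(
    path: str | Path, expected_grid: WavelengthGrid | None = WavelengthGrid()
) -> list[Spectrum]:
    """Read a wide-format scan table (CSV) into :class:`Spectrum` objects.

    The header must carry the identifier columns followed by wavelength
    columns named ``w<nm>``; the wavelength columns must form a valid
    uniform grid matching ``expected_grid`` (the 740-1070/1 nm sensor grid
    by default; pass ``None`` to accept any valid uniform grid, e.g. for
    resampled data).  Duplicate or missing ``scan_id`` values and
    non-numeric reflectance cells are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={c: str for c in _ID_COLUMNS[:3]},
        float_precision="round_trip",
    )
    for col in _ID_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    wave_cols = [c for c in df.columns if c not in _ID_COLUMNS]
    grid = WavelengthGrid.from_columns(wave_cols)
    if expected_grid is not None and grid != expected_grid:
        raise GridMismatchError(
            f"{path}: wavelength columns form grid {grid.start_nm}-"
            f"{grid.end_nm}/{grid.step_nm} nm ({grid.n_points} points), "
            f"expected {expected_grid.start_nm}-{expected_grid.end_nm}/"
            f"{expected_grid.step_nm} nm ({expected_grid.n_points} points)"
        )

    if df["scan_id"].isna().any():
        raise ValueError(f"{path}: missing scan_id")
    dup = df["scan_id"][df["scan_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated scan_id(s): {sorted(set(dup))}")

    values = df[wave_cols]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        row = int(np.argwhere(bad.to_numpy())[0][0])
        col = bad.columns[int(np.argwhere(bad.to_numpy())[0][1])]
        raise ValueError(
            f"{path}: non-numeric or missing reflectance at row "
            f"{row} (scan_id={df['scan_id'].iat[row]!r}), column {col!r}"
        )

    mat = numeric.to_numpy(dtype=float)
    return [
        Spectrum(
            scan_id=str(df["scan_id"].iat[i]),
            sample_id=str(df["sample_id"].iat[i]),
            scanner_id=str(df["scanner_id"].iat[i]),
            replicate_index=int(df["replicate_index"].iat[i]),
            values=mat[i],
        )
        for i in range(len(df))
    ]


def write_scans(
    path: str | Path, scans: Iterable[Spectrum], grid: WavelengthGrid | None = None
) -> None:
    """Write scans as a wide CSV; inverse of :func:`read_scans`."""
    scans = list(scans)
    if grid is None:
        grid = WavelengthGrid()
    cols = grid.column_names()
    rows = []
    for s in scans:
        if len(s.values) != grid.n_points:
            raise GridMismatchError(
                f"scan {s.scan_id}: {len(s.values)} values != grid "
                f"n_points {grid.n_points}"
            )
        rows.append(
            dict(
                scan_id=s.scan_id,
                sample_id=s.sample_id,
                scanner_id=s.scanner_id,
                replicate_index=s.replicate_index,
                **dict(zip(cols, s.values)),
            )
        )
    pd.DataFrame(rows, columns=_ID_COLUMNS + cols).to_csv(path, index=False)


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read the per-sample metadata table; consistency-checked records."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "identity": str, "set_tag": str})
    required = ["sample_id", "identity", "cocaine_form", "cocaine_wt_pct", "set_tag"]
    missing = [c for c in required if c not in df.columns]
    if missing and len(df.columns) and not df.empty:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        logger.warning("%s: empty sample metadata table", path)
        return []
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated sample_id(s): {sorted(set(dup))}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                identity=str(row["identity"]),
                cocaine_form=CocaineForm(str(row["cocaine_form"]).lower()),
                cocaine_wt_pct=float(row["cocaine_wt_pct"]),
                set_tag=str(row["set_tag"]),
            )
        )
    return records


def write_sample_metadata(path: str | Path, meta: Iterable[SampleMeta]) -> None:
    pd.DataFrame(
        [
            dict(
                sample_id=m.sample_id,
                identity=m.identity,
                cocaine_form=m.cocaine_form.value,
                cocaine_wt_pct=m.cocaine_wt_pct,
                set_tag=m.set_tag,
            )
            for m in meta
        ],
        columns=["sample_id", "identity", "cocaine_form", "cocaine_wt_pct", "set_tag"],
    ).to_csv(path, index=False)


def build_library(
    scans: Sequence[Spectrum],
    meta: Iterable[SampleMeta],
    grid: WavelengthGrid | None = None,
) -> LabeledLibrary:
    """Assemble scans + metadata into a raw :class:`LabeledLibrary`.

    Every scan's ``sample_id`` must resolve to exactly one metadata record;
    orphan scans are reported collectively.
    """
    if grid is None:
        grid = WavelengthGrid()
    meta_map = {m.sample_id: m for m in meta}
    orphans = sorted({s.scan_id for s in scans if s.sample_id not in meta_map})
    if orphans:
        raise KeyError(f"scans without sample metadata: {orphans}")
    if not scans:
        raise ValueError("cannot build a library from zero scans")
    matrix = np.vstack([s.values for s in scans])
    scan_meta = pd.DataFrame(
        {
            "scan_id": [s.scan_id for s in scans],
            "sample_id": [s.sample_id for s in scans],
            "scanner_id": [s.scanner_id for s in scans],
            "replicate_index": [s.replicate_index for s in scans],
        }
    )
    if scan_meta["scan_id"].duplicated().any():
        dups = scan_meta["scan_id"][scan_meta["scan_id"].duplicated()]
        raise ValueError(f"duplicated scan_id(s): {sorted(set(dups))}")
    used = set(scan_meta["sample_id"])
    return LabeledLibrary(
        grid=grid,
        matrix=matrix,
        scan_meta=scan_meta,
        sample_meta={sid: m for sid, m in meta_map.items() if sid in used},
        preprocess_tag="raw",
    )
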