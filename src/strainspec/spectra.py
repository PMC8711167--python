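"""Per-plaque composite spectral vectors.

Each plaque is imaged with three conformation-sensitive dyes (curcumin, FSB,
BF-188); every dye yields a 40-channel emission spectrum spanning 385-780 nm,
acquired with a sliding 15-nm detection window.  The analysis row unit is the
*composite vector*: the three per-dye spectra, each max-normalized, concatenated
in a fixed dye order (120 values by default).  To avoid biasing the eigenspace
toward heavily sampled patients, the number of composite vectors per patient is
capped (default 30) by uniform random subsampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_DYES: tuple[str, ...] = ("curcumin", "FSB", "BF-188")

META_COLUMNS = ["plaque_id", "patient_id", "cohort"]


class MissingCoverageError(ValueError):
    """A spectrum does not cover the target wavelength grid."""


class IncompletePlaqueError(ValueError):
    """A plaque is missing one or more required dye spectra."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Channel-center grid for emission spectra.

    40 channels evenly spaced on [385, 780] nm inclusive (step ~10.13 nm),
    each channel integrating a 15-nm-wide detection window.
    """

    n_channels: int = 40
    span: tuple[float, float] = (385.0, 780.0)
    window_width: float = 15.0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if not self.span[0] < self.span[1]:
            raise ValueError("span lower bound must be below upper bound")

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(self.span[0], self.span[1], self.n_channels)


@dataclass
class EmissionSpectrum:
    """One dye's emission trace for one plaque (arbitrary fluorescence units)."""

    dye: str
    wavelengths: np.ndarray
    intensities: np.ndarray
    #: set by :func:`normalize_max` when the raw spectrum was identically zero
    all_zero: bool = False

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must have equal length")
        if self.wavelengths.ndim != 1:
            raise ValueError("spectrum arrays must be 1-D")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass
class CompositeVector:
    """Concatenated, per-dye max-normalized 3-dye vector for one plaque."""

    plaque_id: str
    patient_id: str
    cohort: str
    dye_order: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class SpectralMatrix:
    """Stack of composite vectors with aligned row metadata."""

    values: np.ndarray
    meta: pd.DataFrame
    dye_order: tuple[str, ...]
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("meta rows must align with value rows")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta is missing columns: {missing}")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_composites(
        cls, composites: list[CompositeVector], grid: WavelengthGrid | None = None
    ) -> "SpectralMatrix":
        if not composites:
            raise ValueError("no composite vectors supplied")
        dye_order = composites[0].dye_order
        if any(c.dye_order != dye_order for c in composites):
            raise ValueError("all composites must share the same dye order")
        values = np.vstack([c.values for c in composites])
        meta = pd.DataFrame(
            {
                "plaque_id": [c.plaque_id for c in composites],
                "patient_id": [c.patient_id for c in composites],
                "cohort": [c.cohort for c in composites],
            }
        )
        return cls(values=values, meta=meta, dye_order=dye_order, grid=grid or WavelengthGrid())

    def to_frame(self) -> pd.DataFrame:
        ncol = self.values.shape[1]
        wide = pd.DataFrame(
            self.values, columns=[f"v{i + 1:03d}" for i in range(ncol)]
        )
        return pd.concat([self.meta[META_COLUMNS].reset_index(drop=True), wide], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path, dye_order: tuple[str, ...] = DEFAULT_DYES, grid: WavelengthGrid | None = None
    ) -> "SpectralMatrix":
        df = pd.read_csv(path)
        value_cols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
        return cls(
            values=df[value_cols].to_numpy(dtype=float),
            meta=df[META_COLUMNS].copy(),
            dye_order=tuple(dye_order),
            grid=grid or WavelengthGrid(),
        )

    def subset(self, row_index: np.ndarray) -> "SpectralMatrix":
        return SpectralMatrix(
            values=self.values[row_index],
            meta=self.meta.iloc[row_index].reset_index(drop=True),
            dye_order=self.dye_order,
            grid=self.grid,
        )


def resample_to_grid(spectrum: EmissionSpectrum, grid: WavelengthGrid) -> EmissionSpectrum:
    """Linearly interpolate a spectrum onto the grid's channel centers.

    A spectrum already on the grid is returned unchanged.  A spectrum whose
    wavelength span lies strictly inside the grid span cannot be interpolated
    without extrapolation and raises :class:`MissingCoverageError`.
    """
    centers = grid.centers
    if spectrum.wavelengths.shape == centers.shape and np.allclose(
        spectrum.wavelengths, centers
    ):
        return spectrum
    lo, hi = spectrum.wavelengths[0], spectrum.wavelengths[-1]
    tol = 1e-9
    if lo > grid.span[0] + tol or hi < grid.span[1] - tol:
        raise MissingCoverageError(
            f"spectrum span [{lo}, {hi}] does not cover grid span {grid.span}"
        )
    values = np.interp(centers, spectrum.wavelengths, spectrum.intensities)
    return EmissionSpectrum(dye=spectrum.dye, wavelengths=centers, intensities=values)


def normalize_max(spectrum: EmissionSpectrum) -> EmissionSpectrum:
    """Divide a spectrum by its maximum intensity.

    An identically zero spectrum is returned as-is with ``all_zero=True`` and a
    warning; dropping such plaques is a pipeline-level policy, not enforced here.
    """
    peak = spectrum.intensities.max() if spectrum.intensities.size else 0.0
    if peak == 0.0:
        warnings.warn(
            f"all-zero spectrum for dye {spectrum.dye!r}; returned unnormalized",
            stacklevel=2,
        )
        return replace(spectrum, all_zero=True)
    return replace(spectrum, intensities=spectrum.intensities / peak, all_zero=False)


def build_composite(
    per_dye: dict[str, EmissionSpectrum],
    dye_order: tuple[str, ...] = DEFAULT_DYES,
    grid: WavelengthGrid | None = None,
    plaque_id: str = "",
    patient_id: str = "",
    cohort: str = "",
) -> CompositeVector:
    """Concatenate the per-dye max-normalized spectra in ``dye_order``."""
    grid = grid or WavelengthGrid()
    missing = [d for d in dye_order if d not in per_dye]
    if missing:
        raise IncompletePlaqueError(
            f"plaque {plaque_id!r} is missing dye spectra: {missing}"
        )
    blocks = []
    for dye in dye_order:
        spec = normalize_max(resample_to_grid(per_dye[dye], grid))
        blocks.append(spec.intensities)
    return CompositeVector(
        plaque_id=plaque_id,
        patient_id=patient_id,
        cohort=cohort,
        dye_order=tuple(dye_order),
        values=np.concatenate(blocks),
    )


def draw_dye_order(seed: int, dyes: tuple[str, ...] = DEFAULT_DYES) -> tuple[str, ...]:
    """Draw the single random dye concatenation order for an analysis run.

    One order is drawn once per run and applied uniformly to every plaque;
    with a shared order the concatenation is an isometry, so all pairwise
    distances (and hence the eigenspace geometry) are independent of which
    order was drawn.
    """
    rng = np.random.default_rng(seed)
    return tuple(rng.permutation(list(dyes)))


def composites_from_table(
    table: pd.DataFrame,
    dye_order: tuple[str, ...] | None = None,
    grid: WavelengthGrid | None = None,
    seed: int = 0,
) -> SpectralMatrix:
    """Build a :class:`SpectralMatrix` from a long-format spectra table.

    Expected columns: plaque_id, patient_id, cohort, dye, wavelength_nm,
    intensity (one row per channel).  Plaques missing a dye are excluded with
    a warning, mirroring the exclusion of incomplete plaques.
    """
    grid = grid or WavelengthGrid()
    if dye_order is None:
        dye_order = draw_dye_order(seed)
    composites: list[CompositeVector] = []
    for plaque_id, sub in table.groupby("plaque_id", sort=True):
        per_dye: dict[str, EmissionSpectrum] = {}
        for dye, dsub in sub.groupby("dye"):
            dsub = dsub.sort_values("wavelength_nm")
            per_dye[str(dye)] = EmissionSpectrum(
                dye=str(dye),
                wavelengths=dsub["wavelength_nm"].to_numpy(),
                intensities=dsub["intensity"].to_numpy(),
            )
        try:
            composites.append(
                build_composite(
                    per_dye,
                    dye_order=dye_order,
                    grid=grid,
                    plaque_id=str(plaque_id),
                    patient_id=str(sub["patient_id"].iloc[0]),
                    cohort=str(sub["cohort"].iloc[0]),
                )
            )
        except IncompletePlaqueError as exc:
            warnings.warn(str(exc), stacklevel=2)
    return SpectralMatrix.from_composites(composites, grid=grid)


def cap_vectors_per_patient(
    matrix: SpectralMatrix, cap: int = 30, seed: int = 0
) -> SpectralMatrix:
    """Keep at most ``cap`` randomly selected composite vectors per patient.

    Patients at or below the cap keep every row; others keep a uniform random
    subset of exactly ``cap`` rows.  Deterministic given ``seed``.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for _, idx in sorted(
        matrix.meta.groupby("patient_id", sort=True).indices.items()
    ):
        idx = np.sort(idx)
        if len(idx) <= cap:
            keep.append(idx)
        else:
            keep.append(np.sort(rng.choice(idx, size=cap, replace=False)))
    order = np.sort(np.concatenate(keep)) if keep else np.array([], dtype=int)
    return matrix.subset(order)
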