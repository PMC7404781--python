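"""Spectral dataset container and CSV interchange.

A :class:`SpectrumSet` holds a sample-by-wavenumber intensity matrix on a
shared, strictly monotone wavenumber axis (cm^-1, ascending or descending —
both occur in practice, FT-IR instruments commonly export descending axes),
together with one metadata record per sample.  The on-disk form is a wide
CSV: one row per sample, fixed leading metadata columns, then one column per
wavenumber whose header cell is the numeric axis value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

META_COLUMNS = [
    "sample_id",
    "class_label",
    "adulterant",
    "concentration",
    "variety",
    "set_role",
]

CLASS_LABELS = {"pure", "adulterated"}
ADULTERANTS = {"none", "apricot", "peanut"}
SET_ROLES = {"calibration", "validation1", "validation2", "test"}


class SpectralFormatError(ValueError):
    """Malformed spectral CSV (ragged rows, bad header, non-numeric cells)."""


class SpectralValidationError(ValueError):
    """Inconsistent dataset contents (duplicate ids, metadata conflicts)."""


class RegionError(ValueError):
    """Requested wavenumber region does not overlap the axis."""


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample study metadata.

    ``class_label`` is ``pure`` iff ``concentration`` is 0 iff ``adulterant``
    is ``none``; concentration is a mass percentage in [0, 100].
    """

    sample_id: str
    class_label: str = "pure"
    adulterant: str = "none"
    concentration: float = 0.0
    variety: int = 1
    set_role: str = "test"

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise SpectralValidationError(
                f"unknown class_label {self.class_label!r} for sample {self.sample_id!r}"
            )
        if self.adulterant not in ADULTERANTS:
            raise SpectralValidationError(
                f"unknown adulterant {self.adulterant!r} for sample {self.sample_id!r}"
            )
        if not 0.0 <= self.concentration <= 100.0:
            raise SpectralValidationError(
                f"concentration {self.concentration} outside [0, 100] "
                f"for sample {self.sample_id!r}"
            )
        pure = self.class_label == "pure"
        if pure != (self.concentration == 0.0) or pure != (self.adulterant == "none"):
            raise SpectralValidationError(
                f"sample {self.sample_id!r}: class_label/concentration/adulterant "
                f"are inconsistent ({self.class_label}, {self.concentration}, "
                f"{self.adulterant})"
            )


def _meta_frame(meta: pd.DataFrame | Sequence[SampleMeta]) -> pd.DataFrame:
    if isinstance(meta, pd.DataFrame):
        df = meta.reset_index(drop=True).copy()
    else:
        df = pd.DataFrame([m.__dict__ for m in meta])
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SpectralValidationError(f"metadata missing columns: {missing}")
    df = df[META_COLUMNS]
    df["sample_id"] = df["sample_id"].astype(str)
    df["concentration"] = df["concentration"].astype(float)
    df["variety"] = df["variety"].astype(int)
    return df


@dataclass
class SpectrumSet:
    """Aligned spectra plus per-sample metadata.

    Parameters
    ----------
    wavenumbers : array of float
        Strictly monotone axis in cm^-1 (ascending or descending).
    intensities : array, shape (n_samples, n_wavenumbers)
        Absorbance/reflectance values; no missing entries.
    meta : DataFrame or sequence of SampleMeta
        One record per row of ``intensities``.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float).ravel()
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.meta is None:
            self.meta = pd.DataFrame(
                [SampleMeta(sample_id=f"s{i}").__dict__ for i in range(len(self.intensities))]
            )
        self.meta = _meta_frame(self.meta)
        self._validate()

    def _validate(self) -> None:
        n, p = self.intensities.shape
        if self.wavenumbers.size != p:
            raise SpectralValidationError(
                f"axis length {self.wavenumbers.size} != intensity columns {p}"
            )
        if len(self.meta) != n:
            raise SpectralValidationError(
                f"metadata rows {len(self.meta)} != intensity rows {n}"
            )
        if p >= 2:
            d = np.diff(self.wavenumbers)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise SpectralValidationError("wavenumber axis is not strictly monotone")
        if not np.all(np.isfinite(self.intensities)):
            raise SpectralValidationError("intensity matrix contains non-finite values")
        ids = self.meta["sample_id"]
        dup = ids[ids.duplicated()].unique()
        if len(dup):
            raise SpectralValidationError(f"duplicate sample ids: {list(dup)}")
        # re-validate metadata invariants row by row
        for rec in self.meta.itertuples(index=False):
            SampleMeta(**rec._asdict())

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meta["sample_id"])

    @property
    def direction(self) -> str:
        """``ascending`` or ``descending`` axis direction."""
        if self.n_points < 2 or self.wavenumbers[1] > self.wavenumbers[0]:
            return "ascending"
        return "descending"

    def with_intensities(self, intensities: np.ndarray) -> "SpectrumSet":
        """Same axis and metadata, new intensity matrix (shape-preserving)."""
        return SpectrumSet(self.wavenumbers.copy(), np.asarray(intensities, float), self.meta)

    def take(self, indices) -> "SpectrumSet":
        """Row subset (keeps sample/metadata pairing)."""
        indices = np.asarray(indices)
        return SpectrumSet(
            self.wavenumbers.copy(),
            self.intensities[indices],
            self.meta.iloc[indices].reset_index(drop=True),
        )


def read_spectra_csv(path: str | Path) -> SpectrumSet:
    """Read a wide-format spectral CSV.

    The header row carries the metadata column names followed by numeric
    wavenumber values; each subsequent row is one sample.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise SpectralFormatError(f"{path}: malformed CSV ({exc})") from exc
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SpectralFormatError(f"{path}: missing metadata columns {missing}")
    wn_cols = [c for c in df.columns if c not in META_COLUMNS]
    try:
        wavenumbers = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SpectralFormatError(f"{path}: non-numeric wavenumber header ({exc})") from exc
    if df.shape[0]:
        block = df[wn_cols]
        for col in wn_cols:
            coerced = pd.to_numeric(block[col], errors="coerce")
            bad = coerced.isna() & block[col].notna()
            if bad.any() or block[col].isna().any():
                row = int(np.where(coerced.isna() | block[col].isna())[0][0])
                raise SpectralFormatError(
                    f"{path}: non-numeric or missing intensity at row {row}, column {col!r}"
                )
        intensities = block.to_numpy(dtype=float)
    else:
        intensities = np.empty((0, len(wn_cols)))
    meta = df[META_COLUMNS]
    return SpectrumSet(wavenumbers, intensities, meta)


def write_spectra_csv(data: SpectrumSet, path: str | Path) -> Path:
    """Write the wide CSV form; re-reading reproduces values exactly."""
    path = Path(path)
    out = data.meta.copy()
    spec = pd.DataFrame(
        data.intensities, columns=[repr(float(w)) for w in data.wavenumbers]
    )
    out = pd.concat([out, spec], axis=1)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, float_format="%.17g")  # exact round trip
    return path


def select_region(data: SpectrumSet, low: float, high: float) -> SpectrumSet:
    """Keep wavenumbers with ``low <= w <= high`` (closed interval).

    Column order is preserved, so the operation is direction-agnostic;
    metadata is untouched.
    """
    if not low < high:
        raise RegionError(f"invalid region: low={low} must be < high={high}")
    mask = (data.wavenumbers >= low) & (data.wavenumbers <= high)
    if not mask.any():
        raise RegionError(
            f"region [{low}, {high}] does not overlap axis "
            f"[{data.wavenumbers.min()}, {data.wavenumbers.max()}]"
        )
    return SpectrumSet(data.wavenumbers[mask], data.intensities[:, mask], data.meta)
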