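"""Readers, writers and validation for chromatograms, spectra and libraries.

File conventions
----------------
* Chromatogram: wide CSV, first column ``time_min``, remaining column
  headers numeric wavelengths in nm.
* Reference spectrum: two-column CSV ``wavelength_nm,absorbance``.
* Library manifest: TSV with columns ``species``, ``file``, ``source``;
  file paths are resolved relative to the manifest.
* Peak table: TSV with a fixed column order (see ``PEAK_TABLE_COLUMNS``).

Time is always minutes, wavelength always nm, absorbance in AU.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectralChromatogram",
    "ReferenceSpectrum",
    "SpectralLibrary",
    "PEAK_TABLE_COLUMNS",
    "read_chromatogram",
    "write_chromatogram",
    "read_spectrum",
    "write_spectrum",
    "read_library",
    "write_library",
    "write_peak_table",
    "read_peak_table",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an object violates a structural invariant."""


def _check_axis(vec: np.ndarray, name: str) -> np.ndarray:
    vec = np.asarray(vec, dtype=float).ravel()
    if vec.size == 0:
        raise ValidationError(f"empty {name} axis")
    if not np.all(np.isfinite(vec)):
        raise ValidationError(f"non-finite values in {name} axis")
    if vec.size > 1 and not np.all(np.diff(vec) > 0):
        raise ValidationError(f"non-monotone {name} axis")
    return vec


@dataclass
class SpectralChromatogram:
    """Absorbance surface A(t, lambda): the pipeline's central object.

    Attributes
    ----------
    time : ndarray
        Elution time axis in minutes, strictly increasing.
    wavelength : ndarray
        Wavelength axis in nm, strictly increasing.
    absorbance : ndarray, shape (n_time, n_wavelength)
        Absorbance in AU.
    meta : dict
        Free-form provenance (source path, simulation settings, ...).
    """

    time: np.ndarray
    wavelength: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = _check_axis(self.time, "time")
        self.wavelength = _check_axis(self.wavelength, "wavelength")
        A = np.asarray(self.absorbance, dtype=float)
        if A.ndim != 2 or A.shape != (self.time.size, self.wavelength.size):
            raise ValidationError(
                f"absorbance shape {A.shape} does not match axes "
                f"({self.time.size}, {self.wavelength.size})"
            )
        if not np.all(np.isfinite(A)):
            raise ValidationError("non-finite absorbance values")
        self.absorbance = A

    @property
    def shape(self) -> tuple[int, int]:
        return self.absorbance.shape

    def crop_time(self, t_start: float, t_end: float) -> "SpectralChromatogram":
        """Return the sub-chromatogram with t_start <= t <= t_end."""
        mask = (self.time >= t_start) & (self.time <= t_end)
        if not mask.any():
            raise ValidationError("time crop leaves no samples")
        return SpectralChromatogram(
            self.time[mask], self.wavelength.copy(), self.absorbance[mask], dict(self.meta)
        )


@dataclass
class ReferenceSpectrum:
    """A named absorbance-vs-wavelength curve with source provenance.

    ``source`` is free text; conventional values are ``literature``,
    ``measured`` and ``synthetic``. Absorbance scale is arbitrary —
    downstream comparisons are scale-invariant.
    """

    species: str
    wavelength: np.ndarray
    absorbance: np.ndarray
    source: str = "unknown"

    def __post_init__(self) -> None:
        if not str(self.species).strip():
            raise ValidationError("empty species label")
        self.wavelength = _check_axis(self.wavelength, "wavelength")
        a = np.asarray(self.absorbance, dtype=float).ravel()
        if a.size != self.wavelength.size:
            raise ValidationError("wavelength/absorbance length mismatch")
        if not np.all(np.isfinite(a)):
            raise ValidationError("non-finite absorbance values")
        if a.size < 16:
            raise ValidationError("spectrum needs at least 16 samples")
        self.absorbance = a

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelength[0]), float(self.wavelength[-1])


@dataclass
class SpectralLibrary:
    """An ordered collection of reference spectra plus manifest records."""

    entries: list[ReferenceSpectrum]
    manifest: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.manifest is None:
            self.manifest = pd.DataFrame(
                {
                    "species": [e.species for e in self.entries],
                    "file": ["" for _ in self.entries],
                    "source": [e.source for e in self.entries],
                }
            )

    @property
    def species(self) -> list[str]:
        """Distinct species labels in first-appearance order."""
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.species, None)
        return list(seen)

    @property
    def n_classes(self) -> int:
        return len(self.species)

    @property
    def training_fit(self) -> bool:
        """True when the library can train a classifier (>=2 species)."""
        return self.n_classes >= 2

    def by_species(self, label: str) -> list[ReferenceSpectrum]:
        return [e for e in self.entries if e.species == label]

    def subset(self, labels: list[str]) -> "SpectralLibrary":
        keep = set(labels)
        return SpectralLibrary([e for e in self.entries if e.species in keep])

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# chromatogram CSV


def read_chromatogram(path: str | os.PathLike) -> SpectralChromatogram:
    """Load a wide-CSV chromatogram (``time_min`` + wavelength columns)."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"cannot parse chromatogram CSV {path}: {exc}") from exc
    if df.shape[1] < 2 or df.columns[0] != "time_min":
        raise ValidationError(
            f"{path}: first column must be 'time_min' followed by wavelength columns"
        )
    try:
        wl = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric wavelength header: {exc}") from exc
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(values).all(axis=1)
    if bad.any():
        raise ValidationError(
            f"{path}: non-numeric or missing cell in data row {int(np.argmax(bad))}"
        )
    time = values[:, 0]
    A = values[:, 1:]
    order = np.argsort(wl)
    torder = np.argsort(time)
    return SpectralChromatogram(
        time[torder], wl[order], A[torder][:, order], meta={"source": str(path)}
    )


def write_chromatogram(chrom: SpectralChromatogram, path: str | os.PathLike) -> None:
    """Write a chromatogram as wide CSV readable by :func:`read_chromatogram`.

    Wavelength headers are formatted to <=6 significant digits.
    """
    if chrom.absorbance.size == 0:
        raise ValidationError("refusing to write empty chromatogram")
    cols = ["time_min"] + [f"{w:.6g}" for w in chrom.wavelength]
    df = pd.DataFrame(
        np.column_stack([chrom.time, chrom.absorbance]), columns=cols
    )
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# spectra and libraries


def read_spectrum(path: str | os.PathLike, species: str = "", source: str = "unknown") -> ReferenceSpectrum:
    """Load a two-column spectrum CSV (wavelength_nm, absorbance)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (wavelength_nm, absorbance)")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    ab = df.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(wl)
    label = species or os.path.splitext(os.path.basename(str(path)))[0]
    return ReferenceSpectrum(label, wl[order], ab[order], source=source)


def write_spectrum(spec: ReferenceSpectrum, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.wavelength, "absorbance": spec.absorbance}
    ).to_csv(path, index=False, float_format="%.12g")


def read_library(manifest_path: str | os.PathLike) -> SpectralLibrary:
    """Load a library from a manifest TSV (columns species, file, source).

    Spectrum files are resolved relative to the manifest's directory.
    Duplicate species are allowed (replicate spectra per species). A
    library with fewer than 2 distinct species loads but is flagged
    unfit for classifier training via ``SpectralLibrary.training_fit``.
    """
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"species", "file", "source"}
    if not required.issubset(manifest.columns):
        raise ValidationError(
            f"manifest must have columns {sorted(required)}, got {list(manifest.columns)}"
        )
    base = os.path.dirname(os.path.abspath(str(manifest_path)))
    entries = []
    for _, row in manifest.iterrows():
        fpath = row["file"]
        if not os.path.isabs(fpath):
            fpath = os.path.join(base, fpath)
        if not os.path.exists(fpath):
            raise ValidationError(
                f"manifest entry '{row['species']}': file not found: {row['file']}"
            )
        entries.append(read_spectrum(fpath, species=row["species"], source=row["source"]))
    return SpectralLibrary(entries, manifest=manifest)


def write_library(library: SpectralLibrary, directory: str | os.PathLike) -> str:
    """Write every entry as a spectrum CSV plus a ``manifest.tsv``.

    Returns the manifest path.
    """
    os.makedirs(directory, exist_ok=True)
    rows = []
    counts: dict[str, int] = {}
    for entry in library.entries:
        counts[entry.species] = counts.get(entry.species, 0) + 1
        fname = f"{entry.species}_{counts[entry.species]}.csv".replace(" ", "_")
        write_spectrum(entry, os.path.join(directory, fname))
        rows.append({"species": entry.species, "file": fname, "source": entry.source})
    manifest_path = os.path.join(directory, "manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


# ---------------------------------------------------------------------------
# peak tables

PEAK_TABLE_COLUMNS = [
    "peak_id",
    "retention_time",
    "apex_absorbance",
    "start",
    "end",
    "species",
    "posterior",
    "r2",
    "frechet",
    "deconvolved",
]


def write_peak_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write an annotated peak table as TSV with the fixed column order."""
    out = pd.DataFrame(table, columns=PEAK_TABLE_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_peak_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"peak table missing columns {missing}")
    return df[PEAK_TABLE_COLUMNS]
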