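"""Domain containers, delimited-matrix I/O and preprocessing.

The central object is a quenching series: a matrix ``Y`` of emission
spectra (rows) recorded for a ladder of quencher concentrations ``Q``
starting at ``Q = 0`` (the unquenched reference row).  For the indirect
rank-annihilation method the data come instead as one matrix per quencher
level whose rows are spectra taken at different excitation lines; that
layout is held by :class:`MultiExcitationSet`.

Preprocessing mirrors what is routinely done to measured quenching data
before resolution: solvent-baseline subtraction, multiplicative
inner-filter (self-absorption) correction, rank-truncated SVD smoothing
and restriction to a wavelength window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QuenchingSeries",
    "MultiExcitationSet",
    "ResolutionResult",
    "Dialect",
    "ValidationError",
    "ParseError",
    "load_matrix",
    "load_series",
    "save_series",
    "load_excitation_block",
    "save_excitation_block",
    "load_multi_excitation",
    "save_multi_excitation",
    "load_multi_excitation_dir",
    "subtract_baseline",
    "inner_filter_correct",
    "svd_reproduce",
    "reduce_range",
]


class ValidationError(ValueError):
    """A container invariant is violated (grids, ordering, shapes)."""


class ParseError(ValueError):
    """A delimited table could not be interpreted as spectral data."""


def _as_1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {a.shape}")
    return a


@dataclass
class QuenchingSeries:
    """Emission spectra of one excitation line over a quencher ladder.

    Parameters
    ----------
    wavelengths : array, shape (nλ,)
        Strictly increasing emission grid in nm.
    quencher_concs : array, shape (nQ + 1,)
        Quencher concentrations in M, strictly increasing with
        ``quencher_concs[0] == 0`` (the unquenched reference sample).
    intensities : array, shape (nQ + 1, nλ)
        Row ``i`` is the spectrum recorded at ``quencher_concs[i]``.
        Arbitrary units; negative entries are allowed (noise).
    excitation : float, optional
        Excitation wavelength in nm (metadata only).
    history : list of str
        Log of preprocessing steps applied, newest last.
    """

    wavelengths: np.ndarray
    quencher_concs: np.ndarray
    intensities: np.ndarray
    excitation: float | None = None
    history: list = field(default_factory=list)

    def __post_init__(self):
        self.wavelengths = _as_1d(self.wavelengths, "wavelengths")
        self.quencher_concs = _as_1d(self.quencher_concs, "quencher_concs")
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValidationError("intensities must be a 2-D matrix")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if self.quencher_concs[0] != 0:
            raise ValidationError(
                f"first quencher concentration must be 0 (unquenched reference), "
                f"got {self.quencher_concs[0]!r}"
            )
        if not np.all(np.diff(self.quencher_concs) > 0):
            raise ValidationError("quencher concentrations must be strictly increasing")
        if self.intensities.shape != (self.quencher_concs.size, self.wavelengths.size):
            raise ValidationError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{self.quencher_concs.size} quencher levels x "
                f"{self.wavelengths.size} wavelengths"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities must be finite")

    @property
    def n_levels(self) -> int:
        """Number of rows, i.e. nonzero quencher levels + 1."""
        return self.quencher_concs.size

    @property
    def y0(self) -> np.ndarray:
        """Unquenched reference spectrum (row at Q = 0)."""
        return self.intensities[0]

    def with_intensities(self, Y: np.ndarray, note: str) -> "QuenchingSeries":
        return replace(self, intensities=np.asarray(Y, float),
                       history=[*self.history, note])


@dataclass
class MultiExcitationSet:
    """Per-quencher-level matrices whose rows scan the excitation lines.

    ``matrices[k]`` has shape (nex, nλ): the spectra recorded at every
    excitation line for quencher level ``quencher_concs[k]``.
    ``matrices[0]`` is the unquenched reference matrix M0.
    """

    wavelengths: np.ndarray
    excitations: np.ndarray
    quencher_concs: np.ndarray
    matrices: list

    def __post_init__(self):
        self.wavelengths = _as_1d(self.wavelengths, "wavelengths")
        self.excitations = _as_1d(self.excitations, "excitations")
        self.quencher_concs = _as_1d(self.quencher_concs, "quencher_concs")
        self.matrices = [np.asarray(m, float) for m in self.matrices]
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if self.quencher_concs[0] != 0:
            raise ValidationError("first quencher concentration must be 0")
        if not np.all(np.diff(self.quencher_concs) > 0):
            raise ValidationError("quencher concentrations must be strictly increasing")
        if len(self.matrices) != self.quencher_concs.size:
            raise ValidationError(
                f"{len(self.matrices)} matrices for "
                f"{self.quencher_concs.size} quencher levels"
            )
        shape = (self.excitations.size, self.wavelengths.size)
        for k, m in enumerate(self.matrices):
            if m.shape != shape:
                raise ValidationError(
                    f"matrix {k} has shape {m.shape}, expected {shape}"
                )
            if not np.all(np.isfinite(m)):
                raise ValidationError(f"matrix {k} contains non-finite entries")

    @property
    def n_excitations(self) -> int:
        return self.excitations.size

    @property
    def M0(self) -> np.ndarray:
        return self.matrices[0]


@dataclass
class ResolutionResult:
    """Outcome of a matrix resolution.

    ``C`` holds the resolved intensity-decay profiles (one column per
    component, anchored to 1 at Q = 0 for hard methods), ``S`` the pure
    emission spectra (nλ x n), ``K`` the Stern-Volmer constants in 1/M for
    methods that estimate them (``None`` for the soft-profile MCR-ALS
    output), and ``fractions`` the spectral fraction profiles where the
    fractional formulation was used.
    """

    K: np.ndarray | None
    C: np.ndarray
    S: np.ndarray
    method: str
    fractions: np.ndarray | None = None
    ssq: float = np.nan
    n_iter: int = 0
    converged: bool = True
    wavelengths: np.ndarray | None = None
    quencher_concs: np.ndarray | None = None
    ssq_trace: list | None = None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

@dataclass
class Dialect:
    """Layout of a delimited spectral table.

    ``layout`` is ``"series"`` (leading column = quencher concentration,
    first data row must have Q = 0) or ``"excitation"`` (leading column =
    excitation wavelengths).  ``delimiter=None`` picks comma for ``.csv``
    and tab otherwise.
    """

    layout: str = "series"
    delimiter: str | None = None


def _read_table(path, delimiter):
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=delimiter, header=0, index_col=0,
                         float_precision="round_trip")
        df.columns = [float(c) for c in df.columns]
        df.index = [float(i) for i in df.index]
    except Exception as exc:  # surface the offending cell where pandas names it
        raise ParseError(f"{path}: cannot parse delimited spectral table: {exc}") from exc
    coerced = df.apply(pd.to_numeric, errors="coerce")
    if coerced.isna().any().any():
        i, j = np.argwhere(coerced.isna().to_numpy())[0]
        raise ParseError(f"{path}: missing/non-numeric value at data row {i}, column {j}")
    return coerced


def load_series(path, delimiter: str | None = None,
                excitation: float | None = None) -> QuenchingSeries:
    """Read a quenching series: header row = wavelengths (nm), leading
    column = quencher concentration (M), first row Q = 0."""
    df = _read_table(path, delimiter)
    return QuenchingSeries(
        wavelengths=np.array(df.columns, float),
        quencher_concs=np.array(df.index, float),
        intensities=df.to_numpy(float),
        excitation=excitation,
    )


def save_series(series: QuenchingSeries, path, delimiter: str | None = None) -> None:
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(series.intensities, index=series.quencher_concs,
                      columns=series.wavelengths)
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def load_excitation_block(path, delimiter: str | None = None):
    """Read one multi-excitation matrix: header row = emission wavelengths,
    leading column = excitation wavelengths.  Returns (excitations,
    wavelengths, matrix)."""
    df = _read_table(path, delimiter)
    wavelengths = np.array(df.columns, float)
    excitations = np.array(df.index, float)
    if not np.all(np.diff(wavelengths) > 0):
        raise ValidationError(f"{path}: emission wavelengths not strictly increasing")
    return excitations, wavelengths, df.to_numpy(float)


def save_excitation_block(excitations, wavelengths, matrix, path,
                          delimiter: str | None = None) -> None:
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(np.asarray(matrix, float), index=np.asarray(excitations, float),
                      columns=np.asarray(wavelengths, float))
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def load_multi_excitation(paths: Sequence, quencher_concs,
                          delimiter: str | None = None) -> MultiExcitationSet:
    """Assemble a :class:`MultiExcitationSet` from one file per quencher
    level (ordered as ``quencher_concs``, first = unquenched)."""
    blocks = [load_excitation_block(p, delimiter) for p in paths]
    ex0, wl0 = blocks[0][0], blocks[0][1]
    for k, (ex, wl, _) in enumerate(blocks[1:], start=1):
        if not (np.array_equal(ex, ex0) and np.array_equal(wl, wl0)):
            raise ValidationError(f"file {paths[k]}: grids differ from the first file")
    return MultiExcitationSet(
        wavelengths=wl0, excitations=ex0,
        quencher_concs=np.asarray(quencher_concs, float),
        matrices=[b[2] for b in blocks],
    )


def save_multi_excitation(mset: MultiExcitationSet, dirpath,
                          delimiter: str | None = None) -> None:
    """Write a multi-excitation set as a directory: one block file per
    quencher level plus ``quencher_levels.csv`` mapping Q to file name."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    names = [f"level_{k:02d}.csv" for k in range(mset.quencher_concs.size)]
    for name, m in zip(names, mset.matrices):
        save_excitation_block(mset.excitations, mset.wavelengths, m,
                              dirpath / name, delimiter)
    pd.DataFrame({"quencher_conc": mset.quencher_concs,
                  "file": names}).to_csv(dirpath / "quencher_levels.csv",
                                         index=False)


def load_multi_excitation_dir(dirpath,
                              delimiter: str | None = None) -> MultiExcitationSet:
    """Read a directory written by :func:`save_multi_excitation`."""
    dirpath = Path(dirpath)
    index = pd.read_csv(dirpath / "quencher_levels.csv")
    return load_multi_excitation([dirpath / f for f in index["file"]],
                                 index["quencher_conc"].to_numpy(float),
                                 delimiter)


def load_matrix(path, dialect: Dialect = Dialect()):
    """Dispatch on :class:`Dialect.layout` (``series`` or ``excitation``)."""
    if dialect.layout == "series":
        return load_series(path, dialect.delimiter)
    if dialect.layout == "excitation":
        return load_excitation_block(path, dialect.delimiter)
    raise ValueError(f"unknown layout {dialect.layout!r}")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def subtract_baseline(series: QuenchingSeries, baseline) -> QuenchingSeries:
    """Subtract a solvent baseline spectrum (same grid) from every row."""
    baseline = np.asarray(baseline, float)
    if baseline.shape != series.wavelengths.shape:
        raise ValidationError(
            f"baseline length {baseline.size} does not match grid of "
            f"{series.wavelengths.size} wavelengths"
        )
    return series.with_intensities(series.intensities - baseline[None, :],
                                   "baseline subtracted")


def inner_filter_correct(series: QuenchingSeries, A_ex_endpoints,
                         A_em_endpoints) -> QuenchingSeries:
    """Multiplicative inner-filter (self-absorption) correction.

    Absorbances at the excitation line (scalars) and over the emission grid
    (spectra) are supplied for the two outermost samples, Q = 0 and
    Q = Q_max, and interpolated linearly in Q in between.  Each observed
    intensity is scaled by ``10**((A_ex + A_em)/2)`` — the usual half-path
    correction for right-angle geometry.
    """
    a_ex = np.asarray(A_ex_endpoints, float)
    if a_ex.shape != (2,):
        raise ValidationError("A_ex_endpoints must be two scalars (Q=0, Q=Qmax)")
    a_em = np.asarray(A_em_endpoints, float)
    if a_em.shape != (2, series.wavelengths.size):
        raise ValidationError(
            "A_em_endpoints must be two spectra on the series grid"
        )
    if (a_ex < 0).any() or (a_em < 0).any():
        warnings.warn("negative absorbance clipped to 0", stacklevel=2)
        a_ex = np.clip(a_ex, 0, None)
        a_em = np.clip(a_em, 0, None)
    Q = series.quencher_concs
    t = Q / Q[-1] if Q[-1] > 0 else np.zeros_like(Q)
    A_ex = (1 - t) * a_ex[0] + t * a_ex[1]                    # (nQ+1,)
    A_em = (1 - t)[:, None] * a_em[0] + t[:, None] * a_em[1]  # (nQ+1, nλ)
    factor = 10.0 ** ((A_ex[:, None] + A_em) / 2.0)
    return series.with_intensities(series.intensities * factor,
                                   "inner-filter corrected")


def svd_reproduce(Y: np.ndarray, rank: int) -> np.ndarray:
    """Best rank-``rank`` approximation of ``Y`` (truncated SVD smoothing)."""
    Y = np.asarray(Y, float)
    if rank <= 0:
        raise ValueError(f"rank must be positive, got {rank}")
    if rank > min(Y.shape):
        raise ValueError(f"rank {rank} exceeds min(shape) = {min(Y.shape)}")
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    return (U[:, :rank] * s[:rank]) @ Vt[:rank]


def reduce_range(series: QuenchingSeries, lo: float, hi: float) -> QuenchingSeries:
    """Keep only emission wavelengths in [lo, hi] nm."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got {lo} >= {hi}")
    keep = (series.wavelengths >= lo) & (series.wavelengths <= hi)
    if not keep.any():
        raise ValueError(
            f"window [{lo}, {hi}] nm does not overlap the grid "
            f"[{series.wavelengths[0]}, {series.wavelengths[-1]}] nm"
        )
    return replace(
        series,
        wavelengths=series.wavelengths[keep],
        intensities=series.intensities[:, keep],
        history=[*series.history, f"range reduced to {lo}-{hi} nm"],
    )
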