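"""Synthetic quenching-data generator.

Builds bilinear datasets Y = C Sᵀ in which each pure-component emission
spectrum is a sum of Gaussian bands and each decay column follows the
linear Stern-Volmer law C(Q, n) = 1 / (1 + K_n Q).  Two imperfection
models mimic real measurements:

* additive spectral noise — instrumental, signal-independent:
  ``F(λ) + y · r · max(F)`` with ``r ~ U(-1, 1)`` per entry, ``max(F)``
  the largest intensity in the whole series and ``y`` in parts per
  thousand (per mille);
* proportional concentration noise — a sample-preparation error:
  the concentrations actually used to build the data are
  ``Q · (1 + x · r)`` with ``x`` in percent, while the dataset reports the
  nominal ladder (downstream algorithms never see the true values).

The default three-component system (``default_components``) emulates a
mixture of anthracene-like fluorophores with strongly overlapping vibronic
emission bands and constants K = [5.00, 100, 20.0] 1/M, quenched over
Q = 0 … 0.2 M in 21 steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import MultiExcitationSet, QuenchingSeries

__all__ = [
    "ComponentSpec",
    "NoiseSpec",
    "default_components",
    "default_grid",
    "default_quencher_levels",
    "default_excitation_weights",
    "gaussian_spectrum",
    "sv_decay_matrix",
    "add_spectral_noise",
    "perturb_concentrations",
    "synthesize_series",
    "synthesize_multi_excitation",
]


@dataclass
class ComponentSpec:
    """One fluorophore: Gaussian emission bands plus its quenching constant.

    ``bands`` is a list of ``(center_nm, width_nm, amplitude)`` triples;
    ``width`` is the Gaussian standard deviation, so a single band peaks at
    exactly ``amplitude`` at its center.  ``K`` is the Stern-Volmer
    constant in 1/M.
    """

    bands: list
    K: float
    label: str = ""

    def __post_init__(self):
        for c, w, a in self.bands:
            if w <= 0:
                raise ValueError(f"band width must be > 0, got {w}")
            if a < 0:
                raise ValueError(f"band amplitude must be >= 0, got {a}")
        if self.K <= 0:
            raise ValueError(f"Stern-Volmer constant must be > 0, got {self.K}")


@dataclass
class NoiseSpec:
    """Noise levels: ``spectral_permille`` = y (‰), ``concentration_percent``
    = x (%), and the RNG seed making a realization reproducible."""

    spectral_permille: float = 0.0
    concentration_percent: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.spectral_permille < 0 or self.concentration_percent < 0:
            raise ValueError("noise levels must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_grid() -> np.ndarray:
    """Emission grid 380–600 nm at 0.5-nm step (441 points)."""
    return np.arange(380.0, 600.0 + 0.25, 0.5)


def default_quencher_levels() -> np.ndarray:
    """21 quencher levels linearly increasing from 0 to 0.2 M."""
    return np.linspace(0.0, 0.2, 21)


def default_components() -> list:
    """Three overlapping anthracene-like emitters, K = [5.00, 100, 20.0] 1/M.

    Band positions/intensities are loosely modeled on the vibronic emission
    of 9-cyanoanthracene-type fluorophores in methanol; the three spectra
    overlap strongly over most of the grid, with partially selective edges.
    """
    return [
        ComponentSpec(
            bands=[(410.0, 9.0, 0.90), (435.0, 11.0, 1.00),
                   (463.0, 13.0, 0.55), (495.0, 16.0, 0.20)],
            K=5.00, label="A",
        ),
        ComponentSpec(
            bands=[(433.0, 9.0, 0.80), (459.0, 11.0, 1.00),
                   (490.0, 14.0, 0.50), (523.0, 17.0, 0.18)],
            K=100.0, label="B",
        ),
        ComponentSpec(
            bands=[(420.0, 9.0, 0.85), (445.0, 11.0, 1.00),
                   (474.0, 13.0, 0.50), (506.0, 16.0, 0.18)],
            K=20.0, label="C",
        ),
    ]


def default_excitation_weights(nex: int = 5, n: int = 3,
                               seed: int = 20180403) -> np.ndarray:
    """Strictly positive nex x n excitation-weight matrix with condition
    number < 50 (distinct component mixes per excitation line), seeded."""
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        W = rng.uniform(0.2, 1.0, size=(nex, n))
        if np.linalg.cond(W) < 50:
            return W
    raise RuntimeError("could not draw a well-conditioned weight matrix")


def gaussian_spectrum(spec: ComponentSpec, grid) -> np.ndarray:
    """Evaluate the sum of Gaussian envelopes of one component on a grid."""
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("empty wavelength grid")
    s = np.zeros_like(grid)
    for center, width, amp in spec.bands:
        s += amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return s


def sv_decay_matrix(K, Q) -> np.ndarray:
    """Stern-Volmer decay matrix C[i, j] = 1 / (1 + K_j * Q_i)."""
    K = np.atleast_1d(np.asarray(K, float))
    Q = np.asarray(Q, float)
    if (Q < 0).any():
        raise ValueError("quencher concentrations must be >= 0")
    if (K <= 0).any():
        raise ValueError("Stern-Volmer constants must be > 0")
    return 1.0 / (1.0 + np.outer(Q, K))


def add_spectral_noise(Y, y_permille: float, rng: np.random.Generator) -> np.ndarray:
    """Additive instrumental noise: each entry perturbed by
    ``y · r · max(F)``, r ~ U(-1, 1), max over the whole series."""
    Y = np.asarray(Y, float)
    if y_permille < 0:
        raise ValueError("spectral noise level must be >= 0")
    if y_permille == 0:
        return Y.copy()
    r = rng.uniform(-1.0, 1.0, size=Y.shape)
    return Y + (y_permille / 1000.0) * r * Y.max()


def perturb_concentrations(Q, x_percent: float, rng: np.random.Generator) -> np.ndarray:
    """Proportional concentration noise Q_i (1 + x·r_i); Q = 0 stays 0."""
    Q = np.asarray(Q, float)
    if x_percent < 0:
        raise ValueError("concentration noise level must be >= 0")
    if x_percent == 0:
        return Q.copy()
    r = rng.uniform(-1.0, 1.0, size=Q.shape)
    return Q * (1.0 + (x_percent / 100.0) * r)


def _pure_spectra(components, grid) -> np.ndarray:
    S = np.column_stack([gaussian_spectrum(c, grid) for c in components])
    return S


def synthesize_series(components=None, grid=None, Q=None,
                      noise: NoiseSpec | None = None,
                      excitation: float | None = None):
    """Simulate a single-excitation quenching series.

    Returns ``(series, truth)`` where ``truth`` carries the ground-truth
    constants ``K``, decay matrix ``C`` (built from the noise-perturbed
    concentrations actually "used"), pure spectra ``S`` (nλ x n) and the
    perturbed concentrations ``Q_actual``.  The series itself reports the
    nominal ladder — the preparation imperfection is invisible downstream.
    """
    components = default_components() if components is None else components
    if len(components) == 0:
        raise ValueError("need at least one component")
    grid = default_grid() if grid is None else np.asarray(grid, float)
    Q = default_quencher_levels() if Q is None else np.asarray(Q, float)
    noise = NoiseSpec() if noise is None else noise
    rng = noise.rng()

    K = np.array([c.K for c in components])
    S = _pure_spectra(components, grid)
    Q_actual = perturb_concentrations(Q, noise.concentration_percent, rng)
    C = sv_decay_matrix(K, Q_actual)
    Y = add_spectral_noise(C @ S.T, noise.spectral_permille, rng)
    series = QuenchingSeries(wavelengths=grid, quencher_concs=Q,
                             intensities=Y, excitation=excitation)
    truth = {"K": K, "C": C, "S": S, "Q_actual": Q_actual}
    return series, truth


def synthesize_multi_excitation(components=None, grid=None, Q=None,
                                weights=None, noise: NoiseSpec | None = None,
                                excitations=None):
    """Simulate a multi-excitation set for the indirect RAFA method.

    ``weights`` (nex x n, strictly positive, full column rank) sets the
    relative amount of each component excited at each line; the matrix at
    quencher level Q is ``M_Q = W diag(1/(1+K_j Q)) Sᵀ``.  Concentration
    noise is drawn once per quencher level (one cuvette measured at all
    lines); spectral noise is per entry, scaled by the global maximum.
    """
    components = default_components() if components is None else components
    grid = default_grid() if grid is None else np.asarray(grid, float)
    Q = default_quencher_levels() if Q is None else np.asarray(Q, float)
    noise = NoiseSpec() if noise is None else noise
    n = len(components)
    weights = default_excitation_weights(5, n) if weights is None else np.asarray(weights, float)
    if weights.shape[1] != n:
        raise ValueError(f"weights must have {n} columns, got {weights.shape}")
    if weights.shape[0] < n:
        raise ValueError("need at least as many excitation lines as components")
    if np.linalg.matrix_rank(weights) < n:
        raise ValueError(
            "excitation-weight matrix is rank deficient: every component "
            "mix must differ between lines for annihilation to be defined"
        )
    if excitations is None:
        # five lines on the red absorption edge, as used for anthracene dyes
        excitations = np.array([365.0, 368.0, 371.0, 374.0, 377.0])[: weights.shape[0]]
        if excitations.size != weights.shape[0]:
            excitations = 365.0 + 3.0 * np.arange(weights.shape[0])
    excitations = np.asarray(excitations, float)

    rng = noise.rng()
    K = np.array([c.K for c in components])
    S = _pure_spectra(components, grid)
    Q_actual = perturb_concentrations(Q, noise.concentration_percent, rng)
    C = sv_decay_matrix(K, Q_actual)  # (nQ+1, n)

    clean = [weights @ np.diag(C[k]) @ S.T for k in range(Q.size)]
    peak = max(m.max() for m in clean)
    y = noise.spectral_permille / 1000.0
    matrices = []
    for m in clean:
        if y > 0:
            m = m + y * rng.uniform(-1.0, 1.0, size=m.shape) * peak
        matrices.append(m)
    mset = MultiExcitationSet(wavelengths=grid, excitations=excitations,
                              quencher_concs=Q, matrices=matrices)
    truth = {"K": K, "C": C, "S": S, "Q_actual": Q_actual, "weights": weights}
    return mset, truth
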