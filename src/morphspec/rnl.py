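"""Receptor-noise-limited colour distances and tetrahedral colour space.

Quantum catches are unit-step Riemann sums Q_i = sum_lambda R I S_i on the
1 nm grid; signals are Weber--Fechner log catches f_i = ln Q_i. Chromatic
distance between two stimuli is the noise-scaled opponent distance

    dS = sqrt(N / D),  with, for a tetrachromat,
    N = e1^2 e2^2 (df4-df3)^2 + e1^2 e3^2 (df4-df2)^2 + e1^2 e4^2 (df3-df2)^2
      + e2^2 e3^2 (df4-df1)^2 + e2^2 e4^2 (df3-df1)^2 + e3^2 e4^2 (df2-df1)^2
    D = (e1 e2 e3)^2 + (e1 e2 e4)^2 + (e1 e3 e4)^2 + (e2 e3 e4)^2

(df_i the per-channel log-catch differences, e_i the channel noise), and
achromatic distance is dL = |df_A| / omega_A, both in JND units. The
general n-channel form replaces each numerator term by the product of the
squared noises of all *other* channels, so the same code serves di-, tri-
and tetrachromats.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .receptors import Illuminant, VisualSystem
from .spectra import SpectralDataset

__all__ = [
    "QuantumCatchTable",
    "ColorDistanceMatrix",
    "JND_THRESHOLD",
    "JND_EASY",
    "quantum_catches",
    "chromatic_distance",
    "chromatic_distance_quadratic",
    "achromatic_distance",
    "pairwise_distance_matrices",
    "tetra_coordinates",
    "TETRA_VERTICES",
]

# Reporting thresholds: 1 JND = discrimination threshold; >= 3 JND = easily
# discriminable even in poor light.
JND_THRESHOLD = 1.0
JND_EASY = 3.0


@dataclass(frozen=True)
class QuantumCatchTable:
    """Per-individual receptor catches under one visual system + illuminant."""

    ids: tuple
    channels: tuple
    Q: np.ndarray  # (n_individuals, n_channels) raw catches
    Q_achro: np.ndarray  # (n_individuals,)
    visual_system: str
    illuminant: str

    @property
    def f(self) -> np.ndarray:
        """Log catches ln Q."""
        return np.log(self.Q)

    @property
    def f_achro(self) -> np.ndarray:
        return np.log(self.Q_achro)

    @property
    def relative(self) -> np.ndarray:
        """Relative catches q_i = Q_i / sum(Q), rows summing to 1."""
        return self.Q / self.Q.sum(axis=1, keepdims=True)

    @property
    def n(self) -> int:
        return len(self.ids)

    def row(self, individual: str) -> np.ndarray:
        return self.Q[self.ids.index(individual)]

    def to_frame(self, kind: str = "raw") -> pd.DataFrame:
        data = {"raw": self.Q, "log": self.f, "relative": self.relative}[kind]
        df = pd.DataFrame(data, columns=list(self.channels))
        df.insert(0, "individual_id", list(self.ids))
        if kind == "raw":
            df["achro"] = self.Q_achro
        elif kind == "log":
            df["achro"] = self.f_achro
        return df


def quantum_catches(ds: SpectralDataset, vs: VisualSystem,
                    ill: Illuminant) -> QuantumCatchTable:
    """Photon catches per individual and receptor channel.

    Q_i = sum_lambda R(lambda) I(lambda) S_i(lambda) over the shared 1 nm
    grid, including the achromatic channel. A zero catch (spectrum not
    overlapping a sensitivity band) is an error naming individual and
    channel, since log signals would be undefined.
    """
    if len(ds.grid) != len(vs.grid) or not np.allclose(ds.grid, vs.grid):
        raise ValueError("spectra and visual system are on different grids")
    if len(ds.grid) != len(ill.grid) or not np.allclose(ds.grid, ill.grid):
        raise ValueError("spectra and illuminant are on different grids")
    R = ds.array()  # (n_wl, n_ind)
    weighted = ill.irradiance[:, None] * R  # (n_wl, n_ind)
    Q = (vs.sensitivities @ weighted).T  # (n_ind, n_chan)
    Qa = vs.achromatic @ weighted  # (n_ind,)
    bad = np.argwhere(Q <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive quantum catch for individual {ds.ids[i]!r}, "
            f"channel {vs.spec.channels[j]!r}"
        )
    if np.any(Qa <= 0):
        i = int(np.argwhere(Qa <= 0)[0][0])
        raise ValueError(f"non-positive achromatic catch for {ds.ids[i]!r}")
    return QuantumCatchTable(
        ids=tuple(ds.ids), channels=tuple(vs.spec.channels),
        Q=Q, Q_achro=Qa, visual_system=vs.name, illuminant=ill.name,
    )


def _delta_f(a, b) -> np.ndarray:
    fa = np.log(np.asarray(a, dtype=float))
    fb = np.log(np.asarray(b, dtype=float))
    return fa - fb


def chromatic_distance(a, b, vs: VisualSystem) -> float:
    """Chromatic JND distance between two catch vectors (raw catches)."""
    return float(_rnl_from_df(_delta_f(a, b)[None, :], vs.noise)[0])


def _rnl_from_df(df: np.ndarray, e: np.ndarray) -> np.ndarray:
    """General n-channel RNL distance for rows of log-catch differences."""
    e = np.asarray(e, dtype=float)
    n = len(e)
    if df.shape[1] != n:
        raise ValueError("channel count mismatch between signals and noise")
    if n < 2:
        raise ValueError("need at least 2 receptor channels")
    e2 = e ** 2
    prod_all = np.prod(e2)
    denom = np.sum(prod_all / e2)  # sum over i of prod_{k != i} e_k^2
    num = np.zeros(df.shape[0])
    for i, j in combinations(range(n), 2):
        coef = prod_all / (e2[i] * e2[j])  # prod over k not in {i, j}
        num += coef * (df[:, i] - df[:, j]) ** 2
    return np.sqrt(num / denom)


def chromatic_distance_quadratic(a, b, vs: VisualSystem) -> float:
    """Mahalanobis-form evaluation of the same chromatic distance.

    The RNL distance is the norm of the log-catch difference under noise
    covariance diag(e_i^2), restricted to the chromatic hyperplane
    (orthogonal to uniform intensity shifts):

        dS^2 = df' (W - W 1 1' W / (1' W 1)) df,   W = diag(1/e_i^2).

    Kept as an independent route for cross-checking the closed form.
    """
    df = _delta_f(a, b)
    w = 1.0 / vs.noise ** 2
    s = w.sum()
    M = np.diag(w) - np.outer(w, w) / s
    return float(np.sqrt(df @ M @ df))


def achromatic_distance(a_achro, b_achro, vs: VisualSystem) -> float:
    """Achromatic JND distance dL = |ln Qa - ln Qb| / omega_achromatic."""
    return float(abs(np.log(float(a_achro)) - np.log(float(b_achro)))
                 / vs.omega_achromatic)


@dataclass(frozen=True)
class ColorDistanceMatrix:
    """Symmetric pairwise chromatic and achromatic JND matrices."""

    ids: tuple
    chromatic: np.ndarray
    achromatic: np.ndarray
    visual_system: str
    illuminant: str

    def __post_init__(self):
        for m in (self.chromatic, self.achromatic):
            if m.shape != (len(self.ids), len(self.ids)):
                raise ValueError("distance matrix shape mismatch")

    def frame(self, channel: str = "chromatic") -> pd.DataFrame:
        m = self.chromatic if channel == "chromatic" else self.achromatic
        return pd.DataFrame(m, index=list(self.ids), columns=list(self.ids))


def pairwise_distance_matrices(t: QuantumCatchTable,
                               vs: VisualSystem) -> ColorDistanceMatrix:
    """All-pairs dS and dL matrices (zero diagonal, symmetric)."""
    if t.n < 2:
        raise ValueError("need at least 2 individuals for pairwise distances")
    f = t.f
    iu, ju = np.triu_indices(t.n, k=1)
    d = _rnl_from_df(f[iu] - f[ju], vs.noise)
    ds_mat = np.zeros((t.n, t.n))
    ds_mat[iu, ju] = d
    ds_mat += ds_mat.T
    fa = t.f_achro
    dl_mat = np.abs(fa[:, None] - fa[None, :]) / vs.omega_achromatic
    np.fill_diagonal(dl_mat, 0.0)
    return ColorDistanceMatrix(
        ids=t.ids, chromatic=ds_mat, achromatic=dl_mat,
        visual_system=t.visual_system, illuminant=t.illuminant,
    )


# Tetrahedron with the UV vertex on the vertical axis and the achromatic
# point (equal stimulation) at the origin; S/M/L on the base plane.
TETRA_VERTICES = np.array([
    [0.0, 0.0, 0.75],  # u
    [-np.sqrt(6.0) / 4.0, -np.sqrt(2.0) / 4.0, -0.25],  # s
    [np.sqrt(6.0) / 4.0, -np.sqrt(2.0) / 4.0, -0.25],  # m
    [0.0, np.sqrt(2.0) / 2.0, -0.25],  # l
])


def tetra_coordinates(t: QuantumCatchTable) -> pd.DataFrame:
    """Tetrahedral colour-space coordinates from relative catches.

    Each individual maps to the convex combination of the four cone
    vertices weighted by its relative catches (u, s, m, l); equal
    stimulation lands at the origin.
    """
    if len(t.channels) != 4:
        raise ValueError("tetrahedral coordinates require a tetrachromat")
    xyz = t.relative @ TETRA_VERTICES
    df = pd.DataFrame(xyz, columns=["x", "y", "z"])
    df.insert(0, "individual_id", list(t.ids))
    return df
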