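"""Visual systems (pigment templates, cone abundances, noise) and illuminants.

Receptor sensitivities are built from the A1 visual-pigment nomogram
(Govardovskii-type alpha band plus beta band) at configured peak
wavelengths, area-normalised on the 300--700 nm grid. Channel noise
follows the receptor-noise parameterisation

    e_i = omega_ref * sqrt(eta_ref / eta_i)

where omega_ref is the Weber fraction of the reference (long-wavelength)
cone and eta the relative cone abundances, so the stated Weber fraction
applies exactly to the LW channel.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_GRID",
    "VisualSystemSpec",
    "VisualSystem",
    "Illuminant",
    "pigment_template",
    "noise_vector",
    "build_visual_system",
    "builtin_visual_system",
    "load_visual_system_config",
    "load_illuminant",
    "forest_shade_illuminant",
    "energy_to_quanta",
    "BUILTIN_SYSTEMS",
]

DEFAULT_GRID = np.arange(300.0, 701.0, 1.0)
BUILTIN_SYSTEMS = ("lizard", "bird", "snake")


def pigment_template(lmax: float, grid=None) -> np.ndarray:
    """A1 visual-pigment nomogram at peak ``lmax``, area-normalised.

    Alpha band: S(x) = 1 / (exp(A(a - x)) + exp(B(b - x)) + exp(C(c - x)) + D)
    with x = lmax/lambda, A=69.7, B=28, b=0.922, C=-14.9, c=1.104, D=0.674
    and a = 0.8795 + 0.0459 exp(-(lmax - 300)^2 / 11940); plus the standard
    beta band (Gaussian at 189 + 0.315 lmax with width -40.5 + 0.195 lmax,
    amplitude 0.26 of the alpha peak).
    """
    wl = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if not (wl[0] <= lmax <= wl[-1]):
        raise ValueError(f"lambda_max {lmax} outside grid [{wl[0]}, {wl[-1]}]")
    x = lmax / wl
    a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lmb = 189.0 + 0.315 * lmax
    bb = -40.5 + 0.195 * lmax
    beta = 0.26 * np.exp(-(((wl - lmb) / bb) ** 2))
    s = alpha + beta
    s = s / s.max()  # peak 1 before area normalisation
    return s / s.sum()


def noise_vector(eta, weber_ref: float, ref_index: int = -1) -> np.ndarray:
    """Per-channel noise e_i = omega_ref * sqrt(eta_ref / eta_i)."""
    eta = np.asarray(eta, dtype=float)
    if np.any(eta <= 0) or weber_ref <= 0:
        raise ValueError("cone abundances and Weber fraction must be positive")
    return weber_ref * np.sqrt(eta[ref_index] / eta)


@dataclass(frozen=True)
class VisualSystemSpec:
    """Configuration of a visual system (peaks, abundances, noise)."""

    name: str
    lambda_max: tuple  # nm per chromatic channel, increasing
    eta: tuple  # relative cone abundances, same length
    weber_ref: float  # Weber fraction of the reference (last, LW) channel
    channels: tuple = ("u", "s", "m", "l")
    achromatic_channel: str = "l"  # which sensitivity curve drives luminance
    achromatic_weber: float | None = None  # defaults to weber_ref

    def __post_init__(self):
        lm, eta = tuple(self.lambda_max), tuple(self.eta)
        object.__setattr__(self, "lambda_max", lm)
        object.__setattr__(self, "eta", eta)
        if len(lm) != len(eta) or len(lm) < 2:
            raise ValueError("lambda_max and eta must match, with >= 2 channels")
        ch = tuple(self.channels)[: len(lm)] if len(self.channels) >= len(lm) else \
            tuple(f"c{i}" for i in range(len(lm)))
        object.__setattr__(self, "channels", ch)
        if any(b <= a for a, b in zip(lm, lm[1:])):
            raise ValueError("lambda_max values must be strictly increasing")
        if any(e <= 0 for e in eta) or self.weber_ref <= 0:
            raise ValueError("eta and weber_ref must be positive")
        if self.achromatic_channel not in ch:
            raise ValueError(f"unknown achromatic channel {self.achromatic_channel!r}")

    @property
    def n_channels(self) -> int:
        return len(self.lambda_max)

    @property
    def omega_achromatic(self) -> float:
        return self.weber_ref if self.achromatic_weber is None else self.achromatic_weber

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "lambda_max": list(self.lambda_max),
            "eta": list(self.eta),
            "weber_ref": self.weber_ref,
            "channels": list(self.channels),
            "achromatic": {
                "channel": self.achromatic_channel,
                "weber": self.omega_achromatic,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VisualSystemSpec":
        ach = d.get("achromatic", {})
        return cls(
            name=d["name"],
            lambda_max=tuple(d["lambda_max"]),
            eta=tuple(d["eta"]),
            weber_ref=float(d["weber_ref"]),
            channels=tuple(d.get("channels", ("u", "s", "m", "l"))),
            achromatic_channel=ach.get("channel", "l"),
            achromatic_weber=ach.get("weber"),
        )


@dataclass(frozen=True)
class VisualSystem:
    """Realised visual system: sensitivity curves and noise on a grid."""

    spec: VisualSystemSpec
    grid: np.ndarray
    sensitivities: np.ndarray  # (n_channels, n_wavelengths), each area = 1
    achromatic: np.ndarray  # (n_wavelengths,), area = 1
    noise: np.ndarray = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "noise",
                           noise_vector(self.spec.eta, self.spec.weber_ref))

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def n_channels(self) -> int:
        return self.spec.n_channels

    @property
    def omega_achromatic(self) -> float:
        return self.spec.omega_achromatic


def build_visual_system(spec: VisualSystemSpec, grid=None,
                        custom_curves: pd.DataFrame | None = None,
                        transmission: np.ndarray | None = None) -> VisualSystem:
    """Build curves from templates (or a curves table) and derive noise.

    ``custom_curves``, if given, is a DataFrame with a ``wl`` column plus
    one column per channel, overriding the pigment templates. An optional
    ocular-media ``transmission`` curve multiplies every channel before
    normalisation.
    """
    wl = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if custom_curves is not None:
        missing = [c for c in spec.channels if c not in custom_curves.columns]
        if missing or "wl" not in custom_curves.columns:
            raise ValueError(f"curves table missing columns: {missing or ['wl']}")
        src_wl = custom_curves["wl"].to_numpy(dtype=float)
        if src_wl[0] > wl[0] or src_wl[-1] < wl[-1]:
            raise ValueError("custom curves do not cover the grid")
        S = np.vstack([
            np.interp(wl, src_wl, custom_curves[c].to_numpy(dtype=float))
            for c in spec.channels
        ])
        if np.any(S < 0):
            raise ValueError("negative sensitivity in custom curves")
    else:
        S = np.vstack([pigment_template(lm, wl) for lm in spec.lambda_max])
    if transmission is not None:
        S = S * np.asarray(transmission, dtype=float)[None, :]
    S = S / S.sum(axis=1, keepdims=True)
    ach = S[spec.channels.index(spec.achromatic_channel)].copy()
    return VisualSystem(spec=spec, grid=wl, sensitivities=S, achromatic=ach)


def load_visual_system_config(path) -> VisualSystemSpec:
    with open(path) as fh:
        return VisualSystemSpec.from_dict(yaml.safe_load(fh))


def builtin_visual_system(name: str, grid=None) -> VisualSystem:
    """One of the bundled systems: ``lizard``, ``bird`` or ``snake``.

    Peak sensitivities ship in editable YAML configs (``morphspec/data``):
    they come from the source literature for a lacertid lizard, a
    violet-sensitive raptor and a colubrid snake, since only the abundance
    ratios and Weber fractions are fixed by the study design (lizard and
    snake 1:1:1:4 with omega_LW = 0.05, bird 1:2:2:4 with omega = 0.10).
    """
    if name not in BUILTIN_SYSTEMS:
        raise ValueError(f"unknown builtin system {name!r}; choose from {BUILTIN_SYSTEMS}")
    ref = resources.files("morphspec.data") / f"{name}.yaml"
    with resources.as_file(ref) as path:
        spec = load_visual_system_config(path)
    return build_visual_system(spec, grid)


@dataclass(frozen=True)
class Illuminant:
    """Ambient irradiance I(lambda), tracked as energy or quanta units."""

    name: str
    grid: np.ndarray
    irradiance: np.ndarray
    units: str = "quanta"  # or "energy"

    def __post_init__(self):
        irr = np.asarray(self.irradiance, dtype=float)
        if np.any(irr < 0):
            raise ValueError("negative irradiance")
        if not np.any(irr > 0):
            raise ValueError("illuminant is identically zero")
        if self.units not in ("quanta", "energy"):
            raise ValueError(f"units must be 'quanta' or 'energy', got {self.units!r}")
        object.__setattr__(self, "irradiance", irr)
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))


def energy_to_quanta(ill: Illuminant) -> Illuminant:
    """Convert an energy-unit illuminant to relative quanta (I *= lambda).

    Output is renormalised to unit mean. Converting an illuminant already
    in quanta is an error (the flag is tracked to prevent double conversion).
    """
    if ill.units != "energy":
        raise ValueError(f"illuminant {ill.name!r} is already in quanta units")
    q = ill.irradiance * ill.grid
    q = q / q.mean()
    return Illuminant(ill.name, ill.grid, q, units="quanta")


def _regrid_illuminant(name, wl, irr, grid, units, quanta=True) -> Illuminant:
    if wl[0] > grid[0] or wl[-1] < grid[-1]:
        raise ValueError(
            f"illuminant grid [{wl[0]}, {wl[-1]}] does not cover "
            f"[{grid[0]}, {grid[-1]}]"
        )
    out = np.interp(grid, wl, irr)
    ill = Illuminant(name, grid, out, units=units)
    if quanta and units == "energy":
        ill = energy_to_quanta(ill)
    return ill


def load_illuminant(source: str = "d65", grid=None, units: str = "energy",
                    quanta: bool = True) -> Illuminant:
    """Load a builtin illuminant (``d65``, ``forestshade``) or a CSV file.

    Files need columns ``wl`` and ``irradiance`` covering the grid; the
    ``units`` flag states what the file contains. By default the result is
    converted to relative quanta (unit mean), which is the scale quantum
    catches are defined on. Absolute scale is irrelevant to JND distances.
    """
    wl_grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if source == "d65":
        ref = resources.files("morphspec.data") / "d65.csv"
        with resources.as_file(ref) as path:
            tab = pd.read_csv(path)
        return _regrid_illuminant("d65", tab["wl"].to_numpy(dtype=float),
                                  tab["irradiance"].to_numpy(dtype=float),
                                  wl_grid, "energy", quanta)
    if source == "forestshade":
        return forest_shade_illuminant(grid=wl_grid)
    tab = pd.read_csv(source)
    for col in ("wl", "irradiance"):
        if col not in tab.columns:
            raise ValueError(f"illuminant file missing column {col!r}")
    irr = tab["irradiance"].to_numpy(dtype=float)
    if np.any(irr < 0):
        raise ValueError("negative irradiance in illuminant file")
    return _regrid_illuminant(str(source), tab["wl"].to_numpy(dtype=float),
                              irr, wl_grid, units, quanta)


def forest_shade_illuminant(peak_nm: float = 550.0, red_rise_nm: float = 680.0,
                            gauss_width: float = 60.0, rise_width: float = 8.0,
                            weights: tuple = (1.0, 0.5), grid=None) -> Illuminant:
    """Parametric forest-shade irradiance: yellow-green peak + far-red rise.

    A broad Gaussian centred at ``peak_nm`` (the canopy-filtered green
    peak) plus a logistic rise beginning near ``red_rise_nm``, normalised
    to unit mean quanta. Measured forest-shade spectra can be supplied via
    ``load_illuminant(<file>)`` instead.
    """
    wl = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if gauss_width <= 0 or rise_width <= 0:
        raise ValueError("degenerate widths")
    if not (wl[0] <= peak_nm <= wl[-1]) or not (wl[0] <= red_rise_nm <= wl[-1]):
        raise ValueError("peaks must lie within the grid")
    w_peak, w_rise = weights
    gauss = np.exp(-(((wl - peak_nm) / gauss_width) ** 2))
    rise = 1.0 / (1.0 + np.exp(-(wl - red_rise_nm) / rise_width))
    irr = w_peak * gauss + w_rise * rise
    irr = irr / irr.mean()
    return Illuminant("forestshade", wl, irr, units="quanta")
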