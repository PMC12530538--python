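"""Synthetic morph-structured reflectance datasets.

The generator emulates the statistical structure of a three-morph throat
colour study: orange and yellow morphs are long-wavelength cut-ons
(logistic step with morph-specific inflection), the white morph has a
high, nearly flat reflectance rising in the blue, and a subset of white
and orange individuals carries a UV reflectance spike near 370 nm.
Individuals vary in cut-on position and amplitude; replicate measurements
add iid electrical noise, clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .spectra import SpectralDataset

__all__ = [
    "MorphProfile",
    "StudyConfig",
    "generate_individual",
    "generate_dataset",
    "default_study_config",
    "DEFAULT_GROUP_SIZES",
]

# morph x sex group sizes of the default study design (total 102, 52M:50F)
DEFAULT_GROUP_SIZES = {
    ("orange", "M"): 23, ("orange", "F"): 22,
    ("white", "M"): 13, ("white", "F"): 12,
    ("yellow", "M"): 16, ("yellow", "F"): 16,
}


@dataclass(frozen=True)
class MorphProfile:
    """Spectral shape parameters of one morph."""

    name: str
    baseline: float  # percent reflectance floor
    amplitude: float  # cut-on step height (percent)
    cuton_center: float  # nm, inflection of the logistic step
    cuton_steepness: float  # nm, logistic scale
    uv_spike_prob: float = 0.0  # fraction of individuals with a UV spike
    uv_center: float = 370.0
    uv_width: float = 12.0
    uv_height: float = 14.0
    replicate_noise_sd: float = 1.5  # percent, per replicate and wavelength
    center_sd: float = 5.0  # between-individual sd of the cut-on centre
    amplitude_sd: float = 5.0  # between-individual sd of the amplitude

    def __post_init__(self):
        if not (0.0 <= self.uv_spike_prob <= 1.0):
            raise ValueError("uv_spike_prob must be in [0, 1]")
        for nm, v in (("uv_width", self.uv_width),
                      ("cuton_steepness", self.cuton_steepness)):
            if v <= 0:
                raise ValueError(f"{nm} must be positive")
        for nm, v in (("replicate_noise_sd", self.replicate_noise_sd),
                      ("center_sd", self.center_sd),
                      ("amplitude_sd", self.amplitude_sd)):
            if v < 0:
                raise ValueError(f"{nm} must be nonnegative")
        if not (300.0 <= self.cuton_center <= 700.0):
            raise ValueError("cuton_center must lie within 300-700 nm")


@dataclass(frozen=True)
class StudyConfig:
    """Full design: group sizes, replicates, grid, seed and morph profiles."""

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    replicates: int = 6
    grid: np.ndarray = field(default_factory=lambda: np.arange(300.0, 701.0))
    seed: int = 0
    profiles: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")

    def to_dict(self) -> dict:
        return {
            "group_sizes": {f"{m}_{s}": n for (m, s), n in self.group_sizes.items()},
            "replicates": self.replicates,
            "grid": [float(self.grid[0]), float(self.grid[-1])],
            "seed": self.seed,
            "profiles": {k: asdict(v) for k, v in self.profiles.items()},
        }


def _default_profiles() -> dict:
    # Cut-on centres sit where each morph's mid-reflectance wavelength
    # should land: orange ~541 nm, yellow ~502 nm, white rising in the
    # blue (~410 nm) with a high floor so its chroma is lowest. UV-spike
    # prevalence matches the observed subsets (10/25 white, 4/45 orange).
    return {
        "orange": MorphProfile(
            name="orange", baseline=5.0, amplitude=80.0,
            cuton_center=541.0, cuton_steepness=10.0,
            uv_spike_prob=4.0 / 45.0, uv_height=12.0,
            center_sd=5.0, amplitude_sd=6.0,
        ),
        "white": MorphProfile(
            name="white", baseline=15.0, amplitude=48.0,
            cuton_center=410.0, cuton_steepness=22.0,
            uv_spike_prob=10.0 / 25.0, uv_height=15.0,
            center_sd=5.0, amplitude_sd=5.0,
        ),
        "yellow": MorphProfile(
            name="yellow", baseline=6.0, amplitude=72.0,
            cuton_center=502.0, cuton_steepness=12.0,
            uv_spike_prob=0.0,
            center_sd=4.0, amplitude_sd=5.0,
        ),
    }


def default_study_config(seed: int = 0, separation_scale: float = 1.0) -> StudyConfig:
    """The default three-morph design: 102 individuals, 6 replicates each.

    ``separation_scale`` moves the orange and yellow cut-on centres away
    from (scale > 1) or toward (scale < 1) the white morph's centre,
    keeping everything else fixed — useful for sensitivity analyses of
    discriminability versus spectral separation.
    """
    profiles = _default_profiles()
    if separation_scale != 1.0:
        ref = profiles["white"].cuton_center
        for k in ("orange", "yellow"):
            p = profiles[k]
            new_center = ref + separation_scale * (p.cuton_center - ref)
            new_center = float(np.clip(new_center, 310.0, 690.0))
            d = asdict(p)
            d["cuton_center"] = new_center
            profiles[k] = MorphProfile(**d)
    return StudyConfig(seed=seed, profiles=profiles)


def generate_individual(profile: MorphProfile, rng: np.random.Generator,
                        grid=None, replicates: int = 6):
    """Latent spectrum and replicate measurements for one individual.

    latent = baseline + amplitude * logistic((lambda - centre)/steepness)
    plus an optional Gaussian UV spike (Bernoulli draw); replicates add
    iid Gaussian noise and are clipped at zero.

    Returns ``(latent, replicates_array)`` with replicates of shape
    (n_wavelengths, n_replicates).
    """
    wl = np.arange(300.0, 701.0) if grid is None else np.asarray(grid, dtype=float)
    center = profile.cuton_center + rng.normal(0.0, profile.center_sd)
    amplitude = max(profile.amplitude + rng.normal(0.0, profile.amplitude_sd), 1.0)
    latent = profile.baseline + amplitude / (
        1.0 + np.exp(-(wl - center) / profile.cuton_steepness))
    if rng.random() < profile.uv_spike_prob:
        latent = latent + profile.uv_height * np.exp(
            -(((wl - profile.uv_center) / profile.uv_width) ** 2))
    noise = rng.normal(0.0, profile.replicate_noise_sd, size=(len(wl), replicates)) \
        if profile.replicate_noise_sd > 0 else np.zeros((len(wl), replicates))
    reps = np.clip(latent[:, None] + noise, 0.0, None)
    return latent, reps


def generate_dataset(cfg: StudyConfig):
    """Generate the full study: wide spectra dataset + metadata table.

    Measurement columns are named ``<individual>_<replicate>``; the
    metadata has one row per individual (individual_id, morph, sex).
    Per-individual random streams are spawned from the config seed, so
    output is reproducible and order-independent.
    """
    profiles = cfg.profiles or _default_profiles()
    slots = [(m, s) for (m, s), n in cfg.group_sizes.items() for _ in range(n)]
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(slots))
    cols, meta_rows = {}, []
    counter: dict = {}
    for (morph, sex), child in zip(slots, children):
        if morph not in profiles:
            raise ValueError(f"no profile for morph {morph!r}")
        counter[(morph, sex)] = counter.get((morph, sex), 0) + 1
        ind = f"{morph}_{sex}{counter[(morph, sex)]:02d}"
        rng = np.random.default_rng(child)
        _, reps = generate_individual(profiles[morph], rng, cfg.grid,
                                      cfg.replicates)
        for r in range(cfg.replicates):
            cols[f"{ind}_{r + 1}"] = reps[:, r]
        meta_rows.append({"individual_id": ind, "morph": morph, "sex": sex})
    meta = pd.DataFrame(meta_rows, columns=["individual_id", "morph", "sex"])
    values = pd.DataFrame(cols) if cols else pd.DataFrame(index=range(len(cfg.grid)))
    ds = SpectralDataset(np.asarray(cfg.grid, dtype=float), values,
                         provenance=[f"simulate:seed={cfg.seed}"])
    return ds, meta
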