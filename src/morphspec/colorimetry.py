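"""Colorimetric variables: brightness, chroma and hue, with group summaries.

Brightness is the mean reflectance over the analysed range, chroma the
reflectance span scaled by brightness ((Rmax - Rmin)/brightness), and hue
the wavelength at middle reflectance, i.e. the grid wavelength whose
reflectance is closest to (Rmax + Rmin)/2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spectra import SpectralDataset, Spectrum, validate_metadata

__all__ = [
    "brightness",
    "chroma",
    "hue",
    "hue_detail",
    "colorimetric_table",
    "summarize_groups",
]


def _refl(s) -> np.ndarray:
    r = s.reflectance if isinstance(s, Spectrum) else np.asarray(s, dtype=float)
    if r.size == 0:
        raise ValueError("empty spectrum")
    return r


def brightness(s) -> float:
    """Mean reflectance over the spectral range."""
    return float(np.mean(_refl(s)))


def chroma(s) -> float:
    """(Rmax - Rmin) / mean brightness; 0 iff the spectrum is constant."""
    r = _refl(s)
    b = float(np.mean(r))
    if b <= 0:
        raise ValueError("chroma undefined for zero (or negative) brightness")
    return float((r.max() - r.min()) / b)


def hue_detail(s) -> tuple[float, int]:
    """Hue plus the number of crossings of the mid-reflectance level.

    Returns ``(hue_nm, n_crossings)``. More than one crossing (e.g. a UV
    spike on a cut-on spectrum) makes "wavelength at middle reflectance"
    ambiguous; the nearest-to-Rmid grid point is returned, ties broken
    toward the shorter wavelength.
    """
    if isinstance(s, Spectrum):
        wl, r = s.wavelengths, s.reflectance
    else:
        wl, r = s
        wl, r = np.asarray(wl, dtype=float), np.asarray(r, dtype=float)
    if r.size == 0:
        raise ValueError("empty spectrum")
    rmax, rmin = r.max(), r.min()
    if rmax == rmin:
        raise ValueError("hue undefined for a constant spectrum")
    rmid = 0.5 * (rmax + rmin)
    idx = int(np.argmin(np.abs(r - rmid)))  # argmin keeps the first (shortest) tie
    sign = np.sign(r - rmid)
    nz = sign[sign != 0]
    n_crossings = int(np.sum(np.diff(nz) != 0)) if nz.size else 0
    return float(wl[idx]), max(n_crossings, 1)


def hue(s) -> float:
    """Wavelength (nm) at middle reflectance (Rmax + Rmin)/2."""
    return hue_detail(s)[0]


def colorimetric_table(ds: SpectralDataset) -> pd.DataFrame:
    """Per-spectrum brightness, chroma and hue as a DataFrame."""
    rows = []
    for spec in ds.spectra():
        h, k = hue_detail(spec)
        rows.append({
            "individual_id": spec.name,
            "brightness": brightness(spec),
            "chroma": chroma(spec),
            "hue": h,
            "hue_ambiguous": k > 1,
        })
    return pd.DataFrame(rows)


def summarize_groups(ds: SpectralDataset, meta: pd.DataFrame) -> pd.DataFrame:
    """Morph x sex summary: n, mean brightness, mean chroma, hue.

    Brightness and chroma are arithmetic means of per-individual values.
    ``hue`` (primary, as conventionally printed) is the hue of the group
    mean spectrum; ``hue_mean_individual`` is the mean of per-individual
    hues, given for comparison.
    """
    meta = validate_metadata(meta)
    per = colorimetric_table(ds).set_index("individual_id")
    missing = set(ds.ids) - set(meta["individual_id"])
    if missing:
        raise ValueError(f"individuals without metadata: {sorted(missing)}")
    rows = []
    for (morph, sex), grp in meta.groupby(["morph", "sex"], sort=False):
        members = [i for i in grp["individual_id"] if i in per.index]
        if not members:
            raise ValueError(f"empty group {morph}/{sex}")
        sub = per.loc[members]
        mean_spec = ds.values[members].to_numpy().mean(axis=1)
        rows.append({
            "morph": morph,
            "sex": sex,
            "n": len(members),
            "brightness": float(sub["brightness"].mean()),
            "chroma": float(sub["chroma"].mean()),
            "hue": hue((ds.grid, mean_spec)),
            "hue_mean_individual": float(sub["hue"].mean()),
        })
    out = pd.DataFrame(rows)
    order = {m: i for i, m in enumerate(("orange", "white", "yellow"))}
    return out.sort_values(
        ["morph", "sex"],
        key=lambda c: c.map(order) if c.name == "morph" else c.map({"M": 0, "F": 1}),
    ).reset_index(drop=True)
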