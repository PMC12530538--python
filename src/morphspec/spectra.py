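"""Reading, validation and preprocessing of reflectance spectra.

Spectra are stored wide: one wavelength column plus one column per
measurement. Processing for the discrimination analysis follows the
conventional order restrict -> aggregate replicates -> smooth -> validate,
yielding one non-negative spectrum per individual on the integer
300--700 nm grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectralDataset",
    "read_spectra",
    "write_spectra",
    "read_metadata",
    "validate_metadata",
    "restrict_and_regrid",
    "aggregate_replicates",
    "smooth_spectra",
    "validate_nonnegative",
    "process_dataset",
]

MORPHS = ("orange", "white", "yellow")
SEXES = ("M", "F")


@dataclass(frozen=True)
class Spectrum:
    """A single reflectance spectrum R(lambda) in percent reflectance."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    name: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or wl.shape != r.shape:
            raise ValueError("wavelengths and reflectance must be 1-D and equal length")
        if len(wl) and np.any(np.diff(wl) <= 0):
            raise ValueError("non-monotone wavelengths")
        if not np.all(np.isfinite(r)):
            raise ValueError(f"non-finite reflectance in spectrum {self.name!r}")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", r)


@dataclass
class SpectralDataset:
    """Ordered collection of spectra sharing one wavelength grid.

    ``values`` has one row per grid wavelength and one column per
    measurement id; column order is meaningful and preserved.
    """

    grid: np.ndarray
    values: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 1:
            raise ValueError("grid must be 1-D")
        if len(self.grid) != len(self.values):
            raise ValueError("grid length does not match value rows")
        if len(self.grid) > 1 and np.any(np.diff(self.grid) <= 0):
            raise ValueError("non-monotone wavelengths")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate measurement ids: {dupes}")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("non-finite reflectance values in dataset")

    @property
    def ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_spectra(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return self.n_spectra

    def __getitem__(self, key: str) -> Spectrum:
        return Spectrum(self.grid, self.values[key].to_numpy(), name=key)

    def spectra(self):
        for key in self.ids:
            yield self[key]

    def array(self) -> np.ndarray:
        """Values as (n_wavelengths, n_spectra) float array."""
        return self.values.to_numpy(dtype=float)

    def with_values(self, arr: np.ndarray, step: str | None = None,
                    columns=None) -> "SpectralDataset":
        cols = self.values.columns if columns is None else columns
        df = pd.DataFrame(np.asarray(arr, dtype=float), columns=cols)
        prov = self.provenance + ([step] if step else [])
        return SpectralDataset(self.grid.copy(), df, provenance=prov)


def read_spectra(path, wl_column: str = "wl") -> SpectralDataset:
    """Read a wide-format spectra CSV on its native grid.

    The file must have a wavelength column (default ``wl``) and at least
    one measurement column. Non-numeric cells and duplicated column names
    are errors; column order is preserved.
    """
    import csv

    with open(path, newline="") as fh:
        cols = next(csv.reader(fh))
    if wl_column not in cols:
        raise ValueError(f"missing wavelength column {wl_column!r} in {path}")
    seen, dupes = set(), []
    for c in cols:
        if c in seen:
            dupes.append(c)
        seen.add(c)
    if dupes:
        raise ValueError(f"duplicate column names: {dupes}")
    df = pd.read_csv(path, float_precision="round_trip")
    meas = [c for c in cols if c != wl_column]
    if not meas:
        raise ValueError("no measurement columns")
    for c in cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        if converted.isna().any() and not df[c].isna().any():
            bad = df[c][converted.isna()].iloc[0]
            raise ValueError(f"non-numeric cell {bad!r} in column {c!r}")
        if converted.isna().any():
            raise ValueError(f"missing value in column {c!r}")
        df[c] = converted.astype(float)
    wl = df[wl_column].to_numpy()
    if np.any(np.diff(wl) <= 0):
        raise ValueError("non-monotone wavelengths")
    return SpectralDataset(wl, df[meas].reset_index(drop=True),
                           provenance=[f"read:{path}"])


def write_spectra(ds: SpectralDataset, path, wl_column: str = "wl") -> None:
    """Write a dataset in the same wide CSV layout ``read_spectra`` expects."""
    out = pd.concat([pd.DataFrame({wl_column: ds.grid}),
                     ds.values.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    required = {"individual_id", "morph", "sex"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if meta["individual_id"].duplicated().any():
        dupes = meta.loc[meta["individual_id"].duplicated(), "individual_id"].tolist()
        raise ValueError(f"duplicate individual ids in metadata: {dupes}")
    bad_morph = set(meta["morph"]) - set(MORPHS)
    if bad_morph:
        raise ValueError(f"unknown morphs {sorted(bad_morph)}; expected {MORPHS}")
    bad_sex = set(meta["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sexes {sorted(bad_sex)}; expected {SEXES}")
    return meta.reset_index(drop=True)


def read_metadata(path) -> pd.DataFrame:
    """Read the sample table (columns individual_id, morph, sex)."""
    return validate_metadata(pd.read_csv(path, dtype=str))


def restrict_and_regrid(ds: SpectralDataset, lo: float = 300.0,
                        hi: float = 700.0) -> SpectralDataset:
    """Linearly interpolate every spectrum onto the integer 1 nm grid lo..hi.

    The source grid must cover [lo, hi]; wavelengths outside are dropped.
    """
    if ds.grid[0] > lo or ds.grid[-1] < hi:
        raise ValueError(
            f"source grid [{ds.grid[0]}, {ds.grid[-1]}] does not cover [{lo}, {hi}]"
        )
    target = np.arange(float(lo), float(hi) + 0.5, 1.0)
    vals = ds.array()
    out = np.empty((len(target), vals.shape[1]))
    for j in range(vals.shape[1]):
        out[:, j] = np.interp(target, ds.grid, vals[:, j])
    df = pd.DataFrame(out, columns=ds.values.columns)
    return SpectralDataset(target, df,
                           provenance=ds.provenance + [f"restrict:{lo}-{hi}"])


def measurement_to_individual(measurement_ids, meta: pd.DataFrame) -> dict:
    """Map measurement ids named ``<individual>_<replicate>`` to individuals."""
    known = set(meta["individual_id"])
    mapping = {}
    for mid in measurement_ids:
        if mid in known:  # already individual-level
            mapping[mid] = mid
            continue
        ind = mid.rsplit("_", 1)[0]
        if ind not in known:
            raise ValueError(f"measurement {mid!r} has no metadata entry")
        mapping[mid] = ind
    return mapping


def aggregate_replicates(ds: SpectralDataset, meta: pd.DataFrame) -> SpectralDataset:
    """Average replicate measurements per individual (pointwise mean).

    Output holds one spectrum per individual, keyed and ordered by
    ``individual_id`` as listed in the metadata.
    """
    meta = validate_metadata(meta)
    mapping = measurement_to_individual(ds.ids, meta)
    vals = ds.array()
    cols = {}
    for ind in meta["individual_id"]:
        members = [j for j, mid in enumerate(ds.ids) if mapping[mid] == ind]
        if not members:
            raise ValueError(f"individual {ind!r} has no measurements")
        cols[ind] = vals[:, members].mean(axis=1)
    df = pd.DataFrame(cols)
    return SpectralDataset(ds.grid.copy(), df,
                           provenance=ds.provenance + ["aggregate"])


def _loess_matrix(n: int, span: float) -> np.ndarray:
    """Hat matrix of a tricube-weighted local quadratic regression.

    The window at each grid point is the ``ceil(span * n)`` nearest points;
    tricube weights are taken on distance normalised by the window radius.
    Rows reproduce constants and straight lines exactly (the local quadratic
    fit is unbiased for polynomials up to degree 2).
    """
    k = int(np.ceil(span * n))
    k = min(max(k, 4), n)
    H = np.zeros((n, n))
    idx = np.arange(n)
    for i in range(n):
        start = min(max(i - (k - 1) // 2, 0), n - k)
        win = idx[start:start + k]
        d = np.abs(win - i).astype(float)
        dmax = d.max()
        if dmax == 0:
            H[i, win] = 1.0
            continue
        w = (1.0 - np.minimum(d / dmax, 1.0) ** 3) ** 3
        w[w <= 0] = 1e-12  # boundary point of its own window
        t = (win - i).astype(float)
        X = np.column_stack([np.ones_like(t), t, t * t])
        XtW = X.T * w
        beta_row = np.linalg.solve(XtW @ X, XtW)[0]
        H[i, win] = beta_row
    return H


def smooth_spectra(ds: SpectralDataset, span: float = 0.2) -> SpectralDataset:
    """Smooth each spectrum by local quadratic regression (loess-style).

    ``span`` is the fraction of grid points in each local window,
    in (0, 1]. The grid is unchanged.
    """
    if not (0 < span <= 1):
        raise ValueError(f"span must be in (0, 1], got {span}")
    H = _loess_matrix(len(ds.grid), span)
    return ds.with_values(H @ ds.array(), step=f"smooth:span={span}")


def validate_nonnegative(ds: SpectralDataset, fix: str = "error"):
    """Check for sub-zero reflectance values.

    With ``fix='error'`` any negative value raises, naming the measurement
    and wavelength. With ``fix='clip_zero'`` negatives are set to 0.
    Returns ``(dataset, n_clipped)``.
    """
    if fix not in ("error", "clip_zero"):
        raise ValueError(f"fix must be 'error' or 'clip_zero', got {fix!r}")
    vals = ds.array()
    neg = vals < 0
    count = int(neg.sum())
    if count == 0:
        return ds.with_values(vals, step="validate:ok"), 0
    if fix == "error":
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"negative reflectance {vals[i, j]:.4g} in measurement "
            f"{ds.ids[j]!r} at {ds.grid[i]:.0f} nm ({count} total)"
        )
    return ds.with_values(np.maximum(vals, 0.0),
                          step=f"validate:clipped={count}"), count


def process_dataset(ds: SpectralDataset, meta: pd.DataFrame, *,
                    lo: float = 300.0, hi: float = 700.0, span: float = 0.2,
                    smooth_before_aggregate: bool = False,
                    negative_policy: str = "error") -> SpectralDataset:
    """Full preprocessing chain: restrict -> aggregate -> smooth -> validate.

    Replicate averaging precedes smoothing by default; set
    ``smooth_before_aggregate`` to smooth replicate-level spectra instead.
    """
    out = restrict_and_regrid(ds, lo, hi)
    if smooth_before_aggregate:
        out = smooth_spectra(out, span)
        out = aggregate_replicates(out, meta)
    else:
        out = aggregate_replicates(out, meta)
        out = smooth_spectra(out, span)
    out, n_clipped = validate_nonnegative(out, fix=negative_policy)
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} negative values to zero")
    return out
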