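"""Group-level inference: bootstrap JND distances, PERMANOVA, dispersions.

All Monte-Carlo procedures take an explicit seed and carry it (with the
replicate count) in their results, so every run is reproducible from its
own provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd

from .receptors import VisualSystem
from .rnl import QuantumCatchTable, _rnl_from_df
from .spectra import validate_metadata

__all__ = [
    "BootDistResult",
    "PermanovaResult",
    "DispersionResult",
    "boot_group_distance",
    "permanova",
    "pairwise_permanova",
    "dispersion_test",
    "boot_results_frame",
    "permanova_results_frame",
]


@dataclass(frozen=True)
class BootDistResult:
    pair: str
    channel: str  # "chromatic" | "achromatic"
    point: float  # JND between full-sample group centroids
    ci_low: float
    ci_high: float
    B: int
    seed: int
    visual_system: str = ""
    illuminant: str = ""


@dataclass(frozen=True)
class PermanovaResult:
    comparison: str
    df: int
    ss: float  # between-group sum of squares
    ss_within: float
    ss_total: float
    F: float
    R2: float
    p: float
    p_adjusted: float
    n_perm: int
    seed: int

    def __post_init__(self):
        if not (0.0 <= self.R2 <= 1.0 + 1e-12):
            raise ValueError(f"R2 out of range: {self.R2}")


@dataclass(frozen=True)
class DispersionResult:
    groups: tuple
    mean_distances: tuple  # per-group mean distance to own centroid
    F: float
    p: float
    n_perm: int
    seed: int
    note: str = "Levene-style test on distances to group centroids (metric scaling)"


def _group_indices(ids, meta: pd.DataFrame) -> dict:
    meta = validate_metadata(meta)
    morph_of = dict(zip(meta["individual_id"], meta["morph"]))
    missing = [i for i in ids if i not in morph_of]
    if missing:
        raise ValueError(f"individuals without metadata: {missing}")
    groups: dict[str, list[int]] = {}
    for k, ind in enumerate(ids):
        groups.setdefault(morph_of[ind], []).append(k)
    return groups


def boot_group_distance(t: QuantumCatchTable, meta: pd.DataFrame,
                        vs: VisualSystem, pairs=None, B: int = 1000,
                        seed: int = 0, level: float = 0.95,
                        centroid: str = "log") -> list[BootDistResult]:
    """Bootstrap chromatic and achromatic distances between group centroids.

    The point estimate is the RNL distance between full-sample group
    centroids (per-channel mean of log catches by default; ``centroid='raw'``
    averages raw catches before taking logs). Each replicate resamples
    individuals with replacement within each group; the CI is the
    percentile interval over ``B`` replicates.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    groups = _group_indices(t.ids, meta)
    for g, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    if pairs is None:
        pairs = [tuple(p) for p in combinations(sorted(groups), 2)]
    else:
        for a, b in pairs:
            if a not in groups or b not in groups:
                raise ValueError(f"unknown pair label {(a, b)!r}")
    if centroid not in ("log", "raw"):
        raise ValueError("centroid must be 'log' or 'raw'")
    if centroid == "log":
        sig, sig_a = np.log(t.Q), np.log(t.Q_achro)
    else:
        sig, sig_a = t.Q, t.Q_achro

    def cent(s, idx_mat):
        # mean over the sampled-individual axis: -2 for per-channel
        # signals, -1 for the scalar achromatic signal
        m = s[idx_mat].mean(axis=-2 if s.ndim == 2 else -1)
        return np.log(m) if centroid == "raw" else m
    alpha = (1.0 - level) / 2.0
    rng = np.random.default_rng(seed)
    results = []
    for a, b in pairs:
        ia = np.asarray(groups[a])
        ib = np.asarray(groups[b])
        # full-sample centroids
        fa, fb = cent(sig, ia), cent(sig, ib)
        faa, fba = cent(sig_a, ia), cent(sig_a, ib)
        point_c = float(_rnl_from_df((fa - fb)[None, :], vs.noise)[0])
        point_a = float(abs(faa - fba) / vs.omega_achromatic)
        # resampled centroids, vectorised over replicates
        ra = ia[rng.integers(0, len(ia), size=(B, len(ia)))]
        rb = ib[rng.integers(0, len(ib), size=(B, len(ib)))]
        dfc = cent(sig, ra) - cent(sig, rb)  # (B, n_chan)
        boot_c = _rnl_from_df(dfc, vs.noise)
        boot_a = np.abs(cent(sig_a, ra) - cent(sig_a, rb)) / vs.omega_achromatic
        for channel, point, boot in (("chromatic", point_c, boot_c),
                                     ("achromatic", point_a, boot_a)):
            lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
            results.append(BootDistResult(
                pair=f"{a}-{b}", channel=channel, point=point,
                ci_low=float(lo), ci_high=float(hi), B=B, seed=seed,
                visual_system=t.visual_system, illuminant=t.illuminant,
            ))
    return results


def _ss_decomposition(D2: np.ndarray, labels: np.ndarray):
    """Total/within sums of squares from a squared distance matrix."""
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ss_total = D2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += np.triu(sub, k=1).sum() / len(idx)
    return ss_total, ss_within


def _pseudo_f(D2, labels, n_groups):
    n = len(labels)
    ss_total, ss_within = _ss_decomposition(D2, labels)
    ss_between = ss_total - ss_within
    df_b, df_w = n_groups - 1, n - n_groups
    if ss_within <= 0:
        return np.inf, ss_total, ss_within, ss_between
    F = (ss_between / df_b) / (ss_within / df_w)
    return F, ss_total, ss_within, ss_between


def permanova(D: np.ndarray, labels, n_perm: int = 999, seed: int = 0,
              method: str = "permutation", comparison: str = "",
              bonferroni_m: int = 1) -> PermanovaResult:
    """Distance-based one-way PERMANOVA.

    SS_total = (1/N) sum_{i<j} d_ij^2; SS_within sums (1/n_g) over
    within-group pairs; pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a)).
    ``method='permutation'`` permutes labels uniformly at random, with
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm); ``method='exact'``
    enumerates all distinct label orderings (small N only).
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T) or np.any(D < 0) or np.any(np.diag(D) != 0):
        raise ValueError("need a symmetric nonnegative matrix with zero diagonal")
    uniq = np.unique(labels)
    a = len(uniq)
    if a < 2 or n < 3:
        raise ValueError("need >= 2 groups and >= 3 observations")
    D2 = D ** 2
    F_obs, ss_total, ss_within, ss_between = _pseudo_f(D2, labels, a)
    if method == "exact":
        stats = []
        seen = set()
        for perm in permutations(range(n)):
            key = tuple(labels[list(perm)])
            if key in seen:
                continue
            seen.add(key)
            stats.append(_pseudo_f(D2, np.asarray(key), a)[0])
        stats = np.asarray(stats)
        p = float(np.mean(stats >= F_obs - 1e-12))
        n_used = len(stats)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm_labels = labels[rng.permutation(n)]
            if _pseudo_f(D2, perm_labels, a)[0] >= F_obs - 1e-12:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + n_perm)
        n_used = n_perm
    else:
        raise ValueError("method must be 'permutation' or 'exact'")
    return PermanovaResult(
        comparison=comparison or "-".join(str(u) for u in uniq),
        df=a - 1, ss=float(ss_between), ss_within=float(ss_within),
        ss_total=float(ss_total), F=float(F_obs),
        R2=float(ss_between / ss_total) if ss_total > 0 else 0.0,
        p=float(p), p_adjusted=float(min(1.0, p * bonferroni_m)),
        n_perm=n_used, seed=seed,
    )


def pairwise_permanova(D: np.ndarray, labels, adjust: str = "bonferroni",
                       n_perm: int = 999, seed: int = 0) -> list[PermanovaResult]:
    """One PERMANOVA per unordered group pair, Bonferroni-adjusted.

    The Bonferroni multiplier is the number of pairs compared; pass
    ``adjust='none'`` for raw p-values.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError("adjust must be 'bonferroni' or 'none'")
    labels = np.asarray(labels)
    uniq = sorted(np.unique(labels))
    pairs = list(combinations(uniq, 2))
    m = len(pairs) if adjust == "bonferroni" else 1
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(pairs))]
    results = []
    for (ga, gb), child in zip(pairs, child_seeds):
        mask = np.isin(labels, [ga, gb])
        results.append(permanova(
            np.asarray(D)[np.ix_(mask, mask)], labels[mask], n_perm=n_perm,
            seed=child, comparison=f"{ga}-{gb}", bonferroni_m=m,
        ))
    return results


def _pcoa(D: np.ndarray) -> np.ndarray:
    """Classical metric scaling; negative eigenvalues truncated."""
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-10, 1e-8 * max(abs(vals[0]), 1.0))
    if vals[-1] < -tol:
        warnings.warn("negative eigenvalues truncated in metric scaling")
    keep = vals > tol
    return vecs[:, keep] * np.sqrt(vals[keep])


def dispersion_test(D: np.ndarray, labels, n_perm: int = 999,
                    seed: int = 0) -> DispersionResult:
    """Multivariate homogeneity of group dispersions (Levene analogue).

    Embeds the distance matrix by classical metric scaling, measures each
    sample's distance to its own group centroid, and tests group equality
    of those distances with a one-way ANOVA F whose null is generated by
    permuting the group labels of the distances.
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    if not np.any(D > 0):
        raise ValueError("all-zero distance matrix")
    X = _pcoa(D)
    uniq = np.unique(labels)
    dist = np.empty(len(labels))
    for g in uniq:
        idx = labels == g
        cen = X[idx].mean(axis=0)
        dist[idx] = np.linalg.norm(X[idx] - cen, axis=1)

    def anova_f(z, lab):
        grand = z.mean()
        ssb = sum((z[lab == g].mean() - grand) ** 2 * np.sum(lab == g) for g in uniq)
        ssw = sum(((z[lab == g] - z[lab == g].mean()) ** 2).sum() for g in uniq)
        df_b, df_w = len(uniq) - 1, len(z) - len(uniq)
        tol = 1e-12 * max(float(np.sum(z ** 2)), 1e-300)
        if ssw <= tol:
            return 0.0 if ssb <= tol else np.inf
        return (ssb / df_b) / (ssw / df_w)

    F_obs = anova_f(dist, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if anova_f(dist, labels[rng.permutation(len(labels))]) >= F_obs - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    means = tuple(float(dist[labels == g].mean()) for g in uniq)
    return DispersionResult(groups=tuple(uniq), mean_distances=means,
                            F=float(F_obs), p=float(p), n_perm=n_perm, seed=seed)


def boot_results_frame(results: list[BootDistResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def permanova_results_frame(results: list[PermanovaResult]) -> pd.DataFrame:
    cols = ["comparison", "df", "ss", "F", "p", "p_adjusted", "R2",
            "ss_within", "ss_total", "n_perm", "seed"]
    return pd.DataFrame([r.__dict__ for r in results])[cols]
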