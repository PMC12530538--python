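"""Model/Results interface over the discrimination analysis.

``ReceptorNoiseModel`` binds a processed spectral dataset, sample
metadata, a visual system and an illuminant; ``fit`` computes quantum
catches, pairwise JND distance matrices, bootstrap group distances and
pairwise PERMANOVAs (with the dispersion check) and returns a
``ReceptorNoiseResults`` carrying estimates, intervals and a printable
summary, in the style of statsmodels model objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import group_stats, rnl, spectra
from .receptors import (Illuminant, VisualSystem, builtin_visual_system,
                        load_illuminant)

__all__ = ["ReceptorNoiseModel", "ReceptorNoiseResults"]


class ReceptorNoiseModel:
    """Receptor-noise-limited discrimination model for grouped spectra.

    Parameters
    ----------
    dataset : SpectralDataset
        One spectrum per individual on the 300--700 nm grid (use
        ``from_raw``/``process_dataset`` to get there from replicate-level
        measurements).
    metadata : DataFrame
        Columns ``individual_id``, ``morph``, ``sex``.
    visual_system : VisualSystem or builtin name
    illuminant : Illuminant or builtin name ("d65", "forestshade")
    """

    def __init__(self, dataset: spectra.SpectralDataset, metadata: pd.DataFrame,
                 visual_system, illuminant):
        self.dataset = dataset
        self.metadata = spectra.validate_metadata(metadata)
        self.visual_system: VisualSystem = (
            builtin_visual_system(visual_system, grid=dataset.grid)
            if isinstance(visual_system, str) else visual_system)
        self.illuminant: Illuminant = (
            load_illuminant(illuminant, grid=dataset.grid)
            if isinstance(illuminant, str) else illuminant)
        missing = set(dataset.ids) - set(self.metadata["individual_id"])
        if missing:
            raise ValueError(f"individuals without metadata: {sorted(missing)}")

    @classmethod
    def from_raw(cls, dataset: spectra.SpectralDataset, metadata: pd.DataFrame,
                 visual_system, illuminant, span: float = 0.2,
                 smooth_before_aggregate: bool = False,
                 negative_policy: str = "error") -> "ReceptorNoiseModel":
        """Build from replicate-level spectra, running the processing chain."""
        processed = spectra.process_dataset(
            dataset, metadata, span=span,
            smooth_before_aggregate=smooth_before_aggregate,
            negative_policy=negative_policy)
        return cls(processed, metadata, visual_system, illuminant)

    @classmethod
    def from_csv(cls, spectra_path, meta_path, visual_system, illuminant,
                 **kwargs) -> "ReceptorNoiseModel":
        ds = spectra.read_spectra(spectra_path)
        meta = spectra.read_metadata(meta_path)
        return cls.from_raw(ds, meta, visual_system, illuminant, **kwargs)

    def fit(self, n_boot: int = 1000, n_perm: int = 999,
            seed: int = 0) -> "ReceptorNoiseResults":
        """Run catches, distances, bootstrap and PERMANOVA for this model."""
        catches = rnl.quantum_catches(self.dataset, self.visual_system,
                                      self.illuminant)
        matrices = rnl.pairwise_distance_matrices(catches, self.visual_system)
        labels = self._labels(catches.ids)
        ss = np.random.SeedSequence(seed)
        seed_boot, seed_chrom, seed_achro, seed_disp = (
            int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4))
        boot = group_stats.boot_group_distance(
            catches, self.metadata, self.visual_system, B=n_boot, seed=seed_boot)
        perm = {
            "chromatic": group_stats.pairwise_permanova(
                matrices.chromatic, labels, n_perm=n_perm, seed=seed_chrom),
            "achromatic": group_stats.pairwise_permanova(
                matrices.achromatic, labels, n_perm=n_perm, seed=seed_achro),
        }
        disp = {
            ch: group_stats.dispersion_test(getattr(matrices, ch), labels,
                                            n_perm=n_perm, seed=seed_disp)
            for ch in ("chromatic", "achromatic")
        }
        tetra = (rnl.tetra_coordinates(catches)
                 if self.visual_system.n_channels == 4 else None)
        return ReceptorNoiseResults(
            model=self, catches=catches, matrices=matrices, boot=boot,
            permanova=perm, dispersion=disp, tetra=tetra,
            seed=seed, n_boot=n_boot, n_perm=n_perm)

    def _labels(self, ids) -> np.ndarray:
        morph_of = dict(zip(self.metadata["individual_id"], self.metadata["morph"]))
        return np.asarray([morph_of[i] for i in ids])


@dataclass
class ReceptorNoiseResults:
    """Fitted discriminability results for one visual system x illuminant."""

    model: ReceptorNoiseModel
    catches: rnl.QuantumCatchTable
    matrices: rnl.ColorDistanceMatrix
    boot: list  # BootDistResult
    permanova: dict  # channel -> list[PermanovaResult]
    dispersion: dict  # channel -> DispersionResult
    tetra: pd.DataFrame | None
    seed: int
    n_boot: int
    n_perm: int

    @property
    def boot_frame(self) -> pd.DataFrame:
        df = group_stats.boot_results_frame(self.boot)
        df["above_threshold"] = df["ci_low"] > rnl.JND_THRESHOLD
        df["easily_discriminable"] = df["point"] >= rnl.JND_EASY
        return df

    def permanova_frame(self, channel: str = "chromatic") -> pd.DataFrame:
        df = group_stats.permanova_results_frame(self.permanova[channel])
        df.insert(0, "illuminant", self.catches.illuminant)
        df.insert(0, "system", self.catches.visual_system)
        df.insert(2, "channel", channel)
        return df

    def summary(self) -> str:
        vs, ill = self.catches.visual_system, self.catches.illuminant
        lines = [
            "Receptor-noise-limited discrimination results",
            "=" * 45,
            f"visual system: {vs}   illuminant: {ill}",
            f"individuals: {self.catches.n}   channels: {len(self.catches.channels)}",
            f"seed: {self.seed}   bootstrap B: {self.n_boot}   permutations: {self.n_perm}",
            "",
            "Group distances (JND, 95% percentile CI)",
            "-" * 45,
        ]
        for r in self.boot:
            flag = (" ***" if r.point >= rnl.JND_EASY
                    else " *" if r.point > rnl.JND_THRESHOLD else "")
            lines.append(f"{r.pair:>16s} {r.channel:>10s} "
                         f"{r.point:7.3f} [{r.ci_low:6.3f}, {r.ci_high:6.3f}]{flag}")
        lines += ["", "Pairwise PERMANOVA (Bonferroni-adjusted p)", "-" * 45]
        for ch in ("chromatic", "achromatic"):
            for r in self.permanova[ch]:
                lines.append(
                    f"{r.comparison:>16s} {ch:>10s} df={r.df} SS={r.ss:8.4f} "
                    f"F={r.F:9.3f} R2={r.R2:6.4f} p(adj)={r.p_adjusted:6.3f}")
        lines += ["", "Dispersion (Levene analogue): " + "; ".join(
            f"{ch} F={d.F:.3f} p={d.p:.3f}" for ch, d in self.dispersion.items())]
        lines.append("(* > 1 JND threshold, *** >= 3 JND easily discriminable)")
        return "\n".join(lines)
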