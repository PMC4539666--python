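"""Domain containers for dose-response expression profiles.

Doses are coded as ordinal indices 1..m (control = 1), not physical
concentrations, so that logarithms and negative powers of the dose are
always defined.  Values are log2 fold changes versus the control dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IN_VITRO = "in_vitro"
IN_VIVO = "in_vivo"
SYSTEMS = (IN_VITRO, IN_VIVO)


@dataclass(frozen=True)
class DoseDesign:
    """Layout of a dose-response experiment.

    Parameters
    ----------
    n_replicates : tuple of int
        Replicate count per dose level; its length is the number of dose
        levels ``m``.  Dose indices run 1..m.
    """

    n_replicates: tuple[int, ...]

    def __post_init__(self):
        if len(self.n_replicates) < 2:
            raise ValueError("need at least 2 dose levels")
        if any(int(n) < 1 for n in self.n_replicates):
            raise ValueError("each dose level needs >= 1 replicate")
        object.__setattr__(
            self, "n_replicates", tuple(int(n) for n in self.n_replicates)
        )

    @property
    def m(self) -> int:
        return len(self.n_replicates)

    @property
    def n_obs(self) -> int:
        return int(sum(self.n_replicates))

    @property
    def dose_indices(self) -> np.ndarray:
        """Per-observation dose index, 1..m, replicates contiguous."""
        return np.repeat(np.arange(1, self.m + 1), self.n_replicates)

    @classmethod
    def balanced(cls, m: int, n_per_dose: int) -> "DoseDesign":
        return cls((n_per_dose,) * m)


#: TG-GATEs-like defaults: 4 dose levels (control + 3 active),
#: 2 replicates per dose in vitro, 3 in vivo.
TGP_VITRO_DESIGN = DoseDesign((2, 2, 2, 2))
TGP_VIVO_DESIGN = DoseDesign((3, 3, 3, 3))


@dataclass
class ExpressionProfile:
    """Replicated expression of one gene under one compound in one system.

    ``dose_idx[j]`` is the 1-based dose level of observation ``j`` and
    ``values[j]`` its log2 fold change versus control.
    """

    gene_id: str
    compound_id: str
    system: str
    dose_idx: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.dose_idx = np.asarray(self.dose_idx, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.system not in SYSTEMS:
            raise ValueError(f"system must be one of {SYSTEMS}, got {self.system!r}")
        if self.dose_idx.shape != self.values.shape or self.dose_idx.ndim != 1:
            raise ValueError("dose_idx and values must be 1-d arrays of equal length")
        if self.dose_idx.size and self.dose_idx.min() < 1:
            raise ValueError("dose indices must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")

    @property
    def n_obs(self) -> int:
        return self.values.size

    @property
    def n_dose_levels(self) -> int:
        return np.unique(self.dose_idx).size

    def dose_means(self) -> dict[int, float]:
        return {
            int(i): float(self.values[self.dose_idx == i].mean())
            for i in np.unique(self.dose_idx)
        }


@dataclass
class CombinedProfile:
    """Pooled two-system observations for one gene x compound.

    ``system_code`` is 1 for in vitro and 2 for in vivo.
    """

    gene_id: str
    compound_id: str
    dose_idx: np.ndarray
    system_code: np.ndarray
    values: np.ndarray = field(default=None)

    def __post_init__(self):
        self.dose_idx = np.asarray(self.dose_idx, dtype=int)
        self.system_code = np.asarray(self.system_code, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.dose_idx.shape == self.system_code.shape == self.values.shape):
            raise ValueError("dose_idx, system_code and values must align")
        codes = set(np.unique(self.system_code).tolist())
        if not codes <= {1, 2}:
            raise ValueError("system_code must be 1 (in vitro) or 2 (in vivo)")
        if codes != {1, 2}:
            raise ValueError("combined profile must contain both systems")

    @classmethod
    def from_profiles(
        cls, vitro: ExpressionProfile, vivo: ExpressionProfile
    ) -> "CombinedProfile":
        if vitro.gene_id != vivo.gene_id or vitro.compound_id != vivo.compound_id:
            raise ValueError(
                "profiles refer to different genes/compounds: "
                f"({vitro.gene_id}, {vitro.compound_id}) vs "
                f"({vivo.gene_id}, {vivo.compound_id})"
            )
        if vitro.system != IN_VITRO or vivo.system != IN_VIVO:
            raise ValueError("expected (in_vitro, in_vivo) profile pair")
        return cls(
            gene_id=vitro.gene_id,
            compound_id=vitro.compound_id,
            dose_idx=np.concatenate([vitro.dose_idx, vivo.dose_idx]),
            system_code=np.concatenate(
                [np.ones(vitro.n_obs, int), np.full(vivo.n_obs, 2)]
            ),
            values=np.concatenate([vitro.values, vivo.values]),
        )

    @property
    def n_obs(self) -> int:
        return self.values.size
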