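"""Synthetic paired in vitro / in vivo dose-response data and the two
validation studies of the disconnect method's operating characteristics.

The generator emulates a TG-GATEs-like design: 4 dose levels (control +
3 active), 2 replicates per dose in vitro and 3 in vivo, i.i.d. Gaussian
noise on the log2 fold-change scale.  Seven scenario kinds cover the no-
disconnect null and six disconnected patterns (opposite profiles, or a
dose effect in only one system, each either linear or second-order
fractional polynomial in shape).

Study 1 estimates per-scenario sensitivity/specificity of the raw
disconnect test at level alpha.  Study 2 mimics a genome-scale screen:
datasets of half null / half disconnected genes, BH-adjusted calls at
FDR q, with per-dataset sensitivity, specificity, empirical FDR/FNR and
ROC curves averaged on a fixed false-positive-rate grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from ._batch import BatchDesign, p_from_rss
from .disconnect import adjust_bh
from .fp import eval_f, eval_g
from .profiles import (
    IN_VITRO,
    IN_VIVO,
    DoseDesign,
    ExpressionProfile,
    TGP_VITRO_DESIGN,
    TGP_VIVO_DESIGN,
)

SCENARIO_KINDS = (
    "null_flat",
    "opposite_linear",
    "opposite_fp2",
    "vivo_only_linear",
    "vivo_only_fp2",
    "vitro_only_linear",
    "vitro_only_fp2",
)

#: Default residual standard deviation (log2 fold-change units).
DEFAULT_SIGMA = 0.25
#: Default FP2 shape powers for the nonlinear scenarios.
DEFAULT_TRUTH_POWERS = (0.5, 2.0)
_SIGMA_FLOOR = 1e-12


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario.

    ``delta`` is the maximal |mean| of the active system's profile in
    log2 units; for "opposite" kinds the maximal between-system
    dose-specific fold change is therefore ``2 * delta``, for "only"
    kinds it equals ``delta``.
    """

    kind: str
    delta: float = 0.6
    sigma: float = DEFAULT_SIGMA
    vitro_design: DoseDesign = TGP_VITRO_DESIGN
    vivo_design: DoseDesign = TGP_VIVO_DESIGN
    truth_powers: tuple[float, float] = DEFAULT_TRUTH_POWERS

    def __post_init__(self):
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"kind must be one of {SCENARIO_KINDS}")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.vitro_design.m != self.vivo_design.m:
            raise ValueError("both systems must share the dose levels")

    @property
    def m(self) -> int:
        return self.vitro_design.m

    @property
    def is_disconnected(self) -> bool:
        return self.kind != "null_flat"

    @property
    def max_between_system_fc(self) -> float:
        if self.kind == "null_flat":
            return 0.0
        return 2 * self.delta if self.kind.startswith("opposite") else self.delta


def _unit_curve(kind: str, m: int, truth_powers) -> np.ndarray:
    """Per-dose shape, 0 at control, rescaled to max |value| = 1."""
    i = np.arange(1, m + 1, dtype=float)
    if kind.endswith("linear"):
        c = (i - 1) / (m - 1)
    else:
        p1, p2 = truth_powers
        u = eval_f(i, p1) + eval_g(i, p1, p2)
        c = u - u[0]
    amp = np.abs(c).max()
    if amp == 0:
        raise ValueError(f"degenerate FP2 shape at powers {truth_powers}")
    return c / amp


def mean_profile(spec: ScenarioSpec, system: str) -> np.ndarray:
    """Per-dose mean log2 fold change for one system under a scenario."""
    if system not in (IN_VITRO, IN_VIVO):
        raise ValueError("system must be in_vitro or in_vivo")
    m = spec.m
    if spec.kind == "null_flat":
        return np.zeros(m)
    if spec.kind.startswith("vitro_only") and system == IN_VIVO:
        return np.zeros(m)
    if spec.kind.startswith("vivo_only") and system == IN_VITRO:
        return np.zeros(m)
    mu = spec.delta * _unit_curve(spec.kind, m, spec.truth_powers)
    if spec.kind.startswith("opposite") and system == IN_VIVO:
        mu = -mu
    return mu


def simulate_gene(
    spec: ScenarioSpec, rng: np.random.Generator, gene_id: str = "g0",
    compound_id: str = "sim",
) -> tuple[ExpressionProfile, ExpressionProfile]:
    """Draw one paired (in vitro, in vivo) profile under a scenario."""
    sigma = max(spec.sigma, _SIGMA_FLOOR)
    out = []
    for system, design in (
        (IN_VITRO, spec.vitro_design),
        (IN_VIVO, spec.vivo_design),
    ):
        idx = design.dose_indices
        mu = mean_profile(spec, system)[idx - 1]
        out.append(
            ExpressionProfile(
                gene_id=gene_id,
                compound_id=compound_id,
                system=system,
                dose_idx=idx,
                values=mu + rng.normal(0.0, sigma, idx.size),
            )
        )
    return tuple(out)


def _simulate_batch(spec: ScenarioSpec, n: int, rng: np.random.Generator):
    """(Y_vitro, Y_vivo) matrices of n genes under one scenario."""
    idx_v = spec.vitro_design.dose_indices
    idx_w = spec.vivo_design.dose_indices
    mu_v = mean_profile(spec, IN_VITRO)[idx_v - 1]
    mu_w = mean_profile(spec, IN_VIVO)[idx_w - 1]
    sigma = max(spec.sigma, _SIGMA_FLOOR)
    Yv = mu_v[None, :] + rng.normal(0.0, sigma, (n, idx_v.size))
    Yw = mu_w[None, :] + rng.normal(0.0, sigma, (n, idx_w.size))
    return Yv, Yw


def default_study1_scenarios(
    delta: float = 0.6, sigma: float = DEFAULT_SIGMA, **kwargs
) -> list[ScenarioSpec]:
    """All seven scenario kinds at a common amplitude and noise level."""
    return [
        ScenarioSpec(kind=k, delta=(0.0 if k == "null_flat" else delta),
                     sigma=sigma, **kwargs)
        for k in SCENARIO_KINDS
    ]


@dataclass
class StudyResult:
    """Operating characteristics of a simulation study."""

    scenario_metrics: pd.DataFrame | None = None  # study 1
    per_dataset: pd.DataFrame | None = None       # study 2
    roc_fpr: np.ndarray | None = None
    roc_tpr_mean: np.ndarray | None = None
    mean_auc: float = np.nan

    def _mean(self, col: str) -> float:
        return float(self.per_dataset[col].mean())

    @property
    def mean_sensitivity(self) -> float:
        return self._mean("sensitivity")

    @property
    def mean_specificity(self) -> float:
        return self._mean("specificity")

    @property
    def mean_fdr(self) -> float:
        return self._mean("fdr")

    @property
    def mean_fnr(self) -> float:
        return self._mean("fnr")


def _disconnect_pvalues(Yv, Yw, bd: BatchDesign, calibration: str):
    _, rss0, rss1, _ = bd.disconnect_rss(Yv, Yw)
    return p_from_rss(rss0, rss1, bd.n, df=3, k_full_mean=6,
                      calibration=calibration)


def run_study1(
    n_rep: int,
    specs: list[ScenarioSpec] | None = None,
    alpha: float = 0.10,
    seed: int = 0,
    calibration: str = "f",
) -> StudyResult:
    """Per-scenario sensitivity/specificity of the raw disconnect test.

    For every scenario, ``n_rep`` independent gene-pairs are simulated
    and tested (powers selected in vitro, projected to in vivo, 3-df
    LRT); a gene is called disconnected when its raw p-value is at most
    ``alpha``.  Specificity is reported for the null scenario and
    sensitivity for the six disconnected ones.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if specs is None:
        specs = default_study1_scenarios()
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specs:
        bd = BatchDesign(spec.vitro_design.dose_indices,
                         spec.vivo_design.dose_indices)
        Yv, Yw = _simulate_batch(spec, n_rep, rng)
        p = _disconnect_pvalues(Yv, Yw, bd, calibration)
        called = p <= alpha
        rate = float(called.mean())
        rows.append({
            "kind": spec.kind,
            "delta": spec.delta,
            "sigma": spec.sigma,
            "n_rep": n_rep,
            "n_called": int(called.sum()),
            "call_rate": rate,
            "sensitivity": rate if spec.is_disconnected else np.nan,
            "specificity": np.nan if spec.is_disconnected else 1.0 - rate,
        })
    return StudyResult(scenario_metrics=pd.DataFrame(rows))


@dataclass
class Study2Dataset:
    """One simulated genome-scale dataset with per-gene truth labels."""

    Y_vitro: np.ndarray
    Y_vivo: np.ndarray
    truth: np.ndarray  # True = genuinely disconnected
    vitro_design: DoseDesign = TGP_VITRO_DESIGN
    vivo_design: DoseDesign = TGP_VIVO_DESIGN


def simulate_dataset_study2(
    n_genes: int = 6000,
    spec: ScenarioSpec | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> Study2Dataset:
    """Half null genes, half FP2-opposite disconnected genes.

    The disconnected half follows a second-order fractional polynomial
    in vitro profile of maximal amplitude ``spec.delta`` (default 1 log2
    unit, the minimal fold change of interest) with the negated profile
    in vivo.
    """
    if n_genes % 2:
        raise ValueError("n_genes must be even (half null, half disconnect)")
    if spec is None:
        spec = ScenarioSpec(kind="opposite_fp2", delta=1.0)
    if rng is None:
        rng = np.random.default_rng(seed)
    half = n_genes // 2
    null_spec = ScenarioSpec(
        kind="null_flat", delta=0.0, sigma=spec.sigma,
        vitro_design=spec.vitro_design, vivo_design=spec.vivo_design,
        truth_powers=spec.truth_powers,
    )
    Yv0, Yw0 = _simulate_batch(null_spec, half, rng)
    Yv1, Yw1 = _simulate_batch(spec, half, rng)
    truth = np.zeros(n_genes, bool)
    truth[half:] = True
    return Study2Dataset(
        Y_vitro=np.vstack([Yv0, Yv1]),
        Y_vivo=np.vstack([Yw0, Yw1]),
        truth=truth,
        vitro_design=spec.vitro_design,
        vivo_design=spec.vivo_design,
    )


def confusion_metrics(calls, truth) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, FDR, FNR) from binary calls vs truth.

    FDR uses the empty-rejection convention FP / max(1, FP + TP) = 0.
    """
    calls = np.asarray(calls, bool)
    truth = np.asarray(truth, bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    tp = int((calls & truth).sum())
    fp = int((calls & ~truth).sum())
    fn = int((~calls & truth).sum())
    tn = int((~calls & ~truth).sum())
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    fdr = fp / max(1, fp + tp)
    fnr = fn / (tp + fn) if (tp + fn) else np.nan
    return sens, spec, fdr, fnr


def roc_points(p_values, truth) -> tuple[np.ndarray, np.ndarray]:
    """ROC staircase (FPR, TPR) sweeping the p-value threshold."""
    p = np.asarray(p_values, float)
    truth = np.asarray(truth, bool)
    if p.shape != truth.shape:
        raise ValueError("p_values and truth must have equal length")
    if truth.all() or not truth.any():
        raise ValueError("truth must contain both classes")
    fpr, tpr, _ = _skm.roc_curve(truth, -p)
    return fpr, tpr


def run_study2(
    n_datasets: int = 100,
    n_genes: int = 600,
    q: float = 0.10,
    spec: ScenarioSpec | None = None,
    seed: int = 0,
    calibration: str = "f",
    n_roc_grid: int = 101,
) -> StudyResult:
    """Genome-scale screen: BH-adjusted disconnect calls at FDR ``q``.

    Per dataset the full pipeline runs (power selection in vitro,
    projected vs interaction LRT per gene, BH across the dataset's
    genes); sensitivity, specificity, empirical FDR and FNR are recorded
    per dataset, and ROC curves are vertically averaged on a fixed
    ``n_roc_grid``-point FPR grid.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    if spec is None:
        spec = ScenarioSpec(kind="opposite_fp2", delta=1.0)
    rng = np.random.default_rng(seed)
    bd = BatchDesign(spec.vitro_design.dose_indices,
                     spec.vivo_design.dose_indices)
    fpr_grid = np.linspace(0.0, 1.0, n_roc_grid)
    tpr_sum = np.zeros(n_roc_grid)
    aucs = []
    rows = []
    for d in range(n_datasets):
        ds = simulate_dataset_study2(n_genes, spec=spec, rng=rng)
        p = _disconnect_pvalues(ds.Y_vitro, ds.Y_vivo, bd, calibration)
        calls = adjust_bh(p) <= q
        sens, specf, fdr, fnr = confusion_metrics(calls, ds.truth)
        fpr, tpr = roc_points(p, ds.truth)
        tpr_sum += np.interp(fpr_grid, fpr, tpr)
        aucs.append(_skm.auc(fpr, tpr))
        rows.append({
            "dataset": d, "n_genes": n_genes, "n_called": int(calls.sum()),
            "sensitivity": sens, "specificity": specf, "fdr": fdr, "fnr": fnr,
            "auc": aucs[-1],
        })
    return StudyResult(
        per_dataset=pd.DataFrame(rows),
        roc_fpr=fpr_grid,
        roc_tpr_mean=tpr_sum / n_datasets,
        mean_auc=float(np.mean(aucs)),
    )
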