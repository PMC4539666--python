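"""In vitro / in vivo disconnect testing.

The workflow per gene and compound:

1. select FP2 powers by AIC on the *source* system (in vitro for the
   ``vitro_to_vivo`` direction, in vivo for ``vivo_to_vitro``);
2. fit the *projected* model — the selected FP2 curve with one shared set
   of coefficients on the pooled two-system data — against the
   *interaction* model, which adds target-system offsets (gamma0, gamma1,
   gamma2) to intercept and both dose terms, sharing a single residual
   variance;
3. a 3-df likelihood ratio test of gamma0 = gamma1 = gamma2 = 0; a
   rejection means the dose-response relationship is disconnected between
   the systems;
4. Benjamini-Hochberg adjustment across genes (per compound and
   direction) at FDR q, plus a fold-change filter discarding genes whose
   maximal dose-specific difference between the systems is below
   ``fc_min`` log2 units.

P-values default to the exact finite-sample calibration of the Gaussian
LRT (its monotone F-statistic transform referred to F(df, N-k)); the
large-sample chi-square reference is available via ``calibration="chisq"``
but is noticeably anti-conservative at TG-GATEs-like sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from ._batch import BatchDesign, p_from_rss
from .fp import CANONICAL_PAIRS, FPFit, fit_ols, fp_design_matrix, select_powers
from .profiles import IN_VITRO, IN_VIVO, CombinedProfile, ExpressionProfile

VITRO_TO_VIVO = "vitro_to_vivo"
VIVO_TO_VITRO = "vivo_to_vitro"
DIRECTIONS = (VITRO_TO_VIVO, VIVO_TO_VITRO)

GROUPS = ("both", "vitro_only", "vivo_only", "neither")


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseTestResult:
    gene_id: str
    compound_id: str
    system: str
    powers: tuple[float, float]
    stat: float
    df: int
    p_raw: float
    significant: bool


@dataclass
class DisconnectTestResult:
    gene_id: str
    compound_id: str
    direction: str
    powers: tuple[float, float]
    gamma: tuple[float, float, float]
    stat: float
    df: int
    p_raw: float
    max_fc: float
    p_bh: float = np.nan
    disconnected: bool | None = None


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def lrt(logL_full: float, logL_reduced: float, df: int) -> tuple[float, float]:
    """Chi-square likelihood ratio test for nested models.

    Returns ``(statistic, p)`` with the statistic clipped at zero.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = max(0.0, 2.0 * (logL_full - logL_reduced))
    return stat, float(stats.chi2.sf(stat, df))


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=0.1, method="fdr_bh")[1]


def max_dose_fold_change(
    vitro: ExpressionProfile,
    vivo: ExpressionProfile,
    mode: str = "between_systems",
) -> float:
    """Maximal dose-specific fold change on the log2 scale.

    The default ``between_systems`` reading is the max over shared doses
    of |per-dose mean difference| between the systems.  The alternative
    ``within_systems`` reading is the max over both systems of the
    profile's own amplitude |per-dose mean| (fold change vs control).
    """
    mv, mw = vitro.dose_means(), vivo.dose_means()
    if mode == "within_systems":
        return max(abs(v) for means in (mv, mw) for v in means.values())
    if mode != "between_systems":
        raise ValueError("mode must be 'between_systems' or 'within_systems'")
    common = sorted(set(mv) & set(mw))
    if not common:
        raise ValueError("profiles share no dose level")
    return max(abs(mv[i] - mw[i]) for i in common)


def classify_gene(vitro_significant: bool, vivo_significant: bool) -> str:
    """Gene grouping by which systems show a significant dose-response."""
    if vitro_significant and vivo_significant:
        return "both"
    if vitro_significant:
        return "vitro_only"
    if vivo_significant:
        return "vivo_only"
    return "neither"


# ---------------------------------------------------------------------------
# model fits on combined two-system data
# ---------------------------------------------------------------------------

def fit_projected(combined: CombinedProfile, powers) -> FPFit:
    """Shared-coefficient FP2 fit on the pooled two-system observations."""
    p1, p2 = powers
    X = fp_design_matrix(combined.dose_idx, p1, p2)
    return fit_ols(combined.values, X, powers=(float(p1), float(p2)))


def fit_interaction(combined: CombinedProfile, powers) -> FPFit:
    """FP2 fit with system-2 offsets on all three mean parameters.

    Coefficients are laid out as (beta0, beta1, beta2, gamma0, gamma1,
    gamma2) where the gammas shift the second system's intercept and dose
    terms; one residual variance is shared across systems.
    """
    p1, p2 = powers
    X = fp_design_matrix(combined.dose_idx, p1, p2)
    ind = (combined.system_code == 2).astype(float)[:, None]
    return fit_ols(combined.values, np.hstack([X, X * ind]), powers=(float(p1), float(p2)))


def test_dose_response(
    profile: ExpressionProfile,
    alpha: float = 0.10,
    calibration: str = "f",
) -> DoseResponseTestResult:
    """2-df LRT of the AIC-selected FP2 model against no dose effect."""
    best = select_powers(profile)
    y = profile.values
    rss0 = float(((y - y.mean()) ** 2).sum())
    stat = max(0.0, profile.n_obs * np.log(max(rss0, 1e-300) / max(best.rss, 1e-300)))
    p = float(
        p_from_rss(rss0, best.rss, profile.n_obs, df=2, k_full_mean=3,
                   calibration=calibration)
    )
    return DoseResponseTestResult(
        gene_id=profile.gene_id,
        compound_id=profile.compound_id,
        system=profile.system,
        powers=best.powers,
        stat=float(stat),
        df=2,
        p_raw=p,
        significant=bool(p <= alpha),
    )


def test_disconnect(
    vitro: ExpressionProfile,
    vivo: ExpressionProfile,
    direction: str = VITRO_TO_VIVO,
    calibration: str = "f",
) -> DisconnectTestResult:
    """3-df disconnect LRT for one gene x compound.

    Powers are selected on the direction's source system; the gamma
    offsets belong to the projected-to (target) system.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if vitro.gene_id != vivo.gene_id or vitro.compound_id != vivo.compound_id:
        raise ValueError("profiles refer to different genes/compounds")
    source, target = (vitro, vivo) if direction == VITRO_TO_VIVO else (vivo, vitro)

    best = select_powers(source)
    # stacked source-first; offsets on the target system
    combined = CombinedProfile(
        gene_id=vitro.gene_id,
        compound_id=vitro.compound_id,
        dose_idx=np.concatenate([source.dose_idx, target.dose_idx]),
        system_code=np.concatenate(
            [np.ones(source.n_obs, int), np.full(target.n_obs, 2)]
        ),
        values=np.concatenate([source.values, target.values]),
    )
    reduced = fit_projected(combined, best.powers)
    full = fit_interaction(combined, best.powers)
    stat = max(0.0, 2.0 * (full.logL - reduced.logL))
    p = float(
        p_from_rss(reduced.rss, full.rss, combined.n_obs, df=3, k_full_mean=6,
                   calibration=calibration)
    )
    return DisconnectTestResult(
        gene_id=vitro.gene_id,
        compound_id=vitro.compound_id,
        direction=direction,
        powers=best.powers,
        gamma=tuple(float(g) for g in full.beta[3:6]),
        stat=float(stat),
        df=3,
        p_raw=p,
        max_fc=max_dose_fold_change(vitro, vivo),
    )


def call_disconnects(
    results: list[DisconnectTestResult],
    q: float = 0.10,
    fc_min: float = 1.0,
) -> list[DisconnectTestResult]:
    """BH-adjust one multiplicity family and apply the fold-change filter.

    The caller groups results into families (per compound per direction by
    default).  A gene is called disconnected when its BH-adjusted p-value
    is at most ``q`` and its maximal dose-specific fold change between the
    systems is at least ``fc_min`` (the boundary value is kept).
    """
    if not results:
        return []
    p_bh = adjust_bh([r.p_raw for r in results])
    return [
        replace(
            r,
            p_bh=float(pb),
            disconnected=bool(pb <= q and r.max_fc >= fc_min),
        )
        for r, pb in zip(results, p_bh)
    ]


# ---------------------------------------------------------------------------
# dataset-level estimator
# ---------------------------------------------------------------------------

class DisconnectAnalyzer(BaseEstimator):
    """Detect genes with disconnected dose-response between systems.

    Runs the full per-compound pipeline on a fold-change expression matrix:
    AIC power selection on the source system, projected vs interaction
    LRT per gene, BH adjustment, fold-change filtering and the per-system
    dose-response grouping.

    Parameters
    ----------
    q : float, default 0.10
        FDR level for the BH-adjusted disconnect calls.
    fc_min : float, default 1.0
        Minimum maximal dose-specific fold change (log2) between systems.
    direction : {"both", "vitro_to_vivo", "vivo_to_vitro"}, default "both"
        Projection direction(s) to analyse.
    alpha_dose_response : float, default 0.10
        Level for the per-system 2-df dose-response tests (gene grouping).
    calibration : {"f", "chisq"}, default "f"
        Null reference for the LRT p-values.
    bh_family : {"per_compound", "global"}, default "per_compound"
        Multiplicity family: across genes within compound x direction, or
        across all gene x compound tests per direction.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per gene x compound x direction with columns gene_id,
        compound_id, direction, p1, p2, gamma0..gamma2, lrt_stat, p_raw,
        p_bh, max_fc, disconnected, group.
    """

    def __init__(self, q=0.10, fc_min=1.0, direction="both",
                 alpha_dose_response=0.10, calibration="f",
                 bh_family="per_compound"):
        self.q = q
        self.fc_min = fc_min
        self.direction = direction
        self.alpha_dose_response = alpha_dose_response
        self.calibration = calibration
        self.bh_family = bh_family

    def _directions(self) -> tuple[str, ...]:
        if self.direction == "both":
            return DIRECTIONS
        if self.direction in DIRECTIONS:
            return (self.direction,)
        raise ValueError(f"direction must be 'both' or one of {DIRECTIONS}")

    def fit(self, expression: pd.DataFrame, metadata: pd.DataFrame):
        """Run the pipeline.

        Parameters
        ----------
        expression : DataFrame, genes x samples, log2 fold changes.
        metadata : DataFrame with columns sample_id, compound_id,
            dose_level, system, replicate; sample_id must match the
            expression columns.
        """
        if self.bh_family not in ("per_compound", "global"):
            raise ValueError("bh_family must be 'per_compound' or 'global'")
        meta = metadata.set_index("sample_id")
        missing = [c for c in expression.columns if c not in meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing[:5]}")
        genes = expression.index.to_numpy()
        rows: list[dict] = []
        group_rows: list[dict] = []
        for compound in sorted(meta["compound_id"].unique()):
            cmeta = meta[meta["compound_id"] == compound]
            cols = {}
            for system in (IN_VITRO, IN_VIVO):
                smeta = cmeta[cmeta["system"] == system].sort_values(
                    ["dose_level", "replicate"]
                )
                if smeta.empty:
                    raise ValueError(f"compound {compound!r} lacks {system} samples")
                cols[system] = smeta
            Yv = expression[cols[IN_VITRO].index].to_numpy(float)
            Yw = expression[cols[IN_VIVO].index].to_numpy(float)
            idx_v = cols[IN_VITRO]["dose_level"].to_numpy(int)
            idx_w = cols[IN_VIVO]["dose_level"].to_numpy(int)

            group_rows.extend(
                self._dose_response_rows(compound, genes, Yv, Yw, idx_v, idx_w)
            )
            for direction in self._directions():
                if direction == VITRO_TO_VIVO:
                    bd = BatchDesign(idx_v, idx_w)
                    Ys, Yt = Yv, Yw
                else:
                    bd = BatchDesign(idx_w, idx_v)
                    Ys, Yt = Yw, Yv
                sel, rss0, rss1, gamma = bd.disconnect_rss(Ys, Yt)
                p = p_from_rss(rss0, rss1, bd.n, df=3, k_full_mean=6,
                               calibration=self.calibration)
                stat = np.maximum(bd.n * np.log(
                    np.maximum(rss0, 1e-300) / np.maximum(rss1, 1e-300)), 0.0)
                max_fc = bd.max_dose_fold_change(Ys, Yt)
                for g in range(genes.size):
                    p1, p2 = CANONICAL_PAIRS[sel[g]]
                    rows.append({
                        "gene_id": genes[g], "compound_id": compound,
                        "direction": direction, "p1": p1, "p2": p2,
                        "gamma0": gamma[g, 0], "gamma1": gamma[g, 1],
                        "gamma2": gamma[g, 2], "lrt_stat": stat[g],
                        "p_raw": p[g], "max_fc": max_fc[g],
                    })
        res = pd.DataFrame(rows)
        dr = pd.DataFrame(group_rows)
        res = self._adjust_and_call(res)
        res = res.merge(dr[["gene_id", "compound_id", "group"]],
                        on=["gene_id", "compound_id"], how="left")
        self.results_ = res
        self.dose_response_ = dr
        return self

    def _dose_response_rows(self, compound, genes, Yv, Yw, idx_v, idx_w):
        sig = {}
        for system, Y, idx in ((IN_VITRO, Yv, idx_v), (IN_VIVO, Yw, idx_w)):
            bd = BatchDesign(idx, idx)
            sel = bd.select_powers(Y)
            rss1, rss0 = bd.dose_response_rss(Y, sel)
            p = p_from_rss(rss0, rss1, idx.size, df=2, k_full_mean=3,
                           calibration=self.calibration)
            sig[system] = p <= self.alpha_dose_response
        out = []
        for g in range(genes.size):
            out.append({
                "gene_id": genes[g], "compound_id": compound,
                "vitro_significant": bool(sig[IN_VITRO][g]),
                "vivo_significant": bool(sig[IN_VIVO][g]),
                "group": classify_gene(sig[IN_VITRO][g], sig[IN_VIVO][g]),
            })
        return out

    def _adjust_and_call(self, res: pd.DataFrame) -> pd.DataFrame:
        keys = (["direction"] if self.bh_family == "global"
                else ["compound_id", "direction"])
        res = res.copy()
        res["p_bh"] = np.nan
        for _, idx in res.groupby(keys).groups.items():
            res.loc[idx, "p_bh"] = adjust_bh(res.loc[idx, "p_raw"].to_numpy())
        res["disconnected"] = (
            (res["p_bh"] <= self.q) & (res["max_fc"] >= self.fc_min)
        ).astype(int)
        return res


def analyze_disconnects(expression, metadata, **params) -> pd.DataFrame:
    """Functional wrapper around :class:`DisconnectAnalyzer`."""
    return DisconnectAnalyzer(**params).fit(expression, metadata).results_
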