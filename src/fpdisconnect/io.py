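"""TSV readers/writers, fold-change preprocessing and fixture generation.

Expression tables are genes x samples TSVs (gene ids in the first
column) holding either raw log2 intensities or log2 fold changes versus
control; the accompanying metadata TSV maps each sample to its compound,
dose level (1 = control), system and replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import IN_VITRO, IN_VIVO, SYSTEMS, DoseDesign
from .simulate import ScenarioSpec, mean_profile

METADATA_COLUMNS = ("sample_id", "compound_id", "dose_level", "system", "replicate")

#: Fixed float formatting for reproducible output diffs.
FLOAT_FORMAT = "%.6g"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus what they represent."""

    values: pd.DataFrame
    is_fold_change: bool


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a sample-metadata TSV."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "compound_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    bad = set(meta["system"]) - set(SYSTEMS)
    if bad:
        raise ValueError(f"unknown system labels: {sorted(bad)}")
    key = ["compound_id", "system", "dose_level", "replicate"]
    if meta.duplicated(subset=key).any():
        raise ValueError("duplicate (compound, system, dose, replicate) entries")
    for (comp, system), grp in meta.groupby(["compound_id", "system"]):
        doses = np.sort(grp["dose_level"].unique())
        if doses[0] != 1 or not np.array_equal(doses, np.arange(1, doses.size + 1)):
            raise ValueError(
                f"dose levels for {comp}/{system} must form 1..m, got {doses.tolist()}"
            )
    return meta


def read_expression(path, is_fold_change: bool = True) -> ExpressionMatrix:
    """Read a genes x samples expression TSV (gene ids in first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression table")
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample ids in expression table")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression values: {exc}") from exc
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError("expression values must be finite")
    return ExpressionMatrix(values=df, is_fold_change=is_fold_change)


def check_samples(matrix: ExpressionMatrix, metadata: pd.DataFrame) -> None:
    """Cross-check expression columns against metadata sample ids."""
    missing = set(matrix.values.columns) - set(metadata["sample_id"])
    if missing:
        raise ValueError(f"samples absent from metadata: {sorted(missing)[:5]}")


def compute_fold_change(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    control_dose: int = 1,
) -> ExpressionMatrix:
    """Log2 fold change versus the control-dose mean.

    Per gene, compound and system, subtracts the mean of the control-dose
    replicates from every sample; control columns become mean-zero.
    Idempotent on data that is already centred at control.
    """
    check_samples(matrix, metadata)
    values = matrix.values.copy()
    meta = metadata.set_index("sample_id")
    for (comp, system), grp in meta.groupby(["compound_id", "system"]):
        samples = [s for s in grp.index if s in values.columns]
        if not samples:
            continue
        ctrl = [s for s in samples if meta.loc[s, "dose_level"] == control_dose]
        if not ctrl:
            raise ValueError(f"no control-dose samples for {comp}/{system}")
        baseline = values[ctrl].mean(axis=1)
        values[samples] = values[samples].sub(baseline, axis=0)
    return ExpressionMatrix(values=values, is_fold_change=True)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a results table as TSV with fixed float formatting."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# synthetic fixtures (stand-in for a repository download)
# ---------------------------------------------------------------------------

def generate_fixtures(
    n_genes: int = 30,
    n_compounds: int = 2,
    seed: int = 0,
    out_dir=None,
    sigma: float = 0.25,
    delta: float = 1.0,
    frac_disconnected: float = 0.5,
    vitro_design: DoseDesign | None = None,
    vivo_design: DoseDesign | None = None,
):
    """Small synthetic dataset emulating the TG-GATEs design.

    A mixture of null genes and planted opposite-FP2 disconnects (per
    compound), written as expression + metadata + truth TSVs when
    ``out_dir`` is given.  Returns ``(ExpressionMatrix, metadata, truth)``.
    """
    if n_genes < 1 or n_compounds < 1:
        raise ValueError("sizes must be >= 1")
    rng = np.random.default_rng(seed)
    vitro_design = vitro_design or DoseDesign((2, 2, 2, 2))
    vivo_design = vivo_design or DoseDesign((3, 3, 3, 3))
    genes = [f"gene{g:04d}" for g in range(n_genes)]
    compounds = [f"compound{c:02d}" for c in range(n_compounds)]

    meta_rows = []
    data = {}
    truth_rows = []
    n_disc = int(round(frac_disconnected * n_genes))
    for comp in compounds:
        disc = np.zeros(n_genes, bool)
        disc[rng.choice(n_genes, size=n_disc, replace=False)] = True
        for system, design in ((IN_VITRO, vitro_design), (IN_VIVO, vivo_design)):
            idx = design.dose_indices
            reps = np.concatenate(
                [np.arange(1, n + 1) for n in design.n_replicates]
            )
            spec_alt = ScenarioSpec(kind="opposite_fp2", delta=delta, sigma=sigma,
                                    vitro_design=vitro_design,
                                    vivo_design=vivo_design)
            mu_alt = mean_profile(spec_alt, system)[idx - 1]
            Y = rng.normal(0.0, sigma, (n_genes, idx.size))
            Y[disc] += mu_alt[None, :]
            for j, (dose, rep) in enumerate(zip(idx, reps)):
                sample = f"{comp}_{'vt' if system == IN_VITRO else 'vv'}_d{dose}_r{rep}"
                meta_rows.append({
                    "sample_id": sample, "compound_id": comp,
                    "dose_level": int(dose), "system": system,
                    "replicate": int(rep),
                })
                data[sample] = Y[:, j]
        truth_rows.extend(
            {"gene_id": g, "compound_id": comp, "disconnected": int(d)}
            for g, d in zip(genes, disc)
        )

    expr = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    matrix = ExpressionMatrix(values=expr, is_fold_change=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        expr.round(6).to_csv(out / "expression.tsv", sep="\t")
        meta.to_csv(out / "metadata.tsv", sep="\t", index=False)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return matrix, meta, truth
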