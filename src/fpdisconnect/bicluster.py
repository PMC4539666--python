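"""Binary disconnect matrix and Bimax-style biclustering.

Disconnect calls across compounds form a binary genes x compounds matrix
D, with D[g, c] = 1 when gene g is disconnected for compound c.  Subsets
of genes disconnected in common across subsets of compounds are exactly
the inclusion-maximal all-ones submatrices of D.  They are enumerated by
a divide-and-conquer recursion over compounds (a closed-concept
enumeration: each maximal submatrix is closed in both dimensions), which
yields precisely the bicluster set the Bimax algorithm targets, in a
deterministic order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


@dataclass(frozen=True)
class Bicluster:
    """An inclusion-maximal all-ones submatrix: genes x compounds."""

    genes: tuple[str, ...]
    compounds: tuple[str, ...]

    @property
    def area(self) -> int:
        return len(self.genes) * len(self.compounds)


def build_disconnect_matrix(results) -> pd.DataFrame:
    """Genes x compounds 0/1 DataFrame of disconnect calls.

    ``results`` is either a DataFrame with columns gene_id, compound_id,
    disconnected, or a list of flagged :class:`DisconnectTestResult`.
    Rows are restricted to genes disconnected for at least one compound;
    rows and columns are ordered lexicographically.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "compound_id": r.compound_id,
                    "disconnected": int(bool(r.disconnected)),
                }
                for r in results
            ]
        )
    if results.empty:
        return pd.DataFrame(dtype=int)
    compounds = sorted(results["compound_id"].unique())
    flagged = results[results["disconnected"].astype(bool)]
    genes = sorted(flagged["gene_id"].unique())
    D = pd.DataFrame(0, index=genes, columns=compounds, dtype=int)
    for _, row in flagged.iterrows():
        D.loc[row["gene_id"], row["compound_id"]] = 1
    return D


class BimaxWorkLimit(RuntimeError):
    """Raised when bicluster enumeration exceeds the work cap."""


def bimax_enumerate(
    D,
    min_genes: int = 2,
    min_compounds: int = 2,
    max_biclusters: int = 100_000,
) -> list[Bicluster]:
    """All inclusion-maximal all-ones submatrices meeting the size bounds.

    ``D`` is a genes x compounds 0/1 DataFrame (or array; rows/columns
    then get integer labels).  Worst-case exponential; enumeration aborts
    with :class:`BimaxWorkLimit` beyond ``max_biclusters`` results.
    """
    if min_genes < 1 or min_compounds < 1:
        raise ValueError("minimum sizes must be >= 1")
    if not isinstance(D, pd.DataFrame):
        D = np.asarray(D)
        D = pd.DataFrame(
            D,
            index=[f"g{i}" for i in range(D.shape[0])],
            columns=[f"c{j}" for j in range(D.shape[1])],
        )
    if D.size == 0:
        return []
    M = D.to_numpy(bool)
    n_rows, n_cols = M.shape
    gene_ids = np.asarray(D.index)
    compound_ids = np.asarray(D.columns)

    out: list[Bicluster] = []

    def close_cols(rows: np.ndarray) -> np.ndarray:
        return M[rows].all(axis=0)

    def recurse(cols: list[int], rows: np.ndarray, start: int):
        # canonical (first-parent) closed-set enumeration over columns
        colset = set(cols)
        for j in range(start, n_cols):
            if j in colset:
                continue
            rows2 = rows & M[:, j]
            n2 = int(rows2.sum())
            if n2 < min_genes:
                continue
            closure = close_cols(rows2)
            if closure[:j].any() and not np.array_equal(
                np.flatnonzero(closure[:j]),
                np.asarray([c for c in cols if c < j], dtype=int),
            ):
                continue  # closure already generated from an earlier branch
            new_cols = sorted(np.flatnonzero(closure).tolist())
            if len(new_cols) >= min_compounds:
                out.append(
                    Bicluster(
                        genes=tuple(gene_ids[rows2]),
                        compounds=tuple(compound_ids[new_cols]),
                    )
                )
                if len(out) > max_biclusters:
                    raise BimaxWorkLimit(
                        f"more than {max_biclusters} biclusters; "
                        "raise max_biclusters or the size thresholds"
                    )
            recurse(new_cols, rows2, j + 1)

    all_rows = np.ones(n_rows, bool)
    base_closure = close_cols(all_rows)
    if (
        all_rows.sum() >= min_genes
        and int(base_closure.sum()) >= min_compounds
    ):
        out.append(
            Bicluster(
                genes=tuple(gene_ids),
                compounds=tuple(compound_ids[np.flatnonzero(base_closure)]),
            )
        )
    recurse(sorted(np.flatnonzero(base_closure).tolist()), all_rows, 0)
    return out


def rank_and_take(biclusters: list[Bicluster], k: int = 10) -> list[Bicluster]:
    """Top-k biclusters by area, then compound count, then labels."""
    return sorted(
        biclusters,
        key=lambda b: (-b.area, -len(b.compounds), b.compounds, b.genes),
    )[:k]


def bicluster_membership_table(biclusters: list[Bicluster]) -> pd.DataFrame:
    """Compound x bicluster 0/1 membership table (for reporting/plots)."""
    if not biclusters:
        return pd.DataFrame(dtype=int)
    compounds = sorted({c for b in biclusters for c in b.compounds})
    table = pd.DataFrame(
        0,
        index=compounds,
        columns=[f"bicluster_{i + 1}" for i in range(len(biclusters))],
        dtype=int,
    )
    for i, b in enumerate(biclusters):
        table.loc[list(b.compounds), f"bicluster_{i + 1}"] = 1
    return table


class Bimax(BaseEstimator):
    """Biclustering estimator over a binary disconnect matrix.

    Parameters mirror :func:`bimax_enumerate`; after :meth:`fit`,
    ``biclusters_`` holds the ranked top-``n_biclusters`` results and
    ``membership_`` the compound x bicluster table.
    """

    def __init__(self, min_genes=2, min_compounds=2, n_biclusters=10,
                 max_biclusters=100_000):
        self.min_genes = min_genes
        self.min_compounds = min_compounds
        self.n_biclusters = n_biclusters
        self.max_biclusters = max_biclusters

    def fit(self, D, y=None):
        all_bc = bimax_enumerate(
            D,
            min_genes=self.min_genes,
            min_compounds=self.min_compounds,
            max_biclusters=self.max_biclusters,
        )
        self.n_found_ = len(all_bc)
        self.biclusters_ = rank_and_take(all_bc, self.n_biclusters)
        self.membership_ = bicluster_membership_table(self.biclusters_)
        return self
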