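"""Group-level statistics and RNA-seq TPM filtering rules.

Covers the statistics the study design needs beyond off-the-shelf omnibus
tests: exact two-sided Fisher tests on responder tables, mean ± SEM group
summaries, Benjamini–Hochberg adjustment, and the expression-table rules
(TPM ≥ 0.2 detection threshold, protein-coding renormalisation, the +0.2
offset log₂ transform).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "Contingency2x2",
    "TpmMatrix",
    "fisher_exact_2x2",
    "proportion",
    "summarize_groups",
    "bh_adjust",
    "filter_expressed_genes",
    "log_tpm",
    "TPM_DETECTION",
]

TPM_DETECTION = 0.2  # TPM below this is treated as not expressed


@dataclass(frozen=True)
class Contingency2x2:
    """Counts [[a, b], [c, d]]; rows = groups, columns = outcome classes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for x in (self.a, self.b, self.c, self.d):
            if x < 0 or int(x) != x:
                raise ValueError("contingency counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table must have a positive margin")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact_2x2(table: Contingency2x2 | np.ndarray) -> tuple[float, bool]:
    """Exact two-sided Fisher p for a 2×2 table.

    Sums the point probabilities of every table with the observed margins
    whose hypergeometric probability does not exceed the observed table's
    (no normal approximation).  Returns ``(p, degenerate)`` where a
    degenerate table (an empty margin) gives p = 1 by convention.
    """
    if not isinstance(table, Contingency2x2):
        t = np.asarray(table)
        table = Contingency2x2(int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1]))
    a, b, c, d = table.a, table.b, table.c, table.d
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 in (0, n_total) or col1 in (0, n_total):
        return 1.0, True
    k = np.arange(max(0, row1 + col1 - n_total), min(row1, col1) + 1)
    pmf = hypergeom.pmf(k, n_total, col1, row1)
    p_obs = hypergeom.pmf(a, n_total, col1, row1)
    # relative tolerance guards the <= comparison against floating error
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return min(p, 1.0), False


def proportion(k: int, n: int, decimals: int = 0) -> float:
    """Percentage 100·k/n, rounded to ``decimals`` places."""
    if n <= 0:
        raise ValueError("proportion requires a positive denominator")
    return round(100.0 * k / n, decimals)


def summarize_groups(cells: pd.DataFrame, metrics: list[str],
                     group_col: str = "group",
                     respect_inclusion: bool = True) -> pd.DataFrame:
    """Mean ± SEM and n per metric × group.

    Cells failing the V_rest inclusion rule (``included == False``) are
    omitted before any statistic.  SEM is sample SD/√n and is NaN for
    single-cell groups.
    """
    df = cells
    if respect_inclusion and "included" in df.columns:
        df = df[df["included"].astype(bool)]
    known = set(df[group_col].unique())
    rows = []
    for (grp,), sub in df.groupby([group_col]):
        for m in metrics:
            if m not in df.columns:
                raise KeyError(f"unknown metric {m!r}")
            vals = sub[m].astype(float).dropna()
            n = len(vals)
            rows.append({
                group_col: grp, "metric": m, "n": n,
                "mean": vals.mean() if n else math.nan,
                "sem": vals.std(ddof=1) / math.sqrt(n) if n >= 2 else math.nan,
            })
    return pd.DataFrame(rows)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class TpmMatrix:
    """A genes × samples TPM table with a sample→group map.

    ``protein_coding`` is a boolean per-gene Series (same index as ``tpm``)
    used by the renormalisation mode.
    """

    tpm: pd.DataFrame  # genes x samples, values >= 0
    groups: pd.Series  # sample -> group label
    protein_coding: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.tpm.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        missing = set(self.tpm.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group assignment: {sorted(missing)}")
        for g, cols in self.groups.groupby(self.groups).groups.items():
            if len(cols) == 0:
                raise ValueError(f"group {g!r} has no samples")


def filter_expressed_genes(matrix: TpmMatrix, renormalize: bool = True
                           ) -> tuple[pd.Index, pd.DataFrame]:
    """Apply the detection-threshold expression filter.

    With ``renormalize`` (requires protein-coding flags) each sample's
    protein-coding TPMs are first rescaled to sum to 10⁶ over protein-coding
    genes and non-coding genes are dropped.  A gene is then kept iff there
    is at least one treatment group in which *every* sample exceeds 0.2 TPM.
    Returns the kept gene index and the (renormalised) matrix restricted to
    kept genes.
    """
    tpm = matrix.tpm
    if renormalize:
        if matrix.protein_coding is None:
            raise ValueError("renormalization requires protein-coding flags")
        pc = matrix.protein_coding.reindex(tpm.index).fillna(False).astype(bool)
        tpm = tpm.loc[pc]
        sums = tpm.sum(axis=0)
        if (sums <= 0).any():
            raise ValueError("a sample has zero protein-coding TPM mass")
        tpm = tpm * (1e6 / sums)
    keep = pd.Series(False, index=tpm.index)
    for g in matrix.groups.unique():
        cols = matrix.groups.index[matrix.groups == g]
        cols = [c for c in cols if c in tpm.columns]
        if not cols:
            raise ValueError(f"group {g!r} has no samples in the matrix")
        keep |= (tpm[cols] > TPM_DETECTION).all(axis=1)
    kept = tpm.index[keep]
    return kept, tpm.loc[kept]


def log_tpm(values) -> np.ndarray:
    """log₂(TPM + 0.2): the detection threshold is added before the transform."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("TPM values must be non-negative")
    return np.log2(v + TPM_DETECTION)
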