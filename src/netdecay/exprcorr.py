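"""Expression-divergence layer: ortholog pairing, TPM filtering, correlations.

Expression tables are gene -> TPM mappings per species.  Reference genes
are paired with their one-to-one orthologs, pairs where either member is
at or below the abundance floor (5 TPM by default) are discarded, and the
surviving pairs are correlated with Spearman's rho (default), Kendall's
tau-b, or Pearson's r on log2-transformed values.  The resulting
correlations are the similarity measures the rate framework consumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_TPM_FLOOR = 5.0
MIN_PAIRS = 10

METRICS = ("spearman", "kendall", "pearson_log2")


def read_expression(path) -> pd.DataFrame:
    """Read a TSV expression table with columns gene_id, tpm."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "tpm"} <= set(df.columns):
        raise ValueError(f"{path} must have columns gene_id, tpm")
    return validate_expression(df)


def validate_expression(table: pd.DataFrame) -> pd.DataFrame:
    if table["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in expression table")
    if (table["tpm"] < 0).any():
        raise ValueError("negative TPM values")
    return table


def pair_orthologs(
    table_ref: pd.DataFrame,
    table_other: pd.DataFrame,
    ortholog_map: dict[str, str],
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned TPM vectors of reference genes and their one-to-one orthologs.

    The map must be one-to-one (no duplicated source or target); genes
    absent from either table are skipped.
    """
    validate_expression(table_ref)
    validate_expression(table_other)
    targets = list(ortholog_map.values())
    if len(set(ortholog_map)) != len(ortholog_map) or len(set(targets)) != len(
        targets
    ):
        raise ValueError("ortholog map is not one-to-one")
    ref = dict(zip(table_ref["gene_id"], table_ref["tpm"]))
    oth = dict(zip(table_other["gene_id"], table_other["tpm"]))
    xs, ys = [], []
    for g_ref, g_oth in ortholog_map.items():
        if g_ref in ref and g_oth in oth:
            xs.append(ref[g_ref])
            ys.append(oth[g_oth])
    if not xs:
        raise ValueError("no genes shared between tables and ortholog map")
    return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)


def correlate_expression(
    x: np.ndarray,
    y: np.ndarray,
    metric: str = "spearman",
    tpm_floor: float | None = DEFAULT_TPM_FLOOR,
    floor_scope: str = "either",
) -> float:
    """Correlation of paired expression values after abundance filtering.

    A pair is dropped when the floored member's TPM is <= ``tpm_floor``;
    ``floor_scope`` "either" (default) drops the pair if either species is
    at/below the floor, "reference" only checks the first vector.  The log2
    transform for ``pearson_log2`` uses log2(TPM) after filtering (all
    values > floor) or log2(TPM + 1) when the filter is off.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if tpm_floor is not None:
        if floor_scope == "either":
            keep = (x > tpm_floor) & (y > tpm_floor)
        elif floor_scope == "reference":
            keep = x > tpm_floor
        else:
            raise ValueError("floor_scope must be 'either' or 'reference'")
        x, y = x[keep], y[keep]
    if len(x) < MIN_PAIRS:
        raise ValueError(
            f"only {len(x)} pairs survive filtering; >= {MIN_PAIRS} required"
        )
    if metric == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if metric == "kendall":
        return float(stats.kendalltau(x, y).statistic)  # tau-b
    if tpm_floor is not None:
        lx, ly = np.log2(x), np.log2(y)
    else:
        lx, ly = np.log2(x + 1.0), np.log2(y + 1.0)
    return float(stats.pearsonr(lx, ly).statistic)
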