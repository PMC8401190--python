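"""Per-target selection runs and candidate-pair post-processing.

For each target gene the dependency column is modeled from one feature
cohort (binary mutation status or expression) and confirmed features become
candidate pairs.  Pairs are then self-filtered, sign-filtered on their
Pearson correlation with the dependency (positive for mutation, negative
for expression), min-max scaled within each (method, feature_type) group,
and annotated with per-gene dependency statistics for essentiality
filtering.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import replace

import numpy as np
import pandas as pd

from .boruta_core import (
    CONFIRMED,
    TENTATIVE,
    BorutaConfig,
    ForestConfig,
    boruta_select,
)
from .io_depmap import OmicsMatrix

logger = logging.getLogger(__name__)

PAIR_COLUMNS = [
    "target_gene",
    "feature_gene",
    "feature_type",
    "method",
    "importance",
    "scaled_importance",
    "pcc",
    "n_samples",
]


def empty_pair_table() -> pd.DataFrame:
    return pd.DataFrame(columns=PAIR_COLUMNS)


def pearson(x, y) -> float:
    """Pairwise-complete Pearson correlation; NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def target_seed(master_seed: int, target: str, feature_type: str, method: str) -> int:
    """Stable per-model seed: master seed mixed with a CRC of the run key."""
    key = f"{target}|{feature_type}|{method}".encode()
    return (int(master_seed) * 1_000_003 + zlib.crc32(key)) % (2**31)


def run_target(
    target: str,
    dep: OmicsMatrix,
    features: OmicsMatrix,
    feature_type: str,
    method: str,
    bcfg: BorutaConfig | None = None,
    fcfg: ForestConfig | None = None,
    include_tentative: bool = False,
) -> pd.DataFrame:
    """Model one target's dependency from one feature cohort.

    Samples with a missing response are dropped for this target only;
    missing feature cells are imputed with the column median.  The target's
    own feature column (if present) is retained here and removed later by
    :func:`drop_self_pairs`.
    """
    if target not in dep.data.columns:
        raise KeyError(f"target {target!r} absent from the dependency matrix")
    if feature_type not in ("mutation", "expression"):
        raise ValueError(f"unknown feature_type {feature_type!r}")
    bcfg = bcfg or BorutaConfig(importance_method=method)
    if bcfg.importance_method != method:
        raise ValueError("method must match bcfg.importance_method")
    fcfg = fcfg or ForestConfig()

    y = dep.data[target]
    keep = y.notna()
    y = y[keep]
    X = features.data.loc[keep.index[keep]]
    X = X.fillna(X.median())
    # all-NaN feature columns have no median; they carry no information
    X = X.dropna(axis=1, how="any")

    result = boruta_select(
        X.to_numpy(), y.to_numpy(), feature_names=list(X.columns), bcfg=bcfg, fcfg=fcfg
    )
    wanted = (CONFIRMED, TENTATIVE) if include_tentative else (CONFIRMED,)
    rows = []
    for feat in result.features_with(*wanted):
        try:
            r = pearson(X[feat].to_numpy(), y.to_numpy())
        except ValueError:
            logger.warning("dropping pair (%s -> %s): constant input", feat, target)
            continue
        if np.isnan(r):
            logger.warning("dropping pair (%s -> %s): undefined correlation", feat, target)
            continue
        rows.append(
            {
                "target_gene": target,
                "feature_gene": feat,
                "feature_type": feature_type,
                "method": method,
                "importance": result.final_importance(feat),
                "scaled_importance": np.nan,
                "pcc": r,
                "n_samples": int(len(y)),
            }
        )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def drop_self_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Remove pairs where a gene would explain its own dependency."""
    if pairs.empty:
        return pairs
    return pairs[pairs["target_gene"] != pairs["feature_gene"]].reset_index(drop=True)


def apply_direction_filter(pairs: pd.DataFrame, enabled: bool = True) -> pd.DataFrame:
    """Keep mutation pairs with positive and expression pairs with negative
    correlation; identity when disabled (bypass mode)."""
    if not enabled or pairs.empty:
        return pairs
    keep = ((pairs["feature_type"] == "mutation") & (pairs["pcc"] > 0)) | (
        (pairs["feature_type"] == "expression") & (pairs["pcc"] < 0)
    )
    return pairs[keep].reset_index(drop=True)


def scale_by_group(pairs: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale importances to [0, 1] within each (method, feature_type)
    group; degenerate (zero-span or singleton) groups map to 1.0."""
    if pairs.empty:
        return pairs

    def _scale(g: pd.Series) -> pd.Series:
        lo, hi = g.min(), g.max()
        if hi == lo:
            return pd.Series(1.0, index=g.index)
        return (g - lo) / (hi - lo)

    pairs = pairs.copy()
    pairs["scaled_importance"] = pairs.groupby(["method", "feature_type"], group_keys=False)[
        "importance"
    ].apply(_scale)
    return pairs


def node_dependency_stats(dep: OmicsMatrix, cv_threshold: float = 0.3) -> pd.DataFrame:
    """Per-gene dependency statistics: median, cv (= sd/|mean|), sd, range,
    and the essentiality flag (cv < threshold).

    Zero-mean columns have an undefined cv and are treated as non-essential
    with a logged warning.
    """
    stats = []
    for gene in dep.data.columns:
        col = dep.data[gene].dropna().to_numpy()
        if len(col) == 0:
            stats.append((gene, np.nan, np.nan, np.nan, np.nan, False))
            continue
        mean = float(np.mean(col))
        sd = float(np.std(col, ddof=1)) if len(col) > 1 else 0.0
        median = float(np.median(col))
        rng_ = float(np.max(col) - np.min(col))
        if mean == 0.0:
            logger.warning("gene %s: zero-mean dependency, cv undefined", gene)
            cv = np.nan
            essential = False
        else:
            cv = sd / abs(mean)
            essential = cv < cv_threshold
        stats.append((gene, median, cv, sd, rng_, essential))
    return pd.DataFrame(
        stats, columns=["gene", "median_dependency", "cv", "sd", "range", "is_essential"]
    ).set_index("gene")


def essentiality_filter(
    dep: OmicsMatrix, cv_threshold: float = 0.3
) -> tuple[list[str], pd.DataFrame]:
    """Return (eligible target genes, per-gene NodeStats table).

    Genes with cv < threshold are flagged essential and excluded from
    prioritization; they remain available as network nodes.
    """
    stats = node_dependency_stats(dep, cv_threshold)
    eligible = [g for g in stats.index if not stats.at[g, "is_essential"]]
    return eligible, stats


def run_cohort(
    targets: list[str],
    dep: OmicsMatrix,
    mut_matrix: OmicsMatrix | None,
    expr_matrix: OmicsMatrix | None,
    methods: list[str],
    bcfg: BorutaConfig | None = None,
    fcfg: ForestConfig | None = None,
    master_seed: int = 0,
    direction_filter: bool = True,
    cv_threshold: float = 0.3,
    include_tentative: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every target x feature-cohort x method model and post-process.

    Returns the scaled pair table (with a ``target_essential`` column) and
    the per-gene NodeStats table.  Deterministic under ``master_seed``: each
    model derives its own seed from the master seed and a stable hash of the
    run key, so results are order-independent.
    """
    base_b = bcfg or BorutaConfig()
    base_f = fcfg or ForestConfig()
    cohorts = []
    if mut_matrix is not None:
        cohorts.append(("mutation", mut_matrix))
    if expr_matrix is not None:
        cohorts.append(("expression", expr_matrix))

    tables = []
    for target in targets:
        if target not in dep.data.columns:
            raise KeyError(f"target {target!r} absent from the dependency matrix")
        for feature_type, features in cohorts:
            for method in methods:
                seed = target_seed(master_seed, target, feature_type, method)
                b = replace(base_b, importance_method=method)
                f = replace(base_f, seed=seed)
                t = run_target(
                    target, dep, features, feature_type, method,
                    bcfg=b, fcfg=f, include_tentative=include_tentative,
                )
                tables.append(t)

    tables = [t for t in tables if not t.empty]
    pairs = (
        pd.concat(tables, ignore_index=True) if tables else empty_pair_table()
    )
    pairs = drop_self_pairs(pairs)
    pairs = apply_direction_filter(pairs, enabled=direction_filter)
    pairs = scale_by_group(pairs)
    _, stats = essentiality_filter(dep, cv_threshold)
    if not pairs.empty:
        pairs = pairs.copy()
        pairs["target_essential"] = (
            pairs["target_gene"].map(stats["is_essential"]).fillna(False).astype(bool)
        )
    else:
        pairs["target_essential"] = pd.Series(dtype=bool)
    return pairs.reset_index(drop=True), stats


def prioritize_pairs(pairs: pd.DataFrame, rank_method: str = "permutation_raw") -> pd.DataFrame:
    """Drop pairs whose target is essential and rank the rest by their
    scaled importance under ``rank_method`` (descending)."""
    if pairs.empty:
        return pairs
    out = pairs[~pairs["target_essential"]]
    out = out[out["method"] == rank_method] if rank_method else out
    return out.sort_values(
        ["scaled_importance", "target_gene", "feature_gene"], ascending=[False, True, True]
    ).reset_index(drop=True)
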