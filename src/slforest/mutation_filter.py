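"""Pathogenicity labeling of mutation calls and binary predictor construction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_depmap import MutationCallTable, OmicsMatrix


@dataclass
class PathogenicityRule:
    """A call is pathogenic if its coding score strictly exceeds the
    threshold, or it carries an enabled damaging / hotspot annotation."""

    coding_score_threshold: float = 0.7
    use_damaging_flag: bool = True
    use_hotspot_flag: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.coding_score_threshold <= 1.0:
            raise ValueError("coding_score_threshold must lie in [0, 1]")


def is_pathogenic(record, rule: PathogenicityRule | None = None) -> bool:
    """Decide pathogenicity for a single call (mapping or namedtuple-like).

    Missing evidence contributes nothing: a missing coding score fails the
    score clause, absent flags fail their clauses.
    """
    rule = rule or PathogenicityRule()
    get = record.get if hasattr(record, "get") else lambda k, d=None: getattr(record, k, d)
    score = get("coding_score")
    if score is not None and not pd.isna(score) and float(score) > rule.coding_score_threshold:
        return True
    if rule.use_damaging_flag and bool(get("damaging_flag", False)):
        return True
    if rule.use_hotspot_flag and bool(get("hotspot_flag", False)):
        return True
    return False


def _pathogenic_mask(records: pd.DataFrame, rule: PathogenicityRule) -> pd.Series:
    score_ok = records["coding_score"].astype(float) > rule.coding_score_threshold
    score_ok = score_ok.fillna(False)
    mask = score_ok
    if rule.use_damaging_flag:
        mask = mask | records["damaging_flag"].fillna(False).astype(bool)
    if rule.use_hotspot_flag:
        mask = mask | records["hotspot_flag"].fillna(False).astype(bool)
    return mask


def build_binary_matrix(
    table: MutationCallTable,
    samples: list[str],
    genes: list[str],
    rule: PathogenicityRule | None = None,
) -> OmicsMatrix:
    """Collapse calls to a samples x genes 0/1 matrix.

    A cell is 1 iff at least one pathogenic call exists for that
    (sample, gene); genes with no pathogenic call stay as all-zero columns.
    """
    if not samples or not genes:
        raise ValueError("samples and genes must be nonempty")
    rule = rule or PathogenicityRule()
    data = pd.DataFrame(0.0, index=pd.Index(samples, name="sample_id"), columns=list(genes))
    recs = table.records
    if len(recs):
        patho = recs[_pathogenic_mask(recs, rule)]
        hits = patho[patho["sample_id"].isin(samples) & patho["gene_id"].isin(genes)]
        for s, g in zip(hits["sample_id"], hits["gene_id"]):
            data.at[s, g] = 1.0
    return OmicsMatrix(data=data, kind="mutation_binary")


def filter_min_positives(matrix: OmicsMatrix, min_mutated_samples: int = 1) -> OmicsMatrix:
    """Drop near-constant binary predictors with fewer than
    ``min_mutated_samples`` positives.  The default of 1 keeps everything
    that is mutated at least once."""
    if matrix.kind != "mutation_binary":
        raise ValueError("filter_min_positives expects a mutation_binary matrix")
    counts = matrix.data.sum(axis=0)
    keep = counts[counts >= min_mutated_samples].index
    return OmicsMatrix(data=matrix.data[list(keep)], kind="mutation_binary")
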