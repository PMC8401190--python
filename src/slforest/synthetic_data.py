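"""Download-free synthetic cohorts with planted vulnerability structure.

The generator emulates the statistical shape of a dependency-screen
cohort: continuous per-target dependency responses driven by planted
positive mutation effects and negative expression effects, collinear
feature blocks (equicorrelated, anchored on planted features), pure-noise
features, sparse binary mutation columns, and essential targets with
uniformly strong dependency (cv < 0.3 by construction).

Sample and gene naming: samples ``CL0001``..; targets ``T01``..; mutation
features ``M001``..; expression features ``E001``..
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_depmap import MutationCallTable, OmicsMatrix, write_omics_matrix


def sample_names(n: int) -> list[str]:
    return [f"CL{i + 1:04d}" for i in range(n)]


def target_names(n: int) -> list[str]:
    return [f"T{i + 1:02d}" for i in range(n)]


def mut_feature_names(n: int) -> list[str]:
    return [f"M{i + 1:03d}" for i in range(n)]


def expr_feature_names(n: int) -> list[str]:
    return [f"E{i + 1:03d}" for i in range(n)]


@dataclass(frozen=True)
class PlantedPair:
    target: str
    feature: str
    feature_type: str  # "mutation" | "expression"
    effect_size: float  # in units of noise_sd


@dataclass
class SimConfig:
    n_samples: int = 300
    n_targets: int = 20
    n_mut_features: int = 25
    n_expr_features: int = 25
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    mutation_frequency: float = 0.15
    noise_sd: float = 1.0
    collinear_block: tuple[int, float] | None = None  # (size incl. anchor, correlation)
    #: latent-Gaussian correlation override for mutation blocks; thresholding
    #: to 0/1 attenuates correlation, so a higher latent value is usually
    #: needed to reach a comparable binary (phi) correlation
    mutation_block_correlation: float | None = None
    essential_fraction: float = 0.0
    essential_mean: float = -1.0
    essential_sd: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 < self.mutation_frequency < 1.0:
            raise ValueError("mutation_frequency must lie in (0, 1)")
        if not 0.0 <= self.essential_fraction < 1.0:
            raise ValueError("essential_fraction must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.collinear_block is not None:
            size, rho = self.collinear_block
            if size < 2 or not 0.0 < rho < 1.0:
                raise ValueError("collinear_block requires size >= 2 and correlation in (0,1)")
        for p in self.planted_pairs:
            if not np.isfinite(p.effect_size):
                raise ValueError(f"non-finite effect size for {p}")
            if p.feature_type not in ("mutation", "expression"):
                raise ValueError(f"bad feature_type in {p}")


@dataclass
class SyntheticDataset:
    dependency: OmicsMatrix
    expression: OmicsMatrix
    mutation_binary: OmicsMatrix
    truth: pd.DataFrame  # target_gene, feature_gene, feature_type, effect_size
    config: SimConfig
    essential_targets: list[str] = field(default_factory=list)
    collinear_mates: dict[str, list[str]] = field(default_factory=dict)

    def mutation_calls(self, coding_score: float = 0.95) -> MutationCallTable:
        """Long-format call table equivalent to the binary matrix (one
        pathogenic-scored call per mutated cell)."""
        rows = []
        m = self.mutation_binary.data
        for gene in m.columns:
            for sample in m.index[m[gene] == 1.0]:
                rows.append((sample, gene, coding_score, False, False))
        return MutationCallTable(
            records=pd.DataFrame(
                rows,
                columns=["sample_id", "gene_id", "coding_score", "damaging_flag", "hotspot_flag"],
            )
        )


def _equicorrelated_normal(
    rng: np.random.Generator, n: int, k: int, rho: float
) -> np.ndarray:
    """n x k matrix with pairwise correlation rho (single shared factor)."""
    common = rng.normal(size=(n, 1))
    return np.sqrt(rho) * common + np.sqrt(1.0 - rho) * rng.normal(size=(n, k))


def _bernoulli_from_latent(latent: np.ndarray, frequency: float) -> np.ndarray:
    from scipy.stats import norm

    cut = norm.ppf(1.0 - frequency)
    return (latent > cut).astype(float)


def simulate(cfg: SimConfig) -> SyntheticDataset:
    """Generate a fully reproducible cohort from ``cfg``.

    Planted features anchor collinear blocks when ``collinear_block`` is
    set; block mates are taken from the unplanted feature pool (mutation
    mates share a latent Gaussian factor before thresholding).  A planted
    mutation column that comes out all-0 or all-1 is resampled once and
    then raises.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = sample_names(cfg.n_samples)
    targets = target_names(cfg.n_targets)
    mut_genes = mut_feature_names(cfg.n_mut_features)
    expr_genes = expr_feature_names(cfg.n_expr_features)

    planted_mut = [p.feature for p in cfg.planted_pairs if p.feature_type == "mutation"]
    planted_expr = [p.feature for p in cfg.planted_pairs if p.feature_type == "expression"]
    for f in planted_mut:
        if f not in mut_genes:
            raise ValueError(f"planted mutation feature {f!r} outside the feature pool")
    for f in planted_expr:
        if f not in expr_genes:
            raise ValueError(f"planted expression feature {f!r} outside the feature pool")
    for p in cfg.planted_pairs:
        if p.target not in targets:
            raise ValueError(f"planted target {p.target!r} outside the target pool")

    # assign collinear block mates (anchor + size-1 unplanted features)
    mates: dict[str, list[str]] = {}
    if cfg.collinear_block is not None:
        size, _rho = cfg.collinear_block
        for pool, anchors in ((mut_genes, planted_mut), (expr_genes, planted_expr)):
            free = [g for g in pool if g not in anchors]
            needed = (size - 1) * len(set(anchors))
            if needed > len(free):
                raise ValueError("feature pool too small for the requested collinear blocks")
            for anchor in dict.fromkeys(anchors):  # stable unique order
                mates[anchor], free = free[: size - 1], free[size - 1:]

    # ---- expression matrix (standard-normal deviations around gene means)
    expr_z = pd.DataFrame(
        rng.normal(size=(cfg.n_samples, cfg.n_expr_features)),
        index=samples, columns=expr_genes,
    )
    if cfg.collinear_block is not None:
        _, rho = cfg.collinear_block
        for anchor in planted_expr:
            block = [anchor] + mates.get(anchor, [])
            expr_z[block] = _equicorrelated_normal(rng, cfg.n_samples, len(block), rho)
    expr_means = pd.Series(rng.uniform(2.0, 9.0, size=cfg.n_expr_features), index=expr_genes)
    expression = expr_z + expr_means

    # ---- mutation matrix (sparse binary; blocks via shared latent factor)
    latent = pd.DataFrame(
        rng.normal(size=(cfg.n_samples, cfg.n_mut_features)),
        index=samples, columns=mut_genes,
    )
    if cfg.collinear_block is not None:
        _, rho = cfg.collinear_block
        if cfg.mutation_block_correlation is not None:
            rho = cfg.mutation_block_correlation
        for anchor in planted_mut:
            block = [anchor] + mates.get(anchor, [])
            latent[block] = _equicorrelated_normal(rng, cfg.n_samples, len(block), rho)
    mutation = pd.DataFrame(
        _bernoulli_from_latent(latent.to_numpy(), cfg.mutation_frequency),
        index=samples, columns=mut_genes,
    )
    for f in set(planted_mut):
        s = mutation[f].sum()
        if s in (0, cfg.n_samples):
            mutation[f] = _bernoulli_from_latent(
                rng.normal(size=cfg.n_samples), cfg.mutation_frequency
            )
            s = mutation[f].sum()
            if s in (0, cfg.n_samples):
                raise RuntimeError(f"planted mutation column {f!r} degenerate after resampling")

    # ---- dependency responses
    n_ess = int(round(cfg.essential_fraction * cfg.n_targets))
    essential = targets[cfg.n_targets - n_ess:] if n_ess else []
    planted_by_target: dict[str, list[PlantedPair]] = {}
    for p in cfg.planted_pairs:
        if p.target in essential:
            raise ValueError(f"cannot plant a pair on essential target {p.target!r}")
        planted_by_target.setdefault(p.target, []).append(p)

    dep = pd.DataFrame(index=samples, columns=targets, dtype=float)
    for t in targets:
        if t in essential:
            dep[t] = rng.normal(cfg.essential_mean, cfg.essential_sd, size=cfg.n_samples)
            continue
        y = rng.normal(0.0, cfg.noise_sd, size=cfg.n_samples)
        for p in planted_by_target.get(t, []):
            beta = p.effect_size * cfg.noise_sd
            if p.feature_type == "mutation":
                y = y + beta * mutation[p.feature].to_numpy()
            else:
                y = y - beta * expr_z[p.feature].to_numpy()
        dep[t] = y

    truth = pd.DataFrame(
        [(p.target, p.feature, p.feature_type, p.effect_size) for p in cfg.planted_pairs],
        columns=["target_gene", "feature_gene", "feature_type", "effect_size"],
    )
    return SyntheticDataset(
        dependency=OmicsMatrix(data=dep, kind="dependency"),
        expression=OmicsMatrix(data=expression, kind="expression"),
        mutation_binary=OmicsMatrix(data=mutation, kind="mutation_binary"),
        truth=truth,
        config=cfg,
        essential_targets=list(essential),
        collinear_mates=mates,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write the three matrices (io_depmap CSV dialect), the mutation call
    table and the planted-truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dependency": outdir / "dependency.csv",
        "expression": outdir / "expression.csv",
        "mutation": outdir / "mutation_calls.csv",
        "truth": outdir / "truth.csv",
    }
    write_omics_matrix(ds.dependency, paths["dependency"])
    write_omics_matrix(ds.expression, paths["expression"])
    ds.mutation_calls().records.to_csv(paths["mutation"], index=False)
    ds.truth.to_csv(paths["truth"], index=False)
    return paths


def evaluate_recovery(
    pair_table: pd.DataFrame,
    truth: pd.DataFrame,
    threshold: float | dict,
) -> tuple[float | None, float, pd.DataFrame]:
    """Score a pair table against the planted truth.

    Predicted pairs are the unique (target, feature, feature_type) keys
    whose scaled importance strictly exceeds the threshold (a scalar, or a
    dict keyed by feature_type or (method, feature_type)).  Returns
    (precision, recall, per-pair hit table); precision is None when nothing
    is predicted.
    """
    key = ["target_gene", "feature_gene", "feature_type"]

    def _thr(row) -> float:
        if isinstance(threshold, dict):
            k = (row["method"], row["feature_type"])
            if k in threshold:
                return threshold[k]
            return threshold[row["feature_type"]]
        return float(threshold)

    if pair_table.empty:
        predicted: set[tuple] = set()
    else:
        above = pair_table[
            pair_table.apply(lambda r: r["scaled_importance"] > _thr(r), axis=1)
        ]
        predicted = {tuple(r) for r in above[key].itertuples(index=False)}
    truth_keys = {tuple(r) for r in truth[key].itertuples(index=False)}

    tp = predicted & truth_keys
    precision = len(tp) / len(predicted) if predicted else None
    recall = len(tp) / len(truth_keys) if truth_keys else 0.0
    hit_table = truth.copy()
    hit_table["recovered"] = [
        tuple(r) in predicted for r in truth[key].itertuples(index=False)
    ]
    return precision, recall, hit_table
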