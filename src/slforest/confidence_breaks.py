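"""Head/tail-breaks clustering of heavy-tailed score distributions.

The recursion repeatedly splits the current set at its mean and keeps the
head (values strictly above the mean) while the head remains a minority.
Two minority criteria are supported: the literal head-over-tail ratio
(default) and the canonical head-over-all fraction.  The last (largest)
break point serves as the high-confidence threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODES = ("head_over_tail", "head_over_all")

#: absolute scaled-importance cutoffs used when a distribution yields no break
FALLBACK_THRESHOLDS = {"expression": 0.4, "mutation": 0.5}


@dataclass
class BreakSet:
    breaks: list[float] = field(default_factory=list)
    head_counts: list[int] = field(default_factory=list)
    stop_ratio: float = 0.40
    mode: str = "head_over_tail"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breaks must be strictly ascending")


def head_tail_breaks(
    values, stop_ratio: float = 0.40, mode: str = "head_over_tail"
) -> BreakSet:
    """Partition ``values`` by recursive mean-splitting.

    A mean is recorded as a break only when the minority condition held for
    the head it produced; recursion continues on that head.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("values must be nonempty")
    if not np.isfinite(vals).all():
        raise ValueError("values must be finite")

    breaks: list[float] = []
    head_counts: list[int] = []
    current = vals
    while True:
        m = float(np.mean(current))
        head = current[current > m]
        if head.size == 0:
            break
        tail_size = current.size - head.size
        if mode == "head_over_tail":
            ok = tail_size > 0 and head.size / tail_size <= stop_ratio
        else:
            ok = head.size / current.size <= stop_ratio
        if not ok:
            break
        breaks.append(m)
        head_counts.append(int(head.size))
        current = head
    return BreakSet(breaks=breaks, head_counts=head_counts, stop_ratio=stop_ratio, mode=mode)


def high_confidence_threshold(bs: BreakSet) -> float | None:
    """The last (largest) break, or None when no break exists."""
    return bs.breaks[-1] if bs.breaks else None


def group_thresholds(
    pairs: pd.DataFrame,
    stop_ratio: float = 0.40,
    mode: str = "head_over_tail",
    fallbacks: dict[str, float] | None = None,
) -> dict[tuple[str, str], float]:
    """High-confidence threshold per (method, feature_type) group of a pair
    table, falling back to the configured absolute cutoffs when the group's
    distribution yields no break."""
    fallbacks = fallbacks or FALLBACK_THRESHOLDS
    out: dict[tuple[str, str], float] = {}
    for (method, ftype), g in pairs.groupby(["method", "feature_type"]):
        bs = head_tail_breaks(g["scaled_importance"].to_numpy(), stop_ratio, mode)
        thr = high_confidence_threshold(bs)
        if thr is None:
            thr = fallbacks.get(ftype, 0.5)
        out[(method, ftype)] = float(thr)
    return out


def label_confidence(
    pairs: pd.DataFrame, thresholds: dict[str, float] | dict[tuple[str, str], float]
) -> pd.DataFrame:
    """Label each pair (identity key: target, feature, feature_type) as
    ``high`` if its scaled importance strictly exceeds the threshold under
    any method it was selected by, ``low`` otherwise.

    ``thresholds`` maps a method name -- or a (method, feature_type) tuple
    -- to a cutoff; pairs count only under methods where they are present.
    """
    if pairs.empty:
        out = pairs.copy()
        out["confidence"] = pd.Series(dtype=object)
        return out

    def _thr(method: str, ftype: str) -> float:
        if (method, ftype) in thresholds:
            return thresholds[(method, ftype)]
        return thresholds[method]

    above = pairs.apply(
        lambda r: r["scaled_importance"] > _thr(r["method"], r["feature_type"]), axis=1
    )
    key = ["target_gene", "feature_gene", "feature_type"]
    any_above = above.groupby([pairs[k] for k in key]).transform("max")
    out = pairs.copy()
    out["confidence"] = np.where(any_above, "high", "low")
    return out


def assign_tiers(pairs: pd.DataFrame, bs: BreakSet, n_tiers: int = 3) -> pd.DataFrame:
    """Ordinal confidence tier per pair: the number of the top
    ``n_tiers - 1`` breaks its scaled importance exceeds (0 = lowest)."""
    if n_tiers < 1:
        raise ValueError("n_tiers must be >= 1")
    cuts = bs.breaks[-(n_tiers - 1):] if n_tiers > 1 else []
    out = pairs.copy()
    if pairs.empty:
        out["tier"] = pd.Series(dtype=int)
        return out
    scores = pairs["scaled_importance"].to_numpy()
    tier = np.zeros(len(scores), dtype=int)
    for c in cuts:
        tier += scores > c
    out["tier"] = tier
    return out
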