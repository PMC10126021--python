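"""Top-share predictive hit rate.

For each observed interaction we ask whether the model would have flagged
it: rank all candidate events in the active risk set by predicted rate and
mark a hit if the observed candidate falls in the top share (5% by
default).  Group interactions count once -- their dyadic constituents share
a statistic block, and the best-ranked constituent decides the hit.  Since
only ranks matter, the metric is invariant to monotone transforms of the
rates; ties are broken by a seeded random permutation, which makes a
rate-constant (baseline-only) model hit at about the share itself on
purely dyadic data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DesignArray, ValidationError


@dataclass
class GofResult:
    """Hit proportion over original (pre-split) events."""

    hit_rate: float
    hits: np.ndarray  # bool per original event, in block order
    top_k: int
    share: float
    seed: int | None

    def __post_init__(self) -> None:
        assert np.isclose(self.hit_rate, float(np.mean(self.hits)))


def top_share_hit_rate(
    beta: np.ndarray,
    design: DesignArray,
    share: float = 0.05,
    seed: int | None = None,
) -> GofResult:
    """Proportion of original events whose (best) dyad ranks in the top share.

    ``beta`` may be fitted or hypothesized.  The top-set size is
    k = ceil(share * |active risk set|), guaranteeing a non-empty set.
    """
    if not 0 < share <= 1:
        raise ValidationError(f"share must be in (0, 1], got {share}")
    beta = np.asarray(beta, dtype=float)
    rng = np.random.default_rng(seed)
    n_blocks = design.X.shape[0]
    hits = np.empty(n_blocks, dtype=bool)
    top_k = 0
    for g in range(n_blocks):
        act = design.active[g]
        n_active = int(act.sum())
        k = math.ceil(share * n_active)
        top_k = k
        eta = design.X[g] @ beta
        tiebreak = rng.random(len(eta))
        # rank of an entry = number of active entries strictly preferred
        # under (rate desc, tiebreak asc)
        order = np.lexsort((tiebreak, -eta))
        order = order[act[order]]
        ranks = np.empty(len(eta), dtype=np.int64)
        ranks[order] = np.arange(n_active)
        obs = design.obs_index[design.event_block == g]
        hits[g] = bool((ranks[obs] < k).any())
    return GofResult(
        hit_rate=float(hits.mean()), hits=hits, top_k=top_k, share=share, seed=seed
    )
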