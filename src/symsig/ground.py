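"""Ground similarity: Jaccard distances between tagged signals and JD_mu.

The *ground* of a signal is the set of salient facts about the referent that
the signaller chose to draw, operationalised as a set of canonical tag
strings produced by a coder ("tagger").  The Jaccard distance between two
tag sets X, Y,

    JD(X, Y) = 1 - |X n Y| / |X u Y|,

measures how differently two independently produced signals construe the
same item.  Averaging JD over all unordered pairs of *first-exposure*
signals for an item gives JD_mu, the item's ground unpredictability: 0 for a
code-like item always drawn the same way, 1 for an item whose grounds never
overlap.  JD_mu is computed per tagger and then averaged across taggers
("consensus"); agreement between taggers is summarised by Spearman rank
correlation of their by-item JD_mu vectors.

The measure is content-insensitive (bijective relabelling of one tagger's
vocabulary changes nothing) and proportional (a uniformly more detailed
tagger adds elements to numerator and denominator alike).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


def canonical_tags(tags: Iterable[str]) -> frozenset[str]:
    """Canonicalise labels: strip whitespace, uppercase, drop empties."""
    out = {t.strip().upper() for t in tags}
    out.discard("")
    return frozenset(out)


@dataclass(frozen=True)
class TagSet:
    """The coded ground of one signal by one tagger."""

    signal_id: str
    item_id: str
    tagger_id: str
    tags: frozenset[str]

    @classmethod
    def make(cls, signal_id: str, item_id: str, tagger_id: str, tags: Iterable[str]) -> "TagSet":
        return cls(signal_id, item_id, tagger_id, canonical_tags(tags))


@dataclass(frozen=True)
class ItemJD:
    """Mean pairwise Jaccard distance for one item (per tagger or consensus)."""

    item_id: str
    tagger_id: str  # a tagger id or "consensus"
    jd_mu: float
    n_signals: int
    n_pairs: int


def jaccard_distance(a: TagSet | frozenset[str] | set[str], b: TagSet | frozenset[str] | set[str]) -> float:
    """Jaccard distance 1 - |a n b| / |a u b| between two canonical tag sets.

    Two empty sets are treated as identical grounds (distance 0, logged),
    since the ratio is 0/0 there.
    """
    sa = a.tags if isinstance(a, TagSet) else frozenset(a)
    sb = b.tags if isinstance(b, TagSet) else frozenset(b)
    union = len(sa | sb)
    if union == 0:
        logger.warning("jaccard_distance of two empty tag sets: returning 0")
        return 0.0
    return 1.0 - len(sa & sb) / union


def item_jd_mean(signals: Sequence[TagSet]) -> ItemJD:
    """JD_mu of one item for one tagger: mean JD over all unordered signal pairs.

    ``signals`` must be the tagger's codings of the item's first-exposure
    signals; at least two are needed for the mean to be defined.
    """
    if len(signals) < 2:
        raise ValueError(
            f"JD_mu undefined with {len(signals)} signal(s); need at least 2"
        )
    items = {s.item_id for s in signals}
    taggers = {s.tagger_id for s in signals}
    if len(items) > 1 or len(taggers) > 1:
        raise ValueError(f"signals mix items {items} or taggers {taggers}")
    dists = [jaccard_distance(x, y) for x, y in itertools.combinations(signals, 2)]
    return ItemJD(
        item_id=items.pop(),
        tagger_id=taggers.pop(),
        jd_mu=float(np.mean(dists)),
        n_signals=len(signals),
        n_pairs=len(dists),
    )


def consensus_jd(per_tagger: Sequence[ItemJD]) -> ItemJD:
    """Average an item's JD_mu across taggers."""
    if not per_tagger:
        raise ValueError("consensus_jd needs at least one tagger value")
    items = {j.item_id for j in per_tagger}
    if len(items) > 1:
        raise ValueError(f"consensus_jd mixes items {items}")
    return ItemJD(
        item_id=items.pop(),
        tagger_id="consensus",
        jd_mu=float(np.mean([j.jd_mu for j in per_tagger])),
        n_signals=min(j.n_signals for j in per_tagger),
        n_pairs=min(j.n_pairs for j in per_tagger),
    )


def tagger_agreement(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (rho, p) between two aligned by-item JD_mu vectors.

    The p-value uses the t approximation for n >= 10 and an exact two-sided
    permutation test below that.  Constant vectors have no defined rank
    correlation and return (nan, nan).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and aligned on the same items")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 items for a rank correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("tagger_agreement: constant vector, correlation undefined")
        return (math.nan, math.nan)
    rho, p_t = stats.spearmanr(x, y)
    if n >= 10:
        return float(rho), float(p_t)
    # exact permutation distribution of rho (ties handled by average ranks)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (rx[perms] * ry).mean(axis=1)
    obs = float((rx * ry).mean())
    p = float(np.mean(np.abs(rhos) >= abs(obs) - 1e-12))
    return float(rho), p
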