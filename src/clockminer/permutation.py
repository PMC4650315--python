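"""Empirical null distribution of evidence scores.

The null model: each dataset's published hit count is reassigned uniformly at
random, without replacement, to the genes of the master list, independently
across datasets.  Any one gene's null score is therefore a weighted sum of
independent Bernoulli(h_d / n_genes) indicators, which admits an exact
convolution oracle alongside the Monte-Carlo shuffle.

Because the per-gene marginal is identical for every gene, all n_genes scores
from every iteration are pooled into one empirical distribution, maximizing
resolution at a given iteration count.  "More extreme" means >= the observed
score (a higher score is more evidence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .registry import DATA_CLASSES, Registry
from .scoring import PrefactorTriple, ScoreTable, combine_class_scores

__all__ = [
    "NullDistribution",
    "shuffle_null",
    "exact_null",
    "attach_pvalues",
    "significance_threshold",
]


@dataclass(frozen=True)
class NullDistribution:
    """Right-tail representation of a score null.

    ``tail_prob[i]`` = P(null score >= ``support[i]``), with ``support``
    strictly ascending.  ``n_iterations`` is 0 for the exact convolution.
    """

    support: np.ndarray
    tail_prob: np.ndarray
    n_iterations: int
    method: str
    n_pooled: int = field(default=0)  # pooled sample size behind a shuffle null

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        tail = np.asarray(self.tail_prob, dtype=float)
        if support.ndim != 1 or support.shape != tail.shape:
            raise ValueError("support and tail_prob must be 1-D and congruent")
        if np.any(np.diff(support) <= 0):
            raise ValueError("support must be strictly ascending")
        if np.any(np.diff(tail) > 1e-15):
            raise ValueError("tail_prob must be non-increasing in the score")
        if self.method not in ("shuffle", "exact"):
            raise ValueError(f"unknown method {self.method!r}")
        support.setflags(write=False)
        tail.setflags(write=False)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "tail_prob", tail)

    def pvalue(self, scores) -> np.ndarray:
        """P(null >= score) for each query score.

        Scores beyond the support take the nearest tail value; a shuffle null
        therefore never returns 0 (its floor is 1 / n_pooled).
        """
        s = np.atleast_1d(np.asarray(scores, dtype=float))
        idx = np.searchsorted(self.support, s, side="left")
        p = np.where(idx >= len(self.support), self.tail_prob[-1], self.tail_prob[np.minimum(idx, len(self.support) - 1)])
        return p if np.ndim(scores) else float(p[0])


def _pooled_to_null(pooled: np.ndarray, n_iterations: int) -> NullDistribution:
    support, counts = np.unique(pooled, return_counts=True)
    n = counts.sum()
    tail = counts[::-1].cumsum()[::-1] / n
    return NullDistribution(
        support=support,
        tail_prob=tail,
        n_iterations=n_iterations,
        method="shuffle",
        n_pooled=int(n),
    )


def _class_index(registry: Registry) -> np.ndarray:
    return np.array([DATA_CLASSES.index(r.data_class) for r in registry.records])


def shuffle_null(
    registry: Registry,
    n_iterations: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    prefactors: PrefactorTriple | None = None,
    batch_size: int | None = None,
) -> NullDistribution:
    """Monte-Carlo null by random reassignment of each dataset's hits.

    Per iteration, each dataset's ``expected_hits`` genes are drawn uniformly
    without replacement, independently across datasets; the n_genes scores of
    every iteration are pooled.  With ``prefactors`` the class-weighted score
    S(g) replaces the unit-weight total.  Reproducible under ``seed``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    n = registry.n_genes
    rng = np.random.default_rng(seed)
    cls_idx = _class_index(registry)
    weights = registry.weights
    hits = registry.expected_hits

    if batch_size is None:
        batch_size = max(1, min(n_iterations, 20_000_000 // max(n, 1)))

    pooled_parts = []
    done = 0
    while done < n_iterations:
        b = min(batch_size, n_iterations - done)
        class_sums = np.zeros((b, n, 3), dtype=np.int32)
        for d in range(len(registry)):
            h = int(hits[d])
            if h == 0:
                continue
            if h == n:
                class_sums[:, :, cls_idx[d]] += weights[d]
                continue
            # h smallest entries of iid uniforms = a uniform h-subset, per row
            r = rng.random((b, n))
            sel = np.argpartition(r, h - 1, axis=1)[:, :h]
            np.put_along_axis(
                class_sums[:, :, cls_idx[d]],
                sel,
                np.take_along_axis(class_sums[:, :, cls_idx[d]], sel, axis=1) + weights[d],
                axis=1,
            )
        if prefactors is None:
            pooled_parts.append(class_sums.sum(axis=2).ravel().astype(np.int64))
        else:
            pooled_parts.append(combine_class_scores(class_sums, prefactors).ravel())
        done += b
    pooled = np.concatenate(pooled_parts)
    return _pooled_to_null(pooled, n_iterations)


def _class_pmfs(registry: Registry) -> list[np.ndarray]:
    """Exact pmf of the weighted within-class hit sum of one gene, per class."""
    n = registry.n_genes
    pmfs = []
    for cls in DATA_CLASSES:
        mask = registry.class_mask(cls)
        cmax = int(registry.weights[mask].sum())
        pmf = np.zeros(cmax + 1)
        pmf[0] = 1.0
        for d in np.flatnonzero(mask):
            p = registry.expected_hits[d] / n
            w = int(registry.weights[d])
            new = pmf * (1.0 - p)
            new[w:] += pmf[: len(pmf) - w] * p
            pmf = new
        pmfs.append(pmf)
    return pmfs


def exact_null(
    registry: Registry, prefactors: PrefactorTriple | None = None
) -> NullDistribution:
    """Analytic null by convolution of the weighted Bernoulli sum.

    A single gene's null score is sum_d w_d * Bernoulli(h_d / n_genes),
    independent across datasets; with pre-factors the three class sums are
    convolved separately and combined as alpha*a + beta*b + gamma*c over the
    finite support of class-sum triples.
    """
    pmfs = _class_pmfs(registry)
    if prefactors is None:
        total = pmfs[0]
        for pmf in pmfs[1:]:
            total = np.convolve(total, pmf)
        support = np.arange(len(total), dtype=float)
        probs = total
    else:
        a, b, c = (np.arange(len(p)) for p in pmfs)
        grid = np.stack(np.meshgrid(a, b, c, indexing="ij"), axis=-1)
        scores = combine_class_scores(grid, prefactors).ravel()
        probs_grid = (
            pmfs[0][:, None, None] * pmfs[1][None, :, None] * pmfs[2][None, None, :]
        ).ravel()
        support, inv = np.unique(scores, return_inverse=True)
        probs = np.bincount(inv, weights=probs_grid)
    keep = probs > 0
    support, probs = support[keep], probs[keep]
    tail = np.clip(probs[::-1].cumsum()[::-1], 0.0, 1.0)
    # guard monotonicity against convolution round-off
    tail = np.maximum.accumulate(tail[::-1])[::-1]
    return NullDistribution(
        support=support, tail_prob=tail, n_iterations=0, method="exact"
    )


def attach_pvalues(
    scores: ScoreTable, null: NullDistribution, level: float | None = None
) -> ScoreTable:
    """Attach P(null >= observed) per gene; optionally flag significance.

    The null must have been built under the same registry and weighting as
    the observed scores.  Returns a new ScoreTable.
    """
    p = null.pvalue(scores.total_score)
    df = scores.table.copy()
    df["p_value"] = p
    if level is not None:
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        df["significant"] = p < level
    return ScoreTable(table=df, dataset_ids=scores.dataset_ids)


def significance_threshold(null: NullDistribution, level: float) -> float:
    """Smallest score whose right-tail probability is strictly below ``level``.

    If no support value qualifies, the next integer above the support is
    returned for an exact null (whose tail truly vanishes there); for a
    shuffle null whose resolution cannot represent ``level`` a ValueError
    advises more iterations or the exact oracle.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    below = np.flatnonzero(null.tail_prob < level)
    if below.size:
        return float(null.support[below[0]])
    if null.method == "shuffle" and null.n_pooled and level <= 1.0 / null.n_pooled:
        raise ValueError(
            f"level {level} is below the shuffle resolution 1/{null.n_pooled}; "
            "increase n_iterations or use exact_null"
        )
    return float(math.floor(null.support[-1]) + 1)
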