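"""Weight-robustness screen over the constrained pre-factor simplex.

Binary scoring hands the ChIP-seq class most of the weight simply because it
has the most datasets.  The screen compensates by re-balancing the three
evidence classes with random pre-factors (alpha, beta, gamma) drawn uniformly
from the simplex slice {sum = 1, 0.165 < each < 0.5} (each class weight
perturbed by at most 50% around the equal split 1/3), re-running the score
and its permutation null per draw, and retaining only genes significant under
every draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .permutation import NullDistribution, exact_null, shuffle_null
from .registry import HitMatrix, Registry
from .scoring import PrefactorTriple, class_scores, combine_class_scores

__all__ = [
    "RobustnessResult",
    "sample_prefactors",
    "robust_candidates",
    "constrained_simplex_fraction",
]

LOWER_DEFAULT = 0.165
UPPER_DEFAULT = 0.5


def constrained_simplex_fraction(lower: float, upper: float) -> float:
    """Area fraction of the simplex slice {sum=1, lower < each < upper}
    relative to the full 2-simplex (inclusion-exclusion on the box bounds)."""
    t = 1.0 - 3.0 * lower
    u = upper - lower
    if t <= 0 or u <= 0:
        return 0.0
    return t * t - 3.0 * max(t - u, 0.0) ** 2 + 3.0 * max(t - 2 * u, 0.0) ** 2


def _check_bounds(lower: float, upper: float) -> None:
    if not (lower < upper):
        raise ValueError(f"degenerate bounds: lower {lower} must be < upper {upper}")
    if not (3 * lower < 1 < 3 * upper):
        raise ValueError(
            f"infeasible bounds: need 3*lower < 1 < 3*upper, got lower={lower}, upper={upper}"
        )


def sample_prefactors(
    n_draws: int,
    lower: float = LOWER_DEFAULT,
    upper: float = UPPER_DEFAULT,
    seed: int | np.random.SeedSequence | None = None,
    return_attempts: bool = False,
):
    """I.i.d. uniform pre-factor triples on the constrained simplex.

    Rejection sampling: draw uniform on the full simplex (symmetric Dirichlet
    with unit concentration) and reject draws violating the open box bounds,
    which is provably uniform on the slice.  Draws are generated one at a
    time so that, for a fixed seed, the first k draws of any run coincide
    (nested draw sequences).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    _check_bounds(lower, upper)
    rng = np.random.default_rng(seed)
    draws: list[PrefactorTriple] = []
    attempts = 0
    while len(draws) < n_draws:
        a, b, g = rng.dirichlet((1.0, 1.0, 1.0))
        attempts += 1
        if lower < a < upper and lower < b < upper and lower < g < upper:
            draws.append(PrefactorTriple(a, b, 1.0 - a - b))
    if return_attempts:
        return draws, attempts
    return draws


@dataclass(frozen=True)
class RobustnessResult:
    """Outcome of the screen: per-draw significant gene sets and their
    intersection."""

    draws: tuple[PrefactorTriple, ...]
    per_draw_significant: tuple[frozenset, ...]
    per_draw_threshold: tuple[float, ...]
    robust_genes: frozenset

    def __post_init__(self) -> None:
        for sig in self.per_draw_significant:
            if not self.robust_genes <= sig:
                raise ValueError("robust_genes must be contained in every draw's set")


def robust_candidates(
    hits: HitMatrix,
    registry: Registry,
    n_draws: int = 100,
    level: float = 0.001,
    null_iterations: int = 1000,
    seed: int | None = None,
    null_method: str = "shuffle",
    lower: float = LOWER_DEFAULT,
    upper: float = UPPER_DEFAULT,
    draws: Sequence[PrefactorTriple] | None = None,
) -> RobustnessResult:
    """Genes significant at ``level`` under every sampled pre-factor triple.

    For each draw the class-weighted scores S(g) are recomputed, a fresh null
    is built under the same pre-factors (Monte-Carlo shuffle with
    ``null_iterations`` iterations, or the exact convolution when
    ``null_method="exact"``), and genes with p < level are flagged; the
    robust set is the intersection over draws.  Per-draw null seeds derive
    deterministically from ``seed``.

    ``draws`` overrides the sampler with explicit pre-factor triples (used
    e.g. to screen at exactly the equal split).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if null_method not in ("shuffle", "exact"):
        raise ValueError(f"unknown null_method {null_method!r}")
    if draws is None:
        draws = sample_prefactors(
            n_draws, lower=lower, upper=upper,
            seed=np.random.SeedSequence(entropy=seed, spawn_key=(0,)),
        )
    else:
        draws = list(draws)
    cs = class_scores(hits, registry)
    gene_ids = np.asarray(hits.gene_ids)

    per_draw_sig: list[frozenset] = []
    per_draw_thr: list[float] = []
    for k, w in enumerate(draws):
        s = combine_class_scores(cs, w)
        if null_method == "exact":
            null = exact_null(registry, prefactors=w)
        else:
            null = shuffle_null(
                registry,
                n_iterations=null_iterations,
                seed=np.random.SeedSequence(entropy=seed, spawn_key=(1, k)),
                prefactors=w,
            )
        p = null.pvalue(s)
        sig = frozenset(gene_ids[p < level])
        per_draw_sig.append(sig)
        per_draw_thr.append(_threshold_or_nan(null, level))
    robust = frozenset.intersection(*per_draw_sig) if per_draw_sig else frozenset()
    return RobustnessResult(
        draws=tuple(draws),
        per_draw_significant=tuple(per_draw_sig),
        per_draw_threshold=tuple(per_draw_thr),
        robust_genes=robust,
    )


def _threshold_or_nan(null: NullDistribution, level: float) -> float:
    from .permutation import significance_threshold

    try:
        return significance_threshold(null, level)
    except ValueError:
        return float("nan")
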