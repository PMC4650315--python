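"""Per-dataset overrepresentation of circadian hits.

Annotates a dataset's hit count in the master list with significance stars
for enrichment relative to a background universe, using the one-sided
hypergeometric (Fisher) upper-tail test — the standard gene-list
overrepresentation test.  The background universe size is a required input
and is never silently defaulted.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

__all__ = ["EnrichmentResult", "dataset_enrichment"]

_STAR_THRESHOLDS = (("***", 0.001), ("**", 0.01), ("*", 0.05))


def _stars(p: float) -> str:
    for label, cut in _STAR_THRESHOLDS:
        if p < cut:
            return label
    return "ns"


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric overrepresentation of one dataset's hits.

    ``stars``: *** p<0.001, ** p<0.01, * p<0.05, ns otherwise.
    """

    dataset_id: str
    hits_in_list: int
    list_size: int
    background_hits: int
    background_size: int
    p_value: float
    stars: str


def dataset_enrichment(
    hits_in_list: int,
    list_size: int,
    background_hits: int,
    background_size: int,
    dataset_id: str = "",
) -> EnrichmentResult:
    """Upper-tail hypergeometric p-value of observing >= ``hits_in_list``
    successes in a draw of ``list_size`` from a ``background_size`` universe
    containing ``background_hits`` successes."""
    if not 0 <= hits_in_list <= list_size:
        raise ValueError("need 0 <= hits_in_list <= list_size")
    if not 0 <= background_hits <= background_size:
        raise ValueError("need 0 <= background_hits <= background_size")
    if list_size > background_size:
        raise ValueError("list_size exceeds background_size")
    if hits_in_list > background_hits:
        raise ValueError("hits_in_list exceeds background_hits")
    if list_size - hits_in_list > background_size - background_hits:
        raise ValueError("non-hits in list exceed background non-hits")
    p = float(hypergeom.sf(hits_in_list - 1, background_size, background_hits, list_size))
    p = min(max(p, 0.0), 1.0)
    return EnrichmentResult(
        dataset_id=dataset_id,
        hits_in_list=hits_in_list,
        list_size=list_size,
        background_hits=background_hits,
        background_size=background_size,
        p_value=p,
        stars=_stars(p),
    )
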