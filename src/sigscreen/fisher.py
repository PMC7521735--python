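"""Signed rank-based correlation between a signature and a bioset.

The running Fisher test asks whether the top of one effect-size-ranked
gene list is improbably enriched for the members of another.  The
ranked query list is scanned prefix by prefix; at each prefix length
``i`` the overlap with the target set is scored with an exact
hypergeometric upper tail on the shared gene universe of size ``N``;
the best (minimum) tail probability over the scan is then Bonferroni
corrected by the number of prefixes evaluated and capped at 1.  The
scan-and-correct construction is deliberately conservative and is
monotone: growing the universe with the overlaps fixed can only
sharpen significance.

Directionality: the query and target are each split into up- and
down-regulated sub-lists.  The two concordant pairings (up/up,
down/down) and the two discordant pairings (up/down, down/up) are
scored separately and aggregated as

    value = [−log10 p(up,up) − log10 p(down,down)]
          − [−log10 p(up,down) − log10 p(down,up)]

so a target that mirrors the signature scores positive, a target that
opposes it scores the exact negative (antisymmetry under sign flip),
and an unrelated target scores near zero.  Throughout the package a
value ≥ 4 is read as activation of the factor and ≤ −4 as suppression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .core import Bioset, GeneUniverse
from .biomarker import Biomarker

__all__ = ["SignedScore", "hypergeom_tail", "running_min_p", "signed_score"]


@dataclass(frozen=True)
class SignedScore:
    """Signed −log10(p) with its four directional sub-test p-values."""

    value: float
    direction: Literal["positive", "negative", "none"]
    components: dict[str, float]  # keys: up_up, down_down, up_down, down_up

    def __float__(self) -> float:
        return self.value


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` successes observed in a prefix (sample) of size ``n`` drawn
    without replacement from a universe of ``N`` genes of which ``K``
    belong to the target set.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(
            f"hypergeometric bounds violated: k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def running_min_p(
    ranked_query: Sequence[str], target_set: Iterable[str], N: int
) -> float:
    """Best Bonferroni-corrected hypergeometric tail over all query prefixes.

    ``ranked_query`` must already be ordered by descending |fold change|
    (ties broken lexicographically by gene id for determinism).  Returns
    1.0 for an empty query or target.
    """
    target = set(target_set)
    n_query = len(ranked_query)
    if n_query == 0 or not target:
        return 1.0
    if n_query > N or len(target) > N:
        raise ValueError("query or target larger than the universe")
    member = np.fromiter((g in target for g in ranked_query), dtype=bool, count=n_query)
    k = np.cumsum(member)  # overlap at each prefix
    i = np.arange(1, n_query + 1)  # prefix sizes
    tails = stats.hypergeom.sf(k - 1, N, len(target), i)
    tails = np.where(k == 0, 1.0, tails)
    return float(min(tails.min() * n_query, 1.0))


def _query_parts(query: Biomarker | Bioset) -> tuple[set[str], set[str], dict[str, float]]:
    return query.up_genes(), query.down_genes(), query.fold_changes()


def signed_score(
    query: Biomarker | Bioset,
    target: Bioset,
    universe: GeneUniverse | None = None,
) -> SignedScore:
    """Signed running-Fisher correlation between *query* and *target*.

    The universe defaults to the target's platform; pass one explicitly
    to restrict further (e.g. to a cross-platform intersection).  Query
    genes outside the universe are dropped before scanning; an empty
    sub-list contributes p = 1 (zero evidence) to its pairings.
    """
    if universe is None:
        universe = target.platform
        if isinstance(query, Bioset):
            universe = query.platform.intersection(target.platform)
    N = len(universe)

    fcs = query.fold_changes()
    q_ranked = [g for g in query.ranked_gene_ids() if g in universe]
    q_up_ranked = [g for g in q_ranked if fcs[g] > 0]
    q_down_ranked = [g for g in q_ranked if fcs[g] < 0]

    t_up = {g for g in target.up_genes() if g in universe}
    t_down = {g for g in target.down_genes() if g in universe}

    components = {
        "up_up": running_min_p(q_up_ranked, t_up, N),
        "down_down": running_min_p(q_down_ranked, t_down, N),
        "up_down": running_min_p(q_up_ranked, t_down, N),
        "down_up": running_min_p(q_down_ranked, t_up, N),
    }
    s_pos = -np.log10(components["up_up"]) - np.log10(components["down_down"])
    s_neg = -np.log10(components["up_down"]) - np.log10(components["down_up"])
    value = float(s_pos - s_neg)
    direction = "none" if value == 0 else ("positive" if value > 0 else "negative")
    return SignedScore(value=value, direction=direction, components=components)
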