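"""Hypergeometric over-representation analysis of retained modules.

Each (retained module, gene set) pair is scored by the upper-tail
hypergeometric probability P(X >= k) of drawing at least the observed
overlap when the module is sampled without replacement from the universe,
with gene sets first restricted to the universe.  BH adjustment is pooled
across all module x set tests.  The universe defaults to the DE gene
list the modules were drawn from.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .mcl import ModuleAssignment
from .types import GeneSetCollection, ValidationError
from .expression import benjamini_hochberg


def hypergeom_overrep_p(overlap: int, module: int, set_size: int, universe: int) -> float:
    """Upper-tail P(X >= overlap), X ~ Hypergeom(universe, set_size, module)."""
    k, n, K, N = overlap, module, set_size, universe
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError("set and module sizes must lie within the universe")
    if not 0 <= k <= min(n, K):
        raise ValidationError(f"overlap {k} infeasible for module {n}, set {K}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_modules(
    modules: ModuleAssignment,
    sets: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """One hypergeometric test per (retained module, non-empty restricted set).

    Returns a table with columns module_id, set_name, overlap,
    module_size, set_size, universe_size, p, q, sorted by q then p.
    """
    universe = set(universe)
    rows = []
    for cid in sorted(modules.retained):
        members = set(modules.clusters[cid])
        outside = members - universe
        if outside:
            raise ValidationError(
                f"module {cid} gene {sorted(outside)[0]!r} not in universe"
            )
        for name in sorted(sets):
            restricted = sets.members(name) & universe
            if not restricted:
                continue
            k = len(members & restricted)
            p = hypergeom_overrep_p(k, len(members), len(restricted), len(universe))
            rows.append(
                {
                    "module_id": cid,
                    "set_name": name,
                    "overlap": k,
                    "module_size": len(members),
                    "set_size": len(restricted),
                    "universe_size": len(universe),
                    "p": p,
                }
            )
    result = pd.DataFrame(
        rows,
        columns=[
            "module_id", "set_name", "overlap", "module_size",
            "set_size", "universe_size", "p",
        ],
    )
    result["q"] = benjamini_hochberg(result.p.to_numpy()) if len(result) else []
    return result.sort_values(["q", "p", "module_id", "set_name"]).reset_index(drop=True)
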