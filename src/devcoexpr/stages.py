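"""Stage-specificity calls from averaged SDR profiles.

A gene is called specific to one developmental stage when its mean SDR in
that stage is at least 0.4 and exceeds every other stage's mean by at
least 0.3 (additively).  Failing that, it is called specific to a pair of
consecutive stages when both stage means are at least 0.3, their average
is at least 0.4, and that average exceeds every other stage's mean by at
least 0.3.  All comparisons are inclusive.  Because the margin is
positive, at most one stage (and, given precedence, at most one label)
can ever qualify.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .types import ValidationError

NO_CALL = ""
PAIR_SEP = "+"


@dataclass(frozen=True)
class SpecificityRule:
    single_min: float = 0.4
    single_margin: float = 0.3
    dual_each_min: float = 0.3
    dual_mean_min: float = 0.4
    dual_margin: float = 0.3

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")


def classify_profile(values: dict[str, float], stage_order, rule: SpecificityRule) -> str:
    """Label one gene's stage-mean SDR profile: a stage, "A+B", or ""."""
    missing = [s for s in stage_order if s not in values]
    if missing:
        raise ValidationError(f"profile missing stage {missing[0]!r}")
    # single-stage rule first, in stage order
    for s in stage_order:
        v = values[s]
        if v >= rule.single_min and all(
            v >= values[t] + rule.single_margin for t in stage_order if t != s
        ):
            return s
    # then consecutive pairs, in stage order; first qualifying pair wins
    for a, b in zip(stage_order[:-1], stage_order[1:]):
        va, vb = values[a], values[b]
        mean = (va + vb) / 2.0
        if (
            va >= rule.dual_each_min
            and vb >= rule.dual_each_min
            and mean >= rule.dual_mean_min
            and all(
                mean >= values[t] + rule.dual_margin
                for t in stage_order
                if t not in (a, b)
            )
        ):
            return f"{a}{PAIR_SEP}{b}"
    return NO_CALL


def classify_stage_specific(
    profile: pd.DataFrame,
    rule: SpecificityRule = SpecificityRule(),
    stage_order: tuple[str, ...] | None = None,
) -> pd.Series:
    """Apply the SDR threshold rules to every gene in a genes x stages table.

    Returns a Series gene -> label ("" for no call).  ``stage_order``
    defaults to the profile's column order.
    """
    order = tuple(stage_order) if stage_order is not None else tuple(profile.columns)
    missing = [s for s in order if s not in profile.columns]
    if missing:
        raise ValidationError(f"profile missing stage {missing[0]!r}")
    labels = {
        gene: classify_profile(row.to_dict(), order, rule)
        for gene, row in profile.iterrows()
    }
    return pd.Series(labels, name="stage_label")


def annotate_gene_list(calls: pd.Series, gene_list) -> pd.Series:
    """Restrict calls to genes in the supplied list (e.g. an SSTF catalogue)."""
    wanted = set(gene_list)
    return calls[calls.index.isin(wanted)]
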