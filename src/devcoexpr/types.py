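"""Shared domain types for the developmental co-expression pipeline.

The pipeline's currency is a stage-labelled count matrix: raw integer
counts for each gene in each biological replicate, with replicates grouped
into ordered developmental stages (e.g. embryonic days E11 < E12 < E13 <
E14).  Everything downstream — normalization, differential expression,
signed difference ratios, the co-expression network — consumes these
containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Mapping

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass(frozen=True)
class CountMatrix:
    """Raw gene x sample integer counts with ordered, unique identifiers."""

    counts: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        df = self.counts
        dup_genes = df.index[df.index.duplicated()].unique()
        if len(dup_genes):
            raise ValidationError(f"duplicate gene id: {dup_genes[0]!r}")
        dup_samples = df.columns[df.columns.duplicated()].unique()
        if len(dup_samples):
            raise ValidationError(f"duplicate sample id: {dup_samples[0]!r}")
        values = df.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                # accept float input only if integral
                if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                    bad = np.argwhere(~np.isfinite(values) | (values != np.floor(values)))[0]
                    raise ValidationError(
                        f"non-integer count at gene {df.index[bad[0]]!r}, "
                        f"sample {df.columns[bad[1]]!r}"
                    )
                object.__setattr__(self, "counts", df.astype(np.int64))
                values = self.counts.to_numpy()
            if np.any(values < 0):
                bad = np.argwhere(values < 0)[0]
                raise ValidationError(
                    f"negative count at gene {df.index[bad[0]]!r}, "
                    f"sample {df.columns[bad[1]]!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass(frozen=True)
class SampleMetadata:
    """Sample -> developmental stage mapping with an explicit stage order.

    Stage labels are opaque strings; ordering is biological and comes only
    from ``stage_order`` (lexical sorting would put "E9" after "E11").
    """

    stage_of: Mapping[str, str]
    stage_order: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage_of", dict(self.stage_of))
        object.__setattr__(self, "stage_order", tuple(self.stage_order))
        if len(set(self.stage_order)) != len(self.stage_order):
            raise ValidationError("stage_order contains duplicates")
        if len(self.stage_order) < 2:
            raise ValidationError("at least 2 stages are required")
        known = set(self.stage_order)
        for sample, stage in self.stage_of.items():
            if stage not in known:
                raise ValidationError(
                    f"sample {sample!r} has stage {stage!r} not in stage_order"
                )
        for stage in self.stage_order:
            n = sum(1 for s in self.stage_of.values() if s == stage)
            if n < 2:
                raise ValidationError(
                    f"stage {stage!r} has {n} samples; >= 2 required"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.stage_of)

    def samples_of(self, stage: str) -> list[str]:
        """Samples assigned to ``stage``, in metadata order."""
        return [s for s, st in self.stage_of.items() if st == stage]

    def consecutive_pairs(self) -> list[tuple[str, str]]:
        """Consecutive stage pairs in developmental order."""
        return list(zip(self.stage_order[:-1], self.stage_order[1:]))


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (a GMT-style collection) for over-representation tests."""

    sets: Mapping[str, tuple[str, frozenset[str]]]  # name -> (description, members)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sets", dict(self.sets))
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]


@dataclass
class RunConfig:
    """All pipeline tunables with their documented defaults.

    Defaults mirror the published analysis where it states a value: a 1.5
    minimum fold change and q <= 0.05 for the consecutive-stage DE filter,
    a network FDR cutoff of 1e-16 chosen against a scale-free-topology
    R^2 requirement of 0.88, a module size of at least nine nodes, and
    stage-specificity thresholds of 0.4 (level) and 0.3 (additive margin).
    """

    pseudocount: float = 1.0
    de_fc_min: float = 1.5
    de_q_max: float = 0.05
    scan_grid: tuple[float, ...] = (
        1e-2, 1e-4, 1e-6, 1e-8, 1e-10, 1e-12, 1e-14, 1e-16,
    )
    network_cutoff: float = 1e-16
    scale_free_r2: float = 0.88
    mcl_expansion: int = 2
    mcl_inflation: float = 2.0
    mcl_prune: float = 1e-5
    mcl_tolerance: float = 1e-8
    mcl_max_iterations: int = 100
    mcl_self_loop: float = 1.0
    module_min_size: int = 9
    single_stage_min: float = 0.4
    single_stage_margin: float = 0.3
    dual_stage_min: float = 0.3
    dual_mean_min: float = 0.4
    dual_margin: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        if self.de_fc_min < 1:
            raise ValidationError("de_fc_min must be >= 1")
        if not 0 <= self.de_q_max <= 1:
            raise ValidationError("de_q_max must be in [0, 1]")
        self.scan_grid = tuple(float(c) for c in self.scan_grid)
        if not self.scan_grid or any(not 0 < c <= 1 for c in self.scan_grid):
            raise ValidationError("scan_grid cutoffs must be in (0, 1]")
        if not 0 < self.network_cutoff <= 1:
            raise ValidationError("network_cutoff must be in (0, 1]")
        if not 0 <= self.scale_free_r2 <= 1:
            raise ValidationError("scale_free_r2 must be in [0, 1]")
        if self.mcl_expansion < 2 or int(self.mcl_expansion) != self.mcl_expansion:
            raise ValidationError("mcl_expansion must be an integer >= 2")
        if self.mcl_inflation <= 1:
            raise ValidationError("mcl_inflation must be > 1")
        if self.mcl_prune < 0:
            raise ValidationError("mcl_prune must be >= 0")
        if self.module_min_size < 1:
            raise ValidationError("module_min_size must be >= 1")
        for name in ("single_stage_min", "single_stage_margin", "dual_stage_min",
                     "dual_mean_min", "dual_margin"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scan_grid"] = list(self.scan_grid)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "scan_grid" in kwargs:
            kwargs["scan_grid"] = tuple(kwargs["scan_grid"])
        return cls(**kwargs)
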