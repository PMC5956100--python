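"""Synthetic bulk RNA-seq time courses with planted structure.

The generator emulates a four-stage developmental time course with
unbalanced biological replicates (6/7/9/6 by default, 28 samples in all)
and produces negative-binomial counts with three kinds of planted signal,
each recorded in a ground-truth table:

* **DE blocks** — contiguous blocks of genes whose log2 mean is shifted by
  a fixed amount in one stage or in a run of consecutive stages, so they
  are differentially expressed between the flanking consecutive stage
  pairs.  Blocks confined to one stage (or one consecutive pair) double as
  stage-specific marker genes for the SDR classification rules.
* **Modules** — blocks of genes sharing a single latent Gaussian factor.
  Each sample draws one factor value (a stage-dependent activity level
  plus unit-variance jitter) and every member gene adds
  ``loading * factor`` to its log2 mean, which plants high within-module
  Pearson correlation for the network and clustering stages to recover.
* **Library-size variation** — per-sample scaling factors drawn
  log-uniformly within a configurable fold range (2-fold by default),
  exercising the CPM normalization.

Counts are NB(mean, dispersion) with variance ``mu + dispersion * mu^2``;
dispersion 0 degrades to Poisson.  A fixed seed gives byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import CountMatrix, SampleMetadata, ValidationError

DEFAULT_STAGES = ("E11", "E12", "E13", "E14")
DEFAULT_REPLICATES = (6, 7, 9, 6)


@dataclass(frozen=True)
class DEBlock:
    """A block of genes up-shifted by ``log2fc`` in the given consecutive stages."""

    size: int
    stages: tuple[str, ...]
    log2fc: float


@dataclass(frozen=True)
class ModuleSpec:
    """A block of co-regulated genes driven by one latent factor.

    ``activity`` maps stage -> mean factor level; per-sample jitter is
    N(0, factor_sd), so ``loading`` directly tunes within-module
    correlation while ``factor_sd`` controls how much the factor wanders
    around its stage activity.  ``baseline_log2`` overrides the global
    baseline draw so module genes sit at a well-measured expression level.
    """

    size: int
    loading: float
    activity: dict[str, float]
    factor_sd: float = 1.0
    baseline_log2: float | None = 7.0


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 1200
    stage_order: tuple[str, ...] = DEFAULT_STAGES
    replicates: tuple[int, ...] = DEFAULT_REPLICATES
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    dispersion: float = 0.05
    de_blocks: tuple[DEBlock, ...] = ()
    modules: tuple[ModuleSpec, ...] = ()
    library_fold: float = 2.0
    seed: int = 2018

    def __post_init__(self) -> None:
        if len(self.replicates) != len(self.stage_order):
            raise ValidationError("replicates must match stage_order length")
        if any(r < 2 for r in self.replicates):
            raise ValidationError("every stage needs >= 2 replicates")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.library_fold < 1:
            raise ValidationError("library_fold must be >= 1")
        planted = sum(b.size for b in self.de_blocks) + sum(m.size for m in self.modules)
        if planted > self.n_genes:
            raise ValidationError(
                f"planted blocks need {planted} genes but n_genes = {self.n_genes}"
            )
        stages = set(self.stage_order)
        for b in self.de_blocks:
            if not set(b.stages) <= stages:
                raise ValidationError(f"DE block stages {b.stages} not in stage_order")
            idx = [self.stage_order.index(s) for s in b.stages]
            if sorted(idx) != list(range(min(idx), max(idx) + 1)):
                raise ValidationError(f"DE block stages {b.stages} must be consecutive")
        for m in self.modules:
            if not set(m.activity) <= stages:
                raise ValidationError("module activity references unknown stage")

    @property
    def n_samples(self) -> int:
        return sum(self.replicates)


def default_study_config() -> SimConfig:
    """The default study design: 4 stages, 6/7/9/6 replicates, 28 samples.

    Plants one single-stage DE block per stage and one block per
    consecutive stage pair (log2 fold change 2), plus three 30-gene
    latent-factor modules active at E11, E13 and E14 respectively with
    loading 1.8 — strong enough that module edges survive even the most
    stringent scanned significance cutoff, while keeping the modules'
    share of each library small enough that counts-per-million values of
    unrelated genes are not visibly distorted.
    """
    stages = DEFAULT_STAGES
    de_blocks = tuple(
        DEBlock(size=40, stages=(s,), log2fc=2.0) for s in stages
    ) + tuple(
        DEBlock(size=20, stages=(a, b), log2fc=2.0)
        for a, b in zip(stages[:-1], stages[1:])
    )
    modules = tuple(
        ModuleSpec(
            size=30,
            loading=1.8,
            activity={st: (2.0 if st == active else 0.0) for st in stages},
            factor_sd=0.6,
        )
        for active in ("E11", "E13", "E14")
    )
    return SimConfig(de_blocks=de_blocks, modules=modules, dispersion=0.01,
                     seed=2018)


def _sample_layout(config: SimConfig) -> tuple[list[str], list[str]]:
    """Sample ids and their stage labels, grouped by stage in order."""
    sample_ids, stages = [], []
    for stage, n in zip(config.stage_order, config.replicates):
        for i in range(1, n + 1):
            sample_ids.append(f"{stage}_r{i}")
            stages.append(stage)
    return sample_ids, stages


def simulate_dataset(
    config: SimConfig,
) -> tuple[CountMatrix, SampleMetadata, pd.DataFrame]:
    """Draw one dataset; returns (counts, metadata, ground-truth table).

    The ground truth has one row per gene with columns ``is_de``,
    ``de_pairs`` (comma-joined "A|B" consecutive pairs with a planted mean
    change), ``module_id`` (-1 for none) and ``stage_label`` (the intended
    stage-specificity call: a stage, "A+B", or "").
    """
    rng = np.random.default_rng(config.seed)
    sample_ids, sample_stages = _sample_layout(config)
    n_samples = len(sample_ids)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          config.n_genes)
    log2mu = np.tile(baseline[:, None], (1, n_samples))

    stage_of_col = np.array(sample_stages)
    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "is_de": False,
            "de_pairs": "",
            "module_id": -1,
            "stage_label": "",
        }
    ).set_index("gene")

    cursor = 0
    # planted modules first, then DE blocks, then null genes
    for m_id, mod in enumerate(config.modules):
        idx = range(cursor, cursor + mod.size)
        cursor += mod.size
        activity = np.array([mod.activity.get(st, 0.0) for st in sample_stages])
        factor = activity + rng.normal(0.0, mod.factor_sd, n_samples)
        if mod.baseline_log2 is not None:
            log2mu[list(idx), :] = mod.baseline_log2
        log2mu[list(idx), :] += mod.loading * factor[None, :]
        for g in idx:
            truth.iloc[g, truth.columns.get_loc("module_id")] = m_id
        # the stage activity profile also shifts consecutive-stage means
        means = {st: mod.loading * mod.activity.get(st, 0.0)
                 for st in config.stage_order}
        pairs = _changed_pairs(means, config.stage_order)
        if pairs:
            truth.iloc[list(idx), truth.columns.get_loc("is_de")] = True
            truth.iloc[list(idx), truth.columns.get_loc("de_pairs")] = ",".join(pairs)

    for block in config.de_blocks:
        idx = list(range(cursor, cursor + block.size))
        cursor += block.size
        mask = np.isin(stage_of_col, block.stages)
        log2mu[np.ix_(idx, np.where(mask)[0])] += block.log2fc
        means = {st: (block.log2fc if st in block.stages else 0.0)
                 for st in config.stage_order}
        pairs = _changed_pairs(means, config.stage_order)
        truth.iloc[idx, truth.columns.get_loc("is_de")] = bool(pairs)
        truth.iloc[idx, truth.columns.get_loc("de_pairs")] = ",".join(pairs)
        if block.log2fc > 0 and len(block.stages) in (1, 2):
            truth.iloc[idx, truth.columns.get_loc("stage_label")] = "+".join(
                block.stages
            )

    # library-size factors, log-uniform within [1/sqrt(f), sqrt(f)]
    half = np.log2(config.library_fold) / 2.0
    lib_log2 = rng.uniform(-half, half, n_samples)
    mu = np.exp2(log2mu + lib_log2[None, :])

    if config.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / config.dispersion
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)

    matrix = CountMatrix(
        pd.DataFrame(counts.astype(np.int64), index=gene_ids, columns=sample_ids)
    )
    meta = SampleMetadata(dict(zip(sample_ids, sample_stages)), config.stage_order)
    return matrix, meta, truth.reset_index()


def _changed_pairs(stage_means: dict[str, float], stage_order: tuple[str, ...]) -> list[str]:
    pairs = []
    for a, b in zip(stage_order[:-1], stage_order[1:]):
        if stage_means[a] != stage_means[b]:
            pairs.append(f"{a}|{b}")
    return pairs


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
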