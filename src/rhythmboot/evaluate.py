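"""Benchmarking: confusion counts against simulation truth, consensus
curves, replicate-count sensitivity, and overlap (venn) region counts.

Everything here scores detector output against the ground-truth labels the
generators produced.  Because false/true negatives follow from the class
totals, the interesting quantities are TP and FP as functions of the
consensus threshold k; consensus sets are nested decreasing in k, so both
curves are non-increasing in k by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .detectors import make_detector
from .exceptions import InputError
from .resample import (
    ConsensusTable,
    ResamplingConsensus,
    average_dataset,
    consensus_set,
)
from .simdata import (
    SimulationConfig,
    TruthLabels,
    assemble_initial_datasets,
    simulate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "BenchmarkConfig",
    "BenchmarkResult",
    "confusion_at_consensus",
    "confusion_from_mask",
    "run_benchmark",
    "replicate_sensitivity",
    "overlap_counts",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN at one consensus level.

    Invariants: tp + fn equals the number of truth-positive genes and
    fp + tn the number of truth-negative genes.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    consensus_k: int | None = None
    method: str | None = None
    simulation: str | None = None


def confusion_from_mask(called, truth) -> ConfusionCounts:
    """Confusion cells for a boolean called-rhythmic mask."""
    called = np.asarray(called, dtype=bool)
    pos = truth.rhythmic if isinstance(truth, TruthLabels) else np.asarray(truth, bool)
    if called.shape != pos.shape:
        raise InputError("call mask and truth labels differ in length")
    return ConfusionCounts(
        tp=int((called & pos).sum()),
        fp=int((called & ~pos).sum()),
        tn=int((~called & ~pos).sum()),
        fn=int((~called & pos).sum()),
    )


def confusion_at_consensus(table: ConsensusTable, truth: TruthLabels,
                           k: int) -> ConfusionCounts:
    """Confusion cells of the consensus-k call set against truth labels."""
    if list(table.gene_ids) != list(truth.gene_ids):
        raise InputError("consensus table and truth labels use different gene universes")
    sel = consensus_set(table, k)
    called = np.array([g in sel for g in table.gene_ids])
    c = confusion_from_mask(called, truth)
    return ConfusionCounts(c.tp, c.fp, c.tn, c.fn, consensus_k=k)


def overlap_counts(call_sets) -> dict[tuple[bool, ...], int]:
    """Venn-region counts over 2-6 call sets.

    Keys are membership signatures (one bool per dataset, in input order);
    the value counts genes called in exactly that subset of datasets.  All
    non-empty signatures are present, zero counts included.
    """
    n = len(call_sets)
    if not 2 <= n <= 6:
        raise InputError("overlap_counts supports between 2 and 6 call sets")
    sets = [set(s) for s in call_sets]
    regions = {
        sig: 0
        for sig in product((False, True), repeat=n)
        if any(sig)
    }
    for g in set().union(*sets):
        sig = tuple(g in s for s in sets)
        regions[sig] += 1
    return regions


@dataclass(frozen=True)
class BenchmarkConfig:
    """One cell of the simulation benchmark.

    ``kinds`` selects which dataset views are scored: individual
    replicates, the replicate average, consensus over the initial
    replicates, consensus over resampled datasets, and consensus over the
    original per-individual simulations (the ideal ceiling where one
    organism could be measured repeatedly).
    """

    simulation: str = "ld"
    method: str = "arser"
    n_rhythmic: int = 8400
    n_null: int = 8400
    n_individuals: int = 36
    n_replicates: int = 3
    n_resamples: int = 36
    resample_mode: str = "per_gene"
    kinds: tuple[str, ...] = (
        "replicates",
        "averaged",
        "initial_consensus",
        "resampled_consensus",
        "original_consensus",
    )
    seed: int = 0
    sim_kwargs: dict = field(default_factory=dict)
    detector_kwargs: dict = field(default_factory=dict)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_rhythmic=self.n_rhythmic,
            n_null=self.n_null,
            n_individuals=self.n_individuals,
            **self.sim_kwargs,
        )


@dataclass
class BenchmarkResult:
    """Long-form confusion table plus the seeds that produced it."""

    table: pd.DataFrame
    seed: int
    sub_seeds: dict = field(default_factory=dict)

    def rows(self, kind: str) -> pd.DataFrame:
        return self.table[self.table["kind"] == kind]


def _rows_for_curve(masks, truth, kind, config, rows):
    """Append confusion rows for consensus k = 1..len(masks)."""
    counts = np.sum(masks, axis=0)
    for k in range(1, len(masks) + 1):
        c = confusion_from_mask(counts >= k, truth)
        rows.append(
            dict(
                simulation=config.simulation, method=config.method, kind=kind,
                k=k, tp=c.tp, fp=c.fp, tn=c.tn, fn=c.fn, seed=config.seed,
            )
        )


def run_benchmark(config: BenchmarkConfig) -> BenchmarkResult:
    """Simulate, assemble, detect, and score one benchmark cell.

    The pipeline is: simulate ``n_individuals`` organisms; assemble the
    initial ``n_replicates``-replicate dataset by destructive sampling;
    then, per requested kind, score the individual replicates, the
    averaged dataset, the consensus across initial replicates, the
    consensus across resampled datasets, and the consensus across the
    original simulations.
    """
    ss = np.random.SeedSequence(config.seed)
    s_sim, s_asm, s_res = ss.spawn(3)
    sub_seeds = {
        "simulate": int(s_sim.generate_state(1)[0]),
        "assemble": int(s_asm.generate_state(1)[0]),
        "resample": int(s_res.generate_state(1)[0]),
    }
    sim_cfg = config.simulation_config()
    individuals = simulate(config.simulation, sim_cfg,
                           rng=np.random.default_rng(s_sim))
    dataset, truth = assemble_initial_datasets(
        individuals, config.n_replicates, np.random.default_rng(s_asm),
        timepoints=sim_cfg.times,
    )
    times = sim_cfg.times
    rows: list[dict] = []

    def detector():
        return make_detector(config.method, **config.detector_kwargs)

    replicate_masks = None
    if "replicates" in config.kinds or "initial_consensus" in config.kinds:
        replicate_masks = []
        for r in range(config.n_replicates):
            mask = detector().fit(dataset.replicate(r), times=times).rhythmic_
            replicate_masks.append(mask)
            logger.info("replicate %d: %d genes called", r + 1, int(mask.sum()))

    if "replicates" in config.kinds:
        for r, mask in enumerate(replicate_masks):
            c = confusion_from_mask(mask, truth)
            rows.append(
                dict(simulation=config.simulation, method=config.method,
                     kind=f"replicate_{r + 1}", k=None, tp=c.tp, fp=c.fp,
                     tn=c.tn, fn=c.fn, seed=config.seed)
            )

    if "averaged" in config.kinds:
        mask = detector().fit(average_dataset(dataset), times=times).rhythmic_
        c = confusion_from_mask(mask, truth)
        rows.append(
            dict(simulation=config.simulation, method=config.method,
                 kind="averaged", k=None, tp=c.tp, fp=c.fp, tn=c.tn, fn=c.fn,
                 seed=config.seed)
        )

    if "initial_consensus" in config.kinds:
        _rows_for_curve(replicate_masks, truth, "initial_consensus", config, rows)

    if "resampled_consensus" in config.kinds:
        rc = ResamplingConsensus(
            detector=detector(), n_resamples=config.n_resamples,
            mode=config.resample_mode,
            random_state=sub_seeds["resample"],
        ).fit(dataset)
        sub_seeds["resample_children"] = rc.sub_seeds_
        _rows_for_curve(rc.call_masks_, truth, "resampled_consensus", config, rows)

    if "original_consensus" in config.kinds:
        masks = [
            detector().fit(ind.matrix, times=times).rhythmic_
            for ind in individuals
        ]
        _rows_for_curve(masks, truth, "original_consensus", config, rows)

    table = pd.DataFrame(rows)
    _check_confusion_invariants(table, truth)
    return BenchmarkResult(table=table, seed=config.seed, sub_seeds=sub_seeds)


def _check_confusion_invariants(table: pd.DataFrame, truth: TruthLabels):
    n_pos, n_neg = truth.n_rhythmic, truth.n_null
    if len(table) and (
        np.any(table["tp"] + table["fn"] != n_pos)
        or np.any(table["fp"] + table["tn"] != n_neg)
    ):
        raise AssertionError("confusion counts violate class-total conservation")
    for kind, grp in table.groupby("kind"):
        if grp["k"].notna().all() and len(grp) > 1:
            g = grp.sort_values("k")
            if np.any(np.diff(g["tp"]) > 0) or np.any(np.diff(g["fp"]) > 0):
                raise AssertionError(
                    f"TP/FP not non-increasing in k for kind {kind!r}"
                )


def replicate_sensitivity(
    n_individuals: int = 72,
    replicate_counts=(2, 3, 4, 5, 6),
    simulation: str = "ll",
    method: str = "arser",
    n_rhythmic: int = 8400,
    n_null: int = 8400,
    n_resamples: int | None = 36,
    seed: int = 0,
    sim_kwargs: dict | None = None,
    detector_kwargs: dict | None = None,
) -> BenchmarkResult:
    """How replicate count affects consensus accuracy.

    From one pool of ``n_individuals`` simulated organisms, assemble
    datasets with each requested replicate count, score the consensus
    across initial replicates (k = 1..r), and — unless ``n_resamples`` is
    None — the consensus across resampled datasets.  Rows carry
    ``kind='initial_consensus'`` or ``'resampled_consensus'`` plus an
    ``n_replicates`` column.
    """
    sim_kwargs = dict(sim_kwargs or {})
    detector_kwargs = dict(detector_kwargs or {})
    sim_cfg = SimulationConfig(
        n_rhythmic=n_rhythmic, n_null=n_null, n_individuals=n_individuals,
        **sim_kwargs,
    )
    max_r = max(replicate_counts)
    if n_individuals < max_r * sim_cfg.times.size:
        raise InputError(
            f"{n_individuals} individuals cannot supply {max_r} replicates"
        )
    ss = np.random.SeedSequence(seed)
    s_sim, s_asm, s_res = ss.spawn(3)
    res_children = s_res.spawn(len(replicate_counts))
    individuals = simulate(simulation, sim_cfg, rng=np.random.default_rng(s_sim))
    asm_rng = np.random.default_rng(s_asm)
    rows: list[dict] = []
    for i, r in enumerate(replicate_counts):
        dataset, truth = assemble_initial_datasets(
            individuals, r, asm_rng, timepoints=sim_cfg.times
        )
        masks = [
            make_detector(method, **detector_kwargs)
            .fit(dataset.replicate(j), times=sim_cfg.times).rhythmic_
            for j in range(r)
        ]
        counts = np.sum(masks, axis=0)
        for k in range(1, r + 1):
            c = confusion_from_mask(counts >= k, truth)
            rows.append(
                dict(simulation=simulation, method=method,
                     kind="initial_consensus", n_replicates=r, k=k,
                     tp=c.tp, fp=c.fp, tn=c.tn, fn=c.fn, seed=seed)
            )
        if n_resamples:
            rc = ResamplingConsensus(
                detector=make_detector(method, **detector_kwargs),
                n_resamples=n_resamples,
                random_state=int(res_children[i].generate_state(1)[0] >> 1),
            ).fit(dataset)
            for k in range(1, n_resamples + 1):
                c = confusion_from_mask(rc.consensus_counts_ >= k, truth)
                rows.append(
                    dict(simulation=simulation, method=method,
                         kind="resampled_consensus", n_replicates=r, k=k,
                         tp=c.tp, fp=c.fp, tn=c.tn, fn=c.fn, seed=seed)
                )
    table = pd.DataFrame(rows)
    return BenchmarkResult(table=table, seed=seed)
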