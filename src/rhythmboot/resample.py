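"""Replicate resampling, replicate averaging, and consensus calling.

The core of the method: from a gene x timepoint x replicate dataset, build
many single-replicate datasets by picking, at every timepoint, one of the
replicate values uniformly at random ("resampling"); run a rhythmicity
detector on each; and call a gene rhythmic at consensus k if it was
detected in at least k of the datasets.  Resampled values are always actual
measured values — no interpolation or averaging is involved — so the
procedure propagates real between-individual variation into the calls.

Two granularities are supported: ``per_gene`` draws an independent
replicate choice for every (gene, timepoint) cell, which is the literal
"expression values of each gene are selected independently" reading;
``per_sample`` picks one replicate per timepoint for all genes jointly,
which treats the replicate (a whole organism) as the sampling unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, clone

from .detectors import make_detector
from .exceptions import InputError
from .simdata import ExpressionDataset

__all__ = [
    "ResamplePlan",
    "ConsensusTable",
    "resample_dataset",
    "average_dataset",
    "consensus_counts",
    "consensus_set",
    "run_resampling_analysis",
    "ResamplingConsensus",
]


@dataclass(frozen=True)
class ResamplePlan:
    """How many resampled datasets to draw, at which granularity."""

    n_resamples: int = 36
    mode: str = "per_gene"
    seed: int | None = None

    def __post_init__(self):
        if self.n_resamples < 1:
            raise InputError("n_resamples must be at least 1")
        if self.mode not in ("per_gene", "per_sample"):
            raise InputError("mode must be 'per_gene' or 'per_sample'")


def _values_of(dataset) -> np.ndarray:
    if isinstance(dataset, ExpressionDataset):
        return dataset.values
    v = np.asarray(dataset, dtype=float)
    if v.ndim != 3:
        raise InputError("expected an ExpressionDataset or a 3-D array")
    return v


def resample_dataset(dataset, rng, mode="per_gene") -> np.ndarray:
    """One resampled single-replicate (gene x timepoint) matrix.

    Every output value equals one of the input replicate values at the same
    (gene, timepoint); each replicate has equal selection probability and
    timepoints are treated independently.
    """
    v = _values_of(dataset)
    n_genes, n_t, n_rep = v.shape
    if n_genes == 0 or n_t == 0:
        raise InputError("dataset is empty")
    if n_rep == 1:
        return v[:, :, 0].copy()
    if mode == "per_gene":
        idx = rng.integers(0, n_rep, size=(n_genes, n_t))
        return np.take_along_axis(v, idx[:, :, None], axis=2)[:, :, 0]
    if mode == "per_sample":
        idx = rng.integers(0, n_rep, size=n_t)
        return v[:, np.arange(n_t), idx]
    raise InputError("mode must be 'per_gene' or 'per_sample'")


def average_dataset(dataset) -> np.ndarray:
    """Arithmetic mean across replicates at every (gene, timepoint)."""
    v = _values_of(dataset)
    if v.shape[0] == 0 or v.shape[1] == 0:
        raise InputError("dataset is empty")
    return v.mean(axis=2)


@dataclass
class ConsensusTable:
    """Per-gene count of datasets whose rhythmic call-set contains the gene."""

    gene_ids: list
    counts: np.ndarray
    n_datasets: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0) or np.any(self.counts > self.n_datasets):
            raise InputError("counts must lie in [0, n_datasets]")

    def as_dict(self) -> dict:
        return dict(zip(self.gene_ids, self.counts.tolist()))


def consensus_counts(call_sets, universe=None) -> ConsensusTable:
    """Count, per gene, how many of the call sets contain it.

    ``call_sets`` are per-dataset sets of rhythmic gene ids over a common
    universe; if ``universe`` is given, any gene outside it is an error,
    otherwise the universe is the sorted union.
    """
    call_sets = [set(s) for s in call_sets]
    union = set().union(*call_sets) if call_sets else set()
    if universe is None:
        universe = sorted(union)
    else:
        universe = list(universe)
        stray = union - set(universe)
        if stray:
            raise InputError(f"gene ids outside the universe: {sorted(stray)[:5]}")
    counts = np.array(
        [sum(g in s for s in call_sets) for g in universe], dtype=int
    )
    return ConsensusTable(universe, counts, len(call_sets))


def consensus_set(table: ConsensusTable, k: int) -> set:
    """Genes counted in at least k datasets; k=1 is the union of the call
    sets and k=n_datasets their intersection."""
    if not 1 <= k <= table.n_datasets:
        raise InputError(f"k must lie in [1, {table.n_datasets}]")
    return {g for g, c in zip(table.gene_ids, table.counts) if c >= k}


class ResamplingConsensus(BaseEstimator):
    """Consensus-of-resamples rhythmicity caller.

    Draws ``n_resamples`` resampled single-replicate datasets from a
    replicate dataset, runs a (cloned) detector on each, and records the
    per-gene consensus counts.

    Parameters
    ----------
    detector : estimator or str
        A detector instance (e.g. ``ArserDetector()``) or one of 'arser',
        'haystack', 'fftnlls'.
    n_resamples : int
        Number of resampled datasets (reference design: 36).
    mode : str
        'per_gene' or 'per_sample' resampling granularity.
    random_state : int or None
        Master seed; per-resample sub-seeds are spawned from it and stored
        in ``sub_seeds_``.

    Attributes
    ----------
    call_masks_ : (n_resamples, n_genes) bool array of per-dataset calls.
    consensus_counts_ : per-gene count of datasets calling the gene.
    """

    def __init__(self, detector="arser", n_resamples=36, mode="per_gene",
                 random_state=None):
        self.detector = detector
        self.n_resamples = n_resamples
        self.mode = mode
        self.random_state = random_state

    def _make_detector(self):
        if isinstance(self.detector, str):
            return make_detector(self.detector)
        return clone(self.detector)

    def fit(self, X, times=None):
        plan = ResamplePlan(self.n_resamples, self.mode, self.random_state)
        if isinstance(X, ExpressionDataset):
            values, t = X.values, X.timepoints
            self.gene_ids_ = list(X.gene_ids)
        else:
            values = _values_of(X)
            if times is None:
                raise InputError("sampling times (hours) are required")
            t = np.asarray(times, dtype=float)
            self.gene_ids_ = None
        ss = np.random.SeedSequence(plan.seed)
        children = ss.spawn(plan.n_resamples)
        self.sub_seeds_ = [int(c.generate_state(1)[0]) for c in children]
        masks = []
        for child in children:
            rng = np.random.default_rng(child)
            mat = resample_dataset(values, rng, mode=plan.mode)
            det = self._make_detector().fit(mat, times=t)
            masks.append(det.rhythmic_.copy())
        self.call_masks_ = np.array(masks)
        self.consensus_counts_ = self.call_masks_.sum(axis=0)
        self.n_datasets_ = plan.n_resamples
        return self

    def consensus_mask(self, k: int) -> np.ndarray:
        if not 1 <= k <= self.n_datasets_:
            raise InputError(f"k must lie in [1, {self.n_datasets_}]")
        return self.consensus_counts_ >= k

    def consensus_table(self) -> ConsensusTable:
        ids = self.gene_ids_
        if ids is None:
            ids = list(range(self.consensus_counts_.size))
        return ConsensusTable(ids, self.consensus_counts_, self.n_datasets_)


def run_resampling_analysis(dataset, detector, plan: ResamplePlan,
                            times=None):
    """Resample, detect, and count: returns (call_sets, ConsensusTable).

    ``call_sets`` are sets of gene ids (or integer indices when the input
    carries none), one per resampled dataset, in draw order.
    """
    rc = ResamplingConsensus(
        detector=detector, n_resamples=plan.n_resamples, mode=plan.mode,
        random_state=plan.seed,
    ).fit(dataset, times=times)
    ids = rc.gene_ids_ if rc.gene_ids_ is not None else list(
        range(rc.call_masks_.shape[1])
    )
    ids_arr = np.asarray(ids, dtype=object)
    call_sets = [set(ids_arr[m]) for m in rc.call_masks_]
    table = ConsensusTable(ids, rc.consensus_counts_, rc.n_datasets_)
    return call_sets, table
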