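"""Synthetic circadian time-course generators and replicate-dataset assembly.

Three kinds of rhythmic profiles are produced, each mixed with an equal-sized
block of white-noise null genes:

* **LD** ("entrained"): every individual in the population is synchronised;
  each rhythmic gene g follows ``x_t = SNR * 2 * cos(2*pi/tau_g * (t - phi_g))
  + eps``, with one period ``tau_g ~ U(22, 28) h`` and one phase ``phi_g``
  from a 0-28 h grid at 0.1 h steps shared across individuals, and
  ``eps ~ N(0, 1)`` drawn independently per (gene, timepoint, individual).
* **LL** ("free-running"): as LD, but each *individual* j runs at its own
  period ``tau_j ~ N(25, 3) h`` (truncated below 10 h), shared by all of its
  rhythmic genes — individuals desynchronise, genes within one do not.
* **ODE**: non-sinusoidal waveforms taken from a limit-cycle oscillator
  (:mod:`rhythmboot.oscillator`); each rhythmic gene is a phase-shifted copy
  of one z-scored model species, scaled to the same nominal amplitude as the
  cosine simulations, with the same additive noise.

Individuals model *destructive sampling*: a real time-course replicate is a
chimera of distinct organisms, one per (timepoint, replicate) slot.
:func:`assemble_initial_datasets` performs exactly that random injective
assignment and records it as provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import AssemblyError, ConfigurationError, SimulationError
from .oscillator import GoodwinOscillator, LimitCycle, extract_limit_cycle

__all__ = [
    "SimulationConfig",
    "IndividualTimeCourse",
    "ExpressionDataset",
    "TruthLabels",
    "simulate_ld",
    "simulate_ll",
    "simulate_ode",
    "simulate_null",
    "assemble_initial_datasets",
    "simulate_initial_dataset",
]

_DEFAULT_TIMEPOINTS = tuple(float(t) for t in range(0, 48, 4))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic benchmarks.

    Defaults reproduce the reference design: 12 timepoints at 4 h intervals
    spanning 48 h, 8400 rhythmic plus 8400 null genes, SNR = 2 with unit
    noise, LD periods uniform on [22, 28] h, phases on a 0-28 h grid at
    0.1 h steps, LL periods Normal(25, 3) h, and 36 simulated individuals
    (12 timepoints x 3 replicates).
    """

    n_rhythmic: int = 8400
    n_null: int = 8400
    timepoints: tuple[float, ...] = _DEFAULT_TIMEPOINTS
    snr: float = 2.0
    noise_sd: float = 1.0
    amplitude: float | None = None  # override; default SNR * 2
    period_range_ld: tuple[float, float] = (22.0, 28.0)
    phase_grid: tuple[float, float, float] = (0.0, 28.0, 0.1)
    ll_period_mean: float = 25.0
    ll_period_sd: float = 3.0
    ll_period_floor: float = 10.0
    ode_period: float = 24.0
    n_individuals: int = 36
    seed: int | None = None

    def __post_init__(self):
        t = np.asarray(self.timepoints, dtype=float)
        if t.size == 0:
            raise ConfigurationError("timepoints must be non-empty")
        if np.any(np.diff(t) <= 0):
            raise ConfigurationError("timepoints must be strictly increasing")
        if self.n_rhythmic < 0 or self.n_null < 0 or self.n_rhythmic + self.n_null == 0:
            raise ConfigurationError("gene counts must be non-negative and not both zero")
        if self.n_individuals <= 0:
            raise ConfigurationError("n_individuals must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        lo, hi = self.period_range_ld
        if not lo < hi:
            raise ConfigurationError("period_range_ld must satisfy low < high")
        if self.phase_grid[2] <= 0:
            raise ConfigurationError("phase grid step must be positive")
        if self.ll_period_sd <= 0:
            raise ConfigurationError("ll_period_sd must be positive")

    @property
    def signal_amplitude(self) -> float:
        return self.snr * 2.0 if self.amplitude is None else self.amplitude

    @property
    def n_genes(self) -> int:
        return self.n_rhythmic + self.n_null

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.timepoints, dtype=float)

    def gene_ids(self) -> list[str]:
        width = max(5, len(str(self.n_genes)))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class IndividualTimeCourse:
    """One simulated organism: a gene x timepoint matrix plus the generating
    parameters of every gene (class, period, phase, waveform tag).

    Null genes carry NaN period and phase ("not applicable").
    """

    individual_id: str
    matrix: np.ndarray
    gene_params: pd.DataFrame

    def __post_init__(self):
        if self.matrix.shape[0] != len(self.gene_params):
            raise ConfigurationError("matrix rows must match gene_params length")


@dataclass
class TruthLabels:
    """Ground-truth rhythmic/non-rhythmic flag per gene."""

    gene_ids: list[str]
    rhythmic: np.ndarray

    def __post_init__(self):
        self.rhythmic = np.asarray(self.rhythmic, dtype=bool)
        if len(self.gene_ids) != self.rhythmic.size:
            raise ConfigurationError("gene_ids and rhythmic flags differ in length")

    @property
    def n_rhythmic(self) -> int:
        return int(self.rhythmic.sum())

    @property
    def n_null(self) -> int:
        return int((~self.rhythmic).sum())


@dataclass
class ExpressionDataset:
    """Gene x timepoint x replicate expression array with time metadata.

    ``provenance`` maps each (timepoint_index, replicate_index) slot to the
    id of the simulated individual the value came from; it is absent for
    real data and must be injective when present.
    """

    values: np.ndarray
    timepoints: np.ndarray
    gene_ids: list[str]
    provenance: dict[tuple[int, int], str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.values.ndim != 3:
            raise ConfigurationError("values must be a 3-D (gene, timepoint, replicate) array")
        if self.values.shape[1] != self.timepoints.size:
            raise ConfigurationError("timepoint axis does not match timepoints metadata")
        if self.values.shape[0] != len(self.gene_ids):
            raise ConfigurationError("gene axis does not match gene_ids")
        if self.values.shape[2] < 1:
            raise ConfigurationError("need at least one replicate")
        if self.provenance is not None:
            ids = list(self.provenance.values())
            if len(set(ids)) != len(ids):
                raise ConfigurationError("provenance is not injective")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def replicate(self, r: int) -> np.ndarray:
        """The 2-D (gene x timepoint) matrix of replicate ``r`` (0-based)."""
        return self.values[:, :, r]

    @classmethod
    def from_matrix(cls, matrix, timepoints, gene_ids=None) -> "ExpressionDataset":
        matrix = np.asarray(matrix, dtype=float)
        if gene_ids is None:
            gene_ids = [f"g{i:05d}" for i in range(matrix.shape[0])]
        return cls(matrix[:, :, None], np.asarray(timepoints, float), list(gene_ids))


def _rng_for(config: SimulationConfig, rng) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(config.seed)


def _phase_values(config: SimulationConfig) -> np.ndarray:
    lo, hi, step = config.phase_grid
    n = int(math.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def _gene_params_frame(config, periods, phases, waveforms) -> pd.DataFrame:
    n_r, n_n = config.n_rhythmic, config.n_null
    return pd.DataFrame(
        {
            "gene_id": config.gene_ids(),
            "rhythmic": [True] * n_r + [False] * n_n,
            "period": np.concatenate([periods, np.full(n_n, np.nan)]),
            "phase": np.concatenate([phases, np.full(n_n, np.nan)]),
            "waveform": list(waveforms) + ["noise"] * n_n,
        }
    )


def simulate_null(n_null, timepoints, mean, sd, rng) -> np.ndarray:
    """An ``n_null x len(timepoints)`` block of i.i.d. Normal(mean, sd) noise."""
    if sd < 0:
        raise ConfigurationError("noise standard deviation must be non-negative")
    if n_null < 0:
        raise ConfigurationError("n_null must be non-negative")
    t = np.asarray(timepoints, dtype=float)
    return rng.normal(mean, sd, size=(int(n_null), t.size)) if sd > 0 else np.full(
        (int(n_null), t.size), float(mean)
    )


def _assemble_individuals(config, signal_per_individual, params_per_individual, rng):
    """Stack signal + per-individual noise + null block into IndividualTimeCourse list."""
    t = config.times
    out = []
    for j in range(config.n_individuals):
        signal = signal_per_individual(j)
        noisy = signal + rng.normal(0.0, config.noise_sd, size=signal.shape) if config.noise_sd > 0 else signal.copy()
        null = simulate_null(config.n_null, t, 0.0, config.noise_sd, rng)
        matrix = np.vstack([noisy, null])
        out.append(
            IndividualTimeCourse(f"ind{j:03d}", matrix, params_per_individual(j))
        )
    return out


def simulate_ld(config: SimulationConfig, rng=None) -> list[IndividualTimeCourse]:
    """Synchronised (entrained) cosine population.

    One period and phase per rhythmic gene, shared by every individual; only
    the additive noise differs between individuals.
    """
    rng = _rng_for(config, rng)
    t = config.times
    lo, hi = config.period_range_ld
    periods = rng.uniform(lo, hi, size=config.n_rhythmic)
    phases = rng.choice(_phase_values(config), size=config.n_rhythmic)
    amp = config.signal_amplitude
    signal = amp * np.cos(2.0 * np.pi / periods[:, None] * (t[None, :] - phases[:, None]))
    params = _gene_params_frame(config, periods, phases, ["cosine"] * config.n_rhythmic)
    return _assemble_individuals(config, lambda j: signal, lambda j: params, rng)


def _truncated_normal_period(rng, mean, sd, floor) -> float:
    for _ in range(1000):
        p = rng.normal(mean, sd)
        if p > floor:
            return float(p)
    raise SimulationError("could not draw a period above the floor in 1000 attempts")


def simulate_ll(config: SimulationConfig, rng=None) -> list[IndividualTimeCourse]:
    """Free-running population: a single period per individual.

    Each individual draws its own period from Normal(ll_period_mean,
    ll_period_sd), truncated below ``ll_period_floor`` by redrawing; all
    rhythmic genes within that individual oscillate at that period.
    Per-gene phases are drawn once and shared across individuals.
    """
    rng = _rng_for(config, rng)
    t = config.times
    phases = rng.choice(_phase_values(config), size=config.n_rhythmic)
    tau_j = np.array(
        [
            _truncated_normal_period(
                rng, config.ll_period_mean, config.ll_period_sd, config.ll_period_floor
            )
            for _ in range(config.n_individuals)
        ]
    )
    amp = config.signal_amplitude

    def signal(j):
        return amp * np.cos(2.0 * np.pi / tau_j[j] * (t[None, :] - phases[:, None]))

    def params(j):
        return _gene_params_frame(
            config,
            np.full(config.n_rhythmic, tau_j[j]),
            phases,
            ["cosine"] * config.n_rhythmic,
        )

    return _assemble_individuals(config, signal, params, rng)


def simulate_ode(
    config: SimulationConfig,
    rng=None,
    oscillator=None,
    limit_cycle: LimitCycle | None = None,
) -> list[IndividualTimeCourse]:
    """Non-sinusoidal rhythmic genes from a limit-cycle oscillator.

    Each rhythmic gene is one model species, z-scored over the cycle and
    scaled to the nominal amplitude (SNR * 2), shifted by a phase from a
    0.1 h grid over one nominal period, and sampled at the configured
    timepoints; individuals share the signal and differ only in noise
    (synchronised population, as under entrainment).
    """
    rng = _rng_for(config, rng)
    t = config.times
    if limit_cycle is None:
        limit_cycle = extract_limit_cycle(oscillator if oscillator is not None else GoodwinOscillator())
    std = limit_cycle.standardized()
    period = config.ode_period
    shifts = rng.choice(np.arange(0.0, period, 0.1), size=config.n_rhythmic)
    species = np.arange(config.n_rhythmic) % std.n_species
    amp = config.signal_amplitude
    signal = np.empty((config.n_rhythmic, t.size))
    for s in range(std.n_species):
        sel = species == s
        if not sel.any():
            continue
        u = ((t[None, :] - shifts[sel, None]) / period) % 1.0
        signal[sel] = amp * std.value(s, u)
    waveforms = [f"ode_species{s}" for s in species]
    params = _gene_params_frame(
        config, np.full(config.n_rhythmic, period), shifts, waveforms
    )
    return _assemble_individuals(config, lambda j: signal, lambda j: params, rng)


def simulate_noise_only(config: SimulationConfig, rng=None) -> list[IndividualTimeCourse]:
    """Pure white-noise datasets (no rhythmic block): the all-null control."""
    cfg = config.with_(n_rhythmic=0)
    rng = _rng_for(cfg, rng)
    empty = np.empty((0, cfg.times.size))
    params = _gene_params_frame(cfg, np.empty(0), np.empty(0), [])
    return _assemble_individuals(cfg, lambda j: empty, lambda j: params, rng)


_GENERATORS = {
    "ld": simulate_ld,
    "ll": simulate_ll,
    "ode": simulate_ode,
    "noise": simulate_noise_only,
}


def simulate(mode: str, config: SimulationConfig, rng=None, **kwargs):
    """Dispatch to one of the generators by name ('ld', 'll', 'ode', 'noise')."""
    try:
        gen = _GENERATORS[mode]
    except KeyError:
        raise ConfigurationError(f"unknown simulation mode {mode!r}") from None
    return gen(config, rng=rng, **kwargs)


def truth_from_individuals(individuals: list[IndividualTimeCourse]) -> TruthLabels:
    gp = individuals[0].gene_params
    return TruthLabels(list(gp["gene_id"]), gp["rhythmic"].to_numpy())


def assemble_initial_datasets(
    individuals: list[IndividualTimeCourse],
    n_replicates: int,
    rng,
    timepoints=None,
) -> tuple[ExpressionDataset, TruthLabels]:
    """Build a replicate dataset by destructive sampling of individuals.

    Every (timepoint, replicate) slot is filled from a *distinct* individual,
    chosen by a random injective assignment; the dataset value at
    (gene, t, r) is that individual's value at (gene, t).  Excess
    individuals are left unused (subset sampled without replacement).
    """
    if n_replicates < 1:
        raise AssemblyError("need at least one replicate")
    n_t = individuals[0].matrix.shape[1]
    need = n_replicates * n_t
    if len(individuals) < need:
        raise AssemblyError(
            f"need {need} individuals for {n_replicates} replicates x {n_t} "
            f"timepoints, got {len(individuals)}"
        )
    if timepoints is None:
        timepoints = _DEFAULT_TIMEPOINTS[:n_t] if n_t <= len(_DEFAULT_TIMEPOINTS) else np.arange(n_t) * 4.0
    chosen = rng.permutation(len(individuals))[:need]
    n_genes = individuals[0].matrix.shape[0]
    values = np.empty((n_genes, n_t, n_replicates))
    provenance: dict[tuple[int, int], str] = {}
    for r in range(n_replicates):
        for ti in range(n_t):
            ind = individuals[chosen[r * n_t + ti]]
            values[:, ti, r] = ind.matrix[:, ti]
            provenance[(ti, r)] = ind.individual_id
    labels = truth_from_individuals(individuals)
    dataset = ExpressionDataset(
        values, np.asarray(timepoints, float), labels.gene_ids, provenance
    )
    return dataset, labels


def simulate_initial_dataset(
    mode: str,
    config: SimulationConfig,
    n_replicates: int = 3,
    rng=None,
    **kwargs,
) -> tuple[ExpressionDataset, TruthLabels, list[IndividualTimeCourse]]:
    """Convenience: simulate individuals then assemble the initial dataset."""
    rng = _rng_for(config, rng)
    individuals = simulate(mode, config, rng=rng, **kwargs)
    dataset, labels = assemble_initial_datasets(
        individuals, n_replicates, rng, timepoints=config.times
    )
    return dataset, labels, individuals
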