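"""Generation-by-generation engine for chromosome and cell populations.

The simulated unit is a "cell" of N chromosomes (N = 1 recovers the model
of independently dividing chromosomes; N = 46 is the human cell model).
Each generation every tracked individual is classified:

* **senescent** — any telomere of any chromosome has reached the critical
  threshold (min <= threshold); the cell is retained unchanged and can
  never divide again;
* **potential** — the cell could divide but either its division draw
  failed (u >= P_div(n_bar), with n_bar the mean telomere length over the
  cell) or a Werner deletion drawn for one of its chromosomes was
  infeasible (it would have taken a telomere below the threshold); it is
  retained unchanged and may divide later;
* **divided** — every chromosome replicated successfully; the parent is
  replaced by two daughter cells, each chromosome's (shorter, identical)
  daughter pair being allocated to the two cells independently and
  uniformly at random (2**N possible allocations).

The tracked sample is capped by passaging: when it exceeds ``passage_cap``
cells, a uniform without-replacement subsample of that size is retained,
mimicking experimental cell-culture passaging.  Population growth beyond
the cap is carried by a *notional* population size N(g), updated from the
dividing fraction of the tracked sample,

    N(g+1) = (1 + phi_div(g)) * N(g),     pd = log2(N(g) / N(0)),

so population doublings (pd) keep accumulating after the cap is reached.

Internally the population is a float array of shape (K, N, 4) — K cells,
N chromosomes, 4 telomere entries ordered (top_left, top_right,
bottom_left, bottom_right) as in :mod:`telosim.replication_core`; the
array path implements exactly the same replication rules as the scalar
operations there.  The per-generation random-draw protocol is fixed (and
relied on by reproducibility guarantees): (1) one uniform u per
non-senescent cell in index order; (2) for each division candidate, one
uniform r per chromosome, then one variant index per chromosome (the
variant draw is consumed even for chromosomes whose r >= p_w); (3) one
allocation bit per chromosome of each successfully dividing cell; (4) the
passaging subsample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rate_models import ModelSet, loss_y, p_div
from .replication_core import ChromosomeQuartet

__all__ = [
    "Cell",
    "PopulationState",
    "GenerationRecord",
    "StepCounts",
    "SimulationResult",
    "initial_state",
    "step_population",
    "passage",
    "accounting_update",
    "run_simulation",
    "DEFAULT_QUARTET",
]

#: Default initial quartet: three telomeres of 6000 bp and one of 5800 bp,
#: i.e. the canonical parent state (m, n / m, n-y) with m = n = 6000,
#: y = 200.
DEFAULT_QUARTET: tuple[float, float, float, float] = (6000.0, 6000.0, 6000.0, 5800.0)


@dataclass(frozen=True)
class Cell:
    """Read-only view of one individual: N chromosome quartets."""

    lengths: np.ndarray  # shape (N, 4)

    @property
    def n_chromosomes(self) -> int:
        return self.lengths.shape[0]

    @property
    def chromosomes(self) -> list[ChromosomeQuartet]:
        return [ChromosomeQuartet.from_array(row) for row in self.lengths]

    def is_senescent(self, threshold: float) -> bool:
        """A cell is senescent iff any chromosome has a telomere at or
        below threshold; once true it stays true (lengths never increase)."""
        return bool(self.lengths.min() <= threshold)

    def mean_length(self) -> float:
        return float(self.lengths.mean())

    def shortest(self) -> float:
        return float(self.lengths.min())


@dataclass
class PopulationState:
    """Tracked sample plus notional population-size bookkeeping."""

    lengths: np.ndarray  # shape (K, N, 4)
    generation: int = 0
    notional_n: float = 1.0
    initial_n0: float = 1.0

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.ndim != 3 or self.lengths.shape[2] != 4:
            raise ValueError("lengths must have shape (K, N, 4)")
        if self.lengths.size and self.lengths.min() < 0:
            raise ValueError("telomere lengths must be >= 0")

    @property
    def n_individuals(self) -> int:
        return self.lengths.shape[0]

    @property
    def n_chromosomes(self) -> int:
        return self.lengths.shape[1]

    @property
    def individuals(self) -> list[Cell]:
        return [Cell(row) for row in self.lengths]

    def senescent_mask(self, threshold: float) -> np.ndarray:
        # senescent once the shortest telomere reaches the critical length
        return self.lengths.reshape(self.n_individuals, -1).min(axis=1) <= threshold


@dataclass(frozen=True)
class StepCounts:
    """Classification counts of one generation's tracked sample."""

    divided: int
    potential: int
    senescent: int

    @property
    def total(self) -> int:
        return self.divided + self.potential + self.senescent


@dataclass(frozen=True)
class GenerationRecord:
    """Per-generation bookkeeping of one simulation."""

    g: int
    notional_n: float
    pd: float
    mean_length: float
    sd_length: float
    mean_shortest: float
    phi_div: float
    phi_pot: float
    phi_sen: float
    n_divided: int
    n_potential: int
    n_senescent: int
    n_tracked: int


@dataclass
class SimulationResult:
    """Trajectory of GenerationRecords plus the final tracked sample."""

    records: list[GenerationRecord]
    final_lengths: np.ndarray
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)

    def to_frame(self):
        """Trajectory as a pandas DataFrame (one row per generation)."""
        import pandas as pd

        return pd.DataFrame([vars(r) for r in self.records])


def initial_state(
    n_chromosomes: int = 1,
    quartet: tuple[float, float, float, float] = DEFAULT_QUARTET,
    n_individuals: int = 1,
) -> PopulationState:
    """Population of identical individuals, every chromosome at ``quartet``."""
    if n_chromosomes < 1 or n_individuals < 1:
        raise ValueError("need at least one chromosome and one individual")
    q = np.asarray(quartet, dtype=float)
    if q.shape != (4,):
        raise ValueError("quartet must have exactly four entries")
    lengths = np.broadcast_to(q, (n_individuals, n_chromosomes, 4)).copy()
    return PopulationState(
        lengths=lengths, notional_n=float(n_individuals), initial_n0=float(n_individuals)
    )


# Werner variant -> (0 = shorter daughter, 1 = identical daughter;
# entry indices of the deleted column).  Matches replication_core.
_VARIANTS = {1: (1, (1, 3)), 2: (1, (0, 2)), 3: (0, (0, 2)), 4: (0, (1, 3))}


def _daughters(lengths: np.ndarray, models: ModelSet) -> tuple[np.ndarray, np.ndarray]:
    """Normal-aging daughter quartets for an array of chromosomes.

    ``lengths`` has shape (..., 4); returns (shorter, identical) arrays of
    the same shape, entries clamped at zero.  The shorter daughter is
    re-oriented into the canonical presentation exactly as in
    :func:`telosim.replication_core.replicate_normal`.
    """
    tl, tr, bl, br = (lengths[..., i] for i in range(4))
    y_right = loss_y(tr, models.loss)
    y_left = loss_y(bl, models.loss)
    identical = np.stack([tl, tr, tl, np.clip(tr - y_right, 0.0, None)], axis=-1)
    shorter = np.stack([br, bl, br, np.clip(bl - y_left, 0.0, None)], axis=-1)
    return shorter, identical


def step_population(
    state: PopulationState, models: ModelSet, rng: np.random.Generator
) -> tuple[PopulationState, StepCounts]:
    """Advance the population by one generation.

    Returns the post-division state (retained individuals in their
    original order followed by the daughter cells of dividers) and the
    classification counts of the pre-division sample.  Passaging and
    notional-size accounting are separate steps.
    """
    K = state.n_individuals
    if K == 0:
        raise ValueError("cannot step an empty population")
    L = state.lengths
    sen = state.senescent_mask(models.threshold)
    nonsen_idx = np.flatnonzero(~sen)

    # division draw: u < P_div(mean telomere length of the cell)
    u = rng.random(nonsen_idx.size)
    nbar = L[nonsen_idx].mean(axis=(1, 2))
    cand_idx = nonsen_idx[u < p_div(nbar, models.division)]
    D = cand_idx.size

    divided_idx = cand_idx
    daughters_a = daughters_b = np.empty((0, state.n_chromosomes, 4))
    if D > 0:
        N = state.n_chromosomes
        p_w, x = models.werner.p_w, models.werner.x
        r = rng.random((D, N))
        variants = rng.integers(1, 5, size=(D, N))
        shorter, identical = _daughters(L[cand_idx], models)
        if p_w > 0.0 and x > 0.0:
            wmask = r < p_w
            # a deletion that would take any telomere of the modified
            # daughter below the senescence threshold is physically
            # unrealistic: the whole cell then fails to divide
            infeasible = np.zeros((D, N), dtype=bool)
            for v, (which, cols) in _VARIANTS.items():
                sel = wmask & (variants == v)
                if not sel.any():
                    continue
                arr = identical if which == 1 else shorter
                block = arr[sel]
                block[:, cols] -= x
                arr[sel] = block
                infeasible[sel] = block.min(axis=-1) < models.threshold
            ok = ~infeasible.any(axis=1)
        else:
            ok = np.ones(D, dtype=bool)
        divided_idx = cand_idx[ok]
        nd = divided_idx.size
        if nd > 0:
            bits = rng.integers(0, 2, size=(nd, N)).astype(bool)[..., None]
            sh, ident = shorter[ok], identical[ok]
            daughters_a = np.where(bits, ident, sh)
            daughters_b = np.where(bits, sh, ident)

    nd = divided_idx.size
    retained = np.ones(K, dtype=bool)
    retained[divided_idx] = False
    new_lengths = np.concatenate([L[retained], daughters_a, daughters_b], axis=0)
    counts = StepCounts(
        divided=nd, potential=K - nd - int(sen.sum()), senescent=int(sen.sum())
    )
    new_state = PopulationState(
        lengths=new_lengths,
        generation=state.generation + 1,
        notional_n=state.notional_n,
        initial_n0=state.initial_n0,
    )
    return new_state, counts


def passage(
    state: PopulationState, cap: int, rng: np.random.Generator
) -> PopulationState:
    """Subsample the tracked population to at most ``cap`` individuals.

    A uniform without-replacement sample is kept (in original order); the
    notional population size is unaffected.
    """
    if cap < 1:
        raise ValueError("passage cap must be >= 1")
    if state.n_individuals <= cap:
        return state
    keep = np.sort(rng.choice(state.n_individuals, size=cap, replace=False))
    return PopulationState(
        lengths=state.lengths[keep],
        generation=state.generation,
        notional_n=state.notional_n,
        initial_n0=state.initial_n0,
    )


def accounting_update(state: PopulationState, counts: StepCounts) -> GenerationRecord:
    """Update the notional population size and summarise the generation.

    The dividing/potential/senescent fractions come from the pre-division
    classification counts; length statistics are taken over the current
    (post-division) tracked sample.  Updates ``state.notional_n`` in place
    via N(g+1) = (1 + phi_div) N(g).
    """
    total = counts.total
    if total == 0:
        raise ValueError("counts must cover at least one individual")
    if state.notional_n <= 0:
        raise ValueError("notional population size must be positive")
    phi_div = counts.divided / total
    phi_sen = counts.senescent / total
    phi_pot = counts.potential / total
    state.notional_n = (1.0 + phi_div) * state.notional_n
    return _make_record(state, phi_div, phi_pot, phi_sen, counts)


def _make_record(
    state: PopulationState,
    phi_div: float,
    phi_pot: float,
    phi_sen: float,
    counts: StepCounts,
) -> GenerationRecord:
    per_cell_mean = state.lengths.mean(axis=(1, 2))
    per_cell_min = state.lengths.reshape(state.n_individuals, -1).min(axis=1)
    return GenerationRecord(
        g=state.generation,
        notional_n=state.notional_n,
        pd=float(np.log2(state.notional_n / state.initial_n0)),
        mean_length=float(per_cell_mean.mean()),
        sd_length=float(per_cell_mean.std()),
        mean_shortest=float(per_cell_min.mean()),
        phi_div=phi_div,
        phi_pot=phi_pot,
        phi_sen=phi_sen,
        n_divided=counts.divided,
        n_potential=counts.potential,
        n_senescent=counts.senescent,
        n_tracked=state.n_individuals,
    )


def run_simulation(
    models: ModelSet,
    *,
    n_chromosomes: int = 1,
    initial_quartet: tuple[float, float, float, float] = DEFAULT_QUARTET,
    n_initial: int = 1,
    passage_cap: int = 200,
    max_generations: int = 500,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    snapshot_generations: tuple[int, ...] = (),
) -> SimulationResult:
    """Run one simulation to full senescence or the generation budget.

    Starts from ``n_initial`` identical individuals, iterates
    step -> accounting -> passage, and records every generation (including
    generation 0).  The run stops once the whole tracked sample is
    classified senescent — or, if length-distribution snapshots are
    requested beyond that point, continues recording the frozen population
    up to the last requested generation.  Deterministic for a given seed.
    """
    if max_generations < 1:
        raise ValueError("max_generations must be >= 1")
    if passage_cap < 1:
        raise ValueError("passage_cap must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    state = initial_state(
        n_chromosomes=n_chromosomes, quartet=initial_quartet, n_individuals=n_initial
    )
    snapshots: dict[int, np.ndarray] = {}
    last_snapshot = max(snapshot_generations, default=0)

    n_sen0 = int(state.senescent_mask(models.threshold).sum())
    phi_sen0 = n_sen0 / state.n_individuals
    counts0 = StepCounts(
        divided=0, potential=state.n_individuals - n_sen0, senescent=n_sen0
    )
    records = [_make_record(state, 0.0, 1.0 - phi_sen0, phi_sen0, counts0)]
    if 0 in snapshot_generations:
        snapshots[0] = state.lengths.copy()
    if phi_sen0 == 1.0 and last_snapshot == 0:
        return SimulationResult(records, state.lengths, snapshots)

    for g in range(1, max_generations + 1):
        state, counts = step_population(state, models, rng)
        record = accounting_update(state, counts)
        records.append(record)
        state = passage(state, passage_cap, rng)
        if g in snapshot_generations:
            snapshots[g] = state.lengths.copy()
        if record.phi_sen == 1.0 and g >= last_snapshot:
            break
    return SimulationResult(records, state.lengths, snapshots)
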