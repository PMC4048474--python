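"""Replicate ensembles, senescence summaries, histograms and Gompertz fits.

Single runs of the simulator are noisy; the quantities of scientific
interest — mean telomere length versus generation, the dividing fraction,
the population doubling (pd) at which senescence first appears and at
which the whole population is senescent — are ensemble averages over many
independent replicates.  This module runs such ensembles, aligns the
variable-length trajectories on the generation axis (a fully senescent
population is frozen, so trajectories are extended by their last value),
and reduces them to per-generation means and standard deviations plus a
per-replicate senescence summary.

It also provides telomere-length histograms of a tracked sample (per-cell
mean or per-cell shortest telomere) and a fit of the saturating Gompertz
growth law N(t) = a * exp(-b * exp(-c t)) to population-size
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .population_engine import GenerationRecord, SimulationResult

__all__ = [
    "EnsembleSummary",
    "SenescenceSummary",
    "LengthHistogram",
    "GompertzFit",
    "GompertzFitError",
    "run_ensemble",
    "senescence_summary",
    "telomere_histogram",
    "interpolate_on_pd",
    "count_modes",
    "gompertz_fit",
]

_TRAJECTORY_FIELDS = (
    "mean_length",
    "sd_length",
    "mean_shortest",
    "phi_div",
    "phi_pot",
    "phi_sen",
    "pd",
    "notional_n",
)


@dataclass(frozen=True)
class SenescenceSummary:
    """Key senescence milestones of one trajectory.

    ``pd_first`` is the pd at the first generation with at least one
    senescent individual in the tracked sample; ``final_pd`` the pd when
    the whole sample is senescent; ``mean_length_at_senescence`` the
    population mean telomere length at that generation.  A run that never
    reaches full senescence within its generation budget is *censored*:
    the fields that require full senescence are NaN and ``censored`` is
    set, never silently zero.
    """

    pd_first: float
    final_pd: float
    mean_length_at_senescence: float
    generation_full_senescence: int | None
    censored: bool


@dataclass
class EnsembleSummary:
    """Across-replicate statistics of an ensemble of simulations."""

    n_replicates: int
    generations: np.ndarray
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    replicate_summaries: list[SenescenceSummary]
    n_censored: int = 0
    #: mean over replicates of the pd at which each replicate's first
    #: senescent individual appears
    pd_first_senescence: float = float("nan")
    #: ensemble-level first appearance: the earliest pd, across all
    #: replicates, at which any senescent individual is seen (this is the
    #: natural reading of "pd at which senescent cells first appear" for a
    #: pooled ensemble)
    pd_first_appearance: float = float("nan")
    final_pd: float = float("nan")
    mean_length_at_senescence: float = float("nan")
    sem_final_pd: float = float("nan")
    sem_mean_length_at_senescence: float = float("nan")

    @property
    def censored(self) -> bool:
        return self.n_censored > 0


@dataclass(frozen=True)
class LengthHistogram:
    """Histogram of per-cell telomere lengths at one generation."""

    generation: int
    mode: str  # "mean" or "shortest"
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def n_individuals(self) -> int:
        return int(self.counts.sum())


class GompertzFitError(RuntimeError):
    """Raised when the Gompertz growth law cannot be fitted."""


@dataclass(frozen=True)
class GompertzFit:
    """Fitted parameters of N(t) = a * exp(-b * exp(-c t))."""

    a: float
    b: float
    c: float
    rms_log_residual: float
    r_squared: float

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a * np.exp(-self.b * np.exp(-self.c * t))


def senescence_summary(records: list[GenerationRecord]) -> SenescenceSummary:
    """Senescence milestones of one trajectory (see SenescenceSummary)."""
    if not records:
        raise ValueError("empty trajectory")
    pd_first = float("nan")
    for rec in records:
        if rec.n_senescent > 0 or rec.phi_sen > 0:
            pd_first = rec.pd
            break
    for rec in records:
        if rec.phi_sen == 1.0:
            return SenescenceSummary(
                pd_first=pd_first,
                final_pd=rec.pd,
                mean_length_at_senescence=rec.mean_length,
                generation_full_senescence=rec.g,
                censored=False,
            )
    return SenescenceSummary(
        pd_first=pd_first,
        final_pd=float("nan"),
        mean_length_at_senescence=float("nan"),
        generation_full_senescence=None,
        censored=True,
    )


def run_ensemble(
    run_one,
    n_replicates: int,
    base_seed: int = 0,
    seeds: list[int] | None = None,
) -> EnsembleSummary:
    """Run ``n_replicates`` independent simulations and aggregate them.

    ``run_one`` is a callable mapping a seed to a
    :class:`~telosim.population_engine.SimulationResult` (e.g. a
    ``functools.partial`` of ``run_simulation``).  Replicate i uses seed
    ``base_seed + i`` unless an explicit ``seeds`` list is given.
    Trajectories are aligned by generation, shorter ones extended by their
    final (frozen) value.  At least two replicates are required for the
    across-replicate standard deviation to be defined.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates for ensemble statistics")
    if seeds is None:
        seeds = [base_seed + i for i in range(n_replicates)]
    elif len(seeds) != n_replicates:
        raise ValueError("len(seeds) must equal n_replicates")

    trajectories: list[list[GenerationRecord]] = []
    summaries: list[SenescenceSummary] = []
    for s in seeds:
        result: SimulationResult = run_one(seed=s)
        trajectories.append(result.records)
        summaries.append(senescence_summary(result.records))

    n_gen = max(len(t) for t in trajectories)
    stacked = {f: np.empty((n_replicates, n_gen)) for f in _TRAJECTORY_FIELDS}
    for i, records in enumerate(trajectories):
        for f in _TRAJECTORY_FIELDS:
            vals = [getattr(r, f) for r in records]
            vals.extend([vals[-1]] * (n_gen - len(vals)))
            stacked[f][i] = vals

    mean = {f: stacked[f].mean(axis=0) for f in _TRAJECTORY_FIELDS}
    sd = {f: stacked[f].std(axis=0) for f in _TRAJECTORY_FIELDS}

    uncensored = [s for s in summaries if not s.censored]
    summary = EnsembleSummary(
        n_replicates=n_replicates,
        generations=np.arange(n_gen),
        mean=mean,
        sd=sd,
        replicate_summaries=summaries,
        n_censored=len(summaries) - len(uncensored),
    )
    firsts = [s.pd_first for s in summaries if np.isfinite(s.pd_first)]
    if firsts:
        summary.pd_first_senescence = float(np.mean(firsts))
        summary.pd_first_appearance = float(np.min(firsts))
    if uncensored:
        finals = np.array([s.final_pd for s in uncensored])
        lens = np.array([s.mean_length_at_senescence for s in uncensored])
        summary.final_pd = float(finals.mean())
        summary.mean_length_at_senescence = float(lens.mean())
        if len(uncensored) > 1:
            root_n = np.sqrt(len(uncensored))
            summary.sem_final_pd = float(finals.std(ddof=1) / root_n)
            summary.sem_mean_length_at_senescence = float(lens.std(ddof=1) / root_n)
    return summary


def interpolate_on_pd(
    records: list[GenerationRecord],
    pd_grid,
    fields: tuple[str, ...] = ("mean_length", "phi_sen"),
) -> dict[str, np.ndarray]:
    """Re-index a trajectory from generation onto population doublings.

    Experimental telomere data are usually reported against population
    doublings rather than generations, and pd advances non-uniformly (it
    stalls as the dividing fraction falls).  This interpolates the
    requested per-generation fields onto a common pd grid so replicate
    curves can be averaged on the pd axis; beyond a trajectory's final pd
    the last (frozen) value is carried forward.
    """
    pd_grid = np.asarray(pd_grid, dtype=float)
    pds = np.array([r.pd for r in records])
    out = {}
    for f in fields:
        vals = np.array([getattr(r, f) for r in records])
        out[f] = np.interp(pd_grid, pds, vals)
    return out


def telomere_histogram(
    lengths: np.ndarray,
    mode: str = "mean",
    bin_width: float = 100.0,
    generation: int = 0,
) -> LengthHistogram:
    """Histogram the per-cell mean or per-cell shortest telomere length.

    ``lengths`` is a tracked-sample array of shape (K, N, 4).  Bin edges
    start at 0 with the given width and cover the largest observed value;
    counts sum to K.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.ndim != 3 or lengths.shape[0] == 0:
        raise ValueError("lengths must be a non-empty (K, N, 4) array")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if mode == "mean":
        values = lengths.mean(axis=(1, 2))
    elif mode == "shortest":
        values = lengths.reshape(lengths.shape[0], -1).min(axis=1)
    else:
        raise ValueError("mode must be 'mean' or 'shortest'")
    n_bins = max(int(np.ceil((values.max() + 1e-9) / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    return LengthHistogram(
        generation=generation, mode=mode, bin_edges=edges, counts=counts
    )


def count_modes(counts: np.ndarray, min_count: int = 2) -> int:
    """Number of local maxima of a histogram, ignoring sparse bins.

    Each maximal run of bins holding fewer than ``min_count`` observations
    is coalesced into a single bin (its sum), so isolated near-empty bins
    cannot create spurious peaks while genuine valleys between peaks are
    preserved; strict local maxima of the coalesced sequence are then
    counted, with flat plateaus counted once.  Two or more modes indicate
    a multimodal length distribution.
    """
    counts = np.asarray(counts)
    merged: list[int] = []
    sparse_acc = 0
    in_sparse = False
    for c in counts:
        c = int(c)
        if c < min_count:
            sparse_acc += c
            in_sparse = True
        else:
            if in_sparse:
                merged.append(sparse_acc)
                sparse_acc, in_sparse = 0, False
            merged.append(c)
    if in_sparse:
        merged.append(sparse_acc)
    if not merged:
        return 0
    # drop consecutive duplicates so plateaus count once
    seq = [merged[0]]
    for v in merged[1:]:
        if v != seq[-1]:
            seq.append(v)
    n_modes = 0
    for i, v in enumerate(seq):
        left = seq[i - 1] if i > 0 else -1
        right = seq[i + 1] if i + 1 < len(seq) else -1
        if v > left and v > right:
            n_modes += 1
    return n_modes


def gompertz_fit(generations, sizes) -> GompertzFit:
    """Fit the Gompertz growth law N(t) = a exp(-b e^{-c t}).

    The fit is nonlinear least squares on log N (population sizes span
    orders of magnitude, so a log-scale residual weights early and late
    growth evenly).  Requires at least 4 strictly positive sizes.  Raises
    :class:`GompertzFitError` with diagnostics on non-convergence or
    non-positive parameters.
    """
    t = np.asarray(generations, dtype=float)
    n = np.asarray(sizes, dtype=float)
    if t.shape != n.shape or t.size < 4:
        raise ValueError("need at least 4 matching (generation, size) points")
    if np.any(n <= 0):
        raise ValueError("population sizes must be > 0")
    log_n = np.log(n)

    def model(tt, log_a, b, c):
        return log_a - b * np.exp(-c * tt)

    # initial guesses: a slightly above the observed maximum, b from the
    # initial deficit, c from the decay of the deficit over the time span
    log_a0 = log_n.max() + 0.05
    deficit = np.clip(log_a0 - log_n, 1e-12, None)
    b0 = deficit[0]
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = deficit[-1] / deficit[0]
    c0 = -np.log(max(ratio, 1e-12)) / span
    c0 = c0 if np.isfinite(c0) and c0 > 0 else 1.0 / span
    try:
        popt, _ = curve_fit(
            model, t, log_n, p0=(log_a0, b0, c0), maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - depends on data
        raise GompertzFitError(
            f"Gompertz fit did not converge (p0={(log_a0, b0, c0)}): {exc}"
        ) from exc
    log_a, b, c = popt
    if not (np.isfinite(popt).all() and b > 0 and c > 0):
        raise GompertzFitError(f"non-physical Gompertz parameters: {popt}")
    resid = log_n - model(t, *popt)
    ss_res = float((resid**2).sum())
    ss_tot = float(((log_n - log_n.mean()) ** 2).sum())
    return GompertzFit(
        a=float(np.exp(log_a)),
        b=float(b),
        c=float(c),
        rms_log_residual=float(np.sqrt(np.mean(resid**2))),
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
    )
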