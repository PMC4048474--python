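import numpy as np
import pytest

from telosim.population_engine import (
    PopulationState,
    StepCounts,
    accounting_update,
    initial_state,
    passage,
    run_simulation,
    step_population,
)
from telosim.rate_models import ModelSet, WernerParams, p_div, preset_case
from telosim.replication_core import (
    ChromosomeQuartet,
    replicate_normal,
    replicate_werner,
)

from conftest import werner_model


def reference_step(state, models, rng):
    """Pure-python re-implementation of one generation using the scalar
    chromosome operations and the engine's documented draw protocol.

    Serves as an independent oracle for the vectorised engine.
    """
    K = state.n_individuals
    sen = state.senescent_mask(models.threshold)
    nonsen = np.flatnonzero(~sen)
    u = rng.random(nonsen.size)
    nbar = state.lengths[nonsen].mean(axis=(1, 2))
    cand = nonsen[u < p_div(nbar, models.division)]
    D, N = cand.size, state.n_chromosomes
    r = rng.random((D, N))
    variants = rng.integers(1, 5, size=(D, N))
    divided, daughters = [], []
    for i, ci in enumerate(cand):
        pairs, feasible = [], True
        for j in range(N):
            chrom = ChromosomeQuartet.from_array(state.lengths[ci, j])
            if models.werner.p_w > 0 and r[i, j] < models.werner.p_w:
                out = replicate_werner(
                    chrom,
                    models.loss,
                    models.werner.x,
                    int(variants[i, j]),
                    floor=models.threshold,
                )
                if not out.divided:
                    feasible = False
                    break
                pairs.append(out.daughters)
            else:
                pairs.append(replicate_normal(chrom, models.loss))
        if feasible:
            divided.append(ci)
            daughters.append(pairs)
    new = []
    div_set = set(divided)
    for ci in range(K):
        if ci not in div_set:
            new.append(state.lengths[ci])
    cell_a, cell_b = [], []
    bits_all = rng.integers(0, 2, size=(len(divided), N))
    for idx in range(len(divided)):
        bits = bits_all[idx]
        a = np.empty((N, 4))
        b = np.empty((N, 4))
        for j in range(N):
            sh, ident = daughters[idx][j]
            if bits[j]:
                a[j], b[j] = ident.as_array(), sh.as_array()
            else:
                a[j], b[j] = sh.as_array(), ident.as_array()
        cell_a.append(a)
        cell_b.append(b)
    new.extend(cell_a)
    new.extend(cell_b)
    counts = StepCounts(
        divided=len(divided),
        potential=K - len(divided) - int(sen.sum()),
        senescent=int(sen.sum()),
    )
    return np.array(new), counts


class TestStepPopulation:
    def test_single_chromosome_division(self, case_a1, rng):
        state = initial_state(n_chromosomes=1)
        new, counts = step_population(state, case_a1, rng)
        assert counts == StepCounts(divided=1, potential=0, senescent=0)
        assert new.n_individuals == 2
        got = {tuple(row) for row in new.lengths[:, 0, :]}
        assert (6000, 6000, 6000, 5800) in got  # identical daughter
        assert (5800, 6000, 5800, 5800) in got  # shorter daughter

    def test_degenerate_threshold_freezes_population(self, rng):
        ms = preset_case("A1")
        frozen = ModelSet(loss=ms.loss, division=ms.division, threshold=7000.0)
        state = initial_state(n_chromosomes=2, n_individuals=5)
        new, counts = step_population(state, frozen, rng)
        assert counts.senescent == 5 and counts.divided == 0
        np.testing.assert_array_equal(new.lengths, state.lengths)

    def test_full_cell_population_doubles(self, case_a1, rng):
        # 46 chromosomes, all telomeres far above threshold: P_div = 1 and
        # no feasibility failures, so the tracked population doubles
        state = initial_state(n_chromosomes=46, n_individuals=20)
        new, counts = step_population(state, case_a1, rng)
        assert counts.divided == 20
        assert new.n_individuals == 40

    def test_empty_population_rejected(self, case_a1, rng):
        state = initial_state(n_chromosomes=1)
        state.lengths = state.lengths[:0]
        with pytest.raises(ValueError):
            step_population(state, case_a1, rng)

    @pytest.mark.parametrize("p_w, x", [(0.0, 0.0), (0.5, 300.0), (1.0, 1000.0)])
    def test_matches_scalar_reference(self, p_w, x):
        # vectorised engine equals the scalar-operation oracle draw-for-draw
        models = ModelSet(
            loss=preset_case("A2").loss,
            division=preset_case("B1.2").division,
            werner=WernerParams(p_w, x),
            threshold=150.0,
        )
        base = np.random.default_rng(7).uniform(100, 7000, size=(8, 3, 4))
        state = PopulationState(lengths=base.copy())
        got, counts = step_population(state, models, np.random.default_rng(99))
        exp_lengths, exp_counts = reference_step(
            PopulationState(lengths=base.copy()), models, np.random.default_rng(99)
        )
        assert counts == exp_counts
        np.testing.assert_allclose(got.lengths, exp_lengths)


class TestPassage:
    def test_caps_population(self, rng):
        state = initial_state(n_chromosomes=1, n_individuals=300)
        assert passage(state, 200, rng).n_individuals == 200
        small = initial_state(n_chromosomes=1, n_individuals=150)
        assert passage(small, 200, rng) is small

    def test_notional_size_unaffected(self, rng):
        state = initial_state(n_chromosomes=1, n_individuals=300)
        state.notional_n = 1e6
        assert passage(state, 200, rng).notional_n == 1e6

    def test_subsampling_is_unbiased(self, rng):
        # heterogeneous population: retained-sample mean should match the
        # parent mean within 3 sigma of the sampling error over many trials
        lengths = np.linspace(500, 6000, 400).reshape(400, 1, 1) * np.ones((1, 1, 4))
        state = PopulationState(lengths=lengths)
        pop_mean = lengths.mean()
        diffs = []
        for _ in range(400):
            kept = passage(state, 200, rng)
            diffs.append(kept.lengths.mean() - pop_mean)
        per_sample_sd = lengths.mean(axis=(1, 2)).std() / np.sqrt(200)
        sem = per_sample_sd / np.sqrt(len(diffs))  # ignores FPC: conservative
        assert abs(np.mean(diffs)) < 3 * sem


class TestAccounting:
    def test_fraction_formulas(self):
        state = initial_state(n_chromosomes=1, n_individuals=100)
        rec = accounting_update(state, StepCounts(50, 30, 20))
        assert (rec.phi_div, rec.phi_pot, rec.phi_sen) == (0.5, 0.3, 0.2)
        assert rec.phi_div + rec.phi_pot + rec.phi_sen == 1.0

    def test_eight_doublings_reach_two_hundred_cells(self, case_a1):
        # from one cell with certain division, eight generations take the
        # notional population to 256 >= 200 and pd to exactly 8
        res = run_simulation(case_a1, n_chromosomes=1, max_generations=8, seed=0)
        rec = res.records[-1]
        assert rec.notional_n == 256
        assert rec.pd == 8.0
        assert all(r.pd == r.g for r in res.records)

    def test_no_divisions_leave_pd_unchanged(self):
        state = initial_state(n_chromosomes=1, n_individuals=10)
        state.notional_n, state.initial_n0 = 512.0, 1.0
        rec = accounting_update(state, StepCounts(0, 0, 10))
        assert rec.notional_n == 512.0 and rec.pd == 9.0

    def test_zero_total_rejected(self):
        state = initial_state(n_chromosomes=1)
        with pytest.raises(ValueError):
            accounting_update(state, StepCounts(0, 0, 0))


class TestRunSimulation:
    def test_seed_reproducibility(self, case_a1):
        kw = dict(n_chromosomes=1, max_generations=300)
        a = run_simulation(case_a1, seed=42, **kw)
        b = run_simulation(case_a1, seed=42, **kw)
        assert a.records == b.records
        np.testing.assert_array_equal(a.final_lengths, b.final_lengths)

    def test_immediate_senescence(self):
        ms = preset_case("A1")
        high = ModelSet(loss=ms.loss, division=ms.division, threshold=6500.0)
        res = run_simulation(high, n_chromosomes=1, seed=1)
        assert len(res.records) == 1
        rec = res.records[0]
        assert rec.phi_sen == 1.0 and rec.pd == 0.0

    def test_werner_engine_with_pw_zero_matches_normal(self, case_a1):
        kw = dict(n_chromosomes=1, max_generations=120, seed=11)
        normal = run_simulation(case_a1, **kw)
        degenerate = run_simulation(werner_model(0.0, 750.0), **kw)
        assert normal.records == degenerate.records

    def test_cell_engine_with_one_chromosome_is_chromosome_model(self):
        from telosim.cli_io import SimConfig

        chrom = SimConfig(model="chromosome", case="A1", max_generations=150)
        cell = SimConfig(model="cell", case="A1", n_chromosomes=1,
                         max_generations=150)
        assert chrom.run(seed=3).records == cell.run(seed=3).records

    def test_alpha_zero_case_b_reduces_to_case_a(self, case_a1):
        # with alpha = 0 the division probability is identically 1
        # whatever (a, b) are, so Case B collapses onto Case A
        ms = preset_case("A1")
        caseb = ModelSet(
            loss=ms.loss,
            division=type(ms.division)(a=-5.0, b=2.0, alpha=0.0),
            threshold=ms.threshold,
        )
        kw = dict(n_chromosomes=1, max_generations=120, seed=21)
        assert run_simulation(case_a1, **kw).records == run_simulation(caseb, **kw).records

    def test_senescent_set_only_grows_without_passaging(self, case_a1):
        res = run_simulation(
            case_a1, n_chromosomes=1, passage_cap=10**6, max_generations=100, seed=9
        )
        counts = [r.n_senescent for r in res.records]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_pd_never_exceeds_generation(self, case_a1):
        res = run_simulation(case_a1, n_chromosomes=1, max_generations=400, seed=17)
        assert all(r.pd <= r.g + 1e-12 for r in res.records)


class TestEarlyDrift:
    def test_enumeration_of_division_outcomes(self, case_a1):
        # both daughters of Eq-style replication together average the
        # parent mean minus y/4, whatever the allocation
        parent = ChromosomeQuartet(6000, 6000, 6000, 5800)
        shorter, identical = replicate_normal(parent, case_a1.loss)
        combined = (sum(shorter) + sum(identical)) / 8.0
        assert combined == sum(parent) / 4.0 - 200 / 4.0

    def test_population_mean_declines_by_y0_over_4_before_cap(self, case_a1):
        # while every cell divides and both daughters are tracked, the mean
        # length drops by exactly y0/4 = 50 bp per generation
        res = run_simulation(case_a1, n_chromosomes=1, max_generations=8, seed=2)
        for rec in res.records:
            assert rec.mean_length == pytest.approx(5950.0 - 50.0 * rec.g)

    def test_ensemble_drift_with_passaging(self, case_a1):
        # after the cap, passaging noise enters; the ensemble-mean slope
        # stays -y0/4 within 3 standard errors
        slopes = []
        for i in range(300):
            res = run_simulation(case_a1, n_chromosomes=1, max_generations=30,
                                 seed=4000 + i)
            means = [r.mean_length for r in res.records]
            slopes.append((means[30] - means[8]) / 22.0)
        slopes = np.asarray(slopes)
        sem = slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert abs(slopes.mean() + 50.0) < 3 * sem
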