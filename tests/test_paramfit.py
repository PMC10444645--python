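import copy

import numpy as np
import pytest

from clashfix.paramfit import (
    ClashReweightLoop,
    FitSettings,
    RepulsionFit,
    ReweightSettings,
    _FeatureTable,
    objective,
)
from clashfix.refdata import CLASH_WEIGHT_CEILING
from clashfix.repulsion import PairRepulsionParams, RepulsionParamSet
from clashfix.surrogate import SurrogateModel
from clashfix.synthdata import (
    LOOP_BOUNDS,
    default_init_params,
    make_recovery_training,
    make_test_chains,
    make_toy_chain,
    make_training_set,
    pathological_model,
)

BARE = SurrogateModel(wells={}, softcore_scale=0.0)


def single_datum_training(weight=2.0, reference=0.0):
    from clashfix.refdata import proxy_datum
    from clashfix.synthdata import canonical_spec

    datum = proxy_datum(canonical_spec(("O", "H")), BARE, target=reference)
    datum.weight = weight
    return [datum]


class TestObjective:
    def test_exact_predictions_give_zero(self):
        true = PairRepulsionParams(("O", "H"), 2.0, 1.5, 3.0)
        training, bare = make_recovery_training(true)
        assert objective(RepulsionParamSet([true]), training, bare) == pytest.approx(0.0, abs=1e-18)

    def test_single_datum_weighted_square(self):
        # weight 2, error 0.5 kcal/mol -> (2 * 0.5)^2 = 1
        training = single_datum_training(weight=2.0)
        ps = RepulsionParamSet([PairRepulsionParams(("O", "H"), 1.0, 8.0, 2.57)])
        pred = training[0].predict(BARE.replace(repulsion=ps))
        training[0].reference = pred - 0.5
        assert objective(ps, training, BARE) == pytest.approx(1.0, rel=1e-6)

    def test_doubling_weight_quadruples_contribution(self):
        training = single_datum_training(weight=3.0, reference=1.0)
        ps = RepulsionParamSet([PairRepulsionParams(("O", "H"), 2.0, 1.0, 2.57)])
        f1 = objective(ps, training, BARE)
        training[0].weight *= 2
        assert objective(ps, training, BARE) == pytest.approx(4 * f1, rel=1e-12)

    def test_feature_table_matches_generic_objective(self):
        """The precomputed-feature fast path reproduces the generic
        payload-evaluation objective exactly."""
        model = pathological_model()
        training = make_training_set(model, n_hbond_anchors=2, n_far_anchors=2, seed=1)
        table = _FeatureTable(training, model)
        rng = np.random.default_rng(0)
        for _ in range(5):
            ps = RepulsionParamSet(
                [
                    PairRepulsionParams(pair, rng.uniform(0, 3), rng.uniform(0.5, 2), rng.uniform(2, 4))
                    for pair in default_init_params().pairs()
                ]
            )
            assert table.objective(ps) == pytest.approx(objective(ps, training, model), rel=1e-9)


class TestFit:
    def test_noise_free_parameter_recovery(self):
        true = PairRepulsionParams(("O", "H"), 3.0, 2.0, 3.2)
        training, bare = make_recovery_training(true, noise_sigma=0.0, seed=0)
        init = RepulsionParamSet([PairRepulsionParams(("O", "H"), 3.6, 1.6, 3.84)])
        res = RepulsionFit(training, bare, init).fit(FitSettings(maxiter=2000))
        p = res.params.get("O", "H")
        assert p.a == pytest.approx(3.0, rel=0.01)
        assert p.b == pytest.approx(2.0, rel=0.01)
        assert p.c == pytest.approx(3.2, rel=0.01)
        assert res.objective <= res.model.objective_value(init) + 1e-12

    def test_zero_targets_drive_amplitude_to_zero(self):
        true = PairRepulsionParams(("O", "H"), 3.0, 2.0, 3.2)
        training, bare = make_recovery_training(true, noise_sigma=0.0, seed=0)
        for d in training:
            d.reference = 0.0
        init = RepulsionParamSet([PairRepulsionParams(("O", "H"), 1.0, 2.0, 3.2)])
        res = RepulsionFit(training, bare, init).fit()
        assert res.params.get("O", "H").a == pytest.approx(0.0, abs=1e-4)

    def test_zero_weight_datum_has_no_influence(self):
        true = PairRepulsionParams(("O", "H"), 3.0, 2.0, 3.2)
        training, bare = make_recovery_training(true, noise_sigma=0.1, seed=3)
        rogue = copy.copy(training[0])
        rogue.reference += 25.0
        rogue.weight = 0.0
        init = RepulsionParamSet([PairRepulsionParams(("O", "H"), 2.5, 1.8, 3.0)])
        res_without = RepulsionFit(training, bare, init).fit()
        res_with = RepulsionFit(training + [rogue], bare, init).fit()
        p0, p1 = res_without.params.get("O", "H"), res_with.params.get("O", "H")
        assert (p0.a, p0.b, p0.c) == pytest.approx((p1.a, p1.b, p1.c), rel=1e-9)

    def test_summary_contains_parameters_and_residuals(self):
        true = PairRepulsionParams(("O", "H"), 3.0, 2.0, 3.2)
        training, bare = make_recovery_training(true, seed=0)
        res = RepulsionFit(training, bare, RepulsionParamSet([true])).fit()
        text = res.summary()
        assert "H-O" in text and "objective" in text  # pairs print in canonical order
        assert len(res.resid) == len(training)

    def test_empty_init_rejected(self):
        with pytest.raises(ValueError):
            RepulsionFit(single_datum_training(), BARE, RepulsionParamSet())


class TestReweightLoop:
    @staticmethod
    def _loop(test_structures, max_cycles, **kw):
        model = pathological_model()
        training = make_training_set(model, n_hbond_anchors=2, n_far_anchors=2, seed=0)
        clean, graph, _ = make_toy_chain(3)
        bound = model.with_reference(clean, graph)
        from clashfix.surrogate import OptimizerSettings

        return ClashReweightLoop(
            training,
            test_structures,
            bound,
            default_init_params(),
            fit_settings=FitSettings(maxiter=60),
            optimizer_settings=OptimizerSettings(max_cycles=200),
            settings=ReweightSettings(max_cycles=max_cycles, **kw),
            bounds=LOOP_BOUNDS,
        )

    def test_zero_cycles_returns_initial_fit_and_empty_trace(self):
        chains = make_test_chains(n_chains=1, residues=3, seed=0)
        loop = self._loop(chains, max_cycles=0)
        result, trace = loop.run(seed=0)
        assert trace == []
        assert len(result.params) == len(default_init_params())

    def test_clash_free_structures_leave_weights_unchanged(self):
        clean, graph, _ = make_toy_chain(3)
        loop = self._loop([(clean, graph)], max_cycles=1, clashscore_target=1000.0)
        before = {d.id: d.weight for d in loop.training if d.datum_class == "clash_proxy"}
        result, trace = loop.run(seed=0)
        assert len(trace) == 1
        assert trace[0].weights == before

    def test_weights_monotone_and_capped(self):
        chains = make_test_chains(n_chains=1, residues=3, seed=0)
        loop = self._loop(chains, max_cycles=3, clashscore_target=0.0)
        before = {d.id: d.weight for d in loop.training if d.datum_class == "clash_proxy"}
        _, trace = loop.run(seed=0)
        prev = before
        for state in trace:
            for key, w in state.weights.items():
                assert w >= prev[key]
                assert w <= CLASH_WEIGHT_CEILING
            prev = state.weights

    def test_caller_training_not_mutated(self):
        model = pathological_model()
        training = make_training_set(model, n_hbond_anchors=0, n_far_anchors=1, seed=0)
        weights = [d.weight for d in training]
        chains = make_test_chains(n_chains=1, residues=3, seed=0)
        clean, graph, _ = make_toy_chain(3)
        from clashfix.surrogate import OptimizerSettings

        loop = ClashReweightLoop(
            training,
            chains,
            model.with_reference(clean, graph),
            default_init_params(),
            fit_settings=FitSettings(maxiter=40),
            optimizer_settings=OptimizerSettings(max_cycles=100),
            settings=ReweightSettings(max_cycles=1, clashscore_target=0.0),
        )
        loop.run(seed=0)
        assert [d.weight for d in training] == weights


def test_noisy_recovery_median_error():
    """Median relative error of the recovered amplitude stays below 10%
    over 20 seeded noisy training sets (sigma = 0.1 kcal/mol)."""
    true = PairRepulsionParams(("O", "H"), 3.0, 2.0, 3.2)
    errs = []
    for seed in range(20):
        training, bare = make_recovery_training(true, noise_sigma=0.1, seed=seed)
        rng = np.random.default_rng(1000 + seed)
        f = 1 + 0.2 * rng.uniform(-1, 1, size=3)
        init = RepulsionParamSet(
            [PairRepulsionParams(("O", "H"), 3.0 * f[0], max(2.0 * f[1], 0.1), 3.2 * f[2])]
        )
        res = RepulsionFit(training, bare, init).fit(FitSettings(maxiter=1000))
        errs.append(abs(res.params.get("O", "H").a - 3.0) / 3.0)
    assert float(np.median(errs)) < 0.10
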