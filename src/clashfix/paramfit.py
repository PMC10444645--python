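"""Weighted least-squares fitting of repulsion parameters.

The objective is the weighted sum of squares

    chi2(theta) = sum_d ( w_d * (predicted_d(theta) - reference_d) )**2

over a training set of :class:`~clashfix.refdata.ReferenceDatum`, where
the per-datum weights w_d (1/(kcal/mol)) render each residual
dimensionless.  theta collects the (a, b, c) triples of every element
pair in the parameter set; all pairs are optimized simultaneously with a
bounded derivative-free local search.

:class:`RepulsionFit` is the model object (training data + surrogate +
initial parameters); :meth:`RepulsionFit.fit` returns a
:class:`RepulsionFitResults` carrying the fitted parameter set, the final
objective, per-datum weighted residuals and a summary table.

:class:`ClashReweightLoop` implements the iterative protocol that made
the pair term effective: fit parameters, optimize test-structure
geometries under the fitted model, detect clashes, raise the weights of
the clash-proxy data matching the worst offending element pairs
(multiplicatively, capped at 100), and repeat until the average
clashscore is acceptably small.
"""

from __future__ import annotations

import copy
import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .refdata import CLASH_WEIGHT_CEILING, ReferenceDatum
from .repulsion import PairRepulsionParams, RepulsionParamSet
from .structures import BondGraph, Structure
from .surrogate import OptimizerSettings, SurrogateModel, optimize_geometry
from .validate import atom_vdw_radii, detect_clashes

__all__ = [
    "FitSettings",
    "RepulsionFit",
    "RepulsionFitResults",
    "ReweightSettings",
    "ReweightState",
    "ClashReweightLoop",
    "objective",
    "fit_parameters",
    "clash_reweight_loop",
]

DEFAULT_BOUNDS = {"a": (0.0, 20.0), "b": (0.05, 10.0), "c": (0.5, 6.0)}


class _FeatureTable:
    """Precomputed repulsion features for fast objective evaluation.

    A datum's payload geometries never change during a fit, so its
    prediction decomposes as (repulsion-free baseline) + (sum of pair
    terms over fixed non-bonded distances).  Per element pair we store
    flat arrays of (datum index, sign, distance) and rebuild predictions
    for any candidate parameter set in a few vector operations.
    """

    def __init__(self, training, model: SurrogateModel):
        from .structures import neighbor_pairs

        base = model.replace(repulsion=None)
        self.base_pred = np.array([d.predict(base) for d in training])
        self.references = np.array([d.reference for d in training])
        self.update_weights(training)
        feats: dict[tuple[str, str], list[tuple[int, float, float]]] = {}
        for di, datum in enumerate(training):
            kind = datum.payload[0]
            if kind == "difference":
                parts = [(datum.payload[1], 1.0), (datum.payload[2], -1.0)]
            elif kind == "single":
                parts = [(datum.payload[1], 1.0)]
            elif kind == "interaction":
                parts = [(datum.payload[1], 1.0), (datum.payload[2], -1.0), (datum.payload[3], -1.0)]
            else:
                raise ValueError(f"unknown payload kind {kind!r}")
            for (s, g), sign in parts:
                elements = s.elements
                for i, j, dist in neighbor_pairs(s, model.cutoff):
                    if (i, j) in g.excluded:
                        continue
                    pair = tuple(sorted((elements[i], elements[j])))
                    feats.setdefault(pair, []).append((di, sign, dist))
        self.features = {
            pair: (
                np.array([t[0] for t in rows], dtype=int),
                np.array([t[1] for t in rows]),
                np.array([t[2] for t in rows]),
            )
            for pair, rows in feats.items()
        }
        self.n = len(training)

    def update_weights(self, training) -> None:
        self.weights = np.array([d.weight for d in training])

    def predictions(self, params: RepulsionParamSet) -> np.ndarray:
        pred = self.base_pred.copy()
        for pair, (di, sign, dist) in self.features.items():
            p = params.get(*pair)
            if p is None:
                continue
            dr = dist - p.c
            e = np.where(dr > 0, p.a * np.exp(-p.b * dr**2), p.a)
            pred += np.bincount(di, weights=sign * e, minlength=self.n)
        return pred

    def objective(self, params: RepulsionParamSet) -> float:
        resid = self.weights * (self.predictions(params) - self.references)
        return float(np.dot(resid, resid))


def objective(
    params: RepulsionParamSet,
    training: Sequence[ReferenceDatum],
    model: SurrogateModel,
) -> float:
    """Weighted sum-of-squares objective (dimensionless)."""
    total = 0.0
    m = model.replace(repulsion=params)
    for datum in training:
        pred = datum.predict(m)
        if not np.isfinite(pred):
            raise ValueError(f"non-finite prediction for datum {datum.id!r}")
        total += (datum.weight * (pred - datum.reference)) ** 2
    return total


@dataclasses.dataclass
class FitSettings:
    xtol: float = 1e-8
    ftol: float = 1e-10
    maxiter: int = 2000


def _pack(params: RepulsionParamSet) -> tuple[list[tuple[str, str]], np.ndarray]:
    pairs = params.pairs()
    x = []
    for pair in pairs:
        p = params.get(*pair)
        x.extend([p.a, p.b, p.c])
    return pairs, np.array(x)


def _unpack(pairs: list[tuple[str, str]], x: np.ndarray) -> RepulsionParamSet:
    out = RepulsionParamSet()
    for k, pair in enumerate(pairs):
        a, b, c = x[3 * k : 3 * k + 3]
        out.add(PairRepulsionParams(pair, float(max(a, 0.0)), float(b), float(c)))
    return out


class RepulsionFitResults:
    """Estimates, residuals and diagnostics from a repulsion-parameter fit."""

    def __init__(self, model_obj: "RepulsionFit", params: RepulsionParamSet, objective_value: float, nit: int, converged: bool):
        self.model = model_obj
        self.params = params
        self.objective = float(objective_value)
        self.nit = int(nit)
        self.converged = bool(converged)
        m = model_obj.surrogate.replace(repulsion=params)
        self.predicted = np.array([d.predict(m) for d in model_obj.training])
        self.references = np.array([d.reference for d in model_obj.training])
        self.weights = np.array([d.weight for d in model_obj.training])
        #: weighted (dimensionless) residuals, one per training datum
        self.resid = self.weights * (self.predicted - self.references)

    def summary(self) -> str:
        lines = [
            "Repulsion parameter fit",
            "=" * 64,
            f"training data: {len(self.model.training)}    objective: {self.objective:.6g}"
            f"    iterations: {self.nit}    converged: {self.converged}",
            "",
            "pair      a (kcal/mol)   b (1/A^2)      c (A)",
            "-" * 48,
        ]
        for pair in self.params.pairs():
            p = self.params.get(*pair)
            lines.append(f"{pair[0]}-{pair[1]:<6s}{p.a:>12.4f}{p.b:>12.4f}{p.c:>11.4f}")
        lines += ["", "datum\tclass\tweight\treference\tpredicted\tweighted_resid"]
        for d, pred, res in zip(self.model.training, self.predicted, self.resid):
            lines.append(
                f"{d.id}\t{d.datum_class}\t{d.weight:g}\t{d.reference:.4f}\t{pred:.4f}\t{res:.4f}"
            )
        return "\n".join(lines)

    def report_tsv(self) -> str:
        lines = ["datum\tclass\tweight\treference\tpredicted\tweighted_resid"]
        for d, pred, res in zip(self.model.training, self.predicted, self.resid):
            lines.append(
                f"{d.id}\t{d.datum_class}\t{d.weight:g}\t{d.reference:.6f}\t{pred:.6f}\t{res:.6f}"
            )
        return "\n".join(lines) + "\n"


class RepulsionFit:
    """Model object: training data + surrogate + initial parameter set.

    Parameters
    ----------
    training : sequence of ReferenceDatum
    surrogate : SurrogateModel
        Baseline model the repulsion term is embedded in during prediction.
    init : RepulsionParamSet
        Starting values; the element pairs present here are the ones fitted.
    bounds : optional dict with "a", "b", "c" -> (lo, hi)
    """

    def __init__(
        self,
        training: Sequence[ReferenceDatum],
        surrogate: SurrogateModel,
        init: RepulsionParamSet,
        bounds: Optional[dict] = None,
    ):
        if not len(init):
            raise ValueError("initial parameter set is empty: nothing to fit")
        self.training = list(training)
        self.surrogate = surrogate
        self.init = init
        self.bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
        for key in ("a", "b", "c"):
            lo, hi = self.bounds[key]
            if key == "a" and lo < 0:
                raise ValueError("lower bound on a must be >= 0")
            if key in ("b", "c") and lo <= 0:
                raise ValueError(f"lower bound on {key} must be > 0")
            if hi <= lo:
                raise ValueError(f"empty bound interval for {key}")

    def objective_value(self, params: RepulsionParamSet) -> float:
        return objective(params, self.training, self.surrogate)

    def _features(self) -> _FeatureTable:
        if getattr(self, "_feature_table", None) is None:
            self._feature_table = _FeatureTable(self.training, self.surrogate)
        self._feature_table.update_weights(self.training)
        return self._feature_table

    def fit(self, settings: FitSettings | None = None, seed: int = 0) -> RepulsionFitResults:
        """Bounded local minimization of the objective from the initial values.

        Deterministic for given inputs; ``seed`` is recorded for interface
        uniformity (the Powell search itself draws no random numbers).
        """
        st = settings or FitSettings()
        pairs, x0 = _pack(self.init)
        table = self._features()
        f0 = table.objective(_unpack(pairs, x0))
        if not np.isfinite(f0):
            raise ValueError("objective is non-finite at the initial parameters")
        bounds = [self.bounds[k] for _ in pairs for k in ("a", "b", "c")]

        def fun(x: np.ndarray) -> float:
            return table.objective(_unpack(pairs, x))

        res = minimize(
            fun,
            x0,
            method="Powell",
            bounds=bounds,
            options={"xtol": st.xtol, "ftol": st.ftol, "maxiter": st.maxiter},
        )
        best_x, best_f = (res.x, float(res.fun)) if res.fun <= f0 else (x0, f0)
        return RepulsionFitResults(self, _unpack(pairs, best_x), best_f, res.nit, res.success)


def fit_parameters(
    training: Sequence[ReferenceDatum],
    init: RepulsionParamSet,
    bounds: Optional[dict] = None,
    settings: FitSettings | None = None,
    seed: int = 0,
    surrogate: SurrogateModel | None = None,
) -> RepulsionFitResults:
    """Functional wrapper around :class:`RepulsionFit`."""
    model = RepulsionFit(training, surrogate or SurrogateModel(), init, bounds)
    return model.fit(settings=settings, seed=seed)


@dataclasses.dataclass
class ReweightSettings:
    increment: float = 1.5  # multiplicative weight update per offending cycle
    ceiling: float = CLASH_WEIGHT_CEILING
    clashscore_target: float = 5.0  # "acceptably small"
    max_cycles: int = 8
    n_worst: int = 5  # how many largest clashes seed each update


@dataclasses.dataclass
class ReweightState:
    """Trace record for one reweighting cycle."""

    cycle: int
    weights: dict[str, float]  # clash-proxy datum id -> weight after the update
    average_clashscore: float
    worst_pairs: list[tuple[str, str]]  # element pairs of the ranked worst clashes
    uncovered_pairs: list[tuple[str, str]]  # clash pairs with no matching proxy datum


class ClashReweightLoop:
    """Iterative clash-driven reweighting of clash-proxy training data."""

    def __init__(
        self,
        training: Sequence[ReferenceDatum],
        test_structures: Sequence[tuple[Structure, BondGraph]],
        surrogate: SurrogateModel,
        init: RepulsionParamSet,
        fit_settings: FitSettings | None = None,
        optimizer_settings: OptimizerSettings | None = None,
        settings: ReweightSettings | None = None,
        bounds: Optional[dict] = None,
    ):
        self.training = [copy.copy(d) for d in training]
        self.test_structures = list(test_structures)
        self.surrogate = surrogate
        self.init = init
        self.fit_settings = fit_settings
        self.optimizer_settings = optimizer_settings
        self.settings = settings or ReweightSettings()
        self.bounds = bounds
        self._fit_model = RepulsionFit(self.training, self.surrogate, self.init, self.bounds)

    def _fit(self, seed: int) -> RepulsionFitResults:
        return self._fit_model.fit(settings=self.fit_settings, seed=seed)

    def _average_clashscore(self, params: RepulsionParamSet):
        scores = []
        all_clashes = []
        for s, g in self.test_structures:
            # honor pre-bound bond/angle references (e.g. the clean fixture
            # geometry); otherwise take them from the structure itself
            bound = self.surrogate if self.surrogate.bond_refs is not None else self.surrogate.with_reference(s, g)
            m = bound.replace(repulsion=params)
            opt, _ = optimize_geometry(s, g, m, self.optimizer_settings)
            report = detect_clashes(opt, g)
            scores.append(report.clashscore)
            elements = opt.elements
            for c in report.clashes:
                pair = tuple(sorted((elements[c.i], elements[c.j])))
                all_clashes.append((c.overlap, pair))
        all_clashes.sort(key=lambda t: -t[0])
        return float(np.mean(scores)), all_clashes

    def run(self, seed: int = 0) -> tuple[RepulsionFitResults, list[ReweightState]]:
        st = self.settings
        result = self._fit(seed)
        trace: list[ReweightState] = []
        for cycle in range(1, st.max_cycles + 1):
            avg, ranked = self._average_clashscore(result.params)
            # the worst distinct pair types, in decreasing-overlap order:
            # each offending type's proxy weight is raised once per cycle
            worst: list[tuple[str, str]] = []
            for _, pair in ranked:
                if pair not in worst:
                    worst.append(pair)
                if len(worst) >= st.n_worst:
                    break
            uncovered: list[tuple[str, str]] = []
            updated = False
            if avg > st.clashscore_target:
                for pair in worst:
                    matches = [
                        d
                        for d in self.training
                        if d.datum_class == "clash_proxy" and d.element_pair == pair
                    ]
                    if not matches:
                        uncovered.append(pair)
                        continue
                    for d in matches:
                        new_w = min(d.weight * st.increment, st.ceiling)
                        if new_w > d.weight:
                            d.weight = new_w
                            updated = True
            trace.append(
                ReweightState(
                    cycle=cycle,
                    weights={
                        d.id: d.weight for d in self.training if d.datum_class == "clash_proxy"
                    },
                    average_clashscore=avg,
                    worst_pairs=worst,
                    uncovered_pairs=uncovered,
                )
            )
            if avg <= st.clashscore_target:
                break
            if not updated:
                break  # every matched proxy weight is at the ceiling: no lever left
            # warm-start the refit from the previous parameter estimate
            self._fit_model.init = result.params
            result = self._fit(seed)
        return result, trace


def clash_reweight_loop(
    training: Sequence[ReferenceDatum],
    test_structures: Sequence[tuple[Structure, BondGraph]],
    surrogate: SurrogateModel,
    init: RepulsionParamSet,
    fit_settings: FitSettings | None = None,
    optimizer_settings: OptimizerSettings | None = None,
    loop_settings: ReweightSettings | None = None,
    seed: int = 0,
) -> tuple[RepulsionFitResults, list[ReweightState]]:
    """Functional wrapper around :class:`ClashReweightLoop`."""
    loop = ClashReweightLoop(
        training,
        test_structures,
        surrogate,
        init,
        fit_settings=fit_settings,
        optimizer_settings=optimizer_settings,
        settings=loop_settings,
    )
    return loop.run(seed=seed)


def reweight_trace_tsv(trace: Sequence[ReweightState]) -> str:
    lines = ["cycle\taverage_clashscore\tworst_pairs\tuncovered\tweights"]
    for s in trace:
        worst = ";".join("-".join(p) for p in s.worst_pairs)
        unc = ";".join("-".join(p) for p in s.uncovered_pairs)
        weights = ";".join(f"{k}={v:g}" for k, v in sorted(s.weights.items()))
        lines.append(f"{s.cycle}\t{s.average_clashscore:.3f}\t{worst}\t{unc}\t{weights}")
    return "\n".join(lines) + "\n"
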