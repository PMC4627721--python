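"""Fitting the normalization model to behavioral data, and model comparison.

The seven free parameters (n, sigma, w_I, w_x, w_v, p, sigma_n) are found by
bounded least squares between the model's predicted d'(c) and the per-cell d'
estimates, from multiple seeded starting points.  The attentional gain
factors are constrained to stay non-negative via an exact hinge penalty, so
the optimizer may sit on the constraint boundary (the goal-driven magnitude
typically does).

Model comparison between the feature-specific (FS) and eye-specific (ES)
stimulus-driven attention variants uses

* trial-level cross-validation: trials are randomly partitioned in half,
  group-averaged psychometric functions are computed on each half, both
  variants are fit on the training half and scored (R^2) on the held-out
  half; the distribution of R^2_FS - R^2_ES over many partitions is the
  comparison index;
* the Bayesian information criterion with a binomial likelihood of the
  per-cell correct counts under P(correct) = Phi(d'/2);
* a numerical Hessian of the objective at the optimum, whose rank (via SVD)
  detects parameter redundancy and whose smallest-eigenvalue eigenvector
  indicates which parameter is least constrained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

from .descriptive import dprime_cells, cell_counts, estimate_dprime
from .grid import NeuronGrid
from .population import ModelParams, PsychometricPredictor, VARIANTS

__all__ = [
    "PARAM_BOUNDS",
    "NormalizationModel",
    "FitResult",
    "fit_model",
    "bootstrap_fit",
    "ComparisonResult",
    "crossval_compare",
    "bic_compare",
    "HessianReport",
    "hessian_rank",
]

PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "n": (0.5, 6.0),
    "sigma": (1e-5, 0.1),
    "w_I": (0.0, 5.0),
    "w_x": (0.0, 10.0),
    "w_v": (0.0, 10.0),
    "p": (0.0, 1.0),
    "sigma_n": (0.1, 20.0),
    "w_x_eye": (0.0, 10.0),
    "w_LR": (0.0, 5.0),
    "w_RL": (0.0, 5.0),
}

_BASE_NAMES = ("n", "sigma", "w_I", "w_x", "w_v", "p", "sigma_n")
# log-scale parameters are searched in log space so multiplicative structure
# (sigma spans four decades) does not defeat the line search
_LOG_SCALE = {"sigma", "sigma_n"}


def _free_names(variant: str, directional: bool, fixed: dict) -> list[str]:
    names = list(_BASE_NAMES)
    if directional:
        names.remove("w_I")
        names += ["w_LR", "w_RL"]
    if variant == "compound":
        names.append("w_x_eye")
    return [nm for nm in names if nm not in fixed]


def _to_vector(values: dict, names: list[str]) -> np.ndarray:
    return np.array(
        [np.log(values[nm]) if nm in _LOG_SCALE else values[nm] for nm in names]
    )


def _from_vector(x: np.ndarray, names: list[str], fixed: dict) -> ModelParams:
    vals = dict(fixed)
    for nm, xi in zip(names, x):
        vals[nm] = float(np.exp(xi)) if nm in _LOG_SCALE else float(xi)
    vals.setdefault("w_I", 0.0)
    return ModelParams(**{k: v for k, v in vals.items() if k in ModelParams.__dataclass_fields__})


@dataclass
class FitResult:
    """Best fit of one model variant, with optional bootstrap intervals."""

    variant: str
    params: ModelParams
    r_squared: float
    sse: float
    gain_report: pd.DataFrame
    start_objectives: np.ndarray
    ci68: dict[str, tuple[float, float]] | None = None
    ci95: dict[str, tuple[float, float]] | None = None
    bootstrap_samples: pd.DataFrame | None = field(repr=False, default=None)


class NormalizationModel:
    """Scikit-learn style estimator for the interocular suppression model.

    Parameters
    ----------
    variant : {"fs", "es", "compound"}
        Form of the stimulus-driven attentional gain field.
    grid : NeuronGrid, optional
        Population sampling grid (default: the reference grid).
    n_starts : int
        Number of seeded optimizer starts; the best objective wins.
    seed : int
        Seed for the start generator.
    fixed : dict, optional
        Parameters pinned at given values (excluded from the search), e.g.
        ``{"w_x": 4.62, "p": 0.26}`` for constrained refits.
    directional : bool
        Replace the single interocular weight by separate w_LR / w_RL.
    init : ModelParams, optional
        Warm start; used as the first optimizer start.
    maxiter : int
        Iteration cap per start (L-BFGS-B).

    After ``fit``: ``params_``, ``r_squared_``, ``sse_``, ``objective_``,
    ``start_objectives_``, ``x_opt_``, ``predictor_``.
    """

    def __init__(
        self,
        variant: str = "fs",
        grid: NeuronGrid | None = None,
        n_starts: int = 10,
        seed: int = 0,
        fixed: dict | None = None,
        directional: bool = False,
        init: ModelParams | None = None,
        maxiter: int = 300,
        competitor_contrast: float = 0.23,
    ):
        self.variant = variant
        self.grid = grid
        self.n_starts = n_starts
        self.seed = seed
        self.fixed = fixed
        self.directional = directional
        self.init = init
        self.maxiter = maxiter
        self.competitor_contrast = competitor_contrast

    def get_params(self, deep: bool = True) -> dict:
        return {
            "variant": self.variant,
            "grid": self.grid,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "fixed": self.fixed,
            "directional": self.directional,
            "init": self.init,
            "maxiter": self.maxiter,
            "competitor_contrast": self.competitor_contrast,
        }

    def set_params(self, **kw):
        valid = self.get_params()
        for k, v in kw.items():
            if k not in valid:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- data plumbing ------------------------------------------------------

    def _design_from(self, trials: pd.DataFrame):
        cells = dprime_cells(trials, "group_average")
        piv = cells.pivot_table(
            index=["condition", "target_eye"], columns="contrast", values="dprime"
        )
        conds = [tuple(ix) for ix in piv.index]
        contrasts = piv.columns.to_numpy(dtype=float)
        Y = piv.to_numpy(dtype=float)
        return conds, contrasts, Y

    def _objective_factory(self, predictor, Y, mask):
        names = self._names
        fixed = dict(self.fixed or {})
        sst = np.nansum((Y[mask] - np.nanmean(Y[mask])) ** 2)
        penalty_scale = 1e4 * max(sst, 1.0)

        def objective(x: np.ndarray) -> float:
            params = _from_vector(x, names, fixed)
            g_min = predictor.min_gain(params)
            if g_min < -0.5:
                # deep in the infeasible region the model itself may be
                # pathological; steer back with the penalty alone
                return penalty_scale * (1.0 + g_min ** 2)
            # mild violations are evaluated as-is (the response stays finite)
            # plus a hinge penalty, keeping the objective smooth across the
            # non-negativity boundary where the optimum often sits
            sse = self._sse_at(predictor, params, Y, mask)
            if not np.isfinite(sse):
                return penalty_scale * (1.0 + max(0.0, -g_min) ** 2)
            return sse + penalty_scale * min(0.0, g_min) ** 2

        return objective, sst

    @staticmethod
    def _sse_at(predictor, params, Y, mask) -> float:
        pred = predictor.dprime(params)
        r = pred[mask] - Y[mask]
        return float(r @ r)

    def _start_vectors(self, rng, names, fixed):
        starts = []
        if self.init is not None:
            vals = {nm: getattr(self.init, nm) for nm in names}
            starts.append(_to_vector(vals, names))
        heur = {
            "n": 2.0, "sigma": 0.01, "w_I": 1.0, "w_x": 2.0, "w_v": 2.0,
            "p": 0.3, "sigma_n": 3.0, "w_x_eye": 1.0, "w_LR": 1.0, "w_RL": 1.0,
        }
        starts.append(_to_vector({nm: heur[nm] for nm in names}, names))
        while len(starts) < self.n_starts:
            vals = {}
            for nm in names:
                lo, hi = PARAM_BOUNDS[nm]
                if nm in _LOG_SCALE:
                    vals[nm] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                else:
                    vals[nm] = float(rng.uniform(lo, hi))
            # keep random starts inside the non-negative-gain region
            vals["w_v"] = min(vals.get("w_v", 1.0), 4.0)
            vals["w_x"] = min(vals.get("w_x", 1.0), 4.0)
            starts.append(_to_vector(vals, names))
        return starts[: self.n_starts]

    # -- estimator API ------------------------------------------------------

    def fit(self, trials: pd.DataFrame):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        fixed = dict(self.fixed or {})
        conds, contrasts, Y = self._design_from(trials)
        if len(conds) < 2:
            raise ValueError("need at least two conditions to fit the model")
        mask = np.isfinite(Y)
        predictor = PsychometricPredictor(
            conds, contrasts, grid=self.grid, variant=self.variant,
            competitor_contrast=self.competitor_contrast,
        )
        self._names = _free_names(self.variant, self.directional, fixed)
        objective, sst = self._objective_factory(predictor, Y, mask)
        bounds = []
        for nm in self._names:
            lo, hi = PARAM_BOUNDS[nm]
            bounds.append((np.log(lo), np.log(hi)) if nm in _LOG_SCALE else (lo, hi))
        if not self._names:
            # every parameter pinned: pure evaluation, no search
            self.x_opt_ = np.empty(0)
            self.params_ = _from_vector(self.x_opt_, self._names, fixed)
            self.objective_ = objective(self.x_opt_)
            self.sse_ = self._sse_at(predictor, self.params_, Y, mask)
            self.r_squared_ = 1.0 - self.sse_ / sst if sst > 0 else np.nan
            self.start_objectives_ = np.array([self.objective_])
            self.predictor_ = predictor
            self.data_dprime_ = Y
            self.data_mask_ = mask
            self.conditions_ = conds
            self.contrasts_ = contrasts
            self.objective_fn_ = objective
            return self
        rng = np.random.default_rng(self.seed)
        results = []
        for x0 in self._start_vectors(rng, self._names, fixed):
            try:
                sol = minimize(
                    objective, x0, method="L-BFGS-B", bounds=bounds,
                    options={"maxiter": self.maxiter, "ftol": 1e-12, "gtol": 1e-9},
                )
                results.append(sol)
            except FloatingPointError as exc:
                warnings.warn(f"optimizer start failed: {exc}")
        if not results:
            raise RuntimeError(
                "all optimizer starts failed; diagnostics: no successful solve"
            )
        objs = np.array([r.fun for r in results])
        best = results[int(np.argmin(objs))]
        self.x_opt_ = best.x
        self.params_ = _from_vector(best.x, self._names, fixed)
        self.objective_ = float(best.fun)
        self.sse_ = self._sse_at(predictor, self.params_, Y, mask)
        self.r_squared_ = 1.0 - self.sse_ / sst if sst > 0 else np.nan
        self.start_objectives_ = objs
        self.predictor_ = predictor
        self.data_dprime_ = Y
        self.data_mask_ = mask
        self.conditions_ = conds
        self.contrasts_ = contrasts
        self.objective_fn_ = objective
        return self

    def predict(self, conditions=None, contrasts=None) -> pd.DataFrame:
        """Predicted d' table at the fitted parameters."""
        if conditions is None and contrasts is None:
            pred = self.predictor_
        else:
            pred = PsychometricPredictor(
                conditions if conditions is not None else self.conditions_,
                contrasts if contrasts is not None else self.contrasts_,
                grid=self.grid, variant=self.variant,
                competitor_contrast=self.competitor_contrast,
            )
        dmat = pred.dprime(self.params_)
        rows = []
        for i, (name, eye) in enumerate(pred.conditions):
            for j, c in enumerate(pred.contrasts):
                rows.append((name, eye, float(c), dmat[i, j]))
        return pd.DataFrame(rows, columns=["condition", "target_eye", "contrast", "dprime"])

    def score(self, trials: pd.DataFrame) -> float:
        """R^2 of the fitted parameters on (possibly new) trial data."""
        conds, contrasts, Y = self._design_from(trials)
        pred = PsychometricPredictor(
            conds, contrasts, grid=self.grid, variant=self.variant,
            competitor_contrast=self.competitor_contrast,
        )
        mask = np.isfinite(Y)
        r = pred.dprime(self.params_)[mask] - Y[mask]
        sst = float(((Y[mask] - Y[mask].mean()) ** 2).sum())
        return 1.0 - float(r @ r) / sst if sst > 0 else np.nan

    def gain_report(self) -> pd.DataFrame:
        return self.predictor_.gain_report(self.params_)


def fit_model(
    trials: pd.DataFrame,
    variant: str = "fs",
    fixed: dict | None = None,
    bootstrap: int = 0,
    seed: int = 0,
    **kwargs,
) -> FitResult:
    """Fit one variant and package the result (optionally with bootstrap CIs)."""
    model = NormalizationModel(variant=variant, fixed=fixed, seed=seed, **kwargs).fit(trials)
    res = FitResult(
        variant=variant,
        params=model.params_,
        r_squared=model.r_squared_,
        sse=model.sse_,
        gain_report=model.gain_report(),
        start_objectives=model.start_objectives_,
    )
    if bootstrap:
        res.ci68, res.ci95, res.bootstrap_samples = bootstrap_fit(
            model, trials, B=bootstrap, seed=seed
        )
    return res


def _resample_cells(trials: pd.DataFrame, rng) -> pd.DataFrame:
    """Trial resampling with replacement within each cell, as counts."""
    counts = cell_counts(trials)
    n = counts["n_trials"].to_numpy()
    p = counts["n_correct"].to_numpy() / n
    counts = counts.copy()
    counts["n_correct"] = rng.binomial(n.astype(int), p)
    return counts


def _counts_to_trials(counts: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, r in counts.iterrows():
        n, k = int(r.n_trials), int(r.n_correct)
        rows.append(
            pd.DataFrame(
                {
                    "observer": r.observer,
                    "condition": r.condition,
                    "target_eye": r.target_eye,
                    "contrast": r.contrast,
                    "trial": np.arange(n),
                    "correct": np.r_[np.ones(k, int), np.zeros(n - k, int)],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def bootstrap_fit(model: NormalizationModel, trials: pd.DataFrame, B: int = 2000,
                  seed: int | None = None):
    """Percentile CIs of the model parameters by trial resampling + refit."""
    rng = np.random.default_rng(seed)
    names = model._names
    samples = []
    for _ in range(B):
        resampled = _counts_to_trials(_resample_cells(trials, rng))
        m = NormalizationModel(
            **{**model.get_params(), "n_starts": 1, "init": model.params_, "maxiter": 120}
        ).fit(resampled)
        samples.append({nm: getattr(m.params_, nm) for nm in names})
    samp = pd.DataFrame(samples)
    ci68 = {nm: (float(np.percentile(samp[nm], 16)), float(np.percentile(samp[nm], 84)))
            for nm in names}
    ci95 = {nm: (float(np.percentile(samp[nm], 2.5)), float(np.percentile(samp[nm], 97.5)))
            for nm in names}
    return ci68, ci95, samp


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Cross-validated comparison of two model variants."""

    variants: tuple[str, str]
    r2_diff: np.ndarray  # held-out R^2 of variants[0] minus variants[1], (B,)
    exceedance_fraction: float
    r2_train: dict[str, np.ndarray]
    r2_test: dict[str, np.ndarray]
    decision: str
    redraws: int = 0
    bic: dict[str, float] | None = None


def _split_counts(trials: pd.DataFrame, rng, split_fraction: float):
    """Random trial-level partition of every cell into train / test counts."""
    counts = cell_counts(trials)
    n = counts["n_trials"].to_numpy().astype(int)
    k = counts["n_correct"].to_numpy().astype(int)
    n_train = np.maximum(1, np.round(n * split_fraction).astype(int))
    n_train = np.minimum(n_train, n - 1)
    # hypergeometric draw = permuting the cell's trials and cutting in half
    k_train = rng.hypergeometric(k, n - k, n_train)
    train = counts.copy()
    train["n_trials"] = n_train
    train["n_correct"] = k_train
    test = counts.copy()
    test["n_trials"] = n - n_train
    test["n_correct"] = k - k_train
    return train, test


def _group_dprime_from_counts(counts: pd.DataFrame):
    counts = counts.copy()
    counts["dprime"] = estimate_dprime(counts["n_correct"], counts["n_trials"])
    piv = (
        counts.groupby(["condition", "target_eye", "contrast"], sort=True)["dprime"]
        .mean()
        .reset_index()
        .pivot_table(index=["condition", "target_eye"], columns="contrast", values="dprime")
    )
    conds = [tuple(ix) for ix in piv.index]
    return conds, piv.columns.to_numpy(dtype=float), piv.to_numpy(dtype=float)


def crossval_compare(
    trials: pd.DataFrame,
    B: int = 2000,
    split_fraction: float = 0.5,
    seed: int | None = None,
    variants: tuple[str, str] = ("fs", "es"),
    grid: NeuronGrid | None = None,
    n_starts_full: int = 8,
    maxiter: int = 150,
) -> ComparisonResult:
    """Repeated split-half cross-validation of two model variants.

    Per repetition the trials of every cell are randomly halved; both
    variants are fit to the group-averaged training half (warm-started from
    their full-data fits) and scored on the held-out half.  The comparison
    index is the distribution of held-out R^2 differences.
    """
    if B < 1:
        raise ValueError("B must be positive")
    rng = np.random.default_rng(seed)
    full_fits = {
        v: NormalizationModel(
            variant=v, grid=grid, n_starts=n_starts_full, seed=0 if seed is None else seed
        ).fit(trials)
        for v in variants
    }
    conds, contrasts, _ = full_fits[variants[0]]._design_from(trials)
    predictors = {
        v: full_fits[v].predictor_ for v in variants
    }
    r2_test = {v: np.empty(B) for v in variants}
    r2_train = {v: np.empty(B) for v in variants}
    redraws = 0
    b = 0
    while b < B:
        train_c, test_c = _split_counts(trials, rng, split_fraction)
        if (train_c["n_trials"] < 1).any() or (test_c["n_trials"] < 1).any():
            redraws += 1
            continue
        tr = _group_dprime_from_counts(train_c)
        te = _group_dprime_from_counts(test_c)
        for v in variants:
            m = NormalizationModel(
                variant=v, grid=grid, n_starts=1, init=full_fits[v].params_,
                maxiter=maxiter, seed=0,
            )
            m._names = _free_names(v, False, {})
            predictor = predictors[v]
            maskY = np.isfinite(tr[2])
            objective, sst = m._objective_factory(predictor, tr[2], maskY)
            x0 = _to_vector({nm: getattr(full_fits[v].params_, nm) for nm in m._names}, m._names)
            bounds = [
                (np.log(PARAM_BOUNDS[nm][0]), np.log(PARAM_BOUNDS[nm][1]))
                if nm in _LOG_SCALE else PARAM_BOUNDS[nm]
                for nm in m._names
            ]
            sol = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": maxiter, "ftol": 1e-11})
            params = _from_vector(sol.x, m._names, {})
            pred_tr = predictor.dprime(params)
            r2_train[v][b] = 1.0 - float(((pred_tr - tr[2])[maskY] ** 2).sum()) / sst
            maskT = np.isfinite(te[2])
            res = (predictor.dprime(params) - te[2])[maskT]
            sst_t = float(((te[2][maskT] - te[2][maskT].mean()) ** 2).sum())
            r2_test[v][b] = 1.0 - float(res @ res) / sst_t
        b += 1
    diff = r2_test[variants[0]] - r2_test[variants[1]]
    exceed = float(np.mean(diff > 0.0))
    if exceed >= 0.95:
        decision = f"{variants[0]} outperforms {variants[1]}"
    elif exceed <= 0.05:
        decision = f"{variants[1]} outperforms {variants[0]}"
    else:
        decision = "no reliable difference"
    return ComparisonResult(
        variants=variants, r2_diff=diff, exceedance_fraction=exceed,
        r2_train=r2_train, r2_test=r2_test, decision=decision, redraws=redraws,
    )


def bic_compare(
    trials: pd.DataFrame,
    variants=("fs", "es"),
    fits: dict[str, "NormalizationModel"] | None = None,
    grid: NeuronGrid | None = None,
    seed: int = 0,
    **fit_kwargs,
) -> dict[str, dict[str, float]]:
    """BIC per variant from a binomial likelihood of per-cell correct counts.

    Counts are pooled across observers per (condition, contrast) cell since
    the fit is to group-averaged data; P(correct) = Phi(d'_model / 2) clipped
    away from 0 and 1.  BIC = k ln(N_cells) - 2 lnL, lower is better.
    """
    if fits is None:
        fits = {
            v: NormalizationModel(variant=v, grid=grid, seed=seed, **fit_kwargs).fit(trials)
            for v in variants
        }
    counts = cell_counts(trials)
    pooled = (
        counts.groupby(["condition", "target_eye", "contrast"], sort=True)
        .agg(n_trials=("n_trials", "sum"), n_correct=("n_correct", "sum"))
        .reset_index()
    )
    out = {}
    for v, m in fits.items():
        pred = m.predict()
        merged = pooled.merge(
            pred, on=["condition", "target_eye", "contrast"], validate="one_to_one"
        )
        p = np.clip(ndtr(merged["dprime"].to_numpy() / 2.0), 1e-6, 1.0 - 1e-6)
        k_corr = merged["n_correct"].to_numpy()
        n_tot = merged["n_trials"].to_numpy()
        lnl = float(np.sum(k_corr * np.log(p) + (n_tot - k_corr) * np.log1p(-p)))
        k_free = len(_free_names(v, m.directional, dict(m.fixed or {})))
        out[v] = {
            "bic": k_free * np.log(len(merged)) - 2.0 * lnl,
            "loglik": lnl,
            "k": k_free,
            "n_cells": len(merged),
        }
    return out


# ---------------------------------------------------------------------------
# identifiability
# ---------------------------------------------------------------------------

@dataclass
class HessianReport:
    hessian: np.ndarray
    singular_values: np.ndarray
    rank: int
    tolerance: float
    smallest_eigvec: np.ndarray
    projections: dict[str, float]


def hessian_rank(
    model: NormalizationModel,
    rel_step: float = 1e-4,
    max_shrink: int = 4,
) -> HessianReport:
    """Central-difference Hessian of the fit objective at the optimum.

    The rank is computed from the singular values with the standard numerical
    tolerance max(dim) * eps * s_max; the eigenvector of the smallest
    eigenvalue is reported with its projection on each free parameter, which
    flags directions (parameters) the data barely constrain.
    """
    f = model.objective_fn_
    x0 = np.asarray(model.x_opt_, dtype=float)
    names = model._names
    dim = x0.size
    step = rel_step * np.maximum(np.abs(x0), 1.0)
    for _ in range(max_shrink + 1):
        H = np.empty((dim, dim))
        f0 = f(x0)
        ok = np.isfinite(f0)
        for i in range(dim):
            for j in range(i, dim):
                ei = np.zeros(dim); ei[i] = step[i]
                ej = np.zeros(dim); ej[j] = step[j]
                if i == j:
                    val = (f(x0 + ei) - 2.0 * f0 + f(x0 - ei)) / step[i] ** 2
                else:
                    val = (
                        f(x0 + ei + ej) - f(x0 + ei - ej)
                        - f(x0 - ei + ej) + f(x0 - ei - ej)
                    ) / (4.0 * step[i] * step[j])
                H[i, j] = H[j, i] = val
                ok = ok and np.isfinite(val)
        if ok:
            break
        step = step / 10.0
    else:  # pragma: no cover
        raise FloatingPointError("non-finite second differences after step shrinking")
    if not ok:
        raise FloatingPointError("non-finite second differences after step shrinking")
    s = np.linalg.svd(H, compute_uv=False)
    tol = dim * np.finfo(float).eps * s.max()
    rank = int(np.sum(s > tol))
    evals, evecs = np.linalg.eigh(H)
    i_min = int(np.argmin(np.abs(evals)))
    vec = evecs[:, i_min]
    return HessianReport(
        hessian=H,
        singular_values=s,
        rank=rank,
        tolerance=tol,
        smallest_eigvec=vec,
        projections={nm: float(vec[i]) for i, nm in enumerate(names)},
    )
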