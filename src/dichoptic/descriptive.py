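"""Descriptive psychometric analysis: d' estimation and Naka-Rushton fits.

Behavioral performance in the two-choice orientation-discrimination task is
summarised per (condition, target contrast) cell as a sensitivity index

    d'(c) = d'_m c^n / (c^n + c50^n),

the Naka-Rushton (hyperbolic ratio) function.  A change of the
semi-saturation contrast ``c50`` is a *contrast-gain* change (horizontal
shift on log contrast); a change of the asymptote ``d'_m`` is a
*response-gain* change.  The exponent is shared across competitor
configurations within an observer.

d' is estimated from the proportion correct of an unbiased observer in a
single-interval two-choice identification: d' = 2 * Phi^-1(PC), with the
proportion clipped away from 0 and 1 by half a trial.  Statistical tests on
parameter differences between conditions use a bootstrap that resamples
individual trials with replacement within each (observer, condition,
contrast) cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import ndtri

__all__ = [
    "naka_rushton",
    "estimate_dprime",
    "cell_counts",
    "dprime_cells",
    "NakaRushtonModel",
    "DescriptiveFit",
    "fit_descriptive",
    "bootstrap_gain_tests",
    "GainTestResult",
]

DM_MAX = 10.0
N_BOUNDS = (0.2, 8.0)


def naka_rushton(c, d_m, c50, n_d):
    """Hyperbolic-ratio psychometric function; d'(0) = 0, d'(c50) = d_m / 2."""
    c = np.asarray(c, dtype=float)
    cn = c ** n_d
    return d_m * cn / (cn + c50 ** n_d)


def estimate_dprime(n_correct, n_trials):
    """d' of an unbiased two-choice observer from correct counts.

    The proportion correct is clipped to [1/(2n), 1 - 1/(2n)] so that perfect
    or chance-floor cells give finite estimates.
    """
    n_correct = np.asarray(n_correct, dtype=float)
    n_trials = np.asarray(n_trials, dtype=float)
    if np.any(n_trials < 1):
        raise ValueError("each cell needs at least one trial")
    if np.any(n_correct < 0) or np.any(n_correct > n_trials):
        raise ValueError("n_correct must lie in [0, n_trials]")
    lo = 1.0 / (2.0 * n_trials)
    p = np.clip(n_correct / n_trials, lo, 1.0 - lo)
    return 2.0 * ndtri(p)


def cell_counts(trials: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a trial table to per-cell (n_trials, n_correct) counts."""
    g = (
        trials.groupby(["observer", "condition", "target_eye", "contrast"], sort=True)
        .agg(n_trials=("correct", "size"), n_correct=("correct", "sum"))
        .reset_index()
    )
    return g


def dprime_cells(trials: pd.DataFrame, grouping: str = "group_average") -> pd.DataFrame:
    """Per-cell d' estimates, optionally averaged across observers.

    ``grouping="per_observer"`` keeps one row per observer cell;
    ``"group_average"`` takes the unweighted mean of the per-observer d'
    estimates within each (condition, target_eye, contrast) cell.
    """
    counts = cell_counts(trials)
    counts["dprime"] = estimate_dprime(counts["n_correct"], counts["n_trials"])
    if grouping == "per_observer":
        return counts
    if grouping == "group_average":
        return (
            counts.groupby(["condition", "target_eye", "contrast"], sort=True)["dprime"]
            .mean()
            .reset_index()
        )
    raise ValueError(f"unknown grouping {grouping!r}")


# ---------------------------------------------------------------------------
# shared-exponent Naka-Rushton fitting
# ---------------------------------------------------------------------------

def _profile_sse(contrasts, Y, n_vals, c50_grids):
    """SSE of the shared-exponent fit on grids, with d_m profiled out.

    contrasts: (nc,); Y: (n_cond, nc) d' estimates; n_vals: (N,);
    c50_grids: (n_cond, M).  For fixed n and c50 the best d_m is the
    linear-least-squares solution, clipped to [0, DM_MAX].
    Returns sse (N, n_cond, M) and dm (N, n_cond, M).
    """
    cn = contrasts[None, :] ** n_vals[:, None]  # (N, nc)
    c50n = c50_grids[None, :, :] ** n_vals[:, None, None]  # (N, n_cond, M)
    phi = cn[:, None, None, :] / (cn[:, None, None, :] + c50n[..., None])  # (N,nc_,M,nc)
    num = np.einsum("nkmc,kc->nkm", phi, Y)
    den = np.einsum("nkmc,nkmc->nkm", phi, phi)
    with np.errstate(invalid="ignore", divide="ignore"):
        dm = np.clip(num / den, 0.0, DM_MAX)
    sse = (Y ** 2).sum(axis=1)[None, :, None] - 2.0 * dm * num + dm ** 2 * den
    return sse, dm


def _parabolic_refine(xs, ys):
    """Vertex of the parabola through three points; falls back to the middle."""
    x0, x1, x2 = xs
    y0, y1, y2 = ys
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    if denom == 0:
        return x1
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 ** 2 * (y0 - y1) + x1 ** 2 * (y2 - y0) + x0 ** 2 * (y1 - y2)) / denom
    if a <= 0:
        return x1
    v = -b / (2 * a)
    return min(max(v, min(xs)), max(xs))


def fit_shared_naka(
    contrasts: np.ndarray,
    Y: np.ndarray,
    c50_bounds: tuple[float, float] | None = None,
    polish: bool = False,
    shared_exponent: bool = True,
):
    """Least-squares Naka-Rushton fit of several conditions at once.

    Two-stage grid search over the shared exponent and per-condition log c50
    with the asymptote profiled out in closed form, followed by parabolic
    refinement (and an optional Levenberg-Marquardt polish).  Deterministic
    and fast enough to sit inside a bootstrap loop.

    Returns a dict with keys n_d (scalar or per-condition array), d_m, c50,
    sse, r_squared, c50_at_bound, dm_at_bound.
    """
    contrasts = np.asarray(contrasts, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n_cond = Y.shape[0]
    if contrasts.size < 2:
        raise ValueError("need at least two contrast levels")
    if c50_bounds is None:
        c50_bounds = (contrasts.min() / 10.0, contrasts.max() * 10.0)
    llo, lhi = np.log(c50_bounds[0]), np.log(c50_bounds[1])

    if not shared_exponent:
        parts = [
            fit_shared_naka(contrasts, Y[k: k + 1], c50_bounds, polish=polish)
            for k in range(n_cond)
        ]
        sse = float(sum(p["sse"] for p in parts))
        sst = float(((Y - Y.mean()) ** 2).sum())
        return {
            "n_d": np.array([p["n_d"] for p in parts]),
            "d_m": np.array([p["d_m"][0] for p in parts]),
            "c50": np.array([p["c50"][0] for p in parts]),
            "sse": sse,
            "r_squared": 1.0 - sse / sst if sst > 0 else np.nan,
            "c50_at_bound": np.array([p["c50_at_bound"][0] for p in parts]),
            "dm_at_bound": np.array([p["dm_at_bound"][0] for p in parts]),
        }

    # stage A: coarse joint grid
    nA = np.geomspace(N_BOUNDS[0], N_BOUNDS[1], 19)
    lcA = np.linspace(llo, lhi, 41)
    gridA = np.broadcast_to(np.exp(lcA), (n_cond, lcA.size))
    sseA, _ = _profile_sse(contrasts, Y, nA, gridA)
    tot = sseA.min(axis=2).sum(axis=1)
    i_n = int(np.argmin(tot))

    # stage B: local grids around the stage-A optimum
    n_lo = nA[max(i_n - 1, 0)]
    n_hi = nA[min(i_n + 1, nA.size - 1)]
    nB = np.geomspace(n_lo, n_hi, 15)
    j_best = np.argmin(sseA[i_n], axis=1)
    step = lcA[1] - lcA[0]
    lcB = np.clip(
        lcA[j_best][:, None] + np.linspace(-step, step, 17)[None, :], llo, lhi
    )
    sseB, dmB = _profile_sse(contrasts, Y, nB, np.exp(lcB))
    totB = sseB.min(axis=2).sum(axis=1)
    i_n = int(np.argmin(totB))

    # stage C: parabolic refinement of n, then of each log c50
    if 0 < i_n < nB.size - 1:
        n_best = _parabolic_refine(np.log(nB[i_n - 1: i_n + 2]), totB[i_n - 1: i_n + 2])
        n_best = float(np.exp(n_best))
    else:
        n_best = float(nB[i_n])
    sseC, dmC = _profile_sse(contrasts, Y, np.array([n_best]), np.exp(lcB))
    sseC, dmC = sseC[0], dmC[0]
    c50 = np.empty(n_cond)
    d_m = np.empty(n_cond)
    sse_cond = np.empty(n_cond)
    for k in range(n_cond):
        j = int(np.argmin(sseC[k]))
        if 0 < j < lcB.shape[1] - 1:
            lc = _parabolic_refine(lcB[k, j - 1: j + 2], sseC[k, j - 1: j + 2])
        else:
            lc = lcB[k, j]
        c50[k] = np.exp(lc)
        s1, dm1 = _profile_sse(
            contrasts, Y[k: k + 1], np.array([n_best]), np.array([[c50[k]]])
        )
        sse_cond[k] = s1[0, 0, 0]
        d_m[k] = dm1[0, 0, 0]

    if polish:
        x0 = np.concatenate([[np.log(n_best)], np.log(np.maximum(d_m, 1e-6)), np.log(c50)])

        def resid(x):
            nd = np.exp(x[0])
            dm = np.exp(x[1: 1 + n_cond])
            cc = np.exp(x[1 + n_cond:])
            pred = np.stack([naka_rushton(contrasts, dm[k], cc[k], nd) for k in range(n_cond)])
            return (pred - Y).ravel()

        lb = np.concatenate(
            [[np.log(N_BOUNDS[0])], np.full(n_cond, np.log(1e-6)), np.full(n_cond, llo)]
        )
        ub = np.concatenate(
            [[np.log(N_BOUNDS[1])], np.full(n_cond, np.log(DM_MAX)), np.full(n_cond, lhi)]
        )
        try:
            sol = least_squares(resid, np.clip(x0, lb, ub), bounds=(lb, ub), xtol=1e-12)
            if sol.cost * 2 < sse_cond.sum():
                n_best = float(np.exp(sol.x[0]))
                d_m = np.exp(sol.x[1: 1 + n_cond])
                c50 = np.exp(sol.x[1 + n_cond:])
                sse_cond = np.array(
                    [
                        ((naka_rushton(contrasts, d_m[k], c50[k], n_best) - Y[k]) ** 2).sum()
                        for k in range(n_cond)
                    ]
                )
        except Exception as exc:  # pragma: no cover - polish failures fall back
            warnings.warn(f"Naka-Rushton polish failed ({exc}); using profile fit")

    sse = float(sse_cond.sum())
    sst = float(((Y - Y.mean()) ** 2).sum())
    rel = np.minimum(c50 / c50_bounds[0], c50_bounds[1] / c50)
    return {
        "n_d": float(n_best),
        "d_m": d_m,
        "c50": c50,
        "sse": sse,
        "r_squared": 1.0 - sse / sst if sst > 0 else np.nan,
        "c50_at_bound": rel < 1.05,
        "dm_at_bound": (d_m <= 1e-5) | (d_m >= DM_MAX * (1 - 1e-9)),
    }


@dataclass
class DescriptiveFit:
    """Result of a descriptive Naka-Rushton analysis."""

    params: pd.DataFrame  # columns: [observer,] condition, d_m, c50, flags
    n_d: dict[str, float] | float
    r_squared: dict[str, float] | float
    grouping: str
    contrasts: np.ndarray = field(repr=False, default=None)


class NakaRushtonModel:
    """Descriptive psychometric model, one curve per competitor condition.

    Shares the exponent across conditions (within an observer) unless
    ``shared_exponent=False``.  Follows the scikit-learn estimator protocol:
    ``fit`` consumes a trial table and sets trailing-underscore attributes.
    """

    def __init__(self, shared_exponent: bool = True, polish: bool = True,
                 grouping: str = "group_average"):
        self.shared_exponent = shared_exponent
        self.polish = polish
        self.grouping = grouping

    # minimal scikit-learn-style parameter plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {
            "shared_exponent": self.shared_exponent,
            "polish": self.polish,
            "grouping": self.grouping,
        }

    def set_params(self, **kw):
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, trials: pd.DataFrame):
        cells = dprime_cells(trials, self.grouping)
        groups = (
            [(None, cells)]
            if self.grouping == "group_average"
            else list(cells.groupby("observer"))
        )
        rows, n_d, r2 = [], {}, {}
        contrasts = None
        for obs, sub in groups:
            piv = sub.pivot_table(index="condition", columns="contrast", values="dprime")
            contrasts = piv.columns.to_numpy(dtype=float)
            Y = piv.to_numpy(dtype=float)
            res = fit_shared_naka(
                contrasts, Y, polish=self.polish, shared_exponent=self.shared_exponent
            )
            key = obs if obs is not None else "group"
            n_d[key] = res["n_d"]
            r2[key] = res["r_squared"]
            for k, cond in enumerate(piv.index):
                rows.append(
                    {
                        "observer": key,
                        "condition": cond,
                        "d_m": float(res["d_m"][k]),
                        "c50": float(res["c50"][k]),
                        "n_d": res["n_d"] if np.isscalar(res["n_d"]) else float(res["n_d"][k]),
                        "c50_at_bound": bool(res["c50_at_bound"][k]),
                        "dm_at_bound": bool(res["dm_at_bound"][k]),
                    }
                )
        self.curves_ = pd.DataFrame(rows)
        self.exponent_ = n_d if self.grouping == "per_observer" else n_d["group"]
        self.r_squared_ = r2 if self.grouping == "per_observer" else r2["group"]
        self.contrasts_ = contrasts
        return self

    def predict(self, condition: str, contrasts, observer: str = "group"):
        """Fitted d'(c) for one condition."""
        row = self.curves_[
            (self.curves_.observer == observer) & (self.curves_.condition == condition)
        ].iloc[0]
        return naka_rushton(np.asarray(contrasts, dtype=float), row.d_m, row.c50, row.n_d)


def fit_descriptive(
    trials: pd.DataFrame,
    grouping: str = "group_average",
    shared_exponent: bool = True,
    polish: bool = True,
) -> DescriptiveFit:
    """Fit Naka-Rushton psychometric functions to a trial table."""
    m = NakaRushtonModel(
        shared_exponent=shared_exponent, polish=polish, grouping=grouping
    ).fit(trials)
    return DescriptiveFit(
        params=m.curves_,
        n_d=m.exponent_,
        r_squared=m.r_squared_,
        grouping=grouping,
        contrasts=m.contrasts_,
    )


# ---------------------------------------------------------------------------
# bootstrap tests for contrast-gain vs response-gain changes
# ---------------------------------------------------------------------------

@dataclass
class GainTestResult:
    """Bootstrap comparison of c50 and d'_m between condition pairs."""

    table: pd.DataFrame  # pair, parameter, delta, ci68, ci95, p_value
    B: int
    seed: int | None
    deltas: dict = field(repr=False, default=None)  # (pair, parameter) -> (B,) array


def _default_pairs(conditions) -> list[tuple[str, str]]:
    pairs = [(c, "none") for c in conditions if c != "none"]
    if "large" in conditions and "split" in conditions:
        pairs.append(("large", "split"))
    return pairs


def bootstrap_gain_tests(
    trials: pd.DataFrame,
    B: int = 2000,
    seed: int | None = None,
    pairs: list[tuple[str, str]] | None = None,
) -> GainTestResult:
    """Bootstrap tests of condition differences in c50 and d'_m.

    Trials are resampled with replacement within each (observer, condition,
    contrast) cell; since a cell's trials are exchangeable Bernoulli outcomes
    the resampled correct count is drawn directly as Binomial(n, p-hat).  Each
    resample is refit per observer (shared exponent) and the per-condition
    parameters are averaged across observers; two-sided p-values are twice the
    smaller tail fraction of the difference distribution, floored at 1/B.
    """
    if B < 100:
        warnings.warn("B < 100 gives unstable bootstrap p-values")
    counts = cell_counts(trials)
    observers = sorted(counts.observer.unique())
    conditions = sorted(counts.condition.unique())
    if pairs is None:
        pairs = _default_pairs(conditions)

    rng = np.random.default_rng(seed)
    # observed (non-resampled) group-average parameters
    fit0 = fit_descriptive(trials, grouping="per_observer", polish=True)
    obs_tab = fit0.params.pivot_table(index="condition", columns="observer")

    piv_n = counts.pivot_table(
        index=["observer", "condition"], columns="contrast", values="n_trials"
    )
    piv_k = counts.pivot_table(
        index=["observer", "condition"], columns="contrast", values="n_correct"
    )
    contrasts = piv_n.columns.to_numpy(dtype=float)
    boot = {
        (pair, par): np.empty(B) for pair in pairs for par in ("c50", "d_m")
    }
    params_b = {par: np.empty((B, len(observers), len(conditions))) for par in ("c50", "d_m")}
    for oi, obs in enumerate(observers):
        n_mat = piv_n.loc[obs].reindex(conditions).to_numpy(dtype=float)
        k_mat = piv_k.loc[obs].reindex(conditions).to_numpy(dtype=float)
        p_mat = k_mat / n_mat
        draws = rng.binomial(
            n_mat.astype(int)[None, :, :], p_mat[None, :, :], size=(B,) + n_mat.shape
        )
        for b in range(B):
            Y = estimate_dprime(draws[b], n_mat)
            res = fit_shared_naka(contrasts, Y, polish=False)
            params_b["c50"][b, oi] = res["c50"]
            params_b["d_m"][b, oi] = res["d_m"]
    group = {par: params_b[par].mean(axis=1) for par in ("c50", "d_m")}  # (B, n_cond)
    idx = {c: i for i, c in enumerate(conditions)}
    rows = []
    for pair in pairs:
        a, b_ = pair
        for par in ("c50", "d_m"):
            delta = group[par][:, idx[a]] - group[par][:, idx[b_]]
            boot[(pair, par)] = delta
            lo = np.mean(delta <= 0.0)
            hi = np.mean(delta >= 0.0)
            p = min(1.0, max(2.0 * min(lo, hi), 1.0 / B))
            obs_delta = float(
                obs_tab[par].loc[a].mean() - obs_tab[par].loc[b_].mean()
            )
            rows.append(
                {
                    "pair": f"{a} - {b_}",
                    "parameter": par,
                    "delta": obs_delta,
                    "ci68_lo": float(np.percentile(delta, 16.0)),
                    "ci68_hi": float(np.percentile(delta, 84.0)),
                    "ci95_lo": float(np.percentile(delta, 2.5)),
                    "ci95_hi": float(np.percentile(delta, 97.5)),
                    "p_value": p,
                }
            )
    return GainTestResult(table=pd.DataFrame(rows), B=B, seed=seed, deltas=boot)
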