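"""Effective-wavelength selection: CARS, SPA (with SPXY splitting) and random frog.

All three selectors reduce a full spectrum (hundreds of collinear bands) to a
small informative subset before calibration modeling:

* CARS (competitive adaptive reweighted sampling) runs a sequence of Monte
  Carlo PLS fits; each run keeps an exponentially decreasing fraction of bands
  (enforced by the EDF schedule) ranked by |PLS coefficient|, then resamples
  the survivors with coefficient-proportional weights (ARS).  The subset with
  minimal 10-fold RMSECV across runs wins.
* SPA (successive projections algorithm) grows chains of mutually
  least-collinear bands by orthogonal projections, scores each candidate
  subset by PRESS of a linear model on an SPXY calibration/test split, and
  returns the smallest subset not significantly worse than the PRESS minimum
  under an F-test.
* Random frog walks a reversible chain over band subsets, accepting proposals
  by the ratio of cross-validated PLS performance, and reports each band's
  selection probability (fraction of chain states containing it).

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pls import pls_fit, rmsecv

__all__ = [
    "CARSConfig",
    "SPAConfig",
    "FrogConfig",
    "WavelengthSubset",
    "cars_select",
    "spxy_split",
    "spa_select",
    "random_frog_select",
    "variable_reduction",
]


@dataclass(frozen=True)
class CARSConfig:
    """CARS sampling loop parameters (defaults follow the study settings)."""

    n_runs: int = 50
    calibration_fraction: float = 0.8
    max_lv: int = 14
    cv_folds: int = 10
    edf_start_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.calibration_fraction < 1:
            raise ValueError("calibration fraction must lie in (0, 1)")
        if self.n_runs < 2:
            raise ValueError("CARS needs at least 2 sampling runs")


@dataclass(frozen=True)
class SPAConfig:
    """SPA parameters: candidate chain length, SPXY split and F-test level."""

    m_max: int = 50
    test_ratio: float = 1.0 / 3.0
    standardize: bool = True
    f_alpha: float = 0.25

    def __post_init__(self) -> None:
        if self.m_max < 1:
            raise ValueError("m_max must be >= 1")
        if not 0 < self.test_ratio < 1:
            raise ValueError("test ratio must lie in (0, 1)")


@dataclass(frozen=True)
class FrogConfig:
    """Random-frog chain parameters (defaults follow the study settings)."""

    n_iterations: int = 2000
    q_init: int = 2
    resize_sd_factor: float = 0.3     # SD of proposed size, relative to current
    candidate_oversample: float = 3.0  # grow moves draw this many times the deficit
    acceptance_bias: float = 0.1      # temperature: damps acceptance of worse subsets
    max_lv: int = 10
    cv_folds: int = 5
    top_k_range: tuple[int, int] = (2, 30)
    probability_threshold: float | None = None   # None -> top-k rule
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")
        if self.q_init < 1:
            raise ValueError("initial subset size Q must be >= 1")


@dataclass
class WavelengthSubset:
    """Ordered retained band indices plus selector diagnostics."""

    indices: np.ndarray
    selector: str
    diagnostics: dict = field(default_factory=dict)
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise ValueError("a wavelength subset cannot be empty")
        if len(np.unique(self.indices)) != self.indices.size:
            raise ValueError("band indices must be unique")

    def __len__(self) -> int:
        return int(self.indices.size)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"band_index": self.indices})
        if self.wavelengths is not None:
            df["wavelength_nm"] = self.wavelengths[self.indices]
        score = self.diagnostics.get("band_scores")
        if score is not None:
            df["score"] = np.asarray(score)[self.indices]
        return df


def _abs_coef_ranking(X, y, cols, n_lv, rng=None, calib_fraction=None):
    """|PLS coefficient| per column of X[:, cols]; optional random calibration split."""
    rows = np.arange(X.shape[0])
    if calib_fraction is not None:
        n_cal = max(2, int(round(calib_fraction * rows.size)))
        rows = rng.choice(rows, size=n_cal, replace=False)
    a = min(n_lv, rows.size - 1, len(cols))
    model = pls_fit(X[np.ix_(rows, cols)], y[rows], a)
    return np.abs(model.coef)


def cars_select(X, y, config: CARSConfig = CARSConfig()) -> WavelengthSubset:
    """Competitive adaptive reweighted sampling.

    Per run i of N: fit PLS on a random calibration split of the surviving
    bands, rank by |coefficient|, keep the top ``r_i`` fraction with
    ``r_i = a * exp(-k * i)`` decaying from all bands at run 1 to 2 bands at
    run N (the EDF schedule), then adaptively resample the survivors with
    probability proportional to |coefficient|.  Each run's subset is scored by
    k-fold RMSECV; the minimizer is returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 3:
        raise ValueError("CARS needs at least 3 bands")
    rng = np.random.default_rng(config.seed)
    N = config.n_runs
    # EDF through (1, start_ratio) and (N, 2/p)
    end_ratio = 2.0 / p
    k = np.log(config.edf_start_ratio / end_ratio) / (N - 1)
    a_edf = config.edf_start_ratio * np.exp(k)

    retained = np.arange(p)
    subsets, errors, sizes, ratios = [], [], [], []
    for i in range(1, N + 1):
        try:
            w = _abs_coef_ranking(
                X, y, retained, config.max_lv, rng, config.calibration_fraction
            )
        except ValueError as exc:
            raise ValueError(f"PLS failed at CARS run {i}: {exc}") from exc
        r_i = a_edf * np.exp(-k * i)
        n_keep = int(round(min(r_i, 1.0) * p))
        n_keep = max(2, min(n_keep, retained.size))
        # enforced wavelength reduction: top coefficients, ties -> lower index
        order = np.lexsort((retained, -w))
        kept = retained[order[:n_keep]]
        kept_w = w[order[:n_keep]]
        # adaptive reweighted sampling among the survivors
        if kept_w.sum() > 0:
            draw = rng.choice(kept, size=n_keep, replace=True, p=kept_w / kept_w.sum())
            retained = np.unique(draw)
        else:
            retained = np.sort(kept)
        if retained.size < 2:
            retained = np.sort(kept)[:2]
        a_cv = min(config.max_lv, retained.size)
        err = rmsecv(X[:, retained], y, a_cv, folds=config.cv_folds,
                     seed=int(rng.integers(2**31)))
        subsets.append(retained.copy())
        errors.append(err)
        sizes.append(retained.size)
        ratios.append(min(r_i, 1.0))

    best = int(np.argmin(errors))
    return WavelengthSubset(
        indices=np.sort(subsets[best]),
        selector="CARS",
        diagnostics={
            "rmsecv": np.array(errors),
            "subset_sizes": np.array(sizes),
            "edf_ratio": np.array(ratios),
            "best_run": best,
            "best_rmsecv": errors[best],
        },
    )


def spxy_split(X, y, test_ratio: float = 1.0 / 3.0):
    """Sample-set partitioning by joint X-y distance (Kennard-Stone style).

    Pairwise distances in X and y are each normalized by their maximum and
    summed; the calibration set greedily collects the most mutually distant
    samples, starting from the globally most distant pair.  Fully
    deterministic; ties break toward lower sample index.

    Returns ``(calibration_indices, test_indices)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("SPXY needs at least 3 samples")
    if not 0 < test_ratio < 1:
        raise ValueError("test ratio must lie in (0, 1)")
    dx = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    dy = np.abs(y[:, None] - y[None, :])
    mx, my = dx.max(), dy.max()
    d = (dx / mx if mx > 0 else dx) + (dy / my if my > 0 else dy)

    n_test = int(round(n * test_ratio))
    n_test = min(max(n_test, 1), n - 2)
    n_cal = n - n_test

    seed_d = d.copy()
    np.fill_diagonal(seed_d, -np.inf)   # a sample cannot pair with itself
    flat = int(np.argmax(seed_d))       # ties resolve to the lowest index pair
    sel = [flat // n, flat % n]
    remaining = [i for i in range(n) if i not in sel]
    while len(sel) < n_cal:
        dmin = d[np.ix_(remaining, sel)].min(axis=1)
        pick = remaining[int(np.argmax(dmin))]
        sel.append(pick)
        remaining.remove(pick)
    return np.sort(np.array(sel)), np.sort(np.array(remaining))


def _spa_chain(Xc: np.ndarray, start: int, m_max: int) -> list[int]:
    """Chain of successively most-orthogonal columns starting at ``start``."""
    Z = Xc.copy()
    chain = [start]
    z = Z[:, start].copy()
    for _ in range(m_max - 1):
        nz = z @ z
        if nz < 1e-12:
            break
        Z = Z - np.outer(z, (z @ Z) / nz)      # project all columns off z
        norms = np.einsum("ij,ij->j", Z, Z)
        norms[chain] = -1.0
        j = int(np.argmax(norms))
        if norms[j] < 1e-12:                   # nothing left outside the span
            break
        chain.append(j)
        z = Z[:, j].copy()
    return chain


def _press_linear(X_cal, y_cal, X_test, y_test, cols) -> float:
    A = np.column_stack([np.ones(len(y_cal)), X_cal[:, cols]])
    beta, *_ = np.linalg.lstsq(A, y_cal, rcond=None)
    pred = np.column_stack([np.ones(len(y_test)), X_test[:, cols]]) @ beta
    r = y_test - pred
    return float(r @ r)


def spa_select(X, y, config: SPAConfig = SPAConfig()) -> WavelengthSubset:
    """Successive projections algorithm with PRESS/F-test subset sizing."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    cal_idx, test_idx = spxy_split(X, y, config.test_ratio)
    m_max = min(config.m_max, len(cal_idx) - 1, p)
    if m_max < 1:
        raise ValueError("m_max too large for the calibration sample count")
    if config.standardize:
        mu, sd = X[cal_idx].mean(axis=0), X[cal_idx].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
    else:
        Xs = X
    X_cal, X_test = Xs[cal_idx], Xs[test_idx]
    y_cal, y_test = y[cal_idx], y[test_idx]

    best_chain_for_m: dict[int, tuple[float, list[int]]] = {}
    for start in range(p):
        chain = _spa_chain(X_cal, start, m_max)
        for m in range(1, len(chain) + 1):
            cols = chain[:m]
            press = _press_linear(X_cal, y_cal, X_test, y_test, cols)
            if m not in best_chain_for_m or press < best_chain_for_m[m][0]:
                best_chain_for_m[m] = (press, cols)

    sizes = sorted(best_chain_for_m)
    press_by_m = np.array([best_chain_for_m[m][0] for m in sizes])
    press_min = press_by_m.min()
    # smallest subset whose PRESS is not significantly worse than the minimum
    f_crit = stats.f.ppf(1.0 - config.f_alpha, len(test_idx), len(test_idx))
    ok = press_by_m <= f_crit * press_min
    m_sel = sizes[int(np.argmax(ok))]
    cols = best_chain_for_m[m_sel][1]
    return WavelengthSubset(
        indices=np.sort(np.array(cols)),
        selector="SPA",
        diagnostics={
            "press_by_size": dict(zip(sizes, press_by_m)),
            "press_min": float(press_min),
            "selected_size": m_sel,
            "f_critical": float(f_crit),
            "calibration_indices": cal_idx,
            "test_indices": test_idx,
        },
    )


def random_frog_select(X, y, config: FrogConfig = FrogConfig()) -> WavelengthSubset:
    """Random frog: a stochastic chain over band subsets.

    Each iteration proposes a resized candidate subset (shrink: keep the
    highest-|PLS coefficient| members; grow: add uniformly drawn outsiders)
    and accepts it outright when it improves the cross-validated RMSE, or with
    probability ``acceptance_bias * RMSECV_current / RMSECV_candidate`` when it
    does not (the damping keeps the chain near good subsets).
    A band's selection probability is the fraction of chain states containing
    it.  The returned subset is the top-k by probability with k minimizing
    RMSECV (or all bands above ``probability_threshold`` when set).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if config.q_init > p:
        raise ValueError("initial subset size Q exceeds the number of bands")
    rng = np.random.default_rng(config.seed)

    def perf(cols: np.ndarray) -> float:
        a = min(config.max_lv, len(cols))
        return rmsecv(X[:, cols], y, a, folds=min(config.cv_folds, n), seed=7)

    V = np.sort(rng.choice(p, size=config.q_init, replace=False))
    rmse_V = perf(V)
    counts = np.zeros(p)
    trace = []
    for _ in range(config.n_iterations):
        counts[V] += 1          # chain state at the start of the iteration
        q_star = int(round(rng.normal(V.size, config.resize_sd_factor * V.size)))
        q_star = max(1, min(p, q_star))
        if q_star < V.size:
            w = _abs_coef_ranking(X, y, V, config.max_lv)
            order = np.lexsort((V, -w))
            V_star = np.sort(V[order[:q_star]])
        elif q_star > V.size:
            # grow: oversampled random pool, trimmed back to q_star by |coefficient|
            outside = np.setdiff1d(np.arange(p), V, assume_unique=False)
            n_draw = min(
                int(round(config.candidate_oversample * (q_star - V.size))),
                outside.size,
            )
            pool = np.sort(np.concatenate([V, rng.choice(outside, size=n_draw,
                                                         replace=False)]))
            if pool.size > q_star:
                w = _abs_coef_ranking(X, y, pool, config.max_lv)
                order = np.lexsort((pool, -w))
                V_star = np.sort(pool[order[:q_star]])
            else:
                V_star = pool
        else:
            V_star = V
        rmse_star = perf(V_star) if V_star.size != V.size or not np.array_equal(
            V_star, V) else rmse_V
        accept = rmse_star <= rmse_V or (
            rng.uniform() < config.acceptance_bias * rmse_V / rmse_star
        )
        if accept:
            V, rmse_V = V_star, rmse_star
        trace.append((V.size, rmse_V))

    prob = counts / config.n_iterations
    if config.probability_threshold is not None:
        chosen = np.where(prob > config.probability_threshold)[0]
        if chosen.size == 0:
            chosen = np.array([int(np.argmax(prob))])
    else:
        order = np.lexsort((np.arange(p), -prob))
        lo, hi = config.top_k_range
        hi = min(hi, p)
        best_k, best_err = lo, np.inf
        for kk in range(lo, hi + 1):
            err = perf(np.sort(order[:kk]))
            if err < best_err:
                best_k, best_err = kk, err
        chosen = np.sort(order[:best_k])
    return WavelengthSubset(
        indices=np.sort(chosen),
        selector="RF",
        diagnostics={
            "selection_probability": prob,
            "band_scores": prob,
            "chain": trace,
        },
    )


def variable_reduction(total_bands: int, retained) -> float:
    """Percentage of variables removed, reported to 2 decimals.

    ``retained`` may be a WavelengthSubset or a plain count.
    """
    k = len(retained) if not isinstance(retained, (int, np.integer)) else int(retained)
    if k <= 0 or k > total_bands:
        raise ValueError("retained count must be in 1..total_bands")
    return round(100.0 * (1.0 - k / total_bands), 2)
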