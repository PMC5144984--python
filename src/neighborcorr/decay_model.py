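"""Sliding-median smoothing and exponential distance-decay fitting.

Pair correlations sorted by intergenic distance are smoothed with a sliding
median (window advanced one pair at a time), then fitted to

    rho(d) = rho0 * exp(-lambda * d) + c

by bounded nonlinear least squares.  The characteristic correlation distance
is ``dexp = 1 / lambda`` — the mean distance over which a pair of gene
neighbors remain transcriptionally correlated above the baseline ``c``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1000

#: fitted lambda values at or below this bound (per bp) are unidentifiable
LAMBDA_FLOOR = 1e-15


@dataclass
class SmoothedCurve:
    """Sliding-median statistic versus distance.

    ``distances`` are per-window median distances (bp, non-decreasing);
    ``values`` per-window median statistics; ``q25``/``q75`` the per-window
    interquartile band.
    """

    distances: np.ndarray
    values: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    window: int
    statistic_name: str = "rho"

    def __len__(self) -> int:
        return len(self.distances)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "distance_bp": self.distances,
                f"median_{self.statistic_name}": self.values,
                "q25": self.q25,
                "q75": self.q75,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class DecayFit:
    """Fitted exponential decay parameters and diagnostics.

    ``dexp = 1/lam`` is reported in bp.  ``converged`` is False when the
    optimizer failed, the decay rate collapsed to its lower bound, or the
    amplitude is indistinguishable from zero — in all of which cases ``dexp``
    is unreliable.
    """

    rho0: float
    lam: float
    c: float
    dexp: float
    rss: float
    converged: bool
    n_points: int

    def to_dict(self) -> dict:
        d = asdict(self)
        return {
            "rho0": d["rho0"],
            "lambda_per_bp": d["lam"],
            "c": d["c"],
            "dexp_bp": d["dexp"],
            "rss": d["rss"],
            "converged": d["converged"],
            "n_points": d["n_points"],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def sliding_median(
    records: pd.DataFrame | np.ndarray,
    window: int = DEFAULT_WINDOW,
    value_col: str = "rho",
    distance_col: str = "distance_bp",
    statistic_name: str | None = None,
) -> SmoothedCurve:
    """Smooth (distance, value) records with a sliding median, step 1.

    Records are sorted by distance ascending; each contiguous window of
    ``window`` records emits its median distance, median value, and the 25th
    and 75th value percentiles.  ``records`` may be a DataFrame with
    ``distance_col``/``value_col`` columns or an (n, 2) array.
    """
    if isinstance(records, pd.DataFrame):
        d = records[distance_col].to_numpy(dtype=float)
        v = records[value_col].to_numpy(dtype=float)
    else:
        arr = np.asarray(records, dtype=float)
        d, v = arr[:, 0], arr[:, 1]
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if len(d) < window:
        raise ValueError(
            f"{len(d)} records < window {window}; use a smaller window"
        )
    order = np.argsort(d, kind="stable")
    d, v = d[order], v[order]

    ds = pd.Series(d)
    vs = pd.Series(v)
    med_d = ds.rolling(window).median().to_numpy()[window - 1 :]
    med_v = vs.rolling(window).median().to_numpy()[window - 1 :]
    q25 = vs.rolling(window).quantile(0.25).to_numpy()[window - 1 :]
    q75 = vs.rolling(window).quantile(0.75).to_numpy()[window - 1 :]
    return SmoothedCurve(
        distances=med_d,
        values=med_v,
        q25=q25,
        q75=q75,
        window=window,
        statistic_name=statistic_name or value_col,
    )


def _initial_guess(
    d: np.ndarray, v: np.ndarray, bounds: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Derivative-free start: baseline from the far decile, amplitude from
    the near decile, rate from the 1/e crossing distance."""
    n = len(d)
    tenth = max(1, n // 10)
    c0 = float(np.median(v[-tenth:]))
    rho0_0 = float(np.median(v[:tenth]) - c0)
    target = c0 + rho0_0 / np.e
    below = np.flatnonzero(v <= target) if rho0_0 > 0 else np.array([])
    if below.size and d[below[0]] > 0:
        lam0 = 1.0 / d[below[0]]
    else:
        dmed = float(np.median(d))
        lam0 = 1.0 / dmed if dmed > 0 else 1.0
    x0 = np.array([rho0_0, lam0, c0])
    lo, hi = bounds
    return np.clip(x0, lo + 1e-12, np.where(np.isinf(hi), x0, hi - 1e-12))


def fit_exponential_decay(
    curve: SmoothedCurve,
    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    | None = None,
) -> DecayFit:
    """Fit ``rho(d) = rho0 * exp(-lam * d) + c`` to a smoothed curve.

    Unweighted least squares with box bounds (defaults: rho0 in [0, 2],
    lam > 0, c in [-1, 1]).  ``dexp = 1/lam``.  ``converged`` is False when
    the optimizer fails or the solution is degenerate (rate at its floor or
    amplitude ~ 0), in which case ``dexp`` should not be trusted.
    """
    d = np.asarray(curve.distances, dtype=float)
    v = np.asarray(curve.values, dtype=float)
    if len(d) < 10:
        raise ValueError(f"need >= 10 points to fit, got {len(d)}")

    if bounds is None:
        bounds = ((0.0, 2.0), (LAMBDA_FLOOR, np.inf), (-1.0, 1.0))
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    # guard the rate's lower edge so 1/lam stays finite
    lo[1] = max(lo[1], LAMBDA_FLOOR)
    x0 = _initial_guess(d, v, (lo, hi))

    def residuals(p: np.ndarray) -> np.ndarray:
        return p[0] * np.exp(-p[1] * d) + p[2] - v

    try:
        res = scipy.optimize.least_squares(
            residuals,
            x0,
            bounds=(lo, hi),
            method="trf",
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
            max_nfev=10_000,
        )
        success = bool(res.success)
        rho0, lam, c = res.x
        rss = float(2 * res.cost)
    except Exception as exc:  # pragma: no cover - optimizer pathologies
        logger.warning("decay fit failed: %s", exc)
        rho0, lam, c = x0
        rss = float(np.sum(residuals(x0) ** 2))
        success = False

    at_floor = lam <= lo[1] * 10
    amp_scale = max(abs(v.max() - v.min()), 1e-12)
    flat = rho0 < 1e-6 * max(amp_scale, 1.0)
    converged = success and not at_floor and not flat
    if not converged:
        logger.info(
            "decay fit unreliable (success=%s, rate at floor=%s, flat=%s)",
            success,
            at_floor,
            flat,
        )
    return DecayFit(
        rho0=float(rho0),
        lam=float(lam),
        c=float(c),
        dexp=float(1.0 / lam),
        rss=rss,
        converged=converged,
        n_points=len(d),
    )


def fit_raw_pairs(
    records: pd.DataFrame,
    value_col: str = "rho",
    distance_col: str = "distance_bp",
    bounds=None,
) -> DecayFit:
    """Sensitivity-analysis variant: fit the decay model on raw (unsmoothed)
    pairs rather than the sliding-median curve."""
    d = records[distance_col].to_numpy(dtype=float)
    v = records[value_col].to_numpy(dtype=float)
    order = np.argsort(d, kind="stable")
    curve = SmoothedCurve(
        distances=d[order],
        values=v[order],
        q25=np.full(len(d), np.nan),
        q75=np.full(len(d), np.nan),
        window=1,
        statistic_name=value_col,
    )
    return fit_exponential_decay(curve, bounds=bounds)
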