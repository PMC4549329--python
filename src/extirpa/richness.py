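"""Species-richness estimation from incidence data.

Implements the incidence-based coverage estimator (ICE) of total species
richness, randomized species-accumulation curves over sampling units, and a
saturating ("logistic power") fit to cumulative cryptic-species discovery,
y = a / (1 + b * x**-c), whose asymptote ``a`` estimates the number of
cryptic lineages awaiting discovery.

ICE follows the classic Lee-Chao construction: species found in at most
``rare_threshold`` sampling units are "infrequent"; with Q_j the number of
species found in exactly j units, N_infr = sum(j * Q_j), sample coverage
C_ICE = 1 - Q_1 / N_infr, and m_infr the number of units holding at least
one infrequent species,

    ICE = S_freq + S_infr / C_ICE + (Q_1 / C_ICE) * gamma2
    gamma2 = max[(S_infr / C_ICE) * (m_infr / (m_infr - 1))
                 * sum(j * (j-1) * Q_j) / N_infr**2 - 1, 0].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "IncidenceMatrix",
    "ICEEstimate",
    "AccumulationCurve",
    "AsymptoteFit",
    "as_incidence",
    "ice_estimate",
    "accumulation_curve",
    "fit_cryptic_asymptote",
]


@dataclass
class IncidenceMatrix:
    """Binary species x sampling-unit incidence."""

    entries: np.ndarray  # shape (n_species, n_units), bool
    species_labels: list[str]
    unit_labels: list[str]

    @property
    def n_species(self) -> int:
        return self.entries.shape[0]

    @property
    def n_units(self) -> int:
        return self.entries.shape[1]


def as_incidence(data) -> IncidenceMatrix:
    """Coerce a DataFrame/array of counts or presences to binary incidence.

    Empty species rows are dropped (species never seen carry no incidence
    information), with a warning if any are found.
    """
    if isinstance(data, IncidenceMatrix):
        return data
    if isinstance(data, pd.DataFrame):
        entries = data.to_numpy() > 0
        species = [str(s) for s in data.index]
        units = [str(u) for u in data.columns]
    else:
        arr = np.asarray(data)
        entries = arr > 0
        species = [f"sp{i}" for i in range(entries.shape[0])]
        units = [f"u{j}" for j in range(entries.shape[1])]
    keep = entries.any(axis=1)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} species with no incidences", stacklevel=2
        )
        entries = entries[keep]
        species = [s for s, k in zip(species, keep) if k]
    return IncidenceMatrix(entries=entries, species_labels=species, unit_labels=units)


@dataclass
class ICEEstimate:
    """ICE point estimate plus the quantities entering the formula."""

    s_obs: int
    s_freq: int
    s_infr: int
    q: dict[int, int]
    n_infr: int
    c_ice: float
    m_infr: int
    gamma2: float
    ice: float
    sd: float | None = None
    fallback: bool = False
    fallback_reason: str | None = None


def _ice_point(entries: np.ndarray, rare_threshold: int) -> ICEEstimate:
    unit_counts = entries.sum(axis=1).astype(int)
    unit_counts = unit_counts[unit_counts > 0]
    s_obs = int(unit_counts.size)
    infrequent = unit_counts <= rare_threshold
    s_infr = int(infrequent.sum())
    s_freq = s_obs - s_infr
    q = {
        j: int((unit_counts[infrequent] == j).sum())
        for j in range(1, rare_threshold + 1)
    }
    n_infr = int(sum(j * qj for j, qj in q.items()))
    infra_entries = entries[entries.sum(axis=1) > 0][infrequent]
    m_infr = int(infra_entries.any(axis=0).sum()) if s_infr else 0

    def fallback(reason: str) -> ICEEstimate:
        return ICEEstimate(
            s_obs=s_obs, s_freq=s_freq, s_infr=s_infr, q=q, n_infr=n_infr,
            c_ice=0.0 if n_infr else 1.0, m_infr=m_infr, gamma2=0.0,
            ice=float(s_obs), fallback=True, fallback_reason=reason,
        )

    if s_infr == 0:
        est = fallback("no infrequent species; ICE = S_obs")
        est.c_ice = 1.0
        est.fallback = False
        est.fallback_reason = None
        return est
    q1 = q.get(1, 0)
    c_ice = 1.0 - q1 / n_infr
    if c_ice <= 0.0:
        return fallback("all infrequent species are uniques (C_ICE = 0)")
    if m_infr < 2:
        return fallback("fewer than 2 units with infrequent species")
    sum_jj1 = sum(j * (j - 1) * qj for j, qj in q.items())
    gamma2 = max(
        (s_infr / c_ice) * (m_infr / (m_infr - 1)) * sum_jj1 / n_infr**2 - 1.0, 0.0
    )
    ice = s_freq + s_infr / c_ice + (q1 / c_ice) * gamma2
    return ICEEstimate(
        s_obs=s_obs, s_freq=s_freq, s_infr=s_infr, q=q, n_infr=n_infr,
        c_ice=c_ice, m_infr=m_infr, gamma2=gamma2, ice=float(ice),
    )


def ice_estimate(
    incidence,
    rare_threshold: int = 10,
    n_perm: int = 100,
    seed: int | None = None,
) -> ICEEstimate:
    """ICE richness with a resampling dispersion.

    ``sd`` is the standard deviation of the ICE point estimate over
    ``n_perm`` bootstrap resamples of the sampling units (resampling units
    with replacement); set ``n_perm=0`` to skip it.
    """
    inc = as_incidence(incidence)
    if inc.n_units < 2:
        raise ValueError("ICE needs at least 2 sampling units")
    est = _ice_point(inc.entries, rare_threshold)
    if n_perm:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_perm)
        for b in range(n_perm):
            cols = rng.integers(0, inc.n_units, size=inc.n_units)
            boots[b] = _ice_point(inc.entries[:, cols], rare_threshold).ice
        est.sd = float(boots.std(ddof=1))
    return est


@dataclass
class AccumulationCurve:
    """Mean randomized species-accumulation curve over sampling units."""

    n_units: np.ndarray
    mean_richness: np.ndarray
    sd_richness: np.ndarray
    n_perm: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_units": self.n_units, "mean_richness": self.mean_richness,
             "sd_richness": self.sd_richness}
        )


def accumulation_curve(
    incidence, n_perm: int = 100, seed: int | None = None
) -> AccumulationCurve:
    """Randomized accumulation of species over unit orderings.

    Every ordering ends at the observed richness; the mean over orderings is
    monotone non-decreasing by construction.
    """
    inc = as_incidence(incidence)
    if inc.n_units == 0:
        raise ValueError("no sampling units")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    curves = np.empty((n_perm, inc.n_units))
    for p in range(n_perm):
        order = rng.permutation(inc.n_units)
        seen = np.zeros(inc.n_species, dtype=bool)
        for k, u in enumerate(order):
            seen |= inc.entries[:, u]
            curves[p, k] = seen.sum()
    return AccumulationCurve(
        n_units=np.arange(1, inc.n_units + 1),
        mean_richness=curves.mean(axis=0),
        sd_richness=curves.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(inc.n_units),
        n_perm=n_perm,
    )


@dataclass
class AsymptoteFit:
    """Fit of y = a / (1 + b x^-c) to a cumulative discovery curve."""

    a: float
    b: float
    c: float
    rss: float
    converged: bool
    n_points: int = 0

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a / (1.0 + self.b * x ** (-self.c))


def _lp_model(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    a, b, c = np.exp(params)  # optimize on log scale: a, b, c > 0
    return a / (1.0 + b * x ** (-c))


def fit_cryptic_asymptote(x, y, n_starts: int = 8, seed: int = 0) -> AsymptoteFit:
    """Least-squares logistic-power fit with multi-start optimization.

    ``x`` must be strictly increasing (cumulative individuals processed) and
    ``y`` non-decreasing (cumulative species discovered).  The asymptote
    ``a`` estimates the total number of species discoverable by the process.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 (x, y) points")
    if not np.all(np.diff(x) > 0):
        raise ValueError("x must be strictly increasing")
    if np.any(np.diff(y) < 0):
        raise ValueError("y must be non-decreasing")
    if np.all(y == 0):
        return AsymptoteFit(a=0.0, b=1.0, c=1.0, rss=0.0, converged=False,
                            n_points=x.size)

    y_max = y.max()
    rng = np.random.default_rng(seed)
    best = None
    starts = [(max(y_max, 1.0) * f, b0, c0)
              for f in (1.05, 1.5, 3.0)
              for b0 in (1.0, float(np.median(x)))
              for c0 in (0.5, 1.0)]
    while len(starts) < n_starts + 12:
        starts.append(
            (y_max * rng.uniform(1.01, 5.0), rng.uniform(0.1, 2 * x.max()),
             rng.uniform(0.2, 3.0))
        )
    for a0, b0, c0 in starts[: n_starts + 12]:
        p0 = np.log([a0, b0, c0])
        try:
            res = least_squares(lambda p: _lp_model(p, x) - y, p0, method="lm",
                                max_nfev=5000)
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0] - 1e-12:
            best = (rss, res)
    if best is None:
        return AsymptoteFit(a=float(y_max), b=1.0, c=1.0, rss=float("inf"),
                            converged=False, n_points=x.size)
    rss, res = best
    a, b, c = np.exp(res.x)
    converged = bool(res.success) and np.isfinite(rss)
    return AsymptoteFit(a=float(a), b=float(b), c=float(c), rss=rss,
                        converged=converged, n_points=x.size)
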