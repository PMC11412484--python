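"""Synthetic annual-best panel generator.

Emulates the statistical structure the record analysis assumes: each
event's annual best fluctuates as a Gaussian around a level that is either
stationary (the null regime — pure random fluctuation, no systematic
progression) or drifts linearly (the systematic-improvement regime).
Fluctuations may be correlated across events through a user-supplied
correlation matrix, but are independent across years by default (an AR(1)
knob exists, off by default).

The generative model, on a "performance" scale where larger is better:

    perf_e(t) = drift_e * (t - t0) + sigma_e * z_{e,t}
    mark_e(t) = level_e - perf_e(t)   (minimize events, native scale)
              = level_e + perf_e(t)   (maximize events)

where the z_{.,t} are standard Gaussians with the specified cross-event
correlation.  Positive drift therefore always means improvement, and a
planted positive z-correlation between any two events shows up as a
positive TSRF correlation regardless of their directions.

The packaged default spec mimics the shape of the real 24-event 1992-2018
panel: realistic world-class levels, a correlated swim+sprint+marathon
block with mild improvement drift, and an uncorrelated remainder with
slight negative drift.

Also provides seeded Monte-Carlo sampling of iid-Gaussian maxima for
validating the extreme-value prediction model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .records import (
    MAXIMIZE,
    MINIMIZE,
    METERS,
    SECONDS,
    AnnualBestSeries,
    EventCatalog,
    PanelError,
    load_default_catalog,
)

DEFAULT_YEARS = (1992, 2018)


@dataclass
class EventSpec:
    """Generative parameters for one event.

    level : stationary annual-best level (native units, > 0)
    sigma : sd of the annual fluctuation (same units, >= 0)
    drift : mean improvement per year (same units, signed; positive always
            means the event gets better, whatever its direction)
    """

    event_id: str
    direction: str
    unit: str
    level: float
    sigma: float
    drift: float = 0.0

    def __post_init__(self) -> None:
        if self.level <= 0:
            raise PanelError(f"{self.event_id}: level must be positive")
        if self.sigma < 0:
            raise PanelError(f"{self.event_id}: sigma must be nonnegative")


@dataclass
class PanelSpec:
    """Full specification of a synthetic panel.

    ``correlation`` is the cross-event correlation matrix of the
    fluctuation terms (unit diagonal, symmetric PSD); None means identity.
    ``ar1`` adds lag-one autocorrelation across years (default 0 = none).
    """

    events: list[EventSpec]
    correlation: np.ndarray | None = None
    years: tuple[int, int] = DEFAULT_YEARS
    seed: int = 0
    ar1: float = 0.0
    #: Drift accumulates as drift * max(0, t - drift_start_year); None means
    #: the first panel year.  Setting it to the last fit-window year starts
    #: a systematic-improvement regime only after a stationary baseline.
    drift_start_year: int | None = None

    def __post_init__(self) -> None:
        ids = [e.event_id for e in self.events]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate event_id in panel spec")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            k = len(self.events)
            if C.shape != (k, k):
                raise PanelError(f"correlation must be {k}x{k}, got {C.shape}")
            if not np.allclose(C, C.T):
                raise PanelError("correlation matrix is not symmetric")
            if not np.allclose(np.diag(C), 1.0):
                raise PanelError("correlation matrix must have unit diagonal")
            self.correlation = C
        if not (-1.0 < self.ar1 < 1.0):
            raise PanelError(f"ar1 must be in (-1, 1), got {self.ar1}")


def _correlated_noise(spec: PanelSpec, rng: np.random.Generator) -> np.ndarray:
    """(years x events) standard-normal draws with the spec's structure."""
    t0, t1 = spec.years
    n_years = t1 - t0 + 1
    k = len(spec.events)
    eps = rng.standard_normal((n_years, k))
    if spec.correlation is not None:
        try:
            L = np.linalg.cholesky(spec.correlation)
        except np.linalg.LinAlgError:
            # PSD but singular matrices are fine; reject truly indefinite ones
            w, V = np.linalg.eigh(spec.correlation)
            if w.min() < -1e-10:
                raise PanelError(
                    f"correlation matrix is not PSD (min eigenvalue {w.min():.3g})"
                ) from None
            L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        eps = eps @ L.T
    if spec.ar1 != 0.0:
        phi = spec.ar1
        z = np.empty_like(eps)
        z[0] = eps[0]
        scale = np.sqrt(1.0 - phi * phi)
        for t in range(1, n_years):
            z[t] = phi * z[t - 1] + scale * eps[t]
        eps = z
    return eps


def simulate_panel(
    spec: PanelSpec, seed: int | None = None
) -> dict[str, AnnualBestSeries]:
    """Draw one annual-best panel from a :class:`PanelSpec`.

    Identical spec + seed gives a bit-identical panel.  Raises if any
    generated mark is non-positive (choose levels large enough relative to
    sigma and drift).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    t0, t1 = spec.years
    years = np.arange(t0, t1 + 1)
    z = _correlated_noise(spec, rng)
    drift_from = t0 if spec.drift_start_year is None else spec.drift_start_year
    drift_years = np.clip(years - drift_from, 0, None)  # years of accumulated drift
    panel: dict[str, AnnualBestSeries] = {}
    for j, ev in enumerate(spec.events):
        perf = ev.drift * drift_years + ev.sigma * z[:, j]
        if ev.direction == MINIMIZE:
            marks = ev.level - perf
        else:
            marks = ev.level + perf
        if np.any(marks <= 0):
            bad = int(years[np.argmax(marks <= 0)])
            raise PanelError(
                f"{ev.event_id}: generated non-positive mark in {bad}; "
                "increase level or reduce sigma/drift"
            )
        panel[ev.event_id] = AnnualBestSeries(
            ev.event_id,
            ev.direction,
            ev.unit,
            {int(y): float(m) for y, m in zip(years, marks)},
            year_range=(t0, t1),
        )
    return panel


def simulate_iid_maxima(
    N: int, reps: int, seed: int, chunk: int = 200_000
) -> tuple[float, float]:
    """Empirical mean and sd of the maximum of N iid standard Gaussians.

    Draws ``reps`` batches of size N (chunked to bound memory) and returns
    the sample mean and sample sd (n-1) of the batch maxima.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    rng = np.random.default_rng(seed)
    maxima = np.empty(reps)
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        maxima[done:done + m] = rng.standard_normal((m, N)).max(axis=1)
        done += m
    return float(maxima.mean()), float(maxima.std(ddof=1)) if reps > 1 else 0.0


# ---------------------------------------------------------------------------
# packaged default spec
# ---------------------------------------------------------------------------

# (level, sigma) per event, native units: seconds for timed events, meters
# for jumps.  Levels are early-1990s world-class annual bests; sigmas are
# plausible year-to-year spreads of annual bests (a fraction of a percent
# of the level for most events).
_DEFAULT_PARAMS: dict[str, tuple[float, float]] = {
    "100m": (9.92, 0.05),
    "200m": (19.90, 0.09),
    "400m": (43.95, 0.22),
    "800m": (102.6, 0.50),
    "3000m": (442.0, 2.4),
    "10000m": (1600.0, 8.0),
    "marathon": (7580.0, 55.0),
    "100m_back": (53.9, 0.30),
    "200m_back": (117.0, 0.60),
    "100m_breast": (60.9, 0.40),
    "200m_breast": (131.0, 0.70),
    "100m_fly": (52.8, 0.30),
    "200m_fly": (116.5, 0.60),
    "50m_free": (21.95, 0.14),
    "100m_free": (48.6, 0.25),
    "200m_free": (106.8, 0.50),
    "400m_free": (225.5, 1.10),
    "800m_free": (470.0, 2.40),
    "200m_im": (119.5, 0.60),
    "400m_im": (254.0, 1.30),
    "400m_h": (47.4, 0.25),
    "long_jump": (8.60, 0.10),
    "high_jump": (2.40, 0.030),
    "triple_jump": (17.85, 0.12),
}

#: Events forming the correlated, systematically improving block (all
#: swimming events, both sprints and the marathon — the cluster the
#: relevance network is expected to recover).
IMPROVING_BLOCK = (
    "100m", "200m", "marathon",
    "100m_back", "200m_back", "100m_breast", "200m_breast",
    "100m_fly", "200m_fly", "50m_free", "100m_free", "200m_free",
    "400m_free", "800m_free", "200m_im", "400m_im",
)

#: Within-block correlation of annual fluctuations.
DEFAULT_BLOCK_CORRELATION = 0.8

#: Improvement drift of block events, as a fraction of the event level per
#: year (~0.25%/yr, i.e. ~6.5% over 26 years — the scale of the observed
#: swimming-record progression).
BLOCK_DRIFT_FRACTION = 0.0025

#: Slight worsening of the remaining track and field events (~ -0.02%/yr),
#: mirroring their observed negative growth.
OTHER_DRIFT_FRACTION = -0.0002


def default_panel_spec(
    seed: int = 0,
    years: tuple[int, int] = DEFAULT_YEARS,
    block_correlation: float = DEFAULT_BLOCK_CORRELATION,
    stationary: bool = False,
    drift_start_year: int | None = None,
    catalog: EventCatalog | None = None,
) -> PanelSpec:
    """The packaged 24-event spec mimicking the real panel's shape.

    ``stationary=True`` zeroes all drifts (the pure-null regime).
    """
    catalog = catalog or load_default_catalog()
    events = []
    for entry in catalog.entries:
        level, sigma = _DEFAULT_PARAMS[entry.event_id]
        frac = (
            BLOCK_DRIFT_FRACTION
            if entry.event_id in IMPROVING_BLOCK
            else OTHER_DRIFT_FRACTION
        )
        if stationary:
            frac = 0.0
        events.append(
            EventSpec(entry.event_id, entry.direction, entry.unit,
                      level=level, sigma=sigma, drift=frac * level)
        )
    k = len(events)
    C = np.eye(k)
    block_idx = [i for i, e in enumerate(events) if e.event_id in IMPROVING_BLOCK]
    for a in block_idx:
        for b in block_idx:
            if a != b:
                C[a, b] = block_correlation
    return PanelSpec(events=events, correlation=C, years=years, seed=seed,
                     drift_start_year=drift_start_year)


# ---------------------------------------------------------------------------
# YAML round-trip for specs
# ---------------------------------------------------------------------------

def panel_spec_to_yaml(spec: PanelSpec, path) -> None:
    doc = {
        "years": list(spec.years),
        "seed": int(spec.seed),
        "ar1": float(spec.ar1),
        "drift_start_year": spec.drift_start_year,
        "events": [
            {"event_id": e.event_id, "direction": e.direction, "unit": e.unit,
             "level": float(e.level), "sigma": float(e.sigma), "drift": float(e.drift)}
            for e in spec.events
        ],
        "correlation": (
            None if spec.correlation is None
            else [[float(x) for x in row] for row in spec.correlation]
        ),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def panel_spec_from_yaml(path) -> PanelSpec:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    events = [EventSpec(**e) for e in doc["events"]]
    corr = doc.get("correlation")
    return PanelSpec(
        events=events,
        correlation=None if corr is None else np.asarray(corr, dtype=float),
        years=tuple(doc.get("years", DEFAULT_YEARS)),
        seed=int(doc.get("seed", 0)),
        ar1=float(doc.get("ar1", 0.0)),
        drift_start_year=doc.get("drift_start_year"),
    )
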