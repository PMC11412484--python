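"""Relative-fluctuation transform and thresholded correlation network.

Each event's annual bests are turned into a *time series of relative
fluctuation* (TSRF) against a baseline year i (1992 by default): for timed
(minimize) events the value in year j is x_j / x_i, for jump (maximize)
events the reciprocal ratio x_i / x_j, so that an improvement lowers the
TSRF for every event alike and the transform is scale-free.

Pairs of events are then correlated (Pearson, over the shared year axis)
and a network is built with an edge wherever R exceeds a threshold (0.7)
and the two-sided p-value falls below a significance level (0.05, both
strict).  Correlation strength is additionally banded as high (|R| > 0.7),
moderate (0.4 <= |R| <= 0.7) or weak, signed by the correlation's sign.
Connected components of the network summarize co-evolving event clusters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .records import MINIMIZE, AnnualBestSeries, EventCatalog, PanelError

DEFAULT_BASELINE_YEAR = 1992
DEFAULT_R_THRESHOLD = 0.7
DEFAULT_ALPHA = 0.05


@dataclass
class TSRFMatrix:
    """Events x years table of direction-normalized relative fluctuations.

    The baseline year itself is excluded from the year axis.  All values
    are positive; a constant series yields a row of exactly 1.0.
    """

    values: pd.DataFrame  # index: event ids, columns: years
    baseline_year: int

    @property
    def events(self) -> list[str]:
        return list(self.values.index)

    @property
    def years(self) -> list[int]:
        return list(self.values.columns)


def compute_tsrf(
    panel: dict[str, AnnualBestSeries],
    baseline_year: int = DEFAULT_BASELINE_YEAR,
    catalog: EventCatalog | None = None,
) -> TSRFMatrix:
    """Compute the TSRF matrix of a panel against a baseline year.

    Every series must contain the baseline year and all years on the shared
    year axis (the union of post-baseline years across the panel); missing
    interior years are an error — no imputation is attempted.  Rows follow
    catalog order when a catalog is given, else insertion order.
    """
    if not panel:
        raise PanelError("empty panel")
    order = [e for e in (catalog.event_ids if catalog else panel) if e in panel]
    years = sorted({y for s in panel.values() for y in s.years if y != baseline_year})
    if not years:
        raise PanelError("panel has no years besides the baseline")
    rows = {}
    for event_id in order:
        series = panel[event_id]
        if baseline_year not in series.marks:
            raise PanelError(f"{event_id}: baseline year {baseline_year} missing")
        base = series.mark(baseline_year)
        values = []
        for year in years:
            if year not in series.marks:
                raise PanelError(f"{event_id}: year {year} missing (no imputation)")
            x = series.mark(year)
            values.append(x / base if series.direction == MINIMIZE else base / x)
        rows[event_id] = values
    df = pd.DataFrame.from_dict(rows, orient="index", columns=years)
    df.index.name = "event_id"
    return TSRFMatrix(values=df, baseline_year=baseline_year)


def correlation_matrix(tsrf: TSRFMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson R and two-sided p-values over the shared year axis.

    p-values come from the exact t-transform with n-2 degrees of freedom.
    The diagonal is R = 1, p = 0.  A zero-variance row makes the
    correlation undefined and raises an error naming the event.
    """
    X = tsrf.values.to_numpy(dtype=float)
    events = tsrf.events
    n_years = X.shape[1]
    if n_years < 3:
        raise PanelError(f"need >= 3 shared years for correlation, have {n_years}")
    variances = X.var(axis=1)
    for event_id, v in zip(events, variances):
        if v == 0.0:
            raise PanelError(f"{event_id}: zero-variance TSRF, correlation undefined")
    k = len(events)
    R = np.eye(k)
    P = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        res = stats.pearsonr(X[i], X[j])
        R[i, j] = R[j, i] = res.statistic
        P[i, j] = P[j, i] = res.pvalue
    idx = pd.Index(events, name="event_id")
    return (
        pd.DataFrame(R, index=idx, columns=idx),
        pd.DataFrame(P, index=idx, columns=idx),
    )


HIGH_POS = "high+"
MODERATE_POS = "moderate+"
WEAK = "weak"
MODERATE_NEG = "moderate-"
HIGH_NEG = "high-"


def strength_band(r: float, high: float = 0.7, moderate: float = 0.4) -> str:
    """Label a correlation: high |R| > 0.7, moderate 0.4 <= |R| <= 0.7,
    weak otherwise, signed by the correlation's direction."""
    mag = abs(r)
    if mag > high:
        return HIGH_POS if r > 0 else HIGH_NEG
    if mag >= moderate:
        return MODERATE_POS if r > 0 else MODERATE_NEG
    return WEAK


@dataclass
class RelevanceNetwork:
    R: pd.DataFrame
    p: pd.DataFrame
    r_threshold: float
    alpha: float
    edges: set[frozenset] = field(default_factory=set)
    bands: pd.DataFrame | None = None  # long-form pair table
    graph: nx.Graph | None = None

    @property
    def components(self) -> list[set[str]]:
        """Connected components (isolated events are singletons)."""
        return [set(c) for c in nx.connected_components(self.graph)]

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v in sorted(tuple(sorted(e)) for e in self.edges):
            rows.append(
                {"u": u, "v": v, "R": self.R.loc[u, v], "p": self.p.loc[u, v],
                 "band": strength_band(self.R.loc[u, v])}
            )
        return pd.DataFrame(rows, columns=["u", "v", "R", "p", "band"])

    def adjacency(self) -> pd.DataFrame:
        events = list(self.R.index)
        adj = pd.DataFrame(0, index=self.R.index, columns=self.R.columns, dtype=int)
        for e in self.edges:
            u, v = tuple(e)
            adj.loc[u, v] = adj.loc[v, u] = 1
        return adj.loc[events, events]

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(
    R: pd.DataFrame,
    p: pd.DataFrame,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    require_significance: bool = True,
    fdr_correction: bool = False,
) -> RelevanceNetwork:
    """Threshold a correlation matrix into a relevance network.

    An edge joins (u, v) iff R_uv > r_threshold strictly and (unless
    ``require_significance`` is off) p_uv < alpha strictly.  With
    ``fdr_correction`` the p-values are Benjamini-Hochberg adjusted across
    all pairs first (off by default: raw p at 0.05 is the conventional
    reporting for this analysis, despite the 276 simultaneous pairs).
    """
    if not (-1.0 <= r_threshold <= 1.0):
        raise ValueError(f"r_threshold must be in [-1, 1], got {r_threshold}")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if list(R.index) != list(p.index) or list(R.columns) != list(p.columns):
        raise ValueError("R and p matrices are not conformable")
    if not np.allclose(R.to_numpy(), R.to_numpy().T):
        raise ValueError("R matrix is not symmetric")
    events = list(R.index)
    pairs = list(itertools.combinations(events, 2))
    pvals = np.array([p.loc[u, v] for u, v in pairs])
    if fdr_correction and len(pvals):
        pvals = stats.false_discovery_control(pvals, method="bh")
    graph = nx.Graph()
    graph.add_nodes_from(events)
    edges: set[frozenset] = set()
    band_rows = []
    for (u, v), pv in zip(pairs, pvals):
        r = R.loc[u, v]
        significant = (pv < alpha) if require_significance else True
        connected = (r > r_threshold) and significant
        band_rows.append(
            {"u": u, "v": v, "R": r, "p": p.loc[u, v], "p_used": pv,
             "band": strength_band(r), "edge": connected}
        )
        if connected:
            edges.add(frozenset((u, v)))
            graph.add_edge(u, v, R=float(r), p=float(pv))
    return RelevanceNetwork(
        R=R, p=p, r_threshold=r_threshold, alpha=alpha, edges=edges,
        bands=pd.DataFrame(band_rows), graph=graph,
    )
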