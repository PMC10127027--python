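"""Graph-theoretic topology of binarized functional networks.

Two scalar summaries are computed per network:

* clustering coefficient
      Coef = (1/M) * sum_i  2*E_i / (k_i * (k_i - 1)),
  where k_i is the degree of node i and E_i the number of edges among the
  neighbours of i.  Nodes with k_i < 2 contribute 0 (their term is 0/0);
  with that convention Coef lies in [0, 1].

* global efficiency
      Eff = (1/M) * sum_i  [ sum_{j != i} 1/d_ij ] / (M - 1),
  with d_ij the unweighted shortest-path length; disconnected pairs
  contribute 0 (1/inf).  Eff lies in [0, 1].

Both match the standard binary-graph definitions used throughout the
functional-connectivity literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import BandCoherenceMatrix, BinaryNetwork


class NetMetricsError(ValueError):
    pass


@dataclass
class NetworkMetrics:
    coef: float
    eff: float
    band: str = ""
    trial_id: int = -1
    phase: str = ""


@dataclass
class CoherenceDistributionSummary:
    """Normal fit (ML: sample mean, population std) of pooled coherence values."""

    mu: float
    sigma: float
    n_values: int
    band: str = ""
    phase: str = ""


def _as_network(net: BinaryNetwork | np.ndarray) -> BinaryNetwork:
    if isinstance(net, BinaryNetwork):
        return net
    return BinaryNetwork(adjacency=np.asarray(net))  # validates symmetry etc.


def clustering_coefficient(net: BinaryNetwork | np.ndarray) -> float:
    """Mean local clustering over all nodes; in [0, 1]."""
    net = _as_network(net)
    m = net.n_nodes
    if m < 1:
        raise NetMetricsError("network must have at least one node")
    total = 0.0
    degrees = net.degrees
    for i in range(m):
        k = int(degrees[i])
        if k < 2:
            continue
        e_i = net.neighbor_edge_count(i)
        total += 2.0 * e_i / (k * (k - 1))
    return total / m


def global_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs; in [0, 1]."""
    net = _as_network(net)
    m = net.n_nodes
    if m < 2:
        raise NetMetricsError("global efficiency needs at least two nodes")
    d = net.distances()
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum(axis=1).sum() / (m * (m - 1)))


def network_metrics(net: BinaryNetwork) -> NetworkMetrics:
    return NetworkMetrics(
        coef=clustering_coefficient(net),
        eff=global_efficiency(net),
        band=net.band,
        trial_id=net.trial_id,
        phase=net.phase,
    )


def fit_coherence_distribution(
    matrices: Sequence[BandCoherenceMatrix],
) -> CoherenceDistributionSummary:
    """Fit a normal to the pooled strictly-upper-triangle coherence values.

    The fitted (mu, sigma) reconstruct the density curve; sigma uses the
    maximum-likelihood (population) form.  A degenerate pool (all values
    identical) yields sigma = 0 with a warning.
    """
    if not matrices:
        raise NetMetricsError("no coherence matrices given")
    pooled = np.concatenate(
        [m.matrix[np.triu_indices(m.n_channels, k=1)] for m in matrices]
    )
    if pooled.size < 2:
        raise NetMetricsError("need at least 2 pooled coherence values")
    mu = float(pooled.mean())
    sigma = float(pooled.std(ddof=0))
    if sigma == 0.0:
        warnings.warn("degenerate fit: all pooled coherence values identical")
    bands = {m.band.name for m in matrices}
    phases = {m.phase for m in matrices}
    return CoherenceDistributionSummary(
        mu=mu,
        sigma=sigma,
        n_values=int(pooled.size),
        band=bands.pop() if len(bands) == 1 else "",
        phase=phases.pop() if len(phases) == 1 else "",
    )


def radar_summary(
    summaries: Sequence[CoherenceDistributionSummary],
) -> pd.DataFrame:
    """Phase x band table of fitted means (the radar-plot values).

    Cells with no summary are NaN — never silently zero.  Duplicate
    (phase, band) inputs are an error.
    """
    seen = set()
    for s in summaries:
        key = (s.phase, s.band)
        if key in seen:
            raise NetMetricsError(f"duplicate summary for phase/band {key}")
        seen.add(key)
    phases = list(dict.fromkeys(s.phase for s in summaries))
    bands = list(dict.fromkeys(s.band for s in summaries))
    table = pd.DataFrame(np.nan, index=phases, columns=bands)
    for s in summaries:
        table.loc[s.phase, s.band] = s.mu
    table.index.name = "phase"
    table.columns.name = "band"
    return table
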