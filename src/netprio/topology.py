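"""NetworkAnalyzer-style topological parameters of a PPI network.

The headline statistic is the linearized power-law fit of the node-degree
distribution: with P(k) the number of nodes of degree k, the curve
y = beta * x^a is fitted by ordinary least squares on the log-transformed
model ln y = ln beta + a ln x, using every (k, count) point with positive
coordinates (degree-0 nodes cannot enter the fit and are reported
separately).  R^2 is the coefficient of determination of that linear
regression in log-log space; the accompanying "correlation" is the Pearson r
between observed and fitted counts back on the original scale.

The remaining parameters are the standard closed forms: mean local clustering
coefficient, density 2|E|/(N(N-1)), and degree centralization
(N/(N-2)) * (max_degree/(N-1) - density), which is 1 for a star and 0 for any
degree-regular graph.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

from .errors import UndefinedMetricError
from .network import PPINetwork


@dataclass(frozen=True)
class DegreeDistribution:
    """Histogram of positive node degrees: (k, number of nodes of degree k)."""

    points: tuple[tuple[int, int], ...]
    n_zero_degree: int = 0

    def __post_init__(self) -> None:
        ks = [k for k, _ in self.points]
        assert ks == sorted(set(ks)), "k values must be strictly increasing"
        assert all(c > 0 for _, c in self.points)

    @property
    def k(self) -> np.ndarray:
        return np.array([k for k, _ in self.points], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return np.array([c for _, c in self.points], dtype=float)


@dataclass(frozen=True)
class PowerLawFit:
    """y = beta * x^exponent fitted on log-transformed coordinates."""

    beta: float
    exponent: float
    r_squared: float
    correlation: float
    n_points: int

    def predict(self, k: np.ndarray) -> np.ndarray:
        return self.beta * np.asarray(k, dtype=float) ** self.exponent


def degree_distribution(net: PPINetwork) -> DegreeDistribution:
    """Exact degree histogram; degree-0 nodes counted separately."""
    degrees = [d for _, d in net.degree()]
    hist = Counter(d for d in degrees if d > 0)
    return DegreeDistribution(
        points=tuple(sorted(hist.items())),
        n_zero_degree=sum(1 for d in degrees if d == 0),
    )


def fit_power_law(dist: DegreeDistribution) -> PowerLawFit:
    """OLS fit of ln(count) on ln(k) over all histogram points.

    beta = exp(intercept), exponent = slope.  A zero-residual fit (including
    the degenerate constant-count case) has r_squared defined as 1, keeping
    r_squared in [0, 1].
    """
    if len(dist.points) < 2:
        raise UndefinedMetricError(
            f"power-law fit needs >= 2 distinct degrees, got {len(dist.points)}"
        )
    x = np.log(dist.k)
    y = np.log(dist.counts)
    design = np.column_stack([np.ones_like(x), x])
    (intercept, slope), *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted_log = intercept + slope * x
    ss_res = float(np.sum((y - fitted_log) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_res <= 1e-24 * max(1.0, ss_tot):
        r_squared = 1.0
    elif ss_tot == 0.0:
        r_squared = 0.0
    else:
        r_squared = max(0.0, 1.0 - ss_res / ss_tot)

    beta = float(np.exp(intercept))
    fitted = beta * dist.k ** slope
    obs = dist.counts
    if np.ptp(obs) == 0.0 or np.ptp(fitted) == 0.0:
        # Pearson r is undefined for a constant vector; a zero-residual fit is
        # reported as perfect agreement.
        correlation = 1.0 if np.allclose(obs, fitted) else 0.0
    else:
        correlation = float(np.corrcoef(obs, fitted)[0, 1])
    return PowerLawFit(
        beta=beta,
        exponent=float(slope),
        r_squared=float(r_squared),
        correlation=correlation,
        n_points=len(dist.points),
    )


def clustering_coefficient(net: PPINetwork) -> float:
    """Mean local clustering coefficient (degree < 2 nodes contribute 0)."""
    if net.number_of_nodes() == 0:
        raise UndefinedMetricError("clustering coefficient of an empty network")
    return float(nx.average_clustering(net))


def network_density(net: PPINetwork) -> float:
    """2|E| / (N(N-1))."""
    n = net.number_of_nodes()
    if n < 2:
        raise UndefinedMetricError("density needs >= 2 nodes")
    return 2.0 * net.number_of_edges() / (n * (n - 1))


def network_centralization(net: PPINetwork) -> float:
    """(N/(N-2)) * (max_degree/(N-1) - density)."""
    n = net.number_of_nodes()
    if n < 3:
        raise UndefinedMetricError("centralization needs >= 3 nodes")
    max_degree = max(d for _, d in net.degree())
    return (n / (n - 2.0)) * (max_degree / (n - 1.0) - network_density(net))


@dataclass(frozen=True)
class TopologyReport:
    nodes: int
    edges: int
    density: float
    clustering_coefficient: float
    centralization: float
    power_law_beta: float | None
    power_law_exponent: float | None
    power_law_r_squared: float | None
    power_law_correlation: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def topology_report(net: PPINetwork) -> TopologyReport:
    """All topological parameters in one record.

    The power-law fields are None when the degree histogram has fewer than two
    distinct positive degrees (the fit is undefined there).
    """
    dist = degree_distribution(net)
    try:
        fit = fit_power_law(dist)
        fit_fields = (fit.beta, fit.exponent, fit.r_squared, fit.correlation)
    except UndefinedMetricError:
        fit_fields = (None, None, None, None)
    return TopologyReport(
        nodes=net.number_of_nodes(),
        edges=net.number_of_edges(),
        density=network_density(net),
        clustering_coefficient=clustering_coefficient(net),
        centralization=network_centralization(net),
        power_law_beta=fit_fields[0],
        power_law_exponent=fit_fields[1],
        power_law_r_squared=fit_fields[2],
        power_law_correlation=fit_fields[3],
    )
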