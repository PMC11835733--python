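"""Graph communities to a probabilistic Gaussian-mixture partition.

Communities found on the proximity graph (leading-eigenvector seeding,
repeated Leiden modularity optimization) are converted to Gaussian
components whose centers and covariances are estimated with eigenvector-
centrality weights.  A fixed *concordant* reference component (zero mean,
identity covariance) is always part of the mixture; component moments
stay fixed while the mixture weights — the population proportions of the
profiles — are estimated by expectation-maximization.  Individuals
receive posterior allocation probabilities for every profile, summing
to 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg as la
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .discordance import ResidualMatrix
from .graph import ProximityGraph
from .simulate import BIOMARKERS, CONCORDANT


@dataclass
class HardPartition:
    """Single-label community assignment with its modularity."""

    labels: np.ndarray
    modularity: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def seed_partition(graph: ProximityGraph) -> HardPartition:
    """Stable initial communities from the leading-eigenvector method."""
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    comm = graph.g.community_leading_eigenvector()
    labels = np.asarray(comm.membership, dtype=int)
    return HardPartition(labels=labels, modularity=graph.g.modularity(labels))


def leiden_consensus(graph: ProximityGraph, seeds: HardPartition | None = None,
                     n_iter: int = 500, seed: int = 0) -> HardPartition:
    """Best-modularity partition over repeated Leiden runs.

    The Leiden algorithm is restarted ``n_iter`` times from the seed
    partition with different random streams; the run with the highest
    modularity is kept.  Leiden guarantees internally connected
    communities.
    """
    init = None if seeds is None else list(map(int, seeds.labels))
    best_labels, best_q = None, -np.inf
    for i in range(n_iter):
        part = la.find_partition(
            graph.g, la.ModularityVertexPartition,
            initial_membership=init, seed=int(seed + i), n_iterations=2,
        )
        labels = np.asarray(part.membership, dtype=int)
        q = graph.g.modularity(labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return HardPartition(labels=best_labels, modularity=float(best_q))


def centrality_weights(graph: ProximityGraph, partition: HardPartition) -> np.ndarray:
    """Normalized eigenvector centrality of each node within its community.

    Scores are scaled so the most central member of each community has
    weight 1; singletons get weight 1.
    """
    labels = partition.labels
    if labels.shape[0] != graph.n_nodes:
        raise ValueError("partition does not cover all nodes")
    w = np.ones(graph.n_nodes)
    for c in np.unique(labels):
        nodes = np.flatnonzero(labels == c)
        if nodes.size == 1:
            continue
        sub = graph.g.induced_subgraph(nodes)
        ec = np.asarray(sub.eigenvector_centrality(scale=True))
        mx = ec.max()
        w[nodes] = ec / mx if mx > 0 else 1.0
    return np.clip(w, 1e-12, 1.0)


@dataclass
class Component:
    label: str
    mean: np.ndarray
    cov: np.ndarray
    weight: float
    concordant: bool = False

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)


@dataclass
class MixtureModel:
    """Labeled Gaussian components; exactly one flagged concordant."""

    components: list
    loglik_path: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        nc = sum(c.concordant for c in self.components)
        if nc != 1:
            raise ValueError("exactly one component must be concordant")
        c = self.concordant
        if not (np.allclose(c.mean, 0.0) and np.allclose(c.cov, np.eye(len(c.mean)))):
            raise ValueError("concordant component must have zero mean, identity covariance")
        w = self.weights
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-10:
            raise ValueError("component weights must be non-negative and sum to 1")

    @property
    def labels(self):
        return [c.label for c in self.components]

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def concordant(self) -> Component:
        return next(c for c in self.components if c.concordant)

    @property
    def discordant(self):
        return [c for c in self.components if not c.concordant]

    def logpdfs(self, X: np.ndarray) -> np.ndarray:
        """N x K matrix of component log-densities (no weights)."""
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(self.components)))
        for k, c in enumerate(self.components):
            L = np.linalg.cholesky(c.cov)
            dev = np.linalg.solve(L, (X - c.mean).T)
            q = np.einsum("ij,ij->j", dev, dev)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            out[:, k] = -0.5 * (q + logdet + len(c.mean) * np.log(2 * np.pi))
        return out

    def replace_weights(self, w) -> "MixtureModel":
        comps = [Component(c.label, c.mean, c.cov, float(wk), c.concordant)
                 for c, wk in zip(self.components, w)]
        return MixtureModel(comps)

    def to_json(self, path=None) -> str:
        payload = {
            "components": [
                {
                    "label": c.label,
                    "mean": c.mean.tolist(),
                    "cov": c.cov.tolist(),
                    "weight": c.weight,
                    "concordant": c.concordant,
                }
                for c in self.components
            ]
        }
        s = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, src) -> "MixtureModel":
        if isinstance(src, (str, bytes)) and str(src).lstrip().startswith("{"):
            payload = json.loads(src)
        else:
            with open(src) as fh:
                payload = json.load(fh)
        comps = [Component(d["label"], np.array(d["mean"]), np.array(d["cov"]),
                           d["weight"], d["concordant"])
                 for d in payload["components"]]
        return cls(comps)


def _profile_name(mean: np.ndarray, biomarkers, taken) -> str:
    """Name a component by its dominant biomarker deviation."""
    j = int(np.argmax(np.abs(mean)))
    name = f"{biomarkers[j]}_{'high' if mean[j] > 0 else 'low'}"
    base, k = name, 2
    while name in taken:
        name, k = f"{base}{k}", k + 1
    return name


def build_mixture(residuals: ResidualMatrix, partition: HardPartition,
                  weights: np.ndarray, min_size_factor: float = 10.0,
                  min_mean_norm: float = 2.0, ridge: float = 1e-6) -> MixtureModel:
    """Convert communities to mixture components, adding the concordant one.

    Component centers and covariances are centrality-weighted moments of
    the community members.  Communities that are too small
    (< ``min_size_factor`` x dimension members) or centered too close to
    the origin (mean norm < ``min_mean_norm`` z-units, i.e. not separated
    from the BMI-expected profile) are not promoted; their members are
    represented by the injected concordant component (zero mean, identity
    covariance).  Initial weights are proportional to community sizes,
    intended to be refit with :func:`fit_mixture_weights`.
    """
    X = residuals.values
    n, d = X.shape
    labels = partition.labels
    w = np.asarray(weights, dtype=float)
    comps = []
    conc_count = 0
    taken = set()
    for c in np.unique(labels):
        nodes = np.flatnonzero(labels == c)
        if nodes.size < min_size_factor * d:
            conc_count += nodes.size
            continue
        wi = w[nodes][:, None]
        mu = (wi * X[nodes]).sum(axis=0) / wi.sum()
        if np.linalg.norm(mu) < min_mean_norm:
            conc_count += nodes.size
            continue
        dev = X[nodes] - mu
        cov = (wi * dev).T @ dev / wi.sum()
        if np.linalg.eigvalsh(cov).min() < 1e-8:
            cov = cov + ridge * np.eye(d)
        name = _profile_name(mu, residuals.biomarkers, taken)
        taken.add(name)
        comps.append(Component(name, mu, cov, nodes.size / n))
    comps.append(Component(CONCORDANT, np.zeros(d), np.eye(d),
                           max(conc_count, 1) / n, concordant=True))
    wsum = sum(c.weight for c in comps)
    for c in comps:
        c.weight /= wsum
    return MixtureModel(comps)


def fit_mixture_weights(mixture: MixtureModel, residuals: ResidualMatrix | np.ndarray,
                        tol: float = 1e-8, max_iter: int = 1000) -> MixtureModel:
    """Estimate component weights by EM with fixed centers and covariances.

    The weights are the population proportions of the profiles.  Iterates
    responsibilities -> weight averages until ``max |delta pi| < tol``;
    the log-likelihood is non-decreasing.
    """
    X = residuals.values if isinstance(residuals, ResidualMatrix) else np.asarray(residuals, float)
    logphi = mixture.logpdfs(X)
    pi = mixture.weights.copy()
    ll_path = []
    for _ in range(max_iter):
        logp = logphi + np.log(np.clip(pi, 1e-300, None))
        norm = logsumexp(logp, axis=1)
        ll_path.append(float(norm.sum()))
        resp = np.exp(logp - norm[:, None])
        pi_new = resp.mean(axis=0)
        if np.max(np.abs(pi_new - pi)) < tol:
            pi = pi_new
            break
        pi = pi_new
    degenerate = [mixture.labels[k] for k in np.flatnonzero(pi < 1e-6)]
    if degenerate:
        warnings.warn(f"degenerate components (weight < 1e-6): {degenerate}")
    out = mixture.replace_weights(pi / pi.sum())
    out.loglik_path = ll_path
    return out


def allocate(mixture: MixtureModel, residuals: ResidualMatrix | np.ndarray) -> pd.DataFrame:
    """Posterior allocation probabilities (responsibilities) per profile.

    Computed in log space with log-sum-exp; every row sums to 1.
    """
    X = residuals.values if isinstance(residuals, ResidualMatrix) else np.asarray(residuals, float)
    logp = mixture.logpdfs(X) + np.log(np.clip(mixture.weights, 1e-300, None))
    norm = logsumexp(logp, axis=1)
    if not np.all(np.isfinite(norm)):
        raise FloatingPointError("all component densities underflowed for some rows")
    P = np.exp(logp - norm[:, None])
    ids = residuals.ids if isinstance(residuals, ResidualMatrix) and residuals.ids is not None \
        else np.arange(X.shape[0])
    return pd.DataFrame(P, columns=mixture.labels, index=pd.Index(ids, name="id"))


def relative_entropy(alloc: pd.DataFrame) -> float:
    """Partition-separation index ``1 - H/(N ln K)`` in [0, 1].

    1 for one-hot allocations (complete separation), 0 when every
    individual has identical probabilities for all profiles.
    """
    P = np.asarray(alloc, dtype=float)
    n, k = P.shape
    if k == 1:
        warnings.warn("entropy index undefined for a single profile; reporting 1")
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(P > 0, -P * np.log(P), 0.0).sum()
    return float(1.0 - h / (n * np.log(k)))


def partition_quality(alloc: pd.DataFrame, graph: ProximityGraph):
    """Relative-entropy separation index and per-profile transitivity.

    Transitivity is the global clustering coefficient of the subgraph
    induced by each profile's maximum-probability members.
    """
    P = np.asarray(alloc, dtype=float)
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("allocation rows must sum to 1")
    E = relative_entropy(alloc)
    hard = P.argmax(axis=1)
    trans = {}
    for k, lab in enumerate(alloc.columns):
        nodes = np.flatnonzero(hard == k)
        if nodes.size < 3:
            trans[lab] = float("nan")
            continue
        sub = graph.g.induced_subgraph(nodes)
        trans[lab] = sub.transitivity_undirected(mode="zero")
    return E, trans
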