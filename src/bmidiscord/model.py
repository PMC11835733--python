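"""Statsmodels-style front end for the profiling pipeline.

``DiscordanceProfileModel`` holds one sex stratum of a cohort;
``fit()`` runs quality control, BMI-residualization, proximity-graph
construction and graph-seeded soft clustering, returning a
``DiscordanceProfileResults`` object with the mixture, allocation
probabilities, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import discordance as _disc
from . import graph as _graph
from . import replicate as _rep
from .simulate import BIOMARKERS


class DiscordanceProfileModel:
    """BMI-discordance profiling of one sex stratum.

    Parameters
    ----------
    data : pandas.DataFrame
        Raw cohort table with id, sex, age, smoking, bmi and the ten
        biomarkers (plus any outcome columns, carried through untouched).
    sex : str, optional
        Restrict to one level of the ``sex`` column.  All profiling is
        sex-stratified; a mixed table must be subset.
    """

    def __init__(self, data: pd.DataFrame, sex: str | None = None,
                 biomarkers=BIOMARKERS, sd_threshold: float = 5.0):
        if sex is not None:
            data = data[data["sex"] == sex].reset_index(drop=True)
        elif "sex" in data and data["sex"].nunique() > 1:
            raise ValueError("mixed-sex table; pass sex= to select one stratum")
        self.sex = sex if sex is not None else (
            str(data["sex"].iloc[0]) if "sex" in data else "")
        self.biomarkers = list(biomarkers)
        self.sd_threshold = sd_threshold
        self.data, self.qc_log = _disc.remove_outliers(
            data, sd_threshold=sd_threshold, biomarkers=self.biomarkers)

    @classmethod
    def from_csv(cls, path, **kw) -> "DiscordanceProfileModel":
        return cls(pd.read_csv(path), **kw)

    @classmethod
    def from_dataframe(cls, data, **kw) -> "DiscordanceProfileModel":
        """Alias constructor mirroring from_formula-style APIs."""
        return cls(data, **kw)

    def fit(self, seed: int = 0, nn: int | None = None, n_leiden: int = 500,
            min_mean_norm: float = 2.0, min_size_factor: float = 10.0,
            threshold: float = 0.8) -> "DiscordanceProfileResults":
        """Run the full profiling pipeline on this stratum."""
        rm = _disc.residualize(self.data, self.biomarkers, stratum=self.sex)
        g = _graph.build_graph(rm, nn=nn, seed=seed)
        seeds = _cluster.seed_partition(g)
        part = _cluster.leiden_consensus(g, seeds, n_iter=n_leiden, seed=seed)
        w = _cluster.centrality_weights(g, part)
        mix = _cluster.build_mixture(rm, part, w, min_size_factor=min_size_factor,
                                     min_mean_norm=min_mean_norm)
        mix = _cluster.fit_mixture_weights(mix, rm)
        alloc = _cluster.allocate(mix, rm)
        entropy, transitivity = _cluster.partition_quality(alloc, g)
        scores = _disc.mahalanobis_discordance(rm)
        return DiscordanceProfileResults(
            model=self, residuals=rm, graph=g, partition=part,
            centrality=w, mixture=mix, alloc=alloc, entropy=entropy,
            transitivity=transitivity, discordance=scores,
            replication_threshold=threshold,
        )


@dataclass
class DiscordanceProfileResults:
    """Fitted profile partition for one stratum."""

    model: DiscordanceProfileModel
    residuals: _disc.ResidualMatrix
    graph: _graph.ProximityGraph
    partition: _cluster.HardPartition
    centrality: np.ndarray
    mixture: _cluster.MixtureModel
    alloc: pd.DataFrame
    entropy: float
    transitivity: dict
    discordance: pd.DataFrame
    replication_threshold: float = 0.8
    replication_report: dict | None = field(default=None, repr=False)

    @property
    def weights(self) -> pd.Series:
        return pd.Series(self.mixture.weights, index=self.mixture.labels)

    def allocate(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Score new raw data under this stratum's fitted mixture."""
        z = self.residuals.apply(cohort)
        return _cluster.allocate(self.mixture, z)

    def replicate(self, validations, threshold: float | None = None
                  ) -> "DiscordanceProfileResults":
        """Keep only profiles replicated in all validation results.

        ``validations`` are ``DiscordanceProfileResults`` from
        independently fitted cohorts (or bare mixtures).
        """
        thr = self.replication_threshold if threshold is None else threshold
        vmixes = [v.mixture if hasattr(v, "mixture") else v for v in validations]
        replicated, report = _rep.replication_test(
            self.alloc, self.mixture, self.residuals, vmixes, threshold=thr)
        mix, alloc = _rep.finalize_model(self.mixture, replicated, self.residuals)
        entropy, transitivity = _cluster.partition_quality(alloc, self.graph)
        return DiscordanceProfileResults(
            model=self.model, residuals=self.residuals, graph=self.graph,
            partition=self.partition, centrality=self.centrality,
            mixture=mix, alloc=alloc, entropy=entropy,
            transitivity=transitivity, discordance=self.discordance,
            replication_threshold=thr, replication_report=report,
        )

    def summary(self) -> str:
        lines = []
        lines.append("BMI-discordance profile partition")
        lines.append("=" * 58)
        lines.append(f"stratum: {self.model.sex or '(unspecified)'}    "
                     f"n = {self.residuals.n}    "
                     f"profiles = {len(self.mixture.labels)}")
        lines.append(f"graph: nn = {self.graph.nn_used}, "
                     f"modularity = {self.partition.modularity:.3f}")
        lines.append(f"relative entropy (separation index): {self.entropy:.3f}")
        lines.append("-" * 58)
        lines.append(f"{'profile':<18}{'weight':>8}{'transitivity':>14}  top deviations")
        for c in self.mixture.components:
            tr = self.transitivity.get(c.label, float('nan'))
            j = np.argsort(-np.abs(c.mean))[:3]
            tops = ", ".join(
                f"{self.residuals.biomarkers[i]}={c.mean[i]:+.2f}" for i in j
                if abs(c.mean[i]) > 0.1) or "(none)"
            lines.append(f"{c.label:<18}{c.weight:>8.3f}{tr:>14.3f}  {tops}")
        lines.append("-" * 58)
        obs, pbin = _disc.excess_discordance_test(self.discordance["pvalue"])
        lines.append(f"substantial discordance: {100*obs:.1f}% observed vs 5.0% "
                     f"expected (binomial p = {pbin:.3g})")
        return "\n".join(lines)
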