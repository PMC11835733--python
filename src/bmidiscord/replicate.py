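"""Profile replication across cohorts.

Discordant components of a discovery mixture are matched one-to-one to
validation components by cosine similarity of their mean vectors.  A
profile replicates when the discovery individuals confidently allocated
to it (probability > threshold) also receive a high median probability
for the matched profile under every validation mixture; only profiles
replicated in all validation cohorts are retained in the final model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .cluster import MixtureModel, allocate, fit_mixture_weights
from .discordance import ResidualMatrix


@dataclass
class ProfileMatch:
    discovery_label: str
    validation_label: str | None
    similarity: float
    median_probability: float = float("nan")
    replicated: bool = False


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def match_profiles(discovery: MixtureModel, validation: MixtureModel,
                   min_similarity: float = 0.5):
    """Greedy one-to-one matching of discordant components by cosine similarity."""
    d_comps = discovery.discordant
    v_comps = validation.discordant
    sims = np.array([[_cosine(dc.mean, vc.mean) for vc in v_comps] for dc in d_comps])
    matches = {}
    if sims.size:
        order = np.dstack(np.unravel_index(np.argsort(-sims, axis=None), sims.shape))[0]
        used_d, used_v = set(), set()
        for i, j in order:
            if i in used_d or j in used_v or sims[i, j] < min_similarity:
                continue
            matches[i] = j
            used_d.add(i)
            used_v.add(j)
    out = []
    for i, dc in enumerate(d_comps):
        if i in matches:
            j = matches[i]
            out.append(ProfileMatch(dc.label, v_comps[j].label, sims[i, j]))
        else:
            best = float(sims[i].max()) if sims.size else 0.0
            out.append(ProfileMatch(dc.label, None, best))
    return out


def replication_test(discovery_alloc, discovery: MixtureModel,
                     residuals: ResidualMatrix, validations,
                     threshold: float = 0.8, min_similarity: float = 0.5):
    """Which discovery profiles replicate in *all* validation cohorts.

    For each discordant discovery profile, the discovery individuals with
    allocation probability above ``threshold`` are scored under each
    validation mixture; the profile replicates if the median probability
    of the matched validation profile exceeds ``threshold`` in every
    validation cohort.

    Returns
    -------
    (replicated, report) : (set, dict)
        ``report`` maps each profile to its per-validation matches.
    """
    if not validations:
        raise ValueError("at least one validation mixture is required")
    X = residuals.values
    report = {c.label: [] for c in discovery.discordant}
    replicated = set(report)
    for vmix in validations:
        matches = match_profiles(discovery, vmix, min_similarity)
        valloc = allocate(vmix, X)
        for m in matches:
            sel = np.asarray(discovery_alloc[m.discovery_label], float) > threshold
            if not sel.any():
                warnings.warn(
                    f"no individuals above threshold for profile {m.discovery_label!r}"
                )
                m.replicated = False
            elif m.validation_label is None:
                m.replicated = False
            else:
                med = float(np.median(np.asarray(valloc[m.validation_label])[sel]))
                m.median_probability = med
                m.replicated = med > threshold
            if not m.replicated:
                replicated.discard(m.discovery_label)
            report[m.discovery_label].append(m)
    return replicated, report


def finalize_model(discovery: MixtureModel, replicated, residuals: ResidualMatrix):
    """Drop non-replicated discordant components and refit the weights.

    Returns the reduced mixture (weights re-estimated with fixed moments)
    and fresh allocation probabilities.
    """
    if not replicated and len(discovery.discordant) > 0:
        warnings.warn("no discordant profile replicated; final model is concordant-only")
    comps = [c for c in discovery.components if c.concordant or c.label in set(replicated)]
    w = np.array([c.weight for c in comps])
    mix = MixtureModel([type(c)(c.label, c.mean, c.cov, float(wk), c.concordant)
                        for c, wk in zip(comps, w / w.sum())])
    mix = fit_mixture_weights(mix, residuals)
    return mix, allocate(mix, residuals)


def write_report(report: dict, replicated, path) -> None:
    payload = {
        "replicated": sorted(replicated),
        "matches": {k: [asdict(m) for m in v] for k, v in report.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
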