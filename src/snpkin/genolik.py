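"""Damage-aware genotype likelihoods from low-coverage read observations.

Degraded skeletal DNA carries postmortem cytosine deamination: excess
C→T mismatches near the 5' end of a read and, in double-stranded library
preparations, the complementary G→A excess near the 3' end.  At 1X
coverage a single damaged read would otherwise masquerade as evidence
for an alternate allele, so the per-read substitution model combines the
Phred base-error probability with a position-dependent deamination rate
and the likelihoods of all three alt-dosage genotypes are retained
instead of a hard call.

The per-read model, for true template base ``t`` and observed base
``b``::

    P(b | t) = 1 - e_tot                        if b == t
    P(T | C) = d5(dist5) + (1 - d5(dist5))*e/3  (5' C->T deamination)
    P(A | G) = d3(dist3) + (1 - d3(dist3))*e/3  (3' G->A deamination)
    P(b | t) = e/3                              any other mismatch

where ``e`` is the Phred error probability and ``d5``/``d3`` are
empirical terminal mismatch rates.  The four probabilities sum to one by
construction.  Sequencing error is split uniformly over the three wrong
bases, the conventional substitution-agnostic model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import BASES, Panel, SampleProfile, observations_frame

log = logging.getLogger(__name__)

#: observations below this Phred quality are dropped
MIN_BASE_QUALITY = 2

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class DamageProfile:
    """Terminal deamination mismatch rates.

    ``delta5[d]`` is the C→T mismatch rate at distance ``d`` from the 5'
    read end (d = 0..K-1); ``delta3`` the G→A rate from the 3' end.
    Beyond the window ``K`` the pooled interior rate ``baseline``
    applies.  An all-zero profile reduces the substitution model to the
    quality-only form used for undamaged reference samples.
    """

    delta5: np.ndarray
    delta3: np.ndarray
    baseline: float = 0.0
    K: int = field(default=None)

    def __post_init__(self) -> None:
        self.delta5 = np.asarray(self.delta5, dtype=float)
        self.delta3 = np.asarray(self.delta3, dtype=float)
        if self.K is None:
            self.K = len(self.delta5)
        for arr in (self.delta5, self.delta3):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("damage rates must lie in [0, 1]")
        if not 0 <= self.baseline <= 1:
            raise ValueError("baseline rate must lie in [0, 1]")

    @classmethod
    def none(cls, K: int = 15) -> "DamageProfile":
        return cls(np.zeros(K), np.zeros(K), 0.0, K)

    def rate5(self, dist5) -> np.ndarray:
        d = np.asarray(dist5, dtype=int)
        out = np.where(d < self.K, self.delta5[np.minimum(d, self.K - 1)], self.baseline)
        return out

    def rate3(self, dist3) -> np.ndarray:
        d = np.asarray(dist3, dtype=int)
        return np.where(d < self.K, self.delta3[np.minimum(d, self.K - 1)], self.baseline)


def estimate_damage(observations, panel: Panel, K: int = 15) -> DamageProfile:
    """Estimate terminal C→T / G→A mismatch rates from aligned observations.

    For each distance ``d`` below the window ``K``, ``delta5[d]`` is the
    fraction of reads over reference-C positions at 5'-distance ``d``
    that read T (``delta3`` analogously for G→A by 3'-distance).  The
    baseline is the pooled C→T/G→A rate at interior distances (>= K);
    distances with no observations fall back to the baseline.
    """
    df = observations_frame(observations)
    ref = {s.site_id: s.ref for s in panel}
    refs = df["site_id"].map(ref)
    obs = df["obs_base"]

    is_c = (refs == "C").to_numpy()
    is_g = (refs == "G").to_numpy()
    ct = (is_c & (obs == "T").to_numpy())
    ga = (is_g & (obs == "A").to_numpy())
    d5 = df["dist5"].to_numpy(dtype=int)
    d3 = df["dist3"].to_numpy(dtype=int)

    if not is_c.any() and not is_g.any():
        warnings.warn("no reference C or G observations; returning all-baseline profile")
        return DamageProfile.none(K)

    interior = (is_c & (d5 >= K)) | (is_g & (d3 >= K))
    interior_mm = (ct & (d5 >= K)) | (ga & (d3 >= K))
    baseline = interior_mm.sum() / interior.sum() if interior.any() else 0.0

    delta5 = np.full(K, baseline)
    delta3 = np.full(K, baseline)
    for d in range(K):
        den5 = (is_c & (d5 == d)).sum()
        if den5:
            delta5[d] = (ct & (d5 == d)).sum() / den5
        den3 = (is_g & (d3 == d)).sum()
        if den3:
            delta3[d] = (ga & (d3 == d)).sum() / den3
    return DamageProfile(delta5, delta3, float(baseline), K)


def substitution_matrix(true_bases, e, dist5, dist3, damage: DamageProfile | None) -> np.ndarray:
    """Per-read substitution probabilities, rows over reads, columns A/C/G/T.

    Vectorised core shared by :func:`effective_substitution_prob`, the
    GL computation, and the read simulator (which draws from exactly
    this distribution, making simulation the model's inverse).
    """
    true_bases = np.asarray(true_bases, dtype=object)
    e = np.broadcast_to(np.asarray(e, dtype=float), true_bases.shape)
    n = len(true_bases)
    probs = np.tile(e[:, None] / 3.0, (1, 4))
    if damage is not None:
        r5 = damage.rate5(dist5)
        r3 = damage.rate3(dist3)
        c_mask = true_bases == "C"
        g_mask = true_bases == "G"
        probs[c_mask, _BASE_INDEX["T"]] = r5[c_mask] + (1 - r5[c_mask]) * e[c_mask] / 3.0
        probs[g_mask, _BASE_INDEX["A"]] = r3[g_mask] + (1 - r3[g_mask]) * e[g_mask] / 3.0
    ti = np.array([_BASE_INDEX[b] for b in true_bases])
    probs[np.arange(n), ti] = 0.0
    probs[np.arange(n), ti] = 1.0 - probs.sum(axis=1)
    return probs


def effective_substitution_prob(
    true_base: str,
    obs_base: str,
    e: float,
    dist5: int = 0,
    dist3: int = 0,
    damage: DamageProfile | None = None,
) -> float:
    """P(observed base | true template base) under the damage-aware model."""
    m = substitution_matrix(
        np.array([true_base], dtype=object), np.array([e]), [dist5], [dist3], damage
    )
    return float(m[0, _BASE_INDEX[obs_base]])


def compute_gl(observations, site, damage: DamageProfile | None = None):
    """Genotype-likelihood triple for one site from its read observations.

    For alt dosage g with unordered allele pair {a1, a2} the per-read
    contribution is the template-strand mixture
    ``0.5*P(obs|a1) + 0.5*P(obs|a2)``; reads multiply and the triple is
    max-normalised.  Bases that are neither ref nor alt still contribute
    through the substitution model.  Returns None when no observations
    survive the quality floor (the 1X minimum-depth rule).
    """
    from .panel_io import SiteLikelihood

    obs = [o for o in observations if o.base_quality >= MIN_BASE_QUALITY]
    if not obs:
        return None
    e = np.array([o.error_prob for o in obs])
    d5 = np.array([o.dist5 for o in obs])
    d3 = np.array([o.dist3 for o in obs])
    p_ref = substitution_matrix(
        np.full(len(obs), site.ref, dtype=object), e, d5, d3, damage
    )
    p_alt = substitution_matrix(
        np.full(len(obs), site.alt, dtype=object), e, d5, d3, damage
    )
    oi = np.array([_BASE_INDEX[o.obs_base] for o in obs])
    pr = p_ref[np.arange(len(obs)), oi]
    pa = p_alt[np.arange(len(obs)), oi]
    gl = np.array(
        [np.prod(pr), np.prod(0.5 * pr + 0.5 * pa), np.prod(pa)]
    )
    gl = gl / gl.max()
    return SiteLikelihood(site.site_id, tuple(gl), len(obs))


def _gl_from_arrays(site_idx, obs_idx, e, d5, d3, refs, alts, damage):
    """Vectorised GL computation over many sites at once.

    ``site_idx`` maps each read to its (sorted) site; returns per-site
    max-normalised GL triples and depths, in site order of appearance.
    """
    order = np.argsort(site_idx, kind="stable")
    site_idx = site_idx[order]
    obs_idx = obs_idx[order]
    e, d5, d3 = e[order], d5[order], d3[order]
    uniq, starts = np.unique(site_idx, return_index=True)

    p_ref = substitution_matrix(refs[site_idx], e, d5, d3, damage)
    p_alt = substitution_matrix(alts[site_idx], e, d5, d3, damage)
    r = np.arange(len(obs_idx))
    pr = p_ref[r, obs_idx]
    pa = p_alt[r, obs_idx]
    with np.errstate(divide="ignore"):
        logs = np.log(np.stack([pr, 0.5 * pr + 0.5 * pa, pa], axis=1))
    sums = np.add.reduceat(logs, starts, axis=0)
    sums -= sums.max(axis=1, keepdims=True)
    gl = np.exp(sums)
    depth = np.diff(np.append(starts, len(site_idx)))
    return uniq, gl, depth


def build_profile(
    observations,
    panel: Panel,
    sample_id: str,
    damage: DamageProfile | None = None,
    min_depth: int = 1,
    sample_type: str = "reference",
) -> SampleProfile:
    """Build a sample GL profile from its read observations.

    The profile contains exactly the panel sites with at least
    ``min_depth`` surviving reads; damage is applied only when a profile
    for a skeletal extract supplies a damage model (references pass
    ``damage=None``).  Deterministic given its inputs.
    """
    df = observations_frame(observations)
    if len(df) == 0:
        warnings.warn(f"{sample_id}: empty observation set")
        return SampleProfile(
            sample_id, np.array([], dtype=object), np.zeros((0, 3)), np.array([], int),
            sample_type=sample_type, damage=damage,
        )
    df = df[
        df["obs_base"].isin(BASES)
        & (df["base_quality"] >= MIN_BASE_QUALITY)
        & df["site_id"].isin(panel.index)
    ]
    if len(df) == 0:
        return SampleProfile(
            sample_id, np.array([], dtype=object), np.zeros((0, 3)), np.array([], int),
            sample_type=sample_type, damage=damage,
        )
    site_idx = df["site_id"].map(panel.index).to_numpy(dtype=int)
    obs_idx = df["obs_base"].map(_BASE_INDEX).to_numpy(dtype=int)
    e = 10.0 ** (-df["base_quality"].to_numpy(dtype=float) / 10.0)
    d5 = df["dist5"].to_numpy(dtype=int)
    d3 = df["dist3"].to_numpy(dtype=int)
    refs = np.array([s.ref for s in panel], dtype=object)
    alts = np.array([s.alt for s in panel], dtype=object)
    uniq, gl, depth = _gl_from_arrays(site_idx, obs_idx, e, d5, d3, refs, alts, damage)
    keep = depth >= min_depth
    site_ids = np.array([panel[i].site_id for i in uniq[keep]], dtype=object)
    return SampleProfile(
        sample_id, site_ids, gl[keep], depth[keep],
        sample_type=sample_type, damage=damage,
    )
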