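"""Supervised ancestry estimation and kinship frequency-file selection.

Global ancestry proportions ``q`` over five reference populations
(African, Native American, East Asian, Central/South Asian, European)
are estimated from a genotype-likelihood profile by supervised-admixture
EM with the population allele frequencies held fixed: the individual's
per-site alt frequency is the mixture ``f_i = sum_k q_k p_ik``, the
genotype prior is Binomial(2, f_i), and the likelihood marginalises the
GL triple over genotypes.  The E-step assigns each (expected) allele
copy to populations in proportion to its mixture responsibility; the
M-step averages the assignments.  This is the standard EM used for
GL-based admixture estimation; it never decreases the likelihood.

A sample is called admixed when its largest proportion is below 90%.
Admixed African+European samples use the African American kinship
allele-frequency file and Native American+European samples the Latino
file; every other case falls back to the majority population.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import clamp_frequencies
from .panel_io import SampleProfile

log = logging.getLogger(__name__)

GLOBAL_POPULATIONS = [
    "African",
    "NativeAmerican",
    "EastAsian",
    "CentralSouthAsian",
    "European",
]
ADMIXED_POPULATIONS = ["AfricanAmerican", "Latino"]

#: a sample is admixed when max(q) is below this
ADMIXED_CUTOFF = 0.90
#: an ancestry component counts as "present" for file selection above this
PRESENCE_THRESHOLD = 0.10
#: fewer usable sites than this triggers a low-confidence warning
MIN_SITES = 100


@dataclass
class AncestryResults:
    """Estimated ancestry proportions and the selected frequency file."""

    sample_id: str
    q: pd.Series
    n_sites: int
    n_iter: int
    log_likelihood: float
    converged: bool
    low_confidence: bool = False
    admixed: bool = field(init=False)
    selected_population: str = field(init=False)

    def __post_init__(self) -> None:
        self.admixed = is_admixed(self.q)
        self.selected_population = select_frequency_population(self.q)

    def summary(self) -> str:
        lines = [
            f"Ancestry estimate: {self.sample_id} "
            f"({self.n_sites} sites, {self.n_iter} EM iterations"
            f"{'' if self.converged else ', NOT converged'})"
        ]
        for pop, v in self.q.items():
            lines.append(f"  {pop:<18} {100 * v:6.2f}%")
        lines.append(f"  admixed: {'yes' if self.admixed else 'no'}")
        lines.append(f"  kinship frequency file: {self.selected_population}")
        if self.low_confidence:
            lines.append("  WARNING: fewer than 100 usable sites; low confidence")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(self.q.index, self.q.to_numpy())
        ax.axhline(ADMIXED_CUTOFF, ls="--", color="k", lw=0.8)
        ax.set_ylabel("ancestry proportion")
        ax.tick_params(axis="x", rotation=45)
        return ax


class AncestryModel:
    """Supervised admixture model for one GL profile.

    Parameters
    ----------
    profile
        Sample GL profile.
    pop_frequencies
        DataFrame indexed by site_id with one alt-frequency column per
        global reference population (all five must be present).
    """

    def __init__(self, profile: SampleProfile, pop_frequencies: pd.DataFrame):
        missing = set(GLOBAL_POPULATIONS) - set(pop_frequencies.columns)
        if missing:
            raise ValueError(f"missing population frequency columns: {sorted(missing)}")
        self.profile = profile
        self.pop_frequencies = pop_frequencies[GLOBAL_POPULATIONS]

    def fit(self, tol: float = 1e-6, max_iter: int = 300) -> AncestryResults:
        usable = [s for s in self.profile.site_ids if s in self.pop_frequencies.index]
        low_confidence = len(usable) < MIN_SITES
        if low_confidence:
            warnings.warn(
                f"{self.profile.sample_id}: only {len(usable)} usable sites; "
                "ancestry estimate is low-confidence"
            )
        gl = self.profile.gl_of(usable) if usable else np.zeros((0, 3))
        p = clamp_frequencies(self.pop_frequencies.loc[usable].to_numpy())  # (n, 5)
        q, n_iter, ll, converged = _em(gl, p, tol=tol, max_iter=max_iter)
        return AncestryResults(
            self.profile.sample_id,
            pd.Series(q, index=GLOBAL_POPULATIONS),
            len(usable),
            n_iter,
            ll,
            converged,
            low_confidence=low_confidence,
        )


def _loglik(gl: np.ndarray, f: np.ndarray) -> float:
    prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2], axis=1)
    per_site = np.einsum("ng,ng->n", gl, prior)
    return float(np.sum(np.log(np.maximum(per_site, 1e-300))))


def _em(gl: np.ndarray, p: np.ndarray, tol: float, max_iter: int):
    n, k = p.shape
    q = np.full(k, 1.0 / k)
    if n == 0:
        return q, 0, 0.0, True
    ll = _loglik(gl, p @ q)
    for it in range(1, max_iter + 1):
        f = p @ q  # (n,)
        prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2], axis=1)
        w = gl * prior
        w = w / w.sum(axis=1, keepdims=True)
        e_alt = w @ np.array([0.0, 1.0, 2.0])  # expected alt copies per site
        # allele-level responsibilities over populations
        resp_alt = q * p / f[:, None]
        resp_ref = q * (1 - p) / (1 - f)[:, None]
        q_new = (e_alt @ resp_alt + (2 - e_alt) @ resp_ref) / (2 * n)
        q_new = q_new / q_new.sum()
        delta = np.max(np.abs(q_new - q))
        q = q_new
        ll = _loglik(gl, p @ q)
        if delta < tol:
            return q, it, ll, True
    return q, max_iter, ll, False


def estimate_ancestry(profile: SampleProfile, pop_frequencies: pd.DataFrame, **kw) -> AncestryResults:
    """Functional wrapper: build an :class:`AncestryModel` and fit it."""
    return AncestryModel(profile, pop_frequencies).fit(**kw)


def is_admixed(q, cutoff: float = ADMIXED_CUTOFF) -> bool:
    """Admixed iff the highest global ancestry proportion is < ``cutoff``."""
    return bool(np.max(np.asarray(q, dtype=float)) < cutoff)


def select_frequency_population(
    q,
    cutoff: float = ADMIXED_CUTOFF,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> str:
    """Choose the kinship allele-frequency file from ancestry proportions.

    Non-admixed samples use their majority population.  Admixed samples
    with both African and European components present use the African
    American file; Native American plus European use the Latino file.
    When both rules could fire, the larger of the African and Native
    American proportions wins.  Any other admixture falls back to the
    majority population with a warning.
    """
    if isinstance(q, pd.Series):
        q = q.reindex(GLOBAL_POPULATIONS)
    else:
        q = pd.Series(np.asarray(q, dtype=float), index=GLOBAL_POPULATIONS)
    majority = str(q.idxmax())
    if not is_admixed(q, cutoff):
        return majority
    afr = q["African"] >= presence_threshold
    nat = q["NativeAmerican"] >= presence_threshold
    eur = q["European"] >= presence_threshold
    if afr and nat and eur:
        return "AfricanAmerican" if q["African"] >= q["NativeAmerican"] else "Latino"
    if afr and eur:
        return "AfricanAmerican"
    if nat and eur:
        return "Latino"
    warnings.warn(
        "admixed sample matches no admixed frequency file rule; "
        f"falling back to majority population {majority}"
    )
    return majority
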