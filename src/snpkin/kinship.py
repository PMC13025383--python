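"""Relationship inference over IBD hypotheses from genotype likelihoods.

Two low-coverage samples are compared under seven fixed relationship
hypotheses, each a vector ``k = (k0, k1, k2)`` of probabilities that the
pair shares 0, 1 or 2 alleles identical by descent at a locus:

=============== ======================
hypothesis       (k0, k1, k2)
=============== ======================
self             (0, 0, 1)
parent_child     (0, 1, 0)
full_sibling     (0.25, 0.5, 0.25)
second_degree    (0.5, 0.5, 0)
third_degree     (0.75, 0.25, 0)
fourth_degree    (0.875, 0.125, 0)
unrelated        (1, 0, 0)
=============== ======================

For alt-allele frequency ``p`` the joint genotype probability is the
k-mixture of the IBD0 (independent Hardy–Weinberg), IBD1 (one shared
allele) and IBD2 (identical genotype) tables.  Per site the genotype
likelihood triples of the two samples are summed against this 3x3 table;
log10 likelihoods accumulate over the (LD-pruned) overlapping sites.
Each hypothesis is reported with a log10 likelihood ratio versus
unrelated and a posterior probability under equal priors over the seven
hypotheses.  Inbreeding is ignored (no inbred IBD states), and genetic
linkage is not modelled — LD pruning is the independence safeguard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ldprune import dynamic_prune
from .panel_io import Panel, SampleProfile

#: allele-frequency clamp guarding against zero-probability hypotheses
FREQ_CLAMP = 1e-3

#: fixed hypothesis set, ordered from closest to most distant
HYPOTHESES: dict[str, tuple[float, float, float]] = {
    "self": (0.0, 0.0, 1.0),
    "parent_child": (0.0, 1.0, 0.0),
    "full_sibling": (0.25, 0.5, 0.25),
    "second_degree": (0.5, 0.5, 0.0),
    "third_degree": (0.75, 0.25, 0.0),
    "fourth_degree": (0.875, 0.125, 0.0),
    "unrelated": (1.0, 0.0, 0.0),
}

HYPOTHESIS_NAMES = list(HYPOTHESES)

#: default decision thresholds for strong statistical support
DEFAULT_LOG10_LR_MIN = 4.0
DEFAULT_PP_MIN = 0.9999


def clamp_frequencies(p, eps: float = FREQ_CLAMP) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)


def _hw(p: np.ndarray) -> np.ndarray:
    """Hardy–Weinberg genotype priors, shape (n, 3)."""
    q = 1.0 - p
    return np.stack([q * q, 2 * p * q, p * p], axis=-1)


def joint_tables(p) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IBD0/IBD1/IBD2 joint genotype tables for alt frequencies ``p``.

    Shapes (n, 3, 3); rows index the first sample's dosage, columns the
    second's.  Each table sums to one over the nine cells.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    q = 1.0 - p
    h = _hw(p)
    j0 = h[:, :, None] * h[:, None, :]
    j1 = np.zeros((len(p), 3, 3))
    j1[:, 0, 0] = q ** 3
    j1[:, 0, 1] = q * q * p
    j1[:, 1, 0] = p * q * q
    j1[:, 1, 1] = p * q
    j1[:, 1, 2] = p * p * q
    j1[:, 2, 1] = q * p * p
    j1[:, 2, 2] = p ** 3
    j2 = np.zeros((len(p), 3, 3))
    for g in range(3):
        j2[:, g, g] = h[:, g]
    return j0, j1, j2


def joint_genotype_prob(g1: int, g2: int, p: float, k) -> float:
    """P(g1, g2 | p, k): the k-mixture joint genotype probability."""
    if isinstance(k, str):
        k = HYPOTHESES[k]
    j0, j1, j2 = joint_tables([p])
    table = k[0] * j0[0] + k[1] * j1[0] + k[2] * j2[0]
    return float(table[g1, g2])


def relationship_log10_likelihood(gl_a, gl_b, p, k) -> float:
    """log10 likelihood of hypothesis ``k`` over a site set.

    ``gl_a``/``gl_b`` are (n, 3) genotype-likelihood arrays on matching
    sites, ``p`` the matching alt frequencies (already clamped).
    """
    if isinstance(k, str):
        k = HYPOTHESES[k]
    gl_a = np.atleast_2d(gl_a)
    gl_b = np.atleast_2d(gl_b)
    j0, j1, j2 = joint_tables(p)
    table = k[0] * j0 + k[1] * j1 + k[2] * j2
    per_site = np.einsum("nij,ni,nj->n", table, gl_a, gl_b)
    return float(np.sum(np.log10(np.maximum(per_site, 1e-300))))


def _all_hypothesis_log10(gl_a, gl_b, p) -> dict[str, float]:
    j0, j1, j2 = joint_tables(p)
    out = {}
    for name, (k0, k1, k2) in HYPOTHESES.items():
        table = k0 * j0 + k1 * j1 + k2 * j2
        per_site = np.einsum("nij,ni,nj->n", table, gl_a, gl_b)
        out[name] = float(np.sum(np.log10(np.maximum(per_site, 1e-300))))
    return out


@dataclass
class KinshipResults:
    """Per-hypothesis likelihoods, LRs and posterior probabilities.

    ``log10_lr`` is relative to the unrelated hypothesis (exactly 0 for
    unrelated itself); ``pp`` are posteriors under equal priors over the
    seven hypotheses, computed in log space with max-subtraction.  Ties
    in the argmax (measure zero) break toward the more distant category,
    the conservative direction for a forensic claim.
    """

    sample_a: str
    sample_b: str
    log10_likelihood: dict[str, float]
    n_overlap_raw: int
    n_overlap_pruned: int
    population: str | None = None
    failed: bool = False
    log10_lr: dict[str, float] = field(init=False)
    pp: dict[str, float] = field(init=False)
    most_likely: str = field(init=False)

    def __post_init__(self) -> None:
        if self.failed:
            self.log10_lr = {}
            self.pp = {}
            self.most_likely = "failed"
            return
        ll = np.array([self.log10_likelihood[h] for h in HYPOTHESIS_NAMES])
        self.log10_lr = {
            h: self.log10_likelihood[h] - self.log10_likelihood["unrelated"]
            for h in HYPOTHESIS_NAMES
        }
        shifted = ll - ll.max()
        w = 10.0 ** shifted
        pp = w / w.sum()
        self.pp = dict(zip(HYPOTHESIS_NAMES, pp))
        best = ll.max()
        # break exact ties toward the more distant relationship
        self.most_likely = [h for h in HYPOTHESIS_NAMES if ll[HYPOTHESIS_NAMES.index(h)] == best][-1]

    def classify(
        self,
        log10_lr_min: float = DEFAULT_LOG10_LR_MIN,
        pp_min: float = DEFAULT_PP_MIN,
    ) -> "KinshipCall":
        return classify(self, log10_lr_min=log10_lr_min, pp_min=pp_min)

    def to_frame(self) -> pd.DataFrame:
        if self.failed:
            return pd.DataFrame()
        return pd.DataFrame(
            {
                "hypothesis": HYPOTHESIS_NAMES,
                "log10_likelihood": [self.log10_likelihood[h] for h in HYPOTHESIS_NAMES],
                "log10_lr_vs_unrelated": [self.log10_lr[h] for h in HYPOTHESIS_NAMES],
                "posterior_probability": [self.pp[h] for h in HYPOTHESIS_NAMES],
            }
        )

    def summary(self) -> str:
        lines = [
            f"Kinship comparison: {self.sample_a} vs {self.sample_b}",
            f"  overlapping SNPs: {self.n_overlap_raw} raw, "
            f"{self.n_overlap_pruned} after LD pruning",
            f"  allele-frequency population: {self.population or 'n/a'}",
        ]
        if self.failed:
            lines.append("  status: FAILED (no usable overlapping sites)")
            return "\n".join(lines)
        lines.append(
            f"  {'hypothesis':<14} {'log10 L':>12} {'log10 LR':>10} {'PP':>10}"
        )
        for h in HYPOTHESIS_NAMES:
            lines.append(
                f"  {h:<14} {self.log10_likelihood[h]:>12.3f} "
                f"{self.log10_lr[h]:>10.3f} {self.pp[h]:>10.6f}"
            )
        lines.append(f"  most likely: {self.most_likely}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar chart of log10 LR per hypothesis (lazy matplotlib import)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        names = [h for h in HYPOTHESIS_NAMES if h != "unrelated"]
        ax.bar(names, [self.log10_lr[h] for h in names])
        ax.axhline(DEFAULT_LOG10_LR_MIN, ls="--", color="k", lw=0.8)
        ax.set_ylabel("log10 LR vs unrelated")
        ax.tick_params(axis="x", rotation=45)
        return ax


@dataclass(frozen=True)
class KinshipCall:
    """A kinship result together with its conclusiveness status."""

    result: KinshipResults
    status: str  # conclusive | inconclusive | failed
    log10_lr_min: float
    pp_min: float

    @property
    def most_likely(self) -> str:
        return self.result.most_likely


def classify(
    result: KinshipResults,
    log10_lr_min: float = DEFAULT_LOG10_LR_MIN,
    pp_min: float = DEFAULT_PP_MIN,
) -> KinshipCall:
    """Apply the strong-support thresholds to a kinship result.

    Conclusive iff the most likely category's posterior meets ``pp_min``
    and (for any category other than unrelated) its log10 LR versus
    unrelated meets ``log10_lr_min``; an unrelated call is judged on its
    posterior alone.
    """
    if result.failed:
        return KinshipCall(result, "failed", log10_lr_min, pp_min)
    h = result.most_likely
    ok = result.pp[h] >= pp_min and (
        h == "unrelated" or result.log10_lr[h] >= log10_lr_min
    )
    return KinshipCall(result, "conclusive" if ok else "inconclusive", log10_lr_min, pp_min)


class KinshipModel:
    """Pairwise kinship model for two GL profiles.

    Parameters
    ----------
    profile_a, profile_b
        Sample GL profiles (normally a skeletal sample and a reference).
    frequencies
        Allele-frequency table (DataFrame indexed by site_id, one column
        per population) or a site_id -> frequency mapping/Series.
    population
        Column of ``frequencies`` to use.  Defaults to its only column;
        choosing it from estimated ancestry is the caller's job (see
        :mod:`snpkin.ancestry`).
    ld_table
        Stored LD pairs for dynamic pruning; ``None`` disables pruning.
    panel
        Optional panel, used for canonical site ordering.
    """

    def __init__(
        self,
        profile_a: SampleProfile,
        profile_b: SampleProfile,
        frequencies,
        population: str | None = None,
        ld_table=None,
        panel: Panel | None = None,
    ):
        self.profile_a = profile_a
        self.profile_b = profile_b
        self.panel = panel
        self.ld_table = ld_table
        if isinstance(frequencies, pd.DataFrame):
            if population is None:
                if frequencies.shape[1] != 1:
                    raise ValueError(
                        "frequency table has several populations; pass population="
                    )
                population = str(frequencies.columns[0])
            self.freq = frequencies[population]
        else:
            self.freq = pd.Series(frequencies)
        self.population = population

    def fit(self) -> KinshipResults:
        a, b = self.profile_a, self.profile_b
        overlap = dynamic_prune(a, b, None, panel=self.panel)
        pruned = dynamic_prune(a, b, self.ld_table, panel=self.panel)
        pruned = [s for s in pruned if s in self.freq.index]
        if len(pruned) == 0:
            return KinshipResults(
                a.sample_id, b.sample_id, {}, len(overlap), 0,
                population=self.population, failed=True,
            )
        p = clamp_frequencies(self.freq.loc[pruned].to_numpy())
        gl_a = a.gl_of(pruned)
        gl_b = b.gl_of(pruned)
        ll = _all_hypothesis_log10(gl_a, gl_b, p)
        return KinshipResults(
            a.sample_id, b.sample_id, ll, len(overlap), len(pruned),
            population=self.population,
        )


def kinship_compare(
    profile_a: SampleProfile,
    profile_b: SampleProfile,
    frequencies,
    ld_table=None,
    population: str | None = None,
    panel: Panel | None = None,
) -> KinshipResults:
    """Functional wrapper: build a :class:`KinshipModel` and fit it."""
    return KinshipModel(
        profile_a, profile_b, frequencies,
        population=population, ld_table=ld_table, panel=panel,
    ).fit()
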