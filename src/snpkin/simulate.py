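"""Synthetic low-coverage SNP capture data and a validation-study driver.

Every upstream input can be simulated: panels, population allele
frequencies (Balding–Nichols around a shared ancestral frequency),
IBD-conditional genotype pairs, admixed genotypes, Poisson-depth read
observations with quality-derived base error and terminal deamination,
sporadic control blanks, and an all-vs-all case-type study.

Simulation is the exact inverse of the inference model: IBD states are
drawn i.i.d. per site from (k0, k1, k2) — genetic linkage is
deliberately not simulated, matching the inference model's independence
assumption — and read bases are drawn from the same substitution matrix
the genotype-likelihood computation inverts.  That makes
parameter-recovery tests sharp: any systematic disagreement is a bug,
not model misspecification.

Default conditions emulate the validated capture workflow at desk
scale: minor allele frequencies Uniform(0.05, 0.5) (the panel targets
common SNPs), Poisson read depth with mean 4, base error 0.01 (Q20),
fragment lengths uniform on 40–120 bp for degraded skeletal material
and 200–500 bp for references (which affects only where within a read a
site falls, hence the damage position draws).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import qc
from .genolik import DamageProfile, build_profile, substitution_matrix
from .kinship import (
    HYPOTHESES,
    HYPOTHESIS_NAMES,
    kinship_compare,
)
from .panel_io import BASES, Panel, PanelSite

_BASE_ARR = np.array(BASES, dtype=object)


@dataclass
class SimConfig:
    """Generator settings; ``seed`` fixes every draw."""

    n_sites: int = 5000
    maf_low: float = 0.05
    maf_high: float = 0.5
    depth: float = 4.0  # Poisson mean per site
    error: float = 0.01  # per-base error probability (Q20)
    damage: DamageProfile | None = None
    frag_min: int = 200
    frag_max: int = 500
    fst: float = 0.1
    seed: int = 0

    @classmethod
    def skeletal(cls, **kw) -> "SimConfig":
        """Degraded-sample preset: short fragments (damage positions
        concentrate near read ends)."""
        return cls(frag_min=40, frag_max=120, **kw)

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_panel(n_sites: int, rng=None, chrom: str = "1") -> Panel:
    """A synthetic biallelic panel with random distinct ref/alt alleles."""
    rng = np.random.default_rng(rng)
    refs = rng.integers(0, 4, n_sites)
    alts = (refs + rng.integers(1, 4, n_sites)) % 4
    sites = [
        PanelSite(f"rs{i:07d}", chrom, 1000 + i * 1000, BASES[r], BASES[a])
        for i, (r, a) in enumerate(zip(refs, alts))
    ]
    return Panel(sites)


def simulate_frequencies(
    panel_or_n,
    populations=("European",),
    fst: float = 0.1,
    rng=None,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
) -> pd.DataFrame:
    """Per-population alt frequencies via the Balding–Nichols model.

    An ancestral frequency is drawn Uniform(maf_low, maf_high) per site;
    each population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) around
    it.  As F -> 0 the populations collapse onto the ancestral value.
    """
    rng = np.random.default_rng(rng)
    if isinstance(panel_or_n, Panel):
        site_ids = panel_or_n.site_ids
    else:
        site_ids = [f"rs{i:07d}" for i in range(int(panel_or_n))]
    n = len(site_ids)
    p_anc = rng.uniform(maf_low, maf_high, n)
    cols = {}
    ratio = (1.0 - fst) / fst if fst > 0 else None
    for pop in populations:
        if ratio is None:
            cols[pop] = p_anc.copy()
        else:
            cols[pop] = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio)
    df = pd.DataFrame(cols, index=pd.Index(site_ids, name="site_id"))
    return df.clip(1e-6, 1 - 1e-6)


def simulate_genotype_pair(p, hypothesis, rng=None, return_states: bool = False):
    """Joint genotypes for a pair under an IBD hypothesis.

    Per site an IBD state is drawn from (k0, k1, k2); under IBD0 the two
    genotypes are independent Hardy–Weinberg draws, under IBD1 they
    share one allele drawn from the frequency, and under IBD2 the
    genotype is copied.  This inverts exactly the joint tables used by
    the kinship likelihood.
    """
    rng = np.random.default_rng(rng)
    p = np.asarray(p, dtype=float)
    k = np.asarray(HYPOTHESES[hypothesis] if isinstance(hypothesis, str) else hypothesis)
    n = len(p)
    state = rng.choice(3, size=n, p=k)
    shared = (rng.random(n) < p).astype(int)
    extra_a = (rng.random(n) < p).astype(int)
    extra_b = (rng.random(n) < p).astype(int)
    hw_a = rng.binomial(2, p)
    hw_b = rng.binomial(2, p)
    g_a = np.select([state == 0, state == 1, state == 2], [hw_a, shared + extra_a, hw_a])
    g_b = np.select([state == 0, state == 1, state == 2], [hw_b, shared + extra_b, hw_a])
    if return_states:
        return g_a, g_b, state
    return g_a, g_b


def simulate_relative_given(g_a, p, hypothesis, rng=None) -> np.ndarray:
    """Genotypes of a relative conditional on an existing individual.

    Draws from the conditional of the IBD joint table given ``g_a``:
    per site an IBD state is drawn from k; IBD2 copies the genotype,
    IBD1 passes one uniformly chosen allele of ``g_a`` and adds an
    independent population allele, IBD0 is an independent
    Hardy–Weinberg draw.  Used when one individual is related to
    several others.
    """
    rng = np.random.default_rng(rng)
    p = np.asarray(p, dtype=float)
    g_a = np.asarray(g_a, dtype=int)
    k = np.asarray(HYPOTHESES[hypothesis] if isinstance(hypothesis, str) else hypothesis)
    n = len(p)
    state = rng.choice(3, size=n, p=k)
    shared = (rng.random(n) < g_a / 2.0).astype(int)
    extra = (rng.random(n) < p).astype(int)
    hw = rng.binomial(2, p)
    return np.select([state == 0, state == 1, state == 2], [hw, shared + extra, g_a])


def simulate_admixed_genotypes(pop_frequencies: pd.DataFrame, q, rng=None) -> np.ndarray:
    """Genotypes of an admixed individual: Binomial(2, sum_k q_k p_k)."""
    rng = np.random.default_rng(rng)
    q = np.asarray(q, dtype=float)
    if not np.isclose(q.sum(), 1.0):
        raise ValueError("ancestry proportions must sum to 1")
    f = pop_frequencies.to_numpy() @ q
    return rng.binomial(2, f)


def simulate_observations(genotypes, panel: Panel, config: SimConfig, rng=None) -> pd.DataFrame:
    """Reads over panel sites for one individual.

    Depth is Poisson(config.depth) per site; each read carries the site
    on a fragment of uniform length between ``frag_min`` and
    ``frag_max`` at a uniform position, and its base is drawn from the
    damage-aware substitution matrix.  Sites with zero reads produce no
    records.  Returns the columnar observation table consumed by
    :func:`snpkin.genolik.build_profile`.
    """
    rng = np.random.default_rng(rng)
    genotypes = np.asarray(genotypes, dtype=int)
    n = len(genotypes)
    if n != len(panel):
        raise ValueError("genotype vector length must match panel size")
    depths = rng.poisson(config.depth, n)
    site_rep = np.repeat(np.arange(n), depths)
    m = len(site_rep)
    if m == 0:
        return pd.DataFrame(
            columns=["site_id", "obs_base", "base_quality", "dist5", "dist3"]
        )
    refs = np.array([s.ref for s in panel], dtype=object)
    alts = np.array([s.alt for s in panel], dtype=object)
    take_alt = rng.random(m) < genotypes[site_rep] / 2.0
    true = np.where(take_alt, alts[site_rep], refs[site_rep])
    frag = rng.integers(config.frag_min, config.frag_max + 1, m)
    pos = rng.integers(0, frag)
    d5 = pos
    d3 = frag - 1 - pos
    e = np.full(m, config.error)
    probs = substitution_matrix(true, e, d5, d3, config.damage)
    u = rng.random(m)
    obs_idx = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    # cap the written quality at Q90 so a zero error rate stays finite
    quality = int(round(-10.0 * np.log10(max(config.error, 1e-9))))
    site_ids = np.array(panel.site_ids, dtype=object)[site_rep]
    return pd.DataFrame(
        {
            "site_id": site_ids,
            "obs_base": _BASE_ARR[np.minimum(obs_idx, 3)],
            "base_quality": quality,
            "dist5": d5,
            "dist3": d3,
        }
    )


def simulate_blank(panel: Panel, frequencies, rate: float, rng=None, quality: int = 20) -> pd.DataFrame:
    """Sporadic background signal: each panel site is covered
    independently with probability ``rate`` at depth 1, the base drawn
    from the population allele frequency (no single-source genome)."""
    rng = np.random.default_rng(rng)
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    covered = np.nonzero(rng.random(len(panel)) < rate)[0]
    p = np.asarray(frequencies, dtype=float)[covered]
    take_alt = rng.random(len(covered)) < p
    refs = np.array([s.ref for s in panel], dtype=object)
    alts = np.array([s.alt for s in panel], dtype=object)
    obs = np.where(take_alt, alts[covered], refs[covered])
    return pd.DataFrame(
        {
            "site_id": np.array(panel.site_ids, dtype=object)[covered],
            "obs_base": obs,
            "base_quality": quality,
            "dist5": 30,
            "dist3": 30,
        }
    )


def simulate_profile_pair(
    hypothesis,
    config: SimConfig,
    rng=None,
    panel: Panel | None = None,
    frequencies=None,
):
    """Convenience: a related pair end-to-end (panel, freqs, genotypes,
    reads, GL profiles).  Returns (profile_a, profile_b, frequencies)."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    if panel is None:
        panel = simulate_panel(config.n_sites, rng)
    if frequencies is None:
        frequencies = simulate_frequencies(
            panel, ("pop",), fst=0.0, rng=rng,
            maf_low=config.maf_low, maf_high=config.maf_high,
        )
    p = frequencies.iloc[:, 0].to_numpy()
    g_a, g_b = simulate_genotype_pair(p, hypothesis, rng)
    obs_a = simulate_observations(g_a, panel, config, rng)
    obs_b = simulate_observations(g_b, panel, config, rng)
    prof_a = build_profile(obs_a, panel, "A", damage=config.damage)
    prof_b = build_profile(obs_b, panel, "B", damage=config.damage)
    return prof_a, prof_b, frequencies


# ---------------------------------------------------------------------------
# Report arithmetic (used by the study driver's summary tables)


def panel_fraction_count(fraction: float, panel_size: int = qc.PANEL_SIZE) -> int:
    """Number of panel SNPs corresponding to a recovery fraction."""
    return int(fraction * panel_size)


def study_design_counts(n_queries: int, n_refs: int, related_counts: dict) -> dict:
    """All-vs-all comparison bookkeeping for a case-type study design."""
    total = n_queries * n_refs
    related = int(sum(related_counts.values()))
    return {
        "n_comparisons": total,
        "n_related_expected": related,
        "n_unrelated_expected": total - related,
    }


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage as printed in summary tables."""
    return round(100.0 * count / total, ndigits)


# ---------------------------------------------------------------------------
# Validation-study driver


@dataclass
class StudyConfig:
    """Design of a simulated all-vs-all case-type study.

    ``related_pairs`` maps (query index, reference index) to a
    relationship category; every other query/reference pair is
    unrelated.  ``query_sites`` optionally caps the number of panel
    sites a query covers, emulating variable skeletal SNP recovery.
    """

    n_queries: int = 2
    n_refs: int = 3
    n_sites: int = 2000
    depth_query: float = 4.0
    depth_ref: float = 10.0
    error: float = 0.01
    seed: int = 0
    related_pairs: dict = field(default_factory=dict)
    query_sites: dict = field(default_factory=dict)
    log10_lr_min: float = 4.0

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        pairs = {}
        for q, r, cat in d.pop("related_pairs", []):
            pairs[(int(q), int(r))] = cat
        d["related_pairs"] = pairs
        d["query_sites"] = {int(k): int(v) for k, v in d.pop("query_sites", {}).items()}
        return cls(**d)


def run_validation_study(config: StudyConfig) -> dict:
    """Simulate the study and run every pairwise kinship comparison.

    Returns a dict of DataFrames: ``comparisons`` (one row per pair),
    ``related_summary`` (per-category conclusive counts at the 95% and
    99.99% posterior thresholds) and ``unrelated_summary`` (distribution
    of most-likely calls for expected-unrelated pairs), plus the design
    bookkeeping under ``design``.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    panel = simulate_panel(config.n_sites, rng)
    freqs = simulate_frequencies(panel, ("pop",), fst=0.0, rng=rng)
    p = freqs["pop"].to_numpy()

    g_query = [None] * config.n_queries
    g_ref = [None] * config.n_refs
    for (qi, ri), cat in sorted(config.related_pairs.items()):
        if g_query[qi] is None:
            g_q, g_r = simulate_genotype_pair(p, cat, rng)
            g_query[qi] = g_q
        else:
            g_r = simulate_relative_given(g_query[qi], p, cat, rng)
        g_ref[ri] = g_r
    for i in range(config.n_queries):
        if g_query[i] is None:
            g_query[i] = rng.binomial(2, p)
    for i in range(config.n_refs):
        if g_ref[i] is None:
            g_ref[i] = rng.binomial(2, p)

    cfg_q = SimConfig.skeletal(
        n_sites=config.n_sites, depth=config.depth_query, error=config.error
    )
    cfg_r = SimConfig(
        n_sites=config.n_sites, depth=config.depth_ref, error=config.error
    )
    profiles_q = []
    for i, g in enumerate(g_query):
        obs = simulate_observations(g, panel, cfg_q, rng)
        cap = config.query_sites.get(i)
        if cap is not None and cap < config.n_sites:
            keep = set(
                np.array(panel.site_ids, dtype=object)[
                    rng.choice(config.n_sites, cap, replace=False)
                ]
            )
            obs = obs[obs["site_id"].isin(keep)]
        profiles_q.append(
            build_profile(obs, panel, f"Q{i}", sample_type="skeletal")
        )
    profiles_r = [
        build_profile(
            simulate_observations(g, panel, cfg_r, rng), panel, f"R{i}"
        )
        for i, g in enumerate(g_ref)
    ]

    rows = []
    for qi, pq in enumerate(profiles_q):
        for ri, pr in enumerate(profiles_r):
            expected = config.related_pairs.get((qi, ri), "unrelated")
            res = kinship_compare(pq, pr, freqs, population="pop", panel=panel)
            call95 = res.classify(config.log10_lr_min, 0.95)
            call9999 = res.classify(config.log10_lr_min, 0.9999)
            rows.append(
                {
                    "query": pq.sample_id,
                    "ref": pr.sample_id,
                    "expected": expected,
                    "most_likely": res.most_likely,
                    "n_overlap_raw": res.n_overlap_raw,
                    "n_overlap_pruned": res.n_overlap_pruned,
                    "log10_lr": res.log10_lr.get(res.most_likely, np.nan),
                    "pp": res.pp.get(res.most_likely, np.nan),
                    "status_95": call95.status,
                    "status_9999": call9999.status,
                }
            )
    comparisons = pd.DataFrame(rows)

    related = comparisons[comparisons["expected"] != "unrelated"]
    rel_rows = []
    for cat in HYPOTHESIS_NAMES:
        sub = related[related["most_likely"] == cat]
        rel_rows.append(
            {
                "category": cat,
                "expected": int((related["expected"] == cat).sum()),
                "n_pp95": int((sub["status_95"] == "conclusive").sum()),
                "n_pp9999": int((sub["status_9999"] == "conclusive").sum()),
                "n_inconclusive": int((sub["status_9999"] != "conclusive").sum()),
            }
        )
    related_summary = pd.DataFrame(rel_rows)

    unrelated = comparisons[comparisons["expected"] == "unrelated"]
    n_unrel = max(len(unrelated), 1)
    unrel_rows = []
    for cat in HYPOTHESIS_NAMES:
        sub = unrelated[unrelated["most_likely"] == cat]
        unrel_rows.append(
            {
                "category": cat,
                "n_total": len(sub),
                "pct_total": percent(len(sub), n_unrel),
                "n_pp95": int((sub["status_95"] == "conclusive").sum()),
                "n_pp9999": int((sub["status_9999"] == "conclusive").sum()),
            }
        )
    unrelated_summary = pd.DataFrame(unrel_rows)

    design = study_design_counts(
        config.n_queries,
        config.n_refs,
        {c: list(config.related_pairs.values()).count(c) for c in set(config.related_pairs.values())},
    )
    return {
        "comparisons": comparisons,
        "related_summary": related_summary,
        "unrelated_summary": unrelated_summary,
        "design": design,
        "seed": config.seed,
    }
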