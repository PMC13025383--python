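"""Pairwise LD (r²) from a reference dosage panel and dynamic pruning.

The kinship likelihood assumes marker independence, so before each
pairwise comparison the overlapping SNP set is pruned: for every stored
pair in LD (r² >= 0.2 within a 1000-SNP window, mirroring plink's
``--r2 --ld-window-r2`` semantics) the member with the lower combined
coverage across the two samples is removed.  Pruning is per comparison
("dynamic") because the overlap and the depths differ for every sample
pair.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .panel_io import Panel, SampleProfile

#: plink-style defaults used throughout
DEFAULT_WINDOW = 1000
DEFAULT_R2_MIN = 0.2


def pairwise_r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation of two dosage vectors (0/1/2).

    Missing values (NaN) are handled pairwise-complete.  Monomorphic or
    degenerate input (fewer than two complete pairs, zero variance)
    returns 0 by convention.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        warnings.warn("fewer than 2 complete pairs; r2 set to 0")
        return 0.0
    a, b = a[ok], b[ok]
    va = a - a.mean()
    vb = b - b.mean()
    den = (va @ va) * (vb @ vb)
    if den == 0:
        return 0.0
    r = (va @ vb) / np.sqrt(den)
    return float(r * r)


def build_ld_table(
    dosage_matrix,
    site_ids,
    window: int = DEFAULT_WINDOW,
    r2_min: float = DEFAULT_R2_MIN,
) -> pd.DataFrame:
    """All within-window site pairs with r² >= ``r2_min``.

    ``dosage_matrix`` has one row per reference individual and one
    column per panel site, columns in panel (chrom, pos) order; the
    window is counted in panel SNP indices, not base pairs.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    mat = np.asarray(dosage_matrix, dtype=float)
    n_sites = mat.shape[1]
    has_nan = np.isnan(mat).any()
    rows_a, rows_b, rows_r2 = [], [], []
    if not has_nan:
        centred = mat - mat.mean(axis=0)
        norms = np.einsum("ij,ij->j", centred, centred)
    for d in range(1, min(window, n_sites - 1) + 1):
        if has_nan:
            r2 = np.array(
                [pairwise_r2(mat[:, j], mat[:, j + d]) for j in range(n_sites - d)]
            )
        else:
            num = np.einsum("ij,ij->j", centred[:, :-d], centred[:, d:])
            den = norms[:-d] * norms[d:]
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = np.where(den > 0, num * num / den, 0.0)
        for j in np.nonzero(r2 >= r2_min)[0]:
            rows_a.append(site_ids[j])
            rows_b.append(site_ids[j + d])
            rows_r2.append(float(r2[j]))
    table = pd.DataFrame({"site_id_a": rows_a, "site_id_b": rows_b, "r2": rows_r2})
    return table.sort_values(["site_id_a", "site_id_b"], ignore_index=True)


def dynamic_prune(
    profile_a: SampleProfile,
    profile_b: SampleProfile,
    ld_table: pd.DataFrame | None,
    panel: Panel | None = None,
) -> list:
    """Comparison-specific LD pruning of the two profiles' overlap.

    Starting from the sites present in both profiles, each stored LD
    pair with both members still retained loses the member with the
    lower coverage score (sum of the two samples' depths at the site);
    ties retain the site earlier in panel order.  The result is
    idempotent and symmetric in the sample labels.
    """
    if panel is not None:
        order = panel.index
        overlap = [s for s in panel.site_ids if s in profile_a and s in profile_b]
    else:
        order = {s: i for i, s in enumerate(profile_a.site_ids)}
        overlap = [s for s in profile_a.site_ids if s in profile_b]
    retained = set(overlap)
    if ld_table is None or len(ld_table) == 0:
        return overlap

    score = {
        s: int(profile_a.depth[profile_a.index[s]]) + int(profile_b.depth[profile_b.index[s]])
        for s in overlap
    }
    pairs = [
        (order.get(a, -1), order.get(b, -1), a, b)
        for a, b in zip(ld_table["site_id_a"], ld_table["site_id_b"])
        if a in retained and b in retained
    ]
    for _, _, a, b in sorted(pairs):
        if a in retained and b in retained:
            if score[a] < score[b]:
                retained.discard(a)
            elif score[b] < score[a]:
                retained.discard(b)
            else:
                # tie: keep the earlier site in panel order (a <= b there)
                drop = b if order.get(a, 0) <= order.get(b, 0) else a
                retained.discard(drop)
    return [s for s in overlap if s in retained]
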