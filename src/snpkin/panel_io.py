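"""Readers and writers for every on-disk artifact.

All formats are plain text: the SNP panel is a five-column TSV (or a
sites-only VCF), allele frequencies are a TSV with one column per
population, per-read observations are a six-column TSV, and sample
genotype-likelihood profiles use the Beagle GL text layout (the de-facto
exchange format for low-coverage pipelines) with read depth carried in a
small sidecar TSV, because the Beagle layout itself has no depth field.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")


class PanelError(ValueError):
    """Raised when a panel, frequency, or observation file is malformed."""


@dataclass(frozen=True)
class PanelSite:
    """One biallelic SNP on the capture panel (1-based VCF coordinates)."""

    site_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise PanelError(
                f"{self.site_id}: alleles must be A/C/G/T, got {self.ref}/{self.alt}"
            )
        if self.ref == self.alt:
            raise PanelError(f"{self.site_id}: ref and alt alleles are identical")


class Panel(Sequence):
    """An ordered collection of panel sites with fast site_id lookup.

    Sites are kept in canonical (chrom, pos) order; two reads of the same
    file always yield identical ordering.
    """

    def __init__(self, sites: Iterable[PanelSite]):
        sites = sorted(sites, key=lambda s: (s.chrom, s.pos))
        seen: set[str] = set()
        for s in sites:
            if s.site_id in seen:
                raise PanelError(f"duplicate site_id {s.site_id!r} in panel")
            seen.add(s.site_id)
        self._sites: list[PanelSite] = sites
        self.index: dict[str, int] = {s.site_id: i for i, s in enumerate(sites)}

    def __len__(self) -> int:
        return len(self._sites)

    def __getitem__(self, i):
        return self._sites[i]

    def __iter__(self) -> Iterator[PanelSite]:
        return iter(self._sites)

    def __contains__(self, site_id) -> bool:  # type: ignore[override]
        return site_id in self.index

    def site(self, site_id: str) -> PanelSite:
        return self._sites[self.index[site_id]]

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self._sites]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": [s.site_id for s in self._sites],
                "chrom": [s.chrom for s in self._sites],
                "pos": [s.pos for s in self._sites],
                "ref": [s.ref for s in self._sites],
                "alt": [s.alt for s in self._sites],
            }
        )


def read_panel(path) -> Panel:
    """Read a panel site list from TSV (site_id, chrom, pos, ref, alt) or a
    sites-only VCF (``.vcf`` suffix; the ID column supplies site_ids)."""
    path = str(path)
    if path.endswith(".vcf"):
        return _read_panel_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"site_id", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"panel file missing columns: {sorted(missing)}")
    sites = [
        PanelSite(str(r.site_id), str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples(index=False)
    ]
    return Panel(sites)


def _read_panel_vcf(path: str) -> Panel:
    sites = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 5:
                raise PanelError(f"malformed VCF line: {line.rstrip()!r}")
            chrom, pos, vid, ref, alt = f[0], int(f[1]), f[2], f[3], f[4]
            if vid in (".", ""):
                vid = f"{chrom}_{pos}"
            sites.append(PanelSite(vid, chrom, pos, ref, alt))
    return Panel(sites)


def write_panel(panel: Panel, path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Allele-frequency tables


def read_frequencies(path, panel: Panel | None = None) -> pd.DataFrame:
    """Read an allele-frequency TSV (site_id, then one column per population).

    Returns a DataFrame indexed by site_id whose columns are population
    labels and whose values are alt-allele frequencies in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str}).set_index("site_id")
    bad = df.columns[((df < 0) | (df > 1)).any()]
    if len(bad):
        raise PanelError(f"allele frequencies outside [0,1] in columns {list(bad)}")
    if panel is not None:
        missing = set(panel.site_ids) - set(df.index)
        if missing:
            raise PanelError(
                f"{len(missing)} panel sites missing from frequency table "
                f"(e.g. {sorted(missing)[:3]})"
            )
        df = df.loc[panel.site_ids]
    return df


def write_frequencies(freqs: pd.DataFrame, path) -> None:
    freqs.rename_axis("site_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Per-read observations


@dataclass(frozen=True)
class SiteObservation:
    """A single sequenced base over a panel site.

    ``dist5``/``dist3`` are distances (in bases) of the observed position
    from the original 5' and 3' ends of the read, which the deamination
    model consumes.
    """

    site_id: str
    obs_base: str
    base_quality: int
    dist5: int
    dist3: int

    @property
    def error_prob(self) -> float:
        return 10.0 ** (-self.base_quality / 10.0)


OBS_COLUMNS = ["sample_id", "site_id", "obs_base", "base_quality", "dist5", "dist3"]


def read_observations(path, min_quality: int = 2):
    """Read a per-read observation TSV into per-sample observation lists.

    Rows with a non-ACGT observed base or a quality below ``min_quality``
    are dropped and counted (logged), not treated as errors: low-quality
    tails are expected in capture data.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"sample_id": str, "site_id": str, "obs_base": str},
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PanelError(f"cannot parse observation file {path}: {exc}") from exc
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise PanelError(f"observation file missing columns: {sorted(missing)}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if not np.isfinite(row.base_quality) or row.dist5 < 0 or row.dist3 < 0:
            raise PanelError(f"{path}: malformed observation at line {i}")
    n_bad_base = int((~df["obs_base"].isin(BASES)).sum())
    n_low_q = int((df["base_quality"] < min_quality).sum())
    if n_bad_base or n_low_q:
        log.info(
            "dropped %d non-ACGT and %d low-quality observations", n_bad_base, n_low_q
        )
    df = df[df["obs_base"].isin(BASES) & (df["base_quality"] >= min_quality)]
    out: dict[str, list[SiteObservation]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.sample_id, []).append(
            SiteObservation(
                r.site_id, r.obs_base, int(r.base_quality), int(r.dist5), int(r.dist3)
            )
        )
    return out


def observations_frame(observations: Sequence[SiteObservation]) -> pd.DataFrame:
    """Columnar view of an observation list (internal fast path)."""
    if isinstance(observations, pd.DataFrame):
        return observations
    return pd.DataFrame(
        {
            "site_id": [o.site_id for o in observations],
            "obs_base": [o.obs_base for o in observations],
            "base_quality": [o.base_quality for o in observations],
            "dist5": [o.dist5 for o in observations],
            "dist3": [o.dist3 for o in observations],
        }
    )


def write_observations(obs_by_sample: Mapping[str, Sequence], path) -> None:
    frames = []
    for sample_id, obs in obs_by_sample.items():
        df = observations_frame(obs).copy()
        df.insert(0, "sample_id", sample_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample GL profiles (Beagle genotype-likelihood text + depth sidecar)


@dataclass
class SampleProfile:
    """Per-site genotype-likelihood triples and read depths for one sample.

    ``gl`` rows are likelihoods for alt-allele dosage 0/1/2, max-normalised
    per site.  Only sites covered by at least ``min_depth`` reads are
    present.  ``sample_type`` is one of reference/skeletal/blank and
    controls whether the damage model was applied upstream.
    """

    sample_id: str
    site_ids: np.ndarray
    gl: np.ndarray
    depth: np.ndarray
    sample_type: str = "reference"
    damage: object | None = None
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        self.gl = np.asarray(self.gl, dtype=float).reshape(-1, 3)
        self.depth = np.asarray(self.depth, dtype=int)
        if np.any(self.gl < 0):
            raise PanelError(f"{self.sample_id}: negative genotype likelihood")
        if len(self.site_ids):
            m = self.gl.max(axis=1)
            if np.any(m <= 0):
                raise PanelError(f"{self.sample_id}: all-zero likelihood triple")
            self.gl = self.gl / m[:, None]
        self._index = {s: i for i, s in enumerate(self.site_ids)}

    def __len__(self) -> int:
        return len(self.site_ids)

    def __contains__(self, site_id) -> bool:
        return site_id in self._index

    @property
    def index(self) -> dict:
        return self._index

    @property
    def n_1x(self) -> int:
        return int((self.depth >= 1).sum())

    def site(self, site_id: str):
        i = self._index[site_id]
        return SiteLikelihood(site_id, tuple(self.gl[i]), int(self.depth[i]))

    def depth_of(self, site_ids) -> np.ndarray:
        return np.array([self.depth[self._index[s]] for s in site_ids], dtype=int)

    def gl_of(self, site_ids) -> np.ndarray:
        rows = [self._index[s] for s in site_ids]
        return self.gl[rows]

    def depth_map(self) -> dict:
        return {s: int(d) for s, d in zip(self.site_ids, self.depth)}


@dataclass(frozen=True)
class SiteLikelihood:
    site_id: str
    gl: tuple
    depth: int


def _depth_sidecar(path) -> str:
    return str(path) + ".depth.tsv"


def write_profile(profile: SampleProfile, path) -> None:
    """Write a profile as Beagle GL text plus a depth sidecar TSV."""
    with open(path, "w") as fh:
        fh.write("marker\tallele1\tallele2\t{0}\t{0}\t{0}\n".format(profile.sample_id))
        for sid, gl in zip(profile.site_ids, profile.gl):
            fh.write(
                f"{sid}\t0\t1\t{gl[0]:.10g}\t{gl[1]:.10g}\t{gl[2]:.10g}\n"
            )
    with open(_depth_sidecar(path), "w") as fh:
        fh.write("site_id\tdepth\tsample_type\n")
        for sid, d in zip(profile.site_ids, profile.depth):
            fh.write(f"{sid}\t{d}\t{profile.sample_type}\n")


def read_profile(path, panel: Panel | None = None) -> SampleProfile:
    """Read a Beagle GL profile (and its depth sidecar, when present).

    Sites not in ``panel`` (when a panel is given) are skipped with a
    warning; negative likelihoods are a hard error.
    """
    site_ids, gls = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 6:
            raise PanelError(f"{path}: not a Beagle GL file (too few columns)")
        sample_id = header[3]
        skipped = 0
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sid = f[0]
            triple = [float(x) for x in f[3:6]]
            if any(v < 0 for v in triple):
                raise PanelError(f"{path}: negative likelihood at {sid}")
            if panel is not None and sid not in panel:
                skipped += 1
                continue
            site_ids.append(sid)
            gls.append(triple)
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} sites not on the panel")
        log.warning("%s: skipped %d off-panel sites", path, skipped)
    depth = np.ones(len(site_ids), dtype=int)
    sample_type = "reference"
    try:
        side = pd.read_csv(_depth_sidecar(path), sep="\t", dtype={"site_id": str})
        dm = dict(zip(side["site_id"], side["depth"]))
        depth = np.array([dm.get(s, 1) for s in site_ids], dtype=int)
        if "sample_type" in side.columns and len(side):
            sample_type = str(side["sample_type"].iloc[0])
    except FileNotFoundError:
        pass
    return SampleProfile(
        sample_id, np.array(site_ids, dtype=object), np.array(gls), depth, sample_type
    )


# ---------------------------------------------------------------------------
# LD table and reference dosage matrices


def read_ld_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"site_id_a": str, "site_id_b": str})
    missing = {"site_id_a", "site_id_b", "r2"} - set(df.columns)
    if missing:
        raise PanelError(f"LD table missing columns: {sorted(missing)}")
    return df


def write_ld_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_dosage_matrix(path) -> tuple[list[str], np.ndarray]:
    """Read a reference genotype dosage TSV (rows = individuals, columns =
    panel site_ids in panel order; values 0/1/2, blank = missing)."""
    df = pd.read_csv(path, sep="\t")
    site_ids = [c for c in df.columns if c != "individual"]
    mat = df[site_ids].to_numpy(dtype=float)
    return site_ids, mat


def write_dosage_matrix(site_ids, matrix: np.ndarray, path) -> None:
    df = pd.DataFrame(matrix, columns=list(site_ids))
    df.insert(0, "individual", [f"ind{i}" for i in range(len(df))])
    df.to_csv(path, sep="\t", index=False)
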