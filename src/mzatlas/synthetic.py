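"""Synthetic data generators with known ground truth.

Three arms mirror the three experimental arms of the analysis:

* suspension cytometry — mixtures of subset archetypes on the arcsinh scale,
  with truth subset labels per event;
* imaging mass cytometry — zoned tissue geometry (epithelium band, memory
  band beneath it, GC disc with an adjacent MZ annulus, naive region, T
  zone) rendered to a multichannel image plus truth masks;
* IgH repertoire — clonal families sharing V/J and junction length whose
  members diverge by somatic hypermutation, carry subset/site/isotype/donor
  labels, may be chimeric splice artefacts, and can be serialised down to
  MID-tagged, primer-flanked FASTQ reads.

Intensities are simulated directly on an arcsinh-like scale (location-scale
normal, truncated at zero) because the analysis operates post-transform.
All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cytometry import EventTable
from .panels import ARCHETYPE_LOCS, DEFAULT_SCALE, IMC_CHANNELS, PANEL

NT = np.array(list("ACGT"))


# ------------------------------------------------------------- cytometry ---

@dataclass
class SubsetArchetype:
    """Location-scale description of one subset on the arcsinh scale."""

    name: str
    marker_loc: dict[str, float]
    marker_scale: dict[str, float]
    prevalence: float

    def validate(self, markers: list[str]) -> None:
        missing = [m for m in markers if m not in self.marker_loc]
        if missing:
            raise ValueError(f"archetype {self.name!r} lacks markers {missing}")


DEFAULT_PREVALENCES: dict[str, float] = {
    "transitional": 0.05, "naive": 0.25, "precursor": 0.05, "mz": 0.15,
    "igm_only": 0.08, "csm_igg": 0.12, "csm_iga": 0.10,
    "cd27neg_switched": 0.05, "cd27neg_igm_only": 0.03, "gc": 0.07,
    "plasmablast": 0.05,
}


def default_archetypes(prevalences: dict[str, float] | None = None,
                       scale: float = DEFAULT_SCALE) -> list[SubsetArchetype]:
    """The twelve-subset default panel mixture (eleven cell archetypes; the
    twelfth subset, "other", is an assignment outcome, not a population)."""
    prev = dict(DEFAULT_PREVALENCES if prevalences is None else prevalences)
    out = []
    for name, p in prev.items():
        locs = {m: ARCHETYPE_LOCS[name].get(m, 0.3) for m in PANEL}
        out.append(SubsetArchetype(name, locs, {m: scale for m in PANEL}, p))
    return out


def gen_cytometry_sample(archetypes: list[SubsetArchetype], n_cells: int,
                         seed: int, markers: list[str] | None = None,
                         sample_id: str = "s1", tissue: str = "galt",
                         donor: str = "d1") -> EventTable:
    """Draw ``n_cells`` events from the archetype mixture.

    Each event belongs to exactly one archetype (multinomial over
    prevalences); intensities are normal(loc, scale) truncated at 0; the
    truth subset is recorded per event.
    """
    if not archetypes:
        raise ValueError("archetype list is empty")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    markers = list(markers or archetypes[0].marker_loc)
    for a in archetypes:
        a.validate(markers)
    prev = np.array([a.prevalence for a in archetypes], float)
    if abs(prev.sum() - 1.0) > 1e-9:
        raise ValueError("prevalences must sum to 1")
    rng = np.random.default_rng(seed)
    which = rng.choice(len(archetypes), size=n_cells, p=prev)
    loc = np.array([[a.marker_loc[m] for m in markers] for a in archetypes])
    sc = np.array([[a.marker_scale[m] for m in markers] for a in archetypes])
    x = np.maximum(0.0, rng.normal(loc[which], sc[which]))
    df = pd.DataFrame(x, columns=markers)
    df["truth_subset"] = [archetypes[i].name for i in which]
    df["sample_id"] = sample_id
    df["tissue"] = tissue
    df["donor"] = donor
    return EventTable(df, markers)


def gen_tissue_sample(tissue: str, sample_id: str, n_cells: int, seed: int,
                      prevalences: dict[str, float] | None = None,
                      tissue_effect_sd: float = 0.1,
                      donor: str = "d1") -> EventTable:
    """A biological sample from a named tissue.

    Tissue identity imposes a reproducible per-marker location offset
    (normal, sd ``tissue_effect_sd``, seeded by the tissue name) shared by
    all subsets — the tissue-microenvironment effect that makes biological
    replicates of a tissue resemble each other more than samples of other
    tissues.  Replicates differ only through sampling noise and their seed.
    """
    import hashlib
    arch = default_archetypes(prevalences)
    tseed = int(hashlib.sha256(tissue.encode()).hexdigest()[:8], 16)
    rng_t = np.random.default_rng(tseed)
    offset = {m: float(rng_t.normal(0.0, tissue_effect_sd)) for m in PANEL}
    shifted = [SubsetArchetype(a.name,
                               {m: max(0.05, a.marker_loc[m] + offset[m])
                                for m in PANEL},
                               a.marker_scale, a.prevalence) for a in arch]
    return gen_cytometry_sample(shifted, n_cells, seed, sample_id=sample_id,
                                tissue=tissue, donor=donor)


# --------------------------------------------------------------- imaging ---

@dataclass(frozen=True)
class Zone:
    """A named tissue region with an archetype; one of four shapes."""

    name: str
    archetype: str       # key into the zone archetype table
    kind: str            # "band" | "rect" | "disc" | "annulus"
    params: tuple        # band: (r0, r1); rect: (r0, r1, c0, c1);
    #                      disc: (cr, cc, r); annulus: (cr, cc, r_in, r_out)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        h, w = shape
        rr, cc = np.mgrid[0:h, 0:w]
        if self.kind == "band":
            r0, r1 = self.params
            return (rr >= r0) & (rr < r1)
        if self.kind == "rect":
            r0, r1, c0, c1 = self.params
            return (rr >= r0) & (rr < r1) & (cc >= c0) & (cc < c1)
        if self.kind == "disc":
            cr, cc0, rad = self.params
            return (rr - cr) ** 2 + (cc - cc0) ** 2 <= rad ** 2
        if self.kind == "annulus":
            cr, cc0, r_in, r_out = self.params
            d2 = (rr - cr) ** 2 + (cc - cc0) ** 2
            return (d2 > r_in ** 2) & (d2 <= r_out ** 2)
        raise ValueError(f"unknown zone kind {self.kind!r}")


@dataclass
class TissueGeometry:
    shape: tuple[int, int]
    zones: list[Zone]
    noise: float = 0.35
    channels: list[str] = field(default_factory=lambda: list(IMC_CHANNELS))

    def validate(self) -> None:
        cover = np.zeros(self.shape, dtype=int)
        for z in self.zones:
            m = z.mask(self.shape)
            if not m.any():
                raise ValueError(f"zone {z.name!r} lies outside the image")
            cover += m
        if (cover > 1).any():
            raise ValueError("zones overlap")

    def zone_masks(self) -> dict[str, np.ndarray]:
        return {z.name: z.mask(self.shape) for z in self.zones}


# Zone archetypes over the imaging channels; unlisted channels sit at 0.2.
_IMC_EXTRA: dict[str, dict[str, float]] = {
    "epithelium": {"cytokeratin": 2.8, "CD45": 0.3},
    "t_zone": {"CD3": 2.8, "CD45": 2.8},
    "background": {},
}


def imc_zone_locs(archetype: str) -> dict[str, float]:
    # "csm" (class-switched memory, isotype not imaged) uses the IgG-memory
    # surface pattern; the switched-isotype channels are absent anyway
    archetype = {"csm": "csm_igg"}.get(archetype, archetype)
    base = ARCHETYPE_LOCS.get(archetype, _IMC_EXTRA.get(archetype))
    if base is None:
        raise KeyError(f"unknown zone archetype {archetype!r}")
    if archetype in ARCHETYPE_LOCS:
        # tissue B cells: no cytokeratin signal
        base = {**base, "cytokeratin": 0.2}
    return {ch: base.get(ch, 0.2) for ch in IMC_CHANNELS}


def default_tissue_geometry(shape: tuple[int, int] = (512, 512),
                            noise: float = 0.35) -> TissueGeometry:
    """Default zoned follicle: epithelium on top, class-switched memory band
    beneath it, GC disc deeper in the tissue with the MZ annulus sharing the
    GC boundary, a naive region and a T zone to the sides."""
    h, w = shape
    cr, cc = int(h * 0.625), w // 2
    rad = int(min(h, w) * 0.125)
    geom = TissueGeometry(shape, [
        Zone("epithelium", "epithelium", "band", (0, int(h * 0.0625))),
        Zone("memory", "csm", "band", (int(h * 0.0625), int(h * 0.1875))),
        Zone("gc", "gc", "disc", (cr, cc, rad)),
        Zone("mz", "mz", "annulus", (cr, cc, rad, int(rad * 1.5))),
        Zone("naive", "naive", "rect",
             (int(h * 0.27), int(h * 0.43), int(w * 0.06), int(w * 0.29))),
        Zone("t_zone", "t_zone", "rect",
             (int(h * 0.27), int(h * 0.43), int(w * 0.72), int(w * 0.94))),
    ], noise=noise)
    geom.validate()
    return geom


def gen_imc_image(geometry: TissueGeometry, seed: int
                  ) -> tuple[np.ndarray, list[str], dict[str, np.ndarray]]:
    """Render the geometry to an H x W x C image plus truth zone masks.

    Every pixel's channel vector is its zone archetype location plus
    gaussian background noise (sd = geometry.noise), truncated at zero;
    pixels outside all zones carry the background archetype.
    """
    geometry.validate()
    h, w = geometry.shape
    chans = geometry.channels
    rng = np.random.default_rng(seed)
    loc = np.empty((h, w, len(chans)))
    bg = imc_zone_locs("background")
    loc[:] = np.array([bg[c] for c in chans])
    masks = geometry.zone_masks()
    for z in geometry.zones:
        zl = imc_zone_locs(z.archetype)
        loc[masks[z.name]] = np.array([zl[c] for c in chans])
    img = loc if geometry.noise == 0 else np.maximum(
        0.0, loc + rng.normal(0.0, geometry.noise, size=loc.shape))
    return img, list(chans), masks


# ------------------------------------------------------------ repertoire ---

@dataclass
class GermlinePool:
    v: dict[str, str]  # allele-level call -> sequence
    j: dict[str, str]

    def validate(self) -> None:
        if not self.v or not self.j:
            raise ValueError("germline pool must contain V and J segments")
        for name, seq in {**self.v, **self.j}.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"{name}: germline must be A/C/G/T only")


def default_germline_pool(n_v: int = 10, n_j: int = 4, v_len: int = 210,
                          j_len: int = 30, seed: int = 7) -> GermlinePool:
    """Toy germline set: ~10 V and 4 J segments of realistic length."""
    rng = np.random.default_rng(seed)
    v_names = [f"IGHV{1 + i % 7}-{11 + 4 * i}*01" for i in range(n_v)]
    j_names = [f"IGHJ{1 + i}*02" for i in range(n_j)]
    v = {nm: "".join(rng.choice(NT, v_len)) for nm in v_names}
    j = {nm: "".join(rng.choice(NT, j_len)) for nm in j_names}
    return GermlinePool(v, j)


@dataclass
class CloneClass:
    """A clone-level behaviour profile: which subsets its members occupy,
    how mutated they are, and where they home."""

    prob: float
    subset_weights: dict[str, float]
    shm_scale: float
    sites: dict[str, float]
    spread: float = 0.3  # probability a member sits away from the home site


def default_clone_classes() -> dict[str, CloneClass]:
    # memory clones home in GALT but recirculate through blood; clones are
    # isotype-faithful (dissemination predominantly within isotype)
    sites = {"PP": 0.3, "A": 0.275, "CF": 0.275, "blood": 0.15}
    return {
        "naive": CloneClass(0.25, {"naive": 1.0}, 0.0, {"blood": 1.0}, 0.0),
        "mz": CloneClass(0.30, {"mz": 0.9930, "gc": 0.0035,
                                "precursor": 0.0035}, 0.5, sites),
        "igm_mem": CloneClass(0.30, {"igm_only": 0.9899, "gc": 0.0035,
                                     "csm_iga": 0.0066}, 1.0, sites),
        "csm_a": CloneClass(0.09, {"csm_iga": 1.0}, 1.0, sites),
        "csm_g": CloneClass(0.06, {"csm_igg": 1.0}, 1.0, sites),
    }


DEFAULT_ISOTYPE_WEIGHTS: dict[str, dict[str, float]] = {
    "naive": {"IgM": 1.0}, "precursor": {"IgM": 1.0}, "mz": {"IgM": 1.0},
    "igm_only": {"IgM": 1.0}, "csm_iga": {"IgA": 1.0}, "csm_igg": {"IgG": 1.0},
    "gc": {"IgM": 0.7, "IgA": 0.3},
}


@dataclass
class RepertoireSimConfig:
    n_clones: int = 500
    clone_size_power: float = 2.5
    clone_size_max: int = 50
    germline_pool: GermlinePool = field(default_factory=default_germline_pool)
    shm_rate: float = 0.02
    isotype_switch_prob: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_ISOTYPE_WEIGHTS.items()})
    site_probs: dict[str, float] = field(
        default_factory=lambda: {"PP": 0.3, "A": 0.25, "CF": 0.25,
                                 "blood": 0.2})
    chimera_rate: float = 0.02
    nonfunctional_rate: float = 0.02
    mid_mismatch_rate: float = 0.01
    clone_classes: dict[str, CloneClass] = field(
        default_factory=default_clone_classes)
    hotspot: dict[str, float] | None = None  # 5-mer -> rate multiplier
    donor: str = "d1"
    seed: int = 0

    def validate(self) -> None:
        self.germline_pool.validate()
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        for p in (self.shm_rate, self.chimera_rate, self.nonfunctional_rate,
                  self.mid_mismatch_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            hotspot: dict[str, float] | None = None) -> str:
    """Independent per-base substitutions at ``rate``; an optional 5-mer
    hot-spot table multiplies the rate per position (uniform by default)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1").copy()
    n = len(arr)
    rates = np.full(n, rate)
    if hotspot:
        pad = "NN" + seq + "NN"
        for i in range(n):
            rates[i] = min(1.0, rate * hotspot.get(pad[i:i + 5], 1.0))
    hits = np.flatnonzero(rng.random(n) < rates)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _draw_sizes(cfg: RepertoireSimConfig, rng: np.random.Generator,
                n: int) -> np.ndarray:
    u = rng.random(n)
    s = np.floor(u ** (-1.0 / (cfg.clone_size_power - 1.0))).astype(int)
    return np.clip(s, 1, cfg.clone_size_max)


def _random_junction(rng: np.random.Generator, length: int) -> str:
    return "TGT" + "".join(rng.choice(NT, length - 3))


def gen_repertoire(config: RepertoireSimConfig) -> pd.DataFrame:
    """Simulate an annotated repertoire; one row per unique sequence.

    Columns follow AIRR Rearrangement naming where one exists (sequence_id,
    sequence, v_call, j_call, junction, junction_length, c_call) plus
    subset, site, donor, duplicate_count, germline_alignment and the truth
    columns clone_id_truth / is_chimera_truth; functional and mid_consistent
    flags stand in for upstream germline-annotation QC.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pool = config.germline_pool
    v_names = sorted(pool.v)
    j_names = sorted(pool.j)
    class_names = sorted(config.clone_classes)
    class_p = np.array([config.clone_classes[c].prob for c in class_names])
    class_p = class_p / class_p.sum()
    sizes = _draw_sizes(config, rng, config.n_clones)
    rows: list[dict] = []
    seq_no = 0
    for clone_id in range(config.n_clones):
        cc = config.clone_classes[
            class_names[rng.choice(len(class_names), p=class_p)]]
        v_call = v_names[rng.integers(len(v_names))]
        j_call = j_names[rng.integers(len(j_names))]
        v_seq, j_seq = pool.v[v_call], pool.j[j_call]
        jl = int(3 * rng.integers(8, 20))  # 24..57 nt
        founder_j = _random_junction(rng, jl)
        site_names = sorted(cc.sites)
        site_p = np.array([cc.sites[s] for s in site_names])
        home = site_names[rng.choice(len(site_names), p=site_p / site_p.sum())]
        sub_names = sorted(cc.subset_weights)
        sub_p = np.array([cc.subset_weights[s] for s in sub_names])
        sub_p = sub_p / sub_p.sum()
        rate = config.shm_rate * cc.shm_scale
        for _ in range(sizes[clone_id]):
            subset = sub_names[rng.choice(len(sub_names), p=sub_p)]
            if cc.spread > 0 and len(site_names) > 1 and rng.random() < cc.spread:
                others = [s for s in site_names if s != home]
                site = others[rng.integers(len(others))]
            else:
                site = home
            iso_w = config.isotype_switch_prob.get(subset, {"IgM": 1.0})
            iso_names = sorted(iso_w)
            iso_p = np.array([iso_w[i] for i in iso_names])
            isotype = iso_names[rng.choice(len(iso_names), p=iso_p / iso_p.sum())]
            v_mut = _mutate(v_seq, rate, rng, config.hotspot)
            j_mut = _mutate(j_seq, rate, rng, config.hotspot)
            junction = _mutate(founder_j, rate, rng, config.hotspot)
            is_chimera = bool(rng.random() < config.chimera_rate)
            if is_chimera:
                donors_v = [nm for nm in v_names if nm != v_call] or [v_call]
                other_v = pool.v[donors_v[rng.integers(len(donors_v))]]
                bp = int(rng.integers(40, len(v_seq) - 40))
                v_mut = v_mut[:bp] + other_v[bp:]
            rows.append({
                "sequence_id": f"seq{seq_no:06d}",
                "sequence": v_mut + junction + j_mut,
                "v_call": v_call,
                "j_call": j_call,
                "junction": junction,
                "junction_length": jl,
                "c_call": isotype,
                "subset": subset,
                "site": site,
                "donor": config.donor,
                "duplicate_count": int(1 + rng.geometric(0.6) - 1),
                "germline_alignment": v_seq + "N" * jl + j_seq,
                "clone_id_truth": clone_id,
                "is_chimera_truth": is_chimera,
                "functional": bool(rng.random() >= config.nonfunctional_rate),
                "mid_consistent": bool(rng.random() >= config.mid_mismatch_rate),
            })
            seq_no += 1
    df = pd.DataFrame(rows)
    df["duplicate_count"] = df["duplicate_count"].clip(lower=1)
    return df


def multi_donor_repertoire(seed: int, n_donors: int = 4,
                           n_clones: int = 500,
                           **config_kwargs) -> pd.DataFrame:
    """Pooled repertoire from ``n_donors`` independent donors (the study
    design: three gut sites plus blood from four individuals).  Truth clone
    ids are offset per donor so clones never span donors — public identical
    sequences across donors are vanishingly rare and the generator does not
    create them."""
    dfs = []
    for d in range(n_donors):
        cfg = RepertoireSimConfig(n_clones=n_clones,
                                  seed=int(seed + 1000 * d),
                                  donor=f"d{d + 1}", **config_kwargs)
        rep = gen_repertoire(cfg)
        rep["clone_id_truth"] += d * n_clones
        rep["sequence_id"] = f"d{d + 1}_" + rep["sequence_id"]
        dfs.append(rep)
    return pd.concat(dfs, ignore_index=True)


# ----------------------------------------------------------------- reads ---

@dataclass
class QualityModel:
    """Per-read mean Phred model: a fraction of reads drops to a low mean."""

    mean_q: float = 35.0
    base_sd: float = 2.0
    low_fraction: float = 0.0
    low_mean_q: float = 15.0


#: Default 10-nt multiplex identifiers (sample barcodes), 12 tags.
DEFAULT_MIDS = ["ACGTACGTAC", "TGCATGCATG", "GATCGATCGA", "CTAGCTAGCT",
                "AACCGGTTAA", "TTGGCCAATT", "AGAGTCTCGA", "TCTCAGAGCT",
                "CACAGTGTGT", "GTGTCACACA", "ACACTGTGCA", "TGTGACACGT"]

DEFAULT_FWD_PRIMER = ("VFWD1", "ACGGTCTTGACGTTAGCCAT")
DEFAULT_REV_PRIMERS = {
    "IgM": "TTGGCAGCAACTGGACTCAG",
    "IgD": "CCAGTTGGAACAGCGGTTAC",
    "IgG": "GACCGATGGGCCCTTGGTGG",
    "IgA": "GAAGACCTTGGGGCTGGTCG",
}


def assign_mids(df: pd.DataFrame, mids: list[str]) -> pd.Series:
    """Deterministic (donor, site) -> MID assignment, cycling the MID list."""
    keys = sorted(set(zip(df["donor"], df["site"])))
    table = {k: mids[i % len(mids)] for i, k in enumerate(keys)}
    return pd.Series([table[(d, s)] for d, s in zip(df["donor"], df["site"])],
                     index=df.index)


def gen_reads(records: pd.DataFrame, mids: list[str],
              fwd_primer: tuple[str, str] = DEFAULT_FWD_PRIMER,
              rev_primers: dict[str, str] | None = None,
              quality: QualityModel | None = None, seed: int = 0,
              ) -> list[tuple[str, str, str]]:
    """Emit (read_id, sequence, phred33 string) triplets.

    Read layout (5'→3'): MID + forward primer + rearrangement sequence +
    reverse (constant-region) primer + MID.  The reverse primer is chosen by
    the record's isotype; records flagged MID-inconsistent get a different
    MID at the 3' end (the chimera signature the QC stage screens for).
    Each record is emitted ``duplicate_count`` times.
    """
    for m in mids:
        if len(m) != 10:
            raise ValueError("MIDs must be 10 nt")
    rev_primers = rev_primers or DEFAULT_REV_PRIMERS
    if not fwd_primer[1] or not rev_primers:
        raise ValueError("primers must be non-empty")
    quality = quality or QualityModel()
    rng = np.random.default_rng(seed)
    mid_of = assign_mids(records, mids)
    reads = []
    for idx, rec in records.iterrows():
        mid5 = mid_of.loc[idx]
        mid3 = mid5
        if not rec.get("mid_consistent", True):
            alternatives = [m for m in mids if m != mid5] or [mid5]
            mid3 = alternatives[rng.integers(len(alternatives))]
        seq = (mid5 + fwd_primer[1] + rec["sequence"]
               + rev_primers[rec["c_call"]] + mid3)
        low = rng.random() < quality.low_fraction
        mean_q = quality.low_mean_q if low else quality.mean_q
        for dup in range(int(rec["duplicate_count"])):
            q = np.clip(np.rint(rng.normal(mean_q, quality.base_sd,
                                           len(seq))), 2, 40).astype(int)
            # pin the realised mean to the intended side of the Q20 gate
            if low and q.mean() >= 20:
                q = np.minimum(q, int(mean_q))
            phred = "".join(chr(33 + int(v)) for v in q)
            reads.append((f"{rec['sequence_id']}|dup{dup}", seq, phred))
    return reads


# -------------------------------------------------------------------- IO ---

def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    from Bio import SeqIO
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(33 + q)
                       for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq), qual))
    return out


def write_airr(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_airr(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_event_csv(table: EventTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def read_event_csv(path: str | Path, markers: list[str]) -> EventTable:
    return EventTable(pd.read_csv(path), list(markers))


def write_image(img: np.ndarray, channels: list[str], path: str | Path) -> None:
    """Multichannel TIFF (C x H x W planes) plus a JSON channel sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(img, -1, 0).astype(np.float32))
    path.with_suffix(".channels.json").write_text(json.dumps(channels))


def read_image(path: str | Path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    img = np.moveaxis(tifffile.imread(path), 0, -1).astype(float)
    channels = json.loads(path.with_suffix(".channels.json").read_text())
    return img, channels


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), mask.astype(np.uint8))


def write_config(config: RepertoireSimConfig, path: str | Path) -> None:
    d = {
        "n_clones": config.n_clones,
        "clone_size_power": config.clone_size_power,
        "clone_size_max": config.clone_size_max,
        "shm_rate": config.shm_rate,
        "chimera_rate": config.chimera_rate,
        "nonfunctional_rate": config.nonfunctional_rate,
        "mid_mismatch_rate": config.mid_mismatch_rate,
        "site_probs": config.site_probs,
        "donor": config.donor,
        "seed": config.seed,
    }
    Path(path).write_text(json.dumps(d, indent=2))
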