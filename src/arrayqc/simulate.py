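"""Seeded generator for Infinium-style genotyping data with WGA artifacts.

The generator emulates the statistical structure of a large SNP-array
study that genotyped both native genomic DNA (gDNA) and whole-genome
amplified DNA (wgaDNA) from three biospecimen sources (blood, buccal
mouthwash, Oragene saliva):

* a probe manifest with a rare-variant-heavy MAF spectrum, duplicate
  probes assaying the same locus, and smooth positional GC / CpG tracks;
* a cohort with blinded replicate structure (full replicates carrying
  2 gDNA + 2 wgaDNA samples, partial replicates of each pair type),
  plate/chip placement and reported sex;
* per-call genotypes with a GenCall-style confidence score, raw
  intensities, Log R Ratio (LRR) and B allele frequency (BAF);
* WGA-specific artifacts: per-sample quality driven by source material,
  subtelomeric under-amplification that fails loci across every wgaDNA
  sample, allele drop-out at heterozygous sites, chip- and plate-level
  systematic failures, GC/CpG waves on LRR, and injected CNV / mosaic
  events with full truth tables.

Everything is driven by a single integer seed through independent named
streams, so identical ``(seed, config)`` pairs produce byte-identical
output files.

Allele drop-out model
---------------------
Drop-out is modelled as *locus-level vulnerability*: for each
(individual, locus) pair a small fraction of heterozygous sites are
"vulnerable", with a fixed allele that survives amplification.  Each
wgaDNA sample of that individual then independently drops the other
allele with high conditional probability.  Because both wgaDNA
replicates of an individual tend to fail at the *same* sites in the
*same* direction, wgaDNA–wgaDNA replicate pairs stay more concordant
than gDNA–wgaDNA pairs — the ordering observed in real data — which an
independent per-call drop-out model cannot produce.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genotype_io as gio
from .genotype_io import AA, AB, BB, NC

# stream ids for the named RNG streams
_S_MANIFEST, _S_COHORT, _S_CALLS, _S_STR, _S_EVENTS = 11, 23, 37, 53, 71

#: Identifiler-style panel: 15 autosomal STRs plus amelogenin
STR_MARKERS = (
    "D8S1179", "D21S11", "D7S820", "CSF1PO", "D3S1358", "TH01",
    "D13S317", "D16S539", "D2S1338", "D19S433", "vWA", "TPOX",
    "D18S51", "D5S818", "FGA", "AMEL",
)
AMEL = "AMEL"
#: plausible integer repeat-number ranges per autosomal marker
_STR_RANGES = {m: (6 + (i % 4), 14 + (i % 6)) for i, m in enumerate(STR_MARKERS)
               if m != AMEL}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ReplicateDesign:
    """Counts of blinded QC replicate individuals by pair composition."""
    n_full: int = 81        # 2 gDNA + 2 wgaDNA samples
    n_partial_gw: int = 21  # 1 gDNA + 1 wgaDNA
    n_partial_gg: int = 18  # 2 gDNA
    n_partial_ww: int = 5   # 2 wgaDNA

    @property
    def n_replicate_individuals(self) -> int:
        return self.n_full + self.n_partial_gw + self.n_partial_gg + self.n_partial_ww


@dataclass
class CNVSpecItem:
    """One injected event family: class, span in probes, carriers."""
    kind: str                     # gain | loss | cnloh | mosaic_cnloh
    n_probes: int
    n_carriers: int
    mosaic_fraction: float | None = None


@dataclass
class SimulationConfig:
    """Every knob of the generator, with defaults set to the study conditions.

    Quality ``q`` is a latent per-sample score in [0, 1]; the per-call
    no-call probability is ``nocall_rate_coef * (1 - q)``, so with the
    default coefficient 0.10 a sample fails the 95% call-rate threshold
    exactly when ``q < 0.5``.  The per-stratum means/sds below were
    derived by inverting the observed stratum failure rates under that
    mapping (gDNA ~4% failing everywhere; wgaDNA buccal ≫ blood >
    Oragene).
    """
    seed: int = 0

    # --- manifest -----------------------------------------------------
    n_chromosomes: int = 8
    chromosome_length_bp: int = 30_000_000
    n_loci: int = 4000            # number of probes on the simulated array
    duplicate_locus_fraction: float = 0.015
    #: mixture on the 2*MAF scale: (weight, alpha, beta); MAF = X/2.
    #: calibrated analytically so E[2m(1-m)] = 0.137 (median heterozygosity)
    maf_mixture: tuple = ((0.744, 0.35, 6.0), (0.256, 1.8, 1.2))

    # --- cohort -------------------------------------------------------
    n_individuals: int = 400
    replicate_design: ReplicateDesign = field(default_factory=ReplicateDesign)
    source_mix: dict = field(default_factory=lambda: {
        "blood": 0.215, "buccal": 0.285, "oragene": 0.500})
    singleton_gdna_fraction: float = 0.63
    chips_per_plate: int = 24

    # --- per-sample quality / no-calls --------------------------------
    #: (input_type, source) -> (mean, sd) of clipped-normal quality q
    quality_model: dict = field(default_factory=lambda: {
        ("gDNA", "blood"): (0.772, 0.15),
        ("gDNA", "buccal"): (0.760, 0.15),
        ("gDNA", "oragene"): (0.763, 0.15),
        ("wgaDNA", "blood"): (0.701, 0.15),
        ("wgaDNA", "buccal"): (0.604, 0.15),
        ("wgaDNA", "oragene"): (0.723, 0.15),
    })
    nocall_rate_coef: float = 0.10
    gc_score_threshold: float = gio.DEFAULT_GC_THRESHOLD
    gc_score_good_params: tuple = (5.0, 1.5)   # Beta on [threshold, 1]

    # --- genotype artifacts -------------------------------------------
    genotype_error_rate: float = 5e-5
    dropout_vulnerability_coef: float = 0.0143  # v = coef * (1 - q_ind), per locus
    dropout_given_vulnerable: float = 0.8       # per wgaDNA sample at vulnerable hets

    # --- systematic / positional failures -----------------------------
    complete_fail_fraction: float = 0.0019      # probes failing everything
    subtelomere_windows: int = 3                # terminal 50-kb windows per end
    end_fail_fraction: float = 0.5              # chromosome ends under-amplified
    subtelomere_fail_prob: float = 0.8          # P(locus fails all wgaDNA | flagged end)
    chip_fail_rate: float = 0.005
    plate_fail_rate: float = 0.01
    window_size: int = 50_000

    # --- intensities / LRR / BAF --------------------------------------
    gc_wave_amplitude: float = 0.6              # LRR per unit GC deviation
    cpg_wave_amplitude: float = 2.0             # LRR per unit CpG-density deviation
    wave_sample_sd: float = 0.2                 # per-sample wave-amplitude scatter
    chip_lrr_offset_sd: float = 0.05
    lrr_noise_sd: float = 0.12
    wga_noise_coef: float = 1.2                 # wgaDNA noise grows with (1-q)
    noise_jitter_sd: float = 0.15               # lognormal per-sample jitter
    baf_noise_sd: float = 0.03
    cluster_thetas: tuple = (0.1, 0.5, 0.9)
    cluster_r: float = 2.0

    # --- CNV truth ----------------------------------------------------
    cnv_spec: list = field(default_factory=lambda: [
        CNVSpecItem("gain", 30, 6),
        CNVSpecItem("loss", 25, 3),
        CNVSpecItem("cnloh", 40, 1),
        CNVSpecItem("mosaic_cnloh", 60, 2, mosaic_fraction=0.4),
    ])
    lrr_shift: dict = field(default_factory=lambda: {
        "gain": 0.32, "loss": -0.45, "cnloh": 0.0, "mosaic_cnloh": 0.0})

    # --- STR profiles -------------------------------------------------
    str_dropout_coef: float = 0.35     # per het marker, * (1 - q)
    str_failure_coef: float = 0.08     # per marker, * (1 - q)
    str_contamination_rate: float = 0.005

    def validate(self) -> "SimulationConfig":
        if self.chromosome_length_bp <= 0:
            raise ValueError("chromosome_length_bp must be positive")
        if self.n_loci < 100:
            raise ValueError("n_loci must be >= 100")
        if not 0 <= self.duplicate_locus_fraction < 0.5:
            raise ValueError("duplicate_locus_fraction must be in [0, 0.5)")
        if abs(sum(self.source_mix.values()) - 1.0) > 1e-9:
            raise ValueError("source_mix must sum to 1")
        for name in ("genotype_error_rate", "chip_fail_rate", "plate_fail_rate",
                     "subtelomere_fail_prob", "end_fail_fraction",
                     "str_contamination_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.replicate_design.n_replicate_individuals > self.n_individuals:
            raise ValueError("replicate design exceeds cohort size")
        for ev in self.cnv_spec:
            if ev.n_probes < 1:
                raise ValueError("every configured event needs size >= 1 probe")
        return self

    # -- (de)serialisation --------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["quality_model"] = {f"{k[0]}:{k[1]}": list(v)
                              for k, v in self.quality_model.items()}
        d["maf_mixture"] = [list(c) for c in self.maf_mixture]
        d["cluster_thetas"] = list(self.cluster_thetas)
        d["gc_score_good_params"] = list(self.gc_score_good_params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "quality_model" in d:
            d["quality_model"] = {tuple(k.split(":")): tuple(v)
                                  for k, v in d["quality_model"].items()}
        if "replicate_design" in d and isinstance(d["replicate_design"], dict):
            d["replicate_design"] = ReplicateDesign(**d["replicate_design"])
        if "cnv_spec" in d:
            d["cnv_spec"] = [CNVSpecItem(**e) if isinstance(e, dict) else e
                             for e in d["cnv_spec"]]
        for k in ("maf_mixture", "cluster_thetas", "gc_score_good_params"):
            if k in d:
                d[k] = tuple(tuple(c) if isinstance(c, (list, tuple)) else c
                             for c in d[k])
        return cls(**d).validate()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class TruthTables:
    """Ground truth for every injected artifact, for parameter recovery."""
    samples: pd.DataFrame          # sample_id, q, p_nc, lrr_sd, ...
    loci: pd.DataFrame             # locus_id, maf, f_b, subtel_wga_fail
    probes: pd.DataFrame           # probe_id, complete_fail
    nocall_mask: np.ndarray        # (n_samples, n_probes) bool, injected NC
    genotype_error_idx: np.ndarray  # (k, 2) [sample_idx, probe_idx]
    dropout_idx: np.ndarray        # (k, 2) [sample_idx, probe_idx]
    cnv_events: pd.DataFrame       # per-sample injected events
    str_truth: pd.DataFrame | None = None
    sample_order: list | None = None
    probe_order: list | None = None


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def _unique_positions(rng, n: int, length: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.05) + 16))
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def generate_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Generate the probe manifest.

    Probes are sorted by (chromosome, position).  A configured fraction
    are second probes duplicating an existing locus (same locus id,
    position and alleles), mirroring arrays that assay some variants
    with more than one bead type.  GC fraction follows a smooth
    two-frequency sinusoidal process along each chromosome; CpG density
    is a noisy monotone function of GC.
    """
    config.validate()
    rng = _rng(config.seed, _S_MANIFEST)
    n_probes = config.n_loci
    n_dup = int(round(n_probes * config.duplicate_locus_fraction))
    n_unique = n_probes - n_dup

    chrom_idx = np.sort(rng.integers(0, config.n_chromosomes, size=n_unique))
    positions = np.empty(n_unique, dtype=np.int64)
    for c in range(config.n_chromosomes):
        m = chrom_idx == c
        positions[m] = _unique_positions(rng, int(m.sum()),
                                         config.chromosome_length_bp)

    # smooth positional GC process, chromosome-specific phases
    ph1 = rng.uniform(0, 2 * np.pi, config.n_chromosomes)
    ph2 = rng.uniform(0, 2 * np.pi, config.n_chromosomes)
    gc = (0.41
          + 0.07 * np.sin(2 * np.pi * positions / 2.0e6 + ph1[chrom_idx])
          + 0.05 * np.sin(2 * np.pi * positions / 7.3e6 + ph2[chrom_idx])
          + rng.normal(0, 0.015, n_unique))
    gc = np.clip(gc, 0.25, 0.65)
    cpg = np.clip(0.012 * (gc / 0.41) ** 2 + rng.normal(0, 0.0015, n_unique),
                  1e-5, None)

    bases = np.array(list("ACGT"))
    ai = rng.integers(0, 4, size=n_unique)
    bi = (ai + rng.integers(1, 4, size=n_unique)) % 4

    locus_ids = np.array([f"L{i:06d}" for i in range(n_unique)])
    base = pd.DataFrame({
        "locus_id": locus_ids,
        "chromosome": [f"chr{c + 1}" for c in chrom_idx],
        "position": positions,
        "allele_a": bases[ai],
        "allele_b": bases[bi],
        "gc_fraction": gc,
        "cpg_density": cpg,
    })

    dup_rows = base.iloc[np.sort(rng.choice(n_unique, size=n_dup, replace=False))]
    manifest = pd.concat([base, dup_rows], ignore_index=True)
    order = np.lexsort((
        manifest["position"].to_numpy(),
        manifest["chromosome"].str.removeprefix("chr").astype(int).to_numpy()))
    manifest = manifest.iloc[order].reset_index(drop=True)
    manifest.insert(0, "probe_id", [f"P{i:06d}" for i in range(len(manifest))])
    return gio.validate_manifest(manifest[gio.MANIFEST_COLUMNS])


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate the sample sheet with blinded replicate structure.

    The first individuals in the design are full QC replicates (2 gDNA +
    2 wgaDNA samples), then the partial pair types; the remainder are
    singletons split between input types.  Samples are shuffled before
    chip assignment so replicates are interspersed across plates (4
    samples per chip, ``chips_per_plate`` chips per plate).
    """
    config.validate()
    rng = _rng(config.seed, _S_COHORT)
    rd = config.replicate_design
    n = config.n_individuals

    sources = list(config.source_mix)
    src_p = np.array([config.source_mix[s] for s in sources])
    ind_source = rng.choice(sources, size=n, p=src_p)
    ind_sex = rng.choice(["M", "F"], size=n)
    ind_ids = [f"I{i:04d}" for i in range(n)]

    rows = []
    for i in range(n):
        if i < rd.n_full:
            types = ["gDNA", "gDNA", "wgaDNA", "wgaDNA"]
        elif i < rd.n_full + rd.n_partial_gw:
            types = ["gDNA", "wgaDNA"]
        elif i < rd.n_full + rd.n_partial_gw + rd.n_partial_gg:
            types = ["gDNA", "gDNA"]
        elif i < rd.n_replicate_individuals:
            types = ["wgaDNA", "wgaDNA"]
        else:
            types = ["gDNA" if rng.random() < config.singleton_gdna_fraction
                     else "wgaDNA"]
        for t in types:
            rows.append((ind_ids[i], t, ind_source[i], ind_sex[i]))

    cohort = pd.DataFrame(rows, columns=["individual_id", "input_type",
                                         "source_material", "reported_sex"])
    cohort = cohort.iloc[rng.permutation(len(cohort))].reset_index(drop=True)
    cohort.insert(0, "sample_id", [f"S{i:05d}" for i in range(len(cohort))])
    chip = np.arange(len(cohort)) // 4
    cohort["chip_id"] = [f"C{c:04d}" for c in chip]
    cohort["chip_position"] = np.arange(len(cohort)) % 4 + 1
    cohort["plate_id"] = [f"PL{c // config.chips_per_plate:03d}" for c in chip]
    return gio.validate_sample_sheet(cohort[gio.SAMPLE_SHEET_COLUMNS])


# ---------------------------------------------------------------------------
# Call table
# ---------------------------------------------------------------------------

def _draw_maf(rng, config, n: int) -> np.ndarray:
    """Draw per-locus MAF from the configured Beta mixture (MAF = X/2)."""
    weights = np.array([c[0] for c in config.maf_mixture])
    comp = rng.choice(len(weights), size=n, p=weights / weights.sum())
    x = np.empty(n)
    for k, (_, a, b) in enumerate(config.maf_mixture):
        m = comp == k
        x[m] = rng.beta(a, b, size=int(m.sum()))
    return 0.5 * x


def _subtelomeric_locus_mask(manifest_loci: pd.DataFrame, config,
                             rng) -> np.ndarray:
    """Bernoulli under-amplified ends -> loci failing all wgaDNA samples."""
    span = config.subtelomere_windows * config.window_size
    fail = np.zeros(len(manifest_loci), dtype=bool)
    for chrom, grp in manifest_loci.groupby("chromosome", sort=False):
        for is_start in (True, False):
            if rng.random() >= config.end_fail_fraction:
                continue
            pos = grp["position"].to_numpy()
            if is_start:
                in_end = pos <= span
            else:
                in_end = pos > config.chromosome_length_bp - span
            idx = grp.index[in_end]
            hit = rng.random(len(idx)) < config.subtelomere_fail_prob
            fail[manifest_loci.index.get_indexer(idx[hit])] = True
    return fail


def _place_cnv_events(rng, config, manifest: pd.DataFrame,
                      cohort: pd.DataFrame) -> pd.DataFrame:
    """Assign injected events to carrier individuals at random probe runs.

    Carriers are drawn preferentially from individuals with both input
    types so matched-pair CNV concordance can be evaluated; events never
    cross a chromosome boundary and never overlap within an individual.
    """
    chrom = manifest["chromosome"].to_numpy()
    pos = manifest["position"].to_numpy()
    by_type = cohort.groupby("individual_id")["input_type"].agg(set)
    paired = [i for i, s in by_type.items() if len(s) == 2]
    others = [i for i in by_type.index if i not in set(paired)]
    pool = paired + others

    taken: dict[str, list[tuple[int, int]]] = {}
    rows = []
    cursor = 0
    for ev in config.cnv_spec:
        for _ in range(ev.n_carriers):
            carrier = pool[cursor % len(pool)]
            cursor += 1
            placed = False
            for _try in range(200):
                start = int(rng.integers(0, len(manifest) - ev.n_probes + 1))
                end = start + ev.n_probes - 1
                if chrom[start] != chrom[end]:
                    continue
                if any(not (end < a or start > b)
                       for a, b in taken.get(carrier, [])):
                    continue
                placed = True
                break
            if not placed:
                continue
            taken.setdefault(carrier, []).append((start, end))
            rows.append((carrier, chrom[start], int(pos[start]), int(pos[end]),
                         start, end, ev.n_probes, ev.kind,
                         ev.mosaic_fraction if ev.kind == "mosaic_cnloh" else np.nan))
    return pd.DataFrame(rows, columns=[
        "individual_id", "chromosome", "start_bp", "end_bp",
        "start_probe_idx", "end_probe_idx", "n_probes", "kind",
        "mosaic_fraction"])


def generate_call_table(manifest: pd.DataFrame, cohort: pd.DataFrame,
                        config: SimulationConfig):
    """Simulate the full per-call table and its truth tables.

    Returns ``(calls, truth)`` where ``calls`` is a long-form DataFrame
    with the columns of :data:`arrayqc.genotype_io.CALL_COLUMNS` in
    sample-major order and ``truth`` is a :class:`TruthTables`.
    """
    config.validate()
    rng = _rng(config.seed, _S_CALLS)
    ev_rng = _rng(config.seed, _S_EVENTS)

    S, P = len(cohort), len(manifest)
    sample_ids = cohort["sample_id"].to_numpy()
    probe_ids = manifest["probe_id"].to_numpy()
    is_wga = (cohort["input_type"] == "wgaDNA").to_numpy()

    # ---- locus truth: MAF and genotypes under HWE --------------------
    locus_first = manifest.drop_duplicates("locus_id")
    L = len(locus_first)
    locus_ids = locus_first["locus_id"].to_numpy()
    locus_of_probe = pd.Index(locus_ids).get_indexer(manifest["locus_id"])
    maf = _draw_maf(rng, config, L)
    flip = rng.random(L) < 0.5
    f_b = np.where(flip, maf, 1.0 - maf)

    individuals = cohort["individual_id"].drop_duplicates().to_numpy()
    ind_index = pd.Index(individuals)
    ind_of_sample = ind_index.get_indexer(cohort["individual_id"])
    n_ind = len(individuals)
    G_ind = rng.binomial(2, f_b[None, :].repeat(n_ind, axis=0)).astype(np.int8)

    # ---- per-sample quality -------------------------------------------
    mu = np.empty(S)
    sd = np.empty(S)
    for (itype, src), (m, s) in config.quality_model.items():
        mask = ((cohort["input_type"] == itype)
                & (cohort["source_material"] == src)).to_numpy()
        mu[mask], sd[mask] = m, s
    q = np.clip(rng.normal(mu, sd), 0.02, 0.98)

    chips = cohort["chip_id"].drop_duplicates().to_numpy()
    failed_chips = chips[rng.random(len(chips)) < config.chip_fail_rate]
    plates = cohort["plate_id"].drop_duplicates().to_numpy()
    failed_plates = plates[rng.random(len(plates)) < config.plate_fail_rate]
    on_failed_chip = cohort["chip_id"].isin(failed_chips).to_numpy()
    on_failed_plate = cohort["plate_id"].isin(failed_plates).to_numpy()
    q = np.where(on_failed_chip, np.minimum(q, 0.20), q)
    q = np.where(on_failed_plate, np.minimum(q, 0.30), q)
    p_nc = np.clip(config.nocall_rate_coef * (1.0 - q), 0.0, 0.9)

    # ---- genotype matrix per sample -----------------------------------
    G = G_ind[ind_of_sample][:, locus_of_probe]  # (S, P) int8 view->copy

    # allele drop-out: locus-level vulnerability shared within individual
    q_ind_wga = np.full(n_ind, float(np.mean(q)))
    for k in range(n_ind):
        m = (ind_of_sample == k) & is_wga
        if m.any():
            q_ind_wga[k] = q[m].mean()
    v = np.clip(config.dropout_vulnerability_coef * (1.0 - q_ind_wga), 0, 1)
    vulnerable = rng.random((n_ind, L)) < v[:, None]
    retain_b = rng.random((n_ind, L)) < 0.5  # which allele survives
    vul_probe = vulnerable[:, locus_of_probe][ind_of_sample]       # (S, P)
    retain_b_probe = retain_b[:, locus_of_probe][ind_of_sample]
    drop_draw = rng.random((S, P)) < config.dropout_given_vulnerable
    dropout = (vul_probe & drop_draw & is_wga[:, None] & (G == AB))
    G = np.where(dropout, np.where(retain_b_probe, BB, AA), G).astype(np.int8)

    # genotype errors: uniform among the two other classes
    err = rng.random((S, P)) < config.genotype_error_rate
    shift = rng.integers(1, 3, size=(S, P))
    G = np.where(err, (G + shift) % 3, G).astype(np.int8)

    # ---- no-call mask -------------------------------------------------
    complete_fail = rng.random(P) < config.complete_fail_fraction
    subtel_locus = _subtelomeric_locus_mask(
        locus_first.reset_index(drop=True), config, rng)
    subtel_probe = subtel_locus[locus_of_probe]
    nc_mask = rng.random((S, P)) < p_nc[:, None]
    nc_mask |= complete_fail[None, :]
    nc_mask |= (subtel_probe[None, :] & is_wga[:, None])

    # ---- GC scores ----------------------------------------------------
    thr = config.gc_score_threshold
    a, b = config.gc_score_good_params
    score = thr + (1 - thr) * rng.beta(a, b, size=(S, P))
    score_bad = rng.uniform(0, thr, size=(S, P))
    score = np.where(nc_mask, score_bad, score).astype(np.float32)

    G_called = np.where(nc_mask, NC, G).astype(np.int8)

    # ---- LRR ----------------------------------------------------------
    gc = manifest["gc_fraction"].to_numpy()
    cpg = manifest["cpg_density"].to_numpy()
    wave = (config.gc_wave_amplitude * (gc - gc.mean())
            + config.cpg_wave_amplitude * (cpg - cpg.mean()))
    wave_scale = 1.0 + rng.normal(0, config.wave_sample_sd, S)
    chip_index = pd.Index(chips)
    chip_of_sample = chip_index.get_indexer(cohort["chip_id"])
    chip_offset = rng.normal(0, config.chip_lrr_offset_sd, len(chips))
    jitter = rng.lognormal(0, config.noise_jitter_sd, S)
    lrr_sd = config.lrr_noise_sd * jitter * np.where(
        is_wga, 1.0 + config.wga_noise_coef * (1.0 - q), 1.0)
    lrr = (wave_scale[:, None] * wave[None, :]
           + chip_offset[chip_of_sample][:, None]
           + rng.normal(0, 1, (S, P)) * lrr_sd[:, None]).astype(np.float32)

    # ---- BAF ----------------------------------------------------------
    noise = rng.normal(0, config.baf_noise_sd, (S, P))
    centers = np.choose(G, [0.0, 0.5, 1.0])
    baf = centers + noise
    baf[G == AA] = np.abs(noise[G == AA])
    baf[G == BB] = 1.0 - np.abs(noise[G == BB])

    # ---- injected CNV events ------------------------------------------
    events = _place_cnv_events(ev_rng, config, manifest, cohort)
    ev_rows = []
    side_b = ev_rng.random((max(len(events), 1), P)) < 0.5  # BAF side per locus
    for e_i, ev in enumerate(events.itertuples(index=False)):
        carriers = np.flatnonzero(
            cohort["individual_id"].to_numpy() == ev.individual_id)
        sl = slice(ev.start_probe_idx, ev.end_probe_idx + 1)
        for s_idx in carriers:
            kind = ev.kind
            lrr[s_idx, sl] += config.lrr_shift[kind]
            het = G[s_idx, sl] == AB
            side = side_b[e_i, sl][het]
            if kind == "gain":
                c = np.where(side, 2.0 / 3.0, 1.0 / 3.0)
            elif kind in ("loss", "cnloh"):
                c = np.where(side, 1.0, 0.0)
            else:  # mosaic_cnloh
                m = ev.mosaic_fraction
                c = np.where(side, 0.5 + m / 2.0, 0.5 - m / 2.0)
            baf[s_idx, sl][het] = c + rng.normal(0, config.baf_noise_sd,
                                                 int(het.sum()))
            ev_rows.append((sample_ids[s_idx],) + tuple(ev))
    cnv_truth = pd.DataFrame(ev_rows, columns=["sample_id"] + list(events.columns))
    cnv_truth = cnv_truth.rename(columns={"kind": "class"})

    baf = np.clip(baf, 0.0, 1.0).astype(np.float32)

    # ---- intensities consistent with the cluster model ----------------
    t_aa, t_ab, t_bb = config.cluster_thetas
    theta = np.interp(baf, [0.0, 0.5, 1.0], [t_aa, t_ab, t_bb])
    r = (2.0 ** lrr) * config.cluster_r
    x_raw = (r * np.cos(theta * np.pi / 2)).astype(np.float32)
    y_raw = (r * np.sin(theta * np.pi / 2)).astype(np.float32)

    calls = pd.DataFrame({
        "sample_id": pd.Categorical(np.repeat(sample_ids, P),
                                    categories=sample_ids),
        "probe_id": pd.Categorical(np.tile(probe_ids, S), categories=probe_ids),
        "genotype": G_called.ravel(),
        "gc_score": score.ravel(),
        "x_raw": x_raw.ravel(),
        "y_raw": y_raw.ravel(),
        "lrr": lrr.ravel(),
        "baf": baf.ravel(),
    })

    truth = TruthTables(
        samples=pd.DataFrame({
            "sample_id": sample_ids,
            "individual_id": cohort["individual_id"].to_numpy(),
            "input_type": cohort["input_type"].to_numpy(),
            "source_material": cohort["source_material"].to_numpy(),
            "q": q, "p_nc": p_nc, "lrr_sd": lrr_sd,
            "on_failed_chip": on_failed_chip,
            "on_failed_plate": on_failed_plate,
            "n_injected_nc": nc_mask.sum(axis=1),
        }),
        loci=pd.DataFrame({"locus_id": locus_ids, "maf": maf, "f_b": f_b,
                           "subtel_wga_fail": subtel_locus}),
        probes=pd.DataFrame({"probe_id": probe_ids,
                             "complete_fail": complete_fail,
                             "subtel_wga_fail": subtel_probe}),
        nocall_mask=nc_mask,
        genotype_error_idx=np.argwhere(err & ~nc_mask),
        dropout_idx=np.argwhere(dropout & ~nc_mask),
        cnv_events=cnv_truth,
        sample_order=list(sample_ids),
        probe_order=list(probe_ids),
    )
    return calls, truth


# ---------------------------------------------------------------------------
# STR profiles
# ---------------------------------------------------------------------------

def generate_str_profiles(cohort: pd.DataFrame, config: SimulationConfig,
                          sample_quality: pd.DataFrame | None = None):
    """Simulate Identifiler-style 16-marker profiles.

    Every individual gets a ground-truth profile (amelogenin set by
    reported sex).  gDNA samples reproduce the truth exactly; wgaDNA
    samples suffer quality-dependent allele drop-out at heterozygous
    markers, whole-marker failures, and rare contamination that adds
    third alleles at several autosomal markers.  A synthetic source-gDNA
    reference profile (``SRC_<individual>``) is emitted for every
    individual so each wgaDNA sample has a comparison partner even when
    the source gDNA was not array-genotyped.

    Returns ``(profiles, str_truth)``.
    """
    config.validate()
    rng = _rng(config.seed, _S_STR)
    if sample_quality is not None:
        qmap = dict(zip(sample_quality["sample_id"], sample_quality["q"]))
    else:
        qmap = {}

    individuals = cohort.drop_duplicates("individual_id")
    truth: dict[str, dict[str, frozenset]] = {}
    for ind in individuals.itertuples(index=False):
        prof = {}
        for m in STR_MARKERS:
            if m == AMEL:
                prof[m] = (frozenset({"X", "Y"}) if ind.reported_sex == "M"
                           else frozenset({"X"}))
            else:
                lo, hi = _STR_RANGES[m]
                prof[m] = frozenset(str(a) for a in
                                    rng.integers(lo, hi + 1, size=2))
        truth[ind.individual_id] = prof

    rows = []

    def emit(sample_id, ind_id, profile):
        for m in STR_MARKERS:
            rows.append((sample_id, m, profile[m]))

    for ind_id, prof in truth.items():
        emit(f"SRC_{ind_id}", ind_id, prof)

    for s in cohort.itertuples(index=False):
        prof = dict(truth[s.individual_id])
        if s.input_type == "wgaDNA":
            q = qmap.get(s.sample_id, 0.7)
            d = np.clip(config.str_dropout_coef * (1 - q), 0, 0.9)
            f = np.clip(config.str_failure_coef * (1 - q), 0, 0.9)
            for m in STR_MARKERS:
                if m == AMEL:
                    continue
                if rng.random() < f:
                    prof[m] = frozenset()
                elif len(prof[m]) == 2 and rng.random() < d:
                    keep = rng.choice(sorted(prof[m]))
                    prof[m] = frozenset({keep})
            if rng.random() < config.str_contamination_rate:
                markers = rng.choice(
                    [m for m in STR_MARKERS if m != AMEL], size=3, replace=False)
                for m in markers:
                    lo, hi = _STR_RANGES[m]
                    extra = {str(a) for a in range(lo, hi + 1)} - prof[m]
                    if extra and prof[m]:
                        prof[m] = prof[m] | {sorted(extra)[0]}
        emit(s.sample_id, s.individual_id, prof)

    profiles = pd.DataFrame(rows, columns=["sample_id", "marker", "alleles"])
    truth_rows = [(i, m, a) for i, p in truth.items() for m, a in p.items()]
    str_truth = pd.DataFrame(truth_rows,
                             columns=["individual_id", "marker", "alleles"])
    return profiles, str_truth


# ---------------------------------------------------------------------------
# Convenience: run everything, optionally to disk
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig):
    """Generate manifest, cohort, calls, truth and STR profiles."""
    manifest = generate_manifest(config)
    cohort = generate_cohort(config)
    calls, truth = generate_call_table(manifest, cohort, config)
    profiles, str_truth = generate_str_profiles(cohort, config, truth.samples)
    truth.str_truth = str_truth
    return manifest, cohort, calls, truth, profiles


def write_simulation(outdir, config: SimulationConfig):
    """Run the generator and write every output as plain text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest, cohort, calls, truth, profiles = simulate_all(config)
    config.to_yaml(outdir / "config.yaml")
    gio.write_manifest(manifest, outdir / "manifest.csv")
    gio.write_sample_sheet(cohort, outdir / "samples.tsv")
    gio.write_final_report(calls, outdir / "final_report.txt")
    gio.write_str_profiles(profiles, outdir / "str_profiles.tsv")
    truth.samples.to_csv(outdir / "truth_samples.tsv", sep="\t", index=False)
    truth.loci.to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
    truth.cnv_events.to_csv(outdir / "truth_cnv.tsv", sep="\t", index=False)
    return manifest, cohort, calls, truth, profiles
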