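"""Self-contained synthetic dataset with planted ground truth.

The generator emulates the data shape of a two-factor chromatin profiling
study: a "SMAD"-like signal factor and a co-factor are profiled in two
genotypes (co-factor present, ``wt``, and co-factor null, ``ko``) with
replicates, alongside a promoter-activity factor in three conditions and a
per-cell dot-count table.  Planted structure:

* a fraction of SMAD sites are co-bound by the co-factor; their SMAD
  signal drops by ``2**-delta`` in the null genotype;
* a fraction ``rho`` of co-bound sites acquires an ectopic SMAD site at a
  bounded offset (<= relocation_distance) in the null genotype only;
* motif content differs by site class (palindromic SMAD motif at co-bound
  sites, a GC-rich SMAD-binding element at solo sites, an AP1 site at
  ectopic sites), written into the genome at the site centres;
* promoter windows of planted repressed gene sets have elevated activity
  in the corresponding perturbed condition;
* the count table has planted genotype effects and one correlated gene
  pair driven by a shared latent factor.

Coverage is modelled at the per-base level: expected counts are a flat
background plus triangular peaks of width ``peak_width``, Poisson-sampled
per base.  There is no read/fragment model, and no mappability or GC bias.

Layout: chromosome 1 carries co-bound sites (and their ectopic partners),
chromosome 2 carries solo sites, chromosome 3 carries genes; any further
chromosomes are background only.  Keeping solo sites on their own
chromosome guarantees that the planted flanking set of the co-bound sites
consists exactly of the ectopic sites.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .errors import SizingError
from .intervals import GeneModel, GenomicInterval, write_bed
from .motifscan import DEFAULT_MOTIFS, IUPAC, MotifPattern

FACTORS = ("smad", "cofactor", "igg", "activity")
GENOTYPES = ("wt", "ko")
ACTIVITY_CONDITIONS = ("treated", "untreated", "null_treated")

# dot-count model per gene: (mean CH wt, mean ChP wt, mut ChP log2 effect,
# driven by the shared proliferation latent factor?)
DEFAULT_CELL_GENES: dict[str, tuple[float, float, float, bool]] = {
    "Ttr": (2.0, 30.0, -3.0, False),
    "Foxj1": (1.0, 10.0, -2.5, False),
    "Wnt2b": (20.0, 2.0, 0.0, False),
    "Wnt7b": (6.0, 1.0, 2.0, False),
    "Wnt3a": (4.0, 1.0, 1.5, False),
    "Axin2": (8.0, 2.0, 1.5, True),
    "Mki67": (10.0, 1.0, 2.0, True),
    "Sox2": (8.0, 2.0, 1.5, False),
    "Hes5": (6.0, 1.0, 1.5, False),
    "Bmp4": (3.0, 15.0, 0.0, False),
}


@dataclass
class CellTableConfig:
    n_cells_per_region: int = 110
    n_replicates: int = 3
    latent_sd: float = 0.6  # sd of the shared log-normal proliferation factor
    effects_override: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticConfig:
    """Planted parameters of the synthetic study.

    ``repressed_set_sizes`` is (n_bmp_repressed, n_cofactor_repressed,
    n_overlap).  ``genome_length`` may be left None to size the genome from
    the layout; an explicit value smaller than the layout requires raises
    :class:`SizingError`.
    """

    n_smad_sites: int = 200
    cobound_fraction: float = 0.5
    dependence_effect_delta: float = 1.0
    relocation_fraction_rho: float = 0.5
    relocation_distance: int = 200_000
    n_replicates: int = 3
    library_size: float = 1_000_000.0
    peak_width: int = 1_000
    background_rate: float = 0.02
    n_genes: int = 500
    repressed_set_sizes: tuple[int, int, int] = (50, 50, 20)
    promoter_effect: float = 1.0  # log2 elevation at repressed promoters
    genome_length: int | None = None
    n_chroms: int = 3
    site_spacing: int = 25_000
    gene_spacing: int = 3_000
    ectopic_offset_range: tuple[int, int] = (4_000, 11_000)
    motif_rates: dict[str, float] = field(
        default_factory=lambda: {"cobound": 0.8, "solo": 0.6, "ectopic": 0.8}
    )
    bound_gene_probs: dict[str, float] = field(
        default_factory=lambda: {
            "co_repressed": 0.8,
            "bmp_only": 0.5,
            "cofactor_only": 0.5,
            "other": 0.2,
        }
    )
    cell_table: CellTableConfig = field(default_factory=CellTableConfig)
    seed: int = 1

    def validate(self) -> None:
        n_bmp, n_cof, n_overlap = self.repressed_set_sizes
        if n_overlap > min(n_bmp, n_cof):
            raise ValueError("n_overlap must be <= min(set sizes)")
        if n_bmp + n_cof - n_overlap > self.n_genes:
            raise ValueError("repressed sets exceed the gene universe")
        for name, v in (
            ("cobound_fraction", self.cobound_fraction),
            ("relocation_fraction_rho", self.relocation_fraction_rho),
        ):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dependence_effect_delta < 0:
            raise ValueError("dependence_effect_delta must be >= 0")
        if self.n_chroms < 3:
            raise ValueError("layout needs at least 3 chromosomes")
        lo, hi = self.ectopic_offset_range
        if not (0 < lo <= hi <= self.relocation_distance):
            raise ValueError(
                "ectopic offsets must satisfy 0 < lo <= hi <= relocation_distance"
            )
        if hi + self.peak_width >= self.site_spacing:
            raise SizingError(
                "ectopic offset plus peak width must be smaller than the "
                "site spacing so ectopic peaks stay clear of neighbouring sites"
            )
        if self.peak_width > 2 * self.gene_spacing:
            raise SizingError("peak_width exceeds twice the gene spacing")

    # ------------------------------------------------------------ layout
    @property
    def n_cobound(self) -> int:
        return int(round(self.n_smad_sites * self.cobound_fraction))

    @property
    def n_solo(self) -> int:
        return self.n_smad_sites - self.n_cobound

    def chrom_lengths(self) -> dict[str, int]:
        lengths = {
            "chr1": max(self.n_cobound, 1) * self.site_spacing,
            "chr2": max(self.n_solo, 1) * self.site_spacing,
            "chr3": self.n_genes * self.gene_spacing + self.gene_spacing,
        }
        for extra in range(3, self.n_chroms):
            lengths[f"chr{extra + 1}"] = 50_000
        required = sum(lengths.values())
        if self.genome_length is not None:
            if self.genome_length < required:
                raise SizingError(
                    f"genome_length {self.genome_length} cannot hold the site "
                    f"layout (requires >= {required}: "
                    f"{self.n_smad_sites} sites x {self.site_spacing} bp spacing "
                    f"plus {self.n_genes} genes x {self.gene_spacing} bp)"
                )
            lengths["chr3"] += self.genome_length - required
        return lengths


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus planted truth.

    ``tracks`` maps (factor, condition, replicate) to raw-count coverage;
    condition is a genotype for the binding factors and a treatment label
    for the activity factor.  Amplitudes (expected reads per planted site)
    are exposed so tests can recompute expectations from the planted
    Poisson rates.
    """

    config: SyntheticConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    truth_sites: pd.DataFrame
    truth_genes: pd.DataFrame
    truth_cell_effects: pd.DataFrame
    tracks: dict[tuple[str, str, int], CoverageTrack]
    counts: pd.DataFrame
    site_amplitude: float
    cofactor_amplitude: float
    activity_amplitude: float

    def track_group(self, factor: str, condition: str) -> list[CoverageTrack]:
        n = (
            self.config.cell_table.n_replicates
            if factor == "counts"
            else self.config.n_replicates
        )
        return [self.tracks[(factor, condition, r)] for r in range(n)]

    def site_intervals(self, classes: tuple[str, ...] | None = None
                       ) -> list[GenomicInterval]:
        out = []
        for _, row in self.truth_sites.iterrows():
            if classes and row["site_class"] not in classes:
                continue
            out.append(
                GenomicInterval(
                    row["chrom"], int(row["start"]), int(row["end"]),
                    row["site_id"], 0.0, ".", int(row["summit"]),
                )
            )
        return out


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([seed % (2**31), *tags])


def _triangle(width: int) -> np.ndarray:
    """Unit-mass triangular kernel over ``width`` bases."""
    half = width / 2.0
    x = np.arange(width) + 0.5
    k = np.clip(1.0 - np.abs(x - half) / half, 0.0, None)
    return k / k.sum()


def _instantiate(iupac: str, rng: np.random.Generator) -> str:
    return "".join(
        c if len(IUPAC[c]) == 1 else IUPAC[c][rng.integers(len(IUPAC[c]))]
        for c in iupac
    )


def _motif_by_class(cls: str) -> MotifPattern:
    lookup = {"cobound": "palindromic", "solo": "gc_rich", "ectopic": "ap1"}
    for m in DEFAULT_MOTIFS:
        if m.motif_class == lookup[cls]:
            return m
    raise KeyError(cls)


def simulate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full dataset in memory.  Deterministic in (config, seed):
    independent random streams are derived from the master seed with fixed
    tags, so e.g. adding replicates does not perturb the genome or layout."""
    config.validate()
    seed = config.seed
    lengths = config.chrom_lengths()
    layout_rng = _rng(seed, 1)

    # ---------------------------------------------------------- site layout
    sites: list[dict] = []
    half_spacing = config.site_spacing // 2
    for i in range(config.n_cobound):
        center = half_spacing + i * config.site_spacing
        sites.append({"site_class": "cobound", "chrom": "chr1", "center": center})
    for i in range(config.n_solo):
        center = half_spacing + i * config.site_spacing
        sites.append({"site_class": "solo", "chrom": "chr2", "center": center})
    n_ectopic = int(round(config.relocation_fraction_rho * config.n_cobound))
    ectopic_hosts = layout_rng.choice(config.n_cobound, size=n_ectopic,
                                      replace=False) if n_ectopic else []
    lo, hi = config.ectopic_offset_range
    for host in sorted(int(h) for h in ectopic_hosts):
        offset = int(layout_rng.integers(lo, hi + 1))
        sign = 1 if layout_rng.random() < 0.5 else -1
        center = sites[host]["center"] + sign * offset
        if not 0 <= center - config.peak_width // 2 < center + config.peak_width // 2 <= lengths["chr1"]:
            center = sites[host]["center"] - sign * offset
        sites.append({"site_class": "ectopic", "chrom": "chr1", "center": center,
                      "host": sites[host]["center"]})

    # ------------------------------------------------------------ gene sets
    n_bmp, n_cof, n_overlap = config.repressed_set_sizes
    perm = layout_rng.permutation(config.n_genes)
    co_set = set(perm[:n_overlap].tolist())
    bmp_only = set(perm[n_overlap : n_bmp].tolist())
    cof_only = set(perm[n_bmp : n_bmp + n_cof - n_overlap].tolist())

    genes: list[GeneModel] = []
    gene_rows = []
    probs = config.bound_gene_probs
    for g in range(config.n_genes):
        tss = config.gene_spacing // 2 + g * config.gene_spacing
        strand = "+" if g % 2 == 0 else "-"
        gid = f"gene_{g:04d}"
        genes.append(GeneModel(gid, "chr3", tss, strand))
        if g in co_set:
            cls, p_bound = "co_repressed", probs["co_repressed"]
        elif g in bmp_only:
            cls, p_bound = "bmp_only", probs["bmp_only"]
        elif g in cof_only:
            cls, p_bound = "cofactor_only", probs["cofactor_only"]
        else:
            cls, p_bound = "other", probs["other"]
        bound = bool(layout_rng.random() < p_bound)
        gene_rows.append(
            {
                "gene_id": gid,
                "chrom": "chr3",
                "tss": tss,
                "strand": strand,
                "set_class": cls,
                "bmp_repressed": cls in ("co_repressed", "bmp_only"),
                "cofactor_repressed": cls in ("co_repressed", "cofactor_only"),
                "bound": bound,
                "planted_effect": config.promoter_effect
                if cls != "other"
                else 0.0,
            }
        )
        if bound:
            sites.append({"site_class": "promoter", "chrom": "chr3",
                          "center": tss, "gene_id": gid})
    truth_genes = pd.DataFrame(gene_rows)

    # ------------------------------------------------------------ amplitudes
    # sized against the most-loaded condition so that every condition's
    # expected total fits within the library once the background absorbs
    # the slack (composition balance; see the sampling step below)
    total_len = sum(lengths.values())
    bg_total = config.background_rate * total_len
    budget = config.library_size - bg_total
    if budget <= 0:
        raise SizingError(
            "background consumes the whole library; lower background_rate "
            "or raise library_size"
        )
    n_ectopic_planned = int(round(config.relocation_fraction_rho * config.n_cobound))
    n_promoter = sum(s["site_class"] == "promoter" for s in sites)
    atten = 2.0 ** (-config.dependence_effect_delta)
    load_wt = config.n_cobound + config.n_solo + n_promoter
    load_ko = (
        config.n_cobound * atten + config.n_solo + n_promoter + n_ectopic_planned
    )
    site_amplitude = budget / max(load_wt, load_ko, 1)
    cofactor_amplitude = budget / max(config.n_cobound, 1)
    lift_excess = 2.0 ** config.promoter_effect - 1.0
    n_bmp, n_cof, _ = config.repressed_set_sizes
    act_load = config.n_genes + lift_excess * max(n_bmp, n_cof)
    activity_amplitude = budget / act_load

    # -------------------------------------------------------------- genome
    genome_rng = _rng(seed, 0)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    raw_genome: dict[str, bytearray] = {}
    for chrom, length in lengths.items():
        arr = bases[genome_rng.integers(0, 4, size=length)]
        raw_genome[chrom] = bytearray(arr.tobytes())

    # plant motifs at site centres
    motif_rng = _rng(seed, 4)
    site_rows = []
    w = config.peak_width
    for idx, s in enumerate(sites):
        cls = s["site_class"]
        center = s["center"]
        motif_name, motif_start = "", -1
        if cls in config.motif_rates and motif_rng.random() < config.motif_rates[cls]:
            pattern = _motif_by_class(cls)
            concrete = _instantiate(pattern.iupac, motif_rng)
            motif_start = center - len(concrete) // 2
            raw_genome[s["chrom"]][motif_start : motif_start + len(concrete)] = (
                concrete.encode("ascii")
            )
            motif_name = pattern.name
        if cls == "cobound":
            planted = -config.dependence_effect_delta
        elif cls == "ectopic":
            planted = float("nan")  # absent in wt; gained in ko
        else:
            planted = 0.0
        site_rows.append(
            {
                "site_id": f"{cls}_{idx:04d}",
                "site_class": cls,
                "chrom": s["chrom"],
                "start": center - w // 2,
                "end": center + w // 2,
                "summit": center,
                "host_center": s.get("host", -1),
                "gene_id": s.get("gene_id", ""),
                "planted_motif": motif_name,
                "motif_start": motif_start,
                "planted_log2fc": planted,
            }
        )
    truth_sites = pd.DataFrame(site_rows)
    genome = {c: b.decode("ascii") for c, b in raw_genome.items()}

    # -------------------------------------------------------------- tracks
    kernel = _triangle(w)
    attenuation = 2.0 ** (-config.dependence_effect_delta)

    # per (factor, condition): chrom -> list of (center, amplitude) peaks
    peak_specs: dict[tuple[str, str], dict[str, list[tuple[int, float]]]] = {}

    def add_peak(spec, chrom, center, amplitude):
        spec.setdefault(chrom, []).append((center, amplitude))

    for genotype in GENOTYPES:
        smad: dict[str, list[tuple[int, float]]] = {}
        cof: dict[str, list[tuple[int, float]]] = {}
        for s in sites:
            cls, chrom, center = s["site_class"], s["chrom"], s["center"]
            if cls == "cobound":
                amp = site_amplitude * (attenuation if genotype == "ko" else 1.0)
                add_peak(smad, chrom, center, amp)
                if genotype == "wt":
                    add_peak(cof, chrom, center, cofactor_amplitude)
            elif cls in ("solo", "promoter"):
                add_peak(smad, chrom, center, site_amplitude)
            elif cls == "ectopic" and genotype == "ko":
                add_peak(smad, chrom, center, site_amplitude)
        peak_specs[("smad", genotype)] = smad
        peak_specs[("cofactor", genotype)] = cof
        peak_specs[("igg", genotype)] = {}

    lift = 2.0 ** config.promoter_effect
    for cond in ACTIVITY_CONDITIONS:
        act: dict[str, list[tuple[int, float]]] = {}
        for row in gene_rows:
            amp = activity_amplitude
            if cond == "untreated" and row["bmp_repressed"]:
                amp *= lift
            elif cond == "null_treated" and row["cofactor_repressed"]:
                amp *= lift
            add_peak(act, "chr3", row["tss"], amp)
        peak_specs[("activity", cond)] = act

    # Sampling: per-base Poisson with rate = background + triangular peaks
    # is realized as a Poisson total split into uniform background reads and
    # peak reads drawn from the concatenated peak profile (Poisson thinning).
    tracks: dict[tuple[str, str, int], CoverageTrack] = {}
    factor_code = {"smad": 0, "cofactor": 1, "igg": 2, "activity": 3}
    cond_code = {"wt": 0, "ko": 1, "treated": 0, "untreated": 1, "null_treated": 2}
    for (factor, cond), spec in peak_specs.items():
        profiles = {}
        peak_total = 0.0
        for chrom, peaks in spec.items():
            pos = np.concatenate(
                [np.arange(c - w // 2, c - w // 2 + w) for c, _ in peaks]
            )
            cum = np.cumsum(np.concatenate([amp * kernel for _, amp in peaks]))
            peak_total += float(cum[-1])
            profiles[chrom] = (pos, cum)
        # conditions with planted enrichment keep the same expected total as
        # the reference library: the background absorbs the planted excess,
        # so library normalization does not manufacture fold changes at
        # unperturbed features (composition balance)
        if peak_total > 0:
            bg_rate = (config.library_size - peak_total) / total_len
            if bg_rate <= 0:
                raise SizingError(
                    f"planted peaks for {factor}/{cond} exceed the library; "
                    "raise library_size or lower effect sizes"
                )
        else:
            bg_rate = config.background_rate
        for rep in range(config.n_replicates):
            rng = _rng(seed, 2, factor_code[factor], cond_code[cond], rep)
            positions = {}
            for chrom, length in lengths.items():
                n_bg = rng.poisson(bg_rate * length)
                reads = [rng.integers(0, length, size=n_bg)]
                if chrom in profiles:
                    pos, cum = profiles[chrom]
                    total = float(cum[-1])
                    n_pk = rng.poisson(total)
                    u = rng.random(n_pk) * total
                    reads.append(pos[np.searchsorted(cum, u, side="right")])
                positions[chrom] = np.concatenate(reads)
            tracks[(factor, cond, rep)] = CoverageTrack.from_positions(positions)

    # ---------------------------------------------------------- cell counts
    counts, cell_effects = _simulate_cells(config, _rng(seed, 3))

    return SyntheticDataset(
        config=config,
        genome=genome,
        genes=genes,
        truth_sites=truth_sites,
        truth_genes=truth_genes,
        truth_cell_effects=cell_effects,
        tracks=tracks,
        counts=counts,
        site_amplitude=site_amplitude,
        cofactor_amplitude=cofactor_amplitude,
        activity_amplitude=activity_amplitude,
    )


def _simulate_cells(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    cfg = config.cell_table
    gene_specs = {
        g: (
            ch,
            chp,
            cfg.effects_override.get(g, eff),
            latent,
        )
        for g, (ch, chp, eff, latent) in DEFAULT_CELL_GENES.items()
    }
    rows = []
    cell_idx = 0
    for genotype in ("wt", "mut"):
        for rep in range(cfg.n_replicates):
            for region in ("CH", "ChP"):
                for _ in range(cfg.n_cells_per_region):
                    z = float(np.exp(rng.normal(0.0, cfg.latent_sd)))
                    row = {
                        "cell_id": f"cell_{cell_idx:05d}",
                        "region": region,
                        "genotype": genotype,
                        "replicate": rep,
                    }
                    for g, (mu_ch, mu_chp, eff, latent) in gene_specs.items():
                        mu = mu_ch if region == "CH" else mu_chp
                        if genotype == "mut" and region == "ChP":
                            mu *= 2.0 ** eff
                        if latent:
                            mu *= z
                        row[g] = int(rng.poisson(mu))
                    rows.append(row)
                    cell_idx += 1
    counts = pd.DataFrame(rows)
    effects = pd.DataFrame(
        [
            {
                "gene": g,
                "mean_ch_wt": spec[0],
                "mean_chp_wt": spec[1],
                "mut_chp_log2_effect": spec[2],
                "latent_coupled": spec[3],
            }
            for g, spec in gene_specs.items()
        ]
    )
    return counts, effects


# --------------------------------------------------------------------- I/O
def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def generate_dataset(config: SyntheticConfig, out_dir) -> SyntheticDataset:
    """Generate and write the dataset under ``out_dir``.

    Files: genome.fa, genes.tsv, truth.tsv (sites), truth_genes.tsv,
    truth_cells.tsv, truth_sites.bed, counts.tsv, tracks/*.bedgraph and a
    tracks.tsv manifest.
    """
    ds = simulate(config)
    out = Path(out_dir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    write_fasta(ds.genome, out / "genome.fa")
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss, g.strand) for g in ds.genes],
        columns=["gene_id", "chrom", "tss", "strand"],
    ).to_csv(out / "genes.tsv", sep="\t", index=False)
    ds.truth_sites.to_csv(out / "truth.tsv", sep="\t", index=False)
    ds.truth_genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    ds.truth_cell_effects.to_csv(out / "truth_cells.tsv", sep="\t", index=False)
    write_bed(ds.site_intervals(), out / "truth_sites.bed")
    ds.counts.to_csv(out / "counts.tsv", sep="\t", index=False)
    manifest = []
    for (factor, cond, rep), track in ds.tracks.items():
        name = f"{factor}_{cond}_rep{rep}.bedgraph"
        track.write_bedgraph(out / "tracks" / name)
        manifest.append(
            {
                "file": f"tracks/{name}",
                "factor": factor,
                "condition": cond,
                "replicate": rep,
                "library_size": track.library_size,
            }
        )
    pd.DataFrame(manifest).to_csv(out / "tracks.tsv", sep="\t", index=False)
    return ds


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
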