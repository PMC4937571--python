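"""Synthetic data with the statistical structure of a barcoded enhancer screen.

The generator emulates a captured-fragment reporter experiment: regions of
interest, a fraction of which carry one planted 20-bp TP53 response element;
random 17-nt barcodes coupled to regions (with chimeric couplings and
optional barcode substitution noise); negative-binomial plasmid and cDNA
counts where responsive regions are induced by a single multiplicative
``activity_fold`` in the p53-high condition (the binary on/off behaviour of
TP53 enhancers); and a sites-by-experiments ChIP coverage matrix with
shared strong/weak/unbound tiers plus experiment-private indirect peaks.

Every draw flows from ``SimConfig.seed`` through one ``numpy.random.Generator``
per operation, so outputs are byte-identical for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motif_model import BASES, PWM, reverse_complement, tp53_tetramer_pwm

SITE_LENGTH = 20  # duplicated RRRCWWGYYY half-site, zero spacer


@dataclass
class SimConfig:
    """Parameters of the synthetic screen.

    Counts follow NB(mean, dispersion) with variance mean + dispersion*mean^2.
    ``tier_means`` are the shared strong/weak/unbound coverage means of the
    multi-experiment simulation and must be strictly decreasing.
    """

    n_regions: int = 500
    region_length: int = 500
    frac_positive: float = 0.4
    barcode_length: int = 17
    mean_barcodes_per_region: float = 1.2
    coupling_depth: float = 10.0  # long-read support per true coupling
    chimera_rate: float = 0.05
    barcode_error_rate: float = 0.0
    n_replicates: int = 2
    depth: float = 1000.0
    activity_fold: float = 8.0
    nb_dispersion: float = 0.05
    n_sites: int = 300
    n_experiments: int = 3
    tier_means: tuple[float, float, float] = (100.0, 20.0, 2.0)
    tier_fractions: tuple[float, float, float] = (0.2, 0.3, 0.5)
    indirect_rate: float = 0.1
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    at_depletion: bool = False
    graded_activity_sd: float = 0.0  # log2 sd around log2(activity_fold); 0 = binary
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_positive", "chimera_rate", "barcode_error_rate",
                     "indirect_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.activity_fold < 1.0:
            raise ValueError("activity_fold must be >= 1")
        if not (self.tier_means[0] > self.tier_means[1] > self.tier_means[2] > 0):
            raise ValueError("tier_means must be strictly decreasing and positive")
        if self.mean_barcodes_per_region < 1.0:
            raise ValueError("mean_barcodes_per_region must be >= 1")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class SimTruth:
    """Planted ground truth: exactly describes the emitted data."""

    region_class: dict[str, str] = field(default_factory=dict)  # responsive/unresponsive
    motif_offset: dict[str, int] = field(default_factory=dict)
    motif_strand: dict[str, str] = field(default_factory=dict)
    barcode_region: dict[str, str] = field(default_factory=dict)
    barcode_collisions: list[str] = field(default_factory=list)
    site_tier: dict[str, str] = field(default_factory=dict)  # strong/weak/unbound/indirect
    site_private_experiment: dict[str, str] = field(default_factory=dict)
    site_interval: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {k: getattr(self, k) for k in
                   ("region_class", "motif_offset", "motif_strand",
                    "barcode_region", "barcode_collisions", "site_tier",
                    "site_private_experiment", "site_interval")}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def sample_site(pwm: PWM, rng: np.random.Generator,
                consensus: bool = False) -> str:
    """One site drawn column-wise from the PWM (or its argmax consensus)."""
    if consensus:
        return pwm.consensus()
    cols = [rng.choice(4, p=row) for row in pwm.matrix]
    return "".join(BASES[c] for c in cols)


def _background_codes(n: int, freqs, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(4, size=n, p=np.asarray(freqs, float))


def simulate_regions(config: SimConfig, pwm: PWM | None = None,
                     consensus_sites: bool = False
                     ) -> tuple[list[tuple[str, str]], SimTruth]:
    """Regions as (id, sequence) pairs; positives carry one planted full site.

    Exactly ``round(n_regions * frac_positive)`` regions receive one 20-bp
    site sampled from the PWM at a uniform interior offset on a random
    strand; the rest are i.i.d. background.  With ``at_depletion`` the
    responsive flanks 50-150 bp from the site midpoint are GC-shifted,
    mimicking the A/T-dinucleotide depletion seen around bound sites.
    """
    pwm = pwm or tp53_tetramer_pwm()
    if len(pwm) != SITE_LENGTH:
        raise ValueError("full tetramer site required")
    if config.region_length < len(pwm):
        raise ValueError("region_length shorter than the PWM")
    rng = config.rng(1)
    n_pos = int(round(config.n_regions * config.frac_positive))
    positive_idx = set(rng.choice(config.n_regions, size=n_pos, replace=False).tolist())

    truth = SimTruth()
    records: list[tuple[str, str]] = []
    gc_shift = np.array([0.15, 0.35, 0.35, 0.15])
    for i in range(config.n_regions):
        rid = f"region_{i:05d}"
        codes = _background_codes(config.region_length, config.base_freqs, rng)
        seq = "".join(BASES[c] for c in codes)
        if i in positive_idx:
            offset = int(rng.integers(0, config.region_length - SITE_LENGTH + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            site = sample_site(pwm, rng, consensus=consensus_sites)
            planted = site if strand == "+" else reverse_complement(site)
            seq = seq[:offset] + planted + seq[offset + SITE_LENGTH:]
            if config.at_depletion:
                mid = offset + SITE_LENGTH // 2
                chars = list(seq)
                for pos in range(config.region_length):
                    d = abs(pos - mid)
                    if 50 <= d <= 150:
                        chars[pos] = BASES[int(rng.choice(4, p=gc_shift))]
                # keep the planted site itself intact
                chars[offset:offset + SITE_LENGTH] = planted
                seq = "".join(chars)
            truth.region_class[rid] = "responsive"
            truth.motif_offset[rid] = offset
            truth.motif_strand[rid] = strand
        else:
            truth.region_class[rid] = "unresponsive"
        records.append((rid, seq))
    return records, truth


def _random_barcode(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[c] for c in rng.integers(0, 4, size=length))


def simulate_library(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Coupling reads: (barcode, region_id, n_reads) long-read evidence.

    Barcodes per region are 1 + Poisson(mean - 1); a ``chimera_rate``
    fraction of barcodes additionally emit a few reads attributed to a
    second random region.  Chance barcode collisions across regions are
    recorded in ``truth.barcode_collisions`` rather than merged.
    """
    if not truth.region_class:
        raise ValueError("truth has no regions; run simulate_regions first")
    rng = config.rng(2)
    regions = sorted(truth.region_class)
    rows: list[tuple[str, str, int]] = []
    seen: dict[str, str] = {}
    for rid in regions:
        k = 1 + rng.poisson(config.mean_barcodes_per_region - 1.0)
        for _ in range(k):
            bc = _random_barcode(rng, config.barcode_length)
            if bc in seen and seen[bc] != rid:
                truth.barcode_collisions.append(bc)
            seen[bc] = rid
            truth.barcode_region[bc] = rid
            n_reads = 1 + rng.poisson(config.coupling_depth - 1.0)
            if config.barcode_error_rate > 0:
                p_err = 1.0 - (1.0 - config.barcode_error_rate) ** config.barcode_length
                n_bad = rng.binomial(n_reads, p_err)
                n_reads -= n_bad
                for _ in range(n_bad):
                    pos = int(rng.integers(config.barcode_length))
                    sub = BASES[int((rng.integers(1, 4) + "ACGT".index(bc[pos])) % 4)]
                    rows.append((bc[:pos] + sub + bc[pos + 1:], rid, 1))
            if n_reads > 0:
                rows.append((bc, rid, n_reads))
            if rng.random() < config.chimera_rate:
                other = regions[int(rng.integers(len(regions)))]
                rows.append((bc, other, 1 + rng.poisson(1.0)))
    return pd.DataFrame(rows, columns=["barcode", "region_id", "n_reads"])


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float,
             size: int) -> np.ndarray:
    if mean <= 0:
        raise ValueError("depth must be > 0")
    if dispersion <= 0:
        return rng.poisson(mean, size)
    n = 1.0 / dispersion
    return rng.negative_binomial(n, n / (n + mean), size)


def sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = []
    for rep in range(1, config.n_replicates + 1):
        rows.append((f"plasmid_rep{rep}", "plasmid", "input", rep))
        rows.append((f"cdna_high_rep{rep}", "cDNA", "p53_high", rep))
        rows.append((f"cdna_off_rep{rep}", "cDNA", "p53_off", rep))
    return pd.DataFrame(rows, columns=["sample_id", "material", "condition",
                                       "replicate"])


def simulate_counts(couplings: pd.DataFrame, truth: SimTruth,
                    config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Barcode x sample NB counts plus the sample sheet.

    Plasmid and p53-off cDNA counts have mean ``depth``; p53-high cDNA of a
    barcode on a responsive region has mean ``depth * activity_fold`` (the
    binary on/off model; ``graded_activity_sd`` adds per-region log2 jitter).
    """
    if config.depth <= 0:
        raise ValueError("depth must be > 0")
    rng = config.rng(3)
    barcodes = sorted(set(couplings["barcode"]) & set(truth.barcode_region))
    samples = sample_sheet(config)
    region_fold: dict[str, float] = {}
    for rid, cls in sorted(truth.region_class.items()):
        if cls != "responsive":
            region_fold[rid] = 1.0
        elif config.graded_activity_sd > 0:
            region_fold[rid] = 2.0 ** rng.normal(np.log2(config.activity_fold),
                                                 config.graded_activity_sd)
        else:
            region_fold[rid] = config.activity_fold

    data = {}
    n = len(barcodes)
    folds = np.array([region_fold[truth.barcode_region[b]] for b in barcodes])
    for _, s in samples.iterrows():
        if s["material"] == "plasmid" or s["condition"] == "p53_off":
            means = np.full(n, config.depth)
        else:
            means = config.depth * folds
        col = np.empty(n, dtype=int)
        for i in range(n):
            col[i] = _nb_draw(rng, means[i], config.nb_dispersion, 1)[0]
        data[s["sample_id"]] = col
    counts = pd.DataFrame(data, index=pd.Index(barcodes, name="barcode"))
    return counts, samples


def simulate_coverage(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Sites x experiments coverage with shared tiers and private peaks.

    Shared sites draw NB coverage around their tier mean in every
    experiment; ``round(indirect_rate * n_sites)`` extra experiment-private
    sites get strong coverage in exactly one experiment and background
    coverage elsewhere, mimicking indirect (non-motif) ChIP peaks.  Sites
    get synthetic coordinates on one chromosome, 1 kb apart.
    """
    if config.n_experiments < 2:
        raise ValueError("n_experiments must be >= 2")
    rng = config.rng(4)
    strong, weak, unbound = config.tier_means
    fr = np.asarray(config.tier_fractions, float)
    n_tier = np.round(fr / fr.sum() * config.n_sites).astype(int)
    n_tier[-1] = config.n_sites - n_tier[:-1].sum()
    tiers = (["strong"] * n_tier[0] + ["weak"] * n_tier[1]
             + ["unbound"] * n_tier[2])
    n_private = int(round(config.indirect_rate * config.n_sites))
    experiments = [f"exp_{j + 1}" for j in range(config.n_experiments)]
    mean_of = {"strong": strong, "weak": weak, "unbound": unbound}

    truth = SimTruth()
    rows = []
    site_ids = []
    order = rng.permutation(len(tiers))
    for i, idx in enumerate(order):
        sid = f"site_{i:05d}"
        tier = tiers[idx]
        site_ids.append(sid)
        truth.site_tier[sid] = tier
        rows.append([_nb_draw(rng, mean_of[tier], config.nb_dispersion, 1)[0]
                     for _ in experiments])
    for p in range(n_private):
        sid = f"site_p{p:05d}"
        owner = experiments[int(rng.integers(config.n_experiments))]
        site_ids.append(sid)
        truth.site_tier[sid] = "indirect"
        truth.site_private_experiment[sid] = owner
        rows.append([_nb_draw(rng, strong if e == owner else unbound,
                              config.nb_dispersion, 1)[0]
                     for e in experiments])
    for i, sid in enumerate(site_ids):
        start = 1000 + i * 1000
        truth.site_interval[sid] = ("chrS", start, start + 200)
    matrix = pd.DataFrame(rows, index=pd.Index(site_ids, name="site_id"),
                          columns=experiments)
    return matrix, truth


def write_outputs(outdir, config: SimConfig, pwm: PWM | None = None) -> dict:
    """Run the full simulation and write TSV/FASTA/JSON artifacts to outdir."""
    from pathlib import Path

    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    regions, truth = simulate_regions(config, pwm)
    seqio_write([SeqRecord(Seq(s), id=r, description="") for r, s in regions],
                outdir / "regions.fa", "fasta")
    couplings = simulate_library(truth, config)
    couplings.to_csv(outdir / "couplings.tsv", sep="\t", index=False)
    counts, samples = simulate_counts(couplings, truth, config)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    coverage, cov_truth = simulate_coverage(config)
    coverage.to_csv(outdir / "coverage.tsv", sep="\t")
    truth.site_tier = cov_truth.site_tier
    truth.site_private_experiment = cov_truth.site_private_experiment
    truth.site_interval = cov_truth.site_interval
    truth.to_json(outdir / "truth.json")
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1)
    return {"regions": len(regions), "barcodes": counts.shape[0],
            "sites": coverage.shape[0]}
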