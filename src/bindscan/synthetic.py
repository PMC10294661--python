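"""Seeded synthetic data carrying the statistical structure the analysis
modules assume.

Four generators are provided:

* random genomes with planted degenerate-consensus motif instances;
* paired ChIP sample/control depth tracks — flat Poisson background, with
  fold-enrichment at planted sites attenuated by a triangular kernel whose
  half-width reflects the ~600-bp sonication fragment scale;
* SPR cycles from an equilibrium-occupancy model in which each intact direct
  repeat contributes additively to the binding free energy, so the dissociation
  constant is ``KD = baseline_kd * exp(sum(ddG_intact) / RT)`` and the analyte
  response is ``theta * Rmax`` with occupancy ``theta = c / (c + KD)``;
* negative-binomial count matrices with planted log2 fold changes, for
  exercising volcano-style classification.

Every generator is a pure function of its configuration, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chip import DepthTrack
from .repeats import IUPAC_SETS
from .spr import DuplexDesign, SPRCycle, duplex_mw, theoretical_rmax

__all__ = [
    "RT_KCAL_25C",
    "SyntheticGenome",
    "PlantedSite",
    "ChipSimConfig",
    "SprSimConfig",
    "CountSimTruth",
    "make_genome",
    "plant_motifs",
    "simulate_chip_tracks",
    "simulate_spr_cycles",
    "simulate_counts",
]

#: RT at 25 degrees C, kcal/mol.
RT_KCAL_25C = 0.593

_BASES = np.array(list("ACGT"))


@dataclass
class PlantedSite:
    start: int
    motif_instance: str
    label: str


@dataclass
class SyntheticGenome:
    """A synthetic linear replicon with a record of planted motif instances."""

    name: str
    sequence: str
    planted_sites: list[PlantedSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError("genome sequence must contain only A/C/G/T")
        for site in self.planted_sites:
            sub = self.sequence[site.start : site.start + len(site.motif_instance)]
            if sub != site.motif_instance:
                raise ValueError(
                    f"planted site {site.label!r} does not match the sequence at {site.start}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ChipSimConfig:
    """Configuration for paired ChIP sample/control depth simulation."""

    genome_length: int
    base_depth: float
    sites: list[tuple[int, float]] = field(default_factory=list)
    fragment_width: int = 600
    noise: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.base_depth <= 0:
            raise ValueError("base_depth must be positive")
        if self.fragment_width <= 0:
            raise ValueError("fragment_width must be positive")
        if self.noise != "poisson":
            raise ValueError(f"unsupported noise model {self.noise!r}")
        for center, fold in self.sites:
            if fold < 1:
                raise ValueError("site fold must be >= 1")
            if not 0 <= center < self.genome_length:
                raise ValueError(f"site center {center} outside genome")


@dataclass
class SprSimConfig:
    """Equilibrium-occupancy SPR simulation parameters.

    ``repeat_energies`` maps repeat labels to ddG contributions in kcal/mol
    (negative = stabilizing); a design's KD multiplies ``baseline_kd`` by
    ``exp(sum of its intact repeats' ddG / RT)`` at 25 degrees C.
    """

    repeat_energies: dict[str, float]
    baseline_kd: float
    protein_conc: float
    r_dna: float = 100.0
    noise_sd: float = 0.0
    analyte_mw: float = 30_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_kd <= 0:
            raise ValueError("baseline_kd must be positive")
        if self.protein_conc < 0:
            raise ValueError("protein_conc must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.r_dna <= 0:
            raise ValueError("r_dna must be positive")


@dataclass
class CountSimTruth:
    """Ground truth for one simulated gene."""

    gene: str
    true_log2fc: float
    is_de: bool

    def __post_init__(self) -> None:
        if self.is_de != (self.true_log2fc != 0):
            raise ValueError("is_de must hold exactly when true_log2fc != 0")


def make_genome(length: int, gc_fraction: float = 0.5, seed: int = 0, name: str = "synthetic") -> SyntheticGenome:
    """Random genome with independent base draws at the given GC content."""
    if length < 0:
        raise ValueError(f"genome length must be non-negative, got {length}")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    seq = "".join(rng.choice(_BASES, size=length, p=probs)) if length else ""
    return SyntheticGenome(name, seq)


def plant_motifs(
    genome: SyntheticGenome,
    consensus: str,
    starts: list[int],
    seed: int = 0,
    label_prefix: str = "site",
) -> SyntheticGenome:
    """Plant realizations of a degenerate consensus at the given offsets.

    Degenerate positions (X is read as N) are realized by a uniform seeded draw
    from the code's base set, so every instance matches the consensus with zero
    mismatches.  Instances must fit in the sequence and must not overlap.
    """
    consensus = consensus.upper()
    bad = set(consensus) - set(IUPAC_SETS)
    if bad:
        raise ValueError(f"invalid IUPAC codes in consensus: {sorted(bad)}")
    k = len(consensus)
    ordered = sorted(starts)
    prev_end = -1
    for s in ordered:
        if s < 0 or s + k > genome.length:
            raise ValueError(f"motif at {s} does not fit within the {genome.length}-nt sequence")
        if s < prev_end:
            raise ValueError(f"planted motifs overlap at offset {s}")
        prev_end = s + k

    rng = np.random.default_rng(seed)
    seq = list(genome.sequence)
    new_sites = list(genome.planted_sites)
    for idx, s in enumerate(ordered):
        instance = "".join(
            code if len(IUPAC_SETS[code]) == 1 else rng.choice(sorted(IUPAC_SETS[code]))
            for code in consensus
        )
        seq[s : s + k] = instance
        new_sites.append(PlantedSite(s, instance, f"{label_prefix}_{idx + 1}"))
    return replace(genome, sequence="".join(seq), planted_sites=new_sites)


def _fold_profile(config: ChipSimConfig) -> np.ndarray:
    """Expected relative depth: 1 plus triangular bumps at each site."""
    pos = np.arange(config.genome_length)
    f = np.ones(config.genome_length)
    for center, fold in config.sites:
        kernel = np.clip(1.0 - np.abs(pos - center) / config.fragment_width, 0.0, None)
        f += (fold - 1.0) * kernel
    return f


def simulate_chip_tracks(config: ChipSimConfig) -> tuple[DepthTrack, DepthTrack]:
    """Paired (sample, control) Poisson depth tracks.

    Control depth is Poisson(base_depth) everywhere; sample depth is
    Poisson(base_depth * f) where f carries a triangular enrichment bump of
    half-width ``fragment_width`` at each planted site, peaking at the site's
    fold.  The triangular shape reflects the overlap geometry of randomly
    sheared fragments spanning a single bound position.
    """
    rng = np.random.default_rng(config.seed)
    f = _fold_profile(config)
    sample = rng.poisson(config.base_depth * f).astype(float)
    control = rng.poisson(config.base_depth, size=config.genome_length).astype(float)
    return (
        DepthTrack("synthetic", sample),
        DepthTrack("synthetic", control),
    )


def design_kd(design: DuplexDesign, config: SprSimConfig) -> float:
    """Dissociation constant for a design given its intact repeats."""
    ddg = sum(config.repeat_energies[label] for label in design.intact_repeats)
    return config.baseline_kd * float(np.exp(ddg / RT_KCAL_25C))


def simulate_spr_cycles(
    designs: list[DuplexDesign],
    config: SprSimConfig,
    n_replicates: int = 1,
) -> list[SPRCycle]:
    """Simulate SPR cycles from the equilibrium-occupancy model.

    For each design, occupancy is ``theta = c / (c + KD)``; the analyte
    response is ``theta * Rmax`` (Rmax from the captured-duplex and analyte
    masses) plus Gaussian noise, and the captured-DNA response is ``r_dna``
    plus Gaussian noise.  Designs must carry intact-repeat annotations for
    every label they reference.
    """
    for d in designs:
        unknown = set(d.intact_repeats) - set(config.repeat_energies)
        if unknown:
            raise ValueError(
                f"design {d.design_id!r} references unannotated repeats: {sorted(unknown)}"
            )
    rng = np.random.default_rng(config.seed)
    cycles = []
    for d in designs:
        kd = design_kd(d, config)
        theta = config.protein_conc / (config.protein_conc + kd)
        rmax = theoretical_rmax(config.analyte_mw, duplex_mw(d), config.r_dna)
        for _ in range(n_replicates):
            r_dna = config.r_dna + rng.normal(0.0, config.noise_sd)
            r_protein = theta * rmax + rng.normal(0.0, config.noise_sd)
            cycles.append(SPRCycle(d.design_id, r_dna, r_protein))
    return cycles


def simulate_counts(
    n_genes: int,
    n_reps: int,
    lib_size: float,
    dispersion: float = 0.1,
    de_fraction: float = 0.05,
    log2fc: float = 0.0,
    seed: int = 0,
):
    """Two-group negative-binomial count matrix with planted fold changes.

    Per-gene baseline means are drawn log-normally around ``lib_size/n_genes``;
    a ``de_fraction`` of genes have the second group's mean multiplied by
    ``2**log2fc``.  Counts are gamma-Poisson with the given NB dispersion
    (variance = mu + dispersion * mu^2); dispersion 0 is the Poisson limit.
    Returns a genes-by-samples pandas DataFrame and a ground-truth list.
    """
    import pandas as pd

    if n_genes <= 0 or n_reps <= 0 or lib_size <= 0:
        raise ValueError("n_genes, n_reps and lib_size must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    base_mean = lib_size / n_genes
    mu = base_mean * rng.lognormal(mean=-0.5, sigma=1.0, size=n_genes)

    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    lfc = np.zeros(n_genes)
    lfc[de_idx] = log2fc

    mu_a = np.repeat(mu[:, None], n_reps, axis=1)
    mu_b = np.repeat((mu * 2.0**lfc)[:, None], n_reps, axis=1)
    means = np.hstack([mu_a, mu_b])

    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=means * dispersion)
    else:
        lam = means
    counts = rng.poisson(lam)

    genes = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    columns = [f"A{r + 1}" for r in range(n_reps)] + [f"B{r + 1}" for r in range(n_reps)]
    frame = pd.DataFrame(counts, index=genes, columns=columns)
    truth = [
        CountSimTruth(genes[i], float(lfc[i]), bool(lfc[i] != 0)) for i in range(n_genes)
    ]
    return frame, truth
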