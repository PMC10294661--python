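"""ReDCaT SPR duplex design and %Rmax binding analysis.

ReDCaT (reusable DNA capture technology) immobilizes a biotinylated ssDNA
linker on a streptavidin SPR chip; each test duplex carries a constant 20-nt
single-stranded overhang on its bottom strand that anneals to the linker, so
the chip is reused across test sequences.  Test duplexes are at most 40 bp.

Because the SPR response is proportional to the mass bound at the surface,
responses to different DNA ligands are made comparable by expressing the
protein response as a percentage of the theoretical maximum response,

    Rmax = (MW_analyte / MW_ligand) * R_ligand * stoichiometry,

where R_ligand is the response from capturing the DNA itself.  Footprint
boundaries are inferred from truncation series: walking in 2-bp steps from
either end of a bound region, binding is declared lost at the first member
whose %Rmax falls below a fraction of the full-length signal.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "REDCAT_OVERHANG",
    "DuplexDesign",
    "SPRCycle",
    "BindingResult",
    "Footprint",
    "make_redcat_duplex",
    "tile_region",
    "truncation_series",
    "substitution_series",
    "dna_strand_mw",
    "duplex_mw",
    "protein_mw",
    "protein_pi",
    "theoretical_rmax",
    "percent_rmax",
    "analyze_cycles",
    "infer_footprint",
]

#: 20-nt single-stranded overhang appended to every bottom strand; it is the
#: sequence complementary to the chip-immobilized biotinylated capture linker.
REDCAT_OVERHANG = "CCTACCCTACGTCCTCCTGC"

MAX_TEST_LEN = 40

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Average masses of the deoxynucleotide monophosphate residues (Da) and the
# correction for a 5'-OH, free 3'-OH strand.
_DNMP_MASS = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}
_STRAND_OFFSET = 61.96

_WATER = 18.02

# Bjellqvist pKa set: side chains, termini, and residue-specific N-terminal
# values, as used by the common pI web calculators.
_PKA_POSITIVE = {"K": 10.0, "R": 12.0, "H": 5.98}
_PKA_NEGATIVE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
_PKA_NTERM_DEFAULT = 7.5
_PKA_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
_PKA_CTERM_DEFAULT = 3.55
_PKA_CTERM = {"D": 4.55, "E": 4.75}

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return seq


@dataclass
class DuplexDesign:
    """A test duplex plus its ReDCaT capture overhang.

    ``region_start``/``region_end`` locate ``test_seq`` within the source
    region (0-based half-open) for series generated from a region; they are
    None for manual designs.
    """

    design_id: str
    test_seq: str
    bottom_strand: str
    intact_repeats: tuple[str, ...] = ()
    provenance: str = "manual"
    region_start: int | None = None
    region_end: int | None = None

    def __post_init__(self) -> None:
        self.test_seq = _check_dna(self.test_seq, "test_seq")
        if not 1 <= len(self.test_seq) <= MAX_TEST_LEN:
            raise ValueError(
                f"test sequence must be 1-{MAX_TEST_LEN} nt for ReDCaT capture "
                f"(got {len(self.test_seq)} nt)"
            )
        expected = _revcomp(self.test_seq) + REDCAT_OVERHANG
        if self.bottom_strand.upper() != expected:
            raise ValueError("bottom strand must be revcomp(test_seq) + capture overhang")
        self.bottom_strand = self.bottom_strand.upper()
        self.intact_repeats = tuple(self.intact_repeats)


@dataclass
class SPRCycle:
    """One SPR cycle reduced to two responses: captured DNA, then analyte."""

    design_id: str
    r_dna: float
    r_protein: float

    def __post_init__(self) -> None:
        if self.r_dna <= 0:
            raise ValueError("r_dna must be positive for an analyzable cycle")


@dataclass
class BindingResult:
    """Replicate-averaged %Rmax for one duplex design."""

    design_id: str
    rmax_theoretical: float
    percent_rmax: float
    sem: float
    n_cycles: int
    bound: bool
    flagged_high: bool = False


@dataclass
class Footprint:
    """Footprint interval in original-region coordinates, half-open."""

    start: int
    end: int
    left_lost: bool
    right_lost: bool
    warnings: tuple[str, ...] = ()


def make_redcat_duplex(test_seq: str, design_id: str, **kwargs) -> DuplexDesign:
    """Build a capture duplex: bottom strand is revcomp(test) + the overhang."""
    test_seq = _check_dna(test_seq, "test_seq")
    if len(test_seq) > MAX_TEST_LEN:
        raise ValueError(
            f"test sequence is {len(test_seq)} nt; ReDCaT duplexes must be <= {MAX_TEST_LEN} bp"
        )
    bottom = _revcomp(test_seq) + REDCAT_OVERHANG
    return DuplexDesign(design_id, test_seq, bottom, **kwargs)


def tile_region(region_seq: str, oligo_len: int = 40, n_oligos: int = 1) -> list[DuplexDesign]:
    """Split a region into ``n_oligos`` evenly spaced, overlapping oligos.

    Starts are ``round(i * (L - oligo_len) / (n_oligos - 1))``; the first oligo
    begins at 0 and the last ends at L, so the union covers the whole region.
    """
    region_seq = _check_dna(region_seq, "region")
    L = len(region_seq)
    if n_oligos < 1:
        raise ValueError("n_oligos must be >= 1")
    if L < oligo_len:
        raise ValueError(f"region ({L} nt) is shorter than oligo_len ({oligo_len})")
    if n_oligos * oligo_len < L:
        raise ValueError(
            f"{n_oligos} oligos of {oligo_len} nt cannot cover a {L}-nt region"
        )
    designs = []
    for i in range(n_oligos):
        if n_oligos == 1:
            start = 0
        else:
            start = math.floor(i * (L - oligo_len) / (n_oligos - 1) + 0.5)
        designs.append(
            make_redcat_duplex(
                region_seq[start : start + oligo_len],
                f"O{i + 1}",
                provenance="tiling",
                region_start=start,
                region_end=start + oligo_len,
            )
        )
    return designs


def truncation_series(
    region_seq: str, side: str, step: int = 2, min_len: int | None = None
) -> list[DuplexDesign]:
    """Truncate ``step`` bp at a time from the chosen end.

    Member k removes ``k * step`` bases, down to ``min_len``; every member is a
    contiguous substring of the region.  Used for SPR footprinting.
    """
    region_seq = _check_dna(region_seq, "region")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if step < 1:
        raise ValueError("step must be >= 1")
    L = len(region_seq)
    if min_len is None:
        min_len = step
    if min_len > L:
        raise ValueError(f"min_len ({min_len}) exceeds region length ({L})")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    prefix = "LH" if side == "left" else "RH"
    n = (L - min_len) // step + 1
    designs = []
    for k in range(n):
        if side == "left":
            start, end = k * step, L
        else:
            start, end = 0, L - k * step
        designs.append(
            make_redcat_duplex(
                region_seq[start:end],
                f"{prefix}{k + 1}",
                provenance="truncation",
                region_start=start,
                region_end=end,
            )
        )
    return designs


def substitution_series(
    region_seq: str,
    repeat_spans: list[tuple[str, int, int]],
    seed: int,
    gc_match: bool = False,
) -> list[DuplexDesign]:
    """Replace repeats with random DNA, one subset at a time.

    For each non-empty subset of the labeled repeat spans, the spans *not* in
    the subset are replaced by seeded random bases of the same length (so three
    repeats yield exactly 7 designs, each the original length).  ``gc_match``
    draws replacement bases at the region's GC content instead of uniformly.
    """
    region_seq = _check_dna(region_seq, "region")
    L = len(region_seq)
    spans = sorted(repeat_spans, key=lambda x: x[1])
    prev_end = 0
    for label, start, end in spans:
        if start < prev_end:
            raise ValueError(f"repeat spans overlap at {label!r}")
        if start < 0 or end > L or end <= start:
            raise ValueError(f"repeat span {label!r} [{start}, {end}) out of bounds")
        prev_end = end
    labels = [s[0] for s in spans]
    if len(set(labels)) != len(labels):
        raise ValueError("repeat labels must be unique")

    if gc_match:
        gc = (region_seq.count("G") + region_seq.count("C")) / L
        probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    else:
        probs = np.full(4, 0.25)
    bases = np.array(list("ACGT"))
    rng = np.random.default_rng(seed)

    designs = []
    for size in range(len(spans), 0, -1):
        for kept in itertools.combinations(spans, size):
            kept_labels = tuple(k[0] for k in kept)
            seq = list(region_seq)
            for label, start, end in spans:
                if label in kept_labels:
                    continue
                seq[start:end] = rng.choice(bases, size=end - start, p=probs)
            designs.append(
                make_redcat_duplex(
                    "".join(seq),
                    "keep_" + "+".join(kept_labels),
                    intact_repeats=kept_labels,
                    provenance="substitution",
                    region_start=0,
                    region_end=L,
                )
            )
    return designs


def dna_strand_mw(seq: str) -> float:
    """Average molecular weight (Da) of a ssDNA strand, 5'-OH convention."""
    seq = _check_dna(seq, "strand")
    if not seq:
        raise ValueError("strand must be non-empty")
    return sum(_DNMP_MASS[b] for b in seq) - _STRAND_OFFSET


def duplex_mw(design: DuplexDesign) -> float:
    """Mass of the complete captured species: both strands, overhang included."""
    return dna_strand_mw(design.test_seq) + dna_strand_mw(design.bottom_strand)


def _check_protein(seq: str) -> str:
    seq = seq.upper().replace("*", "")
    bad = set(seq) - _AA20
    if bad:
        raise ValueError(f"unknown amino-acid letters: {sorted(bad)}")
    if not seq:
        raise ValueError("protein sequence must be non-empty")
    return seq


def protein_mw(protein_seq: str) -> float:
    """Average molecular weight (Da) of a protein: residue masses plus water."""
    from Bio.SeqUtils import molecular_weight

    seq = _check_protein(protein_seq)
    return float(molecular_weight(seq, seq_type="protein"))


def _net_charge(seq: str, ph: float) -> float:
    def pos(pk: float) -> float:
        return 10**pk / (10**pk + 10**ph)

    def neg(pk: float) -> float:
        return 10**ph / (10**pk + 10**ph)

    charge = pos(_PKA_NTERM.get(seq[0], _PKA_NTERM_DEFAULT)) - neg(
        _PKA_CTERM.get(seq[-1], _PKA_CTERM_DEFAULT)
    )
    for aa, pk in _PKA_POSITIVE.items():
        charge += seq.count(aa) * pos(pk)
    for aa, pk in _PKA_NEGATIVE.items():
        charge -= seq.count(aa) * neg(pk)
    return charge


def protein_pi(protein_seq: str, tol: float = 0.01) -> float:
    """Isoelectric point by bisection on net charge (Bjellqvist pKa set)."""
    seq = _check_protein(protein_seq)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if _net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def theoretical_rmax(
    mw_analyte: float, mw_ligand: float, r_ligand: float, stoichiometry: float = 1
) -> float:
    """Theoretical maximum SPR response for an analyte:ligand pair."""
    if mw_analyte <= 0 or mw_ligand <= 0 or r_ligand <= 0 or stoichiometry <= 0:
        raise ValueError("all Rmax inputs must be positive")
    return (mw_analyte / mw_ligand) * r_ligand * stoichiometry


def percent_rmax(r_protein: float, rmax: float) -> float:
    """Observed analyte response as a percentage of theoretical Rmax.

    Values slightly above 100 are permitted (noise); above 120 a warning is
    emitted, since that suggests a wrong stoichiometry or mass.
    """
    if rmax <= 0:
        raise ValueError("rmax must be positive")
    value = 100.0 * r_protein / rmax
    if value > 120.0:
        warnings.warn(
            f"%Rmax = {value:.1f} exceeds 120; check stoichiometry and masses",
            stacklevel=2,
        )
    return value


def analyze_cycles(
    cycles: list[SPRCycle],
    designs: list[DuplexDesign],
    analyte_mw: float,
    stoichiometry: float = 1,
    bound_threshold: float = 20.0,
) -> list[BindingResult]:
    """Reduce SPR cycles to per-design mean %Rmax with standard errors.

    The ligand mass is that of the complete captured duplex (both strands,
    overhang included).  Each cycle's Rmax uses that cycle's captured-DNA
    response; replicate %Rmax values are then averaged.  ``bound`` flags
    designs whose mean %Rmax reaches ``bound_threshold``.
    """
    by_id = {d.design_id: d for d in designs}
    grouped: dict[str, list[SPRCycle]] = {}
    for c in cycles:
        if c.design_id not in by_id:
            raise ValueError(f"cycle references unknown design_id {c.design_id!r}")
        grouped.setdefault(c.design_id, []).append(c)

    results = []
    for design_id, cyc in grouped.items():
        ligand_mw = duplex_mw(by_id[design_id])
        percents = []
        rmaxes = []
        for c in cyc:
            rmax = theoretical_rmax(analyte_mw, ligand_mw, c.r_dna, stoichiometry)
            rmaxes.append(rmax)
            percents.append(percent_rmax(c.r_protein, rmax))
        percents = np.array(percents)
        mean = float(percents.mean())
        sem = float(percents.std(ddof=1) / math.sqrt(len(percents))) if len(percents) > 1 else 0.0
        results.append(
            BindingResult(
                design_id=design_id,
                rmax_theoretical=float(np.mean(rmaxes)),
                percent_rmax=mean,
                sem=sem,
                n_cycles=len(cyc),
                bound=mean >= bound_threshold,
                flagged_high=mean > 120.0,
            )
        )
    return results


def _series_boundary(
    results: list[BindingResult],
    designs_by_id: dict[str, DuplexDesign],
    side: str,
    loss_fraction: float,
) -> tuple[int, bool]:
    """Walk an ordered truncation series; return the last-retained boundary."""
    full = results[0].percent_rmax
    if full <= 0:
        raise ValueError("full-length design shows no binding; footprint undefined")
    cutoff = loss_fraction * full
    last_retained = designs_by_id[results[0].design_id]
    for res in results[1:]:
        if res.percent_rmax < cutoff:
            boundary = (
                last_retained.region_start if side == "left" else last_retained.region_end
            )
            return int(boundary), True
        last_retained = designs_by_id[res.design_id]
    boundary = (
        designs_by_id[results[0].design_id].region_start
        if side == "left"
        else designs_by_id[results[0].design_id].region_end
    )
    return int(boundary), False


def infer_footprint(
    left_series: list[BindingResult],
    right_series: list[BindingResult],
    designs: list[DuplexDesign],
    loss_fraction: float = 0.2,
) -> Footprint:
    """Infer footprint boundaries from left and right truncation series.

    Each series must be ordered from the full-length design inward.  Binding is
    declared lost at the first member whose %Rmax falls below ``loss_fraction``
    of the full-length %Rmax; the boundary on that side is the last-retained
    member's edge, in original-region coordinates.  If binding is never lost on
    a side, the full region's edge is returned with a warning flag.
    """
    if not 0 < loss_fraction < 1:
        raise ValueError("loss_fraction must be in (0, 1)")
    if not left_series or not right_series:
        raise ValueError("both truncation series must be non-empty")
    by_id = {d.design_id: d for d in designs}
    for res in itertools.chain(left_series, right_series):
        d = by_id.get(res.design_id)
        if d is None or d.region_start is None:
            raise ValueError(f"design {res.design_id!r} missing or lacks region coordinates")

    start, left_lost = _series_boundary(left_series, by_id, "left", loss_fraction)
    end, right_lost = _series_boundary(right_series, by_id, "right", loss_fraction)
    warns = []
    if not left_lost:
        warns.append("binding never lost on the left; boundary set to region edge")
    if not right_lost:
        warns.append("binding never lost on the right; boundary set to region edge")
    return Footprint(start, end, left_lost, right_lost, tuple(warns))
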