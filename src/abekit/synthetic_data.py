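"""Synthetic inputs with known truth: read mixtures, planted genomes, and
the PAH c.1222C>T locus fixture.

The read simulator emits amplicon reads drawn from a mixture of edited
haplotypes (corrective edit, synonymous and nonsynonymous bystander edits,
small deletions) overlaid with iid substitution sequencing error, together
with a per-read truth table.  The genome simulator plants near-matches of a
spacer at known mismatch/bulge configurations, including deliberate
negative controls outside the admission criteria.  Everything is
byte-reproducible from the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .editor_models import GuideCandidate
from .offtarget import OffTargetCriteria, scan_hits
from .seqcore import Locus, revcomp

__all__ = [
    "ReadMixtureSpec",
    "PlantedSite",
    "PlantedGenomeSpec",
    "simulate_reads",
    "simulate_genome",
    "build_pah_fixture",
    "synthetic_pah_slice",
    "pah_locus",
    "write_fastq",
    "write_fasta",
    "DEFAULT_PROPORTIONS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Study-condition mixture used as the simulator default: most reads carry the
# corrective edit alone, a smaller share co-edit a nonsynonymous bystander,
# with minor bystander-only, indel, and residual unedited fractions.
DEFAULT_PROPORTIONS = {
    "correction_only": 0.60,
    "unwanted_bystander": 0.12,
    "bystander_only": 0.05,
    "indel": 0.03,
    "unedited": 0.20,
}


# --------------------------------------------------------------------------
# PAH c.1222C>T fixture
# --------------------------------------------------------------------------

# Codon identities printed for the locus: 406 ATA (Ile), 407 CCT (Pro),
# 408 CGG (Arg; TGG Trp in the patient), 410 TTC (Phe).
PAH_PRINTED_CODONS = {406: "ATA", 407: "CCT", 408: "CGG", 410: "TTC"}
PAH_VARIANT_CDS_POSITION = 1222  # first base of codon 408

# Synthetic reconstruction of sense c.1198-1242 (codons 400-414).  Codons
# 406/407/408/410 are the published identities; codons 401-403 follow from
# the six published guide PAMs (AGC, GCA, CAA, AAA, AAG, AGT), which sit at
# consecutive antisense placements and pin sense c.1202-1210 to ACTTTGCT
# preceded by an A; the remaining codons are free choices kept free of
# sense-strand T near the editing window so the locus has exactly the four
# documented non-target antisense adenines.  This is NOT the RefSeq
# NM_000277.3 sequence; pass a real slice to build_pah_fixture to use one.
_PAH_SYNTHETIC_CODONS = {
    400: "CAG",
    401: "AAC",
    402: "TTT",
    403: "GCT",
    404: "GCC",
    405: "ACC",
    406: "ATA",
    407: "CCT",
    408: "CGG",
    409: "CCC",
    410: "TTC",
    411: "AGC",
    412: "GTG",
    413: "CGG",
    414: "TAC",
}


def synthetic_pah_slice() -> tuple[str, int]:
    """Synthetic corrected-allele sense slice (codons 400-414) and its first
    codon number.  See the module source for which codons are pinned by
    published facts and which are free choices."""
    seq = "".join(_PAH_SYNTHETIC_CODONS[n] for n in sorted(_PAH_SYNTHETIC_CODONS))
    return seq, min(_PAH_SYNTHETIC_CODONS)


def build_pah_fixture(reference_slice: str, first_codon: int) -> Locus:
    """Build the patient PAH c.1222C>T locus from a corrected-allele coding
    slice.

    ``reference_slice`` must start at the first base of codon
    ``first_codon`` and contain codons 406-410.  Construction validates the
    published codon identities (406 ATA, 407 CCT, 408 CGG, 410 TTC) and
    fails loudly, naming the codon, on any contradiction.  The c.1222C>T
    change is applied, the reading frame is anchored at codon 406, and any
    antisense adenine in codon 409 (unexpected given the published
    four-bystander geometry) is surfaced as a warning, never dropped.
    """
    seq = reference_slice.upper()
    if len(seq) % 3:
        raise ValueError("reference slice must be codon-aligned (length % 3 == 0)")
    last_codon = first_codon + len(seq) // 3 - 1
    if first_codon > 406 or last_codon < 410:
        raise ValueError("slice must cover codons 406-410")

    def codon(n: int) -> str:
        off = 3 * (n - first_codon)
        return seq[off : off + 3]

    for number, expected in PAH_PRINTED_CODONS.items():
        observed = codon(number)
        if observed != expected:
            raise ValueError(
                f"supplied sequence contradicts the published codon {number}: "
                f"expected {expected}, found {observed}"
            )
    if "T" in codon(409):
        warnings.warn(
            f"codon 409 ({codon(409)}) carries an antisense adenine "
            "(sense T) not part of the documented four-bystander geometry; "
            "it will appear in bystander annotations",
            stacklevel=2,
        )
    variant_offset = 3 * (408 - first_codon)  # c.1222, first base of codon 408
    patient = seq[:variant_offset] + "T" + seq[variant_offset + 1 :]
    return Locus(
        context=patient,
        variant_offset=variant_offset,
        ref_base="C",
        alt_base="T",
        frame_anchor_offset=3 * (406 - first_codon),
        frame_anchor_codon=406,
        edited_strand="antisense",
        allele="patient",
        name="PAH_c.1222C>T",
    )


def pah_locus() -> Locus:
    """Patient PAH c.1222C>T locus built from the synthetic slice."""
    return build_pah_fixture(*synthetic_pah_slice())


# --------------------------------------------------------------------------
# read mixtures
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadMixtureSpec:
    """Mixture of edited haplotypes to emit as amplicon reads.

    ``proportions`` maps the five truth categories to fractions summing to 1.
    Reads in corrective categories co-carry a synonymous bystander edit with
    probability ``synonymous_coedit_fraction`` (when the guide has one);
    unwanted/bystander-only reads edit one nonsynonymous protospacer
    bystander chosen uniformly.  The indel category deletes 1-3 nt inside
    the protospacer.  Substitution sequencing error is iid at ``error_rate``
    with no simulated indel errors, so category truth stays unambiguous.
    Half of the reads are emitted reverse-complemented
    (``revcomp_fraction``) to exercise orientation normalization.
    """

    locus: Locus
    guide: GuideCandidate
    proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    n_reads: int = 10_000
    error_rate: float = 0.001
    read_start: int = 0
    read_length: int | None = None
    synonymous_coedit_fraction: float = 0.5
    revcomp_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.proportions) != set(DEFAULT_PROPORTIONS):
            raise ValueError(
                f"proportions must have exactly the keys {sorted(DEFAULT_PROPORTIONS)}"
            )
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("proportions must be non-negative")
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1 (tolerance 1e-9)")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


def _bystander_sense_edits(spec: ReadMixtureSpec):
    """(synonymous, nonsynonymous) lists of (sense offset, new base) edits."""
    locus = spec.locus.as_patient()
    new_base = "C" if locus.edited_strand == "antisense" else "G"
    syn, nonsyn = [], []
    for b in spec.guide.bystanders:
        off = locus.sense_offset_of(b.offset)
        if b.consequence is None or b.consequence.synonymous:
            syn.append((off, new_base))
        else:
            nonsyn.append((off, new_base))
    return syn, nonsyn


def simulate_reads(spec: ReadMixtureSpec):
    """Generate reads and their truth table.

    Returns ``(reads, truth)``: ``reads`` is a list of ``(read_id,
    sequence, quality)`` with constant Q37 quality, ``truth`` a DataFrame
    with one row per read (read_id, category, edited sense offsets, indel
    descriptor, orientation).  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    locus = spec.locus.as_patient()
    template = locus.context
    target_edit = (
        locus.variant_offset,
        "C" if locus.edited_strand == "antisense" else "G",
    )
    syn_edits, nonsyn_edits = _bystander_sense_edits(spec)
    categories = list(DEFAULT_PROPORTIONS)
    probs = np.array([spec.proportions[c] for c in categories])
    for cat in ("unwanted_bystander", "bystander_only"):
        if spec.proportions[cat] > 0 and not nonsyn_edits:
            raise ValueError(
                f"{cat} proportion > 0 but the guide has no nonsynonymous bystander"
            )
    proto_lo = min(spec.guide.sense_start, spec.guide.sense_end - 1)
    proto_hi = spec.guide.sense_end

    reads, truth_rows = [], []
    draw = rng.choice(len(categories), size=spec.n_reads, p=probs)
    for k in range(spec.n_reads):
        category = categories[draw[k]]
        hap = list(template)
        edits: list[tuple[int, str]] = []
        indel = ""
        if category in ("correction_only", "unwanted_bystander"):
            edits.append(target_edit)
            if syn_edits and rng.random() < spec.synonymous_coedit_fraction:
                edits.append(syn_edits[int(rng.integers(len(syn_edits)))])
            if category == "unwanted_bystander":
                edits.append(nonsyn_edits[int(rng.integers(len(nonsyn_edits)))])
        elif category == "bystander_only":
            edits.append(nonsyn_edits[int(rng.integers(len(nonsyn_edits)))])
        for off, base in edits:
            hap[off] = base
        if category == "indel":
            del_len = int(rng.integers(1, 4))
            del_start = int(rng.integers(proto_lo, proto_hi - del_len))
            del hap[del_start : del_start + del_len]
            indel = f"del:{del_start}:{del_len}"
        seq = "".join(hap)
        if spec.read_length is not None:
            seq = seq[spec.read_start : spec.read_start + spec.read_length]
        if spec.error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hit = np.nonzero(rng.random(len(arr)) < spec.error_rate)[0]
            for p in hit:
                choices = _BASES[_BASES != arr[p]]
                arr[p] = choices[int(rng.integers(3))]
            seq = arr.tobytes().decode()
        flipped = rng.random() < spec.revcomp_fraction
        if flipped:
            seq = revcomp(seq)
        read_id = f"read{k:06d}"
        reads.append((read_id, seq, "F" * len(seq)))
        truth_rows.append(
            {
                "read_id": read_id,
                "category": category,
                "edited_offsets": ",".join(str(o) for o, _ in sorted(edits)),
                "indel": indel,
                "orientation": "-" if flipped else "+",
            }
        )
    truth = pd.DataFrame(truth_rows)
    return reads, truth


# --------------------------------------------------------------------------
# planted genomes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSite:
    """A near-match of the spacer to plant: its edit configuration, genomic
    position (of the site's first base), and strand."""

    mismatches: int
    dna_bulges: int
    rna_bulges: int
    position: int
    strand: str = "+"
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.mismatches, self.dna_bulges, self.rna_bulges) < 0:
            raise ValueError("edit counts must be non-negative")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def bulges(self) -> int:
        return self.dna_bulges + self.rna_bulges

    @property
    def length(self) -> int:
        return 20 + self.dna_bulges - self.rna_bulges


@dataclass(frozen=True)
class PlantedGenomeSpec:
    spacer: str
    genome_length: int = 20_000
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    sites: tuple[PlantedSite, ...] = ()
    seq_name: str = "chr_sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.spacer) != 20 or any(ch not in "ACGT" for ch in self.spacer):
            raise ValueError("spacer must be a 20-mer over ACGT")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")
        intervals = sorted(
            (s.position, s.position + s.length, s) for s in self.sites
        )
        for (s0, e0, a), (s1, e1, b) in zip(intervals, intervals[1:]):
            if s1 < e0:
                raise ValueError(
                    f"planted sites overlap: [{s0},{e0}) and [{s1},{e1})"
                )
        for s0, e0, s in intervals:
            if s0 < 0 or e0 > self.genome_length:
                raise ValueError(f"planted site [{s0},{e0}) outside the genome")


def _mutate_spacer(spacer: str, site: PlantedSite, rng) -> str:
    """One random realisation of the site's edit configuration."""
    seq = list(spacer)
    # RNA bulges: drop interior spacer bases (positions 2..19)
    r_positions = sorted(
        rng.choice(np.arange(2, 20), size=site.rna_bulges, replace=False)
    ) if site.rna_bulges else []
    for pos in sorted(r_positions, reverse=True):
        del seq[pos - 1]
    # substitutions at surviving positions (never the termini of the site,
    # to keep the planted configuration's accounting canonical)
    subs = (
        sorted(rng.choice(np.arange(1, len(seq) - 1), size=site.mismatches, replace=False))
        if site.mismatches
        else []
    )
    for pos in subs:
        others = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = others[int(rng.integers(3))]
    # DNA bulges: insert random genomic bases at interior junctions
    if site.dna_bulges:
        junctions = sorted(
            rng.choice(np.arange(1, len(seq)), size=site.dna_bulges, replace=True)
        )
        for j in sorted(junctions, reverse=True):
            seq.insert(int(j), "ACGT"[int(rng.integers(4))])
    return "".join(seq)


def _admissible_in_context(
    spacer: str,
    segment: str,
    planted_lo: int,
    planted_hi: int,
    criteria: OffTargetCriteria,
) -> bool:
    """Does any admissible alignment overlap the planted span of ``segment``?

    Both orientations are scanned; flanking sequence is included so
    boundary-crossing alignments (which a site-only check would miss) are
    caught.
    """
    n = len(segment)
    for oriented, flip in ((segment, False), (revcomp(segment), True)):
        hits, _ = scan_hits(spacer, oriented, criteria)
        for (start, length) in hits:
            lo, hi = (n - start - length, n - start) if flip else (start, start + length)
            if lo < planted_hi and hi > planted_lo:
                return True
    return False


def simulate_genome(
    spec: PlantedGenomeSpec,
    criteria: OffTargetCriteria = OffTargetCriteria(),
    max_retries: int = 50,
):
    """Random genome with planted near-matches and a truth table.

    Each planted site is built by applying its stated substitutions,
    insertions (DNA bulges) and deletions (RNA bulges) to the spacer.
    Configurations outside ``criteria`` are negative controls; their random
    realisation is resampled (up to ``max_retries``) until the constructed
    sequence genuinely has no admissible alignment on either strand, so a
    flagged control is always a true control.  Returns ``(genome, truth)``
    with ``genome`` a single-entry dict and ``truth`` a DataFrame (one row
    per planted site: coordinates, strand, accounting, admissible flag).
    """
    rng = np.random.default_rng(spec.seed)
    arr = rng.choice(_BASES, size=spec.genome_length, p=list(spec.base_probs))
    genome = bytearray(arr.tobytes())
    truth_rows = []
    for idx, site in enumerate(spec.sites):
        admissible = criteria.allows(site.mismatches, site.bulges)
        flank = 25
        left = site.position - max(0, site.position - flank)
        for attempt in range(max_retries):
            site_seq = _mutate_spacer(spec.spacer, site, rng)
            planted = site_seq if site.strand == "+" else revcomp(site_seq)
            if admissible:
                break
            # negative control: re-check in genomic context so that
            # boundary-crossing alignments cannot sneak past the criteria
            segment = (
                genome[site.position - left : site.position].decode()
                + planted
                + genome[
                    site.position + len(planted) : site.position + len(planted) + flank
                ].decode()
            )
            if not _admissible_in_context(
                spec.spacer, segment, left, left + len(planted), criteria
            ):
                break
        else:
            raise RuntimeError(
                f"could not realise planted site {idx} as a true negative "
                f"control in {max_retries} attempts"
            )
        genome[site.position : site.position + len(planted)] = planted.encode()
        truth_rows.append(
            {
                "seq_name": spec.seq_name,
                "start": site.position,
                "end": site.position + site.length,
                "strand": site.strand,
                "mismatches": site.mismatches,
                "dna_bulges": site.dna_bulges,
                "rna_bulges": site.rna_bulges,
                "admissible": admissible,
                "label": site.label or f"site{idx}",
            }
        )
    return {spec.seq_name: genome.decode()}, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# plain-text writers
# --------------------------------------------------------------------------


def write_fastq(reads, path: str | Path) -> None:
    """Write (read_id, sequence, quality) triples as FASTQ."""
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
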