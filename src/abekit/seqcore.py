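"""Strand-aware sequence primitives, codon translation, and the locus model.

All sequences are stored on the sense strand, 5'->3', with 0-based half-open
coordinates.  Transcript-style 1-based c. positions exist only at the
reporting layer.  For a sense-strand C>T variant the adenine targeted by an
adenine base editor (ABE) sits on the *antisense* strand; "downstream on the
antisense strand" therefore means *decreasing* sense coordinate, and a
bystander adenine ``k`` positions downstream of the target maps to sense
offset ``variant_offset - k``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import yaml
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "revcomp",
    "translate_codon",
    "Locus",
    "CodonChange",
    "codon_change",
    "antisense_adenine_offsets",
    "load_locus",
    "dump_locus",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")
_DNA = set("ACGT")

# Standard nuclear genetic code; stop rendered as "*".
_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N).

    Raises ``ValueError`` naming the first offending position for any other
    character.
    """
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise ValueError(f"non-IUPAC base {ch!r} at position {i}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one DNA triplet to a one-letter amino-acid code ('*' = stop)."""
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    if any(ch not in _DNA for ch in codon):
        raise ValueError(f"invalid base in codon {codon!r}")
    return _CODON_TABLE[codon]


@dataclass(frozen=True)
class CodonChange:
    """One codon altered by a set of edits, evaluated jointly."""

    codon_number: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str

    @property
    def synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa

    def __post_init__(self) -> None:
        if len(self.ref_codon) != 3 or len(self.alt_codon) != 3:
            raise ValueError("codons must be triplets")


@dataclass(frozen=True)
class Locus:
    """A genomic context around a single-nucleotide variant.

    Parameters
    ----------
    context
        Sense-strand sequence, 5'->3', over A/C/G/T.
    variant_offset
        0-based index of the variant base within ``context``.
    ref_base, alt_base
        Reference (corrected) and variant (patient) base on the sense strand.
    frame_anchor_offset
        0-based index of the first base of a codon of known number.
    frame_anchor_codon
        Amino-acid number of that anchor codon.
    edited_strand
        Strand carrying the target adenine: ``"antisense"`` for a sense C>T
        variant, ``"sense"`` for a sense T>C-style target.
    allele
        ``"patient"`` (context carries alt_base) or ``"corrected"``.
    name
        Free-text label used in reports.
    """

    context: str
    variant_offset: int
    ref_base: str
    alt_base: str
    frame_anchor_offset: int
    frame_anchor_codon: int
    edited_strand: str = "antisense"
    allele: str = "patient"
    name: str = "locus"

    def __post_init__(self) -> None:
        if any(ch not in _DNA for ch in self.context):
            bad = next(i for i, ch in enumerate(self.context) if ch not in _DNA)
            raise ValueError(f"context has non-ACGT base at position {bad}")
        if not 0 <= self.variant_offset < len(self.context):
            raise ValueError("variant_offset outside context")
        if self.edited_strand not in ("sense", "antisense"):
            raise ValueError(f"bad edited_strand {self.edited_strand!r}")
        if self.allele not in ("patient", "corrected"):
            raise ValueError(f"bad allele {self.allele!r}")
        expected = self.alt_base if self.allele == "patient" else self.ref_base
        observed = self.context[self.variant_offset]
        if observed != expected:
            raise ValueError(
                f"{self.allele} locus must carry {expected!r} at the variant "
                f"position, found {observed!r}"
            )
        if not 0 <= self.frame_anchor_offset < len(self.context):
            raise ValueError("frame_anchor_offset outside context")

    # -- coordinate helpers -------------------------------------------------

    def codon_offset(self, codon_number: int) -> int:
        """Sense offset of the first base of the given codon."""
        return self.frame_anchor_offset + 3 * (codon_number - self.frame_anchor_codon)

    def codon_number_at(self, offset: int) -> int | None:
        """Codon number containing a sense offset, or None outside a complete codon."""
        rel = offset - self.frame_anchor_offset
        number = self.frame_anchor_codon + (rel // 3)
        start = self.codon_offset(number)
        if start < 0 or start + 3 > len(self.context):
            return None
        return number

    def codon(self, codon_number: int) -> str:
        start = self.codon_offset(codon_number)
        if start < 0 or start + 3 > len(self.context):
            raise ValueError(f"codon {codon_number} not fully inside the context")
        return self.context[start : start + 3]

    @property
    def variant_codon_number(self) -> int:
        number = self.codon_number_at(self.variant_offset)
        if number is None:
            raise ValueError("variant does not fall inside a complete codon")
        return number

    def as_corrected(self) -> "Locus":
        """The same locus with the reference base restored at the variant."""
        if self.allele == "corrected":
            return self
        ctx = (
            self.context[: self.variant_offset]
            + self.ref_base
            + self.context[self.variant_offset + 1 :]
        )
        return replace(self, context=ctx, allele="corrected")

    def as_patient(self) -> "Locus":
        if self.allele == "patient":
            return self
        ctx = (
            self.context[: self.variant_offset]
            + self.alt_base
            + self.context[self.variant_offset + 1 :]
        )
        return replace(self, context=ctx, allele="patient")

    def sense_offset_of(self, offset_from_target: int) -> int:
        """Map a protospacer-strand offset from the target to a sense offset.

        Positive offsets point downstream (toward the PAM) on the edited
        strand; on the antisense strand that is decreasing sense coordinate.
        """
        if self.edited_strand == "antisense":
            return self.variant_offset - offset_from_target
        return self.variant_offset + offset_from_target


def codon_change(
    locus: Locus, edits: set[tuple[int, str]] | list[tuple[int, str]]
) -> tuple[list[CodonChange], list[int]]:
    """Joint codon consequences of a set of sense-strand edits.

    ``edits`` is a collection of ``(sense offset, new base)`` pairs; an
    antisense A->G deamination presents here as a sense T->C edit.  Codons
    touched by more than one edit are evaluated jointly (both Phe-codon
    adenines edited gives one TTC->CCC record, not two).  Edits that fall
    outside any complete codon are returned in the second element as
    non-coding offsets rather than raising.

    Returns ``(changes, noncoding_offsets)`` with changes sorted by codon
    number.
    """
    per_codon: dict[int, list[tuple[int, str]]] = {}
    noncoding: list[int] = []
    for offset, base in edits:
        if not 0 <= offset < len(locus.context):
            raise ValueError(f"edit offset {offset} outside context")
        if base not in _DNA:
            raise ValueError(f"invalid edit base {base!r} at offset {offset}")
        number = locus.codon_number_at(offset)
        if number is None:
            noncoding.append(offset)
            continue
        per_codon.setdefault(number, []).append((offset, base))

    changes: list[CodonChange] = []
    for number in sorted(per_codon):
        start = locus.codon_offset(number)
        ref = locus.context[start : start + 3]
        alt = list(ref)
        for offset, base in per_codon[number]:
            alt[offset - start] = base
        alt_codon = "".join(alt)
        if alt_codon == ref:
            continue  # edit restored the reference base; no change to report
        changes.append(
            CodonChange(
                codon_number=number,
                ref_codon=ref,
                alt_codon=alt_codon,
                ref_aa=translate_codon(ref),
                alt_aa=translate_codon(alt_codon),
            )
        )
    return changes, sorted(set(noncoding))


def antisense_adenine_offsets(locus: Locus, lo: int, hi: int) -> list[int]:
    """Offsets in ``[lo, hi]`` (relative to the target, protospacer-strand
    polarity, 0 excluded) at which the edited strand carries an adenine.

    On the antisense strand an adenine shows as a sense-strand T.
    """
    want = "T" if locus.edited_strand == "antisense" else "A"
    out = []
    for k in range(lo, hi + 1):
        if k == 0:
            continue
        off = locus.sense_offset_of(k)
        if 0 <= off < len(locus.context) and locus.context[off] == want:
            out.append(k)
    return out


# -- locus config I/O -------------------------------------------------------

_LOCUS_KEYS = {
    "context",
    "variant_offset",
    "ref_base",
    "alt_base",
    "frame_anchor_offset",
    "frame_anchor_codon",
    "edited_strand",
    "allele",
    "name",
}


def load_locus(path: str | Path) -> Locus:
    """Read a Locus from a small YAML/JSON config file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: locus config must be a mapping")
    unknown = set(data) - _LOCUS_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown locus keys {sorted(unknown)}")
    return Locus(**data)


def dump_locus(locus: Locus, path: str | Path) -> None:
    data = {k: getattr(locus, k) for k in sorted(_LOCUS_KEYS)}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
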