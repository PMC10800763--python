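"""Cas PAM profiles, deaminase editing windows, and candidate guide design.

An adenine base editor can correct a sense-strand C>T variant only if a
protospacer on the antisense strand places the target adenine inside the
deaminase editing window (protospacer positions numbered 1 at the 5',
PAM-distal end; the PAM occupies positions 21-23 immediately 3').  This
module enumerates such placements for a given Cas PAM profile, annotates
every other protospacer adenine as a potential bystander with its codon
consequence, and ranks editor/guide combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .seqcore import CodonChange, Locus, codon_change, revcomp

__all__ = [
    "PamProfile",
    "DeaminaseProfile",
    "BystanderAnnotation",
    "GuideCandidate",
    "builtin_profiles",
    "pam_matches",
    "enumerate_guides",
    "annotate_bystanders",
    "rank_strategies",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

TIERS = ("preferred", "tolerated")


def _iupac_match(pattern: str, seq: str) -> bool:
    return len(pattern) == len(seq) and all(
        s in _IUPAC[p] for p, s in zip(pattern, seq)
    )


@dataclass(frozen=True)
class PamProfile:
    """A Cas protein's PAM preference as an ordered list of IUPAC 3-mers.

    Patterns are tried in order; the first match wins, so preferred patterns
    must be listed before tolerated ones.
    """

    cas_name: str
    patterns: tuple[tuple[str, str], ...]  # (IUPAC 3-mer, tier)

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("a PamProfile needs at least one pattern")
        for pat, tier in self.patterns:
            if len(pat) != 3 or any(ch not in _IUPAC for ch in pat):
                raise ValueError(f"invalid IUPAC PAM pattern {pat!r}")
            if tier not in TIERS:
                raise ValueError(f"invalid tier {tier!r}")

    def match(self, pam: str) -> str | None:
        """Tier of the first matching pattern, or None if no pattern matches."""
        for pat, tier in self.patterns:
            if _iupac_match(pat, pam):
                return tier
        return None


def pam_matches(profile: PamProfile, pam: str) -> str | None:
    return profile.match(pam)


@dataclass(frozen=True)
class DeaminaseProfile:
    """An adenosine deaminase editing window in protospacer coordinates.

    ``window_start``/``window_end`` are 1-based inclusive protospacer
    positions within which deamination is efficient.
    """

    name: str
    window_start: int
    window_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.window_start <= self.window_end <= 20:
            raise ValueError("editing window must satisfy 1 <= start <= end <= 20")

    def in_window(self, position: int) -> bool:
        return self.window_start <= position <= self.window_end

    @property
    def center(self) -> float:
        return (self.window_start + self.window_end) / 2.0


def builtin_profiles() -> tuple[list[PamProfile], list[DeaminaseProfile]]:
    """Built-in Cas PAM profiles and deaminase windows.

    PAM tiers encode published qualitative preferences: SpCas9 prefers NGG
    and tolerates NAG/NGA; iSpyMac prefers NAA; SpG engages NGN; SpRY is
    near-PAMless with a purine preference at position 2, encoded as NRN
    preferred / NYN tolerated so tier reporting stays meaningful.

    Window extents are defaults that respect the published breadth ordering
    (ABE8e broadest, ABE8.8 narrowest); they are configuration, not measured
    biology, and every entry point accepts overrides.
    """
    pams = [
        PamProfile("SpCas9", (("NGG", "preferred"), ("NAG", "tolerated"), ("NGA", "tolerated"))),
        PamProfile("iSpyMac", (("NAA", "preferred"),)),
        PamProfile("SpG", (("NGN", "preferred"),)),
        PamProfile("SpRY", (("NRN", "preferred"), ("NYN", "tolerated"))),
    ]
    deaminases = [
        DeaminaseProfile("ABE7.10", 4, 7),
        DeaminaseProfile("ABE8e", 3, 9),
        DeaminaseProfile("ABE8.20", 3, 9),
        DeaminaseProfile("ABE8.8", 4, 8),
    ]
    return pams, deaminases


@dataclass(frozen=True)
class BystanderAnnotation:
    """A non-target adenine in a protospacer and what editing it would do.

    ``offset`` is signed along the protospacer strand relative to the target
    adenine (positive = downstream, toward the PAM).  ``consequence`` is the
    single-edit codon change evaluated on the corrected background, or None
    when the adenine falls outside any complete codon (non-coding).
    """

    offset: int
    protospacer_position: int
    in_window: bool
    consequence: CodonChange | None

    def __post_init__(self) -> None:
        if self.offset == 0:
            raise ValueError("a bystander cannot sit at the target position")

    @property
    def synonymous(self) -> bool | None:
        if self.consequence is None:
            return None
        return self.consequence.synonymous


@dataclass(frozen=True)
class GuideCandidate:
    """A 20-nt protospacer placement putting the target adenine in the window."""

    protospacer: str  # protospacer-strand, 5'->3'
    strand: str  # "sense" | "antisense"
    sense_start: int  # protospacer span on the sense strand, half-open
    sense_end: int
    pam: str
    pam_tier: str
    cas_name: str
    deaminase_name: str
    window: tuple[int, int]
    target_position: int  # 1..20
    bystanders: tuple[BystanderAnnotation, ...] = ()

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if self.protospacer[self.target_position - 1] != "A":
            raise ValueError("target position must hold an A on the protospacer strand")

    @property
    def n_nonsyn_in_window(self) -> int:
        return sum(
            1
            for b in self.bystanders
            if b.in_window and b.synonymous is False
        )

    @property
    def worst_in_window(self) -> str:
        """Human-readable worst in-window bystander consequence."""
        worst = "none"
        for b in self.bystanders:
            if not b.in_window:
                continue
            if b.consequence is None:
                if worst == "none":
                    worst = "non-coding"
            elif b.consequence.synonymous:
                if worst in ("none", "non-coding"):
                    worst = "synonymous"
            else:
                c = b.consequence
                return f"{c.ref_aa}{c.codon_number}{c.alt_aa}"
        return worst


def _protospacer_frame(locus: Locus) -> tuple[str, int]:
    """Edited-strand sequence and the target index within it."""
    if locus.edited_strand == "antisense":
        return revcomp(locus.context), len(locus.context) - 1 - locus.variant_offset
    return locus.context, locus.variant_offset


def enumerate_guides(
    locus: Locus,
    pam: PamProfile,
    deaminase: DeaminaseProfile,
) -> list[GuideCandidate]:
    """All protospacer placements on the edited strand that put the target
    adenine inside the deaminase window next to a matching PAM.

    Only the strand carrying the target adenine is searched: ABE correction
    requires the target A on the protospacer strand.  Results are sorted by
    target position.
    """
    locus = locus.as_patient()
    strand_seq, t = _protospacer_frame(locus)
    if strand_seq[t] != "A":
        raise ValueError(
            "edited strand does not carry an A at the variant position; "
            "check edited_strand and allele"
        )
    needed = (deaminase.window_end - 1) + 23 - (deaminase.window_start - 1)
    if len(strand_seq) < needed:
        raise ValueError(
            f"context too short to host a 23-mer at every window placement; "
            f"need at least {needed} nt"
        )
    out: list[GuideCandidate] = []
    n = len(strand_seq)
    for pos in range(deaminase.window_start, deaminase.window_end + 1):
        start = t - (pos - 1)
        if start < 0 or start + 23 > n:
            continue
        pam_seq = strand_seq[start + 20 : start + 23]
        tier = pam.match(pam_seq)
        if tier is None:
            continue
        protospacer = strand_seq[start : start + 20]
        if locus.edited_strand == "antisense":
            sense_start = n - (start + 20)
            sense_end = n - start
        else:
            sense_start, sense_end = start, start + 20
        cand = GuideCandidate(
            protospacer=protospacer,
            strand=locus.edited_strand,
            sense_start=sense_start,
            sense_end=sense_end,
            pam=pam_seq,
            pam_tier=tier,
            cas_name=pam.cas_name,
            deaminase_name=deaminase.name,
            window=(deaminase.window_start, deaminase.window_end),
            target_position=pos,
        )
        cand = replace(
            cand, bystanders=tuple(annotate_bystanders(cand, locus, deaminase))
        )
        out.append(cand)
    out.sort(key=lambda c: c.target_position)
    return out


def annotate_bystanders(
    guide: GuideCandidate, locus: Locus, deaminase: DeaminaseProfile
) -> list[BystanderAnnotation]:
    """Annotate every non-target adenine in the protospacer.

    Consequences are single-edit codon changes computed on the corrected
    background (the clinically relevant comparison once the target is fixed).
    """
    corrected = locus.as_corrected()
    anns: list[BystanderAnnotation] = []
    for i, base in enumerate(guide.protospacer, start=1):
        if base != "A" or i == guide.target_position:
            continue
        offset = i - guide.target_position
        sense_off = locus.sense_offset_of(offset)
        new_base = "C" if locus.edited_strand == "antisense" else "G"
        changes, noncoding = codon_change(corrected, {(sense_off, new_base)})
        consequence = changes[0] if changes else None
        anns.append(
            BystanderAnnotation(
                offset=offset,
                protospacer_position=i,
                in_window=deaminase.in_window(i),
                consequence=consequence,
            )
        )
    return anns


_TIER_ORDER = {tier: i for i, tier in enumerate(TIERS)}


def rank_strategies(candidates: list[GuideCandidate]) -> list[dict]:
    """Deterministically rank annotated editor/guide candidates.

    Ordering: fewest nonsynonymous in-window bystanders, then target
    centrality within the window, then PAM tier, then lexicographic
    protospacer.  Score components are reported; no editing-efficiency
    prediction is claimed.
    """
    def key(c: GuideCandidate):
        centrality = abs(c.target_position - (c.window[0] + c.window[1]) / 2.0)
        return (c.n_nonsyn_in_window, centrality, _TIER_ORDER[c.pam_tier], c.protospacer)

    ranked = sorted(candidates, key=key)
    report = []
    for rank, c in enumerate(ranked, start=1):
        report.append(
            {
                "rank": rank,
                "candidate": c,
                "n_nonsyn_in_window": c.n_nonsyn_in_window,
                "target_centrality": abs(
                    c.target_position - (c.window[0] + c.window[1]) / 2.0
                ),
                "pam_tier": c.pam_tier,
                "worst_in_window": c.worst_in_window,
            }
        )
    return report
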