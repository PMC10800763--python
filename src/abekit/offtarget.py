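"""Off-target candidate nomination by bounded mismatch/bulge matching.

A genomic site is admitted when the 20-nt spacer aligns to it with

* up to ``max_mm_nobulge`` (default 2) mismatches and no bulges, **or**
* up to ``max_mm_withbulge`` (default 1) mismatch and up to ``max_bulges``
  (default 2) bulges,

with no constraint on the PAM (the 3-mer 3' of each site is reported for
inspection but never filtered on).  A DNA bulge is an unpaired genomic
base, an RNA bulge an unpaired spacer base; every bulge is a single-nt gap
(bulges are counted, not measured), two bulges may be adjacent or split and
may sit on either molecule, but the first and last spacer bases must pair
(a terminal bulge is just a shifted alignment).  A spacer base opposite a
gap is a bulge, never also a mismatch.

The scanner enumerates every admissible bulge placement ("shape") and
evaluates all genome windows per shape with vectorized comparisons.  An
independent layered dynamic program (``exhaustive_dp_ends``) computes the
same admission decision by a different route and serves as the oracle in
tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .seqcore import revcomp

__all__ = [
    "OffTargetCriteria",
    "OffTargetSite",
    "SiteEditing",
    "find_candidate_sites",
    "scan_hits",
    "exhaustive_dp_ends",
    "verify_site",
    "quantify_site_editing",
]

_INF = np.iinfo(np.int32).max // 2


@dataclass(frozen=True)
class OffTargetCriteria:
    """Admission rule: (mm <= max_mm_nobulge and bulges == 0) or
    (mm <= max_mm_withbulge and bulges <= max_bulges)."""

    max_mm_nobulge: int = 2
    max_mm_withbulge: int = 1
    max_bulges: int = 2
    pam_constrained: bool = False

    def __post_init__(self) -> None:
        if min(self.max_mm_nobulge, self.max_mm_withbulge, self.max_bulges) < 0:
            raise ValueError("criteria fields must be non-negative")
        if self.pam_constrained:
            raise ValueError(
                "PAM-constrained search is not supported; filter on the "
                "reported pam field downstream"
            )

    def allows(self, mismatches: int, bulges: int) -> bool:
        if bulges == 0:
            return mismatches <= self.max_mm_nobulge
        return bulges <= self.max_bulges and mismatches <= self.max_mm_withbulge


@dataclass(frozen=True)
class OffTargetSite:
    """A genomic near-match of a spacer, 0-based half-open coordinates."""

    seq_name: str
    start: int
    end: int
    strand: str  # "+" | "-"
    site_sequence: str  # protospacer-strand orientation
    mismatches: int
    dna_bulges: int
    rna_bulges: int
    pam: str  # 3-mer 3' of the site on the protospacer strand ("" at an edge)
    spacer_to_site: tuple[int | None, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.end - self.start != 20 + self.dna_bulges - self.rna_bulges:
            raise ValueError("site span inconsistent with bulge accounting")

    @property
    def total_edits(self) -> int:
        return self.mismatches + self.dna_bulges + self.rna_bulges

    @property
    def bulges(self) -> int:
        return self.dna_bulges + self.rna_bulges


# -- alignment shapes -------------------------------------------------------


def _shape_layout(d_junctions: tuple[int, ...], r_positions: tuple[int, ...]):
    """Pairing layout of a bulge placement.

    ``d_junctions``: junctions (after spacer position j, 1..19) holding an
    unpaired genomic base; repeats mean adjacent DNA bulges.  ``r_positions``:
    spacer positions (2..19, distinct) left unpaired.  Returns
    ``(site_length, pairs)`` with ``pairs`` the (spacer_index_0based,
    site_offset) couples.
    """
    pairs = []
    offset = 0
    for i in range(1, 21):
        if i not in r_positions:
            pairs.append((i - 1, offset))
            offset += 1
        offset += d_junctions.count(i)
    return offset, pairs


def _enumerate_shapes(max_bulges: int):
    """Every placement of <= max_bulges interior single-nt bulges."""
    shapes = [((), ())]
    singles_d = [((j,), ()) for j in range(1, 20)]
    singles_r = [((), (j,)) for j in range(2, 20)]
    if max_bulges >= 1:
        shapes += singles_d + singles_r
    if max_bulges >= 2:
        shapes += [
            (tuple(sorted(dd)), ())
            for dd in itertools.combinations_with_replacement(range(1, 20), 2)
        ]
        shapes += [((), rr) for rr in itertools.combinations(range(2, 20), 2)]
        shapes += [((d,), (r,)) for d in range(1, 20) for r in range(2, 20)]
    if max_bulges >= 3:
        raise NotImplementedError("shape enumeration supports at most 2 bulges")
    return shapes


def _to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def scan_hits(spacer: str, seq: str, criteria: OffTargetCriteria):
    """Raw admissible placements of ``spacer`` on one strand of ``seq``.

    Returns ``(hits, n_skipped)``: ``hits`` maps ``(start, length)`` to the
    best ``(mismatches, d_junctions, r_positions)`` accounting (fewest total
    edits, then fewest bulges, then fewest DNA bulges); windows containing N
    are skipped and counted in ``n_skipped``.
    """
    if len(spacer) != 20 or any(ch not in "ACGT" for ch in spacer):
        raise ValueError("spacer must be a 20-mer over ACGT")
    text = _to_bytes(seq)
    n = len(text)
    sp = _to_bytes(spacer)
    is_n = text == ord("N")
    n_cum = np.concatenate([[0], np.cumsum(is_n)])
    hits: dict[tuple[int, int], tuple[int, tuple[int, ...], tuple[int, ...]]] = {}
    n_skipped = 0
    for d_junctions, r_positions in _enumerate_shapes(criteria.max_bulges):
        bulges = len(d_junctions) + len(r_positions)
        mm_allow = criteria.max_mm_nobulge if bulges == 0 else criteria.max_mm_withbulge
        length, pairs = _shape_layout(d_junctions, r_positions)
        n_win = n - length + 1
        if n_win <= 0:
            continue
        mm = np.zeros(n_win, dtype=np.int16)
        for i, off in pairs:
            mm += text[off : off + n_win] != sp[i]
        has_n = (n_cum[length:] - n_cum[:-length]) > 0
        if bulges == 0:
            n_skipped = int(has_n.sum())
        ok = (mm <= mm_allow) & ~has_n
        for start in np.nonzero(ok)[0]:
            key = (int(start), length)
            cand = (int(mm[start]), d_junctions, r_positions)
            prev = hits.get(key)
            if prev is None or _edit_rank(cand) < _edit_rank(prev):
                hits[key] = cand
        # a second shape with the same (start, length) can only differ in
        # bulge placement; keep the lower-edit accounting
    return hits, n_skipped


def _edit_rank(acct):
    mm, d, r = acct
    bulges = len(d) + len(r)
    return (mm + bulges, bulges, len(d), d, r)


def _hit_to_site(seq_name, seq, start, length, acct, strand, n) -> OffTargetSite:
    mm, d_junctions, r_positions = acct
    _, pairs = _shape_layout(d_junctions, r_positions)
    spacer_to_site: list[int | None] = [None] * 20
    for i, off in pairs:
        spacer_to_site[i] = off
    if strand == "+":
        g_start, g_end = start, start + length
        site_seq = seq[g_start:g_end]
        pam = seq[g_end : g_end + 3]
    else:
        g_start, g_end = n - (start + length), n - start
        site_seq = revcomp(seq[g_start:g_end])
        pam = revcomp(seq[max(0, g_start - 3) : g_start])
    if len(pam) < 3:
        pam = ""
    return OffTargetSite(
        seq_name=seq_name,
        start=g_start,
        end=g_end,
        strand=strand,
        site_sequence=site_seq,
        mismatches=mm,
        dna_bulges=len(d_junctions),
        rna_bulges=len(r_positions),
        pam=pam,
        spacer_to_site=tuple(spacer_to_site),
    )


def _merge_strand_hits(hits):
    """Cluster overlapping (start, length) hits; keep the best per cluster."""
    if not hits:
        return []
    items = sorted(hits.items(), key=lambda kv: (kv[0][0], kv[0][1]))
    clusters = []
    cur = [items[0]]
    cur_end = items[0][0][0] + items[0][0][1]
    for item in items[1:]:
        (start, length), _ = item
        if start < cur_end:
            cur.append(item)
            cur_end = max(cur_end, start + length)
        else:
            clusters.append(cur)
            cur = [item]
            cur_end = start + length
    clusters.append(cur)
    best = []
    for cluster in clusters:
        best.append(
            min(
                cluster,
                key=lambda kv: _edit_rank(kv[1]) + (kv[0][0],),
            )
        )
    return best


def find_candidate_sites(
    spacer: str,
    genome: dict[str, str],
    criteria: OffTargetCriteria = OffTargetCriteria(),
    log: dict | None = None,
) -> list[OffTargetSite]:
    """Scan both strands of every genome sequence for admissible sites.

    Overlapping admissible placements on the same strand are merged keeping
    the best (fewest total edits, then fewest bulges, then leftmost).
    Output is sorted by (sequence name, start, strand); windows containing N
    are skipped (counts available via ``log``).
    """
    sites: list[OffTargetSite] = []
    for seq_name in sorted(genome):
        seq = genome[seq_name].upper()
        n = len(seq)
        for strand, strand_seq in (("+", seq), ("-", revcomp(seq))):
            hits, skipped = scan_hits(spacer, strand_seq, criteria)
            if log is not None:
                log[f"{seq_name}:{strand}:n_windows_skipped"] = skipped
            for (start, length), acct in _merge_strand_hits(hits):
                sites.append(_hit_to_site(seq_name, seq, start, length, acct, strand, n))
    sites.sort(key=lambda s: (s.seq_name, s.start, s.strand))
    return sites


def verify_site(spacer: str, site: OffTargetSite, criteria: OffTargetCriteria) -> bool:
    """Independently re-check a site's accounting from its aligned sequence."""
    if not criteria.allows(site.mismatches, site.bulges):
        return False
    mm = 0
    seen = set()
    for i, off in enumerate(site.spacer_to_site):
        if off is None:
            continue
        seen.add(off)
        if site.site_sequence[off] != spacer[i]:
            mm += 1
    dna = len(site.site_sequence) - len(seen)
    rna = sum(1 for off in site.spacer_to_site if off is None)
    return (
        mm == site.mismatches
        and dna == site.dna_bulges
        and rna == site.rna_bulges
        and site.spacer_to_site[0] == 0
        and site.spacer_to_site[19] == len(site.site_sequence) - 1
    )


# -- exhaustive-DP oracle ---------------------------------------------------


def exhaustive_dp_ends(
    spacer: str, seq: str, criteria: OffTargetCriteria
) -> dict[int, int]:
    """Admissible alignment end positions on one strand, by exhaustive DP.

    Independent cross-check for the shape scanner: a layered semi-global
    dynamic program over (gap count, spacer prefix, text position) computes,
    for every text end position ``j`` (exclusive), the minimum mismatch count
    at each bulge count, with bulges restricted to the interior exactly as in
    the admission rule.  Returns ``{end: minimum total edits}`` for admissible
    ends.  Alignments touching an N are excluded, mirroring the scanner's
    window skipping.
    """
    if len(spacer) != 20:
        raise ValueError("spacer must be a 20-mer")
    text = _to_bytes(seq)
    sp = _to_bytes(spacer)
    n = len(text)
    G = criteria.max_bulges
    n_forbid = text == ord("N")
    # layer[g][i] over end positions j = 0..n (prefix of text consumed)
    prev_layers: list[list[np.ndarray]] = []
    for g in range(G + 1):
        rows = [np.full(n + 1, _INF, dtype=np.int32) for _ in range(21)]
        if g == 0:
            rows[0][:] = 0  # free start, no leading bulges
        for i in range(1, 21):
            # pair spacer i with text base j-1
            pair = np.full(n + 1, _INF, dtype=np.int32)
            mmvec = np.where(n_forbid, _INF, (text != sp[i - 1]).astype(np.int32))
            pair[1:] = rows[i - 1][:-1] + mmvec
            best = pair
            if g > 0:
                if 2 <= i <= 19:  # RNA bulge: skip spacer position i
                    best = np.minimum(best, prev_layers[g - 1][i - 1])
                if 1 <= i <= 19:  # DNA bulge after spacer position i
                    dna = np.full(n + 1, _INF, dtype=np.int32)
                    dna[1:] = np.where(n_forbid, _INF, prev_layers[g - 1][i][:-1])
                    best = np.minimum(best, dna)
            rows[i] = np.minimum(rows[i], best) if g == 0 else best
        prev_layers.append(rows)
    ends: dict[int, int] = {}
    for j in range(1, n + 1):
        best_edits = None
        if prev_layers[0][20][j] <= criteria.max_mm_nobulge:
            best_edits = int(prev_layers[0][20][j])
        for g in range(1, G + 1):
            mm = int(prev_layers[g][20][j])
            if mm <= criteria.max_mm_withbulge:
                edits = mm + g
                if best_edits is None or edits < best_edits:
                    best_edits = edits
        if best_edits is not None:
            ends[j] = best_edits
    return ends


# -- per-site editing quantification ---------------------------------------


@dataclass(frozen=True)
class SiteEditing:
    """Proportion of retained reads with >=1 in-window A->G at a site."""

    proportion: float | None
    n_retained: int
    n_edited: int


def quantify_site_editing(
    reads: list[str],
    site: OffTargetSite,
    deaminase,
    reference: str,
    site_start_in_ref: int,
    identity_floor: float = 0.6,
) -> SiteEditing:
    """Fraction of retained reads with >=1 adenine edited to guanine within
    the editing window at a (possibly bulged) candidate site.

    ``reference`` is the site amplicon in protospacer-strand orientation,
    with the aligned site starting at ``site_start_in_ref``.  Editing-window
    protospacer positions are mapped through the spacer-site alignment
    (RNA-bulged spacer positions have no genomic counterpart and are
    skipped).  Reads failing the identity floor or not covering the window
    are dropped; with no retained reads the proportion is None.
    """
    from .amplicon_quant import align_read

    window_refs = []
    for pos in range(deaminase.window_start, deaminase.window_end + 1):
        off = site.spacer_to_site[pos - 1]
        if off is None:
            continue
        p = site_start_in_ref + off
        if 0 <= p < len(reference) and reference[p] == "A":
            window_refs.append(p)
    n_retained = n_edited = 0
    for k, read in enumerate(reads):
        aln = align_read(read, reference, read_id=f"r{k}")
        if aln.identity < identity_floor:
            continue
        bases = [aln.read_base_at_ref[p] for p in window_refs]
        if any(b is None for b in bases):
            continue
        n_retained += 1
        if any(b == "G" for b in bases):
            n_edited += 1
    if n_retained == 0:
        return SiteEditing(None, 0, 0)
    return SiteEditing(n_edited / n_retained, n_retained, n_edited)
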