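"""Amplicon-sequencing editing quantification.

Reads are aligned to the amplicon reference (the patient-allele locus
context), orientation-normalized, and classified into editing categories:

``correction_only``
    the target adenine is edited to guanine (sense T->C for an antisense
    target) and the jointly translated local peptide equals the corrected
    wild type — synonymous co-edits such as the adjacent CCT->CCC adenine
    are permitted;
``unwanted_bystander``
    the target is edited but at least one co-edit changes an amino acid;
``bystander_only``
    >=1 non-target adenine edited without the corrective edit;
``unedited``; ``indel`` (any alignment gap overlapping the quantification
window); ``discarded`` (poor alignment or window not covered).

Proportions are reported over retained (non-discarded) reads.  The module
also fits a four-parameter logistic (4PL) dose-response curve to recover an
EC50, and computes net editing (treated minus control, floored at zero) for
off-target comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from scipy.optimize import curve_fit

from .seqcore import Locus, revcomp, translate_codon

__all__ = [
    "QuantWindow",
    "AlignmentResult",
    "ReadClassification",
    "EditingSummary",
    "DoseResponseFit",
    "make_aligner",
    "align_read",
    "classify_read",
    "summarize",
    "allele_table",
    "net_editing",
    "fit_dose_response",
]

RETAINED_CATEGORIES = (
    "correction_only",
    "unwanted_bystander",
    "bystander_only",
    "unedited",
    "indel",
)
CATEGORIES = RETAINED_CATEGORIES + ("discarded",)


@dataclass(frozen=True)
class QuantWindow:
    """Sense-strand span (half-open) used for quantification.

    By default the protospacer footprint plus a 5-nt flank on each side,
    clipped to the amplicon.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("window must be non-empty with start >= 0")

    @classmethod
    def from_guide(cls, guide, reference_length: int, flank: int = 5) -> "QuantWindow":
        start = max(0, guide.sense_start - flank)
        end = min(reference_length, guide.sense_end + flank)
        return cls(start, end)

    def __contains__(self, offset: int) -> bool:
        return self.start <= offset < self.end

    def __len__(self) -> int:
        return self.end - self.start


def make_aligner() -> Align.PairwiseAligner:
    """Global aligner with free end gaps (match +2, mismatch -1, gap open -5,
    gap extend -1)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    aligner.end_insertion_score = 0  # free end gaps, both sequences
    aligner.end_deletion_score = 0
    return aligner


@dataclass
class AlignmentResult:
    """A read placed on the reference, orientation-normalized.

    ``read_base_at_ref[p]`` is the read base aligned to reference position
    ``p``, ``'-'`` for a deletion, or None where the read does not cover the
    reference.  ``insertions_after`` holds reference junction indices ``p``
    with read bases inserted between ``p-1`` and ``p``.
    """

    read_id: str
    strand: str  # "+" read used as-is, "-" reverse-complemented
    score: float
    identity: float
    read_base_at_ref: list[str | None]
    insertions_after: set[int] = field(default_factory=set)

    def covers(self, window: QuantWindow) -> bool:
        return all(self.read_base_at_ref[p] is not None for p in range(window.start, window.end))

    def has_gap_in(self, window: QuantWindow) -> bool:
        if any(self.read_base_at_ref[p] == "-" for p in range(window.start, window.end)):
            return True
        # an insertion at junction p sits between ref p-1 and p; it overlaps
        # the window when strictly inside it
        return any(window.start < p < window.end for p in self.insertions_after)


def _project(alignment, reference: str, read: str) -> tuple[list[str | None], set[int], float]:
    """Per-reference-position read bases, insertion junctions, identity."""
    per_ref: list[str | None] = [None] * len(reference)
    insertions: set[int] = set()
    t_blocks, q_blocks = alignment.aligned
    matches = mismatches = internal_gap_cols = 0
    prev_t_end = prev_q_end = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t_end is not None:
            t_jump = ts - prev_t_end
            q_jump = qs - prev_q_end
            if t_jump:  # deletion in the read
                for p in range(prev_t_end, ts):
                    per_ref[p] = "-"
                internal_gap_cols += t_jump
            if q_jump:  # insertion in the read
                insertions.add(ts)
                internal_gap_cols += q_jump
        for p, q in zip(range(ts, te), range(qs, qe)):
            per_ref[p] = read[q]
            if reference[p] == read[q]:
                matches += 1
            else:
                mismatches += 1
        prev_t_end, prev_q_end = te, qe
    denom = matches + mismatches + internal_gap_cols
    identity = matches / denom if denom else 0.0
    return per_ref, insertions, identity


def align_read(read: str, reference: str, read_id: str = "read") -> AlignmentResult:
    """Align a read to the reference, auto-detecting orientation.

    Both the read and its reverse complement are aligned; the better score
    wins (ties keep the forward orientation).  Deterministic for a fixed
    scoring scheme: of the optimal alignments Biopython's first is used.
    """
    if not read or not reference:
        raise ValueError("read and reference must be non-empty")
    aligner = make_aligner()
    fwd = aligner.align(reference, read)
    rc = revcomp(read)
    rev = aligner.align(reference, rc)
    if rev.score > fwd.score:
        best, seq, strand = rev[0], rc, "-"
    else:
        best, seq, strand = fwd[0], read, "+"
    per_ref, insertions, identity = _project(best, reference, seq)
    return AlignmentResult(
        read_id=read_id,
        strand=strand,
        score=best.score,
        identity=identity,
        read_base_at_ref=per_ref,
        insertions_after=insertions,
    )


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    category: str
    edited_offsets: frozenset[int] = frozenset()
    mismatch_count: int = 0
    reason: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _window_peptide(context: str, locus: Locus, window: QuantWindow) -> list[tuple[int, str]]:
    """(codon number, amino acid) for complete codons overlapping the window."""
    first = locus.codon_number_at(window.start)
    last = locus.codon_number_at(window.end - 1)
    # walk outward until complete codons are found (window edges may fall in
    # partial codons at the context boundary)
    numbers = []
    n_lo = locus.frame_anchor_codon + math.ceil(-locus.frame_anchor_offset / 3)
    start_num = first if first is not None else n_lo
    p = start_num
    while locus.codon_offset(p) + 3 <= window.start:
        p += 1
    out = []
    while True:
        off = locus.codon_offset(p)
        if off >= window.end or off + 3 > len(context):
            break
        if off >= 0:
            out.append((p, translate_codon(context[off : off + 3])))
        p += 1
    return out


def classify_read(
    aln: AlignmentResult,
    locus: Locus,
    window: QuantWindow,
    identity_floor: float = 0.6,
    window_mismatch_frac: float = 0.3,
) -> ReadClassification:
    """Classify one aligned read into an editing category.

    Priority: discarded (low identity / window uncovered / too many
    non-edit window mismatches) -> indel (any gap overlapping the window) ->
    corrective categories -> bystander_only -> unedited.  The reference is
    the patient allele; an antisense A->G deamination presents as sense
    T->C.  ``correction_only`` tolerates any co-edit combination whose joint
    translation equals the corrected wild-type peptide, which generalizes
    the adjacent-synonymous-adenine exception to any locus.
    """
    locus = locus.as_patient()
    reference = locus.context
    if aln.identity < identity_floor:
        return ReadClassification(aln.read_id, "discarded", reason="low_identity")
    if not aln.covers(window):
        return ReadClassification(aln.read_id, "discarded", reason="window_uncovered")

    edit_from, edit_to = ("T", "C") if locus.edited_strand == "antisense" else ("A", "G")
    edited: set[int] = set()
    mismatches = 0
    for p in range(window.start, window.end):
        base = aln.read_base_at_ref[p]
        if base in (None, "-") or base == reference[p]:
            continue
        if reference[p] == edit_from and base == edit_to:
            edited.add(p)
        else:
            mismatches += 1
    if mismatches / len(window) > window_mismatch_frac:
        return ReadClassification(
            aln.read_id, "discarded", mismatch_count=mismatches, reason="window_mismatches"
        )
    if aln.has_gap_in(window):
        return ReadClassification(
            aln.read_id, "indel", frozenset(edited), mismatches
        )

    corrected = locus.variant_offset in edited
    if corrected:
        hap = list(reference)
        for p in edited:
            hap[p] = edit_to
        hap_pep = _window_peptide("".join(hap), locus, window)
        wt_pep = _window_peptide(locus.as_corrected().context, locus, window)
        category = "correction_only" if hap_pep == wt_pep else "unwanted_bystander"
    elif edited:
        category = "bystander_only"
    else:
        category = "unedited"
    return ReadClassification(aln.read_id, category, frozenset(edited), mismatches)


@dataclass
class EditingSummary:
    counts: dict[str, int]
    proportions: dict[str, float]
    overall_corrective: float
    n_total: int
    n_discarded: int
    n_retained: int
    empty: bool = False


def summarize(classifications: list[ReadClassification]) -> EditingSummary:
    """Category counts and proportions over retained reads.

    When every read is discarded the summary is returned with ``empty=True``
    and no proportions, as an explicit signal rather than a crash.
    """
    counts = {c: 0 for c in CATEGORIES}
    for cl in classifications:
        counts[cl.category] += 1
    n_total = len(classifications)
    n_discarded = counts["discarded"]
    n_retained = n_total - n_discarded
    if n_retained == 0:
        return EditingSummary(counts, {}, 0.0, n_total, n_discarded, 0, empty=True)
    props = {c: counts[c] / n_retained for c in RETAINED_CATEGORIES}
    overall = props["correction_only"] + props["unwanted_bystander"]
    return EditingSummary(counts, props, overall, n_total, n_discarded, n_retained)


def allele_table(
    classifications: list[ReadClassification],
    alignments: list[AlignmentResult],
    locus: Locus,
    window: QuantWindow,
):
    """Ranked window-haplotype table with per-codon amino-acid rendering.

    One row per distinct window haplotype among retained reads, ordered by
    count (desc) then sequence; the amino-acid column lists codons whose
    translation differs from the patient baseline as e.g. ``W408R`` (baseline
    identity first, post-editing identity second).  Gapped haplotypes are
    rendered ``indel``.
    """
    import pandas as pd

    locus = locus.as_patient()
    by_id = {a.read_id: a for a in alignments}
    tallies: dict[str, int] = {}
    for cl in classifications:
        if cl.category == "discarded":
            continue
        aln = by_id[cl.read_id]
        hap = "".join(aln.read_base_at_ref[p] or "N" for p in range(window.start, window.end))
        tallies[hap] = tallies.get(hap, 0) + 1
    total = sum(tallies.values())
    rows = []
    for hap, count in sorted(tallies.items(), key=lambda kv: (-kv[1], kv[0])):
        if "-" in hap or "N" in hap:
            rendering = "indel"
        else:
            ctx = list(locus.context)
            ctx[window.start : window.end] = hap
            base_pep = dict(_window_peptide(locus.context, locus, window))
            hap_pep = dict(_window_peptide("".join(ctx), locus, window))
            changes = [
                f"{base_pep[n]}{n}{hap_pep[n]}"
                for n in sorted(base_pep)
                if n in hap_pep and hap_pep[n] != base_pep[n]
            ]
            rendering = ",".join(changes) if changes else "reference"
        rows.append(
            {
                "haplotype": hap,
                "count": count,
                "frequency": count / total if total else float("nan"),
                "amino_acids": rendering,
            }
        )
    return pd.DataFrame(rows, columns=["haplotype", "count", "frequency", "amino_acids"])


def net_editing(treated: list[float], control: list[float]) -> float:
    """Mean treated proportion minus mean control proportion, floored at 0."""
    if not treated or not control:
        raise ValueError("both arms need at least one value")
    return max(0.0, float(np.mean(treated)) - float(np.mean(control)))


@dataclass
class DoseResponseFit:
    floor: float
    ceiling: float
    hill: float
    ec50: float
    success: bool
    message: str
    n: int
    rmse: float

    def __post_init__(self) -> None:
        if self.success and not (self.floor <= self.ceiling and self.ec50 > 0):
            raise ValueError("invalid converged fit")

    def predict(self, dose):
        dose = np.asarray(dose, dtype=float)
        return self.floor + (self.ceiling - self.floor) / (
            1.0 + (self.ec50 / dose) ** self.hill
        )


def _four_pl(log_dose, floor, ceiling, hill, log_ec50):
    return floor + (ceiling - floor) / (1.0 + np.exp(-hill * (log_dose - log_ec50)))


def fit_dose_response(doses, responses) -> DoseResponseFit:
    """Least-squares four-parameter logistic fit on log dose.

    Initialization from the data extremes and the dose bracketing the
    half-maximal response; fixed iteration cap; non-convergence and
    degenerate inputs yield a diagnostic failure object, never silence.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape or doses.ndim != 1:
        raise ValueError("doses and responses must be equal-length 1-D")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct positive doses")
    n = len(doses)

    def fail(msg: str) -> DoseResponseFit:
        return DoseResponseFit(
            float("nan"), float("nan"), float("nan"), float("nan"), False, msg, n, float("nan")
        )

    if np.ptp(responses) < 1e-12 * max(1.0, abs(float(np.mean(responses)))):
        return fail("degenerate input: responses are constant")

    log_dose = np.log(doses)
    lo, hi = float(responses.min()), float(responses.max())
    half = (lo + hi) / 2.0
    # dose bracketing the half-maximum, interpolated on the dose-sorted means
    order = np.argsort(log_dose)
    ld, r = log_dose[order], responses[order]
    log_ec50_0 = float(np.median(ld))
    for i in range(len(ld) - 1):
        r0, r1 = r[i], r[i + 1]
        if (r0 - half) * (r1 - half) <= 0 and r0 != r1:
            frac = (half - r0) / (r1 - r0)
            log_ec50_0 = float(ld[i] + frac * (ld[i + 1] - ld[i]))
            break
    hill_0 = 1.0 if r[-1] >= r[0] else -1.0
    p0 = (lo, hi, hill_0, log_ec50_0)
    try:
        popt, pcov = curve_fit(
            _four_pl, log_dose, responses, p0=p0, method="lm", maxfev=20000
        )
    except RuntimeError as exc:
        return fail(f"non-convergence: {exc}")
    if not np.all(np.isfinite(popt)):
        return fail("non-convergence: non-finite parameters")
    floor, ceiling, hill, log_ec50 = (float(v) for v in popt)
    if floor > ceiling:  # equivalent parameterisation; normalize
        floor, ceiling, hill = ceiling, floor, -hill
    resid = responses - _four_pl(log_dose, floor, ceiling, hill, log_ec50)
    return DoseResponseFit(
        floor=floor,
        ceiling=ceiling,
        hill=hill,
        ec50=float(np.exp(log_ec50)),
        success=True,
        message="converged",
        n=n,
        rmse=float(np.sqrt(np.mean(resid**2))),
    )
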