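"""Sequence-side analyses: pairwise global alignment and identity,
Schechter–Berger subsite labelling, peptide fragment masses, and
mass-based cleavage-site localisation on the reactive-center loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .assay_io import AMINO_ACIDS, SerpinRecord
from .errors import DomainError, InputError, ValidationError

__all__ = [
    "AlignScoring",
    "AlignmentResult",
    "CleavageAssignment",
    "global_align",
    "label_p_positions",
    "fragment_mass",
    "map_cleavage_site",
    "project_span",
    "annotate_rcl",
    "find_hinge",
    "WATER_MONO",
    "WATER_AVG",
]

# monoisotopic / average residue masses (Da), unmodified side chains
MONO_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
AVG_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MONO = 18.010565
WATER_AVG = 18.0153

# carbamidomethylation of Cys, applied only when modifications are enabled
CAM_MONO = 57.02146
CAM_AVG = 57.0513

PRIME = "′"


@dataclass
class AlignScoring:
    """Scoring configuration for pairwise global alignment.

    With ``matrix`` set (default BLOSUM62) the match/mismatch scores are
    ignored. A gap of length L costs ``gap_open + (L-1)*gap_extend``.
    ``identity_denominator`` is 'columns' (aligned columns, excluding
    all-gap columns) or 'shorter' (length of the shorter sequence).
    """

    matrix: str | None = "BLOSUM62"
    match: float = 1.0
    mismatch: float = 0.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    identity_denominator: str = "columns"


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    n_identical: int
    n_aligned_columns: int


@dataclass
class CleavageAssignment:
    bond: tuple[int, int]
    fragment_terminus: str
    theoretical_mass: float
    observed_mass: float
    error_ppm: float
    p_labels: tuple[str, str] | None = None


def _check_sequence(seq: str, what: str) -> None:
    if not seq:
        raise InputError(f"{what}: empty sequence")
    bad = sorted(set(seq) - AMINO_ACIDS)
    if bad:
        raise ValidationError(f"{what}: non-amino-acid symbols {bad}")


def global_align(a: str, b: str, scoring: AlignScoring | None = None) -> AlignmentResult:
    """Optimal global (Needleman–Wunsch/Gotoh) alignment of two sequences.

    Ties are broken deterministically by taking the aligner's first
    reported traceback (diagonal preferred over vertical over horizontal).
    """
    scoring = scoring or AlignScoring()
    _check_sequence(a, "sequence a")
    _check_sequence(b, "sequence b")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if scoring.matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    else:
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend

    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    n_cols = sum(1 for x, y in zip(ga, gb) if not (x == "-" and y == "-"))
    n_id = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    if scoring.identity_denominator == "columns":
        denom = n_cols
    elif scoring.identity_denominator == "shorter":
        denom = min(len(a), len(b))
    else:
        raise ValidationError(
            f"unknown identity_denominator {scoring.identity_denominator!r}"
        )
    return AlignmentResult(
        aligned_a=ga,
        aligned_b=gb,
        score=float(aln.score),
        identity_pct=100.0 * n_id / denom,
        n_identical=n_id,
        n_aligned_columns=n_cols,
    )


def label_p_positions(bond: tuple[int, int], p1_index: int) -> tuple[str, str]:
    """Schechter–Berger labels for the two residues flanking a bond.

    Residue j <= P1 is labelled P(p1-j+1); residue j > P1 is labelled
    P(j-p1)' (non-primed side counts N-terminally away from the scissile
    bond, primed side C-terminally).
    """
    i, j = bond
    if j != i + 1:
        raise ValidationError(f"bond {bond} must be consecutive residue indices")
    if i < 1 or p1_index < 1:
        raise ValidationError("residue indices are 1-based and must be positive")

    def one(idx: int) -> str:
        if idx <= p1_index:
            return f"P{p1_index - idx + 1}"
        return f"P{idx - p1_index}{PRIME}"

    return one(i), one(j)


def fragment_mass(
    seq: str,
    span: tuple[int, int] | None = None,
    mass_type: str = "monoisotopic",
    carbamidomethyl_cys: bool = False,
) -> float:
    """Neutral peptide mass of seq[span] (1-based inclusive), plus water.

    An empty span (lo > hi) returns the bare water mass.
    """
    if mass_type == "monoisotopic":
        table, water, cam = MONO_MASS, WATER_MONO, CAM_MONO
    elif mass_type == "average":
        table, water, cam = AVG_MASS, WATER_AVG, CAM_AVG
    else:
        raise DomainError(f"mass_type must be 'monoisotopic' or 'average', got {mass_type!r}")

    if span is None:
        span = (1, len(seq))
    lo, hi = span
    if lo < 1 or hi > len(seq):
        raise InputError(f"span {span} outside sequence of length {len(seq)}")
    sub = seq[lo - 1 : hi]
    _check_sequence(sub, "fragment") if sub else None
    mass = water + sum(table[r] for r in sub)
    if carbamidomethyl_cys:
        mass += cam * sub.count("C")
    return mass


def map_cleavage_site(
    record: SerpinRecord,
    observed_mass: float,
    fragment_terminus: str = "N",
    tolerance_ppm: float = 20.0,
    restrict_to_rcl: bool = False,
    mass_type: str = "monoisotopic",
) -> list[CleavageAssignment]:
    """Locate the backbone bond whose N- or C-terminal fragment matches a mass.

    Enumerates every candidate bond (i, i+1) — optionally only those
    inside the annotated RCL span — computes the fragment mass on the
    requested side, and returns all assignments within ``tolerance_ppm``
    ranked by absolute mass error. P labels are attached when the record
    carries a P1 index. An empty list means no bond matches.
    """
    if fragment_terminus not in ("N", "C"):
        raise DomainError(f"fragment_terminus must be 'N' or 'C', got {fragment_terminus!r}")
    if tolerance_ppm <= 0:
        raise DomainError("tolerance_ppm must be > 0")
    water = WATER_MONO if mass_type == "monoisotopic" else WATER_AVG
    if observed_mass <= water:
        return []

    seq = record.residues
    n = len(seq)
    bonds = range(1, n)
    if restrict_to_rcl:
        if record.rcl_span is None:
            raise InputError(f"record {record.seq_id!r} has no rcl_span annotation")
        lo, hi = record.rcl_span
        bonds = range(max(lo, 1), min(hi, n - 1) + 1)

    hits = []
    for i in bonds:
        span = (1, i) if fragment_terminus == "N" else (i + 1, n)
        theo = fragment_mass(seq, span, mass_type=mass_type)
        err_ppm = (observed_mass - theo) / theo * 1e6
        if abs(err_ppm) <= tolerance_ppm:
            labels = (
                label_p_positions((i, i + 1), record.p1_index)
                if record.p1_index is not None
                else None
            )
            hits.append(
                CleavageAssignment(
                    bond=(i, i + 1),
                    fragment_terminus=fragment_terminus,
                    theoretical_mass=theo,
                    observed_mass=observed_mass,
                    error_ppm=err_ppm,
                    p_labels=labels,
                )
            )
    hits.sort(key=lambda h: abs(h.error_ppm))
    return hits


# ---------------------------------------------------------------------------
# annotation helpers

def project_span(
    result: AlignmentResult, span: tuple[int, int]
) -> tuple[int, int] | None:
    """Map a 1-based span on sequence a through an alignment onto sequence b.

    Returns the smallest span on b covering all b-residues aligned inside
    the a-span, or None if the span aligns entirely to gaps.
    """
    pos_a = pos_b = 0
    lo_b = hi_b = None
    for x, y in zip(result.aligned_a, result.aligned_b):
        if x != "-":
            pos_a += 1
        if y != "-":
            pos_b += 1
        if x != "-" and y != "-" and span[0] <= pos_a <= span[1]:
            if lo_b is None:
                lo_b = pos_b
            hi_b = pos_b
    if lo_b is None:
        return None
    return (lo_b, hi_b)


def annotate_rcl(
    query: SerpinRecord,
    reference: SerpinRecord,
    scoring: AlignScoring | None = None,
) -> SerpinRecord:
    """Transfer the reference's RCL span (and P1 index) onto the query by
    projecting through a pairwise global alignment."""
    if reference.rcl_span is None:
        raise InputError(f"reference {reference.seq_id!r} has no rcl_span")
    aln = global_align(reference.residues, query.residues, scoring)
    span = project_span(aln, reference.rcl_span)
    if span is None:
        raise InputError(
            f"RCL of {reference.seq_id!r} aligns to gaps only in {query.seq_id!r}"
        )
    p1 = None
    if reference.p1_index is not None:
        projected = project_span(aln, (reference.p1_index, reference.p1_index))
        if projected is not None and span[0] <= projected[0] <= span[1]:
            p1 = projected[0]
    return query.replace(rcl_span=span, p1_index=p1)


def find_hinge(
    residues: str,
    window: int = 4,
    alphabet: str = "GASV",
    search_span: tuple[int, int] | None = None,
) -> tuple[int, int] | None:
    """First run of >= ``window`` consecutive small residues (G/A/S/V),
    the sequence signature of an inhibitory-serpin hinge.

    Returns the full run as a 1-based inclusive span, or None.
    """
    lo, hi = search_span or (1, len(residues))
    small = set(alphabet)
    run_start = None
    best = None
    for idx in range(lo, hi + 1):
        if residues[idx - 1] in small:
            if run_start is None:
                run_start = idx
            if idx - run_start + 1 >= window and best is None:
                best = run_start
        else:
            if best is not None:
                return (best, idx - 1)
            run_start = None
    if best is not None:
        return (best, hi)
    return None
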