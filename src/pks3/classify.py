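"""Type III PKS candidacy validation and ASCL/ORS class assignment.

A query is a type III PKS candidate if it carries the catalytic
Cys-His-Asn triad at reference-homologous positions and the (G/A)FGPG
signature motif. Class membership (ASCL vs ORS vs other) is decided by
class-diagnostic residues read off the query after transferring the
reference numbering through a pairwise global alignment — ASCL sites on
the ASCL reference alignment, ORS sites on the ORS reference alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import AlignmentError, EmptyInputError, NoDomainError
from .io import ReferenceProfile, SequenceRecord

#: Sentinel returned by :func:`map_position` when a reference position
#: aligns to a gap in the query.
GAP = "gap"


@dataclass(frozen=True)
class ScoringConfig:
    """Pairwise-alignment scoring: substitution matrix plus affine gaps."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0   # cost of the first residue of a gap
    gap_extend: float = 1.0  # cost of each further gap residue


DEFAULT_SCORING = ScoringConfig()


def _make_aligner(scoring: ScoringConfig, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    aligner.mode = mode
    return aligner


@dataclass
class PairwiseAlignment:
    """A global alignment of a query against a reference, with the
    position mapping used for numbering transfer.

    ``ref_to_query`` maps 1-based reference positions to 1-based query
    positions; reference positions facing a query gap are absent.
    """

    ref_id: str
    query_id: str
    aligned_ref: str
    aligned_query: str
    score: float
    ref_to_query: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_query):
            raise AlignmentError("aligned rows differ in length")

    @property
    def ref_length(self) -> int:
        return len(self.aligned_ref) - self.aligned_ref.count("-")


def _mapping_from_rows(aligned_ref: str, aligned_query: str) -> dict[int, int]:
    mapping: dict[int, int] = {}
    r = q = 0
    for cr, cq in zip(aligned_ref, aligned_query):
        if cr != "-":
            r += 1
        if cq != "-":
            q += 1
        if cr != "-" and cq != "-":
            mapping[r] = q
    return mapping


def align_to_reference(
    query: SequenceRecord,
    profile: ReferenceProfile,
    scoring: ScoringConfig = DEFAULT_SCORING,
) -> PairwiseAlignment:
    """Optimal global alignment of ``query`` against ``profile.record``.

    Deterministic: of the co-optimal alignments the aligner's first
    enumeration order is used.
    """
    if not query.residues or not profile.record.residues:
        raise EmptyInputError("cannot align empty sequences")
    aligner = _make_aligner(scoring, "global")
    alignments = aligner.align(profile.record.residues, query.residues)
    best = alignments[0]
    aligned_ref, aligned_query = str(best[0]), str(best[1])
    return PairwiseAlignment(
        ref_id=profile.name,
        query_id=query.id,
        aligned_ref=aligned_ref,
        aligned_query=aligned_query,
        score=float(best.score),
        ref_to_query=_mapping_from_rows(aligned_ref, aligned_query),
    )


def map_position(alignment: PairwiseAlignment, ref_pos: int) -> int | str:
    """Transfer a 1-based reference position to the query through the alignment.

    Returns the 1-based query position, or the string ``"gap"`` when the
    reference column faces a gap in the query.
    """
    if not 1 <= ref_pos <= alignment.ref_length:
        raise ValueError(
            f"reference position {ref_pos} out of range 1..{alignment.ref_length}"
        )
    return alignment.ref_to_query.get(ref_pos, GAP)


def find_signature_motif(
    residues: str,
    pattern: Sequence[frozenset[str]] = (
        frozenset("GA"), frozenset("F"), frozenset("G"), frozenset("P"), frozenset("G"),
    ),
) -> list[int]:
    """All 1-based start positions of the signature motif; overlaps allowed.

    Default pattern is the type III PKS signature (G/A)FGPG.
    """
    k = len(pattern)
    hits = []
    for start in range(len(residues) - k + 1):
        if all(residues[start + i] in pattern[i] for i in range(k)):
            hits.append(start + 1)
    return hits


@dataclass(frozen=True)
class SiteEvidence:
    """Observed evidence at one annotated reference position."""

    ref_position: int
    required: str               # residue(s) required, joined for display
    query_position: int | str   # 1-based query position or "gap"
    observed: str               # query residue or "-" at a gap
    satisfied: bool


@dataclass
class TriadEvidence:
    sites: tuple[SiteEvidence, ...]
    ok: bool


def check_triad(
    query: SequenceRecord,
    profile: ReferenceProfile,
    alignment: PairwiseAlignment,
) -> TriadEvidence:
    """Check the catalytic Cys-His-Asn triad at reference-mapped positions.

    A position mapped to a gap, or an X in the query, counts as unsatisfied.
    """
    sites = []
    for site in profile.triad_positions:
        qpos = map_position(alignment, site.position)
        if qpos == GAP:
            observed, ok = "-", False
        else:
            observed = query.residues[qpos - 1]
            ok = observed == site.required
        sites.append(SiteEvidence(site.position, site.required, qpos, observed, ok))
    return TriadEvidence(sites=tuple(sites), ok=bool(sites) and all(s.satisfied for s in sites))


def check_diagnostics(
    query: SequenceRecord,
    profile: ReferenceProfile,
    alignment: PairwiseAlignment,
    class_tag: str,
) -> tuple[tuple[SiteEvidence, ...], bool]:
    """Evaluate one class's diagnostic residues on the class-profile alignment."""
    sites = []
    for site in profile.diagnostics_for(class_tag):
        qpos = map_position(alignment, site.position)
        if qpos == GAP:
            observed, ok = "-", False
        else:
            observed = query.residues[qpos - 1]
            ok = observed in site.allowed
        sites.append(
            SiteEvidence(
                site.position, "".join(sorted(site.allowed)), qpos, observed, ok
            )
        )
    return tuple(sites), bool(sites) and all(s.satisfied for s in sites)


@dataclass
class ClassificationResult:
    """Per-sequence evidence and final class label.

    ``label`` is one of ASCL, ORS, other_PKSIII, not_PKSIII, ambiguous:
    not_PKSIII when the triad fails or the motif is absent (or no usable
    alignment exists); ASCL/ORS when exactly one full diagnostic set is
    satisfied; ambiguous when both are; other_PKSIII otherwise.
    """

    query_id: str
    best_reference: str
    triad: TriadEvidence
    motif_hits: list[int]
    diagnostic_evidence: dict[str, tuple[SiteEvidence, ...]]
    label: str
    note: str = ""

    @property
    def triad_ok(self) -> bool:
        return self.triad.ok


def classify_sequence(
    query: SequenceRecord,
    profiles: Sequence[ReferenceProfile],
    scoring: ScoringConfig = DEFAULT_SCORING,
    min_alignment_score: float = 0.0,
) -> ClassificationResult:
    """Validate candidacy and assign a class label to one query.

    The triad is checked against the best-scoring profile alignment; each
    class's diagnostic residues are read through the alignment to that
    class's own profile (the reference whose numbering defines them).
    """
    if not profiles:
        raise ValueError("no reference profiles supplied")
    alignments = {p.name: align_to_reference(query, p, scoring) for p in profiles}
    by_class = {p.class_tag: p for p in profiles}
    best_profile = max(profiles, key=lambda p: alignments[p.name].score)
    best_aln = alignments[best_profile.name]

    motif_hits: list[int] = []
    for p in profiles:
        if p.motif_pattern:
            motif_hits = find_signature_motif(query.residues, p.motif_pattern)
            break

    if best_aln.score < min_alignment_score:
        return ClassificationResult(
            query_id=query.id,
            best_reference=best_profile.name,
            triad=TriadEvidence(sites=(), ok=False),
            motif_hits=motif_hits,
            diagnostic_evidence={},
            label="not_PKSIII",
            note="no usable alignment to any reference profile",
        )

    triad = check_triad(query, best_profile, best_aln)

    evidence: dict[str, tuple[SiteEvidence, ...]] = {}
    satisfied: dict[str, bool] = {}
    for class_tag in ("ASCL", "ORS"):
        profile = by_class.get(class_tag)
        if profile is None or not profile.diagnostics_for(class_tag):
            continue
        sites, ok = check_diagnostics(query, profile, alignments[profile.name], class_tag)
        evidence[class_tag] = sites
        satisfied[class_tag] = ok

    if not triad.ok or not motif_hits:
        label = "not_PKSIII"
    elif satisfied.get("ASCL") and satisfied.get("ORS"):
        label = "ambiguous"
    elif satisfied.get("ASCL"):
        label = "ASCL"
    elif satisfied.get("ORS"):
        label = "ORS"
    else:
        label = "other_PKSIII"

    return ClassificationResult(
        query_id=query.id,
        best_reference=best_profile.name,
        triad=triad,
        motif_hits=motif_hits,
        diagnostic_evidence=evidence,
        label=label,
    )


def classify_all(
    queries: Sequence[SequenceRecord],
    profiles: Sequence[ReferenceProfile],
    scoring: ScoringConfig = DEFAULT_SCORING,
    min_alignment_score: float = 0.0,
) -> list[ClassificationResult]:
    return [
        classify_sequence(q, profiles, scoring, min_alignment_score) for q in queries
    ]


def extract_pks_domain(
    fusion: SequenceRecord,
    profile: ReferenceProfile,
    scoring: ScoringConfig = DEFAULT_SCORING,
    margin: int = 20,
    score_floor: float = 100.0,
) -> SequenceRecord:
    """Extract the type III PKS domain from a fusion protein.

    The contiguous query segment covered by the best local alignment to the
    reference is returned, padded by ``margin`` residues each side and
    clipped to the sequence bounds; the id is suffixed ``|pksdomain``.
    Raises :class:`NoDomainError` when the best local score is below
    ``score_floor``.
    """
    if not fusion.residues:
        raise EmptyInputError("cannot extract a domain from an empty sequence")
    aligner = _make_aligner(scoring, "local")
    score = aligner.score(profile.record.residues, fusion.residues)
    if score < score_floor:
        raise NoDomainError(
            f"no PKS domain found in {fusion.id!r} "
            f"(best local score {score} below floor {score_floor})"
        )
    best = aligner.align(profile.record.residues, fusion.residues)[0]
    qblocks = best.aligned[1]  # aligned segments in query coordinates (0-based)
    qstart = int(qblocks[0][0])
    qend = int(qblocks[-1][1])
    start = max(0, qstart - margin)
    end = min(len(fusion.residues), qend + margin)
    return replace(
        fusion,
        id=f"{fusion.id}|pksdomain",
        residues=fusion.residues[start:end],
        is_fusion=False,
        description=(fusion.description + f" [pks domain {start + 1}-{end}]").strip(),
    )
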