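"""Sequence, reference-profile and taxon-table I/O.

Core data model for the pipeline: protein sequence records, annotated
reference profiles (catalytic triad, signature motif, class-diagnostic
residues) and taxon metadata tables. All positions exposed here are
1-based and inclusive, matching the residue-numbering convention of the
reference sequences (e.g. "Gly225" names the 225th residue).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import (
    AnnotationError,
    DuplicateIdError,
    EmptyInputError,
    InvalidResidueError,
)

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: X is accepted in query sequences but never satisfies a residue requirement.
QUERY_ALPHABET = AMINO_ACIDS | {"X"}

LINEAGE_GROUPS = (
    "bryophyte",
    "other_embryophyte",
    "charophyte",
    "other_alga",
    "cyanobacterium",
    "unknown",
)

#: Map from taxonomy strings as they appear in metadata tables (first token
#: of the lineage column) to the coarse lineage groups the census uses.
LINEAGE_SYNONYMS = {
    "bryophyta": "bryophyte",
    "marchantiophyta": "bryophyte",
    "anthocerotophyta": "bryophyte",
    "bryophyte": "bryophyte",
    "charophyta": "charophyte",
    "charophyte": "charophyte",
    "chlorophyta": "other_alga",
    "ochrophyta": "other_alga",
    "sar": "other_alga",
    "rhodophyta": "other_alga",
    "other_alga": "other_alga",
    "alga": "other_alga",
    "cyanobacteria": "cyanobacterium",
    "cyanobacterium": "cyanobacterium",
    "lycopodiophyta": "other_embryophyte",
    "polypodiopsida": "other_embryophyte",
    "gymnosperms": "other_embryophyte",
    "eudicots": "other_embryophyte",
    "monocots": "other_embryophyte",
    "tracheophyte": "other_embryophyte",
    "other_embryophyte": "other_embryophyte",
    "embryophyte": "other_embryophyte",
    "unknown": "unknown",
}

CLASS_LABELS = ("ASCL", "ORS", "other_PKSIII", "not_PKSIII", "ambiguous")


@dataclass
class SequenceRecord:
    """One protein sequence with optional taxon metadata.

    ``residues`` is validated on construction: non-empty, upper case and
    restricted to the 20 amino-acid letters plus X (no gap characters —
    unaligned records only).
    """

    id: str
    residues: str
    species: str = ""
    lineage_group: str = "unknown"
    is_fusion: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be non-empty and whitespace-free: {self.id!r}")
        self.residues = self.residues.upper()
        if not self.residues:
            raise EmptyInputError(f"sequence {self.id!r} has no residues")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in QUERY_ALPHABET:
                raise InvalidResidueError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )
        if self.lineage_group not in LINEAGE_GROUPS:
            raise ValueError(f"unknown lineage group {self.lineage_group!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DiagnosticSite:
    """One class-diagnostic residue requirement at a reference position."""

    position: int            # 1-based on the reference sequence
    allowed: frozenset[str]  # residues satisfying the site
    class_tag: str           # class this site diagnoses (ASCL / ORS / ...)


@dataclass(frozen=True)
class TriadSite:
    """One catalytic-triad requirement (Cys, His or Asn) at a reference position."""

    position: int
    required: str


@dataclass
class ReferenceProfile:
    """Annotated reference sequence used for numbering transfer.

    ``motif_pattern`` is a tuple of per-position allowed residue sets for
    the 5-residue signature, default ({G,A}, {F}, {G}, {P}, {G}).
    """

    name: str
    record: SequenceRecord
    class_tag: str = "other_PKSIII"
    triad_positions: tuple[TriadSite, ...] = ()
    motif_pattern: tuple[frozenset[str], ...] = (
        frozenset("GA"), frozenset("F"), frozenset("G"), frozenset("P"), frozenset("G"),
    )
    diagnostic_positions: tuple[DiagnosticSite, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check position ranges and reference self-consistency."""
        n = len(self.record)
        seq = self.record.residues
        for site in self.triad_positions:
            if not 1 <= site.position <= n:
                raise AnnotationError(
                    f"profile {self.name!r}: triad position {site.position} beyond "
                    f"sequence length {n}"
                )
            if seq[site.position - 1] != site.required:
                raise AnnotationError(
                    f"profile {self.name!r}: reference has {seq[site.position - 1]!r} at "
                    f"annotated triad position {site.position}, expected {site.required!r}"
                )
        for site in self.diagnostic_positions:
            if not 1 <= site.position <= n:
                raise AnnotationError(
                    f"profile {self.name!r}: diagnostic position {site.position} beyond "
                    f"sequence length {n}"
                )
            if seq[site.position - 1] not in site.allowed:
                raise AnnotationError(
                    f"profile {self.name!r}: reference residue "
                    f"{seq[site.position - 1]!r} at position {site.position} violates "
                    f"allowed set {sorted(site.allowed)}"
                )

    def diagnostics_for(self, class_tag: str) -> tuple[DiagnosticSite, ...]:
        return tuple(s for s in self.diagnostic_positions if s.class_tag == class_tag)


@dataclass(frozen=True)
class TaxonInfo:
    species: str
    lineage_group: str
    expected_class: str | None = None


@dataclass
class TaxonTable:
    """Map from sequence id to species / lineage / optional expected class."""

    entries: dict[str, TaxonInfo] = field(default_factory=dict)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.entries

    def __getitem__(self, seq_id: str) -> TaxonInfo:
        return self.entries[seq_id]

    def __len__(self) -> int:
        return len(self.entries)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read protein sequences from a FASTA file.

    The first whitespace-delimited token of each defline is the record id;
    the remainder is kept as free-text description. Residues are upper-cased
    and validated against the amino-acid alphabet (X allowed).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq),
                description=desc,
                is_fusion="[fusion]" in desc,
            )
        )
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA, preserving ids and descriptions."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(Path(path)), "fasta")


def _parse_allowed(token: str) -> frozenset[str]:
    """Parse an allowed-residue set: either 'G' or '[AV]'."""
    token = token.strip()
    if token.startswith("[") and token.endswith("]"):
        token = token[1:-1]
    if not token or not set(token) <= AMINO_ACIDS:
        raise AnnotationError(f"invalid allowed-residue set {token!r}")
    return frozenset(token)


def _parse_motif(text: str) -> tuple[frozenset[str], ...]:
    """Parse a motif pattern like '[GA]FGPG' into per-position allowed sets."""
    sets: list[frozenset[str]] = []
    i = 0
    while i < len(text):
        if text[i] == "[":
            j = text.index("]", i)
            sets.append(_parse_allowed(text[i : j + 1]))
            i = j + 1
        else:
            sets.append(_parse_allowed(text[i]))
            i += 1
    if not sets:
        raise AnnotationError("empty motif pattern")
    return tuple(sets)


def _motif_to_text(pattern: tuple[frozenset[str], ...]) -> str:
    out = []
    for allowed in pattern:
        residues = "".join(sorted(allowed))
        out.append(residues if len(residues) == 1 else f"[{residues}]")
    return "".join(out)


def load_reference_profiles(
    fasta_path: str | Path, annotation_path: str | Path
) -> list[ReferenceProfile]:
    """Load annotated reference profiles from FASTA + tab-separated annotations.

    The annotation table has a header row with columns
    ``name, class, triad, motif, diagnostics``:

    * ``triad`` — comma-separated ``position:residue`` entries, e.g.
      ``170:C,305:H,338:N`` (empty allowed for unannotated scaffolds);
    * ``motif`` — pattern such as ``[GA]FGPG``;
    * ``diagnostics`` — semicolon-separated ``position:allowed:class`` entries,
      e.g. ``225:G:ASCL;240:[AV]:ASCL``.

    Every profile is validated for self-consistency: the reference's own
    residues must satisfy every annotation (guarding against numbering drift).
    """
    records = {r.id: r for r in read_fasta(fasta_path)}
    profiles: list[ReferenceProfile] = []
    with open(annotation_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name", "class", "triad", "motif", "diagnostics"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise AnnotationError(
                f"annotation table must have columns {sorted(required)}"
            )
        for row in reader:
            name = row["name"].strip()
            if name not in records:
                raise AnnotationError(f"profile {name!r} has no sequence in {fasta_path}")
            triad: list[TriadSite] = []
            if row["triad"].strip():
                for part in row["triad"].split(","):
                    pos_s, res = part.strip().split(":")
                    triad.append(TriadSite(position=int(pos_s), required=res.strip()))
            diagnostics: list[DiagnosticSite] = []
            if row["diagnostics"].strip():
                for part in row["diagnostics"].split(";"):
                    pos_s, allowed_s, cls = (p.strip() for p in part.split(":"))
                    diagnostics.append(
                        DiagnosticSite(int(pos_s), _parse_allowed(allowed_s), cls)
                    )
            motif = _parse_motif(row["motif"].strip()) if row["motif"].strip() else ()
            profiles.append(
                ReferenceProfile(
                    name=name,
                    record=records[name],
                    class_tag=row["class"].strip(),
                    triad_positions=tuple(triad),
                    motif_pattern=motif,
                    diagnostic_positions=tuple(diagnostics),
                )
            )
    if not profiles:
        raise EmptyInputError(f"no profiles in {annotation_path}")
    return profiles


def write_reference_profiles(
    profiles: Sequence[ReferenceProfile],
    fasta_path: str | Path,
    annotation_path: str | Path,
) -> None:
    """Serialise profiles to the FASTA + annotation-table format."""
    write_fasta([p.record for p in profiles], fasta_path)
    with open(annotation_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["name", "class", "triad", "motif", "diagnostics"])
        for p in profiles:
            triad = ",".join(f"{s.position}:{s.required}" for s in p.triad_positions)
            motif = _motif_to_text(p.motif_pattern) if p.motif_pattern else ""
            diags = ";".join(
                f"{s.position}:{_set_text(s.allowed)}:{s.class_tag}"
                for s in p.diagnostic_positions
            )
            writer.writerow([p.name, p.class_tag, triad, motif, diags])


def _set_text(allowed: frozenset[str]) -> str:
    residues = "".join(sorted(allowed))
    return residues if len(residues) == 1 else f"[{residues}]"


def load_default_profiles() -> list[ReferenceProfile]:
    """Load the packaged reference profiles.

    These are synthetic stand-ins for the PpASCL / PpORS / generic type III
    PKS references: randomly generated scaffolds carrying the catalytic
    Cys-His-Asn triad, the (G/A)FGPG signature and the published diagnostic
    positions (Gly225, Ala/Val240 for ASCL; Gln218, Val/Ala277, Ala286 for
    ORS) at their published coordinates. To reproduce results on real data,
    supply profiles built from the actual reference sequences instead.
    """
    data = resources.files("pks3") / "data"
    with resources.as_file(data / "synthetic_references.fasta") as fp, resources.as_file(
        data / "synthetic_references.tsv"
    ) as ap:
        return load_reference_profiles(fp, ap)


def normalize_lineage(text: str) -> str:
    """Map a free-text lineage string to a coarse lineage group.

    Only the first comma- or whitespace-delimited token is considered, so
    strings like ``"Ochrophyta, Ochromonadales"`` resolve via the synonym map.
    Unrecognised strings map to ``unknown`` with a logged warning.
    """
    token = text.replace(",", " ").split()
    key = token[0].lower() if token else ""
    if key in LINEAGE_SYNONYMS:
        return LINEAGE_SYNONYMS[key]
    logger.warning("unrecognised lineage %r mapped to 'unknown'", text)
    return "unknown"


def read_taxon_table(path: str | Path) -> TaxonTable:
    """Read a tab-separated taxon table with header id/species/lineage_group[/expected_class]."""
    entries: dict[str, TaxonInfo] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise EmptyInputError(f"empty taxon table {path}")
        cols = [c.strip() for c in reader.fieldnames]
        if "id" not in cols or "species" not in cols or "lineage_group" not in cols:
            raise AnnotationError(
                f"taxon table {path} must have columns id, species, lineage_group"
            )
        for row in reader:
            seq_id = row["id"].strip()
            if seq_id in entries:
                raise DuplicateIdError(f"duplicate id {seq_id!r} in taxon table {path}")
            expected = (row.get("expected_class") or "").strip() or None
            if expected is not None and expected not in CLASS_LABELS:
                raise AnnotationError(
                    f"taxon table {path}: unknown expected_class {expected!r} for {seq_id!r}"
                )
            entries[seq_id] = TaxonInfo(
                species=row["species"].strip(),
                lineage_group=normalize_lineage(row["lineage_group"].strip()),
                expected_class=expected,
            )
    return TaxonTable(entries=entries)


def write_taxon_table(table: TaxonTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "species", "lineage_group", "expected_class"])
        for seq_id, info in table.entries.items():
            writer.writerow(
                [seq_id, info.species, info.lineage_group, info.expected_class or ""]
            )


def attach_metadata(
    records: Sequence[SequenceRecord], table: TaxonTable
) -> list[SequenceRecord]:
    """Return copies of ``records`` with species/lineage filled from ``table``."""
    out = []
    for rec in records:
        if rec.id in table:
            info = table[rec.id]
            out.append(replace(rec, species=info.species, lineage_group=info.lineage_group))
        else:
            out.append(rec)
    return out
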