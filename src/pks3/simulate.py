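"""Synthetic type III PKS families with known truth labels.

Generates protein families that carry (or lack) the catalytic Cys-His-Asn
triad, the (G/A)FGPG signature and class-diagnostic residues at annotated
reference positions, diverged along random trees under the JTT model with
optional indels. Every stage of the pipeline can be exercised on these
families without any external data; truth labels, generating trees and
post-indel planted coordinates are recorded alongside.

Default layout (400-residue scaffold, 1-based): triad C170/H305/N338,
signature GFGPG at 370, ASCL diagnostics Gly225 + Ala240, ORS diagnostics
Gln218 + Val277 + Ala286 — the published diagnostic numbering of the
PpASCL/PpORS references re-used on a synthetic backbone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from . import jtt
from .errors import AnnotationError
from .io import (
    DiagnosticSite,
    ReferenceProfile,
    SequenceRecord,
    TaxonInfo,
    TaxonTable,
    TriadSite,
    write_fasta,
    write_reference_profiles,
    write_taxon_table,
)
from .phylo import to_newick

CLASSES = ("ASCL", "ORS", "other_PKSIII", "not_PKSIII")

#: Default planted layout (1-based positions on the scaffold).
TRIAD_LAYOUT = ((170, "C"), (305, "H"), (338, "N"))
MOTIF_START = 370
MOTIF_RESIDUES = "GFGPG"
ASCL_SITES = ((225, "G", frozenset("G")), (240, "A", frozenset("AV")))
ORS_SITES = ((218, "Q", frozenset("Q")), (277, "V", frozenset("VA")), (286, "A", frozenset("A")))
#: Residue planted at diagnostic positions of classes that must NOT satisfy
#: them; Leu is in none of the allowed sets above.
BLOCK_RESIDUE = "L"


@dataclass
class SyntheticFamilySpec:
    """Generator parameters; ``seed`` fixes all randomness."""

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"ASCL": 1, "ORS": 2, "other_PKSIII": 1, "not_PKSIII": 0}
    )
    scaffold_length: int = 400
    class_divergence: float = 0.3   # subs/site from the shared ancestral scaffold
    birth_rate: float = 1.0         # Yule rate shaping the within-class trees
    target_height: float = 0.5      # root-to-tip height, expected subs/site
    indel_rate: float = 0.01        # events per site per substitution unit
    mean_indel_length: float = 3.0
    fusion_fraction: float = 0.1    # probability a leaf gains non-PKS flanks
    flank_length_range: tuple[int, int] = (50, 200)
    preserve_diagnostics: bool = True
    include_outgroup: bool = True
    outgroup_divergence: float = 1.5
    lineages: dict[str, str] = field(
        default_factory=lambda: {
            "ASCL": "bryophyte",
            "ORS": "bryophyte",
            "other_PKSIII": "other_embryophyte",
            "not_PKSIII": "other_embryophyte",
        }
    )
    species: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scaffold_length < MOTIF_START + len(MOTIF_RESIDUES):
            raise AnnotationError(
                f"scaffold length {self.scaffold_length} too short for the planted layout"
            )
        for key, value in self.n_per_class.items():
            if key not in CLASSES:
                raise ValueError(f"unknown class {key!r}")
            if value < 0:
                raise ValueError("class counts must be >= 0")
        if self.target_height <= 0 or self.class_divergence < 0:
            raise ValueError("divergences must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated dataset."""

    classes: dict[str, str] = field(default_factory=dict)       # id -> true class
    trees: dict[str, str] = field(default_factory=dict)         # class -> newick
    planted: dict[str, dict[str, int]] = field(default_factory=dict)
    # id -> {site name -> 1-based position in the final sequence}

    def to_json(self) -> str:
        return json.dumps(
            {"classes": self.classes, "trees": self.trees, "planted": self.planted},
            indent=2,
            sort_keys=True,
        )


def _sample_background(length: int, rng: np.random.Generator) -> list[str]:
    idx = rng.choice(20, size=length, p=jtt.JTT_FREQS)
    return [jtt.AA_ORDER[i] for i in idx]


def _planted_layout(class_tag: str) -> dict[int, str]:
    """Planted residue per 1-based position for one class scaffold."""
    layout: dict[int, str] = {}
    for pos, res in TRIAD_LAYOUT:
        layout[pos] = res
    for offset, res in enumerate(MOTIF_RESIDUES):
        layout[MOTIF_START + offset] = res
    for pos, res, _allowed in ASCL_SITES:
        layout[pos] = res if class_tag == "ASCL" else BLOCK_RESIDUE
    for pos, res, _allowed in ORS_SITES:
        layout[pos] = res if class_tag == "ORS" else BLOCK_RESIDUE
    if class_tag == "not_PKSIII":
        # break candidacy: triad Cys -> Ser and signature Phe -> Ser
        layout[TRIAD_LAYOUT[0][0]] = "S"
        layout[MOTIF_START + 1] = "S"
    return layout


def _apply_layout(seq: list[str], layout: dict[int, str]) -> None:
    for pos, res in layout.items():
        seq[pos - 1] = res


def _evolve_branch(
    seq: list[str],
    positions: list[int],
    t: float,
    spec: SyntheticFamilySpec,
    rng: np.random.Generator,
    mask: bool,
) -> tuple[list[str], list[int]]:
    """Evolve one branch: JTT substitutions, then indels; ``positions`` are
    0-based planted coordinates remapped through any indels."""
    seq = list(seq)
    positions = list(positions)
    if t <= 0:
        return seq, positions
    planted = set(positions) if mask else set()

    p = jtt.transition_matrix(t)
    cum = np.cumsum(p, axis=1)
    u = rng.random(len(seq))
    for i, ch in enumerate(seq):
        if i in planted:
            continue
        old = jtt.AA_INDEX.get(ch)
        if old is None:
            continue
        seq[i] = jtt.AA_ORDER[int(np.searchsorted(cum[old], u[i]))]

    n_events = rng.poisson(spec.indel_rate * len(seq) * t)
    for _ in range(n_events):
        is_insertion = rng.random() < 0.5
        length = int(rng.geometric(1.0 / spec.mean_indel_length))
        if is_insertion:
            # an insertion between two adjacent planted residues (e.g. inside
            # the signature motif) would destroy the planted feature
            forbidden = (
                {q + 1 for q in planted if (q + 1) in planted} if mask else set()
            )
            at = None
            for _attempt in range(20):
                cand = int(rng.integers(0, len(seq) + 1))
                if cand not in forbidden:
                    at = cand
                    break
            if at is None:
                continue
            seq[at:at] = _sample_background(length, rng)
            positions = [q + length if q >= at else q for q in positions]
        else:
            if len(seq) - length < 10:
                continue
            ok = False
            for _attempt in range(20):
                at = int(rng.integers(0, len(seq) - length + 1))
                span = set(range(at, at + length))
                if not (span & planted):
                    ok = True
                    break
            if not ok:
                continue
            del seq[at : at + length]

            def _remap(q: int) -> int:
                if q >= at + length:
                    return q - length
                if q >= at:  # planted site deleted (mask off): nearest survivor
                    return min(at, len(seq) - 1)
                return q

            positions = [_remap(q) for q in positions]
        planted = set(positions) if mask else set()
    return seq, positions


def random_tree(
    ids: Sequence[str],
    height: float,
    rng: np.random.Generator,
    birth_rate: float = 1.0,
    min_internal_branch: float | None = None,
) -> dendropy.Tree:
    """Yule tree over ``ids``, scaled to root-to-tip ``height``.

    Internal edges are floored at ``min_internal_branch`` (default one fifth
    of the height) so that the simulated topology is identifiable: an
    internal edge much shorter than the sampling noise of pairwise distance
    estimates carries no recoverable signal, and a topology-recovery test
    against such a tree would measure the resolvability of the random tree
    rather than the correctness of the inference. The default floor comes
    from a pilot power analysis (see the methods note). The tree is
    therefore only approximately ultrametric.
    """
    tns = dendropy.TaxonNamespace()
    if len(ids) == 1:
        node = dendropy.Node()
        node.taxon = tns.new_taxon(label=ids[0])
        node.edge.length = height
        root = dendropy.Node()
        root.add_child(node)
        tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
        tree.is_rooted = True
        return tree

    depths = {0: 0.0}
    children: dict[int, list[int]] = {}
    active = [0]
    next_id = 1
    now = 0.0
    while len(active) < len(ids):
        now += rng.exponential(1.0 / (birth_rate * len(active)))
        split = active[int(rng.integers(0, len(active)))]
        left, right = next_id, next_id + 1
        next_id += 2
        depths[left] = depths[right] = now
        children[split] = [left, right]
        active.remove(split)
        active.extend([left, right])
    total = now + rng.exponential(1.0 / (birth_rate * len(active)))
    scale = height / total if total > 0 else 1.0

    leaf_ids = iter(sorted(ids))
    nodes: dict[int, dendropy.Node] = {}

    def build(k: int) -> dendropy.Node:
        node = dendropy.Node()
        nodes[k] = node
        if k in children:
            for c in children[k]:
                child = build(c)
                child.edge.length = (
                    (depths[c] if c in children else total) - depths[k]
                ) * scale
                node.add_child(child)
        else:
            node.taxon = tns.new_taxon(label=next(leaf_ids))
        return node

    root = build(0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    floor = height / 5.0 if min_internal_branch is None else min_internal_branch
    for edge in tree.preorder_edge_iter():
        if (
            edge.tail_node is not None
            and not edge.head_node.is_leaf()
            and edge.length is not None
            and edge.length < floor
        ):
            edge.length = floor
    return tree


#: Names of the planted sites, for the truth record.
SITE_NAMES = (
    ["triad_C", "triad_H", "triad_N"]
    + [f"motif_{i + 1}" for i in range(len(MOTIF_RESIDUES))]
    + [f"ASCL_{pos}" for pos, _, _ in ASCL_SITES]
    + [f"ORS_{pos}" for pos, _, _ in ORS_SITES]
)


def _site_positions() -> list[int]:
    """0-based planted coordinates in SITE_NAMES order."""
    pos = [p - 1 for p, _ in TRIAD_LAYOUT]
    pos += [MOTIF_START - 1 + i for i in range(len(MOTIF_RESIDUES))]
    pos += [p - 1 for p, _, _ in ASCL_SITES]
    pos += [p - 1 for p, _, _ in ORS_SITES]
    return pos


def make_reference_scaffold(
    spec: SyntheticFamilySpec, seed: int | None = None
) -> dict[str, ReferenceProfile]:
    """One annotated reference profile per class, sharing a common ancestral
    background so cross-class alignments are meaningful.

    The ASCL/ORS/other profiles pass self-consistency; the not_PKSIII
    scaffold carries no annotations (it is a decoy, not a reference).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    base = _sample_background(spec.scaffold_length, rng)
    planted0 = _site_positions()

    profiles: dict[str, ReferenceProfile] = {}
    scaffold_spec = replace(spec, indel_rate=0.0)  # keep the base coordinate frame
    for class_tag in CLASSES:
        seq, _ = _evolve_branch(
            base, planted0, spec.class_divergence, scaffold_spec, rng, mask=True
        )
        _apply_layout(seq, _planted_layout(class_tag))
        record = SequenceRecord(
            id=f"{class_tag}_ref",
            residues="".join(seq),
            species=f"Synthetic {class_tag} reference",
        )
        if class_tag == "not_PKSIII":
            profiles[class_tag] = ReferenceProfile(
                name=record.id, record=record, class_tag=class_tag,
                triad_positions=(), motif_pattern=(), diagnostic_positions=(),
            )
            continue
        diagnostics: list[DiagnosticSite] = []
        if class_tag == "ASCL":
            diagnostics = [DiagnosticSite(p, allowed, "ASCL") for p, _, allowed in ASCL_SITES]
        elif class_tag == "ORS":
            diagnostics = [DiagnosticSite(p, allowed, "ORS") for p, _, allowed in ORS_SITES]
        profiles[class_tag] = ReferenceProfile(
            name=record.id,
            record=record,
            class_tag=class_tag,
            triad_positions=tuple(TriadSite(p, r) for p, r in TRIAD_LAYOUT),
            diagnostic_positions=tuple(diagnostics),
        )
    return profiles


def evolve_family(
    profile: ReferenceProfile,
    tree: dendropy.Tree,
    spec: SyntheticFamilySpec,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Evolve the profile's sequence along ``tree`` under JTT (+ indels).

    Planted positions are held invariant when ``spec.preserve_diagnostics``;
    the truth records their final (1-based) coordinates per leaf.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    root_seq = list(profile.record.residues)
    root_positions = _site_positions()

    truth = SyntheticTruth()
    records: list[SequenceRecord] = []

    state = {id(tree.seed_node): (root_seq, root_positions)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq, parent_pos = state[id(node.parent_node)]
        seq, pos = _evolve_branch(
            parent_seq, parent_pos, node.edge.length or 0.0, spec, rng,
            mask=spec.preserve_diagnostics,
        )
        state[id(node)] = (seq, pos)
        if node.is_leaf():
            label = node.taxon.label
            records.append(
                SequenceRecord(
                    id=label,
                    residues="".join(seq),
                    species=f"Synthetic {profile.class_tag}",
                )
            )
            truth.classes[label] = profile.class_tag
            truth.planted[label] = {
                name: p + 1 for name, p in zip(SITE_NAMES, pos)
            }
    truth.trees[profile.class_tag] = to_newick(tree)
    return records, truth


@dataclass
class SyntheticDataset:
    records: list[SequenceRecord]
    taxa: TaxonTable
    profiles: dict[str, ReferenceProfile]
    truth: SyntheticTruth


def _add_fusion_flanks(
    record: SequenceRecord,
    truth: SyntheticTruth,
    spec: SyntheticFamilySpec,
    rng: np.random.Generator,
) -> SequenceRecord:
    lo, hi = spec.flank_length_range
    n_len = int(rng.integers(lo, hi + 1))
    c_len = int(rng.integers(lo, hi + 1))
    n_flank = "".join(_sample_background(n_len, rng))
    c_flank = "".join(_sample_background(c_len, rng))
    truth.planted[record.id] = {
        name: p + n_len for name, p in truth.planted[record.id].items()
    }
    return replace(
        record,
        residues=n_flank + record.residues + c_flank,
        is_fusion=True,
        description=(record.description + " [fusion]").strip(),
    )


def generate_dataset(spec: SyntheticFamilySpec, outdir: str | Path | None = None) -> SyntheticDataset:
    """Generate all pipeline inputs: sequences, taxon table, reference
    profiles and a truth record; deterministic under ``spec.seed``.

    When ``outdir`` is given, writes ``sequences.fasta``, ``taxa.tsv``,
    ``references.fasta``/``references.tsv`` and ``truth.json`` there.
    """
    rng = np.random.default_rng(spec.seed)
    profiles = make_reference_scaffold(spec, seed=int(rng.integers(2**31)))

    records: list[SequenceRecord] = []
    taxa = TaxonTable()
    truth = SyntheticTruth()

    for class_tag in CLASSES:
        n = spec.n_per_class.get(class_tag, 0)
        if n == 0:
            continue
        ids = [f"{class_tag}_{i + 1}" for i in range(n)]
        tree = random_tree(
            ids, spec.target_height, rng, birth_rate=spec.birth_rate
        )
        fam_records, fam_truth = evolve_family(
            profiles[class_tag], tree, spec, seed=int(rng.integers(2**31))
        )
        truth.classes.update(fam_truth.classes)
        truth.planted.update(fam_truth.planted)
        truth.trees.update(fam_truth.trees)
        for rec in fam_records:
            if rng.random() < spec.fusion_fraction:
                rec = _add_fusion_flanks(rec, truth, spec, rng)
            records.append(rec)
            taxa.entries[rec.id] = TaxonInfo(
                species=rec.species,
                lineage_group=spec.lineages.get(class_tag, "unknown"),
                expected_class=class_tag,
            )

    if spec.include_outgroup and records:
        og_tree = random_tree(["outgroup"], spec.outgroup_divergence, rng)
        og_records, og_truth = evolve_family(
            profiles["other_PKSIII"], og_tree, spec, seed=int(rng.integers(2**31))
        )
        og = replace(og_records[0], species="Synthetic cyanobacterium")
        records.append(og)
        truth.classes["outgroup"] = "other_PKSIII"
        truth.planted["outgroup"] = og_truth.planted["outgroup"]
        taxa.entries["outgroup"] = TaxonInfo(
            species=og.species, lineage_group="cyanobacterium",
            expected_class="other_PKSIII",
        )

    dataset = SyntheticDataset(records=records, taxa=taxa, profiles=profiles, truth=truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, outdir / "sequences.fasta")
        write_taxon_table(taxa, outdir / "taxa.tsv")
        write_reference_profiles(
            [profiles[c] for c in ("ASCL", "ORS", "other_PKSIII")],
            outdir / "references.fasta",
            outdir / "references.tsv",
        )
        (outdir / "truth.json").write_text(truth.to_json())
    return dataset
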