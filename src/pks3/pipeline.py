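"""End-to-end orchestration: classify, align, tree, clades, census.

Stages compose through files in an output directory; every run writes a
human-readable log and a machine-readable manifest (config, seed, stage
timings). Identical config + seed reproduces byte-identical classification
tables and Newick output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .classify import (
    ClassificationResult,
    ScoringConfig,
    classify_all,
    extract_pks_domain,
)
from .clades import concordance_report
from .errors import Pks3Error
from .io import (
    ReferenceProfile,
    SequenceRecord,
    TaxonTable,
    attach_metadata,
    load_default_profiles,
    load_reference_profiles,
    read_fasta,
    read_taxon_table,
)
from .msa import MultipleAlignment, import_alignment, progressive_align, write_alignment
from .phylo import (
    bootstrap_support,
    build_distance_matrix,
    nni_refine,
    root_with_outgroup,
    write_newick,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, scoring and stage toggles for a full run."""

    sequences: str | Path = ""
    references_fasta: str | Path | None = None      # None -> packaged profiles
    references_table: str | Path | None = None
    alignment: str | Path | None = None             # pre-computed MSA (optional)
    taxon_table: str | Path | None = None
    outdir: str | Path = "pks3_run"
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    bootstrap: int = 1000
    seed: int = 0
    outgroup: str | None = None
    bionj: bool = False
    nni: bool = False
    skip_msa: bool = False
    skip_tree: bool = False
    support_threshold: float | None = None
    min_alignment_score: float = 0.0
    fusion_length_factor: float = 1.8  # treat sequences this many times the
    # reference length as putative fusions even without an explicit flag

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("sequences", "references_fasta", "references_table",
                    "alignment", "taxon_table", "outdir"):
            if d[key] is not None:
                d[key] = str(d[key])
        return d


def load_profiles(config: PipelineConfig) -> list[ReferenceProfile]:
    if config.references_fasta is None and config.references_table is None:
        return load_default_profiles()
    if config.references_fasta is None or config.references_table is None:
        raise Pks3Error("references not found: need both FASTA and annotation table")
    for p in (config.references_fasta, config.references_table):
        if not Path(p).exists():
            raise Pks3Error(f"references not found: {p}")
    return load_reference_profiles(config.references_fasta, config.references_table)


def resolve_fusions(
    records: Sequence[SequenceRecord],
    profiles: Sequence[ReferenceProfile],
    config: PipelineConfig,
) -> list[SequenceRecord]:
    """Replace fusion proteins by their extracted type III PKS domain.

    A record is treated as a fusion when flagged ``is_fusion`` or when it is
    longer than ``fusion_length_factor`` times the longest reference.
    """
    ref_len = max(len(p.record) for p in profiles)
    out = []
    for rec in records:
        if rec.is_fusion or len(rec) > config.fusion_length_factor * ref_len:
            best = max(
                profiles,
                key=lambda p: _local_score(rec, p, config.scoring),
            )
            extracted = extract_pks_domain(rec, best, config.scoring)
            logger.info(
                "extracted PKS domain from %s (%d -> %d aa)",
                rec.id, len(rec), len(extracted),
            )
            out.append(dataclasses.replace(extracted, id=rec.id))
        else:
            out.append(rec)
    return out


def _local_score(rec: SequenceRecord, profile: ReferenceProfile, scoring) -> float:
    from .classify import _make_aligner

    return _make_aligner(scoring, "local").score(profile.record.residues, rec.residues)


def classification_table(results: Sequence[ClassificationResult]) -> str:
    """Tab-separated per-sequence evidence report."""
    lines = [
        "id\tlabel\tbest_reference\ttriad_ok\ttriad_evidence\tmotif_hits\tdiagnostic_evidence\tnote"
    ]

    def fmt_sites(sites) -> str:
        return ";".join(
            f"{s.ref_position}:{s.required}:{s.query_position}:{s.observed}:{int(s.satisfied)}"
            for s in sites
        )

    for r in results:
        diag = "|".join(
            f"{tag}={fmt_sites(sites)}" for tag, sites in sorted(r.diagnostic_evidence.items())
        )
        lines.append(
            "\t".join(
                [
                    r.query_id,
                    r.label,
                    r.best_reference,
                    str(int(r.triad_ok)),
                    fmt_sites(r.triad.sites),
                    ",".join(str(h) for h in r.motif_hits),
                    diag,
                    r.note,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def classification_json(results: Sequence[ClassificationResult]) -> str:
    def site(s):
        return {
            "ref_position": s.ref_position,
            "required": s.required,
            "query_position": s.query_position,
            "observed": s.observed,
            "satisfied": s.satisfied,
        }

    payload = [
        {
            "id": r.query_id,
            "label": r.label,
            "best_reference": r.best_reference,
            "triad_ok": r.triad_ok,
            "triad": [site(s) for s in r.triad.sites],
            "motif_hits": r.motif_hits,
            "diagnostics": {
                tag: [site(s) for s in sites]
                for tag, sites in sorted(r.diagnostic_evidence.items())
            },
            "note": r.note,
        }
        for r in results
    ]
    return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class CensusReport:
    """Lineage x class contingency plus per-species counts."""

    by_lineage: pd.DataFrame
    by_species: pd.DataFrame

    def to_tsv(self) -> str:
        out = ["# lineage_group x label"]
        out.append(self.by_lineage.to_csv(sep="\t"))
        out.append("# species x label")
        out.append(self.by_species.to_csv(sep="\t"))
        return "\n".join(out)


def summarize_census(
    results: Sequence[ClassificationResult], taxa: TaxonTable
) -> CensusReport:
    """Contingency of lineage_group x label and species x label.

    Sequences absent from the taxon table are counted under lineage
    ``unknown`` with a logged warning.
    """
    rows = []
    for r in results:
        if r.query_id in taxa:
            info = taxa[r.query_id]
            rows.append((info.lineage_group, info.species, r.label))
        else:
            logger.warning("id %r missing from taxon table; counted as unknown", r.query_id)
            rows.append(("unknown", "unknown", r.label))
    if not rows:
        empty = pd.DataFrame()
        return CensusReport(by_lineage=empty, by_species=empty)
    df = pd.DataFrame(rows, columns=["lineage_group", "species", "label"])
    by_lineage = (
        df.pivot_table(index="lineage_group", columns="label", aggfunc="size", fill_value=0)
        .sort_index()
    )
    by_species = (
        df.pivot_table(index="species", columns="label", aggfunc="size", fill_value=0)
        .sort_index()
    )
    return CensusReport(by_lineage=by_lineage, by_species=by_species)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all configured stages; returns the output directory.

    Outputs: ``classifications.tsv``/``.json``, ``alignment.fasta``,
    ``distances.tsv``, ``tree.nwk``, ``clade_report.json``/``.tsv``,
    ``census.tsv``, ``run.log`` and ``manifest.json``. On a stage failure
    the exception propagates; outputs of completed stages remain on disk
    and the log records the failing stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("pks3")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    timings: dict[str, float] = {}
    stage = "setup"
    try:
        t0 = time.perf_counter()
        seq_path = Path(config.sequences)
        if not seq_path.exists():
            raise Pks3Error(f"sequence file not found: {seq_path}")
        records = read_fasta(seq_path)
        taxa = read_taxon_table(config.taxon_table) if config.taxon_table else TaxonTable()
        records = attach_metadata(records, taxa)
        profiles = load_profiles(config)
        timings["setup"] = time.perf_counter() - t0

        stage = "fusion-extraction"
        t0 = time.perf_counter()
        records = resolve_fusions(records, profiles, config)
        timings[stage] = time.perf_counter() - t0

        stage = "classification"
        t0 = time.perf_counter()
        results = classify_all(
            records, profiles, config.scoring, config.min_alignment_score
        )
        (outdir / "classifications.tsv").write_text(classification_table(results))
        (outdir / "classifications.json").write_text(classification_json(results))
        logger.info("classified %d sequences", len(results))
        timings[stage] = time.perf_counter() - t0

        if config.taxon_table:
            stage = "census"
            t0 = time.perf_counter()
            census = summarize_census(results, taxa)
            (outdir / "census.tsv").write_text(census.to_tsv())
            timings[stage] = time.perf_counter() - t0

        skip_tree = config.skip_tree or (config.skip_msa and not config.alignment)
        if not skip_tree:
            stage = "alignment"
            t0 = time.perf_counter()
            class_profiles = [p for p in profiles if p.class_tag in ("ASCL", "ORS", "other_PKSIII")]
            tree_records = records + [
                p.record for p in class_profiles if p.record.id not in {r.id for r in records}
            ]
            if config.alignment:
                msa = import_alignment(config.alignment)
            else:
                msa = progressive_align(tree_records)
            write_alignment(msa, outdir / "alignment.fasta")
            timings[stage] = time.perf_counter() - t0

            stage = "tree"
            t0 = time.perf_counter()
            dm = build_distance_matrix(msa)
            dm.write_phylip(outdir / "distances.tsv")
            tree = bootstrap_support(
                msa, n_reps=max(1, config.bootstrap), seed=config.seed,
                bionj=config.bionj,
            )
            if config.nni:
                support = getattr(tree, "bipartition_support", None)
                tree = nni_refine(tree, dm)
                tree.bipartition_support = support or {}
            if config.outgroup:
                tree = root_with_outgroup(tree, config.outgroup)
            write_newick(tree, outdir / "tree.nwk", config.support_threshold)
            timings[stage] = time.perf_counter() - t0

            stage = "clades"
            t0 = time.perf_counter()
            reference_labels = {p.name: p.class_tag for p in class_profiles}
            report = concordance_report(results, tree, reference_labels)
            (outdir / "clade_report.json").write_text(report.to_json())
            (outdir / "clade_report.tsv").write_text(report.to_tsv())
            timings[stage] = time.perf_counter() - t0

        stage = "manifest"
        cfg = config.to_dict()
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": cfg,
            "config_hash": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.info("run complete: %s", outdir)
        return outdir
    except Exception:
        logger.exception("pipeline failed during stage %r", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
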