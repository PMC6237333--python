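"""Pipeline orchestration: one call runs every characterization stage.

`characterize` runs architecture -> composition -> codon usage -> control
region -> tRNA folding on one annotated genome and collects the results in
a versioned, JSON-serializable report. Stages are independent: a stage that
cannot run (e.g. no sequence was provided, only a feature table) is recorded
as skipped with the reason, and the remaining stages still run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from typing import Any

from pydantic import BaseModel, Field

from . import __version__
from .architecture import characterize_architecture
from .codon_usage import (VERTEBRATE_MITO, GeneticCode, codon_usage_table,
                          extract_codons)
from .composition import (base_composition, pcg_concat_composition,
                          per_gene_composition)
from .control_region import (DEFAULT_CSB_PROFILE, find_tandem_repeats,
                             hairpin_check, scan_csb_profile)
from .io_formats import FeatureTable, GenomeRecord, extract_gene_sequence
from .trna_structure import count_gu_pairs, fold_cloverleaf

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"


class ReportConfig(BaseModel):
    """All tunable thresholds of the characterization pipeline."""

    genetic_code: int = 2
    exclude_start_codons: bool = True       # matches published RSCU tables
    motif_max_mismatch: int = 0
    repeat_min_period: int = 1
    repeat_max_period: int = 10
    repeat_min_copies: float = 2.0
    csb_profile: dict[str, tuple[str, int]] = Field(
        default_factory=lambda: dict(DEFAULT_CSB_PROFILE))
    seed: int = 0

    model_config = {"extra": "forbid"}


def _sha256(data: str) -> str:
    return hashlib.sha256(data.encode()).hexdigest()


def _skipped(reason: str) -> dict[str, str]:
    return {"skipped": reason}


def characterize(table: FeatureTable, record: GenomeRecord | None = None,
                 config: ReportConfig | None = None) -> dict[str, Any]:
    """Full characterization report as a plain JSON-serializable dict.

    ``record`` may be None (table-only mode): architecture still runs,
    sequence-dependent sections are marked skipped.
    """
    config = config or ReportConfig()
    code = GeneticCode.from_ncbi(config.genetic_code)
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "package_version": __version__,
            "config": json.loads(config.model_dump_json()),
            "genome_sha256": _sha256(record.sequence) if record else None,
            "n_features": len(table),
        },
    }

    report["architecture"] = characterize_architecture(table).to_dict()

    if record is None:
        reason = "skipped: no sequence"
        for section in ("composition", "codon", "control_region", "trna"):
            report[section] = _skipped(reason)
        return report

    # composition
    try:
        comp = {"genome": base_composition(record.sequence).rounded()}
        for scope, rep in pcg_concat_composition(record, table).items():
            comp[scope] = rep.rounded()
        comp["per_gene"] = {name: rep.rounded() for name, rep in
                            per_gene_composition(record, table).items()}
        report["composition"] = comp
    except Exception as exc:  # stage independence: record and continue
        logger.exception("composition stage failed")
        report["composition"] = _skipped(f"failed: {exc}")

    # codon usage
    try:
        codon_lists, classifications = [], {}
        for f in table.pcgs:
            cds = extract_gene_sequence(record, f)
            codons, cls = extract_codons(cds, code, gene=f.name)
            codon_lists.append(codons)
            classifications[f.name] = {
                "start_codon": cls.start_codon,
                "stop_codon": cls.stop_codon,
                "stop_complete": cls.stop_complete,
                "canonical_start": cls.canonical_start,
            }
        cut = codon_usage_table(codon_lists, code,
                                exclude_start=config.exclude_start_codons)
        report["codon"] = {
            "classification": classifications,
            "counts": cut.counts,
            "rscu": {c: (None if v is None else round(v, 4))
                     for c, v in cut.rscu.items()},
            "total_codons": sum(cut.counts.values()),
        }
    except Exception as exc:
        logger.exception("codon stage failed")
        report["codon"] = _skipped(f"failed: {exc}")

    # control region + OL
    try:
        cr_section: dict[str, Any] = {}
        crs = table.by_class("CR")
        if crs:
            cr_seq = extract_gene_sequence(record, crs[0])
            hits = scan_csb_profile(cr_seq, config.csb_profile)
            cr_section["motifs"] = {
                name: [{"position": h.position, "strand": h.strand,
                        "mismatches": h.mismatches} for h in hs]
                for name, hs in hits.items()
            }
            reps = find_tandem_repeats(cr_seq, config.repeat_min_period,
                                       config.repeat_max_period,
                                       config.repeat_min_copies)
            cr_section["tandem_repeats"] = [
                {"period": r.period, "copies": round(r.copies, 2),
                 "start": r.start, "consensus": r.consensus} for r in reps
            ]
        ols = table.by_class("OL")
        if ols:
            ol_seq = extract_gene_sequence(record, ols[0])
            hp = hairpin_check(ol_seq)
            cr_section["ol_hairpin"] = {
                "stem_length": hp.stem_length, "loop_length": hp.loop_length,
                "paired_fraction": round(hp.paired_fraction, 4),
            }
        report["control_region"] = cr_section or _skipped("no CR/OL features")
    except Exception as exc:
        logger.exception("control-region stage failed")
        report["control_region"] = _skipped(f"failed: {exc}")

    # tRNA folding
    try:
        trna_section = {}
        total_gu = 0
        for f in table.by_class("tRNA"):
            seq = extract_gene_sequence(record, f)
            try:
                model = fold_cloverleaf(seq)
            except ValueError as exc:
                trna_section[f.name] = {"foldable": False, "reason": str(exc)}
                continue
            gu = count_gu_pairs(model, seq)
            total_gu += gu
            trna_section[f.name] = {
                "foldable": True,
                "acceptor_stem": model.acceptor_stem,
                "dhu_arm": list(model.dhu_arm) if model.dhu_arm else None,
                "anticodon_arm": list(model.anticodon_arm),
                "tpsic_arm": list(model.tpsic_arm),
                "anticodon": model.anticodon,
                "gu_pairs": gu,
            }
        report["trna"] = {"per_trna": trna_section, "total_gu_pairs": total_gu}
    except Exception as exc:
        logger.exception("tRNA stage failed")
        report["trna"] = _skipped(f"failed: {exc}")

    return report


def report_json(report: dict[str, Any]) -> str:
    """Deterministic (sorted-key) JSON rendering of a report."""
    return json.dumps(report, indent=2, sort_keys=True)
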