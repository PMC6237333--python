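"""Core data model and I/O for annotated mitogenomes.

Coordinates are 1-based and inclusive everywhere inside the package, matching
the convention of published mitogenome feature tables; converters at the I/O
boundary (GenBank, FASTA) isolate other conventions. Features that wrap the
origin of the circular molecule are rejected: a typical teleost annotation
places the control-region boundary at the origin so no feature spans it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "OL", "CR")

#: canonical lowercase gene symbols, in the gene order of a typical
#: teleost mitogenome (trnF first, control region last)
CANONICAL_GENE_ORDER = (
    "trnF", "rrnS", "trnV", "rrnL", "trnL1", "nad1", "trnI", "trnQ", "trnM",
    "nad2", "trnW", "trnA", "trnN", "OL", "trnC", "trnY", "cox1", "trnS1",
    "trnD", "cox2", "trnK", "atp8", "atp6", "cox3", "trnG", "nad3", "trnR",
    "nad4l", "nad4", "trnH", "trnS2", "trnL2", "nad5", "nad6", "trnE",
    "cytb", "trnT", "trnP", "CR",
)

PCG_NAMES = ("nad1", "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
             "nad4l", "nad4", "nad5", "nad6", "cytb")

#: synonym map for GenBank qualifier spellings -> canonical symbols
GENE_SYNONYMS = {
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4l", "nd5": "nad5", "nd6": "nad6",
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "cox1": "cox1", "cox2": "cox2", "cox3": "cox3",
    "cytb": "cytb", "cob": "cytb", "atp6": "atp6", "atp8": "atp8",
    "atpase6": "atp6", "atpase8": "atp8",
    "12s rrna": "rrnS", "16s rrna": "rrnL", "rrns": "rrnS", "rrnl": "rrnL",
    "s-rrna": "rrnS", "l-rrna": "rrnL",
    "d-loop": "CR", "control region": "CR", "ol": "OL",
}

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "leu": "L", "lys": "K",
    "met": "M", "phe": "F", "pro": "P", "ser": "S", "thr": "T", "trp": "W",
    "tyr": "Y", "val": "V",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


class UnsupportedLocationError(ValueError):
    """GenBank location type (join/wrap) not supported."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A (possibly circular) DNA molecule."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Feature:
    """One annotated element: gene, tRNA, rRNA, replication origin or CR.

    ``start``/``end`` are 1-based inclusive; ``strand`` is ``H`` (heavy,
    the reference strand) or ``L`` (light, reverse complement).
    """

    name: str
    feature_class: str
    strand: str
    start: int
    end: int
    start_codon: str | None = None
    stop_codon: str | None = None
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be 'H' or 'L', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.name}: need 1 <= start <= end, got {self.start}..{self.end}"
            )
        if self.stop_codon is not None and not 1 <= len(self.stop_codon) <= 3:
            raise ValueError(f"{self.name}: stop codon length must be 1-3")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FeatureTable:
    """Ordered annotation of one circular genome (sorted by start)."""

    genome_length: int
    features: list[Feature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.end > self.genome_length:
                raise ValueError(
                    f"{f.name}: end {f.end} exceeds genome length {self.genome_length}"
                )

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_class(self, feature_class: str) -> list[Feature]:
        return [f for f in self.features if f.feature_class == feature_class]

    @property
    def pcgs(self) -> list[Feature]:
        return self.by_class("PCG")


def normalize_gene_name(raw: str) -> str:
    """Map a GenBank-style gene label to the package's canonical symbol.

    tRNA labels like ``tRNA-Asn`` or ``trnN`` become ``trnN``; unknown labels
    are returned lowercased and stripped.
    """
    token = raw.strip()
    low = token.lower()
    if low in GENE_SYNONYMS:
        return GENE_SYNONYMS[low]
    if low.startswith("trna-") or low.startswith("trna"):
        rest = low.removeprefix("trna-").removeprefix("trna").strip()
        # keep an explicit isoacceptor tag, e.g. "Leu (L1)" -> trnL1
        for tag in ("l1", "l2", "s1", "s2"):
            if tag in rest.replace(" ", "").replace("(", "").replace(")", ""):
                return "trn" + tag.upper()[0] + tag[1]
        aa = rest.split()[0][:3] if rest else ""
        if aa in _AA3_TO_1:
            return "trn" + _AA3_TO_1[aa]
        if len(rest) == 1:
            return "trn" + rest.upper()
    if low.startswith("trn") and len(token) <= 6:
        return "trn" + token[3:].upper()[0] + token[4:]
    return low if not low.startswith("trn") else token


def disambiguate_trna_duplicates(features: list[Feature]) -> list[Feature]:
    """Number duplicate tRNA names by coordinate order (trnL -> trnL1, trnL2).

    Published tables occasionally print the same serine/leucine label twice;
    when anticodons are absent the only safe rule is positional.
    """
    seen: dict[str, int] = {}
    counts: dict[str, int] = {}
    for f in features:
        if f.feature_class == "tRNA":
            counts[f.name] = counts.get(f.name, 0) + 1
    out = []
    for f in sorted(features, key=lambda x: (x.start, x.end)):
        if f.feature_class == "tRNA" and counts.get(f.name, 0) > 1:
            seen[f.name] = seen.get(f.name, 0) + 1
            out.append(replace(f, name=f"{f.name}{seen[f.name]}"))
        else:
            out.append(f)
    return out


# ---------------------------------------------------------------------------
# feature-table TSV dialect
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("feature", "class", "strand", "start", "end",
                "start_codon", "stop_codon")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read the tab-separated feature-table dialect.

    Columns: ``feature class strand start end [start_codon stop_codon]``;
    ``#`` lines are comments; pragmas ``# genome_length: N`` and
    ``# circular: true|false`` override the defaults (max end; circular).
    """
    path = Path(path)
    genome_length: int | None = None
    circular = True
    features: list[Feature] = []
    saw_any_line = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                body = line.lstrip("# ").strip()
                if body.lower().startswith("genome_length"):
                    genome_length = int(body.split(":", 1)[1].strip())
                elif body.lower().startswith("circular"):
                    circular = body.split(":", 1)[1].strip().lower() in ("true", "1", "yes")
                continue
            parts = line.split("\t")
            if parts[0].strip().lower() == "feature":  # header row
                saw_any_line = True
                continue
            saw_any_line = True
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected >= 5 tab-separated fields")
            name, fclass, strand = (p.strip() for p in parts[:3])
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if start > end:
                raise ParseError(f"{path}:{lineno}: start {start} > end {end}")
            if strand not in ("H", "L"):
                raise ParseError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            start_codon = parts[5].strip() or None if len(parts) > 5 else None
            stop_codon = parts[6].strip() or None if len(parts) > 6 else None
            try:
                features.append(Feature(name, fclass, strand, start, end,
                                        start_codon, stop_codon))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not saw_any_line or not features:
        raise ParseError(f"{path}: no feature rows found")
    if genome_length is None:
        genome_length = max(f.end for f in features)
    return FeatureTable(genome_length=genome_length, features=features,
                        circular=circular)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# genome_length: {table.genome_length}\n")
        fh.write(f"# circular: {'true' if table.circular else 'false'}\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for f in table.features:
            fh.write("\t".join([
                f.name, f.feature_class, f.strand, str(f.start), str(f.end),
                f.start_codon or "", f.stop_codon or "",
            ]).rstrip("\t") + "\n")


def reference_feature_table() -> FeatureTable:
    """The packaged H. quoyi (MG851912.1) annotation, 38 features / 16,525 bp."""
    return read_feature_table(Path(__file__).parent / "data" / "mg851912_features.tsv")


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_GB_CLASS = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "CR"}


def read_genbank(path: str | Path) -> tuple[GenomeRecord, FeatureTable]:
    """Read a GenBank flat file into the 1-based inclusive convention.

    ``complement(...)`` locations map to strand ``L``. Joined or
    origin-wrapping locations are rejected; a record without sequence raises
    with a message pointing at table-only (TSV) input instead.
    """
    path = Path(path)
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: not parseable as GenBank ({exc}); for a "
                         "table-only input use the TSV reader") from exc
    try:
        seq = str(rec.seq).upper()
    except Exception:  # undefined sequence (no ORIGIN content)
        seq = ""
    if not seq or set(seq) == {"N"}:
        raise ParseError(
            f"{path}: record has no ORIGIN sequence; use the table-only TSV reader"
        )
    circular = rec.annotations.get("topology", "circular") == "circular"
    genome = GenomeRecord(id=rec.id or rec.name, sequence=seq, circular=circular)

    features: list[Feature] = []
    n_cds = 0
    for gbf in rec.features:
        if gbf.type not in _GB_CLASS:
            continue
        loc = gbf.location
        if loc is None or len(getattr(loc, "parts", [loc])) > 1:
            raise UnsupportedLocationError(
                f"{path}: joined/wrapped location on {gbf.type} feature"
            )
        start = int(loc.start) + 1  # 0-based half-open -> 1-based inclusive
        end = int(loc.end)
        strand = "L" if loc.strand == -1 else "H"
        fclass = _GB_CLASS[gbf.type]
        if fclass == "PCG":
            n_cds += 1
        q = gbf.qualifiers
        raw_name = (q.get("gene") or q.get("product") or [gbf.type])[0]
        name = normalize_gene_name(raw_name) if fclass != "CR" else "CR"
        start_codon = stop_codon = None
        if fclass == "PCG":
            cds = seq[start - 1:end]
            if strand == "L":
                cds = reverse_complement(cds)
            start_codon = cds[:3]
            tail = len(cds) % 3 or 3
            stop_codon = cds[-tail:]
        features.append(Feature(name, fclass, strand, start, end,
                                start_codon, stop_codon))
    # misc_feature named OL
    for gbf in rec.features:
        if gbf.type == "misc_feature":
            note = " ".join(gbf.qualifiers.get("note", [])).lower()
            if "light" in note or note.strip() in ("ol", "o_l"):
                loc = gbf.location
                features.append(Feature("OL", "OL",
                                        "L" if loc.strand == -1 else "H",
                                        int(loc.start) + 1, int(loc.end)))
    if n_cds != 13:
        logger.warning("%s: expected 13 protein-coding genes, found %d", path, n_cds)
    features = disambiguate_trna_duplicates(features)
    return genome, FeatureTable(genome_length=len(seq), features=features,
                                circular=circular)


def write_genbank(record: GenomeRecord, table: FeatureTable,
                  path: str | Path) -> None:
    """Emit a minimal GenBank flat file readable by :func:`read_genbank`."""
    rec = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                    description="synthetic mitogenome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if record.circular else "linear"
    type_map = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop",
                "OL": "misc_feature"}
    for f in table.features:
        loc = SimpleLocation(f.start - 1, f.end, strand=-1 if f.strand == "L" else 1)
        quals = {"gene": [f.name]}
        if f.feature_class == "OL":
            quals = {"note": ["origin of light-strand replication; OL"]}
        rec.features.append(SeqFeature(loc, type=type_map[f.feature_class],
                                       qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {id: uppercase sequence} mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ParseError(f"{path}: no FASTA records")
    return out


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]],
                path: str | Path, width: int = 70) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with Path(path).open("w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# sequence extraction
# ---------------------------------------------------------------------------

def extract_gene_sequence(record: GenomeRecord, f: Feature) -> str:
    """Substring ``start..end`` (1-based inclusive), reverse-complemented for
    L-strand features so the result reads 5'->3' in the gene's own sense."""
    if f.end > len(record.sequence):
        raise ValueError(
            f"{f.name}: end {f.end} exceeds sequence length {len(record.sequence)}"
        )
    sub = record.sequence[f.start - 1:f.end]
    return reverse_complement(sub) if f.strand == "L" else sub
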