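"""Annotated-genome data model and readers/writers.

Coordinates are stored 1-based inclusive throughout (GFF3 convention);
any half-open arithmetic is converted at the boundary.  "Adjacency" of
genes everywhere in this package means consecutive position in the
start-sorted gene list of a contig, regardless of strand or distance.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_CATEGORIES = ("core", "lineage_specific", "species_specific", "unclassified")

FLAGS_COLUMNS = (
    "gene_id",
    "secreted",
    "protein_length",
    "cysteines",
    "family_id",
    "category",
    "orphan",
    "pfam_families",
    "expanded_family",
    "qvalue",
)


@dataclass(frozen=True)
class GeneModel:
    """One gene: coordinates plus spliced CDS (coding orientation) and protein."""

    gene_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    cds: str = ""
    protein: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")

    @property
    def sort_key(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.gene_id)


@dataclass(frozen=True)
class GeneFlags:
    """Per-gene annotation labels supplied as input (not predicted here)."""

    gene_id: str
    secreted: bool = False
    protein_length: int = 1
    cysteines: int = 0
    family_id: str | None = None
    category: str = "unclassified"
    orphan: bool = False
    pfam_families: frozenset[str] = field(default_factory=frozenset)
    expanded_family: bool = False
    qvalue: float | None = None

    def __post_init__(self) -> None:
        if self.category not in VALID_CATEGORIES:
            raise ValueError(f"{self.gene_id}: invalid category {self.category!r}")
        if self.protein_length <= 0:
            raise ValueError(f"{self.gene_id}: protein_length must be positive")
        if self.cysteines > self.protein_length:
            raise ValueError(f"{self.gene_id}: cysteines exceed protein length")
        if self.orphan and self.pfam_families:
            raise ValueError(f"{self.gene_id}: orphan gene with Pfam families")
        if self.qvalue is not None and not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(f"{self.gene_id}: qvalue outside [0,1]")


class GenomeAnnotation:
    """Contig sequences, per-contig start-sorted gene lists, per-gene flags."""

    def __init__(
        self,
        genes: Iterable[GeneModel],
        flags: dict[str, GeneFlags] | None = None,
        contigs: dict[str, str] | None = None,
    ) -> None:
        self.contigs: dict[str, str] = dict(contigs or {})
        self.genes_by_contig: dict[str, list[GeneModel]] = {}
        seen: set[str] = set()
        for gene in genes:
            if gene.gene_id in seen:
                raise ValueError(f"duplicate gene_id {gene.gene_id!r}")
            seen.add(gene.gene_id)
            self.genes_by_contig.setdefault(gene.contig, []).append(gene)
        self.genes_by_contig = {
            name: sorted(lst, key=lambda g: g.sort_key)
            for name, lst in sorted(self.genes_by_contig.items())
        }
        self.flags: dict[str, GeneFlags] = {}
        provided = dict(flags or {})
        for gene in self.iter_genes():
            if gene.gene_id in provided:
                self.flags[gene.gene_id] = provided[gene.gene_id]
            else:
                logger.warning(
                    "gene %s missing from flags table; defaulting to unclassified",
                    gene.gene_id,
                )
                self.flags[gene.gene_id] = GeneFlags(
                    gene_id=gene.gene_id,
                    protein_length=max(1, len(gene.protein) or len(gene.cds) // 3 or 1),
                )

    def iter_genes(self) -> Iterator[GeneModel]:
        for contig in self.genes_by_contig:
            yield from self.genes_by_contig[contig]

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.genes_by_contig.values())

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.iter_genes():
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.iter_genes()]

    def validate(self) -> None:
        """Check structural invariants; raises ValueError on violation."""
        for gid in self.gene_ids():
            if gid not in self.flags:
                raise ValueError(f"gene {gid} has no flags entry")
        for contig, genes in self.genes_by_contig.items():
            keys = [g.sort_key for g in genes]
            if len(set(keys)) != len(keys):
                raise ValueError(f"contig {contig}: genes not uniquely orderable")
            if contig in self.contigs:
                clen = len(self.contigs[contig])
                for g in genes:
                    if g.end > clen:
                        raise ValueError(
                            f"gene {g.gene_id} end {g.end} beyond contig length {clen}"
                        )


# ---------------------------------------------------------------------------
# flags TSV
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _parse_bool(text: str, where: str) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"{where}: cannot parse boolean {text!r}")


def read_flags_tsv(path: str | os.PathLike) -> dict[str, GeneFlags]:
    """Read the per-gene flags table (tab-separated, header required)."""
    flags: dict[str, GeneFlags] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        missing = {"gene_id"} - set(idx)
        if missing:
            raise ValueError(f"flags table missing columns: {sorted(missing)}")

        def get(row: list[str], col: str, default: str = "") -> str:
            i = idx.get(col)
            if i is None or i >= len(row):
                return default
            return row[i]

        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            row = line.split("\t")
            gid = get(row, "gene_id")
            if gid in flags:
                raise ValueError(f"duplicate gene_id {gid!r} in flags table")
            fam = get(row, "family_id") or None
            qtxt = get(row, "qvalue").strip()
            pfam_txt = get(row, "pfam_families").strip()
            pfams = frozenset(p for p in pfam_txt.split(";") if p)
            flags[gid] = GeneFlags(
                gene_id=gid,
                secreted=_parse_bool(get(row, "secreted"), f"line {lineno}"),
                protein_length=int(get(row, "protein_length", "1") or 1),
                cysteines=int(get(row, "cysteines", "0") or 0),
                family_id=fam,
                category=get(row, "category", "unclassified") or "unclassified",
                orphan=_parse_bool(get(row, "orphan"), f"line {lineno}"),
                pfam_families=pfams,
                expanded_family=_parse_bool(get(row, "expanded_family"), f"line {lineno}"),
                qvalue=float(qtxt) if qtxt else None,
            )
    return flags


def write_flags_tsv(flags: dict[str, GeneFlags], path: str | os.PathLike, order: list[str] | None = None) -> None:
    ids = order if order is not None else sorted(flags)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(FLAGS_COLUMNS) + "\n")
        for gid in ids:
            f = flags[gid]
            fh.write(
                "\t".join(
                    [
                        f.gene_id,
                        "true" if f.secreted else "false",
                        str(f.protein_length),
                        str(f.cysteines),
                        f.family_id or "",
                        f.category,
                        "true" if f.orphan else "false",
                        ";".join(sorted(f.pfam_families)),
                        "true" if f.expanded_family else "false",
                        "" if f.qvalue is None else repr(f.qvalue),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3 + FASTA
# ---------------------------------------------------------------------------


def _read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _extract_cds(db: gffutils.FeatureDB, gene: gffutils.Feature, contigs: dict[str, str]) -> str:
    """Spliced CDS in coding orientation from genome sequence."""
    parts = sorted(
        db.children(gene, featuretype="CDS"), key=lambda f: (f.start, f.end)
    )
    if not parts:
        return ""
    seq = "".join(contigs[gene.seqid][f.start - 1 : f.end] for f in parts)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq.upper()


def load_annotation(
    gff3_path: str | os.PathLike,
    genome_fasta: str | os.PathLike | None = None,
    protein_fasta: str | os.PathLike | None = None,
    cds_fasta: str | os.PathLike | None = None,
    flags_tsv: str | os.PathLike | None = None,
) -> GenomeAnnotation:
    """Assemble a :class:`GenomeAnnotation` from GFF3 + FASTA + flags TSV.

    CDS sequences come from ``cds_fasta`` when given (keyed by gene_id); with
    a genome they are extracted from CDS features instead.  A CDS whose FASTA
    length disagrees with the coordinate-derived length is kept as supplied,
    with a warning.
    """
    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        contigs = _read_fasta(genome_fasta) if genome_fasta else {}
        return GenomeAnnotation([], flags={}, contigs=contigs)
    contigs = _read_fasta(genome_fasta) if genome_fasta else {}
    cds_map = _read_fasta(cds_fasta) if cds_fasta else {}
    prot_map = _read_fasta(protein_fasta) if protein_fasta else {}

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        if gid in seen:
            raise ValueError(f"duplicate gene_id {gid!r} in {gff3_path}")
        seen.add(gid)
        cds_from_coords = _extract_cds(db, feat, contigs) if contigs else ""
        cds = cds_map.get(gid, "")
        if cds and cds_from_coords and len(cds) != len(cds_from_coords):
            logger.warning(
                "gene %s: FASTA CDS length %d != coordinate-derived length %d; "
                "keeping FASTA sequence",
                gid,
                len(cds),
                len(cds_from_coords),
            )
        elif not cds:
            cds = cds_from_coords
        protein = prot_map.get(gid, "")
        if not protein and len(cds) >= 3:
            trimmed = cds[: len(cds) - len(cds) % 3]
            protein = str(Seq(trimmed).translate()).rstrip("*")
        genes.append(
            GeneModel(
                gene_id=gid,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                cds=cds,
                protein=protein,
            )
        )

    flags = read_flags_tsv(flags_tsv) if flags_tsv else {}
    extra = set(flags) - seen
    for gid in sorted(extra):
        logger.debug("flags entry %s has no gene model; ignored", gid)
        del flags[gid]
    return GenomeAnnotation(genes, flags=flags, contigs=contigs)


def write_annotation(ann: GenomeAnnotation, out_dir: str | os.PathLike) -> set[Path]:
    """Write GFF3 + FASTA files + flags TSV; load_annotation round-trips."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: set[Path] = set()

    gff_path = out / "genes.gff3"
    with open(gff_path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for gene in ann.iter_genes():
            cols = [gene.contig, "parasitome", "gene", str(gene.start), str(gene.end), ".", gene.strand, "."]
            fh.write("\t".join(cols + [f"ID={gene.gene_id}"]) + "\n")
            mrna = f"{gene.gene_id}.t1"
            cols[2] = "mRNA"
            fh.write("\t".join(cols + [f"ID={mrna};Parent={gene.gene_id}"]) + "\n")
            cols[2] = "CDS"
            cols[7] = "0"
            fh.write("\t".join(cols + [f"ID={mrna}.cds;Parent={mrna}"]) + "\n")
    written.add(gff_path)

    def _write_fasta(records: list[tuple[str, str]], path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, seq in records:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        written.add(path)

    if ann.contigs:
        _write_fasta(sorted(ann.contigs.items()), out / "genome.fasta")
    genes = list(ann.iter_genes())
    _write_fasta([(g.gene_id, g.cds) for g in genes if g.cds], out / "cds.fasta")
    _write_fasta([(g.gene_id, g.protein) for g in genes if g.protein], out / "proteins.fasta")

    flags_path = out / "flags.tsv"
    write_flags_tsv(ann.flags, flags_path, order=ann.gene_ids())
    written.add(flags_path)
    return written


def reload_annotation(out_dir: str | os.PathLike) -> GenomeAnnotation:
    """Load an annotation previously written by :func:`write_annotation`."""
    out = Path(out_dir)
    genome = out / "genome.fasta"
    return load_annotation(
        out / "genes.gff3",
        genome_fasta=genome if genome.exists() else None,
        protein_fasta=out / "proteins.fasta",
        cds_fasta=out / "cds.fasta",
        flags_tsv=out / "flags.tsv",
    )
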