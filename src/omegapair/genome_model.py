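"""Genome/CDS data model, FASTA + GFF3 I/O, coding density and size metrics.

A genome is a set of nucleotide contigs plus protein-coding (CDS)
annotations.  All downstream stages (orthology, dN/dS, ANI) consume the
:class:`GenomeRecord` produced here.  Coordinates follow the GFF3
convention externally (1-based, inclusive); Python slicing happens only at
the point of sequence extraction.

Translation uses NCBI genetic code table 11 (bacteria/archaea) by default;
the table is configurable per call because the organisms analysed span both
prokaryotic domains.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

STOP_AA = "*"


class GenomeValidationError(ValueError):
    """A CDS annotation is inconsistent with its genome sequence."""


@dataclass
class CdsFeature:
    """One protein-coding gene: coordinates plus extracted/translated sequence.

    ``start``/``end`` are 1-based inclusive on the forward strand of
    ``contig_id``; ``nt_seq`` is strand-resolved (reverse-complemented for
    ``-`` features) and ``aa_seq`` is its translation with the terminal stop
    removed.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    nt_seq: str = ""
    aa_seq: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise GenomeValidationError(
                f"CDS {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.start < 1 or self.end < self.start:
            raise GenomeValidationError(
                f"CDS {self.gene_id}: bad coordinates {self.start}..{self.end}"
            )


@dataclass
class GenomeRecord:
    """Contigs plus validated CDS features for one genome."""

    genome_id: str
    contigs: list[tuple[str, str]]
    cds_list: list[CdsFeature] = field(default_factory=list)
    taxon_label: str = ""
    skip_report: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.contigs]
        if len(set(ids)) != len(ids):
            raise GenomeValidationError(f"{self.genome_id}: duplicate contig ids")
        if self.size_bp() <= 0:
            raise GenomeValidationError(f"{self.genome_id}: genome has zero length")

    def size_bp(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    def contig_seq(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise GenomeValidationError(
            f"{self.genome_id}: unknown contig {contig_id!r}"
        )

    def proteome(self) -> dict[str, str]:
        """gene_id -> amino-acid sequence for all retained CDS."""
        return {c.gene_id: c.aa_seq for c in self.cds_list}

    def cds_by_id(self, gene_id: str) -> CdsFeature:
        for c in self.cds_list:
            if c.gene_id == gene_id:
                return c
        raise KeyError(gene_id)


@dataclass
class GenomeSizeMetrics:
    """The two genome-size measures used in cohort correlations, plus density.

    Genome size is reported both in base pairs and as the number of
    protein-coding sequences; published size/selection correlations are
    robust to either choice, so both are carried through the pipeline.
    """

    size_bp: int
    size_cds: int
    coding_density_pct: float


def translate_cds(nt_seq: str, table: int = 11) -> str:
    """Translate a CDS codon-by-codon.

    Codons containing characters outside {A,C,G,T} become ``X`` rather than
    raising, so ambiguity handling stays uniform with the later pairwise
    deletion of N-containing codons in the dN/dS stage.  The string includes
    ``*`` for stop codons; callers strip/inspect stops themselves.
    """
    code = CodonTable.unambiguous_dna_by_id[table]
    out = []
    for i in range(0, len(nt_seq) - len(nt_seq) % 3, 3):
        codon = nt_seq[i : i + 3].upper()
        if codon in code.stop_codons:
            out.append(STOP_AA)
        elif set(codon) <= set("ACGT"):
            out.append(code.forward_table[codon])
        else:
            out.append("X")
    return "".join(out)


def _extract_and_check(
    contig_seq: str, feat: CdsFeature, table: int
) -> tuple[str, str, str | None]:
    """Return (nt_seq, aa_seq, skip_reason)."""
    if feat.end > len(contig_seq):
        raise GenomeValidationError(
            f"CDS {feat.gene_id}: end {feat.end} beyond contig "
            f"{feat.contig_id} length {len(contig_seq)}"
        )
    nt = contig_seq[feat.start - 1 : feat.end].upper()
    if feat.strand == "-":
        nt = str(Seq(nt).reverse_complement())
    if len(nt) % 3 != 0:
        return nt, "", f"length {len(nt)} not divisible by 3"
    aa = translate_cds(nt, table=table)
    if aa and aa.endswith(STOP_AA):
        aa = aa[:-1]
    if STOP_AA in aa:
        return nt, "", "internal stop codon"
    return nt, aa, None


def _parse_gff3_cds(path: Path) -> list[CdsFeature]:
    feats: list[CdsFeature] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeValidationError(f"{path}: malformed GFF3 line: {line!r}")
            if cols[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("Parent")
            if gid is None:
                raise GenomeValidationError(
                    f"{path}: CDS without ID attribute: {line!r}"
                )
            # multi-part CDS (joined features) are out of scope; disambiguate
            if gid in seen:
                seen[gid] += 1
                gid = f"{gid}.part{seen[gid]}"
            else:
                seen[gid] = 1
            feats.append(
                CdsFeature(
                    gene_id=gid,
                    contig_id=cols[0],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                )
            )
    return feats


def _parse_cds_table(path: Path) -> list[CdsFeature]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "contig_id", "start", "end", "strand"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise GenomeValidationError(
                f"{path}: CDS table needs columns {sorted(required)}"
            )
        return [
            CdsFeature(
                gene_id=row["gene_id"],
                contig_id=row["contig_id"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
            )
            for row in reader
        ]


def read_genome(
    fasta_path: str | Path,
    annotation_path: str | Path,
    genome_id: str | None = None,
    table: int = 11,
) -> GenomeRecord:
    """Load a genome from FASTA plus CDS annotation (GFF3 or 5-column TSV).

    CDS whose extracted sequence fails the reading-frame or internal-stop
    checks are excluded and recorded in ``skip_report`` with a reason; a CDS
    that names an unknown contig or overruns it raises
    :class:`GenomeValidationError`.
    """
    fasta_path = Path(fasta_path)
    annotation_path = Path(annotation_path)
    contigs = [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    if not contigs:
        raise GenomeValidationError(f"{fasta_path}: no contigs parsed")
    gid = genome_id or fasta_path.stem

    with open(annotation_path) as fh:
        first = fh.readline()
    if annotation_path.suffix.lower() in {".gff", ".gff3"} or first.startswith(
        "##gff-version"
    ):
        raw_feats = _parse_gff3_cds(annotation_path)
    else:
        raw_feats = _parse_cds_table(annotation_path)

    record = GenomeRecord(genome_id=gid, contigs=contigs)
    contig_map = dict(contigs)
    for feat in raw_feats:
        if feat.contig_id not in contig_map:
            raise GenomeValidationError(
                f"CDS {feat.gene_id}: unknown contig {feat.contig_id!r}"
            )
        nt, aa, reason = _extract_and_check(contig_map[feat.contig_id], feat, table)
        if reason is not None:
            record.skip_report.append((feat.gene_id, reason))
            continue
        feat.nt_seq, feat.aa_seq = nt, aa
        record.cds_list.append(feat)
    if record.skip_report:
        logger.info(
            "%s: skipped %d CDS (see skip report)", gid, len(record.skip_report)
        )
    return record


def write_genome(
    genome: GenomeRecord,
    fasta_path: str | Path,
    gff_path: str | Path,
    line_width: int = 70,
) -> None:
    """Write FASTA + GFF3 so that :func:`read_genome` round-trips exactly."""
    with open(fasta_path, "w") as fh:
        for cid, seq in genome.contigs:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, seq in genome.contigs:
            fh.write(f"##sequence-region {cid} 1 {len(seq)}\n")
        for c in genome.cds_list:
            fh.write(
                f"{c.contig_id}\tomegapair\tCDS\t{c.start}\t{c.end}\t.\t"
                f"{c.strand}\t0\tID={c.gene_id}\n"
            )


def write_skip_report(genome: GenomeRecord, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene_id", "reason"])
        w.writerows(genome.skip_report)


def coding_density(genome: GenomeRecord, mode: str = "union") -> float:
    """Percent of the genome that is protein-coding.

    ``union`` counts each genome position once however many CDS cover it,
    guaranteeing a result in [0, 100]; ``literal`` sums CDS lengths directly
    (the textbook coding-density formula), which can exceed 100% when genes
    overlap.  The two agree exactly on non-overlapping annotations.
    """
    if mode not in {"union", "literal"}:
        raise ValueError(f"unknown coding-density mode {mode!r}")
    total = genome.size_bp()
    if total <= 0:
        raise GenomeValidationError(f"{genome.genome_id}: empty genome")
    if not genome.cds_list:
        logger.warning("%s: no CDS; coding density reported as 0", genome.genome_id)
        return 0.0
    if mode == "literal":
        coding = sum(c.end - c.start + 1 for c in genome.cds_list)
    else:
        coding = 0
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for c in genome.cds_list:
            by_contig.setdefault(c.contig_id, []).append((c.start, c.end))
        for ivs in by_contig.values():
            ivs.sort()
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e + 1:
                    cur_e = max(cur_e, e)
                else:
                    coding += cur_e - cur_s + 1
                    cur_s, cur_e = s, e
            coding += cur_e - cur_s + 1
    return 100.0 * coding / total


def genome_size_metrics(genome: GenomeRecord, mode: str = "union") -> GenomeSizeMetrics:
    """Both size measures (bp and CDS count) plus coding density."""
    dens = coding_density(genome, mode=mode) if genome.cds_list else 0.0
    return GenomeSizeMetrics(
        size_bp=genome.size_bp(),
        size_cds=len(genome.cds_list),
        coding_density_pct=dens,
    )
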