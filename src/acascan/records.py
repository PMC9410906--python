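"""Genome records and flat-file I/O.

Internally all coordinates are 0-based half-open ``[start, end)``; the GFF3
reader/writer owns the conversion to the format's 1-based inclusive
convention. CDS features carry their protein translation, derived from the
contig sequence, so downstream protein-level stages never re-read the
nucleotide file.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTRYKMSWNacgtrykmswn", "TGCAYRMKSWNtgcayrmkswn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware for common codes)."""
    return seq.translate(COMPLEMENT)[::-1]


def translate_cds(nt: str) -> str:
    """Translate a coding-strand CDS, dropping a trailing stop if present."""
    prot = str(Seq(nt).translate())
    return prot[:-1] if prot.endswith("*") else prot


@dataclass(frozen=True)
class CdsFeature:
    """One CDS on a contig; ``start``/``end`` are 0-based half-open."""

    cds_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    translation: str = ""
    product: str = ""
    family_labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def coding_sequence(self, contig_seq: str) -> str:
        nt = contig_seq[self.start : self.end]
        return revcomp(nt) if self.strand == "-" else nt


@dataclass
class GenomeRecord:
    """A contig with its CDS annotation, features kept sorted by start."""

    contig_id: str
    sequence: str
    features: list[CdsFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.cds_id))
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.cds_id} [{f.start},{f.end}) outside contig "
                    f"{self.contig_id} of length {len(self.sequence)}"
                )

    def feature_by_id(self, cds_id: str) -> CdsFeature:
        for f in self.features:
            if f.cds_id == cds_id:
                return f
        raise KeyError(f"no CDS {cds_id!r} on contig {self.contig_id}")

    def reverse_complement(self) -> "GenomeRecord":
        """Mirror the contig: revcomp sequence, flip coordinates and strands."""
        n = len(self.sequence)
        flipped = [
            replace(
                f,
                start=n - f.end,
                end=n - f.start,
                strand="-" if f.strand == "+" else "+",
            )
            for f in self.features
        ]
        return GenomeRecord(self.contig_id, revcomp(self.sequence), flipped)


def _esc(value: str) -> str:
    return urllib.parse.quote(value, safe=" ()/.,-_:")


def write_genomes(
    genomes: list[GenomeRecord], fasta_path: str | Path, gff_path: str | Path
) -> None:
    """Write contigs as FASTA and features as GFF3 (1-based inclusive)."""
    SeqIO.write(
        (SeqRecord(Seq(g.sequence), id=g.contig_id, description="") for g in genomes),
        str(fasta_path),
        "fasta",
    )
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genomes:
            fh.write(f"##sequence-region {g.contig_id} 1 {len(g.sequence)}\n")
        for g in genomes:
            for f in g.features:
                attrs = f"ID={_esc(f.cds_id)}"
                if f.product:
                    attrs += f";product={_esc(f.product)}"
                if f.family_labels:
                    attrs += ";family=" + ",".join(sorted(f.family_labels))
                fh.write(
                    "\t".join(
                        [
                            g.contig_id,
                            "acascan",
                            "CDS",
                            str(f.start + 1),
                            str(f.end),
                            ".",
                            f.strand,
                            "0",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_genomes(fasta_path: str | Path, gff_path: str | Path) -> list[GenomeRecord]:
    """Read FASTA + GFF3 back into GenomeRecords; translations re-derived."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    feats: dict[str, list[CdsFeature]] = {cid: [] for cid in seqs}
    with open(gff_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9 or cols[2] != "CDS":
                continue
            contig, _, _, start1, end1, _, strand, _, attr_col = cols
            attrs = {}
            for item in attr_col.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k] = urllib.parse.unquote(v)
            start, end = int(start1) - 1, int(end1)
            nt = seqs[contig][start:end]
            if strand == "-":
                nt = revcomp(nt)
            translation = translate_cds(nt) if len(nt) % 3 == 0 else ""
            feats[contig].append(
                CdsFeature(
                    cds_id=attrs.get("ID", f"{contig}:{start}-{end}"),
                    contig_id=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    translation=translation,
                    product=attrs.get("product", ""),
                    family_labels=frozenset(
                        x for x in attrs.get("family", "").split(",") if x
                    ),
                )
            )
    return [GenomeRecord(cid, seq, feats[cid]) for cid, seq in seqs.items()]


def write_protein_fasta(genomes: list[GenomeRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(f.translation), id=f.cds_id, description=f.product or "")
        for g in genomes
        for f in g.features
        if f.translation
    ]
    SeqIO.write(records, str(path), "fasta")
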