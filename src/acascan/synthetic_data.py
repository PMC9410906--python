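"""Synthetic annotated genomes with planted acr-aca loci and ground truth.

The generator emulates the genomic structures the analysis targets: acr-aca
operons (one or more acr genes upstream of an aca on the coding strand,
separated by short intergenic gaps), solo aca genes, and sigma70-like
promoters planted directly upstream of each locus carrying -35/-10 hexamers
and one or two inverted repeats (IRs). Background DNA is i.i.d. per base at a
configurable GC content and background CDSs are random stop-free ORFs, so
every downstream stage (profile scanning, operon calling, association
classification, promoter/IR detection) has realistic negatives and an exact
TruthManifest to be graded against.

All randomness flows from a single integer seed through numpy Generators; two
runs with the same config produce byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .records import CdsFeature, GenomeRecord, revcomp, translate_cds

BASES = "ACGT"

# Synthetic family reference proteins (invented sequences, styled on small
# HTH repressors and short Acr-like proteins; they match no real accession).
ACA_REFERENCE = (
    "MNTIEQLGARIRELRKQKGLSQEELAEKAGISVRTIQRIEAGETSPRGYTLKALAEALEVDVSELF"
)
ACR_KNOWN_REFERENCE = (
    "MSYDLIKQWAEENPDVFEATVNGHTKILDDMGFSREQAEAIVNGDPEKLAELSGGKYDFATLSEWQ"
    "KENLRPEDFAMVSKGFGWDEARKMLDF"
)
ACR_CANDIDATE_REFERENCE = (
    "MTKEQFIDWLNSHPEVLREGNVAFDHGKGTVEISDLPADAQKLVFDLVRETGKLSPEEANEWLSKY"
    "GDNLEKVRDMFLK"
)

DEFAULT_ACA_FAMILIES = {"AcaS1": ACA_REFERENCE}
DEFAULT_ACR_FAMILIES = {
    "AcrK1": (ACR_KNOWN_REFERENCE, "known"),
    "AcrC1": (ACR_CANDIDATE_REFERENCE, "candidate"),
}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(_STANDARD_TABLE.forward_table.items()):
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
_STOP_CODONS = sorted(_STANDARD_TABLE.stop_codons)
_SENSE_CODONS = sorted(_STANDARD_TABLE.forward_table)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class CapacityError(ValueError):
    """Planted elements cannot be placed without overflowing a contig."""


@dataclass(frozen=True)
class PlantedPromoterSpec:
    """Geometry of a planted promoter: core hexamers plus inverted repeats.

    ``ir_mismatches`` substitutions are applied per IR (each in a randomly
    chosen arm position), so the two arms stay within ``ir_mismatches`` of
    perfect reverse complementarity.
    """

    minus35: str = "TTGACA"
    minus10: str = "TATAAT"
    spacer: int = 17
    ir_arm: int = 6
    ir_spacer: int = 8
    ir_count: int = 1
    ir_mismatches: int = 0

    def __post_init__(self) -> None:
        if len(self.minus35) != 6 or len(self.minus10) != 6:
            raise ValueError("-35 and -10 elements must be hexamers")
        if not set(self.minus35 + self.minus10) <= set(BASES):
            raise ValueError("core elements must be ACGT strings")
        if not 15 <= self.spacer <= 19:
            raise ValueError("core spacer must lie in [15, 19]")
        if self.ir_arm < 4:
            raise ValueError("ir_arm must be >= 4")
        if self.ir_count not in (1, 2):
            raise ValueError("ir_count must be 1 or 2")


@dataclass(frozen=True)
class SyntheticConfig:
    n_contigs: int = 10
    contig_length: int = 30_000
    gc_content: float = 0.5
    n_acr_aca_operons: int = 5
    n_solo_aca: int = 5
    n_background_cds: int = 50
    operon_gap_range: tuple[int, int] = (0, 55)
    promoter_spec: PlantedPromoterSpec = field(default_factory=PlantedPromoterSpec)
    mutation_rate: float = 0.0  # per-site substitution rate in planted proteins
    solo_mutation_rate: float | None = None  # defaults to mutation_rate
    seed: int = 0
    promoter_length: int = 400
    acrs_per_operon: tuple[int, int] = (1, 2)
    intergenic_pad: tuple[int, int] = (200, 800)
    solo_isolation: int = 5_100  # min bp between any solo aca and any acr CDS
    aca_families: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ACA_FAMILIES)
    )
    acr_families: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_ACR_FAMILIES)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie strictly in (0, 1)")
        lo, hi = self.operon_gap_range
        if not 0 <= lo <= hi:
            raise ValueError("operon_gap_range must be 0 <= min <= max")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must lie in [0, 1)")


@dataclass
class TruthManifest:
    """Ground truth for everything the generator planted.

    Coordinates are 0-based half-open, matching the package's internal
    convention. Promoter element intervals (``minus35``, ``minus10``, IR arms)
    are offsets within the promoter's coding-strand-oriented sequence.
    """

    planted_operons: list[dict] = field(default_factory=list)
    planted_promoters: list[dict] = field(default_factory=list)
    planted_family_members: dict[str, list[str]] = field(default_factory=dict)
    solo_aca_ids: list[str] = field(default_factory=list)
    acr_class_of_family: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    """i.i.d. background DNA with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=p))


def mutate_sequence(seq: str, n_subs: int, seed: int | np.random.Generator) -> str:
    """Substitute exactly ``n_subs`` distinct positions, each to a new base."""
    if n_subs > len(seq):
        raise ValueError("n_subs exceeds sequence length")
    rng = _rng(seed)
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        alternatives = [b for b in BASES if b != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def mutate_protein(prot: str, rate: float, rng: np.random.Generator) -> str:
    out = list(prot)
    for i, aa in enumerate(out):
        if rng.random() < rate:
            alternatives = [a for a in AMINO_ACIDS if a != aa]
            out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def reverse_translate(prot: str, rng: np.random.Generator) -> str:
    """Encode a protein as DNA with uniformly random synonymous codons + stop."""
    codons = [
        _CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))] for aa in prot
    ]
    codons.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(codons)


def random_orf(rng: np.random.Generator, min_nt: int = 150, max_nt: int = 900) -> str:
    """A random stop-free ORF: ATG, random sense codons, one stop codon."""
    n_codons = int(rng.integers(min_nt // 3, max_nt // 3 + 1))
    body = [_SENSE_CODONS[i] for i in rng.integers(len(_SENSE_CODONS), size=n_codons - 2)]
    return "ATG" + "".join(body) + _STOP_CODONS[rng.integers(len(_STOP_CODONS))]


def make_seed_alignment(
    reference: str, n: int, subs_rate: float, seed: int | np.random.Generator
) -> list[str]:
    """Gap-free seed alignment: the reference plus n-1 mutated copies."""
    rng = _rng(seed)
    return [reference] + [mutate_protein(reference, subs_rate, rng) for _ in range(n - 1)]


def plant_promoter(
    spec: PlantedPromoterSpec,
    length: int,
    seed: int | np.random.Generator,
    gc: float = 0.5,
) -> tuple[str, dict]:
    """Build a promoter sequence with planted core elements and IRs.

    Layout (3' end = position adjacent to the start codon): the -10 hexamer
    ends 20 nt from the 3' end; the -35 sits ``spec.spacer`` nt upstream of
    the -10. IR #1 is anchored with its left arm ending immediately 5' of the
    -35 and its right arm ``ir_spacer`` nt downstream of the left arm, so the
    IR span always overlaps the core promoter (an IR1 by construction). An
    optional second IR with the same arm consensus is placed entirely 5' of
    the -35 (an IR2). Returns the sequence and an element dict with 0-based
    half-open offsets.
    """
    rng = _rng(seed)
    arm, ir_sp = spec.ir_arm, spec.ir_spacer
    m10_s = length - 20 - 6
    m35_s = m10_s - spec.spacer - 6
    # right arm must avoid both hexamers: inside the core spacer or 3' of -10
    fits_in_spacer = ir_sp >= 6 and ir_sp + arm <= 6 + spec.spacer
    past_minus10 = ir_sp >= 6 + spec.spacer + 6
    if not (fits_in_spacer or past_minus10):
        raise ValueError("IR geometry collides with planted core elements")
    ir1_left_s = m35_s - arm
    footprint_start = ir1_left_s
    if spec.ir_count == 2:
        footprint_start = ir1_left_s - 4 - (2 * arm + ir_sp)
    if footprint_start < 0 or length < 2 * arm + ir_sp:
        raise ValueError(
            f"promoter length {length} cannot hold the planted footprint"
        )
    seq = list(random_dna(length, gc, rng))
    seq[m35_s : m35_s + 6] = spec.minus35
    seq[m10_s : m10_s + 6] = spec.minus10
    left_arm = random_dna(arm, gc, rng)
    irs = []
    placements = [ir1_left_s]
    if spec.ir_count == 2:
        placements.insert(0, footprint_start)
    for ls in placements:
        rs = ls + arm + ir_sp
        seq[ls : ls + arm] = left_arm
        seq[rs : rs + arm] = revcomp(left_arm)
        for _ in range(spec.ir_mismatches):
            which = ls if rng.random() < 0.5 else rs
            pos = which + int(rng.integers(arm))
            alternatives = [b for b in BASES if b != seq[pos]]
            seq[pos] = alternatives[rng.integers(len(alternatives))]
        irs.append(
            {
                "left": [ls, ls + arm],
                "right": [rs, rs + arm],
                "mismatches": spec.ir_mismatches,
            }
        )
    elements = {
        "minus35": [m35_s, m35_s + 6],
        "minus10": [m10_s, m10_s + 6],
        "irs": irs,
    }
    return "".join(seq), elements


@dataclass
class _Block:
    """A contiguous planted segment in coding orientation, pre-placement."""

    seq: str
    strand: str
    kind: str  # 'operon', 'solo', 'background'
    cds: list[dict] = field(default_factory=list)  # relative coords, coding strand
    promoter: dict | None = None
    has_acr: bool = False
    has_solo_aca: bool = False


def _build_locus_block(
    config: SyntheticConfig,
    rng: np.random.Generator,
    kind: str,
    counter: dict,
) -> _Block:
    """Assemble promoter + gene run (acr*..aca or solo aca) on the coding strand."""
    strand = "+" if rng.random() < 0.5 else "-"
    spec = config.promoter_spec
    prom_seq, elements = plant_promoter(
        spec, config.promoter_length, rng, config.gc_content
    )
    parts = [prom_seq]
    cursor = len(prom_seq)
    cds: list[dict] = []
    genes: list[tuple[str, str]] = []  # (family, role)
    if kind == "operon":
        n_acr = int(rng.integers(config.acrs_per_operon[0], config.acrs_per_operon[1] + 1))
        acr_names = sorted(config.acr_families)
        for _ in range(n_acr):
            genes.append((acr_names[rng.integers(len(acr_names))], "acr"))
    aca_names = sorted(config.aca_families)
    genes.append((aca_names[rng.integers(len(aca_names))], "aca"))
    gaps: list[int] = []
    for i, (family, role) in enumerate(genes):
        if i > 0:
            gap = int(rng.integers(config.operon_gap_range[0], config.operon_gap_range[1] + 1))
            gaps.append(gap)
            parts.append(random_dna(gap, config.gc_content, rng))
            cursor += gap
        ref = (
            config.aca_families[family]
            if role == "aca"
            else config.acr_families[family][0]
        )
        rate = config.mutation_rate
        if kind == "solo" and config.solo_mutation_rate is not None:
            rate = config.solo_mutation_rate
        prot = mutate_protein(ref, rate, rng)
        nt = reverse_translate(prot, rng)
        counter["gene"] += 1
        cds.append(
            {
                "id": f"g{counter['gene']:04d}",
                "start": cursor,
                "end": cursor + len(nt),
                "family": family,
                "role": role,
            }
        )
        parts.append(nt)
        cursor += len(nt)
    return _Block(
        seq="".join(parts),
        strand=strand,
        kind=kind,
        cds=cds,
        promoter={"start": 0, "end": len(prom_seq), "elements": elements, "gaps": gaps},
        has_acr=any(c["role"] == "acr" for c in cds),
        has_solo_aca=(kind == "solo"),
    )


def _build_background_block(config: SyntheticConfig, rng: np.random.Generator, counter: dict) -> _Block:
    strand = "+" if rng.random() < 0.5 else "-"
    nt = random_orf(rng)
    counter["gene"] += 1
    return _Block(
        seq=nt,
        strand=strand,
        kind="background",
        cds=[{"id": f"g{counter['gene']:04d}", "start": 0, "end": len(nt), "family": None, "role": "background"}],
    )


def generate_genomes(
    config: SyntheticConfig,
) -> tuple[list[GenomeRecord], TruthManifest]:
    """Generate annotated contigs plus the TruthManifest of planted elements.

    Operons and solo aca loci are assigned to contigs from opposite ends of
    the contig list and the placer enforces ``solo_isolation`` bp between any
    solo aca and any acr gene, so planted association labels are recoverable
    under the 5 kb neighborhood rule.
    """
    rng = np.random.default_rng(config.seed)
    counter = {"gene": 0}

    per_contig: list[list[_Block]] = [[] for _ in range(config.n_contigs)]
    for i in range(config.n_acr_aca_operons):
        per_contig[i % config.n_contigs].append(
            _build_locus_block(config, rng, "operon", counter)
        )
    for i in range(config.n_solo_aca):
        per_contig[config.n_contigs - 1 - (i % config.n_contigs)].append(
            _build_locus_block(config, rng, "solo", counter)
        )
    for i in range(config.n_background_cds):
        per_contig[i % config.n_contigs].append(
            _build_background_block(config, rng, counter)
        )

    manifest = TruthManifest(
        acr_class_of_family={f: cls for f, (_, cls) in sorted(config.acr_families.items())}
    )
    genomes: list[GenomeRecord] = []
    op_counter = 0
    for ci, blocks in enumerate(per_contig):
        contig_id = f"contig{ci + 1:02d}"
        order = rng.permutation(len(blocks))
        blocks = [blocks[int(k)] for k in order]
        seq_parts: list[str] = []
        cursor = 0
        features: list[CdsFeature] = []
        last_acr_end = -(10**9)
        last_solo_end = -(10**9)
        for block in blocks:
            pad = int(rng.integers(config.intergenic_pad[0], config.intergenic_pad[1] + 1))
            start = cursor + pad
            if block.has_solo_aca and start < last_acr_end + config.solo_isolation:
                start = last_acr_end + config.solo_isolation
            if block.has_acr and start < last_solo_end + config.solo_isolation:
                start = last_solo_end + config.solo_isolation
            if start + len(block.seq) > config.contig_length:
                raise CapacityError(
                    f"contig {contig_id}: planted elements exceed contig_length "
                    f"{config.contig_length}"
                )
            seq_parts.append(random_dna(start - cursor, config.gc_content, rng))
            block_seq = block.seq if block.strand == "+" else revcomp(block.seq)
            seq_parts.append(block_seq)
            L = len(block.seq)

            def abs_interval(rel_s: int, rel_e: int) -> tuple[int, int]:
                if block.strand == "+":
                    return start + rel_s, start + rel_e
                return start + L - rel_e, start + L - rel_s

            member_ids = []
            for c in block.cds:
                s, e = abs_interval(c["start"], c["end"])
                nt = block.seq[c["start"] : c["end"]]
                features.append(
                    CdsFeature(
                        cds_id=c["id"],
                        contig_id=contig_id,
                        start=s,
                        end=e,
                        strand=block.strand,
                        translation=translate_cds(nt),
                        product=c["role"],
                    )
                )
                member_ids.append(c["id"])
                if c["family"] is not None:
                    manifest.planted_family_members.setdefault(c["family"], []).append(
                        c["id"]
                    )
                if c["role"] == "acr":
                    last_acr_end = max(last_acr_end, start + L)
                if block.has_solo_aca:
                    last_solo_end = max(last_solo_end, start + L)
            if block.kind == "operon":
                op_counter += 1
                owner_id = f"op{op_counter:03d}"
                manifest.planted_operons.append(
                    {
                        "operon_id": owner_id,
                        "contig": contig_id,
                        "strand": block.strand,
                        "member_ids": member_ids,  # coding order: acr(s) then aca
                        "gaps": block.promoter["gaps"],
                    }
                )
            elif block.kind == "solo":
                owner_id = member_ids[0]
                manifest.solo_aca_ids.append(owner_id)
            if block.promoter is not None:
                ps, pe = abs_interval(block.promoter["start"], block.promoter["end"])
                manifest.planted_promoters.append(
                    {
                        "owner_id": owner_id,
                        "leader_id": member_ids[0],
                        "contig": contig_id,
                        "start": ps,
                        "end": pe,
                        "strand": block.strand,
                        "elements": block.promoter["elements"],
                    }
                )
            cursor = start + L
        if cursor > config.contig_length:
            raise CapacityError(f"contig {contig_id} overflow")
        seq_parts.append(random_dna(config.contig_length - cursor, config.gc_content, rng))
        genomes.append(GenomeRecord(contig_id, "".join(seq_parts), features))
    return genomes, manifest


def write_synthetic_community(
    config: SyntheticConfig, outdir: str | Path
) -> tuple[list[GenomeRecord], TruthManifest]:
    """Generate and write FASTA, GFF3, protein FASTA, seed alignments, labels, manifest."""
    from .records import write_genomes, write_protein_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes, manifest = generate_genomes(config)
    write_genomes(genomes, outdir / "community.fna", outdir / "community.gff3")
    write_protein_fasta(genomes, outdir / "community.faa")
    manifest.to_json(outdir / "truth_manifest.json")

    align_rng = np.random.default_rng((config.seed + 777) % 2**31)
    refs = {name: ref for name, ref in sorted(config.aca_families.items())}
    refs.update({name: ref for name, (ref, _) in sorted(config.acr_families.items())})
    for name, ref in refs.items():
        rows = make_seed_alignment(ref, n=8, subs_rate=0.05, seed=align_rng)
        with open(outdir / f"seed_{name}.afa", "w") as fh:
            for i, row in enumerate(rows):
                fh.write(f">{name}_seed{i}\n{row}\n")
    with open(outdir / "acr_labels.tsv", "w") as fh:
        fh.write("family\tlabel\n")
        for fam, cls in sorted(manifest.acr_class_of_family.items()):
            fh.write(f"{fam}\t{cls}\n")
    return genomes, manifest
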