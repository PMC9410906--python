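"""Gene neighborhoods, operon calling, acr association, co-occurrence network.

Operons follow the intergenic-distance heuristic: a maximal run of same-strand
CDS where consecutive genes are separated by at most ``max_gap`` intervening
bases (default 55). An opposite-strand CDS interposed between two same-strand
genes breaks the run, since transcriptional read-through across it is
implausible. Association of an aca-like gene with acr genes is decided within
its operon first, then within a +/-5 kb neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .homology import HomologHit
from .records import CdsFeature, GenomeRecord

ACR_CLASS_RANK = {"known": 0, "candidate": 1, "putative": 2}


@dataclass
class Neighborhood:
    center_hit: HomologHit
    contig_id: str
    window: tuple[int, int]  # 0-based half-open, clipped to the contig
    features: list[CdsFeature]  # genomic order, overlap >= 1 base


@dataclass
class Operon:
    operon_id: str
    strand: str
    members: list[CdsFeature]  # genomic order

    @property
    def leader(self) -> CdsFeature:
        """5'-most member on the coding strand."""
        return self.members[0] if self.strand == "+" else self.members[-1]

    @property
    def member_ids(self) -> list[str]:
        return [m.cds_id for m in self.members]


@dataclass
class AssociationRecord:
    aca_hit: HomologHit
    label: str  # acr_associated | proximal | solo
    acr_class: str  # known | candidate | putative | none
    linked_acr_ids: list[str] = field(default_factory=list)
    operon_id: str | None = None


@dataclass
class AssociationNetwork:
    """Family co-occurrence network; symmetric edge counts."""

    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], int] = field(default_factory=dict)

    def add_edge(self, fam_a: str, fam_b: str) -> None:
        key = tuple(sorted((fam_a, fam_b)))
        self.edges[key] = self.edges.get(key, 0) + 1
        self.nodes.update(key)

    def weight(self, fam_a: str, fam_b: str) -> int:
        return self.edges.get(tuple(sorted((fam_a, fam_b))), 0)

    def total_weight(self) -> int:
        return sum(self.edges.values())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for (a, b), w in sorted(self.edges.items()):
            g.add_edge(a, b, weight=w)
        return g


def extract_neighborhood(
    genome: GenomeRecord, hit: HomologHit, flank: int = 5000
) -> Neighborhood:
    """All CDS overlapping the window [center.start - flank, center.end + flank)."""
    center = genome.feature_by_id(hit.cds_id)  # KeyError for unknown CDS
    lo = max(0, center.start - flank)
    hi = min(len(genome.sequence), center.end + flank)
    feats = [f for f in genome.features if f.start < hi and f.end > lo]
    return Neighborhood(hit, genome.contig_id, (lo, hi), feats)


def intergenic_gap(prev: CdsFeature, nxt: CdsFeature) -> int:
    """Strictly intervening bases between two features (negative = overlap)."""
    return nxt.start - prev.end


def call_operons(
    features: list[CdsFeature], max_gap: int = 55, id_prefix: str = "operon"
) -> list[Operon]:
    """Partition sorted single-contig features into operons.

    Same-strand neighbors with <= max_gap intervening bases (or overlapping)
    share an operon; a strand switch always closes the current run.
    """
    for a, b in zip(features, features[1:]):
        if b.start < a.start:
            raise ValueError("features must be sorted by start")
    contigs = {f.contig_id for f in features}
    if len(contigs) > 1:
        raise ValueError(f"features span multiple contigs: {sorted(contigs)}")
    operons: list[Operon] = []
    run: list[CdsFeature] = []
    for feat in features:
        if run and (
            feat.strand != run[-1].strand or intergenic_gap(run[-1], feat) > max_gap
        ):
            operons.append(Operon(f"{id_prefix}{len(operons) + 1:04d}", run[0].strand, run))
            run = []
        run.append(feat)
    if run:
        operons.append(Operon(f"{id_prefix}{len(operons) + 1:04d}", run[0].strand, run))
    return operons


def classify_association(
    nbhd: Neighborhood,
    operons: list[Operon],
    acr_labels: dict[str, str],
) -> AssociationRecord:
    """Label an aca-like hit by its relation to labelled acr genes.

    acr_associated if a labelled acr shares the aca's operon; proximal if one
    lies elsewhere in the neighborhood; otherwise solo. acr_class is the best
    class present (known > candidate > putative).
    """
    aca_id = nbhd.center_hit.cds_id
    homes = [op for op in operons if aca_id in op.member_ids]
    if len(homes) != 1:
        raise ValueError(
            f"aca CDS {aca_id} found in {len(homes)} operons; expected exactly 1"
        )
    operon = homes[0]
    operonic = [m.cds_id for m in operon.members if m.cds_id in acr_labels and m.cds_id != aca_id]
    if operonic:
        linked, label = operonic, "acr_associated"
    else:
        nearby = [
            f.cds_id
            for f in nbhd.features
            if f.cds_id in acr_labels and f.cds_id != aca_id
        ]
        if nearby:
            linked, label = nearby, "proximal"
        else:
            linked, label = [], "solo"
    acr_class = (
        min((acr_labels[c] for c in linked), key=lambda cls: ACR_CLASS_RANK[cls])
        if linked
        else "none"
    )
    return AssociationRecord(
        aca_hit=nbhd.center_hit,
        label=label,
        acr_class=acr_class,
        linked_acr_ids=linked,
        operon_id=operon.operon_id,
    )


def build_network(
    records: list[AssociationRecord],
    family_of: dict[str, str],
    include_unlinked_nodes: bool = True,
) -> AssociationNetwork:
    """Aca-family x acr-family co-occurrence counts over operonic associations.

    Each acr_associated record increments the edge between its aca family and
    every distinct acr family it links to; proximal/solo records contribute
    nodes only (when include_unlinked_nodes).
    """
    net = AssociationNetwork()
    for rec in records:
        if include_unlinked_nodes:
            net.nodes.add(rec.aca_hit.family_name)
        if rec.label != "acr_associated":
            continue
        fams = set()
        for cid in rec.linked_acr_ids:
            if cid not in family_of:
                raise KeyError(f"linked acr {cid} has no family assignment")
            fams.add(family_of[cid])
        for fam in sorted(fams):
            net.add_edge(rec.aca_hit.family_name, fam)
    return net
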