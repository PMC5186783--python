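"""Physical co-localization of gene-system members and arrangement labels.

Two member genes co-cluster when they lie on the same replicon with at
most ``max_intervening`` non-member genes between them (transitive
closure); there is no base-pair distance criterion, so the rule is
independent of annotation density. Arrangements are then classified:

* hox: groups G1-G3 and G7 from their published definitions (EFUYH
  clustered + distal W; EFUYHW single cluster; EFUY cluster with H and W
  elsewhere; FUYHW cluster with distal E); G4-G6 share the hoxE+hoxF
  co-clustering and are told apart by a partition-signature lookup table
  shipped as editable data (the published grouping shows them only
  collectively).
* hup: hupS and hupL always co-cluster; the label follows two axes —
  whether hupW sits in the hupSL cluster, and whether an xisC element
  interrupts hupS or hupL — through a configurable axis table.
* hyp: the canonical partition signature of cluster sizes; a single
  six-gene cluster is class 1 and a five-plus-one split is class 2, with
  the remaining signatures enumerated deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .families import (HOX_SYSTEM, HUP_SYSTEM, HYP_SYSTEM, SYSTEM_FAMILIES,
                       XIS_FAMILY, PresenceMap, presence_map)
from .genome_io import GeneFeature, Genome, GenomeIOError

DEFAULT_MAX_INTERVENING = 3

_SHORT = {"hoxE": "E", "hoxF": "F", "hoxU": "U", "hoxY": "Y", "hoxH": "H",
          "hoxW": "W", "hupS": "S", "hupL": "L", "hupW": "W",
          "hypA": "A", "hypB": "B", "hypC": "C", "hypD": "D", "hypE": "E",
          "hypF": "F"}

_GENE_ORDER = {f: i for i, f in enumerate(
    HOX_SYSTEM + HUP_SYSTEM + HYP_SYSTEM)}

# hox G4/G5/G6 partition-signature lookup. The published grouping defines
# these only collectively (hoxE+hoxF co-clustered, rest in various
# combinations); this default assignment is a placeholder to be replaced
# with curated data, and unknown signatures fall back to "unclassified".
DEFAULT_HOX_LOOKUP = {
    "UYHW+EF": "G4",
    "UYH+EF+W": "G5",
    "EF+UY+H+W": "G6",
}

# hup group lookup over (hupW location, xisC interruption target). The two
# axes are published; the numeric group assignment is a placeholder table.
DEFAULT_HUP_LOOKUP = {
    ("clustered", "none"): "G1",
    ("distal", "none"): "G2",
    ("clustered", "hupS"): "G3",
    ("clustered", "hupL"): "G4",
    ("distal", "hupS"): "G5",
}


@dataclass
class GeneCluster:
    replicon_id: str
    members: list[tuple[str, str, str]]  # (family_name, gene_id, strand), by start
    span: tuple[int, int]

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(m[0] for m in self.members)

    @property
    def orientation_uniform(self) -> bool:
        return len({m[2] for m in self.members}) <= 1

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ArrangementLabel:
    system: str
    label: str
    partition_signature: str
    orientation_uniform: list[bool] = field(default_factory=list)
    interrupted_by: Optional[str] = None


def _member_features(genome: Genome, presence: PresenceMap,
                     families: Sequence[str]) -> list[tuple[GeneFeature, str]]:
    """(feature, family) for every present member gene, with coordinates."""
    protein_to_family: dict[str, str] = {}
    for fam in families:
        p = presence.get(fam)
        if p is None or not p.is_present:
            continue
        for pid in p.member_protein_ids:
            protein_to_family[pid] = fam
    found: list[tuple[GeneFeature, str]] = []
    seen: set[str] = set()
    for feat in genome.features:
        if feat.protein_id in protein_to_family:
            found.append((feat, protein_to_family[feat.protein_id]))
            seen.add(feat.protein_id)
    missing = set(protein_to_family) - seen
    if missing:
        raise GenomeIOError(
            f"genome {genome.genome_id!r}: member proteins without gene "
            f"coordinates: {sorted(missing)}")
    return found


def find_clusters(genome: Genome, presence, system: str,
                  max_intervening: int = DEFAULT_MAX_INTERVENING) -> list[GeneCluster]:
    """Partition a system's present member genes into physical clusters.

    Consecutive members (by start coordinate, per replicon) are joined when
    at most ``max_intervening`` non-member genes lie between them, i.e.
    start after the earlier member's start and end before the later one's
    end — a rule symmetric under coordinate mirroring. Every present member
    lands in exactly one cluster; singletons are allowed.
    """
    if not isinstance(presence, Mapping):
        presence = presence_map(presence)
    families = SYSTEM_FAMILIES[system]
    members = _member_features(genome, presence, families)
    member_gene_ids = {feat.gene_id for feat, _fam in members}

    by_replicon: dict[str, list[tuple[GeneFeature, str]]] = {}
    for feat, fam in members:
        by_replicon.setdefault(feat.replicon_id, []).append((feat, fam))

    clusters: list[GeneCluster] = []
    for replicon_id in sorted(by_replicon):
        entries = sorted(by_replicon[replicon_id],
                         key=lambda e: (e[0].start, e[0].end, e[0].gene_id))
        others = sorted((f for f in genome.features
                         if f.replicon_id == replicon_id
                         and f.gene_id not in member_gene_ids),
                        key=lambda f: (f.start, f.end))
        current: list[tuple[GeneFeature, str]] = [entries[0]]
        for prev, nxt in zip(entries, entries[1:]):
            intervening = sum(1 for f in others
                              if f.start > prev[0].start and f.end < nxt[0].end)
            if intervening <= max_intervening:
                current.append(nxt)
            else:
                clusters.append(_make_cluster(replicon_id, current))
                current = [nxt]
        clusters.append(_make_cluster(replicon_id, current))
    clusters.sort(key=lambda c: (c.replicon_id, c.span))
    return clusters


def _make_cluster(replicon_id: str, entries: list[tuple[GeneFeature, str]]) -> GeneCluster:
    return GeneCluster(
        replicon_id=replicon_id,
        members=[(fam, feat.gene_id, feat.strand) for feat, fam in entries],
        span=(min(f.start for f, _ in entries), max(f.end for f, _ in entries)),
    )


def partition_signature(clusters: Sequence[GeneCluster]) -> str:
    """Canonical signature: blocks of short gene letters, largest first.

    Within a block, letters follow the canonical gene order (not genomic
    order), so the signature is invariant under coordinate mirroring.
    """
    blocks = []
    for c in clusters:
        letters = "".join(_SHORT[f] for f in
                          sorted(c.families, key=lambda f: _GENE_ORDER[f]))
        blocks.append(letters)
    blocks.sort(key=lambda b: (-len(b), b))
    return "+".join(blocks)


def size_signature(clusters: Sequence[GeneCluster]) -> str:
    sizes = sorted((len(c) for c in clusters), reverse=True)
    return "+".join(str(s) for s in sizes)


def _check_complete(presence: PresenceMap, families: Sequence[str], system: str) -> None:
    missing = [f for f in families if f not in presence or not presence[f].is_present]
    if missing:
        raise ValueError(
            f"classify_{system} requires the complete gene set; missing: {missing}")


def classify_hox(clusters: Sequence[GeneCluster], presence,
                 lookup: Optional[Mapping[str, str]] = None) -> ArrangementLabel:
    """Label a complete hox system's arrangement G1-G7 or unclassified."""
    if not isinstance(presence, Mapping):
        presence = presence_map(presence)
    _check_complete(presence, HOX_SYSTEM, "hox")
    lookup = DEFAULT_HOX_LOOKUP if lookup is None else lookup
    sig = partition_signature(clusters)
    orient = [c.orientation_uniform for c in clusters]

    def cluster_with(*families: str) -> Optional[GeneCluster]:
        wanted = set(families)
        for c in clusters:
            if set(c.families) == wanted:
                return c
        return None

    # extra hoxW copies in their own clusters are an orthogonal observed
    # state (multicopy endopeptidase) and do not change the group
    w_only_elsewhere = all(set(c.families) == {"hoxW"}
                           for c in clusters if "hoxW" in c.families
                           and len(set(c.families)) == 1)
    core = ("hoxE", "hoxF", "hoxU", "hoxY", "hoxH")
    label = "unclassified"
    six = cluster_with(*core, "hoxW")
    efuyh = cluster_with(*core)
    efuy = cluster_with("hoxE", "hoxF", "hoxU", "hoxY")
    fuyhw = cluster_with("hoxF", "hoxU", "hoxY", "hoxH", "hoxW")
    if six is not None and six.orientation_uniform:
        label = "G2"
    elif efuyh is not None and efuyh.orientation_uniform and w_only_elsewhere:
        label = "G1"
    elif efuy is not None and efuy.orientation_uniform \
            and not any("hoxE" in c.families for c in clusters if c is not efuy):
        # hoxH and hoxW elsewhere, in any arrangement
        label = "G3"
    elif fuyhw is not None and cluster_with("hoxE") is not None:
        label = "G7"
    else:
        ef_together = any({"hoxE", "hoxF"} <= set(c.families) for c in clusters)
        if ef_together:
            label = lookup.get(sig, "unclassified")
    return ArrangementLabel(system="hox", label=label, partition_signature=sig,
                            orientation_uniform=orient)


def detect_xis_interruption(genome: Genome, presence) -> Optional[str]:
    """Which hup subunit (if any) an xisC element interrupts.

    Interruption is an xisC-family gene lying strictly within the span of a
    hupS or hupL feature, or a subunit split into two features flanking an
    xisC feature.
    """
    if not isinstance(presence, Mapping):
        presence = presence_map(presence)
    xis = presence.get(XIS_FAMILY)
    if xis is None or not xis.is_present:
        return None
    xis_feats = [f for f in genome.features if f.protein_id in set(xis.member_protein_ids)]
    for subunit in ("hupS", "hupL"):
        p = presence.get(subunit)
        if p is None or not p.is_present:
            continue
        feats = [f for f in genome.features
                 if f.protein_id in set(p.member_protein_ids)]
        for xf in xis_feats:
            for sf in feats:
                if sf.replicon_id == xf.replicon_id \
                        and sf.start < xf.start and xf.end < sf.end:
                    return subunit
            if len(feats) == 2:
                a, b = sorted(feats, key=lambda f: f.start)
                if a.replicon_id == xf.replicon_id == b.replicon_id \
                        and a.end <= xf.start and xf.end <= b.start:
                    return subunit
    return None


def classify_hup(clusters: Sequence[GeneCluster], genome: Genome, presence,
                 lookup: Optional[Mapping[tuple[str, str], str]] = None
                 ) -> ArrangementLabel:
    """Label a complete hup system from the hupW-location and xisC axes."""
    if not isinstance(presence, Mapping):
        presence = presence_map(presence)
    _check_complete(presence, HUP_SYSTEM, "hup")
    lookup = DEFAULT_HUP_LOOKUP if lookup is None else lookup
    sig = partition_signature(clusters)
    orient = [c.orientation_uniform for c in clusters]
    interruption = detect_xis_interruption(genome, presence)

    sl_together = any({"hupS", "hupL"} <= set(c.families) for c in clusters)
    if not sl_together:
        return ArrangementLabel("hup", "unclassified", sig, orient, interruption)
    w_clustered = any({"hupS", "hupL", "hupW"} <= set(c.families) for c in clusters)
    axes = ("clustered" if w_clustered else "distal", interruption or "none")
    label = lookup.get(axes, "unclassified")
    return ArrangementLabel("hup", label, sig, orient, interruption)


def classify_hyp(clusters: Sequence[GeneCluster], presence) -> ArrangementLabel:
    """Label a complete hyp system by its cluster-size partition.

    A single six-gene cluster is class "1"; five clustered genes plus one
    distal gene is class "2"; every other shape is labelled by its size
    signature (e.g. "4+2", "1+1+1+1+1+1").
    """
    if not isinstance(presence, Mapping):
        presence = presence_map(presence)
    _check_complete(presence, HYP_SYSTEM, "hyp")
    sig = partition_signature(clusters)
    sizes = size_signature(clusters)
    if sizes == "6":
        label = "1"
    elif sizes == "5+1":
        label = "2"
    else:
        label = sizes
    return ArrangementLabel("hyp", label, sig,
                            [c.orientation_uniform for c in clusters])


def classify_all(genome: Genome, presence,
                 max_intervening: int = DEFAULT_MAX_INTERVENING,
                 hox_lookup: Optional[Mapping[str, str]] = None,
                 hup_lookup: Optional[Mapping[tuple[str, str], str]] = None
                 ) -> dict[str, ArrangementLabel]:
    """Arrangement labels for every system whose gene set is complete."""
    if not isinstance(presence, Mapping):
        presence = presence_map(presence)
    out: dict[str, ArrangementLabel] = {}
    def have_all(fams):
        return all(f in presence and presence[f].is_present for f in fams)
    if have_all(HOX_SYSTEM):
        cl = find_clusters(genome, presence, "hox", max_intervening)
        out["hox"] = classify_hox(cl, presence, hox_lookup)
    if have_all(HUP_SYSTEM):
        cl = find_clusters(genome, presence, "hup", max_intervening)
        out["hup"] = classify_hup(cl, genome, presence, hup_lookup)
    if have_all(HYP_SYSTEM):
        cl = find_clusters(genome, presence, "hyp", max_intervening)
        out["hyp"] = classify_hyp(cl, presence)
    return out
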