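"""Per-family thresholded homolog search with reciprocal-best-hit confirmation.

The search aligns every target protein against each query of a family and
keeps targets whose Karlin-Altschul e-value against their best-scoring
query passes the family threshold. A hit is RBH-confirmed when the hit
protein's best-scoring partner in the *source proteome of the queries*
(panel queries plus their genomic neighbours, including paralogs) is the
original query — the mechanism that discriminates paralogous false
positives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from .align import AlignmentParams, default_params, evalue, local_score, log10_evalue
from .genome_io import Genome, GenomeIOError, ProteinRecord, read_fasta

logger = logging.getLogger(__name__)

# threshold defaults: tight for structural subunits, looser for
# accessory/maturation proteins; overridable per family in config
DEFAULT_STRUCTURAL_THRESHOLD = 1e-10
DEFAULT_ACCESSORY_THRESHOLD = 1e-6

STRUCTURAL_FAMILIES = frozenset({
    "hoxE", "hoxF", "hoxU", "hoxY", "hoxH",
    "hupS", "hupL",
    "nifH", "nifD", "nifK",
    "mbh1_large", "mbh1_small",
    "sh3b_alpha", "sh3b_beta", "sh3b_gamma", "sh3b_delta",
})


@dataclass
class QueryFamily:
    """A named gene family: query protein(s) + its e-value threshold."""

    family_name: str
    query_sequences: list[ProteinRecord]
    evalue_threshold: float

    def __post_init__(self) -> None:
        if not self.query_sequences:
            raise ValueError(f"family {self.family_name!r} has no query sequences")
        if not self.evalue_threshold > 0:
            raise ValueError(f"family {self.family_name!r}: threshold must be > 0")


@dataclass(frozen=True)
class HomologHit:
    family_name: str
    genome_id: str
    protein_id: str
    best_query_id: str
    score: float
    evalue: float
    log10_evalue: float = field(default=0.0, compare=False)
    rbh: bool = False


def default_threshold(family_name: str) -> float:
    if family_name in STRUCTURAL_FAMILIES:
        return DEFAULT_STRUCTURAL_THRESHOLD
    return DEFAULT_ACCESSORY_THRESHOLD


def _best_partner(sequence: str, candidates: Sequence[ProteinRecord],
                  params: AlignmentParams) -> tuple[ProteinRecord, float]:
    """Highest-scoring candidate; ties broken by lexicographically smallest id."""
    best: Optional[ProteinRecord] = None
    best_score = -math.inf
    for cand in candidates:
        s = local_score(sequence, cand.sequence, params)
        if s > best_score or (s == best_score and best is not None
                              and cand.protein_id < best.protein_id):
            best, best_score = cand, s
    assert best is not None
    return best, best_score


def search_family(family: QueryFamily, genome: Genome,
                  params: Optional[AlignmentParams] = None) -> list[HomologHit]:
    """All genome proteins passing the family e-value threshold.

    One hit per passing target protein, scored against its best-scoring
    query (ties: lexicographically smallest query id); output sorted by
    ascending e-value, then descending score, then protein id. The
    database size for the e-value is the genome's total proteome length.
    """
    if not genome.proteins:
        raise ValueError(f"genome {genome.genome_id!r} has an empty proteome")
    params = params or default_params()
    db_residues = genome.total_residues
    log_threshold = math.log10(family.evalue_threshold) \
        if math.isfinite(family.evalue_threshold) else math.inf
    hits: list[HomologHit] = []
    for target in genome.proteins:
        query, score = _best_partner(target.sequence, family.query_sequences, params)
        log_e = log10_evalue(score, len(query), db_residues, params)
        if log_e <= log_threshold:
            hits.append(HomologHit(
                family_name=family.family_name,
                genome_id=genome.genome_id,
                protein_id=target.protein_id,
                best_query_id=query.protein_id,
                score=score,
                evalue=evalue(score, len(query), db_residues, params),
                log10_evalue=log_e,
            ))
    hits.sort(key=lambda h: (h.log10_evalue, -h.score, h.protein_id))
    return hits


def confirm_rbh(hit: HomologHit, genome: Genome,
                reference_proteome: Sequence[ProteinRecord],
                params: Optional[AlignmentParams] = None) -> bool:
    """True iff the hit protein's best partner in the reference proteome
    is the query that produced the hit.

    The reference proteome is the source proteome of the query panel and
    must contain the queries themselves; paralogous neighbours in it are
    what reject spurious hits.
    """
    params = params or default_params()
    target = genome.protein_index.get(hit.protein_id)
    if target is None:
        raise GenomeIOError(
            f"hit protein {hit.protein_id!r} not found in genome {genome.genome_id!r}")
    best, _ = _best_partner(target.sequence, reference_proteome, params)
    return best.protein_id == hit.best_query_id


def rbh_pairs(proteome_a: Sequence[ProteinRecord], proteome_b: Sequence[ProteinRecord],
              params: Optional[AlignmentParams] = None) -> set[tuple[str, str]]:
    """Mutual-best pairs between two proteomes (symmetric by construction)."""
    params = params or default_params()
    best_ab = {p.protein_id: _best_partner(p.sequence, proteome_b, params)[0].protein_id
               for p in proteome_a}
    best_ba = {p.protein_id: _best_partner(p.sequence, proteome_a, params)[0].protein_id
               for p in proteome_b}
    return {(a, b) for a, b in best_ab.items() if best_ba.get(b) == a}


def search_panel(panel: Sequence[QueryFamily], genome: Genome,
                 reference_proteome: Sequence[ProteinRecord],
                 params: Optional[AlignmentParams] = None) -> list[HomologHit]:
    """Search every family and RBH-confirm each hit.

    The reciprocal best-partner lookup is computed once per distinct hit
    protein (a protein hitting several related families reuses it).
    """
    params = params or default_params()
    raw: list[HomologHit] = []
    for family in panel:
        raw.extend(search_family(family, genome, params))
    partner_cache: dict[str, str] = {}
    confirmed: list[HomologHit] = []
    index = genome.protein_index
    for hit in raw:
        if hit.protein_id not in partner_cache:
            best, _ = _best_partner(index[hit.protein_id].sequence,
                                    reference_proteome, params)
            partner_cache[hit.protein_id] = best.protein_id
        confirmed.append(replace(hit, rbh=partner_cache[hit.protein_id] == hit.best_query_id))
    return confirmed


# ---------------------------------------------------------------------------
# Panel configuration I/O


def load_query_panel(config_path, base_dir=None,
                     threshold_overrides: Optional[dict[str, float]] = None
                     ) -> list[QueryFamily]:
    """Load a query panel from YAML: family_name -> {fasta: path, threshold: x}.

    Paths are resolved relative to the config file (or ``base_dir``).
    Missing thresholds fall back to the structural/accessory defaults.
    """
    config_path = Path(config_path)
    base = Path(base_dir) if base_dir else config_path.parent
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    overrides = threshold_overrides or {}
    panel: list[QueryFamily] = []
    for name, entry in cfg["families"].items():
        records = read_fasta(base / entry["fasta"], genome_id="panel")
        threshold = overrides.get(name, entry.get("threshold", default_threshold(name)))
        panel.append(QueryFamily(family_name=name, query_sequences=records,
                                 evalue_threshold=float(threshold)))
    return panel


def write_hits_tsv(hits: Iterable[HomologHit], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("family\tgenome\tprotein\tquery\tscore\tevalue\trbh\n")
        for h in hits:
            fh.write(f"{h.family_name}\t{h.genome_id}\t{h.protein_id}\t"
                     f"{h.best_query_id}\t{h.score:g}\t{h.evalue:.6g}\t"
                     f"{int(h.rbh)}\n")
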