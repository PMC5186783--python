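"""Synthetic annotated genomes and cohorts with planted ground truth.

Every genome is laid out on one replicon as an ordered sequence of gene
blocks separated by runs of background genes, so requested cluster
arrangements are realized exactly. Planted genes are copies of the panel
queries with at most 2% random substitutions (always recoverable by the
reciprocal-best-hit search) that avoid catalytic motif sites, keeping
presence detection and motif verdicts independent test axes. Paralog
decoys are derived from the paralog siblings living in the query source
proteome, so the reciprocal check rejects them; background genes are
drawn from a uniform residue model at 150-600 aa. Everything is
deterministic per seed.

The expected outcome of every pipeline stage is derivable from the plant
specification alone and is returned as a truth row beside the genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import families as fam
from .genome_io import (GeneFeature, Genome, GenomeMetadata, ProteinRecord,
                        write_fasta, write_features, write_metadata)
from .panel import PanelBundle, default_panel, mutate_sequence, random_protein

PLANT_SUBSTITUTION_RATE = 0.02   # planted homolog divergence from its query
BACKGROUND_LENGTH_RANGE = (150, 600)
INTERGENIC_NT = 80               # spacing between adjacent genes
SEPARATOR_GENES = 4              # background genes isolating distinct blocks
DEFAULT_DECOYS = 50


class PlantError(ValueError):
    """Raised when a requested genome layout cannot be realized."""


@dataclass(frozen=True)
class SiteMutation:
    family: str
    site: int          # 1-based position on the family's query/anchor
    replacement: str


@dataclass(frozen=True)
class Truncation:
    family: str
    truncate_fraction: float  # C-terminal fraction removed


@dataclass
class SystemPlan:
    """Requested gene content and physical arrangement for one system."""

    partition: list[list[str]]          # blocks of family names
    expected_label: Optional[str] = None
    mixed_orientation_blocks: frozenset[int] = frozenset()
    xis_target: Optional[str] = None    # hup only: subunit interrupted by xisC

    @property
    def families(self) -> list[str]:
        return [f for block in self.partition for f in block]


@dataclass
class PlantSpec:
    genome_id: str
    seed: int
    habitat: str = "freshwater"
    subsection: str = "unknown"
    systems: dict[str, SystemPlan] = field(default_factory=dict)
    other_families: list[str] = field(default_factory=list)
    mutations: list[SiteMutation | Truncation] = field(default_factory=list)
    decoys: int = DEFAULT_DECOYS
    paralog_decoys: list[tuple[str, float]] = field(default_factory=list)
    extra_copies: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for family, identity in self.paralog_decoys:
            if not 0 < identity < 1:
                raise PlantError(
                    f"paralog decoy identity for {family!r} must be in (0,1)")

    @property
    def planted_families(self) -> list[str]:
        out: list[str] = []
        for system in ("hox", "hup", "hyp", "nif"):
            if system in self.systems:
                out.extend(self.systems[system].families)
        out.extend(self.other_families)
        if any(p.xis_target for p in self.systems.values()) \
                and fam.XIS_FAMILY not in out:
            out.append(fam.XIS_FAMILY)
        return out


@dataclass
class TruthRow:
    """Expected pipeline output, derived from the spec without running it."""

    genome_id: str
    habitat: str
    subsection: str
    family_copies: dict[str, int]
    degenerate_families: frozenset[str]
    labels: dict[str, str]              # system -> expected arrangement label
    hox_functional: bool
    hup_functional: bool
    nitrogen_fixing: bool
    o2_verdicts: dict[str, str]         # group -> expected verdict
    hox_state: str
    hup_state: str
    nif_state: str

    def family_status(self, family: str) -> str:
        if self.family_copies.get(family, 0) == 0:
            return "absent"
        return "present_degenerate" if family in self.degenerate_families else "present"


# ---------------------------------------------------------------------------
# Canonical arrangement plans

HOX_PARTITIONS = {
    "G1": [["hoxE", "hoxF", "hoxU", "hoxY", "hoxH"], ["hoxW"]],
    "G2": [["hoxE", "hoxF", "hoxU", "hoxY", "hoxH", "hoxW"]],
    "G3": [["hoxE", "hoxF", "hoxU", "hoxY"], ["hoxH"], ["hoxW"]],
    "G4": [["hoxE", "hoxF"], ["hoxU", "hoxY", "hoxH", "hoxW"]],
    "G5": [["hoxE", "hoxF"], ["hoxU", "hoxY", "hoxH"], ["hoxW"]],
    "G6": [["hoxE", "hoxF"], ["hoxU", "hoxY"], ["hoxH"], ["hoxW"]],
    "G7": [["hoxF", "hoxU", "hoxY", "hoxH", "hoxW"], ["hoxE"]],
}

HUP_PLANS = {
    "G1": ([["hupS", "hupL", "hupW"]], None),
    "G2": ([["hupS", "hupL"], ["hupW"]], None),
    "G3": ([["hupS", "hupL", "hupW"]], "hupS"),
    "G4": ([["hupS", "hupL", "hupW"]], "hupL"),
    "G5": ([["hupS", "hupL"], ["hupW"]], "hupS"),
}

HYP_PARTITIONS = {
    "1": [["hypA", "hypB", "hypC", "hypD", "hypE", "hypF"]],
    "2": [["hypA", "hypB", "hypC", "hypD", "hypE"], ["hypF"]],
    "4+2": [["hypA", "hypB", "hypC", "hypD"], ["hypE", "hypF"]],
    "3+2+1": [["hypA", "hypB", "hypC"], ["hypD", "hypE"], ["hypF"]],
    "1+1+1+1+1+1": [[f] for f in ("hypA", "hypB", "hypC", "hypD", "hypE", "hypF")],
}

SUPPORTED_LABELS = {"hox": tuple(HOX_PARTITIONS), "hup": tuple(HUP_PLANS),
                    "hyp": tuple(HYP_PARTITIONS)}


def hox_plan(label: str) -> SystemPlan:
    if label not in HOX_PARTITIONS:
        raise PlantError(f"unsupported hox arrangement {label!r}")
    return SystemPlan(partition=[list(b) for b in HOX_PARTITIONS[label]],
                      expected_label=label)


def hup_plan(label: str) -> SystemPlan:
    if label not in HUP_PLANS:
        raise PlantError(f"unsupported hup arrangement {label!r}")
    partition, xis = HUP_PLANS[label]
    return SystemPlan(partition=[list(b) for b in partition],
                      expected_label=label, xis_target=xis)


def hyp_plan(label: str) -> SystemPlan:
    if label not in HYP_PARTITIONS:
        raise PlantError(f"unsupported hyp arrangement {label!r}")
    return SystemPlan(partition=[list(b) for b in HYP_PARTITIONS[label]],
                      expected_label=label)


def nif_plan(include_dispensable: bool = False) -> SystemPlan:
    genes = list(fam.NIF_REQUIRED) + (list(fam.NIF_DISPENSABLE)
                                      if include_dispensable else [])
    return SystemPlan(partition=[genes], expected_label=None)


# ---------------------------------------------------------------------------
# Genome construction


def _validate(spec: PlantSpec, panel: PanelBundle) -> None:
    planted = spec.planted_families
    dupes = {f for f in planted if planted.count(f) > 1}
    if dupes:
        raise PlantError(f"{spec.genome_id}: families planted twice: {sorted(dupes)}")
    known = set(fam.ALL_FAMILIES)
    unknown = [f for f in planted if f not in known]
    if unknown:
        raise PlantError(f"{spec.genome_id}: unknown families {unknown}")
    for system, plan in spec.systems.items():
        allowed = set(fam.SYSTEM_FAMILIES.get(system, ()))
        extra = [f for f in plan.families if f not in allowed]
        if extra:
            raise PlantError(
                f"{spec.genome_id}: {system} plan contains foreign genes {extra}")
        if plan.xis_target is not None and plan.xis_target not in plan.families:
            raise PlantError(
                f"{spec.genome_id}: xisC target {plan.xis_target!r} not planted")
        if plan.xis_target is not None and fam.XIS_FAMILY in spec.other_families:
            raise PlantError(
                f"{spec.genome_id}: xisC cannot be both an interruption and a "
                f"free-standing gene")
    for family, _identity in spec.paralog_decoys:
        if family not in panel.siblings:
            raise PlantError(
                f"{spec.genome_id}: no paralog sibling available for {family!r}")
    n_blocks = sum(len(p.partition) for p in spec.systems.values())
    n_blocks += math.ceil(len(spec.other_families) / 4) or 0
    needed = SEPARATOR_GENES * max(0, n_blocks - 1) if n_blocks > 1 else 0
    if spec.decoys + len(spec.paralog_decoys) < needed:
        raise PlantError(
            f"{spec.genome_id}: {spec.decoys} background genes cannot isolate "
            f"{n_blocks} blocks (need >= {needed})")


def _planted_sequence(spec: PlantSpec, panel: PanelBundle, family: str,
                      rng: np.random.Generator) -> str:
    base = panel.query(family).sequence
    avoid = panel.motif_positions(family)
    seq = mutate_sequence(base, PLANT_SUBSTITUTION_RATE, rng, avoid_positions=avoid)
    for mut in spec.mutations:
        if mut.family != family:
            continue
        if isinstance(mut, SiteMutation):
            if not 1 <= mut.site <= len(seq):
                raise PlantError(
                    f"{spec.genome_id}: mutation site {mut.site} outside {family}")
            seq = seq[:mut.site - 1] + mut.replacement + seq[mut.site:]
        else:
            keep = int(round(len(seq) * (1.0 - mut.truncate_fraction)))
            if keep < 30:
                raise PlantError(
                    f"{spec.genome_id}: truncation of {family} leaves <30 aa")
            seq = seq[:keep]
    return seq


def _expected_degenerate(spec: PlantSpec, panel: PanelBundle) -> frozenset[str]:
    """Families whose motif verdict the mutations make degenerate."""
    out = set()
    for family, defs in panel.motif_map.items():
        if family not in spec.planted_families:
            continue
        ref_len = len(panel.query(family).sequence)
        kept = ref_len
        broken = False
        for mut in spec.mutations:
            if mut.family != family:
                continue
            if isinstance(mut, Truncation):
                kept = min(kept, int(round(ref_len * (1.0 - mut.truncate_fraction))))
        for defn in defs:
            for site in defn.sites:
                if site.reference_position > kept:
                    broken = True
                for mut in spec.mutations:
                    if isinstance(mut, SiteMutation) and mut.family == family \
                            and mut.site == site.reference_position \
                            and mut.replacement not in site.allowed_residues:
                        broken = True
        if broken:
            out.add(family)
    return frozenset(out)


def _truth(spec: PlantSpec, panel: PanelBundle) -> TruthRow:
    copies = {f: 1 + spec.extra_copies.get(f, 0) for f in spec.planted_families}
    degenerate = _expected_degenerate(spec, panel)

    def strict_present(families: Sequence[str]) -> bool:
        return all(copies.get(f, 0) > 0 and f not in degenerate for f in families)

    def any_present(families: Sequence[str]) -> bool:
        return any(copies.get(f, 0) > 0 for f in families)

    hyp_ok = strict_present(fam.HYP_SYSTEM)
    hox_ok = strict_present(fam.HOX_SYSTEM) and hyp_ok
    hup_ok = strict_present(fam.HUP_SYSTEM) and hyp_ok
    nif_ok = strict_present(fam.NIF_REQUIRED)

    labels = {}
    for system, plan in spec.systems.items():
        if plan.expected_label is not None:
            labels[system] = plan.expected_label

    o2: dict[str, str] = {}
    if any_present(fam.MBH_STRUCTURAL):
        pair = strict_present(fam.MBH_STRUCTURAL)
        sig = pair and "mbh1_small" not in degenerate
        minimum = strict_present(fam.MBH_ACCESSORY_MINIMUM)
        full = strict_present(fam.MBH_ACCESSORY_FULL)
        if pair and sig and minimum and full:
            o2["1"] = "candidate"
        elif pair and sig and minimum:
            o2["1"] = "questionable"
        else:
            o2["1"] = "rejected"
    if any_present(fam.SH3B_SUBUNITS):
        ok = strict_present(fam.SH3B_SUBUNITS) and hyp_ok \
            and "sh3b_delta" not in degenerate
        o2["3b"] = "candidate" if ok else "rejected"
    if any_present(fam.HOX_SYSTEM) and hox_ok:
        o2["3d"] = "candidate"

    def state(system: str, complete: bool) -> str:
        if not any_present(fam.SYSTEM_FAMILIES[system]):
            return "absent"
        return "complete" if complete else "incomplete"

    return TruthRow(
        genome_id=spec.genome_id, habitat=spec.habitat, subsection=spec.subsection,
        family_copies=copies, degenerate_families=degenerate, labels=labels,
        hox_functional=hox_ok, hup_functional=hup_ok, nitrogen_fixing=nif_ok,
        o2_verdicts=o2,
        hox_state=state("hox", strict_present(fam.HOX_SYSTEM)),
        hup_state=state("hup", strict_present(fam.HUP_SYSTEM)),
        nif_state=state("nif", nif_ok),
    )


def generate_genome(spec: PlantSpec,
                    panel: Optional[PanelBundle] = None) -> tuple[Genome, TruthRow]:
    """Realize a plant specification as an annotated genome plus its truth."""
    panel = panel or default_panel()
    _validate(spec, panel)
    rng = np.random.default_rng(spec.seed)

    proteins: list[ProteinRecord] = []
    features: list[GeneFeature] = []
    gid = spec.genome_id

    # sequences for every planted gene copy
    planted_seqs: dict[str, list[str]] = {}
    for family in spec.planted_families:
        n = 1 + spec.extra_copies.get(family, 0)
        planted_seqs[family] = [_planted_sequence(spec, panel, family, rng)
                                for _ in range(n)]

    # blocks to lay out: system partitions, then extra copies and other
    # families as their own scattered/chunked blocks
    blocks: list[list[tuple[str, int]]] = []   # (family, copy index)
    xis_targets = {p.xis_target for p in spec.systems.values() if p.xis_target}
    mixed: set[int] = set()
    for system in ("hox", "hup", "hyp", "nif"):
        plan = spec.systems.get(system)
        if plan is None:
            continue
        for bi, block in enumerate(plan.partition):
            if bi in plan.mixed_orientation_blocks:
                mixed.add(len(blocks))
            blocks.append([(f, 0) for f in block])
    for family, extra in spec.extra_copies.items():
        for copy_idx in range(1, extra + 1):
            blocks.append([(family, copy_idx)])
    others = [f for f in spec.other_families]
    if fam.XIS_FAMILY in spec.planted_families \
            and fam.XIS_FAMILY not in others \
            and not any(fam.XIS_FAMILY == f for p in spec.systems.values()
                        for f in p.families):
        pass  # xisC planted only as an interruption; emitted with its target
    for i in range(0, len(others), 4):
        blocks.append([(f, 0) for f in others[i:i + 4]])

    order = list(rng.permutation(len(blocks))) if blocks else []

    background: list[str] = [
        random_protein(rng, int(rng.integers(*BACKGROUND_LENGTH_RANGE)))
        for _ in range(spec.decoys)]
    decoy_seqs: list[tuple[str, str]] = []
    for family, identity in spec.paralog_decoys:
        sibling = panel.siblings[family]
        decoy_seqs.append((family, mutate_sequence(sibling.sequence,
                                                   1.0 - identity, rng)))

    cursor = 200
    bg_iter = iter(range(len(background)))
    bg_emitted = 0

    def emit(protein_id: str, sequence: str, strand: str,
             span_extra: int = 0) -> GeneFeature:
        nonlocal cursor
        length_nt = 3 * (len(sequence) + 1) + span_extra
        feat = GeneFeature(gene_id=protein_id, genome_id=gid, replicon_id="chr",
                           start=cursor, end=cursor + length_nt, strand=strand,
                           protein_id=protein_id)
        proteins.append(ProteinRecord(protein_id=protein_id, genome_id=gid,
                                      sequence=sequence))
        features.append(feat)
        cursor = feat.end + INTERGENIC_NT
        return feat

    def emit_background(count: int) -> None:
        nonlocal bg_emitted
        for _ in range(count):
            try:
                i = next(bg_iter)
            except StopIteration:
                return
            emit(f"{gid}_bg{i:03d}", background[i], "+")
            bg_emitted += 1

    xis_seq = planted_seqs.get(fam.XIS_FAMILY, [None])[0]
    for pos, bi in enumerate(order):
        if pos > 0:
            emit_background(SEPARATOR_GENES)
        block = blocks[bi]
        block_strand = "+" if rng.integers(2) == 0 else "-"
        for mi, (family, copy_idx) in enumerate(block):
            strand = block_strand
            if bi in mixed and mi % 2 == 1:
                strand = "-" if block_strand == "+" else "+"
            name = f"{gid}_{family}" + (f"_{copy_idx}" if copy_idx else "")
            if family in xis_targets:
                # interrupted subunit: its gene span is widened to hold the
                # nested xisC element
                xis_nt = 3 * (len(xis_seq) + 1)
                feat = emit(name, planted_seqs[family][copy_idx], strand,
                            span_extra=xis_nt + 2 * INTERGENIC_NT)
                xis_start = feat.start + (len(feat) - xis_nt) // 2
                features.append(GeneFeature(
                    gene_id=f"{gid}_xisC", genome_id=gid, replicon_id="chr",
                    start=xis_start, end=xis_start + xis_nt, strand="+",
                    protein_id=f"{gid}_xisC"))
                proteins.append(ProteinRecord(protein_id=f"{gid}_xisC",
                                              genome_id=gid, sequence=xis_seq))
            else:
                emit(name, planted_seqs[family][copy_idx], strand)

    # paralog decoys and remaining background fill the tail of the replicon
    for di, (family, seq) in enumerate(decoy_seqs):
        emit_background(1)
        emit(f"{gid}_decoy_{family}_{di}", seq, "+")
    emit_background(len(background) - bg_emitted)

    metadata = GenomeMetadata(genome_id=gid, habitat=spec.habitat,
                              subsection=spec.subsection)
    genome = Genome(genome_id=gid, proteins=proteins, features=features,
                    metadata=metadata)
    return genome, _truth(spec, panel)


def write_genome(genome: Genome, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genome.proteins, outdir / f"{genome.genome_id}.faa")
    write_features(genome.features, outdir / f"{genome.genome_id}.gff3")


# ---------------------------------------------------------------------------
# Cohorts


def _cycler(values: Sequence[str]):
    i = 0
    def nxt() -> str:
        nonlocal i
        v = values[i % len(values)]
        i += 1
        return v
    return nxt


ARCHETYPES = ("both", "hox_only", "hup_only", "nif_only", "none")

DEFAULT_MIX = {"both": 0.25, "hox_only": 0.25, "hup_only": 0.2, "nif_only": 0.1,
               "none": 0.2}

DEFAULT_HABITATS = {"freshwater": 0.4, "open_ocean": 0.15, "coastal": 0.15,
                    "terrestrial": 0.15, "hot_spring": 0.1, "salt_lake": 0.05}


def _apportion(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder integer apportionment of n among categories."""
    total = sum(proportions.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"mix proportions must sum to 1 (got {total})")
    raw = {k: n * p for k, p in proportions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    leftover = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))[:leftover]:
        counts[k] += 1
    return counts


def spec_for_archetype(archetype: str, genome_id: str, seed: int,
                       habitat: str, subsection: str,
                       hox_label: str = "G1", hup_label: str = "G1",
                       hyp_label: str = "1") -> PlantSpec:
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    systems: dict[str, SystemPlan] = {}
    if archetype in ("both", "hox_only"):
        systems["hox"] = hox_plan(hox_label)
    if archetype in ("both", "hup_only"):
        systems["hup"] = hup_plan(hup_label)
    if archetype in ("both", "hox_only", "hup_only"):
        systems["hyp"] = hyp_plan(hyp_label)
    if archetype in ("both", "hup_only", "nif_only"):
        systems["nif"] = nif_plan()
    return PlantSpec(genome_id=genome_id, seed=seed, habitat=habitat,
                     subsection=subsection, systems=systems)


def generate_cohort(n: int, mix: Optional[dict[str, float]] = None,
                    habitat_distribution: Optional[dict[str, float]] = None,
                    seed: int = 0, outdir=None,
                    panel: Optional[PanelBundle] = None
                    ) -> tuple[list[Genome], pd.DataFrame]:
    """Generate ``n`` genomes whose category mix follows ``mix``.

    Per-genome seeds derive from the master seed; arrangement labels cycle
    through the supported set so cohorts exercise the whole taxonomy. With
    ``outdir`` set, genomes, metadata, truth table and a manifest are
    written in the dialects the readers consume.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    panel = panel or default_panel()
    mix = mix or DEFAULT_MIX
    habitat_distribution = habitat_distribution or DEFAULT_HABITATS
    rng = np.random.default_rng(seed)
    counts = _apportion(n, mix)
    habitat_counts = _apportion(n, habitat_distribution)
    habitats = [h for h, c in sorted(habitat_counts.items()) for _ in range(c)]
    rng.shuffle(habitats)

    hox_next = _cycler(SUPPORTED_LABELS["hox"])
    hup_next = _cycler(SUPPORTED_LABELS["hup"])
    hyp_next = _cycler(SUPPORTED_LABELS["hyp"])
    subsections = _cycler(("I", "II", "III", "IV", "V"))

    genomes: list[Genome] = []
    truths: list[TruthRow] = []
    idx = 0
    for archetype in sorted(counts):
        for _ in range(counts[archetype]):
            gid = f"syn{idx:03d}"
            child_seed = int(rng.integers(2 ** 31))
            spec = spec_for_archetype(
                archetype, gid, child_seed, habitats[idx], subsections(),
                hox_label=hox_next(), hup_label=hup_next(), hyp_label=hyp_next())
            genome, truth = generate_genome(spec, panel)
            genomes.append(genome)
            truths.append(truth)
            idx += 1

    truth_df = truth_frame(truths)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for genome in genomes:
            write_genome(genome, outdir)
        write_metadata([g.metadata for g in genomes], outdir / "metadata.tsv")
        truth_df.to_csv(outdir / "truth.tsv", sep="\t")
        manifest = {"n": n, "seed": seed, "mix": mix,
                    "habitat_distribution": habitat_distribution,
                    "genomes": [g.genome_id for g in genomes]}
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return genomes, truth_df


def truth_frame(truths: Sequence[TruthRow]) -> pd.DataFrame:
    rows = []
    for t in truths:
        rows.append({
            "genome_id": t.genome_id,
            "habitat": t.habitat,
            "subsection": t.subsection,
            "families": ";".join(f"{f}:{c}" for f, c in sorted(t.family_copies.items())),
            "degenerate": ";".join(sorted(t.degenerate_families)),
            "hox_label": t.labels.get("hox", ""),
            "hup_label": t.labels.get("hup", ""),
            "hyp_label": t.labels.get("hyp", ""),
            "hox_functional": t.hox_functional,
            "hup_functional": t.hup_functional,
            "nitrogen_fixing": t.nitrogen_fixing,
            "o2": ";".join(f"{g}:{v}" for g, v in sorted(t.o2_verdicts.items())),
            "hox_state": t.hox_state,
            "hup_state": t.hup_state,
            "nif_state": t.nif_state,
        })
    return pd.DataFrame(rows).set_index("genome_id")


# ---------------------------------------------------------------------------
# The survey-style benchmark cohort: every supported arrangement label,
# degenerate motifs, incomplete sets, multicopy hoxW, paralog decoys,
# O2-tolerance archetypes and hydrogenase-free genomes in 30 genomes.


def survey_cohort_specs(seed: int) -> list[PlantSpec]:
    rng = np.random.default_rng(seed)

    def child() -> int:
        return int(rng.integers(2 ** 31))

    specs: list[PlantSpec] = []
    hyp_next = _cycler(tuple(HYP_PARTITIONS))
    idx = 0

    def gid() -> str:
        nonlocal idx
        idx += 1
        return f"syn{idx - 1:03d}"

    # one genome per hox arrangement, hyp labels cycling, occasional nif
    for i, label in enumerate(SUPPORTED_LABELS["hox"]):
        systems = {"hox": hox_plan(label), "hyp": hyp_plan(hyp_next())}
        extra = {}
        decoys = []
        if label == "G2":
            extra = {"hoxW": 2}          # multicopy endopeptidase state
        if label == "G1":
            decoys = [("hoxH", 0.9)]     # paralog decoy the RBH must reject
        if i % 2 == 0:
            systems["nif"] = nif_plan(include_dispensable=(i == 0))
        specs.append(PlantSpec(genome_id=gid(), seed=child(), habitat="freshwater",
                               subsection="III", systems=systems,
                               extra_copies=extra, paralog_decoys=decoys))

    # one genome per hup arrangement (xisC interruptions included)
    for label in SUPPORTED_LABELS["hup"]:
        systems = {"hup": hup_plan(label), "hyp": hyp_plan(hyp_next()),
                   "nif": nif_plan()}
        specs.append(PlantSpec(genome_id=gid(), seed=child(), habitat="terrestrial",
                               subsection="IV", systems=systems,
                               paralog_decoys=[("hupS", 0.85)] if label == "G2" else []))

    # genomes carrying both enzymes
    for hox_label, hup_label in (("G1", "G1"), ("G2", "G2"), ("G5", "G3"), ("G7", "G4")):
        systems = {"hox": hox_plan(hox_label), "hup": hup_plan(hup_label),
                   "hyp": hyp_plan(hyp_next()), "nif": nif_plan()}
        specs.append(PlantSpec(genome_id=gid(), seed=child(), habitat="coastal",
                               subsection="V", systems=systems))

    # incomplete sets: missing structural gene, missing peptidase, missing hyp
    specs.append(PlantSpec(
        genome_id=gid(), seed=child(), habitat="hot_spring", subsection="I",
        systems={"hox": SystemPlan(partition=[["hoxE", "hoxF", "hoxU", "hoxY"]]),
                 "hyp": hyp_plan("1")}))
    specs.append(PlantSpec(
        genome_id=gid(), seed=child(), habitat="freshwater", subsection="III",
        systems={"hup": SystemPlan(partition=[["hupS", "hupL"]]),
                 "hyp": hyp_plan("2"), "nif": nif_plan()}))
    specs.append(PlantSpec(
        genome_id=gid(), seed=child(), habitat="terrestrial", subsection="I",
        systems={"hox": hox_plan("G2"),
                 "hyp": SystemPlan(partition=[["hypA", "hypB"]])}))

    # degenerate catalytic residues: substitution and truncation
    specs.append(PlantSpec(
        genome_id=gid(), seed=child(), habitat="coastal", subsection="I",
        systems={"hox": hox_plan("G1"), "hyp": hyp_plan("1")},
        mutations=[SiteMutation("hoxU", 28, "S")]))
    specs.append(PlantSpec(
        genome_id=gid(), seed=child(), habitat="freshwater", subsection="IV",
        systems={"hup": hup_plan("G1"), "hyp": hyp_plan("2"), "nif": nif_plan()},
        mutations=[Truncation("hupS", 0.7)]))

    # O2-tolerance archetypes: full MBH candidate, accessory-poor MBH,
    # and a group 3b candidate
    specs.append(PlantSpec(
        genome_id=gid(), seed=child(), habitat="open_ocean", subsection="III",
        systems={"hyp": hyp_plan("1")},
        other_families=list(fam.MBH_STRUCTURAL) + list(fam.MBH_ACCESSORY_FULL)))
    specs.append(PlantSpec(
        genome_id=gid(), seed=child(), habitat="coastal", subsection="III",
        systems={"hyp": hyp_plan("1")},
        other_families=list(fam.MBH_STRUCTURAL) + list(fam.MBH_ACCESSORY_MINIMUM)))
    specs.append(PlantSpec(
        genome_id=gid(), seed=child(), habitat="freshwater", subsection="I",
        systems={"hyp": hyp_plan("1")},
        other_families=list(fam.SH3B_SUBUNITS)))

    # hydrogenase-free genomes: plain, nif-only, and decoy-bearing
    for i in range(6):
        systems = {"nif": nif_plan()} if i % 2 == 0 else {}
        decoys = [("nifH", 0.85)] if i == 1 else []
        habitat = "open_ocean" if i < 3 else "salt_lake"
        specs.append(PlantSpec(genome_id=gid(), seed=child(), habitat=habitat,
                               subsection="II", systems=systems,
                               paralog_decoys=decoys))

    assert len(specs) == 30
    return specs
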