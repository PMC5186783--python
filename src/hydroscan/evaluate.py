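"""Benchmark evaluations: truth-table round trips and oracle sweeps.

Used by the acceptance checks and the analysis drivers; everything here
runs the production pipeline (or the production aligner) against an
independently derived expectation and reports agreement fractions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .align import global_score, local_score
from .families import presence_map
from .genome_io import GenomeMetadata
from .motifs import check_motif
from .naive_align import (enumerate_global, enumerate_local, gotoh_global,
                          gotoh_local)
from .panel import PanelBundle, default_panel
from .pipeline import run_classify, scan_genome
from .summary import categorize, summarize
from .synth import (PlantSpec, generate_genome, hup_plan, hyp_plan,
                    nif_plan, survey_cohort_specs)


@dataclass
class RoundTrip:
    """Agreement between pipeline output and planted truth on a cohort."""

    n_genomes: int = 0
    presence_total: int = 0
    presence_correct: int = 0
    motif_total: int = 0
    motif_correct: int = 0
    label_total: int = 0
    label_correct: int = 0
    o2_total: int = 0
    o2_correct: int = 0
    capability_tp: int = 0
    capability_fp: int = 0
    capability_fn: int = 0
    capability_tn: int = 0
    mismatches: list = field(default_factory=list)

    @property
    def presence_accuracy(self) -> float:
        return self.presence_correct / self.presence_total

    @property
    def motif_accuracy(self) -> float:
        return self.motif_correct / self.motif_total if self.motif_total else 1.0

    @property
    def label_accuracy(self) -> float:
        return self.label_correct / self.label_total if self.label_total else 1.0

    @property
    def o2_accuracy(self) -> float:
        return self.o2_correct / self.o2_total if self.o2_total else 1.0

    @property
    def capability_precision(self) -> float:
        denom = self.capability_tp + self.capability_fp
        return self.capability_tp / denom if denom else 1.0

    @property
    def capability_recall(self) -> float:
        denom = self.capability_tp + self.capability_fn
        return self.capability_tp / denom if denom else 1.0


def roundtrip_survey(seed: int, panel: PanelBundle | None = None
                     ) -> tuple[RoundTrip, list, dict]:
    """Run the full pipeline on the 30-genome benchmark cohort and score it
    against the planted truth.

    Returns the scorecard, the capability calls, and the per-genome truth
    rows (for downstream summaries).
    """
    panel = panel or default_panel()
    specs = survey_cohort_specs(seed)
    rt = RoundTrip()
    capabilities = {}
    truths = {}
    scans = {}
    genomes = {}
    for spec in specs:
        genome, truth = generate_genome(spec, panel)
        scan = scan_genome(genome, panel)
        genomes[genome.genome_id] = genome
        scans[genome.genome_id] = scan
        truths[genome.genome_id] = truth
        rt.n_genomes += 1

        pm = presence_map(scan.presence)
        for family, p in pm.items():
            rt.presence_total += 1
            expected = (truth.family_status(family),
                        truth.family_copies.get(family, 0))
            if (p.status, p.copy_number) == expected:
                rt.presence_correct += 1
            else:
                rt.mismatches.append((genome.genome_id, "presence", family,
                                      (p.status, p.copy_number), expected))

        for family in panel.motif_map:
            if truth.family_copies.get(family, 0) == 0:
                continue
            rt.motif_total += 1
            reports = scan.motif_reports.get(family, [])
            got_degenerate = bool(reports) and all(
                r.verdict == "degenerate" for r in reports)
            if got_degenerate == (family in truth.degenerate_families):
                rt.motif_correct += 1
            else:
                rt.mismatches.append((genome.genome_id, "motif", family))

    arrangements, caps = run_classify(list(genomes.values()), scans)
    for gid, truth in truths.items():
        call = caps[gid]
        capabilities[gid] = call
        for system, expected in truth.labels.items():
            rt.label_total += 1
            got = arrangements[gid].get(system)
            if got is not None and got.label == expected:
                rt.label_correct += 1
            else:
                rt.mismatches.append((gid, "label", system,
                                      got.label if got else None, expected))
        for got, expected in ((call.hox_functional, truth.hox_functional),
                              (call.hup_functional, truth.hup_functional),
                              (call.nitrogen_fixing, truth.nitrogen_fixing)):
            if got and expected:
                rt.capability_tp += 1
            elif got and not expected:
                rt.capability_fp += 1
            elif expected and not got:
                rt.capability_fn += 1
            else:
                rt.capability_tn += 1
        got_o2 = {g: v for g, v, _ in call.o2_tolerant_candidates}
        rt.o2_total += 1
        if got_o2 == truth.o2_verdicts:
            rt.o2_correct += 1
        else:
            rt.mismatches.append((gid, "o2", got_o2, truth.o2_verdicts))
    return rt, capabilities, truths


# ---------------------------------------------------------------------------
# Alignment oracle sweeps

ORACLE_ALPHABET = "ARND"


def _random_peptides(rng: np.random.Generator, n: int, max_len: int) -> list[str]:
    out = []
    for _ in range(n):
        length = int(rng.integers(1, max_len + 1))
        out.append("".join(rng.choice(list(ORACLE_ALPHABET), length)))
    return out


def oracle_sweep(seed: int, exhaustive_len: int = 3, n_enum_global: int = 300,
                 n_enum_local: int = 100, n_gotoh: int = 1500) -> dict[str, int]:
    """Compare production scores against the independent oracles.

    Exhaustive all-pairs up to ``exhaustive_len`` over the 4-letter
    alphabet against the full enumeration oracle (local and global), plus
    seeded random pairs up to length 6 against the enumeration and Gotoh
    oracles. Returns counts of compared and agreeing pairs.
    """
    rng = np.random.default_rng(seed)
    seqs = []
    for length in range(1, exhaustive_len + 1):
        seqs.extend("".join(t) for t in
                    itertools.product(ORACLE_ALPHABET, repeat=length))
    stats = {"local_total": 0, "local_agree": 0,
             "global_total": 0, "global_agree": 0}

    def record(kind: str, production: float, oracle: float) -> None:
        stats[f"{kind}_total"] += 1
        if production == oracle:
            stats[f"{kind}_agree"] += 1

    for a, b in itertools.product(seqs, repeat=2):
        record("local", local_score(a, b), enumerate_local(a, b))
        record("global", global_score(a, b), enumerate_global(a, b))

    pool = _random_peptides(rng, 2 * n_enum_global, 6)
    for i in range(n_enum_global):
        a, b = pool[2 * i], pool[2 * i + 1]
        record("global", global_score(a, b), enumerate_global(a, b))
    pool = _random_peptides(rng, 2 * n_enum_local, 6)
    for i in range(n_enum_local):
        a, b = pool[2 * i], pool[2 * i + 1]
        record("local", local_score(a, b), enumerate_local(a, b))
    pool = _random_peptides(rng, 2 * n_gotoh, 6)
    for i in range(n_gotoh):
        a, b = pool[2 * i], pool[2 * i + 1]
        record("local", local_score(a, b), gotoh_local(a, b))
        record("global", global_score(a, b), gotoh_global(a, b))
    return stats


# ---------------------------------------------------------------------------
# Signature logic check


def mbh_signature_check(panel: PanelBundle | None = None) -> dict[str, int]:
    """Verify the O2-tolerance signature call on the anchor and on every
    single-site disallowed substitution of it."""
    panel = panel or default_panel()
    defn = next(m for m in panel.motifs if m.motif_id == "mbh_proximal_4Fe3S")
    anchor = defn.reference_protein
    identity = check_motif(defn, anchor)
    results = {
        "reference_failed_sites": len(identity.failed_sites),
        "n_sites": len(defn.sites),
        "single_mutants_checked": 0,
        "single_mutants_with_one_failed_site": 0,
    }
    for site in defn.sites:
        seq = list(anchor.sequence)
        seq[site.reference_position - 1] = \
            "A" if "A" not in site.allowed_residues else "G"
        mutant = anchor.__class__(protein_id=f"mut{site.reference_position}",
                                  genome_id="synthetic",
                                  sequence="".join(seq))
        report = check_motif(defn, mutant)
        results["single_mutants_checked"] += 1
        if report.verdict == "degenerate" \
                and report.failed_sites == [site.reference_position]:
            results["single_mutants_with_one_failed_site"] += 1
    return results


# ---------------------------------------------------------------------------
# Stratified accounting check


def open_ocean_stratum(seed: int, panel: PanelBundle | None = None
                       ) -> dict[str, float]:
    """Plant a 9-genome open-ocean stratum (8 hydrogenase-free, 1 hup-only),
    run the pipeline and return the stratum's percentage split."""
    panel = panel or default_panel()
    rng = np.random.default_rng(seed)
    specs = [PlantSpec(genome_id=f"oo{i}", seed=int(rng.integers(2 ** 31)),
                       habitat="open_ocean", subsection="I", decoys=15,
                       systems={})
             for i in range(8)]
    specs.append(PlantSpec(
        genome_id="oo8", seed=int(rng.integers(2 ** 31)), habitat="open_ocean",
        subsection="I", decoys=15,
        systems={"hup": hup_plan("G1"), "hyp": hyp_plan("1"), "nif": nif_plan()}))
    presence_by_genome = {}
    metadata = {}
    for spec in specs:
        genome, _ = generate_genome(spec, panel)
        scan = scan_genome(genome, panel)
        presence_by_genome[genome.genome_id] = scan.presence
        metadata[genome.genome_id] = GenomeMetadata(genome.genome_id,
                                                    "open_ocean", "I")
    table = summarize(categorize(presence_by_genome), metadata, axis="habitat")
    free = table[table.combination.str.startswith("hox-/hup-")]
    hup_only = table[table.combination.str.startswith("hox-/hup+")]
    return {
        "h2ase_free_pct": int(free.percentage_display.iloc[0]),
        "hup_only_pct": int(hup_only.percentage_display.iloc[0]),
        "h2ase_free_count": int(free["count"].iloc[0]),
        "hup_only_count": int(hup_only["count"].iloc[0]),
        "denominator": int(table["denominator"].iloc[0]),
    }
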