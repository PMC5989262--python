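"""End-to-end orchestration: flow calls -> ploidy -> cytotypes -> popgen.

The pipeline consumes either a synthetic cohort (generated in memory) or
on-disk inputs (per-sample event CSVs plus a blade manifest, and a GenAlEx
genotype CSV), and produces a deterministic set of report tables: per-sample
genome-size calls, blade cytotype profiles, per-species cytotype incidence,
per-group diversity, pairwise differentiation matrices, PCA coordinates and
a neighbour-joining tree.  Failing samples are excluded with a logged reason,
never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .flowcyto import (
    EventTable,
    GenomeSizeCall,
    StandardRef,
    analyze_sample,
)
from .genotypes import (
    PolyploidGenotype,
    assign_groups,
    bin_alleles,
    concordance_check,
    fit_grid_offset,
    impute_missing,
)
from .ploidy import (
    BaseCalibration,
    CytotypeProfile,
    PloidyCall,
    assign_ploidy,
    build_profile,
    calibrate_base,
    summarize_cytotype_frequencies,
)
from .popgen import (
    allele_freqs_ml,
    allele_freqs_naive,
    diversity,
    individual_distances,
    nj_tree,
    pairwise_differentiation,
    pca_allelic,
)
from .synthetic import Cohort, SimConfig, simulate_cohort, study_cohort

__all__ = [
    "RunConfig",
    "RunReport",
    "process_flow_cohort",
    "profiles_from_calls",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    seed: int = 0
    use_study_design: bool = True
    sim: SimConfig | None = None
    outdir: str | None = None
    rel_tol: float = 0.15
    max_cv: float = 5.0
    standard_tolerance: float = 0.15
    g2_max_proportion: float = 0.25
    em_tol: float = 1e-8
    dosage_corrected: bool = True


@dataclass
class RunReport:
    """All report tables of one run plus a provenance block."""

    flow_calls: pd.DataFrame
    profiles: pd.DataFrame
    cytotype_frequencies: pd.DataFrame
    diversity_table: pd.DataFrame
    gst_matrix: pd.DataFrame
    d_matrix: pd.DataFrame
    pca_coords: pd.DataFrame
    newick: str
    failures: list[tuple[str, str]]
    provenance: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.flow_calls.to_csv(out / "flow_calls.tsv", sep="\t", index=False)
        self.profiles.to_csv(out / "cytotype_profiles.tsv", sep="\t", index=False)
        self.cytotype_frequencies.to_csv(
            out / "cytotype_frequencies.tsv", sep="\t", index=False
        )
        self.diversity_table.to_csv(out / "diversity.tsv", sep="\t", index=False)
        self.gst_matrix.to_csv(out / "pairwise_gst.tsv", sep="\t")
        self.d_matrix.to_csv(out / "pairwise_jost_d.tsv", sep="\t")
        self.pca_coords.to_csv(out / "pca_coords.tsv", sep="\t")
        (out / "nj_tree.nwk").write_text(self.newick + "\n")
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=1, sort_keys=True)
        if self.failures:
            pd.DataFrame(self.failures, columns=["sample_id", "reason"]).to_csv(
                out / "failures.tsv", sep="\t", index=False
            )


def process_flow_cohort(
    samples: Iterable[tuple[EventTable, str, str]],
    std: StandardRef,
    max_cv: float = 5.0,
    standard_tolerance: float = 0.15,
) -> tuple[list[tuple[str, GenomeSizeCall]], list[tuple[str, str]]]:
    """Run the single-sample flow chain over a cohort.

    *samples* yields (events, blade_id, section_type).  Returns
    (blade_id, GenomeSizeCall) pairs for the successful samples and
    (sample_id, reason) pairs for the failures.
    """
    calls: list[tuple[str, GenomeSizeCall]] = []
    failures: list[tuple[str, str]] = []
    for events, blade_id, section in samples:
        try:
            _, call = analyze_sample(
                events,
                std,
                section_type=section,
                standard_tolerance=standard_tolerance,
                max_cv=max_cv,
            )
            calls.append((blade_id, call))
        except (ValueError, RuntimeError) as exc:
            failures.append((events.sample_id, str(exc)))
    return calls, failures


def profiles_from_calls(
    calls: Sequence[tuple[str, GenomeSizeCall]],
    species_of: dict[str, str],
    cal: BaseCalibration | None = None,
    rel_tol: float = 0.15,
) -> tuple[list[CytotypeProfile], BaseCalibration]:
    """Assign ploidies to every genome-size call and classify blades.

    The base calibration is derived from the gamete sections unless given.
    """
    if cal is None:
        cal = calibrate_base([c for _, c in calls])
    by_blade: dict[str, dict[str, PloidyCall]] = {}
    for blade_id, call in calls:
        ploidies, sizes, unassigned = [], [], []
        for size in call.sizes_pg:
            p = assign_ploidy(size, cal, rel_tol)
            if p is None:
                unassigned.append((size, "ratio off-grid"))
            else:
                ploidies.append(p)
                sizes.append(size)
        pc = PloidyCall(
            sample_id=call.sample_id,
            section_type=call.section_type,
            ploidies=ploidies,
            genome_sizes_pg=sizes,
            unassigned=unassigned,
        )
        sections = by_blade.setdefault(blade_id, {})
        if call.section_type in sections:
            # merge repeated analyses of the same section type
            prev = sections[call.section_type]
            merged = sorted(set(prev.ploidies) | set(pc.ploidies))
            prev.ploidies = merged
            prev.genome_sizes_pg = sorted(set(prev.genome_sizes_pg) | set(sizes))
        else:
            sections[call.section_type] = pc
    profiles = [
        build_profile(blade_id, species_of.get(blade_id, ""), sections)
        for blade_id, sections in sorted(by_blade.items())
    ]
    return profiles, cal


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in vars(cfg).items() if k != "sim"}, sort_keys=True
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, cohort: Cohort | None = None) -> RunReport:
    """Execute flowcyto -> ploidy -> genotypes -> popgen on a cohort.

    With no *cohort*, one is generated from ``cfg``: the fixed survey design
    when ``cfg.use_study_design`` else a random draw from ``cfg.sim``.
    Deterministic: identical config and seed give identical report bodies.
    """
    if cohort is None:
        if cfg.use_study_design:
            cohort = study_cohort(cfg.seed, cfg.sim)
        else:
            sim = cfg.sim if cfg.sim is not None else SimConfig()
            sim.seed = cfg.seed
            cohort = simulate_cohort(sim)
    std = cohort.config.flow.standard_ref()

    sample_iter = (
        (events, truth.blade_id, truth.section_type)
        for events, truth in cohort.flow_samples()
    )
    calls, failures = process_flow_cohort(
        sample_iter, std, max_cv=cfg.max_cv, standard_tolerance=cfg.standard_tolerance
    )
    species_of = {b.blade_id: b.species for b in cohort.blades}
    profiles, cal = profiles_from_calls(calls, species_of, rel_tol=cfg.rel_tol)
    if not any(p.cytotype for p in profiles):
        raise RuntimeError(
            "no classifiable blades; per-sample failures: " + repr(failures)
        )

    flow_rows = []
    for blade_id, call in calls:
        flow_rows.append(
            dict(
                blade_id=blade_id,
                sample_id=call.sample_id,
                section_type=call.section_type,
                sizes_pg=";".join(f"{s:.3f}" for s in call.sizes_pg),
                cvs=";".join(f"{c:.2f}" for c in call.cvs),
                qc_pass=call.qc_pass,
            )
        )
    flow_df = pd.DataFrame(flow_rows).sort_values("sample_id").reset_index(drop=True)

    prof_df = pd.DataFrame(
        [
            dict(
                blade_id=p.blade_id,
                species=p.species,
                notation=p.notation,
                cytotype=p.cytotype,
                group=p.group,
                cell_lines=",".join(map(str, sorted(p.cell_lines))),
                unclassified_reason=p.unclassified_reason or "",
            )
            for p in profiles
        ]
    )

    freqs = summarize_cytotype_frequencies(profiles)
    freq_rows = []
    for species in sorted(freqs):
        f = freqs[species]
        for ct in sorted(f.cytotype_counts):
            freq_rows.append(
                dict(
                    species=species,
                    cytotype=ct,
                    count=f.cytotype_counts[ct],
                    pct=round(f.cytotype_pct(ct), 1),
                    n_classified=f.n_classified,
                )
            )
    freq_df = pd.DataFrame(freq_rows)

    # --- genotype branch -------------------------------------------------
    offsets = {
        l.name: fit_grid_offset(
            [a for g in cohort.genotypes for a in g.loci.get(l.name, ())],
            l.repeat_unit,
        )
        for l in cohort.loci
    }
    binned = [bin_alleles(g, cohort.loci, offsets) for g in cohort.genotypes]
    # cross-check: allele-count ploidy bound vs the flow-cytometric ploidy
    discordant = [
        g.individual_id
        for g in binned
        if g.ploidy is not None
        and g.scored_loci()
        and not concordance_check(g, g.ploidy)
    ]
    assignment = assign_groups(binned, cohort.rule_table)
    groups: dict[str, list[PolyploidGenotype]] = {}
    for g in binned:
        gid = assignment.assignments.get(g.individual_id)
        if gid is not None:
            groups.setdefault(gid, []).append(g)

    imputed_groups: dict[str, list[PolyploidGenotype]] = {}
    for gid in sorted(groups):
        members, _ = impute_missing(groups[gid], seed=cfg.seed)
        imputed_groups[gid] = members

    div_rows = []
    for gid in sorted(imputed_groups):
        members = imputed_groups[gid]
        if len(members) < 2:
            continue
        for corrected in (False, True):
            if corrected:
                fr = allele_freqs_ml(members, group_id=gid, tol=cfg.em_tol)
            else:
                fr = allele_freqs_naive(members, group_id=gid)
            rep = diversity(fr)
            s = rep.summary()
            div_rows.append(
                dict(
                    group=gid,
                    n=len(members),
                    dosage_corrected=corrected,
                    num=round(s["num"][0], 2),
                    eff_num=round(s["eff_num"][0], 2),
                    hs=round(s["hs"][0], 3),
                    ht=round(s["ht"][0], 3),
                )
            )
    div_df = pd.DataFrame(div_rows)

    big_groups = {
        gid: m for gid, m in imputed_groups.items() if len(m) >= 2
    }
    diff = pairwise_differentiation(big_groups, dosage_corrected=cfg.dosage_corrected)

    all_imputed = [g for gid in sorted(imputed_groups) for g in imputed_groups[gid]]
    coords, explained = pca_allelic(all_imputed)
    coords = coords.iloc[:, : min(5, coords.shape[1])].round(4)
    dist = individual_distances(all_imputed)
    newick = nj_tree(dist)

    provenance = dict(
        package_version=__version__,
        seed=cfg.seed,
        config_hash=_config_hash(cfg),
        n_flow_samples=cohort.n_flow_analyses(),
        n_blades=len(cohort.blades),
        n_genotypes=len(cohort.genotypes),
        base_calibration_pg=round(cal.base_size_pg, 4),
        n_discordant_genotypes=len(discordant),
        explained_variance=[round(float(v), 4) for v in explained[:5]],
    )
    report = RunReport(
        flow_calls=flow_df,
        profiles=prof_df,
        cytotype_frequencies=freq_df,
        diversity_table=div_df,
        gst_matrix=diff.gst.round(4),
        d_matrix=diff.d.round(4),
        pca_coords=coords,
        newick=newick,
        failures=failures,
        provenance=provenance,
    )
    if cfg.outdir:
        report.write(cfg.outdir)
    return report
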