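"""End-to-end orchestration: ITS -> intron annotation -> genotyping ->
haplotype network (bipartite-lineage genotypes only) -> selectivity, with a
single markdown report.

Tripartite-lineage genotypes are excluded from the median-joining network but
kept in the subgroup tables, mirroring how the distinct cephalodial *Nostoc*
lineage is handled in guild analyses.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import fungal_its, genotyper, mjn, selectivity, seq_io
from .intron_annotator import BIPARTITE_TYPE, ReferenceProfile, annotate_set, \
    annotations_to_rows


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    its_fasta: str
    intron_fasta: str
    metadata: str
    out_dir: str
    profile_path: Optional[str] = None
    epsilon: int = 0
    thin_support: int = selectivity.DEFAULT_THIN_SUPPORT
    major_repeat_delta: int = genotyper.DEFAULT_MAJOR_REPEAT_DELTA
    n_permutations: int = 1000
    seed: int = 0
    tripartite_species: Optional[list[str]] = None
    allow_partial_its: bool = True

    def validate(self) -> None:
        for p in (self.its_fasta, self.intron_fasta, self.metadata):
            if not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class RunResult:
    report_path: Path
    fungal_genotypes: list
    nostoc_genotypes: list
    network: Optional[mjn.HaplotypeNetwork]
    association: Optional[selectivity.AssociationTable]
    profiles: list
    mosaic: Optional[selectivity.MosaicTest]
    contingency: pd.DataFrame
    log: list[dict] = field(default_factory=list)


def run_all(config: RunConfig) -> RunResult:
    """Execute the full analysis; any stage error aborts with the stage name
    and cause, retaining partial outputs already written."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(json.dumps(asdict(config), indent=1))
    log: list[dict] = []

    def _stage(name):
        def deco(fn):
            def wrapped(*a, **kw):
                t0 = time.perf_counter()
                try:
                    r = fn(*a, **kw)
                except Exception as e:  # noqa: BLE001 - abort with stage name
                    raise PipelineError(name, e) from e
                log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
                return r
            return wrapped
        return deco

    @_stage("read_inputs")
    def _read():
        its = seq_io.read_fasta(config.its_fasta, "ITS")
        introns = seq_io.read_fasta(config.intron_fasta, "trnL_intron")
        records = seq_io.read_metadata(config.metadata, its, introns)
        return its, introns, records

    its_set, intron_set, records = _read()
    summary = seq_io.dataset_summary(records, its_set, intron_set)

    @_stage("fungal_its")
    def _its():
        delims = fungal_its.delimit_all(its_set)
        genos = fungal_its.collapse_its(delims, records,
                                        allow_partial=config.allow_partial_its)
        pd.DataFrame(
            [{"seq_id": d.seq_id, "start": d.its_start, "end": d.its_end,
              "length": d.its_length, "flank5": d.flank5_found,
              "flank3": d.flank3_found, "length_ok": d.length_ok}
             for d in delims]
        ).to_csv(out / "its_delimitations.tsv", sep="\t", index=False)
        return delims, genos

    its_delims, fungal_genos = _its()

    @_stage("intron_annotation")
    def _annot():
        profile = (ReferenceProfile.from_yaml(config.profile_path)
                   if config.profile_path else ReferenceProfile.default())
        anns = annotate_set(intron_set, profile)
        pd.DataFrame(annotations_to_rows(anns.values())).to_csv(
            out / "intron_annotations.tsv", sep="\t", index=False)
        return anns

    annotations = _annot()

    @_stage("genotyping")
    def _geno():
        genos = genotyper.collapse_introns(intron_set, annotations)
        genotyper.assign_subgroups(genos, config.major_repeat_delta)
        genotyper.name_genotypes(genos)
        pd.DataFrame(genotyper.genotypes_to_rows(genos)).to_csv(
            out / "nostoc_genotypes.tsv", sep="\t", index=False)
        return genos

    nostoc_genos = _geno()

    @_stage("network")
    def _net():
        bip = [g for g in nostoc_genos if g.lineage_call == BIPARTITE_TYPE]
        if len(bip) < 2:
            return None
        aln = mjn.align_genotypes([(g.code, g.representative_seq) for g in bip])
        net = mjn.median_join(aln, epsilon=config.epsilon)
        mjn.export_network(net, out / "network.graphml", "graphml")
        mjn.export_network(net, out / "network_edges.tsv", "edgelist")
        return net

    network = _net()

    @_stage("selectivity")
    def _sel():
        geno_of = genotyper.genotype_of_sequence(nostoc_genos)
        paired = [r for r in records if r.is_paired
                  and r.photobiont_seq_id in geno_of]
        if not paired:
            return None, [], None, None, pd.DataFrame(), pd.DataFrame()
        table = selectivity.build_association(paired, geno_of)
        profiles = selectivity.selectivity_profiles(table, config.thin_support)
        sharing = selectivity.sharing_graph(table)
        mosaic = selectivity.mosaic_permutation_test(
            table, config.n_permutations, config.seed, config.thin_support)
        fg_of = fungal_its.genotype_of_sequence(fungal_genos)
        pairs, genos_lr = selectivity.long_range_consistency(paired, fg_of, geno_of)
        table.counts.to_csv(out / "association.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"species": p.species, "k_global": p.k_global,
              "mosaic_ratio": p.mosaic_ratio,
              "sharing_partners": ",".join(sorted(p.sharing_partners)),
              "thin_regions": ",".join(p.thin_regions)}
             for p in profiles]
        ).to_csv(out / "selectivity_profiles.tsv", sep="\t", index=False)
        pairs.to_csv(out / "trans_regional_pairs.tsv", sep="\t", index=False)
        return table, profiles, sharing, mosaic, pairs, genos_lr

    table, profiles, sharing, mosaic, lr_pairs, lr_genos = _sel()

    # lineage x host-type contingency
    tri_sp = set(config.tripartite_species or [])
    geno_of = genotyper.genotype_of_sequence(nostoc_genos)
    lineage_of_code = {g.code: g.lineage_call for g in nostoc_genos}
    if not tri_sp:  # infer host type from the majority photobiont lineage
        per_sp: dict[str, list[str]] = {}
        for r in records:
            if r.photobiont_seq_id in geno_of:
                per_sp.setdefault(r.fungal_species, []).append(
                    lineage_of_code[geno_of[r.photobiont_seq_id]])
        from .intron_annotator import TRIPARTITE_TYPE
        tri_sp = {sp for sp, calls in per_sp.items()
                  if calls.count(TRIPARTITE_TYPE) * 2 > len(calls)}
    rows = []
    for r in records:
        if r.photobiont_seq_id in geno_of:
            rows.append({
                "host_type": "tripartite" if r.fungal_species in tri_sp else "bipartite",
                "lineage": lineage_of_code[geno_of[r.photobiont_seq_id]],
            })
    contingency = (
        pd.crosstab(pd.DataFrame(rows).host_type, pd.DataFrame(rows).lineage)
        if rows else pd.DataFrame()
    )

    report = _render_report(summary, fungal_genos, nostoc_genos, network,
                            table, profiles, sharing, mosaic, lr_pairs,
                            contingency, log)
    report_path = out / "report.md"
    report_path.write_text(report)
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return RunResult(
        report_path=report_path, fungal_genotypes=fungal_genos,
        nostoc_genotypes=nostoc_genos, network=network, association=table,
        profiles=profiles, mosaic=mosaic, contingency=contingency, log=log,
    )


def _render_report(summary, fungal_genos, nostoc_genos, network, table,
                   profiles, sharing, mosaic, lr_pairs, contingency, log) -> str:
    lines = ["# guildnet run report", ""]
    lines += [
        "## Dataset",
        f"- paired specimens: {summary.n_paired}",
        f"- fungal-only: {summary.n_fungal_only}",
        f"- photobiont-only: {summary.n_photobiont_only}",
        f"- ITS sequences: {summary.n_its_sequences}; "
        f"intron sequences: {summary.n_intron_sequences}",
        "",
        "## Genotypes",
        f"- fungal ITS genotypes: {len(fungal_genos)}",
        f"- Nostoc genotypes: {len(nostoc_genos)} in "
        f"{len({g.subgroup for g in nostoc_genos})} subgroups",
        "",
    ]
    if contingency is not None and not contingency.empty:
        lines += ["## Photobiont lineage by host type", "",
                  contingency.to_markdown(), ""]
    if network is not None:
        lines += [
            "## Haplotype network (bipartite-lineage genotypes)",
            f"- nodes: {network.graph.number_of_nodes()} "
            f"({network.n_medians} median vectors)",
            f"- edges: {network.graph.number_of_edges()}; "
            f"epsilon = {network.epsilon}",
            "",
        ]
    if table is None:
        lines += ["## Association", "",
                  "No paired specimens: association analysis not possible.", ""]
    else:
        lines += ["## Guild structure"]
        for _, row in sharing.flags.iterrows():
            lines.append(
                f"- {row.species}: shares_with_other={bool(row.shares_with_other)}, "
                f"single_genotype={bool(row.single_genotype)}")
        lines += ["", "## Geographic mosaic"]
        for p in profiles:
            lines.append(
                f"- {p.species}: k_global={p.k_global}, "
                f"mosaic_ratio={p.mosaic_ratio:.3f}")
        if mosaic is not None:
            lines += [
                "",
                f"Mean mosaic ratio {mosaic.observed_mean:.3f} vs "
                f"region-shuffled null (p = {mosaic.p_value:.4f}, "
                f"{mosaic.n_permutations} permutations).",
            ]
        if lr_pairs is not None and len(lr_pairs):
            lines += ["", "## Trans-regional symbiont combinations"]
            for _, r in lr_pairs.iterrows():
                lines.append(f"- ({r.fungal_genotype}, {r.nostoc_genotype}) "
                             f"in {r.regions}")
    lines += ["", "## Stage timings"]
    lines += [f"- {e['stage']}: {e['seconds']} s" for e in log]
    return "\n".join(lines) + "\n"
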