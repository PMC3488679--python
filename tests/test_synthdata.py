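import dataclasses
import warnings

import pytest

from guildnet import iupac
from guildnet.fungal_its import FLANK5_MOTIF, delimit_its
from guildnet.intron_annotator import ReferenceProfile, annotate_intron
from guildnet.synthdata import (
    CORE3,
    CORE5,
    SPACER,
    SimulationConfig,
    SynthError,
    simulate_dataset,
    simulate_introns,
    simulate_its,
    write_dataset,
)


def _quiet(fn, *a, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn(*a, **kw)


class TestConfig:
    def test_rates_validated(self):
        with pytest.raises(SynthError):
            SimulationConfig(member_mutation_rate=1.5)
        with pytest.raises(SynthError):
            SimulationConfig(founder_concentration=0.0)
        with pytest.raises(SynthError):
            SimulationConfig(tripartite_species=("N. missing",))

    def test_fixed_cores_are_anchor_free(self, profile):
        anchors = [profile.p5b_flank5, profile.p5b_flank3, profile.p6b_flank5,
                   profile.p6b_flank3, FLANK5_MOTIF]
        for seg in (CORE5, SPACER, CORE3):
            for a in anchors:
                assert iupac.count_motif(seg, a) == 0
        assert len(CORE5) == 56  # anchors reference coordinate 71


class TestSimulateIntrons:
    def test_lengths_within_bounds(self, default_dataset):
        lo, hi = default_dataset.config.intron_length_bounds
        for key, info in default_dataset.truth.intron_genotypes.items():
            assert lo <= len(info["sequence"]) <= hi, key

    def test_zero_variation_collapses_with_warning(self):
        cfg = dataclasses.replace(SimulationConfig(),
                                  branch_substitutions=0.0,
                                  branch_slippage_rate=0.0)
        with pytest.warns(UserWarning, match="zero-variation"):
            seqs, truth = simulate_introns(cfg)
        by_subgroup = {}
        for key, info in truth.intron_genotypes.items():
            by_subgroup.setdefault(info["subgroup"], set()).add(info["sequence"])
        assert all(len(s) == 1 for s in by_subgroup.values())

    def test_determinism_byte_identical(self):
        cfg = SimulationConfig(seed=7)
        s1, _ = _quiet(simulate_introns, cfg)
        s2, _ = _quiet(simulate_introns, cfg)
        assert s1.records == s2.records

    def test_planted_lineage_recovered_by_annotator(self, default_dataset, profile):
        for key, info in default_dataset.truth.intron_genotypes.items():
            ann = annotate_intron(info["sequence"], key, profile)
            assert ann.lineage_call == info["lineage"]

    def test_distinct_genotypes(self, default_dataset):
        seqs = [v["sequence"] for v in
                default_dataset.truth.intron_genotypes.values()]
        assert len(seqs) == len(set(seqs)) == 40


class TestSimulateIts:
    def test_roundtrip_through_delimitation(self):
        cfg = dataclasses.replace(SimulationConfig(),
                                  its_genotypes_per_species=2)
        seqs, truth = _quiet(simulate_its, cfg)
        assert len(seqs) == 2 * len(cfg.species_names)
        for sid, seq in seqs:
            d = delimit_its(seq, sid)
            assert d.its_seq == truth.its_genotypes[sid]["its"]
            assert d.flank5_found and d.flank3_found

    def test_zero_divergence_gives_one_genotype_per_species(self):
        from guildnet.fungal_its import collapse_its

        cfg = dataclasses.replace(SimulationConfig(),
                                  genotype_its_divergence=0.0,
                                  its_genotypes_per_species=3)
        seqs, truth = _quiet(simulate_its, cfg)
        delims = [delimit_its(seq, sid) for sid, seq in seqs]
        genos = collapse_its(delims, None, per_species=False)
        assert len(genos) == len(cfg.species_names)

    def test_planted_lengths_within_bounds(self, default_dataset):
        lo, hi = default_dataset.config.its_length_bounds
        for info in default_dataset.truth.its_genotypes.values():
            assert lo <= len(info["its"]) <= hi


class TestSampling:
    def test_zero_specimens_yields_empty_pipeline(self):
        from guildnet.seq_io import dataset_summary

        cfg = dataclasses.replace(SimulationConfig(), specimens_per_cell=0,
                                  n_fungal_only_per_cell=0,
                                  n_photobiont_only_per_cell=0,
                                  n_trans_regional=0,
                                  ensure_all_genotypes_sampled=False)
        ds = _quiet(simulate_dataset, cfg)
        assert ds.records == []
        s = dataset_summary(ds.records, ds.its_set, ds.intron_set)
        assert (s.n_paired, s.n_fungal_only, s.n_photobiont_only) == (0, 0, 0)

    def test_truth_consistent_with_emitted_files(self, default_dataset):
        ds = default_dataset
        its_ids = set(ds.its_set.ids)
        intron_ids = set(ds.intron_set.ids)
        for rec in ds.records:
            if rec.fungal_seq_id:
                assert rec.fungal_seq_id in its_ids
            if rec.photobiont_seq_id:
                assert rec.photobiont_seq_id in intron_ids
        assert set(ds.truth.seq_to_intron_genotype) == intron_ids
        assert set(ds.truth.seq_to_its_genotype) == its_ids

    def test_every_planted_genotype_observed(self, default_dataset):
        ds = default_dataset
        sampled = set(ds.truth.seq_to_intron_genotype.values())
        assert sampled == set(ds.truth.intron_genotypes)

    def test_founder_concentration_controls_regional_dominance(self):
        import numpy as np

        def dominance(conc):
            cfg = dataclasses.replace(SimulationConfig(),
                                      founder_concentration=conc,
                                      member_mutation_rate=0.0)
            ds = _quiet(simulate_dataset, cfg)
            fracs = []
            per_cell: dict[tuple, list[str]] = {}
            for s in ds.truth.specimens:
                if s["intron_genotype"] and s["its_genotype"]:
                    per_cell.setdefault((s["species"], s["region"]), []).append(
                        s["intron_genotype"])
            for cell, genos in per_cell.items():
                if len(genos) >= 3:
                    top = max(np.unique(genos, return_counts=True)[1])
                    fracs.append(top / len(genos))
            return float(np.mean(fracs))

        assert dominance(0.05) > dominance(100.0)

    def test_dataset_determinism(self):
        cfg = SimulationConfig(seed=11)
        d1 = _quiet(simulate_dataset, cfg)
        d2 = _quiet(simulate_dataset, cfg)
        assert d1.intron_set.records == d2.intron_set.records
        assert d1.its_set.records == d2.its_set.records
        assert d1.records == d2.records

    def test_write_dataset_files(self, default_dataset, tmp_path):
        from guildnet.seq_io import read_fasta, read_metadata

        write_dataset(default_dataset, tmp_path)
        introns = read_fasta(tmp_path / "introns.fa", "trnL_intron")
        its = read_fasta(tmp_path / "its.fa", "ITS")
        records = read_metadata(tmp_path / "metadata.tsv", its, introns)
        assert records == default_dataset.records
        assert introns.records == default_dataset.intron_set.records


class TestEndToEndRecovery:
    def test_partition_recovery_with_default_noise(self, default_dataset,
                                                   default_annotations):
        """At the default (tiny) member-noise rate the exact-identity
        partition still agrees with the planted genotypes at ARI >= 0.95."""
        from sklearn.metrics import adjusted_rand_score

        from guildnet.genotyper import collapse_introns

        ds = default_dataset
        genos = _quiet(collapse_introns, ds.intron_set, default_annotations)
        label_of = {}
        for i, g in enumerate(genos):
            for sid in g.member_seq_ids:
                label_of[sid] = i
        sids = [s for s in ds.intron_set.ids if s in label_of]
        pred = [label_of[s] for s in sids]
        true = [ds.truth.seq_to_intron_genotype[s] for s in sids]
        assert adjusted_rand_score(true, pred) >= 0.95
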