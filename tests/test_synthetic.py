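"""Synthetic-data generators: planted truth must be recoverable."""

import numpy as np
import pandas as pd
import pytest

from mcsite.annotation import window_methylation
from mcsite.profiling import AmpliconSpec, profile_amplicon
from mcsite.sequtil import revcomp
from mcsite.synthetic import (
    ChromatinPlan,
    EditingPlan,
    FeatureRegion,
    GenomePlan,
    MethylationWindowSpec,
    PlantedFamily,
    build_genome,
    cytosine_contexts,
    simulate_amplicon_reads,
    simulate_methylation,
    simulate_tracks,
)
from tests.conftest import naive_scan


class TestBuildGenome:
    def test_planted_family_recovered_exactly(self, planted_genome):
        plan, genome, registry = planted_genome
        seq = plan.families[0].sequence
        hits = naive_scan(genome).get(seq, [])
        assert len(hits) == 7
        assert sorted(h[1] for h in hits) == sorted(registry["start"])

    def test_registry_slices_reproduce_the_sequence(self, planted_genome):
        _, genome, registry = planted_genome
        for _, row in registry.iterrows():
            piece = genome[row["chrom"]][row["start"] : row["end"]]
            if row["strand"] == "-":
                piece = revcomp(piece)
            assert piece == row["sequence"]

    def test_minus_strand_planting(self):
        fam = PlantedFamily("f", "ACGTACGTACGTACGTACGTAGG", [("c", 100, "-")])
        genome, _ = build_genome(GenomePlan({"c": 2000}, [fam], seed=3))
        assert genome["c"][100:123] == revcomp(fam.sequence)

    def test_empty_plan_gives_empty_registry(self):
        genome, registry = build_genome(GenomePlan({"c": 500}, [], seed=0))
        assert registry.empty and len(genome["c"]) == 500

    def test_seeded_determinism(self, planted_genome):
        plan, genome, _ = planted_genome
        again, _ = build_genome(plan)
        assert again == genome

    @pytest.mark.parametrize(
        "loci, message",
        [([("c", 490, "+")], "overflow"), ([("c", 10, "+"), ("c", 20, "+")], "collide")],
    )
    def test_bad_loci_fail_descriptively(self, loci, message):
        with pytest.raises(ValueError, match=message):
            GenomePlan(
                {"c": 500},
                [PlantedFamily("f", "ACGTACGTACGTACGTACGTAGG", loci)],
                seed=0,
            )

    def test_background_gc_close_to_plan(self):
        genome, _ = build_genome(GenomePlan({"c": 50_000}, [], gc=0.36, seed=9))
        gc = sum(genome["c"].count(b) for b in "GC") / 50_000
        assert abs(gc - 0.36) < 0.01


class TestSimulateMethylation:
    def test_context_labels_match_definition(self):
        # CGA: C->CG; CAG: C->CHG; CAA: C->CHH; and minus-strand mirror
        seq = "CGACAGCAATT"
        ctx = {(p, s): c for p, s, c in cytosine_contexts(seq)}
        assert ctx[(0, "+")] == "CG"
        assert ctx[(3, "+")] == "CHG"
        assert ctx[(6, "+")] == "CHH"
        assert ctx[(1, "-")] == "CG"  # G pairing the CG cytosine

    def test_zero_level_gives_zero_counts(self):
        genome = {"c": "ACGTACGGATCCGATCGATTGCAT" * 10}
        plan = ChromatinPlan(
            windows=[MethylationWindowSpec("c", 0, 240, 0.0, 0.0, 0.0)], depth=30, seed=1
        )
        calls = simulate_methylation(genome, plan)
        assert (calls["mc_count"] == 0).all()
        assert (calls["total_count"] == 30).all()

    def test_window_recomputation_converges_to_plan(self):
        genome, _ = build_genome(GenomePlan({"c": 1000}, [], gc=0.4, seed=5))
        plan = ChromatinPlan(
            windows=[MethylationWindowSpec("c", 0, 100, 0.6, 0.5, 0.05)], depth=200, seed=2
        )
        calls = simulate_methylation(genome, plan)
        win = window_methylation(calls, {"c": 1000}).iloc[0]
        assert abs(win["mCG"] - 0.6) < 0.05
        assert abs(win["mCHG"] - 0.5) < 0.05
        assert abs(win["mCHH"] - 0.05) < 0.05

    def test_window_without_cytosines_warns_and_skips(self):
        genome = {"c": "AT" * 200}
        plan = ChromatinPlan(
            windows=[MethylationWindowSpec("c", 0, 100, 0.5, 0.5, 0.5)], depth=10, seed=0
        )
        with pytest.warns(UserWarning, match="no cytosines"):
            calls = simulate_methylation(genome, plan)
        assert calls.empty

    def test_window_outside_genome_fails(self):
        with pytest.raises(ValueError, match="exceeds"):
            simulate_methylation(
                {"c": "ACGT" * 10},
                ChromatinPlan(windows=[MethylationWindowSpec("c", 0, 100, 0, 0, 0)]),
            )


class TestSimulateTracks:
    def test_constant_signal_and_peaks(self):
        genome = {"c": "A" * 3000}
        plan = ChromatinPlan(
            peaks=[("c", 100, 300)],
            features={"f": [FeatureRegion("c", 0, 2000, 1.0)]},
            noise_sd=0.0,
            seed=0,
        )
        peaks, tracks = simulate_tracks(genome, plan)
        assert peaks.iloc[0][["start", "end"]].tolist() == [100, 300]
        track = tracks["f"]
        assert (track["value"] == 1.0).all()
        assert track["start"].iloc[0] == 0 and track["end"].iloc[-1] == 2000

    def test_negative_planned_signal_fails(self):
        with pytest.raises(ValueError, match="non-negative"):
            FeatureRegion("c", 0, 100, -1.0)


class TestSimulateAmpliconReads:
    REF = "ATGCGTACGGATCTTACGGATCCGATTAGCCTAGCATCGGATCGATCGGCTAGCTAGGATCGTAGCTAGCTAACGGATCGAT"
    CUT = 40

    def test_all_unmodified_zero_error_profiles_clean(self):
        plan = EditingPlan(total_reads=200, proportions={"unmodified": 1.0}, seed=7)
        reads, truth = simulate_amplicon_reads(self.REF, self.CUT, plan)
        assert (truth["true_class"] == "unmodified").all()
        spec = AmpliconSpec("s", self.REF, self.CUT - 17)
        assert profile_amplicon(reads, spec).indel_frequency == 0.0

    def test_mixture_recovered_within_multinomial_bound(self):
        plan = EditingPlan(
            total_reads=10_000,
            proportions={"+1bp": 0.7, "del_1_5": 0.2, "del_gt10": 0.1},
            seed=11,
        )
        _, truth = simulate_amplicon_reads(self.REF, self.CUT, plan)
        freq = truth["true_class"].value_counts(normalize=True)
        assert abs(freq["+1bp"] - 0.7) < 0.02
        assert abs(freq["del_1_5"] - 0.2) < 0.02
        assert abs(freq["del_gt10"] - 0.1) < 0.02

    def test_templated_insertion_duplicates_base_5prime_of_cut(self):
        ref = self.REF[: self.CUT - 1] + "T" + self.REF[self.CUT :]
        plan = EditingPlan(total_reads=50, proportions={"+1bp": 1.0}, seed=3)
        reads, truth = simulate_amplicon_reads(ref, self.CUT, plan)
        assert all(op.endswith(":T") for op in truth["op"])
        assert all(seq[self.CUT] == "T" and seq[self.CUT - 1] == "T" for _, seq in reads)

    def test_fixed_base_insertion_rule(self):
        plan = EditingPlan(
            total_reads=20, proportions={"+1bp": 1.0}, insertion_rule="G", seed=3
        )
        _, truth = simulate_amplicon_reads(self.REF, self.CUT, plan)
        assert all(op.endswith(":G") for op in truth["op"])

    def test_deletions_overlap_the_cut(self):
        plan = EditingPlan(total_reads=500, proportions={"del_6_10": 1.0}, seed=5)
        _, truth = simulate_amplicon_reads(self.REF, self.CUT, plan)
        for op in truth["op"]:
            _, start, size = op.split(":")
            start, size = int(start), int(size)
            assert 6 <= size <= 10
            assert start <= self.CUT - 1 <= start + size  # spans or abuts the cut

    def test_short_amplicon_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            simulate_amplicon_reads("ACGT" * 10, 20, EditingPlan(10, {"unmodified": 1.0}))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"proportions": {"unmodified": 0.5}},
            {"proportions": {"unmodified": 1.0}, "substitution_error": 0.2},
        ],
    )
    def test_invalid_plan_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EditingPlan(total_reads=10, **kwargs)

    def test_emitted_files_round_trip(self, tmp_path):
        from mcsite import fileio

        genome = {"c": "ACGTACGGATCCGATCGATTGCAT" * 10}
        fileio.write_fasta(genome, tmp_path / "g.fa")
        assert fileio.read_fasta(tmp_path / "g.fa") == genome

        plan = ChromatinPlan(
            windows=[MethylationWindowSpec("c", 0, 200, 0.5, 0.2, 0.05)],
            depth=20,
            peaks=[("c", 10, 50)],
            features={"f": [FeatureRegion("c", 0, 200, 2.0)]},
            seed=4,
        )
        calls = simulate_methylation(genome, plan)
        fileio.write_calls(calls, tmp_path / "calls.tsv")
        assert fileio.read_calls(tmp_path / "calls.tsv").equals(calls)

        peaks, tracks = simulate_tracks(genome, plan)
        fileio.write_bed(peaks, tmp_path / "p.bed")
        assert fileio.read_bed(tmp_path / "p.bed")[["chrom", "start", "end"]].equals(
            peaks[["chrom", "start", "end"]]
        )
        fileio.write_bedgraph(tracks["f"], tmp_path / "f.bedgraph")
        assert fileio.read_bedgraph(tmp_path / "f.bedgraph").equals(tracks["f"])

        ep = EditingPlan(total_reads=20, proportions={"unmodified": 1.0}, seed=0)
        reads, _ = simulate_amplicon_reads(self.REF, self.CUT, ep)
        fileio.write_fastq(reads, tmp_path / "r.fastq")
        assert list(fileio.read_fastq(tmp_path / "r.fastq")) == reads

    def test_truth_has_one_row_per_read(self):
        plan = EditingPlan(
            total_reads=100, proportions={"unmodified": 0.5, "+1bp": 0.5}, seed=1
        )
        reads, truth = simulate_amplicon_reads(self.REF, self.CUT, plan)
        assert len(reads) == len(truth) == 100
        assert set(truth["true_class"]) <= {"unmodified", "+1bp"}
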