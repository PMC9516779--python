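"""Target scanning and the candidate filter cascade."""

import numpy as np
import pandas as pd
import pytest

from mcsite import discovery
from mcsite.discovery import (
    DEFAULT_ENZYMES,
    RestrictionEnzyme,
    annotate_restriction_overlap,
    apply_filter_cascade,
    filter_copy_range,
    passes_gc,
    passes_organellar,
    passes_simple_motif,
    scan_pam_sites,
    select_mcsite_families,
)
from mcsite.sequtil import revcomp
from mcsite.synthetic import GenomePlan, build_genome
from tests.conftest import naive_gc, naive_has_run, naive_iupac_hits, naive_scan


class TestScanner:
    def test_no_pam_no_occurrences(self):
        assert len(scan_pam_sites({"c": "A" * 100})) == 0
        assert len(scan_pam_sites({})) == 0

    def test_planted_family_copy_number(self, planted_genome):
        plan, genome, _ = planted_genome
        catalog = scan_pam_sites(genome)
        assert catalog.copy_number(plan.families[0].sequence) == 7

    def test_minus_strand_convention(self):
        target = "ACGTACGTACGTACGTACGTAGG"
        background = "ATATATATAT" * 20
        seq = background + revcomp(target) + background
        catalog = scan_pam_sites({"c": seq})
        occ = [o for o in catalog.occurrences(target)]
        assert len(occ) == 1
        assert occ[0].strand == "-"
        assert revcomp(seq[occ[0].start : occ[0].end]) == target

    def test_n_windows_excluded(self):
        target = "ACGTACGTACGTACGTACGTAGG"
        seq = "T" * 30 + target.replace("A", "N", 1) + "T" * 30
        assert target not in scan_pam_sites({"c": seq})

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_on_random_genomes(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(300, 3000))
        genome, _ = build_genome(GenomePlan({"c": length}, [], gc=float(rng.uniform(0.3, 0.6)), seed=seed))
        catalog = scan_pam_sites(genome)
        oracle = naive_scan(genome)
        assert set(catalog) == set(oracle)
        for seq in oracle:
            got = sorted((o.chrom, o.start, o.strand) for o in catalog.occurrences(seq))
            assert got == sorted(oracle[seq])

    def test_every_occurrence_slices_back_to_its_key(self, planted_genome):
        _, genome, _ = planted_genome
        catalog = scan_pam_sites(genome)
        for seq, occs in catalog.items():
            for occ in occs[:3]:
                piece = genome[occ.chrom][occ.start : occ.end]
                assert (piece if occ.strand == "+" else revcomp(piece)) == seq


class TestFilters:
    @pytest.mark.parametrize("copies, kept", [(6, False), (7, True), (25, True), (26, False), (1, False)])
    def test_copy_range_bounds_inclusive(self, copies, kept):
        occs = [discovery.TargetOccurrence("c", i * 30, "+") for i in range(copies)]
        catalog = discovery.TargetCatalog({"X" * 23: occs})
        assert (len(filter_copy_range(catalog)) == 1) is kept

    def test_copy_range_inverted_bounds_fail(self):
        with pytest.raises(ValueError, match="inverted"):
            filter_copy_range(discovery.TargetCatalog(), lo=25, hi=7)

    @pytest.mark.parametrize(
        "proto, passes",
        [
            ("ACGTACGTACGTACGTACGT", True),
            ("AAAAACGTACGTACGTACGT", False),
            ("AAAACGTACGTACGTACGTC", True),  # run of 4 is allowed
            ("ACGTACGTTTTTTACGTACG", False),
        ],
    )
    def test_simple_motif_rule(self, proto, passes):
        assert passes_simple_motif(proto) is passes
        assert passes is (not naive_has_run(proto))

    @pytest.mark.parametrize("n_gc, passes", [(7, False), (8, True), (12, True), (13, False)])
    def test_gc_bounds_inclusive(self, n_gc, passes):
        proto = "G" * n_gc + "A" * (20 - n_gc)
        assert passes_gc(proto) is passes
        assert passes is (0.40 <= naive_gc(proto) <= 0.60)

    def test_organellar_match_both_strands(self):
        target = "ACGTACGTACGTACGTACGTAGG"
        assert not passes_organellar(target, {"mt": "TTT" + target + "TTT"})
        assert not passes_organellar(target, {"mt": "TTT" + revcomp(target) + "TTT"})
        assert passes_organellar(target, {"mt": "A" * 100})
        assert passes_organellar(target, {})


class TestRestrictionOverlap:
    def test_motif_covering_cut_site_returned(self):
        # AGCT placed at 0-based 15..19 covers protospacer bases 17-18
        seq = "ACGTACGTACGTACGAGCTCGGG"
        assert "AluI" in annotate_restriction_overlap(seq, [RestrictionEnzyme("AluI", "AGCT")])

    def test_motif_far_from_cut_not_returned(self):
        seq = "AGCTACGTACGTAAATTTACCGG"
        assert annotate_restriction_overlap(seq, [RestrictionEnzyme("AluI", "AGCT")]) == []

    def test_degenerate_motif_matches_by_iupac_expansion(self):
        # GANTC across 0-based 14..19 covers base 17
        seq = "ACGTACGTACGTACGACTCTAGG"
        enzyme = RestrictionEnzyme("HinfI", "GANTC")
        hits = naive_iupac_hits(seq, "GANTC")
        assert any(a <= 16 < b or a <= 17 < b for a, b in hits)
        assert "HinfI" in annotate_restriction_overlap(seq, [enzyme])

    def test_agreement_with_iupac_oracle_on_random_sequences(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(50):
            seq = "".join(rng.choice(bases, size=21)) + "GG"
            for enzyme in DEFAULT_ENZYMES[:8]:
                hits = naive_iupac_hits(seq, enzyme.motif)
                expected = any(a <= 16 < b or a <= 17 < b for a, b in hits)
                got = enzyme.name in annotate_restriction_overlap(seq, [enzyme])
                assert got is expected, (seq, enzyme)

    def test_malformed_motif_names_the_enzyme(self):
        with pytest.raises(ValueError, match="motif"):
            RestrictionEnzyme("bad", "AGQT")


class TestCascade:
    def test_counts_monotone_and_first_failure_named(self, planted_genome):
        plan, genome, _ = planted_genome
        catalog = scan_pam_sites(genome)
        survivors, report = apply_filter_cascade(catalog)
        counts = list(report.stage_counts.values())
        assert counts == sorted(counts, reverse=True)
        assert report.stage_counts["distinct"] == len(catalog)
        assert len(survivors) == report.stage_counts["restriction"]
        for seq, stage in report.first_failure.items():
            assert stage in discovery.CASCADE_STAGES[1:]
            assert seq not in survivors

    def test_survivors_equal_independent_predicate_intersection(self, planted_genome):
        plan, genome, _ = planted_genome
        catalog = scan_pam_sites(genome)
        survivors, _ = apply_filter_cascade(catalog)
        expected = {
            seq
            for seq in catalog
            if 7 <= catalog.copy_number(seq) <= 25
            and passes_simple_motif(seq[:20])
            and passes_gc(seq[:20])
            and annotate_restriction_overlap(seq)
        }
        assert set(survivors) == expected


class TestFamilySelection:
    @staticmethod
    def _catalog_and_annotations(acc, domains, states):
        occs = [discovery.TargetOccurrence("c", 100 * i, "+") for i in range(len(acc))]
        catalog = discovery.TargetCatalog({"T" * 23: occs})
        ann = pd.DataFrame(
            {"accessibility": acc, "domain": domains, "state": states},
            index=[o.site_id for o in occs],
        )
        return catalog, ann

    def test_diverse_family_selected(self):
        catalog, ann = self._catalog_and_annotations(
            ["open", "closed", "closed"],
            ["unmethylated", "RdDM", "heterochromatin"],
            ["4", "8", "8"],
        )
        assert select_mcsite_families(catalog, ann) == ["T" * 23]

    @pytest.mark.parametrize(
        "acc, domains, states",
        [
            (["open"] * 3, ["unmethylated", "RdDM", "heterochromatin"], ["4", "8", "9"]),
            (["open", "closed", "open"], ["unmethylated", "RdDM", "RdDM"], ["4", "8", "9"]),
            (["open", "closed", "open"], ["unmethylated", "RdDM", "heterochromatin"], ["4", "4", "4"]),
        ],
    )
    def test_insufficient_diversity_rejected(self, acc, domains, states):
        catalog, ann = self._catalog_and_annotations(acc, domains, states)
        assert select_mcsite_families(catalog, ann) == []

    def test_unannotated_member_fails_with_site_name(self):
        catalog, ann = self._catalog_and_annotations(
            ["open", "closed", "closed"],
            ["unmethylated", "RdDM", "heterochromatin"],
            ["4", "8", "8"],
        )
        with pytest.raises(ValueError, match="c:200"):
            select_mcsite_families(catalog, ann.drop(index="c:200:+"))
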