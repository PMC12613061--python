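import pytest

from conftest import make_table
from regumirror.formats import (
    GenomicInterval,
    NarrowPeakRecord,
    OrthologMap,
    TSSRecord,
)
from regumirror.funnel import (
    FunnelOptions,
    PromoterOccupancy,
    assign_promoter_peaks,
    build_promoter_windows,
    build_target_panel,
    classify_tier,
    cross_species_consensus,
    effective_score,
    remove_blacklisted,
    run_funnel,
    species_occupancy_filter,
)
from regumirror.simulate import DECOY_STAGES


def peak(chrom, start, end, score=300, q=None, name="p"):
    return NarrowPeakRecord(
        interval=GenomicInterval(chrom, start, end),
        name=name,
        score=score,
        neglog10_q=q,
    )


class TestTierScale:
    @pytest.mark.parametrize(
        "score,tier",
        [
            (0, "blue"), (199, "blue"),
            (200, "cyan"), (499, "cyan"),
            (500, "green"), (749, "green"),
            (750, "yellow"), (999, "yellow"),
            (1000, "red"), (5000, "red"),
        ],
    )
    def test_boundaries(self, score, tier):
        assert classify_tier(score) == tier

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_tier(-1)

    def test_stepwise_non_decreasing(self):
        order = ["blue", "cyan", "green", "yellow", "red"]
        ranks = [order.index(classify_tier(s)) for s in range(0, 1500, 7)]
        assert ranks == sorted(ranks)


class TestEffectiveScore:
    def test_positive_score_passes_through(self):
        assert effective_score(peak("c", 0, 10, score=300)) == 300

    def test_zero_score_repaired_from_q(self):
        assert effective_score(peak("c", 0, 10, score=0, q=30.0)) == 300

    def test_zero_score_no_q_is_zero(self):
        assert effective_score(peak("c", 0, 10, score=0)) == 0


class TestBlacklist:
    def test_one_bp_overlap_removed(self):
        kept = remove_blacklisted(
            [peak("c", 100, 600)], [GenomicInterval("c", 599, 700)]
        )
        assert kept == []

    def test_half_open_abutment_kept(self):
        kept = remove_blacklisted(
            [peak("c", 100, 600)], [GenomicInterval("c", 600, 700)]
        )
        assert len(kept) == 1

    def test_empty_blacklist_identity(self):
        peaks = [peak("c", 0, 10), peak("c", 20, 30)]
        assert remove_blacklisted(peaks, []) == peaks


class TestPromoterWindows:
    def test_symmetric_window(self):
        (w,) = build_promoter_windows([TSSRecord("G", "c", "+", 5000)])
        assert (w.interval.start, w.interval.end) == (3000, 7000)

    def test_left_clip_at_zero(self):
        (w,) = build_promoter_windows([TSSRecord("G", "c", "-", 1500)])
        assert (w.interval.start, w.interval.end) == (0, 3500)

    def test_multiple_tss_multiple_windows(self):
        ws = build_promoter_windows(
            [TSSRecord("G", "c", "+", 5000), TSSRecord("G", "c", "+", 9000)]
        )
        assert len(ws) == 2
        assert {w.gene_symbol for w in ws} == {"G"}


class TestAssignment:
    def windows(self):
        return build_promoter_windows(
            [TSSRecord("G1", "c", "+", 5000), TSSRecord("G2", "c", "+", 8500)]
        )

    def test_highest_scoring_peak_retained(self):
        occ = assign_promoter_peaks(
            {"YAP1": [peak("c", 4000, 4200, 300), peak("c", 5500, 5700, 800)]},
            self.windows(),
            "human",
        )
        (o,) = [x for x in occ if x.gene_symbol == "G1"]
        assert o.factors["YAP1"].effective_score == 800
        assert o.factors["YAP1"].tier == "yellow"

    def test_peak_shared_between_overlapping_windows(self):
        # windows [3000,7000) and [6500,10500): a peak in the overlap counts
        # toward both genes
        occ = assign_promoter_peaks(
            {"TEAD1": [peak("c", 6600, 6800, 400)]}, self.windows(), "human"
        )
        assert {o.gene_symbol for o in occ} == {"G1", "G2"}

    def test_absent_factor_slot_missing(self):
        occ = assign_promoter_peaks(
            {"YAP1": [peak("c", 4000, 4200)], "TEAD3": []}, self.windows(), "human"
        )
        (o,) = [x for x in occ if x.gene_symbol == "G1"]
        assert "TEAD3" not in o.factors

    def test_score_tie_breaks_by_start(self):
        occ = assign_promoter_peaks(
            {"YAP1": [peak("c", 5500, 5700, 400), peak("c", 4000, 4200, 400)]},
            self.windows(),
            "human",
        )
        (o,) = [x for x in occ if x.gene_symbol == "G1"]
        assert o.factors["YAP1"].peak.interval.start == 4000


class TestOccupancyFilter:
    def occ(self, gene, factors):
        o = PromoterOccupancy(species="human", gene_symbol=gene)
        for f in factors:
            o.factors[f] = assign_factor_peak()
        return o

    def test_yap1_plus_tead_passes(self):
        assert species_occupancy_filter([self.occ("G", ["YAP1", "TEAD1"])]) == {"G"}

    def test_yap1_only_fails(self):
        assert species_occupancy_filter([self.occ("G", ["YAP1"])]) == set()

    def test_teads_without_yap1_fail(self):
        occ = self.occ("G", ["TEAD1", "TEAD2", "TEAD3", "TEAD4"])
        assert species_occupancy_filter([occ]) == set()


def assign_factor_peak():
    from regumirror.funnel import FactorPeak

    return FactorPeak(peak("c", 0, 10), 300, "cyan")


class TestConsensus:
    def test_pair_passing_both_species(self):
        omap = OrthologMap(pairs=[("SRF", "SRF")])
        assert cross_species_consensus({"SRF"}, {"SRF"}, omap) == [("SRF", "SRF")]

    def test_mouse_failure_drops_pair(self):
        omap = OrthologMap(pairs=[("SRF", "SRF")])
        assert cross_species_consensus({"SRF"}, set(), omap) == []

    def test_gene_without_ortholog_dropped(self):
        omap = OrthologMap(pairs=[("NEXN", "NEXN")])
        assert cross_species_consensus({"SRF"}, {"SRF"}, omap) == []

    def test_one_to_many_first_qualifying(self):
        omap = OrthologMap(pairs=[("FGFR2", "FGFR2B"), ("FGFR2", "FGFR2")])
        out = cross_species_consensus({"FGFR2"}, {"FGFR2", "FGFR2B"}, omap)
        assert out == [("FGFR2", "FGFR2")]


class TestPanelGate:
    def setup_args(self, lfc2=-1.0, p2=0.01, lfc8=-0.5, p8=0.01, motif=True):
        occ = {
            "SRF": PromoterOccupancy("human", "SRF", {"YAP1": assign_factor_peak()}),
        }
        mocc = {
            "SRF": PromoterOccupancy("mouse", "SRF", {"YAP1": assign_factor_peak()}),
        }
        return dict(
            consensus=[("SRF", "SRF")],
            motif_present={"SRF": motif},
            deg_2wk=make_table([("SRF", lfc2, p2)], "2wk"),
            deg_8wk=make_table([("SRF", lfc8, p8)], "8wk"),
            human_occ=occ,
            mouse_occ=mocc,
        )

    def test_passing_gene_in_panel(self):
        (rec,) = build_target_panel(**self.setup_args())
        assert rec.gene_symbol == "SRF"
        assert rec.tead_motif_present
        assert rec.human_tier == "cyan"

    def test_down_at_one_time_point_excluded(self):
        assert build_target_panel(**self.setup_args(lfc2=+1.0)) == []
        assert build_target_panel(**self.setup_args(p8=0.2)) == []

    def test_motif_gate(self):
        assert build_target_panel(**self.setup_args(motif=False)) == []

    def test_empty_consensus_empty_panel(self):
        args = self.setup_args()
        args["consensus"] = []
        assert build_target_panel(**args) == []


class TestFunnelOnFixture:
    def test_recovers_planted_targets_exactly(self, fixture_dir, fixture_inputs):
        _, truth = fixture_dir
        h, m, pfms, orth, d2, d8, _ = fixture_inputs
        res = run_funnel(h, m, pfms, orth, d2, d8)
        assert sorted(res.panel_genes()) == sorted(truth.planted_targets)

    def test_stage_counts_monotone_non_increasing(self, fixture_dir, fixture_inputs):
        h, m, pfms, orth, d2, d8, _ = fixture_inputs
        sc = run_funnel(h, m, pfms, orth, d2, d8).stage_counts
        path = [
            min(sc["promoter_occupancy_human"], sc["promoter_occupancy_mouse"]),
            sc["cross_species_consensus"],
            sc["tead_motif"],
            sc["downregulated_panel"],
        ]
        assert path == sorted(path, reverse=True)

    def test_each_decoy_fails_exactly_its_gate(self, fixture_dir, fixture_inputs):
        """Disabling one gate recovers exactly the decoys built to violate it."""
        _, truth = fixture_dir
        h, m, pfms, orth, d2, d8, _ = fixture_inputs
        base = set(run_funnel(h, m, pfms, orth, d2, d8).panel_genes())
        all_pairs = sorted(
            set(orth.pairs)
            | {(g, g) for g in truth.decoys}
            | {(g, g) for g in truth.planted_targets}
        )
        variants = {
            "blacklist": dict(options=FunnelOptions(apply_blacklist=False)),
            "no_yap1": dict(options=FunnelOptions(require_yap1=False)),
            "no_tead": dict(options=FunnelOptions(require_tead=False)),
            "no_ortholog": dict(orthologs=OrthologMap(pairs=all_pairs)),
            "no_motif": dict(options=FunnelOptions(require_motif=False)),
            "not_down_2wk": dict(options=FunnelOptions(require_down_2wk=False)),
            "not_down_8wk": dict(options=FunnelOptions(require_down_8wk=False)),
        }
        assert set(variants) == set(DECOY_STAGES)
        for stage, kw in variants.items():
            got = set(
                run_funnel(
                    h, m, pfms,
                    kw.get("orthologs", orth),
                    d2, d8,
                    kw.get("options", FunnelOptions()),
                ).panel_genes()
            )
            expect = base | {g for g, s in truth.decoys.items() if s == stage}
            assert got == expect, f"gate {stage}"
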