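import json

import numpy as np
import pytest

from acetrank.colocalization import quadrant_table
from acetrank.io_formats import (
    TSSAnnotation,
    read_bedgraph,
    read_counts,
    read_narrowpeak,
)
from acetrank.preference import preference_table, region_universe
from acetrank.se_caller import call_superenhancers
from acetrank.synthetic_data import (
    SimConfig,
    interval_jaccard,
    simulate,
    simulate_quadrant,
    truth_compare,
)

SMALL = dict(
    n_typical_peaks=120,
    n_se_clusters=3,
    n_genes=60,
    chrom_lengths=(("chrS1", 8_000_000), ("chrS2", 8_000_000)),
)


def measured_agreement(sim):
    universe = region_universe(sim.peaks_a, sim.peaks_b)
    records = preference_table(
        universe,
        sim.tracks[("mark_a", "control")],
        sim.tracks[("mark_b", "control")],
    )
    report = truth_compare(sim.truth, records=records)
    return report["group_recovery"]["agreement"]


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        paths1 = simulate(SimConfig(seed=5, **SMALL)).write(tmp_path / "a")
        paths2 = simulate(SimConfig(seed=5, **SMALL)).write(tmp_path / "b")
        assert paths1.keys() == paths2.keys()
        for key in paths1:
            assert paths1[key].read_bytes() == paths2[key].read_bytes(), key

    def test_different_seeds_differ(self, tmp_path):
        p1 = simulate(SimConfig(seed=5, **SMALL)).write(tmp_path / "a")
        p2 = simulate(SimConfig(seed=6, **SMALL)).write(tmp_path / "b")
        assert p1["mark_a_peaks"].read_bytes() != p2["mark_a_peaks"].read_bytes()


class TestEmittedFilesAreValidInputs:
    def test_round_trip_through_readers(self, sim_small, sim_small_paths):
        peaks = read_narrowpeak(sim_small_paths["mark_a_peaks"])
        assert len(peaks) == len(sim_small.peaks_a)
        track = read_bedgraph(sim_small_paths["mark_a_control"])
        # densities survive the text round trip
        p = peaks[0]
        assert np.isclose(
            track.integral(p.chrom, p.start, p.end) * 1000 / p.interval.length,
            sim_small.truth["peaks"][0]["density_a"],
            rtol=1e-4,
        )
        tss = TSSAnnotation.from_tsv(sim_small_paths["tss"])
        assert len(tss) == len(sim_small.tss)
        counts = read_counts(sim_small_paths["counts"])
        assert counts.equals(sim_small.counts)
        truth = json.loads(sim_small_paths["truth"].read_text())
        assert truth["peaks"] == sim_small.truth["peaks"]

    def test_peaks_match_truth_record(self, sim_small):
        for peak, entry in zip(sim_small.peaks_a, sim_small.truth["peaks"]):
            assert (peak.chrom, peak.start, peak.end) == (
                entry["chrom"], entry["start"], entry["end"],
            )
            assert np.isclose(peak.signal, entry["density_a"])


class TestPlantedStructure:
    def test_noiseless_preference_recovery_is_exact(self):
        sim = simulate(SimConfig(seed=21, jitter_sd=0.0, **SMALL))
        assert measured_agreement(sim) == 1.0

    def test_recovery_monotone_in_jitter(self):
        agreements = [
            measured_agreement(simulate(SimConfig(seed=21, jitter_sd=sd, **SMALL)))
            for sd in (0.0, 0.25, 0.6)
        ]
        assert agreements[0] >= agreements[1] >= agreements[2]
        assert agreements[0] == 1.0

    def test_group_proportions_respected_exactly(self):
        sim = simulate(SimConfig(seed=3, **SMALL))
        groups = [p["group"] for p in sim.truth["peaks"]]
        n = len(groups)
        props = SimConfig().group_proportions
        for g in range(1, 7):
            assert abs(groups.count(g) - props[g - 1] * n) <= 1  # largest remainder

    def test_planted_clusters_called_superenhancers(self, sim_small):
        res = call_superenhancers(
            sim_small.peaks_a, sim_small.tracks[("mark_a", "control")]
        )
        report = truth_compare(sim_small.truth, se_result=res)
        assert report["se_recovery"]["n_clusters"] == 3
        assert report["se_recovery"]["jaccard_min"] >= 0.9

    def test_expression_counts_track_planted_logfc(self, sim_small):
        truth_genes = sim_small.truth["genes"]
        counts = sim_small.counts
        est = np.log2(counts[["trt_1", "trt_2"]].mean(axis=1) + 1) - np.log2(
            counts[["ctrl_1", "ctrl_2"]].mean(axis=1) + 1
        )
        planted = np.array([g["true_log2fc"] for g in truth_genes])
        # noisy per-gene, but strongly correlated in aggregate
        assert np.corrcoef(planted, est.values)[0, 1] > 0.4

    def test_infeasible_placement_rejected(self):
        config = SimConfig(
            seed=0,
            chrom_lengths=(("tiny", 400_000),),
            n_typical_peaks=120,
            n_se_clusters=1,
            n_genes=10,
        )
        with pytest.raises(ValueError, match="infeasible"):
            simulate(config)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(group_proportions=(0.5, 0.5, 0.5, 0, 0, 0)).validate()


class TestQuadrantSim:
    def test_thresholds_recover_planted_table_exactly(self):
        qs = simulate_quadrant(5000, 2.0, seed=9)
        table = quadrant_table(qs.x, qs.y, qs.thresh_x, qs.thresh_y)
        assert (table == qs.table).all()
        assert table.sum() == 5000

    def test_or_one_is_independence(self):
        qs = simulate_quadrant(50_000, 0.0, seed=10)
        t = qs.table.astype(float)
        orr = t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0])
        assert abs(np.log(orr)) < 3 * np.sqrt((1 / t).sum())


class TestTruthCompare:
    def test_truth_vs_truth_is_perfect(self, sim_small):
        universe = region_universe(sim_small.peaks_a, sim_small.peaks_b)
        records = preference_table(
            universe,
            sim_small.tracks[("mark_a", "control")],
            sim_small.tracks[("mark_b", "control")],
        )
        # replace measured groups by truth groups -> exact diagonal
        import dataclasses

        truth_group = {
            (p["chrom"], p["start"], p["end"]): p["group"]
            for p in sim_small.truth["peaks"]
        }
        exact = [
            dataclasses.replace(
                r, group=truth_group[(r.region.chrom, r.region.start, r.region.end)]
            )
            for r in records
        ]
        report = truth_compare(sim_small.truth, records=exact)
        confusion = np.array(report["group_recovery"]["confusion"])
        assert report["group_recovery"]["agreement"] == 1.0
        assert confusion.sum() == confusion.trace()

    def test_unknown_region_rejected(self, sim_small):
        from acetrank.io_formats import GenomicInterval
        from acetrank.preference import PreferenceRecord

        alien = [PreferenceRecord(GenomicInterval("chrZ", 0, 10), 0, 0, 0.0, 4)]
        with pytest.raises(ValueError, match="not found"):
            truth_compare(sim_small.truth, records=alien)


def test_interval_jaccard_basics():
    from acetrank.io_formats import GenomicInterval as GI

    a = GI("c", 0, 100)
    assert interval_jaccard(a, a) == 1.0
    assert interval_jaccard(a, GI("c", 100, 200)) == 0.0
    assert interval_jaccard(a, GI("d", 0, 100)) == 0.0
    assert interval_jaccard(a, GI("c", 50, 150)) == pytest.approx(50 / 150)
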