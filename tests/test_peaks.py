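"""Peak reconciliation: confidence classes, reproducibility, counting, testing."""
import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from chromlink import (
    SimulationConfig,
    classify_confidence,
    count_fragments_in_peaks,
    differential_peaks,
    generate_gene_models,
    merge_peaks,
    reproducible_peaks,
    sicer_percentile_classes,
    simulate_counts,
    simulate_peak_calls,
)


def _calls(rows, replicate=1):
    return pd.DataFrame(
        [
            {"chrom": c, "start": s, "end": e, "name": f"c{i}", "score": 0.0,
             "caller": caller, "replicate": replicate, "fdr": fdr}
            for i, (c, s, e, caller, fdr) in enumerate(rows)
        ]
    )


def _region(start, end, confidence, replicate, chrom="chr1"):
    return pd.DataFrame([{
        "chrom": chrom, "start": start, "end": end, "replicate": replicate,
        "confidence": confidence, "min_fdr": 0.01 if confidence == "strong" else 0.3,
    }])


class TestPercentileClasses:
    def _domains(self, n):
        return pd.DataFrame({
            "chrom": "chr1", "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 500, "score": np.arange(n, dtype=float),
        })

    def test_hundred_domains(self):
        cls = sicer_percentile_classes(self._domains(100))
        assert (cls == "high_confidence").sum() == 1
        assert (cls != "other").sum() == 5  # top 5% is a superset of the top 1%

    def test_ten_domains_ceiling(self):
        cls = sicer_percentile_classes(self._domains(10))
        # ceil(0.01*10) = 1 high; ceil(0.05*10) = 1, already taken by high
        assert (cls == "high_confidence").sum() == 1
        assert (cls != "other").sum() == 1

    def test_equal_scores_tie_break_deterministic(self):
        d = self._domains(100)
        d["score"] = 1.0
        cls1 = sicer_percentile_classes(d)
        cls2 = sicer_percentile_classes(d.sample(frac=1, random_state=0).sort_index())
        assert (cls1 == cls2).all()
        # ties resolved by (chrom, start): lowest coordinates win
        assert cls1.iloc[0] == "high_confidence"


class TestClassifyConfidence:
    def test_single_strong_call(self):
        regions = classify_confidence(_calls([("chr1", 100, 200, "caller_A", 0.03)]))
        assert list(regions["confidence"]) == ["strong"]

    def test_overlapping_weak_calls(self):
        regions = classify_confidence(_calls([
            ("chr1", 100, 200, "caller_A", 0.3),
            ("chr1", 150, 250, "caller_B", 0.45),
        ]))
        assert list(regions["confidence"]) == ["weak"]
        assert regions.iloc[0]["start"] == 100 and regions.iloc[0]["end"] == 250

    def test_unclassified_call(self):
        regions = classify_confidence(_calls([("chr1", 100, 200, "caller_A", 0.6)]))
        assert list(regions["confidence"]) == ["unclassified"]

    def test_mixed_replicates_rejected(self):
        calls = pd.concat([_calls([("chr1", 0, 10, "caller_A", 0.01)], 1),
                           _calls([("chr1", 0, 10, "caller_A", 0.01)], 2)])
        with pytest.raises(ValueError, match="replicate"):
            classify_confidence(calls)

    def test_strong_subset_of_weak(self, rng):
        rows = [("chr1", int(s), int(s) + 300, "caller_A", float(f))
                for s, f in zip(rng.integers(0, 10**6, 200), rng.random(200))]
        regions = classify_confidence(_calls(rows))
        strong = regions[regions["confidence"] == "strong"]
        assert (strong["min_fdr"] < 0.05).all()
        weak_or_strong = regions[regions["confidence"] != "unclassified"]
        assert (weak_or_strong["min_fdr"] < 0.5).all()


class TestReproducibility:
    @pytest.mark.parametrize(
        "classes,expected",
        [
            (("strong", "strong"), True),
            (("strong", "weak"), True),
            (("weak", "strong"), True),
            (("weak", "weak"), False),
            (("strong", "unclassified"), False),
        ],
    )
    def test_two_replicate_rule(self, classes, expected):
        regions = [_region(100, 200, c, rep) for rep, c in enumerate(classes, 1)]
        out = reproducible_peaks(regions, n_replicates=2)
        assert bool(out["reproducible"].iloc[0]) is expected

    def test_absent_replicate_fails(self):
        out = reproducible_peaks(
            [_region(100, 200, "strong", 1), _region(5000, 5100, "strong", 2)],
            n_replicates=2,
        )
        assert not out["reproducible"].any()

    def test_merged_interval_is_union_span(self):
        out = reproducible_peaks(
            [_region(100, 220, "strong", 1), _region(180, 300, "weak", 2)],
            n_replicates=2,
        )
        row = out.iloc[0]
        assert (row["start"], row["end"]) == (100, 300)

    def test_replicate_order_invariance(self, rng):
        frames = []
        for rep in (1, 2, 3):
            starts = rng.integers(0, 10**6, 50)
            frames.append(pd.concat([
                _region(int(s), int(s) + 400,
                        ["strong", "weak", "unclassified"][rng.integers(3)], rep)
                for s in starts
            ], ignore_index=True))
        a = reproducible_peaks(frames, n_replicates=3)
        b = reproducible_peaks(frames[::-1], n_replicates=3)
        pd.testing.assert_frame_equal(a, b)

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError, match="replicates"):
            reproducible_peaks([_region(0, 10, "strong", 1)], n_replicates=1)


class TestMerge:
    def test_overlap_bookend_nested(self):
        df = pd.DataFrame({
            "chrom": ["chr1"] * 2, "start": [100, 150], "end": [200, 250],
        })
        assert merge_peaks(df).iloc[0].tolist() == ["chr1", 100, 250]
        bookend = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [100, 200], "end": [200, 300]})
        assert len(merge_peaks(bookend)) == 2  # half-open: no shared base
        nested = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [100, 200], "end": [500, 300]})
        assert merge_peaks(nested).iloc[0].tolist() == ["chr1", 100, 500]

    def test_output_disjoint_sorted_and_bounded(self, rng):
        df = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], 300),
            "start": rng.integers(0, 10**5, 300),
        })
        df["end"] = df["start"] + rng.integers(1, 5000, 300)
        merged = merge_peaks(df)
        for _, g in merged.groupby("chrom"):
            assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()
        assert (merged["end"] - merged["start"]).sum() <= (df["end"] - df["start"]).sum()


class TestFragmentCounting:
    peaks = pd.DataFrame({
        "chrom": ["chr1", "chr1"], "start": [100, 1000], "end": [200, 1100],
        "peak_id": ["p1", "p2"],
    })

    def test_long_fragment_excluded(self):
        frag = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2500]})
        mat = count_fragments_in_peaks(self.peaks, {"s": frag})
        assert mat["s"].sum() == 0
        exactly_2000 = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [2000]})
        assert count_fragments_in_peaks(self.peaks, {"s": exactly_2000})["s"].sum() == 0

    def test_partial_overlap_counts(self):
        frag = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [350]})
        mat = count_fragments_in_peaks(self.peaks, {"s": frag})
        assert mat.loc["p1", "s"] == 1 and mat.loc["p2", "s"] == 0

    def test_fragment_spanning_two_peaks_counts_in_both(self):
        frag = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [1050]})
        mat = count_fragments_in_peaks(self.peaks, {"s": frag})
        assert mat["s"].tolist() == [1, 1]

    def test_no_fragments_all_zero(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        mat = count_fragments_in_peaks(self.peaks, {"s": empty})
        assert (mat == 0).all().all()

    def test_matches_bruteforce_on_random_data(self, rng):
        peaks = merge_peaks(pd.DataFrame({
            "chrom": "chr1", "start": rng.integers(0, 50_000, 40),
        }).assign(end=lambda d: d["start"] + rng.integers(100, 2000, 40)))
        peaks["peak_id"] = [f"m{i}" for i in range(len(peaks))]
        frag = pd.DataFrame({"chrom": "chr1", "start": rng.integers(0, 50_000, 500)})
        frag["end"] = frag["start"] + rng.integers(50, 3000, 500)
        mat = count_fragments_in_peaks(peaks, {"s": frag})
        for p in peaks.itertuples(index=False):
            expected = sum(
                1 for f in frag.itertuples(index=False)
                if (f.end - f.start) < 2000 and f.start < p.end and f.end > p.start
            )
            assert mat.loc[p.peak_id, "s"] == expected


class TestDifferentialPeaks:
    groups = {"c1": "control", "c2": "control", "t1": "treatment", "t2": "treatment"}

    def test_identical_groups_and_zero_peak(self):
        mat = pd.DataFrame(
            {"c1": [30, 0], "c2": [40, 0], "t1": [30, 0], "t2": [40, 0]},
            index=["pk1", "pk0"],
        )
        res = differential_peaks(mat, self.groups)
        assert res.loc["pk1", "log2fc"] == 0.0 and res.loc["pk1", "p_value"] == 1.0
        assert res.loc["pk0", "log2fc"] == 0.0 and res.loc["pk0", "p_value"] == 1.0

    def test_planted_twofold_peak_detected(self, rng):
        n = 100
        base = rng.poisson(200, size=(n, 2))
        trt = rng.poisson(200, size=(n, 2))
        trt[0] = rng.poisson(400, size=2)  # planted 2-fold gain
        mat = pd.DataFrame(np.hstack([base, trt]), columns=list(self.groups),
                           index=[f"pk{i}" for i in range(n)])
        res = differential_peaks(mat, self.groups)
        assert res.iloc[0]["fdr"] < 0.05
        assert res.iloc[0]["log2fc"] > 0

    def test_library_size_normalization(self):
        # treatment libraries sequenced twice as deep; counts double but
        # supplied totals double too, so nothing is differential
        mat = pd.DataFrame(
            {"c1": [50, 100], "c2": [50, 100], "t1": [100, 200], "t2": [100, 200]},
            index=["a", "b"],
        )
        libs = pd.Series({"c1": 10_000.0, "c2": 10_000.0, "t1": 20_000.0, "t2": 20_000.0})
        res = differential_peaks(mat, self.groups, library_sizes=libs)
        assert np.allclose(res["log2fc"], 0.0)


def test_all_strong_planted_peaks_all_reproducible(small_config):
    """With no borderline or spurious calls every planted peak is strong in
    both replicates, so the reproducible set recovers the planted set exactly."""
    cfg = dataclasses.replace(small_config, borderline_frac=0.0, spurious_frac=0.0)
    genes = generate_gene_models(cfg)
    _, _, truth = simulate_counts(genes, cfg)
    peaks, calls = simulate_peak_calls(genes, truth, cfg)
    regions = {
        rep: classify_confidence(calls[calls["replicate"] == rep])
        for rep in sorted(calls["replicate"].unique())
    }
    repro = reproducible_peaks(regions, n_replicates=cfg.n_replicates)
    assert int(repro["reproducible"].sum()) == len(peaks)


def test_reproducibility_rule_exhaustive_truth_table():
    """All 3^n support-class combinations for 2 and 3 replicates classify
    exactly per the rule: strong everywhere, or one strong + weak elsewhere."""
    for n in (2, 3):
        for combo in itertools.product(["strong", "weak", "unclassified"], repeat=n):
            regions = [_region(100, 200, c, rep) for rep, c in enumerate(combo, 1)]
            out = reproducible_peaks(regions, n_replicates=n)
            expected = all(c == "strong" for c in combo) or (
                any(c == "strong" for c in combo)
                and all(c in ("strong", "weak") for c in combo)
            )
            assert bool(out["reproducible"].iloc[0]) is expected, combo
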