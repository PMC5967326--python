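"""IMD, exact PCF segmentation, NB background and hotspot calling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lungsig.hotspots import (
    PCFParams,
    call_hotspots,
    compute_imd,
    count_breakpoints,
    expected_breakpoints,
    fit_background,
    make_bins,
    normalize_features,
    pcf_segment,
)
from lungsig.io_formats import RearrangementRecord
from lungsig.simulate import generate_features, simulate_breakpoints


def brute_force_pcf(values, gamma, kmin):
    """Enumerate every valid segmentation; return the minimal objective."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < kmin:
        return float(((v - v.mean()) ** 2).sum()) + gamma
    best = np.inf
    # choose boundary positions among 1..n-1
    for k in range(0, n):
        for cuts in itertools.combinations(range(1, n), k):
            bounds = (0,) + cuts + (n,)
            if any(b - a < kmin for a, b in zip(bounds, bounds[1:])):
                continue
            obj = sum(
                ((v[a:b] - v[a:b].mean()) ** 2).sum() + gamma
                for a, b in zip(bounds, bounds[1:])
            )
            best = min(best, obj)
    return best


def pcf_objective(values, segments, gamma):
    v = np.asarray(values, dtype=float)
    return sum(
        ((v[a : b + 1] - v[a : b + 1].mean()) ** 2).sum() + gamma
        for a, b, _ in segments
    )


class TestComputeImd:
    def test_imd_definition(self):
        recs = [
            RearrangementRecord("s", "chr1", 100, "chr1", 600, "DEL"),
            RearrangementRecord("s", "chr1", 1600, "chr1", 9000, "DUP"),
        ]
        bps = [b for b in compute_imd(recs) if b.chrom == "chr1"]
        assert [b.pos for b in bps] == [100, 600, 1600, 9000]
        assert [b.imd for b in bps] == [None, 500, 1000, 7400]

    def test_both_ends_and_tra_contribute(self):
        recs = [
            RearrangementRecord("s", "chr1", 10, "chr1", 20, "DEL"),
            RearrangementRecord("s", "chr2", 5, "chr3", 7, "TRA"),
        ]
        bps = compute_imd(recs)
        assert len(bps) == 4
        # single breakpoint per chromosome -> no defined IMD
        assert all(b.imd is None for b in bps if b.chrom in ("chr2", "chr3"))


class TestPCF:
    def test_constant_sequence_single_segment(self):
        segs = pcf_segment([3.0] * 20, PCFParams())
        assert segs == [(0, 19, 3.0)]

    def test_two_level_sequence_splits_at_step(self):
        values = [0.0] * 10 + [100.0] * 10
        segs = pcf_segment(values, PCFParams(gamma=8, kmin=8))
        assert [(s, e) for s, e, _ in segs] == [(0, 9), (10, 19)]
        assert segs[0][2] == pytest.approx(0.0)
        assert segs[1][2] == pytest.approx(100.0)

    def test_short_sequence_single_segment(self):
        segs = pcf_segment([1.0, 5.0, 2.0], PCFParams(kmin=8))
        assert segs == [(0, 2, pytest.approx(8 / 3))]

    @pytest.mark.parametrize("kmin", [2, 3])
    @pytest.mark.parametrize("gamma", [0.5, 2.0, 8.0])
    def test_dp_equals_brute_force(self, gamma, kmin):
        """The DP objective matches exhaustive enumeration for all random
        fixtures of length <= 15."""
        rng = np.random.default_rng(17)
        for n in (4, 7, 10, 13, 15):
            for _ in range(4):
                v = np.round(rng.normal(0, 1, n), 3)
                if rng.random() < 0.5:  # adversarial: planted step
                    v[n // 2 :] += rng.choice([2.0, 10.0])
                params = PCFParams(gamma=gamma, kmin=kmin)
                segs = pcf_segment(v, params)
                assert pcf_objective(v, segs, gamma) == pytest.approx(
                    brute_force_pcf(v, gamma, kmin)
                )

    def test_segments_partition_sequence(self):
        rng = np.random.default_rng(5)
        v = rng.normal(0, 1, 60)
        segs = pcf_segment(v, PCFParams(gamma=2, kmin=4))
        covered = [i for s, e, _ in segs for i in range(s, e + 1)]
        assert covered == list(range(60))


class TestBackgroundModel:
    @staticmethod
    def simulated_bins(n=5000, m=1.0, w=(0.5, -0.3), dispersion=0.5, seed=0):
        rng = np.random.default_rng(seed)
        bins = pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(n) * 500_000,
            "end": (np.arange(n) + 1) * 500_000,
            "f1": rng.normal(0, 1, n),
            "f2": rng.normal(0, 1, n),
        })
        bins = normalize_features(bins, ["f1", "f2"])
        mu = np.exp(m + w[0] * bins["f1"] + w[1] * bins["f2"])
        lam = rng.gamma(1 / dispersion, dispersion * mu)
        bins["observed"] = rng.poisson(lam)
        return bins

    def test_parameter_recovery_at_5000_bins(self):
        bins = self.simulated_bins()
        model = fit_background(bins, ["f1", "f2"])
        assert model.m == pytest.approx(1.0, abs=0.1)
        assert model.w[0] == pytest.approx(0.5, abs=0.1)
        assert model.w[1] == pytest.approx(-0.3, abs=0.1)

    def test_intercept_only_limit(self):
        rng = np.random.default_rng(3)
        n = 2000
        bins = pd.DataFrame({
            "chrom": "chr1", "start": np.arange(n), "end": np.arange(n) + 1,
            "f1": np.concatenate([rng.normal(0, 1, n)]),
        })
        bins = normalize_features(bins, ["f1"])
        bins["observed"] = rng.poisson(3.0, n)
        model = fit_background(bins, ["f1"])
        assert abs(model.w[0]) < 0.05
        assert np.exp(model.m) == pytest.approx(bins["observed"].mean(), rel=0.05)

    def test_scale_invariance_after_normalization(self):
        """Fitting on a rescaled raw feature agrees after z-normalization."""
        bins = self.simulated_bins(n=3000, seed=5)
        raw = bins.copy()
        raw["f1"] = raw["f1"] * 2 + 7  # affine rescale, then renormalize
        renorm = normalize_features(raw, ["f1", "f2"])
        a = fit_background(bins, ["f1", "f2"])
        b = fit_background(renorm, ["f1", "f2"])
        assert a.w == pytest.approx(b.w, abs=1e-6)

    def test_expected_breakpoints_closed_forms(self):
        from lungsig.hotspots import BackgroundModel

        model = BackgroundModel(m=1.3, w=np.zeros(3), dispersion=0.2,
                                feature_names=["a", "b", "c"])
        assert expected_breakpoints(model, [5.0, -2.0, 0.1]) == pytest.approx(np.e**1.3)
        model2 = BackgroundModel(m=0.0, w=np.array([1.0]), dispersion=0.2,
                                 feature_names=["a"])
        assert expected_breakpoints(model2, [1.0]) == pytest.approx(np.e)
        with pytest.raises(ValueError):
            expected_breakpoints(model2, [1.0, 2.0])

    def test_formula_matches_fitted_means(self):
        """b_i from the closed-form formula equals the regression's fitted
        mean on every training bin."""
        import statsmodels.api as sm

        bins = self.simulated_bins(n=1500, seed=9)
        model = fit_background(bins, ["f1", "f2"])
        F = bins[["f1", "f2"]].to_numpy()
        b = model.expected(F)
        X = sm.add_constant(F)
        eta = X @ np.concatenate([[model.m], model.w])
        assert b == pytest.approx(np.exp(eta))


class TestCallHotspots:
    @staticmethod
    def planted_genome(seed, n_clusters=5):
        contigs = {f"chr{i + 1}": 10_000_000 for i in range(20)}
        feats = generate_features(contigs, seed=seed)
        rng = np.random.default_rng(seed + 1000)
        chroms = rng.choice(20, size=n_clusters, replace=False)
        clusters = []
        for c in chroms:
            start = int(rng.integers(500_000, 9_000_000))
            clusters.append((f"chr{c + 1}", start, start + 50_000, 30))
        bins, bps = simulate_breakpoints(
            feats, ["timing", "repeats", "noise"], m=1.0, w=(0.5, -0.3, 0.0),
            dispersion=0.3, clusters=clusters, seed=seed + 2000,
        )
        return bins, bps, clusters

    @staticmethod
    def match(hotspots, clusters, slop=500_000):
        hits = set()
        fp = 0
        for h in hotspots:
            matched = False
            for k, (chrom, start, end, _n) in enumerate(clusters):
                if h.chrom == chrom and h.start < end + slop and h.end > start - slop:
                    hits.add(k)
                    matched = True
            fp += not matched
        return hits, fp

    def test_planted_clusters_recovered(self):
        bins, bps, clusters = self.planted_genome(seed=101)
        model = fit_background(bins, ["timing", "repeats", "noise"])
        hotspots = call_hotspots(bps, model, bins)
        hits, _fp = self.match(hotspots, clusters)
        assert len(hits) == 5
        # boundaries within one bin of the planted interval
        for h in hotspots:
            for chrom, start, end, _n in clusters:
                if h.chrom == chrom and h.start < end and h.end > start:
                    assert abs(h.start - start) <= 500_000
                    assert abs(h.end - end) <= 500_000

    def test_null_genome_rarely_calls_hotspots(self):
        """Uniform breakpoints with a correct background model: <= 1 false
        call per replicate on average."""
        total = 0
        for seed in range(5):
            contigs = {f"chr{i + 1}": 10_000_000 for i in range(20)}
            feats = generate_features(contigs, seed=300 + seed)
            bins, bps = simulate_breakpoints(
                feats, ["timing", "repeats", "noise"], m=1.0, w=(0.0, 0.0, 0.0),
                dispersion=0.3, seed=400 + seed,
            )
            model = fit_background(bins, ["timing", "repeats", "noise"])
            total += len(call_hotspots(bps, model, bins))
        assert total / 5 <= 1.0

    def test_high_imd_segment_never_hotspot(self):
        bins, bps, _ = self.planted_genome(seed=55)
        model = fit_background(bins, ["timing", "repeats", "noise"])
        hotspots = call_hotspots(bps, model, bins)
        imds = [b.imd for b in bps if b.imd is not None]
        genome_mean = np.mean(imds)
        assert all(h.mean_imd <= genome_mean / 2 for h in hotspots)
        assert all(h.n_breakpoints > h.expected_count for h in hotspots)

    def test_invariance_to_relabeling_and_shift(self):
        """Hotspot calls are invariant under chromosome renaming and a
        global coordinate shift by a whole number of bins."""
        from dataclasses import replace

        bins, bps, clusters = self.planted_genome(seed=77)
        model = fit_background(bins, ["timing", "repeats", "noise"])
        base = call_hotspots(bps, model, bins)

        renamed_bins = bins.copy()
        mapping = {f"chr{i + 1}": f"K{i + 1}" for i in range(20)}
        renamed_bins["chrom"] = renamed_bins["chrom"].map(mapping)
        renamed_bps = [replace(b, chrom=mapping[b.chrom]) for b in bps]
        renamed = call_hotspots(renamed_bps, model, renamed_bins)
        assert sorted((mapping[h.chrom], h.start, h.end) for h in base) == sorted(
            (h.chrom, h.start, h.end) for h in renamed
        )

        shift = 1_000_000
        shifted_bins = bins.copy()
        shifted_bins["start"] += shift
        shifted_bins["end"] += shift
        shifted_bps = [replace(b, pos=b.pos + shift) for b in bps]
        shifted = call_hotspots(shifted_bps, model, shifted_bins)
        assert sorted((h.chrom, h.start + shift, h.end + shift) for h in base) == sorted(
            (h.chrom, h.start, h.end) for h in shifted
        )


def test_make_bins_and_counting():
    bins = make_bins({"chrA": 1_200_000}, bin_size=500_000)
    assert list(bins["end"]) == [500_000, 1_000_000, 1_200_000]
    from lungsig.hotspots import Breakpoint

    bps = [Breakpoint("chrA", 500_000, "s", None), Breakpoint("chrA", 500_001, "s", 1)]
    counted = count_breakpoints(bins, bps)
    # 1-based pos 500000 belongs to the first bin [0, 500000)
    assert list(counted["observed"]) == [1, 1, 0]
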