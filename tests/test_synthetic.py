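import numpy as np
import pandas as pd
import pytest

import picarch as pc
from picarch.annotations import ValidationError


def _simulate(**kw):
    defaults = dict(
        n_promoters=30,
        architectures=pc.human_mode_architectures(),
        noise=pc.NoiseSpec(background_cpm=0.0),
        seed=5,
    )
    defaults.update(kw)
    return pc.simulate_dataset(**defaults)


class TestDeterminismAndIsolation:
    def test_same_seed_bit_identical(self):
        a, b = _simulate(), _simulate()
        for key in a.tracks:
            np.testing.assert_array_equal(
                a.tracks[key].data["chr1"], b.tracks[key].data["chr1"]
            )
        pd.testing.assert_frame_equal(a.truth.summits, b.truth.summits)

    def test_different_seed_differs(self):
        a, b = _simulate(seed=5), _simulate(seed=6)
        occ_a = a.truth.occupancy["occupancy"].to_numpy()
        occ_b = b.truth.occupancy["occupancy"].to_numpy()
        assert not np.allclose(occ_a, occ_b)

    def test_adding_a_factor_leaves_others_unchanged(self):
        """Per-factor RNG streams: extending the factor list must not
        perturb existing factors' occupancies or tracks."""
        base = [pc.FactorArchitecture("TBP"), pc.FactorArchitecture("PolII", offset_bp=50)]
        extra = base + [pc.FactorArchitecture("SP1", offset_bp=-80)]
        a = _simulate(architectures=base)
        b = _simulate(architectures=extra)
        for f in ("TBP", "PolII"):
            np.testing.assert_array_equal(
                a.track(f).data["chr1"], b.track(f).data["chr1"]
            )


class TestTruth:
    def test_truth_covers_every_region_factor_pair(self):
        ds = _simulate(n_promoters=10)
        assert len(ds.truth.occupancy) == 10 * 3
        assert len(ds.truth.summits) == 10 * 3  # one replicate each

    def test_truth_report_reproducible_bytes(self, tmp_path):
        for sub in ("a", "b"):
            pc.truth_report(_simulate().truth, tmp_path / sub)
        for name in ("truth_summits.tsv", "truth_occupancy.tsv",
                     "truth_regions.tsv", "params.yaml"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_planted_label_lands_in_gene_class(self):
        spec = pc.DiscordanceSpec("SP1", "TBP", planted_fraction=0.5,
                                  log2_shift=-2.0, planted_label="low_sp1")
        ds = _simulate(n_promoters=50, discordance=[spec])
        members = ds.truth.members("low_sp1")
        assert 10 < len(members) < 40
        tagged = ds.genes.set_index("gene_id").loc[members, "gene_class"]
        assert (tagged.str.contains("low_sp1")).all()


class TestPlantedGeometry:
    def test_noise_free_summits_recovered_within_one_bin(self):
        ds = _simulate()
        for (f, rep), tr in ds.tracks.items():
            calls = pc.call_summits(tr, ds.promoters, background=0.0)
            truth = ds.truth.summits.query(
                "factor == @f and replicate == @rep"
            ).set_index("region_id")["summit"]
            err = (calls.set_index("region_id")["summit"] - truth).abs()
            assert err.max() <= ds.bin_size

    def test_zero_coupling_noise_gives_perfect_log_correlation(self):
        archs = [pc.FactorArchitecture("A"),
                 pc.FactorArchitecture("B", coupling=("A", 0.0))]
        ds = _simulate(architectures=archs)
        occ = ds.truth.occupancy.pivot(index="region_id", columns="factor",
                                       values="occupancy")
        r = np.corrcoef(np.log10(occ["A"]), np.log10(occ["B"]))[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_coupling_requires_base_generated_first(self):
        archs = [pc.FactorArchitecture("B", coupling=("A", 0.1)),
                 pc.FactorArchitecture("A")]
        with pytest.raises(ValidationError, match="generated first"):
            _simulate(architectures=archs)

    def test_enhancers_have_bidirectional_peaks(self):
        ds = _simulate(n_promoters=0, n_enhancers=5,
                       architectures=[pc.FactorArchitecture("Med1")],
                       enhancer_asymmetry_log2_sd=0.2)
        tr = ds.track("Med1")
        for r in ds.enhancers:
            w = tr.values_in(r.chrom, r.anchor - 300, r.anchor + 300)
            sm = pc.smooth(w, 25, tr.bin_size)
            interior = (sm >= np.roll(sm, 1)) & (sm >= np.roll(sm, -1))
            interior[[0, -1]] = False
            peaks = np.flatnonzero(interior & (sm > 0.5 * sm.max()))
            # two divergent PICs ~200 bp apart -> two separated maxima
            assert peaks.max() - peaks.min() >= 150 / tr.bin_size

    def test_pol_ii_body_plateau_present(self):
        archs = [pc.FactorArchitecture("PolII", offset_bp=50)]
        ds = _simulate(
            architectures=archs, gene_length=5000,
            pause_spec=pc.PauseSpec("PolII", body_level_ratio=0.2),
        )
        g = ds.genes.iloc[0]
        tr = ds.track("PolII")
        occ = ds.truth.occupancy.set_index(["region_id", "factor"]) \
            .loc[(g.gene_id, "PolII"), "occupancy"]
        s = 1 if g.strand == "+" else -1
        body = tr.values_in(g.chrom, min(g.tss + s * 2000, g.tss + s * 3000),
                            max(g.tss + s * 2000, g.tss + s * 3000))
        np.testing.assert_allclose(body, 0.2 * occ, rtol=1e-6)

    def test_downstream_peak_subset_is_bimodal(self):
        archs = [pc.FactorArchitecture("Taf7", peak_sd_bp=40)]
        spec = pc.DownstreamPeakSpec("Taf7", fraction=0.5, offset_bp=150,
                                     minor_to_major_height=0.6)
        ds = _simulate(architectures=archs, downstream_peak=spec)
        members = ds.truth.members(spec.group_label)
        assert len(members) > 0
        g = ds.genes.set_index("gene_id").loc[members[0]]
        tr = ds.track("Taf7")
        s = 1 if g.strand == "+" else -1
        at_tss = tr.value_at(g.chrom, int(g.tss))
        at_ds = tr.value_at(g.chrom, int(g.tss + s * 150))
        assert at_ds == pytest.approx(0.6 * at_tss, rel=0.05)
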