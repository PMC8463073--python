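import numpy as np
import pandas as pd
import pytest

import picarch as pc
from picarch.annotations import ValidationError

from conftest import make_track


def _gene(tss=5000, strand="+", length=10_000, gene_id="g"):
    tes = tss + length - 1 if strand == "+" else tss - length + 1
    return pd.Series({"gene_id": gene_id, "chrom": "chr1", "tss": tss,
                      "tes": tes, "strand": strand, "gene_class": ""})


def _piecewise_track(tss=5000, prox=10.0, body=2.0, size=20_000):
    """Proximal window at `prox`, gene body at `body` (plus strand)."""
    x = np.zeros(size)
    x[tss - 50: tss + 300] = prox
    x[tss + 300: tss + 10_000] = body
    return make_track(x, bin_size=1)


class TestPausingIndex:
    def test_uniform_track_gives_index_one(self):
        tr = make_track(np.full(20_000, 3.0), bin_size=1)
        res = pc.pausing_index(tr, _gene())
        assert res.pausing_index == pytest.approx(1.0)
        assert res.status == "ok"

    def test_hand_computed_ratio(self):
        res = pc.pausing_index(_piecewise_track(prox=10.0, body=2.0), _gene())
        assert res.proximal_mean == pytest.approx(10.0)
        assert res.body_mean == pytest.approx(2.0)
        assert res.pausing_index == pytest.approx(5.0)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_orientation_aware_windows(self, strand):
        size = 40_000
        tss = 20_000
        x = np.zeros(size)
        s = 1 if strand == "+" else -1
        lo, hi = sorted((tss + s * -50, tss + s * 300))
        x[lo:hi] = 8.0
        lo, hi = sorted((tss + s * 2000, tss + s * 4000))
        x[lo:hi] = 4.0
        tr = make_track(x, bin_size=1, chrom_len=size)
        res = pc.pausing_index(tr, _gene(tss=tss, strand=strand))
        assert res.pausing_index == pytest.approx(2.0, rel=0.02)

    def test_short_gene_body_truncated_at_tes(self):
        res = pc.pausing_index(_piecewise_track(), _gene(length=2500),
                               min_body=500)
        assert res.status == "short_gene_adjusted"
        assert res.body_window_used == (2000, 2500)
        assert np.isfinite(res.pausing_index)

    def test_gene_below_min_body_excluded(self):
        res = pc.pausing_index(_piecewise_track(), _gene(length=2400),
                               min_body=500)
        assert res.status == "excluded"
        assert np.isnan(res.pausing_index)

    def test_zero_body_excluded_without_division_error(self):
        x = np.zeros(20_000)
        x[4950: 5300] = 10.0  # proximal only, empty body
        res = pc.pausing_index(make_track(x, bin_size=1), _gene())
        assert res.status == "excluded"
        assert np.isnan(res.pausing_index)

    def test_scale_invariance(self):
        tr = _piecewise_track()
        a = pc.pausing_index(tr, _gene()).pausing_index
        b = pc.pausing_index(tr.scaled(13.0), _gene()).pausing_index
        assert a == pytest.approx(b)

    def test_gene_shorter_than_proximal_window_rejected(self):
        with pytest.raises(ValidationError, match="proximal"):
            pc.pausing_index(_piecewise_track(), _gene(length=200))


class TestSyntheticPausing:
    def test_recovered_index_matches_generator_geometry(self):
        """Body plateau at ratio beta of peak height: analytic oracle for the
        windowed proximal mean of a Gaussian over the plateau."""
        beta, sd, off = 0.1, 60.0, 50.0
        arch = [pc.FactorArchitecture("PolII", offset_bp=off, peak_sd_bp=sd)]
        ds = pc.simulate_dataset(
            n_promoters=20, architectures=arch, gene_length=6000,
            pause_spec=pc.PauseSpec("PolII", body_level_ratio=beta),
            noise=pc.NoiseSpec(0.0), seed=21,
        )
        tab = pc.pausing_table(ds.track("PolII"), ds.genes)
        occ = ds.truth.occupancy.set_index("region_id")["occupancy"]
        # windowed mean of h*N(off, sd) over [-50, 300), plus the body
        # plateau where the window overlaps the gene (300 of 350 bp)
        from scipy.stats import norm
        frac = (norm.cdf((300 - off) / sd) - norm.cdf((-50 - off) / sd))
        for gid, row in tab.iterrows():
            h = occ.loc[gid]
            prox_pred = h * frac * sd * np.sqrt(2 * np.pi) / 350 \
                + beta * h * 300 / 350
            # tolerance covers 5 bp discretization of the continuous oracle
            assert row.pausing_index == pytest.approx(prox_pred / (beta * h),
                                                      rel=0.04)

    def test_decile_trend_reproduces_planted_coupling_sign(self):
        """Positive occupancy exponent on the body plateau plants a
        decreasing pausing index across occupancy deciles."""
        archs = [pc.FactorArchitecture("TBP"),
                 pc.FactorArchitecture("PolII", offset_bp=50,
                                       coupling=("TBP", 0.0))]
        ds = pc.simulate_dataset(
            n_promoters=200, architectures=archs, gene_length=6000,
            pause_spec=pc.PauseSpec("PolII", body_level_ratio=0.1,
                                    occupancy_exponent=0.5),
            noise=pc.NoiseSpec(0.0), seed=22,
        )
        tab = pc.occupancy_table(
            {"TBP": ds.track("TBP")}, ds.promoters, method="summit_height")
        pauses = pc.pausing_table(ds.track("PolII"), ds.genes)
        res = pc.decile_summary(tab, "TBP", pauses["pausing_index"])
        # strong monotone decrease: top decile far below bottom decile
        assert res["response_median"].iloc[-1] < res["response_median"].iloc[0]
        rho = np.corrcoef(res["decile"], res["response_median"])[0, 1]
        assert rho < -0.8
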