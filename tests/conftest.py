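import numpy as np
import pandas as pd
import pytest

import picarch as pc


@pytest.fixture(scope="session")
def tiny_layout():
    return pc.GenomeLayout(("chr1",), (100_000,))


@pytest.fixture(scope="session")
def human_noise_free():
    """Small noise-free human-mode dataset: exact geometry, no jitter."""
    return pc.simulate_dataset(
        n_promoters=40,
        architectures=pc.human_mode_architectures(jitter_sd_bp=0.0),
        noise=pc.NoiseSpec(background_cpm=0.0),
        seed=11,
    )


def make_track(values, bin_size=1, chrom="chr1", factor="F", chrom_len=None):
    """Track from an explicit per-bin vector (test helper)."""
    values = np.asarray(values, dtype=float)
    chrom_len = chrom_len or len(values) * bin_size
    layout = pc.GenomeLayout((chrom,), (chrom_len,))
    tr = pc.CoverageTrack.zeros(factor, layout, bin_size)
    tr.data[chrom][: len(values)] = values
    return tr


def region(chrom="chr1", start=0, end=100, region_id="r1", anchor=None,
           strand="+"):
    return pc.RegionSet(pd.DataFrame(
        [(chrom, start, end, region_id,
          anchor if anchor is not None else (start + end) // 2, strand)],
        columns=pc.RegionSet.COLUMNS,
    ))
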