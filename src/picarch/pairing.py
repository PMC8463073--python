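"""Inter-factor summit distances and the replicate-based null scale.

Summits are paired by shared region_id (one summit per factor per
region), mirroring a per-promoter/per-enhancer analysis: the statistic of
interest is the distribution of absolute summit-to-summit distances for a
factor pair, summarized by its median and quartiles. The null scale for
interpreting those distances is the same statistic computed between two
biological replicates of a single factor, which reflects pure
experimental variation in summit position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import ValidationError


class PairingError(ValueError):
    """No usable summit pairs."""


@dataclass
class DistanceStats:
    factor_pair: tuple[str, str]
    distances: pd.Series          # |summit_a - summit_b| per region_id, bp
    median: float
    q25: float
    q75: float
    n_pairs: int
    n_excluded_distance: int = 0  # pairs beyond max_distance
    n_excluded_detection: int = 0  # regions lacking a call in either factor
    label: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "factor_pair": list(self.factor_pair),
                "median": self.median, "q25": self.q25, "q75": self.q75,
                "n_pairs": self.n_pairs,
                "n_excluded_distance": self.n_excluded_distance,
                "n_excluded_detection": self.n_excluded_detection,
                "label": self.label,
            }, fh, indent=1)

    def to_tsv(self, path) -> None:
        self.distances.rename("distance_bp").to_csv(path, sep="\t")


def summit_distances(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    max_distance: float = 500.0,
    label: str = "",
) -> DistanceStats:
    """Absolute per-region summit distances between two factors' calls.

    Only regions where both factors are detected contribute; pairs
    farther apart than max_distance are excluded and counted. Quantiles
    use linear interpolation (boxplot convention).
    """
    if max_distance <= 0:
        raise ValidationError("max_distance must be > 0")
    a = calls_a.loc[calls_a["detected"]].set_index("region_id")["summit"]
    b = calls_b.loc[calls_b["detected"]].set_index("region_id")["summit"]
    common = a.index.intersection(b.index)
    n_det_excl = (len(set(calls_a["region_id"]) | set(calls_b["region_id"]))
                  - len(common))
    d = (a.loc[common] - b.loc[common]).abs().astype(float)
    keep = d <= max_distance
    n_far = int((~keep).sum())
    d = d[keep]
    if d.empty:
        raise PairingError("zero usable summit pairs")
    q25, med, q75 = np.percentile(d.to_numpy(), [25, 50, 75])
    pair = (
        str(calls_a["factor_name"].iloc[0]) if len(calls_a) else "a",
        str(calls_b["factor_name"].iloc[0]) if len(calls_b) else "b",
    )
    return DistanceStats(
        factor_pair=pair, distances=d, median=float(med),
        q25=float(q25), q75=float(q75), n_pairs=int(len(d)),
        n_excluded_distance=n_far, n_excluded_detection=int(n_det_excl),
        label=label,
    )


def replicate_null(
    calls_rep1: pd.DataFrame,
    calls_rep2: pd.DataFrame,
    max_distance: float = 500.0,
) -> DistanceStats:
    """Replicate-vs-replicate distance stats for one factor: the null
    scale of experimental variation against which factor-pair distances
    are interpreted."""
    f1 = set(calls_rep1["factor_name"])
    f2 = set(calls_rep2["factor_name"])
    if f1 and f2 and f1 != f2:
        raise ValidationError("replicate_null requires two replicates of one factor")
    return summit_distances(
        calls_rep1, calls_rep2, max_distance=max_distance,
        label="replicate_null",
    )
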