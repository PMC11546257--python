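"""Two-channel smFISH colocalisation: brightness filtering, nearest
neighbour matching, independent-signal fractions and group comparisons.

A spot is *independent* if the nearest spot of the opposite channel in the
same image (2-D Euclidean distance on z-projected coordinates) is farther
than the colocalisation threshold (default 3 px at 108 nm/px). Fractions
are pooled over all images/fields of a replicate.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import false_discovery_control, ttest_ind

REQUIRED = ["image", "replicate", "cell", "channel", "x_px", "y_px", "brightness"]
CHANNELS = ("upstream", "downstream")


def brightness_top_half(spots: pd.DataFrame,
                        per: tuple[str, ...] = ("channel", "image")
                        ) -> pd.DataFrame:
    """Keep spots with brightness >= the median of their group
    (default channel x image); ceil(n/2) spots survive on odd n, and ties
    at the median are all kept."""
    med = spots.groupby(list(per))["brightness"].transform("median")
    return spots.loc[spots.brightness >= med].copy()


def independent_fraction(spots: pd.DataFrame, dist_threshold_px: float = 3.0,
                         brightness_filter: bool = True,
                         neighbors_unfiltered: bool = True) -> pd.DataFrame:
    """Per (gene, channel, replicate) independent-signal fractions.

    Scored spots are the brightness-filtered set (when
    ``brightness_filter``); nearest-neighbour candidates come from the
    opposite channel's full pre-filter set unless ``neighbors_unfiltered``
    is False. Images with one channel entirely absent count all scored
    spots of the other channel as independent and are flagged.
    """
    missing = [c for c in REQUIRED if c not in spots.columns]
    if missing:
        raise ValueError(f"spot table lacks column(s) {missing}")
    spots = spots.copy()
    if "gene" not in spots.columns:
        spots["gene"] = ""
    scored = brightness_top_half(spots) if brightness_filter else spots
    neighbours = spots if neighbors_unfiltered else scored

    records = []
    for image, img_scored in scored.groupby("image"):
        img_nb = neighbours[neighbours.image == image]
        for channel in CHANNELS:
            mine = img_scored[img_scored.channel == channel]
            if mine.empty:
                continue
            other = img_nb[img_nb.channel != channel]
            if other.empty:
                indep = np.ones(len(mine), dtype=bool)
                flagged = True
            else:
                tree = cKDTree(other[["x_px", "y_px"]].to_numpy())
                dist, _ = tree.query(mine[["x_px", "y_px"]].to_numpy())
                indep = dist > dist_threshold_px
                flagged = False
            for (gene, rep), grp in mine.assign(indep=indep).groupby(
                    ["gene", "replicate"]):
                records.append((gene, channel, rep, image, len(grp),
                                int(grp.indep.sum()), flagged))
    per_img = pd.DataFrame(records, columns=[
        "gene", "channel", "replicate", "image", "n_spots", "n_independent",
        "other_channel_missing"])
    out = (per_img.groupby(["gene", "channel", "replicate"], as_index=False)
           .agg(n_spots_considered=("n_spots", "sum"),
                n_independent=("n_independent", "sum"),
                other_channel_missing=("other_channel_missing", "any")))
    out["fraction_independent"] = out.n_independent / out.n_spots_considered
    return out


def compare_groups(fractions: pd.DataFrame, correction: str = "bh",
                   control: str | None = None) -> pd.DataFrame:
    """Pairwise Welch t-tests on per-replicate fractions between genes,
    within each channel, with Benjamini-Hochberg adjustment across the
    whole table. ``control`` marks contrasts against a control gene."""
    if correction.lower() != "bh":
        raise ValueError("only Benjamini-Hochberg correction is supported")
    rows = []
    for channel, sub in fractions.groupby("channel"):
        genes = sorted(sub.gene.unique())
        for g1, g2 in combinations(genes, 2):
            a = sub.loc[sub.gene == g1, "fraction_independent"].to_numpy()
            b = sub.loc[sub.gene == g2, "fraction_independent"].to_numpy()
            t, p = ttest_ind(a, b, equal_var=False)
            rows.append((channel, g1, g2, float(np.mean(a)), float(np.mean(b)),
                         float(t), float(p),
                         control in (g1, g2) if control else False))
    table = pd.DataFrame(rows, columns=["channel", "gene1", "gene2",
                                        "mean1", "mean2", "t", "p",
                                        "control_contrast"])
    if len(table):
        table["p_adj"] = false_discovery_control(table["p"].fillna(1.0),
                                                 method="bh")
    else:
        table["p_adj"] = []
    return table
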