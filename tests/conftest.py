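"""Shared fixtures: the synthetic demonstration panel and its wavelet
spectra / significance masks are computed once per session (the surrogate
ensembles are the expensive part)."""

from __future__ import annotations

import numpy as np
import pytest

from wavecluster.clustering import (correlation_dissimilarity, ward_cluster,
                                    wavelet_distance_matrix)
from wavecluster.cwt import morlet_cwt
from wavecluster.series import RegularSeriesSet
from wavecluster.significance import (markov_surrogates, significance_mask,
                                      surrogate_power)
from wavecluster.synthetic import make_fig1_panel

N_SURROGATES = 100


@pytest.fixture(scope="session")
def panel():
    return make_fig1_panel()


@pytest.fixture(scope="session")
def panel_series_set(panel) -> RegularSeriesSet:
    return RegularSeriesSet(
        tuple(panel.labels),
        panel.series[0].times,
        np.vstack([s.values for s in panel.series]),
    )


@pytest.fixture(scope="session")
def panel_spectra(panel):
    return {s.label: morlet_cwt(s) for s in panel.series}


@pytest.fixture(scope="session")
def panel_masks(panel, panel_spectra):
    """Clustering-level (90%) and display-level (95%) masks per label."""
    masks90, masks95 = {}, {}
    for i, s in enumerate(panel.series):
        sp = panel_spectra[s.label]
        ens = markov_surrogates(s, N_SURROGATES, seed=1000 + i)
        pw = surrogate_power(ens, sp.params)
        masks90[s.label] = significance_mask(sp, ens, 0.90, pw)
        masks95[s.label] = significance_mask(sp, ens, 0.95, pw)
    return masks90, masks95


@pytest.fixture(scope="session")
def panel_trees(panel, panel_series_set, panel_spectra, panel_masks):
    """Wavelet and Spearman Ward trees of the demonstration panel."""
    masks90, _ = panel_masks
    labels = panel.labels
    dist_w = wavelet_distance_matrix([panel_spectra[l] for l in labels],
                                     [masks90[l] for l in labels])
    tree_w = ward_cluster(dist_w)
    tree_s = ward_cluster(correlation_dissimilarity(panel_series_set, "spearman"))
    return {"wavelet_dist": dist_w, "wavelet": tree_w, "spearman": tree_s}
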