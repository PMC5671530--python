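"""ROI principal-stress statistics: histograms and modal values.

The macro model hands each tissue layer to the capillary sub-models through a
single pair of boundary stresses: the most frequent (modal) maximum and
minimum principal stress in the layer. Frequencies are per element by default
(each element contributes one sample); an area-weighted option exists because
the source material is silent on weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StressHistogram", "collect_roi_stresses", "modal_stress", "roi_modal_pairs"]


@dataclass
class StressHistogram:
    """Histogram of one principal-stress sample with its modal bin centre."""

    bin_edges: np.ndarray
    counts: np.ndarray
    mode: float
    n_samples: int

    def __post_init__(self) -> None:
        if np.issubdtype(np.asarray(self.counts).dtype, np.integer):
            assert int(self.counts.sum()) == self.n_samples


def collect_roi_stresses(macro_result, roi_ids, weighted: bool = False):
    """Per-element (sigma_max, sigma_min) samples over a ROI element set.

    Returns ``(smax, smin)`` or ``(smax, smin, weights)`` when area-weighted
    (weights are revolved element volumes).
    """
    roi_ids = np.asarray(roi_ids, dtype=int)
    if roi_ids.size == 0:
        raise ValueError("empty ROI")
    s_max, _, s_min = macro_result.principal()
    if not weighted:
        return s_max[roi_ids], s_min[roi_ids]
    cent = macro_result.mesh.element_centroids()[roi_ids]
    areas = macro_result.mesh.element_areas()[roi_ids]
    w = 2.0 * np.pi * cent[:, 0] * areas
    return s_max[roi_ids], s_min[roi_ids], w


def modal_stress(samples, bin_rule="fd", weights=None, return_histogram=False):
    """Centre of the most populated histogram bin of a stress sample (MPa).

    ``bin_rule`` is 'fd' (Freedman-Diaconis width, falling back to 20 uniform
    bins for degenerate samples) or an integer bin count. The bin grid is
    anchored so that one bin is *centred* on zero stress: stress samples in
    lightly loaded tissue peak at the unloaded state, and without anchoring
    the sign of the modal value flips with arbitrary bin placement. Ties are
    broken toward the bin of smaller absolute stress. The reported mode is
    clamped into [min(samples), max(samples)].
    """
    s = np.asarray(samples, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("need at least one sample")
    lo, hi = float(s.min()), float(s.max())
    if hi - lo < 1.0e-300 or (hi - lo) < 1.0e-12 * max(abs(hi), abs(lo), 1e-30):
        mode = float(s[0]) if s.size == 1 else float(np.median(s))
        edges = np.array([lo - 0.5, hi + 0.5]) if hi == lo else np.array([lo, hi])
        counts = np.array([s.size])
        hist = StressHistogram(edges, counts, mode, s.size)
        return (mode, hist) if return_histogram else mode

    if bin_rule == "fd":
        iqr = float(np.subtract(*np.percentile(s, [75, 25])))
        w = 2.0 * iqr / s.size ** (1.0 / 3.0)
        if not w > 0:
            w = (hi - lo) / 20.0
    else:
        w = (hi - lo) / int(bin_rule)
    # zero-centred grid: edges at (k + 1/2) * w
    kmin = int(np.floor(lo / w - 0.5))
    kmax = int(np.ceil(hi / w - 0.5))
    edges = (np.arange(kmin, kmax + 2) + 0.5) * w
    counts, edges = np.histogram(s, bins=edges, weights=weights)
    centres = 0.5 * (edges[:-1] + edges[1:])
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    mode = float(centres[tied[np.argmin(np.abs(centres[tied]))]])
    mode = float(min(max(mode, lo), hi))
    hist = StressHistogram(edges, counts, mode, s.size)
    return (mode, hist) if return_histogram else mode


def roi_modal_pairs(macro_result, roi_map, bin_rule="fd", weighted=False):
    """Modal (sigma_max*, sigma_min*) pair and histograms for each ROI layer.

    Returns ``{label: {"sigma_max": ..., "sigma_min": ..., "hist_max": ...,
    "hist_min": ..., "n": ...}}`` ready for the JSON hand-off file.
    """
    out = {}
    for label, ids in roi_map.items():
        if weighted:
            smax, smin, w = collect_roi_stresses(macro_result, ids, weighted=True)
        else:
            smax, smin = collect_roi_stresses(macro_result, ids)
            w = None
        m1, h1 = modal_stress(smax, bin_rule, weights=w, return_histogram=True)
        m2, h2 = modal_stress(smin, bin_rule, weights=w, return_histogram=True)
        out[label] = {
            "sigma_max": m1,
            "sigma_min": m2,
            "hist_max": h1,
            "hist_min": h2,
            "n": int(np.size(ids)),
        }
    return out
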