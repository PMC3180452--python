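"""Per-nucleus geometric feature extraction.

Eleven geometric features are computed per nucleus per frame.  Only two of
them — area ``A`` (pixel count) and average intensity ``I`` (mean grey
level over the object mask) — feed the transition detector; the other
nine standard region descriptors are carried for compatibility and for
the shape terms of the tracker.  Restricting extraction to this geometric
set is what makes the time-series route fast compared to classifier
pipelines that need texture/wavelet/moment features for every nucleus.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.measure import regionprops_table

from .segmentation import LabelMask

__all__ = ["GEOMETRIC_FEATURES", "extract_geometric_features",
           "extract_full_features", "intensity_histograms"]

GEOMETRIC_FEATURES = [
    "area", "mean_intensity", "perimeter", "eccentricity", "solidity",
    "extent", "major_axis_length", "minor_axis_length", "orientation",
    "equivalent_diameter", "circularity",
]

_SKIMAGE_PROPS = [
    "label", "area", "intensity_mean", "perimeter", "eccentricity",
    "solidity", "extent", "axis_major_length", "axis_minor_length",
    "orientation", "equivalent_diameter_area", "centroid",
]

_RENAME = {
    "intensity_mean": "mean_intensity",
    "axis_major_length": "major_axis_length",
    "axis_minor_length": "minor_axis_length",
    "equivalent_diameter_area": "equivalent_diameter",
    "centroid-0": "y",
    "centroid-1": "x",
}


def extract_geometric_features(mask: LabelMask | np.ndarray,
                               frame: np.ndarray,
                               intensity_erosion: int = 1) -> pd.DataFrame:
    """The 11 geometric features (plus label and centroid) per object.

    ``area`` is the exact pixel count over the full object mask.
    ``mean_intensity`` is the mean grey level over the mask eroded by
    ``intensity_erosion`` pixels: boundary pixels straddle the object edge
    and only partially sample the nucleus, so excluding them keeps the
    average intensity representative of the chromatin signal (the erosion
    falls back to the full mask for objects too small to erode).  Raises
    on an empty labeling.
    """
    from scipy import ndimage as ndi

    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    if labels.max() == 0:
        raise ValueError("no labeled objects in frame")
    frame = np.asarray(frame, float)
    tbl = regionprops_table(labels, intensity_image=frame,
                            properties=_SKIMAGE_PROPS)
    df = pd.DataFrame(tbl).rename(columns=_RENAME)
    df["circularity"] = 4 * np.pi * df["area"] / np.maximum(df["perimeter"], 1e-9) ** 2
    if intensity_erosion > 0:
        slices = ndi.find_objects(labels)
        means = []
        for v in df["label"].astype(int):
            sl = slices[v - 1]
            sel = labels[sl] == v
            core = ndi.binary_erosion(sel, iterations=intensity_erosion)
            patch = frame[sl]
            means.append(float(patch[core].mean()) if core.sum() >= 4
                         else float(patch[sel].mean()))
        df["mean_intensity"] = means
    return df


def intensity_histograms(labels: np.ndarray, frame: np.ndarray,
                         bins: int = 16, vmax: float | None = None
                         ) -> dict[int, np.ndarray]:
    """Normalized grey-value histogram per object (tracking feature)."""
    frame = np.asarray(frame, float)
    if vmax is None:
        vmax = max(float(frame.max()), 1.0)
    out: dict[int, np.ndarray] = {}
    for v in np.unique(labels):
        if v == 0:
            continue
        h, _ = np.histogram(frame[labels == v], bins=bins, range=(0, vmax))
        s = h.sum()
        out[int(v)] = h / s if s else h.astype(float)
    return out


def extract_full_features(mask: LabelMask | np.ndarray,
                          frame: np.ndarray) -> pd.DataFrame:
    """Wide feature panel (geometry + moments + texture + wavelets).

    Emulates the classifier-oriented extraction route (~211 features per
    nucleus: Hu and central moments, grey-level co-occurrence texture at
    four orientations, and two-level wavelet energy statistics on the
    object patch).  Provided for benchmarking; the time-series analysis
    never needs it.
    """
    import pywt
    from skimage.feature import graycomatrix, graycoprops
    from skimage.measure import moments_central, moments_hu

    labels = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    base = extract_geometric_features(labels, frame)
    frame = np.asarray(frame, float)
    rows = []
    for v in base["label"].astype(int):
        m = labels == v
        ys, xs = np.nonzero(m)
        patch = frame[ys.min():ys.max() + 1, xs.min():xs.max() + 1].copy()
        pmask = m[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
        patch[~pmask] = 0
        rec: dict[str, float] = {"label": v}
        # moments (central up to order 3 + 7 Hu), raw and intensity-weighted
        for tag, img in (("bin", pmask.astype(float)), ("int", patch)):
            mc = moments_central(img, order=3)
            for i in range(4):
                for j in range(4):
                    rec[f"mu_{tag}_{i}{j}"] = mc[i, j]
            for i, hu in enumerate(moments_hu(mc)):
                rec[f"hu_{tag}_{i}"] = hu
        # co-occurrence texture
        q = np.clip((patch / max(patch.max(), 1) * 31), 0, 31).astype(np.uint8)
        glcm = graycomatrix(q, distances=[1, 2],
                            angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                            levels=32, symmetric=True, normed=True)
        for prop in ("contrast", "dissimilarity", "homogeneity", "energy",
                     "correlation", "ASM"):
            for i, val in enumerate(graycoprops(glcm, prop).ravel()):
                rec[f"glcm_{prop}_{i}"] = float(val)
        # wavelet energies
        coeffs = pywt.wavedec2(patch, "db2", level=2)
        flat = [coeffs[0]] + [c for lvl in coeffs[1:] for c in lvl]
        for i, c in enumerate(flat):
            rec[f"wav_energy_{i}"] = float(np.mean(c ** 2))
            rec[f"wav_mean_{i}"] = float(np.mean(np.abs(c)))
            rec[f"wav_std_{i}"] = float(np.std(c))
        rows.append(rec)
    extra = pd.DataFrame(rows)
    return base.merge(extra, on="label")
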