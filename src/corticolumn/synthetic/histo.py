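"""Synthetic immunofluorescence field generator.

Produces a single-channel WFA-like intensity image with an additive
background gradient and Gaussian noise, PV centroids from a Poisson process
with layer-specific intensities, and optional perineuronal-net rings:
annular intensity at 5-15 um from PV centroids (``pv_centered``), or at
random deep-layer sites away from PV cells (``deep_layer_random``).  The
pial surface is the top edge of the field; depth increases downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import GeneratorConfig, SyntheticTruth

__all__ = ["HistoField", "generate_histo"]

RING_R_IN_UM = 5.0
RING_R_OUT_UM = 15.0
RING_INTENSITY = 0.6
BACKGROUND_SLOPE = 0.15  # intensity ramp amplitude across the field depth
NOISE_SD = 0.02
# relative PV intensity per layer band (fraction of depth); layers 4/5 richest
LAYER_BANDS = {
    "L2/3": (0.00, 0.30, 0.8),
    "L4": (0.30, 0.45, 1.4),
    "L5": (0.45, 0.70, 1.3),
    "L6": (0.70, 1.00, 0.7),
}
DEEP_RING_MIN_FRAC = 0.45  # deep-layer rings live below this depth fraction
PV_EXCLUSION_UM = 20.0


@dataclass
class HistoField:
    """A fluorescence field with geometry annotations.

    ``image`` is a 2-D nonnegative array indexed [row, col] with pixel size
    ``px_size_um``; ``pial_polyline`` is ordered along the pial surface in
    um; ``layer_polygons`` maps layer name to an (n, 2) polygon in um;
    ``pv_centroids`` are (x, y) points in um with y = depth from the pia.
    """

    image: np.ndarray
    px_size_um: float
    pial_polyline: np.ndarray
    cortical_mask: np.ndarray
    layer_polygons: dict[str, np.ndarray] = field(default_factory=dict)
    pv_centroids: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


def _paint_rings(
    img: np.ndarray, centers_um: np.ndarray, px: float, amplitude: float
) -> None:
    h, w = img.shape
    r_out_px = RING_R_OUT_UM / px
    for cx, cy in centers_um:
        c0, r0 = cx / px, cy / px
        rmin = max(int(r0 - r_out_px) - 1, 0)
        rmax = min(int(r0 + r_out_px) + 2, h)
        cmin = max(int(c0 - r_out_px) - 1, 0)
        cmax = min(int(c0 + r_out_px) + 2, w)
        rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
        d_um = np.hypot((cc - c0) * px, (rr - r0) * px)
        ring = (d_um >= RING_R_IN_UM) & (d_um <= RING_R_OUT_UM)
        img[rmin:rmax, cmin:cmax][ring] += amplitude


def generate_histo(
    config: GeneratorConfig, *, add_noise: bool = True
) -> tuple[HistoField, SyntheticTruth]:
    """Generate a synthetic PV/WFA field with ground truth.

    PV centroid counts follow a Poisson process with expected total
    ``pv_density_per_mm2 x mask area (mm^2)``, modulated across layers; rings
    follow ``config.pnn_mode``.  With ``add_noise=False`` and
    ``pnn_mode='none'`` the image equals the deterministic background field.
    """
    px = config.histo_px_size_um
    width_mm, height_mm = config.histo_field_mm
    w = int(round(width_mm * 1000 / px))
    h = int(round(height_mm * 1000 / px))
    if min(w, h) * px < 2 * RING_R_OUT_UM:
        raise ValueError("field smaller than one ring structuring element")
    rng = np.random.default_rng(config.seed + 104729)

    depth_frac = (np.arange(h) + 0.5)[:, None] / h
    img = 0.1 + BACKGROUND_SLOPE * depth_frac * np.ones((h, w))

    mask = np.ones((h, w), dtype=bool)
    area_mm2 = mask.sum() * (px / 1000.0) ** 2

    # layer-modulated Poisson PV centroids
    weights = np.array([v[2] * (v[1] - v[0]) for v in LAYER_BANDS.values()])
    weights /= weights.sum()
    n_pv = rng.poisson(config.pv_density_per_mm2 * area_mm2)
    bands = rng.choice(len(LAYER_BANDS), size=n_pv, p=weights)
    spans = np.array([(v[0], v[1]) for v in LAYER_BANDS.values()])
    y_frac = rng.uniform(spans[bands, 0], spans[bands, 1])
    pv = np.column_stack(
        [rng.uniform(0, w * px, size=n_pv), y_frac * h * px]
    )

    if config.pnn_mode == "pv_centered":
        _paint_rings(img, pv, px, RING_INTENSITY)
    elif config.pnn_mode == "deep_layer_random":
        n_rings = n_pv  # same ring load, displaced from PV cells
        sites = np.empty((0, 2))
        guard = 0
        while sites.shape[0] < n_rings and guard < 50:
            cand = np.column_stack(
                [
                    rng.uniform(0, w * px, size=n_rings),
                    rng.uniform(DEEP_RING_MIN_FRAC * h * px, h * px, size=n_rings),
                ]
            )
            if n_pv:
                d = np.min(
                    np.linalg.norm(cand[:, None, :] - pv[None, :, :], axis=2), axis=1
                )
                cand = cand[d > PV_EXCLUSION_UM]
            sites = np.vstack([sites, cand])
            guard += 1
        _paint_rings(img, sites[:n_rings], px, RING_INTENSITY)

    if add_noise and NOISE_SD > 0:
        img = img + NOISE_SD * rng.standard_normal(img.shape)
    img = np.clip(img, 0.0, None)

    pial = np.column_stack([np.linspace(0, w * px, 50), np.zeros(50)])
    polys = {
        name: np.array(
            [
                [0.0, lo * h * px],
                [w * px, lo * h * px],
                [w * px, hi * h * px],
                [0.0, hi * h * px],
            ]
        )
        for name, (lo, hi, _) in LAYER_BANDS.items()
    }
    fieldobj = HistoField(
        image=img,
        px_size_um=px,
        pial_polyline=pial,
        cortical_mask=mask,
        layer_polygons=polys,
        pv_centroids=pv,
    )
    truth = SyntheticTruth(
        subclass=np.array([]),
        cell_class=np.array([]),
        archetype_weights=np.empty((0, config.it_archetypes)),
        depth_um=pv[:, 1].copy(),
        proportions={},
        density_ratio=None,
        pnn_mode=config.pnn_mode,
    )
    return fieldobj, truth
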