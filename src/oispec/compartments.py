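"""Vessel compartmentalisation of hemodynamic movies by PCA.

The first principal component of the Hbt movie within the activated
region loads on the responding arterial tree (blood-volume changes are
largest in surface arteries), while the first component of the Hbr movie
loads on the draining veins (the stimulus washes deoxyhemoglobin out of
them).  Thresholding the two spatial maps at an upper quantile yields
disjoint artery and vein masks whose mean time courses give the
compartment-specific responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, ValidationError


@dataclass(frozen=True)
class PrincipalMap:
    """First principal component of a (t, y, x) movie within a mask.

    spatial_map has unit norm over the masked pixels (zero elsewhere);
    the sign is fixed so the temporal score covaries positively with the
    stimulus regressor when one is supplied.
    """

    spatial_map: np.ndarray
    temporal_score: np.ndarray
    explained_fraction: float
    sign_fixed_to_stimulus: bool
    mask: np.ndarray

    def __post_init__(self):
        if not (0.0 <= self.explained_fraction <= 1.0 + 1e-12):
            raise ValidationError("explained fraction must lie in [0, 1]")


def first_principal_map(
    movie: np.ndarray,
    mask: np.ndarray,
    stimulus_regressor: np.ndarray | None = None,
) -> PrincipalMap:
    """First singular component of the pixelwise mean-centred movie.

    Only the temporal mean per pixel is removed (no variance scaling),
    so loadings stay in physical response-amplitude units.  PCA sign is
    arbitrary; with a stimulus regressor the component is flipped so the
    temporal score covaries positively with it.
    """
    movie = np.asarray(movie, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if movie.ndim != 3:
        raise ValidationError("movie must be (t, y, x)")
    if movie.shape[0] < 2 or mask.sum() < 2:
        raise ValidationError("need >= 2 frames and >= 2 masked pixels")
    X = movie[:, mask]  # (t, p)
    X = X - X.mean(axis=0, keepdims=True)
    if not np.isfinite(X).all():
        X = np.nan_to_num(X)
    total = float((X ** 2).sum())
    if total == 0.0:
        raise DegenerateDataError("movie has zero variance within the mask")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    score = U[:, 0] * S[0]
    loading = Vt[0]
    sign_fixed = False
    if stimulus_regressor is not None:
        r = np.asarray(stimulus_regressor, dtype=float)
        if r.shape[0] != movie.shape[0]:
            raise ValidationError("stimulus regressor length mismatch")
        cov = float(np.dot(score, r - r.mean()))
        if cov < 0:
            score = -score
            loading = -loading
        sign_fixed = True
    spatial = np.zeros(mask.shape)
    spatial[mask] = loading
    return PrincipalMap(
        spatial_map=spatial,
        temporal_score=score,
        explained_fraction=float(S[0] ** 2 / total),
        sign_fixed_to_stimulus=sign_fixed,
        mask=mask,
    )


def vessel_masks(
    hbt_map: PrincipalMap,
    hbr_map: PrincipalMap,
    roi,
    quantile: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Artery and vein masks from the Hbt and Hbr principal maps.

    Artery: ROI pixels whose Hbt loading exceeds its in-ROI quantile.
    Vein: ROI pixels whose |Hbr| loading exceeds its quantile, minus the
    artery pixels (the two are disjoint by construction).
    """
    roi_pixels = roi.pixels if hasattr(roi, "pixels") else np.asarray(roi, bool)
    if hbt_map.spatial_map.shape != roi_pixels.shape:
        raise ValidationError("principal map grid does not match ROI grid")
    if not (0.0 < quantile < 1.0):
        raise DegenerateDataError(
            f"vessel quantile {quantile} leaves no pixels above threshold"
        )
    hbt_load = hbt_map.spatial_map[roi_pixels]
    hbr_load = np.abs(hbr_map.spatial_map[roi_pixels])
    artery_sel = hbt_load > np.quantile(hbt_load, quantile)
    vein_sel = hbr_load > np.quantile(hbr_load, quantile)
    artery = np.zeros_like(roi_pixels)
    vein = np.zeros_like(roi_pixels)
    artery[roi_pixels] = artery_sel
    vein[roi_pixels] = vein_sel
    vein &= ~artery
    if not artery.any() or not vein.any():
        raise DegenerateDataError(
            f"empty vessel compartment at quantile {quantile} "
            f"(artery {int(artery.sum())} px, vein {int(vein.sum())} px)"
        )
    return artery, vein


def compartment_series(movies, masks: dict) -> dict:
    """Mask-mean fractional Hbt/Hbo/Hbr series per compartment.

    ``masks`` maps compartment name -> boolean pixel mask; returns
    {compartment: {species: series}}.
    """
    out = {}
    for name, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValidationError(f"empty mask for compartment {name!r}")
        out[name] = {
            "Hbt": np.nanmean(movies.fractional_hbt[:, mask], axis=1),
            "Hbo": np.nanmean(movies.fractional_hbo[:, mask], axis=1),
            "Hbr": np.nanmean(movies.fractional_hbr[:, mask], axis=1),
        }
    return out
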