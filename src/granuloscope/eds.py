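"""STEM-EDS count-map analysis: uncalibrated relative composition maps,
line transects, phase-conditioned element statistics and interface
sharpness.

Relative weight fractions are background-subtracted count fractions with
no k-factor or absorption correction — the maps are explicitly
uncalibrated, matching how such data are reported when only relative
contrast between phases is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantoms import EDSMapSet

__all__ = [
    "TransectProfile",
    "relative_wt",
    "transect",
    "phase_element_stats",
    "interface_sharpness",
]


@dataclass
class TransectProfile:
    positions_nm: np.ndarray
    values: dict[str, np.ndarray]
    width_px: int


def _background_rates(mapset: EDSMapSet, background_region: np.ndarray | None) -> dict[str, float]:
    """Flat continuum estimate per element from a declared background region."""
    if background_region is not None:
        bg = np.asarray(background_region).astype(bool)
        if bg.shape != mapset.shape:
            raise ValueError("background_region must be congruent with the maps")
        if not bg.any():
            raise ValueError("background_region is empty")
        return {el: float(mapset.maps[el][bg].mean()) for el in mapset.elements}
    if mapset.background_rate is not None:
        flat = mapset.background_rate * mapset.exposure
        return {el: flat for el in mapset.elements}
    return {el: 0.0 for el in mapset.elements}


def relative_wt(
    mapset: EDSMapSet,
    elements: list[str] | None = None,
    background_region: np.ndarray | None = None,
    smooth_px: int = 0,
) -> dict[str, np.ndarray]:
    """Per-pixel relative fraction of each element's background-subtracted
    counts over the declared element set.

    Pixels whose summed background-subtracted counts are zero are undefined
    (NaN), excluded rather than zero-filled.  Optional box smoothing of
    width ``smooth_px`` is applied to the count maps before the ratio.
    Defined pixels satisfy sum over elements = 1 exactly.
    """
    if elements is None:
        elements = mapset.elements
    if not elements:
        raise ValueError("need at least one element")
    bg = _background_rates(mapset, background_region)
    corrected = {}
    for el in elements:
        m = mapset.maps[el].astype(np.float64)
        if not np.isfinite(m).all():
            raise ValueError(f"non-finite counts in {el!r}")
        if smooth_px > 1:
            m = ndimage.uniform_filter(m, size=smooth_px, mode="reflect")
        corrected[el] = np.clip(m - bg[el], 0.0, None)
    total = sum(corrected.values())
    out = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for el in elements:
            frac = corrected[el] / total
            frac[total == 0] = np.nan
            out[el] = frac
    return out


def transect(
    mapset: EDSMapSet,
    start_point: tuple[float, float],
    end_point: tuple[float, float],
    width_px: int = 5,
    elements: list[str] | None = None,
    values: dict[str, np.ndarray] | None = None,
) -> TransectProfile:
    """Sample maps along a segment, averaging over ``width_px``
    perpendicular to the line (bilinear interpolation); positions in nm.

    ``values`` may supply precomputed maps (e.g. relative fractions) to
    sample instead of raw counts.
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    p0 = np.asarray(start_point, dtype=float)
    p1 = np.asarray(end_point, dtype=float)
    shape = np.asarray(mapset.shape)
    for p in (p0, p1):
        if (p < 0).any() or (p >= shape).any():
            raise ValueError(f"endpoint {tuple(p)} outside map of shape {tuple(shape)}")
    d = p1 - p0
    length_px = float(np.linalg.norm(d))
    if length_px == 0:
        raise ValueError("zero-length transect")
    u = d / length_px
    perp = np.array([-u[1], u[0]])
    n_samples = int(np.ceil(length_px)) + 1
    s = np.linspace(0.0, length_px, n_samples)
    offsets = np.arange(width_px) - (width_px - 1) / 2.0

    rows = p0[0] + s[:, None] * u[0] + offsets[None, :] * perp[0]
    cols = p0[1] + s[:, None] * u[1] + offsets[None, :] * perp[1]
    inside = (rows >= 0) & (rows <= shape[0] - 1) & (cols >= 0) & (cols <= shape[1] - 1)
    if not inside.all():
        import warnings

        warnings.warn("transect averaging band exits the map; clipped to the interior")

    if values is None:
        if elements is None:
            elements = mapset.elements
        values = {el: mapset.maps[el].astype(np.float64) for el in elements}
    profiles = {}
    coords = np.stack([rows.ravel(), cols.ravel()])
    for el, m in values.items():
        samp = ndimage.map_coordinates(
            np.asarray(m, dtype=np.float64), coords, order=1, mode="nearest"
        ).reshape(rows.shape)
        samp = np.where(inside, samp, np.nan)
        with np.errstate(invalid="ignore"):
            profiles[el] = np.nanmean(samp, axis=1)
    return TransectProfile(
        positions_nm=s * mapset.pixel_size_nm, values=profiles, width_px=width_px
    )


def phase_element_stats(
    mapset: EDSMapSet,
    element: str,
    phases: list[str] | None = None,
    ratio_pairs: list[tuple[str, str]] | None = None,
    z: float = 1.96,
) -> pd.DataFrame:
    """Per-phase mean counts with Poisson 95% CIs and pairwise rate ratios.

    The CI uses the normal approximation to the Poisson mean (se =
    sqrt(mean / n)); ratio CIs are delta-method propagated.  Pairwise
    ratios are computed on background-subtracted means (the flat continuum
    contributes equally to both phases and would bias the rate ratio
    toward 1).  A phase is flagged ``background_consistent`` when its raw
    mean lies within 2 standard errors of the declared continuum rate.
    """
    if mapset.labels is None or mapset.phase_names is None:
        raise ValueError("mapset carries no co-registered labels")
    counts = mapset.maps[element].astype(np.float64)
    name_of = dict(mapset.phase_names)
    present = {name_of[int(c)] for c in np.unique(mapset.labels) if int(c) in name_of}
    if phases is None:
        phases = sorted(p for p in present if p != "background")
    stats = {}
    for ph in phases:
        if ph not in present:
            raise ValueError(f"phase {ph!r} absent from labels")
        codes = [c for c, n in name_of.items() if n == ph]
        sel = np.isin(mapset.labels, codes)
        vals = counts[sel]
        n = vals.size
        mean = float(vals.mean())
        se = float(np.sqrt(max(mean, 1e-12) / n))
        bg = (mapset.background_rate or 0.0) * mapset.exposure
        stats[ph] = {
            "phase": ph,
            "element": element,
            "n_pixels": n,
            "mean_counts": mean,
            "mean_bg_subtracted": mean - bg,
            "se": se,
            "ci_low": mean - z * se,
            "ci_high": mean + z * se,
            "background_consistent": bool(abs(mean - bg) <= 2.0 * se),
        }
    rows = list(stats.values())
    if ratio_pairs:
        for a, b in ratio_pairs:
            if a not in stats or b not in stats:
                raise ValueError(f"ratio pair ({a}, {b}) needs both phases computed")
            ma, mb = stats[a]["mean_bg_subtracted"], stats[b]["mean_bg_subtracted"]
            if mb == 0:
                raise ValueError(f"phase {b!r} has zero background-subtracted counts; ratio undefined")
            ratio = ma / mb
            rel_var = (stats[a]["se"] / ma) ** 2 + (stats[b]["se"] / mb) ** 2 if ma > 0 else np.inf
            se_r = ratio * np.sqrt(rel_var)
            rows.append(
                {
                    "phase": f"{a}/{b}",
                    "element": element,
                    "n_pixels": stats[a]["n_pixels"] + stats[b]["n_pixels"],
                    "mean_counts": ratio,
                    "mean_bg_subtracted": ratio,
                    "se": se_r,
                    "ci_low": ratio - z * se_r,
                    "ci_high": ratio + z * se_r,
                    "background_consistent": False,
                }
            )
    return pd.DataFrame(rows)


def interface_sharpness(
    mapset: EDSMapSet,
    element: str,
    phase_a: str,
    phase_b: str,
    max_distance_px: float = 15.0,
    bin_px: float = 1.0,
) -> float:
    """Transition width (nm) of an element profile across a phase boundary.

    Pixel values are binned by signed Euclidean distance to the a/b
    boundary (averaging all profiles perpendicular to it); the width is the
    distance between the empirical 25% and 75% crossings of the monotone
    interpolation between the two plateau levels — no parametric fit.
    """
    if mapset.labels is None or mapset.phase_names is None:
        raise ValueError("mapset carries no co-registered labels")
    name_of = dict(mapset.phase_names)
    a_mask = np.isin(mapset.labels, [c for c, n in name_of.items() if n == phase_a])
    b_mask = np.isin(mapset.labels, [c for c, n in name_of.items() if n == phase_b])
    if not a_mask.any() or not b_mask.any():
        raise ValueError("both phases must be present in the labels")
    boundary = a_mask & ndimage.binary_dilation(b_mask)
    n_boundary = int(boundary.sum())
    if n_boundary < 10:
        raise ValueError(f"boundary of {n_boundary} px is too short (< 10 px)")

    # signed distance: positive into phase a, negative into phase b
    dist_to_b = ndimage.distance_transform_edt(~b_mask)
    dist_to_a = ndimage.distance_transform_edt(~a_mask)
    signed = np.where(a_mask, dist_to_b, -dist_to_a)
    region = a_mask | b_mask
    sel = region & (np.abs(signed) <= max_distance_px)
    d = signed[sel]
    v = mapset.maps[element].astype(np.float64)[sel]

    edges = np.arange(-max_distance_px, max_distance_px + bin_px, bin_px)
    idx = np.digitize(d, edges) - 1
    nb = len(edges) - 1
    ok = (idx >= 0) & (idx < nb)
    sums = np.bincount(idx[ok], weights=v[ok], minlength=nb)
    cnts = np.bincount(idx[ok], minlength=nb)
    good = cnts > 0
    centres = (0.5 * (edges[:-1] + edges[1:]))[good]
    prof = sums[good] / cnts[good]

    # plateau levels from the far thirds of the profile
    k = max(len(prof) // 3, 1)
    lo_level = prof[:k].mean()
    hi_level = prof[-k:].mean()
    if lo_level == hi_level:
        raise ValueError("no contrast across the boundary")
    norm = (prof - lo_level) / (hi_level - lo_level)
    # enforce monotone interpolation by a running envelope
    mono = np.maximum.accumulate(np.clip(norm, 0.0, 1.0))

    def crossing(level: float) -> float:
        above = np.nonzero(mono >= level)[0]
        if above.size == 0:
            return centres[-1]
        i = above[0]
        if i == 0:
            return centres[0]
        x0, x1 = centres[i - 1], centres[i]
        y0, y1 = mono[i - 1], mono[i]
        if y1 == y0:
            return x1
        return x0 + (level - y0) * (x1 - x0) / (y1 - y0)

    width_px = abs(crossing(0.75) - crossing(0.25))
    return float(width_px * mapset.pixel_size_nm)
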