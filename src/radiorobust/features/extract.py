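"""Full 851-feature extraction for one (volume, mask) under one or many configs.

Pipeline order per config: resample to isotropic resolution → wavelet
decomposition of the resampled volume → per-image fixed-bin-width
discretization (re-anchored per sub-band) → features.  Shape features are
computed once per resolution from the resampled mask geometry alone, so they
are bit-identical across bin-width, pixel-distance and interpolator settings.
"""

from __future__ import annotations

from ..images import Mask, Volume
from ..preprocessing import (
    IMAGE_FILTERS,
    ExtractionConfig,
    discretize,
    resample,
    wavelet_decompose,
)
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

FAMILY_COUNTS = {
    "shape": 14,
    "firstorder": 18,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "ngtdm": 5,
    "gldm": 14,
}
N_FEATURES_ORIGINAL = sum(FAMILY_COUNTS.values())  # 107
N_FEATURES_PER_SUBBAND = N_FEATURES_ORIGINAL - FAMILY_COUNTS["shape"]  # 93
N_FEATURES_TOTAL = N_FEATURES_ORIGINAL + 8 * N_FEATURES_PER_SUBBAND  # 851

_INTENSITY_FAMILIES = ("firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm")
_FAMILY_NAMES = {
    "shape": SHAPE_NAMES,
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
    "gldm": GLDM_NAMES,
}


def feature_names() -> list[str]:
    """The stable ordered list of all 851 ``<filter>_<family>_<name>`` keys."""
    names = [f"original_shape_{n}" for n in SHAPE_NAMES]
    for filt in IMAGE_FILTERS:
        for fam in _INTENSITY_FAMILIES:
            names.extend(f"{filt}_{fam}_{n}" for n in _FAMILY_NAMES[fam])
    return names


def _intensity_block(
    image: Volume, mask: Mask, filt: str, config: ExtractionConfig
) -> dict[str, float]:
    out: dict[str, float] = {}
    for name, v in first_order_features(image, mask, config.bin_width).items():
        out[f"{filt}_firstorder_{name}"] = v
    disc = discretize(image, mask, config.bin_width)
    d = config.pixel_distance
    for fam, vals in (
        ("glcm", glcm_features(disc, d)),
        ("glrlm", glrlm_features(disc)),
        ("glszm", glszm_features(disc)),
        ("ngtdm", ngtdm_features(disc, d)),
        ("gldm", gldm_features(disc, d)),
    ):
        for name, v in vals.items():
            out[f"{filt}_{fam}_{name}"] = v
    return out


def extract_all(
    volume: Volume, mask: Mask, config: ExtractionConfig
) -> dict[str, float]:
    """Extract the full 851-feature vector for one configuration."""
    rvol, rmask = resample(volume, mask, config.resolution_mm, config.interpolator)
    out = {f"original_shape_{n}": v for n, v in shape_features(rmask).items()}
    images = {"original": rvol}
    images.update(
        {f"wavelet-{b}": v for b, v in wavelet_decompose(rvol).items()}
    )
    for filt, img in images.items():
        out.update(_intensity_block(img, rmask, filt, config))
    assert len(out) == N_FEATURES_TOTAL
    return out


def extract_grid(
    volume: Volume, mask: Mask, configs: list[ExtractionConfig]
) -> dict[str, dict[str, float]]:
    """Extract over many configs, re-using shared intermediate results.

    Resampling + wavelet decomposition are cached per (resolution,
    interpolator); shape per resolution; each per-image intensity block per
    (resolution, interpolator, bin-width, distance) — with the distance-free
    families (GLRLM, GLSZM) and first-order additionally shared across
    distances.  Values are identical to calling :func:`extract_all` per
    config.
    """
    resampled: dict[tuple, tuple] = {}
    shape_cache: dict[float, dict[str, float]] = {}
    fo_cache: dict[tuple, dict[str, float]] = {}
    disc_cache: dict[tuple, object] = {}
    dirfree_cache: dict[tuple, dict[str, float]] = {}
    dist_cache: dict[tuple, dict[str, float]] = {}

    results: dict[str, dict[str, float]] = {}
    for cfg in configs:
        rkey = (cfg.resolution_mm, cfg.interpolator)
        if rkey not in resampled:
            rvol, rmask = resample(volume, mask, cfg.resolution_mm, cfg.interpolator)
            images = {"original": rvol}
            images.update({f"wavelet-{b}": v for b, v in wavelet_decompose(rvol).items()})
            resampled[rkey] = (images, rmask)
        images, rmask = resampled[rkey]

        if cfg.resolution_mm not in shape_cache:
            shape_cache[cfg.resolution_mm] = shape_features(rmask)
        out = {
            f"original_shape_{n}": v
            for n, v in shape_cache[cfg.resolution_mm].items()
        }

        for filt, img in images.items():
            fkey = rkey + (cfg.bin_width, filt)
            if fkey not in fo_cache:
                fo_cache[fkey] = first_order_features(img, rmask, cfg.bin_width)
                disc_cache[fkey] = discretize(img, rmask, cfg.bin_width)
            for name, v in fo_cache[fkey].items():
                out[f"{filt}_firstorder_{name}"] = v
            disc = disc_cache[fkey]
            if fkey not in dirfree_cache:
                dirfree_cache[fkey] = {
                    **{f"glrlm_{n}": v for n, v in glrlm_features(disc).items()},
                    **{f"glszm_{n}": v for n, v in glszm_features(disc).items()},
                }
            for name, v in dirfree_cache[fkey].items():
                out[f"{filt}_{name}"] = v
            dkey = fkey + (cfg.pixel_distance,)
            if dkey not in dist_cache:
                d = cfg.pixel_distance
                dist_cache[dkey] = {
                    **{f"glcm_{n}": v for n, v in glcm_features(disc, d).items()},
                    **{f"ngtdm_{n}": v for n, v in ngtdm_features(disc, d).items()},
                    **{f"gldm_{n}": v for n, v in gldm_features(disc, d).items()},
                }
            for name, v in dist_cache[dkey].items():
                out[f"{filt}_{name}"] = v

        # restore canonical ordering
        results[cfg.config_id] = {k: out[k] for k in feature_names()}
    return results
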