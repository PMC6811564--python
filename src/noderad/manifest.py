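"""The 285-name radiomic feature manifest.

The panel comprises 18 shape, 17 first-order intensity and 72 texture
features, with the 89 intensity+texture features recomputed on the all-low-
pass (LLL) and all-high-pass (HHH) wavelet subbands for a further 178
(total 285).  Texture features follow the IBSI reference definitions across
five matrix families: grey-level co-occurrence (GLCM, 25), run length
(GLRLM, 16), size zone (GLSZM, 16), neighbourhood grey-tone difference
(NGTDM, 5) and neighbouring grey-level dependence (NGLDM, 10).

Grey levels are produced by fixed-bin-size discretisation (default 5 HU,
anchored at the lower HU window bound) for the original image, and by
fixed-bin-count discretisation (40 bins over the in-ROI range) for wavelet
subbands, whose value scale is not anchored to HU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

SHAPE_NAMES = (
    "shape_mesh_volume",
    "shape_voxel_volume",
    "shape_surface_area",
    "shape_surface_to_volume",
    "shape_sphericity",
    "shape_spherical_disproportion",
    "shape_compactness1",
    "shape_compactness2",
    "shape_asphericity",
    "shape_max_diameter_3d",
    "shape_major_axis",
    "shape_minor_axis",
    "shape_least_axis",
    "shape_elongation",
    "shape_flatness",
    "shape_com_shift",
    "shape_thickness_mean",
    "shape_thickness_sd",
)

INTENSITY_NAMES = (
    "intensity_mean",
    "intensity_variance",
    "intensity_sd",
    "intensity_skewness",
    "intensity_kurtosis",
    "intensity_median",
    "intensity_min",
    "intensity_max",
    "intensity_range",
    "intensity_p10",
    "intensity_p90",
    "intensity_iqr",
    "intensity_mad",
    "intensity_robust_mad",
    "intensity_energy",
    "intensity_rms",
    "intensity_histogram_entropy",
)

GLCM_NAMES = (
    "glcm_joint_max",
    "glcm_joint_average",
    "glcm_joint_variance",
    "glcm_entropy",
    "glcm_sum_average",
    "glcm_sum_variance",
    "glcm_sum_entropy",
    "glcm_difference_average",
    "glcm_difference_variance",
    "glcm_difference_entropy",
    "glcm_asm",
    "glcm_contrast",
    "glcm_dissimilarity",
    "glcm_inverse_difference",
    "glcm_inverse_difference_norm",
    "glcm_inverse_difference_moment",
    "glcm_inverse_difference_moment_norm",
    "glcm_inverse_variance",
    "glcm_correlation",
    "glcm_autocorrelation",
    "glcm_cluster_tendency",
    "glcm_cluster_shade",
    "glcm_cluster_prominence",
    "glcm_imc1",
    "glcm_imc2",
)

GLRLM_NAMES = (
    "glrlm_sre",
    "glrlm_lre",
    "glrlm_lgre",
    "glrlm_hgre",
    "glrlm_srlge",
    "glrlm_srhge",
    "glrlm_lrlge",
    "glrlm_lrhge",
    "glrlm_glnu",
    "glrlm_glnu_norm",
    "glrlm_rlnu",
    "glrlm_rlnu_norm",
    "glrlm_run_percentage",
    "glrlm_gl_variance",
    "glrlm_rl_variance",
    "glrlm_run_entropy",
)

GLSZM_NAMES = (
    "glszm_sze",
    "glszm_lze",
    "glszm_lgze",
    "glszm_hgze",
    "glszm_szlge",
    "glszm_szhge",
    "glszm_lzlge",
    "glszm_lzhge",
    "glszm_glnu",
    "glszm_glnu_norm",
    "glszm_zsnu",
    "glszm_zsnu_norm",
    "glszm_zone_percentage",
    "glszm_gl_variance",
    "glszm_zs_variance",
    "glszm_zone_entropy",
)

NGTDM_NAMES = (
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "ngtdm_strength",
)

NGLDM_NAMES = (
    "ngldm_lde",
    "ngldm_hde",
    "ngldm_lgce",
    "ngldm_hgce",
    "ngldm_glnu",
    "ngldm_dcnu",
    "ngldm_gl_variance",
    "ngldm_dc_variance",
    "ngldm_dc_entropy",
    "ngldm_dc_energy",
)

TEXTURE_NAMES = GLCM_NAMES + GLRLM_NAMES + GLSZM_NAMES + NGTDM_NAMES + NGLDM_NAMES


@dataclass(frozen=True)
class FeatureManifest:
    """Names and discretisation policy of the extracted panel."""

    shape_names: tuple[str, ...] = SHAPE_NAMES
    intensity_names: tuple[str, ...] = INTENSITY_NAMES
    texture_names: tuple[str, ...] = TEXTURE_NAMES
    wavelet_subbands: tuple[str, ...] = ("lll", "hhh")
    bin_width: float = 5.0       # HU, fixed-bin-size for the original image
    subband_bins: int = 40       # fixed-bin-count for wavelet subbands
    wavelet: str = "haar"

    def __post_init__(self):
        if len(self.shape_names) != 18:
            raise ValueError("manifest must list 18 shape features")
        if len(self.intensity_names) != 17:
            raise ValueError("manifest must list 17 intensity features")
        if len(self.texture_names) != 72:
            raise ValueError("manifest must list 72 texture features")

    @property
    def wavelet_names(self) -> tuple[str, ...]:
        base = self.intensity_names + self.texture_names
        return tuple(f"{n}_{sb}" for sb in self.wavelet_subbands for n in base)

    @property
    def all_names(self) -> tuple[str, ...]:
        return (
            self.shape_names
            + self.intensity_names
            + self.texture_names
            + self.wavelet_names
        )

    @property
    def n_features(self) -> int:
        return len(self.all_names)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "shape_names": list(self.shape_names),
                    "intensity_names": list(self.intensity_names),
                    "texture_names": list(self.texture_names),
                    "wavelet_subbands": list(self.wavelet_subbands),
                    "bin_width": self.bin_width,
                    "subband_bins": self.subband_bins,
                    "wavelet": self.wavelet,
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "FeatureManifest":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            shape_names=tuple(d["shape_names"]),
            intensity_names=tuple(d["intensity_names"]),
            texture_names=tuple(d["texture_names"]),
            wavelet_subbands=tuple(d.get("wavelet_subbands", ("lll", "hhh"))),
            bin_width=float(d.get("bin_width", 5.0)),
            subband_bins=int(d.get("subband_bins", 40)),
            wavelet=d.get("wavelet", "haar"),
        )


DEFAULT_MANIFEST = FeatureManifest()
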