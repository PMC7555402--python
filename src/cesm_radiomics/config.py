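"""Configuration objects for cohort synthesis, feature extraction and the pipeline.

Every knob that alters a numerical result lives in one of the dataclasses
below so that a run can be serialized next to its outputs and replayed
exactly.  Defaults emulate a ~68-lesion contrast-enhanced spectral
mammography (CESM) cohort: continuous receptor percentages (ER, PR, Ki67),
a binary HER2 status and a three-level histological grade, with class
proportions typical of a malignant screening population.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "PercentMixture",
    "LabelModel",
    "ImageTexture",
    "CohortConfig",
    "FeatureConfig",
    "PipelineConfig",
    "config_to_dict",
]


@dataclass(frozen=True)
class PercentMixture:
    """Marginal distribution of a receptor percentage on [0, 100].

    A two-component mixture split at the clinical positivity ``cutoff``:
    with probability ``p_high`` the value is drawn from a scaled
    Beta(``high_a``, ``high_b``) on [cutoff, 100], otherwise from a scaled
    Beta(``low_a``, ``low_b``) on [0, cutoff).  This makes the fraction of
    lesions at or above the cutoff exactly ``p_high`` by construction.
    """

    p_high: float
    cutoff: float
    low_a: float = 1.0
    low_b: float = 1.0
    high_a: float = 1.0
    high_b: float = 1.0

    def validate(self) -> None:
        if not 0.0 <= self.p_high <= 1.0:
            raise ValueError(f"p_high must be in [0,1], got {self.p_high}")
        if not 0.0 < self.cutoff < 100.0:
            raise ValueError(f"cutoff must be in (0,100), got {self.cutoff}")
        for name in ("low_a", "low_b", "high_a", "high_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # Closed-form moments of the mixture, used to standardize label values
    # when planting feature-label effects.

    @staticmethod
    def _beta_m1(a: float, b: float) -> float:
        return a / (a + b)

    @staticmethod
    def _beta_m2(a: float, b: float) -> float:
        return a * (a + 1.0) / ((a + b) * (a + b + 1.0))

    def _component_moments(self, lo: float, hi: float, a: float, b: float):
        w = hi - lo
        m1 = lo + w * self._beta_m1(a, b)
        m2 = lo * lo + 2.0 * lo * w * self._beta_m1(a, b) + w * w * self._beta_m2(a, b)
        return m1, m2

    def mean(self) -> float:
        m1l, _ = self._component_moments(0.0, self.cutoff, self.low_a, self.low_b)
        m1h, _ = self._component_moments(self.cutoff, 100.0, self.high_a, self.high_b)
        return (1.0 - self.p_high) * m1l + self.p_high * m1h

    def var(self) -> float:
        _, m2l = self._component_moments(0.0, self.cutoff, self.low_a, self.low_b)
        _, m2h = self._component_moments(self.cutoff, 100.0, self.high_a, self.high_b)
        m2 = (1.0 - self.p_high) * m2l + self.p_high * m2h
        return m2 - self.mean() ** 2

    def sample(self, rng, high: bool | None = None) -> float:
        """Draw one value; ``high`` forces the component (used for coupling)."""
        if high is None:
            high = rng.random() < self.p_high
        if high:
            return self.cutoff + (100.0 - self.cutoff) * rng.beta(self.high_a, self.high_b)
        return self.cutoff * rng.beta(self.low_a, self.low_b)


def _default_er() -> PercentMixture:
    # 58/68 positive at the 1% cutoff; positives skew high (many strongly ER+)
    return PercentMixture(p_high=58 / 68, cutoff=1.0, low_a=1.0, low_b=1.0,
                          high_a=5.0, high_b=1.5)


def _default_pr() -> PercentMixture:
    # 33/68 positive at the 20% cutoff
    return PercentMixture(p_high=33 / 68, cutoff=20.0, low_a=1.0, low_b=2.0,
                          high_a=2.0, high_b=1.2)


def _default_ki67() -> PercentMixture:
    # 47/68 positive at the 20% cutoff
    return PercentMixture(p_high=47 / 68, cutoff=20.0, low_a=2.0, low_b=2.0,
                          high_a=1.3, high_b=2.5)


@dataclass(frozen=True)
class LabelModel:
    """Joint distribution of the histology labels for one synthetic lesion.

    Marginals follow the configured mixtures; ER and PR are coupled through
    ``pr_p_high_given_er_neg`` (hormone receptors co-occur clinically: an
    ER-negative lesion is rarely PR-positive).  The conditional probability
    of PR-positivity given ER-positive is solved so that the PR marginal is
    preserved, hence the standardization moments of PR stay closed-form.
    HER2 and grade are independent of the receptors.
    """

    er: PercentMixture = field(default_factory=_default_er)
    pr: PercentMixture = field(default_factory=_default_pr)
    ki67: PercentMixture = field(default_factory=_default_ki67)
    her2_p: float = 16 / 68
    grade_probs: tuple[float, float, float] = (14 / 68, 28 / 68, 26 / 68)
    pr_p_high_given_er_neg: float = 0.10

    def validate(self) -> None:
        self.er.validate()
        self.pr.validate()
        self.ki67.validate()
        if not 0.0 < self.her2_p < 1.0:
            raise ValueError(f"her2_p must be in (0,1), got {self.her2_p}")
        if len(self.grade_probs) != 3 or any(p < 0 for p in self.grade_probs):
            raise ValueError("grade_probs must be three non-negative probabilities")
        if abs(sum(self.grade_probs) - 1.0) > 1e-12:
            raise ValueError(
                f"grade probabilities must sum to 1 within 1e-12, got {sum(self.grade_probs)!r}"
            )
        if not 0.0 <= self.pr_p_high_given_er_neg <= 1.0:
            raise ValueError("pr_p_high_given_er_neg must be in [0,1]")
        if not 0.0 <= self.pr_p_high_given_er_pos() <= 1.0:
            raise ValueError(
                "PR/ER coupling is inconsistent with the PR marginal: implied "
                f"P(PR+|ER+)={self.pr_p_high_given_er_pos():.4f} outside [0,1]"
            )

    def pr_p_high_given_er_pos(self) -> float:
        p_er = self.er.p_high
        return (self.pr.p_high - self.pr_p_high_given_er_neg * (1.0 - p_er)) / p_er


# -- texture model -----------------------------------------------------------

@dataclass(frozen=True)
class ImageTexture:
    """Latent texture parameters of one image type (LE or RC).

    In-ROI pixel values follow a sinh-arcsinh (SAS) intensity distribution
    with location ``xi``, scale ``omega``, skewness parameter ``eps`` and
    tail-weight parameter ``delta``; each is an affine/log-affine function of
    a standard-normal lesion latent (see :mod:`cesm_radiomics.synthetic`).
    Defaults put intensities comfortably inside a 16-bit range.
    """

    xi0: float
    s_xi: float
    omega0: float
    s_omega: float
    s_eps: float
    s_logdelta: float
    bg_mean: float
    bg_sd: float

    def validate(self) -> None:
        if self.omega0 <= 0:
            raise ValueError("omega0 must be positive")
        if self.bg_sd < 0 or self.s_omega < 0 or self.s_eps < 0 or self.s_logdelta < 0:
            raise ValueError("texture spreads must be non-negative")


def _default_le_texture() -> ImageTexture:
    return ImageTexture(xi0=30000.0, s_xi=1500.0, omega0=4000.0, s_omega=0.25,
                        s_eps=0.35, s_logdelta=0.18, bg_mean=15000.0, bg_sd=2000.0)


def _default_rc_texture() -> ImageTexture:
    # Recombined (subtraction) image: near-zero background, enhancing ROI.
    return ImageTexture(xi0=12000.0, s_xi=800.0, omega0=2500.0, s_omega=0.25,
                        s_eps=0.35, s_logdelta=0.18, bg_mean=300.0, bg_sd=60.0)


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for a synthetic CESM cohort.

    ``effect_map`` lists planted feature-label associations as
    ``(label, feature, target_effect)`` triples, where ``label`` is one of
    ``er_pct``, ``pr_pct``, ``ki67_pct``, ``her2``, ``grade`` and ``feature``
    one of the 14 extracted feature names (e.g. ``RC_VC``).  For continuous
    labels the target is a Pearson correlation in (-1, 1); for ``her2`` and
    ``grade`` (G3 vs G1/G2) it is a standardized mean difference.
    """

    n_lesions: int = 68
    seed: int = 0
    image_size: int = 64
    roi_radius_px: int = 15
    label_model: LabelModel = field(default_factory=LabelModel)
    effect_map: tuple[tuple[str, str, float], ...] = ()
    noise_sd: float = 300.0
    le: ImageTexture = field(default_factory=_default_le_texture)
    rc: ImageTexture = field(default_factory=_default_rc_texture)
    bit_depth: int = 16

    def validate(self) -> None:
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be a positive integer")
        if self.image_size < 4:
            raise ValueError("image_size too small")
        if self.roi_radius_px < 2:
            raise ValueError("roi_radius_px must be at least 2")
        if self.roi_radius_px > (self.image_size - 1) / 2:
            raise ValueError(
                f"roi_radius_px={self.roi_radius_px} does not fit inside a "
                f"{self.image_size}x{self.image_size} frame"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        self.label_model.validate()
        self.le.validate()
        self.rc.validate()
        for triple in self.effect_map:
            if len(triple) != 3:
                raise ValueError(f"effect_map entries must be (label, feature, effect): {triple!r}")

    @property
    def pixel_value_range(self) -> tuple[int, int]:
        return (0, 2 ** self.bit_depth - 1)


# -- feature extraction ------------------------------------------------------

@dataclass(frozen=True)
class FeatureConfig:
    """Conventions for the seven first-order features.

    moments
        ``"population"`` (divide central moments by n) or ``"sample"``
        (variance with n-1); the population convention is the default.
    kurtosis
        ``"raw"`` (m4/sigma^4, normal = 3) or ``"excess"`` (subtract 3).
    n_bins
        equal-width histogram bins for entropy, spanning the ROI's own
        [min, max].
    entropy_log_base
        2 for bits (default) or ``"e"`` for nats.
    vc_epsilon_rel
        |mean| below ``vc_epsilon_rel * representable range`` flags the
        variation coefficient as undefined (subtraction images can have a
        near-zero mean).
    smoothness_norm
        ``"range"`` rescales intensities by the representable range of the
        image (bit depth) before the 1 - 1/(1+sigma^2) transform;
        ``"roi"`` uses the ROI's own min-max span.
    """

    n_bins: int = 256
    moments: str = "population"
    kurtosis: str = "raw"
    entropy_log_base: float | str = 2
    vc_epsilon_rel: float = 1e-9
    smoothness_norm: str = "range"

    def validate(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if self.moments not in ("population", "sample"):
            raise ValueError("moments must be 'population' or 'sample'")
        if self.kurtosis not in ("raw", "excess"):
            raise ValueError("kurtosis must be 'raw' or 'excess'")
        if self.smoothness_norm not in ("range", "roi"):
            raise ValueError("smoothness_norm must be 'range' or 'roi'")


@dataclass(frozen=True)
class PipelineConfig:
    """One document that drives the whole generate/extract/test/classify run."""

    output_dir: str = "cesm_run"
    manifest: str | None = None            # load an existing cohort ...
    synthetic: CohortConfig | None = None  # ... or generate one
    features: FeatureConfig = field(default_factory=FeatureConfig)
    bonferroni_family: str = "per_outcome"  # or "global"
    mannwhitney_mode: str = "auto"          # "auto" | "exact" | "normal"
    ridge: float | None = None              # None -> 1e-6 * trace/p default
    standardize: bool = False
    write_images: bool = True
    image_format: str = "png"               # "png" | "dicom"

    def validate(self) -> None:
        if (self.manifest is None) == (self.synthetic is None):
            raise ValueError("exactly one of 'manifest' or 'synthetic' must be set")
        if self.bonferroni_family not in ("per_outcome", "global"):
            raise ValueError("bonferroni_family must be 'per_outcome' or 'global'")
        if self.mannwhitney_mode not in ("auto", "exact", "normal"):
            raise ValueError("mannwhitney_mode must be auto/exact/normal")
        if self.image_format not in ("png", "dicom"):
            raise ValueError("image_format must be 'png' or 'dicom'")
        self.features.validate()
        if self.synthetic is not None:
            self.synthetic.validate()


# -- (de)serialization -------------------------------------------------------

def config_to_dict(cfg: Any) -> Any:
    """Recursively convert a config dataclass to plain JSON/YAML-able types."""
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        return {f.name: config_to_dict(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)}
    if isinstance(cfg, (list, tuple)):
        return [config_to_dict(v) for v in cfg]
    return cfg


def _cohort_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "label_model" in d and isinstance(d["label_model"], dict):
        lm = dict(d["label_model"])
        for key in ("er", "pr", "ki67"):
            if key in lm and isinstance(lm[key], dict):
                lm[key] = PercentMixture(**lm[key])
        if "grade_probs" in lm:
            lm["grade_probs"] = tuple(lm["grade_probs"])
        d["label_model"] = LabelModel(**lm)
    for key in ("le", "rc"):
        if key in d and isinstance(d[key], dict):
            d[key] = ImageTexture(**d[key])
    if "effect_map" in d:
        d["effect_map"] = tuple(tuple(t) for t in d["effect_map"])
    return CohortConfig(**d)


def pipeline_config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    if d.get("synthetic") is not None:
        d["synthetic"] = _cohort_from_dict(d["synthetic"])
    if d.get("features") is not None and isinstance(d["features"], dict):
        d["features"] = FeatureConfig(**d["features"])
    return PipelineConfig(**d)


def load_pipeline_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return pipeline_config_from_dict(doc)
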