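"""Synthetic CESM cohort generator with plantable feature-label structure.

The study population this emulates is a set of malignant breast lesions,
each with a paired low-energy (LE) and recombined (RC) view, a shared
circular ROI mask, and an immunohistochemistry table (ER%, PR%, Ki67%,
HER2 status, grade G1-G3).  No anatomy is simulated: lesions are
statistical phantoms whose in-ROI gray-level distribution is controlled
through four latent texture parameters per image,

* location  ``xi``     -> Mean
* scale     ``omega``  -> VC, Max-Min, RelativeSmoothness
* skewness  ``eps``    -> Skewness
* tail weight ``delta`` -> Kurtosis, Entropy

In-ROI pixels are a random spatial arrangement of a *stratified* sample of
the sinh-arcsinh (SAS) intensity distribution: the N mask pixels receive
the N standardized SAS quantiles at probabilities (i+0.5)/N, scaled to
``xi + omega * t`` and optionally perturbed by i.i.d. Gaussian pixel noise
of sd ``noise_sd``.  Stratification makes the ROI's sample moments
deterministic functions of the texture parameters (with ``noise_sd = 0``
and no saturated pixels the in-ROI population variance equals
``omega**2`` exactly), so planted effects pass through feature extraction
with very little dilution.  Pixels falling outside the representable
range clip to it, as a saturating detector would.

Effects are planted by mixing a lesion's standardized label value into the
latent that drives the requested feature: ``m = c*u + sqrt(1-c^2)*e`` with
``e ~ N(0,1)``, which yields a population feature-label correlation of
approximately ``c`` times the feature's calibrated latent response (stored
in :mod:`cesm_radiomics.calibration`).  Background pixels are independent
of the labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

from .calibration import ATTENUATION
from .cohort_io import ImagePair, LesionRecord, write_cohort
from .config import CohortConfig, LabelModel, config_to_dict
from .features import FEATURE_NAMES

__all__ = [
    "EffectInfeasibleError",
    "TextureParams",
    "generate_cohort",
    "generate_cohort_files",
    "render_lesion_pair",
    "roi_mask",
    "build_effect_plan",
    "sample_record",
    "label_standardizer",
    "sas_standard_quantiles",
    "CONTINUOUS_LABELS",
    "BINARY_LABELS",
    "DRIVER_OF_FEATURE",
]

CONTINUOUS_LABELS = ("er_pct", "pr_pct", "ki67_pct")
BINARY_LABELS = ("her2", "grade")  # grade enters effects as the G3 indicator

#: latent driver index per feature family (0=location, 1=scale, 2=skew, 3=tail)
DRIVER_OF_FEATURE = {
    "Mean": 0,
    "VC": 1,
    "Max-Min": 1,
    "RelativeSmoothness": 1,
    "Skewness": 2,
    "Entropy": 3,
    "Kurtosis": 3,
}

_GRADES = ("G1", "G2", "G3")


class EffectInfeasibleError(ValueError):
    """Requested effect map cannot be realized by the texture model."""


@dataclass(frozen=True)
class TextureParams:
    """Realized SAS texture parameters of one image of one lesion."""

    xi: float
    omega: float
    eps: float
    delta: float

    @property
    def model_variance(self) -> float:
        """In-ROI population pixel variance at noise_sd = 0 (exact)."""
        return self.omega ** 2


# -- geometry ---------------------------------------------------------------

def roi_mask(image_size: int, roi_radius_px: float) -> np.ndarray:
    """Filled-disc mask centered in the frame; must fit fully inside."""
    if roi_radius_px > (image_size - 1) / 2:
        raise ValueError(
            f"roi_radius_px={roi_radius_px} does not fit inside a "
            f"{image_size}x{image_size} frame"
        )
    c = (image_size - 1) / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= roi_radius_px ** 2


# -- intensity distribution -------------------------------------------------

def sas_standard_quantiles(n: int, eps: float, delta: float) -> np.ndarray:
    """Standardized stratified quantiles of the sinh-arcsinh distribution.

    Returns the n values ``q_i = sinh((asinh(z_i) + eps)/delta)`` at
    probabilities ``(i+0.5)/n``, centered and scaled to population mean 0
    and variance 1 over the n points.  ``eps`` controls asymmetry, ``delta``
    the tail weight (``delta < 1`` -> heavier tails, higher kurtosis).
    """
    if n < 2:
        raise ValueError("need at least 2 quantiles")
    if delta <= 0:
        raise ValueError("delta must be positive")
    u = (np.arange(n) + 0.5) / n
    z = ndtri(u)
    q = np.sinh((np.arcsinh(z) + eps) / delta)
    q -= q.mean()
    sd = math.sqrt(float(np.mean(q * q)))
    return q / sd


# -- labels -----------------------------------------------------------------

def sample_record(index: int, label_model: LabelModel, rng: np.random.Generator) -> LesionRecord:
    """Draw one lesion's histology labels (one lesion per synthetic patient)."""
    lm = label_model
    er_high = rng.random() < lm.er.p_high
    er = lm.er.sample(rng, high=er_high)
    p_pr = lm.pr_p_high_given_er_pos() if er_high else lm.pr_p_high_given_er_neg
    pr = lm.pr.sample(rng, high=rng.random() < p_pr)
    ki67 = lm.ki67.sample(rng)
    her2 = "+" if rng.random() < lm.her2_p else "-"
    grade = _GRADES[int(rng.choice(3, p=np.asarray(lm.grade_probs) / sum(lm.grade_probs)))]
    return LesionRecord(
        lesion_id=f"L{index:04d}", patient_id=f"P{index:04d}",
        er_pct=float(er), pr_pct=float(pr), ki67_pct=float(ki67),
        her2=her2, grade=grade,
    )


def label_standardizer(label_model: LabelModel):
    """Return a function mapping a record to standardized label values.

    Continuous labels are centered/scaled by the closed-form moments of
    their configured marginal mixture; HER2 and grade become standardized
    indicators (grade: G3 vs G1/G2).
    """
    lm = label_model
    stats = {name: (mix.mean(), math.sqrt(mix.var()))
             for name, mix in (("er_pct", lm.er), ("pr_pct", lm.pr), ("ki67_pct", lm.ki67))}
    p_her2 = lm.her2_p
    p_g3 = lm.grade_probs[2]

    def standardize(record: LesionRecord) -> dict[str, float]:
        u = {name: (getattr(record, name) - m) / s for name, (m, s) in stats.items()}
        b = 1.0 if record.her2 == "+" else 0.0
        u["her2"] = (b - p_her2) / math.sqrt(p_her2 * (1.0 - p_her2))
        g = 1.0 if record.grade == "G3" else 0.0
        u["grade"] = (g - p_g3) / math.sqrt(p_g3 * (1.0 - p_g3))
        return u

    return standardize


# -- effect planting --------------------------------------------------------

def build_effect_plan(config: CohortConfig) -> dict[tuple[str, int], tuple[tuple[str, float], ...]]:
    """Convert the effect map into latent-space mixing coefficients.

    Raises :class:`EffectInfeasibleError`, naming the offending triples,
    when a requested effect exceeds what the calibrated texture response
    can deliver or when several effects jointly overload one latent
    channel (sum of squared mixing coefficients >= 1).
    """
    lm = config.label_model
    prevalence = {"her2": lm.her2_p, "grade": lm.grade_probs[2]}
    plan: dict[tuple[str, int], list[tuple[str, float]]] = {}
    triples_by_key: dict[tuple[str, int], list[tuple]] = {}

    for triple in config.effect_map:
        label, feature, effect = triple
        if label not in CONTINUOUS_LABELS + BINARY_LABELS:
            raise EffectInfeasibleError(f"unknown label in effect triple {triple!r}")
        if feature not in FEATURE_NAMES:
            raise EffectInfeasibleError(f"unknown feature in effect triple {triple!r}")
        img, base = feature.split("_", 1)
        a = ATTENUATION[feature]
        if label in CONTINUOUS_LABELS:
            if not -1.0 < effect < 1.0:
                raise EffectInfeasibleError(
                    f"correlation target must lie in (-1, 1): {triple!r}"
                )
            c = effect / a
        else:
            p = prevalence[label]
            t = effect * math.sqrt(p * (1.0 - p))
            c = (t / math.sqrt(1.0 + t * t)) / a
        if not abs(c) < 1.0:
            raise EffectInfeasibleError(
                f"effect triple {triple!r} is infeasible: it requires a latent "
                f"mixing coefficient of {c:.3f} (|c| must be < 1; the calibrated "
                f"response of {feature} is {a:.3f})"
            )
        key = (img, DRIVER_OF_FEATURE[base])
        if any(lbl == label for lbl, _ in plan.get(key, [])):
            raise EffectInfeasibleError(
                f"effect triple {triple!r} duplicates label {label!r} on the "
                f"latent channel shared by "
                f"{[b for b, d in DRIVER_OF_FEATURE.items() if d == key[1]]} of {img}"
            )
        plan.setdefault(key, []).append((label, c))
        triples_by_key.setdefault(key, []).append(triple)

    for key, entries in plan.items():
        c2 = sum(c * c for _, c in entries)
        if c2 >= 1.0:
            raise EffectInfeasibleError(
                f"jointly infeasible effects on latent channel {key}: "
                f"{triples_by_key[key]!r} imply a non-positive-semi-definite "
                f"correlation structure (sum of squared coefficients = {c2:.3f} >= 1)"
            )
    return {k: tuple(v) for k, v in plan.items()}


# -- rendering --------------------------------------------------------------

def _lesion_texture(record: LesionRecord, config: CohortConfig,
                    rng: np.random.Generator, plan, standardize):
    """Draw the latent texture parameters for both images of one lesion."""
    u = standardize(record)
    params: dict[str, TextureParams] = {}
    latents = np.empty((2, 4))
    for k, img in enumerate(("LE", "RC")):
        tex = config.le if img == "LE" else config.rc
        m = np.empty(4)
        for d in range(4):
            e = rng.standard_normal()
            entries = plan.get((img, d), ())
            c2 = sum(c * c for _, c in entries)
            m[d] = sum(c * u[lbl] for lbl, c in entries) + math.sqrt(max(0.0, 1.0 - c2)) * e
        params[img] = TextureParams(
            xi=tex.xi0 + tex.s_xi * m[0],
            omega=tex.omega0 * math.exp(tex.s_omega * m[1]),
            eps=tex.s_eps * m[2],
            delta=math.exp(-tex.s_logdelta * m[3]),
        )
        latents[k] = m
    return params, latents


def _render_image(params: TextureParams, tex, mask: np.ndarray,
                  noise_sd: float, value_range: tuple[float, float],
                  rng: np.random.Generator) -> np.ndarray:
    img = tex.bg_mean + tex.bg_sd * rng.standard_normal(mask.shape)
    n = int(np.count_nonzero(mask))
    t = sas_standard_quantiles(n, params.eps, params.delta)
    vals = params.xi + params.omega * t[rng.permutation(n)]
    if noise_sd > 0:
        vals = vals + noise_sd * rng.standard_normal(n)
    img[mask] = vals
    # detector saturation: rare tail pixels clip to the representable range
    np.clip(img, value_range[0], value_range[1], out=img)
    return img


def _render_pair(record, config, rng, plan, standardize, mask):
    params, latents = _lesion_texture(record, config, rng, plan, standardize)
    vmin, vmax = (float(v) for v in config.pixel_value_range)
    le = _render_image(params["LE"], config.le, mask, config.noise_sd, (vmin, vmax), rng)
    rc = _render_image(params["RC"], config.rc, mask, config.noise_sd, (vmin, vmax), rng)
    pair = ImagePair(lesion_id=record.lesion_id, le=le, rc=rc, mask=mask.copy(),
                     bit_depth=config.bit_depth,
                     pixel_value_range=(vmin, vmax))
    return pair, params, latents


def render_lesion_pair(record: LesionRecord, config: CohortConfig,
                       rng: np.random.Generator, return_params: bool = False):
    """Render one lesion's LE/RC images and mask from its labels.

    ``rng`` is the lesion's private random stream; two calls with
    identically seeded generators produce identical arrays.  With
    ``return_params=True`` the realized :class:`TextureParams` per image
    are returned as well (useful for model-vs-sample checks).
    """
    config.validate()
    plan = build_effect_plan(config)
    standardize = label_standardizer(config.label_model)
    mask = roi_mask(config.image_size, config.roi_radius_px)
    pair, params, _ = _render_pair(record, config, rng, plan, standardize, mask)
    if return_params:
        return pair, params
    return pair


# -- cohort-level API -------------------------------------------------------

def _generate(config: CohortConfig, collect_latents: bool = False):
    config.validate()
    plan = build_effect_plan(config)
    standardize = label_standardizer(config.label_model)
    mask = roi_mask(config.image_size, config.roi_radius_px)

    children = np.random.SeedSequence(config.seed).spawn(config.n_lesions)
    records: list[LesionRecord] = []
    pairs: list[ImagePair] = []
    latents = np.empty((config.n_lesions, 2, 4)) if collect_latents else None
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        rec = sample_record(i, config.label_model, rng)
        pair, _, m = _render_pair(rec, config, rng, plan, standardize, mask)
        records.append(rec)
        pairs.append(pair)
        if collect_latents:
            latents[i] = m
    return records, pairs, latents


def generate_cohort(config: CohortConfig) -> tuple[list[LesionRecord], list[ImagePair]]:
    """Generate a full synthetic cohort: aligned label records and image pairs.

    Deterministic: identical ``config`` (including seed) regenerates a
    byte-identical cohort.  Each lesion draws from its own child stream of
    the root seed, so the cohort is stable under reordering.
    """
    records, pairs, _ = _generate(config)
    return records, pairs


def generate_cohort_files(config: CohortConfig, out_dir,
                          image_format: str = "png"):
    """Generate a cohort and write it to disk; returns the manifest path."""
    records, pairs = generate_cohort(config)
    provenance = {
        "source": "cesm_radiomics.synthetic",
        "bit_depth": config.bit_depth,
        "rng": "numpy Generator (PCG64), per-lesion SeedSequence children",
        "config": config_to_dict(config),
    }
    return write_cohort(records, pairs, out_dir, image_format=image_format,
                        provenance=provenance)
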