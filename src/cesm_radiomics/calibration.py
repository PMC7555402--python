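"""Stored feature-response calibration constants for the synthetic cohort.

Planted feature-label effects are injected on latent texture parameters
(location, scale, skewness, tail weight), not on the extracted features
themselves, because the feature maps are nonlinear.  The entries below are
the measured Pearson correlations between each extracted feature and its
driving latent under the default cohort configuration ("attenuations");
:func:`cesm_radiomics.synthetic.build_effect_plan` divides requested
feature-space effects by them to obtain latent-space mixing coefficients.

Regenerate with ``python scripts/calibrate.py`` after changing the texture
model or its default parameters.  Values are specific to the default
``CohortConfig`` texture/noise settings; other settings make planted
effects approximate.
"""

# measured at n = 60000 null lesions, seed 123, default CohortConfig (see scripts/calibrate.py)
ATTENUATION: dict[str, float] = {
    "LE_Mean": 1.0,
    "LE_VC": 0.9637,
    "LE_Max-Min": 0.9224,
    "LE_Skewness": 0.9268,
    "LE_Entropy": -0.9257,
    "LE_RelativeSmoothness": 0.9392,
    "LE_Kurtosis": 0.7908,
    "RC_Mean": 0.9999,
    "RC_VC": 0.9493,
    "RC_Max-Min": 0.9175,
    "RC_Skewness": 0.9277,
    "RC_Entropy": -0.8832,
    "RC_RelativeSmoothness": 0.9415,
    "RC_Kurtosis": 0.7885,
}

CALIBRATION_META: dict = {"n_lesions": 60000, "seed": 123}
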