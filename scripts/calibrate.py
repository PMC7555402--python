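"""Regenerate the texture-response calibration constants.

Measures, on a large null cohort under the default configuration, the
Pearson correlation between each extracted first-order feature and the
lesion latent that drives its texture-parameter family.  The constants are
written into ``src/cesm_radiomics/calibration.py`` and used to convert
requested feature-label effects into latent mixing coefficients.

Usage:  python scripts/calibrate.py [--n 60000] [--seed 123]
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np

from cesm_radiomics.config import CohortConfig
from cesm_radiomics.features import FEATURE_NAMES, extract_cohort_features, features_to_frame
from cesm_radiomics.synthetic import DRIVER_OF_FEATURE, _generate

HEADER = '''"""Stored feature-response calibration constants for the synthetic cohort.

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
'''


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=60000)
    ap.add_argument("--seed", type=int, default=123)
    args = ap.parse_args()

    cfg = CohortConfig(n_lesions=args.n, seed=args.seed)
    records, pairs, latents = _generate(cfg, collect_latents=True)
    feats = features_to_frame(extract_cohort_features(pairs))

    attenuation: dict[str, float] = {}
    for name in FEATURE_NAMES:
        img, base = name.split("_", 1)
        k = 0 if img == "LE" else 1
        d = DRIVER_OF_FEATURE[base]
        m = latents[:, k, d]
        f = feats[name].to_numpy()
        keep = ~np.isnan(f)
        r = float(np.corrcoef(m[keep], f[keep])[0, 1])
        attenuation[name] = round(r, 4)
        print(f"{name:26s} driver={d}  response r = {r:+.4f}  (n={keep.sum()})")

    out = Path(__file__).resolve().parents[1] / "src" / "cesm_radiomics" / "calibration.py"
    with open(out, "w") as fh:
        fh.write(HEADER)
        fh.write(f"\n# measured at n = {args.n} null lesions, seed {args.seed}, "
                 "default CohortConfig (see scripts/calibrate.py)\n")
        fh.write("ATTENUATION: dict[str, float] = {\n")
        for name in FEATURE_NAMES:
            fh.write(f'    "{name}": {attenuation[name]},\n')
        fh.write("}\n\n")
        fh.write(f'CALIBRATION_META: dict = {{"n_lesions": {args.n}, "seed": {args.seed}}}\n')
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
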