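"""Operating characteristics of the epistasis machinery.

Measures, on freshly generated panels: the type-I error of the bootstrap
epistasis test under pure additivity, its power against magnitude damping
(joint truth at 60% of the additive sum), and the masking classifier's
detection rate. Panel counts match the package's acceptance checks.
"""

import pathlib

import pandas as pd

from thermopanel.simulation import (
    damping_power,
    masking_detection,
    null_calibration,
)

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    calib = null_calibration(n_panels=1000, seed=0)
    power = damping_power(n_panels=200, seed=0)
    mask = masking_detection(n_panels=200, seed=0)
    df = pd.DataFrame(
        [
            {"study": "null_calibration", "n_panels": calib.n_panels,
             "rate": calib.rate, "nominal": 0.05},
            {"study": "damping_power", "n_panels": power.n_panels,
             "rate": power.rate, "nominal": None},
            {"study": "masking_detection", "n_panels": mask.n_panels,
             "rate": mask.rate, "nominal": None},
        ]
    )
    df.to_csv(OUT / "operating_characteristics.csv", index=False)
    print(f"Type-I error at alpha 0.05 (1000 additive panels): {calib.rate:.3f}")
    print(f"Power vs 60%-of-additive damping (200 panels): {power.rate:.3f}")
    print(f"Masking detection at noise=effect/4 (200 panels): {mask.rate:.3f}")


if __name__ == "__main__":
    main()
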