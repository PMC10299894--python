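#!/usr/bin/env python
"""Contact-angle extraction from synthetic sessile-droplet density maps.

Generates cylindrical circular-cap density fields of several sizes with a
known macroscopic angle and a 1/R finite-size bias, runs the interface ->
circle-fit -> angle pipeline on each, and extrapolates cos(theta) against
1/R to the infinite-droplet limit.

Writes results/droplet_angles.csv and results/droplet_extrapolation.csv.
"""

import pandas as pd

from monowet import analyze_droplet, extrapolate_macroscopic
from monowet.io import write_report
from monowet.synth import make_droplet_series

THETA_INF = 113.0  # deg, the nonpolar-substrate benchmark
RADII = (5.0, 8.0, 11.0, 15.0, 20.0)
BIAS_NM = 0.3
SEED = 2026


def main() -> None:
    series, truth = make_droplet_series(
        THETA_INF, RADII, bias_nm=BIAS_NM, noise_sd=0.5, seed=SEED
    )
    rows, estimates = [], []
    for (field, drop_truth), R in zip(series, RADII):
        est = analyze_droplet(field)
        estimates.append(est)
        rows.append(
            {
                "R_nominal_nm": R,
                "R_fit_nm": est.R,
                "theta_true_deg": drop_truth["theta_true_deg"],
                "theta_est_deg": est.theta,
                "n_interface_points": est.n_points,
            }
        )
    per_droplet = pd.DataFrame(rows)
    write_report(per_droplet, "results/droplet_angles.csv")

    res = extrapolate_macroscopic(estimates)
    write_report(
        {
            "theta_macroscopic_deg": res.theta,
            "bias_slope_nm": res.slope,
            "intercept_cos_theta": res.intercept,
            "n_droplets": res.n,
            "theta_true_deg": THETA_INF,
        },
        "results/droplet_extrapolation.csv",
    )

    worst = (per_droplet["theta_est_deg"] - per_droplet["theta_true_deg"]).abs().max()
    print(
        f"Sessile-droplet pipeline on {len(RADII)} synthetic caps "
        f"(R = {RADII[0]:g}-{RADII[-1]:g} nm, noise, seed {SEED}):\n"
        f"  per-droplet angles recovered within {worst:.2f} deg of truth\n"
        f"  1/R extrapolation: theta_macroscopic = {res.theta:.2f} deg vs "
        f"true {THETA_INF:.0f} deg (injected bias slope {BIAS_NM} nm, "
        f"fitted {res.slope:.3f} nm)"
    )


if __name__ == "__main__":
    main()
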