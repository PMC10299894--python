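#!/usr/bin/env python
"""Work of adhesion from synthetic pressure-distance curves.

Generates a Lennard-Jones-like 9-3 pressure-distance curve scaled so its
closed-form work of adhesion equals the bilayer leaflet-separation value
(49 mN/m), integrates it by the trapezoid rule with an analytic power-law
tail, and tabulates the refinement convergence of the integration error.

Writes results/adhesion_convergence.csv.
"""

import pandas as pd

from monowet import work_of_adhesion
from monowet.io import write_report
from monowet.synth import make_pd_curve

# 9-3 amplitude chosen so the exact work 0.1 * 3*eps*sigma/8 is 49 mN/m
EPS_BAR = 49.0 * 8.0 / (3.0 * 0.1)
SIGMA_NM = 1.0


def main() -> None:
    rows = []
    for n_points in (100, 200, 400, 800, 1600):
        curve, truth = make_pd_curve(
            "9-3", eps=EPS_BAR, sigma=SIGMA_NM, n_points=n_points
        )
        w = work_of_adhesion(curve, tail="power")
        exact = truth["analytic_work_mN_per_m"]
        rows.append(
            {
                "n_points": n_points,
                "work_mN_per_m": w,
                "exact_mN_per_m": exact,
                "rel_error": abs(w - exact) / exact,
            }
        )
    conv = pd.DataFrame(rows)
    write_report(conv, "results/adhesion_convergence.csv")

    w200 = conv.loc[conv["n_points"] == 200, "work_mN_per_m"].iloc[0]
    print(
        "Pressure-distance integration (9-3 curve scaled to the 49 mN/m "
        "leaflet-separation work):\n"
        f"  trapezoid + power-law tail at 200 points: {w200:.2f} mN/m "
        f"({conv['rel_error'].iloc[1]:.2%} error)\n"
        "  error falls ~4x per grid doubling (second-order trapezoid):\n"
        + conv.to_string(index=False, float_format=lambda v: f"{v:.6g}")
    )


if __name__ == "__main__":
    main()
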