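"""Transition-probability pipeline on synthetic trial data.

Demonstrates the full chain used to derive transition probabilities
from published survival figures: simulate trial-structured censored
data, publish it as noisy Kaplan-Meier step coordinates with a risk
table, reconstruct pseudo individual-patient data, fit the five
parametric families, select by AIC/BIC and check Cox-Snell residuals.
Writes the fit-selection report and the reconstruction fidelity table.
"""

import pathlib

import numpy as np
import pandas as pd

from smacea import km_estimator, reconstruct_ipd, select_best, coxsnell_residuals
from smacea.survival import fit_all_families, selection_report
from smacea.synthetic import endear_like, publish_km, simulate_trial

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "survival"
SEED = 20
NOISE = 0.005  # digitisation noise on survival coordinates


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scenario = endear_like(seed=SEED)
    data = simulate_trial(scenario)

    fidelity_rows, report_frames = [], []
    for arm, (times, events) in data.items():
        landmarks = np.arange(0, scenario.followup_months + 1, 3.0)
        curve, risk = publish_km(times, events, landmarks,
                                 noise=NOISE, seed=SEED)
        rtimes, revents = reconstruct_ipd(curve, risk)
        km_orig = km_estimator(times, events)
        km_rec = km_estimator(rtimes, revents)

        def surv_at(km, t):
            idx = np.searchsorted(km.times, t, side="right") - 1
            return km.survival[max(idx, 0)]

        for t in landmarks:
            fidelity_rows.append({
                "arm": arm, "time": t,
                "original": surv_at(km_orig, t),
                "reconstructed": surv_at(km_rec, t),
                "abs_error": abs(surv_at(km_orig, t) - surv_at(km_rec, t)),
            })

        fits, failures = fit_all_families(rtimes, revents)
        rep = selection_report(fits)
        rep.insert(0, "arm", arm)
        report_frames.append(rep)
        best = select_best(fits)
        r, d = coxsnell_residuals(best, rtimes, revents)
        km_res = km_estimator(np.maximum(r, 1e-9), d)
        cumhaz = -np.log(np.maximum(km_res.survival, 1e-12))
        slope = np.polyfit(km_res.times, cumhaz, 1)[0]
        print(f"{arm}: n={len(rtimes)}, best family {best.family}, "
              f"Cox-Snell cumulative-hazard slope {slope:.3f} (ideal 1)")

    fid = pd.DataFrame(fidelity_rows)
    fid.to_csv(OUT / "reconstruction_fidelity.csv", index=False)
    pd.concat(report_frames).to_csv(OUT / "fit_selection.csv", index=False)
    print(f"max |S_rec - S_orig| at landmarks: {fid['abs_error'].max():.4f} "
          "(reconstruction tolerance 0.02)")
    print(f"Tables written to {OUT}")


if __name__ == "__main__":
    main()
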