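#!/usr/bin/env python
"""Survival probability and hydrogen-bond kinetics of the exchange system.

Runs the exchange generator (particles dwelling in a coordination
sphere for exponential residence times), measures the strict survival
probability P(τ) with its KWW fit — which should return the planted
mean residence time — and computes continuous vs intermittent
bond-indicator correlation functions from the ground-truth occupancy,
showing the re-entry gap between the two lifetimes.
"""

import json
from pathlib import Path

import pandas as pd

from polymelt.kinetics import hbond_correlations, survival_probability
from polymelt.synth import ExchangeSpec, generate_exchange_trajectory

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    spec = ExchangeSpec(n_particles=200, sphere_radius=0.5, mean_residence=50.0,
                        dt=1.0, n_frames=3000, seed=31)
    traj, topo, indicator = generate_exchange_trajectory(spec)

    curve = survival_probability(
        traj.positions[:, :1], traj.positions[:, 1:], traj.boxes,
        spec.sphere_radius, traj.dt_frame, max_lag_frames=250,
    )
    hb = hbond_correlations(indicator, dt=spec.dt, max_lag_frames=400)

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame({"tau_ps": curve.tau, "P": curve.P}).to_csv(
        RESULTS / "survival.tsv", sep="\t", index=False)
    pd.DataFrame({"lag_ps": hb.continuous.lag,
                  "C_continuous": hb.continuous.value,
                  "C_intermittent": hb.intermittent.value}).to_csv(
        RESULTS / "hbond_correlations.tsv", sep="\t", index=False)

    fits = {"planted_mean_residence_ps": spec.mean_residence,
            "survival_tau_mean_ps": curve.fit.tau_mean,
            "survival_beta": curve.fit.beta,
            "n_origins": curve.n_origins}
    if hb.fit_continuous is not None:
        fits["hb_tau_continuous_ps"] = hb.fit_continuous.tau_mean
        fits["hb_beta_continuous"] = hb.fit_continuous.beta
    if hb.fit_intermittent is not None:
        fits["hb_tau_intermittent_ps"] = hb.fit_intermittent.tau_mean
        fits["hb_beta_intermittent"] = hb.fit_intermittent.beta
        fits["hb_plateau_intermittent"] = hb.fit_intermittent.plateau
    with open(RESULTS / "kinetics_fits.json", "w") as fh:
        json.dump(fits, fh, indent=1)

    print(f"survival ⟨τ_sp⟩ = {curve.fit.tau_mean:.1f} ps "
          f"(planted {spec.mean_residence}), β = {curve.fit.beta:.2f}")
    if hb.fit_continuous is not None and hb.fit_intermittent is not None:
        print(f"HB lifetimes: continuous ⟨τ⟩ = {hb.fit_continuous.tau_mean:.1f} ps "
              f"(≈ planted residence), intermittent decay "
              f"τ = {hb.fit_intermittent.tau:.1f} ps toward plateau "
              f"{hb.fit_intermittent.plateau:.3f}")
    print("the intermittent curve sits above the continuous one at every lag; "
          "for this two-state process it relaxes with the telegraph time "
          "1/(1/τ_in + 1/τ_out) = 25 ps toward the equilibrium occupancy")


if __name__ == "__main__":
    main()
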