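"""Non-compartmental PK metrics per compartment and dosing interval.

AUC by the linear-up/log-down trapezoid, Cmax/Tmax as the observed peak,
terminal half-life from log-linear regression after Tmax, and tissue
penetration as AUC_tissue/AUC_plasma.
"""

from dataclasses import replace

from deadspacepk import (apply_blq_rule, build_profile, catheter_recovery,
                         compute_nca, default_params_calibrated,
                         penetration_ratio, simulate_subject)

params = replace(default_params_calibrated(), noise_cv=0.0)
pig, _ = simulate_subject(params, "pig01")

results = {}
profs = {"plasma": build_profile(pig.plasma, anchor_at_zero=True)}
for comp in ("deadspace", "bone"):
    est = catheter_recovery(pig.dialysates_for(comp), pig.catheter(comp))
    profs[comp] = build_profile(apply_blq_rule(pig.dialysates_for(comp)), est,
                                anchor_at_zero=True)
for comp, prof in profs.items():
    for r in compute_nca(prof, pig.doses):
        results[(comp, r.interval_index)] = r
        print(f"{comp:>9} interval {r.interval_index}: AUC {r.auc:6.0f} min·µg/mL  "
              f"Cmax {r.cmax:5.1f} µg/mL at {r.tmax:3.0f} min  "
              f"T½ {r.t_half:5.0f} min ({r.n_lambda_points} pts)")

pen_ds = penetration_ratio(results[('deadspace', 1)].auc, results[('plasma', 1)].auc)
pen_bn = penetration_ratio(results[('bone', 1)].auc, results[('plasma', 1)].auc)
print(f"\nfirst-interval penetration: deadspace {pen_ds:.2f}, bone {pen_bn:.2f}")
print("deadspace exposure exceeds plasma (drug retained in the haematoma) "
      "while bone sees ~3/4 of the plasma exposure.")
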