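"""PD target attainment: fT>MIC and time-to-threshold, plus a MIC sweep.

Cefuroxime kills time-dependently, so the driving index is the time the
free concentration stays above the MIC (4 µg/mL, the S. aureus ECOFF).
"""

from deadspacepk import simulate_cohort
from deadspacepk.pipeline import analyze_study, mic_sweep

study, _ = simulate_cohort(n_per_group=2, seed=21)
res = analyze_study(study)
pdf = res["pd"]

print("cohort-mean fT>MIC (min of each 480-min interval):")
for comp in ("plasma", "deadspace", "bone"):
    sub = pdf[pdf.compartment == comp]
    m1 = sub[sub.interval == 1].t_above_mic.mean()
    m2 = sub[sub.interval == 2].t_above_mic.mean()
    tt = sub[sub.interval == 2].tt_threshold.mean()
    print(f"  {comp:>9}: {m1:5.0f} + {m2:5.0f} = {m1 + m2:5.0f} min total "
          f"(interval-2 onset {tt:4.1f} min)")
print("the deadspace stays above target far longer than plasma or bone.\n")

sweep = mic_sweep(study, [1.0, 4.0, 16.0])
ds = sweep[(sweep.compartment == "deadspace") & (sweep.interval == 1)]
print("deadspace interval-1 fT>MIC vs MIC (per-subject mean):")
for mic, grp in ds.groupby("mic"):
    print(f"  MIC {mic:4.0f} µg/mL -> {grp.t_above_mic.mean():5.0f} min")
print("attainment falls as the assumed MIC rises - the efficacy claim "
      "depends on the pathogen's susceptibility.")
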