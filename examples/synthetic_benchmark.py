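"""Full synthetic benchmarking run: simulate, align, compare.

Generates a reference pelvic patient plus 11 observers and a biased
auto-segmenter surrogate, scrambles every exported set's coordinate frame,
recovers the frames from the skin fiducials, and prints the CTV comparison
table (one row per observer, mean/SD footer).
"""

from contourbench import align_structure_set, compare_sets, make_cohort, metrics_table

cohort = make_cohort(n_observers=11, seed=7)

# every non-reference set was "exported" through a random translation and/or
# axis inversion; realign via the four fiducials before any comparison
aligned_auto, fit = align_structure_set(cohort.autoseg, cohort.reference.fiducials)
print(f"auto-segmenter frame recovered: signs={fit.transform.signs}, "
      f"offsets=({', '.join(f'{o:.2f}' for o in fit.transform.offsets)}) cm, "
      f"residual {fit.residual_rms:.2e} cm")

records = []
for obs in cohort.observers:
    aligned, _ = align_structure_set(obs, cohort.reference.fiducials)
    records.extend(compare_sets(aligned, aligned_auto, ["CTV"]))

print("\nCTV: observers vs auto-segmenter")
print(metrics_table(records).to_string(index=False))
print(
    "\ndV_pct > 0 everywhere: the auto-segmenter's CTV is systematically small"
    " (atlas volume bias), so every observer volume exceeds it by ~100%."
    "\ndz_inf_cm < 0: observers extend the prostatic apex a few slices more"
    " inferiorly than the automatic contour."
)
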