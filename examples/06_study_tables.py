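"""Reproduce the blocking study's summary statistics from its printed tables.

The regional percent V_T change is the relative difference of the group
means; the SIME-vs-Lassen comparison reports per-subject relative
differences, their mean +/- population SD, and a paired t-test.
"""

from petblock import reference_change_table, reference_sime_comparison

tab = reference_change_table()
print("regional percent V_T change (computed vs printed):")
for _, r in tab[tab["model"] == "2tcm"].head(5).iterrows():
    print(f"  {r['region']:<15} {r['pct_change']:6.2f}% -> {r['pct_change_display']:>3d}% "
          f"(printed {r['pct_change_printed']}%)")
agree = (tab["pct_change_display"] == tab["pct_change_printed"]).sum()
print(f"  {agree}/{len(tab)} cells match the printed integers exactly\n")

comp = reference_sime_comparison()
print(f"SIME V_ND: {comp['sime_mean']:.2f} +/- {comp['sime_sd']:.2f} mL/cm3 (population SD)")
print(f"Lassen 2TCM V_ND mean: {comp['lassen_mean']:.2f} mL/cm3")
print(f"SIME vs Lassen: {comp['rel_dif_mean_pct']:.1f}% +/- {comp['rel_dif_sd_pct']:.1f}%")
print(f"paired t({comp['df']}) = {comp['t']:.2f}, p = {comp['p']:.3f}")
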