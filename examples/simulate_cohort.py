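"""Generate a synthetic study cohort and inspect its age-correlation structure.

Draws 113 specimens (ages truncated-normal, 46.64 +/- 16.33 yr, 12-84) and the
33 bone-matrix parameters with their configured Pearson correlations against
age, then screens every parameter the way the analysis pipeline does.
"""

from ribchron import build_parameter_table, screen

table = build_parameter_table(seed=17)
print(f"cohort: {len(table)} specimens, ages {table.age.min():.0f}-{table.age.max():.0f} yr, "
      f"mean {table.age.mean():.1f}")

report = screen(table)
top = report.reindex(report.pearson_r.abs().sort_values(ascending=False).index)
print("\nstrongest age correlations (r, p):")
for name, row in top.head(6).iterrows():
    print(f"  {name:10s} r = {row.pearson_r:+.2f}  p = {row.pearson_p:.1e}")

# Porosity should dominate (configured r = 0.83), followed by interstitial
# microhardness (0.55): the same ordering the screening stage is built to find.
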