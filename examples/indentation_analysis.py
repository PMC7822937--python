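"""Reduce a nanoindentation load-depth curve with the Oliver-Pharr method.

Renders a physically consistent 10 mN load/hold/unload curve for tissue with
known modulus, hardness, creep and work ratio, then recovers those four
parameters from the curve alone — the same reduction applied to every
instrument-exported curve in the pipeline.
"""

from ribchron.indentation import analyze_indentation, vickers_hv
from ribchron.synthetic import render_indentation_curve

curve = render_indentation_curve(E_GPa=20.0, H_MPa=650.0, C_pct=4.0, eta_pct=32.0)
res = analyze_indentation(curve)

print("generating values:  E_IT = 20.0 GPa, H_IT = 650 MPa, C_IT = 4.0 %, eta_IT = 32.0 %")
print(f"recovered:          E_IT = {res.E_IT_GPa:.2f} GPa, H_IT = {res.H_IT_MPa:.0f} MPa "
      f"({res.H_IT_vickers:.1f} Vickers-equivalent), C_IT = {res.C_IT_pct:.2f} %, "
      f"eta_IT = {res.eta_IT_pct:.2f} %")
print(f"contact stiffness S = {res.stiffness_mN_nm * 1e3:.1f} uN/nm at h_max = {res.h_max_nm:.0f} nm")

# Vickers microhardness from an optically measured indent diagonal:
print(f"\nVickers: 10 gf, 18.5 um diagonal -> HV = {vickers_hv(10.0, 18.5):.1f} kg/mm^2")
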