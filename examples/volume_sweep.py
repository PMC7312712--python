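"""Calibrate the frustum model and sweep the hamate hook angle.

Calibrates the outlet-radius constant B from the reference measurement
(r1 = 8.29 mm at a 98-degree hook angle), then tabulates outlet radius
and tunnel volume every 2 degrees from 98 to 140 degrees."""

import carpalcone as cc

calibration = cc.calibrate_b(r1_0=8.29, alpha0_deg=98.0, cos_decimals=3)
print(f"Calibrated B = {calibration.B} mm^2  "
      f"(from r1_0={calibration.r1_0} mm at alpha0={calibration.alpha0_deg} deg)")

table = cc.generate_volume_table(calibration=calibration)
print(f"\n{'alpha (deg)':>11}  {'r1 (mm)':>9}  {'volume (mm^3)':>13}")
for row in table:
    print(f"{row.alpha_deg:11.0f}  {row.r1:9.4f}  {row.volume:13.3f}")

v0, v1 = table[0].volume, table[-1].volume
print(f"\nOpening the hook angle from 98 to 140 degrees widens the tunnel "
      f"outlet from {table[0].r1:.2f} to {table[-1].r1:.2f} mm and grows the "
      f"modelled volume by {100 * (v1 - v0) / v0:.1f}% "
      f"({v0:.0f} -> {v1:.0f} mm^3).")
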