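"""Classify hematoma expansion between baseline and follow-up scans.

Shows the 6 cc AND 33% conjunction rule on plain volume pairs, then runs
it end to end on a simulated serial phantom pair.
"""

import hemovol as hv

print("conjunction rule on volume pairs (needs >= 6 cc AND >= 33%):")
for baseline, followup in [(10.0, 16.5), (100.0, 107.0), (3.0, 5.0), (20.0, 18.0)]:
    c = hv.compare_serial(baseline, followup)
    print(
        f"  {baseline:6.1f} -> {followup:6.1f} cc: "
        f"abs {c.abs_diff_cc:+6.1f} cc, rel {c.pct_diff:+7.1f}%  "
        f"=> {'HE POSITIVE' if c.he_positive else 'negative'}"
    )

# A 10 cc bleed that grows to 18 cc between scans (both criteria cleared):
spec = hv.PhantomSpec(
    lesions=(
        hv.Lesion(
            center_mm=hv.default_lesion_center(hv.PhantomSpec()),
            semi_axes_mm=hv.sphere_semi_axes(10.0),
        ),
    ),
    falx_plate=True,
    sinus_blob=True,
)
pair = hv.generate_serial_pair(spec, followup_volume_cc=18.0, seed=13)
det_b = hv.detect_ich(pair.baseline[0]).total_volume_cc
det_f = hv.detect_ich(pair.followup[0]).total_volume_cc
call = hv.compare_serial(det_b, det_f)
print("\nserial phantom pair, detected volumes:")
print(f"  baseline {det_b:.2f} cc, follow-up {det_f:.2f} cc "
      f"(truth 10.00 -> 18.00 cc)")
print(f"  pipeline call: {'HE POSITIVE' if call.he_positive else 'negative'}; "
      f"truth label: {'HE POSITIVE' if pair.truth.he_positive else 'negative'}")
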