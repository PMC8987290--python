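"""Generate a synthetic abdominal case and inspect its anatomy.

The phantom emulates the duodenum-pancreas interface: a hollow C-shaped
duodenal tube (sections D1-D4, 2-3 mm wall) wrapping the head-of-pancreas
target, a stomach abutting D1 at the pylorus, and a bowel bag inferior to
the target.  Every run with the same seed is bit-identical.
"""

from spacersim import phantom

case = phantom.generate_phantom(seed=1)
case.validate()

print("structure volumes (cc):")
for name in ("GTV", "GTV_multabc", "PTV", "HOP", "duodenum", "D1", "D2", "D3",
             "D4", "stomach", "bowel"):
    print(f"  {name:12s} {case.volume_cc(name):6.1f}")

wall = phantom.wall_thickness_stats(case)
print(f"duodenal wall thickness (median): {wall['median_mm']:.1f} mm "
      "(distance-transform estimate; generated in the 2-3 mm band)")
print(f"target-duodenum gap drawn for this case: "
      f"{case.meta['anatomy']['gap_mm']:.1f} mm")

placed = phantom.place_virtual_spacer(case, phantom.SpacerScenario("S2"))
print("placed S2 spacer pockets (ml per interface section):")
for group, vol in placed.meta["spacer_volume_ml"].items():
    print(f"  {group:5s} {vol:.1f}  (< 10 ml by protocol)")
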