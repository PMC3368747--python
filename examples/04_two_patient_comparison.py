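"""Compare two synthetic 'patients' with normalised, frame-aligned metrics.

Patient 1 carries a single moderate patellofemoral hotspot; patient 2 a
larger, hotter one with a secondary lobe, scanned in a rotated pose. After
normalisation the comparison is quantitative despite different poses and
(if gains differed) different raw count scales.
"""

import orthospect as osp

scenario = osp.two_patient_scenario(seed=7)
results = {}
for name, ph in scenario.items():
    res = osp.analyze_volumes(ph["ct"], ph["spect"], ph["truth"].landmarks)
    results[name] = res
    m = res["metrics"]
    print(f"{name}: axial realignment {res['realignment']['about_PROX_deg']:.1f} deg, "
          f"{m.voxel_count} voxels above 3x mean, max ratio {m.max_ratio:.2f}, "
          f"mean ratio {m.mean_ratio:.2f}")

report = osp.compare_results(results["P1"], results["P2"], names=("P1", "P2"))
row = report["rows"]["voxel_count"]
print(f"\nP2 hotspot is {row['ratio']:.1f}x the size of P1's at the same "
      f"normalised threshold — the size/intensity ordering a reader of the\n"
      f"unnormalised images (both 'bright') could not establish.")
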