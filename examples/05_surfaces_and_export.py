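"""Extract bone and hotspot surfaces and export a comparable 3D scene.

The bone isosurface comes from the CT at +150 HU, the hotspot boundary from
the SPECT at the clinical (3x reference mean) threshold; both are expressed
in the femoral anatomic frame so exported scenes from different patients
line up.
"""

import tempfile
from pathlib import Path

import orthospect as osp

ph = osp.make_phantom(
    osp.PhantomSpec(hotspots=(osp.Hotspot((0.0, 18.0, 10.0), (12.0, 10.0, 12.0), 4.0),))
)
fem = ph["truth"].femoral_frame

ref = osp.region_stats(
    ph["spect"], osp.ReferenceRegion(((-25, -25, 80), (25, 25, 130)), "femoral"), fem
)
thr = osp.threshold_from_model(
    osp.NormalizationModel("scale_by_mean", ref), {"k_times_mean": 3.0}
)

bone = osp.extract_isosurface(ph["ct"], 150.0, frame=fem, label="bone")
hot = osp.extract_isosurface(ph["spect"], thr, frame=fem, label="hotspot")
print(f"bone surface: {len(bone.vertices)} vertices, area {bone.area_mm2() / 100:.0f} cm^2")
print(f"hotspot surface: {len(hot.vertices)} vertices, "
      f"enclosed volume {hot.enclosed_volume_mm3() / 1000:.2f} mL")

out = Path(tempfile.mkdtemp())
manifest = osp.scene_export(bone, hot, out / "scene.json")
print(f"exported {len(manifest['meshes'])} PLY meshes + manifest to {out}")
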