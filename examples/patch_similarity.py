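"""Five-direction PSNR consensus for one H&E nucleus.

Crops the center/up/down/left/right patches around an H&E nucleus (from the
binary segmentation rendering) and around every candidate DAPI nucleus in
its search region, ranks candidates per direction by PSNR, and reports the
consensus winner.
"""

from nucalign import (
    SceneSpec,
    build_search_region,
    consensus_match,
    generate_scene,
    labels_to_nuclei,
    load_dapi_nuclei,
    segment_he,
)
from nucalign.patches import render_binary_labels, crop_directional_patches

spec = SceneSpec(
    n_nuclei=150, dapi_dims=(300, 450), he_dims=(300, 450), seed=5,
    nucleus_radius_range=(3.0, 6.0), min_center_spacing=20.0,
)
scene = generate_scene(spec)
seg = segment_he(
    scene.he_rgb, "ground_truth", {"label_image": scene.label_image}
)
dapi_nuclei = load_dapi_nuclei(scene.boundary_table)
dapi_by_id = {r.id: r for r in dapi_nuclei}
truth = dict(zip(scene.correspondences.he_label, scene.correspondences.dapi_id))

render = render_binary_labels(seg)
radius, move = 30, 22
for rec in labels_to_nuclei(seg):
    he_patches = crop_directional_patches(render, rec.center, radius, move, 224)
    if he_patches is None:
        continue  # too close to the border for the directional crops
    region = build_search_region(rec.center, 0.5, spec.dapi_dims, dapi_nuclei, 50)
    match = consensus_match(
        he_patches, rec.id, region, scene.dapi, dapi_by_id, radius, move, 224
    )
    print(f"H&E nucleus {rec.id} at ({rec.center[0]:.1f}, {rec.center[1]:.1f})")
    print(f"search region members : {len(region.member_ids)}")
    if match is None:
        print("no consensus across the five directions")
    else:
        print(f"consensus match       : {match.dapi_id} "
              f"(planted counterpart: {truth[rec.id]})")
        for d, v in match.psnr_by_direction.items():
            print(f"  {d:<6} max PSNR = {v:.2f} dB")
    break
# A consensus requires the same DAPI nucleus to top the PSNR ranking in all
# five moving directions; higher PSNR means more similar patches.
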