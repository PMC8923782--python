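"""Rasterize a Labelme-style polygon annotation into a binary mask.

Tongue datasets are typically annotated as polygon contours; this converts
the polygon JSON dialect into the 0/1 label raster the training code
consumes. A pixel becomes tongue when its center lies inside or on the
boundary of any polygon named "tongue".
"""

from spurnet import annotation_to_mask, read_annotation

payload = {
    "shapes": [
        {"label": "tongue", "points": [[3, 2], [12, 2], [14, 9], [8, 13], [2, 9]]},
        {"label": "lip", "points": [[0, 0], [15, 0], [15, 1], [0, 1]]},
    ],
    "imageHeight": 16,
    "imageWidth": 16,
}
ann = read_annotation(payload)
mask = annotation_to_mask(ann, positive_label="tongue")

print(f"categories present: {sorted(ann.category_names)}")
print(f"tongue pixels: {int(mask.labels.sum())} of {mask.labels.size}")
for row in mask.labels:
    print("".join(".#"[v] for v in row))
print("Only polygons named 'tongue' are filled; the 'lip' polygon is ignored,")
print("so multi-class annotation files degrade gracefully to binary masks.")
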