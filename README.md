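# pigparts

Bottom-up instance detection of group-housed pigs from top-down pen
images. Every animal is represented by four back-surface keypoints —
left ear, right ear, shoulder and tail — encoded into a 16-channel
image-space target: four unit-peak Gaussian part heatmaps and twelve
association-vector channels that store, in a disc around each part, the
constant pixel offset to a partner part of the same animal. A decoder
turns any such 16-channel map (ground truth or network output) back into
discrete oriented instances, and an hourglass network learns the mapping
from RGB images to the representation. Because shoulders and tails are
grouped by *learned association vectors* rather than raw proximity, the
method keeps working where nearest-neighbour grouping fails: animals
lying pressed side by side.

Who this is for: researchers in precision livestock monitoring and
computer-vision practitioners who need an instance detector that
survives heavy animal-to-animal contact, plus a fully synthetic test bed
to exercise every stage without collecting footage.

## The method in brief

* **Encoding.** Part *p* of animal *n* becomes a symmetric Gaussian
  kernel with `sigma_n = 0.16 (mu_st + delta_st_n)` (frame-mean plus
  individual shoulder–tail length), scaled to peak 1.0; same-channel
  overlaps take the pointwise maximum. Offsets `p − q` for the pairs
  l↔s, r↔s, s↔t fill the disc where the source kernel exceeds 0.2
  (radius ≈ 1.794 σ); intersecting discs store the kernel-weighted mean.
* **Decoding.** 5×5 box smoothing → 15×15 regional maxima above a
  threshold (default 0.25) → quadratic sub-pixel refinement → sampled
  association distances `d(p_n, q_m) = (|(p→q)_n − q_m| + |(q→p)_m −
  p_n|)/2` → Hungarian assignment per part pair → instances = joined
  shoulder–tail pairs, ears attached afterwards.
* **Matching metric.** A detection counts as a true positive only if it
  and a ground-truth instance are *each other's* minimum of
  `|s_n − s̃_m| + |t_n − t̃_m|` (cross-check / mutual nearest neighbour
  — no distance threshold to tune).
* **Network.** A 41-block SegNet-style hourglass (five pool /
  five index-sharing unpool stages, skip concatenations, ~4.0M
  parameters at default widths) with receptive field 363 px at the
  480-column working scale; training minimizes a selective MSE in which
  association channels receive gradient only where the target is
  assigned. Implemented in NumPy with hand-written backprop.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

```python
import numpy as np
from pigparts import (SceneConfig, generate_scene, encode_frame, decode,
                      cross_check_match, DecoderConfig, AssociationMode)
from pigparts.matching import annotation_to_instances

image, frame = generate_scene(SceneConfig(n_pigs_range=(6, 6), seed=7))
maps = encode_frame(frame)                         # 16-channel target
dets = decode(maps, DecoderConfig(detection_threshold=0.25))
rep = cross_check_match(annotation_to_instances(frame), dets.instances)
print(f"instances: {len(dets)}  tp={rep.tp} fp={rep.fp} fn={rep.fn} "
      f"precision={rep.precision:.3f} recall={rep.recall:.3f}")
for inst in dets.instances[:2]:
    print(f"  shoulder=({inst.shoulder.x:.2f},{inst.shoulder.y:.2f}) "
          f"tail=({inst.tail.x:.2f},{inst.tail.y:.2f}) conf={inst.confidence:.2f}")
```

prints

```
instances: 6  tp=6 fp=0 fn=0 precision=1.000 recall=1.000
  shoulder=(186.05,31.23) tail=(176.83,6.89) conf=0.99
  shoulder=(292.58,57.83) tail=(269.89,21.97) conf=0.99
```

six synthetic animals, all recovered exactly from their own encoding
(sub-pixel coordinates; confidence is the minimum part-peak value after
box smoothing).
Switching to `AssociationMode.EUCLIDEAN` on the abutting fixtures makes
the grouping cross-pair neighbouring animals — the ablation the vector
representation exists to win.

## Command line

```bash
pigparts simulate --out-dir data --n-frames 10 --seed 5   # PNG + JSON scenes
pigparts encode   --annotation data/frame_0000.json --out maps.npz
pigparts decode   --maps maps.npz --out dets.json --threshold 0.25
pigparts train    --data-dir data --out model.npz --epochs 10
pigparts decode   --model model.npz --image data/frame_0000.png --out dets.json
pigparts evaluate --annotations data --detections dets_dir
```

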