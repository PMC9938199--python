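# exuscan

Pixel-wise detection of hard exudates (bright, sharp-margin lipid
deposits) in retinal fundus images, using semicircular radial
intensity-profile analysis.

For every pixel, eight non-overlapping angular sectors (π/4 each) cast
several rays over a radial search range `[r0, r1]`. A ray is
*non-constant* when some consecutive-sample intensity difference is a
drop strictly larger than `Th1`; a sector with more than `Th2`
non-constant rays is an *entrance* sector; a pixel is positive when at
least `Th3` consecutive entrance sectors surround it. Because each ray
finds its drop at its own distance, lesions of irregular shape are
detected without shape priors, vessel segmentation, or contrast
enhancement. An edge-based optic-disc localizer (quarter-sector ring
candidacy + brightest-ray selection) suppresses the main source of
false positives.

The package also ships:

- a seeded synthetic fundus-scene generator (smooth background, dark
  curvilinear vessels, star-convex/elliptic/disc lesions with exact
  ground-truth masks, bright optic disc) used by the entire test suite,
- the patch-based IoU evaluation protocol (square patches; a
  ground-truth patch counts as detected when in-patch IoU > 0.8),
- a CLI tying everything together.

## CLI

```sh
# generate a synthetic scene with ground truth
exuscan simulate --seed 1 --out-dir scene --height 256 --width 256

# detect lesions (defaults: Th1=0.015 Th2=2 Th3=3 r0=4 r1=25, green channel)
exuscan detect scene/image.png --out mask.png --record run.json

# with optic-disc removal and a custom threshold
exuscan detect scene/image.png --remove-od --th1 0.02 --out mask.png

# localize the optic disc only
exuscan locate-od scene/image.png --od-radius 20 --out od.json

# patch-IoU evaluation of a prediction against ground truth
exuscan evaluate scene/he_mask.png mask.png --patch-size 32 --iou-threshold 0.8
```

Options may also come from a flat YAML config file
(`exuscan detect img.png --config params.yaml`), with precedence
flags > file > defaults:

```yaml
th1: 0.015
th2: 2
th3: 3
r0: 4
r1: 25
od_radius: 20
patch_size: 32
```

## Package layout

| module                | purpose                                                     |
| --------------------- | ----------------------------------------------------------- |
| `exuscan.image_io`    | image loading, channel extraction, normalization, masks     |
| `exuscan.geometry`    | sectors, ray directions, radial sampling                    |
| `exuscan.detector`    | the pixel-wise classifier (`detect`, `classify_pixel`)      |
| `exuscan.optic_disc`  | optic-disc localization and exclusion masks                 |
| `exuscan.synthetic`   | seeded scene generator with ground truth                    |
| `exuscan.evaluation`  | patch-IoU scoring (`evaluate`, `patchify`, `patch_iou`)     |
| `exuscan.cli`         | `exuscan` command-line entry point                          |
| `exuscan.config`      | defaults, YAML config files, flag precedence                |
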