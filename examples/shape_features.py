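"""Skeleton metrology of a single synthetic worm against its ground truth.

Renders one hermaphrodite with a known midline and taper profile, then
measures the four shape parameters (length, thickness, tail diameter
ratios r1/r2) from the raster alone and compares them to the truth.
"""

from nemasex import synth
from nemasex.morphometry import extract_features
from nemasex.segmentation import WormRegion

mask, truth = synth.make_worm(synth.default_specs()["hermaphrodite"], rng_seed=7)
region = WormRegion(
    mask=mask,
    bbox=(0, 0, *mask.shape),
    area_px=int(mask.sum()),
    touches_border=False,
    um_per_pixel=6.5,
)
feats = extract_features(region)

d20, d120 = truth.d_probe_um["A"]
print(f"truth length     : {truth.length_um:8.1f} um")
print(f"measured length  : {feats.length_um:8.1f} um "
      f"({100 * (feats.length_um / truth.length_um - 1):+.1f}%)")
print(f"measured thickness: {feats.thickness_um:7.1f} um")
print(f"taper targets    : D(20)={d20:.1f} um, D(120)={d120:.1f} um "
      f"(ratio {d20 / d120:.2f})")
print(f"measured ratios  : r1={feats.r1:.2f}, r2={feats.r2:.2f}")
print()
print("Length agrees with the generator midline to a few percent; the tail")
print("ratios are quantization-limited (the 20-um probe sits ~2 px from the")
print("tip) but preserve the tapered-vs-blunt ordering used to sex animals.")
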