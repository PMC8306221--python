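"""Extract the 275-feature texture panel from two synthetic phantoms.

Builds one endometrioma-like phantom (homogeneous mid-level "ground
glass" speckle) and one hemorrhagic-cyst-like phantom (near-anechoic
content crossed by bright strands), extracts the full panel from each,
and prints the features that separate the two appearances: contrast-type
co-occurrence statistics are higher in the heterogeneous HOC phantom,
while the 10th intensity percentile is higher in the EN phantom.
"""

from echotex import extract_all, simulate_lesion_image

en_img, en_mask = simulate_lesion_image("EN", seed=1)
hoc_img, hoc_mask = simulate_lesion_image("HOC", seed=1)

en = extract_all(en_img, en_mask)
hoc = extract_all(hoc_img, hoc_mask)

print(f"panel size: {len(en)} features")
print(f"{'feature':>16}  {'EN':>10}  {'HOC':>10}")
for name in ("Perc10", "Mean", "CN5D6DifVarnc", "CN4D6Contrast", "RZD6Fraction", "ATeta1"):
    print(f"{name:>16}  {en[name]:>10.3f}  {hoc[name]:>10.3f}")
print(
    "\nPerc10 (the grey level below which 10% of ROI pixels lie) is high for"
    "\nthe ground-glass EN phantom and near zero for the dark HOC phantom;"
    "\nthe difference-of-variance and contrast features show the opposite"
    "\nordering because the HOC content is locally heterogeneous."
)
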