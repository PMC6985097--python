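"""Pearson co-localization between two marker channels at varying co-expression.

Simulates double-labeled fields (GFAP + ALDH1L1) where the underlying cell
populations co-express the two markers to different degrees, then computes
the Pearson correlation between the two channels under both pixel-selection
policies: the whole unexcluded frame, and the union of the two segmentation
masks.  A PCC near 1 means the same cells carry both stains; near 0,
independent populations; below 0, mutually exclusive populations.
"""

from astroquant import ImageSimSpec, colocalize, generate_micrograph, threshold_with_qc

print(f"{'target':>7} {'labels':>7} {'whole-frame':>12} {'union-of-masks':>15}")
for target in (-0.5, 0.0, 0.3, 0.9):
    spec = ImageSimSpec(
        width_px=320,
        height_px=320,
        n_cells=40,
        mean_cell_area_px=600,
        cell_area_dispersion=150,
        marker_positive_fractions={"GFAP": 0.5, "ALDH1L1": 0.5},
        coexpression_pcc_target=target,
        noise_sd=0.02,
        seed=11,
    )
    micrograph, truth = generate_micrograph(spec)
    a = micrograph.channels["GFAP"]
    b = micrograph.channels["ALDH1L1"]
    whole = colocalize(a, b, names=("GFAP", "ALDH1L1"))
    union = colocalize(
        a, b, policy="union",
        masks=(threshold_with_qc(a).mask, threshold_with_qc(b).mask),
        names=("GFAP", "ALDH1L1"),
    )
    print(
        f"{target:+7.1f} {truth.realized_label_pcc:+7.3f} "
        f"{whole.pcc:+12.3f} {union.pcc:+15.3f}"
    )
print()
print("Whole-frame PCC is lifted toward positive values by background the two")
print("channels share (ambient level times the same illumination ramp), while")
print("the union-of-masks policy excludes that background and sits lower,")
print("since pixels lit in only one channel anti-correlate.  Both policies")
print("preserve the rank order of the underlying cell-level co-expression;")
print("comparisons across conditions must therefore hold the policy fixed.")
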