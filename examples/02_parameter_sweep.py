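"""Delivery asymmetry across the explored parameter ranges.

Sweeps the capture rate kon and the actin length scale beta for the
adjacent-pair-plus-distant-bud placement, plus the Smoluchowski estimate
of kon from cable geometry.  Asymmetry rises with kon, peaks at the
intermediate beta where adjacent cable networks begin to overlap, and
vanishes when cables span the whole cell.
"""

from multibud import CableGeometry, build_grid, smoluchowski_kon, sweep_delivery_cv

geom = CableGeometry(Lc=3.0, Rv=0.05, Rc=0.05, n_cables=4)
kon_est = smoluchowski_kon(geom, Dv=0.02)
print(f"Smoluchowski estimate: kon = {kon_est:.2e} 1/s (order 1e-3)")

grid = build_grid(10.0, 6.0, (10.5, 6.6, 6.6), (32, 20, 20))
table = sweep_delivery_cv(
    grid,
    "adjacent2_distant1",
    kon_values=[1e-3, 1e-2, 1e-1],
    Dv_values=[0.01],
    beta_values=[0.5, 1.0, 3.0, 10.0],
)

print("\ndelivery CV (rows: kon, columns: beta in um):")
pivot = table.pivot_table(index="kon", columns="beta", values="delivery_cv")
print(pivot.round(4).to_string())
print()
print("Low kon (few cables): depletion is negligible and all placements are")
print("equivalent. High kon with beta ~ the inter-bud spacing: the adjacent")
print("pair competes and the CV approaches the experimentally observed ~0.1-0.2.")
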