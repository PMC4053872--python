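"""Detect a planted space-time cluster with the discrete-Poisson scan.

A rate-homogeneous panel gets a multiplier-3 cluster injected into three
neighbouring districts over 2008-2012; the scan should recover exactly that
window as the most likely cluster with the minimum attainable p-value.
"""

import greyscan as gs

panel = gs.generate_panel(gs.null_config(seed=7), with_points=False)
panel = gs.inject_cluster(panel, {"D01", "D02", "D06"}, range(2008, 2013), 3.0, seed=7)

results = gs.detect_clusters(
    panel.records, panel.district_info,
    gs.ScanParams(n_replicates=999, seed=7),
)

top = results[0]
print("most likely cluster:")
print(f"  districts: {', '.join(top.districts)}")
print(f"  years:     {top.cylinder.year_start}-{top.cylinder.year_end}")
print(f"  observed {top.observed:.0f} vs expected {top.expected:.1f} admissions")
print(f"  LLR = {top.llr:.1f}, relative risk = {top.relative_risk:.2f}, "
      f"p = {top.p_value:.3f}")
print("\nRR near 3 matches the injected multiplier; p = 0.001 is the smallest")
print("value 999 Monte-Carlo replicates can produce (rank 1 of 1000).")
for r in results[1:]:
    print(f"secondary: {r.districts} {r.cylinder.year_start}-{r.cylinder.year_end} "
          f"RR={r.relative_risk:.2f} p={r.p_value:.3f}")
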