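"""ETDRS-grid topographic summaries of a quantified eye.

Sectorizes en-face maps into the fovea-centered ETDRS subfields (central
1 mm, parafoveal 1-3 mm ring, perifoveal 3-6 mm ring; quadrants along the
+-45 degree diagonals) and prints per-ring thickness, absolute and
relative loss, plus SDD volumes per merged quadrant.
"""

from octbands import EtdrsGrid, generate_cohort, quantify, summarize_subfields
from octbands.etdrs import subfield_areas_mm2
from octbands.phantom import PhantomSpec

print("Nominal ring areas (mm^2):", subfield_areas_mm2())

cohort = generate_cohort(PhantomSpec(seed=5, n_patients=1, prob_both_eyes=0.0))
surfaces = cohort.eyes[0].acquisitions["high_res"]
q = quantify(surfaces)
grid = EtdrsGrid(fovea_center=surfaces.fovea_center,
                 laterality=surfaces.geometry.laterality)
report = summarize_subfields(q, grid)

rings = ["center", "parafoveal_ring", "perifoveal_ring"]
print("\nRPE loss per ring (absolute mm^2 and % of the nominal ring area):")
rows = report.query("band == 'RPE' and subfield in @rings")
for ring in rings:
    a = rows.query("subfield == @ring and metric == 'abs_loss_mm2'").value.iloc[0]
    r = rows.query("subfield == @ring and metric == 'rel_loss_pct'").value.iloc[0]
    print(f"  {ring:16s} {a:6.3f} mm^2  ({r:5.1f} %)")

print("\nSDD volume per merged parafoveal+perifoveal quadrant (nL):")
for quad in ("superior", "nasal", "inferior", "temporal"):
    v = report.query(
        "subfield == @quad and metric == 'sdd_volume_nl'").value.iloc[0]
    print(f"  {quad:9s} {v:6.2f}")
center = report.query(
    "subfield == 'center' and metric == 'sdd_volume_nl'").value.iloc[0]
print(f"  center    {center:6.2f}")
print("\nDeposits spare the central 1 mm by construction; the superior "
      "weighting of their placement emerges at cohort level (single eyes "
      "vary).")
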