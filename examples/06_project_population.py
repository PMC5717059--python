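"""Project habitat-specific densities onto the packaged Sumatran landscape
table: subpopulations, breeding females, SSP status, island change."""

from denstandard import datasets, project

cover = datasets.forest_cover_2000_2012()
subpops = datasets.subpopulations()

# Habitat densities back-derived from the published tables (least squares),
# structurally a lowland-hill baseline with peat/montane and degradation
# multipliers.
dens = project.derive_habitat_densities(
    cover, subpops["adults_2012"].to_numpy(), relative_se=0.47
)
print("habitat densities per 100 km²:")
for k, v in dens.densities.items():
    print(f"  {k:24s} {v:.3f}")

proj12 = project.project_population(cover, dens, epoch="2012")
print(proj12.round(1).to_string(index=False))

body = proj12.iloc[:-1]
priority = body.iloc[:datasets.N_PRIORITY]
print(f"priority-landscape total 2012: {priority['adults'].sum():.0f} adults")

leuser = body[body.landscape == "Gunung Leuser"].iloc[0]
# nearby_bf: breeding females in connected forests (here, the adjacent
# landscape complex jointly holding >= 25)
print(f"Gunung Leuser: {leuser.adults:.0f} adults, "
      f"{leuser.breeding_females} breeding females, "
      f"SSP: {project.classify_ssp(leuser.breeding_females, 20911, 25)}")

island = project.island_loss_pct(
    cover.frame["total_2012_thousand_km2"], cover.frame["deforestation_12yr_pct"]
)
print(f"island-wide forest loss 2000-2012: {island:.1f}%")
print(f"population decline 2000-2012: "
      f"{project.percent_change(subpops.adults_2000.sum(), subpops.adults_2012.sum()):.1f}%")
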