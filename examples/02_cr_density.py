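"""The traditional non-spatial CR pipeline: M0 abundance over the grid,
half-MMDM buffer, convex-hull effective area, density quotient."""

import denstandard as ds
from denstandard import simulate as sim

traps = ds.place_traps(8, 8, 1.5)
x0, y0, x1, y1 = traps.extent()
config = sim.SurveyConfig(
    region=sim.Rectangle(x0 - 10, y0 - 10, x1 + 10, y1 + 10),
    true_density=2.0, g0=0.05, sigma_km=2.5, n_occasions=90, seed=1,
)
_, history = sim.simulate_survey(config, traps)

nhat = ds.estimate_abundance_m0(history)
buffer_km = ds.half_mmdm(history)
area = ds.effective_area(traps, buffer_km)
record = ds.cr_density(nhat, area)

print(f"M_t+1 = {nhat.m_t1} caught, N-hat = {nhat.n_hat:.1f} ± {nhat.se_n:.1f} "
      f"(per-occasion p = {nhat.p_hat:.3f})")
print(f"half-MMDM buffer = {buffer_km:.2f} km, "
      f"effective area = {area.area_km2:.0f} km²")
print(f"CR density = {record.density:.2f} ± {record.se_density:.2f} per 100 km² "
      f"(truth: {config.true_density})")
# With 90 occasions nearly every exposed animal is caught, so N-hat sits at
# M_t+1 with ~zero variance; the overshoot against the simulated truth comes
# entirely from the half-MMDM buffer truncating real ranging distances and
# shrinking the effective area.
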