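"""Dimensionless-group sanity checks for the default device.

Prints the channel Knudsen number (continuum validity of the airflow), the
particle Reynolds and Stokes numbers for the largest particles (creeping-flow
validity of Stokes drag), and the volumetric flow rates of the benchmark
channel cross-sections.
"""

import lungchip as lc

air = lc.air_properties()
geom = lc.ChannelGeometry()

kn = lc.knudsen_number(air, geom.h_air)
print(f"Knudsen number (h = {geom.h_air*1e6:.0f} um): {kn:.2e}"
      f"  -> continuum + no-slip {'valid' if kn < 0.01 else 'NOT valid'}")

for dp in (10e-9, 900e-9):
    rep = lc.validate_regime(air, lc.ParticleProperties(dp, 1180.0), 1e-3, geom)
    print(f"dp = {dp*1e9:4.0f} nm: Re_p = {rep.re_particle:.2e}, "
          f"tau = {rep.relaxation_time:.2e} s, Stk = {rep.stokes_number:.2e}"
          f"  ({'ok' if rep.ok else '; '.join(rep.warnings)})")

print("\nFlow-rate bookkeeping (2 mm wide channels):")
for u, h in ((0.03e-3, 100e-6), (0.1e-3, 100e-6), (0.3e-3, 300e-6)):
    q = lc.flow_rate(u, 2000e-6, h)
    print(f"  u = {u*1e3:5.2f} mm/s, h = {h*1e6:3.0f} um  ->  Q = {q:5.2f} uL/min")

# Re_p << 1 and Kn << 0.01 confirm the laminar, continuum, Stokes-drag regime
# the transport model assumes; the flow rates are what a syringe pump must
# deliver to realize the simulated velocities.
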