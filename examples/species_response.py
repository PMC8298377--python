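"""Biological cascade after a damage stimulus, at a single material point.

Fixed damage values split the collagen density into damaged and intact
pools; MMP rises in response to the damaged pool, degrades it, and the
delayed growth-factor response deposits new collagen.  Prints the peak
species concentrations and the final collagen density for each damage
level — rising peaks and final mass with damage distinguish normal from
pathological (hypertrophic) healing.
"""

from tissueheal.experiments import run_species_study
from tissueheal.params import DAY

series = run_species_study(d_values=(0.0, 0.1, 0.4, 0.7, 1.0), dt=0.5 * DAY)

print(f"{'d':>4} {'peak M (kg/m^3)':>16} {'peak G (kg/m^3)':>16} "
      f"{'final rho_c':>12} {'change':>8}")
for d, df in series.items():
    final = df["rho_c"].iloc[-1]
    print(f"{d:4.1f} {df['M'].max():16.3e} {df['G'].max():16.3e} "
          f"{final:12.1f} {100 * (final / 840.0 - 1):+7.1f}%")

print("\nWith zero damage every trajectory is exactly constant (homeostasis);"
      "\nfor d = 0.1 the collagen mass returns close to its initial value"
      "\n(normal healing), while larger damage overshoots it (pathological).")
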