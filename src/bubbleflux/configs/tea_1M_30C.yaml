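# 1 M aqueous triethanolamine at 30 °C, 101.3 kPa.
# Gas constants are pure-water values; the amine enters only through the
# bulk CO2 saturation ratio. Initial state: air-saturated, CO2-free.
name: tea_1M_30C
medium:
  density: 1018.2            # kg m-3
  dynamic_viscosity: 1.2659e-3   # Pa s
  surface_tension: 62.8e-3   # N m-1
  temperature: 303.15        # K
column:
  fill_height: 0.152         # m of liquid above the sparger
  ambient_pressure: 1.013e+5 # Pa
gases:
  CO2: {henry_constant: 3.46e-4, diffusivity: 1.14e-9, molar_mass: 44.01e-3}
  O2:  {henry_constant: 1.2e-5,  diffusivity: 2.2e-9,  molar_mass: 31.998e-3}
  N2:  {henry_constant: 6.4e-6,  diffusivity: 2.0e-9,  molar_mass: 28.014e-3}
dissolved:
  CO2: 0.0
  O2: 1.0
  N2: 1.0
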