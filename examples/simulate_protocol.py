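"""Simulate the standard favorable/stress/favorable light protocol.

A leaf is exposed to strong blue actinic light (758 µmol·m⁻²·s⁻¹) for an
hour at the cultivation temperature.  The undamaged fraction of linear
electron transport (Aj) erodes irreversibly; chloroplast CO2 and net
assimilation adjust quasi-instantaneously at every step.
"""

from photofvcb import run_protocol, standard_protocol

protocol = standard_protocol(par=758.0)
tc = run_protocol(protocol)
df = tc.to_dataframe()

print(df.iloc[::60][["time_s", "Aj", "Cc_ppm", "Ahv", "limitation"]].to_string(index=False))
print(f"\nfinal Aj after {protocol.total_duration/60:.0f} min: {tc.final_Aj:.4f}")
print("Aj is the remaining fraction of electron-transport capacity: the "
      "closer to 1, the less photodamage the protocol inflicted.")
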